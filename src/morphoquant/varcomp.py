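"""Quantitative-genetic summaries derived from animal-model fits.

From the genotype-free REML fit (the "full additive-variance" model)
come the total additive genetic variance V_A = V_animal, heritability
h^2 = V_animal / (V_animal + V_tank + V_ID) (measurement error is
deliberately excluded from the denominator), evolvability
I_A = V_A / ybar^2 (mean-standardised additive variance), and percent
repeatability R = V_ID / (V_ID + V_error) * 100. From the genotype-
including fit come the allele-substitution effects beta and their
standard errors, yielding each locus' percent contribution to V_A:

    %V_A.locus = 100 * 2 * p_L * p_E * (beta^2 - se(beta)^2) / V_animal

truncated at zero (the se^2 subtraction corrects the upward bias of
beta^2 as an estimator of the squared effect). Uncertainty intervals
come from a large-sample parametric simulator: 10,000 draws of the
variance components (Gaussian at the REML estimates, covariance from
the inverse observed information, truncated at zero) and of the fixed
effects, with the 250th and 9750th order statistics as the 95% CI and
the median reported as the point summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .animal import MixedModelFit
from .pedigree import allele_frequencies

__all__ = [
    "heritability",
    "repeatability_pct",
    "locus_va_contribution",
    "evolvability",
    "posterior_ci",
    "draw_components",
    "VarianceDecomposition",
    "decompose",
]


def heritability(V_animal: float, V_tank: float, V_ID: float) -> float:
    """h^2 = V_animal / (V_animal + V_tank + V_ID); error excluded."""
    for v in (V_animal, V_tank, V_ID):
        if v < 0:
            raise ValueError("variance components must be non-negative")
    denom = V_animal + V_tank + V_ID
    if denom <= 0:
        raise ValueError("zero denominator in heritability")
    return V_animal / denom


def repeatability_pct(V_ID: float, V_error: float) -> float:
    """R = V_ID / (V_ID + V_error) * 100, in percent."""
    if V_ID < 0 or V_error < 0:
        raise ValueError("variance components must be non-negative")
    denom = V_ID + V_error
    if denom <= 0:
        raise ValueError("zero denominator in repeatability")
    return 100.0 * V_ID / denom


def locus_va_contribution(
    beta: float, se_beta: float, freq_L: float, freq_E: float, V_animal: float
) -> float:
    """Percent of V_A explained by one biallelic locus: 100*2pq(b^2-se^2)/V_A.

    Negative estimates (when se^2 exceeds beta^2) are truncated to zero.
    """
    if not (0 <= freq_L <= 1 and 0 <= freq_E <= 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if abs(freq_L + freq_E - 1.0) > 1e-9:
        raise ValueError("allele frequencies must sum to 1")
    if V_animal <= 0:
        raise ValueError("V_animal must be positive")
    pct = 100.0 * 2.0 * freq_L * freq_E * (beta**2 - se_beta**2) / V_animal
    return max(pct, 0.0)


def evolvability(V_A: float, trait_mean: float) -> float:
    """I_A = V_A / ybar^2; unitless, invariant to trait rescaling."""
    if V_A < 0:
        raise ValueError("V_A must be non-negative")
    if trait_mean == 0:
        raise ValueError("evolvability undefined for zero trait mean")
    return V_A / trait_mean**2


def draw_components(
    fit: MixedModelFit, n_sims: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Parametric draws of the variance components (truncated Gaussian).

    Samples from N(theta_hat, Cov) on the raw variance scale using the
    fit's inverse-information covariance and truncates negative draws to
    zero; columns follow ``fit.varcomp`` order.
    """
    rng = np.random.default_rng(seed)
    names = fit.component_names
    mean = np.array([fit.varcomp[c] for c in names])
    cov = np.asarray(fit.varcomp_cov, float)
    # symmetrise + ridge for a valid sampling covariance
    cov = (cov + cov.T) / 2.0
    w, V = np.linalg.eigh(cov)
    w = np.maximum(w, 0.0)
    L = V * np.sqrt(w)
    draws = mean + rng.standard_normal((n_sims, len(names))) @ L.T
    draws = np.maximum(draws, 0.0)
    if not np.all(np.isfinite(draws)):
        n_bad = int((~np.isfinite(draws).all(axis=1)).sum())
        raise RuntimeError(
            f"only {n_sims - n_bad}/{n_sims} valid component draws"
        )
    return pd.DataFrame(draws, columns=names)


def posterior_ci(
    fit: MixedModelFit,
    derived,
    n_sims: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(median, lo, hi) of a derived statistic over parametric draws.

    ``derived`` maps a dict of component draws (plus ``coef``/``se``
    Series of fixed-effect draws) to a scalar; it is evaluated on each
    of ``n_sims`` draws and summarised by the sample median and, for the
    default 10,000 draws, the 250th and 9750th order statistics (the
    standard 95% interval by ranking).
    """
    rng = np.random.default_rng(seed)
    comp = draw_components(fit, n_sims=n_sims, seed=seed)
    beta_mean = fit.coef.to_numpy()
    cb = (fit.cov_beta + fit.cov_beta.T) / 2.0
    w, V = np.linalg.eigh(cb)
    Lb = V * np.sqrt(np.maximum(w, 0.0))
    beta_draws = beta_mean + rng.standard_normal((n_sims, len(beta_mean))) @ Lb.T
    names = list(comp.columns)
    comp_arr = comp.to_numpy()
    idx = fit.coef.index
    vals = np.empty(n_sims)
    for s in range(n_sims):
        row = dict(zip(names, comp_arr[s]))
        row["coef"] = pd.Series(beta_draws[s], index=idx)
        row["se"] = fit.se
        vals[s] = derived(row)
    if not np.all(np.isfinite(vals)):
        good = np.isfinite(vals)
        raise RuntimeError(f"only {int(good.sum())}/{n_sims} valid draws")
    order = np.sort(vals)
    lo_idx = max(int(round(0.025 * n_sims)) - 1, 0)  # 250th of 10,000
    hi_idx = min(int(round(0.975 * n_sims)) - 1, n_sims - 1)  # 9,750th
    if n_sims % 2 == 0:
        med = 0.5 * (order[n_sims // 2 - 1] + order[n_sims // 2])
    else:
        med = order[n_sims // 2]
    return float(med), float(order[lo_idx]), float(order[hi_idx])


@dataclass
class VarianceDecomposition:
    """Table-3-style summary for one trait; (median, lo, hi) triples."""

    trait: str
    V_A: tuple[float, float, float]
    h2: tuple[float, float, float]
    I_A: tuple[float, float, float]
    pct_VA_vgll3: tuple[float, float, float]
    pct_VA_six6: tuple[float, float, float]
    repeatability_pct: tuple[float, float, float]
    point: dict | None = None  # plug-in point estimates per statistic

    def to_row(self) -> dict:
        row: dict = {"trait": self.trait}
        for name in ("V_A", "h2", "I_A", "pct_VA_vgll3", "pct_VA_six6",
                     "repeatability_pct"):
            med, lo, hi = getattr(self, name)
            row[name] = med
            row[f"{name}_lo"] = lo
            row[f"{name}_hi"] = hi
            if self.point and name in self.point:
                row[f"{name}_point"] = self.point[name]
        return row


def decompose(
    fit_full: MixedModelFit,
    fit_geno: MixedModelFit,
    vgll3_codes,
    six6_codes,
    trait_values,
    n_sims: int = 10_000,
    seed: int = 0,
) -> VarianceDecomposition:
    """Assemble the full decomposition for one trait.

    ``fit_full`` is the genotype-free REML fit whose V_animal is the
    total additive variance V_A; ``fit_geno`` is the genotype-including
    fit supplying beta and se for each locus. Medians and 95% CIs come
    from :func:`posterior_ci`; plug-in point estimates are kept
    alongside in ``point`` since either may be quoted.
    """
    for comp in ("animal", "ID", "tank", "error"):
        if comp not in fit_full.varcomp:
            raise ValueError(f"fit_full lacks the {comp} variance component")
    eff = {}
    for locus, codes in (("vgll3", vgll3_codes), ("six6", six6_codes)):
        fE, fL = allele_frequencies(codes)
        eff[locus] = {
            "beta": float(fit_geno.coef[locus]),
            "se": float(fit_geno.se[locus]),
            "fE": fE,
            "fL": fL,
        }
    ybar = float(np.mean(np.asarray(trait_values, float)))
    trait = fit_full.spec.trait

    def stat_va(d):
        return d["animal"]

    # degenerate draws (every component truncated to zero) take the
    # boundary value 0 rather than poisoning the ranking with NaN
    def stat_h2(d):
        denom = d["animal"] + d["tank"] + d["ID"]
        return d["animal"] / denom if denom > 0 else 0.0

    def stat_ia(d):
        return d["animal"] / ybar**2

    def stat_rep(d):
        denom = d["ID"] + d["error"]
        return 100.0 * d["ID"] / denom if denom > 0 else 0.0

    def make_pct(locus):
        e = eff[locus]

        def stat(d):
            if d["animal"] <= 0:
                return 0.0
            return max(
                100.0 * 2 * e["fL"] * e["fE"] * (e["beta"] ** 2 - e["se"] ** 2)
                / d["animal"],
                0.0,
            )

        return stat

    kw = dict(n_sims=n_sims)
    res = VarianceDecomposition(
        trait=trait,
        V_A=posterior_ci(fit_full, stat_va, seed=seed, **kw),
        h2=posterior_ci(fit_full, stat_h2, seed=seed + 1, **kw),
        I_A=posterior_ci(fit_full, stat_ia, seed=seed + 2, **kw),
        pct_VA_vgll3=posterior_ci(fit_full, make_pct("vgll3"), seed=seed + 3, **kw),
        pct_VA_six6=posterior_ci(fit_full, make_pct("six6"), seed=seed + 4, **kw),
        repeatability_pct=posterior_ci(fit_full, stat_rep, seed=seed + 5, **kw),
    )
    va = fit_full.varcomp["animal"]
    vt, vid, ve = (fit_full.varcomp[c] for c in ("tank", "ID", "error"))
    # boundary fits can zero a whole denominator; report the limit value
    res.point = {
        "V_A": va,
        "h2": heritability(va, vt, vid) if va + vt + vid > 0 else 0.0,
        "I_A": evolvability(va, ybar),
        "repeatability_pct": (
            repeatability_pct(vid, ve) if vid + ve > 0 else 0.0
        ),
    }
    if va > 0:
        for locus in ("vgll3", "six6"):
            e = eff[locus]
            res.point[f"pct_VA_{locus}"] = locus_va_contribution(
                e["beta"], e["se"], e["fL"], e["fE"], va
            )
    return res
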