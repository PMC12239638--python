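"""Multivariate linear models on Procrustes shape variables with
residual-randomization permutation (RRPP) inference.

The model regresses the (n x 2k) matrix of aligned shape coordinates on
scaled length, condition factor, feed treatment, tank, sex, the two
additive genotype codes and family, all as fixed terms (tank and family
enter fixed here deliberately; they are random in the univariate animal
models). Each term is tested marginally: its effect sums-of-squares-and
-cross-products (SSCP) matrix comes from comparing the full model with
the reduced model lacking only that term, Pillai's trace summarises the
SSCP pair, and significance comes from permuting reduced-model
residuals (RRPP), which also yields a permutation z-score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "ShapeModelSpec",
    "ShapeModelFit",
    "ShapeTermResult",
    "build_design",
    "prune_aliased_levels",
    "fit_shape_model",
    "pillai_trace",
    "rrpp_test",
    "manova_table",
    "shape_effect_vectors",
]


class RankDeficientError(np.linalg.LinAlgError):
    pass


@dataclass
class ShapeModelSpec:
    """Model specification: response matrix, covariate frame, term order."""

    response: np.ndarray  # (n, q) shape variables (or any multivariate Y)
    covariates: pd.DataFrame
    terms: list[str]
    permutations: int = 999
    seed: int = 0
    log_z: bool = False  # z on log-transformed statistics if True

    def __post_init__(self) -> None:
        self.response = np.atleast_2d(np.asarray(self.response, float))
        if self.response.shape[0] != len(self.covariates):
            raise ValueError("response rows must match covariate rows")
        missing = [t for t in self.terms if t not in self.covariates.columns]
        if missing:
            raise ValueError(f"terms absent from covariates: {missing}")


def _is_categorical(series: pd.Series) -> bool:
    return series.dtype == object or isinstance(
        series.dtype, pd.CategoricalDtype
    ) or series.dtype == bool


def build_design(
    covariates: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, dict[str, list[int]], list[str]]:
    """Design matrix with intercept; returns (X, term->column map, names).

    Categorical terms are dummy coded against their first (sorted)
    level; numeric terms enter as single columns.
    """
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    term_cols: dict[str, list[int]] = {}
    for t in terms:
        s = covariates[t]
        idx: list[int] = []
        if _is_categorical(s):
            levels = sorted(pd.unique(s.astype(str)))
            for lv in levels[1:]:
                cols.append((s.astype(str) == lv).to_numpy(float))
                names.append(f"{t}[{lv}]")
                idx.append(len(cols) - 1)
        else:
            cols.append(s.to_numpy(float))
            names.append(t)
            idx.append(len(cols) - 1)
        term_cols[t] = idx
    X = np.column_stack(cols)
    return X, term_cols, names


def prune_aliased_levels(
    covariates: pd.DataFrame, terms: list[str], tol: float = 1e-8
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Merge categorical levels whose dummies are aliased by earlier terms.

    Columns are examined in term order (so a factor listed last absorbs
    the rank deficiency, as when a family factor fully determines a
    genotype covariate); an aliased dummy's level is recoded to the
    factor's reference level. Aliased *numeric* columns cannot be
    repaired this way and still raise downstream. Returns the pruned
    covariate frame and a map term -> merged levels.
    """
    X, term_cols, names = build_design(covariates, terms)
    n = X.shape[0]
    basis = np.zeros((n, 0))
    merged: dict[str, list[str]] = {}
    out = covariates.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        if norm > tol * max(np.linalg.norm(col), 1.0):
            basis = np.column_stack([basis, resid / norm])
            continue
        term = next((t for t, cs in term_cols.items() if j in cs), None)
        name = names[j]
        if term is None or "[" not in name:
            continue  # intercept or numeric column; leave for the model
        level = name[name.index("[") + 1 : -1]
        levels = sorted(pd.unique(out[term].astype(str)))
        out[term] = out[term].astype(str).replace(level, levels[0])
        merged.setdefault(term, []).append(level)
    if merged:
        warnings.warn(
            "aliased factor levels merged into reference: "
            + "; ".join(f"{t}: {lv}" for t, lv in merged.items())
        )
    return out, merged


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


@dataclass
class ShapeModelFit:
    """Fitted full model plus reduced-model bases for each term."""

    spec: ShapeModelSpec
    X: np.ndarray
    term_cols: dict[str, list[int]]
    column_names: list[str]
    coef: np.ndarray  # (p, q) least-squares coefficients
    q_full: np.ndarray  # orthonormal basis of the full design
    q_reduced: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.coef

    @property
    def residuals(self) -> np.ndarray:
        return self.spec.response - self.fitted

    def reduced_fit(self, term: str) -> tuple[np.ndarray, np.ndarray]:
        """(fitted, residuals) under the model lacking only ``term``."""
        q = self.q_reduced[term]
        y = self.spec.response
        fitted = q @ (q.T @ y)
        return fitted, y - fitted


def fit_shape_model(spec: ShapeModelSpec) -> ShapeModelFit:
    """Fit the full model and every leave-one-term-out reduced model.

    Marginal (type III) SSCPs follow directly: with no interactions in
    the model, the effect SSCP for a term is the difference between the
    projections onto the full and the term-deleted design spaces.
    """
    X, term_cols, names = build_design(spec.covariates, spec.terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n = {n} must exceed the {p} fixed-effect columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify aliased columns by rank-revealing QR pivoting
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = [names[j] for j in piv[rank:]]
        raise RankDeficientError(
            f"design matrix rank {rank} < {p}; aliased columns: {aliased}"
        )
    coef, *_ = np.linalg.lstsq(X, spec.response, rcond=None)
    fit = ShapeModelFit(
        spec=spec,
        X=X,
        term_cols=term_cols,
        column_names=names,
        coef=coef,
        q_full=_orthonormal_basis(X),
    )
    for t in spec.terms:
        keep = [j for j in range(p) if j not in term_cols[t]]
        fit.q_reduced[t] = _orthonormal_basis(X[:, keep])
    return fit


def pillai_trace(effect_sscp: np.ndarray, residual_sscp: np.ndarray) -> float:
    """Pillai's trace: tr(H (H + E)^-1).

    For a single response column this reduces to
    SS_effect / (SS_effect + SS_residual), i.e. eta-squared. A singular
    H + E is handled with the Moore-Penrose pseudo-inverse (warning).
    """
    H = np.atleast_2d(np.asarray(effect_sscp, float))
    E = np.atleast_2d(np.asarray(residual_sscp, float))
    T = H + E
    # rank-deficient responses (e.g. Procrustes shape variables lose 4
    # dimensions to the similarity group) make T singular to working
    # precision; restrict to its non-null eigenspace rather than invert
    # numerically-zero eigenvalues
    w, V = np.linalg.eigh(T)
    wmax = float(w.max(initial=0.0))
    if wmax <= 0.0:
        return 0.0
    keep = w > 1e-10 * wmax
    if not keep.all():
        warnings.warn("singular H + E; Pillai's trace on the non-null eigenspace")
    Vk = V[:, keep]
    return float(np.trace((Vk.T @ H @ Vk) / w[keep]))


@dataclass
class ShapeTermResult:
    term: str
    df: int
    pillai: float
    z: float
    p: float
    null_distribution: np.ndarray | None = None


def _term_pillai(
    y: np.ndarray, q_full: np.ndarray, q_red: np.ndarray
) -> float:
    pf = q_full.T @ y
    pr = q_red.T @ y
    H = pf.T @ pf - pr.T @ pr
    E = y.T @ y - pf.T @ pf
    return pillai_trace(H, E)


def rrpp_test(
    fit: ShapeModelFit, term: str, permutations: int | None = None,
    seed: int | None = None,
) -> ShapeTermResult:
    """Residual-randomization permutation test for one model term.

    Each of B permutations shuffles the rows of the reduced-model
    residuals, adds back the reduced-model fitted values, and recomputes
    the term's Pillai trace. p = (1 + #{perm >= observed}) / (B + 1)
    (ties counted, observed included); z standardises the observed
    statistic against the permutation distribution (optionally on the
    log scale).
    """
    spec = fit.spec
    B = spec.permutations if permutations is None else permutations
    if B < 99:
        warnings.warn(f"only {B} permutations; p-values will be unstable")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    y = spec.response
    q_full, q_red = fit.q_full, fit.q_reduced[term]
    observed = _term_pillai(y, q_full, q_red)
    fitted_red, resid_red = fit.reduced_fit(term)
    n = y.shape[0]
    null = np.empty(B)
    for b in range(B):
        perm = rng.permutation(n)
        y_star = fitted_red + resid_red[perm]
        null[b] = _term_pillai(y_star, q_full, q_red)
    p = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    dist = np.concatenate([[observed], null])
    if spec.log_z:
        safe = np.log(np.maximum(dist, 1e-300))
        obs_t, null_t = safe[0], safe[1:]
    else:
        obs_t, null_t = observed, null
    sd = null_t.std(ddof=1)
    z = (obs_t - null_t.mean()) / sd if sd > 0 else np.nan
    return ShapeTermResult(
        term=term,
        df=len(fit.term_cols[term]),
        pillai=observed,
        z=float(z),
        p=float(p),
        null_distribution=null,
    )


def manova_table(fit: ShapeModelFit) -> pd.DataFrame:
    """RRPP test for every term: columns term, df, Pillai, z, p."""
    rows = []
    for i, t in enumerate(fit.spec.terms):
        # decorrelate term-level streams while keeping the run reproducible
        res = rrpp_test(fit, t, seed=fit.spec.seed + i)
        rows.append(
            {"term": t, "df": res.df, "pillai": res.pillai, "z": res.z, "p": res.p}
        )
    return pd.DataFrame(rows)


def shape_effect_vectors(
    fit: ShapeModelFit, term: str, contrast: tuple[float, float] = (0.0, 2.0),
    magnification: float = 10.0,
) -> np.ndarray:
    """Per-landmark displacement between two genotype codes.

    Predicts the shape at ``contrast[1]`` and ``contrast[0]`` of the
    (numeric, additive) genotype term with every other covariate held at
    its reference (categorical) or mean (numeric) value, and returns the
    difference magnified by ``magnification``, reshaped to (k, 2).
    """
    if term not in fit.term_cols:
        raise KeyError(f"term {term!r} not in the fitted model")
    idx = fit.term_cols[term]
    if len(idx) != 1:
        raise ValueError(f"term {term!r} is not a single-column additive term")
    delta = (contrast[1] - contrast[0]) * fit.coef[idx[0]] * magnification
    return delta.reshape(-1, 2)
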