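"""Univariate pedigree mixed models ("animal models") per trait.

The model for a trait y is

    y = mu + L + CF + Feed + Sex + Vgll3 + Six6 + e_ID + e_tank + e_animal + e_error

with fixed covariates (scaled length L, scaled condition factor CF,
feed treatment, sex, and the two additive genotype codes) and up to
three random terms: an i.i.d. individual effect (e_ID), an i.i.d. tank
effect (e_tank), and an additive-genetic animal effect (e_animal) whose
covariance is V_animal * A for the pedigree relationship matrix A. With
repeated measurements per individual, e_ID absorbs the between-
individual residual while e_error quantifies deviations between
repeated measurements of the same fish.

Estimation maximises the (restricted) log-likelihood over the variance
components on the log scale with a bounded quasi-Newton optimiser and
multiple starts. Because e_ID and e_animal share one incidence matrix
(individual), their joint covariance Z (V_a A + V_id I) Z' collapses,
via the eigendecomposition A = Q L Q', into a single low-rank block
with diagonal inner matrix, and the likelihood is evaluated with the
Woodbury identity at O((m + t)^3) per call for m individuals and t
tanks. Fixed effects are profiled out by GLS.

Wald/Satterthwaite fixed-effect tests, additive-vs-dominance model
comparison, length-by-genotype interaction fits and composite traits
are provided on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .pedigree import RelationshipMatrix
from .shape_model import build_design, RankDeficientError

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "fit_animal_model",
    "satterthwaite_type3",
    "compare_additive_dominance",
    "length_genotype_interaction",
    "composite_trait",
    "ConvergenceError",
]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class MixedModelSpec:
    trait: str
    fixed: tuple[str, ...] = ("length", "condition_factor", "feed", "sex", "vgll3", "six6")
    random: tuple[str, ...] = ("ID", "tank", "animal")
    estimation: str = "REML"  # REML | ML
    n_starts: int = 3

    def __post_init__(self) -> None:
        if self.estimation not in ("REML", "ML"):
            raise ValueError("estimation must be 'REML' or 'ML'")
        bad = set(self.random) - {"ID", "tank", "animal"}
        if bad:
            raise ValueError(f"unknown random terms: {sorted(bad)}")


class _Engine:
    """Precomputed design/Gram matrices and likelihood evaluations."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        ind_codes: np.ndarray | None,
        n_ind: int,
        tank_codes: np.ndarray | None,
        n_tank: int,
        A_eig: tuple[np.ndarray, np.ndarray] | None,
        use_id: bool,
        use_animal: bool,
        use_tank: bool,
    ) -> None:
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.use_id, self.use_animal, self.use_tank = use_id, use_animal, use_tank
        self.components: list[str] = []
        if use_animal:
            self.components.append("animal")
        if use_id:
            self.components.append("ID")
        if use_tank:
            self.components.append("tank")
        self.components.append("error")
        blocks = []
        self.m = n_ind
        self.t = n_tank
        if use_animal:
            Q, lam = A_eig
            self.lam = np.maximum(lam, 0.0)
            W = Q[ind_codes, :]  # (n, m): row i is Q[individual(i)]
            blocks.append(W)
        elif use_id:
            self.lam = None
            W = np.zeros((self.n, n_ind))
            W[np.arange(self.n), ind_codes] = 1.0
            blocks.append(W)
        else:
            self.lam = None
        if use_tank:
            Zt = np.zeros((self.n, n_tank))
            Zt[np.arange(self.n), tank_codes] = 1.0
            blocks.append(Zt)
        if blocks:
            U = np.hstack(blocks)
            self.U = U
            self.UtU = U.T @ U
            self.UtX = U.T @ X
            self.Uty = U.T @ y
        else:
            self.U = None
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.q_ind = self.m if (use_animal or use_id) else 0

    def _d_vector(self, theta: dict[str, float]) -> np.ndarray:
        parts = []
        if self.use_animal or self.use_id:
            d = np.zeros(self.m)
            if self.use_animal:
                d += theta["animal"] * self.lam if self.lam is not None else 0.0
            if self.use_id:
                d += theta["ID"]
            parts.append(d)
        if self.use_tank:
            parts.append(np.full(self.t, theta["tank"]))
        return np.concatenate(parts) if parts else np.zeros(0)

    def gls(self, theta: dict[str, float]):
        """GLS quantities at the given variance components.

        Returns (neg2ll_ml, neg2ll_reml, beta, cov_beta).
        """
        s2e = theta["error"]
        n, p = self.n, self.p
        if self.U is None or not any(
            theta[c] > 0 for c in self.components if c != "error"
        ):
            XtVX = self.XtX / s2e
            XtVy = self.Xty / s2e
            yVy = self.yty / s2e
            logdetV = n * np.log(s2e)
        else:
            d = self._d_vector(theta)
            S = np.sqrt(d)
            M = self.UtU * np.outer(S, S)
            M[np.diag_indices_from(M)] += s2e
            cM, low = linalg.cho_factor(M, lower=True)
            logdetV = (n - len(d)) * np.log(s2e) + 2.0 * np.log(
                np.diag(cM)
            ).sum()
            BtX = S[:, None] * self.UtX
            Bty = S * self.Uty
            MiBtX = linalg.cho_solve((cM, low), BtX)
            MiBty = linalg.cho_solve((cM, low), Bty)
            XtVX = (self.XtX - BtX.T @ MiBtX) / s2e
            XtVy = (self.Xty - BtX.T @ MiBty) / s2e
            yVy = (self.yty - Bty @ MiBty) / s2e
        cX, lowX = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve((cX, lowX), XtVy)
        ypy = yVy - XtVy @ beta
        logdet_XtVX = 2.0 * np.log(np.diag(cX)).sum()
        neg2_ml = n * _LOG2PI + logdetV + ypy
        neg2_reml = (n - p) * _LOG2PI + logdetV + logdet_XtVX + ypy
        cov_beta = linalg.cho_solve((cX, lowX), np.eye(p))
        return neg2_ml, neg2_reml, beta, cov_beta

    def neg2ll(self, theta: dict[str, float], reml: bool) -> float:
        ml, rl, _, _ = self.gls(theta)
        return rl if reml else ml

    def _weight_vector(self, comp: str) -> np.ndarray:
        """dV/dtheta_comp = U diag(g) U' for block components."""
        g = np.zeros(self.UtU.shape[0])
        if comp == "animal":
            g[: self.m] = self.lam
        elif comp == "ID":
            g[: self.m] = 1.0
        elif comp == "tank":
            g[self.q_ind :] = 1.0
        return g

    def neg2ll_grad(
        self, theta: dict[str, float], reml: bool
    ) -> tuple[float, np.ndarray]:
        """-2 log-(restricted-)likelihood and its gradient in theta.

        Uses the profiled-beta identities: for GLS residuals r,
        d(-2l)/dtheta_k = tr(P K_k) - r' V^-1 K_k V^-1 r with
        P = V^-1 - V^-1 X Phi X' V^-1 (REML) or P = V^-1 (ML), and
        K_k = dV/dtheta_k; all traces are evaluated through the
        Woodbury factorisation without forming any n x n matrix.
        """
        s2e = theta["error"]
        n, p = self.n, self.p
        comps = self.components
        if self.U is None or not any(
            theta[c] > 0 for c in comps if c != "error"
        ):
            # OLS limit: V = s2e I
            _, _, beta, _ = self.gls(theta)
            r = self.y - self.X @ beta
            rr = float(r @ r)
            f = self.neg2ll(theta, reml)
            grad = np.zeros(len(comps))
            ie = comps.index("error")
            tr_p = (n - p) / s2e if reml else n / s2e
            grad[ie] = tr_p - rr / s2e**2
            # block components at zero: one-sided derivative
            XtXi = np.linalg.inv(self.XtX)
            for k, c in enumerate(comps):
                if c == "error":
                    continue
                g = self._weight_vector(c)
                Ur = self.Uty - self.UtX @ beta
                quad = float((g * Ur**2).sum()) / s2e**2
                trv = float((g * np.diag(self.UtU)).sum()) / s2e
                if reml:
                    UX = self.UtX
                    trc = float(
                        np.trace(XtXi @ (UX.T * g) @ UX)
                    ) / s2e
                    trv -= trc
                grad[k] = trv - quad
            return f, grad
        d = self._d_vector(theta)
        S = np.sqrt(d)
        M = self.UtU * np.outer(S, S)
        M[np.diag_indices_from(M)] += s2e
        cM, low = linalg.cho_factor(M, lower=True)
        q = len(d)
        logdetV = (n - q) * np.log(s2e) + 2.0 * np.log(np.diag(cM)).sum()
        BtX = S[:, None] * self.UtX
        Bty = S * self.Uty
        MiBtX = linalg.cho_solve((cM, low), BtX)
        MiBty = linalg.cho_solve((cM, low), Bty)
        XtVX = (self.XtX - BtX.T @ MiBtX) / s2e
        XtVy = (self.Xty - BtX.T @ MiBty) / s2e
        yVy = (self.yty - Bty @ MiBty) / s2e
        cX, lowX = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve((cX, lowX), XtVy)
        ypy = yVy - XtVy @ beta
        logdet_XtVX = 2.0 * np.log(np.diag(cX)).sum()
        f = (
            (n - p) * _LOG2PI + logdetV + logdet_XtVX + ypy
            if reml
            else n * _LOG2PI + logdetV + ypy
        )
        # residual pieces
        u_r = self.Uty - self.UtX @ beta  # U'r
        Btr = S * u_r
        w = linalg.cho_solve((cM, low), Btr)
        rr = self.yty - 2.0 * beta @ self.Xty + beta @ (self.XtX @ beta)
        UtU_S = self.UtU * S[None, :]
        v_r = (u_r - UtU_S @ w) / s2e  # U' V^-1 r
        rV2r = (rr - Btr @ w - s2e * (w @ w)) / s2e**2  # r' V^-2 r
        # trace pieces via triangular solves (no explicit M^-1)
        T = UtU_S  # U'B
        G = linalg.solve_triangular(cM, T.T, lower=True)
        diag_UVU = (np.diag(self.UtU) - (G**2).sum(axis=0)) / s2e
        Linv = linalg.solve_triangular(cM, np.eye(q), lower=True)
        tr_invM = float((Linv**2).sum())
        tr_Vi = (n - (q - s2e * tr_invM)) / s2e
        if reml:
            Phi = linalg.cho_solve((cX, lowX), np.eye(p))
            UVX = (self.UtX - T @ MiBtX) / s2e  # U' V^-1 X
            # V^-1 X in full space for the error-component trace
            VX = (self.X - self.U @ (S[:, None] * MiBtX)) / s2e
        grad = np.zeros(len(comps))
        for k, c in enumerate(comps):
            if c == "error":
                trv = tr_Vi
                quad = rV2r
                if reml:
                    trv -= float(np.trace(Phi @ (VX.T @ VX)))
            else:
                g = self._weight_vector(c)
                trv = float(g @ diag_UVU)
                quad = float(g @ v_r**2)
                if reml:
                    trv -= float(np.trace(Phi @ ((UVX.T * g) @ UVX)))
            grad[k] = trv - quad
        return float(f), grad


class _CollapsedEngine:
    """Fast exact likelihood for replicate rows with shared covariates.

    When every individual's rows carry identical covariates and tank,
    the likelihood factorises exactly into a within-individual part
    (SS_w on sigma_e^2) and a between part on the individual means with
    covariance Vbar = Va A + Vid I + Ve N^-1 + Vt Zt Zt'. Rotating by
    the eigenbasis of A leaves a diagonal matrix plus a rank-(r + t)
    correction (r = individuals with replicates, t = tanks), so each
    evaluation costs O(m (r + t)^2) instead of O((m + t)^3). Produces
    numbers identical to :class:`_Engine` (cross-checked in the tests).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        ind_codes: np.ndarray,
        n_ind: int,
        tank_codes: np.ndarray | None,
        n_tank: int,
        A_eig: tuple[np.ndarray, np.ndarray] | None,
        use_id: bool,
        use_animal: bool,
        use_tank: bool,
    ) -> None:
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.m = n_ind
        self.use_id, self.use_animal, self.use_tank = use_id, use_animal, use_tank
        self.components = (
            (["animal"] if use_animal else [])
            + (["ID"] if use_id else [])
            + (["tank"] if use_tank else [])
            + ["error"]
        )
        n_i = np.bincount(ind_codes, minlength=n_ind).astype(float)
        ybar = np.bincount(ind_codes, weights=y, minlength=n_ind) / n_i
        self.ss_w = float((y**2).sum() - (n_i * ybar**2).sum())
        firsts = np.zeros(n_ind, dtype=int)
        firsts[ind_codes[::-1]] = np.arange(self.n - 1, -1, -1)
        Xbar = X[firsts]
        self.n_i = n_i
        self.log_n = float(np.log(n_i).sum())
        if use_animal:
            Q, lam = A_eig
            self.lam = np.maximum(lam, 0.0)
            self.Q = Q
            Xt = Q.T @ Xbar
            yt = Q.T @ ybar
        else:
            self.lam = np.zeros(n_ind)
            self.Q = None
            Xt, yt = Xbar, ybar
        self.Xt, self.yt = Xt, yt
        self.XtX = Xt.T @ Xt
        self.Xty = Xt.T @ yt
        self.yty = float(yt @ yt)
        rep = np.flatnonzero(n_i > 1)
        self.r = len(rep)
        self.d_rep = 1.0 - 1.0 / n_i[rep]
        if self.Q is not None:
            self.Qr = self.Q[rep, :]  # (r, m) rows of Q
        else:
            Qr = np.zeros((self.r, n_ind))
            Qr[np.arange(self.r), rep] = 1.0
            self.Qr = Qr
        self.t = n_tank if use_tank else 0
        if use_tank:
            tank_bar = tank_codes[firsts]
            Zt = np.zeros((n_ind, n_tank))
            Zt[np.arange(n_ind), tank_bar] = 1.0
            self.Zt_rot = self.Q.T @ Zt if self.Q is not None else Zt
        else:
            self.Zt_rot = np.zeros((n_ind, 0))

    # -- core linear algebra ------------------------------------------------
    def _factor(self, theta: dict[str, float]):
        s2e = theta["error"]
        D = theta.get("animal", 0.0) * self.lam + theta.get("ID", 0.0) + s2e
        blocks_F, blocks_j = [], []
        if self.r:
            blocks_F.append(self.Qr.T)
            blocks_j.append(-s2e * self.d_rep)
        s2t = theta.get("tank", 0.0)
        if self.t and s2t > 0:
            blocks_F.append(self.Zt_rot)
            blocks_j.append(np.full(self.t, s2t))
        if blocks_F:
            F = np.hstack(blocks_F)
            j = np.concatenate(blocks_j)
            Gm = F / D[:, None]
            K = np.diag(1.0 / j) + F.T @ Gm
            lu = linalg.lu_factor(K)
            logdet_j = float(np.log(np.abs(j)).sum())
            diagU = lu[0].diagonal()
            logdet_K = float(np.log(np.abs(diagU)).sum())
            return {"D": D, "F": F, "Gm": Gm, "lu": lu, "j": j,
                    "n_rep_block": self.r,
                    "logdetV": float(np.log(D).sum()) + logdet_j + logdet_K}
        return {"D": D, "F": None, "Gm": None, "lu": None, "j": None,
                "n_rep_block": 0,
                "logdetV": float(np.log(D).sum())}

    def _solve(self, fac, mat: np.ndarray) -> np.ndarray:
        out = mat / fac["D"][:, None] if mat.ndim == 2 else mat / fac["D"]
        if fac["F"] is not None:
            rhs = fac["Gm"].T @ mat
            out = out - fac["Gm"] @ linalg.lu_solve(fac["lu"], rhs)
        return out

    def gls(self, theta: dict[str, float]):
        fac = self._factor(theta)
        s2e = theta["error"]
        n, m, p = self.n, self.m, self.p
        Xv = self._solve(fac, self.Xt)
        XtVX = self.Xt.T @ Xv
        XtVy = Xv.T @ self.yt
        vy = self._solve(fac, self.yt)
        yVy = float(self.yt @ vy)
        cX, lowX = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve((cX, lowX), XtVy)
        cov_beta = linalg.cho_solve((cX, lowX), np.eye(p))
        logdet_XtVX = 2.0 * np.log(np.diag(cX)).sum()
        logdetV = (n - m) * np.log(s2e) + self.log_n + fac["logdetV"]
        ypy = self.ss_w / s2e + yVy - XtVy @ beta
        neg2_ml = n * _LOG2PI + logdetV + ypy
        neg2_reml = (n - p) * _LOG2PI + logdetV + logdet_XtVX + ypy
        return neg2_ml, neg2_reml, beta, cov_beta

    def neg2ll(self, theta: dict[str, float], reml: bool) -> float:
        ml, rl, _, _ = self.gls(theta)
        return rl if reml else ml

    def neg2ll_grad(
        self, theta: dict[str, float], reml: bool
    ) -> tuple[float, np.ndarray]:
        fac = self._factor(theta)
        s2e = theta["error"]
        n, m, p = self.n, self.m, self.p
        Xv = self._solve(fac, self.Xt)  # Vbar^-1 X (rotated)
        XtVX = self.Xt.T @ Xv
        XtVy = Xv.T @ self.yt
        vy = self._solve(fac, self.yt)
        yVy = float(self.yt @ vy)
        cX, lowX = linalg.cho_factor(XtVX, lower=True)
        beta = linalg.cho_solve((cX, lowX), XtVy)
        Phi = linalg.cho_solve((cX, lowX), np.eye(p))
        logdet_XtVX = 2.0 * np.log(np.diag(cX)).sum()
        logdetV = (n - m) * np.log(s2e) + self.log_n + fac["logdetV"]
        ypy = self.ss_w / s2e + yVy - XtVy @ beta
        f = (
            (n - p) * _LOG2PI + logdetV + logdet_XtVX + ypy
            if reml
            else n * _LOG2PI + logdetV + ypy
        )
        v = vy - Xv @ beta  # Vbar^-1 (ybar - X beta), rotated
        # diag(Vbar^-1); V^-1 F recovered cheaply via
        # V^-1 F = Gm K^-1 diag(1/j) (Woodbury algebra, no m-sized solve)
        diagV = 1.0 / fac["D"]
        VF = None
        if fac["F"] is not None:
            Gm2 = fac["Gm"] @ linalg.lu_solve(fac["lu"], np.eye(len(fac["j"])))
            diagV = diagV - (fac["Gm"] * Gm2).sum(axis=1)
            VF = Gm2 / fac["j"][None, :]
        # Qr Vbar^-1 Qr' and Zt' pieces
        if self.r:
            VQr = VF[:, : self.r]  # (m, r) = Vbar^-1 Qr'
            qr_diag = (self.Qr.T * VQr).sum(axis=0)  # diag(Qr V^-1 Qr')
            Qr_v = self.Qr @ v
            Qr_Xv = self.Qr @ Xv
        if self.use_tank:
            if VF is not None and VF.shape[1] == self.r + self.t:
                Vz = VF[:, self.r :]
            else:
                Vz = self._solve(fac, self.Zt_rot)
            z_tr = float((self.Zt_rot * Vz).sum())
            Zt_v = self.Zt_rot.T @ v
            Zt_Xv = self.Zt_rot.T @ Xv
        grad = np.zeros(len(self.components))
        for k, c in enumerate(self.components):
            if c == "animal":
                trv = float(self.lam @ diagV)
                quad = float(self.lam @ v**2)
                if reml:
                    Mw = Xv.T @ (self.lam[:, None] * Xv)
                    trv -= float(np.trace(Phi @ Mw))
            elif c == "ID":
                trv = float(diagV.sum())
                quad = float(v @ v)
                if reml:
                    trv -= float(np.trace(Phi @ (Xv.T @ Xv)))
            elif c == "tank":
                trv = z_tr
                quad = float(Zt_v @ Zt_v)
                if reml:
                    trv -= float(np.trace(Phi @ (Zt_Xv.T @ Zt_Xv)))
            else:  # error: I_n in the full data space
                trv = (n - m) / s2e + float(diagV.sum())
                quad = self.ss_w / s2e**2 + float(v @ v)
                corr_X = Xv.T @ Xv
                if self.r:
                    trv -= float(self.d_rep @ qr_diag)
                    quad -= float(self.d_rep @ Qr_v**2)
                    corr_X = corr_X - Qr_Xv.T @ (self.d_rep[:, None] * Qr_Xv)
                if reml:
                    trv -= float(np.trace(Phi @ corr_X))
            grad[k] = trv - quad
        return float(f), grad


@dataclass
class MixedModelFit:
    """Converged mixed-model fit: coefficients, components, likelihoods."""

    spec: MixedModelSpec
    coef: pd.Series
    se: pd.Series
    cov_beta: np.ndarray
    varcomp: dict[str, float]
    varcomp_cov: np.ndarray  # covariance of components, order = varcomp keys
    loglik: float  # log-likelihood of the estimation criterion
    loglik_ml: float
    n_obs: int
    n_fixed: int
    converged: bool
    term_cols: dict[str, list[int]] = field(default_factory=dict)
    engine: "_Engine | None" = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        """AIC from the ML log-likelihood; parameters = fixed + components."""
        k = self.n_fixed + len(self.varcomp)
        return -2.0 * self.loglik_ml + 2.0 * k

    @property
    def component_names(self) -> list[str]:
        return list(self.varcomp)

    def tvalues(self) -> pd.Series:
        return self.coef / self.se


def _prepare(table: pd.DataFrame, A: RelationshipMatrix | None, spec: MixedModelSpec):
    cols_needed = [spec.trait, *spec.fixed]
    if "ID" in spec.random or "animal" in spec.random:
        cols_needed.append("id")
    if "tank" in spec.random:
        cols_needed.append("tank")
    missing = [c for c in cols_needed if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks required columns: {missing}")
    df = table.dropna(subset=[spec.trait, *spec.fixed]).reset_index(drop=True)
    y = df[spec.trait].to_numpy(float)
    X, term_cols, names = build_design(df, list(spec.fixed))
    ind_codes = n_ind = None
    if "ID" in spec.random or "animal" in spec.random:
        ids = pd.Categorical(df["id"].astype(str))
        ind_codes = ids.codes.astype(int)
        ind_levels = list(ids.categories)
        n_ind = len(ind_levels)
    else:
        ind_levels = []
    tank_codes = n_tank = None
    if "tank" in spec.random:
        tanks = pd.Categorical(df["tank"].astype(str))
        tank_codes = tanks.codes.astype(int)
        n_tank = len(tanks.categories)
    A_eig = None
    if "animal" in spec.random:
        if A is None:
            raise ValueError("animal random term requires a relationship matrix")
        known = set(A.ids)
        unmatched = [i for i in ind_levels if i not in known]
        if unmatched:
            raise ValueError(
                f"{len(unmatched)} individual id(s) missing from the "
                f"relationship matrix, e.g. {unmatched[:5]}"
            )
        A_eig = _cached_eig(A, tuple(ind_levels))
    use_id = "ID" in spec.random
    use_animal = "animal" in spec.random
    use_tank = "tank" in spec.random
    engine_cls = _Engine
    if (use_id or use_animal) and _collapsible(X, ind_codes, tank_codes):
        engine_cls = _CollapsedEngine
    eng = engine_cls(
        y, X, ind_codes, n_ind or 0, tank_codes, n_tank or 0, A_eig,
        use_id=use_id, use_animal=use_animal, use_tank=use_tank,
    )
    return df, eng, term_cols, names


def _collapsible(
    X: np.ndarray, ind_codes: np.ndarray, tank_codes: np.ndarray | None
) -> bool:
    """True when all rows of an individual share covariates and tank,
    allowing the exact collapsed (means + within-SS) likelihood."""
    n, m = X.shape[0], int(ind_codes.max()) + 1
    firsts = np.zeros(m, dtype=int)
    firsts[ind_codes[::-1]] = np.arange(n - 1, -1, -1)
    if not np.allclose(X, X[firsts][ind_codes], rtol=0.0, atol=0.0):
        return False
    if tank_codes is not None and not np.array_equal(
        tank_codes, tank_codes[firsts][ind_codes]
    ):
        return False
    return True


def _theta_dict(components: list[str], values: np.ndarray) -> dict[str, float]:
    return dict(zip(components, values))


_EIG_CACHE: dict = {}


def _cached_eig(A: RelationshipMatrix, ind_levels: tuple[str, ...]):
    """Eigendecomposition of A restricted to the modelled individuals.

    Repeated fits on the same dataset (genotype-free vs genotype-full,
    additive vs dominance codings) reuse the factorisation.
    """
    key = (id(A), ind_levels)
    if key not in _EIG_CACHE:
        if len(_EIG_CACHE) > 8:
            _EIG_CACHE.clear()
        lam, Q = np.linalg.eigh(A.submatrix(list(ind_levels)))
        _EIG_CACHE[key] = (Q, lam)
    return _EIG_CACHE[key]


def fit_animal_model(
    table: pd.DataFrame,
    A: RelationshipMatrix | None,
    spec: MixedModelSpec,
) -> MixedModelFit:
    """Fit the mixed model for one trait.

    Rows with a missing trait or covariate are dropped. Variance
    components are optimised on the log scale (L-BFGS-B, three starts by
    default); fixed effects are profiled by GLS at the optimum. With no
    random terms the fit reduces to (ordinary) maximum likelihood
    least squares.
    """
    df, eng, term_cols, names = _prepare(table, A, spec)
    reml = spec.estimation == "REML"
    comps = eng.components
    n_var = len(comps)
    vy = max(float(np.var(eng.y)), 1e-12)
    if n_var == 1:  # error only: closed form
        n, p = eng.n, eng.p
        _, _, beta, _ = eng.gls({"error": 1.0})
        resid = eng.y - eng.X @ beta
        rss = float(resid @ resid)
        s2 = rss / (n - p) if reml else rss / n
        theta_hat = np.array([s2])
        best = {"error": s2}
    else:
        lo, hi = np.log(vy * 1e-8), np.log(vy * 1e3)

        def obj(phi: np.ndarray):
            theta = _theta_dict(comps, np.exp(phi))
            try:
                f, g = eng.neg2ll_grad(theta, reml)
            except linalg.LinAlgError:
                return 1e12, np.zeros(n_var)
            return f, g * np.exp(phi)  # chain rule to the log scale

        starts = []
        eq = np.log(np.full(n_var, vy / n_var))
        starts.append(eq)
        resid_heavy = np.full(n_var, vy * 0.1 / max(n_var - 1, 1))
        resid_heavy[-1] = vy * 0.9
        starts.append(np.log(resid_heavy))
        genet_heavy = np.full(n_var, vy * 0.2 / max(n_var - 1, 1))
        genet_heavy[0] = vy * 0.8
        starts.append(np.log(genet_heavy))
        best_res = None
        for start in starts[: max(spec.n_starts, 1)]:
            res = optimize.minimize(
                obj,
                np.clip(start, lo, hi),
                method="L-BFGS-B",
                jac=True,
                bounds=[(lo, hi)] * n_var,
                options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
            )
            if best_res is None or res.fun < best_res.fun - 1e-10:
                best_res = res
        if best_res is None or not np.isfinite(best_res.fun):
            raise ConvergenceError(f"optimizer failed: {best_res}")
        theta_hat = np.exp(best_res.x)
        # components driven to the lower box edge are boundary zeros
        theta_hat[best_res.x <= lo + 1e-6] = 0.0
        if theta_hat[comps.index("error")] == 0.0:
            theta_hat[comps.index("error")] = vy * 1e-8
        best = _theta_dict(comps, theta_hat)
    neg2_ml, neg2_reml, beta, cov_beta = eng.gls(best)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    vcov = _varcomp_covariance(eng, np.asarray(theta_hat, float), comps, reml, vy)
    return MixedModelFit(
        spec=spec,
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov_beta=cov_beta,
        varcomp=best,
        varcomp_cov=vcov,
        loglik=-0.5 * (neg2_reml if reml else neg2_ml),
        loglik_ml=-0.5 * neg2_ml,
        n_obs=eng.n,
        n_fixed=eng.p,
        converged=True,
        term_cols=term_cols,
        engine=eng,
    )


def _varcomp_covariance(
    eng: _Engine, theta: np.ndarray, comps: list[str], reml: bool, vy: float
) -> np.ndarray:
    """Asymptotic covariance of the variance components.

    Observed information from a central-difference Jacobian of the
    analytic score of the -2 log-(restricted-)likelihood on the raw
    variance scale; Var(theta_hat) = 2 * H^-1 (pseudo-inverse at
    boundary estimates).
    """
    k = len(comps)
    if k == 1:
        n_eff = eng.n - (eng.p if reml else 0)
        return np.array([[2.0 * theta[0] ** 2 / max(n_eff, 1)]])
    floor = vy * 1e-10
    steps = np.maximum(1e-5 * np.maximum(theta, vy * 1e-3), floor)

    def score(t: np.ndarray) -> np.ndarray:
        return eng.neg2ll_grad(_theta_dict(comps, np.maximum(t, floor)), reml)[1]

    H = np.zeros((k, k))
    for i in range(k):
        e = np.zeros(k)
        e[i] = steps[i]
        H[i] = (score(theta + e) - score(theta - e)) / (2 * steps[i])
    H = (H + H.T) / 2.0
    try:
        cov = 2.0 * np.linalg.inv(H)
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = 2.0 * np.linalg.pinv(H)
    return cov


def satterthwaite_type3(fit: MixedModelFit) -> pd.DataFrame:
    """Type-3 F tests with Satterthwaite denominator degrees of freedom.

    For a single-df contrast c, df = 2 (c' Phi c)^2 / Var(c' Phi c)
    where Phi(theta) = (X' V(theta)^-1 X)^-1 and the variance of the
    contrast variance follows from the delta method: g' Cov(theta) g
    with g the (numerical) gradient of c' Phi c in the components. With
    no variance parameters beyond the residual this collapses exactly to
    the classical df = n - p. Multi-column terms report the mean of the
    per-column dfs (a standard approximation for multi-df contrasts).
    """
    eng = fit.engine
    if eng is None:
        raise ValueError("fit carries no engine; refit with fit_animal_model")
    comps = fit.component_names
    theta = np.array([fit.varcomp[c] for c in comps])
    p = fit.n_fixed
    rows = []
    if len(comps) == 1:  # residual-only model: exact classical df
        df_resid = fit.n_obs - p
        for term, cols in fit.term_cols.items():
            F, df1 = _wald_F(fit, cols)
            pval = stats.f.sf(F, df1, df_resid)
            rows.append({"term": term, "F": F, "df1": df1, "df2": float(df_resid), "p": pval})
        return pd.DataFrame(rows)
    vy = max(float(np.var(eng.y)), 1e-12)
    floor = vy * 1e-10
    steps = np.maximum(1e-4 * np.maximum(theta, vy * 1e-3), floor)

    def phi(t: np.ndarray) -> np.ndarray:
        _, _, _, cov_beta = eng.gls(dict(zip(comps, np.maximum(t, floor))))
        return cov_beta

    grads = np.zeros((len(comps), p, p))
    for i in range(len(comps)):
        e = np.zeros(len(comps)); e[i] = steps[i]
        grads[i] = (phi(theta + e) - phi(theta - e)) / (2 * steps[i])
    singular = not np.all(np.isfinite(fit.varcomp_cov))
    for term, cols in fit.term_cols.items():
        F, df1 = _wald_F(fit, cols)
        dfs = []
        for j in cols:
            v = fit.cov_beta[j, j]
            g = grads[:, j, j]
            var_v = float(g @ fit.varcomp_cov @ g)
            if singular or var_v <= 0:
                dfs.append(float(fit.n_obs - p))
            else:
                dfs.append(2.0 * v**2 / var_v)
        df2 = float(np.mean(dfs)) if dfs else float(fit.n_obs - p)
        df2 = min(df2, float(fit.n_obs - p))
        pval = stats.f.sf(F, df1, df2)
        rows.append({"term": term, "F": F, "df1": df1, "df2": df2, "p": pval})
    out = pd.DataFrame(rows)
    if singular:
        warnings.warn("singular component information; residual df fallback used")
    return out


def _wald_F(fit: MixedModelFit, cols: list[int]) -> tuple[float, int]:
    b = fit.coef.to_numpy()[cols]
    V = fit.cov_beta[np.ix_(cols, cols)]
    F = float(b @ np.linalg.solve(V, b)) / len(cols)
    return F, len(cols)


_DOMINANCE_CODINGS = {
    "factor": None,  # free 3-level factor
    "EL_equals_LL": {0: 0.0, 1: 1.0, 2: 1.0},
    "EL_equals_EE": {0: 0.0, 1: 0.0, 2: 1.0},
}


def compare_additive_dominance(
    table: pd.DataFrame,
    A: RelationshipMatrix | None,
    trait: str,
    locus: str = "vgll3",
    spec: MixedModelSpec | None = None,
) -> dict:
    """ML-AIC comparison of additive vs non-additive genotype effects.

    Fits the additive (0/1/2 numeric) model, the free 3-level factor
    model, and the two constrained dominance codings (EL identical to
    LL, and EL identical to EE). All fits use ML so the AICs are
    comparable. Returns AICs, delta = AIC_additive - AIC_factor, and a
    ``meaningful`` flag for delta >= 2 (the conventional AIC support
    threshold). Non-convergence of one side yields a partial result with
    ``converged`` False.
    """
    base = spec or MixedModelSpec(trait=trait)
    base = MixedModelSpec(
        trait=trait, fixed=base.fixed, random=base.random,
        estimation="ML", n_starts=base.n_starts,
    )
    out: dict = {"locus": locus, "trait": trait, "converged": True, "aic": {}}
    try:
        fit_add = fit_animal_model(table, A, base)
        out["aic"]["additive"] = fit_add.aic
    except (ConvergenceError, linalg.LinAlgError):
        out["converged"] = False
    for name, coding in _DOMINANCE_CODINGS.items():
        t2 = table.copy()
        if coding is None:
            t2[locus] = t2[locus].map({0: "EE", 1: "EL", 2: "LL"}).astype(object)
        else:
            t2[locus] = t2[locus].map(coding)
        try:
            fit_v = fit_animal_model(t2, A, base)
            out["aic"][name] = fit_v.aic
        except (ConvergenceError, linalg.LinAlgError):
            out["converged"] = False
    if "additive" in out["aic"] and "factor" in out["aic"]:
        out["delta"] = out["aic"]["additive"] - out["aic"]["factor"]
        out["meaningful"] = out["delta"] >= 2.0
    return out


def length_genotype_interaction(
    table: pd.DataFrame,
    A: RelationshipMatrix | None,
    trait: str,
    length_col: str = "length",
    loci: tuple[str, ...] = ("vgll3", "six6"),
    spec: MixedModelSpec | None = None,
) -> dict:
    """Fit with length-by-genotype interactions and compare main effects.

    Tests whether the loci act on the trait through length (allometry)
    rather than directly: adds L x locus product columns, reports their
    t-values, and the change in the main genetic-effect estimates
    relative to the base (no-interaction) model.
    """
    base = spec or MixedModelSpec(trait=trait)
    fit0 = fit_animal_model(table, A, base)
    t2 = table.copy()
    int_terms = []
    for locus in loci:
        col = f"{length_col}_x_{locus}"
        t2[col] = t2[length_col] * t2[locus]
        int_terms.append(col)
    spec_int = MixedModelSpec(
        trait=trait, fixed=tuple(list(base.fixed) + int_terms),
        random=base.random, estimation=base.estimation, n_starts=base.n_starts,
    )
    fit1 = fit_animal_model(t2, A, spec_int)
    t_int = {c: float(fit1.coef[c] / fit1.se[c]) for c in int_terms}
    main_change = {
        locus: float(fit1.coef[locus] - fit0.coef[locus]) for locus in loci
    }
    return {
        "base_fit": fit0,
        "interaction_fit": fit1,
        "interaction_t": t_int,
        "main_effect_change": main_change,
    }


def composite_trait(
    table: pd.DataFrame, trait_names: list[str], weights=None, name: str | None = None
) -> pd.Series:
    """Weighted mean of z-scored component traits (equal weights default).

    An individual missing any component gets a missing composite.
    """
    if len(trait_names) < 2:
        raise ValueError("composite trait needs at least 2 components")
    w = np.full(len(trait_names), 1.0 / len(trait_names)) if weights is None else (
        np.asarray(weights, float) / np.sum(weights)
    )
    z = pd.DataFrame(index=table.index)
    for t in trait_names:
        v = table[t]
        z[t] = (v - v.mean()) / v.std(ddof=1)
    out = (z * w).sum(axis=1, skipna=False)
    out.name = name or ("composite_" + "_".join(trait_names))
    return out
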