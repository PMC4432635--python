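"""Per-transcript repeated-measures two-way ANOVA with REML variance components.

Model
-----
After per-subject Pre normalization the Pre level is identically zero, so the
mixed model is fitted on the post time points only, with a cell-means
parameterization over group x time:

    y_{g,t,s} = mu_{g,t} + b_s + eps,   b_s ~ N(0, s2_subject),  eps ~ N(0, s2_resid)

Every "versus Pre" hypothesis is a test of a cell mean (or a mean of cell
means) against zero, which is mathematically the paired contrast against the
subject's own baseline.  Variance components are estimated by REML: the
residual variance is profiled out and the single variance ratio
lambda = s2_subject / s2_resid is optimized by a bounded scalar search
(coarse log-grid, then golden-section plus one parabolic refinement), with
negative subject variance truncated at zero and the model refit as fixed
effects.

Tests
-----
* Omnibus Wald F tests: Time (equality of the post-time profiles, averaged
  over groups), Group (averaged over post times) and Time x Group (divergence
  of group profiles across post times).  For balanced complete data these
  reproduce the classical repeated-measures sums-of-squares F statistics.
  A fourth omnibus, TimexGroupVsPre, is the factorial interaction with the
  (implicit, zero) baseline level included: do the groups share the same
  change-from-Pre at every post time?  This is the interaction a reader of
  the original factorial model sees, and the one the time-regulated rule
  screens on.
* Named 1-df contrasts: each group at each post time versus Pre (E2.5h, ...),
  each group pair at each post time (EvC2.5h, SvE5h, ...), and the marginal
  across-group change from Pre at each post time (Time2.5h, Time5h) used by
  the time-regulated rule.

Degrees of freedom: omnibus tests use containment df by default (the
classical strata: subjects-minus-groups for Group, the within-subject
residual df for Time and the interaction); 1-df contrasts mix the two strata,
so they always use Satterthwaite df computed from the REML information
matrix.  ``df_method="satterthwaite"`` switches the omnibus tests to the
eigencontrast Satterthwaite method as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DesignError, ExanovaError
from .io import StudyDesign, PRE_TIME

__all__ = ["ModelSpec", "ContrastScheme", "AnovaResult", "fit_all", "fit_transcript"]

_GOLD = (np.sqrt(5.0) - 1.0) / 2.0

#: conventional single-letter codes for the three arms of the study design
DEFAULT_CODES = {"control": "C", "endurance": "E", "resistance": "S", "strength": "S"}

EFFECT_NAMES = ("Time", "Group", "TimexGroup", "TimexGroupVsPre")


def _tlabel(t: float) -> str:
    return f"{t:g}h"


def make_group_codes(groups) -> dict[str, str]:
    """Single-letter group codes (C/E/S for the canonical labels)."""
    codes: dict[str, str] = {}
    for g in groups:
        c = DEFAULT_CODES.get(g.lower(), g[0].upper())
        while c in codes.values():
            c += g[1:2].upper() or "X"
        codes[g] = c
    return codes


@dataclass(frozen=True)
class ContrastScheme:
    """Naming and lookup for the contrast set of one fitted design."""

    groups: tuple[str, ...]
    post_times: tuple[float, ...]
    codes: dict[str, str]

    def code(self, group: str) -> str:
        return self.codes[group]

    def vs_pre_name(self, group: str, t: float) -> str:
        return f"{self.codes[group]}{_tlabel(t)}"

    def pair_name(self, g1: str, g2: str, t: float) -> str:
        """Canonical 'g1 v g2' name; accepts either argument order."""
        i1, i2 = self.groups.index(g1), self.groups.index(g2)
        if i1 < i2:
            g1, g2 = g2, g1
        return f"{self.codes[g1]}v{self.codes[g2]}{_tlabel(t)}"

    def marginal_name(self, t: float) -> str:
        return f"Time{_tlabel(t)}"

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """Ordered (later, earlier) group pairs, e.g. (E,C), (S,C), (S,E)."""
        out = []
        for i in range(1, len(self.groups)):
            for j in range(i):
                out.append((self.groups[i], self.groups[j]))
        return out

    def contrast_names(self) -> list[str]:
        names = [self.marginal_name(t) for t in self.post_times]
        names += [
            self.vs_pre_name(g, t) for g in self.groups for t in self.post_times
        ]
        names += [self.pair_name(a, b, t) for a, b in self.pairs for t in self.post_times]
        return names


@dataclass
class ModelSpec:
    """Fitting options for the per-transcript mixed model."""

    post_times: tuple[float, ...] | None = None
    groups: tuple[str, ...] | None = None
    df_method: str = "containment"
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    max_nonconverged_frac: float = 0.5
    chunk_size: int = 2048

    def __post_init__(self) -> None:
        if self.df_method not in ("containment", "satterthwaite"):
            raise ConfigError(
                f"df_method must be 'containment' or 'satterthwaite', "
                f"got {self.df_method!r}"
            )
        if self.reml_tol <= 0:
            raise ConfigError("reml_tol must be > 0")
        if self.reml_max_iter < 1:
            raise ConfigError("reml_max_iter must be >= 1")


@dataclass
class AnovaResult:
    """Per-transcript ANOVA table plus the contrast naming scheme used."""

    table: pd.DataFrame
    scheme: ContrastScheme
    spec: ModelSpec
    n_nonconverged: int = 0

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.table.index)

    def p_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.endswith(".p")]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="transcript_id")


class _DesignMatrices:
    """Fixed per-design quantities shared by every transcript's fit."""

    def __init__(self, design: StudyDesign, groups, post_times):
        self.groups = tuple(groups)
        self.post_times = tuple(post_times)
        G, T = len(self.groups), len(self.post_times)
        if G < 2:
            raise DesignError("need at least 2 groups")
        if T < 1:
            raise DesignError("need at least 1 post time point")

        t = design.table
        mask = t["time_h"].isin(self.post_times) & t["group"].isin(self.groups)
        obs = t[mask]
        self.obs_samples = list(obs.index)
        n = len(self.obs_samples)

        subjects = list(dict.fromkeys(obs["subject_id"]))
        for g in self.groups:
            n_sub = obs[obs["group"] == g]["subject_id"].nunique()
            if n_sub < 2:
                raise DesignError(
                    f"group {g!r} has {n_sub} subject(s) with post samples; need >= 2"
                )
        self.subjects = subjects
        S = len(subjects)
        self.p = G * T

        g_idx = {g: i for i, g in enumerate(self.groups)}
        t_idx = {tp: k for k, tp in enumerate(self.post_times)}
        s_idx = {s: k for k, s in enumerate(subjects)}
        cell = np.array(
            [g_idx[g] * T + t_idx[tp] for g, tp in zip(obs["group"], obs["time_h"])]
        )
        subj = np.array([s_idx[s] for s in obs["subject_id"]])

        X = np.zeros((n, self.p))
        X[np.arange(n), cell] = 1.0
        Z = np.zeros((n, S))
        Z[np.arange(n), subj] = 1.0
        cell_counts = X.sum(axis=0)
        if (cell_counts == 0).any():
            k = int(np.flatnonzero(cell_counts == 0)[0])
            raise DesignError(
                f"empty design cell (group {self.groups[k // T]!r}, "
                f"time {self.post_times[k % T]:g} h)"
            )
        self.X, self.Z = X, Z
        self.U = Z.T @ X              # (S, p) per-subject cell patterns
        self.n_s = Z.sum(axis=0)      # obs per subject
        self.B0 = cell_counts         # diagonal of X'X
        self.n_obs, self.S, self.G, self.T = n, S, G, T

        self.between_df = S - G
        self.within_df = n - np.linalg.matrix_rank(np.hstack([X, Z]))
        self.rows_of_subject = [np.flatnonzero(subj == k) for k in range(S)]

        # ---- omnibus effect contrast matrices (cell order: g*T + t) ----
        def e(g, t_):
            v = np.zeros(self.p)
            v[g * T + t_] = 1.0
            return v

        time_rows = [
            sum(e(g, k) - e(g, 0) for g in range(G)) / G for k in range(1, T)
        ]
        group_rows = [
            sum(e(i, k) - e(0, k) for k in range(T)) / T for i in range(1, G)
        ]
        inter_rows = [
            (e(i, k) - e(i, 0)) - (e(0, k) - e(0, 0))
            for i in range(1, G)
            for k in range(1, T)
        ]
        # interaction with the (implicit, zero) baseline level included: are
        # the groups' changes from Pre equal at every post time?
        inter_pre_rows = [
            e(i, k) - e(0, k) for i in range(1, G) for k in range(T)
        ]
        self.L_effects = {
            "Time": np.array(time_rows).reshape(-1, self.p),
            "Group": np.array(group_rows).reshape(-1, self.p),
            "TimexGroup": np.array(inter_rows).reshape(-1, self.p),
            "TimexGroupVsPre": np.array(inter_pre_rows).reshape(-1, self.p),
        }

        # ---- 1-df contrast vectors ----
        self.contrasts: dict[str, np.ndarray] = {}
        scheme = ContrastScheme(self.groups, self.post_times,
                                make_group_codes(self.groups))
        self.scheme = scheme
        for t_ in self.post_times:
            v = sum(e(g, t_idx[t_]) for g in range(G)) / G
            self.contrasts[scheme.marginal_name(t_)] = v
        for g in self.groups:
            for t_ in self.post_times:
                self.contrasts[scheme.vs_pre_name(g, t_)] = e(g_idx[g], t_idx[t_])
        for a, b in scheme.pairs:
            for t_ in self.post_times:
                v = e(g_idx[a], t_idx[t_]) - e(g_idx[b], t_idx[t_])
                self.contrasts[scheme.pair_name(a, b, t_)] = v


# ---------------------------------------------------------------------------
# REML objective (residual variance profiled out; lambda = s2_subj / s2_resid)
# ---------------------------------------------------------------------------


def _suff_stats(Y: np.ndarray, dm: _DesignMatrices):
    return Y @ dm.X, Y @ dm.Z, np.einsum("ij,ij->i", Y, Y)


def _obj_scalar(lam: float, dm, CellSum, SubjSum, yy) -> np.ndarray:
    """-2 REML log-likelihood (up to a constant) at one shared lambda."""
    c = lam / (1.0 + dm.n_s * lam)                      # (S,)
    A = np.diag(dm.B0) - (dm.U.T * c) @ dm.U            # (p, p)
    r = CellSum - (SubjSum * c) @ dm.U                  # (N, p)
    b = np.linalg.solve(A, r.T).T
    quad = yy - SubjSum**2 @ c - np.einsum("ip,ip->i", r, b)
    quad = np.maximum(quad, 1e-300)
    logdetV = np.log1p(dm.n_s * lam).sum()
    sign, logdetA = np.linalg.slogdet(A)
    nmp = dm.n_obs - dm.p
    return nmp * np.log(quad) + logdetV + logdetA


def _obj_vector(lams: np.ndarray, dm, CellSum, SubjSum, yy) -> np.ndarray:
    """Same objective with one lambda per transcript."""
    c = lams[:, None] / (1.0 + dm.n_s[None, :] * lams[:, None])    # (N, S)
    N = lams.shape[0]
    A = np.zeros((N, dm.p, dm.p))
    A[:, np.arange(dm.p), np.arange(dm.p)] = dm.B0
    A -= np.einsum("is,sp,sq->ipq", c, dm.U, dm.U)
    r = CellSum - (c * SubjSum) @ dm.U
    b = np.linalg.solve(A, r[..., None])[..., 0]
    quad = yy - (c * SubjSum**2).sum(axis=1) - np.einsum("ip,ip->i", r, b)
    quad = np.maximum(quad, 1e-300)
    logdetV = np.log1p(np.outer(lams, dm.n_s)).sum(axis=1)
    logdetA = np.linalg.slogdet(A)[1]
    nmp = dm.n_obs - dm.p
    return nmp * np.log(quad) + logdetV + logdetA


def _reml_gradient(lams: np.ndarray, dm, CellSum, SubjSum, yy) -> np.ndarray:
    """d(-2 REML loglik)/d lambda, one lambda per transcript.

    Uses the closed forms available for a single variance ratio:
    d RSS/d lam = -||Z' P y||^2, d log|V|/d lam = sum n_s/(1+n_s lam),
    d log|X'V^-1 X|/d lam = -sum w_s^2 u_s' A^-1 u_s, with w_s = 1/(1+n_s lam).
    """
    w = 1.0 / (1.0 + dm.n_s[None, :] * lams[:, None])            # (N, S)
    c = lams[:, None] * w
    N = lams.shape[0]
    A = np.zeros((N, dm.p, dm.p))
    A[:, np.arange(dm.p), np.arange(dm.p)] = dm.B0
    A -= np.einsum("is,sp,sq->ipq", c, dm.U, dm.U)
    r = CellSum - (c * SubjSum) @ dm.U
    Ainv = np.linalg.inv(A)
    b = np.einsum("ipq,iq->ip", Ainv, r)
    rss = yy - (c * SubjSum**2).sum(axis=1) - np.einsum("ip,ip->i", r, b)
    rss = np.maximum(rss, 1e-300)
    d = w * (SubjSum - b @ dm.U.T)                               # (N, S) = Z'Py
    quad_u = np.einsum("sp,ipq,sq->is", dm.U, Ainv, dm.U)        # u_s' A^-1 u_s
    nmp = dm.n_obs - dm.p
    return (
        -nmp * (d**2).sum(axis=1) / rss
        + (dm.n_s[None, :] * w).sum(axis=1)
        - (w**2 * quad_u).sum(axis=1)
    )


def _optimize_lambda(dm, CellSum, SubjSum, yy, spec: ModelSpec) -> np.ndarray:
    """Per-transcript REML variance ratio; 0 when the boundary fit wins.

    Coarse log-grid on the profiled objective brackets the optimum; the
    stationarity condition (analytic gradient) is then solved by bisection,
    which is far less noise-limited than comparing near-equal likelihoods.
    """
    psis = np.linspace(-8.0, 8.0, 33)
    fgrid = np.stack(
        [_obj_scalar(10.0**psi, dm, CellSum, SubjSum, yy) for psi in psis]
    )
    f_zero = _obj_scalar(0.0, dm, CellSum, SubjSum, yy)
    best = np.argmin(fgrid, axis=0)
    lo = psis[np.maximum(best - 1, 0)]
    hi = psis[np.minimum(best + 1, len(psis) - 1)]

    def grad(psi_vec):
        return _reml_gradient(10.0**psi_vec, dm, CellSum, SubjSum, yy)

    g_lo, g_hi = grad(lo), grad(hi)
    # no interior sign change: collapse to the boundary the gradient points at
    hi = np.where(g_lo >= 0.0, lo, hi)
    lo = np.where(g_hi <= 0.0, hi, lo)

    tol = min(spec.reml_tol, 1e-14)
    n_iter = min(spec.reml_max_iter, int(np.ceil(np.log2(1.0 / tol))))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        g_mid = grad(mid)
        take_right = g_mid < 0.0
        lo = np.where(take_right, mid, lo)
        hi = np.where(take_right, hi, mid)

    psi_hat = 0.5 * (lo + hi)
    lam = 10.0**psi_hat
    f_hat = _obj_vector(lam, dm, CellSum, SubjSum, yy)
    return np.where(f_zero <= f_hat, 0.0, lam)


# ---------------------------------------------------------------------------
# Final statistics at the fitted lambda
# ---------------------------------------------------------------------------


def _fit_chunk(Y: np.ndarray, dm: _DesignMatrices, spec: ModelSpec) -> dict:
    N, n = Y.shape
    p = dm.p
    CellSum, SubjSum, yy = _suff_stats(Y, dm)
    lam = _optimize_lambda(dm, CellSum, SubjSum, yy, spec)

    c = lam[:, None] / (1.0 + dm.n_s[None, :] * lam[:, None])  # (N, S)
    A = np.zeros((N, p, p))
    A[:, np.arange(p), np.arange(p)] = dm.B0
    A -= np.einsum("is,sp,sq->ipq", c, dm.U, dm.U)
    r = CellSum - (c * SubjSum) @ dm.U
    Ainv = np.linalg.inv(A)
    beta = np.einsum("ipq,iq->ip", Ainv, r)
    quad = yy - (c * SubjSum**2).sum(axis=1) - np.einsum("ip,ip->i", r, beta)
    rss = np.maximum(quad, 0.0)
    nmp = n - p
    sigma2_e = rss / nmp
    sigma2_s = lam * sigma2_e
    ols = lam == 0.0

    # --- REML information pieces for Satterthwaite df (normalized scale) ---
    Vinv = np.zeros((N, n, n))
    for s in range(dm.S):
        rows = dm.rows_of_subject[s]
        Vinv[:, rows[:, None], rows[None, :]] = -c[:, s, None, None]
    Vinv[:, np.arange(n), np.arange(n)] += 1.0

    W = Vinv @ dm.X                                     # (N, n, p) = Vinv X
    P = Vinv - (W @ Ainv) @ W.transpose(0, 2, 1)        # (N, n, n)
    PZ = P @ dm.Z                                       # (N, n, S)
    M = np.einsum("ns,inq->isq", dm.Z, PZ)              # (N, S, S) = Z'PZ
    I11 = 0.5 * np.einsum("isq,isq->i", M, M)
    I12 = 0.5 * np.einsum("ins,ins->i", PZ, PZ)
    I22 = 0.5 * np.einsum("inm,inm->i", P, P)
    det = I11 * I22 - I12**2
    good = det > 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        J11 = np.where(good, I22 / det, np.nan)   # Var(s2_subj) / sigma_e^4
        J12 = np.where(good, -I12 / det, np.nan)
        J22 = np.where(good, I11 / det, np.nan)
    K = np.einsum("ns,inp->isp", dm.Z, W)               # (N, S, p) = Z'Vinv X

    def satt_df(l_vec: np.ndarray) -> np.ndarray:
        """Satterthwaite df for contrast(s) l; l is (p,) or (N, p)."""
        if l_vec.ndim == 1:
            h = np.einsum("ipq,q->ip", Ainv, l_vec)
            g_unit = h @ l_vec
        else:
            h = np.einsum("ipq,iq->ip", Ainv, l_vec)
            g_unit = np.einsum("ip,ip->i", h, l_vec)
        g1 = (np.einsum("isp,ip->is", K, h) ** 2).sum(axis=1)
        g2 = (np.einsum("inp,ip->in", W, h) ** 2).sum(axis=1)
        var_g = g1**2 * J11 + 2.0 * g1 * g2 * J12 + g2**2 * J22
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * g_unit**2 / var_g
        df = np.where(np.isfinite(df) & (df > 0), df, float(nmp))
        df = np.where(ols, float(nmp), df)
        return np.clip(df, 1.0, 1e7)

    out: dict[str, np.ndarray] = {
        "sigma2_subject": sigma2_s,
        "sigma2_resid": sigma2_e,
        "converged": np.ones(N, dtype=bool),
    }

    # --- omnibus effects ---
    containment_df = {
        "Time": float(dm.within_df),
        "Group": float(dm.between_df),
        "TimexGroup": float(dm.within_df),
    }
    for name in EFFECT_NAMES:
        L = dm.L_effects[name]
        q = L.shape[0]
        if q == 0:
            out[f"{name}.F"] = np.full(N, np.nan)
            out[f"{name}.p"] = np.full(N, np.nan)
            continue
        LB = beta @ L.T                                   # (N, q)
        S_L = np.einsum("ap,ipq,bq->iab", L, Ainv, L)     # (N, q, q)
        sol = np.linalg.solve(S_L, LB[..., None])[..., 0]
        quadF = np.einsum("iq,iq->i", LB, sol)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = quadF / (q * sigma2_e)
        if spec.df_method == "satterthwaite" or name == "TimexGroupVsPre":
            # the from-Pre interaction mixes the two variance strata, so
            # containment has no natural df for it
            df2 = _satterthwaite_effect_df(L, S_L, Ainv, satt_df, N, q, nmp, ols)
        else:
            df2 = np.full(N, containment_df[name])
            df2 = np.where(ols, float(nmp), df2)
        with np.errstate(invalid="ignore"):
            pvals = stats.f.sf(F, q, df2)
        zero_sig = sigma2_e == 0.0
        F = np.where(zero_sig, np.where(quadF > 0, np.inf, 0.0), F)
        pvals = np.where(zero_sig, np.where(quadF > 0, 0.0, 1.0), pvals)
        out[f"{name}.F"] = F
        out[f"{name}.p"] = pvals

    # --- 1-df contrasts ---
    for name, l_vec in dm.contrasts.items():
        est = beta @ l_vec
        g_unit = np.einsum("ipq,q,p->i", Ainv, l_vec, l_vec)
        se = np.sqrt(np.maximum(sigma2_e * g_unit, 0.0))
        df = satt_df(l_vec)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = est / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        degenerate = se == 0.0
        pvals = np.where(degenerate, np.where(est == 0.0, 1.0, 0.0), pvals)
        out[f"{name}.est"] = est
        out[f"{name}.se"] = se
        out[f"{name}.p"] = pvals

    # --- convergence / sanity flags ---
    bad = ~np.isfinite(sigma2_e) | ~np.isfinite(beta).all(axis=1)
    if bad.any():
        out["converged"] = ~bad
        for key, arr in out.items():
            if key == "converged":
                continue
            arr = np.asarray(arr, dtype=float)
            arr[bad] = np.nan
            out[key] = arr
    return out


def _satterthwaite_effect_df(L, S_L, Ainv, satt_df, N, q, nmp, ols):
    """Denominator df for a multi-df F via the eigencontrast method."""
    vals, vecs = np.linalg.eigh(S_L)                    # (N, q), (N, q, q)
    E = np.zeros(N)
    for k in range(q):
        l_k = np.einsum("aP,ia->iP", L, vecs[:, :, k])  # (N, p)
        nu = satt_df(l_k)
        contrib = np.where(nu > 2.0, nu / (nu - 2.0), 0.0)
        E += contrib
    with np.errstate(divide="ignore", invalid="ignore"):
        df2 = 2.0 * E / (E - q)
    df2 = np.where(np.isfinite(df2) & (E > q), df2, float(nmp))
    df2 = np.where(ols, float(nmp), df2)
    return np.clip(df2, 1.0, 1e7)


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def _column_order(dm: _DesignMatrices) -> list[str]:
    cols = ["sigma2_subject", "sigma2_resid", "converged"]
    for name in EFFECT_NAMES:
        cols += [f"{name}.F", f"{name}.p"]
    for name in dm.scheme.contrast_names():
        cols += [f"{name}.est", f"{name}.se", f"{name}.p"]
    return cols


def fit_all(ratios, design: StudyDesign, spec: ModelSpec | None = None) -> AnovaResult:
    """Fit the mixed model to every transcript of a Pre-normalized matrix.

    ``ratios`` is a :class:`~exanova.preprocess.RatioMatrix` or an equivalent
    DataFrame (transcripts x samples of log2 ratios).  Rows are fitted
    independently, so the result is invariant to transcript order.  Raises
    when more than ``spec.max_nonconverged_frac`` of transcripts fail.
    """
    if isinstance(ratios, pd.DataFrame):
        frame = ratios
    elif isinstance(getattr(ratios, "values", None), pd.DataFrame):
        frame = ratios.values
    else:
        frame = pd.DataFrame(ratios)
    if spec is None:
        spec = ModelSpec()
    groups = spec.groups or tuple(design.groups)
    post_times = spec.post_times or tuple(design.post_times)
    spec = replace(spec, groups=tuple(groups), post_times=tuple(post_times))
    dm = _DesignMatrices(design, groups, post_times)

    Y_all = frame[dm.obs_samples].to_numpy(dtype=float)
    N = Y_all.shape[0]
    chunks = []
    for start in range(0, N, spec.chunk_size):
        chunk = _fit_chunk(Y_all[start : start + spec.chunk_size], dm, spec)
        chunks.append(chunk)
    merged = {
        key: np.concatenate([c[key] for c in chunks]) if chunks else np.array([])
        for key in (chunks[0] if chunks else {})
    }
    table = pd.DataFrame(merged, index=frame.index)
    if N:
        table = table[_column_order(dm)]
    n_bad = int((~table["converged"]).sum()) if N else 0
    if N and n_bad / N > spec.max_nonconverged_frac:
        raise ExanovaError(
            f"{n_bad}/{N} transcripts failed to converge "
            f"(> {spec.max_nonconverged_frac:.0%})"
        )
    return AnovaResult(table=table, scheme=dm.scheme, spec=spec, n_nonconverged=n_bad)


def read_anova(path, design: StudyDesign, spec: ModelSpec | None = None) -> AnovaResult:
    """Reload a written AnovaTable, rebuilding the contrast scheme from the design."""
    table = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if "converged" in table.columns:
        table["converged"] = table["converged"].astype(bool)
    spec = spec or ModelSpec()
    groups = tuple(spec.groups or design.groups)
    post_times = tuple(spec.post_times or design.post_times)
    scheme = ContrastScheme(groups, post_times, make_group_codes(groups))
    n_bad = int((~table["converged"]).sum()) if "converged" in table.columns else 0
    return AnovaResult(table=table, scheme=scheme, spec=spec, n_nonconverged=n_bad)


def fit_transcript(ratios_row, design: StudyDesign, spec: ModelSpec | None = None) -> pd.Series:
    """Fit one transcript (a Series indexed by sample ID); returns its table row."""
    name = getattr(ratios_row, "name", None) or "transcript"
    frame = pd.DataFrame([ratios_row])
    frame.index = [name]
    result = fit_all(frame, design, spec)
    return result.table.iloc[0]
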