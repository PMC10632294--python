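"""REML variance-component engine for clonally replicated spatial field trials.

Model 1 (no genomic data):

    y = X b + Z_u u + Z_v v + e,     u ~ N(0, sigma_u2 I),  v ~ N(0, sigma_v2 I),
    e ~ N(0, R),   R = sigma_r2 I + sigma_s2 (+)_k  AR1(rho_c) x AR1(rho_r)

with the spatial term block-diagonal over master blocks k, sharing the same
(sigma_s2, rho_c, rho_r) across master blocks, and restricted to observed
plots (fillers and controls carry no phenotype and are simply absent rows).

Model 2 splits the genetic effects of genotyped trees into an additive part,
var(u_2a) = sigma_u2 * r_a * G / k, and a non-additive part,
var(u_2d) = sigma_u2 * (1 - r_a) * I, while ungenotyped trees keep
var(u_1) = sigma_u2 * I.  This parameterization builds in the constraint
sigma_u2 = k sigma_a2 + sigma_d2 exactly, with r_a = k sigma_a2 / sigma_u2
the additive fraction of the within-family total genetic variance.

Fitting maximizes the REML log-likelihood over transformed parameters
(log variances, atanh rho, logit r_a) by average-information Newton steps
with analytic gradients and step-halving, multi-started from jittered
moment-based initial values; a Nelder-Mead fallback covers the rare
non-convergent start.  Standard errors come from the numerically
differentiated observed information at the optimum (delta method back to the
natural scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .grm import GenomicRelationship

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialParams",
    "TrialData",
    "REMLFit",
    "ar1_matrix",
    "residual_covariance",
    "reml_loglik",
    "fit",
    "error_fractions",
    "sample_variogram",
]

_LOG2PI = np.log(2.0 * np.pi)
_TBOUND = 20.0  # bound on transformed variances and logit r_a
_RHO_TBOUND = float(np.arctanh(0.999))  # rho constrained to (-0.999, 0.999)
DENSE_PLOT_WARNING = 6000

_PARAMS_M1 = ("sigma_u2", "sigma_v2", "sigma_r2", "sigma_s2", "rho_c", "rho_r")
_PARAMS_M2 = _PARAMS_M1 + ("r_a",)
_VARIANCES = {"sigma_u2", "sigma_v2", "sigma_r2", "sigma_s2"}


@dataclass(frozen=True)
class SpatialParams:
    """Residual decomposition: nugget, spatial variance and AR1 autocorrelations."""

    sigma_r2: float
    sigma_s2: float
    rho_c: float
    rho_r: float

    def __post_init__(self) -> None:
        if self.sigma_r2 < 0 or self.sigma_s2 < 0:
            raise ValueError("variances must be >= 0")
        if max(abs(self.rho_c), abs(self.rho_r)) >= 1:
            raise ValueError("|rho| must be < 1")

    @property
    def f_r(self) -> float:
        return error_fractions(self)[0]

    @property
    def f_s(self) -> float:
        return error_fractions(self)[1]


def error_fractions(spatial: SpatialParams) -> tuple[float, float]:
    """(f_r, f_s): fractions of random (nugget) and spatial error variance."""
    total = spatial.sigma_r2 + spatial.sigma_s2
    if total <= 0:
        raise ValueError("sigma_r2 + sigma_s2 must be > 0")
    fr = spatial.sigma_r2 / total
    return fr, 1.0 - fr


def ar1_matrix(n: int, rho: float) -> np.ndarray:
    """Dense AR1 correlation matrix: entry (i, j) = rho ** |i - j|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if abs(rho) >= 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def residual_covariance(spatial: SpatialParams, layout: pd.DataFrame) -> np.ndarray:
    """R over observed plots: nugget plus separable AR1 x AR1 per master block.

    ``layout`` needs columns master_block, column, row (one row per observed
    plot, in y order).  All master blocks share the same spatial parameters;
    plots in different master blocks are uncorrelated.
    """
    mb = layout["master_block"].to_numpy()
    col = layout["column"].to_numpy()
    row = layout["row"].to_numpy()
    if pd.DataFrame({"m": mb, "c": col, "r": row}).duplicated().any():
        raise ValueError("duplicate plot coordinates")
    n = len(layout)
    same_mb = mb[:, None] == mb[None, :]
    dc = np.abs(col[:, None] - col[None, :])
    dr = np.abs(row[:, None] - row[None, :])
    s = np.where(same_mb, spatial.rho_c ** dc * spatial.rho_r ** dr, 0.0)
    return spatial.sigma_r2 * np.eye(n) + spatial.sigma_s2 * s


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------


@dataclass
class TrialData:
    """One trial's phenotypes, design structure and (optionally) its G matrix.

    Genotype ids are ordered ungenotyped first, genotyped last (matching the
    rows of ``grm`` when present).  Precomputes the dense structure matrices
    the likelihood reuses on every evaluation.
    """

    y: np.ndarray
    X: np.ndarray
    geno_idx: np.ndarray  # per plot, index into genotype_ids
    genotype_ids: list[str]
    n_ungenotyped: int
    block_idx: np.ndarray
    master_block: np.ndarray
    column: np.ndarray
    row: np.ndarray
    grm: GenomicRelationship | None = None
    # derived, filled in __post_init__
    M0: np.ndarray = field(init=False, repr=False)
    M1: np.ndarray = field(init=False, repr=False)
    B: np.ndarray = field(init=False, repr=False)
    _Dc: np.ndarray = field(init=False, repr=False)
    _Dr: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.y.size
        if n > DENSE_PLOT_WARNING:
            logger.warning("dense REML path with %d observed plots; expect slow fits", n)
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValueError("X must be (n, p)")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X must have full column rank")
        gi = self.geno_idx
        self.M0 = (gi[:, None] == gi[None, :]).astype(float)
        self.B = (self.block_idx[:, None] == self.block_idx[None, :]).astype(float)
        # expand (G/k - I) over plots of genotyped trees, zero elsewhere
        self.M1 = np.zeros((n, n))
        if self.grm is not None:
            a = np.full(len(self.genotype_ids), -1, dtype=int)
            a[self.n_ungenotyped:] = np.arange(len(self.grm.ids))
            gmap = a[gi]
            isg = gmap >= 0
            core = self.grm.matrix / self.grm.k - np.eye(len(self.grm.ids))
            sub = np.ix_(np.flatnonzero(isg), np.flatnonzero(isg))
            self.M1[sub] = core[np.ix_(gmap[isg], gmap[isg])]
        # displacement index tables; cross-master-block pairs point at a
        # sentinel slot whose power-table entry is zero
        same_mb = self.master_block[:, None] == self.master_block[None, :]
        dc = np.abs(self.column[:, None] - self.column[None, :])
        dr = np.abs(self.row[:, None] - self.row[None, :])
        self._max_dc = int(dc.max()) if n else 0
        self._max_dr = int(dr.max()) if n else 0
        self._Dc = np.where(same_mb, dc, self._max_dc + 1).astype(np.int32)
        self._Dr = np.where(same_mb, dr, self._max_dr + 1).astype(np.int32)

    @property
    def n(self) -> int:
        return self.y.size

    @classmethod
    def from_trial_frame(
        cls,
        frame: pd.DataFrame,
        grm: GenomicRelationship | None = None,
        covariate: pd.Series | None = None,
    ) -> "TrialData":
        """Build from a tidy trial frame (filler/missing-phenotype rows dropped).

        ``covariate`` (e.g. mean heterozygosity, indexed by genotype id) is
        mean-centred and appended to the intercept-only fixed design;
        genotypes without a value get 0 (the centred mean).
        """
        obs = frame[frame["value"].notna() & frame["genotype_id"].notna()].reset_index(drop=True)
        if obs.empty:
            raise ValueError("no observed phenotypes in frame")
        gen_ids = list(grm.ids) if grm is not None else []
        ungen = sorted(set(obs["genotype_id"]) - set(gen_ids))
        genotype_ids = ungen + gen_ids
        id_to_idx = {g: i for i, g in enumerate(genotype_ids)}
        missing = set(obs["genotype_id"]) - set(genotype_ids)
        if missing:
            raise ValueError(f"plots reference unknown genotypes: {sorted(missing)[:5]}")
        geno_idx = obs["genotype_id"].map(id_to_idx).to_numpy()
        y = obs["value"].to_numpy(dtype=float)
        X = np.ones((len(obs), 1))
        if covariate is not None:
            c = covariate - covariate.mean()
            X = np.column_stack([X, obs["genotype_id"].map(c).fillna(0.0).to_numpy()])
        return cls(
            y=y,
            X=X,
            geno_idx=geno_idx,
            genotype_ids=genotype_ids,
            n_ungenotyped=len(ungen),
            block_idx=obs["block"].to_numpy(),
            master_block=obs["master_block"].to_numpy(),
            column=obs["column"].to_numpy(),
            row=obs["row"].to_numpy(),
            grm=grm,
        )


@dataclass
class REMLFit:
    """REML estimates, curvature standard errors and convergence diagnostics."""

    model: int
    params: dict
    loglik: float
    se: dict
    converged: bool
    n_iter: int
    theta: np.ndarray
    param_names: tuple
    cov_transformed: np.ndarray | None = None
    fixed_ra: float | None = None
    se_approx: dict = field(default_factory=dict)  # from the final AI matrix

    @property
    def spatial(self) -> SpatialParams:
        p = self.params
        return SpatialParams(p["sigma_r2"], p["sigma_s2"], p["rho_c"], p["rho_r"])

    @property
    def r_a(self) -> float | None:
        return self.params.get("r_a")

    @property
    def implied_constraint(self) -> dict:
        """k*sigma_a2 and sigma_d2 implied by (sigma_u2, r_a); sums to sigma_u2 exactly."""
        ra = self.params.get("r_a")
        if ra is None:
            return {}
        su = self.params["sigma_u2"]
        return {"k_sigma_a2": ra * su, "sigma_d2": (1.0 - ra) * su}


# ---------------------------------------------------------------------------
# likelihood core
# ---------------------------------------------------------------------------


def _transform(values: np.ndarray, names: tuple) -> np.ndarray:
    t = np.empty_like(values, dtype=float)
    for i, nm in enumerate(names):
        v = values[i]
        if nm in _VARIANCES:
            t[i] = np.log(max(v, 1e-12))
        elif nm.startswith("rho"):
            t[i] = np.arctanh(np.clip(v, -0.999, 0.999))
        else:  # r_a
            t[i] = np.log(np.clip(v, 1e-9, 1 - 1e-9) / (1 - np.clip(v, 1e-9, 1 - 1e-9)))
    return _clip_theta(t, names)


def _clip_theta(t: np.ndarray, names: tuple) -> np.ndarray:
    bounds = np.asarray([_RHO_TBOUND if nm.startswith("rho") else _TBOUND for nm in names])
    return np.clip(t, -bounds, bounds)


def _back_transform(theta: np.ndarray, names: tuple) -> tuple[np.ndarray, np.ndarray]:
    """Natural values and the Jacobian diagonal d(natural)/d(theta)."""
    v = np.empty_like(theta)
    j = np.empty_like(theta)
    for i, nm in enumerate(names):
        if nm in _VARIANCES:
            v[i] = np.exp(theta[i])
            j[i] = v[i]
        elif nm.startswith("rho"):
            v[i] = np.tanh(theta[i])
            j[i] = 1.0 - v[i] ** 2
        else:
            s = 1.0 / (1.0 + np.exp(-theta[i]))
            v[i] = s
            j[i] = s * (1.0 - s)
    return v, j


class _REMLCore:
    """Dense REML machinery for one trial: V assembly, log-likelihood, AI gradients."""

    def __init__(self, data: TrialData, model: int, fixed_ra: float | None = None):
        if model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        self.data = data
        self.model = model
        self.fixed_ra = fixed_ra
        names = list(_PARAMS_M2 if model == 2 else _PARAMS_M1)
        if model == 2 and fixed_ra is not None:
            names.remove("r_a")
        self.names = tuple(names)
        self._eye = np.eye(data.n)

    # -- parameter plumbing ------------------------------------------------

    def natural(self, theta: np.ndarray) -> dict:
        v, _ = _back_transform(np.asarray(theta, dtype=float), self.names)
        out = dict(zip(self.names, v))
        if self.model == 2 and self.fixed_ra is not None:
            out["r_a"] = self.fixed_ra
        return out

    def _power_tables(self, rho_c, rho_r, derivative=False):
        d = self.data
        kc = np.arange(d._max_dc + 2, dtype=float)
        kr = np.arange(d._max_dr + 2, dtype=float)
        pc = rho_c ** kc
        pr = rho_r ** kr
        pc[-1] = pr[-1] = 0.0  # sentinel: cross-master-block pairs
        if not derivative:
            return pc, pr
        with np.errstate(divide="ignore", invalid="ignore"):
            dpc = np.where(kc > 0, kc * rho_c ** np.maximum(kc - 1, 0), 0.0)
            dpr = np.where(kr > 0, kr * rho_r ** np.maximum(kr - 1, 0), 0.0)
        dpc[-1] = dpr[-1] = 0.0
        return pc, pr, dpc, dpr

    def build_V(self, p: dict) -> np.ndarray:
        d = self.data
        if self.model == 2:
            ra = p["r_a"]
            V = p["sigma_u2"] * d.M0 + (p["sigma_u2"] * ra) * d.M1
        else:
            V = p["sigma_u2"] * d.M0.copy()
        V += p["sigma_v2"] * d.B
        if p["sigma_s2"] > 0:
            pc, pr = self._power_tables(p["rho_c"], p["rho_r"])
            V += p["sigma_s2"] * (pc[d._Dc] * pr[d._Dr])
        V[np.diag_indices_from(V)] += p["sigma_r2"]
        return V

    # -- likelihood ---------------------------------------------------------

    def loglik(self, p: dict, method: str = "cholesky") -> float:
        d = self.data
        V = self.build_V(p)
        n, q = d.n, d.X.shape[1]
        if method == "eigh":
            w, Q = np.linalg.eigh(V)
            if w.min() <= 0:
                return -np.inf
            logdet = float(np.log(w).sum())
            Vi_y = Q @ ((Q.T @ d.y) / w)
            Vi_X = Q @ ((Q.T @ d.X) / w[:, None])
        elif method == "cholesky":
            try:
                c = cho_factor(V, lower=True, check_finite=False)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet = 2.0 * float(np.log(np.diag(c[0])).sum())
            Vi_y = cho_solve(c, d.y, check_finite=False)
            Vi_X = cho_solve(c, d.X, check_finite=False)
        else:
            raise ValueError(f"unknown method {method!r}")
        XtViX = d.X.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtViX, d.X.T @ Vi_y)
        yPy = float(d.y @ Vi_y - (d.X.T @ Vi_y) @ beta)
        return -0.5 * (logdet + logdet_x + yPy + (n - q) * _LOG2PI)

    def loglik_grad_ai(self, theta: np.ndarray):
        """(loglik, gradient, average-information matrix) on the transformed scale.

        Gradients and AI terms are assembled from traces and quadratic forms
        against the base structure matrices (M0, M1, B, I, S, dS/drho), scaled
        by the chain-rule coefficients, so no scaled derivative matrix is ever
        materialized.
        """
        from scipy.linalg.lapack import dpotrf, dpotri

        d = self.data
        _, jac = _back_transform(theta, self.names)
        p = self.natural(theta)
        V = self.build_V(p)
        n, q = d.n, d.X.shape[1]
        cfac, info = dpotrf(V, lower=1, overwrite_a=1)
        if info != 0:
            return -np.inf, None, None
        logdet = 2.0 * float(np.log(np.diag(cfac)).sum())
        Vi, info = dpotri(cfac, lower=1, overwrite_c=1)
        if info != 0:
            return -np.inf, None, None
        Vi = np.tril(Vi) + np.tril(Vi, -1).T
        Vi_X = Vi @ d.X
        XtViX = d.X.T @ Vi_X
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf, None, None
        C = np.linalg.inv(XtViX)
        P = Vi - Vi_X @ C @ Vi_X.T
        Py = P @ d.y
        yPy = float(d.y @ Py)
        ll = -0.5 * (logdet + logdet_x + yPy + (n - q) * _LOG2PI)

        pc, pr, dpc, dpr = self._power_tables(p["rho_c"], p["rho_r"], derivative=True)
        S = pc[d._Dc] * pr[d._Dr]
        dSc = dpc[d._Dc] * pr[d._Dr]
        dSr = pc[d._Dc] * dpr[d._Dr]
        bases = {"M0": d.M0, "B": d.B, "S": S, "dSc": dSc, "dSr": dSr}
        if self.model == 2:
            bases["M1"] = d.M1
        tr = {nm: float(np.sum(P * m)) for nm, m in bases.items()}
        tr["I"] = float(np.trace(P))
        tv = {nm: m @ Py for nm, m in bases.items()}
        tv["I"] = Py
        # per-parameter V-derivatives as scalar combinations of the bases
        combos = {
            "sigma_u2": [("M0", 1.0)] + ([("M1", p["r_a"])] if self.model == 2 else []),
            "sigma_v2": [("B", 1.0)],
            "sigma_r2": [("I", 1.0)],
            "sigma_s2": [("S", 1.0)],
            "rho_c": [("dSc", p["sigma_s2"])],
            "rho_r": [("dSr", p["sigma_s2"])],
            "r_a": [("M1", p["sigma_u2"])],
        }
        k = len(self.names)
        grad = np.empty(k)
        t_vecs = np.empty((k, n))
        for i, nm in enumerate(self.names):
            tr_i = sum(c * tr[b] for b, c in combos[nm])
            t_vecs[i] = sum(c * tv[b] for b, c in combos[nm])
            grad[i] = -0.5 * (tr_i - float(Py @ t_vecs[i]))
        s_vecs = t_vecs @ P  # (k, n): each row P @ t_i (P symmetric)
        ai = 0.5 * (t_vecs @ s_vecs.T)
        ai = (ai + ai.T) / 2.0
        return ll, grad * jac, ai * np.outer(jac, jac)


def reml_loglik(params: dict, data: TrialData, model: int = 1, method: str = "cholesky") -> float:
    """REML log-likelihood at the given natural-scale parameters.

    Fixed effects are profiled out; the constant -(n - p)/2 * log(2*pi) is
    included.  A non-positive-definite V returns -inf (logged), never raises.
    ``method`` selects the Cholesky or the eigendecomposition evaluation path.
    """
    core = _REMLCore(data, model)
    p = dict(params)
    if model == 2 and "r_a" not in p:
        raise ValueError("model 2 requires r_a")
    ll = core.loglik(p, method=method)
    if not np.isfinite(ll):
        logger.info("non-positive-definite V at %s", p)
    return ll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _moment_init(data: TrialData, model: int) -> dict:
    vy = float(np.var(data.y))
    init = {
        "sigma_u2": 0.3 * vy,
        "sigma_v2": 0.05 * vy,
        "sigma_r2": 0.4 * vy,
        "sigma_s2": 0.25 * vy,
        "rho_c": 0.5,
        "rho_r": 0.5,
    }
    if model == 2:
        init["r_a"] = 0.5
    return init


def _newton(core: _REMLCore, theta0: np.ndarray, max_iter: int, gtol: float, ftol: float):
    bounds = np.asarray([_RHO_TBOUND if nm.startswith("rho") else _TBOUND for nm in core.names])
    theta = _clip_theta(theta0.copy(), core.names)
    ll, g, ai = core.loglik_grad_ai(theta)
    if not np.isfinite(ll):
        return theta, -np.inf, False, 0, None
    it = 0
    for it in range(1, max_iter + 1):
        ridge = 1e-8 * max(np.trace(ai) / len(theta), 1.0)
        for _ in range(8):
            try:
                step = np.linalg.solve(ai + ridge * np.eye(len(theta)), g)
                break
            except np.linalg.LinAlgError:
                ridge *= 100
        else:
            step = g
        norm = np.linalg.norm(step)
        if norm > 5.0:  # trust region on the transformed scale
            step *= 5.0 / norm
        alpha, improved = 1.0, False
        for _ in range(12):
            cand = _clip_theta(theta + alpha * step, core.names)
            ll_new = core.loglik(core.natural(cand))  # cheap probe, no gradient
            if np.isfinite(ll_new) and ll_new > ll - 1e-12:
                improved = True
                break
            alpha /= 2.0
        if not improved:
            # stalled line search: converged if the (bound-masked) gradient is flat
            active = (np.abs(theta) >= bounds - 1e-9) & (np.sign(g) == np.sign(theta))
            flat = np.max(np.abs(np.where(active, 0.0, g))) < 10 * gtol
            return theta, ll, bool(flat), it, ai
        ll_new, g_new, ai_new = core.loglik_grad_ai(cand)
        if not np.isfinite(ll_new):
            return theta, ll, False, it, ai
        dll = ll_new - ll
        theta, ll, g, ai = cand, ll_new, g_new, ai_new
        # at a clipped bound the coordinate is at its boundary; ignore its gradient
        active = (np.abs(theta) >= bounds - 1e-9) & (np.sign(g) == np.sign(theta))
        if np.max(np.abs(np.where(active, 0.0, g))) < gtol or (0 <= dll < ftol):
            return theta, ll, True, it, ai
    return theta, ll, False, it, ai


def fit(
    data: TrialData,
    model: int = 2,
    init: dict | None = None,
    fixed_ra: float | None = None,
    n_starts: int = 3,
    optimizer_seed: int = 0,
    max_iter: int = 100,
    gtol: float = 1e-5,
    ftol: float = 1e-10,
    compute_se: bool = True,
    fallback: bool = True,
) -> REMLFit:
    """Maximize the REML log-likelihood; returns estimates and curvature s.e.s.

    ``fixed_ra`` holds the additive fraction constant (used by likelihood
    profiling).  ``n_starts`` jittered restarts guard against local optima;
    a stalled Newton run falls back to Nelder-Mead (disable with
    ``fallback=False`` for speed); residual non-convergence is flagged on
    the returned fit, never silently ignored.  ``se_approx`` (from the final
    average-information matrix) is always available; ``compute_se`` adds the
    observed-information s.e.s.
    """
    core = _REMLCore(data, model, fixed_ra=fixed_ra)
    init_nat = _moment_init(data, model)
    if init:
        init_nat.update(init)
    theta0 = _transform(np.asarray([init_nat[nm] for nm in core.names]), core.names)

    rng = np.random.default_rng(optimizer_seed)
    best = (None, -np.inf, False, 0, None)
    for s in range(max(n_starts, 1)):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.5, size=theta0.size)
        theta, ll, conv, it, ai = _newton(core, start, max_iter, gtol, ftol)
        if not conv and fallback:  # derivative-free fallback from where Newton stalled
            res = optimize.minimize(
                lambda t: -core.loglik(core.natural(t)),
                theta,
                method="Nelder-Mead",
                options={"maxiter": 150 * len(theta), "xatol": 1e-6, "fatol": 1e-9},
            )
            if -res.fun > ll:
                theta2, ll2, conv, it2, ai2 = _newton(core, res.x, 20, gtol, ftol)
                if ll2 >= -res.fun:
                    theta, ll, ai = theta2, ll2, ai2
                else:
                    theta, ll = res.x, -res.fun
                it += it2
        if ll > best[1]:
            best = (theta, ll, conv, it, ai)
        if conv and s == 0 and n_starts == 1:
            break
    theta, ll, conv, n_iter, ai = best
    if theta is None:
        raise RuntimeError("REML optimization failed from every start")
    if not conv:
        logger.warning("REML fit flagged non-convergent (best logL %.6f kept)", ll)

    params = core.natural(theta)
    if model == 2:
        params["r_d"] = 1.0 - params["r_a"]
    se_approx = {}
    if ai is not None:
        try:
            cov_ai = np.linalg.inv(ai)
            if np.all(np.diag(cov_ai) > 0):
                _, jac = _back_transform(theta, core.names)
                sd = np.sqrt(np.diag(cov_ai)) * jac
                se_approx = dict(zip(core.names, map(float, sd)))
        except np.linalg.LinAlgError:
            pass
    se, cov_t = ({}, None)
    if compute_se:
        se, cov_t = _curvature_se(core, theta)
        if model == 2 and fixed_ra is None and "r_a" in se:
            se["r_d"] = se["r_a"]
    return REMLFit(
        model=model,
        params=params,
        loglik=ll,
        se=se,
        converged=conv,
        n_iter=n_iter,
        theta=theta,
        param_names=core.names,
        cov_transformed=cov_t,
        fixed_ra=fixed_ra,
        se_approx=se_approx,
    )


def _curvature_se(core: _REMLCore, theta: np.ndarray, h: float = 1e-4):
    """Observed-information s.e.s: central differences of the analytic gradient."""
    k = theta.size
    H = np.zeros((k, k))
    ok = True
    for i in range(k):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp, _ = core.loglik_grad_ai(tp)
        _, gm, _ = core.loglik_grad_ai(tm)
        if gp is None or gm is None:
            ok = False
            break
        H[i] = (gp - gm) / (2 * h)
    se = {}
    cov = None
    if ok:
        H = (H + H.T) / 2.0
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = None
    if cov is not None and np.all(np.diag(cov) > 0):
        _, jac = _back_transform(theta, core.names)
        sd_t = np.sqrt(np.diag(cov))
        for i, nm in enumerate(core.names):
            se[nm] = float(sd_t[i] * jac[i])  # delta method
    else:
        se = {nm: np.nan for nm in core.names}
    return se, cov


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def sample_variogram(residuals: np.ndarray, layout: pd.DataFrame, max_lag: int | None = None) -> pd.DataFrame:
    """Residual semi-variance by (column, row) displacement within master blocks.

    gamma(dc, dr) is half the mean squared difference of residuals over all
    within-master-block plot pairs at that absolute displacement.  For an
    AR1 x AR1 + nugget residual the variogram rises to sigma_r2 + sigma_s2 at
    large displacement, with the discontinuity at zero equal to the nugget.
    """
    r = np.asarray(residuals, dtype=float)
    frames = []
    for mb, sub in layout.assign(_resid=r).groupby("master_block"):
        cols = sub["column"].to_numpy()
        rows = sub["row"].to_numpy()
        z = np.full((cols.max() + 1, rows.max() + 1), np.nan)
        z[cols, rows] = sub["_resid"].to_numpy()
        mc = min(max_lag or z.shape[0] - 1, z.shape[0] - 1)
        mr = min(max_lag or z.shape[1] - 1, z.shape[1] - 1)
        recs = []
        for dc in range(mc + 1):
            for dr in range(mr + 1):
                if dc == 0 and dr == 0:
                    continue
                a = z[: z.shape[0] - dc, : z.shape[1] - dr]
                b = z[dc:, dr:]
                d2 = (a - b) ** 2
                valid = np.isfinite(d2)
                if valid.sum() == 0:
                    continue
                recs.append((mb, dc, dr, 0.5 * float(d2[valid].mean()), int(valid.sum())))
        frames.append(pd.DataFrame(recs, columns=["master_block", "dcol", "drow", "gamma", "n_pairs"]))
    out = pd.concat(frames, ignore_index=True)
    agg = (
        out.assign(w=out["gamma"] * out["n_pairs"])
        .groupby(["dcol", "drow"], as_index=False)
        .agg(n_pairs=("n_pairs", "sum"), w=("w", "sum"))
    )
    agg["gamma"] = agg["w"] / agg["n_pairs"]
    return agg.drop(columns="w")
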