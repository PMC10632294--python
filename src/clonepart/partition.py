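"""Inference on the additive fraction of within-family genetic variance.

The additive fraction r_a (equal to the full-sib fraction f_a in a pure
full-sib family) is profiled by re-maximizing all nuisance variance
parameters at fixed r_a over a grid in [0, 1]; the 95% confidence interval is
the set where the deviance drop stays below 3.84 (the 95% point of chi^2_1).
Profiles from several families/sites are pooled by summing deviances;
scalar estimates are pooled by inverse-variance weighting.

A family that is secretly a q : (1-q) mixture of two maternal half-sib
families contains extra between-subfamily variance, so its within-mixture
fractions must be rescaled to full-sib terms; the correction coefficients are
derived from the expected additive/dominance variance shares (FS additive
relationship 1/2, HS 1/4; FS dominance relationship 1/4, HS 0).  Within-family
fractions convert to random-mating-population fractions as 3 f / (2 + f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .varcomp import REMLFit, TrialData, fit as reml_fit

logger = logging.getLogger(__name__)

__all__ = [
    "LikelihoodProfile",
    "PooledEstimate",
    "MixtureCorrectionCoeffs",
    "profile_additive_fraction",
    "ci95_from_profile",
    "pool_profiles",
    "pool_by_inverse_variance",
    "heritabilities",
    "mixture_correction_coefficients",
    "random_mating_conversion",
]

CHI2_95_1DF = 3.84


@dataclass
class LikelihoodProfile:
    """Deviance D(r_a) = -2 (logL(r_a) - max logL), normalized so min D = 0."""

    grid: np.ndarray
    deviance: np.ndarray
    label: dict = field(default_factory=dict)
    flagged: np.ndarray | None = None  # grid points whose inner fit did not converge

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.deviance = np.asarray(self.deviance, dtype=float)
        order = np.argsort(self.grid)
        self.grid = self.grid[order]
        self.deviance = self.deviance[order]
        if self.flagged is not None:
            self.flagged = np.asarray(self.flagged, dtype=bool)[order]
        self.deviance = self.deviance - self.deviance.min()

    @property
    def argmin(self) -> float:
        return float(self.grid[int(np.argmin(self.deviance))])

    def interpolator(self):
        """Monotone-cubic interpolant, clamped to the profile's grid range."""
        f = PchipInterpolator(self.grid, self.deviance)
        lo, hi = self.grid[0], self.grid[-1]
        return lambda x: f(np.clip(x, lo, hi))


@dataclass
class PooledEstimate:
    """Consensus estimate from summed profiles, with heterogeneity statistics."""

    estimate: float
    ci: tuple[float, float]
    profile: LikelihoodProfile
    x2: float
    df: int
    p_value: float
    n_profiles: int

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.estimate <= hi):
            raise ValueError("CI must contain the consensus estimate")


def profile_additive_fraction(
    data: TrialData,
    base_fit: REMLFit | None = None,
    grid: np.ndarray | None = None,
    n_coarse: int = 21,
    n_refine: int = 10,
    label: dict | None = None,
    **fit_kwargs,
) -> LikelihoodProfile:
    """Profile the REML log-likelihood over r_a in [0, 1].

    At each grid point all other variance parameters are re-maximized,
    warm-started from the nearest already-fitted point.  The default grid is
    ``n_coarse`` equispaced points plus ``n_refine`` points packed within two
    coarse steps of the running minimum (densest near the optimum); pass
    ``grid`` to override entirely.  Non-convergent points are flagged and
    their deviance interpolated from the neighbours.
    """
    fit_kwargs.setdefault("n_starts", 1)
    fit_kwargs.setdefault("compute_se", False)
    if base_fit is None:
        base_fit = reml_fit(data, model=2, **fit_kwargs)
    ll_max = base_fit.loglik
    ra_hat = base_fit.params["r_a"]

    if grid is None:
        coarse = np.linspace(0.0, 1.0, n_coarse)
        step = coarse[1] - coarse[0]
        lo = max(0.0, ra_hat - 2 * step)
        hi = min(1.0, ra_hat + 2 * step)
        points = np.unique(np.round(np.concatenate([coarse, np.linspace(lo, hi, n_refine + 2), [ra_hat]]), 10))
    else:
        points = np.unique(np.asarray(grid, dtype=float))
    if points.min() < 0 or points.max() > 1:
        raise ValueError("profile grid must lie in [0, 1]")

    # evaluate outward from the unconstrained optimum so warm starts stay close
    order = np.argsort(np.abs(points - ra_hat))
    ll = np.full(points.size, np.nan)
    flagged = np.zeros(points.size, dtype=bool)
    warm: dict[float, dict] = {ra_hat: dict(base_fit.params)}
    for idx in order:
        ra = points[idx]
        nearest = min(warm, key=lambda v: abs(v - ra))
        init = {k: v for k, v in warm[nearest].items() if k not in ("r_a", "r_d")}
        f = reml_fit(data, model=2, fixed_ra=float(ra), init=init, **fit_kwargs)
        ll[idx] = f.loglik
        flagged[idx] = not f.converged
        if f.converged:
            warm[ra] = dict(f.params)
    ll_max = max(ll_max, np.nanmax(ll))
    dev = -2.0 * (ll - ll_max)
    if flagged.any():
        good = ~flagged & np.isfinite(dev)
        if good.any():
            logger.warning("interpolating over %d non-convergent profile points", int(flagged.sum()))
            dev[flagged] = np.interp(points[flagged], points[good], dev[good])
        else:
            logger.warning("no profile point converged; using best-found deviances")
    return LikelihoodProfile(grid=points, deviance=dev, label=label or {}, flagged=flagged)


def _crossings(grid: np.ndarray, dev: np.ndarray, threshold: float) -> list[tuple[float, float]]:
    below = dev < threshold
    intervals = []
    i = 0
    n = grid.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            lo = grid[i]
            if i > 0:  # linear interpolation to the crossing
                lo = grid[i - 1] + (grid[i] - grid[i - 1]) * (dev[i - 1] - threshold) / (dev[i - 1] - dev[i])
            hi = grid[j]
            if j + 1 < n:
                hi = grid[j] + (grid[j + 1] - grid[j]) * (threshold - dev[j]) / (dev[j + 1] - dev[j])
            intervals.append((float(lo), float(hi)))
            i = j + 1
        else:
            i += 1
    return intervals


def ci95_from_profile(profile: LikelihoodProfile, threshold: float = CHI2_95_1DF) -> tuple[float, float]:
    """95% CI: the set where the deviance stays below 3.84, by interpolation.

    An endpoint sits at 0 or 1 when the deviance never crosses the threshold
    on that side (the estimate may be at the boundary).  A non-unimodal
    profile returns the widest enclosing interval with a warning.
    """
    intervals = _crossings(profile.grid, profile.deviance, threshold)
    if not intervals:
        # numerical corner: minimum exactly at threshold; fall back to argmin
        return (profile.argmin, profile.argmin)
    if len(intervals) > 1:
        logger.warning("multimodal profile: returning the widest enclosing interval")
        return (intervals[0][0], intervals[-1][1])
    return intervals[0]


def pool_profiles(profiles: list[LikelihoodProfile], grid_n: int = 201) -> PooledEstimate:
    """Pool deviance profiles by summation on a common grid.

    Each profile is re-interpolated (monotone cubic, no overshoot) onto a
    common ``grid_n``-point grid on [0, 1]; the summed deviance is
    re-normalized to minimum 0, the consensus is its argmin, the CI uses the
    3.84 rule on the pooled curve, and heterogeneity is X^2 = sum of the
    individual deviances at the consensus with (n_profiles - 1) df.
    """
    if not profiles:
        raise ValueError("no profiles to pool")
    grid = np.linspace(0.0, 1.0, grid_n)
    interps = [p.interpolator() for p in profiles]
    stacked = np.vstack([np.maximum(f(grid), 0.0) for f in interps])
    total = stacked.sum(axis=0)
    total -= total.min()
    pooled = LikelihoodProfile(grid=grid, deviance=total, label={"pooled_from": len(profiles)})
    consensus = pooled.argmin
    ci = ci95_from_profile(pooled)
    if len(profiles) == 1:
        x2, df = 0.0, 0
    else:
        x2 = float(sum(max(float(f(consensus)), 0.0) for f in interps))
        df = len(profiles) - 1
    p_value = float(stats.chi2.sf(x2, df)) if df > 0 else 1.0
    return PooledEstimate(
        estimate=consensus, ci=ci, profile=pooled, x2=x2, df=df, p_value=p_value, n_profiles=len(profiles)
    )


def pool_by_inverse_variance(estimates, ses) -> tuple[float, float]:
    """Weighted mean with weights 1 / se^2; pooled se = sqrt(1 / sum of weights)."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape or est.size == 0:
        raise ValueError("estimates and ses must be equal-length and non-empty")
    if (se <= 0).any():
        raise ValueError("standard errors must be > 0")
    w = 1.0 / se**2
    return float((w * est).sum() / w.sum()), float(np.sqrt(1.0 / w.sum()))


def heritabilities(fit, f_a: float) -> tuple[float, float, float]:
    """(sigma_P2, H2, h2) from fitted variance components and the additive fraction.

    sigma_P2 = sigma_u2 + sigma_v2 + sigma_r2 + sigma_s2 estimates the
    phenotypic variance; H2 = sigma_u2 / sigma_P2 is the broad-sense and
    h2 = f_a * H2 the narrow-sense heritability.  ``fit`` may be a REMLFit or
    a dict of the four components.
    """
    p = fit.params if isinstance(fit, REMLFit) else dict(fit)
    sigma_p2 = p["sigma_u2"] + p["sigma_v2"] + p["sigma_r2"] + p["sigma_s2"]
    if sigma_p2 <= 0:
        raise ValueError("phenotypic variance must be > 0")
    h2_broad = p["sigma_u2"] / sigma_p2
    return float(sigma_p2), float(h2_broad), float(f_a * h2_broad)


@dataclass(frozen=True)
class MixtureCorrectionCoeffs:
    """Rescaling of within-mixture fractions to full-sib terms.

    f_a = a1 * r_a / (3 - a2 * r_a) and f_d = d1 * r_d / (2 + d2 * r_d),
    with coefficients derived from the within-family variance shares
    c_A (additive) and c_D (dominance-type) of the q : (1-q) maternal
    half-sib mixture.  At q = 1 the corrections are the identity.
    """

    q: float
    c_a: float
    c_d: float
    a1: float
    a2: float
    d1: float
    d2: float

    def correct_fa(self, r_a: float) -> float:
        return self.a1 * r_a / (3.0 - self.a2 * r_a)

    def correct_fd(self, r_d: float) -> float:
        return self.d1 * r_d / (2.0 + self.d2 * r_d)

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float, float]:
        return tuple(round(c, ndigits) for c in (self.a1, self.a2, self.d1, self.d2))


def mixture_correction_coefficients(q: float) -> MixtureCorrectionCoeffs:
    """Correction coefficients for a q : (1-q) maternal half-sib mixture.

    Within a full-sib family the additive variance is half, and the
    dominance-type variance three quarters, of the population value.  Mixing
    two half-sib families (common mother, unrelated sires) adds between-
    subfamily variance q(1-q)/2 of the population value for each component
    (half-sib additive relationship 1/4, dominance relationship 0), so the
    within-full-sib shares of the mixture variances are

        c_A = 0.5 / (0.5 + q(1-q)/2),   c_D = 0.75 / (0.75 + q(1-q)/2).

    Solving f_a/(1-f_a) = (c_A/c_D) * r_a/(1-r_a) gives
    f_a = c_A r_a / (c_D - (c_D - c_A) r_a) and the mirror form for f_d;
    both are rescaled so the denominator constants are 3 and 2.
    """
    if not (0.5 < q <= 1.0):
        raise ValueError("q must lie in (0.5, 1]")
    b = q * (1.0 - q) / 2.0  # between-subfamily share of the population variance
    c_a = 0.5 / (0.5 + b)
    c_d = 0.75 / (0.75 + b)
    a1 = 3.0 * c_a / c_d
    a2 = 3.0 * (c_d - c_a) / c_d
    d1 = 2.0 * c_d / c_a
    d2 = 2.0 * (c_d - c_a) / c_a
    return MixtureCorrectionCoeffs(q=q, c_a=c_a, c_d=c_d, a1=a1, a2=a2, d1=d1, d2=d2)


def random_mating_conversion(f_a_within: float) -> float:
    """Convert a within-full-sib-family additive fraction to random-mating terms.

    Half of the additive variance but three quarters of the dominance and
    additive-by-additive variance segregates within families, so a
    within-family fraction f corresponds to 3 f / (2 + f) in a random-mating
    population (assuming the non-additive variance is of those kinds).
    """
    f = float(f_a_within)
    if not (0.0 <= f <= 1.0):
        raise ValueError("f_a must lie in [0, 1]")
    return 3.0 * f / (2.0 + f)
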