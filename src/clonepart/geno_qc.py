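"""Within-family genotype quality control.

Sequential call-rate/MAF filters, Mendelian-consistency screening against the
known parents, opposing-homozygote profiling per offspring, detection of a
hidden paternity mixture (a "full-sib" family that is really two maternal
half-sib families), and call-rate CDF summaries of probabilistic genotypes.

Within a full-sib cross the segregating SNPs have expected offspring allele
frequencies of 0.25, 0.5 or 0.75, so an observed MAF below 0.15 is a strong
signal of a genotyping artefact; the default thresholds reflect that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "QCThresholds",
    "MendelReport",
    "MixtureCall",
    "sequential_qc",
    "expected_offspring_distribution",
    "mendel_chi2_screen",
    "opposing_homozygote_profile",
    "detect_paternity_mixture",
    "mixture_fraction_from_counts",
    "callrate_cdf",
    "individual_heterozygosity",
]


def individual_heterozygosity(genotypes: GenotypeMatrix) -> pd.Series:
    """Mean heterozygosity per individual over its non-missing calls.

    Used as an optional fixed covariate in the mixed model (a -1 x inbreeding-
    depression proxy); mean-centring happens where the design matrix is built.
    """
    obs = genotypes.calls != MISSING
    with np.errstate(invalid="ignore"):
        het = ((genotypes.calls == 1) & obs).sum(axis=1) / obs.sum(axis=1)
    return pd.Series(het, index=genotypes.ids, name="heterozygosity")


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; "less than" comparisons are strict, equality is retained."""

    min_ind_callrate: float = 0.6
    min_snp_callrate: float = 0.8
    min_maf: float = 0.15
    alpha: float = 0.05  # Bonferroni-corrected over tested SNPs in the Mendel screen

    def __post_init__(self) -> None:
        for v in (self.min_ind_callrate, self.min_snp_callrate, self.min_maf, self.alpha):
            if not (0.0 <= v <= 1.0):
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class MendelReport:
    """Per-SNP Mendelian test results and per-offspring opposing-homozygote profile."""

    table: pd.DataFrame  # snp_id, expected p0/p1/p2, observed n0/n1/n2, chi2, pvalue, removed, note
    removed_snps: list[str] = field(default_factory=list)
    offspring_rates: pd.DataFrame | None = None


@dataclass
class MixtureCall:
    """Verdict on hidden family structure from opposing-homozygote rates."""

    verdict: str  # "mixture" | "no mixture" | "ambiguous"
    assignment: pd.Series  # offspring -> "A" (compatible majority) or "B" (flagged)
    fraction_a: float
    se: float
    n_flagged: int
    n_total: int
    evidence: dict


def sequential_qc(genotypes: GenotypeMatrix, thresholds: QCThresholds = QCThresholds()):
    """Filter individuals on call rate, then SNPs on call rate and MAF.

    Individuals with call rate < ``min_ind_callrate`` are removed first; SNP
    call rates and MAFs are then computed from the retained individuals only.
    Returns the filtered matrix and a removal log (one row per removed item).
    """
    if genotypes.n_ind == 0 or genotypes.n_snp == 0:
        raise ValueError("empty genotype matrix")
    log = []
    ind_cr = genotypes.ind_call_rate()
    keep_ind = ind_cr >= thresholds.min_ind_callrate
    for i in np.flatnonzero(~keep_ind):
        log.append((genotypes.ids[i], "individual", "call_rate", ind_cr[i]))
    gm = genotypes.subset(ind_idx=np.flatnonzero(keep_ind))
    if gm.n_ind == 0:
        raise ValueError("all individuals removed by call-rate filter")

    snp_cr = gm.snp_call_rate()
    maf = gm.maf()
    low_cr = snp_cr < thresholds.min_snp_callrate
    low_maf = np.nan_to_num(maf, nan=0.0) < thresholds.min_maf
    for j in np.flatnonzero(low_cr):
        log.append((gm.snp_ids[j], "snp", "call_rate", snp_cr[j]))
    for j in np.flatnonzero(low_maf & ~low_cr):
        log.append((gm.snp_ids[j], "snp", "maf", maf[j]))
    gm = gm.subset(snp_idx=np.flatnonzero(~(low_cr | low_maf)))
    if gm.n_snp == 0:
        raise ValueError("all SNPs removed by call-rate/MAF filters")
    removal_log = pd.DataFrame(log, columns=["id", "kind", "reason", "value"])
    return gm, removal_log


def expected_offspring_distribution(parent_genotypes) -> np.ndarray:
    """Mendelian offspring genotype distribution over {0, 1, 2} for one SNP.

    ``parent_genotypes`` is a pair of alt-allele counts in {0, 1, 2};
    a missing parent raises ValueError (callers flag and skip such SNPs).
    """
    pa, pb = parent_genotypes
    if pa == MISSING or pb == MISSING or pa is None or pb is None:
        raise ValueError("missing parent genotype")
    ta, tb = pa / 2.0, pb / 2.0  # transmission probability of the alt allele
    return np.asarray(
        [(1 - ta) * (1 - tb), ta * (1 - tb) + (1 - ta) * tb, ta * tb]
    )


def _pooled_chi2(observed: np.ndarray, expected_p: np.ndarray):
    """Chi-square with cells of expected count < 1 pooled into the nearest class."""
    n = observed.sum()
    exp = expected_p * n
    obs = observed.astype(float).copy()
    order = np.argsort(exp)
    for j in order:
        if 0 < exp[j] < 1.0:
            # pool into the nearest class (by genotype) with expected >= 1
            others = [k for k in range(3) if k != j and exp[k] >= 1.0]
            if not others:
                continue
            k = min(others, key=lambda k: abs(k - j))
            exp[k] += exp[j]
            obs[k] += obs[j]
            exp[j] = obs[j] = 0.0
    live = exp > 0
    df = int(live.sum()) - 1
    if df < 1:
        return np.nan, np.nan, 0
    chi2 = float(((obs[live] - exp[live]) ** 2 / exp[live]).sum())
    return chi2, float(stats.chi2.sf(chi2, df)), df


def mendel_chi2_screen(
    genotypes: GenotypeMatrix,
    parents: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> MendelReport:
    """Screen SNPs whose offspring genotype counts contradict the parental cross.

    For each SNP the observed non-missing offspring genotype counts are tested
    against the Mendelian expectation given the two parental genotypes; a SNP
    is removed iff its chi-square p-value is below ``alpha / M`` where M is the
    number of SNPs actually tested (Bonferroni).  SNPs with a missing parent or
    a degenerate (single-class) expectation are skipped and logged.  Expected
    cells below 1 are pooled into the nearest genotype class; structural zeros
    (genotypes impossible under the cross) are excluded from the chi-square -
    calls landing there are the opposing-homozygote screen's business.
    """
    mother, father = parents["mother"], parents["father"]
    rows = []
    tested = []
    for j, snp in enumerate(genotypes.snp_ids):
        col = genotypes.calls[:, j]
        counts = np.asarray([(col == g).sum() for g in (0, 1, 2)])
        note = ""
        if mother[j] == MISSING or father[j] == MISSING:
            note = "missing parent"
            exp = np.full(3, np.nan)
            chi2 = pval = np.nan
        else:
            exp = expected_offspring_distribution((mother[j], father[j]))
            if (exp > 0).sum() < 2:
                note = "degenerate cross"
                chi2 = pval = np.nan
            elif counts.sum() == 0:
                note = "no observed offspring calls"
                chi2 = pval = np.nan
            else:
                chi2, pval, _ = _pooled_chi2(counts, exp)
                tested.append(j)
        rows.append((snp, *exp, *counts, chi2, pval, note))
    table = pd.DataFrame(
        rows, columns=["snp_id", "p0", "p1", "p2", "n0", "n1", "n2", "chi2", "pvalue", "note"]
    )
    m_tested = len(tested)
    cutoff = alpha / max(m_tested, 1)
    table["removed"] = table["pvalue"] < cutoff
    removed = table.loc[table["removed"], "snp_id"].tolist()
    return MendelReport(table=table, removed_snps=removed)


def opposing_homozygote_profile(genotypes: GenotypeMatrix, parents: dict[str, np.ndarray]):
    """Count parent-offspring opposing homozygotes and censor the offending calls.

    A call is incompatible iff offspring and a parent are homozygous for
    different alleles (0 vs 2); heterozygotes are never incompatible.  The
    parents are taken as reliable, so incompatible offspring calls are set
    missing in the returned matrix.  The per-offspring rate is incompatible
    calls over non-missing comparisons (SNPs with that parent genotyped).
    """
    calls = genotypes.calls
    rates = {}
    incompatible_any = np.zeros_like(calls, dtype=bool)
    for name, pg in parents.items():
        pg = np.asarray(pg)
        comparable = (calls != MISSING) & (pg[None, :] != MISSING)
        opp = comparable & (
            ((calls == 0) & (pg[None, :] == 2)) | ((calls == 2) & (pg[None, :] == 0))
        )
        incompatible_any |= opp
        with np.errstate(invalid="ignore"):
            rates[f"rate_{name}"] = opp.sum(axis=1) / comparable.sum(axis=1)
        rates[f"n_opposing_{name}"] = opp.sum(axis=1)
    profile = pd.DataFrame(rates, index=genotypes.ids)
    cleaned = GenotypeMatrix(
        calls=np.where(incompatible_any, MISSING, calls).astype(np.int8),
        ids=list(genotypes.ids),
        snp_ids=list(genotypes.snp_ids),
        probs=genotypes.probs,
    )
    return profile, cleaned


def mixture_fraction_from_counts(n_flagged: int, n_total: int) -> tuple[float, float]:
    """Majority-group fraction and its binomial standard error."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    p = (n_total - n_flagged) / n_total
    return p, float(np.sqrt(p * (1 - p) / n_total))


def _two_means_1d(x: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Deterministic 1-d 2-means: initialize at min/max, iterate to convergence."""
    c = np.asarray([x.min(), x.max()], dtype=float)
    lab = np.zeros(x.size, dtype=int)
    for _ in range(n_iter):
        new = (np.abs(x[:, None] - c[None, :])).argmin(axis=1)
        if (new == lab).all():
            break
        lab = new
        for k in (0, 1):
            if (lab == k).any():
                c[k] = x[lab == k].mean()
    return lab


def detect_paternity_mixture(
    profile: pd.DataFrame | pd.Series,
    background_rate: float = 0.013,
    rate_column: str | None = None,
    inflation: float = 3.0,
    min_group_fraction: float = 0.02,
) -> MixtureCall:
    """Split offspring into putative sub-families by opposing-homozygote rate.

    Offspring are flagged when their incompatibility rate against the assumed
    father exceeds ``inflation * background_rate`` (the background being the
    genotype-assignment error rate).  The split is confirmed by a 2-means
    clustering of the rates; "mixture" is returned only when both agree,
    "no mixture" when there is no separated minority group, and "ambiguous"
    otherwise.  The reported fraction is the majority (compatible) group with
    its binomial standard error.
    """
    if isinstance(profile, pd.DataFrame):
        col = rate_column or next(c for c in profile.columns if c.startswith("rate"))
        rates = profile[col]
    else:
        rates = profile
    x = rates.to_numpy(dtype=float)
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 offspring for mixture detection")

    threshold = inflation * background_rate
    flagged = x > threshold
    n_flagged = int(flagged.sum())
    frac, se = mixture_fraction_from_counts(n_flagged, n)

    if n_flagged == 0 or n_flagged / n < min_group_fraction:
        verdict = "no mixture"
        assignment = pd.Series("A", index=rates.index)
        frac, se = mixture_fraction_from_counts(0, n)
        return MixtureCall(verdict, assignment, frac, se, 0, n,
                           {"threshold": threshold, "n_above_threshold": n_flagged})

    lab = _two_means_1d(x)
    hi = int(np.argmax([x[lab == 0].mean() if (lab == 0).any() else -np.inf,
                        x[lab == 1].mean() if (lab == 1).any() else -np.inf]))
    cluster_flagged = lab == hi
    agreement = float((cluster_flagged == flagged).mean())
    means = (x[~cluster_flagged].mean(), x[cluster_flagged].mean())
    separated = means[1] > means[0] + 2 * background_rate
    verdict = "mixture" if (agreement >= 0.95 and separated) else "ambiguous"
    assignment = pd.Series(np.where(flagged, "B", "A"), index=rates.index)
    evidence = {
        "threshold": threshold,
        "n_above_threshold": n_flagged,
        "cluster_means": means,
        "cluster_agreement": agreement,
    }
    return MixtureCall(verdict, assignment, frac, se, n_flagged, n, evidence)


def callrate_cdf(probs: np.ndarray, p: float, grid: np.ndarray | None = None):
    """Call-rate CDFs from genotype-probability triples at assignment threshold p.

    A genotype is "called" iff its maximum posterior probability exceeds ``p``
    (p >= 0.5 makes the assignment unique).  Returns a DataFrame with the CDF
    of SNP call rates over offspring and of offspring call rates over SNPs,
    evaluated on ``grid`` (default: 0 to 1 in steps of 0.01).
    """
    if p < 0.5:
        raise ValueError("threshold p must be >= 0.5 for a unique assignment")
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 3 or probs.shape[2] != 3:
        raise ValueError("probs must have shape (n_ind, n_snp, 3)")
    called = probs.max(axis=2) > p
    snp_rates = called.mean(axis=0)  # per SNP, over offspring
    ind_rates = called.mean(axis=1)  # per offspring, over SNPs
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    return pd.DataFrame(
        {
            "call_rate": grid,
            "cdf_snp_over_offspring": [(snp_rates <= g).mean() for g in grid],
            "cdf_offspring_over_snps": [(ind_rates <= g).mean() for g in grid],
        }
    )
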