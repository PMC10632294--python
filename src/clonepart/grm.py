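"""Genomic relationship matrix (VanRaden method 1) and the variance-rescaling scalar k.

G = W W' / sum_i 2 p_i (1 - p_i), where W holds dosages centred at 2 p_i.
Within a full-sib family the centring frequencies are taken from the two
parents (p in {0.25, 0.5, 0.75} for segregating loci); for a family of
unresolved structure the observed offspring frequencies are used instead.

The model parameter attached to G refers to a Hardy-Weinberg population, not
to the family at hand; the family's realized additive variance is k * sigma_a2
with k = mean(diag(G)) - mean(G), which the mixed-model constraint uses to put
genotyped and ungenotyped trees on the same total-genetic-variance scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simdata import MISSING, GenotypeMatrix, PhasedGenotype

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicRelationship",
    "dosage_from_probabilities",
    "parental_allele_frequencies",
    "vanraden_g",
    "scaling_k",
    "grm_from_genotypes",
]


@dataclass
class GenomicRelationship:
    """G over genotyped individuals, the scalar k, and the frequency provenance."""

    matrix: np.ndarray
    ids: list[str]
    k: float
    freqs: np.ndarray
    freq_source: str  # "parental" | "observed"
    snp_ids: list[str]

    def __post_init__(self) -> None:
        g = np.asarray(self.matrix, dtype=float)
        if g.shape[0] != g.shape[1] or g.shape[0] != len(self.ids):
            raise ValueError("G must be square over the genotyped ids")
        if not np.allclose(g, g.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        self.matrix = g

    def is_positive_semidefinite(self, tol: float = 1e-8) -> bool:
        return bool(np.linalg.eigvalsh(self.matrix).min() >= -tol)

    def sidecar(self) -> dict:
        return {
            "k": self.k,
            "freq_source": self.freq_source,
            "n_snps": len(self.snp_ids),
            "n_individuals": len(self.ids),
            "positive_semidefinite": self.is_positive_semidefinite(),
        }


def dosage_from_probabilities(triple) -> float | np.ndarray:
    """Expected alternative-allele dosage 0*P0 + 1*P1 + 2*P2.

    Accepts a single (P0, P1, P2) triple or an array whose last axis is the
    triple.  Probabilities must be non-negative and sum to 1 within 1e-6;
    triples are renormalized so encoding round-off is harmless.
    """
    p = np.asarray(triple, dtype=float)
    if (p < 0).any():
        raise ValueError("negative genotype probability")
    s = p.sum(axis=-1)
    if np.any(np.abs(s - 1.0) > 1e-6):
        raise ValueError("genotype probabilities must sum to 1 (tolerance 1e-6)")
    p = p / s[..., None]
    d = p[..., 1] + 2.0 * p[..., 2]
    return float(d) if d.ndim == 0 else d


def parental_allele_frequencies(parent_genotypes) -> np.ndarray:
    """Per-SNP alt-allele frequency from the two parents: (dose_m + dose_f) / 4.

    For a segregating cross the result is 0.25, 0.5 or 0.75.  Monomorphic
    crosses (p = 0 or 1) yield the value; exclusion is applied downstream.
    Parents may be PhasedGenotype objects or dosage arrays.
    """
    doses = []
    for pg in parent_genotypes:
        d = pg.dosage if isinstance(pg, PhasedGenotype) else np.asarray(pg, dtype=float)
        if np.any(d == MISSING):
            raise ValueError("parent has missing genotypes at some SNPs")
        doses.append(d)
    return (doses[0] + doses[1]) / 4.0


def vanraden_g(
    dosages: np.ndarray,
    freqs: np.ndarray,
    ids: list[str] | None = None,
    snp_ids: list[str] | None = None,
    freq_source: str = "parental",
) -> GenomicRelationship:
    """VanRaden method-1 G from a (n x m) dosage matrix and per-SNP frequencies.

    SNPs monomorphic at the supplied frequencies (p in {0, 1}) carry no
    information and are excluded (logged).  Missing dosages (NaN) are
    mean-imputed at 2p before centring and logged loudly, since imputed
    probability dosages should not normally contain any.
    """
    x = np.asarray(dosages, dtype=float)
    p = np.asarray(freqs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-d dosage matrix with >= 2 individuals")
    if p.shape != (x.shape[1],):
        raise ValueError("freqs must be one per SNP")
    ids = ids or [f"ind{i + 1}" for i in range(x.shape[0])]
    snp_ids = snp_ids or [f"snp{j + 1}" for j in range(x.shape[1])]

    keep = (p > 0) & (p < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d monomorphic-in-family SNPs from G", n_dropped)
    if not keep.any():
        raise ValueError("no segregating SNPs left to build G")
    x = x[:, keep]
    p = p[keep]
    kept_snps = [s for s, k_ in zip(snp_ids, keep) if k_]

    nan_mask = np.isnan(x)
    if nan_mask.any():
        logger.warning(
            "mean-imputing %d missing dosages at 2p before centring", int(nan_mask.sum())
        )
        x = np.where(nan_mask, (2.0 * p)[None, :], x)
    if (x < 0).any() or (x > 2).any():
        raise ValueError("dosages must lie in [0, 2]")

    w = x - 2.0 * p[None, :]
    denom = float((2.0 * p * (1.0 - p)).sum())
    g = (w @ w.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against round-off
    return GenomicRelationship(
        matrix=g, ids=list(ids), k=scaling_k(g), freqs=p, freq_source=freq_source, snp_ids=kept_snps
    )


def scaling_k(g: np.ndarray) -> float:
    """k = mean(diag(G)) - mean(G), the within-group additive rescaling scalar."""
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("empty G")
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("G must be square")
    return float(np.diag(g).mean() - g.mean())


def grm_from_genotypes(
    genotypes: GenotypeMatrix,
    parents: dict[str, np.ndarray] | None = None,
    freq_source: str = "parental",
) -> GenomicRelationship:
    """Convenience builder: dosages from GP triples (or hard calls) then method-1 G.

    ``freq_source = "parental"`` centres at frequencies computed from the two
    parents in ``parents``; ``"observed"`` (the choice for a family of mixed
    paternity) centres at the observed mean offspring frequencies.
    """
    if genotypes.probs is not None:
        dos = dosage_from_probabilities(genotypes.probs)
    else:
        calls = genotypes.calls.astype(float)
        dos = np.where(calls == MISSING, np.nan, calls)
    if freq_source == "parental":
        if parents is None:
            raise ValueError("parental frequencies require parent genotypes")
        p = parental_allele_frequencies([parents["mother"], parents["father"]])
    elif freq_source == "observed":
        p = np.nanmean(dos, axis=0) / 2.0
    else:
        raise ValueError(f"unknown freq_source {freq_source!r}")
    return vanraden_g(
        dos, p, ids=list(genotypes.ids), snp_ids=list(genotypes.snp_ids), freq_source=freq_source
    )
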