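"""Synthetic full-sib families, marker genotypes and clonally replicated field trials.

The generator emulates a forest-tree clonal progeny test: large full-sib
families created by controlled pollination, a subset of offspring genotyped
at mapped biallelic SNPs, and every offspring vegetatively propagated so that
one ramet is planted in each replicate block on each site.  Phenotypes follow
a linear mixed model with a total genetic effect per offspring genotype,
a block effect, a separable AR1 (columns) x AR1 (rows) spatial error per
master block, and an independent nugget error.

All randomness flows through :class:`numpy.random.Generator` objects seeded
explicitly, so every artefact is bit-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMapSpec",
    "FamilyConfig",
    "ArchitectureConfig",
    "TrialLayoutSpec",
    "SiteSpec",
    "NoiseConfig",
    "PhasedGenotype",
    "GenotypeMatrix",
    "FamilySim",
    "GeneticValues",
    "SimulatedTrial",
    "SEGREGATING_CLASSES",
    "simulate_parent_genotypes",
    "simulate_gamete",
    "simulate_family",
    "assign_genetic_values",
    "simulate_trial",
    "apply_genotype_missingness",
    "default_linkage_map",
]

MISSING = -1  # sentinel for a missing hard call, distinct from dosage 0

# mother x father alt-allele counts for crosses that segregate in offspring
SEGREGATING_CLASSES: dict[str, tuple[int, int]] = {
    "AaxAa": (1, 1),
    "AaxAA": (1, 2),
    "AAxAa": (2, 1),
    "Aaxaa": (1, 0),
    "aaxAa": (0, 1),
}
_NON_SEGREGATING = {"AAxAA": (2, 2), "aaxaa": (0, 0), "AAxaa": (2, 0), "aaxAA": (0, 2)}

# Linkage-group lengths (cM) and mapped-SNP counts of the 12-group map used
# as the default study map; loci are placed evenly within each group.
_DEFAULT_GROUP_LENGTHS = [218, 194, 201, 194, 165, 174, 203, 199, 164, 157, 128, 146]
_DEFAULT_GROUP_NSNP = [159, 163, 153, 146, 109, 139, 149, 129, 125, 129, 108, 121]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkageMapSpec:
    """Linkage groups with mapped SNP positions.

    ``groups`` is a list of ``(group_id, length_cM)``; ``loci`` a list of
    ``(group_id, position_cM, snp_id)``.  Positions within a group must be
    non-decreasing and lie in ``[0, length]``.
    """

    groups: list[tuple[str, float]]
    loci: list[tuple[str, float, str]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("linkage map has no groups")
        lengths = dict(self.groups)
        if any(l <= 0 for l in lengths.values()):
            raise ValueError("group lengths must be > 0")
        last: dict[str, float] = {}
        for g, pos, _ in self.loci:
            if g not in lengths:
                raise ValueError(f"locus on unknown group {g!r}")
            if pos < 0 or pos > lengths[g]:
                raise ValueError(f"position {pos} outside group {g!r}")
            if pos < last.get(g, 0.0):
                raise ValueError(f"positions on group {g!r} not non-decreasing")
            last[g] = pos

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def snp_ids(self) -> list[str]:
        return [s for _, _, s in self.loci]

    def group_indices(self) -> dict[str, np.ndarray]:
        """Map group_id -> integer indices of its loci (in map order)."""
        out: dict[str, list[int]] = {g: [] for g, _ in self.groups}
        for i, (g, _, _) in enumerate(self.loci):
            out[g].append(i)
        return {g: np.asarray(ix, dtype=int) for g, ix in out.items()}

    def positions(self) -> dict[str, np.ndarray]:
        pos: dict[str, list[float]] = {g: [] for g, _ in self.groups}
        for g, p, _ in self.loci:
            pos[g].append(p)
        return {g: np.asarray(p, dtype=float) for g, p in pos.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loci, columns=["group", "cM", "snp_id"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LinkageMapSpec":
        lengths = df.groupby("group", sort=False)["cM"].max()
        groups = [(g, float(max(l, 1e-9))) for g, l in lengths.items()]
        loci = [(r.group, float(r.cM), str(r.snp_id)) for r in df.itertuples()]
        return cls(groups=groups, loci=loci)


def default_linkage_map(n_loci: int | None = None) -> LinkageMapSpec:
    """The default 12-linkage-group map with ~1630 evenly spaced SNPs.

    ``n_loci`` scales the per-group SNP counts down proportionally
    (at least one SNP per group) for small test problems.
    """
    counts = np.asarray(_DEFAULT_GROUP_NSNP, dtype=float)
    if n_loci is not None:
        counts = np.maximum(1, np.round(counts * n_loci / counts.sum())).astype(int)
    else:
        counts = counts.astype(int)
    groups, loci = [], []
    for g in range(12):
        gid = f"LG{g + 1:02d}"
        length = float(_DEFAULT_GROUP_LENGTHS[g])
        groups.append((gid, length))
        pos = np.linspace(0.0, length, counts[g] + 2)[1:-1]
        for j, p in enumerate(pos):
            loci.append((gid, float(p), f"{gid}_snp{j + 1}"))
    return LinkageMapSpec(groups=groups, loci=loci)


@dataclass(frozen=True)
class FamilyConfig:
    """One controlled cross: family size, genotyped subset and hidden paternity mix.

    ``mixture_fraction`` q is the proportion of offspring sired by father A;
    q = 1 is a pure full-sib family, q < 1 a maternal half-sib mixture
    (a second father's genotypes are then required).
    """

    n_offspring: int = 1500
    n_genotyped: int = 500
    parent_ids: tuple[str, str] = ("mother", "fatherA")
    mixture_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotyped > self.n_offspring:
            raise ValueError("n_genotyped must be <= n_offspring")
        if not (0.0 < self.mixture_fraction <= 1.0):
            raise ValueError("mixture_fraction q must lie in (0, 1]")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Genetic architecture: target within-family variance and its additive share.

    ``sigma_u2`` is the within-family total genetic variance; ``r_a`` the
    fraction of it that is additive among the simulated offspring.  Effects at
    ``n_causal_add`` additive and ``n_causal_dom`` dominance loci are drawn
    i.i.d. normal and rescaled so the realized variances match the targets.
    """

    sigma_u2: float = 1.0
    r_a: float = 0.75
    n_causal_add: int = 150
    n_causal_dom: int = 150
    effect_sd: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_u2) or self.sigma_u2 <= 0:
            raise ValueError("sigma_u2 must be finite and > 0")
        if not np.isfinite(self.r_a) or not (0.0 <= self.r_a <= 1.0):
            raise ValueError("r_a must lie in [0, 1]")


@dataclass(frozen=True)
class SiteSpec:
    """One trial site: replicate blocks, their master-block partition and grid.

    Each block is a ``block_grid = (n_columns, n_rows)`` rectangle; blocks of
    a master block are stacked in the row direction so each master block is a
    continuous grid.  Every offspring contributes one ramet per block.
    """

    name: str = "site"
    n_blocks: int = 4
    master_blocks: tuple[tuple[int, ...], ...] = ((1, 2, 3, 4),)
    block_grid: tuple[int, int] = (40, 39)

    def __post_init__(self) -> None:
        blocks = [b for mb in self.master_blocks for b in mb]
        if sorted(blocks) != list(range(1, self.n_blocks + 1)):
            raise ValueError("master_blocks must partition blocks 1..n_blocks")

    @property
    def plots_per_block(self) -> int:
        return self.block_grid[0] * self.block_grid[1]


@dataclass(frozen=True)
class TrialLayoutSpec:
    sites: tuple[SiteSpec, ...] = (
        SiteSpec(name="site1", master_blocks=((1, 2, 3, 4),)),
        SiteSpec(name="site2", master_blocks=((1, 2), (3, 4))),
        SiteSpec(name="site3", master_blocks=((1, 2, 3, 4),)),
    )


@dataclass(frozen=True)
class NoiseConfig:
    """Non-genetic variance components of the trial model.

    ``sigma_v2`` block variance, ``sigma_r2`` nugget (random error),
    ``sigma_s2`` spatial error variance, ``rho_c``/``rho_r`` column/row
    autocorrelations of the separable AR1 x AR1 spatial process.
    """

    sigma_v2: float = 0.1
    sigma_r2: float = 2.0
    sigma_s2: float = 0.9
    rho_c: float = 0.85
    rho_r: float = 0.85

    def __post_init__(self) -> None:
        if min(self.sigma_v2, self.sigma_r2, self.sigma_s2) < 0:
            raise ValueError("variances must be >= 0")
        if max(abs(self.rho_c), abs(self.rho_r)) >= 1:
            raise ValueError("autocorrelations must lie in (-1, 1)")


@dataclass
class PhasedGenotype:
    """Two haplotypes (0/1 alt-allele indicators) over the loci of a map."""

    haplotypes: np.ndarray  # (2, n_loci) int8

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


@dataclass
class GenotypeMatrix:
    """Hard calls (0/1/2 alt-allele dosage, -1 missing) with optional GP triples."""

    calls: np.ndarray  # (n_ind, n_snp) int8
    ids: list[str]
    snp_ids: list[str]
    probs: np.ndarray | None = None  # (n_ind, n_snp, 3)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("calls shape does not match ids/snp_ids")

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def ind_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return (self.calls != MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP from non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs, self.calls, 0).sum(axis=0) / (2.0 * obs.sum(axis=0))
        return np.minimum(p, 1.0 - p)

    def subset(self, ind_idx: np.ndarray | None = None, snp_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        ind_idx = np.arange(self.n_ind) if ind_idx is None else np.asarray(ind_idx)
        snp_idx = np.arange(self.n_snp) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            calls=self.calls[np.ix_(ind_idx, snp_idx)],
            ids=[self.ids[i] for i in ind_idx],
            snp_ids=[self.snp_ids[j] for j in snp_idx],
            probs=None if self.probs is None else self.probs[np.ix_(ind_idx, snp_idx)],
        )


@dataclass
class FamilySim:
    """A simulated family: genotypes plus the hidden truth behind them."""

    genotypes: GenotypeMatrix  # all offspring, complete calls
    paternity: np.ndarray  # (n_offspring,) 0 = father A, 1 = father B
    genotyped: np.ndarray  # boolean mask over offspring
    parents: dict[str, PhasedGenotype]
    config: FamilyConfig
    map: LinkageMapSpec


@dataclass
class GeneticValues:
    """Per-offspring total genetic value and its additive/non-additive truth."""

    u: np.ndarray
    u_additive: np.ndarray
    u_dominance: np.ndarray
    causal_add: np.ndarray  # SNP indices
    causal_dom: np.ndarray


@dataclass
class SimulatedTrial:
    """A trial frame plus the truth tables used to generate it."""

    frame: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_parent_genotypes(
    map: LinkageMapSpec,
    seg_class_probs: dict[str, float],
    seed: int,
    n_extra_fathers: int = 0,
    extra_father_freq: float = 0.5,
) -> dict[str, PhasedGenotype]:
    """Draw phased parental genotypes with every SNP segregating in the cross.

    ``seg_class_probs`` gives probabilities over segregation classes such as
    ``"AaxAa"`` (mother x father, ``A`` = alternative allele).  Classes whose
    offspring would show no genotypic segregation are rejected.  Extra fathers
    (for hidden paternity mixtures) are drawn independently at Hardy-Weinberg
    frequency ``extra_father_freq``.
    """
    if map.n_loci == 0:
        raise ValueError("empty linkage map")
    classes = list(seg_class_probs)
    probs = np.asarray([seg_class_probs[c] for c in classes], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("segregation-class probabilities must sum to 1")
    bad = [c for c, p in seg_class_probs.items() if p > 0 and c not in SEGREGATING_CLASSES]
    if bad:
        raise ValueError(f"non-segregating or unknown class(es) with positive mass: {bad}")

    rng = np.random.default_rng(seed)
    m = map.n_loci
    chosen = rng.choice(len(classes), size=m, p=probs)
    mother = np.zeros((2, m), dtype=np.int8)
    father = np.zeros((2, m), dtype=np.int8)
    for haps, which in ((mother, 0), (father, 1)):
        dos = np.asarray([SEGREGATING_CLASSES[classes[c]][which] for c in chosen])
        hom_alt = dos == 2
        het = dos == 1
        haps[:, hom_alt] = 1
        # random phase for heterozygotes
        top = rng.integers(0, 2, size=het.sum())
        haps[0, het] = top
        haps[1, het] = 1 - top
    out = {"mother": PhasedGenotype(mother), "fatherA": PhasedGenotype(father)}
    for k in range(n_extra_fathers):
        hap = (rng.random((2, m)) < extra_father_freq).astype(np.int8)
        out[f"father{chr(ord('B') + k)}"] = PhasedGenotype(hap)
    return out


def simulate_gamete(parent: PhasedGenotype, map: LinkageMapSpec, rng: np.random.Generator | int) -> np.ndarray:
    """One haploid gamete under the Haldane model (Poisson crossovers, no interference).

    Crossovers fall as a Poisson process at rate 1 per Morgan (100 cM) along
    each linkage group, independently across groups.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    gamete = np.empty(map.n_loci, dtype=np.int8)
    positions = map.positions()
    for g, idx in map.group_indices().items():
        if idx.size == 0:
            continue
        length = dict(map.groups)[g]
        n_co = rng.poisson(length / 100.0)
        start = rng.integers(0, 2)
        if n_co == 0:
            hap = np.full(idx.size, start)
        else:
            co_pos = np.sort(rng.uniform(0.0, length, size=n_co))
            n_before = np.searchsorted(co_pos, positions[g], side="left")
            hap = (start + n_before) % 2
        gamete[idx] = parent.haplotypes[hap, idx]
    return gamete


def _gametes(parent: PhasedGenotype, map: LinkageMapSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.stack([simulate_gamete(parent, map, rng) for _ in range(n)])


def simulate_family(
    fcfg: FamilyConfig,
    map: LinkageMapSpec,
    parents: dict[str, PhasedGenotype],
) -> FamilySim:
    """Simulate offspring genotypes for one (possibly mixed-paternity) family."""
    q = fcfg.mixture_fraction
    if q < 1.0 and "fatherB" not in parents:
        raise ValueError("mixture_fraction < 1 requires a second father's genotypes")
    rng = np.random.default_rng(fcfg.seed)
    n = fcfg.n_offspring
    paternity = (rng.random(n) >= q).astype(np.int8)  # 1 = father B
    maternal = _gametes(parents["mother"], map, n, rng)
    paternal = np.empty_like(maternal)
    for i in range(n):
        sire = parents["fatherB" if paternity[i] else "fatherA"]
        paternal[i] = simulate_gamete(sire, map, rng)
    calls = (maternal + paternal).astype(np.int8)
    genotyped = np.zeros(n, dtype=bool)
    genotyped[rng.choice(n, size=fcfg.n_genotyped, replace=False)] = True
    ids = [f"off{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(calls=calls, ids=ids, snp_ids=map.snp_ids)
    return FamilySim(genotypes=gm, paternity=paternity, genotyped=genotyped, parents=parents, config=fcfg, map=map)


def assign_genetic_values(
    genotypes: GenotypeMatrix | np.ndarray,
    arch: ArchitectureConfig,
    seed: int,
) -> GeneticValues:
    """Sample causal effects and rescale so realized variances hit the targets.

    Additive values are linear in alt-allele dosage at ``n_causal_add`` loci.
    Dominance values use the within-family dominance deviation: at each
    ``n_causal_dom`` locus the heterozygosity indicator is residualized on the
    locus dosage within the family (at a locus with one homozygous parent the
    indicator is a linear function of dosage, so its within-family dominance
    deviation is zero and only het x het loci contribute, as quantitative-
    genetic theory requires).  The aggregate dominance value is then
    residualized against the additive value so the realized decomposition is
    exactly orthogonal, and both parts are scaled to variances
    ``r_a * sigma_u2`` and ``(1 - r_a) * sigma_u2``.
    """
    calls = genotypes.calls if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    n, m = calls.shape
    if arch.n_causal_add == 0:
        raise ValueError("need at least one additive causal locus")
    if arch.n_causal_add > m or arch.n_causal_dom > m:
        raise ValueError("more causal loci requested than simulated loci")
    rng = np.random.default_rng(seed)

    # prefer loci that actually vary in this family
    var_ok = np.flatnonzero(calls.std(axis=0) > 0)
    if var_ok.size < max(arch.n_causal_add, arch.n_causal_dom):
        var_ok = np.arange(m)
    causal_add = rng.choice(var_ok, size=min(arch.n_causal_add, var_ok.size), replace=False)
    u_a = calls[:, causal_add].astype(float) @ rng.normal(0.0, arch.effect_sd, size=causal_add.size)
    u_a -= u_a.mean()
    sd_a = u_a.std()
    if sd_a == 0:
        raise ValueError("additive values degenerate: causal loci do not segregate")
    u_a *= np.sqrt(arch.r_a * arch.sigma_u2) / sd_a

    if arch.r_a == 1.0 or arch.n_causal_dom == 0:
        u_d = np.zeros(n)
        causal_dom = np.asarray([], dtype=int)
    else:
        # loci segregating for both homozygotes (het x het crosses) carry
        # within-family dominance variance; prefer them as dominance loci
        both_hom = np.flatnonzero((calls == 0).any(axis=0) & (calls == 2).any(axis=0))
        pool = both_hom if both_hom.size >= min(arch.n_causal_dom, 5) else var_ok
        causal_dom = rng.choice(pool, size=min(arch.n_causal_dom, pool.size), replace=False)
        x = calls[:, causal_dom].astype(float)
        het = (x == 1).astype(float)
        xc = x - x.mean(axis=0)
        denom = (xc**2).sum(axis=0)
        slope = np.where(denom > 0, (het * xc).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
        dom_dev = het - het.mean(axis=0) - xc * slope  # per-locus dominance deviation
        u_d = dom_dev @ rng.normal(0.0, arch.effect_sd, size=causal_dom.size)
        u_d -= u_d.mean()
        if arch.r_a > 0 and u_a.std() > 0:  # orthogonalize the realized split
            u_d -= (u_d @ u_a) / (u_a @ u_a) * u_a
        sd_d = u_d.std()
        if sd_d == 0:
            raise ValueError("dominance values degenerate")
        u_d *= np.sqrt((1.0 - arch.r_a) * arch.sigma_u2) / sd_d
    return GeneticValues(u=u_a + u_d, u_additive=u_a, u_dominance=u_d, causal_add=causal_add, causal_dom=causal_dom)


def _spatial_field(n_cols: int, n_rows: int, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact draw of a separable AR1 x AR1 field via the matrix-normal identity."""
    from scipy.linalg import cholesky

    if noise.sigma_s2 == 0:
        return np.zeros((n_cols, n_rows))
    lc = cholesky(_ar1(n_cols, noise.rho_c), lower=True)
    lr = cholesky(_ar1(n_rows, noise.rho_r), lower=True)
    z = rng.standard_normal((n_cols, n_rows))
    return np.sqrt(noise.sigma_s2) * (lc @ z @ lr.T)


def _ar1(n: int, rho: float) -> np.ndarray:
    i = np.arange(n)
    return rho ** np.abs(i[:, None] - i[None, :])


def simulate_trial(
    site: SiteSpec,
    genetic_values: np.ndarray,
    noise: NoiseConfig,
    seed: int,
    genotype_ids: Sequence[str] | None = None,
    mean: float = 7.6,
    trait: str = "height11",
) -> SimulatedTrial:
    """Lay one family out on one site and draw phenotypes.

    Every offspring gets one ramet per block, assigned to a random plot within
    the block (randomized complete block design); surplus plots become fillers
    with missing phenotypes, standing in for un-cloned control trees.
    """
    u = np.asarray(genetic_values, dtype=float)
    n_off = u.size
    n_cols, rows_per_block = site.block_grid
    if n_off > site.plots_per_block:
        raise ValueError(
            f"grid too small: {site.plots_per_block} plots per block < {n_off} offspring"
        )
    if genotype_ids is None:
        genotype_ids = [f"off{i + 1:04d}" for i in range(n_off)]
    rng = np.random.default_rng(seed)

    v = rng.normal(0.0, np.sqrt(noise.sigma_v2), size=site.n_blocks)

    records = []
    spatial_truth = {}
    for mb_i, mb_blocks in enumerate(site.master_blocks, start=1):
        mb_rows = rows_per_block * len(mb_blocks)
        field = _spatial_field(n_cols, mb_rows, noise, rng)
        spatial_truth[mb_i] = field
        for j, block in enumerate(mb_blocks):
            cells = [(c, r) for c in range(1, n_cols + 1) for r in range(1, rows_per_block + 1)]
            order = rng.permutation(len(cells))
            for slot, cell_i in enumerate(order):
                col, row_in_block = cells[cell_i]
                row = j * rows_per_block + row_in_block
                s = field[col - 1, row - 1]
                if slot < n_off:
                    gid = genotype_ids[slot]
                    e = rng.normal(0.0, np.sqrt(noise.sigma_r2))
                    y = mean + u[slot] + v[block - 1] + s + e
                    records.append((f"{gid}_b{block}", gid, site.name, block, mb_i, col, row, trait, y))
                else:
                    records.append((f"filler_{site.name}_b{block}_{col}_{row}", None, site.name, block, mb_i, col, row, trait, np.nan))
    frame = pd.DataFrame(
        records,
        columns=["tree_id", "genotype_id", "site", "block", "master_block", "column", "row", "trait", "value"],
    )
    dup = frame.duplicated(subset=["master_block", "column", "row"])
    assert not dup.any(), "internal error: duplicate plot coordinates"
    truth = {
        "u": pd.Series(u, index=list(genotype_ids), name="u"),
        "block_effects": v,
        "spatial": spatial_truth,
        "noise": noise,
        "mean": mean,
    }
    return SimulatedTrial(frame=frame, truth=truth)


def _as_rates(dist, size: int, rng: np.random.Generator) -> np.ndarray:
    if callable(dist):
        rates = np.asarray(dist(rng, size), dtype=float)
    else:
        rates = np.broadcast_to(np.asarray(dist, dtype=float), (size,)).copy()
    if rates.min() < 0 or rates.max() > 1:
        raise ValueError("call rates must lie in [0, 1]")
    return rates


def apply_genotype_missingness(
    genotypes: GenotypeMatrix,
    snp_callrate_dist=1.0,
    ind_callrate_dist=1.0,
    posterior_error: float | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Mask calls independently and optionally attach genotype-probability triples.

    Call ``(i, j)`` is kept with probability ``ind_rate[i] * snp_rate[j]``.
    With ``posterior_error`` e, each retained call's probability triple puts
    its bulk mass on the true genotype with probability 1 - e and on a wrong
    genotype otherwise, so e is the argmax error rate; hard calls follow the
    probability argmax, emulating miscalled genotypes.
    """
    rng = np.random.default_rng(seed)
    n, m = genotypes.calls.shape
    snp_rates = _as_rates(snp_callrate_dist, m, rng)
    ind_rates = _as_rates(ind_callrate_dist, n, rng)
    keep = rng.random((n, m)) < ind_rates[:, None] * snp_rates[None, :]
    calls = np.where(keep, genotypes.calls, MISSING).astype(np.int8)

    probs = None
    if posterior_error is not None:
        soft = 0.01  # residual mass spread over the two unassigned genotypes
        assigned = genotypes.calls.astype(np.int64).copy()
        wrong = rng.random((n, m)) < posterior_error
        # a wrong assignment moves to one of the two other genotypes
        shift = rng.integers(1, 3, size=(n, m))
        assigned[wrong] = (assigned[wrong] + shift[wrong]) % 3
        probs = np.full((n, m, 3), soft)
        np.put_along_axis(probs, assigned[:, :, None], 1.0 - 2 * soft, axis=2)
        probs[~keep] = 1.0 / 3.0  # uncalled: uninformative triple
        calls = np.where(keep, assigned.astype(np.int8), MISSING)
    return GenotypeMatrix(calls=calls, ids=list(genotypes.ids), snp_ids=list(genotypes.snp_ids), probs=probs)
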