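"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (GT, plus optional DS dosage and GP genotype-
probability FORMAT fields; read back through cyvcf2), phenotypes/layout and
linkage maps as TSV, the genomic relationship matrix as a plain-text square
matrix with an ID header row and a JSON sidecar, and run configuration as
YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grm import GenomicRelationship
from .simdata import MISSING, GenotypeMatrix, LinkageMapSpec

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_map_tsv",
    "read_map_tsv",
    "write_trial_tsv",
    "read_trial_tsv",
    "write_grm",
    "read_grm",
    "load_yaml",
    "save_yaml",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, map: LinkageMapSpec | None = None) -> None:
    """Write hard calls (GT), expected dosages (DS) and probabilities (GP) as VCF.

    SNP coordinates come from the linkage map when given (linkage group as
    contig, cM position rounded to an integer bp surrogate), else a single
    dummy contig with consecutive positions.
    """
    path = Path(path)
    if map is not None:
        coords = {s: (g, max(1, int(round(p * 1e4)))) for g, p, s in map.loci}
    else:
        coords = {s: ("0", j + 1) for j, s in enumerate(gm.snp_ids)}
    has_gp = gm.probs is not None
    fmt = "GT:DS:GP" if has_gp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_gp:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt-allele dosage">\n')
            fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">\n')
        for contig in dict.fromkeys(g for g, _ in coords.values()):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.ids) + "\n")
        for j, snp in enumerate(gm.snp_ids):
            chrom, pos = coords[snp]
            cells = []
            for i in range(gm.n_ind):
                gt = _GT[int(gm.calls[i, j])]
                if has_gp:
                    p = gm.probs[i, j]
                    ds = p[1] + 2 * p[2]
                    cells.append(f"{gt}:{ds:.4f}:{p[0]:.4f},{p[1]:.4f},{p[2]:.4f}")
                else:
                    cells.append(gt)
            fh.write(f"{chrom}\t{pos}\t{snp}\tA\tC\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT (and GP when present) from a VCF into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    calls, snp_ids, gps = [], [], []
    any_gp = False
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        g = np.asarray(var.genotypes, dtype=int)[:, :2]
        row = np.where((g < 0).any(axis=1), MISSING, g.clip(min=0).sum(axis=1))
        calls.append(row.astype(np.int8))
        gp = var.format("GP")
        if gp is not None:
            any_gp = True
            gps.append(np.asarray(gp, dtype=float))
        else:
            gps.append(None)
    vcf.close()
    calls = np.stack(calls, axis=1) if calls else np.zeros((len(ids), 0), dtype=np.int8)
    probs = None
    if any_gp:
        probs = np.stack(
            [g if g is not None else np.full((len(ids), 3), 1 / 3) for g in gps], axis=1
        )
    return GenotypeMatrix(calls=calls, ids=ids, snp_ids=snp_ids, probs=probs)


def write_map_tsv(map: LinkageMapSpec, path) -> None:
    map.to_frame().to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> LinkageMapSpec:
    return LinkageMapSpec.from_frame(pd.read_csv(path, sep="\t"))


def write_trial_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trial_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_grm(g: GenomicRelationship, path) -> None:
    """Square matrix with an ID header row, plus a .json sidecar (k, provenance)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(g.ids) + "\n")
        np.savetxt(fh, g.matrix, delimiter="\t", fmt="%.10g")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(g.sidecar(), fh, indent=2, sort_keys=True)


def read_grm(path) -> GenomicRelationship:
    path = Path(path)
    with open(path) as fh:
        ids = fh.readline().strip().split("\t")
        mat = np.loadtxt(fh, delimiter="\t", ndmin=2)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        side = json.load(fh)
    from .grm import scaling_k

    return GenomicRelationship(
        matrix=mat,
        ids=ids,
        k=side.get("k", scaling_k(mat)),
        freqs=np.asarray([]),
        freq_source=side.get("freq_source", "unknown"),
        snp_ids=[f"snp{j}" for j in range(side.get("n_snps", 0))],
    )


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
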