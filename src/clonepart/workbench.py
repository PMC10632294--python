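"""End-to-end orchestration: simulate -> qc -> grm -> fit -> profile -> pool -> report.

A run is fully reproducible from its :class:`RunConfig` and seed: every stage
draws from a named substream of the run seed, every artefact is written to
the output directory, and the manifest records a SHA-256 checksum per file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geno_qc, grm as grm_mod, io, partition, simdata, varcomp

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "FamilySpec", "run_pipeline", "demo_config"]


def _subseed(seed: int, *labels) -> int:
    """Deterministic named substream seed (independent of stage replay order)."""
    digest = hashlib.sha256((f"{seed}:" + ":".join(map(str, labels))).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class FamilySpec:
    name: str = "SF1"
    n_offspring: int = 1500
    n_genotyped: int = 500
    mixture_fraction: float = 1.0  # < 1: hidden maternal half-sib mixture


@dataclass
class RunConfig:
    """Serializable description of a complete synthetic study run.

    Defaults emulate the study design: three ~1500-offspring full-sib
    families (one a hidden 0.594 : 0.406 paternal mixture), ~500 genotyped
    offspring each, the 12-group ~1630-SNP map, three sites with four blocks
    and four ramets per offspring per site.
    """

    seed: int = 1
    outdir: str = "clonepart_run"
    trait: str = "height11"
    mean: float = 7.6
    n_loci: int | None = None  # None: the full default map
    families: list[FamilySpec] = field(
        default_factory=lambda: [
            FamilySpec("SF1", 1500, 573, 1.0),
            FamilySpec("SF2", 1500, 474, 1.0),
            FamilySpec("SF3", 1500, 478, 0.594),
        ]
    )
    seg_class_probs: dict = field(
        default_factory=lambda: {"AaxAa": 0.1, "AaxAA": 0.225, "AAxAa": 0.225, "Aaxaa": 0.225, "aaxAa": 0.225}
    )
    architecture: simdata.ArchitectureConfig = field(default_factory=simdata.ArchitectureConfig)
    noise: simdata.NoiseConfig = field(default_factory=simdata.NoiseConfig)
    sites: list[simdata.SiteSpec] = field(default_factory=lambda: list(simdata.TrialLayoutSpec().sites))
    qc: geno_qc.QCThresholds = field(default_factory=geno_qc.QCThresholds)
    snp_callrate: float = 0.79
    ind_callrate: float = 1.0
    posterior_error: float | None = 0.013
    fit_n_starts: int = 1
    profile_n_coarse: int = 21
    profile_n_refine: int = 10

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in d:
            d["families"] = [FamilySpec(**f) for f in d["families"]]
        for key, typ in (
            ("architecture", simdata.ArchitectureConfig),
            ("noise", simdata.NoiseConfig),
            ("qc", geno_qc.QCThresholds),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "sites" in d:
            d["sites"] = [
                simdata.SiteSpec(
                    name=s["name"],
                    n_blocks=s.get("n_blocks", 4),
                    master_blocks=tuple(tuple(mb) for mb in s.get("master_blocks", [[1, 2, 3, 4]])),
                    block_grid=tuple(s.get("block_grid", (40, 39))),
                )
                for s in d["sites"]
            ]
        return cls(**d)


def demo_config(outdir: str = "clonepart_demo", seed: int = 1) -> RunConfig:
    """A scaled-down single-family, single-site run that finishes in seconds."""
    return RunConfig(
        seed=seed,
        outdir=outdir,
        families=[FamilySpec("FAM1", 200, 160, 1.0)],
        sites=[simdata.SiteSpec(name="demo", n_blocks=4, master_blocks=((1, 2), (3, 4)), block_grid=(12, 20))],
        noise=simdata.NoiseConfig(sigma_v2=0.1, sigma_r2=0.7, sigma_s2=0.3, rho_c=0.8, rho_r=0.8),
        profile_n_coarse=11,
        profile_n_refine=4,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages: dict = {}

    def record(self, stage: str, t0: float, artifacts: list[Path]) -> None:
        self.stages[stage] = {
            "wall_time_s": round(time.time() - t0, 3),
            "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
        }
        logger.info("stage %-10s done in %.2fs (%d artifacts)", stage, time.time() - t0, len(artifacts))

    def save(self) -> Path:
        path = self.outdir / "manifest.json"
        _write_json({"stages": self.stages}, path)
        return path


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute all stages in order; halts with the stage named on failure.

    Returns the manifest (also written to ``outdir/manifest.json``) mapping
    each stage to its wall time and artefact checksums.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)  # validates before any compute
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    io.save_yaml(config.to_dict(), out / "config.yaml")

    results: dict = {"families": {}, "trials": {}}
    try:
        lmap = _stage_simulate(config, out, manifest, results)
        _stage_qc_grm(config, out, manifest, results)
        _stage_trials(config, out, manifest, results, lmap)
        _stage_pool_report(config, out, manifest, results)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {results.get('_stage', '?')}: {exc}") from exc
    manifest.stages["config"] = {"artifacts": {"config.yaml": _sha256(out / "config.yaml")}}
    manifest.save()
    return {"stages": manifest.stages, "results": results}


def _stage_simulate(config: RunConfig, out: Path, manifest: _Manifest, results: dict):
    results["_stage"] = "simulate"
    t0 = time.time()
    lmap = simdata.default_linkage_map(config.n_loci)
    io.write_map_tsv(lmap, out / "map.tsv")
    artifacts = [out / "map.tsv"]
    for fam in config.families:
        seed_f = _subseed(config.seed, "family", fam.name)
        parents = simdata.simulate_parent_genotypes(
            lmap, config.seg_class_probs, seed_f, n_extra_fathers=0 if fam.mixture_fraction == 1.0 else 1
        )
        sim = simdata.simulate_family(
            simdata.FamilyConfig(
                n_offspring=fam.n_offspring,
                n_genotyped=fam.n_genotyped,
                mixture_fraction=fam.mixture_fraction,
                seed=seed_f,
            ),
            lmap,
            parents,
        )
        gv = simdata.assign_genetic_values(sim.genotypes, config.architecture, _subseed(config.seed, "gv", fam.name))
        observed = simdata.apply_genotype_missingness(
            sim.genotypes.subset(ind_idx=np.flatnonzero(sim.genotyped)),
            snp_callrate_dist=config.snp_callrate,
            ind_callrate_dist=config.ind_callrate,
            posterior_error=config.posterior_error,
            seed=_subseed(config.seed, "missing", fam.name),
        )
        io.write_vcf(observed, out / f"{fam.name}_genotypes.vcf", map=lmap)
        truth = pd.DataFrame(
            {
                "genotype_id": sim.genotypes.ids,
                "u": gv.u,
                "u_additive": gv.u_additive,
                "u_dominance": gv.u_dominance,
                "paternity": sim.paternity,
                "genotyped": sim.genotyped,
            }
        )
        truth.to_csv(out / f"{fam.name}_truth.tsv", sep="\t", index=False, float_format="%.8g")
        artifacts += [out / f"{fam.name}_genotypes.vcf", out / f"{fam.name}_truth.tsv"]
        results["families"][fam.name] = {"sim": sim, "gv": gv, "observed": observed, "parents": parents}
    manifest.record("simulate", t0, artifacts)
    return lmap


def _stage_qc_grm(config: RunConfig, out: Path, manifest: _Manifest, results: dict) -> None:
    results["_stage"] = "qc"
    t0 = time.time()
    artifacts = []
    for fam in config.families:
        st = results["families"][fam.name]
        parents = st["parents"]
        snp_index = {s: j for j, s in enumerate(st["observed"].snp_ids)}
        gm, log = geno_qc.sequential_qc(st["observed"], config.qc)
        keep = [snp_index[s] for s in gm.snp_ids]
        mother = parents["mother"].dosage[keep]
        father = parents["fatherA"].dosage[keep]
        mendel = geno_qc.mendel_chi2_screen(gm, {"mother": mother, "father": father}, alpha=config.qc.alpha)
        retained = [j for j, s in enumerate(gm.snp_ids) if s not in set(mendel.removed_snps)]
        gm = gm.subset(snp_idx=np.asarray(retained, dtype=int))
        mother, father = mother[retained], father[retained]
        profile, cleaned = geno_qc.opposing_homozygote_profile(gm, {"fatherA": father})
        mixture = geno_qc.detect_paternity_mixture(profile, rate_column="rate_fatherA")
        log.to_csv(out / f"{fam.name}_qc_log.tsv", sep="\t", index=False)
        _write_json(
            {
                "verdict": mixture.verdict,
                "fraction_a": mixture.fraction_a,
                "se": mixture.se,
                "n_flagged": mixture.n_flagged,
                "n_total": mixture.n_total,
                "evidence": mixture.evidence,
            },
            out / f"{fam.name}_mixture.json",
        )
        st["qc_genotypes"] = cleaned
        st["mixture"] = mixture
        st["parent_dosages"] = {"mother": mother, "father": father}
        if st["observed"].probs is not None:
            cdf = geno_qc.callrate_cdf(st["observed"].probs, p=0.9)
            cdf.to_csv(out / f"{fam.name}_callrate_cdf.tsv", sep="\t", index=False, float_format="%.6g")
            artifacts.append(out / f"{fam.name}_callrate_cdf.tsv")

        results["_stage"] = "grm"
        freq_source = "observed" if mixture.verdict == "mixture" else "parental"
        g = grm_mod.grm_from_genotypes(cleaned, parents=st["parent_dosages"], freq_source=freq_source)
        io.write_grm(g, out / f"{fam.name}_grm.txt")
        st["grm"] = g
        artifacts += [
            out / f"{fam.name}_qc_log.tsv",
            out / f"{fam.name}_mixture.json",
            out / f"{fam.name}_grm.txt",
            out / (f"{fam.name}_grm.txt.json"),
        ]
    manifest.record("qc+grm", t0, artifacts)


def _stage_trials(config: RunConfig, out: Path, manifest: _Manifest, results: dict, lmap) -> None:
    results["_stage"] = "fit"
    t0 = time.time()
    artifacts = []
    for fam in config.families:
        st = results["families"][fam.name]
        for site in config.sites:
            trial = simdata.simulate_trial(
                site,
                st["gv"].u,
                config.noise,
                seed=_subseed(config.seed, "trial", fam.name, site.name),
                genotype_ids=st["sim"].genotypes.ids,
                mean=config.mean,
                trait=config.trait,
            )
            tpath = out / f"trial_{site.name}_{fam.name}.tsv"
            io.write_trial_tsv(trial.frame, tpath)
            data = varcomp.TrialData.from_trial_frame(trial.frame, grm=st["grm"])
            fit = varcomp.fit(data, model=2, n_starts=config.fit_n_starts,
                              optimizer_seed=_subseed(config.seed, "fit", fam.name, site.name))
            profile = partition.profile_additive_fraction(
                data,
                base_fit=fit,
                n_coarse=config.profile_n_coarse,
                n_refine=config.profile_n_refine,
                label={"family": fam.name, "site": site.name, "trait": config.trait},
                n_starts=1,
                optimizer_seed=_subseed(config.seed, "profile", fam.name, site.name),
            )
            mixture = st["mixture"]
            coeffs = None
            if mixture.verdict == "mixture" and 0.5 < mixture.fraction_a <= 1.0:
                coeffs = partition.mixture_correction_coefficients(mixture.fraction_a)
                profile = partition.LikelihoodProfile(
                    grid=np.asarray([coeffs.correct_fa(r) for r in profile.grid]),
                    deviance=profile.deviance,
                    label=dict(profile.label, corrected=True),
                )
            f_a = coeffs.correct_fa(fit.params["r_a"]) if coeffs else fit.params["r_a"]
            sigma_p2, h2_broad, h2_narrow = partition.heritabilities(fit, f_a)
            fit_out = {
                "family": fam.name,
                "site": site.name,
                "model": 2,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "params": fit.params,
                "se": fit.se,
                "f_a": f_a,
                "mixture_corrected": coeffs is not None,
                "sigma_P2": sigma_p2,
                "H2": h2_broad,
                "h2": h2_narrow,
            }
            fpath = out / f"fit_{site.name}_{fam.name}.json"
            _write_json(fit_out, fpath)
            ppath = out / f"profile_{site.name}_{fam.name}.tsv"
            pd.DataFrame({"f_a": profile.grid, "deviance": profile.deviance}).to_csv(
                ppath, sep="\t", index=False, float_format="%.8g"
            )
            results["trials"][(site.name, fam.name)] = {"fit": fit_out, "profile": profile}
            artifacts += [tpath, fpath, ppath]
    manifest.record("fit+profile", t0, artifacts)


def _stage_pool_report(config: RunConfig, out: Path, manifest: _Manifest, results: dict) -> None:
    results["_stage"] = "pool"
    t0 = time.time()
    profiles = [t["profile"] for t in results["trials"].values()]
    pooled = partition.pool_profiles(profiles)
    consensus = {
        "f_a": pooled.estimate,
        "ci95": list(pooled.ci),
        "x2_heterogeneity": pooled.x2,
        "df": pooled.df,
        "p_value": pooled.p_value,
        "f_a_random_mating": partition.random_mating_conversion(pooled.estimate),
    }
    _write_json(consensus, out / "pooled.json")
    results["consensus"] = consensus

    lines = [
        "# Variance-partition report",
        "",
        "| site | family | sigma_P2 | sigma_u2 | H2 | f_a | h2 |",
        "|---|---|---|---|---|---|---|",
    ]
    for (site, fam), t in results["trials"].items():
        f = t["fit"]
        lines.append(
            f"| {site} | {fam} | {f['sigma_P2']:.3f} | {f['params']['sigma_u2']:.3f} "
            f"| {f['H2']:.3f} | {f['f_a']:.3f} | {f['h2']:.3f} |"
        )
    lines += [
        "",
        f"Consensus f_a = {pooled.estimate:.3f} (95% CI {pooled.ci[0]:.3f}, {pooled.ci[1]:.3f}); "
        f"heterogeneity X2 = {pooled.x2:.3f} on {pooled.df} df (P = {pooled.p_value:.3f}).",
        f"Random-mating-population equivalent: {consensus['f_a_random_mating']:.3f}.",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
    manifest.record("pool+report", t0, [out / "pooled.json", out / "report.md"])
    results.pop("_stage", None)
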