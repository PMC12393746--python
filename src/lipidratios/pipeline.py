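"""End-to-end orchestration: simulate -> harmonize -> ratios -> associations
-> LSEA -> GWAS, with deterministic seeding and a manifest of outputs.

A :class:`PipelineConfig` either points at input files or carries a
``simulate`` block (:class:`~lipidratios.simulate.SyntheticConfig`).  Every
output TSV starts with commented header lines recording the package
version, seed and stage, so a run is reproducible from its outputs alone;
the manifest records row counts and SHA-256 checksums (identical config +
seed => identical checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import association_frame, fit_association, sex_interaction
from .genotypes import write_vcf
from .gwas import (
    compute_grm, genomic_pcs, ld_prune, lmm_gwas, loco_grms,
    prepare_phenotype, sample_qc, snp_p_gain, variant_qc, VariantQCParams,
)
from .harmonize import (
    apply_correction, matched_subcohort_factors, pqc_median_center,
    reference_correction_factors,
)
from .io import (
    default_ratio_definitions_path, read_cohort, read_lipidomics,
    read_ratio_definitions, write_cohort, write_lipidomics,
)
from .lsea import default_lipid_sets, enrichment, residual_correlation, species_t_statistics
from .ratios import compute_ratio_matrix
from .simulate import GeneticConfig, SyntheticConfig, simulate_study

__all__ = ["PipelineConfig", "run", "ALL_STAGES"]

ALL_STAGES = ("simulate", "harmonize", "ratios", "assoc", "lsea", "gwas")


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    outcomes: tuple[str, ...] = ("WC", "BMI", "WHR")
    simulate: SyntheticConfig | None = None
    # input paths, used when no simulate block is given
    lipidomics_a: str | None = None
    cohort_a: str | None = None
    lipidomics_b: str | None = None
    cohort_b: str | None = None
    genotypes_vcf: str | None = None
    consensus: str | None = None
    ratio_definitions: str | None = None
    gwas_ratios: tuple[str, ...] = ("PC(O)/PC(P)",)
    n_matched_pairs: int = 1000
    n_tests: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim is not None:
            gen = sim.pop("genetics", "default")
            for key in ("n_samples", "scale_factors", "maf_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sc = SyntheticConfig(**sim)
            if gen is None:
                sc.genetics = None
            elif gen != "default":
                if "maf_range" in gen and isinstance(gen["maf_range"], list):
                    gen["maf_range"] = tuple(gen["maf_range"])
                sc.genetics = GeneticConfig(**gen)
            cfg.simulate = sc
        if cfg.simulate is None:
            for name in ("lipidomics_a", "cohort_a"):
                p = getattr(cfg, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config input {name!r} missing: {p}")
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# lipidratios {__version__}\n# seed: {config.seed}\n# stage: {stage}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g", index=index)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {},
    }

    def record(name: str, path: Path, n_rows: int) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "rows": int(n_rows), "sha256": _checksum(path)
        }

    # ---- inputs ----------------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate is not None:
            sim = config.simulate
            study = simulate_study(sim, config.seed)
            ds_a, co_a = study["dataset_a"], study["cohort_a"]
            ds_b, co_b = study["dataset_b"], study["cohort_b"]
            genotypes, consensus = study["genotypes"], study["consensus"]
            if "simulate" in config.stages:
                write_lipidomics(ds_a, out / "lipidomics_a.tsv")
                write_cohort(co_a, out / "cohort_a.tsv")
                write_lipidomics(ds_b, out / "lipidomics_b.tsv")
                write_cohort(co_b, out / "cohort_b.tsv")
                consensus.rename("consensus").to_csv(out / "consensus.tsv", sep="\t")
                record("lipidomics_a", out / "lipidomics_a.tsv", ds_a.n_samples)
                record("cohort_a", out / "cohort_a.tsv", len(co_a.table))
                record("lipidomics_b", out / "lipidomics_b.tsv", ds_b.n_samples)
                record("cohort_b", out / "cohort_b.tsv", len(co_b.table))
                record("consensus", out / "consensus.tsv", len(consensus))
                if genotypes is not None:
                    write_vcf(genotypes, out / "genotypes.vcf")
                    record("genotypes", out / "genotypes.vcf", genotypes.n_variants)
        else:
            ds_a = read_lipidomics(config.lipidomics_a)
            co_a = read_cohort(config.cohort_a)
            ds_b = read_lipidomics(config.lipidomics_b) if config.lipidomics_b else None
            co_b = read_cohort(config.cohort_b) if config.cohort_b else None
            genotypes = None
            if config.genotypes_vcf:
                from .genotypes import read_vcf
                genotypes = read_vcf(config.genotypes_vcf)
            consensus = (
                pd.read_csv(config.consensus, sep="\t", index_col=0)["consensus"]
                if config.consensus
                else None
            )

        # ---- harmonize ---------------------------------------------------
        stage = "harmonize"
        if "harmonize" in config.stages:
            ds_a = pqc_median_center(ds_a)
            if consensus is not None:
                f_ref = reference_correction_factors(ds_a, consensus)
                ds_a = apply_correction(ds_a, f_ref)
                f_ref.to_frame().to_csv(
                    out / "factors_reference_a.tsv", sep="\t", index=False
                )
                record("factors_reference_a", out / "factors_reference_a.tsv",
                       len(f_ref.factors))
            if ds_b is not None:
                ds_b = pqc_median_center(ds_b)
                f_m = matched_subcohort_factors(
                    ds_a, co_a, ds_b, co_b, n_pairs=config.n_matched_pairs
                )
                ds_b = apply_correction(ds_b, f_m)
                f_m.to_frame().to_csv(out / "factors_matched_b.tsv", sep="\t", index=False)
                record("factors_matched_b", out / "factors_matched_b.tsv",
                       len(f_m.factors))

        # ---- ratios ------------------------------------------------------
        stage = "ratios"
        matrices = {}
        definitions = []
        cohorts = {"a": (ds_a, co_a)}
        if ds_b is not None:
            cohorts["b"] = (ds_b, co_b)
        if {"ratios", "assoc", "gwas"} & set(config.stages):
            defs_path = config.ratio_definitions or default_ratio_definitions_path()
            definitions = read_ratio_definitions(defs_path, ds_a.annotations)
            for key, (ds, _) in cohorts.items():
                rm = compute_ratio_matrix(ds, definitions)
                matrices[key] = rm
                if "ratios" in config.stages:
                    rm.write(out / f"ratios_{key}.tsv", out / f"ratio_params_{key}.tsv")
                    record(f"ratios_{key}", out / f"ratios_{key}.tsv", len(rm.values))

        # ---- associations ------------------------------------------------
        stage = "assoc"
        if "assoc" in config.stages:
            for key, (ds, co) in cohorts.items():
                for outcome in config.outcomes:
                    recs = fit_association(
                        matrices[key], ds, definitions, co, outcome,
                        n_tests=config.n_tests or len(definitions),
                    )
                    frame = association_frame(recs)
                    path = out / f"assoc_{key}_{outcome}.tsv"
                    _write_tsv(frame, path, config, "assoc")
                    record(f"assoc_{key}_{outcome}", path, len(frame))
                inter = sex_interaction(
                    matrices[key], ds, definitions, co, config.outcomes[0],
                    n_tests=config.n_tests or len(definitions),
                )
                idf = pd.DataFrame(
                    {
                        "target": [r.target for r in inter],
                        "interaction_p": [r.interaction_p for r in inter],
                        "interaction_p_bh": [r.interaction_p_bh for r in inter],
                        "beta_female": [r.female.beta for r in inter],
                        "p_female": [r.female.p_bh for r in inter],
                        "p_gain_female": [r.female.p_gain for r in inter],
                        "beta_male": [r.male.beta for r in inter],
                        "p_male": [r.male.p_bh for r in inter],
                        "p_gain_male": [r.male.p_gain for r in inter],
                    }
                ).set_index("target")
                path = out / f"interaction_{key}_{config.outcomes[0]}.tsv"
                _write_tsv(idf, path, config, "assoc")
                record(f"interaction_{key}", path, len(idf))

        # ---- LSEA --------------------------------------------------------
        stage = "lsea"
        if "lsea" in config.stages:
            sets = default_lipid_sets(ds_a.annotations)
            tstats = species_t_statistics(ds_a, co_a, config.outcomes[0])
            corr = residual_correlation(ds_a, co_a)
            records = enrichment(tstats, corr, sets)
            edf = pd.DataFrame(
                [
                    {"set": r.name, "category": r.category, "n_lipids": r.n_lipids,
                     "score": r.score, "p": r.p, "p_bh": r.p_bh}
                    for r in records
                ]
            ).set_index("set")
            path = out / "lsea.tsv"
            _write_tsv(edf, path, config, "lsea")
            record("lsea", path, len(edf))

        # ---- GWAS --------------------------------------------------------
        stage = "gwas"
        if "gwas" in config.stages and genotypes is not None:
            key = "b" if "b" in cohorts else "a"
            ds, co = cohorts[key]
            gt, _ = sample_qc(genotypes)
            gt, qc_report = variant_qc(gt, VariantQCParams())
            pruned = ld_prune(gt)
            pcs = genomic_pcs(compute_grm(pruned), k=min(10, gt.n_samples - 1))
            locos = loco_grms(gt)
            rm = matrices[key]
            for label in config.gwas_ratios:
                if label not in rm.labels:
                    raise KeyError(f"gwas ratio {label!r} not in ratio matrix")
                pheno = prepare_phenotype(rm.values[label], co, pcs)
                res = lmm_gwas(pheno, gt, locos)
                safe = label.replace("/", "_over_").replace(" ", "")
                path = out / f"gwas_{safe}.tsv"
                _write_tsv(res, path, config, "gwas", index=False)
                record(f"gwas_{label}", path, len(res))
            manifest["gwas_qc"] = qc_report

    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
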