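"""Parameter-recovery and calibration experiments on synthetic data.

Cohort-level regression betas, GWAS hits and enrichment scores from the
source cohorts require individual-level data, so the package validates its
statistics with simulation experiments instead: each function here runs
one self-contained experiment end-to-end through the public pipeline and
returns the measured quantities.  The experiments double as worked
examples of how the stages compose.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import fit_linear
from .genotypes import GenotypeData
from .gwas import (
    compute_grm, genomic_pcs, ld_prune, lmm_gwas_multi, prepare_phenotype,
    reml_fit, snp_p_gain,
)
from .io import RatioDefinition, resolve_selector
from .lsea import LipidSet, enrichment, residual_correlation, species_t_statistics
from .ratios import _side_sum, compute_ratio_matrix
from .simulate import (
    GeneticConfig, SyntheticConfig, simulate_cohort, simulate_genotypes,
)

__all__ = [
    "causal_locus_trial",
    "causal_locus_pilot",
    "association_recovery_trial",
    "lsea_calibration",
    "reml_h2_recovery",
]


def _standardize(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=1)


def causal_locus_trial(
    seed: int,
    n_samples: int = 4000,
    n_snps: int = 5000,
    effect_a: float = 0.15,
) -> dict:
    """One replicate of the opposing-effect ratio-locus experiment.

    Simulates a genotyped cohort whose causal SNP raises the numerator
    class and lowers the denominator class of the target ratio, then runs
    the full GWAS pipeline (LD-pruned PCs, covariate + RINT phenotype,
    LOCO mixed model on the causal chromosome, SNP-level p-gain against
    the two component scans).  Returns the minimum p over the causal LD
    block, the causal-SNP p-gain and its significance threshold.
    """
    config = SyntheticConfig(
        n_samples=(100, n_samples),
        genetics=GeneticConfig(n_snps=n_snps, effect_a=effect_a),
        seed=seed,
    )
    g = config.genetics
    genotypes = simulate_genotypes(config)
    dataset, cohort = simulate_cohort(config, cohort="b", genotypes=genotypes)

    conc = dataset.concentrations.loc[dataset.biological_samples()]
    num = resolve_selector(g.numerator_class, dataset.annotations)
    den = resolve_selector(g.denominator_class, dataset.annotations)
    ratio = _standardize(np.log2(_side_sum(conc, num)) - np.log2(_side_sum(conc, den)))
    comp_n = _standardize(np.log2(_side_sum(conc, num)))
    comp_d = _standardize(np.log2(_side_sum(conc, den)))

    pcs = genomic_pcs(compute_grm(ld_prune(genotypes)), k=10)
    causal_chrom = str(g.causal_chrom)
    loco = {causal_chrom: compute_grm(genotypes, exclude_chrom=causal_chrom)}
    on_chrom = (genotypes.variants["chrom"].astype(str) == causal_chrom).to_numpy()
    panel = genotypes.subset_variants(on_chrom)

    phenos = pd.DataFrame(
        {
            "ratio": prepare_phenotype(ratio, cohort, pcs),
            "num": prepare_phenotype(comp_n, cohort, pcs),
            "den": prepare_phenotype(comp_d, cohort, pcs),
        }
    )
    res = lmm_gwas_multi(phenos, panel, loco)
    block_ids = genotypes.variants.loc[genotypes.variants["ld_block"], "id"]
    r = res["ratio"]
    block_min_p = float(r.loc[r["id"].isin(block_ids), "p"].min())
    gains = snp_p_gain(r, res["num"], res["den"])
    causal_row = gains.loc[gains["id"] == "rs_causal"].iloc[0]
    return {
        "block_min_p": block_min_p,
        "causal_p": float(r.loc[r["id"] == "rs_causal", "p"].iloc[0]),
        "causal_p_gain": float(causal_row["p_gain"]),
        "p_gain_threshold": float(causal_row["threshold"]),
        "p_gain_significant": bool(causal_row["p_gain_significant"]),
        "n_significant_snps": int(r["significant"].sum()),
    }


def causal_locus_pilot(n_seeds: int = 20, base_seed: int = 0, **kwargs) -> dict:
    """Run :func:`causal_locus_trial` over ``n_seeds`` independent seeds
    and report how often the locus reaches genome-wide significance and a
    significant SNP-level p-gain."""
    hits = gains = 0
    details = []
    for k in range(n_seeds):
        r = causal_locus_trial(seed=base_seed + 1000 + k, **kwargs)
        hits += r["block_min_p"] < 5e-8
        gains += r["p_gain_significant"]
        details.append(r)
    return {
        "n_seeds": n_seeds,
        "fraction_genomewide": hits / n_seeds,
        "fraction_p_gain_significant": gains / n_seeds,
        "details": details,
    }


def association_recovery_trial(
    seed: int,
    n_samples: int = 10000,
    beta_wc: float = -0.01,
    target_class: str = "PC(P)",
    reference_class: str = "PC",
) -> dict:
    """Inject a per-class WC effect and recover it through the ratio
    pipeline.

    With a log2-per-cm effect ``beta_wc`` on the target class and none on
    the reference class, the log2 class-sum ratio has true WC slope
    ``beta_wc``; the fitted standardized slope times the stored log2-ratio
    SD should recover it within sampling error.
    """
    config = SyntheticConfig(
        n_samples=(n_samples, 100),
        effect_wc={target_class: beta_wc},
        effect_sex={},
        effect_wc_sex={},
        genetics=None,
        seed=seed,
    )
    dataset, cohort = simulate_cohort(config, cohort="a")
    label = f"{target_class}/{reference_class}"
    definition = RatioDefinition(
        label=label,
        numerator=resolve_selector(target_class, dataset.annotations),
        denominator=resolve_selector(reference_class, dataset.annotations),
        numerator_selector=target_class,
        denominator_selector=reference_class,
    )
    rm = compute_ratio_matrix(dataset, [definition])
    design = cohort.table[["WC", "age", "sex"]].astype(float)
    fit = fit_linear(rm.values, design).loc[label]
    sd = float(rm.transform_params.loc[label, "sd"])
    return {
        "beta_true_log2": beta_wc,
        "beta_std": float(fit["beta"]),
        "se_std": float(fit["se"]),
        "beta_log2": float(fit["beta"]) * sd,
        "se_log2": float(fit["se"]) * sd,
        "p": float(fit["p"]),
    }


def lsea_calibration(
    seed: int = 0,
    n_datasets: int = 100,
    sets_per_dataset: int = 20,
    n_samples: int = 1000,
    n_species: int = 200,
    n_classes: int = 20,
    class_correlation: float = 0.6,
    alpha: float = 0.05,
) -> dict:
    """Null type-I error of the enrichment score, adjusted vs naive.

    Simulates datasets with within-class correlation but NO outcome
    effects, draws random within-class lipid sets, and measures the
    fraction of sets called significant at ``alpha`` by (a) the
    correlation-adjusted score and (b) the naive sqrt(set size)
    denominator.  The adjusted rate should sit at ``alpha``; the naive
    rate inflates with the within-set correlation.

    Sets drawn from one dataset share its t-statistics, so the budget is
    spread over many small datasets (few sets each) to keep the draws
    close to independent and the Monte-Carlo error near binomial.
    """
    rng = np.random.default_rng(seed)
    p_adj: list[float] = []
    p_naive: list[float] = []
    for d in range(n_datasets):
        config = SyntheticConfig(
            n_samples=(n_samples, 50),
            n_species=n_species,
            n_classes=n_classes,
            class_correlation=class_correlation,
            effect_wc={}, effect_sex={}, effect_wc_sex={},
            genetics=None,
            seed=seed * 10007 + d,
        )
        dataset, cohort = simulate_cohort(config, cohort="a")
        tstats = species_t_statistics(dataset, cohort, "WC")
        corr = residual_correlation(dataset, cohort)
        by_class: dict[str, list[str]] = {}
        for s, a in dataset.annotations.items():
            by_class.setdefault(a.class_code, []).append(s)
        classes = [c for c, m in by_class.items() if len(m) >= 3]
        sets = []
        for k in range(sets_per_dataset):
            cls = classes[int(rng.integers(len(classes)))]
            members = by_class[cls]
            size = int(rng.integers(2, min(len(members), 10) + 1))
            chosen = rng.choice(members, size=size, replace=False)
            sets.append(LipidSet(name=f"null{d}_{k}", category="class",
                                 members=tuple(chosen)))
        p_adj.extend(r.p for r in enrichment(tstats, corr, sets))
        p_naive.extend(
            r.p for r in enrichment(tstats, corr, sets, adjust_correlation=False)
        )
    p_adj_arr, p_naive_arr = np.asarray(p_adj), np.asarray(p_naive)
    n = len(p_adj_arr)
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n))
    return {
        "n_sets": n,
        "alpha": alpha,
        "mc_se": mc_se,
        "type1_adjusted": float((p_adj_arr < alpha).mean()),
        "type1_naive": float((p_naive_arr < alpha).mean()),
    }


def reml_h2_recovery(
    seed: int = 0,
    n_replicates: int = 50,
    n_samples: int = 1000,
    n_snps: int = 2000,
    h2: float = 0.5,
) -> dict:
    """REML heritability recovery on polygenic phenotypes.

    Each replicate simulates independent binomial genotypes, a dense
    polygenic phenotype with true heritability ``h2``, builds the GRM and
    estimates h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) by REML.  The
    per-replicate cohort is sized so the finite-sample convexity bias of
    the variance-ratio estimate is negligible against the Monte-Carlo
    spread of the 50-replicate mean.
    """
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_replicates):
        mafs = rng.uniform(0.1, 0.5, n_snps)
        d = rng.binomial(2, mafs[None, :], size=(n_samples, n_snps)).astype(float)
        p = d.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        z = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        m = z.shape[1]
        w = rng.standard_normal(m) * np.sqrt(h2 / m)
        y = z @ w + rng.standard_normal(n_samples) * np.sqrt(1 - h2)
        K = z @ z.T / m
        dvals, U = np.linalg.eigh(K)
        dvals = np.clip(dvals, 0.0, None)
        vc = reml_fit(dvals, U.T @ y, (U.T @ np.ones(n_samples))[:, None])
        estimates.append(vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2))
    est = np.asarray(estimates)
    return {
        "h2_true": h2,
        "h2_mean": float(est.mean()),
        "h2_se_of_mean": float(est.std(ddof=1) / np.sqrt(len(est))),
        "n_replicates": n_replicates,
    }
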