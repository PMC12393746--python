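"""Synthetic two-cohort plasma lipidome, covariates, genotypes and expression.

The generator emulates the statistical structure a lipid-ratio analysis
assumes so every downstream stage is testable without external data:

* a 735-species / 39-class lipidome whose log2 concentrations follow a
  within-class single-factor model (equicorrelation ``class_correlation``),
  plus per-class effects of waist circumference (WC) and sex, batch
  offsets, pooled-QC (PQC) samples carrying only technical structure, and
  reference-plasma samples whose expected concentrations are shared across
  cohorts up to a per-cohort global scale factor;
* obesity markers (WC, BMI, WHR) generated as near-deterministic functions
  of WC so their pairwise correlations exceed 0.9, mirroring their use as
  interchangeable outcomes;
* a genotype panel with independent binomial dosages, one LD block around
  a causal SNP that pushes the numerator class up and the denominator
  class down (opposing-effect ratio locus), and an optional polygenic
  background on the same ratio;
* two-group log-normal expression matrices with a per-gene shift vector.

One master seed drives everything through named, documented substreams
(bases, cohort A, cohort B, genetics, expression), so adding a stage never
perturbs earlier draws and identical seeds give bit-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .genotypes import GenotypeData, VARIANT_COLUMNS
from .io import CohortTable, LipidomicsDataset, annotations_from_names

__all__ = [
    "GeneticConfig",
    "SyntheticConfig",
    "default_species_roster",
    "species_roster",
    "consensus_concentrations",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_polygenic_phenotype",
    "simulate_study",
]

# ---------------------------------------------------------------------------
# species roster
# ---------------------------------------------------------------------------

_SN1 = ["16:0", "18:0", "18:1", "17:0", "19:0", "20:0"]
_SN2 = ["18:1", "18:2", "18:3", "20:3", "20:4", "20:5",
        "22:4", "22:5", "22:6", "16:0", "17:1", "20:2", "22:0", "24:1"]
_SINGLE = ["14:0", "15:0", "16:0", "16:1", "17:0", "18:0", "18:1", "18:2",
           "18:3", "20:0", "20:3", "20:4", "20:5", "22:4", "22:5", "22:6",
           "24:0", "24:1"]
_TG_CHAINS = ["14:0", "15:0", "16:0", "16:1", "17:0", "18:0", "18:1",
              "18:2", "18:3", "20:0", "20:4", "20:5", "22:6"]

# species named in the published tables/figures; these must exist in the
# default roster so the packaged ratio definitions resolve
_REQUIRED: dict[str, list[str]] = {
    "PE": ["PE(16:0_18:2)", "PE(16:0_20:4)", "PE(18:0_18:2)", "PE(18:0_20:4)",
           "PE(18:0_22:4)", "PE(18:0_22:5)", "PE(18:0_22:6)"],
    "PC": ["PC(16:0_18:2)", "PC(16:0_20:4)", "PC(16:0_18:1)", "PC(18:0_18:1)",
           "PC(18:0_18:2)", "PC(18:0_20:4)", "PC(18:0_22:4)", "PC(18:0_22:5)",
           "PC(18:0_22:6)"],
    "PE(P)": [
        "PE(P-16:0/18:2)", "PE(P-16:0/18:3) [n-3]", "PE(P-16:0/20:4)",
        "PE(P-16:0/20:5)", "PE(P-16:0/22:4)", "PE(P-16:0/22:5) [n-3]",
        "PE(P-16:0/22:5) [n-6]", "PE(P-16:0/22:6)",
        "PE(P-18:0/18:2)", "PE(P-18:0/18:3) [n-3]", "PE(P-18:0/20:4)",
        "PE(P-18:0/20:5)", "PE(P-18:0/22:4)", "PE(P-18:0/22:5) [n-3]",
        "PE(P-18:0/22:5) [n-6]", "PE(P-18:0/22:6)",
        "PE(P-18:1/18:3)",
    ],
    "PE(O)": ["PE(O-16:0/20:4)", "PE(O-18:0/20:4)", "PE(O-16:0/22:6)"],
    "PC(P)": ["PC(P-16:0/20:4)", "PC(P-18:0/20:4)", "PC(P-16:0/22:6)"],
    "PC(O)": ["PC(O-16:0/20:4)", "PC(O-18:0/20:4)", "PC(O-16:0/22:6)"],
    "LPE": ["LPE(16:0) [sn1]", "LPE(18:0) [sn1]", "LPE(18:1) [sn1]",
            "LPE(16:0) [sn2]", "LPE(18:0) [sn2]", "LPE(18:2) [sn2]"],
    "LPC": ["LPC(16:0) [sn1]", "LPC(18:0) [sn1]", "LPC(18:1) [sn1]",
            "LPC(16:0) [sn2]", "LPC(18:0) [sn2]", "LPC(18:2) [sn2]",
            "LPC(20:4) [sn2]", "LPC(22:4) [sn2]", "LPC(22:5) [sn2]",
            "LPC(22:6) [sn2]"],
    "LPE(P)": ["LPE(P-16:0)", "LPE(P-18:0)", "LPE(P-18:1)"],
    "LPC(P)": ["LPC(P-16:0)", "LPC(P-18:0)", "LPC(P-18:1)"],
    "LPC(O)": ["LPC(O-16:0)", "LPC(O-18:0)", "LPC(O-18:1)"],
}

# (class_code, target_count, kind); counts sum to 735 over 39 classes
_ROSTER_SPEC: list[tuple[str, int, str]] = [
    ("PE", 40, "diacyl"),
    ("PC", 80, "diacyl"),
    ("PE(P)", 28, "ether_p"),
    ("PC(P)", 20, "ether_p"),
    ("PE(O)", 16, "ether_o"),
    ("PC(O)", 18, "ether_o"),
    ("LPE", 10, "lyso"),
    ("LPC", 14, "lyso"),
    ("LPE(P)", 4, "lyso_p"),
    ("LPC(P)", 4, "lyso_p"),
    ("LPC(O)", 5, "lyso_o"),
    ("PI", 30, "diacyl"),
    ("LPI", 6, "single"),
    ("PS", 12, "diacyl"),
    ("LPS", 4, "single"),
    ("PG", 8, "diacyl"),
    ("LPG", 3, "single"),
    ("PA", 8, "diacyl"),
    ("LPA", 4, "single"),
    ("TG", 122, "tri"),
    ("TG(O)", 22, "tri_o"),
    ("DG", 25, "diacyl"),
    ("MG", 6, "single"),
    ("CE", 26, "single"),
    ("COH", 1, "bare"),
    ("DE", 4, "single"),
    ("FFA", 28, "single"),
    ("AC", 20, "single"),
    ("SM", 45, "sumcomp"),
    ("dhSM", 10, "sumcomp"),
    ("Cer", 30, "sumcomp"),
    ("dhCer", 12, "sumcomp"),
    ("HexCer", 22, "sumcomp"),
    ("Hex2Cer", 14, "sumcomp"),
    ("Hex3Cer", 10, "sumcomp"),
    ("GM3", 12, "sumcomp"),
    ("GM1", 6, "sumcomp"),
    ("Sph", 4, "sumcomp"),
    ("S1P", 2, "sumcomp"),
]


def _head_and_ether(class_code: str) -> tuple[str, str]:
    if class_code.endswith("(P)"):
        return class_code[:-3], "P"
    if class_code.endswith("(O)"):
        return class_code[:-3], "O"
    return class_code, ""


def _candidates(class_code: str, kind: str):
    head, _ = _head_and_ether(class_code)
    if kind == "bare":
        yield head
    elif kind == "diacyl":
        for c1, c2 in itertools.product(_SN1, _SN2):
            yield f"{head}({c1}_{c2})"
    elif kind in ("ether_p", "ether_o"):
        e = "P" if kind == "ether_p" else "O"
        for c1, c2 in itertools.product(_SN1, _SN2):
            yield f"{head}({e}-{c1}/{c2})"
    elif kind == "lyso":
        for c in _SINGLE:
            yield f"{head}({c}) [sn1]"
    elif kind in ("lyso_p", "lyso_o"):
        e = "P" if kind == "lyso_p" else "O"
        for c in _SINGLE:
            yield f"{head}({e}-{c})"
    elif kind == "single":
        for c in _SINGLE:
            yield f"{head}({c})"
        for c in ["26:0", "26:1", "28:0", "28:1", "30:1", "32:1",
                  "19:1", "21:0", "23:0", "25:0"]:
            yield f"{head}({c})"
    elif kind == "tri":
        for c1, c2, c3 in itertools.combinations_with_replacement(_TG_CHAINS, 3):
            yield f"{head}({c1}_{c2}_{c3})"
    elif kind == "tri_o":
        for c1, c2, c3 in itertools.combinations_with_replacement(_TG_CHAINS[:8], 3):
            yield f"{head}(O-{c1}/{c2}/{c3})"
    elif kind == "sumcomp":
        for c in range(30, 46):
            for d in range(0, 4):
                yield f"{head}({c}:{d})"
    else:  # pragma: no cover
        raise ValueError(f"unknown roster kind {kind!r}")


def default_species_roster() -> dict[str, list[str]]:
    """Ordered class -> species-name roster: 39 classes, 735 species."""
    roster: dict[str, list[str]] = {}
    for class_code, target, kind in _ROSTER_SPEC:
        names = list(_REQUIRED.get(class_code, []))
        for cand in _candidates(class_code, kind):
            if len(names) >= target:
                break
            if cand not in names:
                names.append(cand)
        if len(names) != target:
            raise RuntimeError(
                f"roster for {class_code}: wanted {target}, built {len(names)}"
            )
        roster[class_code] = names
    return roster


def species_roster(n_species: int, n_classes: int) -> dict[str, list[str]]:
    """A reduced roster for small simulations: first ``n_classes`` classes
    of the default roster, members allocated round-robin up to
    ``n_species`` (every class keeps at least one member)."""
    if not 1 <= n_classes <= n_species:
        raise ValueError("need n_species >= n_classes >= 1")
    full = default_species_roster()
    if n_classes > len(full):
        raise ValueError(f"at most {len(full)} classes available")
    classes = list(full)[:n_classes]
    roster = {c: [full[c][0]] for c in classes}
    count = n_classes
    depth = 1
    while count < n_species:
        progressed = False
        for c in classes:
            if count >= n_species:
                break
            if depth < len(full[c]):
                roster[c].append(full[c][depth])
                count += 1
                progressed = True
        depth += 1
        if not progressed and count < n_species:
            raise ValueError(f"roster exhausted at {count} species")
    return roster


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# per-class WC effects on log2 concentration (per cm), the study-like default:
# ether classes fall and neutral/diacyl classes rise with waist circumference
DEFAULT_WC_EFFECTS: dict[str, float] = {
    "PE": 0.004, "PC": 0.002,
    "PE(P)": -0.004, "PE(O)": -0.003, "PC(P)": -0.006, "PC(O)": -0.004,
    "LPE": -0.003, "LPC": -0.002, "LPE(P)": -0.002, "LPC(P)": -0.005,
    "TG": 0.010, "TG(O)": 0.005, "DG": 0.008,
}
DEFAULT_SEX_EFFECTS: dict[str, float] = {
    "PE": 0.10, "TG": 0.15, "PE(P)": -0.05, "LPC": -0.08,
}
# extra WC slope in males (outcome x sex interaction)
DEFAULT_WC_SEX_EFFECTS: dict[str, float] = {
    "LPC": -0.004, "LPE": -0.004,
}


@dataclass
class GeneticConfig:
    """Genotype-panel block of the synthetic configuration."""

    n_snps: int = 5000
    n_chromosomes: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_copy_prob: float = 0.85  # haplotype-copy prob inside the LD block
    causal_maf: float = 0.3
    causal_chrom: int = 1  # 1-based
    effect_a: float = 0.15  # per-allele log2 shift: +a numerator, -a denominator
    numerator_class: str = "PC(O)"
    denominator_class: str = "PC(P)"
    polygenic_h2: float = 0.2  # heritability of the target log2 ratio

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        if not 0 < self.causal_maf <= 0.5:
            raise ValueError("causal MAF must lie in (0, 0.5]")
        if not 0 <= self.polygenic_h2 < 1:
            raise ValueError("polygenic heritability must lie in [0, 1)")
        if self.n_snps < self.ld_block_size:
            raise ValueError("n_snps smaller than the LD block size")
        if not 1 <= self.causal_chrom <= self.n_chromosomes:
            raise ValueError("causal chromosome out of range")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic two-cohort design.

    Cohort sizes default to the two source cohorts (10,339 and 4,492
    biological samples); the lipidome defaults to 735 species in 39
    classes with within-class correlation 0.6.
    """

    n_samples: tuple[int, int] = (10339, 4492)
    n_species: int = 735
    n_classes: int = 39
    class_correlation: float = 0.6
    bio_sd: float = 0.5  # per-species biological log2 SD
    effect_wc: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_WC_EFFECTS))
    effect_sex: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_SEX_EFFECTS))
    effect_wc_sex: dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_WC_SEX_EFFECTS))
    n_batches: int = 4
    batch_sd: float = 0.25  # log2 SD of per-(species, batch) offsets
    n_pqc_per_batch: int = 5
    pqc_noise_sd: float = 0.05
    n_reference_samples: int = 12  # reference plasma run occasions
    reference_noise_sd: float = 0.05
    scale_factors: tuple[float, float] = (1.0, 1.15)  # per-cohort global scale
    wc_mean: float = 93.0  # centering constant for WC effects (cm)
    genetics: GeneticConfig | None = dc_field(default_factory=GeneticConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_species >= self.n_classes >= 1:
            raise ValueError("need n_species >= n_classes >= 1")
        if not 0 <= self.class_correlation < 1:
            raise ValueError("class correlation must lie in [0, 1)")
        if self.n_batches < 1 or self.n_pqc_per_batch < 0:
            raise ValueError("invalid batch configuration")
        if min(self.scale_factors) <= 0:
            raise ValueError("scale factors must be positive")
        if self.genetics is not None:
            self.genetics.validate()

    def roster(self) -> dict[str, list[str]]:
        if (self.n_species, self.n_classes) == (735, 39):
            return default_species_roster()
        return species_roster(self.n_species, self.n_classes)


# substream order under the master seed (fixed; adding stages appends)
_STREAMS = {"bases": 0, "cohort_a": 1, "cohort_b": 2, "genetics": 3, "expression": 4}


def _stream(seed: int, name: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed)
    return np.random.default_rng(ss.spawn(len(_STREAMS))[_STREAMS[name]])


def _species_bases(config: SyntheticConfig, seed: int) -> pd.Series:
    rng = _stream(seed, "bases")
    roster = config.roster()
    names = [s for members in roster.values() for s in members]
    base = rng.uniform(-2.0, 8.0, size=len(names))
    return pd.Series(base, index=names, name="log2_base")


def consensus_concentrations(config: SyntheticConfig, seed: int | None = None) -> pd.Series:
    """Expected reference-plasma concentrations (the harmonization target)."""
    seed = config.seed if seed is None else seed
    return (2.0 ** _species_bases(config, seed)).rename("consensus")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _per_species_effect(table: dict[str, float], names: list[str],
                        class_of: dict[str, str]) -> np.ndarray:
    """Species-level effect vector: species key wins over class key."""
    return np.array(
        [table.get(s, table.get(class_of[s], 0.0)) for s in names], dtype=float
    )


def simulate_cohort(
    config: SyntheticConfig,
    seed: int | None = None,
    cohort: str = "a",
    genotypes: GenotypeData | None = None,
) -> tuple[LipidomicsDataset, CohortTable]:
    """Simulate one cohort's lipidome and covariate table.

    ``cohort`` selects the sample size, scale factor and random substream
    ("a" or "b").  When ``genotypes`` is given (sample count matching the
    cohort's biological samples), the causal-SNP and polygenic effects of
    ``config.genetics`` are written into the numerator/denominator class
    concentrations.
    """
    seed = config.seed if seed is None else seed
    if cohort not in ("a", "b"):
        raise ValueError("cohort must be 'a' or 'b'")
    idx = 0 if cohort == "a" else 1
    n = config.n_samples[idx]
    scale = config.scale_factors[idx]
    rng = _stream(seed, f"cohort_{cohort}")

    roster = config.roster()
    names = [s for members in roster.values() for s in members]
    class_of = {s: c for c, members in roster.items() for s in members}
    cls_list = list(roster)
    cls_idx = np.array([cls_list.index(class_of[s]) for s in names])
    base = _species_bases(config, seed).to_numpy()

    prefix = cohort.upper()
    ids = [f"{prefix}{i:06d}" for i in range(n)]

    # --- covariates -------------------------------------------------------
    age = rng.normal(50.0, 12.0, size=n)
    while (age < 25).any():  # truncate at 25 by redrawing
        bad = age < 25
        age[bad] = rng.normal(50.0, 12.0, size=int(bad.sum()))
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    wc = np.where(sex == 1, rng.normal(98.0, 12.0, n), rng.normal(88.0, 13.0, n))
    wc = np.clip(wc, 55.0, None)
    bmi = 2.0 + 0.28 * wc + rng.normal(0.0, 0.35, n)
    whr = 0.35 + 0.0055 * wc + 0.02 * sex + rng.normal(0.0, 0.004, n)
    chol = rng.normal(5.5, 1.0, n)
    diabetes = rng.binomial(1, 0.07, n)
    cvd = rng.binomial(1, 0.05, n)
    cohort_df = pd.DataFrame(
        {
            "age": age, "sex": sex.astype(int), "WC": wc, "BMI": bmi, "WHR": whr,
            "total_cholesterol": chol,
            "disease_diabetes": diabetes, "disease_cvd": cvd,
        },
        index=pd.Index(ids, name="sample_id"),
    )

    # --- biological concentrations ---------------------------------------
    rho = config.class_correlation
    factors = rng.standard_normal((n, len(cls_list)))
    eps = rng.standard_normal((n, len(names)))
    x = base[None, :] + config.bio_sd * (
        np.sqrt(rho) * factors[:, cls_idx] + np.sqrt(1.0 - rho) * eps
    )
    b_wc = _per_species_effect(config.effect_wc, names, class_of)
    b_sex = _per_species_effect(config.effect_sex, names, class_of)
    b_wcsex = _per_species_effect(config.effect_wc_sex, names, class_of)
    wc_c = wc - config.wc_mean
    x += wc_c[:, None] * b_wc[None, :]
    x += sex[:, None] * b_sex[None, :]
    x += (sex * wc_c)[:, None] * b_wcsex[None, :]

    batch_labels = np.array(
        [f"{prefix}batch{i % config.n_batches}" for i in range(n)]
    )
    batch_names = [f"{prefix}batch{k}" for k in range(config.n_batches)]
    offsets = rng.normal(0.0, config.batch_sd, size=(config.n_batches, len(names)))
    batch_of = {b: k for k, b in enumerate(batch_names)}
    x += offsets[[batch_of[b] for b in batch_labels], :]

    # --- genetic effects on the target ratio classes ----------------------
    if genotypes is not None and config.genetics is not None:
        g = config.genetics
        if genotypes.n_samples != n:
            raise ValueError("genotype sample count does not match cohort size")
        num_mask = np.array([class_of[s] == g.numerator_class for s in names])
        den_mask = np.array([class_of[s] == g.denominator_class for s in names])
        if not num_mask.any() or not den_mask.any():
            raise ValueError("causal classes absent from the species roster")
        causal_j = int(genotypes.variants.index[genotypes.variants["id"] == "rs_causal"][0])
        dose = np.nan_to_num(genotypes.dosages[:, causal_j])
        x[:, num_mask] += (g.effect_a * dose)[:, None]
        x[:, den_mask] -= (g.effect_a * dose)[:, None]
        if g.polygenic_h2 > 0:
            u = _polygenic_component(genotypes, config, rng)
            x[:, num_mask] += (0.5 * u)[:, None]
            x[:, den_mask] -= (0.5 * u)[:, None]

    x += np.log2(scale)
    bio = pd.DataFrame(2.0 ** x, index=ids, columns=names)

    # --- PQC samples: batch offset + technical noise only -----------------
    pqc_rows, pqc_ids, pqc_batches = [], [], []
    for k, bname in enumerate(batch_names):
        for r in range(config.n_pqc_per_batch):
            noise = rng.normal(0.0, config.pqc_noise_sd, len(names))
            pqc_rows.append(2.0 ** (base + offsets[k] + noise + np.log2(scale)))
            pqc_ids.append(f"{prefix}PQC_b{k}_{r}")
            pqc_batches.append(bname)

    # --- reference samples: shared expectation x cohort scale --------------
    ref_rows, ref_ids, ref_batches = [], [], []
    for r in range(config.n_reference_samples):
        k = r % config.n_batches
        noise = rng.normal(0.0, config.reference_noise_sd, len(names))
        ref_rows.append(2.0 ** (base + offsets[k] + noise + np.log2(scale)))
        ref_ids.append(f"{prefix}REF_{r}")
        ref_batches.append(batch_names[k])

    extra = pd.DataFrame(
        pqc_rows + ref_rows, index=pqc_ids + ref_ids, columns=names
    )
    conc = pd.concat([bio, extra])
    batch = pd.Series(
        list(batch_labels) + pqc_batches + ref_batches, index=conc.index, name="batch"
    )
    is_pqc = pd.Series(False, index=conc.index)
    is_pqc.loc[pqc_ids] = True
    is_ref = pd.Series(False, index=conc.index)
    is_ref.loc[ref_ids] = True

    dataset = LipidomicsDataset(
        concentrations=conc,
        annotations=annotations_from_names(names),
        batch=batch,
        is_pqc=is_pqc,
        is_reference=is_ref,
        provenance=[f"simulated cohort {cohort} seed={seed}"],
    )
    return dataset, CohortTable(cohort_df)


def _polygenic_component(
    genotypes: GenotypeData, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Polygenic effect on the target log2 ratio, scaled so its share of
    the ratio's non-causal variance equals ``polygenic_h2``."""
    g = config.genetics
    d = np.nan_to_num(genotypes.dosages)
    if "ld_block" in genotypes.variants.columns:
        in_block = genotypes.variants["ld_block"].to_numpy(bool)
    else:
        in_block = np.zeros(genotypes.n_variants, dtype=bool)
    z = d[:, ~in_block]
    p = z.mean(axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    z = (z[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
    w = rng.standard_normal(z.shape[1]) / np.sqrt(z.shape[1])
    u = z @ w
    u = (u - u.mean()) / max(u.std(), 1e-12)
    # non-genetic variance of the log2 class-sum ratio ~ 2 * class-level var;
    # class log2 variance under the factor model is dominated by the shared
    # factor, bio_sd^2 * rho
    v0 = 2.0 * (config.bio_sd ** 2) * max(config.class_correlation, 0.05)
    target_var = g.polygenic_h2 / (1.0 - g.polygenic_h2) * v0
    return u * np.sqrt(target_var)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SyntheticConfig, seed: int | None = None) -> GenotypeData:
    """Simulate the cohort-b genotype panel described by ``config.genetics``.

    Dosages are Binomial(2, MAF) independent across variants, except an LD
    block of ``ld_block_size`` variants sharing haplotypes with the causal
    SNP (id ``rs_causal``, mid-chromosome on ``causal_chrom``).  Variants
    occupy contiguous position blocks per chromosome.
    """
    if config.genetics is None:
        raise ValueError("config has no genetic block")
    g = config.genetics
    seed = config.seed if seed is None else seed
    rng = _stream(seed, "genetics")
    n = config.n_samples[1]
    m = g.n_snps

    per_chrom = m // g.n_chromosomes
    chroms = np.minimum(np.arange(m) // max(per_chrom, 1), g.n_chromosomes - 1) + 1
    pos = (np.arange(m) % max(per_chrom, 1) + 1) * 10_000

    mafs = rng.uniform(*g.maf_range, size=m)
    causal_candidates = np.flatnonzero(chroms == g.causal_chrom)
    causal_j = int(causal_candidates[len(causal_candidates) // 2])
    block = np.arange(causal_j, min(causal_j + g.ld_block_size, m))
    block = block[chroms[block] == g.causal_chrom]
    if len(block) < g.ld_block_size:
        lo = max(causal_j - (g.ld_block_size - len(block)), causal_candidates[0])
        block = np.arange(lo, block[-1] + 1)
    mafs[block] = g.causal_maf

    dosages = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)
    # LD block: copy causal haplotypes with probability ld_copy_prob
    h1 = rng.binomial(1, g.causal_maf, n)
    h2 = rng.binomial(1, g.causal_maf, n)
    dosages[:, causal_j] = h1 + h2
    for j in block:
        if j == causal_j:
            continue
        keep1 = rng.random(n) < g.ld_copy_prob
        keep2 = rng.random(n) < g.ld_copy_prob
        a1 = np.where(keep1, h1, rng.binomial(1, g.causal_maf, n))
        a2 = np.where(keep2, h2, rng.binomial(1, g.causal_maf, n))
        dosages[:, j] = a1 + a2

    refs = np.full(m, "A", dtype=object)
    alts = np.full(m, "G", dtype=object)
    pal = (np.arange(m) % 50 == 49) & ~np.isin(np.arange(m), block)
    alts[pal] = "T"
    ids = np.array([f"rs{j}" for j in range(m)], dtype=object)
    ids[causal_j] = "rs_causal"

    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms],
            "pos": pos,
            "id": ids,
            "ref": refs,
            "alt": alts,
            "call_rate": 1.0,
            "MAC": 0,
            "MAF": np.nan,
            "hwe_p": np.nan,
            "imputation_r2": rng.uniform(0.7, 1.0, m),
            "palindromic": False,
        },
        columns=VARIANT_COLUMNS,
    )
    variants["ld_block"] = np.isin(np.arange(m), block)
    sample_ids = pd.Index([f"B{i:06d}" for i in range(n)])
    data = GenotypeData(sample_ids=sample_ids, variants=variants, dosages=dosages)
    data.refresh_metadata()
    return data


def simulate_polygenic_phenotype(
    genotypes: GenotypeData, h2: float, seed: int
) -> np.ndarray:
    """A phenotype y = u + e with Var(u)/Var(y) = ``h2`` where u is a dense
    polygenic score over all standardized variants (REML recovery oracle)."""
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    d = np.nan_to_num(genotypes.dosages)
    p = d.mean(axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    z = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
    w = rng.standard_normal(z.shape[1]) * np.sqrt(h2 / z.shape[1])
    u = z @ w
    e = rng.standard_normal(z.shape[0]) * np.sqrt(1.0 - h2)
    return u + e


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    n_per_group: tuple[int, int] = (74, 74),
    n_genes: int = 100,
    shift: np.ndarray | dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group log2 expression: Normal(0, 1) per gene, ``shift`` added to
    group 2.  Returns (genes-in-columns matrix, group labels)."""
    n1, n2 = n_per_group
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    rng = _stream(seed, "expression")
    shifts = np.zeros(n_genes)
    if isinstance(shift, dict):
        for k, v in shift.items():
            shifts[k] = v
    elif shift is not None:
        shifts = np.asarray(shift, dtype=float)
        if shifts.shape != (n_genes,):
            raise ValueError("shift vector length must equal n_genes")
    x1 = rng.standard_normal((n1, n_genes))
    x2 = rng.standard_normal((n2, n_genes)) + shifts[None, :]
    genes = [f"gene{j}" for j in range(n_genes)]
    ids = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
    mat = pd.DataFrame(np.vstack([x1, x2]), index=ids, columns=genes)
    groups = pd.Series([1] * n1 + [2] * n2, index=ids, name="group")
    return mat, groups


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(config: SyntheticConfig, seed: int | None = None) -> dict:
    """Simulate the full two-cohort design: cohort A (reference samples,
    no genotypes) and cohort B (genotyped).  Returns a dict with keys
    ``dataset_a``, ``cohort_a``, ``dataset_b``, ``cohort_b``,
    ``genotypes`` and ``consensus``."""
    seed = config.seed if seed is None else seed
    genotypes = simulate_genotypes(config, seed) if config.genetics else None
    ds_a, co_a = simulate_cohort(config, seed, cohort="a")
    ds_b, co_b = simulate_cohort(config, seed, cohort="b", genotypes=genotypes)
    return {
        "dataset_a": ds_a,
        "cohort_a": co_a,
        "dataset_b": ds_b,
        "cohort_b": co_b,
        "genotypes": genotypes,
        "consensus": consensus_concentrations(config, seed),
    }
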