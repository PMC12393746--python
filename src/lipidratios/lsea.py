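"""Correlation-adjusted lipid-set enrichment analysis (LSEA).

Lipid species within a class or pathway are strongly correlated, so simply
summing their association t-statistics and dividing by sqrt(set size)
overstates significance.  The enrichment score here divides the summed
t-statistics by the square root of the SUM of the covariate-adjusted
(residual) correlation matrix restricted to the set:

    score = (sum_i t_i) / sqrt(sum_ij C_ij)

Under the null the squared score tends to a chi-squared distribution with
one degree of freedom (equivalently the two-sided normal tail of the
score), which is what the adjustment buys: a perfectly duplicated member
inflates numerator and denominator by the same factor and leaves the score
unchanged, whereas the naive sqrt(n) denominator does not.

t-statistics come from the association module's per-species fits; LSEA
never refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust, fit_linear, standardized_log2_species
from .io import CohortTable, LipidomicsDataset

__all__ = [
    "LipidSet",
    "EnrichmentRecord",
    "residual_correlation",
    "enrichment",
    "species_t_statistics",
    "default_lipid_sets",
    "read_lipid_sets",
    "write_lipid_sets",
]

SET_CATEGORIES = ("domain", "subclass", "class", "feature", "PUFA-feature")


@dataclass(frozen=True)
class LipidSet:
    name: str
    category: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in SET_CATEGORIES:
            raise ValueError(f"unknown set category {self.category!r}")
        if len(self.members) < 1:
            raise ValueError(f"set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class EnrichmentRecord:
    name: str
    category: str
    n_lipids: int
    score: float
    p: float
    p_bh: float = np.nan


def residual_correlation(
    dataset: LipidomicsDataset,
    cohort: CohortTable,
    covariates=("age", "sex"),
    samples: pd.Index | None = None,
    species=None,
) -> pd.DataFrame:
    """Pearson correlation of species residuals after regressing out
    covariates (plain correlation when ``covariates`` is empty).

    Species are the standardized log2 concentrations; complete-case
    alignment with the covariates.  A species with zero residual variance
    is an error naming it.
    """
    if samples is None:
        samples = dataset.biological_samples()
    samples = pd.Index(samples).intersection(cohort.sample_ids)
    if species is None:
        species = list(dataset.species)
    Y = standardized_log2_species(dataset, species, samples).to_numpy(dtype=float)
    if covariates:
        C = cohort.table.loc[samples, list(covariates)].to_numpy(dtype=float)
        keep = ~(np.isnan(C).any(axis=1) | np.isnan(Y).any(axis=1))
        Y, C = Y[keep], C[keep]
        X = np.column_stack([np.ones(len(C)), C])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        Y = Y - X @ beta
    else:
        Y = Y[~np.isnan(Y).any(axis=1)]
    sd = Y.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [species[i] for i in dead[:5]]
        raise ValueError(f"zero residual variance for species: {names}")
    corr = np.corrcoef(Y, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=species, columns=species)


def species_t_statistics(
    dataset: LipidomicsDataset,
    cohort: CohortTable,
    outcome: str,
    covariates=("age", "sex"),
    samples: pd.Index | None = None,
) -> pd.Series:
    """Per-species association t-statistics against an outcome (standardized
    log2 species ~ outcome + covariates), the LSEA input."""
    if samples is None:
        samples = dataset.biological_samples()
    samples = pd.Index(samples).intersection(cohort.sample_ids)
    targets = standardized_log2_species(dataset, dataset.species, samples)
    design = cohort.table.loc[samples, [outcome] + list(covariates)].astype(float)
    fit = fit_linear(targets, design)
    return fit["t"]


def enrichment(
    t_stats: pd.Series,
    corr: pd.DataFrame,
    sets: list[LipidSet],
    adjust_correlation: bool = True,
) -> list[EnrichmentRecord]:
    """Correlation-adjusted enrichment score and chi-squared(1) p per set.

    ``adjust_correlation=False`` switches to the naive sqrt(set size)
    denominator (kept only to demonstrate its miscalibration on correlated
    sets).  A set whose correlation-block sum is nonpositive is an error.
    """
    records = []
    for s in sets:
        missing = [m for m in s.members if m not in t_stats.index]
        if missing:
            raise KeyError(f"set {s.name!r}: t-statistics missing for {missing[:5]}")
        t = t_stats.loc[list(s.members)].to_numpy(dtype=float)
        if adjust_correlation:
            block = corr.loc[list(s.members), list(s.members)].to_numpy(dtype=float)
            denom_sq = float(block.sum())
            if denom_sq <= 0:
                raise ValueError(
                    f"set {s.name!r}: correlation-block sum {denom_sq:.3g} <= 0"
                )
        else:
            denom_sq = float(len(s.members))
        score = float(t.sum() / np.sqrt(denom_sq))
        p = float(stats.chi2.sf(score ** 2, df=1))
        records.append(
            EnrichmentRecord(
                name=s.name, category=s.category, n_lipids=len(s.members),
                score=score, p=max(p, np.finfo(float).tiny),
            )
        )
    p_bh = bh_adjust([r.p for r in records])
    return [
        EnrichmentRecord(
            name=r.name, category=r.category, n_lipids=r.n_lipids,
            score=r.score, p=r.p, p_bh=float(q),
        )
        for r, q in zip(records, p_bh)
    ]


# ---------------------------------------------------------------------------
# set construction and IO
# ---------------------------------------------------------------------------

_DOMAINS = {
    "Sphingolipids": ("SM", "dhSM", "Cer", "dhCer", "HexCer", "Hex2Cer",
                      "Hex3Cer", "GM3", "GM1", "Sph", "S1P"),
    "Glycerophospholipids": ("PE", "PC", "PE(O)", "PE(P)", "PC(O)", "PC(P)",
                             "LPE", "LPC", "LPE(P)", "LPC(P)", "LPC(O)",
                             "PI", "LPI", "PS", "LPS", "PG", "LPG", "PA", "LPA"),
    "Neutral lipids": ("TG", "TG(O)", "DG", "MG", "CE", "COH", "DE", "FFA"),
}
_SUBCLASSES = {
    "Ether lipids": ("PE(O)", "PE(P)", "PC(O)", "PC(P)", "LPE(P)", "LPC(P)",
                     "LPC(O)", "TG(O)"),
    "Plasmalogens": ("PE(P)", "PC(P)", "LPE(P)", "LPC(P)"),
    "Lysophospholipids": ("LPE", "LPC", "LPE(P)", "LPC(P)", "LPC(O)",
                          "LPI", "LPS", "LPG", "LPA"),
    "Diacyl phospholipids": ("PE", "PC", "PI", "PS", "PG", "PA"),
}
_DNL_CHAINS = ("14:0", "14:1", "16:0", "16:1", "18:0", "18:1")


def default_lipid_sets(
    annotations, min_size: int = 2
) -> list[LipidSet]:
    """Structural/ontological sets over an annotation dict: domains,
    subclasses, one set per class, fatty-acid feature sets and n-3/n-6
    PUFA sets."""
    by_class: dict[str, list[str]] = {}
    for name, ann in annotations.items():
        by_class.setdefault(ann.class_code, []).append(name)

    sets: list[LipidSet] = []

    def add(name, category, members):
        members = tuple(dict.fromkeys(members))
        if len(members) >= min_size:
            sets.append(LipidSet(name=name, category=category, members=members))

    for dom, classes in _DOMAINS.items():
        add(dom, "domain", [s for c in classes for s in by_class.get(c, [])])
    for sub, classes in _SUBCLASSES.items():
        add(sub, "subclass", [s for c in classes for s in by_class.get(c, [])])
    for cls, members in by_class.items():
        add(cls, "class", members)

    by_chain: dict[str, list[str]] = {}
    for name, ann in annotations.items():
        for ch in ann.chains:
            by_chain.setdefault(ch, []).append(name)
    for ch in _DNL_CHAINS:
        add(f"FA {ch}", "feature", by_chain.get(ch, []))

    for series in ("n-3", "n-6"):
        members = [n for n, a in annotations.items() if a.omega_series == series]
        add(f"PUFA {series}", "PUFA-feature", members)
    return sets


def read_lipid_sets(path) -> list[LipidSet]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for name, grp in df.groupby("set", sort=False):
        out.append(
            LipidSet(
                name=name,
                category=grp["category"].iloc[0],
                members=tuple(grp["species"]),
            )
        )
    return out


def write_lipid_sets(sets: list[LipidSet], path) -> None:
    rows = [
        {"set": s.name, "category": s.category, "species": m}
        for s in sets
        for m in s.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
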