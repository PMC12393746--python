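"""Cross-cohort and cross-batch harmonization of lipid concentrations.

Three multiplicative corrections, mirroring how multi-site lipidomics
datasets are aligned in practice:

* **reference**: per-species factor = median concentration over the
  reference-plasma samples / consensus concentration; the dataset is
  DIVIDED by the factor, so corrected reference medians equal the
  consensus.
* **matched subcohort**: greedy 1:1 nearest-neighbour matching (exact on
  sex and disease flags, Euclidean on standardized age / BMI / total
  cholesterol); per-species factor = median in cohort A / median in cohort
  B over the matched samples; cohort B is MULTIPLIED by the factor,
  aligning it to cohort A.
* **PQC batch centering**: per-(species, batch) factor = batch PQC median
  / global PQC median; every sample in the batch is divided by it, so all
  per-batch PQC medians equal the global PQC median afterwards.  The
  operation is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable, LipidomicsDataset

__all__ = [
    "CorrectionFactors",
    "reference_correction_factors",
    "matched_subcohort_factors",
    "apply_correction",
    "pqc_median_center",
]


@dataclass
class CorrectionFactors:
    """Per-species (and optionally per-batch) positive correction factors."""

    method: str  # reference | matched_subcohort | pqc_batch
    factors: pd.Series  # per-species, for reference / matched_subcohort
    batch_factors: pd.DataFrame | None = None  # batches x species, pqc method
    matched_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.method not in ("reference", "matched_subcohort", "pqc_batch"):
            raise ValueError(f"unknown method {self.method!r}")
        vals = self.factors.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if (finite <= 0).any() or not np.isfinite(finite).all():
            raise ValueError("correction factors must be positive and finite")

    def to_frame(self) -> pd.DataFrame:
        if self.batch_factors is not None:
            long = self.batch_factors.stack().rename("factor").reset_index()
            long.columns = ["batch", "species", "factor"]
            long.insert(1, "method", self.method)
            return long
        df = self.factors.rename("factor").reset_index()
        df.columns = ["species", "factor"]
        df.insert(1, "method", self.method)
        df.insert(2, "batch", "")
        return df


def reference_correction_factors(
    dataset: LipidomicsDataset, consensus: pd.Series
) -> CorrectionFactors:
    """Factors aligning a dataset to consensus reference-plasma values.

    factor_s = median(reference-sample concentration of s) / consensus_s.
    """
    refs = dataset.concentrations[dataset.is_reference.astype(bool).to_numpy()]
    if refs.empty:
        raise ValueError("dataset has no reference samples")
    missing = [s for s in dataset.species if s not in consensus.index]
    if missing:
        raise ValueError(f"species absent from consensus: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    cons = consensus.loc[dataset.species].astype(float)
    bad = cons[(cons <= 0) | cons.isna()].index.tolist()
    if bad:
        raise ValueError(f"zero/missing consensus values for: {bad[:5]}")
    factors = refs.median() / cons
    return CorrectionFactors(method="reference", factors=factors)


def matched_subcohort_factors(
    dataset_a: LipidomicsDataset,
    cohort_a: CohortTable,
    dataset_b: LipidomicsDataset,
    cohort_b: CohortTable,
    n_pairs: int = 1000,
) -> CorrectionFactors:
    """Factors aligning cohort B to cohort A through matched sub-cohorts.

    Greedy nearest-neighbour 1:1 matching without replacement: exact on sex
    and every ``disease_*`` flag, Euclidean distance on standardized (age,
    BMI, total cholesterol).  Ties break on lexicographic sample id.  A
    B-sample with no remaining A-candidate in its stratum is skipped; fewer
    than ``n_pairs``/2 matches is an error.
    """
    covs = ["age", "BMI", "total_cholesterol"]
    strata_cols = ["sex"] + sorted(
        set(cohort_a.disease_columns()) & set(cohort_b.disease_columns())
    )
    ta = cohort_a.table.dropna(subset=covs + strata_cols)
    tb = cohort_b.table.dropna(subset=covs + strata_cols)
    ta = ta.loc[ta.index.intersection(dataset_a.biological_samples())]
    tb = tb.loc[tb.index.intersection(dataset_b.biological_samples())]
    if ta.empty or tb.empty:
        raise ValueError("no usable samples for matching")

    pooled = pd.concat([ta[covs], tb[covs]])
    mu, sd = pooled.mean(), pooled.std(ddof=1).replace(0.0, 1.0)
    za = (ta[covs] - mu) / sd
    zb = (tb[covs] - mu) / sd

    def stratum(t: pd.DataFrame) -> pd.Series:
        return t[strata_cols].astype(int).astype(str).agg("|".join, axis=1)

    sa, sb = stratum(ta), stratum(tb)
    if not set(sa) & set(sb):
        raise ValueError("no shared matching strata between cohorts")

    pairs: list[tuple[str, str]] = []
    available: dict[str, list[str]] = {
        key: sorted(idx) for key, idx in sa.groupby(sa).groups.items()
    }
    n_target = min(n_pairs, len(tb))
    for b_id in sorted(tb.index)[: len(tb)]:
        if len(pairs) >= n_target:
            break
        key = sb.loc[b_id]
        cands = available.get(key)
        if not cands:
            continue
        dists = np.linalg.norm(
            za.loc[cands].to_numpy() - zb.loc[b_id].to_numpy()[None, :], axis=1
        )
        best = int(np.argmin(dists))  # argmin takes the first = lexicographic tie-break
        a_id = cands.pop(best)
        pairs.append((a_id, b_id))
    if len(pairs) < n_pairs / 2:
        raise ValueError(
            f"only {len(pairs)} matched pairs formed (need >= {n_pairs / 2:.0f})"
        )

    ids_a = [p[0] for p in pairs]
    ids_b = [p[1] for p in pairs]
    shared = dataset_a.species.intersection(dataset_b.species)
    med_a = dataset_a.concentrations.loc[ids_a, shared].median()
    med_b = dataset_b.concentrations.loc[ids_b, shared].median()
    factors = med_a / med_b
    return CorrectionFactors(
        method="matched_subcohort", factors=factors, matched_pairs=pairs
    )


def apply_correction(
    dataset: LipidomicsDataset, factors: CorrectionFactors
) -> LipidomicsDataset:
    """Apply correction factors, returning a new dataset.

    Reference factors divide (align to consensus); matched-subcohort
    factors multiply (align B to A); PQC factors divide per batch.
    """
    out = dataset.copy()
    if factors.method == "pqc_batch":
        bf = factors.batch_factors
        for bname, row in bf.iterrows():
            mask = (out.batch == bname).to_numpy()
            out.concentrations.loc[mask, row.index] = (
                out.concentrations.loc[mask, row.index] / row
            )
        out.provenance.append("pqc_batch centering applied")
        return out

    missing = [s for s in dataset.species if s not in factors.factors.index]
    if missing:
        raise ValueError(f"missing correction factors for: {missing[:5]}")
    f = factors.factors.loc[dataset.species]
    if factors.method == "reference":
        out.concentrations = out.concentrations / f
    else:  # matched_subcohort
        out.concentrations = out.concentrations * f
    out.provenance.append(f"{factors.method} correction applied")
    return out


def pqc_median_center(dataset: LipidomicsDataset) -> LipidomicsDataset:
    """Median-center batches on their pooled-QC samples.

    Per (species, batch) factor = median(PQC in batch) / median(all PQC);
    all samples in the batch are divided by it.  A batch without PQC
    samples is an error; a species with no PQC value in some batch is left
    uncorrected there, with a warning.
    """
    is_pqc = dataset.is_pqc.astype(bool).to_numpy()
    pqc = dataset.concentrations[is_pqc]
    batches = pd.unique(dataset.batch)
    empty = [b for b in batches if not (dataset.batch[is_pqc] == b).any()]
    if len(pqc) == 0 or empty:
        raise ValueError(f"batch(es) without PQC samples: {empty or list(batches)}")

    global_med = pqc.median()
    rows = {}
    n_uncorrected = 0
    for b in batches:
        bm = pqc[(dataset.batch[is_pqc] == b).to_numpy()].median()
        factor = bm / global_med
        na = factor.isna() | (factor <= 0)
        n_uncorrected += int(na.sum())
        rows[b] = factor.where(~na, 1.0)
    if n_uncorrected:
        warnings.warn(
            f"{n_uncorrected} (species, batch) cells left uncorrected "
            "(missing or nonpositive PQC median)"
        )
    batch_factors = pd.DataFrame(rows).T
    batch_factors.index.name = "batch"
    cf = CorrectionFactors(
        method="pqc_batch",
        factors=batch_factors.stack(),
        batch_factors=batch_factors,
    )
    return apply_correction(dataset, cf)
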