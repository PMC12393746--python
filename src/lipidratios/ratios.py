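"""Class sums and standardized log2 lipid-ratio phenotypes.

A ratio phenotype is (sum of numerator species) / (sum of denominator
species) per sample, log2-transformed, then centered and scaled to unit
sample standard deviation (n-1 denominator) over non-missing entries.  The
per-ratio (mean, sd) of the log2 ratio are stored so the raw ratio can be
recovered exactly; standardization makes the phenotypes scale-invariant.

Within a side sum, missing member species count as zero unless ALL members
are missing; nonpositive concentrations are treated as missing for ratio
purposes because the log is undefined (class sums, by contrast, keep zeros).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LipidomicsDataset, RatioDefinition
from .nomenclature import LipidAnnotation
from .io import COMPOSITE_CLASSES

__all__ = ["RatioMatrix", "class_sums", "compute_ratio_matrix"]


@dataclass
class RatioMatrix:
    """Standardized log2 ratio phenotypes with back-transform parameters."""

    values: pd.DataFrame  # samples x ratio labels, standardized log2
    transform_params: pd.DataFrame  # per-ratio columns: mean, sd (of log2 ratio)

    def __post_init__(self) -> None:
        if not set(self.values.columns) <= set(self.transform_params.index):
            raise ValueError("transform params missing for some ratios")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def labels(self) -> pd.Index:
        return self.values.columns

    def back_transform(self) -> pd.DataFrame:
        """Recover the raw (unlogged) ratios from the stored parameters."""
        p = self.transform_params.loc[self.values.columns]
        log2r = self.values * p["sd"].to_numpy()[None, :] + p["mean"].to_numpy()[None, :]
        return 2.0 ** log2r

    def write(self, values_path, params_path) -> None:
        v = self.values.copy()
        v.index.name = "sample_id"
        v.to_csv(values_path, sep="\t", float_format="%.12g", na_rep="")
        p = self.transform_params.copy()
        p.index.name = "ratio"
        p.to_csv(params_path, sep="\t", float_format="%.12g")


def class_sums(dataset: LipidomicsDataset) -> LipidomicsDataset:
    """Aggregate species into class-level abundances.

    One column per class code (sum of member species, missing members
    counted as zero; a class value is missing only when every member is
    missing), plus the composite ether classes (Total PE Ether = PE(O) +
    PE(P), Total PC Ether = PC(O) + PC(P)).
    """
    classes = dataset.class_codes()
    conc = dataset.concentrations
    out = {}
    members_of: dict[str, list[str]] = {}
    for cls in pd.unique(classes):
        members = classes.index[classes == cls].tolist()
        members_of[cls] = members
    for comp, parts in COMPOSITE_CLASSES.items():
        members = [s for p in parts if p in members_of for s in members_of[p]]
        if members:
            members_of[comp] = members
    for cls, members in members_of.items():
        block = conc[members]
        total = block.sum(axis=1, skipna=True)
        all_missing = block.isna().all(axis=1)
        out[cls] = total.mask(all_missing)
    df = pd.DataFrame(out, index=conc.index)
    annotations = {
        cls: LipidAnnotation(species_name=cls, class_code=cls) for cls in df.columns
    }
    return LipidomicsDataset(
        concentrations=df,
        annotations=annotations,
        batch=dataset.batch.copy(),
        is_pqc=dataset.is_pqc.copy(),
        is_reference=dataset.is_reference.copy(),
        provenance=dataset.provenance + ["class sums"],
    )


def _side_sum(conc: pd.DataFrame, members: tuple[str, ...]) -> pd.Series:
    """Sum of member species; nonpositive values treated as missing; the
    sum is missing only when every member is missing."""
    block = conc[list(members)]
    block = block.where(block > 0)
    total = block.sum(axis=1, skipna=True)
    return total.mask(block.isna().all(axis=1))


def compute_ratio_matrix(
    dataset: LipidomicsDataset,
    definitions: list[RatioDefinition],
    samples: pd.Index | None = None,
) -> RatioMatrix:
    """Standardized log2 ratio matrix over the dataset's biological samples.

    A ratio value is missing where the denominator is nonpositive/missing
    or the numerator is wholly missing.  A constant or all-missing ratio
    column cannot be standardized and raises an error naming the ratio.
    """
    if samples is None:
        samples = dataset.biological_samples()
    conc = dataset.concentrations.loc[samples]
    cols = {}
    params = {}
    for d in definitions:
        missing = [s for s in d.numerator + d.denominator if s not in conc.columns]
        if missing:
            raise KeyError(f"ratio {d.label!r}: species not in dataset: {missing[:5]}")
        num = _side_sum(conc, d.numerator)
        den = _side_sum(conc, d.denominator)
        raw = num / den
        raw = raw.where((den > 0) & (num > 0))
        log2r = np.log2(raw)
        ok = log2r.dropna()
        if ok.empty:
            raise ValueError(f"ratio {d.label!r}: all values missing")
        mu = float(ok.mean())
        sd = float(ok.std(ddof=1))
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"ratio {d.label!r}: zero variance, cannot standardize")
        cols[d.label] = (log2r - mu) / sd
        params[d.label] = {"mean": mu, "sd": sd}
    values = pd.DataFrame(cols, index=conc.index)
    tp = pd.DataFrame(params).T
    tp.index.name = "ratio"
    return RatioMatrix(values=values, transform_params=tp)
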