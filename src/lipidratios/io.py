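"""Tabular IO and domain containers for the lipid-ratio pipeline.

Formats
-------
* Lipidomics: TSV/CSV, samples in rows (first column ``sample_id``), species
  in columns.  The reserved optional columns ``batch``, ``is_pqc`` and
  ``is_reference`` carry per-sample metadata; every other column must appear
  in the annotation table.  Missing values are empty cells or ``NA``.
* Annotations: TSV with columns (species, class, linkage, sn1, sn2, sn3,
  sn_known, omega, tags).
* Covariates: TSV with ``sample_id``, ``age``, ``sex`` (0 = female,
  1 = male), ``WC`` (cm), ``BMI`` (kg/m^2), ``WHR``, ``total_cholesterol``
  (mmol/L) and any number of binary ``disease_*`` flag columns.
* Ratio definitions: TSV with columns (label, numerator, denominator,
  annotation, provenance).  Selectors are species names, class codes
  (expanded against the annotations), composite classes such as
  ``Total PE Ether`` (= PE(O) + PE(P)), or ``;``-separated lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import LipidAnnotation, parse_lipid_name, render

__all__ = [
    "LipidomicsDataset",
    "CohortTable",
    "RatioDefinition",
    "read_lipidomics",
    "write_lipidomics",
    "read_annotations",
    "write_annotations",
    "read_cohort",
    "write_cohort",
    "read_ratio_definitions",
    "write_ratio_definitions",
    "resolve_selector",
    "default_ratio_definitions_path",
    "printed_associations_path",
]

_RESERVED = ("batch", "is_pqc", "is_reference")

# composite class selectors: union of the listed class codes
COMPOSITE_CLASSES: dict[str, tuple[str, ...]] = {
    "Total PE Ether": ("PE(O)", "PE(P)"),
    "Total PC Ether": ("PC(O)", "PC(P)"),
}


@dataclass
class LipidomicsDataset:
    """Samples x species concentration matrix with annotations and flags.

    ``concentrations`` is a float DataFrame (NaN = missing, all present
    values >= 0) indexed by unique sample ids with one column per species.
    """

    concentrations: pd.DataFrame
    annotations: dict[str, LipidAnnotation]
    batch: pd.Series | None = None
    is_pqc: pd.Series | None = None
    is_reference: pd.Series | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        conc = self.concentrations
        if conc.index.has_duplicates:
            dups = conc.index[conc.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if conc.columns.has_duplicates:
            dups = conc.columns[conc.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dups}")
        missing_ann = [s for s in conc.columns if s not in self.annotations]
        if missing_ann:
            raise ValueError(f"species without annotation: {missing_ann}")
        with np.errstate(invalid="ignore"):
            if (conc.to_numpy(dtype=float) < 0).any():
                raise ValueError("negative concentrations present")
        for name in ("batch", "is_pqc", "is_reference"):
            s = getattr(self, name)
            if s is not None and not s.index.equals(conc.index):
                raise ValueError(f"{name} index does not match sample ids")
        if self.is_pqc is None:
            self.is_pqc = pd.Series(False, index=conc.index)
        if self.is_reference is None:
            self.is_reference = pd.Series(False, index=conc.index)
        if self.batch is None:
            self.batch = pd.Series("batch0", index=conc.index)

    # -- convenience ---------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.concentrations.index

    @property
    def species(self) -> pd.Index:
        return self.concentrations.columns

    @property
    def n_samples(self) -> int:
        return len(self.concentrations)

    def class_codes(self) -> pd.Series:
        return pd.Series(
            {s: self.annotations[s].class_code for s in self.species}, name="class"
        )

    def biological_samples(self) -> pd.Index:
        keep = ~(self.is_pqc.astype(bool) | self.is_reference.astype(bool))
        return self.sample_ids[keep.to_numpy()]

    def copy(self) -> "LipidomicsDataset":
        return LipidomicsDataset(
            concentrations=self.concentrations.copy(),
            annotations=dict(self.annotations),
            batch=self.batch.copy(),
            is_pqc=self.is_pqc.copy(),
            is_reference=self.is_reference.copy(),
            provenance=list(self.provenance),
        )


@dataclass
class CohortTable:
    """Per-sample covariates (age, sex, obesity markers, disease flags)."""

    table: pd.DataFrame

    REQUIRED = ("age", "sex")
    MARKERS = ("WC", "BMI", "WHR")

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in cohort table")
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        for col in self.MARKERS:
            if col in t.columns:
                vals = t[col].dropna()
                if (vals <= 0).any():
                    raise ValueError(f"non-positive values in {col}")
        sexes = set(t["sex"].dropna().unique())
        if not sexes <= {0, 1}:
            raise ValueError(f"sex must be coded 0 (female) / 1 (male), got {sexes}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def disease_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("disease_")]


@dataclass(frozen=True)
class RatioDefinition:
    """A pathway-annotated numerator/denominator pair of species sets."""

    label: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    numerator_selector: str = ""
    denominator_selector: str = ""
    pathway_annotation: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError(f"ratio {self.label!r}: empty member set")
        if set(self.numerator) & set(self.denominator):
            overlap = sorted(set(self.numerator) & set(self.denominator))
            raise ValueError(f"ratio {self.label!r}: sides overlap on {overlap}")


# ---------------------------------------------------------------------------
# selectors
# ---------------------------------------------------------------------------

def resolve_selector(selector: str, annotations: dict[str, LipidAnnotation]) -> tuple[str, ...]:
    """Resolve a selector string to a tuple of concrete species names.

    Resolution order: exact species name; composite class (``Total X
    Ether``); class code (all annotated members); ``;``-separated list of
    selectors.  Raises ``KeyError`` naming the selector when it resolves to
    nothing.
    """
    selector = selector.strip()
    if ";" in selector:
        out: list[str] = []
        for part in selector.split(";"):
            out.extend(resolve_selector(part, annotations))
        return tuple(dict.fromkeys(out))
    if selector in annotations:
        return (selector,)
    if selector in COMPOSITE_CLASSES:
        members = [
            s
            for s, a in annotations.items()
            if a.class_code in COMPOSITE_CLASSES[selector]
        ]
        if not members:
            raise KeyError(f"selector {selector!r} resolves to no species")
        return tuple(members)
    members = [s for s, a in annotations.items() if a.class_code == selector]
    if not members:
        raise KeyError(f"selector {selector!r} resolves to no species")
    return tuple(members)


# ---------------------------------------------------------------------------
# lipidomics read/write
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_annotations(path: str | Path) -> dict[str, LipidAnnotation]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    out: dict[str, LipidAnnotation] = {}
    for _, row in df.iterrows():
        tags = tuple(t for t in str(row.get("tags", "")).split("|") if t)
        ann = LipidAnnotation(
            species_name=row["species"],
            class_code=row["class"],
            linkage=row.get("linkage", "acyl") or "acyl",
            sn1_chain=row.get("sn1") or None,
            sn2_chain=row.get("sn2") or None,
            sn3_chain=row.get("sn3") or None,
            sn_known=str(row.get("sn_known", "1")) in ("1", "True", "true", ""),
            omega_series=row.get("omega") or None,
            feature_tags=tags,
        )
        if row["species"] in out:
            raise ValueError(f"duplicate species annotation: {row['species']}")
        out[row["species"]] = ann
    return out


def write_annotations(annotations: dict[str, LipidAnnotation], path: str | Path) -> None:
    rows = [
        {
            "species": a.species_name,
            "class": a.class_code,
            "linkage": a.linkage,
            "sn1": a.sn1_chain or "",
            "sn2": a.sn2_chain or "",
            "sn3": a.sn3_chain or "",
            "sn_known": int(a.sn_known),
            "omega": a.omega_series or "",
            "tags": "|".join(a.feature_tags),
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def annotations_from_names(names) -> dict[str, LipidAnnotation]:
    """Annotate species by parsing their shorthand names."""
    return {n: parse_lipid_name(n) for n in names}


def read_lipidomics(
    path: str | Path,
    annotation_path: str | Path | None = None,
    annotations: dict[str, LipidAnnotation] | None = None,
) -> LipidomicsDataset:
    """Read a concentration table (+ annotations) into a dataset.

    Values failing nonnegativity are set missing with a warning counting
    them.  A header species absent from the annotations is an error listing
    the unmatched names (annotations default to parsing the header names).
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA", ""])
    meta = {name: df.pop(name) for name in _RESERVED if name in df.columns}
    df = df.astype(float)

    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
    if annotations is None:
        annotations = annotations_from_names(df.columns)
    unmatched = [s for s in df.columns if s not in annotations]
    if unmatched:
        raise ValueError(f"species missing from annotations: {unmatched}")

    neg = df.to_numpy() < 0
    n_neg = int(np.nansum(neg))
    if n_neg:
        warnings.warn(f"{n_neg} negative concentration value(s) set missing")
        df = df.mask(pd.DataFrame(neg, index=df.index, columns=df.columns))

    batch = meta.get("batch")
    if batch is not None:
        batch = batch.astype(str)
    return LipidomicsDataset(
        concentrations=df,
        annotations=annotations,
        batch=batch,
        is_pqc=meta["is_pqc"].astype(bool) if "is_pqc" in meta else None,
        is_reference=meta["is_reference"].astype(bool) if "is_reference" in meta else None,
        provenance=[f"read:{path}"],
    )


def write_lipidomics(dataset: LipidomicsDataset, path: str | Path) -> None:
    """Write a dataset with 12-significant-digit decimal text values."""
    df = dataset.concentrations.copy()
    df.insert(0, "batch", dataset.batch)
    df.insert(1, "is_pqc", dataset.is_pqc.astype(int))
    df.insert(2, "is_reference", dataset.is_reference.astype(int))
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.12g", na_rep="")


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA", ""])
    return CohortTable(df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    df = cohort.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.12g", na_rep="")


# ---------------------------------------------------------------------------
# ratio definitions
# ---------------------------------------------------------------------------

def read_ratio_definitions(
    path: str | Path, annotations: dict[str, LipidAnnotation]
) -> list[RatioDefinition]:
    """Read and resolve a ratio-definition table against annotations.

    Errors: unknown selector (named), empty resolution (named), overlapping
    sides, duplicate labels.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if df["label"].duplicated().any():
        dups = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate ratio labels: {dups}")
    defs: list[RatioDefinition] = []
    for _, row in df.iterrows():
        num = resolve_selector(row["numerator"], annotations)
        den = resolve_selector(row["denominator"], annotations)
        defs.append(
            RatioDefinition(
                label=row["label"],
                numerator=num,
                denominator=den,
                numerator_selector=row["numerator"],
                denominator_selector=row["denominator"],
                pathway_annotation=row.get("annotation", ""),
                provenance=row.get("provenance", ""),
            )
        )
    return defs


def write_ratio_definitions(defs: list[RatioDefinition], path: str | Path) -> None:
    rows = [
        {
            "label": d.label,
            "numerator": d.numerator_selector or ";".join(d.numerator),
            "denominator": d.denominator_selector or ";".join(d.denominator),
            "annotation": d.pathway_annotation,
            "provenance": d.provenance,
        }
        for d in defs
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def default_ratio_definitions_path() -> Path:
    """Path of the packaged 82-ratio definition table."""
    return Path(resources.files("lipidratios").joinpath("data/ratio_definitions.tsv"))


def printed_associations_path() -> Path:
    """Path of the packaged table of published class/species association rows."""
    return Path(resources.files("lipidratios").joinpath("data/printed_associations.tsv"))
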