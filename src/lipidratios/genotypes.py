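"""Genotype container and VCF 4.2 read/write.

Dosages live in a samples x variants float matrix in [0, 2] (NaN =
missing).  Variant metadata (chrom, pos, id, ref, alt, call rate, minor
allele count/frequency, imputation r2, palindromic flag) is a DataFrame
aligned with the dosage columns.  Files are written as plain-text VCF 4.2
with both GT (hard call, dosage rounded) and DS fields; reading prefers DS
and falls back to GT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeData", "read_vcf", "write_vcf"]

_PALINDROMES = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

VARIANT_COLUMNS = [
    "chrom", "pos", "id", "ref", "alt",
    "call_rate", "MAC", "MAF", "hwe_p", "imputation_r2", "palindromic",
]


@dataclass
class GenotypeData:
    """QC-ready dosage matrix with per-variant metadata."""

    sample_ids: pd.Index
    variants: pd.DataFrame
    dosages: np.ndarray  # n_samples x n_variants, float, NaN = missing

    def __post_init__(self) -> None:
        self.sample_ids = pd.Index(self.sample_ids)
        if self.sample_ids.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def refresh_metadata(self) -> None:
        """Recompute call rate, MAC, MAF and palindromic flags from dosages."""
        d = self.dosages
        present = ~np.isnan(d)
        n_present = present.sum(axis=0)
        call_rate = n_present / d.shape[0]
        with np.errstate(invalid="ignore"):
            af = np.nansum(d, axis=0) / np.maximum(2 * n_present, 1)
        maf = np.minimum(af, 1 - af)
        # minor allele count over observed hard calls
        hard = np.round(d)
        alt_count = np.nansum(hard, axis=0)
        mac = np.minimum(alt_count, 2 * n_present - alt_count)
        v = self.variants
        v["call_rate"] = call_rate
        v["MAC"] = mac.astype(int)
        v["MAF"] = maf
        v["palindromic"] = [
            (str(r).upper(), str(a).upper()) in _PALINDROMES
            for r, a in zip(v["ref"], v["alt"])
        ]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeData":
        mask = np.asarray(mask)
        return GenotypeData(
            sample_ids=self.sample_ids,
            variants=self.variants.loc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )

    def subset_samples(self, keep: pd.Index) -> "GenotypeData":
        idx = self.sample_ids.get_indexer(keep)
        if (idx < 0).any():
            raise KeyError("unknown sample ids in subset")
        return GenotypeData(
            sample_ids=pd.Index(keep),
            variants=self.variants.copy(),
            dosages=self.dosages[idx],
        )

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_AA, n_Aa, n_aa) hard-call counts for variant j (A = ref)."""
        hard = np.round(self.dosages[:, j])
        hard = hard[~np.isnan(hard)]
        return (
            int((hard == 0).sum()),
            int((hard == 1).sum()),
            int((hard == 2).sum()),
        )


def write_vcf(data: GenotypeData, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT and DS FORMAT fields."""
    v = data.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lipidratios\n")
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation r2">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, data.sample_ids))
            + "\n"
        )
        for j, row in v.iterrows():
            r2 = row.get("imputation_r2", np.nan)
            info = f"R2={r2:.4g}" if np.isfinite(r2) else "."
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["id"]),
                str(row["ref"]), str(row["alt"]), ".", "PASS", info, "GT:DS",
            ]
            col = data.dosages[:, j]
            calls = []
            for d in col:
                if np.isnan(d):
                    calls.append("./.:.")
                else:
                    g = int(round(d))
                    gt = ("0/0", "0/1", "1/1")[g]
                    calls.append(f"{gt}:{d:.4g}")
            fh.write("\t".join(fields + calls) + "\n")


def read_vcf(path: str | Path) -> GenotypeData:
    """Read a VCF (GT and/or DS) into a :class:`GenotypeData`.

    Dosages come from DS when present, otherwise from the GT hard call.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples)
    rows = []
    cols = []
    for var in vcf:
        r2 = var.INFO.get("R2")
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "id": var.ID if var.ID else f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "call_rate": np.nan,
                "MAC": 0,
                "MAF": np.nan,
                "hwe_p": np.nan,
                "imputation_r2": float(r2) if r2 is not None else np.nan,
                "palindromic": False,
            }
        )
        ds = var.format("DS")
        if ds is not None:
            col = ds[:, 0].astype(float)
            col[col < -0.5] = np.nan  # cyvcf2 missing sentinel
        else:
            gt = np.asarray(var.gt_types, dtype=float)  # 0,1,3 alt counts; 2=unknown
            col = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt))
        cols.append(col)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    data = GenotypeData(sample_ids=samples, variants=variants, dosages=dosages)
    data.refresh_metadata()
    return data
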