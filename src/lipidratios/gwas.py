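"""Mixed-model genome-wide association for ratio phenotypes.

Stages: sample and variant QC; a genetic relationship matrix (GRM) from
standardized dosages with leave-one-chromosome-out (LOCO) construction to
avoid proximal contamination; genomic principal components; phenotype
preparation (covariate adjustment then rank-based inverse normal
transform, RINT); and an EMMA-style linear mixed model — variance
components estimated once per chromosome by REML on the null model via a
one-time eigendecomposition of that chromosome's LOCO GRM, then a
generalized-least-squares Wald test per variant under the fixed variance
ratio.  SNP-level p-gain compares each variant's ratio p-value against the
component-lipid GWAS p-values.

Model: y = X beta + g + e, g ~ N(0, sigma_g^2 K), e ~ N(0, sigma_e^2 I),
with delta = sigma_e^2 / sigma_g^2 profiled by golden-section search on
log(delta) in [-10, 10].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .genotypes import GenotypeData
from .io import CohortTable

__all__ = [
    "GRMatrix",
    "VarianceComponents",
    "VariantQCParams",
    "hwe_test",
    "sample_qc",
    "variant_qc",
    "compute_grm",
    "loco_grms",
    "genomic_pcs",
    "rint",
    "prepare_phenotype",
    "reml_fit",
    "lmm_gwas",
    "snp_p_gain",
    "genomic_inflation",
    "GENOME_WIDE_P",
]

GENOME_WIDE_P = 5e-8


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Pearson 1-df chi-squared test of Hardy-Weinberg proportions.

    Monomorphic counts return p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or (n_AA + n_Aa + n_aa) < 1:
        raise ValueError("genotype counts must be nonnegative with total >= 1")
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def sample_qc(
    genotypes: GenotypeData,
    missing_threshold: float = 0.03,
    het_sd_threshold: float = 5.0,
) -> tuple[GenotypeData, pd.DataFrame]:
    """Drop samples with missingness > 3% or heterozygosity beyond 5 SD of
    the sample-wise mean.  Returns (filtered data, per-sample report)."""
    d = genotypes.dosages
    n, m = d.shape
    missing = np.isnan(d).mean(axis=1)
    hard = np.round(d)
    het = np.nansum(hard == 1, axis=1) / np.maximum((~np.isnan(hard)).sum(axis=1), 1)
    mu, sd = het.mean(), het.std(ddof=1)
    het_z = (het - mu) / sd if sd > 0 else np.zeros(n)

    reasons = []
    for i, sid in enumerate(genotypes.sample_ids):
        r = []
        if missing[i] > missing_threshold:
            r.append("missingness")
        if abs(het_z[i]) > het_sd_threshold:
            r.append("heterozygosity")
        if r:
            reasons.append({"sample_id": sid, "reason": "+".join(r),
                            "missingness": missing[i], "het_z": het_z[i]})
    report = pd.DataFrame(reasons, columns=["sample_id", "reason", "missingness", "het_z"])
    keep = ~genotypes.sample_ids.isin(report["sample_id"])
    if keep.sum() < 10:
        raise ValueError(f"fewer than 10 samples remain after QC ({int(keep.sum())})")
    kept = GenotypeData(
        sample_ids=genotypes.sample_ids[keep],
        variants=genotypes.variants.copy(),
        dosages=genotypes.dosages[np.asarray(keep)],
    )
    kept.refresh_metadata()
    return kept, report


@dataclass
class VariantQCParams:
    """Thresholds for the two QC stages (None disables a filter).

    Defaults mirror the standard array pipeline: pre-imputation call rate
    >= 95%, minor allele count >= 10, HWE p >= 5e-4, palindromic SNPs with
    MAF > 0.4 dropped; post-imputation MAC >= 5 and imputation r2 >= 0.3.
    """

    call_rate_min: float | None = 0.95
    mac_min: int | None = 10
    hwe_p_min: float | None = 5e-4
    palindromic_maf_max: float | None = 0.4
    post_mac_min: int | None = 5
    imputation_r2_min: float | None = 0.3


def variant_qc(
    genotypes: GenotypeData, params: VariantQCParams | None = None
) -> tuple[GenotypeData, dict[str, int]]:
    """Drop variants failing any enabled filter; report counts per filter."""
    params = params or VariantQCParams()
    genotypes.refresh_metadata()
    v = genotypes.variants
    d = genotypes.dosages
    if np.nanmax(np.abs(d - np.round(d))) > 1e-9:
        warnings.warn("fractional dosages: HWE computed on rounded hard calls")

    hwe_p = np.array([hwe_test(*genotypes.genotype_counts(j)) for j in range(len(v))])
    v["hwe_p"] = hwe_p

    fails: dict[str, np.ndarray] = {}
    if params.call_rate_min is not None:
        fails["call_rate"] = v["call_rate"].to_numpy() < params.call_rate_min
    if params.mac_min is not None:
        fails["mac"] = v["MAC"].to_numpy() < params.mac_min
    if params.hwe_p_min is not None:
        fails["hwe"] = hwe_p < params.hwe_p_min
    if params.palindromic_maf_max is not None:
        fails["palindromic"] = (
            v["palindromic"].to_numpy(bool)
            & (v["MAF"].to_numpy() > params.palindromic_maf_max)
        )
    if params.post_mac_min is not None:
        fails["post_mac"] = v["MAC"].to_numpy() < params.post_mac_min
    if params.imputation_r2_min is not None:
        r2 = v["imputation_r2"].to_numpy(float)
        fails["imputation_r2"] = np.isfinite(r2) & (r2 < params.imputation_r2_min)

    report = {name: int(mask.sum()) for name, mask in fails.items()}
    drop = np.zeros(len(v), dtype=bool)
    for mask in fails.values():
        drop |= mask
    report["n_input"] = len(v)
    report["n_removed"] = int(drop.sum())
    report["n_kept"] = int((~drop).sum())
    if report["n_kept"] == 0:
        raise ValueError("no variants survive QC")
    return genotypes.subset_variants(~drop), report


# ---------------------------------------------------------------------------
# GRM / PCs
# ---------------------------------------------------------------------------

@dataclass
class GRMatrix:
    """Genetic relationship matrix K = Z Z^T / m over standardized dosages."""

    matrix: np.ndarray
    sample_ids: pd.Index
    m_variants: int
    excluded_chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.sample_ids),) * 2:
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM not symmetric")


def _standardized_dosages(
    genotypes: GenotypeData, variant_mask: np.ndarray
) -> tuple[np.ndarray, int]:
    """Mean-imputed, (d - 2p)/sqrt(2p(1-p)) standardized dosage columns;
    monomorphic variants skipped with a warning."""
    d = genotypes.dosages[:, variant_mask].copy()
    p = np.nanmean(d, axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    if (~ok).any():
        warnings.warn(f"skipping {int((~ok).sum())} monomorphic variant(s) in GRM")
    d = d[:, ok]
    p = p[ok]
    inds = np.where(np.isnan(d))
    d[inds] = (2 * p)[inds[1]]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    return z, z.shape[1]


def compute_grm(
    genotypes: GenotypeData, exclude_chrom: str | None = None
) -> GRMatrix:
    """GRM from all variants, optionally excluding one chromosome (LOCO)."""
    chroms = genotypes.variants["chrom"].astype(str).to_numpy()
    mask = np.ones(len(chroms), dtype=bool)
    if exclude_chrom is not None:
        mask = chroms != str(exclude_chrom)
        if not mask.any():
            raise ValueError(f"no variants left after excluding chrom {exclude_chrom}")
    z, m = _standardized_dosages(genotypes, mask)
    k = (z @ z.T) / m
    return GRMatrix(
        matrix=k, sample_ids=genotypes.sample_ids, m_variants=m,
        excluded_chromosome=str(exclude_chrom) if exclude_chrom is not None else None,
    )


def loco_grms(genotypes: GenotypeData) -> dict[str, GRMatrix]:
    """One GRM per chromosome, that chromosome left out.

    Built from per-chromosome cross-products so the genotype matrix is
    standardized once.
    """
    chroms = genotypes.variants["chrom"].astype(str).to_numpy()
    uniq = list(dict.fromkeys(chroms))
    pieces: dict[str, tuple[np.ndarray, int]] = {}
    for c in uniq:
        z, m = _standardized_dosages(genotypes, chroms == c)
        pieces[c] = (z @ z.T, m)
    total = sum(s for s, _ in pieces.values())
    m_total = sum(m for _, m in pieces.values())
    out = {}
    for c in uniq:
        s_c, m_c = pieces[c]
        if m_total - m_c <= 0:
            raise ValueError(f"no variants outside chromosome {c}")
        out[c] = GRMatrix(
            matrix=(total - s_c) / (m_total - m_c),
            sample_ids=genotypes.sample_ids,
            m_variants=m_total - m_c,
            excluded_chromosome=c,
        )
    return out


def ld_prune(
    genotypes: GenotypeData,
    r2_threshold: float = 0.2,
    window: int = 100,
    max_samples: int = 1000,
) -> GenotypeData:
    """Greedy LD pruning: scan variants in map order, keeping one when its
    squared correlation with every kept variant in the trailing window (on
    the same chromosome) stays below the threshold.

    Principal components are computed from a pruned panel so that local LD
    blocks cannot masquerade as axes of population structure — with panels
    where n/m is not small, an unpruned block can dominate the GRM
    spectrum and the PC adjustment would then absorb true locus effects.
    """
    d = genotypes.dosages
    if d.shape[0] > max_samples:  # r2 screening needs no more precision
        d = d[:max_samples]
    p = np.nanmean(d, axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    z = np.where(np.isnan(d), 0.0, d - 2 * p)
    norms = np.sqrt((z ** 2).sum(axis=0))
    norms[norms == 0] = 1.0
    z = z / norms
    chroms = genotypes.variants["chrom"].astype(str).to_numpy()
    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for j in range(genotypes.n_variants):
        if not ok[j]:
            continue
        prior = kept_by_chrom.get(chroms[j], [])[-window:]
        if prior:
            r = z[:, prior].T @ z[:, j]
            if np.max(r ** 2) > r2_threshold:
                continue
        kept.append(j)
        kept_by_chrom.setdefault(chroms[j], []).append(j)
    mask = np.zeros(genotypes.n_variants, dtype=bool)
    mask[kept] = True
    return genotypes.subset_variants(mask)


def genomic_pcs(grm: GRMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal component scores (eigenvectors x sqrt(eigenvalue))
    of the GRM, with a deterministic sign convention (largest-magnitude
    loading positive)."""
    n = len(grm.sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k > n // 2 or n < 200:
        vals, vecs = np.linalg.eigh(grm.matrix)
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        v0 = np.full(n, 1.0 / np.sqrt(n))
        vals, vecs = sparse.linalg.eigsh(grm.matrix, k=k, which="LA", v0=v0)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    vals = np.clip(vals, 0.0, None)
    scores = vecs * np.sqrt(vals)[None, :]
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=grm.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )


# ---------------------------------------------------------------------------
# phenotype preparation
# ---------------------------------------------------------------------------

def rint(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets:
    Phi^-1((rank - 3/8) / (n + 1/4)), average ranks for ties."""
    x = np.asarray(values, dtype=float)
    if np.unique(x[~np.isnan(x)]).size < 2:
        raise ValueError("rint needs at least 2 distinct values")
    out = np.full_like(x, np.nan)
    ok = ~np.isnan(x)
    ranks = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (ok.sum() + 0.25))
    return out


def prepare_phenotype(
    ratio_values: pd.Series,
    cohort: CohortTable,
    pcs: pd.DataFrame,
) -> pd.Series:
    """GWAS phenotype: residuals of the ratio on age, sex, age^2, age*sex,
    age^2*sex and the genomic PCs, then RINT.  Complete cases only."""
    common = ratio_values.index.intersection(cohort.sample_ids).intersection(pcs.index)
    y = ratio_values.loc[common].astype(float)
    t = cohort.table.loc[common]
    age = t["age"].astype(float)
    sex = t["sex"].astype(float)
    X = pd.DataFrame(
        {
            "age": age, "sex": sex, "age2": age ** 2,
            "age_sex": age * sex, "age2_sex": age ** 2 * sex,
        },
        index=common,
    )
    X = pd.concat([X, pcs.loc[common]], axis=1)
    keep = ~(y.isna() | X.isna().any(axis=1))
    y, X = y[keep], X[keep]
    Xm = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError("rank-deficient phenotype design matrix")
    beta, *_ = np.linalg.lstsq(Xm, y.to_numpy(), rcond=None)
    resid = y.to_numpy() - Xm @ beta
    return pd.Series(rint(resid), index=y.index, name=ratio_values.name)


# ---------------------------------------------------------------------------
# REML and the mixed-model scan
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    loglik: float


def _reml_loglik(
    log_delta: float, d: np.ndarray, ys: np.ndarray, Xs: np.ndarray, xtx_logdet: float
) -> tuple[float, float]:
    """Profiled REML log-likelihood at delta and the implied sigma_g^2."""
    delta = np.exp(log_delta)
    w = 1.0 / (d + delta)
    XtWX = Xs.T @ (w[:, None] * Xs)
    XtWy = Xs.T @ (w * ys)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(np.sum(w * r * r))
    n, p = len(ys), Xs.shape[1]
    sigma_g2 = rss / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0 or sigma_g2 <= 0:
        return -np.inf, 0.0
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma_g2)
        + (n - p)
        + np.sum(np.log(d + delta))
        + logdet_xtwx
        - xtx_logdet
    )
    return float(ll), sigma_g2


_GOLDEN = (np.sqrt(5) - 1) / 2


def reml_fit(
    d: np.ndarray,
    ys: np.ndarray,
    Xs: np.ndarray,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
    tol: float = 1e-6,
    max_iter: int = 200,
) -> VarianceComponents:
    """REML variance components via golden-section search on log(delta),
    operating in the GRM eigenbasis (``d`` eigenvalues, ``ys``/``Xs``
    rotated phenotype and fixed effects)."""
    _, xtx_logdet = np.linalg.slogdet(Xs.T @ Xs)
    f = lambda ld: _reml_loglik(ld, d, ys, Xs, xtx_logdet)[0]
    a, b = log_delta_bounds
    c1 = b - _GOLDEN * (b - a)
    c2 = a + _GOLDEN * (b - a)
    f1, f2 = f(c1), f(c2)
    it = 0
    while b - a > tol and it < max_iter:
        if f1 < f2:
            a, c1, f1 = c1, c2, f2
            c2 = a + _GOLDEN * (b - a)
            f2 = f(c2)
        else:
            b, c2, f2 = c2, c1, f1
            c1 = b - _GOLDEN * (b - a)
            f1 = f(c1)
        it += 1
    if it >= max_iter:
        raise RuntimeError(
            f"REML golden-section search did not converge (interval [{a:.3g}, {b:.3g}])"
        )
    ld = (a + b) / 2
    ll, sigma_g2 = _reml_loglik(ld, d, ys, Xs, xtx_logdet)
    if not np.isfinite(ll):
        raise RuntimeError("REML likelihood not finite at optimum")
    delta = float(np.exp(ld))
    return VarianceComponents(
        sigma_g2=float(sigma_g2), sigma_e2=float(sigma_g2 * delta),
        delta=delta, loglik=ll,
    )


def lmm_gwas_multi(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeData,
    loco: dict[str, GRMatrix],
    significance_p: float = GENOME_WIDE_P,
) -> dict[str, pd.DataFrame]:
    """Mixed-model association of several phenotypes against every variant.

    Per chromosome the LOCO GRM is eigendecomposed ONCE and the rotated
    genotypes are shared; variance components are estimated per phenotype
    by REML on the intercept-only null (EMMAX-style) and each variant gets
    a GLS Wald test under that phenotype's fixed variance ratio.  Missing
    dosages are mean-imputed.
    """
    common = phenotypes.index.intersection(genotypes.sample_ids)
    if len(common) < 10:
        raise ValueError("fewer than 10 samples shared between phenotypes and genotypes")
    gt = genotypes if common.equals(genotypes.sample_ids) else genotypes.subset_samples(common)
    Y = phenotypes.loc[common].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("phenotypes must be complete over the analysis samples")
    n = len(common)
    chroms = gt.variants["chrom"].astype(str).to_numpy()
    frames: dict[str, list[pd.DataFrame]] = {str(c): [] for c in phenotypes.columns}
    for c in dict.fromkeys(chroms):
        if c not in loco:
            raise KeyError(f"no LOCO GRM for chromosome {c}")
        grm = loco[c]
        if not grm.sample_ids.equals(common):
            idx = grm.sample_ids.get_indexer(common)
            if (idx < 0).any():
                raise ValueError("GRM does not cover the analysis samples")
            K = grm.matrix[np.ix_(idx, idx)]
        else:
            K = grm.matrix
        dvals, U = np.linalg.eigh(K)
        dvals = np.clip(dvals, 0.0, None)
        Ys = U.T @ Y
        Xs = (U.T @ np.ones(n))[:, None]

        mask = chroms == c
        G = gt.dosages[:, mask].copy()
        p_af = np.nanmean(G, axis=0) / 2.0
        inds = np.where(np.isnan(G))
        G[inds] = (2 * p_af)[inds[1]]
        G_rot = U.T @ G

        sub_base = gt.variants.loc[mask, ["chrom", "pos", "id", "ref", "alt"]]
        for t, label in enumerate(phenotypes.columns):
            ys = Ys[:, t]
            vc = reml_fit(dvals, ys, Xs)
            sw = np.sqrt(1.0 / (dvals + vc.delta))
            yw = sw * ys
            xw = sw * Xs[:, 0]
            Gw = sw[:, None] * G_rot

            a11 = float(xw @ xw)
            a12 = xw @ Gw
            a22 = np.einsum("ij,ij->j", Gw, Gw)
            b1 = float(xw @ yw)
            b2 = yw @ Gw
            det = a11 * a22 - a12 ** 2
            det = np.where(np.abs(det) < 1e-30, np.nan, det)
            beta = (a11 * b2 - a12 * b1) / det
            beta0 = (a22 * b1 - a12 * b2) / det
            rss = float(yw @ yw) - beta0 * b1 - beta * b2
            sigma2 = np.clip(rss, 0.0, None) / (n - 2)
            se = np.sqrt(sigma2 * a11 / det)
            tstat = beta / se
            p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
            p = np.clip(np.where(np.isnan(p), 1.0, p), np.finfo(float).tiny, 1.0)

            sub = sub_base.copy()
            sub["af"] = p_af
            sub["beta"] = beta
            sub["se"] = se
            sub["p"] = p
            sub["n"] = n
            sub["significant"] = sub["p"] < significance_p
            frames[str(label)].append(sub)
    return {
        label: pd.concat(parts, ignore_index=True) for label, parts in frames.items()
    }


def lmm_gwas(
    phenotype: pd.Series,
    genotypes: GenotypeData,
    loco: dict[str, GRMatrix],
    significance_p: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Single-phenotype convenience wrapper around :func:`lmm_gwas_multi`."""
    name = phenotype.name if phenotype.name is not None else "phenotype"
    res = lmm_gwas_multi(
        phenotype.to_frame(name), genotypes, loco, significance_p=significance_p
    )
    return res[str(name)]


def snp_p_gain(
    gwas_ratio: pd.DataFrame,
    gwas_component_a: pd.DataFrame,
    gwas_component_b: pd.DataFrame,
    n_significant_snps: int | None = None,
) -> pd.DataFrame:
    """Per-variant p-gain: min(component p) / ratio p, significant when
    above 10 x the number of genome-wide-significant SNPs for the ratio
    (the threshold used for SNP-level p-gain)."""
    r = gwas_ratio.set_index("id")
    a = gwas_component_a.set_index("id")
    b = gwas_component_b.set_index("id")
    if not (r.index.equals(a.index) and r.index.equals(b.index)):
        raise ValueError("variant sets differ between ratio and component GWAS")
    if n_significant_snps is None:
        n_significant_snps = int(r["significant"].sum())
    threshold = 10 * max(n_significant_snps, 1)
    gain = np.minimum(a["p"].to_numpy(), b["p"].to_numpy()) / r["p"].to_numpy()
    out = r[["chrom", "pos", "p"]].copy()
    out["p_component_min"] = np.minimum(a["p"].to_numpy(), b["p"].to_numpy())
    out["p_gain"] = gain
    out["threshold"] = threshold
    out["p_gain_significant"] = gain > threshold
    return out.reset_index()


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor lambda: median chi2 / expected median."""
    p = np.asarray(p_values, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
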