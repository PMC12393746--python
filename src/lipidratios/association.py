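"""Covariate-adjusted association of ratio phenotypes with obesity markers.

The reported effect is the *SD-change of the standardized log2 ratio per
unit of the obesity marker*: the ratio (or identically standardized log2
component lipid) is the regression RESPONSE and the marker the predictor,
adjusting for age and sex.  The p-gain statistic

    p_gain = min(p_numerator, p_denominator) / p_ratio

quantifies the information added by forming the ratio; it is deemed
significant when it exceeds 10 x the number of tests in the family
(10 x 82 = 820 for the ratio panel).  By default p-gain is computed from
the same BH-adjusted p-values that are reported; ``use_adjusted=False``
switches to raw p-values.

Sex interactions use the fully sex-interacted model
``target ~ outcome + age + sex + outcome:sex + age:sex`` so the implied
per-sex slopes coincide exactly with sex-stratified fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CohortTable, LipidomicsDataset, RatioDefinition
from .ratios import RatioMatrix

__all__ = [
    "AssociationRecord",
    "InteractionRecord",
    "bh_adjust",
    "p_gain",
    "fit_linear",
    "fit_association",
    "sex_interaction",
    "standardized_log2_species",
    "concordance",
    "group_difference",
    "association_frame",
]


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class AssociationRecord:
    target: str
    outcome: str
    beta: float
    se: float
    t: float
    p: float
    p_bh: float
    n_used: int
    component_results: dict[str, dict[str, float]] = field(default_factory=dict)
    p_gain: float | None = None
    p_gain_significant: bool | None = None


@dataclass
class InteractionRecord:
    target: str
    outcome: str
    interaction_p: float
    interaction_p_bh: float
    female: AssociationRecord | None = None
    male: AssociationRecord | None = None


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def p_gain(ratio_p: float, component_ps, n_tests: int) -> tuple[float, bool]:
    """min(component p) / ratio p, significant when > 10 x n_tests."""
    component_ps = np.asarray(component_ps, dtype=float)
    if ratio_p <= 0:
        raise ValueError("ratio p-value must be positive (clip upstream)")
    if np.any(component_ps <= 0) or np.any(component_ps > 1) or ratio_p > 1:
        raise ValueError("p-values must lie in (0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    value = float(component_ps.min() / ratio_p)
    return value, value > 10 * n_tests


def p_gain_threshold(n_tests: int) -> float:
    return 10.0 * n_tests


# ---------------------------------------------------------------------------
# OLS core (multi-response, complete-case per fit)
# ---------------------------------------------------------------------------

def fit_linear(
    targets: pd.DataFrame,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of every target column on the design matrix (with intercept).

    Returns per-target beta/se/t/p for the FIRST design column (the
    outcome), complete-case per fit.  Raises for constant outcomes or when
    fewer observations than parameters + 2 remain.
    """
    common = targets.index.intersection(design.index)
    Y = targets.loc[common].to_numpy(dtype=float)
    Xd = design.loc[common].to_numpy(dtype=float)
    if np.isnan(Xd).any():
        keep = ~np.isnan(Xd).any(axis=1)
        Y, Xd = Y[keep], Xd[keep]
    X = np.column_stack([np.ones(len(Xd)), Xd])
    k = X.shape[1]
    if np.ptp(Xd[:, 0]) == 0:
        raise ValueError("constant outcome column")

    out = np.empty((Y.shape[1], 5))
    col_missing = np.isnan(Y).any(axis=0)

    def _fit_block(Yb: np.ndarray, Xb: np.ndarray) -> np.ndarray:
        n = Xb.shape[0]
        if n <= k + 1:
            raise ValueError(f"too few complete cases (n={n}, parameters={k})")
        xtx = Xb.T @ Xb
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (Xb.T @ Yb)
        resid = Yb - Xb @ beta
        sigma2 = (resid ** 2).sum(axis=0) / (n - k)
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        t = beta / se
        p = 2 * stats.t.sf(np.abs(t), df=n - k)
        res = np.empty((Yb.shape[1], 5))
        res[:, 0] = beta[1]
        res[:, 1] = se[1]
        res[:, 2] = t[1]
        res[:, 3] = p[1]
        res[:, 4] = n
        return res

    if (~col_missing).any():
        out[~col_missing] = _fit_block(Y[:, ~col_missing], X)
    for j in np.flatnonzero(col_missing):
        keep = ~np.isnan(Y[:, j])
        out[j] = _fit_block(Y[keep][:, [j]], X[keep])[0]

    df = pd.DataFrame(
        out, index=targets.columns, columns=["beta", "se", "t", "p", "n_used"]
    )
    df["p"] = df["p"].clip(lower=np.finfo(float).tiny)
    df["n_used"] = df["n_used"].astype(int)
    return df


def _design(cohort: CohortTable, outcome: str, covariates) -> pd.DataFrame:
    cols = [outcome] + [c for c in covariates]
    return cohort.table[cols].astype(float)


def standardized_log2_species(
    dataset: LipidomicsDataset, species, samples: pd.Index | None = None
) -> pd.DataFrame:
    """log2-transformed, zero-mean/unit-SD species columns (same transform
    the ratios get), nonpositive values treated as missing."""
    if samples is None:
        samples = dataset.biological_samples()
    block = dataset.concentrations.loc[samples, list(species)]
    block = block.where(block > 0)
    logb = np.log2(block)
    return (logb - logb.mean()) / logb.std(ddof=1)


# ---------------------------------------------------------------------------
# ratio association with component lipids and p-gain
# ---------------------------------------------------------------------------

def fit_association(
    ratio_matrix: RatioMatrix,
    dataset: LipidomicsDataset,
    definitions: list[RatioDefinition],
    cohort: CohortTable,
    outcome: str,
    covariates=("age", "sex"),
    n_tests: int | None = None,
    use_adjusted: bool = True,
) -> list[AssociationRecord]:
    """Associate every ratio (and its two component sides, fitted with the
    identical model) with an obesity marker; BH within each family; p-gain
    per ratio."""
    n_tests = n_tests or len(definitions)
    samples = ratio_matrix.sample_ids.intersection(cohort.sample_ids)
    design = _design(cohort, outcome, covariates)

    ratio_fit = fit_linear(ratio_matrix.values.loc[samples], design)
    ratio_fit["p_bh"] = bh_adjust(ratio_fit["p"].to_numpy())

    # component "lipids" are the side sums, standardized like the ratios
    comp_cols: dict[str, pd.Series] = {}
    from .ratios import _side_sum

    conc = dataset.concentrations.loc[samples]
    for d in definitions:
        for side_label, members in (
            (d.numerator_selector or "+".join(d.numerator), d.numerator),
            (d.denominator_selector or "+".join(d.denominator), d.denominator),
        ):
            if side_label not in comp_cols:
                s = _side_sum(conc, members)
                s = s.where(s > 0)
                logs = np.log2(s)
                comp_cols[side_label] = (logs - logs.mean()) / logs.std(ddof=1)
    comp_df = pd.DataFrame(comp_cols, index=samples)
    comp_fit = fit_linear(comp_df, design)
    comp_fit["p_bh"] = bh_adjust(comp_fit["p"].to_numpy())

    key = "p_bh" if use_adjusted else "p"
    records = []
    for d in definitions:
        num_label = d.numerator_selector or "+".join(d.numerator)
        den_label = d.denominator_selector or "+".join(d.denominator)
        rrow = ratio_fit.loc[d.label]
        comp = {
            lab: {
                "beta": float(comp_fit.loc[lab, "beta"]),
                "p": float(comp_fit.loc[lab, "p"]),
                "p_bh": float(comp_fit.loc[lab, "p_bh"]),
            }
            for lab in (num_label, den_label)
        }
        gain, sig = p_gain(
            float(rrow[key]), [comp[num_label][key], comp[den_label][key]], n_tests
        )
        records.append(
            AssociationRecord(
                target=d.label,
                outcome=outcome,
                beta=float(rrow["beta"]),
                se=float(rrow["se"]),
                t=float(rrow["t"]),
                p=float(rrow["p"]),
                p_bh=float(rrow["p_bh"]),
                n_used=int(rrow["n_used"]),
                component_results=comp,
                p_gain=gain,
                p_gain_significant=sig,
            )
        )
    return records


def association_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Tabular view of association records (one row per ratio)."""
    rows = []
    for r in records:
        row = {
            "target": r.target, "outcome": r.outcome, "beta": r.beta, "se": r.se,
            "t": r.t, "p": r.p, "p_bh": r.p_bh, "n_used": r.n_used,
            "p_gain": r.p_gain, "p_gain_significant": r.p_gain_significant,
        }
        for i, (lab, c) in enumerate(r.component_results.items(), 1):
            row[f"component{i}"] = lab
            row[f"component{i}_beta"] = c["beta"]
            row[f"component{i}_p"] = c["p"]
            row[f"component{i}_p_bh"] = c["p_bh"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("target")


# ---------------------------------------------------------------------------
# sex interaction
# ---------------------------------------------------------------------------

def sex_interaction(
    ratio_matrix: RatioMatrix,
    dataset: LipidomicsDataset,
    definitions: list[RatioDefinition],
    cohort: CohortTable,
    outcome: str,
    n_tests: int | None = None,
    use_adjusted: bool = True,
) -> list[InteractionRecord]:
    """Outcome-by-sex interaction plus sex-stratified association records.

    The joint model interacts every covariate with sex, so the stratified
    per-sex fits and the joint model's implied per-sex slopes agree exactly.
    """
    n_tests = n_tests or len(definitions)
    t = cohort.table
    sexes = set(t["sex"].dropna().unique())
    if sexes != {0, 1}:
        raise ValueError("both sexes must be represented for interaction analysis")
    samples = ratio_matrix.sample_ids.intersection(cohort.sample_ids)

    # joint fully-interacted model: outcome, age, sex, outcome*sex, age*sex
    X = pd.DataFrame(
        {
            "outcome": t.loc[samples, outcome],
            "age": t.loc[samples, "age"],
            "sex": t.loc[samples, "sex"],
        },
        index=samples,
    ).astype(float)
    X["outcome_sex"] = X["outcome"] * X["sex"]
    X["age_sex"] = X["age"] * X["sex"]
    Y = ratio_matrix.values.loc[samples]
    inter = _interaction_pvalues(Y, X)
    inter_bh = bh_adjust(inter)

    per_sex: dict[int, list[AssociationRecord]] = {}
    for sex in (0, 1):
        sub_ids = t.index[t["sex"] == sex]
        sub_cohort = CohortTable(t.loc[sub_ids])
        sub_matrix = RatioMatrix(
            values=ratio_matrix.values.loc[samples.intersection(sub_ids)],
            transform_params=ratio_matrix.transform_params,
        )
        per_sex[sex] = fit_association(
            sub_matrix, dataset, definitions, sub_cohort, outcome,
            covariates=("age",), n_tests=n_tests, use_adjusted=use_adjusted,
        )

    records = []
    for i, d in enumerate(definitions):
        records.append(
            InteractionRecord(
                target=d.label,
                outcome=outcome,
                interaction_p=float(inter[i]),
                interaction_p_bh=float(inter_bh[i]),
                female=per_sex[0][i],
                male=per_sex[1][i],
            )
        )
    return records


def _interaction_pvalues(Y: pd.DataFrame, X: pd.DataFrame) -> np.ndarray:
    """p-value of the outcome x sex coefficient for every target column."""
    Xm = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    j = 1 + list(X.columns).index("outcome_sex")
    Ym = Y.to_numpy(dtype=float)
    keep = ~np.isnan(Xm).any(axis=1)
    Xm, Ym = Xm[keep], Ym[keep]
    out = np.empty(Ym.shape[1])
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    full = ~np.isnan(Ym).any(axis=0)
    k = Xm.shape[1]

    def pvals(Yb, Xb, xtx_inv_b):
        n = Xb.shape[0]
        beta = xtx_inv_b @ (Xb.T @ Yb)
        resid = Yb - Xb @ beta
        sigma2 = (resid ** 2).sum(axis=0) / (n - k)
        se = np.sqrt(xtx_inv_b[j, j] * sigma2)
        return 2 * stats.t.sf(np.abs(beta[j] / se), df=n - k)

    if full.any():
        out[full] = pvals(Ym[:, full], Xm, xtx_inv)
    for jj in np.flatnonzero(~full):
        m = ~np.isnan(Ym[:, jj])
        Xb = Xm[m]
        out[jj] = pvals(Ym[m][:, [jj]], Xb, np.linalg.inv(Xb.T @ Xb))[0]
    return np.clip(out, np.finfo(float).tiny, 1.0)


# ---------------------------------------------------------------------------
# concordance and group comparisons
# ---------------------------------------------------------------------------

def concordance(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    require_significance: bool = True,
) -> dict:
    """Cross-cohort agreement of per-ratio regression coefficients.

    Tables are indexed by ratio label with ``beta`` and ``p_bh`` columns.
    A ratio is concordant when the betas share a sign and (when
    ``require_significance``) both are BH-significant at ``alpha``.
    Returns counts, the Pearson r of betas, and the discordant labels.
    """
    shared = table_a.index.intersection(table_b.index)
    if shared.empty:
        raise ValueError("no shared ratio labels")
    a = table_a.loc[shared]
    b = table_b.loc[shared]
    same_sign = np.sign(a["beta"]) == np.sign(b["beta"])
    if require_significance:
        conc = same_sign & (a["p_bh"] < alpha) & (b["p_bh"] < alpha)
    else:
        conc = same_sign
    r = float(np.corrcoef(a["beta"], b["beta"])[0, 1])
    return {
        "n_shared": int(len(shared)),
        "n_concordant": int(conc.sum()),
        "n_discordant": int((~conc).sum()),
        "pearson_r": r,
        "discordant": shared[~conc].tolist(),
    }


def group_difference(expression: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per gene between two groups.

    Exact enumeration when both groups have n <= 8, otherwise the
    tie-corrected normal approximation; a gene constant across both groups
    gets p = 1 by convention.  BH across genes.
    """
    labels = pd.unique(groups.dropna())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    g1 = expression.loc[groups == labels[0]]
    g2 = expression.loc[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    method = "exact" if (len(g1) <= 8 and len(g2) <= 8) else "asymptotic"
    rows = []
    for gene in expression.columns:
        x, y = g1[gene].dropna(), g2[gene].dropna()
        if x.nunique() <= 1 and y.nunique() <= 1 and set(x.unique()) == set(y.unique()):
            u, p = float(len(x) * len(y) / 2), 1.0
        else:
            try:
                res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            except ValueError:
                res = stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic"
                )
            u, p = float(res.statistic), float(min(res.pvalue, 1.0))
        direction = float(np.sign(y.median() - x.median()))
        rows.append({"gene": gene, "U": u, "p": p, "direction": direction})
    df = pd.DataFrame(rows).set_index("gene")
    df["p_bh"] = bh_adjust(df["p"].to_numpy())
    return df[["U", "p", "p_bh", "direction"]]
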