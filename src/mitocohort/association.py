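"""Case-control statistics.

2x2 odds ratios with Woolf confidence intervals (Haldane 0.5 correction for
zero cells), Fisher's exact test, chi-square tests, single-covariate
logistic regression (IRLS), SNP association with a dual-cohort 5% MAF floor
and Benjamini-Hochberg adjustment, per-region variant-burden comparisons by
Mann-Whitney U, and indel-enrichment contrasts between heteroplasmic and
homoplasmic variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calls import CohortVariantSummary, SampleCall
from .genome import GenomeMap, assign_region

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a=exposed cases, b=unexposed cases, c=exposed controls,
    d=unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @classmethod
    def from_counts(cls, exposed_cases: int, n_cases: int,
                    exposed_controls: int, n_controls: int) -> "ContingencyTable":
        return cls(exposed_cases, n_cases - exposed_cases,
                   exposed_controls, n_controls - exposed_controls)


@dataclass
class ContingencyResult:
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_fisher: float
    p_chi2: float
    p_wald: float
    correction_applied: bool

    def summary(self) -> str:
        t = self.table
        corr = " (Haldane 0.5 correction)" if self.correction_applied else ""
        return (
            f"2x2 table [[{t.a}, {t.b}], [{t.c}, {t.d}]]{corr}\n"
            f"OR {self.odds_ratio:.3f} "
            f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f})\n"
            f"p: Fisher {self.p_fisher:.4g}, chi2 {self.p_chi2:.4g}, "
            f"Wald {self.p_wald:.4g}"
        )


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p (point-probability method)."""
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


@dataclass
class Chi2Result:
    statistic: float
    p: float
    valid: bool  # False when a zero margin makes the test undefined


def chi_square(table, yates: bool = False) -> Chi2Result:
    """Pearson chi-square for a 2x2 (or general r x c) table.

    Zero-margin tables are undefined and returned flagged rather than
    raising."""
    if isinstance(table, ContingencyTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=float)
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return Chi2Result(float("nan"), float("nan"), valid=False)
    res = stats.chi2_contingency(arr, correction=yates)
    return Chi2Result(float(res.statistic), float(res.pvalue), valid=True)


def odds_ratio(t: ContingencyTable) -> ContingencyResult:
    """Odds ratio with Woolf 95% CI.

    OR = ad/bc; CI = exp(ln OR +/- 1.96 * sqrt(1/a+1/b+1/c+1/d)).  Any zero
    cell triggers the Haldane correction (0.5 added to every cell) for the
    OR/CI/Wald computation; exact and chi-square p-values are computed on
    the uncorrected counts.
    """
    if t.n == 0:
        raise ValueError("degenerate all-zero table")
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    correction = bool((cells == 0).any())
    if correction:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = float(np.sqrt((1 / cells).sum()))
    log_or = float(np.log(or_))
    ci_low = float(np.exp(log_or - Z_95 * se))
    ci_high = float(np.exp(log_or + Z_95 * se))
    p_wald = float(2 * stats.norm.sf(abs(log_or) / se))
    chi2 = chi_square(t)
    return ContingencyResult(
        table=t,
        odds_ratio=float(or_),
        ci_low=ci_low,
        ci_high=ci_high,
        p_fisher=fisher_exact(t),
        p_chi2=chi2.p,
        p_wald=p_wald,
        correction_applied=correction,
    )


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticResult:
    beta: float  # slope (log odds ratio)
    se: float
    p_wald: float
    odds_ratio: float
    converged: bool
    fallback: bool = False  # True when separation forced the contingency path


class SeparationWarning(UserWarning):
    pass


def logistic_fit(exposure: Sequence[float], outcome: Sequence[int],
                 tol: float = 1e-10, max_iter: int = 100) -> LogisticResult:
    """Maximum-likelihood intercept+slope logistic regression via IRLS.

    Iterates Newton/IRLS updates until the gradient norm drops below
    ``tol``.  A separated binary exposure (zero cell in the exposure-by-
    outcome table) has no finite MLE; that case falls back to the Haldane-
    corrected contingency odds ratio with a warning.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.shape != y.shape:
        raise ValueError("exposure and outcome must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if len(np.unique(x)) < 2:
        raise ValueError("exposure must not be constant")

    binary = set(np.unique(x)) <= {0.0, 1.0}
    if binary:
        a = int(np.sum((x == 1) & (y == 1)))
        b = int(np.sum((x == 0) & (y == 1)))
        c = int(np.sum((x == 1) & (y == 0)))
        d = int(np.sum((x == 0) & (y == 0)))
        if min(a, b, c, d) == 0:
            warnings.warn(
                "separation detected (zero cell); falling back to the "
                "Haldane-corrected contingency odds ratio",
                SeparationWarning,
            )
            res = odds_ratio(ContingencyTable(a, b, c, d))
            beta = float(np.log(res.odds_ratio))
            se = (np.log(res.ci_high) - np.log(res.ci_low)) / (2 * Z_95)
            return LogisticResult(beta, float(se), res.p_wald,
                                  res.odds_ratio, converged=True, fallback=True)

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        W = mu * (1.0 - mu)
        H = X.T @ (X * W[:, None])
        beta = beta + np.linalg.solve(H, grad)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    W = mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    se = float(np.sqrt(cov[1, 1]))
    slope = float(beta[1])
    p = float(2 * stats.norm.sf(abs(slope) / se)) if se > 0 else float("nan")
    return LogisticResult(slope, se, p, float(np.exp(slope)), converged)


# ---------------------------------------------------------------------------
# SNP association
# ---------------------------------------------------------------------------

def snp_association(
    carrier: pd.DataFrame,
    is_case: pd.Series,
    maf_floor: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP case-control association.

    ``carrier`` is a samples x variants boolean matrix; ``is_case`` a
    boolean series over the same samples.  A SNP is excluded only when its
    minor allele frequency is below the floor in *both* cohorts; retained
    SNPs are tested by logistic regression, reported with the contingency
    OR/CI and raw plus Benjamini-Hochberg-adjusted p-values.
    """
    is_case = is_case.reindex(carrier.index)
    if is_case.isna().any():
        raise ValueError("is_case must cover every sample in the carrier matrix")
    is_case = is_case.astype(bool)
    n_cases = int(is_case.sum())
    n_controls = int((~is_case).sum())
    rows = []
    for snp in carrier.columns:
        x = carrier[snp].astype(int)
        ec = int(x[is_case].sum())
        eo = int(x[~is_case].sum())
        af_cases = ec / n_cases if n_cases else 0.0
        af_controls = eo / n_controls if n_controls else 0.0
        maf_cases = min(af_cases, 1 - af_cases)
        maf_controls = min(af_controls, 1 - af_controls)
        if maf_cases < maf_floor and maf_controls < maf_floor:
            continue  # below the floor in both cohorts
        t = ContingencyTable.from_counts(ec, n_cases, eo, n_controls)
        res = odds_ratio(t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            logi = logistic_fit(x.to_numpy(), is_case.astype(int).to_numpy())
        rows.append({
            "exposure": snp,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "maf_cases": maf_cases, "maf_controls": maf_controls,
            "OR": logi.odds_ratio,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_fisher": res.p_fisher, "p_chi2": res.p_chi2,
            "p_wald": logi.p_wald,
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_bh"] = multipletests(df["p_wald"].fillna(1.0), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Burden comparisons
# ---------------------------------------------------------------------------

def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U statistic of the first sample).

    Exact enumeration when the combined size is at most 20 and there are no
    ties; otherwise normal approximation with tie and continuity
    corrections.  Fully tied data (zero rank variance) yields U = n_x*n_y/2
    and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    if len(np.unique(combined)) == 1:
        return len(x) * len(y) / 2.0, 1.0
    if len(combined) <= 20 and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class BurdenSummary:
    counts: pd.DataFrame       # samples x regions (plus total/coding columns)
    group_stats: pd.DataFrame  # per region: mean/SD per group, U, p
    heteroplasmic_only: bool


def burden_by_region(
    calls: Iterable[SampleCall],
    groups: Mapping[str, str],
    gm: GenomeMap,
    heteroplasmic_only: bool = False,
) -> BurdenSummary:
    """Per-sample variant counts by genome region, compared across groups.

    Counts excluded (HF < 1%) calls never; optionally restricts to
    heteroplasmic calls.  Adds aggregate "total" and "coding" (protein-
    region) columns; each region is compared between cases and controls by
    Mann-Whitney U.
    """
    region_names = [f.name for f in gm.features] + ["intergenic"]
    protein_regions = {f.name for f in gm.features if f.kind == "protein"}
    sample_ids = sorted(groups)
    counts = pd.DataFrame(0, index=sample_ids, columns=region_names)
    for c in calls:
        if c.sample_id not in groups:
            raise ValueError(f"sample {c.sample_id!r} missing from group map")
        state = c.state
        if state == "excluded":
            continue
        if heteroplasmic_only and state != "heteroplasmic":
            continue
        region = assign_region(c.variant, gm)
        counts.loc[c.sample_id, region] += 1
    counts["coding"] = counts[sorted(protein_regions)].sum(axis=1)
    counts["total"] = counts[region_names].sum(axis=1)

    is_case = pd.Series({s: groups[s] == "case" for s in sample_ids})
    rows = []
    for region in counts.columns:
        xc = counts.loc[is_case, region].to_numpy()
        yc = counts.loc[~is_case, region].to_numpy()
        if len(xc) and len(yc):
            u, p = mann_whitney(xc, yc)
        else:
            u, p = float("nan"), float("nan")
        rows.append({
            "region": region,
            "mean_cases": xc.mean() if len(xc) else float("nan"),
            "sd_cases": xc.std(ddof=1) if len(xc) > 1 else float("nan"),
            "mean_controls": yc.mean() if len(yc) else float("nan"),
            "sd_controls": yc.std(ddof=1) if len(yc) > 1 else float("nan"),
            "U": u,
            "p": p,
        })
    return BurdenSummary(counts=counts,
                         group_stats=pd.DataFrame(rows).set_index("region"),
                         heteroplasmic_only=heteroplasmic_only)


# ---------------------------------------------------------------------------
# Indel enrichment
# ---------------------------------------------------------------------------

@dataclass
class IndelEnrichment:
    state_table: pd.DataFrame    # state x {indel, SNV}
    region_table: pd.DataFrame   # region category x {indel, SNV}
    state_chi2: Chi2Result
    state_fisher: Optional[float]
    region_chi2: Chi2Result


_REGION_CATEGORY = {"protein": "coding", "tRNA": "tRNA", "rRNA": "rRNA",
                    "control": "non-coding", "noncoding": "non-coding"}


def indel_enrichment(
    summaries: Iterable[CohortVariantSummary],
    gm: GenomeMap,
) -> IndelEnrichment:
    """Contrast indel representation (i) between heteroplasmic-only and
    homoplasmic-only variants and (ii) across region categories.

    Variants seen in both states inform only the region table.  Degenerate
    tables (e.g. no indels at all) come back with flagged, invalid
    chi-square results rather than errors.
    """
    summaries = list(summaries)
    state_tab = pd.DataFrame(0, index=["heteroplasmic_only", "homoplasmic_only"],
                             columns=["indel", "SNV"])
    categories = ["coding", "tRNA", "rRNA", "non-coding"]
    region_tab = pd.DataFrame(0, index=categories, columns=["indel", "SNV"])
    for s in summaries:
        is_indel = s.variant.var_class != "substitution"
        col = "indel" if is_indel else "SNV"
        if s.state_profile in state_tab.index:
            state_tab.loc[s.state_profile, col] += 1
        region = assign_region(s.variant, gm)
        if region == "intergenic":
            cat = "non-coding"
        else:
            cat = _REGION_CATEGORY[gm.feature_by_name(region).kind]
        region_tab.loc[cat, col] += 1

    state_chi2 = chi_square(state_tab.to_numpy())
    if state_chi2.valid:
        t = ContingencyTable(
            int(state_tab.iloc[0, 0]), int(state_tab.iloc[0, 1]),
            int(state_tab.iloc[1, 0]), int(state_tab.iloc[1, 1]))
        state_fisher = fisher_exact(t)
    else:
        state_fisher = None
    region_nonzero = region_tab.loc[region_tab.sum(axis=1) > 0]
    region_chi2 = chi_square(region_nonzero.to_numpy())
    return IndelEnrichment(state_tab, region_tab, state_chi2,
                           state_fisher, region_chi2)


# ---------------------------------------------------------------------------
# Haplogroup association report
# ---------------------------------------------------------------------------

def haplogroup_association(pooled_counts: pd.DataFrame) -> pd.DataFrame:
    """Carrier-vs-all-others odds ratios for each pooled haplogroup.

    ``pooled_counts`` is the output of
    :func:`mitocohort.haplotyping.pool_haplogroups` with case/control
    columns.  Each haplogroup is contrasted against all remaining
    haplogroups combined (the reference group).
    """
    if not {"case", "control"} <= set(pooled_counts.columns):
        raise ValueError("pooled counts need case and control columns")
    n_cases = int(pooled_counts["case"].sum())
    n_controls = int(pooled_counts["control"].sum())
    rows = []
    for hap, row in pooled_counts.iterrows():
        t = ContingencyTable.from_counts(int(row["case"]), n_cases,
                                         int(row["control"]), n_controls)
        res = odds_ratio(t)
        rows.append({
            "haplogroup": hap,
            "cases": t.a, "controls": t.c,
            "OR": res.odds_ratio,
            "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_fisher": res.p_fisher, "p_chi2": res.p_chi2,
            "p_wald": res.p_wald,
            "correction_applied": res.correction_applied,
        })
    return pd.DataFrame(rows).set_index("haplogroup")
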