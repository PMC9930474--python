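"""ROI volumetry and group statistics.

Volume extraction by voxel counting, total-brain normalization, the paired
percent-difference analysis of the dopaminergic subsystem, nonparametric
group tests (Kruskal-Wallis, Mann-Whitney) with omega-squared effect sizes,
the rank-based false-discovery filter p(i) <= i*q / (V*c(V)) with q = 0.2
and c(V) = 1, the adaptive two-stage step-up FDR used for node statistics,
and the one-sample contract for investigation ratios against chance 0.5.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import InsufficientDataError, ValidationError

__all__ = [
    "roi_volumes",
    "normalize_volumes",
    "percent_pair",
    "paired_t",
    "kruskal_wallis",
    "mann_whitney",
    "one_way_anova",
    "two_way_anova",
    "omega_squared",
    "fdr_critical_value",
    "fdr_filter",
    "fdr_two_stage",
    "ir_ttest",
    "region_table",
]


# ---------------------------------------------------------------- volumetry

def roi_volumes(label_image: np.ndarray,
                voxel_dims: tuple[float, float, float],
                name_table: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI volumes in mm^3 from an integer atlas label image.

    volume(roi) = voxel count x unit voxel volume. Labels listed in the
    name table but absent from the image get volume 0 with a warning. The
    returned frame has columns (label, roi_name, voxel_count, volume_mm3)
    plus a ``total_brain_mm3`` attribute summing every labeled voxel.
    """
    if any(d <= 0 for d in voxel_dims):
        raise ValidationError("voxel_dims must all be positive")
    label_image = np.asarray(label_image)
    if not np.issubdtype(label_image.dtype, np.integer):
        raise ValidationError("label image must be integer valued")
    unit = float(np.prod(voxel_dims))
    counts = np.bincount(label_image.ravel())
    rows = []
    for _, row in name_table.iterrows():
        label = int(row["label"])
        count = int(counts[label]) if label < len(counts) else 0
        if count == 0:
            warnings.warn(f"label {label} ({row['roi_name']}) absent from "
                          "image; volume 0", stacklevel=2)
        rows.append({"label": label, "roi_name": row["roi_name"],
                     "voxel_count": count, "volume_mm3": count * unit})
    out = pd.DataFrame(rows)
    labeled = int(counts[1:].sum()) if len(counts) > 1 else 0
    out.attrs["total_brain_mm3"] = labeled * unit
    return out


def normalize_volumes(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-subject ``volume_fraction`` rows to a long-form table.

    Each subject-session's ROI volumes are divided by that subject-session's
    total brain volume, so fractions sum to 1 over its ROIs.
    """
    vol = table[table["measure"] == "volume_mm3"]
    if vol.empty:
        raise ValidationError("table has no volume_mm3 rows")
    frames = [table]
    for (subj, sess), sub in vol.groupby(["subject_id", "session"]):
        total = sub["value"].sum()
        if total <= 0:
            raise ValidationError(
                f"nonpositive total brain volume for {subj}/{sess}")
        frac = sub.copy()
        frac["measure"] = "volume_fraction"
        frac["value"] = sub["value"] / total
        frames.append(frac)
    return pd.concat(frames, ignore_index=True)


def percent_pair(a: float, b: float) -> tuple[float, float]:
    """Express two matched volumes as complementary percentages of their sum."""
    if a + b <= 0:
        raise ValidationError("percent_pair undefined for a + b <= 0")
    return 100.0 * a / (a + b), 100.0 * b / (a + b)


# ------------------------------------------------------------- basic tests

def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Classical paired t-test; returns (t, two-sided p, mean difference)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise InsufficientDataError("need equal-length vectors of >= 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, 1.0, 0.0  # identical pairs: no effect, no variance
        raise ValidationError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue), float(d.mean())


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H test with tie correction; chi-square p on k-1 df."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("need >= 2 groups of >= 2 values")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _mw_exact_p(u: float, n1: int, n2: int, x: np.ndarray,
                y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all rank assignments (small n)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = n1 + n2
    obs = abs(u - n1 * n2 / 2)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        r1 = ranks[list(combo)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        total += 1
        if abs(u1 - n1 * n2 / 2) >= obs - 1e-12:
            count += 1
    return count / total


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U with tie correction; exact p for n1+n2 <= 12.

    Returns U for the first sample and the two-sided p-value (normal
    approximation with tie correction for larger samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    if n1 + n2 <= 12:
        p = _mw_exact_p(u1, n1, n2, x, y)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
    return float(u1), float(p)


def omega_squared(groups: list[np.ndarray]) -> float:
    """Classical one-way ANOVA omega-squared, reported unclamped.

    omega^2 = (SS_between - (k-1) MS_within) / (SS_total + MS_within).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_t = ss_b + ss_w
    ms_w = ss_w / (n - k)
    return float((ss_b - (k - 1) * ms_w) / (ss_t + ms_w))


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Between/within decomposition; returns (F, p, omega_squared)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("need >= 2 groups of >= 2 values")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_w == 0 and ss_b == 0:
        raise ValidationError("all values identical: F undefined")
    ms_b = ss_b / (k - 1)
    ms_w = ss_w / (n - k)
    if ms_w == 0:
        return float("inf"), 0.0, omega_squared(groups)
    f = ms_b / ms_w
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p, omega_squared(groups)


def two_way_anova(values: np.ndarray, factor_a: np.ndarray,
                  factor_b: np.ndarray) -> pd.DataFrame:
    """Two-factor between-subjects ANOVA with interaction (Type-II SS).

    Handles unbalanced layouts; when a cell is empty the interaction is
    dropped with a warning (main effects only). Returns a frame indexed by
    effect with columns (sum_sq, df, F, p).
    """
    import statsmodels.api as sm_api
    from statsmodels.formula.api import ols

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "A": pd.Categorical(factor_a),
        "B": pd.Categorical(factor_b),
    })
    cells = df.groupby(["A", "B"], observed=False).size()
    formula = "y ~ C(A) * C(B)"
    if (cells == 0).any():
        warnings.warn("empty cell(s): interaction dropped, fitting main "
                      "effects only", stacklevel=2)
        formula = "y ~ C(A) + C(B)"
    fit = ols(formula, data=df).fit()
    if np.ptp(df["y"].to_numpy()) == 0:
        # all-equal response: every effect F = 0 by convention
        table = sm_api.stats.anova_lm(fit, typ=2)
        table["F"] = 0.0
        table["PR(>F)"] = 1.0
    else:
        table = sm_api.stats.anova_lm(fit, typ=2)
    table = table.rename(columns={"PR(>F)": "p"})
    table.index = [i.replace("C(A)", "A").replace("C(B)", "B")
                   for i in table.index]
    return table


# --------------------------------------------------------------------- FDR

def fdr_critical_value(rank: int, v: int, q: float = 0.2,
                       c_v: float = 1.0) -> float:
    """Rank-conditional critical value i*q / (V*c(V)) of the FDR filter."""
    if rank < 1 or rank > v:
        raise ValidationError("rank must lie in [1, V]")
    if not 0 < q <= 1:
        raise ValidationError("q must lie in (0, 1]")
    if c_v <= 0:
        raise ValidationError("c(V) must be positive")
    return rank * q / (v * c_v)


def fdr_filter(pvals: np.ndarray, v: int | None = None, q: float = 0.2,
               c_v: float = 1.0) -> pd.DataFrame:
    """Rank-based false-discovery filter.

    P-values are sorted ascending and assigned ranks i = 1..len; each test's
    critical value is i*q / (V*c(V)) with V the total comparison count
    (defaults to the number of p-values) and c(V) a predetermined constant
    (1 for independent or positively dependent tests). A test passes when
    its p-value is at most its rank's critical value. ``critical_3dp``
    carries the 3-decimal display rounding used in regional report tables.

    Returns a frame aligned with the input order, with columns
    (p, fdr_rank, fdr_critical, critical_3dp, passes_fdr).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if v is None:
        v = len(p)
    if v < len(p):
        raise ValidationError("V must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.empty(len(p), dtype=int)
    ranks[order] = np.arange(1, len(p) + 1)
    critical = ranks * q / (v * c_v)
    passes = p <= critical
    return pd.DataFrame({
        "p": p,
        "fdr_rank": ranks,
        "fdr_critical": critical,
        "critical_3dp": np.round(critical, 3),
        "passes_fdr": passes,
    })


def fdr_two_stage(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Adaptive two-stage step-up FDR (Benjamini-Krieger-Yekutieli).

    Stage 1 runs a linear step-up at level q' = q / (1 + q) to estimate the
    number of true nulls m0 = m - r1; stage 2 reruns the step-up at level
    q' * m / m0. Decisions are monotone in p. Returns a boolean vector in
    the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    q1 = q / (1.0 + q)

    def step_up(level: float) -> np.ndarray:
        order = np.argsort(p, kind="stable")
        sorted_p = p[order]
        crit = np.arange(1, m + 1) * level / m
        below = np.nonzero(sorted_p <= crit)[0]
        out = np.zeros(m, dtype=bool)
        if len(below):
            out[order[: below[-1] + 1]] = True
        return out

    stage1 = step_up(q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return stage1
    if r1 == m:
        return stage1
    m0 = m - r1
    return step_up(q1 * m / m0)


def ir_ttest(investigation_ratios: np.ndarray) -> tuple[float, float]:
    """One-sample t of investigation ratios against chance (0.5), two-sided."""
    ir = np.asarray(investigation_ratios, dtype=float)
    if len(ir) < 2:
        raise InsufficientDataError("need at least 2 ratios")
    if np.std(ir, ddof=1) == 0:
        raise ValidationError("zero variance of investigation ratios")
    res = stats.ttest_1samp(ir, popmean=0.5)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------ group tables

_ORDER_GLYPHS = {1: ">", -1: "<", 0: "="}


@dataclass
class GroupStatResult:
    """Per-ROI group comparison with its FDR annotation."""

    roi_name: str
    test: str
    statistic: float
    p: float
    omega_sq: float
    group_means: dict[str, float]
    group_sds: dict[str, float]
    pattern: str
    fdr_rank: int = 0
    fdr_critical: float = float("nan")
    passes_fdr: bool = False


def region_table(table: pd.DataFrame, measure: str, session: str,
                 groups: tuple[str, ...] | None = None,
                 q: float = 0.2, v: int | None = None,
                 c_v: float = 1.0) -> pd.DataFrame:
    """Publication-style regional comparison for one measure and session.

    Two groups are compared with Mann-Whitney, three or more with
    Kruskal-Wallis; every ROI gets group means +/- SD, an ordering pattern
    (e.g., ``placebo > CBD > THC``), the p-value, omega-squared, and the
    rank-based FDR annotation over V total comparisons (default: the number
    of ROIs tested). Rows are sorted by significance, mirroring the layout
    of ranked regional tables.
    """
    sub = table[(table["measure"] == measure) & (table["session"] == session)]
    if sub.empty:
        raise ValidationError(f"no rows for measure={measure}, "
                              f"session={session}")
    if groups is None:
        groups = tuple(sorted(sub["group"].unique()))
    if len(groups) < 2:
        raise ValidationError("need at least two groups to compare")
    results: list[GroupStatResult] = []
    for roi, roi_rows in sub.groupby("roi_name"):
        vecs = [roi_rows.loc[roi_rows["group"] == g, "value"].to_numpy()
                for g in groups]
        if any(len(vec) < 2 for vec in vecs):
            continue
        if len(groups) == 2:
            stat, p = mann_whitney(vecs[0], vecs[1])
            test = "mann_whitney"
        else:
            stat, p = kruskal_wallis(vecs)
            test = "kruskal_wallis"
        means = {g: float(vec.mean()) for g, vec in zip(groups, vecs)}
        sds = {g: float(vec.std(ddof=1)) for g, vec in zip(groups, vecs)}
        ordered = sorted(groups, key=lambda g: -means[g])
        glyphs = []
        for a, b in zip(ordered[:-1], ordered[1:]):
            glyphs.append(a)
            glyphs.append(_ORDER_GLYPHS[int(np.sign(means[a] - means[b]))])
        glyphs.append(ordered[-1])
        results.append(GroupStatResult(
            roi_name=str(roi), test=test, statistic=stat, p=p,
            omega_sq=omega_squared(vecs), group_means=means, group_sds=sds,
            pattern=" ".join(glyphs)))
    if not results:
        raise InsufficientDataError("no ROI had enough observations per group")
    frame = pd.DataFrame([{
        "roi_name": r.roi_name, "test": r.test, "statistic": r.statistic,
        "p": r.p, "omega_sq": r.omega_sq, "pattern": r.pattern,
        **{f"mean_{g}": r.group_means[g] for g in groups},
        **{f"sd_{g}": r.group_sds[g] for g in groups},
    } for r in results])
    fdr = fdr_filter(frame["p"].to_numpy(), v=v or len(frame), q=q, c_v=c_v)
    frame = pd.concat([frame, fdr.drop(columns=["p"])], axis=1)
    return frame.sort_values("fdr_rank").reset_index(drop=True)
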