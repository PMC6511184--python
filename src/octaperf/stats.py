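"""Nonparametric cohort statistics, power arithmetic, and report tables.

Paired within-group comparisons use the Wilcoxon signed-rank test, between-
group comparisons the Mann-Whitney test, correlations Spearman's rank test;
all two-sided with significance at p < 0.05 and no multiplicity correction.
Small samples are handled exactly (distribution enumeration); larger ones
fall back to tie-corrected normal/t approximations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "spearman_rank",
    "power_two_sample_t",
    "validate_age_matching",
    "summarize_cohort",
    "cohort_report_markdown",
]

EXACT_WILCOXON_MAX_N = 25
EXACT_MANN_WHITNEY_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 7


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def _two_sided_from_cdf(stat: float, pmf_values: np.ndarray, pmf_weights: np.ndarray) -> float:
    """2 * min(P(T <= t), P(T >= t)), capped at 1, from an exact pmf.

    Weights need not be normalized; dividing by the total only once keeps
    the result bit-identical to a direct enumeration count ratio.
    """
    eps = 1e-9
    lo = float(pmf_weights[pmf_values <= stat + eps].sum())
    hi = float(pmf_weights[pmf_values >= stat - eps].sum())
    total = float(pmf_weights.sum())
    return min(1.0, 2.0 * (min(lo, hi) / total))


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _signed_rank_pmf(double_ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of 2*W+ over all sign assignments (mid-ranks doubled so the
    support is an integer lattice even under ties)."""
    total = int(double_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    support = np.arange(total + 1)
    keep = dist > 0
    return support[keep], dist[keep]


def wilcoxon_signed_rank(paired_diffs: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (classic convention).  Exact enumeration of
    the sign-assignment distribution for n <= 25 (tie-aware, via doubled
    mid-ranks); tie-corrected normal approximation above.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one pair")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(0.0, 1.0, 0, "wilcoxon signed rank (all differences zero)")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        support, probs = _signed_rank_pmf(np.rint(2 * ranks).astype(int))
        p = _two_sided_from_cdf(2 * w_plus, support, probs)
        method = "wilcoxon signed rank (exact)"
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts) / 48.0).sum())
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        p = float(2 * sps.norm.sf(abs(z)))
        method = "wilcoxon signed rank (normal approximation)"
    return TestResult(w_plus, min(p, 1.0), n, method)


# ---------------------------------------------------------------------------
# Mann-Whitney


def _mann_whitney_exact_p(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p for untied samples by enumerating the U pmf.

    Classic recurrence on the largest pooled rank: it belongs to sample 1
    (contributing n2 to U) or to sample 2, giving
    f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u).
    """
    max_u = n1 * n2
    f = np.zeros((n1 + 1, n2 + 1, max_u + 1))
    f[0, :, 0] = 1.0
    f[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            f[i, j, j:] += f[i - 1, j, : max_u + 1 - j]
            f[i, j] += f[i, j - 1]
    counts = f[n1, n2]
    support = np.arange(max_u + 1)
    return _two_sided_from_cdf(u, support, counts)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney test of two independent samples.

    Exact enumeration of the U distribution for n_a + n_b <= 12 when there
    are no ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= EXACT_MANN_WHITNEY_MAX_N and not has_ties:
        p = _mann_whitney_exact_p(u1, n1, n2)
        method = "mann-whitney (exact)"
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            return TestResult(u1, 1.0, n, "mann-whitney (degenerate: all tied)")
        z = (u1 - mu) / np.sqrt(sigma2)
        p = float(2 * sps.norm.sf(abs(z)))
        method = "mann-whitney (normal approximation)"
    return TestResult(u1, min(p, 1.0), n1 + n2, method)


# ---------------------------------------------------------------------------
# Spearman


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, TestResult]:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    The p-value is exact (all-permutation enumeration) for n <= 7 and a
    t-approximation above.  A constant input vector leaves rho undefined.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = xv.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("rho undefined for a constant vector")
    rx = sps.rankdata(xv)
    ry = sps.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        from itertools import permutations

        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum())
        count = 0
        total = 0
        for perm in permutations(ry):
            rp = np.asarray(perm) - ry.mean()
            r = float(rx_c @ rp) / (denom * np.sqrt((rp**2).sum()))
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
        method = "spearman (exact permutation)"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2 * sps.t.sf(abs(t), n - 2))
        method = "spearman (t approximation)"
    return rho, TestResult(rho, min(p, 1.0), n, method)


# ---------------------------------------------------------------------------
# power


def power_two_sample_t(effect_size: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Two-sided two-sample t-test power under the noncentral-t model.

    Noncentrality d*sqrt(n/2) with df = 2n - 2; power(0) == alpha.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    df = 2 * n_per_group - 2
    ncp = effect_size * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


# ---------------------------------------------------------------------------
# age matching


def validate_age_matching(
    cohort: pd.DataFrame, tolerance_years: float = 1.0
) -> tuple[bool, pd.DataFrame]:
    """Check that a perfect 1:1 age matching (within +-1 year) exists.

    Greedy pairing on sorted ages, which is exact for interval matching.
    Returns (ok, per-pair report); unequal group sizes fail outright.
    """
    ages = cohort.drop_duplicates("eye_id")
    vmt = np.sort(ages.loc[ages["group"] == "vmt", "age"].to_numpy(dtype=float))
    ctl = np.sort(ages.loc[ages["group"] == "control", "age"].to_numpy(dtype=float))
    if len(vmt) != len(ctl):
        report = pd.DataFrame({"reason": [f"unequal group sizes: {len(vmt)} vs {len(ctl)}"]})
        return False, report
    gaps = np.abs(vmt - ctl)
    report = pd.DataFrame(
        {"age_vmt": vmt, "age_control": ctl, "gap": gaps, "ok": gaps <= tolerance_years}
    )
    return bool(np.all(gaps <= tolerance_years)), report


# ---------------------------------------------------------------------------
# cohort summary tables


def _fmt_mean_sd(values: np.ndarray) -> str:
    return f"{np.mean(values):.3f} ± {np.std(values, ddof=1) if len(values) > 1 else 0.0:.3f}"


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group summary in the study's table layout.

    One row per (extent, plexus, group): baseline and 1-month mean +- SD,
    the within-group paired Wilcoxon p, and per-timepoint between-group
    Mann-Whitney p when both groups are present.  Eyes missing a timepoint
    are flagged incomplete and dropped from the paired test.
    """
    required = {"eye_id", "group", "timepoint", "plexus", "extent_mm", "density"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    rows = []
    for (extent, plexus), sub in cohort.groupby(["extent_mm", "plexus"], sort=True):
        wide_all = sub.pivot_table(
            index=["group", "eye_id"], columns="timepoint", values="density"
        )
        for group, gsub in sub.groupby("group", sort=True):
            wide = wide_all.loc[group] if group in wide_all.index.get_level_values(0) else None
            complete = wide.dropna(subset=["baseline", "month1"]) if wide is not None and {
                "baseline",
                "month1",
            } <= set(wide.columns) else pd.DataFrame()
            n_incomplete = (0 if wide is None else len(wide)) - len(complete)
            if len(complete):
                diffs = complete["month1"] - complete["baseline"]
                paired = wilcoxon_signed_rank(diffs.to_numpy())
                paired_p = paired.p_value
            else:
                paired_p = np.nan
            base = gsub.loc[gsub["timepoint"] == "baseline", "density"].to_numpy()
            month = gsub.loc[gsub["timepoint"] == "month1", "density"].to_numpy()
            rows.append(
                {
                    "extent_mm": extent,
                    "plexus": plexus,
                    "group": group,
                    "n_eyes": gsub["eye_id"].nunique(),
                    "baseline_mean_sd": _fmt_mean_sd(base) if len(base) else "",
                    "month1_mean_sd": _fmt_mean_sd(month) if len(month) else "",
                    "baseline_mean": float(np.mean(base)) if len(base) else np.nan,
                    "month1_mean": float(np.mean(month)) if len(month) else np.nan,
                    "paired_p": paired_p,
                    "incomplete_pairs": n_incomplete,
                }
            )
        # between-group comparisons per timepoint
        groups = sorted(sub["group"].unique())
        if len(groups) == 2:
            for tp in ("baseline", "month1"):
                g0 = sub[(sub["group"] == groups[0]) & (sub["timepoint"] == tp)]["density"]
                g1 = sub[(sub["group"] == groups[1]) & (sub["timepoint"] == tp)]["density"]
                if len(g0) and len(g1):
                    res = mann_whitney(g0.to_numpy(), g1.to_numpy())
                    for row in rows:
                        if row["extent_mm"] == extent and row["plexus"] == plexus:
                            row[f"between_group_p_{tp}"] = res.p_value
    return pd.DataFrame(rows)


def cohort_report_markdown(summary: pd.DataFrame) -> str:
    """Render the summary as a Markdown table (3-decimal densities)."""
    cols = [
        "extent_mm",
        "plexus",
        "group",
        "n_eyes",
        "baseline_mean_sd",
        "month1_mean_sd",
        "paired_p",
    ]
    extra = [c for c in summary.columns if c.startswith("between_group_p_")]
    cols += extra
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in summary.iterrows():
        cells = []
        for c in cols:
            v = row.get(c, "")
            if isinstance(v, float) and not pd.isna(v):
                cells.append(f"{v:.4f}" if "p" in c and c != "plexus" else f"{v}")
            elif pd.isna(v):
                cells.append("")
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    n_tests = summary["paired_p"].notna().sum() + sum(
        summary[c].notna().sum() for c in extra
    )
    lines.append("")
    lines.append(
        f"*{n_tests} hypothesis tests performed; no multiplicity correction applied.*"
    )
    return "\n".join(lines)
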