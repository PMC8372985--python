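"""Descriptive statistics, exact Mann-Whitney comparisons, ICC agreement,
and study-style report tables.

The lateralization comparisons use the exact (permutation) two-sided
Mann-Whitney U test: with seven shoulders per condition the U null
distribution has only C(14,7) = 3432 equally likely group assignments,
so the smallest attainable two-sided p is 2/3432 (about 0.0006).
Rater agreement uses the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(2,1); the consistency form
ICC(3,1) is reported alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_ENUMERATION_LIMIT = 20  # exact p by full enumeration up to n1+n2 = 20


@dataclass(frozen=True)
class Descriptives:
    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __str__(self) -> str:
        if self.n < 2:
            return f"{self.mean:.2f} (n={self.n})"
        return f"{self.mean:.2f}±{self.sd:.2f} ({self.min:g}–{self.max:g})"


def descriptives(values) -> Descriptives:
    """Mean, sample SD (n-1 denominator), min, max."""
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("descriptives of an empty list")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return Descriptives(
        mean=float(x.mean()), sd=sd, min=float(x.min()), max=float(x.max()), n=int(x.size)
    )


def _u_statistic(ranks_x: np.ndarray, n1: int, n2: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, exact by full enumeration.

    Midranks are used for ties.  For n1 + n2 <= 20 the two-sided p is
    obtained by doubling the smaller exact tail of the permutation null
    of U (capped at 1); beyond that the normal approximation with tie
    correction is used.
    Returns (U of the first sample, two-sided p).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n1], n1, n2)

    n = n1 + n2
    if n <= EXACT_ENUMERATION_LIMIT:
        count_le = count_ge = total = 0
        for comb in itertools.combinations(range(n), n1):
            u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
            total += 1
            if u <= u_obs + 1e-9:
                count_le += 1
            if u >= u_obs - 1e-9:
                count_ge += 1
        p = 2 * min(count_le, count_ge) / total
        return u_obs, min(1.0, p)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


@dataclass(frozen=True)
class AgreementResult:
    comparison: str
    icc: float  # ICC(2,1), absolute agreement
    icc_consistency: float  # ICC(3,1)
    target: str
    n_subjects: int
    n_raters: int
    model: str = "two-way random, absolute agreement, single measures"


def icc_agreement(ratings, comparison: str = "", target: str = "") -> AgreementResult:
    """Intraclass correlation for a subjects x raters matrix.

    Computes ICC(2,1) from the two-way mean-squares decomposition:
        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    Raises on degenerate input (no between-subject variance).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 ratings per subject")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom21 = msr + (k - 1) * mse + k * (msc - mse) / n
    denom31 = msr + (k - 1) * mse
    if denom21 <= 0 or np.isclose(msr, 0) and np.isclose(mse, 0) and np.isclose(msc, 0):
        raise ValueError("zero between-subject variance: ICC undefined")
    icc21 = (msr - mse) / denom21
    icc31 = (msr - mse) / denom31 if denom31 > 0 else float("nan")
    return AgreementResult(
        comparison=comparison,
        icc=float(icc21),
        icc_consistency=float(icc31),
        target=target,
        n_subjects=n,
        n_raters=k,
    )


# ---------------------------------------------------------------------------
# Study-style tables
# ---------------------------------------------------------------------------

PAIRS = ((0, 6), (0, 9), (0, 12), (6, 9), (6, 12), (9, 12))
PARAMETERS = (("T", "ANGLE T (degrees)"), ("E", "ANGLE E (degrees)"),
              ("cer", "CER"), ("dma", "DMA (mm)"))


def descriptives_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter, per-slice, per-offset 'mean±SD (min–max)' table
    (biomechanical-parameters layout)."""
    rows = []
    for col, label in PARAMETERS:
        for sl, g_slice in results.groupby("slice_label"):
            row = {"parameter": label, "slice": sl}
            for off, g in g_slice.groupby("offset"):
                row[f"{off:g} mm"] = str(descriptives(g[col]))
            rows.append(row)
    return pd.DataFrame(rows)


def comparison_table(results: pd.DataFrame, pairs=PAIRS) -> pd.DataFrame:
    """Pairwise exact Mann-Whitney p-values per parameter and slice for
    the lateralization conditions (comparison-table layout)."""
    rows = []
    for col, label in PARAMETERS:
        for sl, g_slice in results.groupby("slice_label"):
            row = {"parameter": label, "slice": sl}
            for a, b in pairs:
                ga = g_slice.loc[g_slice.offset == a, col]
                gb = g_slice.loc[g_slice.offset == b, col]
                if len(ga) and len(gb):
                    _, p = mann_whitney_exact(ga, gb)
                    row[f"{a}vs{b}"] = round(p, 4)
                else:
                    row[f"{a}vs{b}"] = None  # explicit gap
            rows.append(row)
    return pd.DataFrame(rows)


def agreement_table(agreements) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": a.comparison,
                "target": a.target,
                "ICC(2,1)": round(a.icc, 3),
                "ICC(3,1)": round(a.icc_consistency, 3),
                "subjects": a.n_subjects,
                "raters": a.n_raters,
            }
            for a in agreements
        ]
    )


def build_tables(results: pd.DataFrame, agreements=(), out_dir=None) -> dict:
    """Assemble the study-style report tables; optionally write CSV and
    Markdown copies under ``out_dir``.

    No multiple-testing correction is applied (alpha = 0.05 per test).
    """
    tables = {
        "descriptives": descriptives_table(results),
        "comparisons": comparison_table(results),
    }
    if agreements:
        tables["agreement"] = agreement_table(agreements)
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
            (out / f"{name}.md").write_text(
                df.to_markdown(index=False)
                + "\n\nNo multiple-testing correction applied (alpha = 0.05 per test).\n"
            )
    return tables
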