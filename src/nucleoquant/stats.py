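"""Condition-level summaries and statistical comparisons.

Two distinct normalized-protein statistics are computed and labeled
explicitly:

* the condition-level ratio of means (mean protein signal / mean DNA
  signal over all nuclei of a condition) — the summary-table statistic
  used for cultured cells, whose derived columns (protein/DNA ratio,
  protein fold-change, DNA-normalized fold-change) are reproduced by
  :func:`derived_columns`;
* the per-nucleus NO/DAPI ratio (protein mean / DNA mean within a single
  nucleus) — the statistic compared between tissue conditions.

Comparisons between two conditions run three tests on the per-nucleus
value lists: Welch's two-tailed t-test, the two-sample Kolmogorov–Smirnov
test, and the Wilcoxon rank-sum test (exact enumeration for small
tie-free samples, normal approximation with tie and continuity
corrections otherwise).  No multiple-testing correction is applied, as a
single pairwise test is reported per channel.

Reported fold-changes and ratios are given at full precision alongside a
2-decimal rendering matching how such tables are printed; note that the
DNA-normalized fold-change of a printed table is conventionally computed
from the 2-dp ratio column (``fold_ratio_2dp``), which can differ in the
last digit from full precision.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger("nucleoquant")

#: per-database minimum population size recommended for stable summaries
MIN_RECOMMENDED_N = 500

#: threshold between exact and asymptotic Wilcoxon rank-sum p-values
EXACT_RANKSUM_MAX_N = 20


@dataclasses.dataclass
class ConditionSummary:
    """Mean and SD over nuclei of the per-nucleus mean intensity."""

    condition: str
    channel: str
    n: int
    mean: float
    sd: float


@dataclasses.dataclass
class Histogram:
    """Left-closed right-open bins (last bin closed), heights in % of total."""

    edges: np.ndarray
    percent: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError("histogram edges must be strictly increasing")


@dataclasses.dataclass
class ComparisonResult:
    """Two-condition comparison: fold-changes and distribution tests.

    ``fold_change_protein`` is mean_b / mean_a of the protein channel;
    ``ratio_a``/``ratio_b`` are condition-level protein/DNA ratios of
    means and ``fold_change_ratio`` their quotient.  The p-values come
    from the three tests run on the per-nucleus values named by
    ``test_on``.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    test_on: str
    mean_protein_a: float
    mean_protein_b: float
    mean_dna_a: float
    mean_dna_b: float
    ratio_a: float
    ratio_b: float
    fold_change_protein: float
    fold_change_ratio: float
    t_stat: float
    p_ttest: float
    ks_stat: float
    p_ks: float
    u_stat: float
    p_wilcoxon: float

    def __post_init__(self) -> None:
        for name in ("p_ttest", "p_ks", "p_wilcoxon"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {p}")

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Fold-changes and ratios at printed (2-dp) precision."""
        return {
            "ratio_a": round(self.ratio_a, ndigits),
            "ratio_b": round(self.ratio_b, ndigits),
            "fold_change_protein": round(self.fold_change_protein, ndigits),
            "fold_change_ratio": round(self.fold_change_ratio, ndigits),
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(
    records: pd.DataFrame, channel: str, condition: str | None = None
) -> ConditionSummary:
    """Mean and sample SD (n−1 denominator) of per-nucleus mean intensities."""
    col = channel if channel in records.columns else f"mean_{channel}"
    if col not in records.columns:
        raise KeyError(f"no column for channel {channel!r}")
    if condition is not None and "condition" in records.columns:
        records = records[records["condition"] == condition]
    values = records[col].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        raise ValueError("cannot summarize an empty population")
    if n < MIN_RECOMMENDED_N:
        log.warning("summary of %s/%s from only %d nuclei (< %d recommended)",
                    condition, channel, n, MIN_RECOMMENDED_N)
    mean = float(values.mean())
    if n == 1:
        log.warning("degenerate summary: single nucleus, SD set to 0")
        sd = 0.0
    else:
        sd = float(values.std(ddof=1))
    return ConditionSummary(condition=condition or "", channel=channel,
                            n=n, mean=mean, sd=sd)


def make_histogram(
    values: Sequence[float] | np.ndarray,
    bins: int = 20,
    edges: Sequence[float] | np.ndarray | None = None,
) -> Histogram:
    """Distribution of per-nucleus values as percent-of-total bins."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("cannot histogram an empty value list")
    if edges is None:
        edges = np.histogram_bin_edges(vals, bins=bins)
        if edges[0] == edges[-1]:  # all values identical
            edges = np.array([vals[0] - 0.5, vals[0] + 0.5])
    edges = np.asarray(edges, dtype=float)
    if vals.min() < edges[0] or vals.max() > edges[-1]:
        raise ValueError("explicit edges must cover the data range")
    counts, _ = np.histogram(vals, bins=edges)
    return Histogram(edges=edges, percent=100.0 * counts / vals.size, n=int(vals.size))


def pool_conditions(
    tables: Iterable[pd.DataFrame] | Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Concatenate per-source measurement tables, preserving provenance.

    When a mapping is given, its keys populate (or overwrite) a
    ``source`` column.  All tables must share one schema.
    """
    if isinstance(tables, Mapping):
        named = [(name, df) for name, df in tables.items()]
    else:
        named = [(None, df) for df in tables]
    if not named:
        raise ValueError("nothing to pool")
    frames = []
    ref_cols = list(named[0][1].columns)
    for name, df in named:
        if list(df.columns) != ref_cols:
            raise ValueError(
                f"schema mismatch while pooling: {list(df.columns)} vs {ref_cols}"
            )
        if name is not None:
            df = df.assign(source=name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# statistical tests
# ----------------------------------------------------------------------

def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Welch (unequal-variance) t-test."""
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def ks_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov–Smirnov test."""
    res = sps.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def ranksum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U of the first sample).

    Exact enumeration when both samples have <= 20 tie-free observations,
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = np.intersect1d(a, b).size > 0 or a.size != np.unique(a).size \
        or b.size != np.unique(b).size
    small = max(a.size, b.size) <= EXACT_RANKSUM_MAX_N
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_conditions(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    label_a: str = "a",
    label_b: str = "b",
    test_on: str = "mean_protein",
) -> ComparisonResult:
    """Compare two condition populations (b relative to reference a).

    ``test_on`` names the per-nucleus value column for the three
    distribution tests: ``mean_protein`` for culture analyses (raw mean
    intensities) or ``ratio_no_dapi`` for tissue analyses (per-nucleus
    NO/DAPI ratios).  Fold-changes are ratios of condition means, b / a.
    """
    for col in ("mean_protein", "mean_dna", test_on):
        for name, df in ((label_a, records_a), (label_b, records_b)):
            if col not in df.columns:
                raise KeyError(f"condition {name!r} lacks column {col!r}")

    def finite(df: pd.DataFrame, col: str) -> np.ndarray:
        v = df[col].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    va, vb = finite(records_a, test_on), finite(records_b, test_on)
    if va.size < 2 or vb.size < 2:
        raise ValueError("need at least 2 nuclei per condition to compare")

    mean_protein_a = float(finite(records_a, "mean_protein").mean())
    mean_protein_b = float(finite(records_b, "mean_protein").mean())
    mean_dna_a = float(finite(records_a, "mean_dna").mean())
    mean_dna_b = float(finite(records_b, "mean_dna").mean())
    if mean_protein_a == 0 or mean_dna_a == 0 or mean_dna_b == 0:
        raise ZeroDivisionError("zero condition mean; fold-changes undefined")

    ratio_a = mean_protein_a / mean_dna_a
    ratio_b = mean_protein_b / mean_dna_b

    t_stat, p_t = welch_ttest(va, vb)
    ks_stat, p_ks = ks_test(va, vb)
    u_stat, p_w = ranksum_test(va, vb)

    return ComparisonResult(
        label_a=label_a, label_b=label_b, n_a=int(va.size), n_b=int(vb.size),
        test_on=test_on,
        mean_protein_a=mean_protein_a, mean_protein_b=mean_protein_b,
        mean_dna_a=mean_dna_a, mean_dna_b=mean_dna_b,
        ratio_a=ratio_a, ratio_b=ratio_b,
        fold_change_protein=mean_protein_b / mean_protein_a,
        fold_change_ratio=ratio_b / ratio_a,
        t_stat=t_stat, p_ttest=p_t,
        ks_stat=ks_stat, p_ks=p_ks,
        u_stat=u_stat, p_wilcoxon=p_w,
    )


# ----------------------------------------------------------------------
# printed summary-table arithmetic
# ----------------------------------------------------------------------

def derived_columns(
    mean_protein: float,
    mean_dna: float,
    ref_mean_protein: float,
    ref_mean_dna: float,
) -> dict[str, float]:
    """Derived cells of a condition-vs-reference summary table.

    Given the printed per-condition mean protein and DNA intensities and
    those of the reference (early-passage) condition, compute the
    protein/DNA ratio, the protein fold-change, and the DNA-normalized
    fold-change.  Full-precision and 2-dp values are both returned;
    ``fold_ratio_2dp`` follows the printed-table convention of dividing
    the already-rounded ratio cells.
    """
    if mean_dna <= 0 or ref_mean_dna <= 0 or ref_mean_protein <= 0:
        raise ZeroDivisionError("means must be positive")
    ratio = mean_protein / mean_dna
    ref_ratio = ref_mean_protein / ref_mean_dna
    ratio_2dp = round(ratio, 2)
    ref_ratio_2dp = round(ref_ratio, 2)
    return {
        "ratio": ratio,
        "ratio_2dp": ratio_2dp,
        "fold_protein": mean_protein / ref_mean_protein,
        "fold_protein_2dp": round(mean_protein / ref_mean_protein, 2),
        "fold_ratio": ratio / ref_ratio,
        "fold_ratio_2dp": round(ratio_2dp / ref_ratio_2dp, 2),
    }


def derived_summary_table(
    conditions: Sequence[tuple[str, float, float]],
    reference: str,
) -> pd.DataFrame:
    """Summary-table surface for several conditions against one reference.

    ``conditions`` is a sequence of (label, mean_protein, mean_dna);
    ``reference`` names the baseline whose fold-changes are 1 by
    definition.
    """
    means = {label: (p, d) for label, p, d in conditions}
    if reference not in means:
        raise KeyError(f"reference condition {reference!r} not given")
    ref_p, ref_d = means[reference]
    rows = []
    for label, p, d in conditions:
        cells = derived_columns(p, d, ref_p, ref_d)
        rows.append({"condition": label, "mean_protein": p, "mean_dna": d, **cells})
    return pd.DataFrame(rows)
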