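"""Per-variant enrichment scoring and shared statistical primitives.

A growth selection is read out as the log2 enrichment of each library variant,

    Enr = log2(f_post / f_pre),

where ``f_pre`` and ``f_post`` are the variant's population frequencies in the
pre- and post-selection sequencing pools.  Frequencies are computed over the
*full* count table; read filtering (default: at least 5 input reads and 1
output read, no pseudocounts) then selects the variants whose scores are
trusted for downstream analyses.  Because frequencies are fixed before
filtering, filtering then scoring equals scoring then dropping.

Group-level uncertainty is reported as the standard error of the mean,
s.e.m. = sigma / sqrt(N) with the sample (N-1) standard deviation, and group
comparisons use Welch's two-sided t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._alphabet import DegenerateInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: Default read-count filter: >=5 reads pre-selection, >=1 read post-selection.
MIN_PRE_READS = 5
MIN_POST_READS = 1


@dataclass(frozen=True)
class GroupSummary:
    """Mean log2 enrichment of a group of variants, with spread and s.e.m."""

    n: int
    mean: float
    sd: float
    sem: float

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        return summarize(values)


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class NormalizedScores:
    """Min-shifted scores Enr_norm = Enr - Enr_min and their relative form.

    ``relative`` is (Enr_norm - <Enr_norm>) / <Enr_norm>, a dimensionless
    quantity comparable across assays (the same form is applied to half-lives).
    """

    enr_min: float
    enr_norm: np.ndarray
    relative: np.ndarray


def compute_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Add ``f_pre``/``f_post`` columns: count / pool total, over ALL rows.

    Frequencies are defined on the unfiltered table so that read filtering
    does not change the denominator.
    """
    for col in ("pre_count", "post_count"):
        if col not in counts.columns:
            raise InvalidParameterError(f"count table lacks column {col!r}")
    tot_pre = int(counts["pre_count"].sum())
    tot_post = int(counts["post_count"].sum())
    if tot_pre == 0 or tot_post == 0:
        raise DegenerateInputError("a sequencing pool has zero total reads")
    out = counts.copy()
    out["f_pre"] = counts["pre_count"] / tot_pre
    out["f_post"] = counts["post_count"] / tot_post
    return out


def filter_variants(
    counts: pd.DataFrame,
    min_pre: int = MIN_PRE_READS,
    min_post: int = MIN_POST_READS,
) -> pd.DataFrame:
    """Keep rows with pre_count >= min_pre and post_count >= min_post."""
    if min_pre < 0 or min_post < 0:
        raise InvalidParameterError("filter thresholds must be >= 0")
    kept = counts[
        (counts["pre_count"] >= min_pre) & (counts["post_count"] >= min_post)
    ].reset_index(drop=True)
    logger.info(
        "read filter (pre>=%d, post>=%d): %d rows in, %d rows kept",
        min_pre, min_post, len(counts), len(kept),
    )
    return kept


def compute_enrichment(filtered: pd.DataFrame) -> pd.DataFrame:
    """Add ``enr`` = log2(f_post / f_pre); frequencies must be pre-computed."""
    if "f_pre" not in filtered.columns or "f_post" not in filtered.columns:
        raise InvalidParameterError("compute_frequencies must run first")
    if ((filtered["f_pre"] <= 0) | (filtered["f_post"] <= 0)).any():
        raise RuntimeError("zero frequency reached the enrichment stage")
    out = filtered.copy()
    out["enr"] = np.log2(out["f_post"].to_numpy() / out["f_pre"].to_numpy())
    return out


def score_library(
    counts: pd.DataFrame,
    min_pre: int = MIN_PRE_READS,
    min_post: int = MIN_POST_READS,
) -> pd.DataFrame:
    """Frequencies → filter → Enr, the standard scoring path for a library."""
    return compute_enrichment(
        filter_variants(compute_frequencies(counts), min_pre, min_post)
    )


def summarize(values) -> GroupSummary:
    """Mean, sample sd and s.e.m. = sd/sqrt(n) of a list of scores.

    For n == 1 the spread is undefined and reported as NaN.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DegenerateInputError("cannot summarize an empty group")
    mean = float(arr.mean())
    if arr.size == 1:
        return GroupSummary(n=1, mean=mean, sd=float("nan"), sem=float("nan"))
    sd = float(arr.std(ddof=1))
    return GroupSummary(n=int(arr.size), mean=mean, sd=sd, sem=sd / np.sqrt(arr.size))


def welch_t_test(a, b) -> WelchResult:
    """Welch's two-sided t-test (unequal variances) between two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs n >= 2 for Welch's test")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateInputError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def normalize_scores(enr) -> NormalizedScores:
    """Shift scores to be non-negative and express them relative to the mean.

    Enr_norm = Enr - Enr_min is always >= 0; the relative score
    (Enr_norm - <Enr_norm>)/<Enr_norm> then has mean zero by construction.
    """
    arr = np.asarray(enr, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError("need at least two variants to normalize")
    enr_min = float(arr.min())
    norm = arr - enr_min
    mean_norm = float(norm.mean())
    if mean_norm <= 0:
        raise DegenerateInputError(
            "all enrichments equal: mean normalized score is zero"
        )
    return NormalizedScores(
        enr_min=enr_min, enr_norm=norm, relative=(norm - mean_norm) / mean_norm
    )


def reference_normalized_mean(library_mean: float, reference_enr: float) -> float:
    """Library mean Enr re-expressed relative to a reference construct.

    Subtracting the enrichment of a shared reference (e.g. the wild-type CYC1
    3' UTR plasmid present in every library) puts libraries whose selections
    differed in stringency on a common scale.
    """
    return library_mean - reference_enr
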