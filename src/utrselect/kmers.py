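"""Exhaustive k-mer effect analysis.

For every k-mer over {A, C, G, U}, compare the mean enrichment of library
sequences containing at least one occurrence (overlaps allowed; a sequence
counts once however many occurrences it has) with that of sequences lacking
it, and rank the k-mers by the containing-group mean.  The per-sequence
distinct-k-mer machinery also yields the exact combinatorial identity

    sum over k-mers of n_with  ==  sum over sequences of #distinct k-mers,

used both as an internal cross-check and for containment expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._alphabet import (
    RNA_BASES,
    DegenerateInputError,
    InvalidParameterError,
    encode_sequences,
)

#: k-mers up to this length are materialized; beyond it only counted.
MAX_MATERIALIZED_K = 12


def kmer_count(k: int) -> int:
    """Number of distinct k-mers over a 4-letter alphabet (any k >= 1)."""
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    return 4 ** k


def enumerate_kmers(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic order (A < C < G < U)."""
    if not 1 <= k <= MAX_MATERIALIZED_K:
        raise InvalidParameterError(
            f"k must be in [1, {MAX_MATERIALIZED_K}] to materialize; "
            "use kmer_count for larger k"
        )
    idx = np.arange(4 ** k)
    out = []
    chars = np.empty((4 ** k, k), dtype="<U1")
    for j in range(k):
        chars[:, k - 1 - j] = np.array(list(RNA_BASES))[(idx >> (2 * j)) & 3]
    return ["".join(row) for row in chars]


def _window_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all length-k windows; shape (n, L-k+1), int64."""
    n, L = enc.shape
    if k > L:
        raise InvalidParameterError("k exceeds sequence length")
    W = L - k + 1
    codes = np.zeros((n, W), dtype=np.int64)
    for j in range(k):
        codes *= 4
        codes += enc[:, j:j + W]
    return codes


def _distinct_window_mask(codes: np.ndarray):
    """Sorted window codes and a mask of first occurrences within each row."""
    srt = np.sort(codes, axis=1)
    mask = np.ones_like(srt, dtype=bool)
    mask[:, 1:] = srt[:, 1:] != srt[:, :-1]
    return srt, mask


def containment_counts(seqs, k: int) -> np.ndarray:
    """n_with per k-mer: how many sequences contain each k-mer at least once."""
    enc = encode_sequences(seqs)
    srt, mask = _distinct_window_mask(_window_codes(enc, k))
    return np.bincount(srt[mask], minlength=4 ** k)


def distinct_kmers_per_sequence(seqs, k: int) -> np.ndarray:
    """Number of distinct k-mers in each sequence."""
    enc = encode_sequences(seqs)
    _, mask = _distinct_window_mask(_window_codes(enc, k))
    return mask.sum(axis=1)


def kmer_summary(variants: pd.DataFrame, k: int) -> pd.DataFrame:
    """With/without enrichment summary and rank for every k-mer.

    ``variants`` needs columns ``n50`` and ``enr``.  Returns one row per
    k-mer: n/mean/sem for the containing and lacking groups, and ``rank``
    (1 = largest mean_with; ties broken lexicographically; k-mers with an
    empty or singleton group report NaN statistics but still hold a rank).
    """
    if len(variants) == 0:
        raise DegenerateInputError("no variants")
    if not 1 <= k <= MAX_MATERIALIZED_K:
        raise InvalidParameterError(f"k must be in [1, {MAX_MATERIALIZED_K}]")
    enr = variants["enr"].to_numpy(dtype=float)
    enc = encode_sequences(variants["n50"].tolist())
    srt, mask = _distinct_window_mask(_window_codes(enc, k))
    codes = srt[mask]
    weights = np.broadcast_to(enr[:, None], srt.shape)[mask]
    m = 4 ** k
    n_with = np.bincount(codes, minlength=m).astype(np.int64)
    sum_with = np.bincount(codes, weights=weights, minlength=m)
    sumsq_with = np.bincount(codes, weights=weights * weights, minlength=m)

    n_tot = len(enr)
    sum_tot = enr.sum()
    sumsq_tot = (enr * enr).sum()

    def _stats(n, s, ss):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
            var = (ss - n * mean ** 2) / np.maximum(n - 1, 1)
            var = np.clip(var, 0.0, None)
            sd = np.where(n > 1, np.sqrt(var), np.nan)
            sem = sd / np.sqrt(np.maximum(n, 1))
        return mean, sem

    mean_with, sem_with = _stats(n_with, sum_with, sumsq_with)
    n_without = n_tot - n_with
    mean_without, sem_without = _stats(
        n_without, sum_tot - sum_with, sumsq_tot - sumsq_with
    )

    kmers = enumerate_kmers(k)
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "n_with": n_with,
            "mean_with": mean_with,
            "sem_with": sem_with,
            "n_without": n_without,
            "mean_without": mean_without,
            "sem_without": sem_without,
        }
    )
    # Rank 1 = largest mean_with; NaN means sort last; ties fall back to the
    # lexicographic order the table is already in (stable mergesort).
    key = np.where(np.isnan(mean_with), -np.inf, mean_with)
    order = np.argsort(-key, kind="mergesort")
    rank = np.empty(m, dtype=np.int64)
    rank[order] = np.arange(1, m + 1)
    df.insert(1, "rank", rank)
    return df


def au_content(seq: str) -> float:
    """Fraction of A and U bases in a sequence."""
    if not seq:
        raise DegenerateInputError("empty sequence")
    return (seq.count("A") + seq.count("U")) / len(seq)


def au_correlation(variants: pd.DataFrame) -> float:
    """Pearson r between per-variant AU fraction and enrichment score."""
    if len(variants) < 3:
        raise DegenerateInputError("need >= 3 variants for a correlation")
    au = np.array([au_content(s) for s in variants["n50"]])
    enr = variants["enr"].to_numpy(dtype=float)
    if au.std() == 0 or enr.std() == 0:
        raise DegenerateInputError("zero variance in AU content or enrichment")
    r, _ = stats.pearsonr(au, enr)
    return float(r)


@dataclass(frozen=True)
class ContainmentExpectation:
    """Mean containment count over all k-mers of a library (exact identity).

    mean over k-mers of n_with = (sum over sequences of distinct k-mers)/4**k.
    """

    mean_containment: float
    n_sequences: int
    k: int


def mean_containment(seqs, k: int = 6) -> ContainmentExpectation:
    counts = containment_counts(seqs, k)
    return ContainmentExpectation(
        mean_containment=float(counts.mean()), n_sequences=len(seqs), k=k
    )
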