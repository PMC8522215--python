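"""Directed motif analyses over a scored library.

The analyses here quantify what a specific 3' UTR motif does to expression:

* **with/without/control triads** — mean enrichment of sequences containing a
  motif vs. those lacking it, against a composition-matched null: sequences
  containing Hamming-constrained shuffles of the motif (same letters, Hamming
  distance >= half the motif length from the original) but not the motif
  itself.  The shuffle group isolates motif *identity* from nucleotide
  content.
* **positional profiles** — mean enrichment as a function of where the
  motif's 5' end sits in the 50-mer (occurrence semantics: a sequence with
  occurrences at several positions contributes at each).
* **mutational scans** — every single-base substitution of a consensus under
  a substitution scheme, with consensus-containing sequences excluded from
  mutant groups.
* **double-motif arrangement** — among sequences carrying two motifs with a
  non-overlapping placement, the fraction with motif A 5' of motif B per
  enrichment bin.
* **per-position base statistics** — kpLogo-style: at each position, compare
  enrichment of sequences carrying each base vs. the rest, Bonferroni
  corrected over positions x bases.

Motifs are written in IUPAC RNA codes (W = A/U, Y = C/U, N = any, ...);
matching is exact under IUPAC expansion, with overlaps reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._alphabet import (
    DegenerateInputError,
    InvalidParameterError,
    encode_sequences,
    expand_iupac,
    is_concrete,
    iupac_regex,
    validate_rna,
)
from .enrichment import GroupSummary, WelchResult, summarize, welch_t_test

logger = logging.getLogger(__name__)

MAX_SHUFFLES = 50
EFFICIENCY_ELEMENT = "UAUAUA"


class InsufficientDataError(ValueError):
    """A required analysis group is empty."""


# ---------------------------------------------------------------------------
# Scanning primitives


def find_occurrences(seq: str, motif: str) -> list[int]:
    """1-based 5'-end positions of all (overlapping) IUPAC matches."""
    pat = iupac_regex(motif)
    if len(motif) > len(seq):
        return []
    out = []
    pos = 0
    while True:
        m = pat.search(seq, pos)
        if m is None:
            return out
        out.append(m.start() + 1)
        pos = m.start() + 1


def count_nonoverlapping(seq: str, motif: str) -> int:
    """Maximum number of mutually disjoint occurrences (greedy 5'-to-3')."""
    count = 0
    end = 0  # first admissible 0-based start
    for p in find_occurrences(seq, motif):
        if p - 1 >= end:
            count += 1
            end = p - 1 + len(motif)
    return count


def contains_mask(seqs, motif_or_set) -> np.ndarray:
    """Boolean mask: does each sequence contain the motif (or any of a set)?"""
    if isinstance(motif_or_set, str):
        pat = iupac_regex(motif_or_set)
    else:
        alts = sorted(set(motif_or_set))
        if not alts:
            return np.zeros(len(list(seqs)), dtype=bool)
        pat = iupac_regex_union(alts)
    search = pat.search
    return np.fromiter((search(s) is not None for s in seqs), dtype=bool)


def iupac_regex_union(patterns):
    """One regex matching any of several IUPAC motifs."""
    import re

    parts = [iupac_regex(p).pattern for p in patterns]
    return re.compile("(?:" + "|".join(parts) + ")")


# ---------------------------------------------------------------------------
# Hamming-constrained shuffles


def _multiset_permutations(letters: str):
    """All distinct permutations of a multiset of letters, lexicographic."""
    pool = sorted(letters)
    n = len(pool)
    out: list[str] = []

    def rec(prefix, remaining):
        if not remaining:
            out.append("".join(prefix))
            return
        prev = None
        for i, ch in enumerate(remaining):
            if ch == prev:
                continue
            prev = ch
            rec(prefix + [ch], remaining[:i] + remaining[i + 1:])

    rec([], pool)
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise InvalidParameterError("Hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def generate_shuffles(
    motif: str,
    min_hamming: int | None = None,
    max_n: int = MAX_SHUFFLES,
    seed: int = 0,
) -> list[str]:
    """Composition-preserving shuffles of a concrete motif.

    Returns distinct permutations of the motif's letters at Hamming distance
    >= ``min_hamming`` (default: half the motif length, rounded up) from the
    original, never the original itself, at most ``max_n`` of them sampled
    reproducibly under ``seed``.  A motif with no valid shuffle (e.g. a
    homopolymer) yields an empty list with a warning.
    """
    validate_rna(motif, allow_iupac=False)
    if min_hamming is None:
        min_hamming = math.ceil(len(motif) / 2)
    valid = [
        p
        for p in _multiset_permutations(motif)
        if p != motif and hamming(p, motif) >= min_hamming
    ]
    if not valid:
        logger.warning("motif %s admits no shuffle at Hamming >= %d", motif, min_hamming)
        return []
    if len(valid) > max_n:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        idx = rng.choice(len(valid), size=max_n, replace=False)
        valid = [valid[i] for i in sorted(idx)]
    return valid


def shuffle_set_for(motif: str, max_n: int = MAX_SHUFFLES, seed: int = 0) -> list[str]:
    """Shuffles of a possibly degenerate motif: expand IUPAC codes first,
    shuffle each concrete expansion, pool, and drop duplicates and anything
    still matching the pattern.  The ``max_n`` cap applies to the pooled set
    (it is a per-motif budget, not a per-expansion one)."""
    expansions = expand_iupac(motif)
    pat = iupac_regex(motif)
    pooled: list[str] = []
    seen: set[str] = set()
    for exp in expansions:
        # enumerate all valid shuffles per expansion; sample after pooling
        for s in generate_shuffles(exp, max_n=10 ** 9, seed=seed):
            if s in seen or pat.fullmatch(s):
                continue
            seen.add(s)
            pooled.append(s)
    if len(pooled) > max_n:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        idx = rng.choice(len(pooled), size=max_n, replace=False)
        pooled = [pooled[i] for i in sorted(idx)]
    return pooled


# ---------------------------------------------------------------------------
# With / without / control triads


@dataclass(frozen=True)
class MotifEffectSummary:
    """The with/without/control triad for one motif.

    ``shuffle_group`` holds the composition-matched control: sequences
    containing at least one accepted shuffle (or the explicit AU-content
    control sequence, when one is supplied) and *not* containing the motif.
    """

    motif: str
    with_group: GroupSummary
    without_group: GroupSummary
    shuffle_group: GroupSummary | None
    p_with_vs_without: WelchResult
    p_with_vs_shuffle: WelchResult | None
    shuffle_set: tuple[str, ...] = field(default_factory=tuple)


def _resolve_control(motif: str, control, max_shuffles: int, seed: int) -> list[str]:
    if control == "shuffles":
        return shuffle_set_for(motif, max_n=max_shuffles, seed=seed)
    if isinstance(control, str):
        return [control]
    return list(control)


def motif_effect(
    variants: pd.DataFrame,
    motif: str,
    control="shuffles",
    exclusions=(),
    seed: int = 0,
    max_shuffles: int = MAX_SHUFFLES,
) -> MotifEffectSummary:
    """With/without/control comparison of a motif's effect on enrichment.

    ``control`` is ``"shuffles"`` (Hamming-constrained shuffles of the motif),
    an explicit control sequence (e.g. an AU-content-matched hexamer), or an
    iterable of control sequences.  ``exclusions`` removes sequences
    containing any excluded motif from *all* groups.
    """
    seqs = variants["n50"].tolist()
    enr = variants["enr"].to_numpy(dtype=float)
    keep = np.ones(len(seqs), dtype=bool)
    for ex in exclusions:
        keep &= ~contains_mask(seqs, ex)
    has = contains_mask(seqs, motif)
    with_mask = has & keep
    without_mask = ~has & keep
    if not with_mask.any():
        raise InsufficientDataError(f"no sequences contain motif {motif}")
    ctrl_set = _resolve_control(motif, control, max_shuffles, seed)
    shuffle_group = None
    p_shuffle = None
    if ctrl_set:
        ctrl_mask = contains_mask(seqs, ctrl_set) & ~has & keep
        if ctrl_mask.any():
            shuffle_group = summarize(enr[ctrl_mask])
            if ctrl_mask.sum() >= 2 and with_mask.sum() >= 2:
                p_shuffle = welch_t_test(enr[with_mask], enr[ctrl_mask])
    with_group = summarize(enr[with_mask])
    without_group = summarize(enr[without_mask])
    p_without = welch_t_test(enr[with_mask], enr[without_mask])
    return MotifEffectSummary(
        motif=motif,
        with_group=with_group,
        without_group=without_group,
        shuffle_group=shuffle_group,
        p_with_vs_without=p_without,
        p_with_vs_shuffle=p_shuffle,
        shuffle_set=tuple(ctrl_set),
    )


# ---------------------------------------------------------------------------
# Positional profiles


@dataclass(frozen=True)
class PositionalProfile:
    """Per-position occurrence statistics for a motif and its shuffles.

    ``motif_profile``/``shuffle_profile`` have one row per occupied 1-based
    5'-end position: n (sequences with an occurrence starting there), mean and
    sem of their enrichment.  The shuffle series pools occurrences of the
    accepted shuffle set over sequences not containing the motif.
    """

    motif: str
    motif_profile: pd.DataFrame
    shuffle_profile: pd.DataFrame
    library_mean: float
    shuffle_set: tuple[str, ...]


def _occurrence_profile(seqs, enr, motif_set) -> pd.DataFrame:
    # one lookahead union regex finds every occupied start in a single pass
    import re

    union = iupac_regex_union(motif_set)
    look = re.compile(f"(?=(?:{union.pattern}))")
    rows: dict[int, list[float]] = {}
    for s, e in zip(seqs, enr):
        for m in look.finditer(s):
            rows.setdefault(m.start() + 1, []).append(e)
    records = []
    for p in sorted(rows):
        g = summarize(rows[p])
        records.append({"position": p, "n": g.n, "mean": g.mean, "sem": g.sem})
    return pd.DataFrame(records, columns=["position", "n", "mean", "sem"])


def positional_profile(
    variants: pd.DataFrame,
    motif: str,
    seed: int = 0,
    max_shuffles: int = MAX_SHUFFLES,
) -> PositionalProfile:
    seqs = variants["n50"].tolist()
    enr = variants["enr"].to_numpy(dtype=float)
    has = contains_mask(seqs, motif)
    motif_prof = _occurrence_profile(
        [s for s, h in zip(seqs, has) if h], enr[has], [motif]
    )
    shuffles = shuffle_set_for(motif, max_n=max_shuffles, seed=seed)
    if shuffles:
        ctrl_mask = contains_mask(seqs, shuffles) & ~has
        shuf_prof = _occurrence_profile(
            [s for s, m in zip(seqs, ctrl_mask) if m], enr[ctrl_mask], shuffles
        )
    else:
        shuf_prof = pd.DataFrame(columns=["position", "n", "mean", "sem"])
    return PositionalProfile(
        motif=motif,
        motif_profile=motif_prof,
        shuffle_profile=shuf_prof,
        library_mean=float(enr.mean()),
        shuffle_set=tuple(shuffles),
    )


# ---------------------------------------------------------------------------
# Mutational scans


SUBSTITUTION_SCHEMES = {
    # AU-content preserving swaps
    "au_swap": {"A": "U", "U": "A"},
    # purine/pyrimidine-identity preserving transitions
    "transition": {"U": "C", "A": "G"},
}


@dataclass(frozen=True)
class MutScanResult:
    """Single-substitution scan of a consensus motif.

    Each mutant group contains sequences carrying the mutant but not the
    consensus (nor any extra exclusion).  ``control_group`` is the AU-content
    control: sequences containing a composition-preserving shuffle of the
    consensus but not the consensus.
    """

    consensus: str
    scheme: str
    mutants: pd.DataFrame
    consensus_group: GroupSummary
    control_group: GroupSummary | None
    library_mean: float


def mutational_scan(
    variants: pd.DataFrame,
    consensus: str,
    scheme: str = "au_swap",
    extra_exclusions=(),
    seed: int = 0,
) -> MutScanResult:
    if not is_concrete(consensus):
        raise InvalidParameterError("mutational scan needs a concrete consensus")
    if scheme not in SUBSTITUTION_SCHEMES:
        raise InvalidParameterError(f"unknown substitution scheme {scheme!r}")
    table = SUBSTITUTION_SCHEMES[scheme]
    seqs = variants["n50"].tolist()
    enr = variants["enr"].to_numpy(dtype=float)
    has_consensus = contains_mask(seqs, consensus)
    keep = np.ones(len(seqs), dtype=bool)
    for ex in extra_exclusions:
        keep &= ~contains_mask(seqs, ex)

    records = []
    for i, ref in enumerate(consensus):
        alt = table.get(ref)
        if alt is None:
            logger.info(
                "scan %s: position %d (%s) undefined under scheme %s; skipped",
                consensus, i + 1, ref, scheme,
            )
            continue
        mutant = consensus[:i] + alt + consensus[i + 1:]
        mask = contains_mask(seqs, mutant) & ~has_consensus & keep
        row = {
            "position": i + 1,
            "ref": ref,
            "alt": alt,
            "mutant": mutant,
            "contains_efficiency_element": EFFICIENCY_ELEMENT in mutant,
        }
        if mask.any():
            g = summarize(enr[mask])
            row.update({"n": g.n, "mean": g.mean, "sd": g.sd, "sem": g.sem})
        else:
            row.update({"n": 0, "mean": np.nan, "sd": np.nan, "sem": np.nan})
        records.append(row)

    shuffles = shuffle_set_for(consensus, seed=seed)
    control_group = None
    if shuffles:
        ctrl_mask = contains_mask(seqs, shuffles) & ~has_consensus & keep
        if ctrl_mask.any():
            control_group = summarize(enr[ctrl_mask])
    cons_mask = has_consensus & keep
    if not cons_mask.any():
        raise InsufficientDataError(f"no sequences contain consensus {consensus}")
    return MutScanResult(
        consensus=consensus,
        scheme=scheme,
        mutants=pd.DataFrame(records),
        consensus_group=summarize(enr[cons_mask]),
        control_group=control_group,
        library_mean=float(enr.mean()),
    )


# ---------------------------------------------------------------------------
# Double-motif arrangement


def _has_disjoint_pair(pos_a, len_a, pos_b, len_b) -> bool:
    if not pos_a or not pos_b:
        return False
    # A strictly before B without overlap, or vice versa
    if max(pos_b) >= min(pos_a) + len_a:
        return True
    if max(pos_a) >= min(pos_b) + len_b:
        return True
    return False


def arrangement_fraction(
    variants: pd.DataFrame,
    motif_a: str,
    motif_b: str,
    n_bins: int = 5,
    require_disjoint: bool = True,
) -> pd.DataFrame:
    """Fraction of sequences with motif A 5' of motif B, per enrichment bin.

    Restricts to sequences containing both motifs (by default with at least
    one non-overlapping placement); the A-before-B order is decided by the
    5'-most occurrence of each motif; bins are equal-width over the observed
    enrichment range of qualifying sequences.
    """
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    la, lb = len(motif_a), len(motif_b)
    rows = []
    for s, e in zip(variants["n50"], variants["enr"]):
        pos_a = find_occurrences(s, motif_a)
        pos_b = find_occurrences(s, motif_b)
        if not pos_a or not pos_b:
            continue
        if require_disjoint and not _has_disjoint_pair(pos_a, la, pos_b, lb):
            continue
        rows.append((e, min(pos_a) < min(pos_b)))
    if not rows:
        raise InsufficientDataError(
            f"no sequences qualify for arrangement of {motif_a} vs {motif_b}"
        )
    enr = np.array([r[0] for r in rows])
    a_first = np.array([r[1] for r in rows])
    edges = np.linspace(enr.min(), enr.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, enr, side="right") - 1, 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        out.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": n,
                "fraction_a_before_b": float(a_first[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Per-position base statistics (kpLogo-style)


def position_base_enrichment(
    variants: pd.DataFrame,
    subsample: int = 50_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment-weighted per-position base statistics.

    For each position p and base b, the enrichment scores of sequences with b
    at p are compared with those of the remaining sequences by a two-sided
    Welch t-test; p-values are Bonferroni corrected by (#positions x 4).
    Sequences are subsampled (reproducibly) to ``subsample`` when the library
    is larger.
    """
    n = len(variants)
    if n == 0:
        raise DegenerateInputError("no variants")
    if n > subsample:
        rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
        take = np.sort(rng.choice(n, size=subsample, replace=False))
        variants = variants.iloc[take]
    else:
        logger.info("library (%d) smaller than subsample (%d); using all", n, subsample)
    enr = variants["enr"].to_numpy(dtype=float)
    enc = encode_sequences(variants["n50"].tolist())
    n, L = enc.shape
    n_tests = L * 4
    tot_sum, tot_ss = enr.sum(), (enr * enr).sum()
    records = []
    for p in range(L):
        col = enc[:, p]
        cnt = np.bincount(col, minlength=4)
        s = np.bincount(col, weights=enr, minlength=4)
        ss = np.bincount(col, weights=enr * enr, minlength=4)
        for b, base in enumerate("ACGU"):
            n1 = int(cnt[b])
            n2 = n - n1
            if n1 < 2 or n2 < 2:
                continue
            m1 = s[b] / n1
            m2 = (tot_sum - s[b]) / n2
            v1 = max((ss[b] - n1 * m1 * m1) / (n1 - 1), 0.0)
            v2 = max(((tot_ss - ss[b]) - n2 * m2 * m2) / (n2 - 1), 0.0)
            se2 = v1 / n1 + v2 / n2
            if se2 == 0:
                continue
            t = (m1 - m2) / math.sqrt(se2)
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            pval = 2.0 * stats.t.sf(abs(t), df)
            p_bonf = min(1.0, pval * n_tests)
            records.append(
                {
                    "position": p + 1,
                    "base": base,
                    "n": n1,
                    "mean": m1,
                    "mean_rest": m2,
                    "t": t,
                    "df": df,
                    "p": pval,
                    "p_bonferroni": p_bonf,
                    "significant": p_bonf < alpha,
                }
            )
    return pd.DataFrame(records)
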