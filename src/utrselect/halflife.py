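"""Motif effects on native mRNA half-life, paired with enrichment effects.

Native-gene 3' UTRs come with measured half-lives per isoform plus a reported
gene-mean half-life.  One representative isoform is kept per gene (the one
whose half-life is nearest the reported gene mean), half-lives are expressed
relative to the cohort mean, (lambda - <lambda>)/<lambda>, and the same
motif / shuffle / exclusion machinery used for the selection library is
applied to the native UTR sequences.  The protein side uses relative
normalized enrichment, (Enr_norm - <Enr_norm>)/<Enr_norm>, so both sides are
dimensionless and sign-comparable.

A synthetic half-life generator with multiplicative planted motif effects
provides ground truth: half-lives are positive and right-skewed, so they are
drawn log-normally and motif effects act as fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._alphabet import DegenerateInputError, InvalidParameterError, iupac_regex
from .enrichment import GroupSummary, WelchResult, normalize_scores, summarize, welch_t_test
from .motifs import InsufficientDataError, _resolve_control, contains_mask
from .simulate import _rng, generate_random_library

HALFLIFE_COLUMNS = ["gene", "isoform_utr_seq", "halflife_min", "gene_mean_halflife_min"]


def select_representative_isoform(
    isoforms: list[tuple[str, float]], gene_mean: float
) -> tuple[str, float]:
    """The isoform whose half-life is nearest the reported gene mean.

    Ties go to the shorter half-life, then to the lexicographically smaller
    sequence, so the choice is deterministic.
    """
    if not isoforms:
        raise DegenerateInputError("empty isoform list")
    return min(isoforms, key=lambda it: (abs(it[1] - gene_mean), it[1], it[0]))


def representative_table(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse an isoform-level table to one representative row per gene."""
    rows = []
    for gene, grp in records.groupby("gene", sort=True):
        gene_mean = float(grp["gene_mean_halflife_min"].iloc[0])
        seq, hl = select_representative_isoform(
            list(zip(grp["isoform_utr_seq"], grp["halflife_min"])), gene_mean
        )
        rows.append(
            {
                "gene": gene,
                "isoform_utr_seq": seq,
                "halflife_min": hl,
                "gene_mean_halflife_min": gene_mean,
            }
        )
    return pd.DataFrame(rows)


def relative_halflife(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``relative_halflife`` = (lambda - <lambda>)/<lambda>; mean is 0."""
    if len(records) < 2:
        raise DegenerateInputError("need >= 2 half-life records")
    lam = records["halflife_min"].to_numpy(dtype=float)
    if (lam <= 0).any():
        raise InvalidParameterError("half-lives must be positive")
    mean = lam.mean()
    out = records.copy()
    out["relative_halflife"] = (lam - mean) / mean
    return out


@dataclass(frozen=True)
class SideTriad:
    """without / with / control group summaries on one measurement side."""

    without_group: GroupSummary
    with_group: GroupSummary
    control_group: GroupSummary | None
    p_with_vs_without: WelchResult | None
    p_with_vs_control: WelchResult | None


@dataclass(frozen=True)
class PairedMotifComparison:
    motif: str
    protein_side: SideTriad
    rna_side: SideTriad
    control_set: tuple[str, ...]


def _triad(values: np.ndarray, seqs: list[str], motif: str, ctrl_set, exclusions) -> SideTriad:
    keep = np.ones(len(seqs), dtype=bool)
    for ex in exclusions:
        keep &= ~contains_mask(seqs, ex)
    has = contains_mask(seqs, motif)
    with_mask = has & keep
    without_mask = ~has & keep
    if not with_mask.any():
        raise InsufficientDataError(f"no sequences contain motif {motif}")
    ctrl_group = None
    p_ctrl = None
    if ctrl_set:
        cmask = contains_mask(seqs, ctrl_set) & ~has & keep
        if cmask.any():
            ctrl_group = summarize(values[cmask])
            if cmask.sum() >= 2 and with_mask.sum() >= 2:
                p_ctrl = welch_t_test(values[with_mask], values[cmask])
    p_wo = None
    if with_mask.sum() >= 2 and without_mask.sum() >= 2:
        p_wo = welch_t_test(values[with_mask], values[without_mask])
    return SideTriad(
        without_group=summarize(values[without_mask]),
        with_group=summarize(values[with_mask]),
        control_group=ctrl_group,
        p_with_vs_without=p_wo,
        p_with_vs_control=p_ctrl,
    )


def paired_motif_comparison(
    variants: pd.DataFrame,
    halflife_records: pd.DataFrame,
    motif: str,
    control="shuffles",
    exclusions=(),
    seed: int = 0,
) -> PairedMotifComparison:
    """Side-by-side triads: relative enrichment vs. relative half-life.

    Both sides use the same motif, the same control policy (shuffles or an
    explicit AU-content control) and the same exclusions.
    """
    if len(variants) == 0 or len(halflife_records) == 0:
        raise DegenerateInputError("both datasets must be non-empty")
    ctrl_set = _resolve_control(motif, control, 50, seed)

    rel_enr = normalize_scores(variants["enr"].to_numpy()).relative
    protein = _triad(rel_enr, variants["n50"].tolist(), motif, ctrl_set, exclusions)

    reps = relative_halflife(representative_table(halflife_records))
    rna = _triad(
        reps["relative_halflife"].to_numpy(),
        reps["isoform_utr_seq"].tolist(),
        motif,
        ctrl_set,
        exclusions,
    )
    return PairedMotifComparison(
        motif=motif, protein_side=protein, rna_side=rna, control_set=tuple(ctrl_set)
    )


def generate_halflife_table(
    n_genes: int = 2000,
    motif_effects=(),
    utr_length: int = 120,
    median_halflife: float = 20.0,
    log_sd: float = 0.6,
    max_isoforms: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic isoform-level half-life table with planted fold effects.

    ``motif_effects`` is a list of (iupac_motif, fold) pairs: an isoform whose
    UTR contains the motif has its half-life multiplied by ``fold``.
    Half-lives are log-normal around ``median_halflife`` minutes; each gene
    carries 1..max_isoforms isoforms and reports the mean of its isoform
    half-lives as the gene mean.
    """
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    rng = _rng(seed, "generate_halflife_table")
    n_iso = rng.integers(1, max_isoforms + 1, size=n_genes)
    total = int(n_iso.sum())
    utrs = generate_random_library(total, length=utr_length, seed=seed)["n50"].tolist()
    lam = median_halflife * np.exp(rng.normal(0.0, log_sd, size=total))
    for motif, fold in motif_effects:
        if fold <= 0:
            raise InvalidParameterError("motif fold effects must be positive")
        pat = iupac_regex(motif)
        hit = np.fromiter((pat.search(u) is not None for u in utrs), dtype=bool)
        lam[hit] *= fold
    rows = []
    pos = 0
    for g in range(n_genes):
        k = int(n_iso[g])
        lams = lam[pos:pos + k]
        gene_mean = float(lams.mean())
        for j in range(k):
            rows.append(
                {
                    "gene": f"g{g:05d}",
                    "isoform_utr_seq": utrs[pos + j],
                    "halflife_min": float(lams[j]),
                    "gene_mean_halflife_min": gene_mean,
                }
            )
        pos += k
    return pd.DataFrame(rows, columns=HALFLIFE_COLUMNS)
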