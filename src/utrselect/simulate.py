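"""Synthetic N50 library generator and growth-selection simulator.

The simulator provides ground truth for every downstream estimator.  It
emulates the structure of a massively parallel 3' UTR reporter selection:

* a library of random 50-mers drawn with equal base probabilities;
* a per-variant true log2 enrichment composed of a baseline, an AU-content
  term, planted motif effects with a 5'-biased linear positional decay, and
  Gaussian noise on the log2 scale;
* selection as a single multiplicative tilt 2**enr_true on pre-selection
  frequencies (any monotone growth model collapses to this, since Enr is
  defined as a frequency ratio);
* log-normal library skew and multinomial sequencing sampling of both pools.

Pairwise differences of true enrichments are preserved in expectation by the
estimated scores: E[Enr_i] = enr_true_i - log2(sum_j f_pre_j 2**enr_true_j),
a common shift that cancels in every group comparison.

Randomness policy: each operation derives its own RNG stream from
``(seed, operation-name)`` so results do not depend on call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alphabet import (
    InvalidParameterError,
    decode_matrix,
    encode_sequences,
    iupac_regex,
    validate_rna,
)
from .kmers import au_content

#: Default library scale and sequencing depths.  The library size matches the
#: number of analyzed variants in the selection this simulator emulates
#: (~590,000 post-filter); per-pool depths are configurable defaults.
DEFAULT_N_VARIANTS = 590_000
DEFAULT_LENGTH = 50
DEFAULT_DEPTH = 20_000_000

UNIFORM_PROBS = (0.25, 0.25, 0.25, 0.25)


def _rng(seed: int, op: str) -> np.random.Generator:
    """Operation-scoped RNG: stream depends only on (seed, op name)."""
    tag = zlib.crc32(op.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass(frozen=True)
class PlantedMotif:
    """A motif with a maximal log2 effect that decays linearly with position.

    The effect of a single occurrence whose 5' end is at 1-based position p in
    a length-L sequence is ``max_effect * (1 - decay * (p - 1) / (L - len))``:
    full strength at the 5' end, reduced by ``decay`` at the last admissible
    start.  Only the 5'-most occurrence counts.
    """

    motif: str
    max_effect: float
    decay: float = 0.0

    def __post_init__(self):
        validate_rna(self.motif, allow_iupac=True)
        if not 0.0 <= self.decay <= 1.0:
            raise InvalidParameterError("decay must lie in [0, 1]")


@dataclass(frozen=True)
class EffectModel:
    """Ground-truth generative model for per-variant log2 enrichment."""

    beta0: float = 0.0
    beta_au: float = 0.0
    planted_motifs: tuple[PlantedMotif, ...] = field(default_factory=tuple)
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        object.__setattr__(self, "planted_motifs", tuple(self.planted_motifs))


def demo_effect_model() -> EffectModel:
    """The default study-condition model used by the analysis drivers.

    Effect sizes are anchored to the printed group means of the selection this
    simulator emulates: the efficiency element UAUAUA lifts carriers by
    2.60 - 0.86 = 1.74 log2 units with a ~45% decline across the 50-mer; the
    positioning element AAWAAA adds 1.20 - 0.86 = 0.34; a Puf3-like site
    (UGUANAUA) adds 1.0 with positional decay; an AU-content slope of 2.0
    log2 per unit AU fraction yields an AU/enrichment Pearson r near 0.27
    given noise_sd = 0.5.
    """
    return EffectModel(
        beta0=0.2,
        beta_au=2.0,
        planted_motifs=(
            PlantedMotif("UAUAUA", 1.74, 0.45),
            PlantedMotif("AAWAAA", 0.34, 0.0),
            PlantedMotif("UGUANAUA", 1.0, 0.5),
        ),
        noise_sd=0.5,
    )


def generate_random_library(
    n_variants: int,
    length: int = DEFAULT_LENGTH,
    base_probs=UNIFORM_PROBS,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n_variants`` i.i.d. random RNA sequences of the given length.

    Returns a DataFrame with columns ``variant_id`` (unique) and ``n50``.
    Duplicate sequences are permitted and kept as distinct variants, as in a
    real random library.
    """
    if n_variants < 1:
        raise InvalidParameterError("n_variants must be >= 1")
    if length < 1:
        raise InvalidParameterError("length must be >= 1")
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("base_probs must be 4 probabilities summing to 1")
    rng = _rng(seed, "generate_random_library")
    if np.allclose(probs, 0.25):
        enc = rng.integers(0, 4, size=(n_variants, length), dtype=np.uint8)
    else:
        cum = np.cumsum(probs)
        cum[-1] = 1.0
        u = rng.random((n_variants, length))
        enc = np.searchsorted(cum, u, side="right").astype(np.uint8)
    seqs = decode_matrix(enc)
    width = len(str(n_variants))
    ids = [f"v{i:0{width}d}" for i in range(n_variants)]
    return pd.DataFrame({"variant_id": ids, "n50": seqs})


def assign_true_enrichment(
    library: pd.DataFrame, model: EffectModel, seed: int = 0
) -> pd.DataFrame:
    """Compute each variant's true log2 enrichment under the effect model.

    enr_true = beta0 + beta_au * AU + sum over planted motifs present of
    max_effect * (1 - decay * (p-1)/(L-|m|)) at the 5'-most occurrence p,
    plus N(0, noise_sd) noise fixed by the seed.
    """
    if len(library) == 0:
        raise InvalidParameterError("library is empty")
    seqs = library["n50"].tolist()
    L = len(seqs[0])
    enr = np.full(len(seqs), model.beta0, dtype=float)
    if model.beta_au != 0.0:
        enr += model.beta_au * np.array([au_content(s) for s in seqs])
    for planted in model.planted_motifs:
        m = len(planted.motif)
        if m > L:
            raise InvalidParameterError(
                f"planted motif {planted.motif!r} longer than sequence length {L}"
            )
        pat = iupac_regex(planted.motif)
        span = L - m  # 0 only when the motif fills the sequence
        for i, s in enumerate(seqs):
            hit = pat.search(s)
            if hit is None:
                continue
            p = hit.start() + 1  # 1-based 5'-most occurrence
            frac = 0.0 if span == 0 else (p - 1) / span
            enr[i] += planted.max_effect * (1.0 - planted.decay * frac)
    if model.noise_sd > 0:
        rng = _rng(seed, "assign_true_enrichment")
        enr += rng.normal(0.0, model.noise_sd, size=len(seqs))
    return pd.DataFrame({"variant_id": library["variant_id"], "enr_true": enr})


def _pool_frequencies(truth_enr: np.ndarray, abundance: np.ndarray):
    f_pre = abundance / abundance.sum()
    tilt = f_pre * np.exp2(truth_enr)
    f_post = tilt / tilt.sum()
    return f_pre, f_post


def simulate_counts(
    library: pd.DataFrame,
    truth: pd.DataFrame,
    depth_pre: int = DEFAULT_DEPTH,
    depth_post: int = DEFAULT_DEPTH,
    skew_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate sequencing of the pre- and post-selection pools.

    Pre-selection abundances are LogNormal(0, skew_sd); the post-selection
    pool is the pre pool tilted by 2**enr_true; both pools are read out as
    multinomial samples at the requested depths.
    """
    if depth_pre < 1 or depth_post < 1:
        raise InvalidParameterError("sequencing depths must be >= 1")
    if skew_sd < 0:
        raise InvalidParameterError("skew_sd must be >= 0")
    if not library["variant_id"].equals(truth["variant_id"]):
        raise InvalidParameterError("library and truth variant_ids do not match")
    rng = _rng(seed, "simulate_counts")
    n = len(library)
    abundance = (
        rng.lognormal(0.0, skew_sd, size=n) if skew_sd > 0 else np.ones(n)
    )
    f_pre, f_post = _pool_frequencies(truth["enr_true"].to_numpy(), abundance)
    pre = rng.multinomial(int(depth_pre), f_pre)
    post = rng.multinomial(int(depth_post), f_post)
    return pd.DataFrame(
        {
            "variant_id": library["variant_id"],
            "n50": library["n50"],
            "pre_count": pre,
            "post_count": post,
        }
    )


def exact_frequencies(
    library: pd.DataFrame, truth: pd.DataFrame, skew_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Infinite-depth limit: exact pool frequencies, no multinomial sampling.

    Useful for exactness tests: estimated Enr differences then equal
    enr_true differences exactly.
    """
    if not library["variant_id"].equals(truth["variant_id"]):
        raise InvalidParameterError("library and truth variant_ids do not match")
    n = len(library)
    if skew_sd > 0:
        abundance = _rng(seed, "exact_frequencies").lognormal(0.0, skew_sd, size=n)
    else:
        abundance = np.ones(n)
    f_pre, f_post = _pool_frequencies(truth["enr_true"].to_numpy(), abundance)
    return pd.DataFrame(
        {
            "variant_id": library["variant_id"],
            "n50": library["n50"],
            "f_pre": f_pre,
            "f_post": f_post,
        }
    )


def simulate_library(
    model: EffectModel,
    n_variants: int = DEFAULT_N_VARIANTS,
    length: int = DEFAULT_LENGTH,
    depth_pre: int = DEFAULT_DEPTH,
    depth_post: int = DEFAULT_DEPTH,
    skew_sd: float = 0.5,
    seed: int = 0,
):
    """Convenience: library + truth + simulated count table in one call."""
    lib = generate_random_library(n_variants, length, seed=seed)
    truth = assign_true_enrichment(lib, model, seed=seed)
    counts = simulate_counts(lib, truth, depth_pre, depth_post, skew_sd, seed=seed)
    return lib, truth, counts


def encode_library(library: pd.DataFrame) -> np.ndarray:
    """Encode a library's sequences as a (n, L) uint8 matrix."""
    return encode_sequences(library["n50"].tolist())
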