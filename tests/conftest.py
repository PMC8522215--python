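import numpy as np
import pandas as pd
import pytest

import utrselect as u


@pytest.fixture(scope="session")
def planted_library():
    """Small scored library with a planted efficiency-element effect.

    20,000 variants, UAUAUA planted at +1.5 log2 units (no positional decay),
    an AU-content slope, mild noise, simulated sequencing at 2M reads/pool.
    Returns (variants, truth, model) with truth merged onto the kept rows.
    """
    model = u.EffectModel(
        beta0=0.3,
        beta_au=1.0,
        planted_motifs=(u.PlantedMotif("UAUAUA", 1.5, 0.0),),
        noise_sd=0.2,
    )
    lib, truth, counts = u.simulate_library(
        model, n_variants=20_000, depth_pre=2_000_000, depth_post=2_000_000,
        skew_sd=0.5, seed=101,
    )
    variants = u.score_library(counts).merge(truth, on="variant_id")
    return variants, truth, model


@pytest.fixture(scope="session")
def null_library():
    """Scored library with no sequence effects at all (pure sampling noise)."""
    model = u.EffectModel(beta0=0.0, beta_au=0.0, noise_sd=0.3)
    _, truth, counts = u.simulate_library(
        model, n_variants=20_000, depth_pre=2_000_000, depth_post=2_000_000,
        skew_sd=0.5, seed=202,
    )
    return u.score_library(counts).merge(truth, on="variant_id")


@pytest.fixture()
def tiny_counts():
    return pd.DataFrame(
        {
            "variant_id": ["a", "b", "c", "d"],
            "n50": ["AUGCAUGCAU", "UUUUUAAAAA", "GCGCGCGCGC", "UAUAUAUAUA"],
            "pre_count": [5, 15, 4, 100],
            "post_count": [1, 30, 100, 0],
        }
    )


def brute_force_distinct_kmers(seq: str, k: int) -> int:
    return len({seq[i:i + k] for i in range(len(seq) - k + 1)})


def brute_force_contains(seq: str, motif_expansions) -> bool:
    return any(e in seq for e in motif_expansions)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(424242)
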