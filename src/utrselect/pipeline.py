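"""End-to-end orchestration: simulate (optional) → score → k-mers → motifs.

``run_pipeline`` executes every stage on one count table and writes all
outputs, the configuration and a log into a single run directory.  Outputs
are stamped with the configuration hash and seed; rerunning with the same
configuration and inputs is bit-identical.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import pandas as pd

from . import halflife as hl
from . import io as uio
from . import kmers, motifs, simulate
from .config import RunConfig
from .enrichment import filter_variants, compute_frequencies, compute_enrichment

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _write_tsv(path: Path, df: pd.DataFrame, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig, out_dir) -> dict[str, Path]:
    """Run every configured stage; returns a name → path map of outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # fail fast on configuration problems, before any compute
    if config.motif_file is not None and not Path(config.motif_file).exists():
        raise PipelineError(f"configuration: motif file not found: {config.motif_file}")
    if config.counts_path is not None and not Path(config.counts_path).exists():
        raise PipelineError(f"configuration: count table not found: {config.counts_path}")

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("utrselect")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers[:-1]):
        root.addHandler(logging.StreamHandler(sys.stderr))

    stamp = f"utrselect config={config.digest()} seed={config.seed}"
    config.to_yaml(out / "config.yaml")
    paths: dict[str, Path] = {"config": out / "config.yaml", "log": out / "run.log"}

    motif_list = list(config.motifs)
    if config.motif_file is not None:
        motif_list += uio.read_motif_list(config.motif_file)

    def stage(name):
        logger.info("stage %s", name)

    try:
        stage("simulate")
        if config.counts_path is None:
            model = simulate.demo_effect_model()
            lib, truth, counts = simulate.simulate_library(
                model,
                n_variants=config.n_variants,
                length=config.length,
                depth_pre=config.depth_pre,
                depth_post=config.depth_post,
                skew_sd=config.skew_sd,
                seed=config.stage_seed("simulate"),
            )
            _write_tsv(out / "counts.tsv", counts, stamp)
            _write_tsv(out / "truth.tsv", truth, stamp)
            uio.write_fasta(out / "library.fasta", lib)
            paths.update(
                counts=out / "counts.tsv",
                truth=out / "truth.tsv",
                library=out / "library.fasta",
            )
        else:
            counts = uio.read_counts(config.counts_path)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"stage simulate failed: {exc}") from exc

    try:
        stage("enrich")
        freq = compute_frequencies(counts)
        kept = filter_variants(freq, config.min_pre, config.min_post)
        logger.info("filter: %d rows in, %d rows kept", len(counts), len(kept))
        variants = compute_enrichment(kept)
        _write_tsv(out / "scores.tsv", variants[uio.SCORE_COLUMNS], stamp)
        paths["scores"] = out / "scores.tsv"
    except Exception as exc:
        raise PipelineError(f"stage enrich failed: {exc}") from exc

    try:
        stage("kmers")
        for k in config.k_list:
            tab = kmers.kmer_summary(variants, k)
            _write_tsv(out / f"kmers_k{k}.tsv", tab, stamp)
            paths[f"kmers_k{k}"] = out / f"kmers_k{k}.tsv"
        logger.info("AU/enrichment Pearson r = %.4f", kmers.au_correlation(variants))
    except Exception as exc:
        raise PipelineError(f"stage kmers failed: {exc}") from exc

    try:
        stage("motifs")
        rows = []
        for m in motif_list:
            eff = motifs.motif_effect(
                variants, m, seed=config.stage_seed(f"shuffle:{m}"),
                max_shuffles=config.max_shuffles,
            )
            rows.append(
                {
                    "motif": m,
                    "n_without": eff.without_group.n,
                    "mean_without": eff.without_group.mean,
                    "sem_without": eff.without_group.sem,
                    "n_with": eff.with_group.n,
                    "mean_with": eff.with_group.mean,
                    "sem_with": eff.with_group.sem,
                    "n_shuffle": eff.shuffle_group.n if eff.shuffle_group else 0,
                    "mean_shuffle": eff.shuffle_group.mean if eff.shuffle_group else float("nan"),
                    "sem_shuffle": eff.shuffle_group.sem if eff.shuffle_group else float("nan"),
                    "p_with_vs_without": eff.p_with_vs_without.p_value,
                    "p_with_vs_shuffle": eff.p_with_vs_shuffle.p_value if eff.p_with_vs_shuffle else float("nan"),
                }
            )
            prof = motifs.positional_profile(
                variants, m, seed=config.stage_seed(f"shuffle:{m}"),
                max_shuffles=config.max_shuffles,
            )
            _write_tsv(out / f"positions_{m}.tsv", prof.motif_profile, stamp)
            paths[f"positions_{m}"] = out / f"positions_{m}.tsv"
        _write_tsv(out / "motif_effects.tsv", pd.DataFrame(rows), stamp)
        paths["motif_effects"] = out / "motif_effects.tsv"
    except Exception as exc:
        raise PipelineError(f"stage motifs failed: {exc}") from exc

    try:
        stage("baselogo")
        base_stats = motifs.position_base_enrichment(
            variants, subsample=config.subsample, seed=config.stage_seed("baselogo")
        )
        _write_tsv(out / "position_base_stats.tsv", base_stats, stamp)
        paths["position_base_stats"] = out / "position_base_stats.tsv"
    except Exception as exc:
        raise PipelineError(f"stage baselogo failed: {exc}") from exc

    try:
        stage("halflife")
        if config.halflife_path is not None:
            table = uio.read_halflife(config.halflife_path)
        else:
            table = hl.generate_halflife_table(
                motif_effects=(("UAUAUA", 1.5),),
                seed=config.stage_seed("halflife"),
            )
            _write_tsv(out / "halflife_synthetic.tsv", table, stamp)
            paths["halflife_synthetic"] = out / "halflife_synthetic.tsv"
        rows = []
        for m in motif_list:
            cmp_ = hl.paired_motif_comparison(
                variants, table, m, seed=config.stage_seed(f"shuffle:{m}")
            )
            for side_name, side in (
                ("protein", cmp_.protein_side),
                ("rna", cmp_.rna_side),
            ):
                rows.append(
                    {
                        "motif": m,
                        "side": side_name,
                        "n_without": side.without_group.n,
                        "mean_without": side.without_group.mean,
                        "n_with": side.with_group.n,
                        "mean_with": side.with_group.mean,
                        "n_control": side.control_group.n if side.control_group else 0,
                        "mean_control": side.control_group.mean if side.control_group else float("nan"),
                    }
                )
        _write_tsv(out / "halflife_comparison.tsv", pd.DataFrame(rows), stamp)
        paths["halflife_comparison"] = out / "halflife_comparison.tsv"
    except Exception as exc:
        raise PipelineError(f"stage halflife failed: {exc}") from exc

    root.removeHandler(handler)
    handler.close()
    return paths
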