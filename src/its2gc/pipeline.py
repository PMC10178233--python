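"""End-to-end orchestration: per-species analysis and cross-species summaries.

For each species matrix the pipeline filters singleton alleles, derives the
consensus structure and column partition, computes GC/diversity statistics,
selects a substitution model by AICc, and derives the GC-dynamics statistics
(formation rates, mismatch-conversion bias, GC* and trends).  Across species
it correlates K with GC content per region.  Failures are per-species: a
species failing any stage is logged, counted and skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .composition import (
    avg_nucleotide_differences,
    gc_report,
    spearman_correlation,
)
from .gc_dynamics import (
    formation_rates,
    gc_star_nucleotide,
    gc_star_pair,
    gc_trend,
    mismatch_conversion,
)
from .io_seqstruct import SpeciesMatrix, filter_singleton_alleles
from .likelihood import select_model
from .mcmc import mcmc_sample
from .structure import consensus_structure, partition_columns
from .synth import SynthConfig, read_family, simulate_family
from .trees import build_nj_tree

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = ("HKY85+RNA16", "HKY85+RNA7", "HKY85")


@dataclass
class RunConfig:
    """Settings of one pipeline run; exactly one input mode must be set."""

    synth: SynthConfig | None = None
    input_dir: str | Path | None = None
    outdir: str | Path = "its2gc_run"
    consensus_threshold: float = 0.70
    candidates: Sequence[str] = DEFAULT_CANDIDATES
    estimator: str = "ml"  # "ml" | "mcmc"
    mcmc_iters: int = 20000
    mcmc_thin: int = 10
    apply_singleton_filter: bool = True
    optimize_branch_lengths: bool = False
    fit_maxiter: int = 200
    trend_tolerance: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.input_dir is None):
            raise ValueError("exactly one of synth / input_dir must be given")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must be in (0, 1]")
        if self.estimator not in ("ml", "mcmc"):
            raise ValueError("estimator must be 'ml' or 'mcmc'")


@dataclass
class PipelineResult:
    gc_table: pd.DataFrame
    diversity_table: pd.DataFrame
    correlations: pd.DataFrame
    model_selection: pd.DataFrame
    transformation_rates: pd.DataFrame
    gcstar_table: pd.DataFrame
    metadata: dict
    warnings: list[str] = field(default_factory=list)


def _analyze_species(matrix: SpeciesMatrix, config: RunConfig) -> dict:
    records = matrix.records
    if config.apply_singleton_filter:
        records = filter_singleton_alleles(records)
        if not records:
            raise ValueError("no alleles left after singleton filter")
    matrix = SpeciesMatrix(
        species_name=matrix.species_name,
        records=records,
        consensus_structure=matrix.consensus_structure,
    )
    consensus = consensus_structure(matrix, threshold=config.consensus_threshold)
    partition = partition_columns(consensus, matrix.ncols)
    if not partition.paired or not partition.unpaired:
        raise ValueError("degenerate partition: need both paired and unpaired columns")
    report = gc_report(matrix, partition)
    K = avg_nucleotide_differences(records) if len(records) >= 2 else 0.0

    tree = build_nj_tree(matrix)
    best, ranking = select_model(
        matrix,
        partition,
        config.candidates,
        tree=tree,
        optimize_branch_lengths=config.optimize_branch_lengths,
        maxiter=config.fit_maxiter,
        seed=config.seed,
    )
    ranking.insert(0, "species", matrix.species_name)

    nuc_model, pair_model = best.nuc_model, best.pair_model
    if config.estimator == "mcmc" and best.family in (
        "HKY85+RNA16", "REV+RNA16", "HKY85+RNA16P", "HKY85+RNA7", "HKY85+RNA7P",
    ):
        mc = mcmc_sample(
            matrix,
            partition,
            best.family,
            tree,
            n_iter=config.mcmc_iters,
            thin=config.mcmc_thin,
            seed=config.seed,
        )
        from .likelihood import get_family

        nuc_model, pair_model = mc.mean_models(get_family(best.family))

    out: dict = {
        "species": matrix.species_name,
        "report": report,
        "K": K,
        "ranking": ranking,
        "best_family": best.family,
    }
    if pair_model is not None:
        trans = formation_rates(pair_model)
        out["transformation"] = trans
        try:
            out["mismatch_ratio"] = mismatch_conversion(pair_model).aggregate_ratio
        except ValueError:
            out["mismatch_ratio"] = np.nan
        out["gcstar_paired"] = gc_trend(
            report.gc_paired,
            gc_star_pair(pair_model),
            config.trend_tolerance,
            region="paired",
        )
    if nuc_model is not None:
        out["gcstar_unpaired"] = gc_trend(
            report.gc_unpaired,
            gc_star_nucleotide(nuc_model),
            config.trend_tolerance,
            region="unpaired",
        )
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; writes TSV tables + run metadata to ``outdir``."""
    if config.synth is not None:
        matrices, truth = simulate_family(config.synth)
    else:
        matrices, truth = read_family(config.input_dir), None
    if not matrices:
        raise ValueError("empty input: no species matrices")

    warnings: list[str] = []
    gc_rows, div_rows, rank_tables, trans_rows, star_rows = [], [], [], [], []
    for matrix in matrices:
        try:
            res = _analyze_species(matrix, config)
        except Exception as err:  # noqa: BLE001 - species are independent analyses
            msg = f"species {matrix.species_name}: {err}"
            logger.warning(msg)
            warnings.append(msg)
            continue
        rep = res["report"]
        gc_rows.append(
            (rep.species, rep.n_alleles, rep.gc_total, rep.gc_paired,
             rep.gc_unpaired, rep.sd_paired, rep.sd_unpaired)
        )
        div_rows.append((rep.species, res["K"]))
        rank_tables.append(res["ranking"])
        if "transformation" in res:
            t = res["transformation"]
            trans_rows.append(
                (rep.species, res["best_family"], t.total_to_gc, t.total_to_au,
                 t.ratio, t.gc_pair_freq, t.au_pair_freq, res["mismatch_ratio"])
            )
        for key in ("gcstar_paired", "gcstar_unpaired"):
            if key in res:
                est = res[key]
                star_rows.append(
                    (rep.species, est.region, est.gc_current, est.gc_star, est.trend)
                )

    gc_table = pd.DataFrame(
        gc_rows,
        columns=["species", "n_alleles", "gc_total", "gc_paired", "gc_unpaired",
                 "sd_paired", "sd_unpaired"],
    )
    diversity = pd.DataFrame(div_rows, columns=["species", "K"])
    if gc_table.empty:
        raise RuntimeError("no species could be analyzed; " + "; ".join(warnings))

    corr_rows = []
    if len(gc_table) >= 3:
        merged = gc_table.merge(diversity, on="species")
        for region, col in (
            ("total", "gc_total"), ("paired", "gc_paired"), ("unpaired", "gc_unpaired")
        ):
            try:
                rho, p = spearman_correlation(merged["K"], merged[col])
                corr_rows.append((region, rho, p, len(merged)))
            except ValueError as err:
                warnings.append(f"correlation {region}: {err}")
    correlations = pd.DataFrame(
        corr_rows, columns=["region", "spearman_rho", "p_value", "n_species"]
    )

    result = PipelineResult(
        gc_table=gc_table,
        diversity_table=diversity,
        correlations=correlations,
        model_selection=(
            pd.concat(rank_tables, ignore_index=True) if rank_tables else pd.DataFrame()
        ),
        transformation_rates=pd.DataFrame(
            trans_rows,
            columns=["species", "family", "total_to_gc", "total_to_au", "ratio",
                     "gc_pair_freq", "au_pair_freq", "mismatch_ratio"],
        ),
        gcstar_table=pd.DataFrame(
            star_rows, columns=["species", "region", "gc_current", "gc_star", "trend"]
        ),
        metadata={
            "version": __version__,
            "seed": config.seed,
            "estimator": config.estimator,
            "consensus_threshold": config.consensus_threshold,
            "candidates": list(config.candidates),
            "singleton_filter": config.apply_singleton_filter,
            "n_species_in": len(matrices),
            "n_species_analyzed": int(len(gc_table)),
            "n_warnings": len(warnings),
            "truth": truth,
        },
        warnings=warnings,
    )
    _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "gc_table.tsv": result.gc_table,
        "diversity_table.tsv": result.diversity_table,
        "correlations.tsv": result.correlations,
        "model_selection.tsv": result.model_selection,
        "transformation_rates.tsv": result.transformation_rates,
        "gcstar_table.tsv": result.gcstar_table,
    }
    for name, df in tables.items():
        df.to_csv(outdir / name, sep="\t", index=False, float_format="%.6f")
    meta = dict(result.metadata)
    meta["warnings"] = result.warnings
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
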