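"""End-to-end orchestration: inputs -> distances -> gap report -> NJ tree.

A run is a pure function of (inputs, config, seed) up to log timestamps.
Artifacts written to the output directory:

    distance_matrix.tsv   square K2P matrix, NA for undefined entries
    species_gap.tsv       per-species max-intra / min-inter-congeneric (%)
    gap_report.json       headline statistics (percent, unrounded + flags)
    level_summaries.tsv   per-class mean/min/max (%)
    discrimination.tsv    per-species discrimination flags and partners
    tree.newick           neighbor-joining tree
    monophyly.tsv         per-taxon monophyly flags
    run.log               policies, seed, exclusion and undefined counts
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io_taxa
from .barcoding_stats import (
    barcoding_gap_report,
    gap_rows_to_frame,
    level_summaries,
    species_gap_rows,
    summaries_to_frame,
)
from .distances import distance_matrix
from .io_taxa import Dataset, build_dataset
from .nj_tree import nj, taxon_monophyly_table
from .synthetic_data import SimulationConfig, simulate_dataset, write_truth

__all__ = ["RunConfig", "run"]

logger = logging.getLogger("barcodegap.pipeline")

ARTIFACTS = (
    "distance_matrix.tsv",
    "species_gap.tsv",
    "gap_report.json",
    "level_summaries.tsv",
    "discrimination.tsv",
    "tree.newick",
    "monophyly.tsv",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``fasta`` + ``taxonomy``) or ``simulate`` must be given.
    """

    out_dir: str | Path
    fasta: str | Path | None = None
    taxonomy: str | Path | None = None
    simulate: SimulationConfig | None = None
    deletion: str = "pairwise"
    criterion: str = "both"
    undefined_policy: str = "drop-specimen"
    report_decimals: int = 1

    def __post_init__(self) -> None:
        has_files = self.fasta is not None and self.taxonomy is not None
        if has_files == (self.simulate is not None):
            raise ValueError(
                "exactly one of (fasta + taxonomy) or simulate must be configured"
            )


def _load(cfg: RunConfig) -> Dataset:
    if cfg.simulate is not None:
        ds, truth = simulate_dataset(cfg.simulate)
        write_truth(truth, Path(cfg.out_dir) / "truth.json")
        io_taxa.write_alignment(ds.barcodes, Path(cfg.out_dir) / "alignment.fasta")
        io_taxa.write_taxonomy(
            list(ds.taxonomy.values()), Path(cfg.out_dir) / "taxonomy.tsv"
        )
        return ds
    barcodes = io_taxa.read_alignment(cfg.fasta)
    taxonomy = io_taxa.read_taxonomy(cfg.taxonomy)
    return build_dataset(barcodes, taxonomy)


def run(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory results keyed by name."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("barcodegap")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        ds = _load(cfg)
        summary = ds.summary()
        logger.info("dataset: %s", summary)
        logger.info(
            "policies: deletion=%s criterion=%s undefined=%s",
            cfg.deletion,
            cfg.criterion,
            cfg.undefined_policy,
        )

        dm = distance_matrix(ds, deletion=cfg.deletion)
        logger.info("undefined distances: %d", dm.n_undefined)
        dm.write_tsv(out / "distance_matrix.tsv")

        rows = species_gap_rows(dm, ds.taxonomy, criterion=cfg.criterion)
        for r in rows:
            if r.n_specimens < 2:
                logger.info("species %s: single specimen, no intraspecific pairs", r.species)
        report = barcoding_gap_report(rows)
        report.to_json(out / "gap_report.json")

        frame = gap_rows_to_frame(rows)
        frame.to_csv(
            out / "species_gap.tsv",
            sep="\t",
            index=False,
            na_rep="NA",
            float_format=f"%.{cfg.report_decimals}f",
        )
        frame[["species", "n_specimens", "discriminated", "failure_partners"]].to_csv(
            out / "discrimination.tsv", sep="\t", index=False
        )

        summaries = level_summaries(dm, ds.taxonomy)
        summaries_to_frame(summaries).to_csv(
            out / "level_summaries.tsv",
            sep="\t",
            index=False,
            na_rep="NA",
            float_format=f"%.{max(cfg.report_decimals, 2)}f",
        )

        tree = nj(dm, undefined=cfg.undefined_policy)
        io_taxa.write_newick(tree, out / "tree.newick")
        mono = taxon_monophyly_table(tree, ds.taxonomy)
        mono.to_csv(out / "monophyly.tsv", sep="\t", index=False)

        n_failed = sum(1 for r in rows if r.discriminated == "no")
        logger.info("species failing discrimination: %d", n_failed)
        return {
            "dataset": ds,
            "distance_matrix": dm,
            "gap_rows": rows,
            "gap_report": report,
            "level_summaries": summaries,
            "tree": tree,
            "monophyly": mono,
            "out_dir": out,
        }
    finally:
        root_logger.removeHandler(handler)
        handler.close()
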