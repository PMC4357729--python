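"""End-to-end orchestration of the spectral-count interactome analysis.

Stage chain (each stage consumes exactly the upstream subset the design
prescribes):

1. read counts, sum cytoplasmic/nuclear fractions;
2. enrichment of every protein against the negative control — the
   enriched set, restricted to proteins seen in both NSC samples, goes on;
3. intensity-binned robust z-test between differentiating and
   proliferating counts — the up-in-differentiation call set becomes the
   GO test set, with all identified proteins as background;
4. GO over-representation (optional, needs an annotation table);
5. physical-edge filtering and first-neighbor subnetwork around the
   enriched proteins (optional, needs a SIF edge list).

All tables are written as TSV plus a plain-text manifest; a rerun on
identical inputs and configuration is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import iotables
from .differential import BinStats, DifferentialConfig, differential_test
from .enrichment import EnrichmentConfig, enrichment_filter
from .go_enrich import go_enrichment
from .iotables import CountMatrix, SampleSummary
from .ppi_network import (DEFAULT_EXCLUDED_TYPES, InteractionGraph,
                          filter_physical_edges, first_neighbor_subnetwork)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    counts: str | Path = ""
    annotations: str | Path | None = None
    term_names: str | Path | None = None
    ppi: str | Path | None = None
    out_dir: str | Path = "results"
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    alpha_go: float = 0.1
    excluded_edge_types: frozenset[str] = DEFAULT_EXCLUDED_TYPES

    def echo(self) -> dict[str, object]:
        """Flat key-value view of the configuration for the manifest."""
        out: dict[str, object] = {
            "counts": str(self.counts),
            "annotations": str(self.annotations),
            "term_names": str(self.term_names),
            "ppi": str(self.ppi),
            "out_dir": str(self.out_dir),
            "alpha_go": self.alpha_go,
            "excluded_edge_types": ",".join(sorted(self.excluded_edge_types)),
        }
        for prefix, cfg in (("enrichment", self.enrichment),
                            ("differential", self.differential)):
            for key, val in vars(cfg).items():
                out[f"{prefix}.{key}"] = val
        return out


@dataclass
class ResultsBundle:
    summary: SampleSummary
    enrichment: pd.DataFrame
    differential: pd.DataFrame
    bin_stats: list[BinStats]
    go: pd.DataFrame | None
    subnetwork: InteractionGraph | None
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def enriched_in_both(self) -> pd.DataFrame:
        return self.enrichment[self.enrichment["enriched"]
                               & self.enrichment["in_both"]]

    @property
    def up_set(self) -> set[str]:
        sel = (self.differential["differential"]
               & (self.differential["direction"] == "up-in-differentiation"))
        return set(self.differential.loc[sel, "protein_id"])

    @property
    def down_set(self) -> set[str]:
        sel = (self.differential["differential"]
               & (self.differential["direction"] == "up-in-maintenance"))
        return set(self.differential.loc[sel, "protein_id"])


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> ResultsBundle:
    """Execute all stages and write the result tables plus manifest."""
    cm = _stage("read-counts")(iotables.read_count_table)(cfg.counts)
    merged = _stage("sum-fractions")(iotables.sum_fractions)(cm)
    return run_pipeline_from_matrix(merged, cfg)


def run_pipeline_from_matrix(merged: CountMatrix, cfg: RunConfig) -> ResultsBundle:
    """As :func:`run_pipeline` but starting from an in-memory merged matrix."""
    summary = _stage("summary")(iotables.sample_summary)(merged)
    logger.info("identified per sample: %s; union %d",
                summary.per_sample, summary.union)

    enr = _stage("enrichment")(enrichment_filter)(merged, cfg.enrichment)
    tested = enr[enr["enriched"] & enr["in_both"]]
    logger.info("enriched %d, of which in both NSC samples %d",
                int(enr["enriched"].sum()), len(tested))

    diff, bin_stats = _stage("differential")(differential_test)(
        tested.reset_index(drop=True), cfg.differential)

    go_table: pd.DataFrame | None = None
    if cfg.annotations is not None:
        annotations = _stage("read-annotations")(iotables.read_annotations)(
            cfg.annotations, cfg.term_names)
        up = set(diff.loc[diff["differential"]
                          & (diff["direction"] == "up-in-differentiation"),
                          "protein_id"])
        background = set(enr["protein_id"])
        go_table = _stage("go-enrichment")(go_enrichment)(
            up, background, annotations, cfg.alpha_go)
        logger.info("GO: %d terms tested, %d significant",
                    len(go_table), int(go_table["significant"].sum())
                    if len(go_table) else 0)

    subnet: InteractionGraph | None = None
    if cfg.ppi is not None:
        edges = _stage("read-edges")(iotables.read_edges)(cfg.ppi)
        physical = _stage("filter-edges")(filter_physical_edges)(
            edges, cfg.excluded_edge_types)
        seeds = set(enr.loc[enr["enriched"], "protein_id"])
        subnet = _stage("subnetwork")(first_neighbor_subnetwork)(physical, seeds)
        logger.info("subnetwork: %d seeds present, %d neighbors, %d edges",
                    len(subnet.seeds), len(subnet.neighbors), len(subnet.edges))

    bundle = ResultsBundle(summary, enr, diff, bin_stats, go_table, subnet)
    bundle.paths = _write_bundle(bundle, cfg)
    return bundle


def _write_bundle(bundle: ResultsBundle, cfg: RunConfig) -> dict[str, Path]:
    out = Path(cfg.out_dir)
    summary_rows = [{"sample": s, "identified": c}
                    for s, c in bundle.summary.per_sample.items()]
    summary_rows.append({"sample": "union", "identified": bundle.summary.union})
    tables: dict[str, pd.DataFrame] = {
        "summary": pd.DataFrame(summary_rows, columns=["sample", "identified"]),
        "enrichment": bundle.enrichment,
        "differential": bundle.differential,
        "bin_stats": pd.DataFrame([vars(b) for b in bundle.bin_stats]),
    }
    if bundle.go is not None:
        tables["go_enrichment"] = bundle.go
    paths = iotables.write_results(tables, out, cfg.echo())
    if bundle.subnetwork is not None:
        sif = out / "subnetwork.sif"
        attrs = out / "subnetwork_nodes.tsv"
        bundle.subnetwork.write(sif, attrs)
        paths["subnetwork"] = sif
        paths["subnetwork_nodes"] = attrs
    return paths
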