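"""End-to-end orchestration: screen → overlap → proximity → subnetwork →
RWR → community → enrichment, from a single flat configuration.

Every stage's parameters and output files are recorded in a machine-readable
manifest (manifest.json) so a run can be audited and reproduced; identical
configuration and seed give byte-identical outputs. Stage failures abort the
run with the stage name and cause, keeping any outputs already written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .errors import NetproxError
from . import community as community_mod
from .enrichment import enrich, overlap, overlapped_terms, read_gmt
from .genesets import GeneSet, load_gene_list, write_gene_list
from .interactome import (
    Interactome,
    induced_subgraph,
    largest_connected_component,
    load_edge_list,
    write_edge_list,
)
from .proximity import proximity_z
from .rwr import build_transition, rank_top, rwr
from .screen import (
    build_bipartite,
    dedup_targets,
    filter_compounds,
    read_compound_table,
    read_pairs,
    write_bipartite,
    write_compound_table,
)

STAGES = ("screen", "overlap", "proximity", "subnetwork", "rwr", "community", "enrichment")


class PipelineError(NetproxError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat run configuration; paths are resolved relative to the config file."""

    graph: str = ""
    disease_genes: str = ""
    targets: str = ""              # precomputed target list (alternative to tables)
    compound_table: str = ""       # raw compound table (runs the ADME screen)
    compound_pairs: str = ""
    rwr_graph: str = ""            # optional second graph for the subnetwork/RWR arm
    gmt: str = ""
    out_dir: str = "netprox_run"
    min_confidence: float = 0.0
    score_scale: str = "unit"
    ob_min: float = 30.0
    dl_min: float = 0.18
    alpha: float = 0.05
    r: float = 0.75
    tol: float = 1e-10
    n_random: int = 1000
    top_k: int = 10
    min_size: int = 3
    use_lcc: bool = True
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = path.parent
        for key in ("graph", "disease_genes", "targets", "compound_table",
                    "compound_pairs", "rwr_graph", "gmt", "out_dir"):
            val = getattr(cfg, key)
            if val:
                setattr(cfg, key, str((base / val) if not Path(val).is_absolute() else Path(val)))
        return cfg

    def validate(self) -> None:
        if not self.graph:
            raise ValueError("config field 'graph' is required")
        if not self.disease_genes:
            raise ValueError("config field 'disease_genes' is required")
        if not self.targets and not (self.compound_table and self.compound_pairs):
            raise ValueError(
                "either 'targets' or both 'compound_table' and 'compound_pairs' are required"
            )
        for key in ("graph", "disease_genes", "targets", "compound_table",
                    "compound_pairs", "rwr_graph", "gmt"):
            val = getattr(self, key)
            if val and not Path(val).exists():
                raise ValueError(f"config field {key!r} points to a missing file: {val}")


@dataclass
class RunReport:
    out_dir: Path
    manifest: dict[str, Any] = field(default_factory=dict)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _write_tsv(path: Path, header: list[str], rows: list[tuple]) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(c) if isinstance(c, float) else str(c) for c in row) + "\n")


def run_all(config: RunConfig) -> RunReport:
    """Execute all pipeline stages in order and write a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": asdict(config), "stages": []}
    report = RunReport(out_dir=out, manifest=manifest)

    def record(stage: str, outputs: list[str], **params):
        manifest["stages"].append(
            {"stage": stage, "status": "completed", "outputs": outputs, "params": params}
        )

    def fail(stage: str, exc: Exception):
        manifest["stages"].append({"stage": stage, "status": "failed", "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise PipelineError(stage, exc) from exc

    graph = load_edge_list(config.graph, config.min_confidence, config.score_scale)
    if config.use_lcc and graph.number_of_nodes():
        graph = largest_connected_component(graph)
    sub_graph_source = graph
    if config.rwr_graph:
        sub_graph_source = load_edge_list(config.rwr_graph, config.min_confidence, config.score_scale)
        if config.use_lcc and sub_graph_source.number_of_nodes():
            sub_graph_source = largest_connected_component(sub_graph_source)
    V = load_gene_list(config.disease_genes, "disease")

    # -- screen ----------------------------------------------------------
    try:
        if config.compound_table:
            records = read_compound_table(config.compound_table)
            pairs = read_pairs(config.compound_pairs)
            kept = filter_compounds(records, config.ob_min, config.dl_min)
            kept_ids = {r.mol_id for r in kept}
            kept_pairs = [(m, t) for m, t in pairs if m in kept_ids]
            T = GeneSet("targets", dedup_targets(kept_pairs).members)
            net = build_bipartite(kept, kept_pairs)
            write_compound_table(kept, out / "screened_compounds.tsv")
            write_bipartite(net, out / "bipartite_edges.tsv", out / "bipartite_nodes.tsv")
            write_gene_list(T, out / "targets.txt")
            record("screen", ["screened_compounds.tsv", "bipartite_edges.tsv",
                              "bipartite_nodes.tsv", "targets.txt"],
                   mode="adme_filter", ob_min=config.ob_min, dl_min=config.dl_min,
                   n_input=len(records), n_pass=len(kept))
        else:
            T = load_gene_list(config.targets, "targets")
            write_gene_list(T, out / "targets.txt")
            record("screen", ["targets.txt"], mode="precomputed_targets", n_targets=len(T))
    except Exception as exc:  # noqa: BLE001 - abort policy
        fail("screen", exc)

    # -- overlap ---------------------------------------------------------
    try:
        ov = overlap(V, T)
        (out / "overlap.json").write_text(json.dumps({
            "shared": sorted(ov.shared), "disease_only": ov.a_only,
            "targets_only": ov.b_only, "both": ov.both,
        }, indent=2, sort_keys=True) + "\n")
        record("overlap", ["overlap.json"], n_shared=ov.both)
    except Exception as exc:
        fail("overlap", exc)

    # -- proximity -------------------------------------------------------
    try:
        prox = proximity_z(graph, V, T, n_random=config.n_random, rng_seed=config.rng_seed)
        (out / "proximity.json").write_text(
            json.dumps(prox.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        record("proximity", ["proximity.json"], n_random=config.n_random,
               rng_seed=config.rng_seed)
    except Exception as exc:
        fail("proximity", exc)

    # -- subnetwork ------------------------------------------------------
    try:
        sub, missing = induced_subgraph(sub_graph_source, V.members | T.members)
        if config.use_lcc and sub.number_of_nodes():
            sub = largest_connected_component(sub)
        write_edge_list(sub, out / "subnetwork_edges.tsv")
        write_gene_list(sub.nodes, out / "subnetwork_nodes.txt")
        record("subnetwork", ["subnetwork_edges.tsv", "subnetwork_nodes.txt"],
               n_nodes=sub.number_of_nodes(), n_edges=sub.number_of_edges(),
               n_missing=len(missing))
    except Exception as exc:
        fail("subnetwork", exc)

    # -- rwr -------------------------------------------------------------
    try:
        model = build_transition(sub)
        result = rwr(model, T, r=config.r, tol=config.tol)
        top = rank_top(result, config.top_k)
        _write_tsv(out / "rwr_top.tsv", ["rank", "gene", "score"],
                   [(i + 1, g, s) for i, (g, s) in enumerate(top)])
        _write_tsv(out / "rwr_scores.tsv", ["gene", "score"],
                   sorted(result.scores.items()))
        record("rwr", ["rwr_top.tsv", "rwr_scores.tsv"], r=config.r, tol=config.tol,
               iterations=result.iterations, converged=result.converged)
    except Exception as exc:
        fail("rwr", exc)

    # -- community -------------------------------------------------------
    try:
        part = community_mod.detect_communities(sub, min_size=config.min_size)
        _write_tsv(out / "clusters.tsv", ["node", "community", "community_size"],
                   sorted((n, c, len(part.communities[c]))
                          for n, c in part.assignment.items()))
        (out / "clusters_summary.json").write_text(json.dumps({
            "n_communities": len(part.clustered_communities()),
            "n_unclustered_nodes": len(part.unclustered),
            "modularity": part.modularity,
        }, indent=2, sort_keys=True) + "\n")
        record("community", ["clusters.tsv", "clusters_summary.json"],
               min_size=config.min_size,
               n_communities=len(part.clustered_communities()))
    except Exception as exc:
        fail("community", exc)

    # -- enrichment ------------------------------------------------------
    try:
        outputs: list[str] = []
        if config.gmt:
            coll = read_gmt(config.gmt)
            def run_enrich(query, tag):
                rows = enrich(query, coll, alpha=config.alpha)
                _write_tsv(out / f"enrichment_{tag}.tsv",
                           ["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj",
                            "significant"],
                           [(r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p, r.p_adj,
                             int(r.significant)) for r in rows])
                outputs.append(f"enrichment_{tag}.tsv")
                return rows

            rows_sub = run_enrich(sub.nodes, "subnetwork")
            rows_v = run_enrich(V, "disease")
            rows_t = run_enrich(T, "targets")
            shared = overlapped_terms(rows_v, rows_t, alpha=config.alpha)
            (out / "overlapped_terms.txt").write_text(
                "".join(f"{t}\n" for t in sorted(shared)))
            outputs.append("overlapped_terms.txt")
            for i, comm in enumerate(part.clustered_communities()):
                if set(comm) & coll.universe:
                    run_enrich(comm, f"cluster{i}")
            record("enrichment", outputs, alpha=config.alpha,
                   n_overlapped_terms=len(shared))
        else:
            record("enrichment", [], note="no term collection supplied")
    except Exception as exc:
        fail("enrichment", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return report
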