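"""End-to-end orchestration: screen -> networks -> contribution -> enrichment.

``run_pipeline`` reads the input tables, applies the ADME screen, builds the
merged component-target network and per-herb subnetworks (plus an optional
target-pathway network), computes contribution scores, runs the
over-representation analysis and the fingerprint-similarity profile, and
writes a JSON run report next to the TSV/GraphML outputs. Any stage failure
raises :class:`PipelineError` naming the stage, and partial outputs are
removed.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from . import io as hio
from .contribution import DegeneratePolicy, contribution_scores, cumulative_report
from .enrichment import rank_annotations
from .network import (
    BipartiteNetwork,
    build_bipartite,
    export_graphml,
    export_sif,
    herb_subnetwork,
    shared_targets,
    summarize,
    top_degree_nodes,
)
from .screen import apply_screen, pairwise_similarity_summary
from .types import GIClass, ScreeningCriteria

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run."""

    components_path: str
    ct_edges_path: str
    out_dir: str
    targets_path: str | None = None
    tp_edges_path: str | None = None
    annotations_path: str | None = None
    fingerprints_path: str | None = None
    criteria: ScreeningCriteria = field(default_factory=ScreeningCriteria)
    cs_policy: DegeneratePolicy = "floor"
    alpha: float = 0.05
    similarity_threshold: float = 0.2
    universe_size: int | None = None
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        crit = d.pop("criteria")
        crit["gi_required"] = self.criteria.gi_required.value
        crit["whitelist"] = sorted(self.criteria.whitelist)
        crit["dl_min_by_herb"] = dict(self.criteria.dl_min_by_herb)
        d["criteria"] = crit
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        crit = dict(d.pop("criteria", {}))
        if crit:
            if "gi_required" in crit:
                crit["gi_required"] = GIClass.parse(crit["gi_required"])
            if "whitelist" in crit:
                crit["whitelist"] = frozenset(crit["whitelist"])
            d["criteria"] = ScreeningCriteria(**crit)
        return cls(**d)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _summary_dict(net: BipartiteNetwork) -> dict[str, Any]:
    s = summarize(net)
    return {
        "n_left": s.n_left,
        "n_right": s.n_right,
        "n_nodes": s.n_nodes,
        "n_edges": s.n_edges,
        "mean_left_degree": s.mean_left_degree,
        "mean_right_degree": s.mean_right_degree,
    }


def _write_decisions(decisions, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("component_id\tpassed\tfailed_criteria\tretained_by_whitelist\n")
        for d in decisions:
            f.write(
                f"{d.component_id}\t{int(d.passed)}\t"
                f"{','.join(d.failed_criteria)}\t{int(d.retained_by_whitelist)}\n"
            )


def _write_cs(results, path: Path) -> None:
    cols = ("rank component_id herb degree degree_in_a degree_in_b omega "
            "affinity target_degree_sum cs cs_pct cum_pct").split()
    with open(path, "w", encoding="utf-8") as f:
        f.write("\t".join(cols) + "\n")
        for r in results:
            f.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")


def _write_enrichment(results, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("rank\tannotation_id\tN\tK\tn\tk\tp\tbh_p\tsignificant\n")
        for r in results:
            q = r.query
            f.write(
                f"{r.rank}\t{r.annotation_id}\t{q.N}\t{q.K}\t{q.n}\t{q.k}\t"
                f"{r.p}\t{r.bh_p}\t{int(r.significant)}\n"
            )


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis; returns the report dict (also written as JSON).

    The report is deterministic for a fixed config apart from the isolated
    ``timestamp`` field.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    report: dict[str, Any] = {
        "tool": "herbnet",
        "version": __version__,
        "config": cfg.to_dict(),
        "input_checksums": {},
    }

    try:
        stage = "screen"
        components = hio.read_component_table(cfg.components_path)
        report["input_checksums"]["components"] = _sha256(cfg.components_path)
        if not components:
            raise ValueError("component table is empty")
        active, decisions = apply_screen(components, cfg.criteria)
        _write_decisions(decisions, emit(out / "decisions.tsv"))
        report["screen"] = {
            "n_components": len(components),
            "n_active": len(active),
            "n_failed": sum(1 for d in decisions if not d.passed),
            "failed_ids": sorted(d.component_id for d in decisions if not d.passed),
            "n_whitelisted": sum(1 for d in decisions if d.retained_by_whitelist),
        }

        stage = "targets"
        if cfg.targets_path:
            targets = hio.read_target_table(cfg.targets_path)
            report["input_checksums"]["targets"] = _sha256(cfg.targets_path)
            report["targets"] = {"n_targets": len(targets)}

        stage = "ct_network"
        ct_edges = hio.read_edge_list(cfg.ct_edges_path)
        report["input_checksums"]["ct_edges"] = _sha256(cfg.ct_edges_path)
        herb_of = {c.id: c.herb for c in components}
        comp_ids = {a for a, _ in ct_edges}
        net = build_bipartite(
            ct_edges, herb_of={c: herb_of[c] for c in comp_ids if c in herb_of}
        )
        if set(net.left_nodes) - set(net.herb_of):
            # edge components absent from the table: infer from id prefix
            inferred = {
                c: hio.infer_herb(c)
                for c in net.left_nodes
                if c not in net.herb_of and hio.infer_herb(c)
            }
            net = build_bipartite(ct_edges, herb_of={**net.herb_of, **inferred})
        report["ct_network"] = _summary_dict(net)
        export_sif(net, emit(out / "ct.sif"))
        export_graphml(net, emit(out / "ct.graphml"))
        report["top_components"] = [
            {"id": n, "degree": d}
            for n, d in top_degree_nodes(net, "left", min(10, len(net.left_nodes)))
        ]

        stage = "herb_subnetworks"
        herbs = sorted(set(net.herb_of.values()))
        subnets = {h: herb_subnetwork(net, h) for h in herbs}
        report["herb_subnetworks"] = {
            h: _summary_dict(s) for h, s in subnets.items() if s.edges
        }
        if len(herbs) == 2:
            common = shared_targets(subnets[herbs[0]], subnets[herbs[1]])
            report["shared_targets"] = {"n": len(common), "targets": sorted(common)}

        stage = "contribution"
        cs_herbs = tuple(herbs) if len(herbs) == 2 else ("ZHISHI", "BAIZHU")
        cs = contribution_scores(net, herbs=cs_herbs, policy=cfg.cs_policy)
        _write_cs(cs, emit(out / "cs.tsv"))
        k90, ach90 = cumulative_report(cs, 90.0)
        report["contribution"] = {
            "n_components": len(cs),
            "cs_pct_sum": sum(r.cs_pct for r in cs),
            "top_component": cs[0].component_id,
            "k_for_90pct": k90,
            "achieved_at_k": ach90,
        }

        stage = "tp_network"
        if cfg.tp_edges_path:
            tp_edges = hio.read_edge_list(cfg.tp_edges_path)
            report["input_checksums"]["tp_edges"] = _sha256(cfg.tp_edges_path)
            tp_net = build_bipartite(tp_edges)
            report["tp_network"] = _summary_dict(tp_net)
            export_sif(tp_net, emit(out / "tp.sif"), interaction="tp")

        stage = "enrichment"
        if cfg.annotations_path:
            universe = hio.read_annotation_map(cfg.annotations_path)
            report["input_checksums"]["annotations"] = _sha256(cfg.annotations_path)
            query = set(net.right_nodes)
            enr = rank_annotations(
                query, universe, alpha=cfg.alpha, universe_size=cfg.universe_size
            )
            _write_enrichment(enr, emit(out / "enrichment.tsv"))
            report["enrichment"] = {
                "n_annotations": len(enr),
                "n_significant": sum(1 for r in enr if r.significant),
                "top_annotation": enr[0].annotation_id,
                "top_p": enr[0].p,
            }

        stage = "similarity"
        if cfg.fingerprints_path:
            fps = hio.read_fingerprints(cfg.fingerprints_path)
            report["input_checksums"]["fingerprints"] = _sha256(cfg.fingerprints_path)
            n_pairs, n_le, frac = pairwise_similarity_summary(
                fps, cfg.similarity_threshold
            )
            report["similarity"] = {
                "n_fingerprints": len(fps),
                "n_pairs": n_pairs,
                "n_below_or_equal": n_le,
                "fraction": frac,
                "threshold": cfg.similarity_threshold,
            }

        stage = "report"
        report["timestamp"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
        with open(out / "report.json", "w", encoding="utf-8") as f:
            json.dump(report, f, indent=2, sort_keys=True)
        return report
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
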