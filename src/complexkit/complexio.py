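"""Shared complex JSON I/O, provenance headers, and the pipeline driver."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .annotation import (
    AnnotatedComplex,
    EvidenceTable,
    annotate_complexes,
    apply_curation,
    format_cqi,
)
from .benchmark import ReferenceSet, frequency_adjusted_scores, grid_search, match_complexes
from .clustering import ClusterParams, cluster_graph
from .expression import collapse_tags, load_expression_matrix, score_complexes
from .network import IntegratedNetwork
from .ontology import (
    TermGraph,
    consistency_index,
    enrichment_test,
    normalize_to_depth,
    random_control_indexes,
    read_annotations,
)
from .paralogs import HomologyTable, paralog_summary

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """Complex JSON does not match the documented schema."""


def provenance_header(seed: int | None = None, **params: Any) -> list[str]:
    header = [f"complexkit {__version__}"]
    if seed is not None:
        header.append(f"seed={seed}")
    header.extend(f"{k}={v}" for k, v in sorted(params.items()))
    return header


def write_tsv(path: str | Path, rows: Sequence[Mapping[str, Any]], header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if not rows:
            return
        cols = list(rows[0].keys())
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


# -- complex JSON ----------------------------------------------------------

def _validate_entry(entry: Mapping[str, Any], pos: int) -> None:
    where = f"$[{pos}]"
    if "id" not in entry or not isinstance(entry["id"], str):
        raise SchemaError(f"{where}.id: missing or not a string")
    members = entry.get("members")
    if not isinstance(members, list) or not all(isinstance(m, str) for m in members):
        raise SchemaError(f"{where}.members: must be a list of strings")
    if len(set(members)) != len(members):
        raise SchemaError(f"{where}.members: duplicate member in complex {entry['id']}")
    cats = entry.get("categories")
    if cats is not None:
        if not isinstance(cats, dict) or set(cats) != set(members):
            raise SchemaError(f"{where}.categories: must map exactly the members")


def write_complexes(path: str | Path, complexes: Sequence[Mapping[str, Any] | AnnotatedComplex], seed: int | None = None, **params: Any) -> None:
    entries: list[dict[str, Any]] = []
    for c in complexes:
        if isinstance(c, AnnotatedComplex):
            entry: dict[str, Any] = {
                "id": c.complex_id,
                "members": sorted(c.members),
                "categories": dict(sorted(c.category_of.items())),
                "cqi": format_cqi(c.cqi),
                "type": c.complex_type,
            }
            if c.name:
                entry["name"] = c.name
        else:
            entry = dict(c)
            entry["members"] = sorted(entry["members"])
        entries.append(entry)
    for i, e in enumerate(entries):
        _validate_entry(e, i)
    payload = {"_provenance": provenance_header(seed=seed, **params), "complexes": entries}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_complexes(path: str | Path) -> list[dict[str, Any]]:
    with open(path) as fh:
        payload = json.load(fh)
    entries = payload["complexes"] if isinstance(payload, dict) else payload
    if not isinstance(entries, list):
        raise SchemaError("$: expected a list of complexes")
    for i, e in enumerate(entries):
        if not isinstance(e, dict):
            raise SchemaError(f"$[{i}]: expected an object")
        _validate_entry(e, i)
        e["members"] = sorted(e["members"])
    return entries


def complexes_as_sets(entries: Sequence[Mapping[str, Any]]) -> dict[str, frozenset[str]]:
    return {e["id"]: frozenset(e["members"]) for e in entries}


def entries_as_annotated(entries: Sequence[Mapping[str, Any]]) -> list[AnnotatedComplex]:
    out = []
    for e in entries:
        cats = e.get("categories") or {m: "III" for m in e["members"]}
        out.append(
            AnnotatedComplex(
                complex_id=e["id"],
                members=frozenset(e["members"]),
                category_of=dict(cats),
                name=e.get("name", ""),
            )
        )
    return out


# -- pipeline --------------------------------------------------------------

@dataclass
class RunConfig:
    """All inputs and parameters for one end-to-end run."""

    network: str
    out_dir: str
    reference: str | None = None
    evidence_i: str | None = None
    evidence_ii: str | None = None
    curation: str | None = None
    term_graph: str | None = None
    annotations: str | None = None
    expression: str | None = None
    homology: str | None = None
    d_in: float = 0.6
    cp_in: float = 0.5
    min_size: int = 3
    overlapping: bool = True
    optimize: bool = False
    grid_step: float = 0.1
    depth: int = 5
    n_reps: int = 100_000
    fdr: float = 0.05
    e_value: float = 1e-5
    n_control_sets: int = 100
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "network", "reference", "evidence_i", "evidence_ii", "curation",
            "term_graph", "annotations", "expression", "homology",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config.{name}: no such file {value}")


@dataclass
class StageFailure(RuntimeError):
    stage: str
    cause: Exception

    def __str__(self) -> str:
        return f"pipeline stage {self.stage!r} failed: {self.cause}"


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """integrate -> predict (or optimize) -> annotate -> validate; returns a summary."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed}
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise StageFailure(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    with stage("integrate"):
        net = IntegratedNetwork.from_tsv(config.network)
        summary["n_proteins"] = net.n_nodes
        summary["n_interactions"] = net.n_edges

    with stage("predict"):
        d_in, cp_in = config.d_in, config.cp_in
        if config.optimize and config.reference:
            reference = ReferenceSet.from_tsv(config.reference)
            table, (d_in, cp_in) = grid_search(
                net, reference, grid_step=config.grid_step, min_size=config.min_size
            )
            write_tsv(
                out_dir / "grid.tsv",
                [vars(g) for g in table],
                provenance_header(seed=config.seed, step=config.grid_step),
            )
            summary["selected_params"] = {"d_in": d_in, "cp_in": cp_in}
        params = ClusterParams(
            d_in=d_in, cp_in=cp_in, min_size=config.min_size, overlapping=config.overlapping
        )
        clusters = cluster_graph(net, params)
        predicted = {f"c{i:05d}": c for i, c in enumerate(clusters)}
        summary["n_predicted_complexes"] = len(clusters)
        write_complexes(
            out_dir / "predicted.json",
            [
                {"id": cid, "members": sorted(c.members), "density": c.density, "seed_node": c.seed}
                for cid, c in predicted.items()
            ],
            seed=config.seed,
            d_in=d_in,
            cp_in=cp_in,
        )
        if config.reference:
            reference = ReferenceSet.from_tsv(config.reference)
            matches = match_complexes(
                {cid: c.members for cid, c in predicted.items()}, reference
            )
            r_sum, p_sum = frequency_adjusted_scores(matches)
            summary["benchmark"] = {
                "n_matched_known": len({m.known_id for m in matches}),
                "adjusted_recall_sum": r_sum,
                "adjusted_precision_sum": p_sum,
            }

    if not clusters:
        summary["note"] = "no complexes predicted; downstream stages skipped"
        summary["timings_s"] = timings
        _write_summary(out_dir, summary)
        return summary

    with stage("annotate"):
        evidence = EvidenceTable.from_tsv(config.evidence_i, config.evidence_ii)
        annotated = annotate_complexes(
            {cid: c.members for cid, c in predicted.items()}, evidence
        )
        if config.curation:
            annotated, audit = apply_curation(annotated, config.curation)
            summary["n_curation_edits"] = len(audit)
        type_counts: dict[str, int] = {}
        for c in annotated:
            type_counts[c.complex_type] = type_counts.get(c.complex_type, 0) + 1
        summary["complex_types"] = type_counts
        summary["category_counts"] = {
            cat: sum(1 for c in annotated for v in c.category_of.values() if v == cat)
            for cat in ("I", "II", "III")
        }
        write_complexes(out_dir / "annotated.json", annotated, seed=config.seed)
        member_sets = {c.complex_id: c.members for c in annotated}

    if config.term_graph and config.annotations:
        with stage("validate_go"):
            graph = (
                TermGraph.from_obo(config.term_graph)
                if str(config.term_graph).endswith(".obo")
                else TermGraph.from_tsv(config.term_graph)
            )
            raw_annotations = read_annotations(config.annotations)
            norm = normalize_to_depth(raw_annotations, graph, config.depth)
            proteome = set(raw_annotations)
            rows = []
            indexes = []
            sizes = []
            for cid, members in sorted(member_sets.items()):
                if len(members) < 2:
                    continue
                score = consistency_index(cid, members, norm)
                enr = enrichment_test(cid, members, norm, proteome)
                best_p = min((e.p_value for e in enr), default=1.0)
                rows.append(
                    {
                        "complex_id": cid,
                        "n_cons": score.n_cons,
                        "n_all": score.n_all,
                        "index": f"{score.index:.4f}",
                        "best_enrichment_p": f"{best_p:.3e}",
                    }
                )
                indexes.append(score.index)
                sizes.append(len(members))
            write_tsv(out_dir / "go_consistency.tsv", rows, provenance_header(seed=config.seed, depth=config.depth))
            controls = random_control_indexes(
                norm, sizes, n_sets=config.n_control_sets, seed=config.seed
            ) if sizes and len(norm) >= max(sizes) else []
            control_flat = [x for s in controls for x in s]
            summary["go"] = {
                "mean_index": sum(indexes) / len(indexes) if indexes else None,
                "control_mean_index": (
                    sum(control_flat) / len(control_flat) if control_flat else None
                ),
                "frac_enriched_p01": (
                    sum(1 for r in rows if float(r["best_enrichment_p"]) <= 0.01) / len(rows)
                    if rows
                    else None
                ),
            }

    if config.expression:
        with stage("validate_expression"):
            matrix = load_expression_matrix(config.expression)
            profiles = collapse_tags(matrix)
            results, skipped = score_complexes(
                member_sets, profiles, n_reps=config.n_reps, seed=config.seed
            )
            write_tsv(
                out_dir / "expression_coherence.tsv",
                [
                    {
                        "complex_id": r.complex_id,
                        "k": r.k,
                        "avg_cosine": f"{r.avg_cosine:.4f}",
                        "p_value": f"{r.p_value:.6g}",
                        "fdr": f"{r.fdr:.6g}",
                        "entropy": f"{r.entropy:.4f}",
                    }
                    for r in results
                ],
                provenance_header(seed=config.seed, reps=config.n_reps),
            )
            summary["expression"] = {
                "n_scored": len(results),
                "n_skipped": len(skipped),
                "n_significant_fdr": sum(1 for r in results if r.fdr <= config.fdr),
            }

    if config.homology:
        with stage("validate_paralogs"):
            table = HomologyTable.from_tsv(config.homology)
            psummary = paralog_summary(member_sets, table, threshold=config.e_value)
            write_tsv(
                out_dir / "paralogs.tsv",
                list(psummary.per_complex),
                provenance_header(seed=config.seed, evalue=config.e_value),
            )
            summary["paralogs"] = {
                "frac_duplicated_genes": psummary.frac_duplicated_genes,
                "frac_complexes_with_pair": psummary.frac_complexes_with_pair,
                "frac_complexes_majority": psummary.frac_complexes_majority,
            }

    summary["timings_s"] = timings
    _write_summary(out_dir, summary)
    return summary


def _write_summary(out_dir: Path, summary: Mapping[str, Any]) -> None:
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    lines = ["# Pipeline summary", ""]
    for key, value in summary.items():
        lines.append(f"- **{key}**: {value}")
    (out_dir / "summary.md").write_text("\n".join(lines) + "\n")
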