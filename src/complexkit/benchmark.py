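"""Matching predicted complexes against a reference set and parameter search.

A predicted complex matches a known one only when they share at least two
proteins; recall normalizes the overlap by the known complex and precision
by the predicted one. To penalize several predictions hitting the same
known complex, each known complex's best recall/precision are divided by
the number of predictions matching it before summing ("frequency
adjustment").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .clustering import ClusterParams, cluster_graph
from .network import IntegratedNetwork, ParseError

__all__ = [
    "ReferenceSet",
    "MatchResult",
    "GridResult",
    "match_complexes",
    "frequency_adjusted_scores",
    "grid_search",
]


@dataclass
class ReferenceSet:
    """Known complexes; proteins may legitimately recur across complexes."""

    complexes: dict[str, frozenset[str]]
    provenance: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if len(members) < 2:
                raise ValueError(f"reference complex {cid} has < 2 members")

    def __len__(self) -> int:
        return len(self.complexes)

    def mean_complexes_per_protein(self) -> float:
        """Average number of reference complexes containing each protein."""
        counts: dict[str, int] = {}
        for members in self.complexes.values():
            for p in members:
                counts[p] = counts.get(p, 0) + 1
        if not counts:
            return 0.0
        return sum(counts.values()) / len(counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferenceSet":
        """TSV: complex_id <TAB> comma-joined member IDs [<TAB> provenance]."""
        complexes: dict[str, frozenset[str]] = {}
        provenance: dict[str, str] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(path, lineno, "expected complex_id<TAB>members")
                cid = fields[0]
                members = frozenset(m for m in fields[1].split(",") if m)
                complexes[cid] = members
                if len(fields) > 2:
                    provenance[cid] = fields[2]
        return cls(complexes=complexes, provenance=provenance or None)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cid in sorted(self.complexes):
                fh.write(f"{cid}\t{','.join(sorted(self.complexes[cid]))}\n")


@dataclass(frozen=True)
class MatchResult:
    known_id: str
    predicted_id: str
    overlap: int
    recall: float
    precision: float


@dataclass(frozen=True)
class GridResult:
    d_in: float
    cp_in: float
    adjusted_recall_sum: float
    adjusted_precision_sum: float
    n_matched_known: int
    n_predicted: int


def match_complexes(
    predicted: Mapping[str, frozenset[str]] | Sequence[frozenset[str]],
    reference: ReferenceSet,
) -> list[MatchResult]:
    """All (known, predicted) pairs with >= 2 shared proteins.

    Pairs overlapping in fewer than two proteins score zero by definition
    and are omitted.
    """
    if not isinstance(predicted, Mapping):
        predicted = {f"pred{i:05d}": frozenset(m) for i, m in enumerate(predicted)}
    results: list[MatchResult] = []
    for kid, known in sorted(reference.complexes.items()):
        for pid, pred in sorted(predicted.items()):
            overlap = len(known & pred)
            if overlap < 2:
                continue
            results.append(
                MatchResult(
                    known_id=kid,
                    predicted_id=pid,
                    overlap=overlap,
                    recall=overlap / len(known),
                    precision=overlap / len(pred),
                )
            )
    return results


def frequency_adjusted_scores(matches: Sequence[MatchResult]) -> tuple[float, float]:
    """Sum each known complex's best recall/precision divided by its match count.

    Best match per known complex is chosen by recall, then precision, then
    smallest predicted ID; the frequency is the number of predicted
    complexes matching that known complex.
    """
    by_known: dict[str, list[MatchResult]] = {}
    for m in matches:
        by_known.setdefault(m.known_id, []).append(m)
    recall_sum = 0.0
    precision_sum = 0.0
    for kid, ms in by_known.items():
        best = max(ms, key=lambda m: (m.recall, m.precision, m.predicted_id))
        # tie on (recall, precision) -> smallest predicted_id
        best = min(
            (m for m in ms if (m.recall, m.precision) == (best.recall, best.precision)),
            key=lambda m: m.predicted_id,
        )
        freq = len(ms)
        recall_sum += best.recall / freq
        precision_sum += best.precision / freq
    return recall_sum, precision_sum


def matched_summary(matches: Sequence[MatchResult]) -> dict[str, float]:
    """Average best-match recall/precision over matched known complexes."""
    by_known: dict[str, list[MatchResult]] = {}
    for m in matches:
        by_known.setdefault(m.known_id, []).append(m)
    if not by_known:
        return {"n_matched_known": 0, "avg_recall": 0.0, "avg_precision": 0.0}
    recs, precs = [], []
    for ms in by_known.values():
        best = max(ms, key=lambda m: (m.recall, m.precision))
        recs.append(best.recall)
        precs.append(best.precision)
    return {
        "n_matched_known": len(by_known),
        "avg_recall": sum(recs) / len(recs),
        "avg_precision": sum(precs) / len(precs),
    }


def _grid_values(step: float) -> list[float]:
    if step <= 0 or step > 1:
        raise ValueError(f"grid step must be in (0,1], got {step}")
    n = round(1.0 / step)
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError(f"grid step {step} does not divide 1.0")
    return [round(i * step, 10) for i in range(n + 1)]


def grid_search(
    graph: IntegratedNetwork,
    reference: ReferenceSet,
    grid_step: float = 0.1,
    min_size: int = 3,
    overlapping: bool = True,
) -> tuple[list[GridResult], tuple[float, float]]:
    """Exhaustive (d_in, cp_in) grid over [0,1]; returns the table and the
    point maximizing adjusted recall + precision (ties: larger d, larger cp)."""
    values = _grid_values(grid_step)
    table: list[GridResult] = []
    for d in values:
        for cp in values:
            params = ClusterParams(d_in=d, cp_in=cp, min_size=min_size, overlapping=overlapping)
            clusters = cluster_graph(graph, params)
            predicted = {
                f"c{i:05d}": c.members for i, c in enumerate(clusters)
            }
            matches = match_complexes(predicted, reference)
            r_sum, p_sum = frequency_adjusted_scores(matches)
            table.append(
                GridResult(
                    d_in=d,
                    cp_in=cp,
                    adjusted_recall_sum=r_sum,
                    adjusted_precision_sum=p_sum,
                    n_matched_known=len({m.known_id for m in matches}),
                    n_predicted=len(clusters),
                )
            )
    best = max(
        table,
        key=lambda g: (g.adjusted_recall_sum + g.adjusted_precision_sum, g.d_in, g.cp_in),
    )
    return table, (best.d_in, best.cp_in)
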