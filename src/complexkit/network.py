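"""Integration of tagged PPI edge lists into one nonredundant network.

Interactions are deduplicated purely at the protein-ID level: the unordered
pair of (optionally remapped) IDs is the identity of an interaction, and
source-database tags accumulate on the merged edge.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Strips "uniprotkb:"-style database prefixes from PSI-MI TAB identifiers.
DEFAULT_ID_PREFIX_RE = re.compile(r"^[A-Za-z0-9_.-]+:")


class ParseError(ValueError):
    """Raised for malformed input lines; carries the 1-based line number."""

    def __init__(self, path: str | Path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One deduplicated PPI: an unordered protein pair plus a source tag."""

    protein_a: str
    protein_b: str
    source: str

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-interaction not allowed: {self.protein_a}")
        # canonical order so that {a,b} == {b,a}
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


class IntegratedNetwork:
    """Simple undirected protein graph; each edge carries >=1 source tag."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------
    def add_interaction(self, a: str, b: str, source: str) -> None:
        if a == b:
            raise ValueError(f"self-loop rejected: {a}")
        if self.graph.has_edge(a, b):
            self.graph.edges[a, b]["sources"].add(source)
        else:
            self.graph.add_edge(a, b, sources={source})

    def add_protein(self, protein: str) -> None:
        """Declare an isolated protein (node without edges)."""
        self.graph.add_node(protein)

    # -- queries ------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> dict[tuple[str, str], frozenset[str]]:
        return {
            (min(a, b), max(a, b)): frozenset(d["sources"])
            for a, b, d in self.graph.edges(data=True)
        }

    def sources(self) -> list[str]:
        tags: set[str] = set()
        for _, _, d in self.graph.edges(data=True):
            tags |= d["sources"]
        return sorted(tags)

    # -- serialization ------------------------------------------------
    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            for (a, b), tags in sorted(self.edges().items()):
                fh.write(f"{a}\t{b}\t{','.join(sorted(tags))}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntegratedNetwork":
        net = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(path, lineno, "expected >=2 tab-separated columns")
                a, b = fields[0], fields[1]
                tags = fields[2].split(",") if len(fields) > 2 and fields[2] else ["unknown"]
                for tag in tags:
                    net.add_interaction(a, b, tag)
        return net

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        for (a, b), tags in self.edges().items():
            g.add_edge(a, b, sources=",".join(sorted(tags)))
        nx.write_graphml(g, path)


def load_interactions(
    path: str | Path,
    source_tag: str,
    id_map: Mapping[str, str] | None = None,
    strip_prefix: re.Pattern | None = None,
) -> list[InteractionRecord]:
    """Read a >=2-column TSV edge list into deduplicated interaction records.

    Self-loops (after mapping) are removed, duplicate unordered pairs within
    the file are collapsed, and records whose IDs miss ``id_map`` are dropped
    with a logged count. ``strip_prefix`` removes PSI-MI TAB-style database
    prefixes (e.g. ``uniprotkb:P12345``) before mapping.
    """
    seen: set[tuple[str, str]] = set()
    records: list[InteractionRecord] = []
    n_unmapped = 0
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, f"expected >=2 columns, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
            if strip_prefix is not None:
                a = strip_prefix.sub("", a)
                b = strip_prefix.sub("", b)
            if id_map is not None:
                if a not in id_map or b not in id_map:
                    n_unmapped += 1
                    continue
                a, b = id_map[a], id_map[b]
            if a == b:
                n_self += 1
                continue
            pair = (min(a, b), max(a, b))
            if pair in seen:
                continue
            seen.add(pair)
            records.append(InteractionRecord(pair[0], pair[1], source_tag))
    if n_lines == 0:
        logger.warning("%s: empty edge list for source %s", path, source_tag)
    if n_unmapped:
        logger.info("%s: dropped %d records with unmapped IDs", path, n_unmapped)
    if n_self:
        logger.info("%s: removed %d self-interactions", path, n_self)
    return records


def merge_networks(records: Iterable[InteractionRecord]) -> IntegratedNetwork:
    """Union interaction records into one simple graph, pooling source tags."""
    net = IntegratedNetwork()
    for rec in records:
        net.add_interaction(rec.protein_a, rec.protein_b, rec.source)
    return net


def overlap_matrix(net: IntegratedNetwork) -> pd.DataFrame:
    """Pairwise source-overlap counts; diagonal = per-source edge counts."""
    sources = net.sources()
    if not sources:
        raise ValueError("network carries no source tags")
    edge_tags = list(net.edges().values())
    mat = pd.DataFrame(0, index=sources, columns=sources, dtype=int)
    for tags in edge_tags:
        for s in tags:
            for t in tags:
                mat.loc[s, t] += 1
    return mat


def shared_in_k_sources(net: IntegratedNetwork) -> dict[int, int]:
    """Histogram: number of edges tagged by exactly k sources, k=1..n_sources."""
    n_sources = len(net.sources())
    hist = {k: 0 for k in range(1, max(n_sources, 1) + 1)}
    for tags in net.edges().values():
        hist[len(tags)] += 1
    return hist


def read_id_map(path: str | Path) -> dict[str, str]:
    """2-column TSV: external ID -> canonical protein ID."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "expected 2 columns in ID map")
            mapping[fields[0]] = fields[1]
    return mapping
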