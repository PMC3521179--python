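"""Ontology depth normalization and per-complex term statistics.

Annotations are flattened to a fixed ontology depth (default 5, shortest
path from the namespace root): shallower terms are dropped, deeper terms
are replaced by all of their depth-5 ancestors. On the normalized
annotations we compute per-complex term enrichment (one-sided
Fisher/hypergeometric against the proteome background) and the
consistency index — the fraction of subunit pairs sharing at least one
term.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Mapping, Sequence

import numpy as np
from scipy import stats

from .network import ParseError

logger = logging.getLogger(__name__)


class CycleError(ValueError):
    """The term graph is not acyclic."""


@dataclass
class TermGraph:
    """Child -> parents DAG of ontology terms."""

    parents: dict[str, set[str]] = field(default_factory=dict)

    def add_term(self, term: str) -> None:
        self.parents.setdefault(term, set())

    def add_edge(self, child: str, parent: str) -> None:
        self.add_term(child)
        self.add_term(parent)
        self.parents[child].add(parent)

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def children_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {t: set() for t in self.parents}
        for child, ps in self.parents.items():
            for p in ps:
                idx[p].add(child)
        return idx

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TermGraph":
        """2-column TSV of child <TAB> parent links."""
        g = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ParseError(path, lineno, "expected child<TAB>parent")
                g.add_edge(fields[0], fields[1])
        return g

    @classmethod
    def from_obo(cls, path: str | Path) -> "TermGraph":
        """Minimal OBO reader: [Term] stanzas, id and is_a lines only."""
        g = cls()
        term_id: str | None = None
        in_term = False
        pending: list[tuple[str, str]] = []
        with open(path) as fh:
            for raw in fh:
                line = raw.strip()
                if line.startswith("["):
                    in_term = line == "[Term]"
                    term_id = None
                    continue
                if not in_term or not line:
                    continue
                if line.startswith("id:"):
                    term_id = line[3:].strip()
                    g.add_term(term_id)
                elif line.startswith("is_a:") and term_id is not None:
                    parent = line[5:].strip().split("!")[0].strip()
                    pending.append((term_id, parent))
                elif line.startswith("is_obsolete:") and "true" in line and term_id:
                    g.parents.pop(term_id, None)
                    term_id = None
        for child, parent in pending:
            if child in g.parents:
                g.add_edge(child, parent)
        return g


def term_depths(graph: TermGraph) -> dict[str, int]:
    """Shortest-path depth from the nearest root (root depth 0) via BFS."""
    roots = graph.roots
    if not roots and graph.parents:
        raise CycleError("term graph has no root; cycle suspected")
    children = graph.children_index()
    depths: dict[str, int] = {}
    queue: deque[str] = deque()
    for r in sorted(roots):
        depths[r] = 0
        queue.append(r)
    while queue:
        t = queue.popleft()
        for c in sorted(children[t]):
            if c not in depths:
                depths[c] = depths[t] + 1
                queue.append(c)
    unreached = graph.terms - set(depths)
    if unreached:
        raise CycleError(f"terms unreachable from any root (cycle?): {sorted(unreached)[:5]}")
    return depths


def _ancestors_at_depth(
    graph: TermGraph, depths: Mapping[str, int], term: str, target: int
) -> set[str]:
    """All ancestors of ``term`` whose depth equals ``target``."""
    # full ancestor closure: in a DAG an ancestor may sit deeper than its
    # descendant under shortest-path depth, so no depth-based pruning
    out: set[str] = set()
    seen: set[str] = set()
    stack = [term]
    while stack:
        t = stack.pop()
        for p in graph.parents.get(t, ()):
            if p in seen:
                continue
            seen.add(p)
            if depths[p] == target:
                out.add(p)
            stack.append(p)
    return out


def normalize_to_depth(
    annotations: Mapping[str, AbstractSet[str]],
    graph: TermGraph,
    target_depth: int = 5,
) -> dict[str, frozenset[str]]:
    """Flatten every annotation set to terms of exactly ``target_depth``.

    Terms shallower than the target are ignored; deeper terms contribute
    all their target-depth ancestors; unknown terms are dropped with a
    warning. Proteins left with no terms are omitted from the result.
    """
    depths = term_depths(graph)
    cache: dict[str, frozenset[str]] = {}
    out: dict[str, frozenset[str]] = {}
    n_unknown = 0
    for protein, terms in annotations.items():
        norm: set[str] = set()
        for t in terms:
            if t not in depths:
                n_unknown += 1
                continue
            if t in cache:
                norm |= cache[t]
                continue
            d = depths[t]
            if d == target_depth:
                mapped = frozenset({t})
            elif d > target_depth:
                mapped = frozenset(_ancestors_at_depth(graph, depths, t, target_depth))
            else:
                mapped = frozenset()
            cache[t] = mapped
            norm |= mapped
        if norm:
            out[protein] = frozenset(norm)
    if n_unknown:
        logger.warning("dropped %d annotations to unknown terms", n_unknown)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    complex_id: str
    term: str
    a: int  # subunits with the term
    b: int  # subunits without it
    c: int  # proteome proteins with the term
    d: int  # proteome proteins without it
    p_value: float


def enrichment_test(
    complex_id: str,
    complex_members: AbstractSet[str],
    annotations: Mapping[str, AbstractSet[str]],
    proteome: AbstractSet[str],
) -> list[EnrichmentResult]:
    """One-sided enrichment p per term hitting >= 1 subunit.

    The 2x2 cells are (a, b) over the complex's annotatable subunits and
    (c, d) over the full proteome (members included, no subtraction). The
    p-value is the hypergeometric upper tail P(X >= a) for drawing a+b
    proteins from a proteome of c+d with c carrying the term.
    """
    if not proteome:
        raise ValueError("enrichment requires a nonempty proteome")
    annotated_members = [m for m in complex_members if m in annotations]
    n = len(annotated_members)
    proteome_terms = {p: annotations.get(p, frozenset()) for p in proteome}
    n_proteome = len(proteome)
    term_count: dict[str, int] = {}
    for terms in proteome_terms.values():
        for t in terms:
            term_count[t] = term_count.get(t, 0) + 1
    results: list[EnrichmentResult] = []
    complex_term_count: dict[str, int] = {}
    for m in annotated_members:
        for t in annotations[m]:
            complex_term_count[t] = complex_term_count.get(t, 0) + 1
    for t in sorted(complex_term_count):
        a = complex_term_count[t]
        b = n - a
        c = max(term_count.get(t, 0), a)  # members outside the proteome still count
        d = n_proteome - term_count.get(t, 0)
        p = float(stats.hypergeom.sf(a - 1, c + d, c, a + b))
        results.append(
            EnrichmentResult(
                complex_id=complex_id, term=t, a=a, b=b, c=c, d=d, p_value=min(max(p, 0.0), 1.0)
            )
        )
    return results


@dataclass(frozen=True)
class ConsistencyScore:
    complex_id: str
    n_cons: int
    n_all: int

    @property
    def index(self) -> float:
        return self.n_cons / self.n_all


def consistency_index(
    complex_id: str,
    complex_members: AbstractSet[str] | Sequence[str],
    annotations: Mapping[str, AbstractSet[str]],
) -> ConsistencyScore:
    """Fraction of unordered subunit pairs sharing >= 1 normalized term."""
    members = sorted(set(complex_members))
    n = len(members)
    if n < 2:
        raise ValueError(f"consistency index requires >= 2 members, got {n}")
    n_all = n * (n - 1) // 2
    n_cons = 0
    for i in range(n):
        ti = annotations.get(members[i], frozenset())
        if not ti:
            continue
        for j in range(i + 1, n):
            if ti & annotations.get(members[j], frozenset()):
                n_cons += 1
    return ConsistencyScore(complex_id=complex_id, n_cons=n_cons, n_all=n_all)


def random_control_indexes(
    annotated_universe: Mapping[str, AbstractSet[str]],
    complex_sizes: Sequence[int],
    n_sets: int = 100,
    seed: int | None = None,
) -> list[list[float]]:
    """Size-matched random complexes drawn from the annotated universe.

    Each of the ``n_sets`` control sets redraws, for every requested size,
    that many genes uniformly without replacement and records the
    consistency index. Reproducible under ``seed``.
    """
    genes = sorted(annotated_universe)
    for s in complex_sizes:
        if s < 2:
            raise ValueError(f"complex size {s} < 2")
        if s > len(genes):
            raise ValueError(f"complex size {s} exceeds universe size {len(genes)}")
    rng = np.random.default_rng(seed)
    out: list[list[float]] = []
    for _ in range(n_sets):
        indexes: list[float] = []
        for s in complex_sizes:
            members = rng.choice(genes, size=s, replace=False)
            indexes.append(
                consistency_index("control", list(members), annotated_universe).index
            )
        out.append(indexes)
    return out


def compare_distributions(
    set_a: Sequence[float],
    set_b: Sequence[float],
    n_comparisons: int = 1,
    n_bins: int = 10,
) -> dict[str, object]:
    """Two-sample Student t test between index lists, plus histogram bins.

    ``n_comparisons`` applies an optional Bonferroni factor to the p-value.
    """
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if a.std() == 0 and b.std() == 0:
        # degenerate samples: identical -> no evidence; separated -> certain
        stat = 0.0 if a.mean() == b.mean() else float(np.sign(a.mean() - b.mean()) * np.inf)
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
    p_adj = min(float(p) * n_comparisons, 1.0)
    return {
        "statistic": float(stat),
        "p_value": p_adj,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "hist_a": np.histogram(a, bins=n_bins, range=(0, 1))[0].tolist(),
        "hist_b": np.histogram(b, bins=n_bins, range=(0, 1))[0].tolist(),
    }


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """protein <TAB> term TSV, one annotation per line."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "expected protein<TAB>term")
            out.setdefault(fields[0], set()).add(fields[1])
    return out
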