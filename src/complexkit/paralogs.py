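"""Within-complex gene duplication statistics from a pairwise homology table.

A member pair is paralogous when its similarity E-value passes the
threshold (strict ``<`` by default). The summary counts genes in at least
one within-complex paralog pair, complexes holding any pair, and
complexes where strictly more than half the members are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import AbstractSet, Mapping

from .network import ParseError

DEFAULT_THRESHOLD = 1e-5


@dataclass
class HomologyTable:
    """Unordered gene pair -> best (smallest) E-value."""

    pairs: dict[frozenset[str], float] = field(default_factory=dict)

    def add(self, gene_a: str, gene_b: str, e_value: float) -> None:
        if gene_a == gene_b:
            return
        if e_value < 0:
            raise ValueError(f"negative E-value for {gene_a}/{gene_b}")
        key = frozenset((gene_a, gene_b))
        if key not in self.pairs or e_value < self.pairs[key]:
            self.pairs[key] = e_value

    def e_value(self, gene_a: str, gene_b: str) -> float | None:
        return self.pairs.get(frozenset((gene_a, gene_b)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologyTable":
        """3-column TSV: gene_a, gene_b, E-value."""
        table = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(path, lineno, "expected gene_a<TAB>gene_b<TAB>e_value")
                try:
                    e = float(fields[2])
                except ValueError:
                    raise ParseError(path, lineno, f"bad E-value {fields[2]!r}") from None
                table.add(fields[0], fields[1], e)
        return table

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.pairs, key=sorted):
                a, b = sorted(key)
                fh.write(f"{a}\t{b}\t{self.pairs[key]:.3e}\n")


@dataclass(frozen=True)
class ParalogSummary:
    n_duplicated_genes: int
    n_total_genes: int
    n_complexes_with_pair: int
    n_complexes_majority_paralog: int
    n_complexes: int
    per_complex: tuple[dict[str, object], ...] = ()

    @property
    def frac_duplicated_genes(self) -> float:
        return self.n_duplicated_genes / self.n_total_genes if self.n_total_genes else 0.0

    @property
    def frac_complexes_with_pair(self) -> float:
        return self.n_complexes_with_pair / self.n_complexes if self.n_complexes else 0.0

    @property
    def frac_complexes_majority(self) -> float:
        return self.n_complexes_majority_paralog / self.n_complexes if self.n_complexes else 0.0


def complex_paralog_pairs(
    members: AbstractSet[str],
    table: HomologyTable,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = False,
) -> set[frozenset[str]]:
    """All unordered member pairs passing the E-value threshold.

    ``inclusive=False`` (default) uses strict ``e < threshold``; set it to
    True for ``e <= threshold``.
    """
    out: set[frozenset[str]] = set()
    ms = sorted(members)
    for i, a in enumerate(ms):
        for b in ms[i + 1 :]:
            e = table.e_value(a, b)
            if e is None:
                continue
            if (e <= threshold) if inclusive else (e < threshold):
                out.add(frozenset((a, b)))
    return out


def paralog_summary(
    complexes: Mapping[str, AbstractSet[str]],
    table: HomologyTable,
    threshold: float = DEFAULT_THRESHOLD,
    inclusive: bool = False,
) -> ParalogSummary:
    """Complex-level duplication counts.

    Duplicated genes are counted once globally (a gene in a paralog pair in
    any of its complexes); the majority flag requires strictly more than
    half of a complex's members to sit in some within-complex pair.
    """
    duplicated: set[str] = set()
    all_genes: set[str] = set()
    n_with_pair = 0
    n_majority = 0
    rows: list[dict[str, object]] = []
    for cid in sorted(complexes):
        members = set(complexes[cid])
        all_genes |= members
        pairs = complex_paralog_pairs(members, table, threshold, inclusive)
        in_pair = set().union(*pairs) if pairs else set()
        duplicated |= in_pair
        has_pair = bool(pairs)
        majority = len(in_pair) > len(members) / 2
        n_with_pair += has_pair
        n_majority += majority
        rows.append(
            {
                "complex_id": cid,
                "n_members": len(members),
                "n_pairs": len(pairs),
                "n_members_in_pair": len(in_pair),
                "has_pair": has_pair,
                "majority_paralog": majority,
            }
        )
    return ParalogSummary(
        n_duplicated_genes=len(duplicated),
        n_total_genes=len(all_genes),
        n_complexes_with_pair=n_with_pair,
        n_complexes_majority_paralog=n_majority,
        n_complexes=len(complexes),
        per_complex=tuple(rows),
    )
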