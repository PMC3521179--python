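"""Evidence categories, the complex quality index (CQI), and curation edits.

Each subunit of a complex is assigned an evidence category:

* ``I``  — confirmed subunit of a known complex (literature / structure),
* ``II`` — function-related evidence only,
* ``III``— predicted, no supporting evidence.

The CQI string "n1.n2.n3/total" summarizes a complex's per-category counts.
A complex is *perfectly matched* when every subunit is category I,
*partially matched* when at least two subunits are category I (but not
all), *hypothetical* when every subunit is category III, and *other*
otherwise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .network import ParseError

logger = logging.getLogger(__name__)

CATEGORIES = ("I", "II", "III")

PERFECTLY_MATCHED = "perfectly_matched"
PARTIALLY_MATCHED = "partially_matched"
HYPOTHETICAL = "hypothetical"
OTHER = "other"

_CQI_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)/(\d+)$")


@dataclass(frozen=True)
class CQI:
    """Counts of category I/II/III subunits, formatted "n1.n2.n3/total"."""

    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.n3) < 0:
            raise ValueError("CQI counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3


def format_cqi(cqi: CQI) -> str:
    return f"{cqi.n1}.{cqi.n2}.{cqi.n3}/{cqi.total}"


def parse_cqi(text: str) -> CQI:
    m = _CQI_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed CQI string: {text!r}")
    n1, n2, n3, total = (int(g) for g in m.groups())
    if n1 + n2 + n3 != total:
        raise ValueError(f"CQI counts {n1}+{n2}+{n3} != total {total}: {text!r}")
    return CQI(n1, n2, n3)


def compute_cqi(category_of: Mapping[str, str]) -> CQI:
    if not category_of:
        raise ValueError("cannot compute CQI of an empty complex")
    bad = {p: c for p, c in category_of.items() if c not in CATEGORIES}
    if bad:
        raise ValueError(f"unknown categories: {bad}")
    counts = {c: 0 for c in CATEGORIES}
    for c in category_of.values():
        counts[c] += 1
    return CQI(counts["I"], counts["II"], counts["III"])


@dataclass
class EvidenceTable:
    """(protein, complex) pairs at the two positive evidence levels."""

    category_I_pairs: set[tuple[str, str]] = field(default_factory=set)
    category_II_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        conflict = self.category_I_pairs & self.category_II_pairs
        if conflict:
            raise ValueError(f"pairs present in both evidence levels: {sorted(conflict)}")

    @classmethod
    def from_tsv(
        cls, path_i: str | Path | None, path_ii: str | Path | None
    ) -> "EvidenceTable":
        """Each file: protein_id <TAB> complex_id, one pair per line."""
        return cls(
            category_I_pairs=_read_pairs(path_i) if path_i else set(),
            category_II_pairs=_read_pairs(path_ii) if path_ii else set(),
        )


def _read_pairs(path: str | Path) -> set[tuple[str, str]]:
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "expected protein<TAB>complex_id")
            pairs.add((fields[0], fields[1]))
    return pairs


def assign_categories(
    complex_id: str,
    members: Iterable[str],
    evidence: EvidenceTable,
) -> dict[str, str]:
    """Category I beats II beats III; membership is per (protein, complex).

    A pair with complex ID ``"*"`` applies to every complex the protein
    appears in (evidence not tied to one specific complex).
    """
    out: dict[str, str] = {}
    for p in members:
        if (p, complex_id) in evidence.category_I_pairs or (p, "*") in evidence.category_I_pairs:
            out[p] = "I"
        elif (p, complex_id) in evidence.category_II_pairs or (p, "*") in evidence.category_II_pairs:
            out[p] = "II"
        else:
            out[p] = "III"
    return out


def classify_complex(category_of: Mapping[str, str]) -> str:
    """Map per-subunit categories to the complex type."""
    if not category_of:
        raise ValueError("cannot classify an empty complex")
    cats = list(category_of.values())
    n1 = cats.count("I")
    if n1 == len(cats):
        return PERFECTLY_MATCHED
    if all(c == "III" for c in cats):
        return HYPOTHETICAL
    if n1 >= 2:
        return PARTIALLY_MATCHED
    return OTHER


@dataclass
class AnnotatedComplex:
    complex_id: str
    members: frozenset[str]
    category_of: dict[str, str]
    name: str = ""
    description: str = ""
    localization: str = ""

    def __post_init__(self) -> None:
        if set(self.category_of) != set(self.members):
            raise ValueError(
                f"complex {self.complex_id}: categories must cover exactly the members"
            )

    @property
    def cqi(self) -> CQI:
        return compute_cqi(self.category_of)

    @property
    def complex_type(self) -> str:
        return classify_complex(self.category_of)

    def default_name(self) -> str:
        return self.name or "-".join(sorted(self.members)[:4]) + " containing complex"


def annotate_complexes(
    complexes: Mapping[str, Iterable[str]],
    evidence: EvidenceTable,
) -> list[AnnotatedComplex]:
    out = []
    for cid in sorted(complexes):
        members = frozenset(complexes[cid])
        out.append(
            AnnotatedComplex(
                complex_id=cid,
                members=members,
                category_of=assign_categories(cid, members, evidence),
            )
        )
    return out


def apply_curation(
    complexes: Sequence[AnnotatedComplex],
    curation_path: str | Path,
) -> tuple[list[AnnotatedComplex], list[str]]:
    """Apply add-subunit / merge directives in file order.

    Directive TSV lines::

        add     <complex_id> <protein> <category>
        merge   <complex_id_a> <complex_id_b> <new_id>

    Returns the edited complexes plus an audit log of applied edits.
    """
    by_id = {c.complex_id: c for c in complexes}
    audit: list[str] = []
    with open(curation_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            op = fields[0]
            if op == "add":
                if len(fields) != 4:
                    raise ParseError(curation_path, lineno, "add needs 3 arguments")
                cid, protein, category = fields[1], fields[2], fields[3]
                if cid not in by_id:
                    raise ParseError(curation_path, lineno, f"unknown complex {cid}")
                if category not in CATEGORIES:
                    raise ParseError(curation_path, lineno, f"unknown category {category}")
                target = by_id[cid]
                if protein in target.members:
                    logger.warning(
                        "%s:%d: %s already a member of %s; no-op", curation_path, lineno, protein, cid
                    )
                    audit.append(f"noop add {protein} to {cid} (already member)")
                    continue
                by_id[cid] = AnnotatedComplex(
                    complex_id=cid,
                    members=target.members | {protein},
                    category_of={**target.category_of, protein: category},
                    name=target.name,
                    description=target.description,
                    localization=target.localization,
                )
                audit.append(f"add {protein} ({category}) to {cid}")
            elif op == "merge":
                if len(fields) != 4:
                    raise ParseError(curation_path, lineno, "merge needs 3 arguments")
                cid_a, cid_b, new_id = fields[1], fields[2], fields[3]
                for cid in (cid_a, cid_b):
                    if cid not in by_id:
                        raise ParseError(curation_path, lineno, f"unknown complex {cid}")
                a, b = by_id.pop(cid_a), by_id.pop(cid_b)
                merged_cats = {**a.category_of}
                for p, cat in b.category_of.items():
                    # category I wins on disagreement between the two parents
                    if p in merged_cats:
                        merged_cats[p] = min(merged_cats[p], cat, key=CATEGORIES.index)
                    else:
                        merged_cats[p] = cat
                by_id[new_id] = AnnotatedComplex(
                    complex_id=new_id,
                    members=a.members | b.members,
                    category_of=merged_cats,
                    name=a.name or b.name,
                )
                audit.append(f"merge {cid_a}+{cid_b} -> {new_id}")
            else:
                raise ParseError(curation_path, lineno, f"unknown directive {op!r}")
    return list(by_id.values()), audit


def hypothetical_protein_report(
    complexes: Sequence[AnnotatedComplex],
    hypothetical_ids: set[str],
) -> list[dict[str, object]]:
    """One row per (hypothetical protein, containing complex).

    A complex is flagged function-inferable when at least half of its
    subunits carry category-I evidence.
    """
    rows: list[dict[str, object]] = []
    for c in sorted(complexes, key=lambda c: c.complex_id):
        n1 = sum(1 for cat in c.category_of.values() if cat == "I")
        inferable = n1 >= len(c.members) / 2
        for p in sorted(c.members & hypothetical_ids):
            rows.append(
                {
                    "protein": p,
                    "complex_id": c.complex_id,
                    "cqi": format_cqi(c.cqi),
                    "complex_type": c.complex_type,
                    "function_inferable": inferable,
                }
            )
    return rows
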