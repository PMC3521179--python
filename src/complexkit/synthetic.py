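"""Synthetic inputs with planted ground truth for every pipeline stage.

Networks carry planted near-clique complexes over an Erdos-Renyi
background; companion generators emit matching ontology annotations,
tissue expression profiles, homology tables, and perturbed reference
sets, so recovery can be checked against known truth without any
external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .benchmark import ReferenceSet
from .network import IntegratedNetwork
from .ontology import TermGraph
from .paralogs import HomologyTable

SOURCE_TAG = "SYN"


@dataclass
class SyntheticTruth:
    """Planted structure behind a generated data set."""

    planted_complexes: list[frozenset[str]]
    shared_subunits: list[tuple[str, int, int]] = field(default_factory=list)
    complex_terms: dict[int, str] = field(default_factory=dict)
    latent_profiles: dict[int, list[float]] = field(default_factory=dict)
    paralog_families: list[dict[str, object]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_complexes": [sorted(c) for c in self.planted_complexes],
            "shared_subunits": [list(s) for s in self.shared_subunits],
            "complex_terms": {str(k): v for k, v in self.complex_terms.items()},
            "latent_profiles": {str(k): v for k, v in self.latent_profiles.items()},
            "paralog_families": self.paralog_families,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_complexes=[frozenset(c) for c in payload["planted_complexes"]],
            shared_subunits=[tuple(s) for s in payload.get("shared_subunits", [])],
            complex_terms={int(k): v for k, v in payload.get("complex_terms", {}).items()},
            latent_profiles={int(k): v for k, v in payload.get("latent_profiles", {}).items()},
            paralog_families=payload.get("paralog_families", []),
        )


def powerlaw_sizes(
    n_complexes: int,
    exponent: float = 2.0,
    size_range: tuple[int, int] = (3, 25),
    seed: int | None = None,
) -> list[int]:
    """Complex sizes from a truncated discrete power law P(s) ~ s^-exponent."""
    lo, hi = size_range
    sizes = np.arange(lo, hi + 1)
    weights = sizes.astype(float) ** -exponent
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(sizes, size=n_complexes, p=weights).tolist()


def gen_network(
    n_background: int,
    complex_sizes: Sequence[int],
    p_in: float = 0.9,
    p_out: float = 0.02,
    n_shared: int = 0,
    seed: int | None = None,
) -> tuple[IntegratedNetwork, SyntheticTruth]:
    """Planted near-cliques (edge prob ``p_in``) over an ER background (``p_out``).

    ``n_shared`` proteins become members of two consecutive planted
    complexes. Background edges never join two members of the same planted
    complex, so the planted intra-density is exactly Bernoulli(p_in).
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    for s in complex_sizes:
        if s < 3:
            raise ValueError(f"planted complex size {s} < 3")
    if n_shared > max(len(complex_sizes) - 1, 0):
        raise ValueError("n_shared cannot exceed number of adjacent complex pairs")
    rng = np.random.default_rng(seed)

    planted: list[set[str]] = []
    counter = 0
    for size in complex_sizes:
        members = {f"P{counter + i:05d}" for i in range(size)}
        counter += size
        planted.append(members)
    shared: list[tuple[str, int, int]] = []
    for i in range(n_shared):
        # donate the largest native member so chained sharing stays pairwise
        donor = sorted(planted[i])[-1]
        victim = sorted(planted[i + 1])[0]
        planted[i + 1].discard(victim)
        planted[i + 1].add(donor)
        shared.append((donor, i, i + 1))
    background = [f"B{j:05d}" for j in range(n_background)]
    complex_nodes = sorted(set().union(*planted)) if planted else []
    all_nodes = complex_nodes + background

    net = IntegratedNetwork()
    for node in all_nodes:
        net.add_protein(node)
    same_complex: set[frozenset[str]] = set()
    for members in planted:
        ms = sorted(members)
        for i, a in enumerate(ms):
            for b in ms[i + 1 :]:
                same_complex.add(frozenset((a, b)))
                if rng.random() < p_in:
                    net.add_interaction(a, b, SOURCE_TAG)
    if p_out > 0:
        for i, a in enumerate(all_nodes):
            for b in all_nodes[i + 1 :]:
                if frozenset((a, b)) in same_complex:
                    continue
                if rng.random() < p_out:
                    net.add_interaction(a, b, SOURCE_TAG)

    truth = SyntheticTruth(
        planted_complexes=[frozenset(m) for m in planted],
        shared_subunits=shared,
    )
    return net, truth


def gen_go(
    truth: SyntheticTruth,
    n_noise_terms: int = 20,
    depth: int = 5,
    f_consistent: float = 1.0,
    noise_terms_per_protein: int = 0,
    seed: int | None = None,
) -> tuple[TermGraph, dict[str, set[str]]]:
    """Term tree of the given depth plus per-complex dedicated deep terms.

    Each planted complex owns one term at ``depth``, annotated to a fraction
    ``f_consistent`` of its members; ``noise_terms_per_protein`` extra random
    depth-``depth`` terms are sprinkled on every planted protein.
    """
    if not 0.0 <= f_consistent <= 1.0:
        raise ValueError("f_consistent must be in [0,1]")
    rng = np.random.default_rng(seed)
    g = TermGraph()
    g.add_term("T:ROOT")
    # one internal chain to hang depth-`depth` leaves from
    chain = ["T:ROOT"]
    for level in range(1, depth):
        t = f"T:L{level}"
        g.add_edge(t, chain[-1])
        chain.append(t)

    leaf_parent = chain[-1]
    complex_terms: dict[int, str] = {}
    for i in range(len(truth.planted_complexes)):
        t = f"T:C{i:04d}"
        g.add_edge(t, leaf_parent)
        complex_terms[i] = t
    noise_terms = [f"T:N{j:04d}" for j in range(n_noise_terms)]
    for t in noise_terms:
        g.add_edge(t, leaf_parent)

    annotations: dict[str, set[str]] = {}
    for i, members in enumerate(truth.planted_complexes):
        ms = sorted(members)
        n_annot = int(round(f_consistent * len(ms)))
        chosen = list(rng.choice(ms, size=n_annot, replace=False)) if n_annot else []
        for p in chosen:
            annotations.setdefault(p, set()).add(complex_terms[i])
        if noise_terms and noise_terms_per_protein:
            for p in ms:
                extra = rng.choice(noise_terms, size=noise_terms_per_protein, replace=False)
                annotations.setdefault(p, set()).update(extra)
    truth.complex_terms = complex_terms
    return g, annotations


def gen_expression(
    truth: SyntheticTruth,
    n_tissues: int = 10,
    coherence: float = 1.0,
    tissue_specific: bool = False,
    noise_sd: float = 0.0,
    tags_per_locus: int = 1,
    n_background_loci: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tag-level expression matrix whose loci follow per-complex latent profiles.

    A member profile is ``coherence * latent + (1 - coherence) * independent``
    plus Gaussian noise (clipped at 0). Tag replicates are positive
    rescalings of the locus profile, so tag averaging changes scale but not
    direction. Background loci get independent profiles.
    """
    if not 0.0 <= coherence <= 1.0:
        raise ValueError("coherence must be in [0,1]")
    rng = np.random.default_rng(seed)

    def draw_latent() -> np.ndarray:
        if tissue_specific:
            v = np.full(n_tissues, 0.02)
            v[rng.integers(n_tissues)] = 1.0
            return v
        return rng.dirichlet(np.ones(n_tissues)) + 0.01

    rows: list[list[object]] = []

    def emit(locus: str, profile: np.ndarray) -> None:
        profile = np.clip(profile, 0.0, None)
        if not profile.any():
            profile = np.full(n_tissues, 1.0 / n_tissues)
        for t in range(tags_per_locus):
            scale = 1.0 + t  # positive rescaling only: cosine-invariant
            rows.append([f"{locus}_tag{t}", locus] + (profile * scale).tolist())

    latents: dict[int, list[float]] = {}
    seen: set[str] = set()
    for i, members in enumerate(truth.planted_complexes):
        latent = draw_latent()
        latents[i] = latent.tolist()
        for p in sorted(members):
            if p in seen:
                continue  # shared subunits keep their first complex's profile
            seen.add(p)
            indep = draw_latent()
            profile = coherence * latent + (1.0 - coherence) * indep
            if noise_sd > 0:
                profile = profile + rng.normal(0.0, noise_sd, size=n_tissues)
            emit(p, profile)
    for j in range(n_background_loci):
        emit(f"BG{j:05d}", draw_latent())
    truth.latent_profiles = latents

    columns = ["tag_id", "locus_id"] + [f"t{i}" for i in range(n_tissues)]
    return pd.DataFrame(rows, columns=columns)


def gen_homology(
    truth: SyntheticTruth,
    family_assignments: Sequence[tuple[Sequence[str], int]] | None = None,
    e_value_strong: float = 1e-5,
    e_value_weak: float = 1e-2,
    seed: int | None = None,
) -> HomologyTable:
    """Homology table realizing per-family paralogy at two evidence tiers.

    ``family_assignments`` lists (genes, n_core) families: pairs among the
    first ``n_core`` genes score far below ``e_value_strong``; pairs touching
    a peripheral member score between the strong and weak thresholds. With
    no explicit families, each planted complex becomes one all-core family.
    """
    if not e_value_strong < e_value_weak:
        raise ValueError("need e_value_strong < e_value_weak")
    rng = np.random.default_rng(seed)
    if family_assignments is None:
        family_assignments = [
            (sorted(members), len(members)) for members in truth.planted_complexes
        ]
    table = HomologyTable()
    families_meta: list[dict[str, object]] = []
    for genes, n_core in family_assignments:
        genes = list(genes)
        if n_core > len(genes):
            raise ValueError("n_core exceeds family size")
        core = set(genes[:n_core])
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if a in core and b in core:
                    e = e_value_strong * 10 ** (-3 + rng.random())
                else:
                    lo, hi = np.log10(e_value_strong), np.log10(e_value_weak)
                    e = 10 ** (lo + rng.random() * (hi - lo))
                table.add(a, b, float(e))
        families_meta.append({"genes": genes, "n_core": n_core})
    truth.paralog_families = families_meta
    return table


def gen_reference(
    truth: SyntheticTruth,
    drop_per_complex: int = 0,
    add_per_complex: int = 0,
    seed: int | None = None,
) -> ReferenceSet:
    """Reference complexes = planted truth, optionally perturbed.

    Dropping members exercises precision < 1 for exact predictions; adding
    foreign members exercises recall < 1.
    """
    rng = np.random.default_rng(seed)
    complexes: dict[str, frozenset[str]] = {}
    for i, members in enumerate(truth.planted_complexes):
        ms = sorted(members)
        if drop_per_complex:
            keep = max(2, len(ms) - drop_per_complex)
            ms = list(rng.choice(ms, size=keep, replace=False))
        for j in range(add_per_complex):
            ms.append(f"X{i:04d}_{j}")
        complexes[f"ref{i:04d}"] = frozenset(ms)
    return ReferenceSet(complexes=complexes)
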