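"""Expression coherence of complex subunits over a 10-tissue profile matrix.

Coherence of a complex is the mean pairwise cosine of its subunits'
expression vectors; significance comes from a Monte-Carlo null built by
repeatedly averaging the cosines of k random genes (size-matched, null
draws cached per k). Benjamini-Hochberg controls the FDR across
complexes, and a Shannon entropy of the normalized profile measures
tissue specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import AbstractSet, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

N_TISSUES = 10


@dataclass(frozen=True)
class CoherenceResult:
    complex_id: str
    k: int
    avg_cosine: float
    p_value: float
    fdr: float = float("nan")
    entropy: float = float("nan")


def load_expression_matrix(path: str | Path, n_tissues: int = N_TISSUES) -> pd.DataFrame:
    """TSV with columns tag_id, locus_id, then ``n_tissues`` value columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] != 2 + n_tissues:
        raise ValueError(
            f"expected {2 + n_tissues} columns (tag, locus, {n_tissues} tissues), got {df.shape[1]}"
        )
    df.columns = ["tag_id", "locus_id"] + [f"t{i}" for i in range(n_tissues)]
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be nonnegative")
    return df


def collapse_tags(matrix: pd.DataFrame) -> dict[str, np.ndarray]:
    """Average multi-tag rows per locus; drop loci collapsing to all-zero."""
    out: dict[str, np.ndarray] = {}
    value_cols = matrix.columns[2:]
    for locus, grp in matrix.groupby("locus_id", sort=True):
        vec = grp[value_cols].to_numpy(dtype=float).mean(axis=0)
        if not vec.any():
            logger.warning("locus %s collapses to all-zero profile; dropped", locus)
            continue
        out[str(locus)] = vec
    return out


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def complex_coherence(
    members: AbstractSet[str] | Sequence[str],
    profiles: Mapping[str, np.ndarray],
) -> tuple[float, int]:
    """Mean cosine over all unordered pairs of profiled members; returns (avg, k)."""
    profiled = sorted(m for m in set(members) if m in profiles)
    k = len(profiled)
    if k < 2:
        raise ValueError(f"complex has {k} profiled members; need >= 2")
    vecs = np.stack([profiles[m] for m in profiled])
    units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    s = units.sum(axis=0)
    # sum of pairwise cosines = (||sum of unit vectors||^2 - k) / 2
    total = (float(s @ s) - k) / 2.0
    return total / (k * (k - 1) / 2.0), k


class CoherenceNull:
    """Cached size-matched Monte-Carlo null of average pairwise cosines.

    For each k the null is ``n_reps`` averages of the pairwise cosines of k
    profiles drawn uniformly without replacement from the universe; draws
    are shared by all complexes of that size.
    """

    def __init__(
        self,
        universe_profiles: Mapping[str, np.ndarray],
        n_reps: int = 100_000,
        seed: int | None = None,
    ) -> None:
        loci = sorted(universe_profiles)
        if len(loci) < 2:
            raise ValueError("null universe needs >= 2 profiles")
        vecs = np.stack([universe_profiles[m] for m in loci])
        self._units = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        self.n_reps = int(n_reps)
        self.seed = seed
        self._cache: dict[int, np.ndarray] = {}

    @property
    def universe_size(self) -> int:
        return self._units.shape[0]

    def null_for(self, k: int) -> np.ndarray:
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > self.universe_size:
            raise ValueError(f"k={k} exceeds universe size {self.universe_size}")
        if k not in self._cache:
            # per-k child seed so each k is reproducible independently
            rng = np.random.default_rng(None if self.seed is None else (self.seed, k))
            n = self.universe_size
            draws = np.empty(self.n_reps, dtype=float)
            batch = max(1, min(self.n_reps, 200_000 // max(k, 1)))
            done = 0
            while done < self.n_reps:
                b = min(batch, self.n_reps - done)
                idx = np.argsort(rng.random((b, n)), axis=1)[:, :k]
                sums = self._units[idx].sum(axis=1)
                sq = np.einsum("ij,ij->i", sums, sums)
                draws[done : done + b] = (sq - k) / (k * (k - 1))
                done += b
            self._cache[k] = draws
        return self._cache[k]

    def p_value(self, avg_cosine: float, k: int) -> float:
        """Permutation p with +1 pseudocount: (1 + #{null >= obs}) / (1 + reps)."""
        null = self.null_for(k)
        # tolerance guards ties lost to float noise (e.g. obs == null exactly)
        n_ge = int(np.count_nonzero(null >= avg_cosine - 1e-12))
        return (1 + n_ge) / (1 + self.n_reps)


def coherence_p_value(
    avg_cosine: float,
    k: int,
    universe_profiles: Mapping[str, np.ndarray],
    n_reps: int = 100_000,
    seed: int | None = None,
    null: CoherenceNull | None = None,
) -> float:
    """Convenience wrapper; prefer a shared :class:`CoherenceNull` for many calls."""
    if null is None:
        null = CoherenceNull(universe_profiles, n_reps=n_reps, seed=seed)
    return null.p_value(avg_cosine, k)


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def profile_entropy(vector: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of the profile's normalized tissue fractions."""
    v = np.asarray(vector, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("entropy undefined for a zero vector")
    frac = v / total
    frac = frac[frac > 0]
    return float(-(frac * (np.log(frac) / np.log(base))).sum())


def score_complexes(
    complexes: Mapping[str, AbstractSet[str]],
    profiles: Mapping[str, np.ndarray],
    n_reps: int = 100_000,
    seed: int | None = None,
) -> tuple[list[CoherenceResult], list[str]]:
    """Coherence, p, FDR, and mean entropy for every scorable complex.

    Complexes with fewer than two profiled members are skipped and their
    IDs returned in the second element.
    """
    null = CoherenceNull(profiles, n_reps=n_reps, seed=seed)
    scored: list[tuple[str, float, int, float]] = []
    skipped: list[str] = []
    for cid in sorted(complexes):
        members = complexes[cid]
        profiled = [m for m in members if m in profiles]
        if len(profiled) < 2:
            skipped.append(cid)
            continue
        avg, k = complex_coherence(members, profiles)
        ent = float(np.mean([profile_entropy(profiles[m]) for m in profiled]))
        scored.append((cid, avg, k, ent))
    ps = [null.p_value(avg, k) for _, avg, k, _ in scored]
    qs = fdr_adjust(ps)
    results = [
        CoherenceResult(complex_id=cid, k=k, avg_cosine=avg, p_value=p, fdr=q, entropy=ent)
        for (cid, avg, k, ent), p, q in zip(scored, ps, qs)
    ]
    return results, skipped


def size_similarity_summary(
    results: Sequence[CoherenceResult],
) -> dict[str, object]:
    """Per-k quartiles of -log10(p) plus a Spearman trend of score vs k."""
    if not results:
        return {"bins": [], "spearman_rho": float("nan"), "spearman_p": float("nan")}
    ks = np.array([r.k for r in results])
    scores = -np.log10(np.array([r.p_value for r in results]))
    bins = []
    for k in sorted(set(ks.tolist())):
        vals = scores[ks == k]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        bins.append(
            {"k": int(k), "n": int(vals.size), "q1": float(q1), "median": float(med), "q3": float(q3)}
        )
    if len(set(ks.tolist())) > 1:
        rho, p = stats.spearmanr(ks, scores)
    else:
        rho, p = float("nan"), float("nan")
    return {"bins": bins, "spearman_rho": float(rho), "spearman_p": float(p)}
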