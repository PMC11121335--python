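"""Adjusted cosine similarity (ACS) between same-kind entities.

Each entity is vectorized as a binary membership vector over the fixed
feature universe of its kind and level (1 at member positions, 0 elsewhere).
The ACS of two vectors centers each by its *own* mean before taking the
cosine:

    R = sum_i (A_i - abar)(B_i - bbar) / sqrt(sum (A_i-abar)^2 sum (B_i-bbar)^2)

On binary vectors this is exactly the Pearson correlation of the two
memberships, i.e. the phi coefficient of their 2x2 contingency table — a
fact the test suite uses as an independent oracle.  Gene-level and
pathway-level similarity matrices are averaged elementwise into the final
("combined") similarity; where one level is degenerate for a pair the other
level alone is used.

Degenerate vectors (all-0 or all-1) have zero centered norm; the ACS of any
pair involving one is defined as 0.0 (no evidence of similarity), except
self-pairs on the matrix diagonal which are 1 by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import EntityProfile, FeatureSpace, Level

logger = logging.getLogger(__name__)

DEGENERATE_SIMILARITY = 0.0


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric entity x entity similarity with a fixed ID order.

    ``nondegenerate`` marks entities whose binary vector at this level was
    non-constant; for the combined level it marks entities with at least one
    usable level.  Off-diagonal entries for degenerate entities are the
    degenerate value 0.0.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    level_tag: str
    nondegenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite values")
        if self.nondegenerate is None:
            object.__setattr__(self, "nondegenerate", np.ones(n, dtype=bool))

    @property
    def index(self) -> dict[str, int]:
        return {eid: i for i, eid in enumerate(self.ids)}

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.index[entity_id]]

    def value(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.values[idx[a], idx[b]])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))
        df.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, level_tag: str = "combined") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=tuple(df.index), values=df.to_numpy(dtype=float), level_tag=level_tag)


def to_binary_vector(profile: EntityProfile, space: FeatureSpace, level: Level) -> np.ndarray:
    """Binary membership vector over the ordered feature universe."""
    ids = space.ids(level)
    index = space.index(level)
    vec = np.zeros(len(ids), dtype=float)
    for m in profile.members(level):
        if m not in index:
            raise KeyError(
                f"{profile.entity_id}: member {m!r} not in {level.value} feature space"
            )
        vec[index[m]] = 1.0
    return vec


def acs(a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray) -> float:
    """Adjusted cosine similarity of two equal-length vectors, in [-1, 1].

    Each vector is centered by its own mean.  A constant vector (all-0 or
    all-1 in the binary case) yields the degenerate value 0.0 rather than
    NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("acs requires two 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("acs requires vector length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na = float(np.linalg.norm(ac))
    nb = float(np.linalg.norm(bc))
    if na == 0.0 or nb == 0.0:
        return DEGENERATE_SIMILARITY
    return float(np.clip(np.dot(ac, bc) / (na * nb), -1.0, 1.0))


def _vectorize_all(
    profiles: Sequence[EntityProfile], space: FeatureSpace, level: Level
) -> np.ndarray:
    return np.vstack([to_binary_vector(p, space, level) for p in profiles])


def level_similarity(
    profiles: Sequence[EntityProfile], space: FeatureSpace, level: Level
) -> SimilarityMatrix:
    """Pairwise ACS over all profiles at one level.

    Symmetric by construction; diagonal fixed at 1 (self-pairs of degenerate
    entities included, by convention).  Degenerate entities are logged.
    """
    if len(profiles) < 2:
        raise ValueError("level_similarity requires >= 2 profiles")
    if len(space.ids(level)) == 0:
        raise ValueError(f"feature space has no {level.value} features")
    ids = tuple(p.entity_id for p in profiles)
    X = _vectorize_all(profiles, space, level)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    nondeg = norms > 0
    n = len(ids)
    S = np.full((n, n), DEGENERATE_SIMILARITY, dtype=float)
    if nondeg.any():
        U = Xc[nondeg] / norms[nondeg, None]
        S[np.ix_(nondeg, nondeg)] = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0  # exact symmetry against fp asymmetry
    n_deg = int((~nondeg).sum())
    if n_deg:
        logger.info(
            "%s-level similarity: %d degenerate (constant-vector) entit%s, pairs set to %.1f",
            level.value, n_deg, "y" if n_deg == 1 else "ies", DEGENERATE_SIMILARITY,
        )
    return SimilarityMatrix(ids=ids, values=S, level_tag=level.value, nondegenerate=nondeg)


def combined_similarity(
    gene_sim: SimilarityMatrix | None, pathway_sim: SimilarityMatrix | None
) -> SimilarityMatrix:
    """Elementwise mean of gene- and pathway-level similarity.

    For a pair where exactly one level is usable (the other degenerate for
    either entity), the usable level's value is taken alone; where neither
    level is usable the degenerate value is kept.  A wholly missing level
    (``None``) degrades to the other matrix retagged "combined".
    """
    if gene_sim is None and pathway_sim is None:
        raise ValueError("at least one level matrix is required")
    if gene_sim is None or pathway_sim is None:
        only = gene_sim if gene_sim is not None else pathway_sim
        return SimilarityMatrix(
            ids=only.ids,
            values=only.values.copy(),
            level_tag="combined",
            nondegenerate=only.nondegenerate.copy(),
        )
    if gene_sim.ids != pathway_sim.ids:
        raise ValueError("gene and pathway similarity matrices index different entities")
    g_ok = np.outer(gene_sim.nondegenerate, gene_sim.nondegenerate)
    p_ok = np.outer(pathway_sim.nondegenerate, pathway_sim.nondegenerate)
    both = g_ok & p_ok
    S = np.full_like(gene_sim.values, DEGENERATE_SIMILARITY)
    S[both] = (gene_sim.values[both] + pathway_sim.values[both]) / 2.0
    only_g = g_ok & ~p_ok
    only_p = p_ok & ~g_ok
    S[only_g] = gene_sim.values[only_g]
    S[only_p] = pathway_sim.values[only_p]
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(
        ids=gene_sim.ids,
        values=S,
        level_tag="combined",
        nondegenerate=gene_sim.nondegenerate | pathway_sim.nondegenerate,
    )


def entity_similarity(
    profiles: Sequence[EntityProfile], space: FeatureSpace
) -> SimilarityMatrix:
    """Convenience: gene- and pathway-level ACS averaged into the final
    similarity for one entity kind, skipping a level absent from the space."""
    gene = (
        level_similarity(profiles, space, Level.GENE) if space.gene_ids else None
    )
    pathway = (
        level_similarity(profiles, space, Level.PATHWAY) if space.pathway_ids else None
    )
    return combined_similarity(gene, pathway)
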