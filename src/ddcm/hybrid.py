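"""Hybrid training matrix construction.

Each row is one disease-drug pair; the feature vector is the row's drug
similarity to every drug (R columns, in the drug matrix's fixed ID order)
concatenated with the row's disease similarity to every disease (D columns).
Known therapeutic pairs carry label 1; sampled non-known pairs carry label
0.  Feature values are the raw combined similarities in [-1, 1] — they are
already on a common scale, so no standardization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class HybridMatrix:
    """Labeled (or query) rows over drug-similarity then disease-similarity
    columns.  ``labels`` is None for query matrices."""

    row_pairs: tuple[tuple[str, str], ...]
    columns: tuple[str, ...]  # "drug:<id>" * R then "disease:<id>" * D
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_pairs), len(self.columns)):
            raise ValueError("hybrid matrix shape mismatch")
        if self.labels is not None and len(self.labels) != len(self.row_pairs):
            raise ValueError("labels length mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.row_pairs)

    def drop_diseases(self, removed: set[str]) -> "HybridMatrix":
        """Training matrix without any rows whose disease is in ``removed``.
        Columns (the feature layout) are unchanged."""
        keep = [i for i, (d, _) in enumerate(self.row_pairs) if d not in removed]
        return HybridMatrix(
            row_pairs=tuple(self.row_pairs[i] for i in keep),
            columns=self.columns,
            values=self.values[keep],
            labels=None if self.labels is None else self.labels[keep],
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "disease_id", [d for d, _ in self.row_pairs])
        df.insert(1, "drug_id", [r for _, r in self.row_pairs])
        if self.labels is not None:
            df.insert(2, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)


def _columns(drug_sim: SimilarityMatrix, disease_sim: SimilarityMatrix) -> tuple[str, ...]:
    return tuple(f"drug:{r}" for r in drug_sim.ids) + tuple(
        f"disease:{d}" for d in disease_sim.ids
    )


def pair_features(
    disease_id: str,
    drug_id: str,
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
) -> np.ndarray:
    """Feature vector [sim(drug, all drugs), sim(disease, all diseases)]."""
    if drug_id not in drug_sim.index:
        raise KeyError(f"unknown drug {drug_id!r}")
    if disease_id not in disease_sim.index:
        raise KeyError(f"unknown disease {disease_id!r}")
    return np.concatenate([drug_sim.row(drug_id), disease_sim.row(disease_id)])


def _parse_negative_policy(policy: str) -> float | None:
    """Return the negatives-per-positive ratio, or None for 'all'."""
    if policy == "all":
        return None
    if policy.startswith("matched:"):
        ratio = float(policy.split(":", 1)[1])
        if ratio <= 0:
            raise ValueError("negative ratio must be positive")
        return ratio
    raise ValueError(f"unknown negative_policy {policy!r} (use 'all' or 'matched:<ratio>')")


def build_training_matrix(
    dataset: Dataset,
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    negative_policy: str = "matched:1",
    seed: int = 0,
) -> HybridMatrix:
    """All known pairs (label 1) plus seeded negatives (label 0).

    Negatives are sampled uniformly without replacement from the non-known
    (disease, drug) combinations; ``matched:<ratio>`` draws ratio x |known|
    of them, ``all`` uses every non-known combination.  Row order (positives
    sorted, then sampled negatives) is deterministic given the seed.
    """
    known = sorted(dataset.associations.pairs)
    if not known:
        raise ValueError("no known disease-drug pairs to train on")
    known_set = set(known)
    unknown = [
        (d, r)
        for d in dataset.disease_ids
        for r in dataset.drug_ids
        if (d, r) not in known_set
    ]
    ratio = _parse_negative_policy(negative_policy)
    if ratio is None:
        negatives = unknown
    else:
        n_neg = min(int(round(ratio * len(known))), len(unknown))
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(unknown), size=n_neg, replace=False)
        negatives = [unknown[i] for i in sorted(idx)]
    pairs = known + negatives
    labels = np.concatenate([np.ones(len(known)), np.zeros(len(negatives))])
    values = np.vstack([pair_features(d, r, drug_sim, disease_sim) for d, r in pairs])
    return HybridMatrix(
        row_pairs=tuple(pairs),
        columns=_columns(drug_sim, disease_sim),
        values=values,
        labels=labels,
    )


def build_query_matrix(
    disease_id: str,
    candidate_drugs: Sequence[str],
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
) -> HybridMatrix:
    """One unlabeled row per candidate drug for a fixed disease, in the
    same column layout as the training matrix."""
    if not candidate_drugs:
        raise ValueError("candidate drug list is empty")
    pairs = tuple((disease_id, r) for r in candidate_drugs)
    values = np.vstack([pair_features(d, r, drug_sim, disease_sim) for d, r in pairs])
    return HybridMatrix(
        row_pairs=pairs, columns=_columns(drug_sim, disease_sim), values=values
    )
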