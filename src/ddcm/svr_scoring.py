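"""Linear epsilon-insensitive support-vector regression scoring.

The model f(x) = <w, x> + phi is fit by minimizing

    1/2 ||w||^2 + C * sum_i (xi_i + xihat_i)

subject to the soft epsilon-tube constraints |y_i - f(x_i)| <= eps + slack.
Labels are 1 for known therapeutic pairs and 0 for non-known pairs; the
continuous output f(x) on a query pair is its disease-drug correlation
score.  The default tube width is eps = 0.1; the cost C defaults to 1.0.
The convex QP is solved by libsvm's SMO (scikit-learn SVR, linear kernel),
deterministic at fixed inputs and tolerance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .data_model import Dataset
from .hybrid import HybridMatrix, build_query_matrix
from .similarity import SimilarityMatrix

DEFAULT_EPSILON = 0.1
DEFAULT_COST = 1.0
SOLVER_TOL = 1e-6


@dataclass(frozen=True)
class ScoringModel:
    """Fitted linear epsilon-SVR: weights, intercept, hyperparameters."""

    weights: np.ndarray
    intercept: float
    epsilon: float
    cost: float
    columns: tuple[str, ...]
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.columns):
            raise ValueError("weight vector length != column count")
        if self.epsilon < 0 or self.cost <= 0:
            raise ValueError("require epsilon >= 0 and cost > 0")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "epsilon": self.epsilon,
            "cost": self.cost,
            "columns": list(self.columns),
            "fit_meta": self.fit_meta,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoringModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            weights=np.asarray(doc["weights"], dtype=float),
            intercept=float(doc["intercept"]),
            epsilon=float(doc["epsilon"]),
            cost=float(doc["cost"]),
            columns=tuple(doc["columns"]),
            fit_meta=doc.get("fit_meta", {}),
        )


@dataclass(frozen=True)
class ScoreTable:
    """De-redundant per-drug correlation scores for one disease."""

    disease_id: str
    scores: pd.Series  # index: drug_id, values: f(x)
    provenance: str = ""

    def top(self, k: int) -> pd.Series:
        """Top-k by descending score, ties broken by ascending drug ID."""
        df = self.scores.rename_axis("drug_id").reset_index(name="score")
        df = df.sort_values(["score", "drug_id"], ascending=[False, True])
        return df.head(k).set_index("drug_id")["score"]

    def to_tsv(self, path: str | Path) -> None:
        df = self.scores.rename_axis("drug_id").reset_index(name="score")
        df.insert(0, "disease_id", self.disease_id)
        df.to_csv(path, sep="\t", index=False)


def _fingerprint(hybrid: HybridMatrix) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(hybrid.values).tobytes())
    if hybrid.labels is not None:
        h.update(np.ascontiguousarray(hybrid.labels).tobytes())
    return h.hexdigest()[:16]


def fit(
    hybrid: HybridMatrix,
    epsilon: float = DEFAULT_EPSILON,
    cost: float = DEFAULT_COST,
    seed: int = 0,
) -> ScoringModel:
    """Fit the linear epsilon-SVR on a labeled hybrid matrix."""
    if hybrid.labels is None:
        raise ValueError("training requires a labeled hybrid matrix")
    if hybrid.n_rows < 2:
        raise ValueError("training requires >= 2 rows")
    if len(np.unique(hybrid.labels)) < 2:
        # legal (the optimum is the flat fit w=0, b=median-ish) but almost
        # certainly a pipeline mistake when labels should be 1/0
        logging.getLogger(__name__).warning("training labels are constant; fitting anyway")
    if not np.all(np.isfinite(hybrid.values)):
        raise ValueError("non-finite feature values")
    svr = SVR(kernel="linear", C=cost, epsilon=epsilon, tol=SOLVER_TOL, cache_size=256)
    svr.fit(hybrid.values, hybrid.labels)
    if svr.fit_status_ != 0:
        raise RuntimeError(
            f"SVR solver did not converge (fit_status={svr.fit_status_}, "
            f"n_rows={hybrid.n_rows}, C={cost}, eps={epsilon})"
        )
    return ScoringModel(
        weights=np.asarray(svr.coef_, dtype=float).ravel(),
        intercept=float(svr.intercept_[0]),
        epsilon=epsilon,
        cost=cost,
        columns=hybrid.columns,
        fit_meta={"n_rows": hybrid.n_rows, "fingerprint": _fingerprint(hybrid), "seed": seed},
    )


def predict(model: ScoringModel, query: HybridMatrix) -> np.ndarray:
    """Score each query row: f(x) = <w, x> + phi."""
    if query.columns != model.columns:
        raise ValueError("query column layout does not match the fitted model")
    return query.values @ model.weights + model.intercept


def score_disease(
    model: ScoringModel,
    disease_id: str,
    dataset: Dataset,
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
) -> ScoreTable:
    """Score all drugs for one disease, de-redundantly.

    If a drug receives multiple scores (duplicate query rows), the highest
    is kept, so the table has exactly one row per drug.
    """
    if disease_id not in dataset.diseases:
        raise KeyError(f"unknown disease {disease_id!r}")
    query = build_query_matrix(disease_id, dataset.drug_ids, drug_sim, disease_sim)
    raw = predict(model, query)
    df = pd.DataFrame({"drug_id": [r for _, r in query.row_pairs], "score": raw})
    scores = df.groupby("drug_id")["score"].max().sort_index()
    return ScoreTable(
        disease_id=disease_id,
        scores=scores,
        provenance=model.fit_meta.get("fingerprint", ""),
    )
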