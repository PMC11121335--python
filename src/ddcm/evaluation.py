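"""Recovery evaluation of held-out therapeutic associations.

The ranking metric is the Mann-Whitney AUC: the probability that a
uniformly random held-out positive drug outscores a uniformly random
negative drug, with ties counting one half.

Two leakage/bias guards shape the report:

* **Global known-drug exclusion.**  A single model trained on the full
  association table inflates the score of every drug that appears in any
  known pair (its own similarity column carries its training label), so
  ranking metrics drop *all* drugs with a known association — not just the
  query disease's own — from the candidate list.  Held-out positives, by
  construction, have no known pair and survive the exclusion.
* **Within-disease stratification.**  A global linear model shifts every
  drug score for a disease by a disease-specific constant, so raw score
  comparisons across diseases are meaningless.  The pooled AUC therefore
  combines only within-disease positive-negative comparisons, weighting
  each disease by its number of such pairs (a stratified Mann-Whitney).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .svr_scoring import ScoreTable


def benchmark_recovery(
    config,
    *,
    null: bool = False,
    epsilon: float = 0.1,
    cost: float = 1.0,
    negative_policy: str = "matched:1",
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full scoring pipeline on one synthetic dataset and return its
    holdout evaluation matrices (see :func:`holdout_matrix`).

    With ``null=True`` the generator's planted overlaps are switched off, so
    the returned matrices realize the no-signal control.
    """
    from .data_model import EntityKind
    from .hybrid import build_training_matrix
    from .similarity import entity_similarity
    from .svr_scoring import fit, score_disease
    from .synthetic import generate, generate_null

    ds = generate_null(config) if null else generate(config)
    d = ds.dataset
    drug_sim = entity_similarity(d.profiles(EntityKind.DRUG), d.drug_space)
    disease_sim = entity_similarity(d.profiles(EntityKind.DISEASE), d.disease_space)
    hybrid = build_training_matrix(
        d, drug_sim, disease_sim, negative_policy=negative_policy, seed=config.seed
    )
    model = fit(hybrid, epsilon=epsilon, cost=cost, seed=config.seed)
    tables = {
        did: score_disease(model, did, d, drug_sim, disease_sim) for did in d.disease_ids
    }
    return holdout_matrix(tables, set(ds.truth), set(ds.holdout))


@dataclass(frozen=True)
class EvalReport:
    per_disease: pd.DataFrame  # auc, recovery_at_k, n_pos, n_neg per disease
    pooled_auc: float
    recovery_at_k: float
    ptdr_recall: float | None = None
    ptdr_precision: float | None = None
    k: int = 50
    notes: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "pooled_auc": self.pooled_auc,
            "recovery_at_k": self.recovery_at_k,
            "ptdr_recall": self.ptdr_recall,
            "ptdr_precision": self.ptdr_precision,
            "k": self.k,
            "notes": self.notes,
            "per_disease": self.per_disease.reset_index().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def auc(scores: ScoreTable, positives: Iterable[str]) -> float:
    """Mann-Whitney AUC of the score table against a positive drug set."""
    pos = set(positives)
    labels = np.array([1 if r in pos else 0 for r in scores.scores.index])
    return _auc_from_arrays(scores.scores.to_numpy(dtype=float), labels)


def _auc_from_arrays(values: np.ndarray, labels: np.ndarray) -> float:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = rankdata(values)  # midranks give ties half credit
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass(frozen=True)
class _Stratum:
    values: np.ndarray
    labels: np.ndarray

    @property
    def weight(self) -> int:
        n_pos = int(self.labels.sum())
        return n_pos * (len(self.labels) - n_pos)


def pooled_auc(strata: Sequence[_Stratum]) -> float:
    """Stratified Mann-Whitney: per-stratum AUCs combined with weight
    n_pos * n_neg, i.e. pooling only within-stratum comparisons."""
    num = den = 0.0
    for s in strata:
        w = s.weight
        if w == 0:
            continue
        num += _auc_from_arrays(s.values, s.labels) * w
        den += w
    if den == 0:
        raise ValueError("no stratum with both a positive and a negative")
    return num / den


def holdout_matrix(
    score_tables: Mapping[str, ScoreTable],
    truth: set[tuple[str, str]],
    holdout: set[tuple[str, str]],
) -> tuple[np.ndarray, np.ndarray]:
    """One dataset's evaluation state as aligned matrices.

    Rows are diseases with at least one holdout positive and one negative;
    columns are the candidate drugs surviving the global known-drug
    exclusion (identical for every disease).  Returns (values, labels).
    """
    strata = holdout_strata(score_tables, truth, holdout)
    rows_v, rows_l = [], []
    for disease_id in sorted(strata):
        s = strata[disease_id]
        if 0 < int(s.labels.sum()) < len(s.labels):
            rows_v.append(s.values)
            rows_l.append(s.labels)
    if not rows_v:
        raise ValueError("no disease with both a holdout positive and a negative")
    return np.vstack(rows_v), np.vstack(rows_l)


def pooled_auc_grouped(groups: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Stratified pooled AUC over several datasets' (values, labels) pairs."""
    strata = [
        _Stratum(values=v[i], labels=l[i])
        for v, l in groups
        for i in range(v.shape[0])
    ]
    return pooled_auc(strata)


def permutation_band(
    groups: Sequence[tuple[np.ndarray, np.ndarray]],
    n_perm: int = 500,
    seed: int = 0,
    z: float = 3.0,
) -> tuple[float, float]:
    """Null band 0.5 +/- z * SE for the grouped pooled AUC.

    Within one dataset all disease strata rank the same candidate drugs
    with the same fitted model, so their AUCs are strongly dependent.  The
    exchangeability hypothesis is therefore permuted at the dataset level:
    one drug permutation per dataset, applied to every stratum's columns at
    once.  SE is the standard deviation of the statistic over such
    permutations.
    """
    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = []
        for values, labels in groups:
            perm = rng.permutation(values.shape[1])
            shuffled.append((values[:, perm], labels))
        stats[i] = pooled_auc_grouped(shuffled)
    se = float(stats.std(ddof=1))
    return 0.5 - z * se, 0.5 + z * se


def holdout_strata(
    score_tables: Mapping[str, ScoreTable],
    truth: set[tuple[str, str]],
    holdout: set[tuple[str, str]],
) -> dict[str, _Stratum]:
    """Per-disease candidate scores and holdout labels after the global
    known-drug exclusion."""
    known = truth - holdout
    known_drugs = {r for _, r in known}
    strata: dict[str, _Stratum] = {}
    for disease_id, table in score_tables.items():
        hold = {r for d, r in holdout if d == disease_id}
        if hold - set(table.scores.index):
            raise ValueError(f"{disease_id}: holdout drugs missing from score table")
        eligible = table.scores.drop(labels=sorted(known_drugs), errors="ignore")
        labels = np.array([1 if r in hold else 0 for r in eligible.index])
        strata[disease_id] = _Stratum(values=eligible.to_numpy(dtype=float), labels=labels)
    return strata


def recovery_report(
    score_tables: Mapping[str, ScoreTable],
    truth: set[tuple[str, str]],
    holdout: set[tuple[str, str]],
    k: int = 50,
    ptdr: Mapping[str, Iterable[str]] | None = None,
) -> EvalReport:
    """Per-disease and pooled recovery of held-out positives.

    Diseases with an empty holdout contribute nothing to the ranking
    metrics and are flagged not-applicable.  ``ptdr``, if given, maps
    disease -> final screened drug set and is scored as a retrieval of the
    holdout (recall/precision pooled over diseases).
    """
    known = truth - holdout
    known_drugs = {r for _, r in known}
    strata = holdout_strata(score_tables, truth, holdout)
    rows = []
    usable: list[_Stratum] = []
    for disease_id in sorted(score_tables):
        table = score_tables[disease_id]
        s = strata[disease_id]
        n_pos = int(s.labels.sum())
        n_neg = int(len(s.labels) - n_pos)
        if n_pos == 0 or n_neg == 0:
            rows.append(
                {"disease_id": disease_id, "auc": np.nan, "recovery_at_k": np.nan,
                 "n_pos": n_pos, "n_neg": n_neg}
            )
            continue
        usable.append(s)
        d_auc = _auc_from_arrays(s.values, s.labels)
        hold = {r for d, r in holdout if d == disease_id}
        eligible = table.scores.drop(labels=sorted(known_drugs), errors="ignore")
        order = eligible.rename_axis("drug_id").reset_index(name="score")
        order = order.sort_values(["score", "drug_id"], ascending=[False, True])
        top_k = set(order.head(k)["drug_id"])
        rows.append(
            {"disease_id": disease_id, "auc": d_auc,
             "recovery_at_k": len(hold & top_k) / len(hold),
             "n_pos": n_pos, "n_neg": n_neg}
        )

    per_disease = pd.DataFrame(rows).set_index("disease_id")
    if usable:
        pool = pooled_auc(usable)
        recovery = float(per_disease["recovery_at_k"].mean(skipna=True))
        notes = {}
    else:
        pool = float("nan")
        recovery = float("nan")
        notes = {"holdout": "empty for every disease; ranking metrics not applicable"}

    ptdr_recall = ptdr_precision = None
    if ptdr is not None:
        hits = total_hold = total_pred = 0
        for disease_id, drug_set in ptdr.items():
            drug_set = set(drug_set)
            hold = {r for d, r in holdout if d == disease_id}
            hits += len(hold & drug_set)
            total_hold += len(hold)
            total_pred += len(drug_set)
        ptdr_recall = hits / total_hold if total_hold else None
        ptdr_precision = hits / total_pred if total_pred else None

    return EvalReport(
        per_disease=per_disease,
        pooled_auc=pool,
        recovery_at_k=recovery,
        ptdr_recall=ptdr_recall,
        ptdr_precision=ptdr_precision,
        k=k,
        notes=notes,
    )
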