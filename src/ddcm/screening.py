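"""Stepwise screening of potential therapeutic drugs.

For a query disease the pipeline is:

1. **Drug candidates (DrC)** — the top-50 drugs by de-redundant correlation
   score from the unperturbed model.
2. **Randomized perturbation** — for each regime j in {1, 2, 5}, repeat M
   times: remove j randomly chosen diseases (never the query) from the
   training rows, refit, rescore the query disease, and record the top-50
   set.  Similarity feature columns are kept so the feature layout — and
   hence model comparability — is fixed across runs.
3. **Stability score** — per drug and regime, S_j = 1 - sample SD (divisor
   M-1) of its M binary top-50 occurrence indicators.  A drug absent from
   every run of a regime also gets S_j = 1 but is ineligible for that
   regime's stable set.
4. **Stable candidates (SDrC)** — DrS_j keeps the top 95% of eligible drugs
   ranked by S_j (ties at the cut retained); SDrC = DrS1 ∩ DrS2 ∩ DrS5 ∩ DrC.
5. **Potential therapeutic drugs (PtDr)** — the total stability SSDrC is
   1 - sample SD over M' = 3M + 1 indicators (the 3M perturbed runs plus
   one unperturbed indicator = DrC membership); PtDr keeps the top 95% of
   SDrC by SSDrC.

The containment chain PtDr ⊆ SDrC ⊆ DrC holds by construction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, EntityKind
from .hybrid import HybridMatrix, build_training_matrix
from .similarity import SimilarityMatrix, entity_similarity
from .svr_scoring import (
    DEFAULT_COST,
    DEFAULT_EPSILON,
    ScoreTable,
    fit,
    score_disease,
)

logger = logging.getLogger(__name__)

REGIMES = (1, 2, 5)


@dataclass(frozen=True)
class ScreenConfig:
    """Pipeline parameters; defaults mirror the method's stated values
    (eps = 0.1, top-50, regimes {1,2,5}, keep = 95%)."""

    k: int = 50
    m_runs: int = 10
    quantile_keep: float = 0.95
    epsilon: float = DEFAULT_EPSILON
    cost: float = DEFAULT_COST
    negative_policy: str = "matched:1"
    stability_variant: str = "sd"  # "sd": 1 - sample SD; "variance": 1 - sample variance
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_runs < 2:
            raise ValueError("m_runs must be >= 2")
        if not 0 < self.quantile_keep <= 1:
            raise ValueError("quantile_keep must be in (0, 1]")
        if self.stability_variant not in ("sd", "variance"):
            raise ValueError("stability_variant must be 'sd' or 'variance'")


@dataclass(frozen=True)
class CandidateList:
    """Top-k drug candidates (DrC) for one disease, descending score."""

    disease_id: str
    drugs: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.drugs) != len(self.scores):
            raise ValueError("drugs/scores length mismatch")

    @property
    def drug_set(self) -> frozenset[str]:
        return frozenset(self.drugs)


@dataclass(frozen=True)
class PerturbationRun:
    regime: int
    run_index: int
    removed_diseases: frozenset[str]
    top_k: frozenset[str]


@dataclass(frozen=True)
class ScreenResult:
    disease_id: str
    config: ScreenConfig
    candidates: CandidateList
    runs: tuple[PerturbationRun, ...]
    stability: pd.DataFrame  # indexed by drug_id
    sdrc: frozenset[str]
    ptdr: frozenset[str]
    score_table: ScoreTable = None  # type: ignore[assignment]


def top_candidates(scores: ScoreTable, k: int = 50) -> CandidateList:
    """Top-k drugs by score descending; ties broken by ascending drug ID.
    Drugs ranked after the k-th are discarded."""
    if len(scores.scores) == 0:
        raise ValueError("empty score table")
    top = scores.top(k)
    return CandidateList(
        disease_id=scores.disease_id,
        drugs=tuple(top.index),
        scores=tuple(float(v) for v in top.to_numpy()),
    )


def stability_score(indicators: Sequence[float] | np.ndarray, variant: str = "sd") -> float:
    """1 minus the sample spread (divisor M-1) of occurrence indicators."""
    s = np.asarray(indicators, dtype=float)
    if s.size < 2:
        raise ValueError("stability_score requires M >= 2 indicators")
    spread = s.var(ddof=1) if variant == "variance" else s.std(ddof=1)
    return float(1.0 - spread)


def _keep_top_fraction(values: Mapping[str, float], keep: float) -> set[str]:
    """Drugs whose value is in the top `keep` fraction of the ranked list;
    ties at the cut retained.  The bottom (1-keep) is discarded."""
    if not values:
        return set()
    items = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    n_keep = max(1, math.ceil(keep * len(items)))
    threshold = items[n_keep - 1][1]
    return {drug for drug, v in items if v >= threshold}


def sample_removals(
    disease_ids: Sequence[str], query_disease: str, j: int, m_runs: int, rng: np.random.Generator
) -> list[frozenset[str]]:
    """M draws of j diseases, uniform without replacement, excluding the query."""
    pool = sorted(d for d in disease_ids if d != query_disease)
    if j > len(pool):
        raise ValueError(f"cannot remove {j} of {len(pool)} non-query diseases")
    return [frozenset(rng.choice(pool, size=j, replace=False)) for _ in range(m_runs)]


def run_perturbations(
    dataset: Dataset,
    train_full: HybridMatrix,
    query_disease: str,
    drug_sim: SimilarityMatrix,
    disease_sim: SimilarityMatrix,
    j: int,
    m_runs: int,
    seed_seq: np.random.SeedSequence,
    config: ScreenConfig,
) -> list[PerturbationRun]:
    """One perturbation regime: M refits on training sets with j diseases'
    rows removed, each recording the query's top-k set."""
    if m_runs < 2:
        raise ValueError("m_runs must be >= 2")
    n_other = len(dataset.disease_ids) - 1
    if j >= n_other:
        raise ValueError(
            f"regime j={j} requires more than {j + 1} diseases (have {len(dataset.disease_ids)})"
        )
    rng = np.random.default_rng(seed_seq)
    removals = sample_removals(dataset.disease_ids, query_disease, j, m_runs, rng)
    runs = []
    for i, removed in enumerate(removals, start=1):
        reduced = train_full.drop_diseases(set(removed))
        model = fit(reduced, epsilon=config.epsilon, cost=config.cost, seed=config.seed)
        table = score_disease(model, query_disease, dataset, drug_sim, disease_sim)
        top = top_candidates(table, config.k)
        runs.append(
            PerturbationRun(
                regime=j, run_index=i, removed_diseases=removed, top_k=top.drug_set
            )
        )
    return runs


def regime_stability(
    runs: Sequence[PerturbationRun], drugs: Sequence[str], variant: str = "sd"
) -> tuple[pd.Series, pd.Series]:
    """Per-drug S_j and eligibility (appeared in >= 1 run of the regime)."""
    ind = np.array([[1.0 if r in run.top_k else 0.0 for run in runs] for r in drugs])
    sj = pd.Series(
        [stability_score(row, variant) for row in ind], index=list(drugs), dtype=float
    )
    eligible = pd.Series(ind.sum(axis=1) > 0, index=list(drugs))
    return sj, eligible


def stable_candidates(
    sj_by_regime: Mapping[int, pd.Series],
    eligible_by_regime: Mapping[int, pd.Series],
    drc: CandidateList,
    quantile_keep: float = 0.95,
) -> tuple[frozenset[str], dict[int, frozenset[str]]]:
    """DrS_j = top-`keep` fraction of eligible drugs by S_j; returns
    SDrC = DrS1 ∩ DrS2 ∩ DrS5 ∩ DrC and the per-regime sets."""
    missing = [j for j in REGIMES if j not in sj_by_regime]
    if missing:
        raise ValueError(f"missing stability for regime(s) {missing}")
    drsj: dict[int, frozenset[str]] = {}
    for j in REGIMES:
        sj = sj_by_regime[j]
        elig = eligible_by_regime[j]
        drsj[j] = frozenset(
            _keep_top_fraction(
                {drug: float(sj[drug]) for drug in sj.index if bool(elig[drug])},
                quantile_keep,
            )
        )
    sdrc = drsj[1] & drsj[2] & drsj[5] & drc.drug_set
    return frozenset(sdrc), drsj


def total_stability(
    runs: Sequence[PerturbationRun],
    drc: CandidateList,
    drugs: Sequence[str],
    variant: str = "sd",
) -> pd.Series:
    """SSDrC over M' = 3M + 1 indicators: every perturbed run plus the
    unperturbed prediction (indicator = DrC membership)."""
    values = {}
    for r in drugs:
        ind = [1.0 if r in run.top_k else 0.0 for run in runs]
        ind.append(1.0 if r in drc.drug_set else 0.0)
        values[r] = stability_score(ind, variant)
    return pd.Series(values, dtype=float).sort_index()


def potential_drugs(
    ssdrc: pd.Series, sdrc: frozenset[str], quantile_keep: float = 0.95
) -> frozenset[str]:
    """PtDr: the top-`keep` fraction of SDrC drugs ranked by total stability."""
    if not sdrc:
        logger.warning("SDrC is empty; no potential therapeutic drugs")
        return frozenset()
    return frozenset(
        _keep_top_fraction({r: float(ssdrc[r]) for r in sdrc}, quantile_keep)
    )


def screen_disease(
    dataset: Dataset,
    query_disease: str,
    config: ScreenConfig = ScreenConfig(),
    *,
    drug_sim: SimilarityMatrix | None = None,
    disease_sim: SimilarityMatrix | None = None,
    out_dir: str | Path | None = None,
) -> ScreenResult:
    """Run the full stepwise pipeline for one disease.

    Randomness: a master seed spawns one deterministic substream per
    regime, so regimes are independently reproducible.  With ``out_dir``
    set, candidates.tsv, stability.tsv, ptdr.tsv and a run-manifest JSON
    are written.
    """
    if query_disease not in dataset.diseases:
        raise KeyError(f"unknown disease {query_disease!r}")
    if drug_sim is None:
        drug_sim = entity_similarity(dataset.profiles(EntityKind.DRUG), dataset.drug_space)
    if disease_sim is None:
        disease_sim = entity_similarity(
            dataset.profiles(EntityKind.DISEASE), dataset.disease_space
        )

    train = build_training_matrix(
        dataset, drug_sim, disease_sim, negative_policy=config.negative_policy, seed=config.seed
    )
    model = fit(train, epsilon=config.epsilon, cost=config.cost, seed=config.seed)
    score_table = score_disease(model, query_disease, dataset, drug_sim, disease_sim)
    drc = top_candidates(score_table, config.k)

    master = np.random.SeedSequence(config.seed)
    regime_seeds = dict(zip(REGIMES, master.spawn(len(REGIMES))))
    all_runs: list[PerturbationRun] = []
    sj_by_regime: dict[int, pd.Series] = {}
    eligible_by_regime: dict[int, pd.Series] = {}
    drug_universe = sorted(
        set(dataset.drug_ids)
    )  # stability reported for every drug; non-candidates are simply never in a top-k
    for j in REGIMES:
        runs = run_perturbations(
            dataset, train, query_disease, drug_sim, disease_sim,
            j, config.m_runs, regime_seeds[j], config,
        )
        all_runs.extend(runs)
        sj_by_regime[j], eligible_by_regime[j] = regime_stability(
            runs, drug_universe, config.stability_variant
        )

    sdrc, drsj = stable_candidates(
        sj_by_regime, eligible_by_regime, drc, config.quantile_keep
    )
    ssdrc = total_stability(all_runs, drc, drug_universe, config.stability_variant)
    ptdr = potential_drugs(ssdrc, sdrc, config.quantile_keep)

    stability = pd.DataFrame(
        {
            "S1": sj_by_regime[1],
            "S2": sj_by_regime[2],
            "S5": sj_by_regime[5],
            "SSDrC": ssdrc,
            "in_DrC": [r in drc.drug_set for r in drug_universe],
            "in_DrS1": [r in drsj[1] for r in drug_universe],
            "in_DrS2": [r in drsj[2] for r in drug_universe],
            "in_DrS5": [r in drsj[5] for r in drug_universe],
            "in_SDrC": [r in sdrc for r in drug_universe],
            "in_PtDr": [r in ptdr for r in drug_universe],
        },
        index=pd.Index(drug_universe, name="drug_id"),
    )

    result = ScreenResult(
        disease_id=query_disease,
        config=config,
        candidates=drc,
        runs=tuple(all_runs),
        stability=stability,
        sdrc=sdrc,
        ptdr=ptdr,
        score_table=score_table,
    )
    if out_dir is not None:
        write_screen_outputs(result, out_dir)
    return result


def write_screen_outputs(result: ScreenResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cand = pd.DataFrame(
        {
            "rank": range(1, len(result.candidates.drugs) + 1),
            "drug_id": result.candidates.drugs,
            "score": result.candidates.scores,
        }
    )
    cand.to_csv(out / "candidates.tsv", sep="\t", index=False)
    result.stability.to_csv(out / "stability.tsv", sep="\t")
    pd.DataFrame({"drug_id": sorted(result.ptdr)}).to_csv(
        out / "ptdr.tsv", sep="\t", index=False
    )
    manifest = {
        "disease_id": result.disease_id,
        "config": {
            "k": result.config.k,
            "m_runs": result.config.m_runs,
            "quantile_keep": result.config.quantile_keep,
            "epsilon": result.config.epsilon,
            "cost": result.config.cost,
            "negative_policy": result.config.negative_policy,
            "stability_variant": result.config.stability_variant,
            "seed": result.config.seed,
        },
        "n_runs": len(result.runs),
        "n_drc": len(result.candidates.drugs),
        "n_sdrc": len(result.sdrc),
        "n_ptdr": len(result.ptdr),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
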