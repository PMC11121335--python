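"""Desk-scale synthetic benchmark generator.

Emulates the statistical structure the method relies on, without any real
database content:

* diseases fall into clusters that share a core pool of pathogenic genes
  and pathways (``within_cluster_gene_overlap`` controls how much of each
  disease's profile comes from the cluster core);
* each disease has a few *true* therapeutic drugs whose target-gene sets
  are drawn to overlap that disease's genes at ``therapeutic_target_overlap``
  (and analogously for pathways), plus background drugs drawn uniformly;
* only ``observed_fraction`` of the true associations are revealed as the
  "known" table; the remainder is the held-out truth used for recovery
  evaluation and is never written into the dataset manifest;
* ``noise_feature_rate`` is the probability that a planted (cluster-core or
  disease-matched) feature is replaced by a uniform random one, degrading
  the signal smoothly toward noise.

Everything is reproducible from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .data_model import (
    AssociationTable,
    Dataset,
    EntityKind,
    assemble_dataset,
    build_profiles,
    write_associations,
    write_gmt,
    write_manifest,
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_diseases: int = 20
    n_drugs: int = 100
    n_genes: int = 500
    n_pathways: int = 120
    n_clusters: int = 4
    genes_per_disease: int = 12
    pathways_per_disease: int = 8
    targets_per_drug: int = 15
    pathways_per_drug: int = 10
    therapeutic_per_disease: int = 3
    within_cluster_gene_overlap: float = 0.6
    within_cluster_pathway_overlap: float = 0.6
    therapeutic_target_overlap: float = 0.6
    observed_fraction: float = 0.7
    noise_feature_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_diseases", "n_drugs", "n_genes", "n_pathways", "n_clusters",
            "genes_per_disease", "pathways_per_disease",
            "targets_per_drug", "pathways_per_drug", "therapeutic_per_disease",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "within_cluster_gene_overlap", "within_cluster_pathway_overlap",
            "therapeutic_target_overlap", "observed_fraction", "noise_feature_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genes_per_disease > self.n_genes:
            raise ValueError("genes_per_disease exceeds n_genes")
        if self.pathways_per_disease > self.n_pathways:
            raise ValueError("pathways_per_disease exceeds n_pathways")
        if self.targets_per_drug > self.n_genes:
            raise ValueError("targets_per_drug exceeds n_genes")
        if self.pathways_per_drug > self.n_pathways:
            raise ValueError("pathways_per_drug exceeds n_pathways")
        n_match = int(np.ceil(self.therapeutic_target_overlap * self.targets_per_drug))
        if n_match > self.genes_per_disease:
            raise ValueError(
                "therapeutic overlap requires more matched targets than the disease has genes"
            )
        if self.therapeutic_per_disease * self.n_diseases > self.n_drugs:
            raise ValueError("not enough drugs for the requested therapeutic assignments")


@dataclass(frozen=True)
class SyntheticDataset:
    dataset: Dataset
    truth: frozenset[tuple[str, str]]
    holdout: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        known = self.dataset.associations.pairs
        if not known <= self.truth:
            raise ValueError("known associations must be a subset of the truth")
        if self.holdout & known:
            raise ValueError("holdout overlaps the known table")


def _width(n: int) -> int:
    return max(2, len(str(n)))


def _sample_with_noise(
    rng: np.random.Generator,
    planted_pool: np.ndarray,
    n_planted: int,
    universe: int,
    total: int,
    noise_rate: float,
) -> frozenset[int]:
    """`n_planted` features from the pool (each replaced by a uniform draw
    with prob `noise_rate`), topped up to `total` with uniform draws."""
    chosen: set[int] = set()
    planted = rng.choice(planted_pool, size=min(n_planted, len(planted_pool)), replace=False)
    for f in planted:
        if rng.random() < noise_rate:
            continue  # dropped; replaced by a background draw below
        chosen.add(int(f))
    while len(chosen) < total:
        chosen.add(int(rng.integers(universe)))
    return frozenset(chosen)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a synthetic dataset with planted held-out associations."""
    rng = np.random.default_rng(config.seed)
    dw, rw = _width(config.n_diseases), _width(config.n_drugs)
    disease_ids = [f"D{i:0{dw}d}" for i in range(1, config.n_diseases + 1)]
    drug_ids = [f"R{i:0{rw}d}" for i in range(1, config.n_drugs + 1)]
    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    pathways = [f"P{i:04d}" for i in range(1, config.n_pathways + 1)]

    # cluster cores: disjoint gene/pathway pools, one per cluster
    core_size_g = max(
        config.genes_per_disease, min(config.n_genes // config.n_clusters, 2 * config.genes_per_disease)
    )
    core_size_p = max(
        config.pathways_per_disease,
        min(config.n_pathways // config.n_clusters, 2 * config.pathways_per_disease),
    )
    gene_perm = rng.permutation(config.n_genes)
    path_perm = rng.permutation(config.n_pathways)
    cores_g = [
        gene_perm[c * core_size_g : (c + 1) * core_size_g] for c in range(config.n_clusters)
    ]
    cores_p = [
        path_perm[c * core_size_p : (c + 1) * core_size_p] for c in range(config.n_clusters)
    ]

    disease_genes: dict[str, frozenset[str]] = {}
    disease_paths: dict[str, frozenset[str]] = {}
    disease_gene_idx: dict[str, np.ndarray] = {}
    disease_path_idx: dict[str, np.ndarray] = {}
    for i, did in enumerate(disease_ids):
        c = i % config.n_clusters
        n_core_g = int(round(config.within_cluster_gene_overlap * config.genes_per_disease))
        n_core_p = int(round(config.within_cluster_pathway_overlap * config.pathways_per_disease))
        g_idx = _sample_with_noise(
            rng, cores_g[c], n_core_g, config.n_genes,
            config.genes_per_disease, config.noise_feature_rate,
        )
        p_idx = _sample_with_noise(
            rng, cores_p[c], n_core_p, config.n_pathways,
            config.pathways_per_disease, config.noise_feature_rate,
        )
        disease_gene_idx[did] = np.array(sorted(g_idx))
        disease_path_idx[did] = np.array(sorted(p_idx))
        disease_genes[did] = frozenset(genes[k] for k in g_idx)
        disease_paths[did] = frozenset(pathways[k] for k in p_idx)

    # first therapeutic_per_disease * n_diseases drugs are planted therapeutics
    truth: set[tuple[str, str]] = set()
    drug_genes: dict[str, frozenset[str]] = {}
    drug_paths: dict[str, frozenset[str]] = {}
    n_ther = config.therapeutic_per_disease * config.n_diseases
    n_match_g = int(np.ceil(config.therapeutic_target_overlap * config.targets_per_drug))
    n_match_p = int(np.ceil(config.therapeutic_target_overlap * config.pathways_per_drug))
    for k, rid in enumerate(drug_ids):
        if k < n_ther:
            did = disease_ids[k % config.n_diseases]
            truth.add((did, rid))
            g_idx = _sample_with_noise(
                rng, disease_gene_idx[did], n_match_g, config.n_genes,
                config.targets_per_drug, config.noise_feature_rate,
            )
            p_idx = _sample_with_noise(
                rng, disease_path_idx[did], min(n_match_p, len(disease_path_idx[did])),
                config.n_pathways, config.pathways_per_drug, config.noise_feature_rate,
            )
        else:
            g_idx = frozenset(
                int(v) for v in rng.choice(config.n_genes, size=config.targets_per_drug, replace=False)
            )
            p_idx = frozenset(
                int(v)
                for v in rng.choice(config.n_pathways, size=config.pathways_per_drug, replace=False)
            )
        drug_genes[rid] = frozenset(genes[i] for i in g_idx)
        drug_paths[rid] = frozenset(pathways[i] for i in p_idx)

    truth_sorted = sorted(truth)
    n_known = int(round(config.observed_fraction * len(truth_sorted)))
    known_idx = rng.choice(len(truth_sorted), size=n_known, replace=False)
    known = frozenset(truth_sorted[i] for i in known_idx)
    holdout = frozenset(truth) - known

    diseases = build_profiles(EntityKind.DISEASE, disease_genes, disease_paths)
    drugs = build_profiles(EntityKind.DRUG, drug_genes, drug_paths)
    associations = AssociationTable(pairs=known, source={p: "synthetic" for p in known})
    dataset = assemble_dataset(diseases, drugs, associations)
    return SyntheticDataset(dataset=dataset, truth=frozenset(truth), holdout=holdout)


def generate_null(config: SyntheticConfig) -> SyntheticDataset:
    """Null control: no cluster structure and no drug-disease target overlap,
    so scores carry no signal about the held-out truth."""
    null_cfg = replace(
        config,
        within_cluster_gene_overlap=0.0,
        within_cluster_pathway_overlap=0.0,
        therapeutic_target_overlap=0.0,
    )
    return generate(null_cfg)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write the GMT/TSV files the data model reads plus a manifest.

    Truth and holdout tables are written alongside for evaluation only and
    are deliberately not referenced by the manifest (leakage guard).
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = ds.dataset
    write_gmt({e: p.genes for e, p in d.diseases.items()}, out / "disease_genes.gmt")
    write_gmt({e: p.pathways for e, p in d.diseases.items()}, out / "disease_pathways.gmt")
    write_gmt({e: p.genes for e, p in d.drugs.items()}, out / "drug_genes.gmt")
    write_gmt({e: p.pathways for e, p in d.drugs.items()}, out / "drug_pathways.gmt")
    write_associations(d.associations, out / "associations.tsv")
    for name, pairs in (("truth.tsv", ds.truth), ("holdout.tsv", ds.holdout)):
        with (out / name).open("w", encoding="utf-8") as fh:
            fh.write("disease_id\tdrug_id\n")
            for dd, rr in sorted(pairs):
                fh.write(f"{dd}\t{rr}\n")
    manifest_path = out / "manifest.json"
    write_manifest(
        {
            "disease_genes": "disease_genes.gmt",
            "disease_pathways": "disease_pathways.gmt",
            "drug_genes": "drug_genes.gmt",
            "drug_pathways": "drug_pathways.gmt",
            "associations": "associations.tsv",
        },
        manifest_path,
    )
    return manifest_path
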