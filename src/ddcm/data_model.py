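"""Dataset model: entity profiles, feature universes, and association tables.

Diseases are described by pathogenic-gene and disease-pathway sets, drugs by
target-gene and drug-pathway sets.  Gene/pathway memberships are read from
GMT files (one per entity kind and level), known therapeutic disease-drug
pairs from a TSV.  Disease and drug features live in *separate* universes:
a disease gene vector is never compared to a drug gene vector.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


class EntityKind(str, Enum):
    DISEASE = "disease"
    DRUG = "drug"


class Level(str, Enum):
    GENE = "gene"
    PATHWAY = "pathway"


class GmtParseError(ValueError):
    """A GMT line violates the format (field count, empty member list)."""


class ValidationError(ValueError):
    """Dataset-level consistency violation (duplicates, unknown IDs)."""


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered, deduplicated feature universes for one entity kind.

    Order is fixed (lexicographic) at construction so every binary
    vectorization, and hence every similarity matrix, is bit-reproducible.
    """

    gene_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, ids in (("gene_ids", self.gene_ids), ("pathway_ids", self.pathway_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate identifiers in {name}")

    def ids(self, level: Level) -> tuple[str, ...]:
        return self.gene_ids if level == Level.GENE else self.pathway_ids

    def index(self, level: Level) -> dict[str, int]:
        return {fid: i for i, fid in enumerate(self.ids(level))}


@dataclass(frozen=True)
class EntityProfile:
    """One disease or drug with its gene set and pathway set."""

    entity_id: str
    entity_kind: EntityKind
    genes: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.genes and not self.pathways:
            raise ValidationError(
                f"profile {self.entity_id!r}: both gene and pathway sets are empty"
            )

    def members(self, level: Level) -> frozenset[str]:
        return self.genes if level == Level.GENE else self.pathways


@dataclass(frozen=True)
class AssociationTable:
    """Known therapeutic (disease_id, drug_id) pairs, deduplicated."""

    pairs: frozenset[tuple[str, str]]
    source: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def diseases(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def drugs_for(self, disease_id: str) -> set[str]:
        return {r for d, r in self.pairs if d == disease_id}


@dataclass(frozen=True)
class Dataset:
    """Assembled, validated dataset ready for similarity computation."""

    diseases: Mapping[str, EntityProfile]
    drugs: Mapping[str, EntityProfile]
    disease_space: FeatureSpace
    drug_space: FeatureSpace
    associations: AssociationTable

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.diseases))

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.drugs))

    def profiles(self, kind: EntityKind) -> list[EntityProfile]:
        table = self.diseases if kind == EntityKind.DISEASE else self.drugs
        return [table[eid] for eid in sorted(table)]

    def space(self, kind: EntityKind) -> FeatureSpace:
        return self.disease_space if kind == EntityKind.DISEASE else self.drug_space


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file: ``set_name<TAB>description<TAB>member...`` per line.

    Returns a mapping from set name to member set.  Lines with fewer than
    three fields, empty member lists, or duplicate set names are rejected.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            members = [m for m in fields[2:] if m]
            if not members:
                raise GmtParseError(f"{path}:{lineno}: set {name!r} has no members")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name in sorted(sets):
            members = sorted(sets[name])
            fh.write("\t".join([name, description, *members]) + "\n")


def read_associations(path: str | Path) -> AssociationTable:
    """Read a TSV with header columns disease_id, drug_id[, source].

    Duplicate pairs are dropped (count logged).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: empty association file")
    header = lines[0].split("\t")
    required = ["disease_id", "drug_id"]
    for col in required:
        if col not in header:
            raise ValidationError(f"{path}: missing required column {col!r} (header: {header})")
    di, ri = header.index("disease_id"), header.index("drug_id")
    si = header.index("source") if "source" in header else None
    pairs: set[tuple[str, str]] = set()
    source: dict[tuple[str, str], str] = {}
    dropped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) <= max(di, ri):
            raise ValidationError(f"{path}:{lineno}: too few fields")
        pair = (fields[di], fields[ri])
        if pair in pairs:
            dropped += 1
            continue
        pairs.add(pair)
        if si is not None and len(fields) > si:
            source[pair] = fields[si]
    if dropped:
        logger.info("read_associations: dropped %d duplicate pair(s) from %s", dropped, path)
    return AssociationTable(pairs=frozenset(pairs), source=source)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("disease_id\tdrug_id\tsource\n")
        for d, r in sorted(table.pairs):
            fh.write(f"{d}\t{r}\t{table.source.get((d, r), '')}\n")


def build_profiles(
    kind: EntityKind,
    gene_sets: Mapping[str, frozenset[str]] | None,
    pathway_sets: Mapping[str, frozenset[str]] | None,
) -> dict[str, EntityProfile]:
    gene_sets = gene_sets or {}
    pathway_sets = pathway_sets or {}
    ids = sorted(set(gene_sets) | set(pathway_sets))
    if not ids:
        raise ValidationError(f"no {kind.value} profiles provided")
    profiles = {}
    for eid in ids:
        profiles[eid] = EntityProfile(
            entity_id=eid,
            entity_kind=kind,
            genes=frozenset(gene_sets.get(eid, frozenset())),
            pathways=frozenset(pathway_sets.get(eid, frozenset())),
        )
    return profiles


def assemble_dataset(
    disease_profiles: Mapping[str, EntityProfile],
    drug_profiles: Mapping[str, EntityProfile],
    associations: AssociationTable,
    *,
    lenient: bool = False,
) -> Dataset:
    """Build feature spaces from observed memberships and cross-validate.

    The feature universe for each (entity kind, level) is the lexicographic
    union of all observed memberships.  Associations naming unknown entities
    raise (or are dropped with a warning under ``lenient``).  Entities that
    carry only one of the two levels are reported; the similarity layer
    falls back to the available level for them.
    """
    if not disease_profiles or not drug_profiles:
        raise ValidationError("profile collections must be non-empty")

    def space(profiles: Mapping[str, EntityProfile]) -> FeatureSpace:
        genes: set[str] = set()
        pathways: set[str] = set()
        for p in profiles.values():
            genes |= p.genes
            pathways |= p.pathways
        return FeatureSpace(tuple(sorted(genes)), tuple(sorted(pathways)))

    disease_space = space(disease_profiles)
    drug_space = space(drug_profiles)

    for profiles, kind in ((disease_profiles, "disease"), (drug_profiles, "drug")):
        for p in profiles.values():
            missing = [lvl.value for lvl in Level if not p.members(lvl)]
            if missing:
                logger.warning("%s %s: %s level missing", kind, p.entity_id, "/".join(missing))

    offenders = sorted(
        pair
        for pair in associations.pairs
        if pair[0] not in disease_profiles or pair[1] not in drug_profiles
    )
    if offenders:
        if not lenient:
            raise ValidationError(
                f"associations reference unknown entities: {offenders[:10]}"
                + (" ..." if len(offenders) > 10 else "")
            )
        logger.warning("dropping %d association(s) with unknown entities", len(offenders))
        keep = associations.pairs - set(offenders)
        associations = AssociationTable(
            pairs=frozenset(keep),
            source={p: s for p, s in associations.source.items() if p in keep},
        )

    return Dataset(
        diseases=dict(disease_profiles),
        drugs=dict(drug_profiles),
        disease_space=disease_space,
        drug_space=drug_space,
        associations=associations,
    )


MANIFEST_KEYS = (
    "disease_genes",
    "disease_pathways",
    "drug_genes",
    "drug_pathways",
    "associations",
)


def load_dataset(manifest_path: str | Path, *, lenient: bool = False) -> Dataset:
    """Load a dataset from a JSON manifest listing the five input files.

    Manifest keys: disease_genes, disease_pathways, drug_genes,
    drug_pathways (GMT; pathway entries optional) and associations (TSV).
    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    base = manifest_path.parent

    def resolve(key: str) -> Path | None:
        val = manifest.get(key)
        return None if val is None else (base / val)

    def load_gmt(key: str) -> dict[str, frozenset[str]] | None:
        p = resolve(key)
        return None if p is None else read_gmt(p)

    diseases = build_profiles(
        EntityKind.DISEASE, load_gmt("disease_genes"), load_gmt("disease_pathways")
    )
    drugs = build_profiles(EntityKind.DRUG, load_gmt("drug_genes"), load_gmt("drug_pathways"))
    assoc_path = resolve("associations")
    if assoc_path is None:
        raise ValidationError("manifest missing 'associations' entry")
    associations = read_associations(assoc_path)
    lenient = bool(manifest.get("lenient", lenient))
    return assemble_dataset(diseases, drugs, associations, lenient=lenient)


def write_manifest(paths: Mapping[str, str], path: str | Path, **options) -> None:
    doc = {k: paths[k] for k in MANIFEST_KEYS if k in paths}
    doc.update(options)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")
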