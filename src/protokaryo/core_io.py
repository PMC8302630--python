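"""Data model, readers/writers and validation.

The coordinate backbone of every analysis here is *gene order*, not base
pairs: a genome is a set of scaffolds, each carrying an ordered list of
genes (``order_index`` 0..n-1, assigned by ascending start coordinate).
Homology evidence is a set of unordered gene-id pairs, classified as
orthologue (genes in different species) or paralogue (same species) purely
from the species of the two members.

File formats are plain TSV throughout: gene tables
(species, scaffold, start, end, gene_id), pair lists (two gene-id columns,
optional score), segment tables (segment_id, species, scaffold,
first_index, last_index), linkage-marker tables
(marker_id, species, scaffold, position, linkage_group).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTable",
    "HomologyPairSet",
    "Segment",
    "Segmentation",
    "LinkageMarkerTable",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "read_gene_table",
    "read_homology_pairs",
    "read_segments",
    "read_linkage_markers",
    "write_gene_table",
    "write_homology_pairs",
    "write_segments",
    "write_report",
]


class FormatError(ValueError):
    """Input file does not match the expected layout."""


class ValidationError(ValueError):
    """Input violates a data-model invariant."""


class ConfigurationError(ValueError):
    """Configuration inconsistent with the supplied data."""


GENE_COLUMNS = ["species", "scaffold", "start", "end", "gene_id"]
VALID_ROLES = {"reference", "post_wgd", "comparator"}


@dataclass
class GeneTable:
    """Ordered genes per scaffold per species.

    ``df`` has columns species, scaffold, start, end, gene_id, order_index,
    sorted by (species, scaffold, order_index).  ``roles`` maps each species
    to "reference" (non-duplicated outgroup anchoring the mixture model),
    "post_wgd" (genome carrying the duplications under study) or
    "comparator" (used only for segmentation labelling).
    """

    df: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in GENE_COLUMNS + ["order_index"] if c not in df.columns]
        if missing:
            raise FormatError(f"gene table missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].head(3).tolist()
            raise ValidationError(f"duplicate gene_id values (e.g. {dups})")
        for (sp, sc), grp in df.groupby(["species", "scaffold"], sort=False):
            idx = sorted(grp["order_index"].tolist())
            if idx != list(range(len(grp))):
                raise ValidationError(
                    f"order_index of {sp}/{sc} is not a 0..n-1 permutation"
                )
        has_coords = df["start"].notna() & df["end"].notna()
        bad = df.loc[has_coords & (df["end"] <= df["start"])]
        if len(bad):
            raise ValidationError(
                f"end <= start for genes {bad['gene_id'].head(3).tolist()}"
            )
        for sp, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ConfigurationError(f"unknown role {role!r} for species {sp!r}")
        unknown = set(self.roles) - set(df["species"].unique())
        if unknown:
            raise ConfigurationError(f"role_map species not in table: {sorted(unknown)}")

    @property
    def species_list(self) -> list[str]:
        return list(dict.fromkeys(self.df["species"]))

    def species_of_role(self, role: str) -> list[str]:
        return [s for s in self.species_list if self.roles.get(s) == role]

    def genes_of(self, species: str) -> pd.DataFrame:
        return self.df[self.df["species"] == species]

    def gene_species(self) -> dict[str, str]:
        return dict(zip(self.df["gene_id"], self.df["species"]))

    def scaffold_genes(self, species: str, scaffold: str) -> list[str]:
        g = self.df[(self.df["species"] == species) & (self.df["scaffold"] == scaffold)]
        return g.sort_values("order_index")["gene_id"].tolist()


@dataclass
class HomologyPairSet:
    """Unordered, deduplicated orthologue and paralogue gene-id pairs.

    Classification is a pure function of the species of the two genes:
    different species -> orthologue, same species -> paralogue.
    """

    orthologues: set[tuple[str, str]] = field(default_factory=set)
    paralogues: set[tuple[str, str]] = field(default_factory=set)
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple],
        gene_species: Mapping[str, str],
        drop_unresolvable: bool = True,
    ) -> "HomologyPairSet":
        out = cls()
        dropped = 0
        for row in pairs:
            a, b = row[0], row[1]
            score = float(row[2]) if len(row) > 2 and row[2] is not None else None
            if a == b:
                logger.warning("self-pair %r dropped", a)
                continue
            sa = gene_species.get(a)
            sb = gene_species.get(b)
            if sa is None or sb is None:
                if not drop_unresolvable:
                    raise ValidationError(f"pair ({a}, {b}) has unknown gene id")
                dropped += 1
                continue
            key = cls._key(a, b)
            (out.paralogues if sa == sb else out.orthologues).add(key)
            if score is not None:
                out.scores[key] = score
        if dropped:
            logger.info("dropped %d pairs with unresolvable gene ids", dropped)
        out.n_dropped = dropped
        return out

    def paralogues_of(self, species: str, gene_species: Mapping[str, str]):
        return {
            p for p in self.paralogues if gene_species.get(p[0]) == species
        }

    def orthologues_between(self, sp_a: str, sp_b: str, gene_species: Mapping[str, str]):
        keep = set()
        for a, b in self.orthologues:
            sp = {gene_species.get(a), gene_species.get(b)}
            if sp == {sp_a, sp_b}:
                keep.add((a, b))
        return keep

    def score(self, a: str, b: str, default: float = 0.0) -> float:
        return self.scores.get(self._key(a, b), default)


@dataclass(frozen=True)
class Segment:
    """Contiguous run of genes on one scaffold: closed ordinal interval
    [first_index, last_index]."""

    segment_id: int
    species: str
    scaffold: str
    first_index: int
    last_index: int

    def __post_init__(self):
        if self.last_index < self.first_index:
            raise ValidationError("segment with last_index < first_index")

    @property
    def n_genes(self) -> int:
        return self.last_index - self.first_index + 1


@dataclass
class Segmentation:
    """Partition of each included scaffold into segments that tile it."""

    segments: list[Segment]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        by_scaffold: dict[tuple[str, str], list[Segment]] = {}
        ids = [s.segment_id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate segment ids")
        for seg in self.segments:
            by_scaffold.setdefault((seg.species, seg.scaffold), []).append(seg)
        for (sp, sc), segs in by_scaffold.items():
            segs = sorted(segs, key=lambda s: s.first_index)
            if segs[0].first_index != 0:
                raise ValidationError(f"{sp}/{sc}: segments do not start at 0")
            for a, b in zip(segs, segs[1:]):
                if b.first_index != a.last_index + 1:
                    raise ValidationError(f"{sp}/{sc}: segments do not tile")

    @classmethod
    def from_scaffolds(cls, gene_table: "GeneTable", species) -> "Segmentation":
        """Trivial segmentation: every scaffold of the given species is one
        segment (used when scaffolds already approximate synteny blocks)."""
        if isinstance(species, str):
            species = [species]
        segs = []
        sid = 0
        for sp in species:
            counts = gene_table.genes_of(sp).groupby("scaffold").size()
            for scaffold in sorted(counts.index):
                segs.append(Segment(sid, sp, scaffold, 0, int(counts[scaffold]) - 1))
                sid += 1
        return cls(segs)

    def for_species(self, species: str) -> list[Segment]:
        return [s for s in self.segments if s.species == species]

    def gene_to_segment(self, gene_table: GeneTable) -> dict[str, int]:
        """Map every gene covered by a segment to its segment_id."""
        out: dict[str, int] = {}
        for seg in self.segments:
            genes = gene_table.scaffold_genes(seg.species, seg.scaffold)
            for i in range(seg.first_index, seg.last_index + 1):
                out[genes[i]] = seg.segment_id
        return out


@dataclass
class LinkageMarkerTable:
    """Markers placed on scaffolds of one species, each tied to one linkage
    group (df columns: marker_id, species, scaffold, position, linkage_group)."""

    df: pd.DataFrame

    def __post_init__(self):
        need = ["marker_id", "species", "scaffold", "position", "linkage_group"]
        missing = [c for c in need if c not in self.df.columns]
        if missing:
            raise FormatError(f"marker table missing columns: {missing}")
        if self.df["marker_id"].duplicated().any():
            raise ValidationError("duplicate marker ids")


# ---------------------------------------------------------------------------
# readers / writers


def read_gene_table(path, role_map: Mapping[str, str] | None = None) -> GeneTable:
    """Read a TSV gene table; order_index is assigned by ascending start
    within each scaffold (stable on ties)."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "scaffold": str, "gene_id": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df.sort_values(["species", "scaffold", "start"], kind="stable").reset_index(drop=True)
    df["order_index"] = df.groupby(["species", "scaffold"], sort=False).cumcount()
    return GeneTable(df=df, roles=dict(role_map or {}))


def write_gene_table(table: GeneTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_homology_pairs(path, gene_table: GeneTable) -> HomologyPairSet:
    """Read a 2- or 3-column TSV of gene-id pairs (+optional score); pairs
    referencing genes absent from the table are dropped with a logged count."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected >= 2 columns")
    rows = df.itertuples(index=False, name=None)
    return HomologyPairSet.from_pairs(rows, gene_table.gene_species())


def write_homology_pairs(pairs: HomologyPairSet, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs.orthologues | pairs.paralogues):
            s = pairs.scores.get((a, b))
            fh.write(f"{a}\t{b}" + (f"\t{s}" if s is not None else "") + "\n")


SEGMENT_COLUMNS = ["segment_id", "species", "scaffold", "first_index", "last_index"]


def read_segments(path) -> Segmentation:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "scaffold": str})
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    segs = [
        Segment(int(r.segment_id), r.species, r.scaffold, int(r.first_index), int(r.last_index))
        for r in df.itertuples()
    ]
    return Segmentation(segs)


def write_segments(segmentation: Segmentation, path) -> None:
    pd.DataFrame(
        [
            (s.segment_id, s.species, s.scaffold, s.first_index, s.last_index)
            for s in segmentation.segments
        ],
        columns=SEGMENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_linkage_markers(path) -> LinkageMarkerTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["position"] = df["position"].astype(int)
    return LinkageMarkerTable(df)


def write_report(result_bundle: Mapping, out_dir) -> dict[str, Path]:
    """Write the standard report files for a pipeline run.

    ``result_bundle`` may contain: "assignments" (DataFrame: segment ->
    ancestral chromosome + confidence), "proto_chromosomes" (DataFrame:
    proto-chromosome membership), "multiplicity" (DataFrame), "metadata"
    (JSON-serializable dict: config, seed, convergence diagnostics).
    Missing parts are written as headers-only files so a report is always
    complete and machine-readable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    defaults = {
        "assignments": ["segment_id", "species", "ancestral_chromosome", "confidence"],
        "proto_chromosomes": ["proto_chromosome", "ancestral_chromosome", "segment_id",
                              "species", "n_genes"],
        "multiplicity": ["ancestral_chromosome", "multiplicity", "n_genes", "fraction"],
    }
    for name, cols in defaults.items():
        df = result_bundle.get(name)
        if df is None:
            df = pd.DataFrame(columns=cols)
        paths[name] = out_dir / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)

    meta = dict(result_bundle.get("metadata", {}))
    paths["metadata"] = out_dir / "run_metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return paths
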