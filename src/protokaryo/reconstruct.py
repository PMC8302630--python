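"""Refining macrosynteny groups into proto-chromosomes.

After the mixture model assigns every post-WGD segment to an ancestral
chromosome, the segments of one ancestral chromosome still mix several
duplicated descendant chromosomes.  Which segments belong to the same
descendant is decided by an exhaustive set-partition search constrained and
seeded by homology evidence:

* paralogous segment pairs (hypergeometric tail < 1e-5) must NOT share a
  descendant chromosome — duplicated copies repel;
* orthologous segment pairs between species, segments on one scaffold, and
  segments sharing a linkage group attract — they are pre-merged into
  clusters by greedy single linkage, refusing any merge that would join a
  forbidden pair;
* clusters with fewer than five genes are dropped as unreconstructable;
* all set partitions of the remaining clusters are enumerated (restricted
  growth strings, pruned by the forbidden pairs; the unconstrained count is
  the Bell number) and each partition is scored by the product of
  hypergeometric tails: per species, enrichment of paralogue pairs between
  different blocks; per species pair, enrichment of orthologue pairs within
  blocks.  The most significant (smallest) product wins.

Groups with more clusters than the enumeration cap are kept as a single
proto-chromosome and flagged — beyond ~15 clusters the Bell number makes
the search infeasible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    ConfigurationError,
    GeneTable,
    HomologyPairSet,
    LinkageMarkerTable,
    Segmentation,
)
from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "bell_number",
    "GroupContext",
    "ConstraintGraph",
    "build_group_context",
    "build_constraints",
    "cluster_segments",
    "drop_small_clusters",
    "enumerate_partitions",
    "score_partition",
    "select_optimal_partition",
    "filter_subgroups",
    "multiplicity_table",
    "reconstruct_group",
    "reconstruct_all",
]


def bell_number(n: int) -> int:
    """Exact Bell number B_n (count of set partitions of n items) by the
    Bell-triangle recurrence."""
    if n < 0:
        raise ValueError("n must be >= 0")
    row = [1]
    for _ in range(n):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        row = new
    return row[0]


@dataclass
class GroupContext:
    """Everything needed to reconstruct the descendants of one ancestral
    chromosome: its member segments with their genes, plus genome-wide pair
    totals for the hypergeometric nulls."""

    ancestral_chromosome: int
    segment_species: dict[int, str]
    segment_genes: dict[int, list[str]]
    genome_gene_counts: dict[str, int]
    paralogues: dict[str, set[tuple[str, str]]]             # per species, genome-wide
    orthologues: dict[tuple[str, str], set[tuple[str, str]]]  # per species pair
    gene_species: dict[str, str] = field(default_factory=dict)

    @property
    def segment_ids(self) -> list[int]:
        return sorted(self.segment_species)

    def n_genes(self, seg_id: int) -> int:
        return len(self.segment_genes[seg_id])

    def species_in_group(self) -> list[str]:
        return sorted(set(self.segment_species.values()))


@dataclass
class ConstraintGraph:
    """Nodes are segment ids; ``forbidden`` pairs repel (significant
    paralogy); ``attractions`` are (tier, tail, a, b) with tier 1 =
    orthology, 2 = same scaffold, 3 = shared linkage group.  A pair that is
    both forbidden and attracting stays forbidden."""

    nodes: list[int]
    forbidden: set[frozenset]
    attractions: list[tuple[int, float, int, int]]


def build_group_context(
    gene_table: GeneTable,
    pairs: HomologyPairSet,
    segmentation: Segmentation,
    assignment: pd.DataFrame,
    ancestral_chromosome: int,
    species: Sequence[str] | None = None,
    exclude_scaffolds: Iterable[tuple[str, str]] = (),
) -> GroupContext:
    """Collect the segments assigned to one ancestral chromosome.

    ``assignment`` is the segment table from :func:`protokaryo.cvb.assign_segments`.
    ``exclude_scaffolds`` lists (species, scaffold) pairs removed before
    reconstruction (e.g. suspected haplotype duplicates).
    """
    excluded = set(exclude_scaffolds)
    gene_species = gene_table.gene_species()
    seg_by_id = {s.segment_id: s for s in segmentation.segments}
    gene_to_seg = segmentation.gene_to_segment(gene_table)

    sub = assignment[assignment["ancestral_chromosome"] == ancestral_chromosome]
    if species is not None:
        sub = sub[sub["species"].isin(list(species))]
    segment_species: dict[int, str] = {}
    segment_genes: dict[int, list[str]] = {}
    for row in sub.itertuples():
        seg = seg_by_id[row.segment_id]
        if (seg.species, seg.scaffold) in excluded:
            continue
        genes = gene_table.scaffold_genes(seg.species, seg.scaffold)
        segment_species[seg.segment_id] = seg.species
        segment_genes[seg.segment_id] = genes[seg.first_index : seg.last_index + 1]

    sp_list = sorted(set(segment_species.values()))
    genome_counts = {
        sp: int((gene_table.df["species"] == sp).sum()) for sp in sp_list
    }
    paras = {sp: pairs.paralogues_of(sp, gene_species) for sp in sp_list}
    orthos = {
        (a, b): pairs.orthologues_between(a, b, gene_species)
        for i, a in enumerate(sp_list)
        for b in sp_list[i + 1:]
    }
    return GroupContext(
        ancestral_chromosome=ancestral_chromosome,
        segment_species=segment_species,
        segment_genes=segment_genes,
        genome_gene_counts=genome_counts,
        paralogues=paras,
        orthologues=orthos,
        gene_species=gene_species,
    )


def _pair_counts_by_segment(
    pair_set: Iterable[tuple[str, str]], gene_to_seg: Mapping[str, int]
) -> dict[frozenset, int]:
    out: dict[frozenset, int] = {}
    for a, b in pair_set:
        sa, sb = gene_to_seg.get(a), gene_to_seg.get(b)
        if sa is None or sb is None or sa == sb:
            continue
        key = frozenset((sa, sb))
        out[key] = out.get(key, 0) + 1
    return out


def build_constraints(
    ctx: GroupContext,
    segmentation: Segmentation | None = None,
    markers: LinkageMarkerTable | None = None,
    gene_table: GeneTable | None = None,
    threshold: float = 1e-5,
) -> ConstraintGraph:
    """Forbidden edges from paralogue screening; attraction edges from
    orthologue screening (tier 1), same-scaffold co-membership (tier 2) and
    shared linkage groups (tier 3).  Conflicts resolve in favour of
    forbidden and are logged."""
    gene_to_seg = {
        g: sid for sid, genes in ctx.segment_genes.items() for g in genes
    }
    forbidden: set[frozenset] = set()
    attractions: list[tuple[int, float, int, int]] = []
    seg_ids = ctx.segment_ids

    # paralogy: within-species segment pairs, genome-wide null
    for sp in ctx.species_in_group():
        n_total = ctx.genome_gene_counts[sp]
        g = n_total * (n_total - 1) // 2
        m = len(ctx.paralogues[sp])
        x_counts = _pair_counts_by_segment(ctx.paralogues[sp], gene_to_seg)
        ids = [s for s in seg_ids if ctx.segment_species[s] == sp]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                n = ctx.n_genes(a) * ctx.n_genes(b)
                x = x_counts.get(frozenset((a, b)), 0)
                if x and hypergeom_tail(g, m, n, x) < threshold:
                    forbidden.add(frozenset((a, b)))

    # orthology: cross-species segment pairs
    for (sa, sb), opairs in ctx.orthologues.items():
        g = ctx.genome_gene_counts[sa] * ctx.genome_gene_counts[sb]
        m = len(opairs)
        x_counts = _pair_counts_by_segment(opairs, gene_to_seg)
        ids_a = [s for s in seg_ids if ctx.segment_species[s] == sa]
        ids_b = [s for s in seg_ids if ctx.segment_species[s] == sb]
        for a in ids_a:
            for b in ids_b:
                n = ctx.n_genes(a) * ctx.n_genes(b)
                x = x_counts.get(frozenset((a, b)), 0)
                if x:
                    tail = hypergeom_tail(g, m, n, x)
                    if tail < threshold:
                        attractions.append((1, tail, min(a, b), max(a, b)))

    # same scaffold
    if segmentation is not None:
        scaf_of = {
            s.segment_id: (s.species, s.scaffold) for s in segmentation.segments
        }
        by_scaffold: dict[tuple, list[int]] = {}
        for sid in seg_ids:
            by_scaffold.setdefault(scaf_of[sid], []).append(sid)
        for ids in by_scaffold.values():
            for i, a in enumerate(sorted(ids)):
                for b in sorted(ids)[i + 1:]:
                    attractions.append((2, 0.0, a, b))

    # shared linkage group
    if markers is not None and gene_table is not None and segmentation is not None:
        seg_of_marker: dict[str, list[int]] = {}
        gene_seg_all = segmentation.gene_to_segment(gene_table)
        for row in markers.df.itertuples():
            genes = gene_table.scaffold_genes(row.species, row.scaffold)
            if not genes:
                continue
            pos = min(int(row.position), len(genes) - 1)
            sid = gene_seg_all.get(genes[pos])
            if sid in ctx.segment_species:
                seg_of_marker.setdefault(row.linkage_group, []).append(sid)
        for ids in seg_of_marker.values():
            uniq = sorted(set(ids))
            for i, a in enumerate(uniq):
                for b in uniq[i + 1:]:
                    attractions.append((3, 0.0, a, b))

    kept = []
    for tier, tail, a, b in attractions:
        if frozenset((a, b)) in forbidden:
            logger.info(
                "segments %s-%s both paralogous and attracting: forbidden wins", a, b
            )
            continue
        kept.append((tier, tail, a, b))
    return ConstraintGraph(nodes=seg_ids, forbidden=forbidden, attractions=kept)


def cluster_segments(graph: ConstraintGraph) -> list[frozenset]:
    """Greedy single-linkage clustering respecting forbidden pairs.

    Attraction edges are processed by (tier, tail, ids); a merge is refused
    whenever the united cluster would contain a forbidden pair."""
    parent = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members: dict[int, set[int]] = {n: {n} for n in graph.nodes}
    for tier, tail, a, b in sorted(graph.attractions):
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        merged = members[ra] | members[rb]
        ok = all(
            frozenset((x, y)) not in graph.forbidden
            for x in members[ra]
            for y in members[rb]
        )
        if not ok:
            continue
        parent[rb] = ra
        members[ra] = merged
        del members[rb]
    clusters = [frozenset(v) for v in members.values()]
    return sorted(clusters, key=lambda c: sorted(c))


def drop_small_clusters(
    clusters: Sequence[frozenset], ctx: GroupContext, min_genes: int = 5
) -> list[frozenset]:
    """Remove clusters with fewer than ``min_genes`` genes (too little
    homology signal to place reliably)."""
    kept = []
    for cl in clusters:
        n = sum(ctx.n_genes(s) for s in cl)
        if n >= min_genes:
            kept.append(cl)
        else:
            logger.info("dropping cluster %s with %d genes", sorted(cl), n)
    return kept


def enumerate_partitions(
    items: Sequence, forbidden: set[frozenset] = frozenset(), max_items: int = 15
) -> Iterator[tuple[frozenset, ...]]:
    """Yield every set partition of ``items`` exactly once (restricted
    growth strings), pruning partitions that put a forbidden pair in one
    block.  Unconstrained, the number of partitions is ``bell_number(n)``.
    """
    items = list(items)
    n = len(items)
    if n > max_items:
        raise ConfigurationError(
            f"{n} clusters exceed the enumeration cap of {max_items} "
            f"(about {bell_number(n):.3g} partitions); raise max_items or "
            "keep the group unpartitioned"
        )
    if n == 0:
        yield ()
        return

    conflict = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            bad = any(
                frozenset((x, y)) in forbidden
                for x in _as_set(items[i])
                for y in _as_set(items[j])
            )
            conflict[i, j] = conflict[j, i] = bad

    rgs = np.zeros(n, dtype=np.int64)

    def rec(i: int, n_blocks: int):
        if i == n:
            blocks: list[set] = [set() for _ in range(n_blocks)]
            for idx, b in enumerate(rgs[:n]):
                blocks[b] |= _as_set(items[idx])
            yield tuple(frozenset(b) for b in blocks)
            return
        for b in range(n_blocks + 1):
            ok = all(
                not conflict[i, j] for j in range(i) if rgs[j] == b
            )
            if not ok:
                continue
            rgs[i] = b
            yield from rec(i + 1, max(n_blocks, b + 1))

    yield from rec(0, 0)


def _as_set(item) -> set:
    if isinstance(item, (set, frozenset)):
        return set(item)
    return {item}


def score_partition(
    partition: Sequence[frozenset],
    ctx: GroupContext,
    mode: str = "cyclostome",
    red_pair_rule: str | Callable = "all",
) -> float:
    """Significance product of a candidate partition of the group.

    Per species: tail probability of the observed count of paralogue pairs
    lying between different blocks (the blocks are duplicated descendants,
    so inter-block paralogy should be enriched).  Per species pair: tail
    probability of orthologue pairs lying within one block (orthologous
    segments must co-segregate).  Factors with no candidate pairs are
    neutral (1).  ``mode="gnathostome"`` restricts the paralogue factor to
    block pairs designated "red" by ``red_pair_rule`` — block pairs expected
    to share duplicated material; the default rule makes every inter-block
    pair red, which reduces to the unrestricted test."""
    if mode not in ("cyclostome", "gnathostome"):
        raise ValueError(f"unknown mode {mode!r}")
    blocks = [frozenset(b) for b in partition if b]

    def is_red(i: int, j: int) -> bool:
        if mode == "cyclostome" or red_pair_rule == "all":
            return True
        return bool(red_pair_rule(blocks[i], blocks[j]))

    gene_to_seg = {g: s for s, genes in ctx.segment_genes.items() for g in genes}
    seg_block = {s: i for i, b in enumerate(blocks) for s in b}

    log10 = 0.0
    # paralogue factors, one per species
    for sp in ctx.species_in_group():
        group_genes = [
            g
            for s, genes in ctx.segment_genes.items()
            for g in genes
            if ctx.segment_species[s] == sp
        ]
        G = len(group_genes)
        g_cs = G * (G - 1) // 2
        in_group = set(group_genes)
        p_pairs = [
            p for p in ctx.paralogues[sp] if p[0] in in_group and p[1] in in_group
        ]
        p_cs = len(p_pairs)
        # n_s: gene pairs between (red) blocks
        sizes: dict[int, int] = {}
        for g in group_genes:
            b = seg_block.get(gene_to_seg[g])
            if b is not None:
                sizes[b] = sizes.get(b, 0) + 1
        n_s = sum(
            sizes[i] * sizes[j]
            for i in sizes
            for j in sizes
            if i < j and is_red(i, j)
        )
        x_s = 0
        for a, b in p_pairs:
            ba, bb = seg_block.get(gene_to_seg[a]), seg_block.get(gene_to_seg[b])
            if ba is None or bb is None or ba == bb:
                continue
            if is_red(min(ba, bb), max(ba, bb)):
                x_s += 1
        if p_cs == 0 or n_s == 0 or n_s >= g_cs:
            logger.debug("neutral paralogue factor for %s", sp)
            continue
        log10 += math.log10(max(hypergeom_tail(g_cs, p_cs, n_s, x_s), 1e-300))

    # orthologue factors, one per species pair
    for (sa, sb), opairs in ctx.orthologues.items():
        ga = [
            g
            for s, genes in ctx.segment_genes.items()
            for g in genes
            if ctx.segment_species[s] == sa
        ]
        gb = [
            g
            for s, genes in ctx.segment_genes.items()
            for g in genes
            if ctx.segment_species[s] == sb
        ]
        g_cst = len(ga) * len(gb)
        in_a, in_b = set(ga), set(gb)
        o_pairs = [
            p
            for p in opairs
            if (p[0] in in_a and p[1] in in_b) or (p[0] in in_b and p[1] in in_a)
        ]
        o_cst = len(o_pairs)
        sizes_a: dict[int, int] = {}
        sizes_b: dict[int, int] = {}
        for g in ga:
            b = seg_block.get(gene_to_seg[g])
            if b is not None:
                sizes_a[b] = sizes_a.get(b, 0) + 1
        for g in gb:
            b = seg_block.get(gene_to_seg[g])
            if b is not None:
                sizes_b[b] = sizes_b.get(b, 0) + 1
        n_st = sum(sizes_a[i] * sizes_b.get(i, 0) for i in sizes_a)
        x_st = 0
        for a, b in o_pairs:
            ba, bb = seg_block.get(gene_to_seg[a]), seg_block.get(gene_to_seg[b])
            if ba is not None and ba == bb:
                x_st += 1
        if o_cst == 0 or n_st == 0 or n_st >= g_cst:
            logger.debug("neutral orthologue factor for %s-%s", sa, sb)
            continue
        log10 += math.log10(max(hypergeom_tail(g_cst, o_cst, n_st, x_st), 1e-300))
    return 10.0 ** log10


def select_optimal_partition(
    clusters: Sequence[frozenset],
    ctx: GroupContext,
    mode: str = "cyclostome",
    forbidden: set[frozenset] = frozenset(),
    max_items: int = 15,
    red_pair_rule: str | Callable = "all",
) -> tuple[tuple[frozenset, ...], float]:
    """Enumerate all valid partitions of the clusters and return the one
    with the most significant (smallest) score; exact ties break toward
    fewer blocks, then enumeration (lexicographic) order."""
    best: tuple[frozenset, ...] | None = None
    best_score = None
    for part in enumerate_partitions(clusters, forbidden, max_items):
        sc = score_partition(part, ctx, mode, red_pair_rule)
        if (
            best_score is None
            or sc < best_score
            or (sc == best_score and len(part) < len(best))
        ):
            best, best_score = part, sc
    if best is None:
        raise ConfigurationError("no valid partition (empty cluster set?)")
    return best, float(best_score)


def filter_subgroups(
    proto: pd.DataFrame,
    min_species: int = 3,
    min_genes: int = 5,
    mode: str = "gnathostome",
) -> pd.DataFrame:
    """Drop unreliable proto-chromosomes: in gnathostome mode those with
    segments from fewer than ``min_species`` species; in cyclostome mode
    those with fewer than ``min_genes`` genes.  Removed gene totals are
    logged."""
    stats = proto.groupby("proto_chromosome").agg(
        n_species=("species", "nunique"), n_genes=("n_genes", "sum")
    )
    if mode == "gnathostome":
        bad = stats.index[stats["n_species"] < min_species]
    else:
        bad = stats.index[stats["n_genes"] < min_genes]
    removed = proto[proto["proto_chromosome"].isin(bad)]
    if len(removed):
        logger.info(
            "filtered %d subgroups totalling %d genes",
            len(bad), int(removed["n_genes"].sum()),
        )
    return proto[~proto["proto_chromosome"].isin(bad)].reset_index(drop=True)


def multiplicity_table(proto: pd.DataFrame, gene_table: GeneTable | None = None) -> pd.DataFrame:
    """Per ancestral chromosome: multiplicity Y_k (number of derived
    proto-chromosomes), gene count and fraction of all reconstructed genes."""
    if proto["ancestral_chromosome"].isna().any():
        raise ValueError("unlabelled proto-chromosome block")
    grp = proto.groupby("ancestral_chromosome").agg(
        multiplicity=("proto_chromosome", "nunique"), n_genes=("n_genes", "sum")
    )
    total = (
        int(len(gene_table.df)) if gene_table is not None else int(grp["n_genes"].sum())
    )
    grp["fraction"] = grp["n_genes"] / max(total, 1)
    return grp.reset_index()


def reconstruct_group(
    ctx: GroupContext,
    segmentation: Segmentation | None = None,
    markers: LinkageMarkerTable | None = None,
    gene_table: GeneTable | None = None,
    threshold: float = 1e-5,
    min_cluster_genes: int = 5,
    max_clusters: int = 15,
    mode: str = "cyclostome",
    red_pair_rule: str | Callable = "all",
) -> pd.DataFrame:
    """Full reconstruction of one ancestral chromosome's descendants.

    Returns a proto-chromosome membership table (proto_chromosome,
    ancestral_chromosome, segment_id, species, n_genes, flagged).  When the
    cluster count exceeds ``max_clusters`` the group is kept as one
    proto-chromosome with ``flagged=True``."""
    graph = build_constraints(ctx, segmentation, markers, gene_table, threshold)
    clusters = cluster_segments(graph)
    clusters = drop_small_clusters(clusters, ctx, min_cluster_genes)
    k = ctx.ancestral_chromosome
    if not clusters:
        return pd.DataFrame(
            columns=["proto_chromosome", "ancestral_chromosome", "segment_id",
                     "species", "n_genes", "flagged"]
        )
    flagged = False
    if len(clusters) > max_clusters:
        logger.warning(
            "group %s has %d clusters (> %d): kept unpartitioned",
            k, len(clusters), max_clusters,
        )
        blocks = (frozenset().union(*clusters),)
        flagged = True
    else:
        blocks, _ = select_optimal_partition(
            clusters, ctx, mode, graph.forbidden, max_clusters, red_pair_rule
        )
    rows = []
    for i, block in enumerate(sorted(blocks, key=lambda b: sorted(b)), start=1):
        name = f"pc{k}.{i}"
        for sid in sorted(block):
            rows.append(
                (name, k, sid, ctx.segment_species[sid], ctx.n_genes(sid), flagged)
            )
    return pd.DataFrame(
        rows,
        columns=["proto_chromosome", "ancestral_chromosome", "segment_id",
                 "species", "n_genes", "flagged"],
    )


def reconstruct_all(
    gene_table: GeneTable,
    pairs: HomologyPairSet,
    segmentation: Segmentation,
    assignment: pd.DataFrame,
    species: Sequence[str] | None = None,
    markers: LinkageMarkerTable | None = None,
    exclude_scaffolds: Iterable[tuple[str, str]] = (),
    threshold: float = 1e-5,
    min_cluster_genes: int = 5,
    max_clusters: int = 15,
    mode: str = "cyclostome",
    min_species: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct every ancestral chromosome's descendants and tabulate
    multiplicities.  Returns (proto-chromosome table, multiplicity table)."""
    frames = []
    for k in sorted(assignment["ancestral_chromosome"].unique()):
        ctx = build_group_context(
            gene_table, pairs, segmentation, assignment, int(k),
            species=species, exclude_scaffolds=exclude_scaffolds,
        )
        if not ctx.segment_species:
            continue
        frames.append(
            reconstruct_group(
                ctx, segmentation, markers, gene_table, threshold,
                min_cluster_genes, max_clusters, mode,
            )
        )
    proto = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["proto_chromosome", "ancestral_chromosome", "segment_id",
                     "species", "n_genes", "flagged"]
        )
    )
    if min_species is not None:
        proto = filter_subgroups(proto, min_species=min_species, mode=mode)
    mult = multiplicity_table(proto, gene_table) if len(proto) else pd.DataFrame(
        columns=["ancestral_chromosome", "multiplicity", "n_genes", "fraction"]
    )
    return proto, mult
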