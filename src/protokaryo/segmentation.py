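"""Macrosynteny segmentation by Bayesian changepoint modelling.

Each gene on a scaffold is labelled, per comparator genome, by the
comparator chromosome that holds most of its co-orthologues ("none" when it
has no orthologue there).  A scaffold is then partitioned into segments of
homogeneous label composition under a Dirichlet-multinomial changepoint
model: the marginal likelihood of a segment is the Dirichlet-multinomial
evidence of its label counts (independent comparator tracks multiply), and
each breakpoint pays a fixed log-prior penalty.  The optimal segmentation
is found exactly by dynamic programming over all O(2^(n-1)) segmentations
in O(n^2) time.

Segmentation runs in two passes — within-clade comparators first, then
outgroup comparators — and the union of the two breakpoint sets defines the
final segments, so lineage-specific and deep breakpoints are both kept.
Breakpoints are between-gene positions: breakpoint ``i`` falls after
order_index ``i``, which makes the union well defined across passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    ConfigurationError,
    GeneTable,
    HomologyPairSet,
    Segment,
    Segmentation,
)

__all__ = [
    "SegmentationParams",
    "LabelSequence",
    "label_genes",
    "segment_scaffold",
    "two_pass_segment",
]


@dataclass
class SegmentationParams:
    """dirichlet_concentration: per-label pseudo-count of the segment
    composition prior; segment_penalty: log-prior cost per breakpoint;
    min_genes_per_scaffold: scaffolds below this are left unsegmented
    (default 10, matching the inclusion rule used genome-wide)."""

    dirichlet_concentration: float = 0.5
    segment_penalty: float = 3.0
    min_genes_per_scaffold: int = 10

    def __post_init__(self):
        if self.dirichlet_concentration <= 0 or self.segment_penalty < 0:
            raise ConfigurationError("concentration must be > 0, penalty >= 0")
        if self.min_genes_per_scaffold < 1:
            raise ConfigurationError("min_genes_per_scaffold must be >= 1")


@dataclass
class LabelSequence:
    """Per-gene category labels for one scaffold, one track per comparator
    genome; ``ambiguous`` marks genes whose majority label was a tie."""

    species: str
    scaffold: str
    tracks: dict[str, list[str]]
    ambiguous: dict[str, list[bool]] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {len(v) for v in self.tracks.values()}
        if len(lengths) > 1:
            raise ValueError("tracks of unequal length")

    @property
    def n_genes(self) -> int:
        return len(next(iter(self.tracks.values()))) if self.tracks else 0


def label_genes(
    gene_table: GeneTable,
    pairs: HomologyPairSet,
    target_species: str,
    comparator_species: Sequence[str],
) -> dict[str, LabelSequence]:
    """Label every gene of the target species by the comparator chromosome
    holding most of its co-orthologues, one track per comparator.

    Ties are broken toward the lexicographically smallest chromosome and
    flagged; genes without orthologues get the label "none".
    """
    all_species = set(gene_table.species_list)
    for sp in comparator_species:
        if sp not in all_species:
            raise ConfigurationError(f"comparator species {sp!r} not in gene table")
    gene_species = gene_table.gene_species()
    gene_scaffold = dict(zip(gene_table.df["gene_id"], gene_table.df["scaffold"]))

    # orthologue partners of each target gene, per comparator
    partners: dict[str, dict[str, list[str]]] = {sp: {} for sp in comparator_species}
    for a, b in pairs.orthologues:
        for x, y in ((a, b), (b, a)):
            if gene_species.get(x) == target_species:
                spy = gene_species.get(y)
                if spy in partners:
                    partners[spy].setdefault(x, []).append(y)

    out: dict[str, LabelSequence] = {}
    for scaffold, grp in gene_table.genes_of(target_species).groupby("scaffold"):
        genes = grp.sort_values("order_index")["gene_id"].tolist()
        tracks: dict[str, list[str]] = {}
        ambiguous: dict[str, list[bool]] = {}
        for sp in comparator_species:
            labels, flags = [], []
            for g in genes:
                votes: dict[str, int] = {}
                for partner in partners[sp].get(g, ()):
                    c = gene_scaffold[partner]
                    votes[c] = votes.get(c, 0) + 1
                if not votes:
                    labels.append("none")
                    flags.append(False)
                else:
                    best = max(votes.values())
                    winners = sorted(c for c, v in votes.items() if v == best)
                    labels.append(winners[0])
                    flags.append(len(winners) > 1)
            tracks[sp] = labels
            ambiguous[sp] = flags
        out[scaffold] = LabelSequence(target_species, scaffold, tracks, ambiguous)
    return out


def _track_codes(track: Sequence[str]) -> np.ndarray:
    alphabet = sorted(set(track))
    code = {lab: i for i, lab in enumerate(alphabet)}
    return np.array([code[lab] for lab in track], dtype=np.int64)


def segment_log_ml(prefix: np.ndarray, i: int, j: int, a: float) -> float:
    """Dirichlet-multinomial log evidence of genes [i, j) of one track,
    from the prefix count matrix (n+1, A)."""
    counts = prefix[j] - prefix[i]
    n = j - i
    A = prefix.shape[1]
    out = lgamma(A * a) - lgamma(A * a + n)
    for c in counts:
        if c:
            out += lgamma(a + c) - lgamma(a)
    return out


def segment_scaffold(
    label_sequence: LabelSequence, params: SegmentationParams
) -> list[int]:
    """Exact maximum-a-posteriori breakpoints of one scaffold.

    Returns between-gene breakpoint positions (breakpoint ``i`` separates
    order_index ``i`` from ``i+1``); an empty list means one segment.  The
    dynamic program is exact over all segmentations: score(segmentation) =
    sum of per-segment Dirichlet-multinomial log evidences over all tracks
    minus ``segment_penalty`` per breakpoint.
    """
    n = label_sequence.n_genes
    if n == 0:
        return []
    a = params.dirichlet_concentration
    prefixes = []
    for track in label_sequence.tracks.values():
        codes = _track_codes(track)
        A = int(codes.max()) + 1
        pre = np.zeros((n + 1, A), dtype=np.int64)
        for i, c in enumerate(codes):
            pre[i + 1] = pre[i]
            pre[i + 1, c] += 1
        prefixes.append(pre)

    def span_score(i: int, j: int) -> float:
        return sum(segment_log_ml(pre, i, j, a) for pre in prefixes)

    best = np.full(n + 1, -np.inf)
    back = np.zeros(n + 1, dtype=np.int64)
    best[0] = params.segment_penalty  # cancels the penalty of the first "break"
    for j in range(1, n + 1):
        for i in range(j):
            s = best[i] + span_score(i, j) - params.segment_penalty
            if s > best[j]:
                best[j] = s
                back[j] = i
    cuts = []
    j = n
    while j > 0:
        i = int(back[j])
        if i > 0:
            cuts.append(i - 1)
        j = i
    return sorted(cuts)


def segmentation_score(
    label_sequence: LabelSequence, breakpoints: Sequence[int], params: SegmentationParams
) -> float:
    """Penalized score of an explicit segmentation (used by the exhaustive
    oracle and the optimality certificate)."""
    n = label_sequence.n_genes
    a = params.dirichlet_concentration
    bounds = [0] + [b + 1 for b in sorted(breakpoints)] + [n]
    total = -params.segment_penalty * len(breakpoints)
    for track in label_sequence.tracks.values():
        codes = _track_codes(track)
        A = int(codes.max()) + 1
        pre = np.zeros((n + 1, A), dtype=np.int64)
        for i, c in enumerate(codes):
            pre[i + 1] = pre[i]
            pre[i + 1, c] += 1
        for i, j in zip(bounds, bounds[1:]):
            total += segment_log_ml(pre, i, j, a)
    return total


def two_pass_segment(
    gene_table: GeneTable,
    pairs: HomologyPairSet,
    target_species: str | Sequence[str],
    pass1_species: Sequence[str],
    pass2_species: Sequence[str],
    params: SegmentationParams | None = None,
) -> Segmentation:
    """Two-pass segmentation of the target species.

    Pass 1 compares against the within-clade genomes, pass 2 against the
    outgroup genomes; the union of the two breakpoint sets defines the final
    segments.  Scaffolds with fewer than ``min_genes_per_scaffold`` genes
    are carried as single unsplit segments.  Segment ids are assigned in
    genome order across all target species.
    """
    params = params or SegmentationParams()
    if not pass1_species or not pass2_species:
        raise ConfigurationError("both comparator species sets must be non-empty")
    targets = [target_species] if isinstance(target_species, str) else list(target_species)
    for t in targets:
        # pass 1 may contain the targets themselves (within-clade comparison;
        # each target is compared against the *other* clade members), but the
        # outgroup pass must not
        if t in set(pass2_species):
            raise ConfigurationError(f"target {t!r} cannot be its own outgroup")
        if not [c for c in pass1_species if c != t]:
            raise ConfigurationError(f"no within-clade comparator left for {t!r}")

    segments: list[Segment] = []
    seg_id = 0
    for sp in targets:
        comp1 = [c for c in pass1_species if c != sp]
        passes = [label_genes(gene_table, pairs, sp, comp) for comp in
                  (comp1, list(pass2_species)) if comp]
        scaffolds = sorted(gene_table.genes_of(sp)["scaffold"].unique())
        counts = gene_table.genes_of(sp).groupby("scaffold").size()
        for scaffold in scaffolds:
            n = int(counts[scaffold])
            cuts: set[int] = set()
            if n >= params.min_genes_per_scaffold:
                for labels in passes:
                    cuts |= set(segment_scaffold(labels[scaffold], params))
            bounds = [0] + [c + 1 for c in sorted(cuts)] + [n]
            for i, j in zip(bounds, bounds[1:]):
                segments.append(Segment(seg_id, sp, scaffold, i, j - 1))
                seg_id += 1
    return Segmentation(segments)
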