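"""Synthetic karyotype evolution: polyploidization, rearrangement, gene loss.

The simulator grows a set of extant genomes from one ancestral genome so
that every reconstruction stage can be tested against known ground truth.
The ancestor has ``K`` chromosomes of ordered genes (default 18, the
reconstructed proto-vertebrate karyotype).  Each lineage then executes an
ordered event program:

* ``("tetraploidize",)`` / ``("hexaploidize",)`` — whole-genome duplication
  or triplication; every chromosome and gene is copied and each copy gets a
  subgenome tag (hexaploidy is modelled as a single triplication event);
* ``("fuse", i, j)`` / ``("fuse",)`` — concatenate two (given or random)
  chromosomes;
* ``("fission", i, pos)`` / ``("fission",)`` — split a chromosome;
* ``("translocate",)`` — move a terminal block between two chromosomes;
* ``("invert", mean)`` — reverse random gene-order intervals, the number of
  inversions per chromosome Poisson with the given mean.

After the event program, per-copy Bernoulli gene loss is applied; an
allopolyploid retention bias multiplies the per-subgenome retention
probabilities so their ratio equals the configured bias factor (the
gnathostome reconstruction shows a retained-gene ratio of about 2.25
between the two subgenomes of the second tetraploidization).

Homology pairs are derived from true gene ancestry: orthologues are
cross-species pairs sharing an ancestral gene (capped per gene at a
configurable co-orthologue limit), paralogues are within-species pairs in
one ohnologue group.  Configurable noise removes true pairs and adds
spurious ones at the stated fraction.

One :class:`numpy.random.Generator` stream drives a whole run; the seed is
recorded in the truth object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ConfigurationError, GeneTable, HomologyPairSet

__all__ = [
    "EvolutionConfig",
    "SimGenome",
    "SimulationTruth",
    "simulate_ancestor",
    "apply_polyploidization",
    "apply_rearrangements_and_loss",
    "derive_homology",
    "simulate",
]


@dataclass(frozen=True)
class SimGene:
    anc_gene: int        # global index of the ancestral gene
    anc_chrom: int       # ancestral chromosome, 1-based
    subgenome: tuple[int, ...] = ()   # copy index per polyploidization event


@dataclass
class SimGenome:
    """One genome: named chromosomes, each an ordered list of genes."""

    chromosomes: dict[str, list[SimGene]]
    ploidy_product: int = 1

    def n_genes(self) -> int:
        return sum(len(g) for g in self.chromosomes.values())

    def copy(self) -> "SimGenome":
        return SimGenome(
            {name: list(genes) for name, genes in self.chromosomes.items()},
            self.ploidy_product,
        )


@dataclass
class SimulationTruth:
    """Ground-truth ancestry of every extant gene plus derived summaries."""

    genes: pd.DataFrame          # gene_id, species, scaffold, order_index,
                                 # anc_gene, anc_chrom, subgenome
    seed: int | None = None

    def multiplicity_vector(self, species: str) -> dict[int, int]:
        """Distinct subgenome copies retained per ancestral chromosome: the
        true number of derived (proto-)chromosomes."""
        sub = self.genes[self.genes["species"] == species]
        return (
            sub.groupby("anc_chrom")["subgenome"].nunique().astype(int).to_dict()
        )

    def breakpoints(self, species: str) -> dict[str, list[int]]:
        """True synteny breakpoints per scaffold: between-gene positions where
        the (ancestral chromosome, subgenome) block identity changes.  A
        breakpoint after position i means between order_index i and i+1."""
        out: dict[str, list[int]] = {}
        sub = self.genes[self.genes["species"] == species]
        for scaffold, grp in sub.groupby("scaffold"):
            grp = grp.sort_values("order_index")
            blocks = list(zip(grp["anc_chrom"], grp["subgenome"]))
            out[scaffold] = [i for i in range(len(blocks) - 1)
                             if blocks[i] != blocks[i + 1]]
        return out


@dataclass
class EvolutionConfig:
    """Study conditions for one simulated clade.

    ``branches`` maps species name -> ordered event program (see module
    docstring).  ``retention`` is the per-copy retention probability (may be
    a per-species mapping); ``subgenome_bias`` >= 1 is the desired ratio of
    retained-gene counts between the two subgenomes of the last
    polyploidization; ``keep_one`` guarantees every ohnologue group keeps at
    least one copy per species.  ``pair_noise`` is the fraction of homology
    pairs removed and (separately) added as spurious pairs.
    """

    k_anc: int = 18
    genes_per_chromosome: int = 100
    branches: Mapping[str, Sequence] = field(default_factory=dict)
    roles: Mapping[str, str] = field(default_factory=dict)
    retention: float | Mapping[str, float] = 1.0
    subgenome_bias: float = 1.0
    keep_one: bool = True
    pair_noise: float = 0.0
    max_co_orthologues: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.k_anc < 1:
            raise ConfigurationError("k_anc must be >= 1")
        if self.subgenome_bias < 1:
            raise ConfigurationError("subgenome_bias must be >= 1")
        rets = (
            self.retention.values()
            if isinstance(self.retention, Mapping)
            else [self.retention]
        )
        if any(not (0 < r <= 1) for r in rets):
            raise ConfigurationError("retention probabilities must be in (0, 1]")


def simulate_ancestor(
    k_anc: int, genes_per_chromosome: int, seed: int | None = None
) -> SimGenome:
    """Ancestral genome: one chromosome per scaffold, genes labelled by a
    bijection with (chromosome, within-chromosome index)."""
    if k_anc < 1 or genes_per_chromosome < 1:
        raise ConfigurationError("k_anc and genes_per_chromosome must be positive")
    chroms: dict[str, list[SimGene]] = {}
    gid = 0
    for k in range(1, k_anc + 1):
        genes = [SimGene(anc_gene=gid + i, anc_chrom=k)
                 for i in range(genes_per_chromosome)]
        gid += genes_per_chromosome
        chroms[f"anc{k}"] = genes
    return SimGenome(chroms)


def apply_polyploidization(genome: SimGenome, ploidy_factor: int) -> SimGenome:
    """Whole-genome duplication (factor 2) or triplication (factor 3):
    every chromosome is copied ``ploidy_factor`` times and each gene copy is
    tagged with its subgenome index."""
    if ploidy_factor not in (2, 3):
        raise ConfigurationError("ploidy_factor must be 2 or 3")
    chroms: dict[str, list[SimGene]] = {}
    for name, genes in genome.chromosomes.items():
        for copy in range(ploidy_factor):
            chroms[f"{name}.{copy}"] = [
                replace(g, subgenome=g.subgenome + (copy,)) for g in genes
            ]
    return SimGenome(chroms, genome.ploidy_product * ploidy_factor)


def _chrom_names(genome: SimGenome) -> list[str]:
    return sorted(genome.chromosomes)


def _apply_event(genome: SimGenome, event: Sequence, rng: np.random.Generator) -> SimGenome:
    kind = event[0]
    if kind == "tetraploidize":
        return apply_polyploidization(genome, 2)
    if kind == "hexaploidize":
        return apply_polyploidization(genome, 3)

    g = genome.copy()
    names = _chrom_names(g)
    if kind == "fuse":
        if len(names) < 2:
            raise ConfigurationError("cannot fuse: fewer than 2 chromosomes")
        if len(event) == 3:
            a, b = str(event[1]), str(event[2])
            if a not in g.chromosomes or b not in g.chromosomes:
                raise ConfigurationError(f"fuse of unknown chromosome {a!r}/{b!r}")
        else:
            a, b = rng.choice(names, size=2, replace=False)
        g.chromosomes[f"{a}+{b}"] = g.chromosomes.pop(a) + g.chromosomes.pop(b)
    elif kind == "fission":
        if len(event) >= 2:
            a = str(event[1])
            if a not in g.chromosomes:
                raise ConfigurationError(f"fission of unknown chromosome {a!r}")
        else:
            a = rng.choice([n for n in names if len(g.chromosomes[n]) >= 2])
        genes = g.chromosomes.pop(a)
        pos = int(event[2]) if len(event) >= 3 else int(rng.integers(1, len(genes)))
        if not 1 <= pos < len(genes):
            raise ConfigurationError(f"fission position {pos} out of range")
        g.chromosomes[f"{a}/L"] = genes[:pos]
        g.chromosomes[f"{a}/R"] = genes[pos:]
    elif kind == "translocate":
        if len(names) < 2:
            raise ConfigurationError("cannot translocate: fewer than 2 chromosomes")
        a, b = rng.choice(names, size=2, replace=False)
        donor = g.chromosomes[a]
        if len(donor) >= 2:
            cut = int(rng.integers(1, len(donor)))
            g.chromosomes[a] = donor[:cut]
            g.chromosomes[b] = g.chromosomes[b] + donor[cut:]
    elif kind == "invert":
        mean = float(event[1]) if len(event) >= 2 else 1.0
        for name in names:
            genes = g.chromosomes[name]
            if len(genes) < 2:
                continue
            for _ in range(rng.poisson(mean)):
                i, j = sorted(rng.integers(0, len(genes), size=2))
                genes[i : j + 1] = genes[i : j + 1][::-1]
    else:
        raise ConfigurationError(f"unknown event {kind!r}")
    return g


def _loss_probabilities(retention: float, bias: float) -> dict[int, float]:
    """Per-subgenome retention probabilities whose ratio equals ``bias``
    and whose mean is ``retention`` (clipped into (0, 1])."""
    lo = 2 * retention / (1 + bias)
    hi = min(1.0, bias * lo)
    return {0: hi, "other": lo}


def apply_rearrangements_and_loss(
    genome: SimGenome,
    events: Sequence[Sequence] = (),
    retention: float = 1.0,
    subgenome_bias: float = 1.0,
    keep_one: bool = True,
    rng: np.random.Generator | None = None,
) -> SimGenome:
    """Run an event program, then drop each gene copy independently with its
    subgenome's retention probability.

    The bias keys on the copy index of the *last* polyploidization (the
    final component of the subgenome tag): copy 0 is the better-retained
    subgenome.  With ``keep_one``, an ohnologue group losing every copy has
    one random copy resurrected, so no ancestral gene disappears entirely.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    g = genome.copy()
    for ev in events:
        g = _apply_event(g, ev, rng)

    if retention >= 1.0:
        return g
    probs = _loss_probabilities(retention, subgenome_bias)

    # decide survival per gene copy
    keep: dict[tuple[str, int], bool] = {}
    group_copies: dict[int, list[tuple[str, int]]] = {}
    for name in _chrom_names(g):
        for i, gene in enumerate(g.chromosomes[name]):
            last = gene.subgenome[-1] if gene.subgenome else 0
            p = probs[0] if last == 0 else probs["other"]
            keep[(name, i)] = bool(rng.random() < p)
            group_copies.setdefault(gene.anc_gene, []).append((name, i))
    if keep_one:
        for anc_gene, copies in group_copies.items():
            if not any(keep[c] for c in copies):
                keep[copies[int(rng.integers(len(copies)))]] = True

    for name in _chrom_names(g):
        g.chromosomes[name] = [
            gene for i, gene in enumerate(g.chromosomes[name]) if keep[(name, i)]
        ]
        if not g.chromosomes[name]:
            del g.chromosomes[name]
    return g


def _genome_records(species: str, genome: SimGenome) -> list[dict]:
    rows = []
    for name in _chrom_names(genome):
        for i, gene in enumerate(genome.chromosomes[name]):
            sub = ".".join(map(str, gene.subgenome))
            rows.append(
                dict(
                    species=species,
                    scaffold=name,
                    order_index=i,
                    start=i * 1000,
                    end=i * 1000 + 500,
                    gene_id=f"{species}|{gene.anc_gene}|{sub or '-'}",
                    anc_gene=gene.anc_gene,
                    anc_chrom=gene.anc_chrom,
                    subgenome=sub,
                )
            )
    return rows


def derive_homology(
    genomes: Mapping[str, SimGenome],
    noise: float = 0.0,
    max_co_orthologues: int = 4,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    shared_prefix: Mapping[frozenset, int] | None = None,
) -> tuple[GeneTable, HomologyPairSet, SimulationTruth]:
    """Emit the gene table, homology pairs and ground truth for a set of
    genomes descending from one simulated ancestor.

    Orthologues are cross-species pairs sharing an ancestral gene whose
    subgenome tags agree on the polyploidizations shared by the two
    lineages (``shared_prefix`` maps a species pair to the number of shared
    leading polyploidization events; default 0, i.e. the lineages split
    before any duplication and every copy pair is co-orthologous).  Genes
    that duplicated after the split therefore give 1-to-many relations,
    capped at ``max_co_orthologues`` partners per gene per other species
    (lexicographic preference, emulating a best-hit cutoff); genes whose
    duplications predate the split pair 1-to-1 with the copy of the same
    subgenome.  Paralogues: within-species pairs in one ohnologue group.
    ``noise`` removes each true pair and adds a matching number of uniform
    spurious pairs, both at the given fraction.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    shared_prefix = shared_prefix or {}
    rows: list[dict] = []
    for sp in sorted(genomes):
        rows.extend(_genome_records(sp, genomes[sp]))
    truth_df = pd.DataFrame(rows)
    table_df = truth_df[["species", "scaffold", "start", "end", "gene_id",
                         "order_index"]].copy()
    gene_table = GeneTable(df=table_df)

    by_group: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for r in rows:
        by_group.setdefault((r["species"], r["anc_gene"]), []).append(
            (r["gene_id"], r["subgenome"])
        )

    species = sorted(genomes)
    anc_genes: dict[int, None] = {r["anc_gene"]: None for r in rows}
    ortho: set[tuple[str, str]] = set()
    para: set[tuple[str, str]] = set()
    for ag in anc_genes:
        per_sp = {sp: sorted(by_group.get((sp, ag), [])) for sp in species}
        for i, sa in enumerate(species):
            ga = per_sp[sa]
            # paralogues: all within-group pairs in one species
            for x in range(len(ga)):
                for y in range(x + 1, len(ga)):
                    para.add((ga[x][0], ga[y][0]))
            for sb in species[i + 1:]:
                gb = per_sp[sb]
                npfx = shared_prefix.get(frozenset((sa, sb)), 0)
                for a, sub_a in ga:
                    pref_a = sub_a.split(".")[:npfx]
                    partners = [
                        b for b, sub_b in gb if sub_b.split(".")[:npfx] == pref_a
                    ]
                    for b in partners[:max_co_orthologues]:
                        ortho.add((a, b) if a <= b else (b, a))

    if noise > 0:
        ortho = _perturb_pairs(ortho, truth_df, noise, rng, cross_species=True)
        para = _perturb_pairs(para, truth_df, noise, rng, cross_species=False)

    pairs = HomologyPairSet.from_pairs(
        [(a, b) for a, b in sorted(ortho | para)], gene_table.gene_species()
    )
    truth = SimulationTruth(genes=truth_df, seed=seed)
    return gene_table, pairs, truth


def _perturb_pairs(
    true_pairs: set[tuple[str, str]],
    truth_df: pd.DataFrame,
    noise: float,
    rng: np.random.Generator,
    cross_species: bool,
) -> set[tuple[str, str]]:
    pairs = sorted(true_pairs)
    keep_mask = rng.random(len(pairs)) >= noise
    kept = {p for p, k in zip(pairs, keep_mask) if k}
    n_add = int(round(noise * len(pairs)))
    ids = truth_df["gene_id"].to_numpy()
    sp = truth_df["species"].to_numpy()
    added = 0
    attempts = 0
    while added < n_add and attempts < 50 * (n_add + 1):
        attempts += 1
        i, j = rng.integers(0, len(ids), size=2)
        if i == j:
            continue
        if cross_species != (sp[i] != sp[j]):
            continue
        key = (ids[i], ids[j]) if ids[i] <= ids[j] else (ids[j], ids[i])
        if key in kept or key in true_pairs:
            continue
        kept.add(key)
        added += 1
    return kept


def simulate(config: EvolutionConfig) -> tuple[GeneTable, HomologyPairSet, SimulationTruth]:
    """Run a full simulation: ancestor, per-branch evolution, homology."""
    rng = np.random.default_rng(config.seed)
    ancestor = simulate_ancestor(config.k_anc, config.genes_per_chromosome)
    genomes: dict[str, SimGenome] = {}
    for sp in sorted(config.branches):
        events = config.branches[sp]
        ret = (
            config.retention.get(sp, 1.0)
            if isinstance(config.retention, Mapping)
            else config.retention
        )
        genomes[sp] = apply_rearrangements_and_loss(
            ancestor,
            events=events,
            retention=ret,
            subgenome_bias=config.subgenome_bias,
            keep_one=config.keep_one,
            rng=rng,
        )
    # shared polyploidization history: identical leading WGD events in two
    # branch programs are treated as one shared (pre-split) event, so true
    # orthologues are the copies with matching subgenome tags there
    wgd_programs = {
        sp: [ev[0] for ev in config.branches[sp]
             if ev[0] in ("tetraploidize", "hexaploidize")]
        for sp in config.branches
    }
    shared_prefix: dict[frozenset, int] = {}
    names = sorted(config.branches)
    for i, sa in enumerate(names):
        for sb in names[i + 1:]:
            n = 0
            for ea, eb in zip(wgd_programs[sa], wgd_programs[sb]):
                if ea != eb:
                    break
                n += 1
            shared_prefix[frozenset((sa, sb))] = n

    gene_table, pairs, truth = derive_homology(
        genomes,
        noise=config.pair_noise,
        max_co_orthologues=config.max_co_orthologues,
        rng=rng,
        seed=config.seed,
        shared_prefix=shared_prefix,
    )
    gene_table.roles = dict(config.roles)
    return gene_table, pairs, truth
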