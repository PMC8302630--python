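"""Probabilistic macrosynteny model fitted by collapsed variational Bayes.

The model is a mixture (topic-model) view of macrosynteny: every gene of a
non-duplicated reference genome descends from one of K ancestral
chromosomes; a reference segment s draws its genes' ancestral chromosomes
from a segment-specific Dirichlet-multinomial (prior alpha_k), and a gene
from chromosome k scatters its co-orthologues over the segments of each
post-WGD genome t according to a chromosome-specific Dirichlet-multinomial
(prior beta_c^(t)).  Observing where each reference gene's co-orthologues
fall (the count tensor n_{t,c}^{s,g}, capped at D^(t) co-orthologues per
species) lets collapsed variational Bayes (CVB0) infer a responsibility
q_{s,g}(k) for every gene over the K chromosomes.

The CVB0 update for gene (s, g) is, up to the normalizing constant,

  log q(k) = log(ahat_k^(s) - q(k))
           + sum_t sum_c sum_{i=1}^{n_{t,c}} log(i - 1 + bhat_c^(k,t) - q(k) n_{t,c})
           - sum_t sum_{i=1}^{n_t} log(i - 1 + sum_c bhat_c^(k,t) - q(k) n_t)

with leave-one-out pseudo-counts

  ahat_k^(s)   = alpha_k + sum_{g' in s} q_{s,g'}(k)
  bhat_c^(k,t) = beta_c^(t) + sum_{s,g} q_{s,g}(k) n_{t,c}^{s,g}

(the "- q(k)" terms remove the gene's own contribution).  To avoid early
convergence to poor optima the prior is annealed: at sweep j the effective
alpha is alpha_k + 0.8^(j-1) while j < 98, exactly alpha_k afterwards.
Sweeps stop when the total L1 change sum_{s,g,k} |q - q'| drops below the
tolerance (default 0.001) or after 100 sweeps.

Normalized pseudo-count rows are the reconstruction confidence scores:
U[s, k] for reference segments and V[t][k, c] for post-WGD segments; hard
assignments take the argmax over k.

The sweep is JIT-compiled (numba); a direct per-gene arithmetic evaluation
of the update is exposed as :func:`cvb0_update_gene` for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import hypergeom as _scipy_hypergeom

from .core_io import ConfigurationError, GeneTable, HomologyPairSet, Segmentation

__all__ = [
    "CVBConfig",
    "CountTensor",
    "CVBResult",
    "build_count_tensor",
    "cvb0_update_gene",
    "cvb0_fit",
    "assign_segments",
    "select_k",
]


class NumericalGuardError(RuntimeError):
    """A log argument in the CVB0 update became non-positive (prior too
    small for the data, or corrupted bookkeeping)."""


@dataclass
class CVBConfig:
    """K: ancestral chromosome count; alpha, beta: Dirichlet priors;
    L: carried hyperparameter (logged, no effect by default); annealing,
    iteration and tolerance constants are the standard run settings."""

    K: int
    alpha: float = 0.1
    beta: float = 0.1
    L: int = 10
    max_iter: int = 100
    anneal_base: float = 0.8
    anneal_cutoff_iter: int = 98
    tol: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.K < 1 or self.alpha <= 0 or self.beta <= 0 or self.tol <= 0:
            raise ConfigurationError("need K >= 1, alpha > 0, beta > 0, tol > 0")


@dataclass
class CountTensor:
    """Sparse co-orthologue placement counts of reference genes.

    Genes are flattened to index j; ``gene_seg[j]`` is the reference-segment
    index s; CSR arrays (indptr, col, cnt) hold the non-zero counts over
    global post-WGD segment columns (column = col_offset[t] + c); ``nt`` is
    the per-species total n_t^{s,g}.
    """

    ref_species: str
    ref_segment_ids: list
    gene_ids: list[str]
    species: list[str]
    segment_ids_per_species: list[list]
    gene_seg: np.ndarray
    indptr: np.ndarray
    col: np.ndarray
    cnt: np.ndarray
    nt: np.ndarray
    col_offset: np.ndarray

    @property
    def S(self) -> int:
        return len(self.ref_segment_ids)

    @property
    def T(self) -> int:
        return len(self.species)

    @property
    def C(self) -> list[int]:
        return [len(ids) for ids in self.segment_ids_per_species]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def validate(self) -> None:
        if np.any(self.cnt < 0):
            raise ValueError("negative counts")
        # totals consistent with sparse entries
        for j in range(self.n_genes):
            sl = slice(self.indptr[j], self.indptr[j + 1])
            for t in range(self.T):
                mask = (self.col[sl] >= self.col_offset[t]) & (
                    self.col[sl] < self.col_offset[t + 1]
                )
                if self.cnt[sl][mask].sum() != self.nt[j, t]:
                    raise ValueError(f"inconsistent totals for gene {j}, species {t}")


def build_count_tensor(
    gene_table: GeneTable,
    pairs: HomologyPairSet,
    segmentation: Segmentation | None,
    d_per_species: int | Mapping[str, int] = 4,
    ref_species: str | None = None,
    post_wgd_species: Sequence[str] | None = None,
) -> CountTensor:
    """Count, for every reference gene, its co-orthologue placements per
    post-WGD segment.

    Reference "segments" are the reference scaffolds.  When a gene has more
    than D co-orthologues in a species, the top D by homology score are
    kept (ties broken by lexicographic gene id).  When ``segmentation`` is
    None, post-WGD scaffolds serve as segments.
    """
    if ref_species is None:
        refs = gene_table.species_of_role("reference")
        if len(refs) != 1:
            raise ConfigurationError(
                f"exactly one reference species required, found {refs}"
            )
        ref_species = refs[0]
    if post_wgd_species is None:
        post_wgd_species = gene_table.species_of_role("post_wgd")
    post_wgd_species = list(post_wgd_species)
    if not post_wgd_species:
        raise ConfigurationError("no post-WGD species")

    gene_species = gene_table.gene_species()
    if segmentation is not None:
        gene_to_seg = segmentation.gene_to_segment(gene_table)
        seg_ids_per_sp = [
            [s.segment_id for s in segmentation.for_species(sp)]
            for sp in post_wgd_species
        ]
    else:
        gene_to_seg = dict(zip(gene_table.df["gene_id"], gene_table.df["scaffold"]))
        seg_ids_per_sp = [
            sorted(gene_table.genes_of(sp)["scaffold"].unique())
            for sp in post_wgd_species
        ]
    seg_index = [
        {sid: c for c, sid in enumerate(ids)} for ids in seg_ids_per_sp
    ]

    ref_df = gene_table.genes_of(ref_species).sort_values(["scaffold", "order_index"])
    ref_segment_ids = sorted(ref_df["scaffold"].unique())
    seg_of_ref = {sid: s for s, sid in enumerate(ref_segment_ids)}
    gene_ids = ref_df["gene_id"].tolist()
    gene_pos = {g: j for j, g in enumerate(gene_ids)}

    # partners per reference gene per species
    partners: dict[int, dict[int, list[str]]] = {}
    sp_index = {sp: t for t, sp in enumerate(post_wgd_species)}
    for a, b in pairs.orthologues:
        for x, y in ((a, b), (b, a)):
            j = gene_pos.get(x)
            t = sp_index.get(gene_species.get(y))
            if j is not None and t is not None:
                partners.setdefault(j, {}).setdefault(t, []).append(y)

    def dmax(sp: str) -> int:
        if isinstance(d_per_species, Mapping):
            return int(d_per_species[sp])
        return int(d_per_species)

    T = len(post_wgd_species)
    J = len(gene_ids)
    col_offset = np.zeros(T + 1, dtype=np.int64)
    for t, ids in enumerate(seg_ids_per_sp):
        col_offset[t + 1] = col_offset[t] + len(ids)

    gene_seg = np.array([seg_of_ref[sc] for sc in ref_df["scaffold"]], dtype=np.int64)
    indptr = [0]
    cols: list[int] = []
    cnts: list[int] = []
    nt = np.zeros((J, T), dtype=np.int64)
    for j, g in enumerate(gene_ids):
        entry: dict[int, int] = {}
        for t, plist in sorted(partners.get(j, {}).items()):
            d = dmax(post_wgd_species[t])
            chosen = sorted(plist, key=lambda y: (-pairs.score(g, y), y))[:d]
            for y in chosen:
                seg = gene_to_seg.get(y)
                if seg is None:
                    raise ConfigurationError(
                        f"gene {y!r} not covered by the segmentation"
                    )
                c = seg_index[t][seg]
                entry[col_offset[t] + c] = entry.get(col_offset[t] + c, 0) + 1
            nt[j, t] = len(chosen)
        for c in sorted(entry):
            cols.append(c)
            cnts.append(entry[c])
        indptr.append(len(cols))

    return CountTensor(
        ref_species=ref_species,
        ref_segment_ids=ref_segment_ids,
        gene_ids=gene_ids,
        species=post_wgd_species,
        segment_ids_per_species=seg_ids_per_sp,
        gene_seg=gene_seg,
        indptr=np.array(indptr, dtype=np.int64),
        col=np.array(cols, dtype=np.int64),
        cnt=np.array(cnts, dtype=np.int64),
        nt=nt,
        col_offset=col_offset,
    )


def cvb0_update_gene(
    alpha_hat_s: np.ndarray,
    q_sg: np.ndarray,
    counts: Mapping[int, int],
    n_t: np.ndarray,
    beta_hat: np.ndarray,
    col_offset: np.ndarray,
) -> np.ndarray:
    """Direct arithmetic evaluation of the CVB0 update for one gene.

    ``alpha_hat_s``: (K,) pseudo-counts of the gene's segment (including
    the gene itself); ``q_sg``: (K,) current responsibility; ``counts``:
    {global column -> n_{t,c}}; ``n_t``: (T,) totals; ``beta_hat``:
    (K, n_columns) pseudo-counts (including the gene).  Returns the new
    normalized responsibility.  This reference path is pure numpy/python
    and is the oracle for the compiled sweep.
    """
    K = len(alpha_hat_s)
    logq = np.empty(K)
    beta_sums = np.add.reduceat(beta_hat, col_offset[:-1], axis=1)
    for k in range(K):
        arg = alpha_hat_s[k] - q_sg[k]
        if arg <= 0:
            raise NumericalGuardError(f"alpha_hat - q <= 0 for k={k}")
        lp = np.log(arg)
        for c, n_tc in counts.items():
            for i in range(1, n_tc + 1):
                v = i - 1 + beta_hat[k, c] - q_sg[k] * n_tc
                if v <= 0:
                    raise NumericalGuardError(f"beta term <= 0 for k={k}, col={c}")
                lp += np.log(v)
        for t, nt_val in enumerate(n_t):
            for i in range(1, int(nt_val) + 1):
                v = i - 1 + beta_sums[k, t] - q_sg[k] * nt_val
                if v <= 0:
                    raise NumericalGuardError(f"beta-sum term <= 0 for k={k}, t={t}")
                lp -= np.log(v)
        logq[k] = lp
    logq -= logq.max()
    w = np.exp(logq)
    return w / w.sum()


@njit(cache=True)
def _sweep(q, sumq_seg, B, Bt, gene_seg, indptr, col, cnt, nt, alpha_eff):
    J, K = q.shape
    T = nt.shape[1]
    total_change = 0.0
    logq = np.empty(K)
    for j in range(J):
        s = gene_seg[j]
        for k in range(K):
            arg = alpha_eff + sumq_seg[s, k] - q[j, k]
            if arg <= 0.0:
                return -1.0
            lp = np.log(arg)
            for e in range(indptr[j], indptr[j + 1]):
                base = B[k, col[e]] - q[j, k] * cnt[e]
                for i in range(cnt[e]):
                    v = i + base
                    if v <= 0.0:
                        return -1.0
                    lp += np.log(v)
            for t in range(T):
                n_t = nt[j, t]
                if n_t == 0:
                    continue
                base = Bt[k, t] - q[j, k] * n_t
                for i in range(n_t):
                    v = i + base
                    if v <= 0.0:
                        return -1.0
                    lp -= np.log(v)
            logq[k] = lp
        m = logq[0]
        for k in range(1, K):
            if logq[k] > m:
                m = logq[k]
        tot = 0.0
        for k in range(K):
            logq[k] = np.exp(logq[k] - m)
            tot += logq[k]
        for k in range(K):
            w = logq[k] / tot
            d = w - q[j, k]
            total_change += abs(d)
            sumq_seg[s, k] += d
            for e in range(indptr[j], indptr[j + 1]):
                B[k, col[e]] += d * cnt[e]
            for t in range(T):
                Bt[k, t] += d * nt[j, t]
            q[j, k] = w
    return total_change


@dataclass
class CVBResult:
    tensor: CountTensor
    config: CVBConfig
    q: np.ndarray                     # (J, K) responsibilities
    alpha_hat: np.ndarray             # (S, K)
    beta_hat: np.ndarray              # (K, n_columns)
    U: np.ndarray                     # (S, K) normalized alpha_hat
    V: list[np.ndarray]               # per species t: (K, C_t) normalized over k
    trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def hard_reference_assignment(self) -> pd.DataFrame:
        rows = []
        for s, sid in enumerate(self.tensor.ref_segment_ids):
            k = int(np.argmax(self.U[s]))
            tie = np.sum(self.U[s] == self.U[s, k]) > 1
            rows.append((sid, self.tensor.ref_species, k + 1, float(self.U[s, k]), bool(tie)))
        return pd.DataFrame(
            rows, columns=["segment_id", "species", "ancestral_chromosome",
                           "confidence", "ambiguous"]
        )


def cvb0_fit(tensor: CountTensor, config: CVBConfig) -> CVBResult:
    """Fit the macrosynteny model by CVB0 sweeps with prior annealing."""
    K = config.K
    J = tensor.n_genes
    if K > J:
        raise ConfigurationError(f"K={K} exceeds gene count {J}")
    rng = np.random.default_rng(config.seed)
    q = rng.dirichlet(np.ones(K), size=J)

    S = tensor.S
    n_cols = int(tensor.col_offset[-1])
    sumq_seg = np.zeros((S, K))
    np.add.at(sumq_seg, tensor.gene_seg, q)
    B = np.full((n_cols, K), config.beta).T.copy()
    for j in range(J):
        for e in range(tensor.indptr[j], tensor.indptr[j + 1]):
            B[:, tensor.col[e]] += q[j] * tensor.cnt[e]
    Bt = np.empty((K, tensor.T))
    for t in range(tensor.T):
        Bt[:, t] = config.beta * tensor.C[t] + (q * tensor.nt[:, t : t + 1]).sum(axis=0)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        anneal = config.anneal_base ** (it - 1) if it < config.anneal_cutoff_iter else 0.0
        change = _sweep(
            q, sumq_seg, B, Bt, tensor.gene_seg, tensor.indptr,
            tensor.col, tensor.cnt, tensor.nt, config.alpha + anneal,
        )
        if change < 0:
            raise NumericalGuardError(
                "non-positive log argument during sweep "
                f"(iteration {it}; alpha={config.alpha}, beta={config.beta})"
            )
        trace.append(float(change))
        if change < config.tol:
            converged = True
            break

    alpha_hat = config.alpha + sumq_seg
    U = alpha_hat / alpha_hat.sum(axis=1, keepdims=True)
    V = []
    for t in range(tensor.T):
        block = B[:, tensor.col_offset[t] : tensor.col_offset[t + 1]]
        V.append(block / block.sum(axis=0, keepdims=True))
    return CVBResult(
        tensor=tensor, config=config, q=q, alpha_hat=alpha_hat, beta_hat=B,
        U=U, V=V, trace=trace, converged=converged, n_iter=it,
    )


def assign_segments(result: CVBResult) -> pd.DataFrame:
    """Hard assignment of every post-WGD segment to the ancestral chromosome
    with the largest reconstruction confidence score (argmax_k V[t][k, c]);
    exact ties go to the lowest chromosome index and are flagged."""
    rows = []
    for t, sp in enumerate(result.tensor.species):
        V = result.V[t]
        for c, sid in enumerate(result.tensor.segment_ids_per_species[t]):
            k = int(np.argmax(V[:, c]))
            tie = np.sum(V[:, c] == V[k, c]) > 1
            rows.append((sid, sp, k + 1, float(V[k, c]), bool(tie)))
    return pd.DataFrame(
        rows, columns=["segment_id", "species", "ancestral_chromosome",
                       "confidence", "ambiguous"]
    )


def _log10_tail(g: int, m: int, n: int, x: int) -> float:
    if x <= 0:
        return 0.0
    return float(_scipy_hypergeom.logsf(x - 1, g, m, n)) / np.log(10)


def select_k(
    gene_table: GeneTable,
    pairs: HomologyPairSet,
    segmentation: Segmentation | None,
    k_range: Sequence[int],
    config: CVBConfig | None = None,
    d_per_species: int | Mapping[str, int] = 4,
    ref_species: str | None = None,
    post_wgd_species: Sequence[str] | None = None,
    n_restarts: int = 3,
) -> tuple[int, pd.DataFrame, dict[int, CVBResult]]:
    """Choose the ancestral chromosome count K by paralogue enrichment.

    For each K the model is fitted (``n_restarts`` seeded restarts, keeping
    the most significant) and every post-WGD segment assigned; under the
    null that paralogues scatter uniformly over all gene pairs of a genome,
    the tail probability of finding x paralogue pairs among the v
    same-chromosome gene pairs measures the reconstruction's quality.  The
    per-species log10 tails are summed and the most significant K wins
    (ties to the smallest K).

    Returns (chosen K, per-K table, fitted results).
    """
    k_range = list(k_range)
    if not k_range:
        raise ConfigurationError("k_range is empty")
    base = config or CVBConfig(K=k_range[0])
    tensor = build_count_tensor(
        gene_table, pairs, segmentation, d_per_species, ref_species, post_wgd_species
    )
    if not any(
        True for _ in pairs.paralogues
    ):
        raise ConfigurationError("no paralogue pairs: K selection is undefined")

    gene_species = gene_table.gene_species()
    if segmentation is not None:
        gene_to_seg = segmentation.gene_to_segment(gene_table)
    else:
        gene_to_seg = dict(zip(gene_table.df["gene_id"], gene_table.df["scaffold"]))

    def assignment_log_tail(assignment: pd.DataFrame) -> float:
        log_tail = 0.0
        for sp in tensor.species:
            sub = assignment[assignment["species"] == sp]
            seg_to_k = dict(zip(sub["segment_id"], sub["ancestral_chromosome"]))
            genes = [
                (g, seg_to_k.get(gene_to_seg.get(g)))
                for g in gene_table.genes_of(sp)["gene_id"]
            ]
            genes = [(g, k) for g, k in genes if k is not None]
            n_genes = len(genes)
            g_total = n_genes * (n_genes - 1) // 2
            sizes: dict[int, int] = {}
            for _, k in genes:
                sizes[k] = sizes.get(k, 0) + 1
            v = sum(c * (c - 1) // 2 for c in sizes.values())
            chrom_of = dict(genes)
            p_total = 0
            x = 0
            for a, b in pairs.paralogues:
                if gene_species.get(a) != sp:
                    continue
                ka, kb = chrom_of.get(a), chrom_of.get(b)
                if ka is None or kb is None:
                    continue
                p_total += 1
                if ka == kb:
                    x += 1
            log_tail += _log10_tail(g_total, v, p_total, x)
        return log_tail

    rows = []
    results: dict[int, CVBResult] = {}
    for K in k_range:
        best_res = None
        best_tail = np.inf
        for r in range(max(1, n_restarts)):
            cfg = CVBConfig(
                K=K, alpha=base.alpha, beta=base.beta, L=base.L,
                max_iter=base.max_iter, anneal_base=base.anneal_base,
                anneal_cutoff_iter=base.anneal_cutoff_iter, tol=base.tol,
                seed=base.seed + 1009 * K + r,
            )
            res = cvb0_fit(tensor, cfg)
            tail = assignment_log_tail(assign_segments(res))
            if tail < best_tail:
                best_res, best_tail = res, tail
        results[K] = best_res
        rows.append((K, best_tail, best_res.converged, best_res.n_iter))
    table = pd.DataFrame(rows, columns=["K", "log10_tail", "converged", "n_iter"])
    chosen = int(table.loc[table["log10_tail"].idxmin(), "K"])
    return chosen, table, results
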