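"""Exact hypergeometric significance machinery.

All enrichment questions in this package reduce to the same null: *m* marked
gene pairs (paralogue or orthologue pairs) scattered uniformly over *g*
candidate gene pairs, with *n* of the candidates falling in a focal class.
The tail probability P(X >= x) of observing x or more marked pairs in the
focal class is the significance of the observation.

Pair-counting conventions (applied consistently everywhere):

* pairs are unordered;
* "gene pairs between two segments A and B" means ``|A| * |B|`` for A != B
  and ``C(|A|, 2)`` within one segment;
* ``g`` is the genome-wide total on the same scale (``C(N, 2)`` within one
  species, ``N_a * N_b`` between two species).

No multiple-testing correction is applied; callers use raw thresholds with
strict ``<`` semantics.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom as _scipy_hypergeom

__all__ = [
    "hypergeom_point",
    "hypergeom_tail",
    "screen_pairs",
]


def _check_query(g: int, m: int, n: int, x: int) -> None:
    for name, v in (("g", g), ("m", m), ("n", n), ("x", x)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if m > g or n > g:
        raise ValueError(f"marked ({m}) and focal ({n}) totals must not exceed g={g}")


def hypergeom_point(g: int, m: int, n: int, x: int, exact: bool = False):
    """P(X = x): probability that exactly ``x`` of the ``m`` marked pairs fall
    in a focal class of ``n`` out of ``g`` candidate pairs.

    Equals C(g-n, m-x) * C(n, x) / C(g, m).  ``exact=True`` returns a
    :class:`fractions.Fraction` computed with integer binomials; the default
    is a float via :mod:`scipy.stats`.
    """
    _check_query(g, m, n, x)
    if x > n or x > m or m - x > g - n:
        return Fraction(0) if exact else 0.0
    if exact:
        return Fraction(math.comb(g - n, m - x) * math.comb(n, x), math.comb(g, m))
    return float(_scipy_hypergeom.pmf(x, g, m, n))


def hypergeom_tail(g: int, m: int, n: int, x: int, exact: bool = False):
    """Upper tail P(X >= x) under the uniform-scatter null.

    Non-increasing in ``x``; P(X >= 0) = 1.  ``exact=True`` sums exact
    rational point masses (used by oracle tests and the rational-mode
    scorers); the default uses the scipy survival function.
    """
    _check_query(g, m, n, x)
    if x <= 0:
        return Fraction(1) if exact else 1.0
    if exact:
        hi = min(m, n)
        return sum((hypergeom_point(g, m, n, i, exact=True) for i in range(x, hi + 1)),
                   Fraction(0))
    return float(_scipy_hypergeom.sf(x - 1, g, m, n))


def _pairs_within(k: int) -> int:
    return k * (k - 1) // 2


def screen_pairs(
    segment_genes: dict,
    marked_pairs: Iterable[tuple[str, str]],
    gene_to_segment: dict,
    mode: str = "paralogue",
    threshold: float = 1e-5,
    total_genes: tuple[int, int] | int | None = None,
    include_within: bool = False,
    segment_species: dict | None = None,
) -> pd.DataFrame:
    """Screen every segment pair for enrichment of marked gene pairs.

    Parameters
    ----------
    segment_genes
        Mapping segment id -> number of genes in the segment.  In
        ``"orthologue"`` mode the ids must be partitionable into the two
        species by the pairs themselves (cross-species pairs only).
    marked_pairs
        Gene-id pairs (paralogue pairs within one species, or orthologue
        pairs between two species, matching ``mode``).
    gene_to_segment
        Mapping gene id -> segment id.  Pairs whose genes do not resolve are
        ignored.
    mode
        ``"paralogue"``: both genes in one species; g = C(N, 2).
        ``"orthologue"``: genes in two species; g = N_a * N_b where the
        totals are given by ``total_genes``.
    total_genes
        Total gene count(s) defining the genome-wide pair total g.  A single
        int for paralogue mode (defaults to the sum over segments); a
        ``(N_a, N_b)`` tuple for orthologue mode (required there: the split
        of segments between species is the caller's knowledge).
    threshold
        Flagging threshold, strict: flagged iff tail < threshold.
    include_within
        Also test each segment against itself (n = C(size, 2)); paralogue
        mode only.
    segment_species
        Mapping segment id -> species.  Required in orthologue mode, where
        only cross-species segment pairs are testable.

    Returns
    -------
    DataFrame with columns seg_a, seg_b, n, x, tail, flagged — symmetric
    (each unordered segment pair appears once, seg_a <= seg_b).
    """
    if mode not in ("paralogue", "orthologue"):
        raise ValueError(f"unknown mode {mode!r}")
    sizes = {s: int(k) for s, k in segment_genes.items()}
    for s, k in sizes.items():
        if k <= 0:
            raise ValueError(f"segment {s!r} has no genes")

    # x per unordered segment pair
    x_counts: dict[tuple, int] = {}
    m = 0
    for a, b in marked_pairs:
        sa = gene_to_segment.get(a)
        sb = gene_to_segment.get(b)
        if sa is None or sb is None:
            continue
        m += 1
        key = (sa, sb) if str(sa) <= str(sb) else (sb, sa)
        x_counts[key] = x_counts.get(key, 0) + 1

    if mode == "paralogue":
        n_total = int(total_genes) if total_genes is not None else sum(sizes.values())
        g = _pairs_within(n_total)
    else:
        if total_genes is None or np.isscalar(total_genes):
            raise ValueError("orthologue mode needs total_genes=(N_a, N_b)")
        if segment_species is None:
            raise ValueError("orthologue mode needs segment_species")
        na, nb = total_genes
        g = int(na) * int(nb)

    seg_ids = sorted(sizes, key=str)
    rows = []
    for i, a in enumerate(seg_ids):
        start = i if (include_within and mode == "paralogue") else i + 1
        for b in seg_ids[start:]:
            if mode == "orthologue" and segment_species[a] == segment_species[b]:
                continue
            n = _pairs_within(sizes[a]) if a == b else sizes[a] * sizes[b]
            x = x_counts.get((a, b) if str(a) <= str(b) else (b, a), 0)
            n = min(n, g)
            x = min(x, min(n, m))
            tail = hypergeom_tail(g, m, n, x)
            rows.append((a, b, n, x, tail, bool(tail < threshold)))
    return pd.DataFrame(rows, columns=["seg_a", "seg_b", "n", "x", "tail", "flagged"])
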