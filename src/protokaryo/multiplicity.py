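"""Combinatorial test of polyploidy versus independent chromosome duplications.

An ancestral genome of ``K`` chromosomes goes through zero, one or two
whole-genome duplications, leaving ``N`` copies of every chromosome
(``X_k = N`` for all k, ``X = K*N`` chromosomes in total).  Afterwards single
chromosomes duplicate independently, one at a time, each extant chromosome
equally likely to duplicate, until there are ``Y`` chromosomes; chromosome
``k`` of the ancestor ends with multiplicity ``Y_k`` (``sum Y_k = Y``).

If the observed multiplicities cluster tightly around a ploidy level ``M``
(six in a tetraploidization-plus-hexaploidization history), that convergence
is unlikely to arise from independent duplications alone.  The test statistic
is the total deviation ``delta = sum_k |Y_k - M|`` and the reported quantity
is the exact conditional probability

    P( delta <= D  |  sum_k Y_k = Y )

under the uniform sequential-duplication null.  The number of ordered
duplication histories ending at a given multiplicity vector is

    S(Y_1..Y_K) = (Y_1-N, ..., Y_K-N)! * prod_k Gamma(Y_k)/Gamma(N)

(multinomial coefficient interleaving the per-chromosome duplication orders,
times the per-chromosome ordered-tree counts), and the total over all
vectors is ``T = Gamma(Y)/Gamma(X)``.  Because the probabilities of interest
are ~1e-5, everything is computed in exact rational arithmetic; the dynamic
program below factorizes the sum over vectors per chromosome with state
(remaining total, remaining deviation budget).

Note on symbols: the total history count Gamma(Y)/Gamma(X) is called
``total_histories`` here (elsewhere in this package T denotes the number of
post-WGD species; the two are unrelated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "Scenario",
    "deviation",
    "scenario_count",
    "total_histories",
    "scenario_probability",
    "evaluate_scenarios",
    "simulate_duplication_process",
    "PAPER_SCENARIOS",
]


def deviation(y_vector: Sequence[int], m: int) -> int:
    """Total deviation ``sum_k |Y_k - M|`` of a multiplicity vector from the
    expected ploidy level ``m``."""
    y = list(y_vector)
    if not y:
        raise ValueError("empty multiplicity vector")
    if any(v < 1 for v in y):
        raise ValueError("multiplicities must be >= 1")
    return int(sum(abs(int(v) - int(m)) for v in y))


def _gamma_ratio(y: int, n: int) -> int:
    """Gamma(y)/Gamma(n) = (y-1)!/(n-1)! for integers y >= n >= 1."""
    out = 1
    for i in range(n, y):
        out *= i
    return out


def total_histories(y_total: int, x_total: int) -> int:
    """Number of ordered duplication histories growing ``x_total`` chromosomes
    into ``y_total``: Gamma(Y)/Gamma(X)."""
    if y_total < x_total or x_total < 1:
        raise ValueError("need Y >= X >= 1")
    return _gamma_ratio(y_total, x_total)


def scenario_count(y_vector: Sequence[int], n: int) -> int:
    """Number of ordered duplication histories ending at the given
    multiplicity vector, starting from ``n`` copies of each chromosome."""
    y = [int(v) for v in y_vector]
    if any(v < n for v in y):
        raise ValueError(f"every multiplicity must be >= N={n}")
    d = [v - n for v in y]
    multinom = math.factorial(sum(d))
    for di in d:
        multinom //= math.factorial(di)
    trees = 1
    for v in y:
        trees *= _gamma_ratio(v, n)
    return multinom * trees


@dataclass
class Scenario:
    """One duplication-history hypothesis.

    K ancestral chromosomes, each with ``N`` copies after polyploidization;
    expected multiplicity ``M``; observed total ``Y`` and deviation bound
    ``D`` (derivable from ``y_vector`` when given).
    """

    K: int
    N: int
    M: int
    Y: int | None = None
    D: int | None = None
    y_vector: tuple[int, ...] | None = None
    name: str = ""

    def __post_init__(self):
        if self.y_vector is not None:
            self.y_vector = tuple(int(v) for v in self.y_vector)
            if len(self.y_vector) != self.K:
                raise ValueError("y_vector length must equal K")
            if any(v < self.N for v in self.y_vector):
                raise ValueError("every Y_k must be >= N")
            y = sum(self.y_vector)
            d = deviation(self.y_vector, self.M)
            if self.Y is None:
                self.Y = y
            elif self.Y != y:
                raise ValueError(f"Y={self.Y} inconsistent with vector sum {y}")
            if self.D is None:
                self.D = d
            elif self.D != d:
                raise ValueError(f"D={self.D} inconsistent with vector deviation {d}")
        if self.Y is None or self.D is None:
            raise ValueError("Y and D must be given or derivable from y_vector")
        if self.N < 1 or self.K < 1:
            raise ValueError("K and N must be >= 1")
        if self.Y < self.K * self.N:
            raise ValueError("Y must be >= K*N")


def scenario_probability(scenario: Scenario, exact: bool = True):
    """Exact P(delta <= D | sum Y_k = Y) under uniform sequential duplication.

    Dynamic program over chromosomes with state (total assigned so far,
    deviation budget used); per-chromosome weight for multiplicity y is
    ``Gamma(y)/Gamma(N) / (y-N)!`` — the shared multinomial numerator
    ``(Y - K*N)!`` and the normalizer ``T`` are applied once at the end.
    Rational arithmetic throughout when ``exact`` (default); ``exact=False``
    converts the exact result to float.
    """
    K, N, M, Y, D = scenario.K, scenario.N, scenario.M, scenario.Y, scenario.D
    X = K * N
    # per-k support: y >= N, and |y - M| <= D caps y above; below, y cannot
    # drop under N.  Upper cap also from the grand total.
    y_max_global = min(M + D, Y - (K - 1) * N)
    weights: dict[int, Fraction] = {}
    for y in range(N, y_max_global + 1):
        weights[y] = Fraction(_gamma_ratio(y, N), math.factorial(y - N))

    # state: {(total, dev_used): sum of product weights}
    states: dict[tuple[int, int], Fraction] = {(0, 0): Fraction(1)}
    for k in range(K):
        remaining = K - 1 - k  # chromosomes after this one
        new_states: dict[tuple[int, int], Fraction] = {}
        for (tot, dev), w0 in states.items():
            for y, wy in weights.items():
                dv = dev + abs(y - M)
                if dv > D:
                    continue
                t = tot + y
                # feasibility: remaining chromosomes need >= N each and can
                # absorb at most y_max_global each
                if t + remaining * N > Y:
                    continue
                if t + remaining * y_max_global < Y:
                    continue
                key = (t, dv)
                new_states[key] = new_states.get(key, Fraction(0)) + w0 * wy
        states = new_states
    mass = sum((w for (tot, _), w in states.items() if tot == Y), Fraction(0))
    if mass == 0:
        import warnings

        warnings.warn("no multiplicity vector satisfies the constraints")
        return Fraction(0) if exact else 0.0
    p = mass * math.factorial(Y - X) / total_histories(Y, X)
    return p if exact else float(p)


# printed reconstruction: multiplicities of the 17 reconstructable ancestral
# chromosomes, and its integer halving used by the pre-duplication scenarios
OBSERVED_MULTIPLICITY = (6, 5, 6, 6, 7, 7, 6, 6, 4, 6, 8, 5, 6, 4, 9, 6, 6)

PAPER_SCENARIOS = {
    "A": dict(N=1, M=6, halved=False),  # duplications only, no tetraploidization
    "B": dict(N=2, M=6, halved=False),  # one tetraploidization, then duplications
    "C": dict(N=4, M=6, halved=False),  # two tetraploidizations, then duplications
    "D": dict(N=1, M=3, halved=True),   # duplications, then one tetraploidization
    "E": dict(N=2, M=3, halved=True),   # 1R, duplications, then 2R
}


def _halve(vector: Sequence[int], n: int) -> tuple[int, ...]:
    # integer halving of the observed multiplicities for scenarios in which a
    # final tetraploidization doubles the counts; clamped at the minimum N
    return tuple(max(max(1, n), int(v) // 2) for v in vector)


def evaluate_scenarios(
    y_vector: Sequence[int] = OBSERVED_MULTIPLICITY,
    scenarios: Sequence[str] = ("A", "B", "C", "D", "E"),
    alpha: float = 0.05,
    k18: bool = False,
    k5: bool = False,
) -> list[dict]:
    """Evaluate the named duplication scenarios on a multiplicity vector.

    Returns one record per scenario with the exact probability (as both a
    Fraction and a float), the configuration used, and a verdict at
    ``alpha`` ("rejected" means independent chromosome-scale duplications
    cannot plausibly produce the observed convergence).

    ``k18`` appends an extra chromosome with multiplicity max(1, N) (the
    unreconstructed eighteenth chromosome); ``k5`` evaluates the K=5 variant
    restricted to the largest, most reliable chromosomes (multiplicity six
    each, so Y = 30 and D = 0).
    """
    base = tuple(int(v) for v in y_vector)
    out = []
    for name in scenarios:
        cfg = PAPER_SCENARIOS[name]
        n, m = cfg["N"], cfg["M"]
        vec = _halve(base, n) if cfg["halved"] else base
        variants: list[tuple[str, tuple[int, ...]]] = [("", vec)]
        if k18:
            variants.append(("K18", vec + (max(1, n),)))
        if k5:
            variants.append(("K5", (m,) * 5))
        for tag, v in variants:
            sc = Scenario(K=len(v), N=n, M=m, y_vector=v,
                          name=f"{name}{'-' + tag if tag else ''}")
            p = scenario_probability(sc)
            out.append(
                {
                    "scenario": sc.name,
                    "K": sc.K,
                    "N": sc.N,
                    "M": sc.M,
                    "Y": sc.Y,
                    "D": sc.D,
                    "probability": float(p),
                    "probability_exact": p,
                    "verdict": "rejected" if p < alpha else "not rejected",
                }
            )
    return out


def simulate_duplication_process(
    K: int, N: int, Y: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws of multiplicity vectors under the uniform
    sequential-duplication null (test utility / cross-check of the DP).

    Starts with ``N`` copies of each of ``K`` chromosomes; repeatedly picks
    an extant chromosome uniformly and duplicates it until ``Y`` chromosomes
    exist.  Returns an (n_draws, K) array of multiplicity vectors.
    """
    out = np.empty((n_draws, K), dtype=np.int64)
    for i in range(n_draws):
        y = np.full(K, N, dtype=np.int64)
        total = K * N
        while total < Y:
            # chromosome k holds y[k] of the extant chromosomes
            k = rng.choice(K, p=y / total)
            y[k] += 1
            total += 1
        out[i] = y
    return out
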