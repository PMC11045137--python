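"""Paired sign-flip permutation comparison of per-split AUC vectors.

Two models evaluated on the same n splits yield paired AUC vectors A and T.
Under the null of no systematic difference, each entry of the gap vector
gv = A - T is symmetric about zero, so flipping signs of its entries leaves
the distribution of the summed gap t = sum(gv) unchanged.  The test compares
t against the 2^n sign-flipped mock gaps m = sn . gv, either by Monte Carlo
sampling of sign vectors or by full enumeration (exact for n <= 20).
Comparisons are non-strict (t <= m), so ties count against significance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GapVector",
    "PermutationResult",
    "gap_vector",
    "permutation_test_mc",
    "permutation_test_exact",
]


@dataclass
class GapVector:
    """Elementwise AUC differences and their sum t."""

    gv: np.ndarray
    t: float


@dataclass
class PermutationResult:
    p1: float  # one-sided
    p2: float  # two-sided
    method: str  # "monte_carlo" | "exact"
    n_draws: int  # iterations, or 2^n for enumeration
    seed: int | None = None


def gap_vector(A: Sequence[float], T: Sequence[float]) -> GapVector:
    """gv = A - T with the summed true gap t."""
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    if A.shape != T.shape:
        raise ValueError("AUC vectors must have equal length")
    gv = A - T
    return GapVector(gv=gv, t=float(gv.sum()))


def permutation_test_mc(gv: GapVector, iterations: int = 35000,
                        seed: int = 0) -> PermutationResult:
    """Monte Carlo sign-flip test.

    Each iteration draws a random sign vector sn in {-1, +1}^n and forms the
    mock gap m = sn . gv.  p1 = (#{t <= m} + 1) / (iterations + 1);
    p2 = (#{t <= |m|} + 1) / (iterations + 1).
    """
    rng = np.random.default_rng(seed)
    g = gv.gv
    if g.size < 1:
        raise ValueError("empty gap vector")
    signs = rng.choice([1.0, -1.0], size=(iterations, g.size))
    m = signs @ g
    p1 = (int(np.sum(gv.t <= m)) + 1) / (iterations + 1)
    p2 = (int(np.sum(gv.t <= np.abs(m))) + 1) / (iterations + 1)
    return PermutationResult(p1=p1, p2=p2, method="monte_carlo",
                             n_draws=iterations, seed=seed)


def permutation_test_exact(gv: GapVector) -> PermutationResult:
    """Exact sign-flip test by enumeration of all 2^n sign patterns.

    p = (#patterns satisfying the comparison) / 2^n; the identity pattern
    always satisfies it, so p > 0.  Refused for n > 20 (use Monte Carlo).
    """
    g = gv.gv
    n = g.size
    if n > 20:
        raise ValueError("enumeration limited to length <= 20; use Monte Carlo")
    signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
    m = signs @ g
    total = 2 ** n
    p1 = int(np.sum(gv.t <= m)) / total
    p2 = int(np.sum(gv.t <= np.abs(m))) / total
    return PermutationResult(p1=p1, p2=p2, method="exact", n_draws=total)
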