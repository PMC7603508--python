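"""Closed-form expected precision of genomic estimated breeding values.

The expected squared correlation between true and estimated breeding values
for a training population of size N, a trait influenced by M effective loci
(loci in LD with the genes underlying the trait) and heritability h^2 is
approximated by

    r^2 = N h^2 / (N h^2 + M (1 - h^2))

which is exact in N h^2 and M (1 - h^2) up to scale: multiplying both N and
M by the same constant leaves the precision unchanged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_N = (10, 269, 534, 1000)
DEFAULT_H2 = (0.5, 0.8)
VERY_HIGH = 0.8


def precision(N: float, M: float, h2: float) -> float:
    """Expected GEBV precision r^2 = N h^2 / (N h^2 + M (1 - h^2)).

    N >= 1 is the training-population size, M >= 0 the number of effective
    loci, h2 in (0, 1] the heritability. M = 0 returns 1.0 (no unlinked
    noise loci); h2 = 0 is defined as 0 with a warning.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if M < 0:
        raise ValueError("M must be >= 0")
    if not 0 <= h2 <= 1:
        raise ValueError("h2 must lie in [0, 1]")
    if h2 == 0:
        warnings.warn("h2 = 0: precision defined as 0", stacklevel=2)
        return 0.0
    if M == 0:
        return 1.0
    return float(N * h2 / (N * h2 + M * (1 - h2)))


def classify_architecture(M: float) -> str:
    """Trait-architecture class from the number of effective loci."""
    if M <= 10:
        return "oligogenic"
    if M <= 100:
        return "complex"
    if M <= 1000:
        return "very complex"
    return "beyond"


def precision_grid(N_list=DEFAULT_N, M_range: np.ndarray | None = None,
                   h2_list=DEFAULT_H2, very_high: float = VERY_HIGH) -> pd.DataFrame:
    """Full precision grid with architecture labels and very-high flags.

    Default M grid is log-spaced over [1, 1e6] (200 points), matching the
    published parameter sweep design.
    """
    if M_range is None:
        M_range = np.unique(np.rint(np.geomspace(1, 1_000_000, 200)).astype(int))
    rows = []
    for N in N_list:
        for h2 in h2_list:
            for M in M_range:
                r = precision(N, M, h2)
                rows.append({
                    "N": N, "M": int(M), "h2": h2, "precision": r,
                    "architecture": classify_architecture(M),
                    "very_high": r >= very_high,
                })
    return pd.DataFrame(rows)
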