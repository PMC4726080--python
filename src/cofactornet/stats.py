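"""Shared statistical primitives: hypergeometric tails, BH adjustment,
half-up percentage rounding used by all report tables."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def hypergeom_right_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    By convention the right tail at k=0 includes all probability mass, so an
    observation of zero marked elements always yields p = 1.
    """
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of the report tables),
    avoiding banker's rounding."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)
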