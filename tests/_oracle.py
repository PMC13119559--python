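"""Brute-force reference implementations of the intensity statistics.

Everything here is written with explicit Python loops over category pairs,
directly transcribing the defining ratios, and deliberately shares no code
with the package. Used to cross-check the vectorized implementations.
"""

from __future__ import annotations

import math


def oracle_interval(c: list[list[float]], dy: float) -> tuple[float, float, float]:
    """(gross change, gross %, annual intensity S_t) by explicit summation."""
    j = len(c)
    total = sum(c[i][k] for i in range(j) for k in range(j))
    gross = sum(c[i][k] for i in range(j) for k in range(j) if i != k)
    return gross, gross / total * 100.0, gross / dy / total * 100.0


def oracle_uniform(mats: list[tuple[list[list[float]], float]]) -> float:
    """U = Σ gross_t / Σ (ΔY_t · total_t) × 100."""
    num = 0.0
    den = 0.0
    for c, dy in mats:
        j = len(c)
        num += sum(c[i][k] for i in range(j) for k in range(j) if i != k)
        den += dy * sum(c[i][k] for i in range(j) for k in range(j))
    return num / den * 100.0


def oracle_gain_loss(c: list[list[float]], dy: float, k: int) -> tuple[float, float]:
    """(G_tk, L_tk) for category index k; NaN on zero denominator."""
    j = len(c)
    end = sum(c[i][k] for i in range(j))
    start = sum(c[k][i] for i in range(j))
    gain = sum(c[i][k] for i in range(j) if i != k)
    loss = sum(c[k][i] for i in range(j) if i != k)
    g = gain / dy / end * 100.0 if end > 0 else math.nan
    lo = loss / dy / start * 100.0 if start > 0 else math.nan
    return g, lo


def oracle_transition(
    c: list[list[float]], dy: float, n: int
) -> tuple[dict[int, float], float]:
    """({m: R_tmn}, W_tn) for gaining category index n."""
    j = len(c)
    rs: dict[int, float] = {}
    for m in range(j):
        if m == n:
            continue
        start_m = sum(c[m][i] for i in range(j))
        rs[m] = c[m][n] / dy / start_m * 100.0 if start_m > 0 else math.nan
    num = sum(c[i][n] for i in range(j) if i != n)
    den = sum(c[i][k] for i in range(j) if i != n for k in range(j))
    w = num / dy / den * 100.0 if den > 0 else math.nan
    return rs, w
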