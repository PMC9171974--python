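"""Two-stage Benjamini-Hochberg (TSBH) adaptive FDR adjustment.

Stage 1 runs plain BH at level ``alpha / (1 + alpha)`` and uses the number
of rejections ``R1`` to estimate the number of true nulls
``m0_hat = m - R1`` (floored at 1).  Stage 2 is the BH step-up with
``m0_hat`` in place of ``m``, so the adjusted p-values are the monotone
minima of ``m0_hat * p_(i) / i``.  With ``R1 = 0`` the procedure reduces to
plain BH; with ``R1 > 0`` it is uniformly less conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AdjustedPValues", "bh_adjust", "tsbh_adjust"]


@dataclass
class AdjustedPValues:
    raw: np.ndarray
    adjusted: np.ndarray
    alpha: float
    m0_hat: int

    def rejections(self, alpha: float | None = None) -> np.ndarray:
        """Indices with FDR-adjusted p below the target level."""
        level = self.alpha if alpha is None else alpha
        return np.flatnonzero(self.adjusted < level)


def _step_up(p: np.ndarray, multiplier: int) -> np.ndarray:
    """BH-type adjusted p-values with an arbitrary null-count multiplier.

    Stable sort (p, then input order) for deterministic tie handling.
    """
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * multiplier / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Plain Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return _step_up(p, p.size)


def tsbh_adjust(pvals, alpha: float = 0.05) -> AdjustedPValues:
    """Two-stage BH adjusted p-values at target FDR level ``alpha``.

    NaN inputs (failed tests) are carried through as NaN and excluded from
    the null-count estimate.
    """
    p_in = np.asarray(list(pvals), dtype=float)
    if p_in.size == 0:
        raise ValueError("empty p-value vector")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    ok = np.isfinite(p_in)
    p = p_in[ok]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    stage1 = _step_up(p, m)
    r1 = int(np.sum(stage1 <= alpha / (1.0 + alpha)))
    m0_hat = max(m - r1, 1)
    adjusted = _step_up(p, m0_hat)
    out = np.full(p_in.size, np.nan)
    out[ok] = adjusted
    return AdjustedPValues(raw=p_in, adjusted=out, alpha=alpha, m0_hat=m0_hat)
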