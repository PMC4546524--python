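"""The large-size-ratio (LSR) statistic and its threshold optimization.

LSR(sample; delta) is the fraction of a sample's CNV fragments whose size
is at least the large-size threshold delta (bp).  Recurrent patients carry
a heavier CNV size tail, so their LSR is shifted upward at a well-chosen
delta.  delta is tuned on training data by maximizing the AUC of LSR
against the outcome labels over a log10(bp) grid; the decision cutoff on
the LSR score itself is tuned by maximizing the Youden index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segment_io import SampleProfile

#: Default search grid for delta, in log10(bp): 3.3 .. 6.5 in steps of 0.1
#: (~2 kb, the minimum retained fragment size, up to ~3.2 Mb).
DEFAULT_DELTA_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(3.3, 6.5 + 1e-9, 0.1), 10)
)


class EmptyProfileError(ValueError):
    """LSR of a sample with zero retained segments is undefined, not 0."""


@dataclass
class LSRParams:
    """A fitted LSR decision rule: size threshold and score cutoff."""

    delta: float  # bp
    lsr_cutoff: float
    delta_grid: tuple[float, ...] = DEFAULT_DELTA_GRID

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not (0.0 <= self.lsr_cutoff <= 1.0):
            raise ValueError("lsr_cutoff must lie in [0, 1]")
        if np.any(np.diff(self.delta_grid) <= 0):
            raise ValueError("delta_grid must be strictly increasing")


def log10_to_bp(exponent: float) -> int:
    """Convert a log10 threshold to an integer bp value, e.g. 4.5 -> 31622."""
    if not math.isfinite(exponent):
        raise ValueError("exponent must be finite")
    return int(math.floor(10.0 ** exponent))


def compute_lsr(profile: SampleProfile, delta: float) -> float:
    """Proportion of the profile's fragments with size >= delta ("large")."""
    if profile.n_segments == 0:
        raise EmptyProfileError(
            f"sample {profile.sample_id}: LSR undefined on an empty profile"
        )
    return float(np.count_nonzero(profile.sizes >= delta)) / profile.n_segments


def lsr_matrix(
    profiles: Sequence[SampleProfile], grid_log10: Sequence[float]
) -> np.ndarray:
    """LSR of every profile at every grid delta: shape (n_samples, n_grid).

    Uses one sort per sample and a searchsorted sweep over the grid, so the
    delta optimization is linear in grid size rather than quadratic.
    """
    deltas = np.array([log10_to_bp(g) for g in grid_log10], dtype=float)
    out = np.empty((len(profiles), deltas.size))
    for i, p in enumerate(profiles):
        if p.n_segments == 0:
            raise EmptyProfileError(
                f"sample {p.sample_id}: LSR undefined on an empty profile"
            )
        sizes = np.sort(p.sizes)
        # count of sizes >= delta = n - first index where sizes >= delta
        out[i] = (sizes.size - np.searchsorted(sizes, deltas, side="left")) / sizes.size
    return out


def optimize_delta(
    profiles: Sequence[SampleProfile],
    labels: Sequence[int],
    grid_log10: Sequence[float] = DEFAULT_DELTA_GRID,
) -> tuple[float, float, np.ndarray]:
    """Pick the grid delta maximizing AUC of LSR against the labels.

    Returns ``(delta_bp, auc_at_delta, curve)`` where ``curve`` is the full
    (log10_delta, auc) table, one row per grid point, for plotting.  Ties
    are broken toward the smallest delta (deterministic).
    """
    from .evaluation import roc_auc  # local import: avoid a module cycle

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("delta optimization needs both classes present")
    scores = lsr_matrix(profiles, grid_log10)
    aucs = np.array([roc_auc(scores[:, j], y)[1] for j in range(scores.shape[1])])
    best = int(np.argmax(aucs))  # argmax takes the first (smallest) maximizer
    curve = np.column_stack([np.asarray(grid_log10, dtype=float), aucs])
    return float(log10_to_bp(grid_log10[best])), float(aucs[best]), curve


def youden_cutoff_candidates(scores: Sequence[float]) -> np.ndarray:
    """Candidate decision cutoffs: the distinct observed scores plus the
    midpoints of adjacent distinct scores."""
    vals = np.unique(np.asarray(scores, dtype=float))
    if vals.size == 1:
        return vals
    mids = (vals[:-1] + vals[1:]) / 2.0
    return np.unique(np.concatenate([vals, mids]))


def fit_lsr_cutoff(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """Score cutoff maximizing the Youden index (sens + spec - 1).

    The decision rule is ``score >= cutoff -> positive``.  Returns
    ``(cutoff, youden)``; ties broken toward the smallest cutoff, so for
    perfectly separated classes the midpoint between them is returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cutoff fitting needs both classes present")
    candidates = youden_cutoff_candidates(s)
    # vectorized sweep: sens/spec at every candidate
    pred = s[None, :] >= candidates[:, None]  # (n_cand, n_samples)
    sens = (pred & (y == 1)[None, :]).sum(axis=1) / n_pos
    spec = (~pred & (y == 0)[None, :]).sum(axis=1) / n_neg
    youden = sens + spec - 1.0
    # smallest candidate within numerical noise of the maximum: the same
    # cutoff regardless of the float summation order of sens/spec
    best = int(np.argmax(youden >= youden.max() - 1e-12))
    return float(candidates[best]), float(youden[best])
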