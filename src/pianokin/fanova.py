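"""Pointwise functional ANOVA over normalized-time curves.

Given groups of curves sampled on a common normalized-time grid (velocity
and acceleration channels treated separately), a one-way F statistic is
computed at every grid point.  The result records, per channel, the F
profile, the critical values at the requested alpha levels, the
significance masks, and the fraction of the region that reaches
significance — the quantity used downstream to select which portions of the
trajectories feed the performer classifier.

The p-values are pointwise (unadjusted); a stricter alpha level (0.001 by
default) serves as the conservative mask.  Degrees of freedom come from the
realized numbers of groups and curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["FanovaResult", "ChannelFanova", "pointwise_fanova", "critical_f"]


def critical_f(df1: int, df2: int, alpha: float) -> float:
    """Upper-alpha quantile of the F(df1, df2) distribution.

    critical_f(3, 41, 0.05) = 2.83: the threshold for comparing four
    performers with 45 curves at every grid point.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(stats.f.isf(alpha, df1, df2))


@dataclass
class ChannelFanova:
    """Pointwise F test results for one channel (velocity or acceleration)."""

    F: np.ndarray
    critical: dict[float, float]
    mask: dict[float, np.ndarray] = field(init=False)
    significant_fraction: dict[float, float] = field(init=False)

    def __post_init__(self):
        self.mask = {a: self.F > c for a, c in self.critical.items()}
        self.significant_fraction = {a: float(np.mean(m)) for a, m in self.mask.items()}


@dataclass
class FanovaResult:
    """Functional ANOVA over one or more channels on a shared grid."""

    grid: np.ndarray
    channels: dict[str, ChannelFanova]
    df_between: int
    df_within: int
    alphas: tuple[float, ...]

    def combined_mask(self, alpha: float) -> np.ndarray:
        """Union of the channel masks: points where any channel separates groups."""
        masks = [ch.mask[alpha] for ch in self.channels.values()]
        return np.logical_or.reduce(masks)


def _f_oneway_pointwise(Y: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Vectorized one-way F across groups at each column of Y (curves x grid)."""
    groups = np.unique(labels)
    k = len(groups)
    n = Y.shape[0]
    grand = Y.mean(axis=0)
    ss_between = np.zeros(Y.shape[1])
    ss_within = np.zeros(Y.shape[1])
    for g in groups:
        Yg = Y[labels == g]
        mg = Yg.mean(axis=0)
        ss_between += len(Yg) * (mg - grand) ** 2
        ss_within += ((Yg - mg) ** 2).sum(axis=0)
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    return np.nan_to_num(F, nan=0.0, posinf=np.inf), df_b, df_w


def pointwise_fanova(curves, group_labels, alphas=(0.05, 0.001),
                     grid=None) -> FanovaResult:
    """Pointwise one-way functional ANOVA.

    Parameters
    ----------
    curves : dict of channel name -> (n_curves, n_grid) arrays, or a single
        such array (treated as channel "value"), or a list of
        PhaseTrajectory objects (channels "velocity" and "acceleration").
    group_labels : one label per curve (e.g. performer identity).
    alphas : significance levels for masks and region fractions.
    grid : normalized-time grid; defaults to linspace(0, 1, n_grid).

    All channels must share one grid; at least two groups with two curves
    each are required.
    """
    from .similarity import PhaseTrajectory

    if isinstance(curves, dict):
        channels = {k: np.asarray(v, float) for k, v in curves.items()}
    elif len(curves) and isinstance(curves[0], PhaseTrajectory):
        channels = {
            "velocity": np.stack([t.velocity for t in curves]),
            "acceleration": np.stack([t.acceleration for t in curves]),
        }
    else:
        channels = {"value": np.asarray(curves, float)}
    widths = {v.shape[1] for v in channels.values()}
    if len(widths) != 1:
        raise ValueError("all channels must share one normalized-time grid")
    n_grid = widths.pop()
    labels = np.asarray(group_labels)
    n_curves = {v.shape[0] for v in channels.values()}
    if len(n_curves) != 1 or n_curves.pop() != len(labels):
        raise ValueError("one group label per curve required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 groups with at least 2 curves each")

    out = {}
    df_b = df_w = None
    for name, Y in channels.items():
        F, df_b, df_w = _f_oneway_pointwise(Y, labels)
        crit = {a: critical_f(df_b, df_w, a) for a in alphas}
        out[name] = ChannelFanova(F=F, critical=crit)
    g = np.linspace(0.0, 1.0, n_grid) if grid is None else np.asarray(grid, float)
    return FanovaResult(grid=g, channels=out, df_between=df_b, df_within=df_w,
                        alphas=tuple(alphas))
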