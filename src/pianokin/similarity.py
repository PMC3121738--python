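"""Procrustes shape similarity of velocity-acceleration phase trajectories.

Each movement is represented as an ordered set of (velocity, acceleration)
points on the normalized region time grid.  Two trajectories are compared by
full Procrustes superposition — optimal translation, rotation and uniform
scaling of one onto the other — and similarity is reported as ``1 - d``
with ``d`` the normalized least-squares residual, so 1 means identical
shape and 0 no shape agreement.

Two conventions matter and are configurable:

* the two axes carry different units (mm/s vs mm/s^2), so each axis is
  standardized to unit variance before superposition;
* reflections are *not* allowed by default — phase-plane orientation
  (direction of travel around the loop) is physically meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import NormalizedCurves

log = logging.getLogger(__name__)

__all__ = [
    "PhaseTrajectory", "SimilarityMatrix",
    "procrustes_similarity", "pairwise_similarity", "consistency_by_region",
]


@dataclass
class PhaseTrajectory:
    """A velocity-acceleration curve on the normalized time grid."""

    velocity: np.ndarray       # mm/s, indexed by tau
    acceleration: np.ndarray   # mm/s^2
    label: str                 # attack | keypress | at_rest
    finger: int
    performer_id: str | None = None
    trajectory_id: str | None = None

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, float)
        self.acceleration = np.asarray(self.acceleration, float)
        if self.velocity.shape != self.acceleration.shape or self.velocity.ndim != 1:
            raise ValueError("velocity and acceleration must be equal-length 1-d arrays")
        if not (np.all(np.isfinite(self.velocity)) and np.all(np.isfinite(self.acceleration))):
            raise ValueError("phase trajectory contains non-finite values")

    @classmethod
    def from_normalized(cls, curves: NormalizedCurves, performer_id=None,
                        trajectory_id=None) -> "PhaseTrajectory":
        return cls(curves.velocity, curves.acceleration, curves.region.label,
                   curves.region.finger, performer_id, trajectory_id)

    def points(self, standardize: bool = True) -> np.ndarray:
        """(n, 2) point matrix, optionally with unit-variance axes."""
        X = np.column_stack([self.velocity, self.acceleration])
        if standardize:
            sd = X.std(axis=0)
            if np.any(sd == 0):
                raise ValueError("degenerate trajectory: an axis has zero variance")
            X = X / sd
        return X


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Procrustes similarities."""

    values: np.ndarray
    index: list[str]

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.index, columns=self.index)

    def pair_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.index), k=1)
        return self.values[iu]


def _prepare_config(traj: PhaseTrajectory, standardize: bool) -> np.ndarray:
    """Centered, unit-norm configuration matrix for Procrustes analysis."""
    X = traj.points(standardize)
    X = X - X.mean(axis=0)
    nrm = np.linalg.norm(X)
    if nrm == 0:
        raise ValueError("degenerate trajectory: all points identical")
    return X / nrm


def procrustes_similarity(a: PhaseTrajectory, b: PhaseTrajectory,
                          allow_reflection: bool = False,
                          standardize: bool = True) -> float:
    """Shape similarity of two phase trajectories in [0, 1].

    Both point sets are centered and scaled to unit Frobenius norm, then b
    is rotated (and, with ``allow_reflection``, possibly reflected) and
    rescaled to best fit a.  The residual d = min ||a - s R b - t||^2 is
    the normalized Procrustes distance; the returned value is 1 - d.
    Identical shapes give 1.0 exactly; the measure is symmetric.
    """
    A = _prepare_config(a, standardize)
    B = _prepare_config(b, standardize)
    if A.shape != B.shape:
        raise ValueError("trajectories must have the same number of points")
    M = B.T @ A
    s = np.linalg.svd(M, compute_uv=False).sum() if allow_reflection else None
    if s is None:
        # rotation-only optimum: trace = sigma1 + sign(det M) * sigma2,
        # which for 2x2 M equals sqrt(||M||_F^2 + 2 det M)
        s = float(np.sqrt(max(np.sum(M**2) + 2.0 * np.linalg.det(M), 0.0)))
    d = 1.0 - s**2
    return float(1.0 - d)


def pairwise_similarity(trajectories: list[PhaseTrajectory],
                        allow_reflection: bool = False,
                        standardize: bool = True) -> SimilarityMatrix:
    """All-pairs similarity matrix, vectorized over trajectories."""
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    X = np.stack([_prepare_config(t, standardize) for t in trajectories])  # (n, p, 2)
    M = np.einsum("ipa,jpb->ijab", X, X)  # M[i,j] = X_i^T X_j (2x2 blocks)
    frob2 = np.einsum("ijab,ijab->ij", M, M)
    det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    if allow_reflection:
        # sigma1 + sigma2 = sqrt(frob2 + 2|det|)
        s = np.sqrt(np.maximum(frob2 + 2.0 * np.abs(det), 0.0))
    else:
        s = np.sqrt(np.maximum(frob2 + 2.0 * det, 0.0))
    vals = s**2
    np.fill_diagonal(vals, 1.0)
    vals = 0.5 * (vals + vals.T)  # exact symmetry against fp noise
    ids = [t.trajectory_id or str(i) for i, t in enumerate(trajectories)]
    return SimilarityMatrix(np.clip(vals, 0.0, 1.0), ids)


def consistency_by_region(trajectories: list[PhaseTrajectory],
                          group_keys=("performer_id", "finger"),
                          allow_reflection: bool = False,
                          standardize: bool = True) -> pd.DataFrame:
    """Mean within-group Procrustes similarity per region label.

    Trajectories are grouped by region label plus ``group_keys`` (by default
    the same finger of the same performer, the unit whose movement
    consistency is being asked about); all unordered distinct pairs within a
    group are compared (n trajectories -> n(n-1)/2 pairs).  Groups with a
    single trajectory are skipped with a warning.

    Returns a table with one row per label: mean similarity, pair count,
    trajectory count.
    """
    df = pd.DataFrame({
        "i": range(len(trajectories)),
        "label": [t.label for t in trajectories],
        **{k: [getattr(t, k) for t in trajectories] for k in group_keys},
    })
    out: dict[str, list] = {}
    for (label, *_), g in df.groupby(["label", *group_keys], dropna=False):
        if len(g) < 2:
            log.warning("skipping singleton trajectory group (label=%s)", label)
            continue
        sub = [trajectories[i] for i in g["i"]]
        sim = pairwise_similarity(sub, allow_reflection, standardize)
        vals = sim.pair_values()
        acc = out.setdefault(label, [])
        acc.append(vals)
    rows = []
    for label, chunks in out.items():
        vals = np.concatenate(chunks)
        rows.append({"label": label, "mean_similarity": float(vals.mean()),
                     "n_pairs": int(vals.size)})
    return pd.DataFrame(rows).set_index("label")
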