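"""Per-subject FC matrices and derived connectivity summaries.

Block averages use raw Pearson r by default (Fisher-z averaging is
available behind a flag); matrix-profile correlations use the strict
lower triangle of the designated ROI subset; the split-half noise
ceiling uses a contiguous first-half/second-half split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog import ROICatalog

__all__ = [
    "FCMatrix",
    "compute_fc_matrix",
    "average_block_fc",
    "laterality_fc",
    "minmax_normalize_profile",
    "matrix_profile_correlation",
    "split_half_noise_ceiling",
    "noise_ceiling_table",
]


@dataclass
class FCMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix for one subject."""

    roi_names: list[str]
    matrix: np.ndarray
    n_frames_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.roi_names)
        if self.matrix.shape != (n, n):
            raise ValueError("FC matrix shape does not match roi_names")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-10):
            raise ValueError("FC matrix must have unit diagonal")
        if np.any(self.matrix < -1.0 - 1e-12) or np.any(self.matrix > 1.0 + 1e-12):
            raise ValueError("FC entries must lie in [-1, 1]")

    def submatrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.roi_names.index(n) for n in names]
        return self.matrix[np.ix_(idx, idx)]


def compute_fc_matrix(series: np.ndarray, roi_names: list[str]) -> FCMatrix:
    """Full pairwise Pearson correlation of the retained frames."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(roi_names):
        raise ValueError("series must be frames x ROIs matching roi_names")
    if x.shape[0] < 10:
        raise ValueError(f"need at least 10 frames, got {x.shape[0]}")
    sd = x.std(axis=0)
    if np.any(sd == 0.0):
        bad = [roi_names[i] for i in np.flatnonzero(sd == 0.0)]
        raise ValueError(f"zero-variance ROI(s): {bad}")
    m = np.corrcoef(x, rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return FCMatrix(roi_names=list(roi_names), matrix=m, n_frames_used=x.shape[0])


def _pair_values(
    fc: FCMatrix, seed_set: Iterable[str], target_set: Iterable[str]
) -> np.ndarray:
    seeds, targets = list(seed_set), list(target_set)
    if not seeds or not targets:
        raise ValueError("seed and target sets must be non-empty")
    if set(seeds) & set(targets):
        raise ValueError(f"seed/target overlap: {sorted(set(seeds) & set(targets))}")
    order = {n: i for i, n in enumerate(fc.roi_names)}
    missing = [n for n in seeds + targets if n not in order]
    if missing:
        raise ValueError(f"ROIs not in FC matrix: {missing}")
    si = [order[n] for n in seeds]
    ti = [order[n] for n in targets]
    return fc.matrix[np.ix_(si, ti)]


def average_block_fc(
    fc: FCMatrix,
    seed_set: Iterable[str],
    target_set: Iterable[str],
    fisher_z: bool = False,
) -> float:
    """Arithmetic mean of r over all seed x target pairs.

    ``fisher_z=True`` averages arctanh(r) and back-transforms; the default
    is the plain mean of raw r values.
    """
    block = _pair_values(fc, seed_set, target_set)
    if fisher_z:
        return float(np.tanh(np.mean(np.arctanh(block))))
    return float(np.mean(block))


def laterality_fc(
    fc: FCMatrix,
    seed_set: Iterable[str],
    target_set: Iterable[str],
    catalog: ROICatalog,
) -> tuple[float, float]:
    """Mean r over same-hemisphere vs opposite-hemisphere seed-target pairs."""
    seeds, targets = list(seed_set), list(target_set)
    for label, names in (("seed", seeds), ("target", targets)):
        hemis = {catalog.hemisphere(n) for n in names}
        if hemis != {"L", "R"}:
            raise ValueError(f"{label} set must contain ROIs in both hemispheres")
    block = _pair_values(fc, seeds, targets)
    same = np.array(
        [[catalog.hemisphere(s) == catalog.hemisphere(t) for t in targets] for s in seeds]
    )
    return float(block[same].mean()), float(block[~same].mean())


def minmax_normalize_profile(values: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] via (x - min) / (max - min)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("all values equal; proportion undefined")
    return (x - lo) / (hi - lo)


def matrix_profile_correlation(
    fc_a: FCMatrix | np.ndarray,
    fc_b: FCMatrix | np.ndarray,
    roi_subset: Sequence[str] | None = None,
) -> float:
    """Pearson r between the strict lower triangles of two group matrices.

    Both matrices must cover the same ROI subset in the same order; the
    unique off-diagonal cells are vectorized and correlated.
    """
    def _sub(fc):
        if isinstance(fc, FCMatrix):
            if roi_subset is None:
                return fc.matrix
            return fc.submatrix(list(roi_subset))
        return np.asarray(fc, dtype=float)

    a, b = _sub(fc_a), _sub(fc_b)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and identically shaped")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 ROIs (3 unique off-diagonal cells)")
    tri = np.tril_indices(a.shape[0], k=-1)
    va, vb = a[tri], b[tri]
    if va.std() == 0.0 or vb.std() == 0.0:
        raise ValueError("degenerate (constant) off-diagonal profile")
    return float(np.corrcoef(va, vb)[0, 1])


def _profile(series: np.ndarray, roi: int) -> np.ndarray:
    """FC profile of one ROI: its correlations to every other ROI."""
    corr = np.corrcoef(series, rowvar=False)
    return np.delete(corr[roi], roi)


def split_half_noise_ceiling(series: np.ndarray, roi: int) -> float:
    """Split-half reliability of one ROI's connectivity profile.

    The series is split into contiguous halves (odd frame counts give the
    extra frame to the first half); per half, the ROI's FC profile is its
    correlation to all other ROIs, and the ceiling is the Pearson r
    between the two profiles.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a frames x ROIs array")
    t, n = x.shape
    if n < 3:
        raise ValueError("need at least 3 ROIs for a correlatable profile")
    if t < 20:
        raise ValueError("need at least 20 frames for a split-half estimate")
    if not 0 <= roi < n:
        raise ValueError(f"roi index {roi} out of range")
    cut = (t + 1) // 2
    p1, p2 = _profile(x[:cut], roi), _profile(x[cut:], roi)
    return float(np.corrcoef(p1, p2)[0, 1])


def noise_ceiling_table(series: np.ndarray, roi_names: list[str]) -> dict[str, float]:
    """Split-half noise ceiling for every ROI of one subject."""
    return {
        name: split_half_noise_ceiling(series, i) for i, name in enumerate(roi_names)
    }
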