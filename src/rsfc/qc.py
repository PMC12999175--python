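"""Quality control: DVARS, outlier flagging, window selection, dropout, exclusion.

Conventions (documented because downstream flags depend on them):

* DVARS at the first frame is defined as 0 and is never flagged on its own.
* Quantiles use linear interpolation between order statistics.
* "Exceeds" is strict at both the DVARS threshold and the outlier-count rule.
* Window ties break to the earliest start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "DvarsTrace",
    "QCReport",
    "QCThresholds",
    "compute_dvars",
    "flag_motion_outliers",
    "select_continuous_window",
    "detect_signal_dropout",
    "apply_exclusion_rules",
]


@dataclass
class DvarsTrace:
    """Per-frame RMS intensity difference between successive frames."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("DVARS trace must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("DVARS values must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class QCReport:
    """Outcome of all QC checks for one subject."""

    subject_id: str
    group: str
    outlier_mask: np.ndarray
    threshold: float
    retained_window: tuple[int, int]  # [start, end) frame indices
    n_outliers_in_window: int
    dropout_rois: list[str]
    excluded: bool
    exclusion_reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        start, end = self.retained_window
        if not (0 <= start < end <= self.outlier_mask.size):
            raise ValueError("retained_window out of bounds")
        if self.n_outliers_in_window != int(self.outlier_mask[start:end].sum()):
            raise ValueError("n_outliers_in_window inconsistent with mask")
        if self.excluded != bool(self.exclusion_reasons):
            raise ValueError("excluded flag inconsistent with exclusion_reasons")


@dataclass
class QCThresholds:
    """Group-specific QC settings (defaults mirror the study's rules)."""

    iqr_factor: float = 1.5
    window_length: int = 1600
    max_outlier_fraction: float = 0.10
    dropout_sd: float = 3.0
    adult_motion_mm: float = 2.0
    adult_motion_deg: float = 2.0

    def __post_init__(self) -> None:
        for name in ("iqr_factor", "max_outlier_fraction", "dropout_sd",
                     "adult_motion_mm", "adult_motion_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")


def compute_dvars(multichannel_series: np.ndarray) -> DvarsTrace:
    """RMS-across-channels of the frame-to-frame signal difference.

    ``values[t] = sqrt(mean_c((x[t, c] - x[t-1, c])**2))`` for ``t >= 1``;
    the first frame has no predecessor and is set to 0.
    """
    x = np.asarray(multichannel_series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("expected a frames x channels array")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute DVARS")
    diffs = np.diff(x, axis=0)
    values = np.sqrt(np.mean(diffs**2, axis=1))
    return DvarsTrace(values=np.concatenate([[0.0], values]))


def flag_motion_outliers(
    dvars: DvarsTrace | np.ndarray, iqr_factor: float = 1.5
) -> tuple[np.ndarray, float]:
    """Flag frames whose DVARS strictly exceeds Q75 + factor * IQR.

    Quantiles are computed with linear interpolation.  An all-equal trace
    yields a threshold equal to the common value and zero flags.
    """
    values = dvars.values if isinstance(dvars, DvarsTrace) else np.asarray(dvars, dtype=float)
    if values.size == 0:
        raise ValueError("empty DVARS trace")
    q25, q75 = np.percentile(values, [25.0, 75.0], method="linear")
    threshold = float(q75 + iqr_factor * (q75 - q25))
    return values > threshold, threshold


def select_continuous_window(
    outlier_mask: np.ndarray, window_length: int
) -> tuple[int, int]:
    """Contiguous window of exactly ``window_length`` frames with fewest flags.

    Ties break to the earliest start.  Returns ``(start, end)`` with the
    usual half-open convention.
    """
    mask = np.asarray(outlier_mask, dtype=bool)
    t = mask.size
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if window_length > t:
        raise ValueError(f"window_length {window_length} exceeds run length {t}")
    counts = np.convolve(mask.astype(int), np.ones(window_length, dtype=int), mode="valid")
    start = int(np.argmin(counts))  # argmin returns the first minimum
    return start, start + window_length


def detect_signal_dropout(
    parcel_means: np.ndarray,
    roi_means: Mapping[str, float],
    sd_cutoff: float = 3.0,
) -> list[str]:
    """ROIs whose mean intensity falls strictly below mu - cutoff * sigma.

    ``mu`` and ``sigma`` (sample SD) are computed across the subject's
    parcel means.  Degenerate case sigma == 0 returns an empty list.
    """
    parcels = np.asarray(parcel_means, dtype=float)
    if parcels.size < 2:
        raise ValueError("need at least 2 parcels")
    if not roi_means:
        raise ValueError("roi_means is empty")
    if any(v is None or not np.isfinite(v) for v in roi_means.values()):
        raise ValueError("roi_means contains missing values")
    mu = float(parcels.mean())
    sigma = float(parcels.std(ddof=1))
    if sigma == 0.0:
        return []
    cut = mu - sd_cutoff * sigma
    return [name for name, value in roi_means.items() if value < cut]


def apply_exclusion_rules(
    subject_id: str,
    group: str,
    dvars: DvarsTrace | np.ndarray,
    parcel_means: np.ndarray,
    roi_means: Mapping[str, float],
    motion_mm: float = 0.0,
    motion_deg: float = 0.0,
    thresholds: Optional[QCThresholds] = None,
) -> QCReport:
    """Run every QC rule for one subject and produce a verdict.

    Infant rule: select the continuous low-motion window (length capped at
    the run length) and exclude when the outlier count within it strictly
    exceeds ``max_outlier_fraction`` of the window.  Adult rule: exclude
    on head motion > 2 mm or rotation > 2 degrees; the whole run is
    retained.  Any-ROI signal dropout excludes in every group.
    """
    cfg = thresholds if thresholds is not None else QCThresholds()
    trace = dvars if isinstance(dvars, DvarsTrace) else DvarsTrace(np.asarray(dvars, dtype=float))
    mask, threshold = flag_motion_outliers(trace, iqr_factor=cfg.iqr_factor)
    t = len(trace)
    reasons: list[str] = []

    if group == "infant":
        window_length = min(cfg.window_length, t)
        window = select_continuous_window(mask, window_length)
        n_outliers = int(mask[window[0]:window[1]].sum())
        if n_outliers > int(round(cfg.max_outlier_fraction * window_length)):
            reasons.append("motion")
    else:
        window = (0, t)
        n_outliers = int(mask.sum())
        if motion_mm > cfg.adult_motion_mm or motion_deg > cfg.adult_motion_deg:
            reasons.append("motion")

    dropout = detect_signal_dropout(parcel_means, roi_means, sd_cutoff=cfg.dropout_sd)
    if dropout:
        reasons.append("dropout")

    return QCReport(
        subject_id=subject_id,
        group=group,
        outlier_mask=mask,
        threshold=threshold,
        retained_window=window,
        n_outliers_in_window=n_outliers,
        dropout_rois=dropout,
        excluded=bool(reasons),
        exclusion_reasons=reasons,
    )
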