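"""Denoising of retained ROI time series.

Default stage order (configurable, always recorded in provenance):
linear detrend -> nuisance component regression -> temporal filter ->
frame censoring.  Censoring runs last so the zero-phase filter never
spans gaps introduced by frame deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "CleanSeries",
    "detrend_linear",
    "temporal_filter",
    "extract_compcor_components",
    "regress_nuisance",
    "censor_frames",
    "clean_series",
]

MIN_RETAINED_FRAMES = 10


@dataclass
class CleanSeries:
    """Residual series plus an ordered record of the applied steps."""

    matrix: np.ndarray  # retained frames x ROIs
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.any(~np.isfinite(self.matrix)):
            raise ValueError("clean series contains non-finite values")


def _as_2d(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("expected a frames x channels array")
    return x


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Residual of a per-channel least-squares fit on intercept + time.

    The output is orthogonal to both regressors, so column means are zero
    and the residual has no linear trend.
    """
    x = _as_2d(series)
    t = x.shape[0]
    if t < 3:
        raise ValueError("need at least 3 frames to detrend")
    design = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def temporal_filter(
    series: np.ndarray,
    tr_seconds: float,
    lowpass_hz: float = 0.08,
    highpass_seconds: float | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth filter (forward-backward).

    Low-pass at ``lowpass_hz``; when ``highpass_seconds`` is given the
    band-pass ``[1/highpass_seconds, lowpass_hz]`` is applied in a single
    filter, the adult configuration (150 s high-pass, 0.08 Hz low-pass).
    """
    x = _as_2d(series)
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    nyquist = 0.5 / tr_seconds
    if lowpass_hz <= 0 or lowpass_hz >= nyquist:
        raise ValueError(f"lowpass_hz must lie in (0, {nyquist}) for TR={tr_seconds}")
    if highpass_seconds is not None:
        hp_hz = 1.0 / highpass_seconds
        if hp_hz >= lowpass_hz:
            raise ValueError("high-pass cutoff must lie below the low-pass cutoff")
        sos = sps.butter(order, [hp_hz, lowpass_hz], btype="bandpass", fs=1.0 / tr_seconds,
                         output="sos")
    else:
        sos = sps.butter(order, lowpass_hz, btype="lowpass", fs=1.0 / tr_seconds, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def extract_compcor_components(
    csf_series: np.ndarray,
    wm_series: np.ndarray,
    k: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """First ``k`` principal-component time courses of the nuisance channels.

    Channels are standardized (zero mean, unit variance), concatenated,
    and decomposed by SVD.  Zero-variance channels are dropped with a
    warning.  Component signs are fixed so the largest-magnitude loading
    is positive, for reproducibility.

    Returns
    -------
    components : ndarray, frames x k
        Mutually orthogonal PC scores ordered by explained variance.
    explained_variance_ratio : ndarray, length k
    """
    csf, wm = _as_2d(csf_series), _as_2d(wm_series)
    if csf.shape[0] != wm.shape[0]:
        raise ValueError("CSF and WM series must have the same frame count")
    x = np.hstack([csf, wm])
    sd = x.std(axis=0)
    dead = sd == 0.0
    if dead.any():
        warnings.warn(f"dropping {int(dead.sum())} zero-variance nuisance channel(s)")
        x, sd = x[:, ~dead], sd[~dead]
    if x.shape[1] == 0:
        raise ValueError("no nuisance channels with variance")
    if k < 1 or k > min(x.shape):
        raise ValueError(f"k must lie in [1, {min(x.shape)}]")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    u, s = u * flip, s  # flip applied to scores via u
    components = u[:, :k] * s[:k]
    evr = s**2 / np.sum(s**2)
    return components, evr[:k]


def regress_nuisance(series: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """Per-channel least-squares residual against intercept + regressors.

    All-zero regressor columns are dropped (regressing on nothing is the
    identity up to demeaning); a genuinely rank-deficient design is
    rejected.
    """
    x = _as_2d(series)
    r = _as_2d(regressors) if np.asarray(regressors).size else np.empty((x.shape[0], 0))
    if r.shape[0] != x.shape[0]:
        raise ValueError("regressor frame count differs from series")
    keep = np.ptp(r, axis=0) > 0.0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant/zero regressor column(s)")
    r = r[:, keep]
    design = np.column_stack([np.ones(x.shape[0]), r])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            f"rank-deficient nuisance design: rank {np.linalg.matrix_rank(design)} "
            f"< {design.shape[1]} columns"
        )
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def censor_frames(series: np.ndarray, outlier_mask: np.ndarray) -> np.ndarray:
    """Delete flagged frames; no interpolation.

    Rejects results with fewer than ``MIN_RETAINED_FRAMES`` frames, below
    which correlations are not meaningful.
    """
    x = _as_2d(series)
    mask = np.asarray(outlier_mask, dtype=bool)
    if mask.size != x.shape[0]:
        raise ValueError("mask length differs from frame count")
    retained = x[~mask]
    if retained.shape[0] < MIN_RETAINED_FRAMES:
        raise ValueError(
            f"only {retained.shape[0]} frames retained after censoring "
            f"(minimum {MIN_RETAINED_FRAMES})"
        )
    return retained


def clean_series(
    series: np.ndarray,
    tr_seconds: float,
    outlier_mask: np.ndarray | None = None,
    nuisance_components: np.ndarray | None = None,
    lowpass_hz: float = 0.08,
    highpass_seconds: float | None = None,
    censor_before_filter: bool = False,
) -> CleanSeries:
    """Run the full denoising chain and record provenance.

    Order: detrend -> nuisance regression -> filter -> censor, unless
    ``censor_before_filter`` flips the last two stages (the alternative
    scrub-first convention); the order actually used is always visible in
    the provenance.
    """
    steps: list[str] = []
    x = detrend_linear(series)
    steps.append("detrend_linear")
    if nuisance_components is not None and np.asarray(nuisance_components).size:
        x = regress_nuisance(x, nuisance_components)
        steps.append(f"regress_nuisance(k={_as_2d(nuisance_components).shape[1]})")

    def _filter(y: np.ndarray) -> np.ndarray:
        steps.append(
            f"temporal_filter(lowpass_hz={lowpass_hz}, highpass_seconds={highpass_seconds})"
        )
        return temporal_filter(y, tr_seconds, lowpass_hz, highpass_seconds)

    def _censor(y: np.ndarray) -> np.ndarray:
        if outlier_mask is None:
            return y
        steps.append(f"censor_frames(n_flagged={int(np.asarray(outlier_mask).sum())})")
        return censor_frames(y, outlier_mask)

    if censor_before_filter:
        x = _filter(_censor(x))
    else:
        x = _censor(_filter(x))
    return CleanSeries(matrix=x, provenance=steps)
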