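"""Synthetic ROI-level BOLD-like cohorts with planted ground truth.

Generates per-subject recordings whose population correlation structure,
artifacts (linear drift, shared physiological nuisance, motion spikes,
parcel-level signal dropout) and QC ground truth are all known, so every
downstream stage (QC, denoising, connectivity, statistics) can be
verified by recovery tests instead of real MRI data.

Three built-in correlation profiles emulate the study populations:

``sighted_like``
    occipital seeds couple more strongly with sensory-motor targets than
    with prefrontal targets; modest within-hemisphere preference.
``blind_like``
    the reverse seed preference (PFC over sensory-motor) and a larger
    within-hemisphere preference.
``infant_like``
    secondary visual seeds PFC-dominant like ``blind_like``, V1 exactly
    balanced, laterality like ``sighted_like``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .catalog import (
    ROICatalog,
    SECONDARY_VISUAL_CATEGORIES,
    PFC_CATEGORIES,
    SENSORY_MOTOR_CATEGORIES,
    default_catalog,
)

__all__ = [
    "CorrelationTemplate",
    "ArtifactSpec",
    "AcquisitionSpec",
    "SubjectRecording",
    "CohortConfig",
    "GroupSpec",
    "nearest_correlation",
    "make_correlation_template",
    "simulate_subject",
    "simulate_cohort",
]

PROFILES = ("sighted_like", "blind_like", "infant_like", "custom")

# Default within-minus-between hemisphere increments on seed-PFC pairs.
_DEFAULT_LATERALITY = {"sighted_like": 0.04, "blind_like": 0.12, "infant_like": 0.04}


# ---------------------------------------------------------------------------
# nearest correlation matrix (alternating projections, Higham 2002)
# ---------------------------------------------------------------------------

def nearest_correlation(
    matrix: np.ndarray, tol: float = 1e-10, max_iter: int = 500
) -> tuple[np.ndarray, float]:
    """Project a symmetric matrix onto the nearest correlation matrix.

    Alternating projections with Dykstra's correction between the cone of
    positive semi-definite matrices and the affine set of unit-diagonal
    symmetric matrices.

    Returns
    -------
    repaired : ndarray
        Symmetric, unit diagonal, positive semi-definite (to ``tol``).
    distance : float
        Frobenius norm of ``repaired - matrix``; every single entry moves
        by at most this much.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    y = a.copy()
    correction = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - correction
        w, v = np.linalg.eigh((r + r.T) / 2.0)
        x = (v * np.clip(w, 0.0, None)) @ v.T
        correction = x - r
        y_next = x.copy()
        np.fill_diagonal(y_next, 1.0)
        if np.max(np.abs(y_next - y)) < tol:
            y = y_next
            break
        y = y_next
    y = (y + y.T) / 2.0
    np.fill_diagonal(y, 1.0)
    return y, float(np.linalg.norm(y - a, "fro"))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CorrelationTemplate:
    """Target population correlation structure for one cohort profile.

    ``matrix`` is the PSD-repaired correlation matrix actually used for
    sampling; ``raw_matrix`` keeps the block values as planted (before
    repair) so recovery tests can assert exact planted differences.
    """

    roi_names: list[str]
    matrix: np.ndarray
    profile_name: str
    raw_matrix: np.ndarray = None  # type: ignore[assignment]
    repair_distance: float = 0.0
    effect_size: float = 0.0
    laterality_increment: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.raw_matrix is None:
            self.raw_matrix = self.matrix.copy()
        if self.profile_name not in PROFILES:
            raise ValueError(f"unknown profile {self.profile_name!r}")
        n = len(self.roi_names)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match roi_names")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("template matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-10):
            raise ValueError("template matrix must have unit diagonal")
        off = self.matrix[~np.eye(n, dtype=bool)]
        if off.size and (np.any(off <= -1.0) or np.any(off >= 1.0)):
            raise ValueError("off-diagonal template entries must lie in (-1, 1)")


@dataclass
class ArtifactSpec:
    """What to inject besides the correlated signal.

    ``spike_amplitude`` is a multiple of the baseline frame-to-frame RMS
    of the clean series; ``nuisance_weight`` is the fraction of each ROI's
    variance contributed by the shared nuisance sources.
    """

    n_motion_spikes: int = 0
    spike_amplitude: float = 5.0
    drift_slope: float = 0.0
    nuisance_weight: float = 0.0
    dropout_rois: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_motion_spikes < 0:
            raise ValueError("n_motion_spikes must be >= 0")
        if self.spike_amplitude < 0:
            raise ValueError("spike_amplitude must be >= 0")
        if not 0.0 <= self.nuisance_weight < 1.0:
            raise ValueError("nuisance_weight must lie in [0, 1)")
        self.dropout_rois = tuple(self.dropout_rois)


@dataclass
class AcquisitionSpec:
    """Frame count, repetition time, cohort label, parcel count."""

    n_frames: int
    tr_seconds: float
    cohort: str = "infant"
    n_parcels: int = 100

    def __post_init__(self) -> None:
        if self.n_frames < 4:
            raise ValueError("need at least 4 frames")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_parcels < 2:
            raise ValueError("need at least 2 parcels")


@dataclass
class SubjectRecording:
    """One subject's ROI time series plus everything QC needs.

    ``ground_truth`` holds the planted facts (spike frames, dropout ROIs,
    nuisance sources) and is carried for recovery tests only; the
    pipeline never reads it.
    """

    subject_id: str
    group: str
    roi_names: list[str]
    roi_series: np.ndarray  # frames x ROIs
    parcel_means: np.ndarray  # length n_parcels
    roi_mean_intensity: dict[str, float]
    csf_series: np.ndarray  # frames x channels
    wm_series: np.ndarray  # frames x channels
    motion_mm: float
    motion_deg: float
    tr_seconds: float
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.roi_series = np.asarray(self.roi_series, dtype=float)
        t, r = self.roi_series.shape
        if r != len(self.roi_names):
            raise ValueError("roi_series column count does not match roi_names")
        if np.any(~np.isfinite(self.roi_series)):
            raise ValueError("roi_series contains non-finite values")
        for name, arr in (("csf_series", self.csf_series), ("wm_series", self.wm_series)):
            arr = np.asarray(arr, dtype=float)
            if arr.shape[0] != t:
                raise ValueError(f"{name} frame count differs from roi_series")
        if set(self.roi_mean_intensity) != set(self.roi_names):
            raise ValueError("roi_mean_intensity keys must match roi_names")

    @property
    def n_frames(self) -> int:
        return self.roi_series.shape[0]


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _block_indices(catalog: ROICatalog) -> dict[str, list[int]]:
    order = {n: i for i, n in enumerate(catalog.names)}
    return {
        "sv": [order[n] for n in catalog.secondary_visual()],
        "v1": [order[n] for n in catalog.v1()],
        "pfc": [order[n] for n in catalog.by_category(*PFC_CATEGORIES)],
        "sm": [order[n] for n in catalog.by_category(*SENSORY_MOTOR_CATEGORIES)],
    }


def make_correlation_template(
    profile_name: str,
    roi_catalog: Optional[ROICatalog] = None,
    effect_size: float = 0.15,
    base_r: float = 0.2,
    laterality_increment: Optional[float] = None,
    psd_tol: float = 1e-10,
) -> CorrelationTemplate:
    """Build a cohort correlation template with planted block contrasts.

    The planted structure, on top of a uniform baseline ``base_r``:

    * seed-PFC minus seed-SM block means equal ``+effect_size``
      (``blind_like``), ``-effect_size`` (``sighted_like``), or
      ``+effect_size`` for secondary-visual seeds with V1 exactly
      balanced (``infant_like``);
    * within-hemisphere seed-PFC pairs exceed between-hemisphere pairs
      by ``laterality_increment`` (profile defaults: blind 0.12,
      sighted/infant 0.04), applied symmetrically so block means are
      unchanged.

    The result is repaired to the nearest correlation matrix when the
    planted matrix is not positive semi-definite.
    """
    if profile_name not in ("sighted_like", "blind_like", "infant_like"):
        raise ValueError(f"unknown profile {profile_name!r}")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    catalog = roi_catalog if roi_catalog is not None else default_catalog()
    if not catalog.secondary_visual() or not catalog.v1():
        raise ValueError("catalog must contain secondary visual and V1 seeds")
    if not catalog.pfc() or not catalog.sensory_motor():
        raise ValueError("catalog must contain PFC and sensory-motor targets")
    lat = _DEFAULT_LATERALITY[profile_name] if laterality_increment is None else laterality_increment
    if lat < 0:
        raise ValueError("laterality_increment must be >= 0")

    names = catalog.names
    n = len(names)
    m = np.full((n, n), base_r, dtype=float)
    np.fill_diagonal(m, 1.0)

    idx = _block_indices(catalog)
    # Signed seed-block preferences: +d means PFC over SM.
    if profile_name == "blind_like":
        deltas = {"sv": effect_size, "v1": effect_size}
    elif profile_name == "sighted_like":
        deltas = {"sv": -effect_size, "v1": -effect_size}
    else:  # infant_like: secondary visual PFC-dominant, V1 balanced
        deltas = {"sv": effect_size, "v1": 0.0}

    for seed_block, d in deltas.items():
        for i in idx[seed_block]:
            for j in idx["pfc"]:
                m[i, j] = m[j, i] = base_r + d / 2.0
            for j in idx["sm"]:
                m[i, j] = m[j, i] = base_r - d / 2.0

    # Laterality on seed-PFC pairs: +lat/2 within hemisphere, -lat/2 between.
    seed_idx = idx["sv"] + idx["v1"]
    hemis = [catalog.hemisphere(nm) for nm in names]
    for i in seed_idx:
        for j in idx["pfc"]:
            shift = lat / 2.0 if hemis[i] == hemis[j] else -lat / 2.0
            m[i, j] += shift
            m[j, i] = m[i, j]

    off = m[~np.eye(n, dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise ValueError(
            "planted entries leave (-1, 1); reduce effect_size, base_r, or "
            f"laterality_increment (max |entry| = {np.max(np.abs(off)):.3f})"
        )

    eigvals = np.linalg.eigvalsh(m)
    if eigvals.min() >= -psd_tol:
        repaired, dist = m.copy(), 0.0
    else:
        repaired, dist = nearest_correlation(m, tol=psd_tol)
    return CorrelationTemplate(
        roi_names=list(names),
        matrix=repaired,
        profile_name=profile_name,
        raw_matrix=m,
        repair_distance=dist,
        effect_size=effect_size,
        laterality_increment=lat,
    )


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------

_N_NUISANCE_SOURCES = 3
_N_CSF_CHANNELS = 6
_N_WM_CHANNELS = 6
_PARCEL_LEVEL = 1000.0
_PARCEL_SD = 20.0
_DROPOUT_SHIFT = 10.0  # in units of _PARCEL_SD below the common level


def _psd_factor(matrix: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(matrix)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_subject(
    template: CorrelationTemplate,
    acquisition: AcquisitionSpec,
    artifact_spec: ArtifactSpec,
    subject_id: str = "sub-000",
    ar1: float = 0.0,
) -> SubjectRecording:
    """Draw one recording with the template's correlation plus artifacts.

    The clean signal is stationary correlated Gaussian noise (optionally
    AR(1) over time with coefficient ``ar1``, variance-normalized).
    Artifacts are layered on deterministically from ``artifact_spec.seed``:
    linear drift, shared nuisance sources mixed into both the ROI series
    and the CSF/WM channels, and single-frame common-mode motion spikes
    flagged in ``ground_truth["spike_frames"]``.
    """
    if not 0.0 <= ar1 < 1.0:
        raise ValueError("ar1 must lie in [0, 1)")
    t, n_roi = acquisition.n_frames, len(template.roi_names)
    unknown = set(artifact_spec.dropout_rois) - set(template.roi_names)
    if unknown:
        raise ValueError(f"dropout_rois not in template: {sorted(unknown)}")
    if artifact_spec.n_motion_spikes > t - 1:
        raise ValueError("more spikes than available frames")
    rng = np.random.default_rng(artifact_spec.seed)

    z = rng.standard_normal((t, n_roi))
    if ar1 > 0.0:
        innov = np.sqrt(1.0 - ar1**2)
        for k in range(1, t):
            z[k] = ar1 * z[k - 1] + innov * z[k]
    signal = z @ _psd_factor(template.matrix).T

    # Shared physiological nuisance sources.
    sources = rng.standard_normal((t, _N_NUISANCE_SOURCES))
    w = artifact_spec.nuisance_weight
    if w > 0.0:
        mix = rng.uniform(0.5, 1.0, size=(_N_NUISANCE_SOURCES, n_roi))
        mix /= np.linalg.norm(mix, axis=0, keepdims=True)
        roi = np.sqrt(1.0 - w) * signal + np.sqrt(w) * (sources @ mix)
    else:
        roi = signal

    def _compartment(n_channels: int) -> np.ndarray:
        weights = rng.uniform(0.5, 1.0, size=(_N_NUISANCE_SOURCES, n_channels))
        weights /= np.linalg.norm(weights, axis=0, keepdims=True)
        return sources @ weights + 0.1 * rng.standard_normal((t, n_channels))

    csf = _compartment(_N_CSF_CHANNELS)
    wm = _compartment(_N_WM_CHANNELS)

    if artifact_spec.drift_slope != 0.0:
        roi = roi + artifact_spec.drift_slope * np.arange(t)[:, None]

    spike_frames = np.array([], dtype=int)
    if artifact_spec.n_motion_spikes > 0:
        baseline_rms = float(np.sqrt(np.mean(np.diff(roi, axis=0) ** 2)))
        jump = artifact_spec.spike_amplitude * baseline_rms
        spike_frames = np.sort(
            rng.choice(np.arange(1, t), size=artifact_spec.n_motion_spikes, replace=False)
        )
        for f in spike_frames:
            roi[f] += jump
            csf[f] += jump
            wm[f] += jump

    parcel_means = rng.normal(_PARCEL_LEVEL, _PARCEL_SD, size=acquisition.n_parcels)
    # Non-dropout ROI intensities clipped to +-2 SD so the -3 SD rule can
    # only fire on planted subjects.
    raw = rng.normal(_PARCEL_LEVEL, _PARCEL_SD, size=n_roi)
    raw = np.clip(raw, _PARCEL_LEVEL - 2 * _PARCEL_SD, _PARCEL_LEVEL + 2 * _PARCEL_SD)
    roi_intensity = dict(zip(template.roi_names, raw.tolist()))
    for name in artifact_spec.dropout_rois:
        roi_intensity[name] = _PARCEL_LEVEL - _DROPOUT_SHIFT * _PARCEL_SD

    return SubjectRecording(
        subject_id=subject_id,
        group=acquisition.cohort,
        roi_names=list(template.roi_names),
        roi_series=roi,
        parcel_means=parcel_means,
        roi_mean_intensity=roi_intensity,
        csf_series=csf,
        wm_series=wm,
        motion_mm=float(rng.uniform(0.05, 0.5)),
        motion_deg=float(rng.uniform(0.05, 0.5)),
        tr_seconds=acquisition.tr_seconds,
        ground_truth={
            "spike_frames": spike_frames.tolist(),
            "dropout_rois": list(artifact_spec.dropout_rois),
            "nuisance_sources": sources,
            "nuisance_weight": w,
            "drift_slope": artifact_spec.drift_slope,
            "profile_name": template.profile_name,
        },
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Per-group generator settings."""

    n: int
    profile: str
    n_frames: int
    tr_seconds: float
    effect_size: float = 0.15
    laterality_increment: Optional[float] = None
    base_r: float = 0.2
    nuisance_weight: float = 0.0
    drift_slope: float = 0.0
    spike_rate: float = 0.0  # fraction of frames receiving a spike
    spike_amplitude: float = 5.0
    # Planted motion exclusions spike 11% of frames: each single-frame jump
    # elevates DVARS at two frames, so the elevated fraction (~21%) must stay
    # below 25% or the Q75-based threshold itself gets contaminated.
    n_excluded_motion: int = 0  # subjects planted above the outlier budget
    excluded_spike_rate: float = 0.11
    n_excluded_dropout: int = 0  # subjects planted with one dropout ROI
    ar1: float = 0.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if self.n_excluded_motion + self.n_excluded_dropout > self.n:
            raise ValueError("more planted exclusions than subjects")


def _default_groups() -> dict[str, GroupSpec]:
    # Cohort sizes default to the study's 50 sighted / 30 blind / 475 infants.
    return {
        "sighted": GroupSpec(n=50, profile="sighted_like", n_frames=300, tr_seconds=2.0),
        "blind": GroupSpec(n=30, profile="blind_like", n_frames=300, tr_seconds=2.0),
        "infant": GroupSpec(n=475, profile="infant_like", n_frames=2300, tr_seconds=0.392),
    }


@dataclass
class CohortConfig:
    """Master configuration for :func:`simulate_cohort`."""

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    master_seed: int = 0
    catalog: Optional[ROICatalog] = None


def simulate_cohort(config: CohortConfig) -> tuple[list[SubjectRecording], dict]:
    """Simulate all groups; return recordings plus a ground-truth ledger.

    Subject seeds are spawned deterministically from ``master_seed``, so
    two calls with the same config produce bit-identical cohorts.  The
    ledger records, for every subject, the planted spike frames, dropout
    ROIs and whether the subject was planted as an intended exclusion,
    plus each group's template block differences.
    """
    catalog = config.catalog if config.catalog is not None else default_catalog()
    seed_seq = np.random.SeedSequence(config.master_seed)
    recordings: list[SubjectRecording] = []
    ledger: dict = {
        "master_seed": config.master_seed,
        "n_subjects": 0,
        "groups": {},
        "subjects": [],
    }
    for group in sorted(config.groups):
        spec = config.groups[group]
        template = make_correlation_template(
            spec.profile,
            catalog,
            effect_size=spec.effect_size,
            base_r=spec.base_r,
            laterality_increment=spec.laterality_increment,
        )
        idx = _block_indices(catalog)
        raw = template.raw_matrix

        def _block_mean(rows: list[int], cols: list[int]) -> float:
            return float(np.mean(raw[np.ix_(rows, cols)]))

        ledger["groups"][group] = {
            "profile": spec.profile,
            "n": spec.n,
            "effect_size": spec.effect_size,
            "laterality_increment": template.laterality_increment,
            "repair_distance": template.repair_distance,
            "true_block_difference": {
                "secondary_visual": _block_mean(idx["sv"], idx["pfc"])
                - _block_mean(idx["sv"], idx["sm"]),
                "V1": _block_mean(idx["v1"], idx["pfc"]) - _block_mean(idx["v1"], idx["sm"]),
            },
        }
        acquisition = AcquisitionSpec(
            n_frames=spec.n_frames, tr_seconds=spec.tr_seconds, cohort=group
        )
        child_seeds = seed_seq.spawn(spec.n)
        for i in range(spec.n):
            subject_id = f"{group}-{i:04d}"
            sub_seed = int(child_seeds[i].generate_state(1)[0])
            if i < spec.n_excluded_motion:
                rate, intended, reason = spec.excluded_spike_rate, True, "motion"
                dropout: tuple[str, ...] = ()
            elif i < spec.n_excluded_motion + spec.n_excluded_dropout:
                rate, intended, reason = spec.spike_rate, True, "dropout"
                dropout = (catalog.names[i % len(catalog.names)],)
            else:
                rate, intended, reason = spec.spike_rate, False, ""
                dropout = ()
            artifact = ArtifactSpec(
                n_motion_spikes=int(round(rate * spec.n_frames)),
                spike_amplitude=spec.spike_amplitude,
                drift_slope=spec.drift_slope,
                nuisance_weight=spec.nuisance_weight,
                dropout_rois=dropout,
                seed=sub_seed,
            )
            rec = simulate_subject(
                template, acquisition, artifact, subject_id=subject_id, ar1=spec.ar1
            )
            if intended and reason == "motion" and group != "infant":
                # Adults are excluded on head-motion summaries, not outlier counts.
                rec.motion_mm = 2.5
            recordings.append(rec)
            ledger["subjects"].append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "seed": sub_seed,
                    "n_spikes": int(round(rate * spec.n_frames)),
                    "spike_frames": rec.ground_truth["spike_frames"],
                    "dropout_rois": list(dropout),
                    "intended_exclusion": intended,
                    "exclusion_reason": reason,
                }
            )
    ledger["n_subjects"] = len(recordings)
    return recordings, ledger
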