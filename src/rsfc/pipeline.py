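"""Orchestration: QC -> preprocess -> connectivity -> group statistics.

The pipeline consumes :class:`~rsfc.synthetic.SubjectRecording` objects
(loaded from disk or simulated in memory), applies the group-specific QC
and denoising settings, and produces tidy per-subject and group-level
tables.  Everything is deterministic given the inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import ROICatalog, default_catalog
from .connectivity import (
    FCMatrix,
    average_block_fc,
    compute_fc_matrix,
    laterality_fc,
    matrix_profile_correlation,
    noise_ceiling_table,
)
from .preprocess import clean_series, extract_compcor_components
from .qc import QCReport, QCThresholds, apply_exclusion_rules, compute_dvars
from .stats import (
    StatResult,
    bonferroni_adjust,
    mixed_anova_interaction,
    oneway_anova_eta,
    paired_ttest_cohend,
    pearson_filon_z,
)
from .synthetic import CohortConfig, GroupSpec, SubjectRecording, simulate_cohort

logger = logging.getLogger("rsfc")

__all__ = [
    "FilterSettings",
    "PipelineConfig",
    "PipelineResult",
    "config_from_dict",
    "cohort_config_from_dict",
    "preprocess_subject",
    "run_pipeline",
    "group_analysis",
    "write_results",
]

ADULT_GROUPS = ("sighted", "blind")


@dataclass
class FilterSettings:
    lowpass_hz: float = 0.08
    highpass_seconds: Optional[float] = None


def _default_filters() -> dict[str, FilterSettings]:
    # Adults get the 150 s high-pass inside the band-pass; infants low-pass only.
    return {
        "sighted": FilterSettings(0.08, 150.0),
        "blind": FilterSettings(0.08, 150.0),
        "infant": FilterSettings(0.08, None),
    }


@dataclass
class PipelineConfig:
    """Every threshold the pipeline applies, in one declarative object."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    compcor_k: int = 5
    compcor_groups: tuple[str, ...] = ("sighted", "blind", "infant")
    filters: dict[str, FilterSettings] = field(default_factory=_default_filters)
    censor_before_filter: bool = False
    fisher_z: bool = False

    def filter_for(self, group: str) -> FilterSettings:
        return self.filters.get(group, FilterSettings())


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed YAML/JSON mapping."""
    cfg = PipelineConfig()
    if "qc" in data:
        cfg.qc = QCThresholds(**data["qc"])
    for key in ("compcor_k", "censor_before_filter", "fisher_z"):
        if key in data:
            setattr(cfg, key, data[key])
    if "compcor_groups" in data:
        cfg.compcor_groups = tuple(data["compcor_groups"])
    if "filters" in data:
        cfg.filters = {g: FilterSettings(**f) for g, f in data["filters"].items()}
    return cfg


def cohort_config_from_dict(data: dict, master_seed: Optional[int] = None) -> CohortConfig:
    """Build a :class:`CohortConfig` from a parsed mapping."""
    groups = {name: GroupSpec(**spec) for name, spec in data["groups"].items()}
    seed = master_seed if master_seed is not None else int(data.get("master_seed", 0))
    return CohortConfig(groups=groups, master_seed=seed)


# ---------------------------------------------------------------------------
# per-subject stage
# ---------------------------------------------------------------------------

def preprocess_subject(
    recording: SubjectRecording,
    config: PipelineConfig,
) -> tuple[QCReport, Optional[np.ndarray], list[str]]:
    """QC one subject and, if retained, denoise its windowed series.

    Returns the QC report, the cleaned (censored) series or ``None`` when
    the subject is excluded, and the provenance strings.
    """
    dvars = compute_dvars(recording.roi_series)
    report = apply_exclusion_rules(
        subject_id=recording.subject_id,
        group=recording.group,
        dvars=dvars,
        parcel_means=recording.parcel_means,
        roi_means=recording.roi_mean_intensity,
        motion_mm=recording.motion_mm,
        motion_deg=recording.motion_deg,
        thresholds=config.qc,
    )
    if report.excluded:
        logger.info("excluding %s: %s", recording.subject_id, report.exclusion_reasons)
        return report, None, []
    start, end = report.retained_window
    window = slice(start, end)
    series = recording.roi_series[window]
    mask = report.outlier_mask[start:end]

    components = None
    if config.compcor_k > 0 and recording.group in config.compcor_groups:
        csf, wm = recording.csf_series[window], recording.wm_series[window]
        if csf.size and wm.size:
            components, _ = extract_compcor_components(csf, wm, k=config.compcor_k)

    filt = config.filter_for(recording.group)
    clean = clean_series(
        series,
        tr_seconds=recording.tr_seconds,
        outlier_mask=mask,
        nuisance_components=components,
        lowpass_hz=filt.lowpass_hz,
        highpass_seconds=filt.highpass_seconds,
        censor_before_filter=config.censor_before_filter,
    )
    return report, clean.matrix, clean.provenance


# ---------------------------------------------------------------------------
# group stage
# ---------------------------------------------------------------------------

_SEED_CLASSES = ("secondary_visual", "V1")
_TARGET_CLASSES = ("PFC", "SM")


def _seed_rois(catalog: ROICatalog, seed_class: str) -> list[str]:
    return catalog.secondary_visual() if seed_class == "secondary_visual" else catalog.v1()


def _target_rois(catalog: ROICatalog, target_class: str) -> list[str]:
    return catalog.pfc() if target_class == "PFC" else catalog.sensory_motor()


def subject_block_table(
    fc_by_subject: dict[str, FCMatrix],
    groups: dict[str, str],
    catalog: ROICatalog,
    fisher_z: bool = False,
) -> pd.DataFrame:
    """Tidy per-subject block means: one row per seed-class x target-class."""
    rows = []
    for sid, fc in fc_by_subject.items():
        for seed_class in _SEED_CLASSES:
            for target_class in _TARGET_CLASSES:
                rows.append(
                    {
                        "subject_id": sid,
                        "group": groups[sid],
                        "seed_class": seed_class,
                        "target_class": target_class,
                        "r": average_block_fc(
                            fc,
                            _seed_rois(catalog, seed_class),
                            _target_rois(catalog, target_class),
                            fisher_z=fisher_z,
                        ),
                    }
                )
    return pd.DataFrame(rows)


def subject_laterality_table(
    fc_by_subject: dict[str, FCMatrix],
    groups: dict[str, str],
    catalog: ROICatalog,
) -> pd.DataFrame:
    """Within- and between-hemisphere seed-PFC means per subject."""
    rows = []
    for sid, fc in fc_by_subject.items():
        for seed_class in _SEED_CLASSES:
            within, between = laterality_fc(
                fc, _seed_rois(catalog, seed_class), catalog.pfc(), catalog
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": groups[sid],
                    "seed_class": seed_class,
                    "within_r": within,
                    "between_r": between,
                }
            )
    return pd.DataFrame(rows)


def _stat_row(res: StatResult, family: str) -> dict:
    dof = tuple(res.dof)
    return {
        "test": res.name,
        "family": family,
        "statistic": res.statistic,
        "df1": dof[0] if len(dof) > 0 else np.nan,
        "df2": dof[1] if len(dof) > 1 else np.nan,
        "p_raw": res.p,
        "p_adjusted": res.p_adjusted if res.p_adjusted is not None else res.p,
        "effect_size": res.effect_size if res.effect_size is not None else np.nan,
        "effect_size_name": res.effect_size_name or "",
        "m_comparisons": res.m_comparisons,
    }


def _contrast_stats(
    wide: pd.DataFrame,
    col_a: str,
    col_b: str,
    family: str,
    anova_pairs: list[tuple[str, str]],
) -> list[dict]:
    """Mixed-ANOVA interactions plus Bonferroni-corrected per-group paired t.

    ``wide`` must have columns ``group``, ``col_a``, ``col_b`` with one row
    per subject; the contrast is ``col_a`` vs ``col_b``.
    """
    rows: list[dict] = []
    present = set(wide["group"].unique())
    for g1, g2 in anova_pairs:
        if {g1, g2} <= present:
            sub = wide[wide["group"].isin([g1, g2])]
            res = mixed_anova_interaction(
                sub[[col_a, col_b]].to_numpy(),
                sub["group"].to_numpy(),
                name=f"{family}:interaction:{g1}_vs_{g2}",
            )
            rows.append(_stat_row(res, family))
    posthoc: list[StatResult] = []
    for group in sorted(present):
        sub = wide[wide["group"] == group]
        if len(sub) >= 3:
            posthoc.append(
                paired_ttest_cohend(
                    sub[col_a].to_numpy(),
                    sub[col_b].to_numpy(),
                    name=f"{family}:paired_t:{group}:{col_a}_vs_{col_b}",
                )
            )
    m = len(posthoc)
    for res in posthoc:
        res.correction = "bonferroni"
        res.m_comparisons = m
        res.p_adjusted = float(bonferroni_adjust(res.p, m))
        rows.append(_stat_row(res, family))
    return rows


def group_analysis(
    fc_by_subject: dict[str, FCMatrix],
    groups: dict[str, str],
    catalog: ROICatalog,
    fisher_z: bool = False,
) -> dict:
    """All group-level tables from per-subject FC matrices.

    Computes block/laterality contrasts with their mixed-ANOVA and post
    hoc tests, group-mean matrices, infant-to-adult matrix-profile
    correlations with the dependent-correlation z, and returns everything
    as tidy frames.
    """
    block = subject_block_table(fc_by_subject, groups, catalog, fisher_z=fisher_z)
    lat = subject_laterality_table(fc_by_subject, groups, catalog)
    present = sorted(set(groups.values()))

    stat_rows: list[dict] = []
    anova_pairs = [("sighted", "blind"), ("blind", "infant"), ("sighted", "infant")]
    for seed_class in _SEED_CLASSES:
        sub = block[block["seed_class"] == seed_class]
        wide = sub.pivot_table(
            index=["subject_id", "group"], columns="target_class", values="r"
        ).reset_index()
        stat_rows += _contrast_stats(
            wide, "PFC", "SM", f"block:{seed_class}", anova_pairs
        )
        lsub = lat[lat["seed_class"] == seed_class]
        stat_rows += _contrast_stats(
            lsub.rename(columns={"within_r": "within", "between_r": "between"}),
            "within",
            "between",
            f"laterality:{seed_class}",
            anova_pairs,
        )

    # Group-mean FC matrices (mean of subject r, the documented default).
    group_fc: dict[str, np.ndarray] = {}
    for group in present:
        stack = [fc.matrix for sid, fc in fc_by_subject.items() if groups[sid] == group]
        group_fc[group] = np.mean(stack, axis=0)

    matrix_rows: list[dict] = []
    if {"sighted", "blind", "infant"} <= set(present):
        names = catalog.names
        for seed_class in _SEED_CLASSES:
            subset = (
                _seed_rois(catalog, seed_class) + catalog.pfc() + catalog.sensory_motor()
            )
            idx = [names.index(n) for n in subset]

            def _sub(group: str) -> np.ndarray:
                return group_fc[group][np.ix_(idx, idx)]

            r_ib = matrix_profile_correlation(_sub("infant"), _sub("blind"))
            r_is = matrix_profile_correlation(_sub("infant"), _sub("sighted"))
            r_bs = matrix_profile_correlation(_sub("blind"), _sub("sighted"))
            n_cells = len(idx) * (len(idx) - 1) // 2
            z = pearson_filon_z(
                r_ib, r_is, r_bs, n=n_cells,
                name=f"matrix:{seed_class}:infant_blind_vs_infant_sighted",
            )
            matrix_rows.append(
                {
                    "seed_class": seed_class,
                    "r_infant_blind": r_ib,
                    "r_infant_sighted": r_is,
                    "r_blind_sighted": r_bs,
                    "n_cells": n_cells,
                    "z": z.statistic,
                    "p": z.p,
                }
            )
            stat_rows.append(_stat_row(z, f"matrix:{seed_class}"))

    return {
        "block_fc": block,
        "laterality": lat,
        "group_fc": group_fc,
        "matrix_correlations": pd.DataFrame(matrix_rows),
        "stats": pd.DataFrame(stat_rows),
    }


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    qc_table: pd.DataFrame
    qc_reports: dict[str, QCReport]
    fc_by_subject: dict[str, FCMatrix]
    groups: dict[str, str]
    block_fc: pd.DataFrame
    laterality: pd.DataFrame
    noise_ceiling: pd.DataFrame
    group_fc: dict[str, np.ndarray]
    matrix_correlations: pd.DataFrame
    stats: pd.DataFrame
    provenance: dict[str, list[str]]

    @property
    def n_included(self) -> int:
        return len(self.fc_by_subject)

    @property
    def n_excluded(self) -> int:
        return len(self.qc_reports) - len(self.fc_by_subject)


def run_pipeline(
    recordings: list[SubjectRecording],
    catalog: Optional[ROICatalog] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run QC, denoising, connectivity and statistics over a cohort.

    Subjects failing QC or preprocessing are excluded with a recorded
    reason, never silently dropped; included + excluded always equals the
    number of recordings supplied.
    """
    catalog = catalog if catalog is not None else default_catalog()
    config = config if config is not None else PipelineConfig()
    logger.info(
        "pipeline start: %d subjects, qc=%s, compcor_k=%d",
        len(recordings), config.qc, config.compcor_k,
    )

    qc_rows, qc_reports, provenance = [], {}, {}
    fc_by_subject: dict[str, FCMatrix] = {}
    groups: dict[str, str] = {}
    ceiling_rows = []
    for rec in recordings:
        report, cleaned, steps = preprocess_subject(rec, config)
        if not report.excluded and cleaned is not None:
            try:
                fc = compute_fc_matrix(cleaned, rec.roi_names)
            except ValueError as exc:
                report.excluded = True
                report.exclusion_reasons = [f"preprocessing: {exc}"]
                cleaned = None
            else:
                fc_by_subject[rec.subject_id] = fc
                groups[rec.subject_id] = rec.group
                provenance[rec.subject_id] = steps
                for roi, ceiling in noise_ceiling_table(cleaned, rec.roi_names).items():
                    ceiling_rows.append(
                        {
                            "subject_id": rec.subject_id,
                            "group": rec.group,
                            "roi": roi,
                            "ceiling": ceiling,
                        }
                    )
        qc_reports[rec.subject_id] = report
        qc_rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "n_outliers": report.n_outliers_in_window,
                "window_start": report.retained_window[0],
                "window_end": report.retained_window[1],
                "dropout_rois": ";".join(report.dropout_rois),
                "excluded": report.excluded,
                "reasons": ";".join(report.exclusion_reasons),
            }
        )
    qc_table = pd.DataFrame(qc_rows)
    logger.info("QC done: %d included / %d excluded",
                len(fc_by_subject), len(recordings) - len(fc_by_subject))

    ceiling = pd.DataFrame(ceiling_rows)
    if fc_by_subject:
        analysis = group_analysis(fc_by_subject, groups, catalog, fisher_z=config.fisher_z)
        stats_df = analysis["stats"]
        ceiling_stats = _noise_ceiling_anova(ceiling)
        if ceiling_stats is not None:
            stats_df = pd.concat(
                [stats_df, pd.DataFrame([_stat_row(ceiling_stats, "noise_ceiling")])],
                ignore_index=True,
            )
    else:
        analysis = {
            "block_fc": pd.DataFrame(),
            "laterality": pd.DataFrame(),
            "group_fc": {},
            "matrix_correlations": pd.DataFrame(),
        }
        stats_df = pd.DataFrame()

    return PipelineResult(
        qc_table=qc_table,
        qc_reports=qc_reports,
        fc_by_subject=fc_by_subject,
        groups=groups,
        block_fc=analysis["block_fc"],
        laterality=analysis["laterality"],
        noise_ceiling=ceiling,
        group_fc=analysis["group_fc"],
        matrix_correlations=analysis["matrix_correlations"],
        stats=stats_df,
        provenance=provenance,
    )


def _noise_ceiling_anova(ceiling: pd.DataFrame) -> Optional[StatResult]:
    """One-way ANOVA on subject-mean noise ceilings across groups."""
    if ceiling.empty:
        return None
    per_subject = ceiling.groupby(["subject_id", "group"])["ceiling"].mean().reset_index()
    samples = [
        sub["ceiling"].to_numpy()
        for _, sub in per_subject.groupby("group")
        if len(sub) >= 2
    ]
    if len(samples) < 2:
        return None
    return oneway_anova_eta(samples, name="noise_ceiling:oneway_anova")


# ---------------------------------------------------------------------------
# output writing (schema-stable CSVs)
# ---------------------------------------------------------------------------

def write_results(result: PipelineResult, directory: str | Path) -> None:
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    result.qc_table.to_csv(out / "qc_report.csv", index=False)
    result.block_fc.to_csv(out / "block_fc.csv", index=False)
    result.laterality.to_csv(out / "laterality.csv", index=False)
    result.noise_ceiling.to_csv(out / "noise_ceiling.csv", index=False)
    result.matrix_correlations.to_csv(out / "matrix_correlations.csv", index=False)
    result.stats.to_csv(out / "stats.csv", index=False)
    names = None
    for sid, fc in result.fc_by_subject.items():
        names = fc.roi_names
        break
    for group, matrix in result.group_fc.items():
        pd.DataFrame(matrix, index=names, columns=names).to_csv(
            out / f"group_fc_{group}.csv", float_format="%.10g"
        )


def simulate_and_run(
    cohort_config: CohortConfig,
    pipeline_config: Optional[PipelineConfig] = None,
    catalog: Optional[ROICatalog] = None,
) -> tuple[PipelineResult, dict]:
    """Convenience wrapper: simulate a cohort and run the pipeline on it."""
    recordings, ledger = simulate_cohort(cohort_config)
    result = run_pipeline(recordings, catalog=catalog, config=pipeline_config)
    return result, ledger
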