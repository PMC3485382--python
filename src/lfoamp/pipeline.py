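"""End-to-end orchestration: cohort -> preprocessing -> amplitude maps ->
group statistics -> cluster-extent correction -> report bundle.

The analysis plan per metric (ALFF, fALFF) is: voxelwise two-sample t maps
of the standardized maps (patients minus controls) without covariates and
with gray-matter volume (voxelwise) and age covariates; voxelwise
correlation of patients' maps with total HRSD scores (optionally partialing
out the covariates); a VBM-style group t map of the smoothed GM maps; and
Monte Carlo cluster-extent correction of every statistic map, with the
demographics comparison table alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .amplitude import AmplitudeMap, compute_alff, compute_falff, standardize_map
from .cluster_inference import (
    Cluster,
    ClusterNull,
    MCConfig,
    apply_cluster_correction,
    clusters_to_table,
    simulate_cluster_null,
)
from .glm_stats import (
    DesignInfo,
    StatMap,
    correlation_map,
    glm_t_map,
    gm_group_difference,
    two_sample_t_map,
)
from .preprocess import (
    Band,
    detrend_linear,
    drop_initial_volumes,
    gaussian_smooth,
    make_group_mask,
    screen_motion,
    smooth_run,
)
from .synthetic_cohort import SyntheticSpec, generate_cohort
from .volume_io import (
    BoldRun,
    BrainMask,
    CohortManifest,
    SubjectRecord,
    read_bold,
    read_manifest,
    read_volume,
    write_volume,
)

__all__ = [
    "AnalysisParams",
    "CohortAnalysis",
    "analyze_cohort",
    "run_pipeline",
    "compare_demographics",
]

logger = logging.getLogger("lfoamp")


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the analysis chain."""

    n_drop: int = 10
    band: Band = field(default_factory=lambda: Band(0.01, 0.08))
    full_band: Band | None = None  # None -> (0, Nyquist)
    gm_mask_threshold: float = 0.15
    fwhm_mm: float = 4.0
    mc: MCConfig = field(default_factory=MCConfig)
    covariates: str = "gm+age"  # 'none' | 'gm' | 'gm+age'
    metrics: tuple[str, ...] = ("alff", "falff")
    screen: bool = True

    def __post_init__(self) -> None:
        if self.covariates not in ("none", "gm", "gm+age"):
            raise ValueError(f"unknown covariate mode {self.covariates!r}")
        bad = [m for m in self.metrics if m not in ("alff", "falff")]
        if bad:
            raise ValueError(f"unknown metrics: {bad}")


@dataclass
class CohortAnalysis:
    """In-memory result bundle of one cohort analysis."""

    mask: BrainMask
    amplitude_maps: dict[str, list[AmplitudeMap]]  # metric -> per-subject (standardized)
    stat_maps: dict[str, StatMap]
    corrected_maps: dict[str, StatMap]
    cluster_tables: dict[str, pd.DataFrame]
    clusters: dict[str, list[Cluster]]
    null: ClusterNull
    demographics: pd.DataFrame
    excluded_subjects: list[tuple[str, str]]
    records: list[SubjectRecord]


def _preprocess(run: BoldRun, params: AnalysisParams) -> BoldRun:
    run = drop_initial_volumes(run, params.n_drop)
    run = smooth_run(run, params.fwhm_mm)
    return detrend_linear(run)


def analyze_cohort(
    manifest: CohortManifest,
    bold_loader: Callable[[SubjectRecord], BoldRun],
    gm_loader: Callable[[SubjectRecord], np.ndarray],
    params: AnalysisParams = AnalysisParams(),
    null: ClusterNull | None = None,
) -> CohortAnalysis:
    """Run the full statistical analysis of a cohort.

    ``bold_loader`` / ``gm_loader`` map a subject record to its 4D run and
    3D GM map, so the same code path serves on-disk and in-memory cohorts.
    A precomputed ``null`` may be supplied to reuse a Monte Carlo run when
    the mask is unchanged.
    """
    manifest.require_both_groups()

    kept: list[SubjectRecord] = []
    excluded: list[tuple[str, str]] = []
    for rec in manifest.records:
        if params.screen:
            result = screen_motion(rec.motion)
            if not result:
                excluded.append((rec.subject_id, result.reason or "motion"))
                continue
        kept.append(rec)
    if excluded:
        logger.warning("excluded %d subject(s) for motion: %s", len(excluded), excluded)
    working = CohortManifest(kept).require_both_groups()

    gm_maps = {rec.subject_id: gm_loader(rec) for rec in working.records}
    grid = None
    metric_maps: dict[str, dict[str, AmplitudeMap]] = {m: {} for m in params.metrics}
    for rec in working.records:
        run = _preprocess(bold_loader(rec), params)
        grid = run.grid
        if "alff" in params.metrics:
            amap = compute_alff(run, params.band)
            amap.subject_id = rec.subject_id
            metric_maps["alff"][rec.subject_id] = amap
        if "falff" in params.metrics:
            fmap = compute_falff(run, params.band, params.full_band)
            fmap.subject_id = rec.subject_id
            metric_maps["falff"][rec.subject_id] = fmap

    mask = make_group_mask(
        [gm_maps[r.subject_id] for r in working.records],
        grid,
        threshold=params.gm_mask_threshold,
    )

    std_maps: dict[str, list[AmplitudeMap]] = {
        metric: [standardize_map(by_id[r.subject_id], mask) for r in working.records]
        for metric, by_id in metric_maps.items()
    }

    smoothed_gm = {
        sid: gaussian_smooth(m, mask.grid, params.fwhm_mm) for sid, m in gm_maps.items()
    }
    patients = working.patients()
    controls = working.controls()
    pat_ids = [r.subject_id for r in patients]
    con_ids = [r.subject_id for r in controls]
    groups = [r.group for r in working.records]
    ages = np.array([r.age_y for r in working.records])
    gm_stack = np.stack([smoothed_gm[r.subject_id] for r in working.records])

    stat_maps: dict[str, StatMap] = {}
    for metric, maps in std_maps.items():
        by_id = {m.subject_id: m for m in maps}
        stat_maps[f"{metric}_group"] = two_sample_t_map(
            [by_id[i] for i in pat_ids],
            [by_id[i] for i in con_ids],
            mask,
            contrast=f"{metric}: patients - controls",
        )
        if params.covariates != "none":
            design = DesignInfo(
                contrast_name=f"{metric}: patients - controls | covariates",
                group_labels=groups,
                scalar_covariates={"age": ages} if params.covariates == "gm+age" else {},
                voxelwise_covariates={"gm": gm_stack},
            )
            stat_maps[f"{metric}_group_cov"] = glm_t_map(maps, design, mask)

        pat_scores = np.array([r.hrsd_total for r in patients])
        pat_maps = [by_id[i] for i in pat_ids]
        if len(pat_maps) >= 3 and np.ptp(pat_scores) > 0:
            stat_maps[f"{metric}_hrsd_r"] = correlation_map(pat_maps, pat_scores, mask)
            if params.covariates != "none":
                partial: dict[str, np.ndarray] = {
                    "gm": np.stack([smoothed_gm[i] for i in pat_ids])
                }
                if params.covariates == "gm+age":
                    partial["age"] = np.array([r.age_y for r in patients])
                if len(pat_maps) - 2 - len(partial) >= 1:
                    stat_maps[f"{metric}_hrsd_r_cov"] = correlation_map(
                        pat_maps, pat_scores, mask, partial_covariates=partial
                    )
                else:
                    logger.warning(
                        "skipping partial HRSD correlation for %s: only %d "
                        "patients for %d covariates",
                        metric, len(pat_maps), len(partial),
                    )
        else:
            logger.warning(
                "skipping HRSD correlation for %s: needs >= 3 patients with "
                "non-constant scores",
                metric,
            )

    stat_maps["gm_group"] = gm_group_difference(
        [smoothed_gm[i] for i in pat_ids],
        [smoothed_gm[i] for i in con_ids],
        mask,
        presmoothed=True,
    )

    if null is None:
        null = simulate_cluster_null(mask, params.mc)
    elif null.mask_n_voxels != mask.n_voxels:
        raise ValueError("supplied cluster null was built for a different mask")

    corrected: dict[str, StatMap] = {}
    tables: dict[str, pd.DataFrame] = {}
    cluster_lists: dict[str, list[Cluster]] = {}
    for name, smap in stat_maps.items():
        thr, clusters = apply_cluster_correction(smap, null)
        corrected[name] = thr
        cluster_lists[name] = clusters
        tables[name] = clusters_to_table(clusters)

    return CohortAnalysis(
        mask=mask,
        amplitude_maps=std_maps,
        stat_maps=stat_maps,
        corrected_maps=corrected,
        cluster_tables=tables,
        clusters=cluster_lists,
        null=null,
        demographics=compare_demographics(working),
        excluded_subjects=excluded,
        records=working.records,
    )


def run_pipeline(
    out_dir: str | Path,
    manifest_path: str | Path | None = None,
    synthetic: SyntheticSpec | None = None,
    params: AnalysisParams = AnalysisParams(),
    tr_s: float | None = None,
) -> CohortAnalysis:
    """Disk-backed pipeline run producing a report bundle under ``out_dir``.

    Either ``manifest_path`` points at an existing cohort, or ``synthetic``
    describes one to generate under ``out_dir/cohort`` first. Outputs:
    NIfTI statistic maps (raw and cluster-corrected), TSV cluster tables,
    the demographics table, the serialized cluster null and a provenance
    log.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if manifest_path is None:
        if synthetic is None:
            raise ValueError("provide either manifest_path or a synthetic spec")
        manifest = generate_cohort(synthetic, out_dir / "cohort")
        tr_s = synthetic.tr_s
    else:
        manifest = read_manifest(manifest_path)

    missing = [
        p
        for r in manifest.records
        for p in (r.bold_path, r.gm_path)
        if not Path(p).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing input volumes: {missing}")

    def bold_loader(rec: SubjectRecord) -> BoldRun:
        return read_bold(rec.bold_path, tr_s=tr_s)

    def gm_loader(rec: SubjectRecord) -> np.ndarray:
        _, data = read_volume(rec.gm_path)
        return data

    analysis = analyze_cohort(manifest, bold_loader, gm_loader, params)

    maps_dir = out_dir / "maps"
    tables_dir = out_dir / "tables"
    maps_dir.mkdir(exist_ok=True)
    tables_dir.mkdir(exist_ok=True)
    write_volume(
        analysis.mask.grid, analysis.mask.include.astype(np.float32), maps_dir / "group_mask.nii.gz"
    )
    for name, smap in analysis.stat_maps.items():
        write_volume(smap.grid, smap.statistic, maps_dir / f"{name}.nii.gz")
        sidecar = {
            "kind": smap.kind,
            "df": smap.df,
            "contrast": smap.contrast,
            "n_degenerate_voxels": smap.n_degenerate,
        }
        (maps_dir / f"{name}.json").write_text(json.dumps(sidecar, indent=2))
    for name, smap in analysis.corrected_maps.items():
        write_volume(smap.grid, smap.statistic, maps_dir / f"{name}_corrected.nii.gz")
    for name, table in analysis.cluster_tables.items():
        table.to_csv(tables_dir / f"{name}_clusters.tsv", sep="\t", index=False)
    analysis.demographics.to_csv(tables_dir / "demographics.tsv", sep="\t", index=False)
    analysis.null.to_json(out_dir / "cluster_null.json")

    provenance = {
        "lfoamp_version": _pkg_version,
        "numpy_version": np.__version__,
        "seed": params.mc.seed if synthetic is None else synthetic.seed,
        "n_subjects_analyzed": len(analysis.records),
        "excluded_subjects": analysis.excluded_subjects,
        "params": {
            "n_drop": params.n_drop,
            "band_hz": [params.band.f_lo_hz, params.band.f_hi_hz],
            "full_band_hz": None
            if params.full_band is None
            else [params.full_band.f_lo_hz, params.full_band.f_hi_hz],
            "gm_mask_threshold": params.gm_mask_threshold,
            "fwhm_mm": params.fwhm_mm,
            "covariates": params.covariates,
            "metrics": list(params.metrics),
            "mc": {
                "voxel_p": params.mc.voxel_p,
                "n_iterations": params.mc.n_iterations,
                "fwhm_mm": params.mc.fwhm_mm,
                "alpha_fw": params.mc.alpha_fw,
                "connectivity": params.mc.connectivity,
                "seed": params.mc.seed,
            },
        },
        "k_min_voxels": analysis.null.k_min_voxels,
        "k_min_mm3": analysis.null.k_min_mm3,
        "mask_n_voxels": analysis.mask.n_voxels,
        "degenerate_voxel_counts": {
            name: smap.n_degenerate for name, smap in analysis.stat_maps.items()
        },
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return analysis


def _chi2_p(table: np.ndarray) -> tuple[float, float]:
    """Chi-squared test without continuity correction; (0, 1) for degenerate
    tables (a margin entirely in one category)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def compare_demographics(manifest: CohortManifest) -> pd.DataFrame:
    """Demographic/clinical comparison table (chi-squared for categorical
    variables, pooled two-sample t for continuous ones)."""
    manifest.require_both_groups()
    pats = manifest.patients()
    cons = manifest.controls()

    def mean_sd(vals: Sequence[float]) -> str:
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return "N/A"
        return f"{vals.mean():.1f}±{vals.std(ddof=1) if vals.size > 1 else 0.0:.1f}"

    def fmt_p(p: float) -> str:
        return ">0.99" if p > 0.99 else f"{p:.3f}"

    rows = []

    sex_table = [
        [sum(r.sex == "male" for r in g), sum(r.sex == "female" for r in g)]
        for g in (pats, cons)
    ]
    chi2, p = _chi2_p(np.array(sex_table))
    rows.append(
        {
            "variable": "Gender (male/female)",
            "patients": f"{sex_table[0][0]}/{sex_table[0][1]}",
            "controls": f"{sex_table[1][0]}/{sex_table[1][1]}",
            "statistic": chi2,
            "p_value": p,
            "p_formatted": fmt_p(p),
            "test": "chi-squared",
        }
    )

    for name, getter in (("Age (years)", "age_y"), ("Education (years)", "education_y")):
        a = np.array([getattr(r, getter) for r in pats], dtype=float)
        b = np.array([getattr(r, getter) for r in cons], dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "variable": name,
                "patients": mean_sd(a),
                "controls": mean_sd(b),
                "statistic": t_stat,
                "p_value": p,
                "p_formatted": fmt_p(p),
                "test": "two-sample t",
            }
        )

    hand_table = [
        [sum(r.handedness == "right" for r in g), sum(r.handedness == "left" for r in g)]
        for g in (pats, cons)
    ]
    chi2, p = _chi2_p(np.array(hand_table))
    rows.append(
        {
            "variable": "Handedness (right/left)",
            "patients": f"{hand_table[0][0]}/{hand_table[0][1]}",
            "controls": f"{hand_table[1][0]}/{hand_table[1][1]}",
            "statistic": chi2,
            "p_value": p,
            "p_formatted": fmt_p(p),
            "test": "chi-squared",
        }
    )

    for name, getter in (
        ("Illness duration (months)", "illness_duration_months"),
        ("Total HRSD score", "hrsd_total"),
        ("Total HAMA score", "hama_total"),
    ):
        a = [getattr(r, getter) for r in pats]
        b = [getattr(r, getter) for r in cons]
        rows.append(
            {
                "variable": name,
                "patients": mean_sd(a),
                "controls": mean_sd(b) if name == "Total HRSD score" else "N/A",
                "statistic": np.nan,
                "p_value": np.nan,
                "p_formatted": "",
                "test": "",
            }
        )

    return pd.DataFrame(
        rows,
        columns=[
            "variable",
            "patients",
            "controls",
            "statistic",
            "p_value",
            "p_formatted",
            "test",
        ],
    )
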