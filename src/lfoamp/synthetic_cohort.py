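"""Synthetic two-group resting-state cohorts with known planted effects.

Generates BOLD runs, gray-matter probability maps and a cohort manifest that
emulate a two-group (18 patients vs 18 matched controls) resting-state fMRI
design: TR = 2 s, 210 acquired volumes (200 analyzed after dropping 10),
3 mm isotropic voxels on a common grid, low-frequency (0.01-0.08 Hz)
oscillations riding on 1/f background noise, aliased physiological
components, and linear scanner drift. Group differences are planted as
spheres in which the in-band oscillation *amplitude* (patients vs controls)
or the GM volume is scaled by a known ratio, giving every downstream stage
a ground truth.

Signal model for one voxel v of subject s (time points t_i = i * TR):

    x(v, t) = baseline
            + drift_slope * (i - (n-1)/2)
            + sum_j  a_j * g_s * J_s(v) * E(v) * sin(2 pi f_j t + phi_sj)
            + sum_p  b_p * sin(2 pi f_p t + psi_sp)
            + background(v, t)

where ``a_j`` are the in-band component amplitudes, ``g_s`` a per-subject
lognormal amplitude factor (global, removed by standardization), ``J_s(v)``
a voxelwise lognormal amplitude jitter field (the between-subject variance
the group tests see), ``E(v)`` the product of planted amplitude ratios of
spheres containing v (patients only), and ``background`` is 1/f^beta noise
with time-domain standard deviation ``white_sd``. The oscillation phase
``phi_sj`` is shared across voxels within a subject (regionally coherent
low-frequency oscillations), so spatial smoothing combines amplitudes
coherently and amplitude maps inherit exactly the applied smoothing — the
assumption the Monte Carlo cluster correction makes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .preprocess import fwhm_to_sigma_mm
from .volume_io import (
    BrainMask,
    BoldRun,
    CohortManifest,
    MotionSummary,
    SubjectRecord,
    VolumeGrid,
    write_manifest,
    write_volume,
)

__all__ = [
    "PlantedEffect",
    "NoiseModel",
    "ScoreModel",
    "SyntheticSpec",
    "make_brain_mask",
    "simulate_bold",
    "simulate_gm_map",
    "simulate_records",
    "generate_cohort",
    "mni_gm_group_mask",
]

# stream tags keeping the per-purpose random streams distinct
_TAG_BOLD, _TAG_GM, _TAG_RECORDS = 101, 202, 303


def _subject_stream(seed: int, subject_id: str, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(subject_id.encode()), tag])


@dataclass(frozen=True)
class PlantedEffect:
    """A spherical region where patients' signal is scaled by a known ratio.

    ``amplitude_ratio`` multiplies the in-band oscillation amplitude
    (``applies_to='bold_amplitude'``) or the GM value
    (``applies_to='gm_volume'``) of patients inside the sphere; > 1 plants an
    increase, < 1 a decrease.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude_ratio: float
    applies_to: str = "bold_amplitude"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be positive")
        if self.applies_to not in ("bold_amplitude", "gm_volume"):
            raise ValueError(f"unknown applies_to {self.applies_to!r}")

    def member_mask(self, grid: VolumeGrid) -> np.ndarray:
        x, y, z = grid.coordinate_arrays()
        cx, cy, cz = self.center_mm
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return d2 <= self.radius_mm**2


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance signal model: 1/f^beta background, physiological sinusoids
    (e.g. aliased respiratory/cardiac components) and linear drift."""

    onef_exponent: float = 1.0
    white_sd: float = 1.0
    physio_components: tuple[tuple[float, float], ...] = ((0.11, 0.3), (0.2, 0.5))
    drift_slope_per_vol: float = 0.01

    def __post_init__(self) -> None:
        if self.onef_exponent < 0:
            raise ValueError("onef_exponent must be >= 0")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")
        object.__setattr__(
            self,
            "physio_components",
            tuple((float(f), float(a)) for f, a in self.physio_components),
        )

    def validate_for(self, nyquist_hz: float) -> None:
        for f, _ in self.physio_components:
            if not 0 < f <= nyquist_hz + 1e-12:
                raise ValueError(
                    f"physio component at {f} Hz outside (0, Nyquist={nyquist_hz}]"
                )


@dataclass(frozen=True)
class ScoreModel:
    """Clinical score distributions (Hamilton depression/anxiety scales)."""

    patient_hrsd_mean: float = 25.0
    patient_hrsd_sd: float = 5.0
    control_hrsd_mean: float = 4.0
    control_hrsd_sd: float = 3.0
    patient_hama_mean: float = 17.0
    patient_hama_sd: float = 6.0
    floor_patient_hrsd_at_24: bool = False  # mimic an HRSD >= 24 inclusion criterion


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort.

    Defaults mirror the emulated study design: 18 subjects per group on a
    64 x 64 x 30 grid of 3 mm voxels, TR = 2 s, 210 acquired volumes of
    which the first 10 are dropped downstream.
    """

    n_per_group: int = 18
    grid: VolumeGrid = field(default_factory=lambda: VolumeGrid.default((64, 64, 30)))
    n_volumes_acquired: int = 210
    tr_s: float = 2.0
    base_band_components: tuple[tuple[float, float], ...] = (
        (0.02, 1.2),
        (0.035, 1.0),
        (0.05, 0.9),
        (0.065, 0.7),
    )
    effects: tuple[PlantedEffect, ...] = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    gm_smoothness_mm: float = 6.0
    gm_mean_level: float = 0.55
    gm_noise_sd: float = 0.08
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0
    baseline: float = 100.0
    subject_amp_cv: float = 0.10  # global amplitude factor across subjects
    voxel_amp_cv: float = 0.12  # voxelwise between-subject amplitude jitter
    brain_semi_axes_mm: tuple[float, float, float] | None = None
    n_drop: int = 10

    def __post_init__(self) -> None:
        if self.n_volumes_acquired <= self.n_drop:
            raise ValueError(
                f"n_volumes_acquired ({self.n_volumes_acquired}) must exceed the "
                f"{self.n_drop} volumes dropped downstream"
            )
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not 0 < self.gm_mean_level < 1:
            raise ValueError("gm_mean_level must be in (0, 1)")
        object.__setattr__(
            self,
            "base_band_components",
            tuple((float(f), float(a)) for f, a in self.base_band_components),
        )
        object.__setattr__(self, "effects", tuple(self.effects))

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def to_json(self, path: str | Path) -> Path:
        """Serialize the cohort description as a JSON config (lossless)."""
        import json
        from dataclasses import asdict

        payload = asdict(self)
        payload["grid"] = {
            "dims": list(self.grid.dims),
            "voxel_size_mm": list(self.grid.voxel_size_mm),
            "affine": self.grid.affine.tolist(),
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        import json

        payload = json.loads(Path(path).read_text())
        g = payload.pop("grid")
        grid = VolumeGrid(
            tuple(g["dims"]), tuple(g["voxel_size_mm"]), np.array(g["affine"])
        )
        effects = tuple(
            PlantedEffect(
                center_mm=tuple(e["center_mm"]),
                radius_mm=e["radius_mm"],
                amplitude_ratio=e["amplitude_ratio"],
                applies_to=e["applies_to"],
            )
            for e in payload.pop("effects")
        )
        noise_d = payload.pop("noise")
        noise = NoiseModel(
            onef_exponent=noise_d["onef_exponent"],
            white_sd=noise_d["white_sd"],
            physio_components=tuple(tuple(p) for p in noise_d["physio_components"]),
            drift_slope_per_vol=noise_d["drift_slope_per_vol"],
        )
        score = ScoreModel(**payload.pop("score_model"))
        payload["base_band_components"] = tuple(
            tuple(c) for c in payload["base_band_components"]
        )
        if payload.get("brain_semi_axes_mm") is not None:
            payload["brain_semi_axes_mm"] = tuple(payload["brain_semi_axes_mm"])
        return cls(grid=grid, effects=effects, noise=noise, score_model=score, **payload)

    def brain_mask(self) -> BrainMask:
        semi = self.brain_semi_axes_mm
        if semi is None:
            # ellipsoid filling ~80% of the half field of view per axis
            semi = tuple(
                0.8 * (d - 1) / 2.0 * v
                for d, v in zip(self.grid.dims, self.grid.voxel_size_mm)
            )
        return make_brain_mask(self.grid, semi)


def make_brain_mask(
    grid: VolumeGrid,
    semi_axes_mm: Sequence[float],
    center_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> BrainMask:
    """Ellipsoidal brain-like mask: voxel centers satisfying the ellipsoid
    inequality sum(((x - c) / a)^2) <= 1."""
    semi = tuple(float(a) for a in semi_axes_mm)
    if len(semi) != 3 or any(a <= 0 for a in semi):
        raise ValueError(f"semi-axes must be 3 positive lengths, got {semi}")
    x, y, z = grid.coordinate_arrays()
    cx, cy, cz = (float(c) for c in center_mm)
    q = (
        ((x - cx) / semi[0]) ** 2
        + ((y - cy) / semi[1]) ** 2
        + ((z - cz) / semi[2]) ** 2
    )
    mask = BrainMask(grid, q <= 1.0)
    if mask.n_voxels == 0:
        raise ValueError("brain mask is empty; semi-axes too small for the grid")
    return mask


def _onef_background(
    rng: np.random.Generator, n_vox: int, n_t: int, tr_s: float, noise: NoiseModel
) -> np.ndarray:
    """1/f^beta noise, time-domain sd ``white_sd``, independent across voxels."""
    if noise.white_sd == 0:
        return np.zeros((n_vox, n_t))
    white = rng.standard_normal((n_vox, n_t))
    beta = noise.onef_exponent
    if beta == 0:
        return noise.white_sd * white
    freqs_full = np.fft.fftfreq(n_t, d=tr_s)
    w_full = np.zeros(n_t)
    nz = freqs_full != 0
    w_full[nz] = np.abs(freqs_full[nz]) ** (-beta / 2.0)
    w_full /= np.sqrt(np.mean(w_full**2))
    w_half = w_full[: n_t // 2 + 1]
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * w_half, n=n_t, axis=-1)
    return noise.white_sd * shaped


def simulate_bold(
    spec: SyntheticSpec, record: SubjectRecord, seed: int | None = None
) -> BoldRun:
    """Simulate one subject's 4D BOLD run; deterministic in (seed, subject_id)."""
    seed = spec.seed if seed is None else seed
    rng = _subject_stream(seed, record.subject_id, _TAG_BOLD)
    spec.noise.validate_for(spec.nyquist_hz)
    for f, _ in spec.base_band_components:
        if f > spec.nyquist_hz + 1e-12:
            raise ValueError(f"band component at {f} Hz exceeds Nyquist")

    mask = spec.brain_mask()
    n_t = spec.n_volumes_acquired
    t = np.arange(n_t) * spec.tr_s
    in_mask = mask.include
    n_vox = mask.n_voxels

    # fixed draw order => reproducibility of every piece
    g_subj = (
        float(np.exp(rng.normal(0.0, spec.subject_amp_cv)))
        if spec.subject_amp_cv > 0
        else 1.0
    )
    comp_phases = rng.uniform(0, 2 * np.pi, size=len(spec.base_band_components))
    jitter = (
        np.exp(rng.normal(0.0, spec.voxel_amp_cv, size=n_vox))
        if spec.voxel_amp_cv > 0
        else np.ones(n_vox)
    )
    physio_phases = rng.uniform(0, 2 * np.pi, size=len(spec.noise.physio_components))
    background = _onef_background(rng, n_vox, n_t, spec.tr_s, spec.noise)

    effect_field = np.ones(n_vox)
    if record.group == "patient":
        for eff in spec.effects:
            if eff.applies_to != "bold_amplitude":
                continue
            sphere = eff.member_mask(spec.grid)
            if not (sphere & in_mask).any():
                raise ValueError(
                    f"planted effect at {eff.center_mm} does not intersect the brain mask"
                )
            effect_field[sphere[in_mask]] *= eff.amplitude_ratio

    amp = g_subj * jitter * effect_field  # (V,)
    series = np.zeros((n_vox, n_t))
    for (f, a), phi in zip(spec.base_band_components, comp_phases):
        series += (a * amp)[:, None] * np.sin(2 * np.pi * f * t + phi)[None, :]
    for (f, b), psi in zip(spec.noise.physio_components, physio_phases):
        series += b * np.sin(2 * np.pi * f * t + psi)[None, :]
    series += background
    series += spec.baseline
    series += spec.noise.drift_slope_per_vol * (np.arange(n_t) - (n_t - 1) / 2.0)[None, :]

    data = np.zeros((*spec.grid.dims, n_t))
    data[in_mask] = series
    return BoldRun(spec.grid, data, spec.tr_s)


def simulate_gm_map(
    spec: SyntheticSpec, record: SubjectRecord, seed: int | None = None
) -> np.ndarray:
    """Smooth random gray-matter probability map in [0, 1].

    Mean level ``gm_mean_level`` inside the brain mask with a Gaussian random
    field of standard deviation ``gm_noise_sd`` and smoothness
    ``gm_smoothness_mm``; planted ``gm_volume`` effects multiply patients'
    values inside their spheres; values clipped to [0, 1]; zero outside the
    brain mask.
    """
    seed = spec.seed if seed is None else seed
    rng = _subject_stream(seed, record.subject_id, _TAG_GM)
    mask = spec.brain_mask()
    gm = np.zeros(spec.grid.dims)

    if spec.gm_noise_sd > 0:
        fieldmap = rng.standard_normal(spec.grid.dims)
        if spec.gm_smoothness_mm > 0:
            sigma_vox = [
                fwhm_to_sigma_mm(spec.gm_smoothness_mm) / v
                for v in spec.grid.voxel_size_mm
            ]
            fieldmap = ndimage.gaussian_filter(fieldmap, sigma_vox, mode="reflect")
        sd = fieldmap[mask.include].std()
        fieldmap = fieldmap / sd * spec.gm_noise_sd if sd > 0 else fieldmap * 0.0
    else:
        fieldmap = np.zeros(spec.grid.dims)

    gm[mask.include] = spec.gm_mean_level + fieldmap[mask.include]

    if record.group == "patient":
        for eff in spec.effects:
            if eff.applies_to != "gm_volume":
                continue
            sphere = eff.member_mask(spec.grid)
            if not (sphere & mask.include).any():
                raise ValueError(
                    f"planted GM effect at {eff.center_mm} does not intersect the brain mask"
                )
            gm[sphere & mask.include] *= eff.amplitude_ratio

    return np.clip(gm, 0.0, 1.0)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Normal draws redrawn into [lo, hi] (clipping would bias the mean)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def simulate_records(spec: SyntheticSpec) -> list[SubjectRecord]:
    """Draw demographics, clinical scores and motion summaries.

    Groups are matched: each control's age is the same-index patient's age
    plus small jitter, and the sex sequence is identical in both groups
    (alternating, giving a 9/9 split at n = 18). Motion is drawn below the
    1 mm / 1 degree screening thresholds.
    """
    if spec.n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng([spec.seed, _TAG_RECORDS])
    n = spec.n_per_group
    sm = spec.score_model

    pat_age = _truncated_normal(rng, 34.0, 13.0, 18.0, 60.0, n)
    con_age = np.clip(pat_age + rng.normal(0.0, 2.0, size=n), 18.0, 60.0)
    pat_edu = _truncated_normal(rng, 13.0, 2.0, 6.0, 22.0, n)
    con_edu = _truncated_normal(rng, 14.0, 2.0, 6.0, 22.0, n)
    hrsd_lo = 24.0 if sm.floor_patient_hrsd_at_24 else 0.0
    pat_hrsd = _truncated_normal(
        rng, sm.patient_hrsd_mean, sm.patient_hrsd_sd, hrsd_lo, 52.0, n
    )
    con_hrsd = _truncated_normal(
        rng, sm.control_hrsd_mean, sm.control_hrsd_sd, 0.0, 6.0, n
    )
    pat_hama = _truncated_normal(rng, sm.patient_hama_mean, sm.patient_hama_sd, 0.0, 56.0, n)
    duration = _truncated_normal(rng, 5.0, 4.0, 1.0, 24.0, n)
    motion = rng.uniform(0.05, 0.85, size=(2 * n, 6))

    sexes = ["male" if i % 2 == 0 else "female" for i in range(n)]
    records: list[SubjectRecord] = []
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"sub-mdd{i + 1:03d}",
                group="patient",
                age_y=round(float(pat_age[i]), 1),
                sex=sexes[i],
                education_y=round(float(pat_edu[i]), 1),
                handedness="right",
                hrsd_total=float(np.round(pat_hrsd[i])),
                hama_total=float(np.round(pat_hama[i])),
                illness_duration_months=round(float(duration[i]), 1),
                motion=MotionSummary(
                    tuple(np.round(motion[i, :3], 3)), tuple(np.round(motion[i, 3:], 3))
                ),
            )
        )
    for i in range(n):
        records.append(
            SubjectRecord(
                subject_id=f"sub-hc{i + 1:03d}",
                group="control",
                age_y=round(float(con_age[i]), 1),
                sex=sexes[i],
                education_y=round(float(con_edu[i]), 1),
                handedness="right",
                hrsd_total=float(np.round(con_hrsd[i])),
                motion=MotionSummary(
                    tuple(np.round(motion[n + i, :3], 3)),
                    tuple(np.round(motion[n + i, 3:], 3)),
                ),
            )
        )
    return records


def generate_cohort(spec: SyntheticSpec, out_dir: str | Path) -> CohortManifest:
    """Write the full cohort (BOLD + GM NIfTI volumes + TSV manifest) to disk.

    Identical (spec, seed) produce byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = simulate_records(spec)
    for rec in records:
        bold = simulate_bold(spec, rec)
        gm = simulate_gm_map(spec, rec)
        # manifest stores paths relative to its own directory, so identical
        # (spec, seed) give byte-identical cohorts wherever they are written
        rec.bold_path = f"{rec.subject_id}_bold.nii.gz"
        rec.gm_path = f"{rec.subject_id}_gm.nii.gz"
        write_volume(spec.grid, bold.data, out_dir / rec.bold_path, tr_s=spec.tr_s)
        write_volume(spec.grid, gm, out_dir / rec.gm_path)
    write_manifest(CohortManifest(records), out_dir / "manifest.tsv")
    from .volume_io import read_manifest

    return read_manifest(out_dir / "manifest.tsv")


def mni_gm_group_mask(threshold: float = 0.15, resolution: int = 3) -> BrainMask:
    """Whole-brain gray-matter mask from the bundled MNI152 template.

    Surrogate for a cohort-mean GM mask when reproducing whole-brain
    cluster-extent thresholds; thresholds the MNI152 GM probability template
    at ``threshold`` (0.15 default, matching the group-mask convention).
    """
    from nilearn.datasets import load_mni152_gm_mask

    img = load_mni152_gm_mask(resolution=resolution, threshold=threshold)
    aff = np.asarray(img.affine, dtype=float)
    dims = tuple(int(d) for d in img.shape[:3])
    voxel_size = tuple(float(v) for v in np.linalg.norm(aff[:3, :3], axis=0))
    grid = VolumeGrid(dims, voxel_size, aff)
    return BrainMask(grid, np.asarray(img.dataobj) > 0)
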