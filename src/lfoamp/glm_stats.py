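"""Voxelwise group statistics: two-sample t maps, covariate GLMs and
clinical-score correlation maps.

All tests are two-sided and mass-univariate within a gray-matter mask.
The two-sample t uses the pooled (equal-variance) estimator with
df = n_a + n_b - 2 and the sign convention patients minus controls
(a Welch variant is available behind a flag). The GLM regresses each
voxel's amplitude on [intercept, group indicator, scalar covariates,
voxelwise covariates]; scalar covariates are mean-centered and voxelwise
covariates centered per voxel so the group coefficient stays interpretable
as the adjusted group difference. Rank-deficient voxels are excluded from
the analyzed mask and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .amplitude import AmplitudeMap
from .preprocess import gaussian_smooth
from .volume_io import BrainMask, VolumeGrid

__all__ = [
    "DesignInfo",
    "StatMap",
    "two_sample_t_map",
    "glm_t_map",
    "correlation_map",
    "gm_group_difference",
    "r_to_t",
]

_RANK_TOL = 1e-10


@dataclass
class DesignInfo:
    """Description of a voxelwise design.

    ``group_labels`` is a per-subject sequence of 'patient'/'control';
    ``scalar_covariates`` maps name -> per-subject values; and
    ``voxelwise_covariates`` maps name -> per-subject stack of 3D maps
    (array of shape (n_subjects, x, y, z)).
    """

    contrast_name: str
    group_labels: Sequence[str]
    scalar_covariates: dict[str, np.ndarray] = field(default_factory=dict)
    voxelwise_covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def group_indicator(self) -> np.ndarray:
        labels = list(self.group_labels)
        bad = sorted({g for g in labels if g not in ("patient", "control")})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        return np.array([1.0 if g == "patient" else 0.0 for g in labels])


@dataclass
class StatMap:
    """A voxelwise statistic volume (t or r) with its inference metadata."""

    grid: VolumeGrid
    statistic: np.ndarray
    kind: str  # 't' | 'r'
    df: int
    mask: BrainMask
    contrast: str = ""
    n_degenerate: int = 0  # zero-variance / rank-deficient voxels excluded

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if self.statistic.shape != self.grid.dims:
            raise ValueError("statistic shape does not match grid")
        if self.kind not in ("t", "r"):
            raise ValueError(f"kind must be 't' or 'r', got {self.kind!r}")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if not np.all(np.isfinite(self.statistic[self.mask.include])):
            raise ValueError("statistic contains non-finite values inside the mask")


def _stack_in_mask(maps: Sequence[AmplitudeMap | np.ndarray], mask: BrainMask) -> np.ndarray:
    """Stack map values inside the mask into an (n_subjects, n_voxels) matrix."""
    rows = []
    for m in maps:
        values = m.values if isinstance(m, AmplitudeMap) else np.asarray(m, dtype=float)
        if values.shape != mask.grid.dims:
            raise ValueError("map shape does not match mask grid")
        rows.append(values[mask.include])
    return np.stack(rows)


def _pooled_t(a: np.ndarray, b: np.ndarray, welch: bool = False) -> tuple[np.ndarray, int, int]:
    """Two-sample t on columns of (n, V) matrices; returns (t, df, n_zero_var)."""
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError(f"each group needs >= 2 subjects, got {na} and {nb}")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        df = na + nb - 2  # conservative df kept integral; Welch se only
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = na + nb - 2
    zero = se2 <= 0
    t = np.zeros_like(ma)
    np.divide(ma - mb, np.sqrt(se2, where=~zero, out=np.ones_like(se2)), out=t, where=~zero)
    return t, df, int(zero.sum())


def two_sample_t_map(
    maps_a: Sequence[AmplitudeMap | np.ndarray],
    maps_b: Sequence[AmplitudeMap | np.ndarray],
    mask: BrainMask,
    contrast: str = "patients - controls",
    welch: bool = False,
) -> StatMap:
    """Pooled-variance two-sample t per in-mask voxel (group a minus group b).

    Voxels with zero pooled variance get t = 0 and are counted in
    ``n_degenerate``.
    """
    mask.require_nonempty()
    a = _stack_in_mask(maps_a, mask)
    b = _stack_in_mask(maps_b, mask)
    t, df, n_zero = _pooled_t(a, b, welch=welch)
    vol = np.zeros(mask.grid.dims)
    vol[mask.include] = t
    return StatMap(mask.grid, vol, "t", df, mask, contrast, n_degenerate=n_zero)


def glm_t_map(
    maps: Sequence[AmplitudeMap | np.ndarray],
    design: DesignInfo,
    mask: BrainMask,
) -> StatMap:
    """OLS of amplitude on [intercept, group, covariates]; t for group.

    With no covariates this reduces exactly to the pooled two-sample t.
    Voxels where the design is rank deficient (e.g. a voxelwise covariate
    collinear with the group indicator) are excluded from the analyzed mask
    and counted in ``n_degenerate``.
    """
    mask.require_nonempty()
    y = _stack_in_mask(maps, mask)  # (n, V)
    n, n_vox = y.shape
    g = design.group_indicator()
    if g.shape[0] != n:
        raise ValueError("design group_labels length does not match number of maps")

    fixed_cols = [np.ones(n), g]
    for name, vals in design.scalar_covariates.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != (n,):
            raise ValueError(f"scalar covariate {name!r} has wrong length")
        fixed_cols.append(vals - vals.mean())
    fixed = np.column_stack(fixed_cols)  # (n, p_fixed)

    vox_covs = []
    for name, stack in design.voxelwise_covariates.items():
        stack = np.asarray(stack, dtype=float)
        if stack.shape != (n, *mask.grid.dims):
            raise ValueError(
                f"voxelwise covariate {name!r} must have shape (n, x, y, z)"
            )
        c = stack[:, mask.include]  # (n, V)
        vox_covs.append(c - c.mean(axis=0, keepdims=True))

    p = fixed.shape[1] + len(vox_covs)
    df = n - p
    if df < 1:
        raise ValueError(f"design leaves no residual degrees of freedom (n={n}, p={p})")

    # X per voxel: (V, n, p) = fixed columns broadcast + per-voxel covariates
    x = np.broadcast_to(fixed, (n_vox, n, fixed.shape[1])).copy()
    if vox_covs:
        extra = np.stack([c.T for c in vox_covs], axis=-1)  # (V, n, k)
        x = np.concatenate([x, extra], axis=-1)

    xtx = np.einsum("vnp,vnq->vpq", x, x)
    xty = np.einsum("vnp,vn->vp", x, y.T)

    eig = np.linalg.eigvalsh(xtx)
    ok = eig[:, 0] > _RANK_TOL * np.maximum(eig[:, -1], 1.0)
    n_bad = int((~ok).sum())

    t_vals = np.zeros(n_vox)
    if ok.any():
        xtx_ok = xtx[ok]
        beta = np.linalg.solve(xtx_ok, xty[ok][..., None])[..., 0]  # (V_ok, p)
        fitted = np.einsum("vnp,vp->vn", x[ok], beta)
        resid = y.T[ok] - fitted
        sigma2 = (resid**2).sum(axis=1) / df
        inv = np.linalg.inv(xtx_ok)
        var_g = sigma2 * inv[:, 1, 1]
        good_var = var_g > 0
        t_ok = np.zeros(ok.sum())
        t_ok[good_var] = beta[good_var, 1] / np.sqrt(var_g[good_var])
        n_bad += int((~good_var).sum())
        t_vals[ok] = t_ok

    include = np.zeros(mask.grid.dims, dtype=bool)
    idx = np.flatnonzero(mask.include.ravel())
    include.ravel()[idx[ok]] = True
    analyzed = BrainMask(mask.grid, include)
    vol = np.zeros(mask.grid.dims)
    vol.ravel()[idx] = t_vals
    vol[~analyzed.include] = 0.0
    return StatMap(
        mask.grid, vol, "t", df, analyzed, design.contrast_name, n_degenerate=n_bad
    )


def correlation_map(
    maps: Sequence[AmplitudeMap | np.ndarray],
    scores: np.ndarray,
    mask: BrainMask,
    partial_covariates: dict[str, np.ndarray] | None = None,
) -> StatMap:
    """Voxelwise Pearson correlation between amplitude and a clinical score.

    ``partial_covariates`` maps name -> per-subject values, either scalar
    (shape (n,)) or voxelwise (shape (n, x, y, z)); both score and amplitude
    are residualized on [intercept, covariates] before correlating, giving
    the partial r. df = n - 2 - n_covariates.
    """
    mask.require_nonempty()
    y = _stack_in_mask(maps, mask)  # (n, V)
    n, n_vox = y.shape
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n,):
        raise ValueError("scores length does not match number of maps")
    if n < 3:
        raise ValueError(f"correlation needs >= 3 subjects, got {n}")
    if np.ptp(scores) == 0:
        raise ValueError("scores are constant; correlation is undefined")

    partial_covariates = partial_covariates or {}
    k = len(partial_covariates)
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough subjects for the requested partial correlation")

    scalar_covs = []
    vox_covs = []
    for name, vals in partial_covariates.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape == (n,):
            scalar_covs.append(vals - vals.mean())
        elif vals.shape == (n, *mask.grid.dims):
            c = vals[:, mask.include]
            vox_covs.append(c - c.mean(axis=0, keepdims=True))
        else:
            raise ValueError(f"partial covariate {name!r} has unsupported shape")

    s = scores - scores.mean()
    yc = y - y.mean(axis=0, keepdims=True)
    if k == 0:
        s_res = np.broadcast_to(s[:, None], yc.shape)
        y_res = yc
    else:
        # residualize per voxel on centered covariates
        cov_stack = [np.broadcast_to(c[:, None], (n, n_vox)) for c in scalar_covs]
        cov_stack += vox_covs
        z = np.stack(cov_stack, axis=-1)  # (n, V, k)
        ztz = np.einsum("nvk,nvl->vkl", z, z)
        ztz += _RANK_TOL * np.eye(z.shape[-1])
        zty = np.einsum("nvk,nv->vk", z, yc)
        zts = np.einsum("nvk,n->vk", z, s)
        beta_y = np.linalg.solve(ztz, zty[..., None])[..., 0]
        beta_s = np.linalg.solve(ztz, zts[..., None])[..., 0]
        y_res = yc - np.einsum("nvk,vk->nv", z, beta_y)
        s_res = np.broadcast_to(s[:, None], (n, n_vox)) - np.einsum(
            "nvk,vk->nv", z, beta_s
        )

    num = (s_res * y_res).sum(axis=0)
    den = np.sqrt((s_res**2).sum(axis=0) * (y_res**2).sum(axis=0))
    zero = den <= 0
    r = np.zeros(n_vox)
    np.divide(num, den, out=r, where=~zero)
    r = np.clip(r, -1.0, 1.0)
    vol = np.zeros(mask.grid.dims)
    vol[mask.include] = r
    return StatMap(
        mask.grid,
        vol,
        "r",
        df,
        mask,
        "amplitude ~ score" + (" (partial)" if k else ""),
        n_degenerate=int(zero.sum()),
    )


def r_to_t(r: np.ndarray, df: int) -> np.ndarray:
    """Convert correlation values to t statistics: t = r sqrt(df / (1 - r^2))."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        return r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))


def gm_group_difference(
    gm_maps_a: Sequence[np.ndarray],
    gm_maps_b: Sequence[np.ndarray],
    mask: BrainMask,
    fwhm_mm: float = 4.0,
    presmoothed: bool = False,
) -> StatMap:
    """Two-sample t map on smoothed GM volume maps (the VBM group contrast).

    Maps are smoothed with ``fwhm_mm`` first unless ``presmoothed``.
    """
    grid = mask.grid
    if not presmoothed and fwhm_mm > 0:
        gm_maps_a = [gaussian_smooth(m, grid, fwhm_mm) for m in gm_maps_a]
        gm_maps_b = [gaussian_smooth(m, grid, fwhm_mm) for m in gm_maps_b]
    return two_sample_t_map(
        list(gm_maps_a), list(gm_maps_b), mask, contrast="GM volume: patients - controls"
    )


def critical_t(voxel_p: float, df: int) -> float:
    """t value whose upper-tail probability is ``voxel_p``."""
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    return float(stats.t.isf(voxel_p, df))
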