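"""Voxelwise single-case comparison of skeletonized FA maps.

One patient's FA skeleton is compared voxel by voxel against a control
cohort, restricted to white matter (control-mean FA >= 0.2).  The default
statistic is the Crawford–Howell single-case t,

    t = (x_patient − mean_c) / (sd_c · sqrt(1 + 1/n_c)),   df = n_c − 1,

the correct inference for one observation against a normative sample.  A
naive z-score form (t = (x − mean_c)/sd_c with a normal p) is kept behind a
flag for comparison; it ignores the sampling error of the control mean/SD
and is anti-conservative.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .synthetic import FASkeletonMap

SINGLE_CASE = "single_case"
ZSCORE = "zscore"

FA_WM_THRESHOLD = 0.2


class FACompareError(ValueError):
    pass


@dataclass
class StatMap:
    """Voxelwise t and two-sided p over the analysis mask (NaN elsewhere)."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # analysis mask: skeleton & control-mean FA >= threshold
    affine: np.ndarray
    n_controls: int
    df: float
    method: str
    n_sd_zero: int  # in-mask voxels dropped for zero control SD


def singlecase_map(
    patient: FASkeletonMap,
    controls: list[FASkeletonMap],
    fa_threshold: float = FA_WM_THRESHOLD,
    method: str = SINGLE_CASE,
) -> StatMap:
    """Patient-vs-controls t/p per skeleton voxel with control-mean FA >= threshold."""
    if len(controls) < 3:
        raise FACompareError("need at least 3 control FA maps")
    if method not in (SINGLE_CASE, ZSCORE):
        raise FACompareError(f"method must be {SINGLE_CASE!r} or {ZSCORE!r}")
    mask = patient.skeleton_mask
    for m in controls:
        if m.fa.shape != patient.fa.shape or not np.array_equal(
            m.skeleton_mask, mask
        ):
            raise FACompareError("FA maps do not share grid and skeleton mask")
        if not np.allclose(m.affine, patient.affine, atol=1e-4):
            raise FACompareError("FA map affines differ beyond 1e-4")

    stack = np.stack([m.fa[mask] for m in controls])  # (n_c, voxels)
    mean_c = stack.mean(axis=0)
    sd_c = stack.std(axis=0, ddof=1)
    n_c = len(controls)

    analysis = mean_c >= fa_threshold
    usable = analysis & (sd_c > 0)
    n_sd_zero = int((analysis & (sd_c == 0)).sum())

    x = patient.fa[mask]
    t_vals = np.full(mask.sum(), np.nan)
    p_vals = np.full(mask.sum(), np.nan)
    if method == SINGLE_CASE:
        se = sd_c[usable] * np.sqrt(1.0 + 1.0 / n_c)
        df = n_c - 1
        t_vals[usable] = (x[usable] - mean_c[usable]) / se
        p_vals[usable] = 2.0 * stats.t.sf(np.abs(t_vals[usable]), df)
    else:
        df = np.inf
        t_vals[usable] = (x[usable] - mean_c[usable]) / sd_c[usable]
        p_vals[usable] = 2.0 * stats.norm.sf(np.abs(t_vals[usable]))

    t_map = np.full(patient.fa.shape, np.nan)
    p_map = np.full(patient.fa.shape, np.nan)
    t_map[mask] = t_vals
    p_map[mask] = p_vals
    full_mask = np.zeros_like(mask)
    full_mask[mask] = usable
    return StatMap(
        t=t_map,
        p=p_map,
        mask=full_mask,
        affine=patient.affine.copy(),
        n_controls=n_c,
        df=float(df),
        method=method,
        n_sd_zero=n_sd_zero,
    )


def overlay_report(
    statmap: StatMap,
    reference: np.ndarray,
    out_prefix: str | Path,
    p_threshold: float = 0.01,
):
    """Thresholded overlay: a NIfTI of significant t values and a PNG render.

    Purely presentational.  Returns ``(nifti_path, png_path)``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import nibabel as nib

    reference = np.asarray(reference)
    if reference.shape != statmap.t.shape:
        raise FACompareError("reference grid does not match the statistic map")
    significant = np.isfinite(statmap.p) & (statmap.p < p_threshold)
    overlay = np.where(significant, statmap.t, 0.0)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    nifti_path = out_prefix.with_suffix(".nii")
    nib.save(nib.Nifti1Image(overlay.astype(np.float32), statmap.affine), nifti_path)

    z = reference.shape[2] // 2
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(reference[:, :, z].T, cmap="gray", origin="lower")
    masked = np.ma.masked_where(overlay[:, :, z] == 0, overlay[:, :, z])
    im = ax.imshow(masked.T, cmap="coolwarm", origin="lower")
    fig.colorbar(im, ax=ax, label="t")
    ax.set_title(f"|p| < {p_threshold} ({statmap.method})")
    ax.axis("off")
    png_path = out_prefix.with_suffix(".png")
    fig.savefig(png_path, dpi=100, bbox_inches="tight")
    plt.close(fig)
    return nifti_path, png_path


def exceedance_fraction(statmap: StatMap, alpha: float = 0.05) -> float:
    """In-mask fraction of |t| beyond the two-sided critical value."""
    t = statmap.t[statmap.mask]
    if statmap.method == SINGLE_CASE:
        crit = stats.t.ppf(1.0 - alpha / 2.0, statmap.df)
    else:
        crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float((np.abs(t) > crit).mean())
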