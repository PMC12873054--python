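"""Voxel-wise perfusion mapping pipeline for 4D dynamic series.

Stages: absolute signal enhancement (S(t) - S0) -> optional rigid
(translation-only) motion correction -> arterial input function
extraction from an aorta ROI -> voxel-wise Patlak fitting inside each
kidney ROI -> per-ROI median summaries in reported units
(Ktrans: mL/100 mL/min, vp: mL/100 mL).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .fitting import (
    FitWindow,
    default_window,
    detect_bolus_arrival,
    fit_patlak,
)
from .kinetic import (
    REPORTED_SCALE,
    ArterialInputFunction,
    TimeGrid,
    TissueCurve,
    cumulative_integral,
)

__all__ = [
    "DynamicSeries",
    "ROIMask",
    "BaselineSpec",
    "ParameterMap",
    "FLAG_KTRANS_CLIPPED",
    "FLAG_VP_CLIPPED",
    "FLAG_FIT_FAILED",
    "compute_enhancement",
    "motion_correct",
    "extract_aif",
    "map_roi",
    "summarize_roi",
    "analyze_animal",
]

ROI_LABELS = ("transplant", "left_native", "right_native", "aorta")

FLAG_KTRANS_CLIPPED = 1
FLAG_VP_CLIPPED = 2
FLAG_FIT_FAILED = 4


@dataclass(frozen=True)
class DynamicSeries:
    """4D dynamic signal volume (x, y, z, frame) on a uniform time grid."""

    voxels: np.ndarray
    grid: TimeGrid
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 4:
            raise ValueError(f"voxels must be 4-D, got shape {vox.shape}")
        if vox.shape[3] != self.grid.n_frames:
            raise ValueError(
                f"frame count {vox.shape[3]} does not match grid "
                f"({self.grid.n_frames} frames)"
            )
        if not np.all(np.isfinite(vox)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "voxels", vox)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass(frozen=True)
class ROIMask:
    """3D boolean mask aligned to a series' spatial grid."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {mask.shape}")
        if not mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class BaselineSpec:
    """Number of pre-bolus frames averaged into the baseline signal S0."""

    n_baseline_frames: int = 3

    def __post_init__(self) -> None:
        if self.n_baseline_frames < 1:
            raise ValueError("n_baseline_frames must be >= 1")


@dataclass(frozen=True)
class ParameterMap:
    """Per-voxel Patlak parameters over one ROI, in reported units.

    ``flags`` is a bitmask per voxel: 1 = ktrans clipped at zero,
    2 = vp clipped at zero, 4 = fit failed.  Values outside the ROI are
    NaN.
    """

    roi: ROIMask
    ktrans_map: np.ndarray
    vp_map: np.ndarray
    flags: np.ndarray


def compute_enhancement(series: DynamicSeries, baseline: BaselineSpec) -> DynamicSeries:
    """Voxel-wise absolute signal enhancement S(t) - S0.

    S0 is the mean of the first ``n_baseline_frames`` frames per voxel;
    enhancement is the absolute difference (not normalized by S0).
    """
    if baseline.n_baseline_frames >= series.grid.n_frames:
        raise ValueError(
            f"baseline ({baseline.n_baseline_frames} frames) must be shorter "
            f"than the series ({series.grid.n_frames} frames)"
        )
    s0 = series.voxels[..., : baseline.n_baseline_frames].mean(axis=3)
    return replace(series, voxels=series.voxels - s0[..., None])


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def motion_correct(
    series: DynamicSeries,
    seed: int = 0,
    max_shift: int = 3,
    min_correlation: float = 0.2,
) -> tuple[DynamicSeries, pd.DataFrame]:
    """Translation-only rigid motion correction against the temporal median.

    Each frame's integer-voxel shift is found by exhaustive search within
    +/- ``max_shift`` voxels per axis, maximizing normalized
    cross-correlation with the voxel-wise temporal median volume.  Shifts
    wrap circularly at the volume edge (adequate for small shifts with
    quiet borders).  Degenerate frames (flat, or best correlation below
    ``min_correlation``) are left unshifted and flagged.  Fully
    deterministic; ``seed`` is accepted for interface uniformity only.

    Returns the corrected series and a per-frame report with the applied
    correction (the negative of any underlying motion), the achieved
    correlation, and a flag column.
    """
    del seed  # grid search is deterministic
    vox = series.voxels
    if vox.shape[3] < 2:
        raise ValueError("motion correction needs >= 2 frames")
    reference = np.median(vox, axis=3)
    ref_flat = reference - reference.mean()
    ref_norm = np.sqrt((ref_flat**2).sum())
    corrected = vox.copy()
    records = []
    offsets = list(
        itertools.product(range(-max_shift, max_shift + 1), repeat=3)
    )
    for f in range(vox.shape[3]):
        frame = vox[..., f]
        flag = ""
        best_shift = (0, 0, 0)
        best_ncc = 1.0
        if frame.std() == 0 or ref_norm == 0:
            flag = "flat"
            best_ncc = 0.0
        else:
            best_ncc = -np.inf
            for shift in offsets:
                cand = np.roll(frame, shift, axis=(0, 1, 2))
                score = _ncc(cand, reference)
                if score > best_ncc:
                    best_ncc = score
                    best_shift = shift
            if best_ncc < min_correlation:
                flag = "low_correlation"
                best_shift = (0, 0, 0)
        if best_shift != (0, 0, 0):
            corrected[..., f] = np.roll(frame, best_shift, axis=(0, 1, 2))
        records.append(
            {
                "frame": f,
                "dx": best_shift[0],
                "dy": best_shift[1],
                "dz": best_shift[2],
                "ncc": best_ncc,
                "flag": flag,
            }
        )
    return replace(series, voxels=corrected), pd.DataFrame(records)


def extract_aif(
    enhancement: DynamicSeries,
    aorta: ROIMask,
    baseline: BaselineSpec,
    stat: str = "median",
) -> ArterialInputFunction:
    """Arterial input function from the aorta ROI of an enhancement series.

    The per-frame aggregate (median by default, mean optional) over the
    aorta voxels is taken; frames before the detected bolus arrival are
    set to zero.  If no arrival is detected (e.g. a flat series) the
    aggregate is returned unmodified — a zero AIF is then rejected
    downstream by the Patlak fit.
    """
    if aorta.mask.shape != enhancement.spatial_shape:
        raise ValueError("aorta mask shape does not match series")
    curves = enhancement.voxels[aorta.mask]  # (n_voxels, n_frames)
    if stat == "median":
        cp = np.median(curves, axis=0)
    elif stat == "mean":
        cp = curves.mean(axis=0)
    else:
        raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")
    arrival = detect_bolus_arrival(cp, n_baseline=baseline.n_baseline_frames)
    if arrival is not None:
        cp = cp.copy()
        cp[:arrival] = 0.0
    return ArterialInputFunction(enhancement.grid, cp)


def map_roi(
    enhancement: DynamicSeries,
    roi: ROIMask,
    aif: ArterialInputFunction,
    window: FitWindow | None = None,
) -> ParameterMap:
    """Voxel-wise Patlak fit inside one ROI.

    All voxels share the same design matrix (built from the AIF), so the
    OLS solution is computed for every voxel in a single solve; the
    result is identical to calling :func:`renalperf.fitting.fit_patlak`
    per voxel and independent of voxel iteration order.  Outputs are in
    reported units (x100).
    """
    if roi.mask.shape != enhancement.spatial_shape:
        raise ValueError("ROI mask shape does not match series")
    if window is None:
        window = default_window(aif)
    sl = window.slice()
    cp = aif.cp[sl]
    if not np.any(cp != 0):
        raise ValueError(
            f"AIF is identically zero inside the fit window for ROI {roi.label!r}"
        )
    design = np.column_stack([cumulative_integral(aif)[sl], cp])
    curves = enhancement.voxels[roi.mask][:, sl]  # (n_voxels, n_window)
    beta, _, _, _ = np.linalg.lstsq(design, curves.T, rcond=None)
    ktrans = beta[0]
    vp = beta[1]
    flags = np.zeros(ktrans.shape, dtype=np.uint8)
    bad = ~(np.isfinite(ktrans) & np.isfinite(vp))
    flags[bad] |= FLAG_FIT_FAILED
    ktrans = np.where(bad, 0.0, ktrans)
    vp = np.where(bad, 0.0, vp)
    flags[ktrans < 0] |= FLAG_KTRANS_CLIPPED
    flags[vp < 0] |= FLAG_VP_CLIPPED
    ktrans = np.clip(ktrans, 0.0, None)
    vp = np.clip(vp, 0.0, None)

    shape = enhancement.spatial_shape
    ktrans_map = np.full(shape, np.nan)
    vp_map = np.full(shape, np.nan)
    flag_map = np.zeros(shape, dtype=np.uint8)
    ktrans_map[roi.mask] = ktrans * REPORTED_SCALE
    vp_map[roi.mask] = vp * REPORTED_SCALE
    flag_map[roi.mask] = flags
    return ParameterMap(roi=roi, ktrans_map=ktrans_map, vp_map=vp_map, flags=flag_map)


def summarize_roi(pmap: ParameterMap) -> dict:
    """Per-ROI median Ktrans and vp over unflagged voxels, reported units."""
    mask = pmap.roi.mask
    ok = mask & (pmap.flags == 0)
    if not ok.any():
        raise ValueError(
            f"all {int(mask.sum())} voxels of ROI {pmap.roi.label!r} are flagged"
        )
    return {
        "roi_label": pmap.roi.label,
        "n_voxels": int(mask.sum()),
        "n_flagged": int(mask.sum() - ok.sum()),
        "median_ktrans": float(np.median(pmap.ktrans_map[ok])),
        "median_vp": float(np.median(pmap.vp_map[ok])),
    }


def analyze_animal(
    series: DynamicSeries,
    masks: dict[str, ROIMask],
    baseline: BaselineSpec = BaselineSpec(),
    motion_correction: bool = True,
    curve_first: bool = False,
    window: FitWindow | None = None,
) -> tuple[pd.DataFrame, dict[str, ParameterMap], pd.DataFrame | None]:
    """Full single-animal pipeline: enhancement -> AIF -> maps -> summaries.

    ``masks`` must contain an ``"aorta"`` entry; kidney ROIs are any of
    ``transplant``, ``left_native``, ``right_native`` present.  With
    ``curve_first=True`` the Patlak fit is run on the ROI-median curve
    instead of per voxel (the per-voxel map is still produced for
    output).  Returns (summary rows, per-ROI parameter maps, motion
    report or None).
    """
    if "aorta" not in masks:
        raise KeyError("masks must include an 'aorta' ROI")
    motion_report = None
    if motion_correction:
        series, motion_report = motion_correct(series)
    enh = compute_enhancement(series, baseline)
    aif = extract_aif(enh, masks["aorta"], baseline)
    if window is None:
        window = default_window(aif, n_baseline=baseline.n_baseline_frames)
    rows = []
    maps: dict[str, ParameterMap] = {}
    for label in ("transplant", "left_native", "right_native"):
        if label not in masks:
            continue
        pmap = map_roi(enh, masks[label], aif, window)
        maps[label] = pmap
        if curve_first:
            median_curve = TissueCurve(
                enh.grid, np.median(enh.voxels[masks[label].mask], axis=0)
            )
            fit = fit_patlak(median_curve, aif, window)
            rows.append(
                {
                    "roi_label": label,
                    "n_voxels": masks[label].n_voxels,
                    "n_flagged": int(
                        (pmap.flags[masks[label].mask] != 0).sum()
                    ),
                    "median_ktrans": fit.params.ktrans * REPORTED_SCALE,
                    "median_vp": fit.params.vp * REPORTED_SCALE,
                }
            )
        else:
            rows.append(summarize_roi(pmap))
    return pd.DataFrame(rows), maps, motion_report
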