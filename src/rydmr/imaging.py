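"""Spatially resolved MFE/RYDMR analysis of widefield image stacks.

A stack is a sequence of frames indexed by field condition (B0, B1, RF
state, repeat).  Region-of-interest sweeps average the fluorescence over
a mask per condition and normalize to the zero-field RF-off condition;
effect maps tile the image into bins, run the field-sweep fit per bin and
write the fitted MFE and RYDMR amplitudes into per-pixel maps, masked
where the signal is below an intensity threshold.  An edge map derived
from the fluorescence image supports the overlay rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from matplotlib import colormaps
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.morphology import skeletonize

from .errors import DataError, FitError, InvalidParameterError
from .fitcore import FieldSweep, fit_field_sweep

__all__ = ["ImageStack", "EffectMaps", "load_stack", "save_stack",
           "roi_sweep", "effect_maps", "edge_map", "render_overlay",
           "detrend_bleach"]

_META_COLUMNS = ["frame", "b0_mT", "b1_mT", "rf_on", "repeat", "t_s"]


@dataclass
class ImageStack:
    """Frames plus per-frame field-condition metadata."""

    frames: np.ndarray             # (n, h, w), non-negative intensities
    meta: pd.DataFrame             # columns: frame, b0_mT, b1_mT, rf_on, repeat, t_s
    pixel_size_um: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise DataError("frames must be a (n, h, w) array")
        if len(self.meta) != self.frames.shape[0]:
            raise DataError(
                f"{self.frames.shape[0]} frames but {len(self.meta)} "
                "metadata rows")
        missing = set(_META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise DataError(f"metadata missing columns: {sorted(missing)}")
        if np.any(self.frames < 0):
            raise DataError("negative intensities in stack")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class EffectMaps:
    """Per-pixel MFE and RYDMR maps (NaN where masked) with diagnostics."""

    mfe_map: np.ndarray
    rydmr_map: np.ndarray
    edge_map: np.ndarray           # boolean
    validity_mask: np.ndarray      # boolean, True where maps carry values
    bin_size: int
    n_failed_fits: int = 0

    def __post_init__(self):
        shapes = {self.mfe_map.shape, self.rydmr_map.shape,
                  self.edge_map.shape, self.validity_mask.shape}
        if len(shapes) != 1:
            raise DataError("all maps must share one shape")


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def load_stack(image_path, metadata_path,
               pixel_size_um: float | None = None) -> ImageStack:
    """Read a multi-page TIFF and its CSV sidecar; fails loudly on mismatch."""
    frames = tifffile.imread(image_path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = pd.read_csv(metadata_path)
    return ImageStack(frames=frames.astype(float), meta=meta,
                      pixel_size_um=pixel_size_um)


def save_stack(stack: ImageStack, image_path, metadata_path) -> None:
    """Write frames as 32-bit float multi-page TIFF plus the CSV sidecar."""
    tifffile.imwrite(image_path, stack.frames.astype(np.float32))
    stack.meta.to_csv(metadata_path, index=False)


# --------------------------------------------------------------------------
# ROI sweeps
# --------------------------------------------------------------------------

def _condition_table(stack: ImageStack, mask: np.ndarray) -> pd.DataFrame:
    vals = stack.frames[:, mask].mean(axis=1)
    df = stack.meta.copy()
    df["signal"] = vals
    grouped = (df.groupby(["b0_mT", "b1_mT", "rf_on"], as_index=False)
                 .agg(signal=("signal", "mean"),
                      spread=("signal", "std"),
                      n=("signal", "size")))
    return grouped


def roi_sweep(stack: ImageStack, roi_mask: np.ndarray,
              rf_on: bool | None = None) -> FieldSweep:
    """Mean-intensity sweep over a mask, repeat-averaged and normalized.

    Fluorescence is normalized to the B0 = 0, RF-off condition; the field
    ordering comes from the metadata, not the frame order.  ``rf_on``
    selects the RF branch (default: RF-on if the stack contains one).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != stack.shape:
        raise DataError("ROI mask shape differs from frame shape")
    if not roi_mask.any():
        raise DataError("ROI mask is empty")
    table = _condition_table(stack, roi_mask)
    off = table[~table.rf_on]
    if off.empty or (off.b0_mT.min() > 0):
        raise DataError("stack lacks the B0 = 0, RF-off reference condition")
    ref = off.loc[off.b0_mT.idxmin(), "signal"]
    if ref <= 0:
        raise DataError("non-positive reference intensity")
    if rf_on is None:
        rf_on = bool(table.rf_on.any())
    branch = table[table.rf_on == rf_on].sort_values("b0_mT")
    if branch.empty:
        raise DataError(f"no frames with rf_on={rf_on}")
    b1 = float(branch.b1_mT.iloc[0]) if rf_on else 0.0
    n_rep = branch["n"].to_numpy()
    spread = branch["spread"].to_numpy()
    # repeat-spread errors are only trustworthy with >= 3 repeats
    f_err = None
    if np.all(n_rep >= 3) and np.all(np.isfinite(spread)) \
            and np.all(spread > 0):
        f_err = spread / np.sqrt(n_rep) / ref
    return FieldSweep(b0=branch.b0_mT.to_numpy(),
                      f_rel=np.clip(branch.signal.to_numpy() / ref,
                                    1e-9, None),
                      f_err=f_err, b1=b1, rf_on=rf_on)


# --------------------------------------------------------------------------
# photobleach detrending
# --------------------------------------------------------------------------

def detrend_bleach(stack: ImageStack) -> ImageStack:
    """Remove a global exponential intensity drift.

    Uses the interleaved reference frames (B0 = 0, RF off) to fit a
    log-linear decay of total intensity versus frame index, then divides
    each frame by the fitted relative scale (1 at the first frame).
    """
    refs = stack.meta[(stack.meta.b0_mT == 0) & (~stack.meta.rf_on)]
    if len(refs) < 2:
        raise DataError("need >= 2 reference frames (B0=0, RF off) to detrend")
    idx = refs.index.to_numpy()
    means = stack.frames[idx].mean(axis=(1, 2))
    slope, intercept = np.polyfit(idx.astype(float), np.log(means), 1)
    scale = np.exp(slope * np.arange(stack.frames.shape[0]))
    corrected = stack.frames / scale[:, None, None]
    return replace(stack, frames=corrected)


# --------------------------------------------------------------------------
# effect maps
# --------------------------------------------------------------------------

def _intensity_threshold(reference: np.ndarray, spec) -> float:
    """Resolve the threshold spec against a reference image.

    None -> 10th percentile of the above-background intensities, with the
    background level estimated as the median of the darkest 20% of pixels;
    a float in (0, 1) -> that fraction of the image maximum; otherwise an
    absolute intensity.
    """
    flat = np.sort(reference.ravel())
    if spec is None:
        dark = flat[: max(flat.size // 5, 1)]
        background = float(np.median(dark))
        noise = 1.4826 * float(np.median(np.abs(dark - background))) + 1e-12
        above = flat[flat > background + 5 * noise]
        if above.size == 0:
            return float(flat[-1])
        return float(np.percentile(above, 10))
    spec = float(spec)
    if 0 < spec < 1:
        return spec * float(flat[-1])
    return spec


def effect_maps(stack: ImageStack, bin_size: int = 4,
                intensity_threshold=None, detrend: bool = False,
                min_points: int = 8) -> EffectMaps:
    """Binned per-pixel MFE and RYDMR maps from a two-branch stack.

    Each bin above the intensity threshold gets an RF-off sweep fit (MFE)
    and an RF-on sweep fit (RYDMR amplitude); bins below threshold or with
    failed fits are masked (NaN) and failures counted.
    """
    if bin_size < 1:
        raise InvalidParameterError("bin_size must be >= 1")
    if not stack.meta.rf_on.any() or stack.meta.rf_on.all():
        raise DataError("stack must contain both RF-on and RF-off sweeps")
    n_off = stack.meta[~stack.meta.rf_on].b0_mT.nunique()
    n_on = stack.meta[stack.meta.rf_on].b0_mT.nunique()
    if min(n_off, n_on) < min_points:
        raise DataError(
            f"fewer than {min_points} field points per sweep branch")
    if detrend:
        stack = detrend_bleach(stack)

    h, w = stack.shape
    reference = stack.frames.mean(axis=0)
    thresh = _intensity_threshold(reference, intensity_threshold)

    # bin the whole stack once; bin means equal ROI means over square bins
    hb, wb = h // bin_size, w // bin_size
    binned = stack.frames[:, :hb * bin_size, :wb * bin_size].reshape(
        stack.frames.shape[0], hb, bin_size, wb, bin_size).mean(axis=(2, 4))
    ref_binned = binned.mean(axis=0)

    # per-condition frame groups, ordering from metadata
    meta = stack.meta
    groups: dict[bool, list[tuple[float, np.ndarray]]] = {False: [], True: []}
    for (b0, rf), sub in meta.groupby(["b0_mT", "rf_on"]):
        groups[bool(rf)].append((float(b0), sub.index.to_numpy()))
    for rf in (False, True):
        groups[rf].sort(key=lambda pair: pair[0])
    if not groups[False] or groups[False][0][0] > 0:
        raise DataError("stack lacks the B0 = 0, RF-off reference condition")
    b1_on = float(meta.loc[meta.rf_on, "b1_mT"].iloc[0])

    def bin_sweep(iy, ix, rf: bool, ref_signal: float) -> FieldSweep:
        b0s, sig, err = [], [], []
        for b0, idx in groups[rf]:
            vals = binned[idx, iy, ix]
            b0s.append(b0)
            sig.append(vals.mean())
            err.append(vals.std(ddof=1) / np.sqrt(vals.size)
                       if vals.size >= 3 else np.nan)
        err = np.asarray(err)
        f_err = err / ref_signal if np.all(np.isfinite(err)) \
            and np.all(err > 0) else None
        return FieldSweep(b0=np.asarray(b0s),
                          f_rel=np.clip(np.asarray(sig) / ref_signal,
                                        1e-9, None),
                          f_err=f_err, b1=b1_on if rf else 0.0, rf_on=rf)

    mfe_map = np.full((h, w), np.nan)
    rydmr_map = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    n_failed = 0
    for iy in range(hb):
        for ix in range(wb):
            if ref_binned[iy, ix] < thresh:
                continue
            sl = (slice(iy * bin_size, (iy + 1) * bin_size),
                  slice(ix * bin_size, (ix + 1) * bin_size))
            ref_signal = binned[groups[False][0][1], iy, ix].mean()
            if ref_signal <= 0:
                n_failed += 1
                continue
            try:
                fit_off = fit_field_sweep(bin_sweep(iy, ix, False,
                                                    ref_signal))
                fit_on = fit_field_sweep(bin_sweep(iy, ix, True, ref_signal))
            except (FitError, DataError):
                n_failed += 1
                continue
            mfe_map[sl] = fit_off.mfe
            rydmr_map[sl] = fit_on.rydmr_amp
            valid[sl] = True

    edges = edge_map(reference)
    return EffectMaps(mfe_map=mfe_map, rydmr_map=rydmr_map, edge_map=edges,
                      validity_mask=valid, bin_size=bin_size,
                      n_failed_fits=n_failed)


# --------------------------------------------------------------------------
# edges and overlays
# --------------------------------------------------------------------------

def edge_map(reference_image: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Thinned gradient-magnitude edges of a fluorescence image.

    Gaussian smoothing, Sobel gradient magnitude, Otsu threshold, then
    morphological thinning; deterministic for fixed parameters.
    """
    img = np.asarray(reference_image, dtype=float)
    if img.size == 0:
        raise DataError("empty image")
    if np.ptp(img) == 0:
        return np.zeros_like(img, dtype=bool)
    grad = sobel(gaussian(img, sigma=sigma, preserve_range=True))
    if np.ptp(grad) == 0:
        return np.zeros_like(img, dtype=bool)
    strong = grad > threshold_otsu(grad)
    return skeletonize(strong)


def render_overlay(maps: EffectMaps, out_path, which: str = "rydmr",
                   cmap: str = "viridis", value_range=None) -> dict:
    """Write a PNG of one effect map over the edge map, plus a JSON sidecar.

    Masked regions are transparent, edges are drawn white, and the sidecar
    records the rendered value range.  Output bytes are deterministic for
    fixed inputs.
    """
    if which not in ("rydmr", "mfe"):
        raise InvalidParameterError("which must be 'rydmr' or 'mfe'")
    values = maps.rydmr_map if which == "rydmr" else maps.mfe_map
    valid = maps.validity_mask & np.isfinite(values)
    if value_range is None:
        if valid.any():
            vmin, vmax = (float(np.min(values[valid])),
                          float(np.max(values[valid])))
        else:
            vmin, vmax = 0.0, 1.0
    else:
        vmin, vmax = map(float, value_range)
    span = (vmax - vmin) or 1.0

    rgba = np.zeros(values.shape + (4,), dtype=np.uint8)
    if valid.any():
        lut = colormaps[cmap]
        norm = np.clip((values[valid] - vmin) / span, 0, 1)
        rgba[valid] = (np.asarray(lut(norm)) * 255).astype(np.uint8)
    rgba[maps.edge_map] = (255, 255, 255, 255)

    out_path = str(out_path)
    iio.imwrite(out_path, rgba, extension=".png")
    sidecar = {
        "schema_version": 1,
        "which": which,
        "cmap": cmap,
        "value_min": vmin,
        "value_max": vmax,
        "bin_size": maps.bin_size,
        "n_failed_fits": maps.n_failed_fits,
    }
    with open(out_path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar
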