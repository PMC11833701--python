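"""Per-nucleus quantification of 3D germline fluorescence stacks.

The pipeline consumes a multi-channel 3D stack together with an integer
nucleus label volume (segmentation is upstream and out of scope) and
produces per-nucleus records: background-corrected total intensities in
the nucleus and on the chromosome-axis mask, the axis/nucleus intensity
ratio, morphological filters, and a normalized position along the germline.

Conventions
-----------
* Arrays are (z, y, x); ``voxel_size`` is (z, y, x) in micrometres.
* Background is the mean intensity in an annulus 10-50 pixels from the
  segmented objects, with distances measured in-plane (per z slice) in
  pixel units, since stacks are strongly anisotropic in z.
* The axis mask is the set of nucleus voxels whose axis-channel intensity
  strictly exceeds the mean intensity within that nucleus (mean threshold).
* Totals are background-corrected by per-voxel subtraction before summing
  and floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import filters, measure

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError

__all__ = [
    "LabeledVolume",
    "NucleusRecord",
    "ProfileResult",
    "FocusCall",
    "background_annulus",
    "segment_axis",
    "nucleus_metrics",
    "filter_nuclei",
    "straighten_positions",
    "profile_bins",
    "normalize_to_slide_wt",
    "detect_foci",
    "focus_intensity_cv",
    "hexanediol_contrast",
]

ANNULUS_RMIN = 10.0
ANNULUS_RMAX = 50.0
VOLUME_BOUNDS = (10.0, 60.0)  # um^3, exclusive
MIN_SPHERICITY = 0.4  # exclusive
RATIO_BOUNDS = (0.3, 0.8)  # inclusive
PROFILE_BINS = 11
RAD51_DIAMETER_BOUNDS = (1.0, 6.0)  # um, equivalent-sphere diameter


@dataclass
class LabeledVolume:
    """Intensity channels plus an integer nucleus label volume.

    ``channels`` maps channel name to a 3D array; ``labels`` is an integer
    array of the same shape with 0 = background; ``voxel_size`` is the
    (z, y, x) voxel edge length in micrometres.
    """

    channels: dict[str, np.ndarray]
    labels: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise InvalidInputError("at least one intensity channel is required")
        shape = self.labels.shape
        if self.labels.ndim != 3:
            raise InvalidInputError("labels must be a 3D array")
        for name, ch in self.channels.items():
            if ch.shape != shape:
                raise InvalidInputError(
                    f"channel {name!r} shape {ch.shape} != labels shape {shape}"
                )
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise InvalidInputError("voxel_size must be three positive numbers")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class NucleusRecord:
    """Per-nucleus 3D intensity and morphology metrics."""

    nucleus_id: int
    centroid: tuple[float, float, float]  # (z, y, x) in um
    volume: float  # um^3
    sphericity: float
    nucleus_totals: dict[str, float]  # background-corrected, per channel
    axis_totals: dict[str, float]
    axis_ratio: float  # axis/nucleus total of the ratio channel
    germline_position: float = np.nan  # normalized [0, 1]
    in_zone: bool = True
    passed_filters: bool = True
    slide: str | None = None
    genotype: str | None = None
    gonad: str | None = None


@dataclass(frozen=True)
class ProfileResult:
    """Binned profile of a per-nucleus value along the germline axis."""

    bin_edges: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: np.ndarray


@dataclass
class FocusCall:
    """A detected focus with sub-voxel 3D Gaussian-fit parameters."""

    nucleus_id: int
    centroid: tuple[float, float, float]  # (z, y, x) voxel coordinates
    amplitude: float
    sigmas: tuple[float, float, float]  # voxel units
    integrated_intensity: float
    fitted: bool = True


def background_annulus(
    channel: np.ndarray,
    labels: np.ndarray,
    rmin: float = ANNULUS_RMIN,
    rmax: float = ANNULUS_RMAX,
) -> float:
    """Mean intensity in an annulus around the segmented objects.

    The annulus holds the voxels whose in-plane (2D, per z slice) distance
    to the nearest labeled voxel lies in ``(rmin, rmax]`` pixels.  All
    labeled objects, including ones later filtered out, shape the annulus.
    """
    if labels.shape != channel.shape:
        raise InvalidInputError("channel and labels must share a shape")
    if not np.any(labels > 0):
        raise InvalidInputError("label volume is empty")
    if rmin < 0 or rmax <= rmin:
        raise InvalidParameterError("need 0 <= rmin < rmax")
    total = 0.0
    count = 0
    for z in range(channel.shape[0]):
        obj = labels[z] > 0
        if not obj.any():
            continue
        dist = ndimage.distance_transform_edt(~obj)
        sel = (dist > rmin) & (dist <= rmax)
        if sel.any():
            total += float(channel[z][sel].sum())
            count += int(sel.sum())
    if count == 0:
        raise InvalidInputError("annulus is empty; no voxels in the distance band")
    return total / count


def segment_axis(axis_channel: np.ndarray, nucleus_mask: np.ndarray) -> np.ndarray:
    """Mean-threshold segmentation of the axis signal within one nucleus.

    Returns the boolean mask of nucleus voxels whose intensity strictly
    exceeds the mean intensity inside the nucleus; a constant-intensity
    nucleus therefore yields an empty axis mask.
    """
    if not nucleus_mask.any():
        raise InvalidInputError("nucleus mask is empty")
    mean = axis_channel[nucleus_mask].mean()
    return nucleus_mask & (axis_channel > mean)


def _sphericity(mask: np.ndarray, voxel_size: tuple[float, float, float]) -> float:
    """Mesh-surface sphericity pi^(1/3) (6V)^(2/3) / A of a binary mask."""
    volume = float(mask.sum()) * float(np.prod(voxel_size))
    padded = np.pad(mask, 1).astype(float)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=voxel_size)
        area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        return np.nan
    if area <= 0:
        return np.nan
    return float(np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area)


def nucleus_metrics(
    volume: LabeledVolume,
    backgrounds: Mapping[str, float],
    axis_channel: str,
    ratio_channel: str | None = None,
) -> list[NucleusRecord]:
    """Compute per-nucleus intensity and morphology records.

    ``axis_channel`` names the channel used to build the axis mask (the
    chromosome-axis stain); ``ratio_channel`` names the channel whose
    axis/nucleus total-intensity ratio is reported (defaults to the axis
    channel itself).  Background-corrected totals are computed for every
    channel, on the whole nucleus and on the axis mask, by per-voxel
    subtraction of the channel background with the total floored at zero.
    """
    if axis_channel not in volume.channels:
        raise InvalidInputError(f"unknown axis channel {axis_channel!r}")
    ratio_channel = ratio_channel or axis_channel
    if ratio_channel not in volume.channels:
        raise InvalidInputError(f"unknown ratio channel {ratio_channel!r}")
    for name in volume.channels:
        if name not in backgrounds:
            raise InvalidInputError(f"missing background for channel {name!r}")
    labels = volume.labels
    vz = volume.voxel_size
    records: list[NucleusRecord] = []
    objects = ndimage.find_objects(labels)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = labels[sl] == idx
        nvox = int(mask.sum())
        com = ndimage.center_of_mass(mask)
        centroid = tuple(
            float((sl[d].start + com[d]) * vz[d]) for d in range(3)
        )
        vol_um3 = nvox * volume.voxel_volume
        axis_mask = segment_axis(volume.channels[axis_channel][sl], mask)
        nucleus_totals: dict[str, float] = {}
        axis_totals: dict[str, float] = {}
        for name, ch in volume.channels.items():
            sub = ch[sl]
            bg = float(backgrounds[name])
            nucleus_totals[name] = max(float(sub[mask].sum()) - bg * nvox, 0.0)
            axis_totals[name] = max(
                float(sub[axis_mask].sum()) - bg * int(axis_mask.sum()), 0.0
            )
        denom = nucleus_totals[ratio_channel]
        ratio = axis_totals[ratio_channel] / denom if denom > 0 else np.nan
        records.append(
            NucleusRecord(
                nucleus_id=idx,
                centroid=centroid,
                volume=float(vol_um3),
                sphericity=_sphericity(mask, vz),
                nucleus_totals=nucleus_totals,
                axis_totals=axis_totals,
                axis_ratio=float(ratio),
            )
        )
    return records


def filter_nuclei(
    records: Sequence[NucleusRecord],
    volume_bounds: tuple[float, float] = VOLUME_BOUNDS,
    min_sphericity: float = MIN_SPHERICITY,
    ratio_bounds: tuple[float, float] = RATIO_BOUNDS,
) -> list[NucleusRecord]:
    """Keep nuclei passing the morphology and intensity-ratio filters.

    A record passes iff its volume lies strictly inside ``volume_bounds``
    (10-60 um^3, both excluded), its sphericity strictly exceeds
    ``min_sphericity`` and its axis/nucleus intensity ratio lies inside
    ``ratio_bounds`` inclusively (0.3-0.8, both included).  The decision is
    a pure function of each record; ``passed_filters`` is set on every
    record and the passing subset is returned.
    """
    passed = []
    for rec in records:
        ok = (
            volume_bounds[0] < rec.volume < volume_bounds[1]
            and rec.sphericity > min_sphericity
            and ratio_bounds[0] <= rec.axis_ratio <= ratio_bounds[1]
        )
        rec.passed_filters = bool(ok)
        if ok:
            passed.append(rec)
    return passed


def _local_quadratic(
    t: np.ndarray, y: np.ndarray, t_eval: np.ndarray, frac: float = 0.5
) -> np.ndarray:
    """Locally weighted quadratic regression with tricube weights."""
    n = len(t)
    k = max(int(np.ceil(frac * n)), 5)
    k = min(k, n)
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    out = np.empty_like(t_eval, dtype=float)
    for i, t0 in enumerate(t_eval):
        d = np.abs(ts - t0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 1e-12, None)
        x = ts[idx] - t0
        X = np.column_stack([np.ones_like(x), x, x**2])
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], ys[idx] * W, rcond=None)
        out[i] = coef[0]
    return out


def straighten_positions(
    centroids: np.ndarray,
    zone_annotations: tuple[int, int],
    frac: float = 0.5,
    n_grid: int = 2000,
) -> np.ndarray:
    """Normalized germline positions from 3D centroids.

    A locally weighted quadratic regression (tricube weights, span
    ``frac``) is fitted through the centroids ordered along the germline's
    long axis (first principal component); each centroid is projected to
    arc length along the fitted curve.  ``zone_annotations`` gives the
    indices of the nuclei marking the start and end landmarks of the
    annotated zone, which map to 0 and 1.  Positions outside [0, 1] are
    returned as-is (callers flag and usually exclude them).
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidInputError("centroids must be an (n, 3) array")
    n = len(pts)
    if n < 10:
        raise InsufficientDataError(f"need >= 10 nuclei to straighten, got {n}")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    if not np.any(cov):
        raise InvalidInputError("all centroids coincide")
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]  # principal direction
    t = centered @ axis
    if np.ptp(t) == 0:
        raise InvalidInputError("centroids are degenerate along the germline axis")
    # smooth each coordinate against the long-axis parameter on a dense grid
    grid = np.linspace(t.min(), t.max(), n_grid)
    curve = np.column_stack(
        [_local_quadratic(t, pts[:, d], grid, frac) for d in range(3)]
    )
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.interp(t, grid, arc)
    i0, i1 = zone_annotations
    s0, s1 = s[i0], s[i1]
    if s1 == s0:
        raise InvalidInputError("zone annotations span zero arc length")
    # orientation comes from the annotations: start -> 0, end -> 1, even if
    # the principal axis points the other way (s1 < s0)
    return (s - s0) / (s1 - s0)


def profile_bins(
    positions: np.ndarray, values: np.ndarray, nbins: int = PROFILE_BINS
) -> ProfileResult:
    """Equal-width binned mean profile over normalized positions [0, 1].

    Per bin: mean, standard error (sample SD over sqrt(n)) and count.
    Empty bins report NaN mean and n = 0.
    """
    if nbins < 1:
        raise InvalidParameterError(f"nbins must be >= 1, got {nbins}")
    pos = np.asarray(positions, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.shape != val.shape:
        raise InvalidInputError("positions and values must have the same length")
    if pos.size and (np.nanmin(pos) < 0 or np.nanmax(pos) > 1):
        raise InvalidInputError("positions must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, nbins + 1)
    idx = np.clip(np.digitize(pos, edges[1:-1]), 0, nbins - 1)
    mean = np.full(nbins, np.nan)
    se = np.full(nbins, np.nan)
    n = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        v = val[idx == b]
        n[b] = v.size
        if v.size:
            mean[b] = v.mean()
            se[b] = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return ProfileResult(bin_edges=edges, mean=mean, se=se, n=n)


def normalize_to_slide_wt(
    records: Sequence[NucleusRecord],
    channel: str,
    wt_genotype: str = "WT",
) -> np.ndarray:
    """Normalize axis totals to the same-slide wild-type mean.

    Each nucleus's axis total in ``channel`` is divided by the mean axis
    total of wild-type nuclei from the same slide, so the wild-type group
    itself averages exactly 1 per slide.  A slide without any wild-type
    nucleus is an error naming the slide.
    """
    slides: dict[str, list[float]] = {}
    for rec in records:
        if rec.slide is None or rec.genotype is None:
            raise InvalidInputError("records need slide and genotype annotations")
        if rec.genotype == wt_genotype:
            slides.setdefault(rec.slide, []).append(rec.axis_totals[channel])
    out = np.empty(len(records), dtype=float)
    for i, rec in enumerate(records):
        ref = slides.get(rec.slide)
        if not ref:
            raise InvalidInputError(
                f"slide {rec.slide!r} has no {wt_genotype!r} reference nuclei"
            )
        out[i] = rec.axis_totals[channel] / float(np.mean(ref))
    return out


def _gauss3d(coords, amp, z0, y0, x0, sz, sy, sx, off):
    z, y, x = coords
    return (
        amp
        * np.exp(
            -0.5
            * (
                ((z - z0) / sz) ** 2
                + ((y - y0) / sy) ** 2
                + ((x - x0) / sx) ** 2
            )
        )
        + off
    )


def _fit_gaussian_spot(
    sub: np.ndarray, origin: tuple[int, int, int]
) -> tuple[tuple[float, float, float], float, tuple[float, float, float], float, bool]:
    """3D Gaussian fit of one candidate spot cutout.

    Returns (centroid zyx, amplitude, sigmas, integrated intensity, fitted).
    Falls back to the intensity-weighted centroid when the fit fails.
    """
    zz, yy, xx = np.indices(sub.shape)
    flat = sub.ravel().astype(float)
    coords = (zz.ravel(), yy.ravel(), xx.ravel())
    off0 = float(flat.min())
    amp0 = float(flat.max() - off0)
    w = np.clip(flat - off0, 0, None)
    wsum = w.sum()
    if wsum <= 0 or amp0 <= 0:
        com = ndimage.center_of_mass(np.ones_like(sub))
        cen = tuple(float(origin[d] + com[d]) for d in range(3))
        return cen, 0.0, (np.nan,) * 3, float(flat.sum()), False
    com = tuple(float((w * c).sum() / wsum) for c in coords)
    sig0 = [
        max(float(np.sqrt((w * (c - com[d]) ** 2).sum() / wsum)), 0.5)
        for d, c in enumerate(coords)
    ]
    p0 = [amp0, *com, *sig0, off0]
    shape = sub.shape
    bounds = (
        [0.0, -1.0, -1.0, -1.0, 0.1, 0.1, 0.1, -np.inf],
        [np.inf, shape[0], shape[1], shape[2], shape[0], shape[1], shape[2], np.inf],
    )
    try:
        popt, _ = optimize.curve_fit(
            _gauss3d, coords, flat, p0=p0, bounds=bounds, maxfev=2000
        )
        amp, z0, y0, x0, sz, sy, sx, off = popt
        cen = (origin[0] + z0, origin[1] + y0, origin[2] + x0)
        integ = float(amp * (2.0 * np.pi) ** 1.5 * sz * sy * sx)
        return tuple(float(c) for c in cen), float(amp), (
            float(sz),
            float(sy),
            float(sx),
        ), integ, True
    except (RuntimeError, ValueError):
        cen = tuple(float(origin[d] + com[d]) for d in range(3))
        return cen, amp0, tuple(float(s) for s in sig0), float(w.sum()), False


def detect_foci(
    channel: np.ndarray,
    labels: np.ndarray,
    threshold_method: Literal["otsu", "yen"] = "otsu",
    min_size: int = 4,
    diameter_bounds: tuple[float, float] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    pad: int = 3,
    presmooth_sigma: float = 1.0,
    min_snr: float = 5.0,
) -> list[FocusCall]:
    """Detect and fit fluorescent foci inside segmented nuclei.

    Per nucleus the channel is thresholded inside the mask (Otsu for
    CO-marker foci, Yen for recombinase foci; 256-bin histograms), the
    above-threshold voxels are split into connected components, and each
    component of at least ``min_size`` voxels is fitted by a 3D Gaussian.
    A failed fit keeps the candidate with its intensity-weighted centroid,
    flagged unfitted.

    Candidate extraction (threshold + connected components) runs on a
    lightly Gaussian-smoothed copy of the channel (``presmooth_sigma``
    voxels, 0 disables), which keeps the histogram-based thresholds stable
    against shot/read noise; the Gaussian fit always uses the raw data.
    Candidates whose amplitude falls below ``min_snr`` robust standard
    deviations (median absolute deviation based) of the nucleus signal are
    discarded — histogram thresholds always split something, even a
    spot-free nucleus of pure noise.

    ``diameter_bounds`` (with ``voxel_size``) restricts scoring to nuclei
    whose equivalent-sphere diameter lies inside the bounds, as used for
    recombinase-focus counting (1-6 um).
    """
    if labels.shape != channel.shape:
        raise InvalidInputError("channel and labels must share a shape")
    if not np.any(labels > 0):
        raise InvalidInputError("label volume is empty")
    if threshold_method not in ("otsu", "yen"):
        raise InvalidParameterError(f"unknown threshold method {threshold_method!r}")
    if diameter_bounds is not None and voxel_size is None:
        raise InvalidParameterError("diameter_bounds requires voxel_size")
    thresh_fn = filters.threshold_otsu if threshold_method == "otsu" else filters.threshold_yen
    smooth = (
        ndimage.gaussian_filter(channel.astype(float), presmooth_sigma)
        if presmooth_sigma > 0
        else channel
    )
    calls: list[FocusCall] = []
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == idx
        if diameter_bounds is not None:
            vol = float(mask.sum()) * float(np.prod(voxel_size))
            diam = (6.0 * vol / np.pi) ** (1.0 / 3.0)
            if not (diameter_bounds[0] <= diam <= diameter_bounds[1]):
                continue
        vals = smooth[sl][mask]
        if vals.size == 0 or np.ptp(vals) == 0:
            continue
        raw_vals = channel[sl][mask]
        raw_median = float(np.median(raw_vals))
        noise_sd = 1.4826 * float(np.median(np.abs(raw_vals - raw_median)))
        thr = thresh_fn(vals, nbins=256)
        binary = mask & (smooth[sl] > thr)
        if not binary.any():
            continue
        lab, nspots = ndimage.label(binary)
        for spot in range(1, nspots + 1):
            spot_mask = lab == spot
            if int(spot_mask.sum()) < min_size:
                continue
            zs, ys, xs = np.nonzero(spot_mask)
            lo = [max(int(c.min()) - pad, 0) for c in (zs, ys, xs)]
            hi = [
                min(int(c.max()) + pad + 1, channel[sl].shape[d])
                for d, c in enumerate((zs, ys, xs))
            ]
            # significance on the observed peak, not the fitted amplitude:
            # noise spikes fit as arbitrarily tall, needle-thin Gaussians
            peak = float(channel[sl][spot_mask].max()) - raw_median
            if peak < min_snr * noise_sd:
                continue
            cut = channel[sl][lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            origin = tuple(sl[d].start + lo[d] for d in range(3))
            cen, amp, sigmas, integ, fitted = _fit_gaussian_spot(cut, origin)
            calls.append(
                FocusCall(
                    nucleus_id=idx,
                    centroid=cen,
                    amplitude=amp,
                    sigmas=sigmas,
                    integrated_intensity=integ,
                    fitted=fitted,
                )
            )
    return calls


def focus_intensity_cv(intensities: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation of focus intensities within one nucleus.

    Sample standard deviation (ddof=1) over the mean; undefined (NaN) for
    fewer than two foci.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        return np.nan
    return float(x.std(ddof=1) / x.mean())


def hexanediol_contrast(records: pd.DataFrame) -> dict[str, float]:
    """Genotype contrast of axis/nucleus ratios via a linear mixed model.

    ``records`` is a long-format frame with columns ``axis_ratio``,
    ``genotype`` (two levels; the reference level is the lexicographically
    first) and ``gonad`` (the random-effect grouping: gonads from
    individual animals).  Returns the genotype fixed-effect estimate, its
    standard error and p-value.  Each genotype must appear in at least two
    gonads, otherwise the random effect is unidentifiable.
    """
    import statsmodels.formula.api as smf

    required = {"axis_ratio", "genotype", "gonad"}
    missing = required - set(records.columns)
    if missing:
        raise InvalidInputError(f"records missing columns: {sorted(missing)}")
    levels = sorted(records["genotype"].unique())
    if len(levels) != 2:
        raise InvalidInputError(f"need exactly two genotypes, got {levels}")
    for g in levels:
        n_gonads = records.loc[records["genotype"] == g, "gonad"].nunique()
        if n_gonads < 2:
            raise InsufficientDataError(
                f"genotype {g!r} has {n_gonads} gonad(s); need >= 2"
            )
    model = smf.mixedlm("axis_ratio ~ genotype", records, groups=records["gonad"])
    fit = model.fit(reml=True)
    term = f"genotype[T.{levels[1]}]"
    return {
        "effect": float(fit.params[term]),
        "se": float(fit.bse[term]),
        "pvalue": float(fit.pvalues[term]),
    }
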