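"""Synthetic data with known ground truth for every pipeline stage.

Every generator in this module returns its data together with a
:class:`SyntheticTruth` describing exactly what was planted (positions,
breakpoints, ploidy states, image parameters), so that downstream modules
can be validated by parameter recovery without any external data.

The generators emulate the study conditions end to end:

* focus placements on chromosomes under an obligate-single-CO regime, a
  homogeneous Poisson regime (no interference) and a stationary
  gamma-renewal regime (tunable interference strength);
* backcross F2 embryos — one paternal Hawaiian chromosome plus one
  maternal Bristol/Hawaiian mosaic chromatid — sequenced at low coverage
  into 5-kb strain-specific window counts and 50-kb depth windows, with
  Mendelian X transmission from the male (sperm carries an X or no X with
  probability one half) and optional nondisjunction;
* 3D germline stacks of spherical nuclei along a curved tube, each with a
  filamentous axis signal carrying a planted fraction of the total
  synaptonemal-complex channel intensity, Gaussian foci, and Poisson shot
  noise plus Gaussian read noise at a requested SNR.

All randomness flows through a single integer seed; identical seed and
parameters give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate

from .comap import DepthTable, WindowCountTable
from .errors import InvalidInputError, InvalidParameterError
from .imagequant import LabeledVolume
from .interference import FocusSet
from .tracing import ChromosomeTrace, resample_trace

__all__ = [
    "SyntheticTruth",
    "CELEGANS_CHROMOSOMES",
    "simulate_focus_placement",
    "simulate_f2_embryo",
    "simulate_germline_stack",
    "simulate_traced_nuclei",
    "simulate_ratio_records",
]

# approximate C. elegans chromosome lengths (bp); chromosome I is listed for
# completeness although mapping studies may exclude it
CELEGANS_CHROMOSOMES: dict[str, int] = {
    "I": 15_072_000,
    "II": 15_279_000,
    "III": 13_784_000,
    "IV": 17_494_000,
    "V": 20_924_000,
    "X": 17_719_000,
}


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    seed: int
    model: str
    params: dict[str, Any]
    truth: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = _to_jsonable(asdict(self))
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _renewal_positions(
    rng: np.random.Generator,
    length: float,
    shape: float,
    mean_gap: float,
    burnin_gaps: int = 30,
) -> np.ndarray:
    """One realization of a stationary gamma-renewal process on [0, length].

    Stationarity is approximated by starting the renewal chain well before
    the observation window (burn-in) and keeping the events that fall
    inside it.
    """
    scale = mean_gap / shape
    start = -burnin_gaps * mean_gap
    pos: list[float] = []
    x = start + rng.gamma(shape, scale)
    while x < length:
        if x >= 0:
            pos.append(float(x))
        x += rng.gamma(shape, scale)
    return np.asarray(pos)


def simulate_focus_placement(
    model: str = "obligate_one",
    n_nuclei: int = 100,
    chromosome_lengths: Sequence[float] = (4.0, 4.2, 4.5, 4.8, 5.2, 5.6),
    mean_count: float = 2.0,
    shape: float = 10.0,
    intensity_mean: float = 100.0,
    intensity_cv: float = 0.4,
    seed: int = 0,
) -> tuple[list[FocusSet], SyntheticTruth]:
    """Plant focus positions on chromosomes under a chosen placement model.

    Models
    ------
    ``obligate_one``
        Exactly one uniformly placed focus per chromosome (the wild-type
        one-CO-per-homolog regime).
    ``poisson``
        Homogeneous Poisson placement with ``mean_count`` expected foci
        per chromosome (no interference).
    ``gamma_renewal``
        Stationary renewal process whose gaps are gamma distributed with
        the given ``shape`` and mean ``length / mean_count`` (interference
        strength grows with the shape).

    Focus intensities are lognormal with the given mean and coefficient of
    variation.  Returns the focus sets and the planted truth (positions
    and intensities per chromosome).
    """
    if model not in ("obligate_one", "poisson", "gamma_renewal"):
        raise InvalidParameterError(f"unknown placement model {model!r}")
    if n_nuclei < 1 or mean_count <= 0 or shape <= 0:
        raise InvalidParameterError("n_nuclei, mean_count and shape must be positive")
    lengths = [float(L) for L in chromosome_lengths]
    if any(L <= 0 for L in lengths):
        raise InvalidInputError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    mu, sig = _lognormal_params(intensity_mean, intensity_cv)
    focus_sets: list[FocusSet] = []
    truth_pos: dict[str, list[float]] = {}
    truth_int: dict[str, list[float]] = {}
    for i in range(n_nuclei):
        for j, L in enumerate(lengths):
            cid = f"n{i}_chr{j}"
            if model == "obligate_one":
                pos = np.array([rng.uniform(0.0, L)])
            elif model == "poisson":
                k = rng.poisson(mean_count)
                pos = np.sort(rng.uniform(0.0, L, size=k))
            else:
                pos = _renewal_positions(rng, L, shape, L / mean_count)
            inten = rng.lognormal(mu, sig, size=len(pos))
            focus_sets.append(FocusSet(cid, L, tuple(pos.tolist())))
            truth_pos[cid] = pos.tolist()
            truth_int[cid] = inten.tolist()
    truth = SyntheticTruth(
        seed=seed,
        model=model,
        params={
            "n_nuclei": n_nuclei,
            "chromosome_lengths": lengths,
            "mean_count": mean_count,
            "shape": shape,
            "intensity_mean": intensity_mean,
            "intensity_cv": intensity_cv,
        },
        truth={"positions": truth_pos, "intensities": truth_int},
    )
    return focus_sets, truth


def _chromatid_breakpoints(
    rng: np.random.Generator,
    length: float,
    co_model: str,
    mean_count: float,
    shape: float,
) -> np.ndarray:
    if co_model == "none":
        return np.empty(0)
    if co_model == "obligate_one":
        return np.array([rng.uniform(0.0, length)])
    if co_model == "poisson":
        k = rng.poisson(mean_count)
        return np.sort(rng.uniform(0.0, length, size=k))
    if co_model == "gamma_renewal":
        return _renewal_positions(rng, length, shape, length / mean_count)
    raise InvalidParameterError(f"unknown co_model {co_model!r}")


def _haplotype_per_window(
    starts: np.ndarray, window: int, breakpoints: np.ndarray, first: int
) -> np.ndarray:
    """Per-window haplotype (0 = Bristol, 1 = Hawaiian) of a mosaic chromatid.

    The haplotype of a window is taken at its midpoint; ``first`` is the
    haplotype left of the first breakpoint.
    """
    mids = starts + window / 2.0
    flips = np.searchsorted(breakpoints, mids)
    return (first + flips) % 2


def simulate_f2_embryo(
    co_model: str = "obligate_one",
    chromosome_lengths: dict[str, int] | None = None,
    coverage: float = 3.0,
    window: int = 5_000,
    depth_window: int = 50_000,
    informative_fraction: float = 0.3,
    read_length: int = 150,
    mean_count: float = 2.0,
    shape: float = 10.0,
    nondisjunction_p: float = 0.0,
    seed: int = 0,
) -> tuple[WindowCountTable, DepthTable, SyntheticTruth]:
    """Simulate one backcross F2 embryo's window count and depth tables.

    Each chromosome carries one maternal chromatid — a Bristol/Hawaiian
    mosaic whose breakpoints are drawn from ``co_model`` and whose leftmost
    haplotype is Bristol or Hawaiian with probability one half — plus one
    paternal Hawaiian copy.  The X is special: the hermaphrodite mother
    always transmits an X, while the Hawaiian male transmits an X or no X
    with probability one half each, so about half of the embryos have a
    haploid X.  With probability ``nondisjunction_p`` a chromosome gains an
    extra paternal copy or loses its paternal copy.

    Per 5-kb window, total reads are Poisson at the coverage scaled by the
    local copy number; a binomial ``informative_fraction`` of them is
    strain-diagnostic and splits between Bristol and Hawaiian according to
    the local fraction of Bristol copies.  Depth windows (50 kb) are
    Poisson draws at the same per-copy rate.
    """
    if chromosome_lengths is None:
        chromosome_lengths = {
            k: v for k, v in CELEGANS_CHROMOSOMES.items() if k != "I"
        }
    if coverage <= 0 or not 0 < informative_fraction <= 1:
        raise InvalidParameterError("coverage and informative_fraction must be valid")
    rng = np.random.default_rng(seed)
    count_frames: list[pd.DataFrame] = []
    depth_frames: list[pd.DataFrame] = []
    truth_chrom: dict[str, Any] = {}
    reads_per_bp = coverage / read_length  # expected reads starting per bp, diploid=2 copies
    for chrom, length in chromosome_lengths.items():
        breakpoints = _chromatid_breakpoints(
            rng, float(length), co_model, mean_count, shape
        )
        first = int(rng.integers(0, 2))
        is_x = str(chrom).removeprefix("chr") == "X"
        # paternal copies: 1 normally; X present with probability 1/2
        paternal = 1
        if is_x:
            paternal = int(rng.integers(0, 2))
        lost_paternal = False
        gained_paternal = False
        if nondisjunction_p > 0 and rng.random() < nondisjunction_p:
            if paternal > 0 and rng.random() < 0.5:
                paternal -= 1
                lost_paternal = True
            else:
                paternal += 1
                gained_paternal = True
        copies = 1 + paternal  # maternal chromatid always present

        n_win = int(np.ceil(length / window))
        starts = np.arange(n_win, dtype=np.int64) * window
        hap = _haplotype_per_window(starts, window, breakpoints, first)
        bristol_copies = (hap == 0).astype(float)  # maternal Bristol segments
        bristol_frac = np.where(copies > 0, bristol_copies / copies, 0.0)
        lam = reads_per_bp * window * copies / 2.0
        total = rng.poisson(lam, size=n_win)
        informative = rng.binomial(total, informative_fraction)
        bristol = rng.binomial(informative, bristol_frac)
        hawaiian = informative - bristol
        count_frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "bristol": bristol,
                    "hawaiian": hawaiian,
                }
            )
        )
        n_dwin = int(np.ceil(length / depth_window))
        dstarts = np.arange(n_dwin, dtype=np.int64) * depth_window
        dlam = reads_per_bp * depth_window * copies / 2.0
        depth = rng.poisson(dlam, size=n_dwin)
        depth_frames.append(
            pd.DataFrame({"chrom": chrom, "start": dstarts, "depth": depth})
        )
        truth_chrom[str(chrom)] = {
            "breakpoints": breakpoints.tolist(),
            "first_haplotype": "bristol" if first == 0 else "hawaiian",
            "copies": copies,
            "paternal_copies": paternal,
            "lost_paternal": lost_paternal,
            "gained_paternal": gained_paternal,
        }
    counts = WindowCountTable(pd.concat(count_frames, ignore_index=True), window)
    depths = DepthTable(pd.concat(depth_frames, ignore_index=True), depth_window)
    truth = SyntheticTruth(
        seed=seed,
        model=f"f2_embryo/{co_model}",
        params={
            "coverage": coverage,
            "window": window,
            "depth_window": depth_window,
            "informative_fraction": informative_fraction,
            "read_length": read_length,
            "mean_count": mean_count,
            "shape": shape,
            "nondisjunction_p": nondisjunction_p,
            "chromosome_lengths": dict(chromosome_lengths),
        },
        truth={"chromosomes": truth_chrom},
    )
    return counts, depths, truth


def _filament_mask(
    rng: np.random.Generator,
    center_um: np.ndarray,
    radius_um: float,
    sphere: np.ndarray,
    lo: np.ndarray,
    voxel_size: tuple[float, float, float],
    n_filaments: int = 3,
    n_control: int = 6,
) -> np.ndarray:
    """Random smooth filaments inside one nucleus, as a local boolean mask.

    ``sphere`` is the nucleus mask in its local bounding box whose corner
    voxel is ``lo``; each filament is a spline through random control
    points, rasterized and dilated by one voxel, clipped to the nucleus.
    """
    from scipy import ndimage

    local = np.zeros_like(sphere, dtype=bool)
    vs = np.asarray(voxel_size)
    for _ in range(n_filaments):
        ctrl = center_um + rng.uniform(-0.65, 0.65, size=(n_control, 3)) * radius_um
        chord = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))]
        )
        if chord[-1] == 0:
            ctrl[-1] += 0.1 * radius_um
            chord = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0), axis=1))]
            )
        spl = interpolate.make_interp_spline(chord, ctrl, k=min(3, n_control - 1))
        dense = spl(np.linspace(0, chord[-1], int(chord[-1] / 0.02) + 2))
        vox = np.round(dense / vs).astype(int) - lo
        vox = vox[((vox >= 0) & (vox < np.asarray(sphere.shape))).all(axis=1)]
        local[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    local = ndimage.binary_dilation(local, iterations=1)
    return local & sphere


def simulate_germline_stack(
    n_nuclei: int = 10,
    nucleus_radius: float = 2.2,
    axis_ratio: float = 0.7,
    foci_per_nucleus: int = 0,
    focus_sigma: tuple[float, float, float] = (0.25, 0.16, 0.16),
    focus_intensity_cv: float = 0.0,
    snr: float = 10.0,
    voxel_size: tuple[float, float, float] = (0.2, 0.1, 0.1),
    background: float = 20.0,
    sc_total: float = 4.0e5,
    focus_amplitude: float = 600.0,
    axis_amplitude: float = 400.0,
    n_filaments: int = 3,
    read_noise: float = 3.0,
    tube_amplitude: float = 1.0,
    min_focus_separation_sigma: float = 6.5,
    seed: int = 0,
    max_attempts: int = 200,
) -> tuple[LabeledVolume, SyntheticTruth]:
    """Simulate a 3-channel germline stack with labelled spherical nuclei.

    Nuclei of radius ``nucleus_radius`` (um) are placed along a gently
    curved tube.  Channels:

    * ``axis``: a random smooth filament inside each nucleus (the
      chromosome-axis stain that defines the axis mask);
    * ``sc``: the synaptonemal-complex channel; a fraction ``axis_ratio``
      of each nucleus's total ``sc_total`` intensity sits on the filament
      voxels, the rest is spread uniformly over the nucleoplasm;
    * ``foci``: ``foci_per_nucleus`` 3D Gaussian spots, amplitudes
      lognormal with CV ``focus_intensity_cv``.  Spot centres keep a
      pairwise Mahalanobis distance of at least
      ``min_focus_separation_sigma`` in units of the per-axis effective
      width (planted sigma plus a 0.2 um detection-smoothing allowance),
      so spots stay individually resolvable in the anisotropic stack.

    Noise: a constant ``background`` is added everywhere and Poisson shot
    noise is applied to every channel.  The axis and SC channels get
    camera-like Gaussian read noise of standard deviation ``read_noise``;
    the focus channel's Gaussian noise is set so that the spot peak sits
    ``snr`` background-noise standard deviations above the background,
    i.e. ``sqrt(max((focus_amplitude/snr)^2 - background, read_noise^2))``.
    ``snr=inf`` disables all noise.

    Returns the labelled volume and the truth (per-nucleus centres,
    planted axis ratio, focus positions and amplitudes).
    """
    if not 0 <= axis_ratio <= 1:
        raise InvalidParameterError("axis_ratio must lie in [0, 1]")
    if n_nuclei < 1 or nucleus_radius <= 0:
        raise InvalidParameterError("need n_nuclei >= 1 and a positive radius")
    rng = np.random.default_rng(seed)
    vz, vy, vx = voxel_size
    r = nucleus_radius
    spacing = 2.4 * r
    margin = 1.5 * r
    extent_x = margin * 2 + spacing * (n_nuclei - 1)
    extent_y = 2 * (r + tube_amplitude) + 2.0
    extent_z = 2 * r + 1.6
    shape = (
        int(np.ceil(extent_z / vz)),
        int(np.ceil(extent_y / vy)),
        int(np.ceil(extent_x / vx)),
    )
    labels = np.zeros(shape, dtype=np.int32)
    axis_ch = np.zeros(shape, dtype=float)
    sc_ch = np.zeros(shape, dtype=float)
    foci_ch = np.zeros(shape, dtype=float)
    zc_um = extent_z / 2.0
    truth_nuclei: list[dict[str, Any]] = []
    coords_um = [np.arange(s) * v for s, v in zip(shape, voxel_size)]
    for i in range(n_nuclei):
        cx = margin + i * spacing
        cy = extent_y / 2.0 + tube_amplitude * np.sin(2 * np.pi * cx / (12 * r))
        center = np.array([zc_um, cy, cx])
        # sphere mask in a local bounding box
        lo = np.maximum(
            ((center - r) / np.asarray(voxel_size)).astype(int) - 1, 0
        )
        hi = np.minimum(
            ((center + r) / np.asarray(voxel_size)).astype(int) + 2, np.asarray(shape)
        )
        zz = coords_um[0][lo[0] : hi[0]][:, None, None]
        yy = coords_um[1][lo[1] : hi[1]][None, :, None]
        xx = coords_um[2][lo[2] : hi[2]][None, None, :]
        dist2 = (
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        )
        sphere = dist2 <= r**2
        sl = tuple(slice(lo[d], hi[d]) for d in range(3))
        if (labels[sl][sphere] != 0).any():
            raise InvalidInputError("overlapping nucleus placement")
        labels[sl][sphere] = i + 1
        nuc_vox_local = np.nonzero(sphere)
        nuc_vox = tuple(nuc_vox_local[d] + lo[d] for d in range(3))
        n_nuc_vox = len(nuc_vox[0])
        # filaments carrying the axis signal
        fil_local = _filament_mask(
            rng, center, r, sphere, lo, voxel_size, n_filaments
        )
        attempts = 0
        while fil_local.sum() < 10 and attempts < 10:
            fil_local = _filament_mask(
                rng, center, r, sphere, lo, voxel_size, n_filaments
            )
            attempts += 1
        n_fil = int(fil_local.sum())
        fil = tuple(c + lo[d] for d, c in enumerate(np.nonzero(fil_local)))
        axis_ch[fil] += axis_amplitude
        sc_ch[fil] += axis_ratio * sc_total / n_fil
        rest = n_nuc_vox - n_fil
        nucleoplasm_value = (1.0 - axis_ratio) * sc_total / rest
        sc_ch[nuc_vox] += nucleoplasm_value
        sc_ch[fil] -= nucleoplasm_value  # nucleoplasm excludes the filament
        # foci
        focus_centers: list[list[float]] = []
        amplitudes: list[float] = []
        if foci_per_nucleus > 0:
            sigma_eff = np.sqrt(np.asarray(focus_sigma) ** 2 + 0.2**2)
            # greedy placement can dead-end; restart the nucleus when it does
            for _restart in range(max_attempts):
                focus_centers = []
                for _spot in range(foci_per_nucleus):
                    for _try in range(100):
                        cand = center + rng.uniform(-0.85, 0.85, size=3) * r
                        if np.sum((cand - center) ** 2) > (0.9 * r) ** 2:
                            continue
                        if all(
                            np.linalg.norm((cand - np.asarray(p)) / sigma_eff)
                            >= min_focus_separation_sigma
                            for p in focus_centers
                        ):
                            focus_centers.append(cand.tolist())
                            break
                    else:
                        break  # dead end: restart this nucleus
                if len(focus_centers) == foci_per_nucleus:
                    break
            else:
                raise InvalidInputError(
                    "could not place foci with the requested separation"
                )
            if focus_intensity_cv > 0:
                mu, sig = _lognormal_params(focus_amplitude, focus_intensity_cv)
                amplitudes = rng.lognormal(mu, sig, size=foci_per_nucleus).tolist()
            else:
                amplitudes = [focus_amplitude] * foci_per_nucleus
            for c, amp in zip(focus_centers, amplitudes):
                c = np.asarray(c)
                flo = np.maximum(
                    ((c - 5 * np.asarray(focus_sigma)) / np.asarray(voxel_size)).astype(int),
                    0,
                )
                fhi = np.minimum(
                    ((c + 5 * np.asarray(focus_sigma)) / np.asarray(voxel_size)).astype(int)
                    + 2,
                    np.asarray(shape),
                )
                fz = coords_um[0][flo[0] : fhi[0]][:, None, None]
                fy = coords_um[1][flo[1] : fhi[1]][None, :, None]
                fx = coords_um[2][flo[2] : fhi[2]][None, None, :]
                g = amp * np.exp(
                    -0.5
                    * (
                        ((fz - c[0]) / focus_sigma[0]) ** 2
                        + ((fy - c[1]) / focus_sigma[1]) ** 2
                        + ((fx - c[2]) / focus_sigma[2]) ** 2
                    )
                )
                foci_ch[
                    flo[0] : fhi[0], flo[1] : fhi[1], flo[2] : fhi[2]
                ] += g
        truth_nuclei.append(
            {
                "nucleus_id": i + 1,
                "center_um": center.tolist(),
                "radius_um": r,
                "axis_ratio": axis_ratio,
                "n_filament_voxels": n_fil,
                "focus_centers_um": focus_centers,
                "focus_amplitudes": amplitudes,
            }
        )
    channels = {"axis": axis_ch, "sc": sc_ch, "foci": foci_ch}
    if np.isfinite(snr):
        foci_sigma = np.sqrt(
            max((focus_amplitude / snr) ** 2 - background, read_noise**2)
        )
        sigmas = {"axis": read_noise, "sc": read_noise, "foci": foci_sigma}
        for name, ch in channels.items():
            noisy = rng.poisson(np.clip(ch + background, 0, None)).astype(float)
            noisy += rng.normal(0.0, sigmas[name], size=ch.shape)
            channels[name] = noisy
    else:
        for name, ch in channels.items():
            channels[name] = ch + background
    volume = LabeledVolume(channels=channels, labels=labels, voxel_size=voxel_size)
    truth = SyntheticTruth(
        seed=seed,
        model="germline_stack",
        params={
            "n_nuclei": n_nuclei,
            "nucleus_radius": nucleus_radius,
            "axis_ratio": axis_ratio,
            "foci_per_nucleus": foci_per_nucleus,
            "focus_sigma": list(focus_sigma),
            "focus_intensity_cv": focus_intensity_cv,
            "snr": snr,
            "voxel_size": list(voxel_size),
            "background": background,
            "sc_total": sc_total,
            "focus_amplitude": focus_amplitude,
            "axis_amplitude": axis_amplitude,
            "n_filaments": n_filaments,
            "read_noise": read_noise,
        },
        truth={"nuclei": truth_nuclei},
    )
    return volume, truth


def simulate_traced_nuclei(
    n_nuclei: int = 3,
    traces_per_nucleus: int = 6,
    trace_length: float = 5.0,
    foci_per_trace: Sequence[int] | int = 1,
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0),
    focus_noise: float = 0.0,
    step: float = 0.05,
    seed: int = 0,
) -> tuple[
    list[ChromosomeTrace], list[tuple[str, str, np.ndarray]], SyntheticTruth
]:
    """Random smooth chromosome traces with foci planted at known arc positions.

    Each trace is a spline through a random-walk set of control points,
    scaled to approximately ``trace_length`` um.  Foci are placed exactly
    on the resampled curve at uniformly drawn arc positions, then shifted
    by ``offset`` and jittered with isotropic Gaussian noise of standard
    deviation ``focus_noise`` — the configuration the channel-offset
    estimator and the focus mapper must invert.
    """
    rng = np.random.default_rng(seed)
    traces: list[ChromosomeTrace] = []
    foci: list[tuple[str, str, np.ndarray]] = []
    truth_foci: list[dict[str, Any]] = []
    if isinstance(foci_per_trace, int):
        foci_counts = None
    else:
        foci_counts = list(foci_per_trace)
    k = 0
    for ni in range(n_nuclei):
        nucleus_id = f"nuc{ni}"
        nucleus_origin = np.array([0.0, 0.0, 30.0 * ni])
        for ti in range(traces_per_nucleus):
            trace_id = f"nuc{ni}_tr{ti}"
            # separate the traces spatially so nearest-trace assignment is
            # unambiguous at zero noise
            origin = nucleus_origin + np.array([0.0, 2.0 * trace_length * ti, 0.0])
            steps = rng.normal(0, 1, size=(6, 3))
            ctrl = origin + np.cumsum(steps, axis=0)
            chord = np.linalg.norm(np.diff(ctrl, axis=0), axis=1).sum()
            ctrl = origin + (ctrl - origin) * (trace_length / chord)
            tr = resample_trace(ctrl, step=step, trace_id=trace_id, nucleus_id=nucleus_id)
            traces.append(tr)
            if foci_counts is None:
                n_foci = foci_per_trace if isinstance(foci_per_trace, int) else 1
            else:
                n_foci = foci_counts[k % len(foci_counts)]
            k += 1
            arcs = np.sort(rng.uniform(0, tr.total_length, size=n_foci))
            for fi, a in enumerate(arcs):
                idx = int(np.argmin(np.abs(tr.arc_positions - a)))
                true_arc = float(tr.arc_positions[idx])
                pos = tr.resampled_points[idx].copy()
                pos = pos + np.asarray(offset) + rng.normal(0, focus_noise, size=3)
                focus_id = f"{trace_id}_f{fi}"
                foci.append((focus_id, nucleus_id, pos))
                truth_foci.append(
                    {
                        "focus_id": focus_id,
                        "trace_id": trace_id,
                        "arc_position": true_arc,
                        "normalized_position": true_arc / tr.total_length,
                    }
                )
    truth = SyntheticTruth(
        seed=seed,
        model="traced_nuclei",
        params={
            "n_nuclei": n_nuclei,
            "traces_per_nucleus": traces_per_nucleus,
            "trace_length": trace_length,
            "offset": list(offset),
            "focus_noise": focus_noise,
            "step": step,
        },
        truth={"foci": truth_foci},
    )
    return traces, foci, truth


def simulate_ratio_records(
    genotypes: Sequence[str] = ("WT", "mutant"),
    effect: float = 0.1,
    n_gonads: int = 6,
    nuclei_per_gonad: int = 30,
    base_ratio: float = 0.6,
    gonad_sd: float = 0.02,
    nucleus_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format axis-ratio table for the mixed-model genotype contrast.

    The second genotype's ratios are shifted by ``-effect`` relative to the
    first (a drop in axis association, as under hexanediol treatment of a
    destabilized synaptonemal complex), with gonad-level random intercepts
    of standard deviation ``gonad_sd`` and per-nucleus noise
    ``nucleus_sd``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gi, geno in enumerate(genotypes):
        shift = -effect * gi
        for g in range(n_gonads):
            gonad_effect = rng.normal(0.0, gonad_sd)
            vals = (
                base_ratio
                + shift
                + gonad_effect
                + rng.normal(0.0, nucleus_sd, size=nuclei_per_gonad)
            )
            for v in vals:
                rows.append(
                    {
                        "axis_ratio": float(np.clip(v, 0.0, 1.0)),
                        "genotype": geno,
                        "gonad": f"{geno}_g{g}",
                    }
                )
    return pd.DataFrame(rows)
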