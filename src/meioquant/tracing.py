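"""Chromosome-trace resampling and focus-to-trace mapping.

Semi-manually traced synaptonemal complexes are exported as ordered 3D
control points per chromosome.  This module interpolates each trace with a
spline, resamples it at equidistant arc-length steps, estimates the global
translation between the focus and trace imaging channels, and maps each
focus centroid to the arc-length position of the nearest sampled point on
the traces of its own nucleus.  Per-trace focus counts and normalized
inter-focus gaps feed the interference module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import interpolate, optimize
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from .interference import FocusSet

__all__ = [
    "ChromosomeTrace",
    "FocusMapping",
    "resample_trace",
    "estimate_channel_offset",
    "map_foci",
    "per_trace_focus_stats",
]

DEFAULT_STEP = 0.05  # um, well below the ~0.1 um synaptonemal-complex width


@dataclass(frozen=True)
class ChromosomeTrace:
    """A resampled chromosome trace with arc-length parametrization."""

    trace_id: str
    nucleus_id: str
    control_points: np.ndarray  # (n, 3) original (z, y, x) control points, um
    resampled_points: np.ndarray  # (m, 3) equidistant samples
    arc_positions: np.ndarray  # (m,) arc length of each sample, um
    total_length: float  # um

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise InvalidInputError(f"trace {self.trace_id}: non-positive length")
        spacing = np.diff(self.arc_positions)
        if spacing.size and np.ptp(spacing) > 0.01 * spacing.mean():
            raise InvalidInputError(
                f"trace {self.trace_id}: resampled spacing varies by more than 1%"
            )


@dataclass(frozen=True)
class FocusMapping:
    """A focus assigned to its nearest trace point."""

    focus_id: str
    trace_id: str | None
    arc_position: float  # um along the trace; NaN if unmapped
    normalized_position: float  # arc_position / total_length; NaN if unmapped
    distance: float  # um from corrected centroid to the nearest sample

    @property
    def mapped(self) -> bool:
        return self.trace_id is not None


def _dedupe(points: np.ndarray) -> np.ndarray:
    """Collapse consecutive duplicate control points."""
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(points, axis=0), axis=1) > 0
    return points[keep]


def resample_trace(
    control_points: Sequence[Sequence[float]] | np.ndarray,
    step: float = DEFAULT_STEP,
    trace_id: str = "trace",
    nucleus_id: str = "nucleus",
    dense_factor: int = 50,
) -> ChromosomeTrace:
    """Spline-interpolate control points and resample at equal arc steps.

    A natural cubic spline (quadratic/linear fallback for 3/2 control
    points) is fitted over the chord-length parameter; arc length is
    accumulated on a dense evaluation grid and inverted so that samples sit
    ``step`` micrometres apart along the curve, endpoints preserved.
    """
    if step <= 0:
        raise InvalidParameterError(f"step must be positive, got {step}")
    pts = _dedupe(np.asarray(control_points, dtype=float).reshape(-1, 3))
    n = len(pts)
    if n < 2:
        raise InvalidInputError("need at least 2 distinct control points")
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    if n == 2:
        curve_fn = lambda t: np.column_stack(
            [np.interp(t, chord, pts[:, d]) for d in range(3)]
        )
    elif n == 3:
        spl = interpolate.make_interp_spline(chord, pts, k=2)
        curve_fn = spl
    else:
        spl = interpolate.CubicSpline(chord, pts, bc_type="natural")
        curve_fn = spl
    dense_t = np.linspace(0.0, chord[-1], max(dense_factor * n, 1000))
    dense = np.asarray(curve_fn(dense_t))
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arc[-1])
    # exactly even spacing as close to `step` as possible, endpoints kept
    m = max(int(round(total / step)), 1) + 1
    targets = np.linspace(0.0, total, m)
    t_of_s = np.interp(targets, arc, dense_t)
    samples = np.asarray(curve_fn(t_of_s))
    samples[0] = pts[0]
    samples[-1] = pts[-1]
    return ChromosomeTrace(
        trace_id=str(trace_id),
        nucleus_id=str(nucleus_id),
        control_points=pts,
        resampled_points=samples,
        arc_positions=targets,
        total_length=total,
    )


def _nearest_sq_dists(points: np.ndarray, tree: cKDTree) -> np.ndarray:
    d, _ = tree.query(points)
    return d**2


def estimate_channel_offset(
    foci: np.ndarray,
    traces: Sequence[ChromosomeTrace],
    robust_trim: float = 0.0,
) -> np.ndarray:
    """Global translation between the focus and trace channels.

    Returns the displacement of the focus channel relative to the trace
    channel: the translation ``v`` such that subtracting ``v`` from the
    focus centroids minimizes the sum of squared distances to their
    nearest trace samples.  Found by coordinate descent (Powell) from
    zero.  With ``robust_trim`` > 0 the estimate is refined once with the
    worst ``robust_trim`` fraction of foci (largest residuals) removed.
    """
    foci = np.asarray(foci, dtype=float).reshape(-1, 3)
    if len(foci) < 3:
        raise InsufficientDataError(f"need >= 3 foci, got {len(foci)}")
    if not traces:
        raise InvalidInputError("no traces supplied")
    if not 0.0 <= robust_trim < 1.0:
        raise InvalidParameterError("robust_trim must lie in [0, 1)")
    all_pts = np.vstack([t.resampled_points for t in traces])
    tree = cKDTree(all_pts)

    def solve(subset: np.ndarray) -> np.ndarray:
        res = optimize.minimize(
            lambda v: float(_nearest_sq_dists(subset - v, tree).sum()),
            x0=np.zeros(3),
            method="Powell",
            options={"xtol": 1e-6, "ftol": 1e-10},
        )
        return res.x

    offset = solve(foci)
    if robust_trim > 0:
        resid = _nearest_sq_dists(foci - offset, tree)
        keep = resid <= np.quantile(resid, 1.0 - robust_trim)
        if keep.sum() >= 3:
            offset = solve(foci[keep])
    return offset


def map_foci(
    foci: Sequence[tuple[str, str, np.ndarray]],
    traces: Sequence[ChromosomeTrace],
    offset: np.ndarray | None = None,
) -> list[FocusMapping]:
    """Map focus centroids to arc positions on their nucleus's traces.

    ``foci`` is a sequence of ``(focus_id, nucleus_id, centroid_zyx)``.
    Each centroid, corrected by subtracting the channel ``offset`` (as
    estimated by :func:`estimate_channel_offset`), is assigned to the
    globally nearest resampled point across all traces of its own nucleus;
    ties are broken by lowest trace_id, then smallest arc position.  A
    focus whose nucleus has no trace is returned unmapped (NaN positions).
    """
    offset = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    by_nucleus: dict[str, list[ChromosomeTrace]] = {}
    for t in traces:
        by_nucleus.setdefault(t.nucleus_id, []).append(t)
    for lst in by_nucleus.values():
        lst.sort(key=lambda t: t.trace_id)
    out: list[FocusMapping] = []
    for focus_id, nucleus_id, centroid in foci:
        c = np.asarray(centroid, dtype=float) - offset
        cand = by_nucleus.get(str(nucleus_id), [])
        if not cand:
            out.append(
                FocusMapping(str(focus_id), None, np.nan, np.nan, np.nan)
            )
            continue
        tol = 1e-18
        best: tuple[float, str, float, float] | None = None
        for t in cand:  # traces pre-sorted by trace_id
            diff = t.resampled_points - c
            d2 = np.einsum("ij,ij->i", diff, diff)
            i = int(np.argmin(d2))  # argmin keeps the smallest arc position
            if (
                best is None
                or d2[i] < best[0] - tol
                # exact tie with an earlier (lower-id) trace: earlier wins
            ):
                best = (float(d2[i]), t.trace_id, float(t.arc_positions[i]), t.total_length)
        d2min, trace_id, arc, total = best
        out.append(
            FocusMapping(
                focus_id=str(focus_id),
                trace_id=trace_id,
                arc_position=arc,
                normalized_position=arc / total,
                distance=float(np.sqrt(d2min)),
            )
        )
    return out


def per_trace_focus_stats(
    mappings: Sequence[FocusMapping], traces: Sequence[ChromosomeTrace]
) -> tuple[dict[str, int], list[FocusSet]]:
    """Per-trace focus counts and FocusSets of mapped arc positions.

    Returns ``(counts, focus_sets)``: counts for every trace (zero
    included) and one :class:`~meioquant.interference.FocusSet` per trace,
    ready for :func:`~meioquant.interference.interfocus_distances`.
    """
    lengths = {t.trace_id: t.total_length for t in traces}
    positions: dict[str, list[float]] = {tid: [] for tid in lengths}
    for m in mappings:
        if m.mapped:
            if m.trace_id not in lengths:
                raise InvalidInputError(f"mapping refers to unknown trace {m.trace_id}")
            positions[m.trace_id].append(m.arc_position)
    counts = {tid: len(pos) for tid, pos in positions.items()}
    focus_sets = [
        FocusSet(
            chromosome_id=tid,
            length=lengths[tid],
            positions=tuple(sorted(pos)),
        )
        for tid, pos in positions.items()
    ]
    return counts, focus_sets
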