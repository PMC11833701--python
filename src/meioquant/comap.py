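"""Crossover mapping and ploidy classification in single F2 embryos.

Backcross F2 embryos of a Bristol(N2)/Hawaiian(CB4856) hybrid hermaphrodite
crossed to a Hawaiian male carry one paternal Hawaiian chromosome and one
maternal chromosome that is a Bristol/Hawaiian mosaic produced by meiotic
recombination in the mother.  Sequencing reads that map exclusively to one
of the two parental genomes are counted in fixed genomic windows (5 kb by
default); a gliding average of the Bristol fraction of these informative
reads assigns a genotype (homozygous Bristol, heterozygous, homozygous
Hawaiian) to each position, and crossovers are called at genotype
transitions that pass read-support and flank-consistency filters.

Ploidy is classified per chromosome from total read depth in coarser
windows (50 kb by default): window depth is converted to a copy number
against a diploid autosomal baseline and the chromosome mean is classified
as haploid (< 1.45), diploid (1.45-2.5, inclusive) or triploid (> 2.5).
Crossovers are only called on diploid chromosomes.

Genomic coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Genotype",
    "Ploidy",
    "WindowCountTable",
    "DepthTable",
    "CrossoverCall",
    "PloidyCall",
    "EmbryoReport",
    "gliding_ratio",
    "classify_genotype",
    "classify_track",
    "call_crossovers",
    "estimate_copy_number",
    "classify_ploidy",
    "analyze_embryo",
]

DEFAULT_WINDOW = 5_000
DEFAULT_DEPTH_WINDOW = 50_000
DEFAULT_SPAN = 100
DEFAULT_MIN_READS = 1_500
DEFAULT_MIN_FLANK = 15_000
BRISTOL_HOM_MIN_RATIO = 0.9
HAWAIIAN_HOM_MAX_RATIO = 0.25
HAPLOID_MAX_CN = 1.45
TRIPLOID_MIN_CN = 2.5


class Genotype(str, enum.Enum):
    BRISTOL_HOM = "BRISTOL_HOM"
    HET = "HET"
    HAWAIIAN_HOM = "HAWAIIAN_HOM"
    UNINFORMATIVE = "UNINFORMATIVE"


class Ploidy(str, enum.Enum):
    HAPLOID = "HAPLOID"
    DIPLOID = "DIPLOID"
    TRIPLOID = "TRIPLOID"


def _validate_windows(df: pd.DataFrame, window_size: int, kind: str) -> None:
    if window_size <= 0:
        raise InvalidParameterError(f"window size must be positive, got {window_size}")
    for chrom, sub in df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if np.any(starts < 0):
            raise InvalidInputError(f"{kind}: negative window start on {chrom}")
        d = np.diff(starts)
        if np.any(d != window_size):
            raise InvalidInputError(
                f"{kind}: windows on {chrom} must be sorted, non-overlapping and "
                f"of constant size {window_size}"
            )


@dataclass(frozen=True)
class WindowCountTable:
    """Per-window strain-specific read counts.

    ``df`` has columns ``chrom``, ``start`` (0-based, half-open windows of
    ``window_size`` bp), ``bristol`` and ``hawaiian`` (reads mapping
    exclusively to the respective genome).
    """

    df: pd.DataFrame
    window_size: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        required = {"chrom", "start", "bristol", "hawaiian"}
        missing = required - set(self.df.columns)
        if missing:
            raise InvalidInputError(f"count table missing columns: {sorted(missing)}")
        if (self.df[["bristol", "hawaiian"]].to_numpy() < 0).any():
            raise InvalidInputError("read counts must be non-negative")
        _validate_windows(self.df, self.window_size, "count table")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


@dataclass(frozen=True)
class DepthTable:
    """Per-window total mapped-read depth used for copy-number work."""

    df: pd.DataFrame
    window_size: int = DEFAULT_DEPTH_WINDOW

    def __post_init__(self) -> None:
        required = {"chrom", "start", "depth"}
        missing = required - set(self.df.columns)
        if missing:
            raise InvalidInputError(f"depth table missing columns: {sorted(missing)}")
        if (self.df["depth"].to_numpy() < 0).any():
            raise InvalidInputError("depth must be non-negative")
        _validate_windows(self.df, self.window_size, "depth table")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))


@dataclass(frozen=True)
class CrossoverCall:
    """A genotype transition that passed the support and flank filters."""

    chromosome_id: str
    interval: tuple[int, int]
    left_class: Genotype
    right_class: Genotype
    support_reads: int
    flank_lengths: tuple[int, int]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


@dataclass(frozen=True)
class PloidyCall:
    chromosome_id: str
    mean_copy_number: float
    ploidy: Ploidy


@dataclass
class EmbryoReport:
    """Per-embryo result: ploidy per chromosome and CO calls on diploids."""

    ploidy: dict[str, PloidyCall]
    calls: list[CrossoverCall]
    skipped_chromosomes: list[str] = field(default_factory=list)


def gliding_ratio(table: WindowCountTable, span: int = DEFAULT_SPAN) -> pd.DataFrame:
    """Gliding average of the Bristol fraction of informative reads.

    For each window the ratio is the ratio of sums ``sum(bristol) /
    (sum(bristol) + sum(hawaiian))`` over a centered span of ``span``
    windows, truncated (not padded) at chromosome ends.  Windows whose span
    contains zero informative reads get ``NaN`` (uninformative).

    Returns a frame with columns ``chrom``, ``start``, ``ratio``.
    """
    if span < 1:
        raise InvalidParameterError(f"span must be >= 1, got {span}")
    parts = []
    left = (span - 1) // 2
    right = span // 2
    for chrom, sub in table.df.groupby("chrom", sort=False):
        b = sub["bristol"].to_numpy(dtype=float)
        h = sub["hawaiian"].to_numpy(dtype=float)
        n = len(sub)
        cb = np.concatenate([[0.0], np.cumsum(b)])
        ct = np.concatenate([[0.0], np.cumsum(b + h)])
        idx = np.arange(n)
        lo = np.maximum(idx - left, 0)
        hi = np.minimum(idx + right + 1, n)
        sb = cb[hi] - cb[lo]
        st = ct[hi] - ct[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(st > 0, sb / st, np.nan)
        parts.append(
            pd.DataFrame({"chrom": chrom, "start": sub["start"].to_numpy(), "ratio": r})
        )
    return pd.concat(parts, ignore_index=True)


def classify_genotype(r: float) -> Genotype:
    """Genotype class of a single smoothed Bristol-fraction ratio.

    Ratios above 0.9 are homozygous Bristol, ratios below 0.25 homozygous
    Hawaiian; everything in between (boundaries included) is heterozygous.
    ``NaN`` (no informative reads in the span) is uninformative.
    """
    if np.isnan(r):
        return Genotype.UNINFORMATIVE
    if r < 0 or r > 1:
        raise InvalidInputError(f"ratio must lie in [0, 1], got {r}")
    if r > BRISTOL_HOM_MIN_RATIO:
        return Genotype.BRISTOL_HOM
    if r < HAWAIIAN_HOM_MAX_RATIO:
        return Genotype.HAWAIIAN_HOM
    return Genotype.HET


def classify_track(track: pd.DataFrame) -> pd.DataFrame:
    """Vectorized genotype classification of a gliding-ratio track.

    Adds a ``genotype`` column to the output of :func:`gliding_ratio`.
    """
    r = track["ratio"].to_numpy(dtype=float)
    finite = r[~np.isnan(r)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise InvalidInputError("ratios must lie in [0, 1]")
    geno = np.empty(len(r), dtype=object)
    geno[:] = Genotype.HET
    geno[r > BRISTOL_HOM_MIN_RATIO] = Genotype.BRISTOL_HOM
    geno[r < HAWAIIAN_HOM_MAX_RATIO] = Genotype.HAWAIIAN_HOM
    geno[np.isnan(r)] = Genotype.UNINFORMATIVE
    out = track.copy()
    out["genotype"] = geno
    return out


def _runs(classes: np.ndarray) -> list[tuple[Genotype, int, int]]:
    """Run-length encode a class array into (class, i0, i1) half-open runs."""
    runs = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            runs.append((classes[start], start, i))
            start = i
    return runs


def _merge_uninformative(
    runs: list[tuple[Genotype, int, int]], window: int, min_flank: int
) -> list[tuple[Genotype, int, int, bool]]:
    """Resolve UNINFORMATIVE runs.

    Short uninformative runs (< ``min_flank`` bp) flanked by the same class
    are absorbed; flanked by different classes they remain as transition
    gaps; at chromosome edges they join their only neighbour.  Long
    uninformative runs break run continuity (no call across them).

    Returns (class, i0, i1, is_barrier) with UNINFORMATIVE entries kept
    only as gaps or barriers.
    """
    resolved: list[tuple[Genotype, int, int, bool]] = []
    i = 0
    while i < len(runs):
        cls, i0, i1 = runs[i]
        if cls is not Genotype.UNINFORMATIVE:
            if resolved and resolved[-1][0] is cls and not resolved[-1][3]:
                _, p0, _, _ = resolved[-1]
                resolved[-1] = (cls, p0, i1, False)
            else:
                resolved.append((cls, i0, i1, False))
            i += 1
            continue
        length_bp = (i1 - i0) * window
        if length_bp >= min_flank:
            resolved.append((cls, i0, i1, True))
            i += 1
            continue
        prev_cls = resolved[-1][0] if resolved and not resolved[-1][3] else None
        next_cls = runs[i + 1][0] if i + 1 < len(runs) else None
        if prev_cls is not None and prev_cls is next_cls:
            # same informative class on both sides: absorb the gap
            _, p0, _, _ = resolved[-1]
            resolved[-1] = (prev_cls, p0, i1, False)
        elif prev_cls is None and next_cls is not None:
            # leading edge: join the following run
            nc, _, n1 = runs[i + 1]
            resolved.append((nc, i0, n1, False))
            i += 2
            continue
        elif next_cls is None and prev_cls is not None:
            # trailing edge: join the preceding run
            _, p0, _, _ = resolved[-1]
            resolved[-1] = (prev_cls, p0, i1, False)
        else:
            # different classes on either side: keep as a transition gap
            resolved.append((cls, i0, i1, False))
        i += 1
    return resolved


def call_crossovers(
    track: pd.DataFrame,
    table: WindowCountTable,
    min_reads: int = DEFAULT_MIN_READS,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[CrossoverCall]:
    """Call crossovers at filtered genotype transitions.

    The genotype track is run-length encoded per chromosome (uninformative
    stretches bridged as described in :func:`_merge_uninformative`).  Each
    boundary between runs of different genotype is a candidate crossover;
    it is retained iff both adjacent runs span at least ``min_flank`` bp of
    consistent genotype and the informative (strain-specific) reads summed
    over the two adjacent runs exceed ``min_reads``.  The reported interval
    is [end of the last left-run window, start of the first right-run
    window]; it is wider than a point only where an uninformative gap
    separates the two runs.
    """
    if "genotype" not in track.columns:
        track = classify_track(track)
    if len(track) != len(table.df) or not np.array_equal(
        track["start"].to_numpy(), table.df["start"].to_numpy()
    ):
        raise InvalidInputError("track and count table are not aligned")
    w = table.window_size
    calls: list[CrossoverCall] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        counts = table.df[table.df["chrom"] == chrom]
        informative = (counts["bristol"] + counts["hawaiian"]).to_numpy(dtype=float)
        starts = counts["start"].to_numpy()
        classes = sub["genotype"].to_numpy()
        runs = _merge_uninformative(_runs(classes), w, min_flank)
        # candidate boundaries between informative runs, optionally across a gap
        for j in range(len(runs) - 1):
            left = runs[j]
            k = j + 1
            gap = None
            if runs[k][0] is Genotype.UNINFORMATIVE:
                if runs[k][3]:  # barrier
                    continue
                gap = runs[k]
                k += 1
                if k >= len(runs):
                    continue
            right = runs[k]
            if left[0] is Genotype.UNINFORMATIVE or right[0] is Genotype.UNINFORMATIVE:
                continue
            if left[0] is right[0]:
                continue
            flank_left = (left[2] - left[1]) * w
            flank_right = (right[2] - right[1]) * w
            if flank_left < min_flank or flank_right < min_flank:
                continue
            support = informative[left[1] : left[2]].sum()
            support += informative[right[1] : right[2]].sum()
            if support <= min_reads:
                continue
            left_bp = int(starts[left[2] - 1]) + w
            right_bp = int(starts[right[1]])
            calls.append(
                CrossoverCall(
                    chromosome_id=str(chrom),
                    interval=(left_bp, right_bp),
                    left_class=left[0],
                    right_class=right[0],
                    support_reads=int(support),
                    flank_lengths=(flank_left, flank_right),
                )
            )
    return calls


def estimate_copy_number(
    depth_table: DepthTable,
    baseline: float | None = None,
    baseline_chromosomes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-chromosome mean copy number from windowed depth.

    Copy number per window is ``2 * depth / baseline`` where ``baseline``
    is the per-window depth expected for a diploid chromosome.  When not
    supplied, the baseline is the median window depth over
    ``baseline_chromosomes`` (default: all chromosomes not named like a sex
    chromosome, i.e. excluding ``X``/``chrX``), which is robust to a single
    aneuploid autosome.
    """
    df = depth_table.df
    if baseline is None:
        if baseline_chromosomes is None:
            baseline_chromosomes = [
                c for c in depth_table.chromosomes if str(c).removeprefix("chr") != "X"
            ]
        sel = df[df["chrom"].isin(baseline_chromosomes)]
        if sel.empty:
            raise InvalidParameterError("no windows available for the depth baseline")
        baseline = float(np.median(sel["depth"].to_numpy(dtype=float)))
    if baseline <= 0:
        raise InvalidParameterError(f"baseline depth must be positive, got {baseline}")
    cn = 2.0 * df["depth"].to_numpy(dtype=float) / baseline
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        out[str(chrom)] = float(cn[sub.index].mean())
    return out


def classify_ploidy(mean_cn: float) -> Ploidy:
    """Classify a chromosome's mean copy number.

    Below 1.45 is haploid, between 1.45 and 2.5 (closed interval) diploid,
    above 2.5 triploid.
    """
    if not np.isfinite(mean_cn) or mean_cn < 0:
        raise InvalidInputError(f"mean copy number must be >= 0, got {mean_cn}")
    if mean_cn < HAPLOID_MAX_CN:
        return Ploidy.HAPLOID
    if mean_cn > TRIPLOID_MIN_CN:
        return Ploidy.TRIPLOID
    return Ploidy.DIPLOID


def analyze_embryo(
    count_table: WindowCountTable,
    depth_table: DepthTable,
    span: int = DEFAULT_SPAN,
    min_reads: int = DEFAULT_MIN_READS,
    min_flank: int = DEFAULT_MIN_FLANK,
    baseline: float | None = None,
    baseline_chromosomes: Sequence[str] | None = None,
) -> EmbryoReport:
    """Full per-embryo analysis: ploidy first, then COs on diploids only.

    Chromosomes classified non-diploid are excluded from crossover calling
    and listed in ``skipped_chromosomes``; chromosomes missing from either
    table are skipped with a warning entry as well.
    """
    import warnings

    cn = estimate_copy_number(depth_table, baseline, baseline_chromosomes)
    ploidy = {
        chrom: PloidyCall(chrom, mean_cn, classify_ploidy(mean_cn))
        for chrom, mean_cn in cn.items()
    }
    skipped: list[str] = []
    count_chroms = set(count_table.chromosomes)
    depth_chroms = set(depth_table.chromosomes)
    for chrom in sorted(count_chroms ^ depth_chroms):
        warnings.warn(f"chromosome {chrom} missing from one input table; skipped")
        skipped.append(str(chrom))
    diploid = {
        c
        for c in (count_chroms & depth_chroms)
        if ploidy[str(c)].ploidy is Ploidy.DIPLOID
    }
    skipped.extend(
        sorted(str(c) for c in (count_chroms & depth_chroms) if c not in diploid)
    )
    sub = count_table.df[count_table.df["chrom"].isin(diploid)]
    calls: list[CrossoverCall] = []
    if not sub.empty:
        sub_table = WindowCountTable(sub.reset_index(drop=True), count_table.window_size)
        track = classify_track(gliding_ratio(sub_table, span))
        calls = call_crossovers(track, sub_table, min_reads, min_flank)
    return EmbryoReport(ploidy=ploidy, calls=calls, skipped_chromosomes=skipped)
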