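"""Amplified-segment detection from windowed read-depth tracks.

A resistant (case) and a susceptible (control) pool-seq library are each
normalized by the mean window depth of an unaffected baseline contig
(chromosome-1 surrogate), which cancels library size. The per-window
case/control ratio then estimates relative copy number along the contig.
Windows where the control library drops below a floor are masked: in this
genome they correspond to repeated elements and unresolved assembly, where
a ratio is meaningless. Maximal runs of high-ratio windows, optionally
bridging short masked gaps, are reported as amplified regions.

Coordinates are 0-based half-open throughout, matching BED/BedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CceampError, GridMismatchError

#: Control windows below this normalized depth are masked as repeat/assembly
#: artifacts (inclusive floor: a window exactly at the floor keeps its ratio).
DEFAULT_MASK_FLOOR = 0.25

#: Minimum window ratio for a window to seed or extend an amplified run.
DEFAULT_FOLD_MIN = 5.0

#: Minimum number of qualifying (unmasked) windows per reported region.
DEFAULT_MIN_WINDOWS = 5

#: Longest run of consecutive masked windows bridged inside one region.
DEFAULT_MAX_MASK_GAP = 10


@dataclass(frozen=True)
class DepthTrack:
    """Windowed mean depth along one contig (sorted, non-overlapping, tiling)."""

    contig: str
    starts: np.ndarray
    ends: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        depth = np.asarray(self.depth, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "depth", depth)
        if not (starts.shape == ends.shape == depth.shape):
            raise CceampError("starts, ends, depth must have equal length")
        if starts.size == 0:
            raise CceampError(f"{self.contig}: empty depth track")
        if np.any(ends <= starts):
            raise CceampError(f"{self.contig}: window end must exceed start")
        if np.any(starts[1:] != ends[:-1]):
            raise CceampError(f"{self.contig}: windows must be sorted and tiling")
        if not np.all(np.isfinite(depth)) or np.any(depth < 0):
            raise CceampError(f"{self.contig}: depths must be finite and >= 0")

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    @property
    def mean_depth(self) -> float:
        """Unweighted mean of window depths."""
        return float(np.mean(self.depth))


@dataclass(frozen=True)
class RatioTrack:
    """Per-window case/control ratio; masked windows carry no ratio (NaN)."""

    contig: str
    starts: np.ndarray
    ends: np.ndarray
    ratio: np.ndarray
    masked: np.ndarray


@dataclass(frozen=True)
class AmplifiedRegion:
    contig: str
    start: int
    end: int
    fold: float  # median ratio of unmasked member windows
    n_windows: int  # unmasked member windows
    n_masked_internal: int

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_depth(track: DepthTrack, baseline: DepthTrack) -> DepthTrack:
    """Divide each window depth by the baseline contig's mean window depth."""
    mean = baseline.mean_depth
    if mean <= 0:
        raise CceampError(
            f"baseline contig {baseline.contig} has non-positive mean depth"
        )
    return DepthTrack(track.contig, track.starts, track.ends, track.depth / mean)


def ratio_track(
    case_norm: DepthTrack,
    control_norm: DepthTrack,
    mask_floor: float = DEFAULT_MASK_FLOOR,
) -> RatioTrack:
    """Per-window case/control ratio with repeat masking.

    Windows whose control normalized depth is strictly below ``mask_floor``
    are masked and assigned no ratio.
    """
    if case_norm.contig != control_norm.contig or not (
        np.array_equal(case_norm.starts, control_norm.starts)
        and np.array_equal(case_norm.ends, control_norm.ends)
    ):
        raise GridMismatchError(
            f"window grids differ between case ({case_norm.contig}) "
            f"and control ({control_norm.contig}) tracks"
        )
    masked = control_norm.depth < mask_floor
    ratio = np.full(case_norm.n_windows, np.nan)
    np.divide(case_norm.depth, control_norm.depth, out=ratio, where=~masked)
    return RatioTrack(case_norm.contig, case_norm.starts, case_norm.ends, ratio, masked)


def call_amplified_regions(
    ratios: RatioTrack,
    fold_min: float = DEFAULT_FOLD_MIN,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    max_mask_gap: int = DEFAULT_MAX_MASK_GAP,
) -> list[AmplifiedRegion]:
    """Call maximal runs of high-ratio windows as amplified regions.

    A region is a maximal run of unmasked windows with ratio >= fold_min,
    allowing interruptions of at most ``max_mask_gap`` consecutive masked
    windows (bridged and counted as internal masked windows). An unmasked
    window below fold_min always terminates the run. Runs with fewer than
    ``min_windows`` qualifying windows are discarded. The region fold is
    the median ratio of its unmasked member windows — robust to residual
    repeat windows — and boundaries are trimmed to qualifying windows.
    """
    regions: list[AmplifiedRegion] = []
    hot_idx: list[int] = []  # qualifying windows of the current run
    pending_mask = 0  # masked windows since the last qualifying window

    def flush() -> None:
        nonlocal hot_idx, pending_mask
        if len(hot_idx) >= min_windows:
            first, last = hot_idx[0], hot_idx[-1]
            members = np.array(hot_idx)
            internal = int(np.sum(ratios.masked[first : last + 1]))
            regions.append(
                AmplifiedRegion(
                    contig=ratios.contig,
                    start=int(ratios.starts[first]),
                    end=int(ratios.ends[last]),
                    fold=float(np.median(ratios.ratio[members])),
                    n_windows=len(hot_idx),
                    n_masked_internal=internal,
                )
            )
        hot_idx = []
        pending_mask = 0

    for i in range(ratios.starts.size):
        if ratios.masked[i]:
            pending_mask += 1
            if pending_mask > max_mask_gap:
                flush()
            continue
        if ratios.ratio[i] >= fold_min:
            hot_idx.append(i)
            pending_mask = 0
        else:
            flush()
    flush()
    return regions


def annotate_region(
    region: AmplifiedRegion, genes: pd.DataFrame
) -> list[str]:
    """Gene ids overlapping the region by >= 1 bp, in positional order.

    ``genes`` is a BED-like frame with columns contig, start, end, name
    (0-based half-open, as read by :func:`cceamp.io.read_genes_bed`).
    """
    required = {"contig", "start", "end", "name"}
    if not required.issubset(genes.columns):
        raise CceampError(f"gene table needs columns {sorted(required)}")
    hits = genes[
        (genes["contig"] == region.contig)
        & (genes["start"] < region.end)
        & (genes["end"] > region.start)
    ]
    return list(hits.sort_values("start")["name"])
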