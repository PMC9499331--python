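"""Sliding-window genotype index (GI) along chromosomes.

Per-marker calls in a low-depth F2 are unreliable (a 2x heterozygote is
miscalled half the time), but the errors are symmetric, so averaging codes
over a window recovers the regional genotype: GI = 0*p0 + 1*p1 + 2*p2 over
the window's non-missing markers sits near 0, 1 or 2 in parent-A,
heterozygous and parent-B regions respectively.  GI is discretized with the
asymmetric thresholds (<=0.2 -> 0, (0.2, 1.8] -> 1, >1.8 -> 2) and a window
needs a minimum number of informative markers to be called at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import MarkerMatrix
from .simulate import MISSING


@dataclass(frozen=True)
class WindowParams:
    window_size: int = 300_000
    step: int = 10_000
    min_markers: int = 10
    low_threshold: float = 0.2
    high_threshold: float = 1.8

    def __post_init__(self):
        if not (self.window_size >= self.step > 0):
            raise ValueError("require window_size >= step > 0")
        if not (0 < self.low_threshold < self.high_threshold < 2):
            raise ValueError("thresholds must satisfy 0 < low < high < 2")


@dataclass
class WindowTrack:
    """Per-chromosome window calls for a set of individuals.

    ``anchors`` are the window centers on the step grid; ``gi`` and ``calls``
    are (n_anchors, n_individuals), with NaN / -1 where fewer than
    ``min_markers`` informative markers fell in the window.
    """

    chrom: str
    anchors: np.ndarray
    gi: np.ndarray
    calls: np.ndarray
    individuals: list[str]

    def __post_init__(self):
        d = np.diff(self.anchors)
        if len(d) and (d <= 0).any():
            raise ValueError("anchors must be strictly increasing")


def genotype_index(codes, min_markers: int = 10) -> float:
    """GI of one window: mean genotype code over non-missing markers.

    Equals 0*p0 + 1*p1 + 2*p2 for the code proportions; NaN when fewer than
    ``min_markers`` markers are informative.
    """
    codes = np.asarray(codes)
    ok = codes != MISSING
    if ok.sum() < min_markers:
        return float("nan")
    return float(codes[ok].mean())


def discretize_gi(gi, params: WindowParams = WindowParams()):
    """Thresholded window call: GI <= 0.2 -> 0; 0.2 < GI <= 1.8 -> 1;
    GI > 1.8 -> 2; NaN -> -1 (no call)."""
    gi = np.asarray(gi, dtype=float)
    call = np.full(gi.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(gi)
    call[ok & (gi <= params.low_threshold)] = 0
    call[ok & (gi > params.low_threshold) & (gi <= params.high_threshold)] = 1
    call[ok & (gi > params.high_threshold)] = 2
    if call.shape == ():
        return int(call)
    return call


def window_scan(matrix: MarkerMatrix, chrom: str, chrom_length: int,
                params: WindowParams = WindowParams()) -> WindowTrack:
    """Slide a fixed window along one chromosome for every individual.

    Anchors sit on the step grid (step, 2*step, ..., <= chrom_length); the
    window around an anchor is half-open [anchor - w/2, anchor + w/2),
    truncated at the chromosome ends.  GI is computed per individual over the
    window's non-missing markers via prefix sums, and discretized.
    """
    sel = (matrix.table["chrom"] == chrom).to_numpy()
    pos = matrix.table.loc[sel, "pos"].to_numpy()
    if len(pos) and (np.diff(pos) < 0).any():
        raise ValueError("markers must be sorted by position")
    codes = matrix.codes[sel]
    anchors = np.arange(params.step, chrom_length + 1, params.step, dtype=np.int64)

    half = params.window_size // 2
    lo = np.searchsorted(pos, anchors - half, side="left")
    hi = np.searchsorted(pos, anchors + half, side="left")

    # prefix sums of non-missing counts and of code sums
    ok = (codes != MISSING)
    vals = np.where(ok, codes, 0).astype(np.int32)
    cum_n = np.concatenate([np.zeros((1, codes.shape[1]), np.int32),
                            np.cumsum(ok, axis=0, dtype=np.int32)])
    cum_v = np.concatenate([np.zeros((1, codes.shape[1]), np.int32),
                            np.cumsum(vals, axis=0, dtype=np.int32)])
    n = cum_n[hi] - cum_n[lo]
    v = cum_v[hi] - cum_v[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        gi = np.where(n >= params.min_markers, v / np.maximum(n, 1), np.nan)
    calls = discretize_gi(gi, params)
    return WindowTrack(chrom, anchors, gi, calls, list(matrix.individuals))


def scan_genome(matrix: MarkerMatrix, chrom_lengths: dict[str, int],
                params: WindowParams = WindowParams()) -> dict[str, WindowTrack]:
    return {c: window_scan(matrix, c, chrom_lengths[c], params)
            for c in matrix.chromosomes() if c in chrom_lengths}


def track_to_frame(track: WindowTrack) -> pd.DataFrame:
    """Long-format TSV view: chrom anchor individual gi call."""
    n_a, n_i = track.gi.shape
    return pd.DataFrame({
        "chrom": track.chrom,
        "anchor": np.repeat(track.anchors, n_i),
        "individual": np.tile(track.individuals, n_a),
        "gi": track.gi.ravel(),
        "call": track.calls.ravel(),
    })
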