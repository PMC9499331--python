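"""Recombination-bin calling from population window tracks.

A recombination bin is a maximal run of consecutive window anchors whose
genotype vectors across the whole population are identical: no crossover is
observed inside it in any individual, so it segregates as a single marker.
Bins whose genotype counts deviate drastically from the Mendelian 1:2:1
ratio (Pearson chi-square > 25 on 2 df, p < 1e-5) are filtered out as
distorted before linkage analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import MISSING
from .windows import WindowTrack


@dataclass
class Bin:
    """A maximal co-segregating anchor run.

    Physical extent is [first_anchor - step/2, last_anchor + step/2), so bin
    lengths are multiples of the step (minimum one step).  ``genotypes`` is
    the per-individual consensus over the member anchors (-1 when every
    member anchor was uncalled for that individual).
    """

    id: str
    chrom: str
    start: int
    end: int
    anchors: np.ndarray
    genotypes: np.ndarray
    chi2: float = float("nan")
    kept: bool = True
    counts: tuple = (0, 0, 0)
    meta: dict = field(default_factory=dict)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def partition_bins(track: WindowTrack, step: int | None = None,
                   chrom_ordinal_offset: int = 0) -> list[Bin]:
    """Split one chromosome's anchor grid into maximal co-segregating runs.

    NA-tolerant co-segregation: an anchor joins the current run if every
    individual called at both the anchor and the run's consensus agrees; the
    consensus absorbs calls where it was still NA.  Every anchor belongs to
    exactly one bin.
    """
    calls = track.calls
    n_anchors, n_ind = calls.shape
    if n_anchors == 0:
        return []
    step = step or int(np.diff(track.anchors).min()) if n_anchors > 1 else (step or 10_000)

    bins: list[Bin] = []
    run_start = 0
    consensus = calls[0].copy()
    for t in range(1, n_anchors):
        row = calls[t]
        both = (row != MISSING) & (consensus != MISSING)
        if np.array_equal(row[both], consensus[both]):
            fill = (consensus == MISSING) & (row != MISSING)
            consensus[fill] = row[fill]
        else:
            bins.append(_make_bin(track, run_start, t, consensus, step,
                                  chrom_ordinal_offset + len(bins)))
            run_start = t
            consensus = row.copy()
    bins.append(_make_bin(track, run_start, n_anchors, consensus, step,
                          chrom_ordinal_offset + len(bins)))
    return bins


def _make_bin(track, i0, i1, consensus, step, ordinal) -> Bin:
    anchors = track.anchors[i0:i1]
    chrom_num = "".join(ch for ch in track.chrom if ch.isdigit()) or track.chrom
    return Bin(
        id=f"B{chrom_num}_{ordinal + 1}",
        chrom=track.chrom,
        start=int(anchors[0] - step // 2),
        end=int(anchors[-1] + step // 2),
        anchors=anchors.copy(),
        genotypes=consensus.astype(np.int8),
    )


def segregation_chi2(genotypes: np.ndarray) -> float:
    """Pearson chi-square of a bin's genotype counts against 1:2:1."""
    g = np.asarray(genotypes)
    n0 = int((g == 0).sum())
    n1 = int((g == 1).sum())
    n2 = int((g == 2).sum())
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("bin has no non-missing genotypes")
    exp = np.array([n / 4, n / 2, n / 4])
    obs = np.array([n0, n1, n2], dtype=float)
    return float(((obs - exp) ** 2 / exp).sum())


def filter_distorted(bins: list[Bin], chi2_max: float = 25.0) -> list[Bin]:
    """Annotate each bin with its 1:2:1 chi-square; drop (kept=False) bins
    exceeding ``chi2_max``.  Returns the kept bins."""
    kept = []
    for b in bins:
        g = b.genotypes
        b.counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        b.chi2 = segregation_chi2(g) if sum(b.counts) else float("nan")
        b.kept = bool(sum(b.counts)) and b.chi2 <= chi2_max
        if b.kept:
            kept.append(b)
    return kept


def detect_breakpoints(calls: np.ndarray, anchors: np.ndarray) -> list[dict]:
    """Genotype transitions of one individual's discretized track.

    NA runs are skipped: a transition is reported between the last called
    anchor and the next called anchor with a different genotype.  A direct
    0<->2 transition implies two crossovers and is flagged.
    """
    out = []
    prev_call, prev_anchor = None, None
    for a, c in zip(anchors, calls):
        if c == MISSING:
            continue
        if prev_call is not None and c != prev_call:
            out.append({
                "anchor_before": int(prev_anchor), "anchor_after": int(a),
                "from_call": int(prev_call), "to_call": int(c),
                "double": abs(int(c) - int(prev_call)) == 2,
            })
        prev_call, prev_anchor = c, a
    return out


def bin_matrix(bins: list[Bin]) -> np.ndarray:
    """Stack bin genotype vectors into a (n_bins, n_individuals) matrix."""
    return np.vstack([b.genotypes for b in bins])


def bins_to_frame(bins: list[Bin]) -> pd.DataFrame:
    """BED-like bin table: chrom start end bin_id n0 n1 n2 chi2 kept."""
    return pd.DataFrame([{
        "chrom": b.chrom, "start": b.start, "end": b.end, "bin_id": b.id,
        "n0": b.counts[0], "n1": b.counts[1], "n2": b.counts[2],
        "chi2": b.chi2, "kept": b.kept,
    } for b in bins])
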