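"""Linkage analysis of recombination bins and genetic-map construction.

Pairwise recombination fractions between bins are maximum-likelihood
estimates for an F2 intercross with codominant markers, obtained by EM over
the phase-ambiguous double-heterozygote class.  Bin order is fixed by the
physical (reference) order within each chromosome; linkage groups are split
at junctions where adjacent bins are effectively unlinked; bins that cannot
be mapped at their physical rank (e.g. mis-assembled segments) are taken as
inquiry bins and re-placed beside their most tightly linked target
("rippling").  Genotype errors that imply an immediate double recombination
are corrected from agreeing flanking bins, co-positioned physically
consecutive bins are merged, and linkage is recomputed until a fixpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins import Bin
from .simulate import MISSING

_R_CAP = 0.4999  # distance cap: keeps map distances finite at r ~ 1/2


# ---------------------------------------------------------------------------
# recombination fraction (F2, codominant) via EM

def _pair_class_counts(gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
    """9-class joint genotype counts for pairs of genotype vectors.

    gi, gj are int arrays broadcastable to (..., n_individuals) with -1 for
    missing; returns counts of shape (..., 9) ordered by 3*g_i + g_j.
    """
    gi, gj = np.broadcast_arrays(np.asarray(gi), np.asarray(gj))
    valid = (gi != MISSING) & (gj != MISSING)
    cls = np.where(valid, 3 * gi.astype(np.int64) + gj.astype(np.int64), 0)
    if gi.ndim == 1:
        return np.bincount(cls[valid], minlength=9)
    lead = gi.shape[:-1]
    rows = np.arange(int(np.prod(lead))).reshape(lead)
    flat = (rows[..., None] * 9 + cls)[valid]
    counts = np.bincount(flat, minlength=9 * int(np.prod(lead)))
    return counts.reshape(lead + (9,))


def _joint_probs(r: np.ndarray) -> np.ndarray:
    """F2 joint genotype probabilities for two loci at recombination
    fraction r (coupling-phase parents), shape (..., 9)."""
    r = np.asarray(r, dtype=float)
    a, b = 1 - r, r
    p = np.stack([
        a * a / 4, a * b / 2, b * b / 4,
        a * b / 2, (a * a + b * b) / 2, a * b / 2,
        b * b / 4, a * b / 2, a * a / 4,
    ], axis=-1)
    return p


def _loglik(counts: np.ndarray, r: np.ndarray) -> np.ndarray:
    p = _joint_probs(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(np.maximum(p, 1e-320))
    return np.where(counts > 0, counts * lp, 0.0).sum(axis=-1)


def em_rf(counts: np.ndarray, max_iter: int = 300, tol: float = 1e-12):
    """EM recombination fraction(s) from 9-class counts (..., 9).

    Non-double-het classes carry a known recombinant-gamete count; the
    double-het class (both loci heterozygous) mixes 0-recombinant and
    2-recombinant phase configurations with posterior weight
    2 r^2 / (r^2 + (1-r)^2).  Returns (r clamped to [0, 0.5], LOD vs r=0.5).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=-1)
    # recombinant gametes in the unambiguous classes
    w_fixed = np.array([0, 1, 2, 1, 0, 1, 2, 1, 0], dtype=float)
    fixed = (counts * w_fixed).sum(axis=-1)
    n11 = counts[..., 4]
    r = np.full(np.shape(n), 0.25, dtype=float)
    safe_n = np.maximum(n, 1)
    for _ in range(max_iter):
        w = 2 * r * r / np.maximum(r * r + (1 - r) ** 2, 1e-320)
        r_new = (fixed + n11 * w) / (2 * safe_n)
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            break
        r = r_new
    r = np.clip(np.where(n > 0, r, 0.5), 0.0, 0.5)
    r = np.where(r < 1e-9, 0.0, r)  # EM approaches 0 asymptotically
    lod = (_loglik(counts, r) - _loglik(counts, np.full_like(r, 0.5))) / math.log(10)
    return r, np.maximum(lod, 0.0)


def estimate_rf_f2(genotypes_i, genotypes_j):
    """MLE recombination fraction and linkage LOD for one bin pair."""
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    if ((gi != MISSING) & (gj != MISSING)).sum() < 2:
        raise ValueError("need >= 2 individuals with both bins observed")
    counts = _pair_class_counts(gi, gj)
    r, lod = em_rf(counts)
    return float(r), float(lod)


# ---------------------------------------------------------------------------
# map functions

def map_function(r, kind: str = "kosambi"):
    """Recombination fraction -> cM (Kosambi default, Haldane selectable)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("require 0 <= r < 0.5")
    if kind == "haldane":
        d = -50.0 * np.log(1 - 2 * r)
    elif kind == "kosambi":
        d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    else:
        raise ValueError(f"unknown map function {kind!r}")
    return float(d) if d.shape == () else d


def inverse_map_function(d, kind: str = "kosambi"):
    """cM -> recombination fraction; exact inverse of ``map_function``."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if kind == "haldane":
        r = 0.5 * (1 - np.exp(-d / 50.0))
    elif kind == "kosambi":
        r = 0.5 * np.tanh(d / 50.0)
    else:
        raise ValueError(f"unknown map function {kind!r}")
    return float(r) if r.shape == () else r


# ---------------------------------------------------------------------------
# map containers

@dataclass
class LinkageGroup:
    name: str
    chrom: str                 # physical chromosome the group represents
    bins: list[Bin]
    cm: np.ndarray = field(default_factory=lambda: np.empty(0))

    def redundant_flags(self, tol: float = 1e-9) -> np.ndarray:
        """A bin is redundant when it shares its cM position with the
        previous bin in the group (contributes no extra mapping information)."""
        flags = np.zeros(len(self.bins), dtype=bool)
        if len(self.cm) > 1:
            flags[1:] = np.diff(self.cm) <= tol
        return flags

    def relocated_flags(self) -> np.ndarray:
        return np.array([b.chrom != self.chrom for b in self.bins], dtype=bool)

    @property
    def length_cm(self) -> float:
        return float(self.cm[-1]) if len(self.cm) else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    map_kind: str = "kosambi"
    unplaced: list[Bin] = field(default_factory=list)
    logs: dict = field(default_factory=dict)

    def all_bins(self):
        return [b for g in self.groups for b in g.bins]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            red = g.redundant_flags()
            rel = g.relocated_flags()
            for b, cm, rd, rl in zip(g.bins, g.cm, red, rel):
                rows.append({"lg": g.name, "bin_id": b.id, "chrom": b.chrom,
                             "phys_start": b.start, "phys_end": b.end,
                             "cm": round(float(cm), 6),
                             "redundant": bool(rd), "relocated": bool(rl)})
        return pd.DataFrame(rows)


def _adjacent_r(bins: list[Bin], map_kind: str, skip: int = 1):
    """Vectorized r/LOD/cM between bins i and i+skip along a chain."""
    if len(bins) <= skip:
        e = np.empty(0)
        return e, e, e
    g = np.vstack([b.genotypes for b in bins])
    counts = _pair_class_counts(g[:-skip], g[skip:])
    r, lod = em_rf(counts)
    d = map_function(np.minimum(r, _R_CAP), map_kind)
    return r, lod, d


def _recompute_positions(group: LinkageGroup, map_kind: str) -> None:
    _, _, d = _adjacent_r(group.bins, map_kind)
    group.cm = np.concatenate([[0.0], np.cumsum(d)])


# ---------------------------------------------------------------------------
# fixed-order map construction

def _lg_name(chrom: str, part: int, n_parts: int) -> str:
    num = "".join(c for c in chrom if c.isdigit()) or chrom
    if n_parts == 1:
        return f"LG{num}"
    return f"LG{num}{chr(ord('a') + part)}"


def build_fixed_order_map(bins: list[Bin], map_kind: str = "kosambi",
                          split_threshold: float = 50.0, lod_split: float = 3.0,
                          min_seg_bins: int = 4, min_seg_frac: float = 0.05,
                          discord_tol: float = 10.0,
                          gap_suspect: float = 15.0) -> GeneticMap:
    """Chain bins in reference order and split into linkage groups.

    Junctions where adjacent bins show no usable linkage (LOD < ``lod_split``
    or distance > ``split_threshold`` cM) break the chain.  Segments smaller
    than max(``min_seg_bins``, ``min_seg_frac`` of the chromosome's bins) --
    e.g. a mis-assembled insert unlinked to both physical flanks -- and
    interior bins whose insertion inflates the local two-interval length by
    more than ``discord_tol`` cM over the direct flank distance, are set
    aside as discordant inquiry bins for rippling (``map.logs['inquiry']``).
    """
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)
    groups: list[LinkageGroup] = []
    inquiry: list[Bin] = []
    for chrom in by_chrom:
        chain = sorted(by_chrom[chrom], key=lambda b: b.start)
        _, lod, d = _adjacent_r(chain, map_kind)
        cuts = [0]
        for j in range(len(chain) - 1):
            if lod[j] < lod_split or d[j] > split_threshold:
                cuts.append(j + 1)
        cuts.append(len(chain))
        segments = [chain[cuts[i]:cuts[i + 1]] for i in range(len(cuts) - 1)]
        min_bins = max(min_seg_bins, int(np.ceil(min_seg_frac * len(chain))))
        real = [s for s in segments if len(s) >= min_bins]
        for s in segments:
            if len(s) < min_bins:
                inquiry.extend(s)
        for part, seg in enumerate(real):
            _peel_outlier_runs(seg, map_kind, gap_suspect, min_bins, inquiry)
            g = LinkageGroup(_lg_name(chrom, part, len(real)), chrom, seg)
            _drop_discordant(g, map_kind, discord_tol, inquiry)
            _recompute_positions(g, map_kind)
            groups.append(g)
    gmap = GeneticMap(groups, map_kind)
    gmap.logs["inquiry"] = inquiry
    return gmap


def _peel_outlier_runs(seg: list[Bin], map_kind: str, gap_suspect: float,
                       min_bins: int, inquiry: list[Bin]) -> None:
    """Evict small bin runs bounded by implausibly large adjacent distances.

    A short run separated from both neighbours by gaps > ``gap_suspect`` cM
    (far beyond any credible local gap, but possibly still weakly linked
    through genotype blending at window boundaries) cannot sit at its
    physical rank; its bins become rippling inquiries.
    """
    while len(seg) > min_bins:
        _, _, d = _adjacent_r(seg, map_kind)
        marks = np.where(d > gap_suspect)[0]
        if len(marks) == 0:
            return
        bounds = [0] + [int(j) + 1 for j in marks] + [len(seg)]
        runs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
        small = [rn for rn in runs if rn[1] - rn[0] < min_bins]
        if not small:
            return
        lo, hi = min(small, key=lambda t: t[1] - t[0])
        inquiry.extend(seg[lo:hi])
        del seg[lo:hi]


def _drop_discordant(group: LinkageGroup, map_kind: str, discord_tol: float,
                     inquiry: list[Bin]) -> None:
    """Move interior bins that inflate the local map length to the inquiry list."""
    changed = True
    while changed and len(group.bins) >= 3:
        changed = False
        _, _, d1 = _adjacent_r(group.bins, map_kind, skip=1)
        _, _, d2 = _adjacent_r(group.bins, map_kind, skip=2)
        excess = d1[:-1] + d1[1:] - d2   # for interior bin j+1
        bad = np.where(excess > discord_tol)[0]
        if len(bad):
            j = int(bad[np.argmax(excess[bad])]) + 1
            inquiry.append(group.bins.pop(j))
            changed = True


# ---------------------------------------------------------------------------
# rippling: placement of discordant bins

def ripple_place_discordant(inquiry: Bin, gmap: GeneticMap,
                            lod_min: float = 6.0) -> dict:
    """Search all mapped bins for the target most tightly linked to the
    inquiry bin; insert beside it on the side adding the least map length.

    Returns a placement record; when no target reaches ``lod_min`` the bin
    goes to ``gmap.unplaced``.
    """
    mapped = gmap.all_bins()
    if not mapped:
        gmap.unplaced.append(inquiry)
        return {"bin": inquiry.id, "placed": False}
    g = np.vstack([b.genotypes for b in mapped])
    counts = _pair_class_counts(g, inquiry.genotypes[None, :])
    r, lod = em_rf(counts)
    best = int(np.argmin(r + np.where(lod <= 0, 1.0, 0.0)))  # prefer linked targets
    if lod[best] < lod_min:
        gmap.unplaced.append(inquiry)
        return {"bin": inquiry.id, "placed": False}
    # locate the target inside its group
    k = 0
    for group in gmap.groups:
        if best < k + len(group.bins):
            t = best - k
            break
        k += len(group.bins)

    def dist(a: Bin, b: Bin) -> float:
        counts = _pair_class_counts(a.genotypes, b.genotypes)
        rr, _ = em_rf(counts)
        return map_function(min(float(rr), _R_CAP), gmap.map_kind)

    target = group.bins[t]
    d_it = dist(inquiry, target)
    added_left = d_it if t == 0 else (
        dist(group.bins[t - 1], inquiry) + d_it - dist(group.bins[t - 1], target))
    added_right = d_it if t == len(group.bins) - 1 else (
        d_it + dist(inquiry, group.bins[t + 1]) - dist(target, group.bins[t + 1]))
    pos = t if added_left <= added_right else t + 1
    group.bins.insert(pos, inquiry)
    inquiry.meta["rippled"] = True
    _recompute_positions(group, gmap.map_kind)
    return {"bin": inquiry.id, "placed": True, "lg": group.name,
            "target": target.id, "r": float(r[best]), "lod": float(lod[best]),
            "relocated": inquiry.chrom != group.chrom}


def place_all_discordant(gmap: GeneticMap, lod_min: float = 6.0) -> list[dict]:
    records = []
    for b in gmap.logs.get("inquiry", []):
        records.append(ripple_place_discordant(b, gmap, lod_min))
    gmap.logs["placements"] = records
    return records


# ---------------------------------------------------------------------------
# error correction and bin merging

def correct_and_merge(gmap: GeneticMap, dd_max: float = 5.0,
                      max_rounds: int = 25) -> GeneticMap:
    """Iterate genotype-error correction and redundant-bin merging to a fixpoint.

    A genotype implying a double recombination within ``dd_max`` cM around a
    single bin -- the bin differs from two agreeing flanks -- is replaced by
    the flanking genotype; missing bin genotypes are imputed the same way.
    Physically consecutive bins at identical cM positions are merged (extent
    union, genotype consensus).  Linkage is recomputed after every pass.
    """
    n_corr = n_merge = 0
    for _ in range(max_rounds):
        changed = False
        for group in gmap.groups:
            _recompute_positions(group, gmap.map_kind)
            if len(group.bins) >= 3:
                g = np.vstack([b.genotypes for b in group.bins])
                span = group.cm[2:] - group.cm[:-2]
                for j in range(1, len(group.bins) - 1):
                    if span[j - 1] > dd_max:
                        continue
                    l, m, r = g[j - 1], g[j], g[j + 1]
                    fix = (l == r) & (l != MISSING) & (m != l)
                    if fix.any():
                        group.bins[j].genotypes[fix] = l[fix]
                        g[j, fix] = l[fix]
                        n_corr += int(fix.sum())
                        changed = True
            _recompute_positions(group, gmap.map_kind)
            j = 0
            while j < len(group.bins) - 1:
                a, b = group.bins[j], group.bins[j + 1]
                same_pos = group.cm[j + 1] - group.cm[j] <= 1e-9
                consecutive = a.chrom == b.chrom and a.end == b.start
                if same_pos and consecutive:
                    _merge_into(a, b)
                    group.bins.pop(j + 1)
                    _recompute_positions(group, gmap.map_kind)
                    n_merge += 1
                    changed = True
                else:
                    j += 1
        if not changed:
            break
    gmap.logs["corrections"] = gmap.logs.get("corrections", 0) + n_corr
    gmap.logs["merges"] = gmap.logs.get("merges", 0) + n_merge
    return gmap


def _merge_into(a: Bin, b: Bin) -> None:
    a.end = b.end
    a.anchors = np.concatenate([a.anchors, b.anchors])
    take = (a.genotypes == MISSING) & (b.genotypes != MISSING)
    a.genotypes[take] = b.genotypes[take]
    a.meta.setdefault("merged", []).append(b.id)


def build_map(bins: list[Bin], map_kind: str = "kosambi",
              split_threshold: float = 50.0, lod_split: float = 3.0,
              min_seg_bins: int = 4, min_seg_frac: float = 0.05,
              discord_tol: float = 10.0,
              ripple_lod_min: float = 6.0, dd_max: float = 5.0) -> GeneticMap:
    """Full map pipeline: fixed-order chaining, rippling, correction/merging."""
    gmap = build_fixed_order_map(bins, map_kind, split_threshold, lod_split,
                                 min_seg_bins, min_seg_frac, discord_tol)
    place_all_discordant(gmap, ripple_lod_min)
    correct_and_merge(gmap, dd_max)
    return gmap


# ---------------------------------------------------------------------------
# summaries

def effective_bin_count(total_bins: int, redundant_bins: int) -> int:
    """Effective (position non-redundant) bin markers: total minus redundant."""
    return total_bins - redundant_bins


def coverage_percent(span_mb: float, full_mb: float) -> float:
    """Physical span as a percentage of full chromosome length (2 dp)."""
    return round(span_mb / full_mb * 100.0, 2)


def mean_spacing(total_length_cm: float, n_gaps: int) -> float:
    return total_length_cm / n_gaps if n_gaps > 0 else float("nan")


def map_summary(gmap: GeneticMap, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Per-linkage-group and total map statistics.

    Columns mirror the usual map table: genetic length, bin and effective-bin
    counts, nominal / effective mean adjacent spacing (length over adjacent
    gaps, aggregated as total length over total gaps), physical span from the
    first to the last bin, full chromosome length, and span coverage %.
    """
    rows = []
    tot_len = tot_bins = tot_eff = tot_gaps = tot_eff_gaps = 0.0
    tot_span = 0.0
    chrom_seen = set()
    for g in gmap.groups:
        n = len(g.bins)
        red = int(g.redundant_flags().sum())
        eff = effective_bin_count(n, red)
        length = g.length_cm
        own = [b for b in g.bins if b.chrom == g.chrom]
        span = (max(b.end for b in own) - min(b.start for b in own)) / 1e6 if own else 0.0
        multi = sum(1 for h in gmap.groups if h.chrom == g.chrom) > 1
        full = chrom_lengths.get(g.chrom, np.nan) / 1e6
        rows.append({
            "lg": g.name, "length_cm": round(length, 1), "n_bins": n,
            "n_effective": eff,
            "spacing_cm": round(mean_spacing(length, n - 1), 2) if n > 1 else np.nan,
            "effective_spacing_cm": round(mean_spacing(length, eff - 1), 2) if eff > 1 else np.nan,
            "span_mb": round(span, 2),
            "full_mb": np.nan if multi else round(full, 2),
            "coverage_pct": np.nan if multi else coverage_percent(span, full),
        })
        tot_len += length
        tot_bins += n
        tot_eff += eff
        tot_gaps += max(n - 1, 0)
        tot_eff_gaps += max(eff - 1, 0)
        tot_span += span
        chrom_seen.add(g.chrom)
    full_total = sum(chrom_lengths[c] for c in chrom_seen) / 1e6
    rows.append({
        "lg": "Total", "length_cm": round(tot_len, 1), "n_bins": int(tot_bins),
        "n_effective": int(tot_eff),
        "spacing_cm": round(mean_spacing(tot_len, int(tot_gaps)), 2),
        "effective_spacing_cm": round(mean_spacing(tot_len, int(tot_eff_gaps)), 2),
        "span_mb": round(tot_span, 2), "full_mb": round(full_total, 2),
        "coverage_pct": coverage_percent(tot_span, full_total),
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genetic-vs-physical profile (regional cM/Mb)

def rgp_profile(group: LinkageGroup, n_candidates: int = 60):
    """Regional ratio of genetic to physical distance along one linkage group.

    Fits a continuous piecewise-linear genetic-position vs physical-position
    curve with 3 segments (or 2 when a terminal high-recombination region is
    absent), choosing breakpoints on the bin grid by least squares and the
    segment count by BIC.  Returns a list of (start_mb, end_mb, slope cM/Mb)
    regions plus the whole-span average.
    """
    own = [(b, c) for b, c in zip(group.bins, group.cm) if b.chrom == group.chrom]
    if len(own) < 6:
        raise ValueError("need >= 6 bins for a regional profile")
    x = np.array([(b.start + b.end) / 2e6 for b, _ in own])
    y = np.array([c for _, c in own], dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    whole = (y[-1] - y[0]) / (x[-1] - x[0])

    interior = x[2:-2]
    if len(interior) <= n_candidates:
        cand = np.unique(interior)
    else:
        idx = np.unique(np.linspace(0, len(interior) - 1, n_candidates).astype(int))
        cand = np.unique(np.sort(interior)[idx])

    def fit(breaks):
        cols = [np.ones_like(x), x] + [np.maximum(x - b, 0.0) for b in breaks]
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((X @ beta - y) ** 2).sum())
        return beta, sse

    best = {"sse": np.inf}
    n = len(x)
    for i, b1 in enumerate(cand):
        beta, sse = fit([b1])
        k = 3
        bic = n * math.log(max(sse / n, 1e-12)) + k * math.log(n)
        if bic < best.get("bic", np.inf):
            best = {"breaks": [b1], "beta": beta, "sse": sse, "bic": bic}
        for b2 in cand[i + 1:]:
            if b2 - b1 < (x[-1] - x[0]) * 0.05:
                continue
            beta, sse = fit([b1, b2])
            k = 4
            bic = n * math.log(max(sse / n, 1e-12)) + k * math.log(n)
            if bic < best.get("bic", np.inf):
                best = {"breaks": [b1, b2], "beta": beta, "sse": sse, "bic": bic}
    breaks = best["breaks"]
    beta = best["beta"]
    slopes = np.cumsum(beta[1:])
    bounds = [x[0]] + list(breaks) + [x[-1]]
    regions = [(float(bounds[i]), float(bounds[i + 1]), float(slopes[i]))
               for i in range(len(slopes))]
    return {"regions": regions, "whole": float(whole)}
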