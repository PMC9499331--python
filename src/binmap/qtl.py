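"""QTL analysis on the bin map from F2:3 line means.

Interval mapping is Haley-Knott regression: at each scan position the
QTL-genotype class probabilities are computed from the flanking bins via the
map function, line means are regressed on the expected additive coding
x in {-1,0,+1} and the F2:3 dominance coding z in {0, 1/2} (an F3 family
from a heterozygous F2 parent segregates 1:2:1, halving the family-mean
dominance deviation), and LOD = (n/2) log10(SS0/SS1).  Genome-wise
significance thresholds come from phenotype permutations.  A naive
per-marker linear-model association scan serves as a cross-check of peak
locations, and candidate variants in a QTL interval are filtered on
parental depth/homozygosity, protein change and reference concordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linkage import GeneticMap, inverse_map_function
from .simulate import MISSING

_F2_PRIOR = np.array([0.25, 0.5, 0.25])


def _transition(r: float) -> np.ndarray:
    return np.array([[1 - r, r], [r, 1 - r]])


def _flank_lookup(r1: float, r2: float) -> np.ndarray:
    """P(QTL genotype | flanking genotypes) for an F2.

    Returns lookup[g1, g2, q] with marker-genotype index 3 meaning missing
    (marginalized).  Built by enumerating the two independent gametes, each a
    3-locus haplotype with no-interference transition probabilities.
    """
    t1, t2 = _transition(r1), _transition(r2)
    H = np.zeros((2, 2, 2))
    for a1 in range(2):
        for aq in range(2):
            for a2 in range(2):
                H[a1, aq, a2] = 0.5 * t1[a1, aq] * t2[aq, a2]
    J = np.zeros((3, 3, 3))  # joint over (g1, q, g2)
    idx = [(a1, aq, a2) for a1 in range(2) for aq in range(2) for a2 in range(2)]
    for h in idx:
        for hp in idx:
            J[h[0] + hp[0], h[1] + hp[1], h[2] + hp[2]] += H[h] * H[hp]
    out = np.zeros((4, 4, 3))
    for g1 in range(4):
        for g2 in range(4):
            sub = J
            sub = sub[g1] if g1 < 3 else sub.sum(axis=0)       # (q, g2)
            vec = sub[:, g2] if g2 < 3 else sub.sum(axis=1)    # (q,)
            s = vec.sum()
            out[g1, g2] = vec / s if s > 0 else _F2_PRIOR
    return out


@dataclass
class _PosDesign:
    lg: str
    cm: float
    left: int
    right: int
    X: np.ndarray          # (n, 3): intercept, E[x], E[z]
    U: np.ndarray = field(default=None, repr=False)  # orthonormal col basis


def build_scan_designs(gmap: GeneticMap, step_cm: float = 1.0) -> list[_PosDesign]:
    """Regression designs for every scan position on the map grid.

    Positions run every ``step_cm`` from 0 to each linkage group's length.
    At a position coinciding with a bin the design collapses to the bin's own
    genotype coding; between bins the flanking-bin genotypes give the
    expected codings through the map-function recombination fractions.
    """
    designs = []
    for group in gmap.groups:
        if len(group.bins) < 2:
            continue
        cm = group.cm
        G = np.vstack([b.genotypes for b in group.bins])
        n = G.shape[1]
        grid = np.arange(0.0, cm[-1] + step_cm / 2, step_cm)
        # bin positions join the grid so peaks can resolve to bin flanks
        grid = np.unique(np.clip(np.concatenate([grid, cm]), 0.0, cm[-1]))
        for p in grid:
            li = int(np.searchsorted(cm, p, side="right")) - 1
            ri = int(np.searchsorted(cm, p, side="left"))
            li, ri = max(li, 0), min(ri, len(cm) - 1)
            r1 = inverse_map_function(p - cm[li], gmap.map_kind)
            r2 = inverse_map_function(cm[ri] - p, gmap.map_kind)
            lut = _flank_lookup(r1, r2)
            g1 = np.where(G[li] == MISSING, 3, G[li])
            g2 = np.where(G[ri] == MISSING, 3, G[ri])
            probs = lut[g1, g2]               # (n, 3)
            x = probs[:, 2] - probs[:, 0]
            z = 0.5 * probs[:, 1]
            X = np.column_stack([np.ones(n), x, z])
            designs.append(_PosDesign(group.name, float(p), li, ri, X))
    return designs


def _orthonormal(X: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    keep = s > s[0] * 1e-10 if s[0] > 0 else s > 0
    return u[:, keep]


def _lod_matrix(designs: list[_PosDesign], Y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """LOD for every position x phenotype column; Y is (n_total, m)."""
    Ym = Y[mask]
    n = Ym.shape[0]
    ss0 = ((Ym - Ym.mean(axis=0)) ** 2).sum(axis=0)
    yy = (Ym ** 2).sum(axis=0)
    lods = np.empty((len(designs), Ym.shape[1]))
    for i, d in enumerate(designs):
        if d.U is None or d.U.shape[0] != n:
            d.U = _orthonormal(d.X[mask])
        proj = d.U.T @ Ym
        ss1 = np.maximum(yy - (proj ** 2).sum(axis=0), 1e-300)
        with np.errstate(divide="ignore"):
            lods[i] = np.maximum(n / 2.0 * np.log10(ss0 / ss1), 0.0)
    return lods


def interval_mapping_scan(gmap: GeneticMap, phenotype, step_cm: float = 1.0,
                          designs: list[_PosDesign] | None = None) -> pd.DataFrame:
    """Genome scan: LOD, additive (a), dominance (d) and PVE at every position.

    ``phenotype`` is aligned with the map's individuals; NaN entries (lines
    without phenotype) are dropped.  The additive coefficient follows the
    convention that +1 dosage is the parent-B (wild) allele: a negative sign
    means the wild allele decreases the trait.
    """
    y = np.asarray(phenotype, dtype=float)
    mask = np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError("need at least 3 phenotyped lines")
    designs = designs if designs is not None else build_scan_designs(gmap, step_cm)
    ym = y[mask]
    ss0 = float(((ym - ym.mean()) ** 2).sum())
    rows = []
    const = ss0 == 0
    for d in designs:
        X = d.X[mask]
        if const:
            rows.append((d.lg, d.cm, 0.0, 0.0, 0.0, 0.0))
            continue
        beta, *_ = np.linalg.lstsq(X, ym, rcond=None)
        resid = ym - X @ beta
        ss1 = max(float((resid ** 2).sum()), 1e-300)
        lod = max(len(ym) / 2.0 * math.log10(ss0 / ss1), 0.0)
        pve = 100.0 * (1.0 - ss1 / ss0)
        rows.append((d.lg, d.cm, lod, float(beta[1]), float(beta[2]), pve))
    return pd.DataFrame(rows, columns=["lg", "cm", "lod", "add", "dom", "pve"])


def permutation_threshold(gmap: GeneticMap, phenotype, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0,
                          step_cm: float = 1.0,
                          designs: list[_PosDesign] | None = None) -> float:
    """Genome-wise LOD threshold: the (1-alpha) quantile of the maximum LOD
    over random phenotype permutations."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alpha >= 1:
        return 0.0
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    mask = np.isfinite(y)
    designs = designs if designs is not None else build_scan_designs(gmap, step_cm)
    ym = y[mask]
    perms = np.column_stack([rng.permutation(ym) for _ in range(n_perm)])
    full = np.full((len(y), n_perm), np.nan)
    full[mask] = perms
    lods = _lod_matrix(designs, full, mask)
    max_lod = lods.max(axis=0)
    return float(np.quantile(max_lod, 1 - alpha))


@dataclass
class QTLPeak:
    """A significant QTL: peak position, flanking-bin interval (genetic and
    physical), LOD against its threshold, and effect estimates."""

    trait: str
    season: str
    lg: str
    pos_cm: float
    lod: float
    tlod: float
    add: float
    dom: float
    pve: float
    bin_left: str = ""
    bin_right: str = ""
    cm_lo: float = float("nan")
    cm_hi: float = float("nan")
    phys_lo_kb: float = float("nan")
    phys_hi_kb: float = float("nan")

    @property
    def width_cm(self) -> float:
        return self.cm_hi - self.cm_lo

    @property
    def width_mb(self) -> float:
        return (self.phys_hi_kb - self.phys_lo_kb) / 1000.0


def call_peaks(curve: pd.DataFrame, gmap: GeneticMap, tlod: float,
               trait: str = "", season: str = "",
               min_separation: float = 20.0) -> list[QTLPeak]:
    """Local LOD maxima above the threshold, at least ``min_separation`` cM
    apart within a linkage group.

    A peak is the LOD argmax of each contiguous run of scan positions at or
    above the threshold; peaks closer than ``min_separation`` keep only the
    higher one.  The reported interval is the pair of bins flanking the peak
    position; the physical interval runs from the start of the left bin to
    the end of the right bin.
    """
    peaks: list[QTLPeak] = []
    for lg_name, sub in curve.groupby("lg", sort=False):
        sub = sub.sort_values("cm").reset_index(drop=True)
        lod = sub["lod"].to_numpy()
        above = lod >= tlod
        runs = []
        i = 0
        while i < len(sub):
            if above[i]:
                j = i
                while j + 1 < len(sub) and above[j + 1]:
                    j += 1
                runs.append(i + int(np.argmax(lod[i:j + 1])))
                i = j + 1
            else:
                i += 1
        runs.sort(key=lambda i: -lod[i])
        chosen: list[int] = []
        for i in runs:
            if all(abs(sub["cm"][i] - sub["cm"][j]) >= min_separation for j in chosen):
                chosen.append(i)
        group = next(g for g in gmap.groups if g.name == lg_name)
        for i in sorted(chosen):
            p = float(sub["cm"][i])
            cm = group.cm
            li = max(int(np.searchsorted(cm, p, side="right")) - 1, 0)
            ri = min(int(np.searchsorted(cm, p, side="left")), len(cm) - 1)
            bl, br = group.bins[li], group.bins[ri]
            peaks.append(QTLPeak(
                trait=trait, season=season, lg=lg_name, pos_cm=p,
                lod=float(lod[i]), tlod=tlod,
                add=float(sub["add"][i]), dom=float(sub["dom"][i]),
                pve=float(sub["pve"][i]),
                bin_left=bl.id, bin_right=br.id,
                cm_lo=float(cm[li]), cm_hi=float(cm[ri]),
                phys_lo_kb=bl.start / 1000.0, phys_hi_kb=br.end / 1000.0,
            ))
    return peaks


def combine_seasons(peaks: list[QTLPeak]) -> QTLPeak:
    """Average a/d/PVE of the same QTL detected in multiple seasons."""
    if len(peaks) == 1:
        return peaks[0]
    first = peaks[0]
    for p in peaks[1:]:
        if (p.lg, p.bin_left, p.bin_right) != (first.lg, first.bin_left,
                                               first.bin_right):
            raise ValueError("peaks do not share a bin interval")
    return QTLPeak(
        trait=first.trait,
        season="+".join(p.season for p in peaks),
        lg=first.lg, pos_cm=first.pos_cm,
        lod=float("nan"), tlod=float("nan"),
        add=float(np.mean([p.add for p in peaks])),
        dom=float(np.mean([p.dom for p in peaks])),
        pve=float(np.mean([p.pve for p in peaks])),
        bin_left=first.bin_left, bin_right=first.bin_right,
        cm_lo=first.cm_lo, cm_hi=first.cm_hi,
        phys_lo_kb=first.phys_lo_kb, phys_hi_kb=first.phys_hi_kb,
    )


def peaks_to_frame(peaks: list[QTLPeak]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trait": p.trait, "season": p.season, "lg": p.lg, "pos_cm": p.pos_cm,
        "interval": f"{p.bin_left}-{p.bin_right}",
        "cm_lo": p.cm_lo, "cm_hi": p.cm_hi,
        "kb_lo": p.phys_lo_kb, "kb_hi": p.phys_hi_kb,
        "lod": p.lod, "tlod": p.tlod,
        "add": p.add, "dom": p.dom, "pve": p.pve,
    } for p in peaks])


# ---------------------------------------------------------------------------
# naive per-marker association scan (peak co-location cross-check)

def association_scan(matrix, phenotype) -> pd.DataFrame:
    """F-test p-value of each marker's additive+dominance model.

    A plain per-marker linear model (no kinship correction): used only to
    check that association peaks co-locate with interval-mapping peaks.
    """
    y = np.asarray(phenotype, dtype=float)
    mask0 = np.isfinite(y)
    if mask0.sum() < 30:
        raise ValueError("need at least 30 phenotyped individuals")
    out = np.full(matrix.n_markers, np.nan)
    codes = matrix.codes
    for m in range(matrix.n_markers):
        g = codes[m]
        ok = mask0 & (g != MISSING)
        n = int(ok.sum())
        if n < 10:
            continue
        x = g[ok].astype(float) - 1.0
        z = (g[ok] == 1).astype(float)
        ym = y[ok]
        X = np.column_stack([np.ones(n), x, z])
        u = _orthonormal(X)
        k = u.shape[1]
        if k < 2:
            continue
        ss0 = float(((ym - ym.mean()) ** 2).sum())
        proj = u.T @ ym
        ss1 = max(float((ym ** 2).sum() - (proj ** 2).sum()), 1e-300)
        df1, df2 = k - 1, n - k
        if ss0 <= 0 or df2 <= 0:
            continue
        f = (ss0 - ss1) / df1 / (ss1 / df2)
        out[m] = stats.f.sf(f, df1, df2)
    return pd.DataFrame({
        "chrom": matrix.table["chrom"], "pos": matrix.table["pos"],
        "p": out, "neglog10p": -np.log10(np.maximum(out, 1e-300)),
    })


# ---------------------------------------------------------------------------
# candidate variant filtering in a QTL interval

def _translate(codon: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(codon.upper()).translate())


def candidate_variant_filter(parent_variants: pd.DataFrame,
                             annotations: pd.DataFrame | None,
                             interval: tuple[str, int, int],
                             min_depth: int = 6) -> pd.DataFrame:
    """Filter parental variants in a QTL interval down to reliable,
    protein-changing, reference-concordant candidates.

    ``parent_variants`` columns: chrom, pos, ref, alt, gt_a, gt_b (genotype
    strings), depth_a, depth_b.  ``annotations`` columns: chrom, pos,
    gene_id, codon_ref, codon_alt -- the codon carrying the site with the
    reference and alternate base substituted.  The three criteria: (1) both
    parents homozygous with depth >= ``min_depth``; (2) the variant changes
    the encoded amino acid (unannotated sites are indeterminate and fail);
    (3) parent A carries the reference allele (the reference genome matches
    parent A's phenotype class), i.e. parent B differs from the reference.
    """
    chrom, start, end = interval
    v = parent_variants[(parent_variants["chrom"] == chrom)
                        & (parent_variants["pos"] >= start)
                        & (parent_variants["pos"] <= end)].copy()
    ann = None
    if annotations is not None:
        ann = annotations.set_index(["chrom", "pos"])

    def hom_allele(gt: str):
        if gt in ("./.", ".", "", None):
            return None
        a, b = str(gt).replace("|", "/").split("/")
        return int(a) if a == b else None

    rows = []
    for _, rec in v.iterrows():
        a_allele = hom_allele(rec["gt_a"])
        b_allele = hom_allele(rec["gt_b"])
        c1 = (a_allele is not None and b_allele is not None
              and a_allele != b_allele
              and rec["depth_a"] >= min_depth and rec["depth_b"] >= min_depth)
        gene = codon_change = aa_change = None
        indeterminate = True
        c2 = False
        if ann is not None and (rec["chrom"], rec["pos"]) in ann.index:
            row = ann.loc[(rec["chrom"], rec["pos"])]
            gene = row["gene_id"]
            ref_aa = _translate(row["codon_ref"])
            alt_aa = _translate(row["codon_alt"])
            codon_change = f"{row['codon_ref']}>{row['codon_alt']}"
            aa_change = f"{ref_aa}>{alt_aa}"
            c2 = ref_aa != alt_aa
            indeterminate = False
        c3 = a_allele == 0 if a_allele is not None else False
        rows.append({
            "chrom": rec["chrom"], "pos": rec["pos"], "ref": rec["ref"],
            "alt": rec["alt"], "gene_id": gene,
            "codon_change": codon_change, "aa_change": aa_change,
            "pass_depth_hom": bool(c1), "pass_protein_change": bool(c2),
            "indeterminate": bool(indeterminate),
            "pass_ref_concordance": bool(c3),
            "candidate": bool(c1 and c2 and c3 and not indeterminate),
        })
    return pd.DataFrame(rows)
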