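"""Marker selection, encoding and population QC for a biparental F2.

Variants are retained as markers when they are diallelic, homozygous in both
parents (for opposite alleles) and have minor allele frequency >= 0.3 in the
F2; genotypes are coded 0 (parent-A homozygote), 1 (het), 2 (parent-B
homozygote), -1 missing.  QC statistics cover the per-marker MAF spectrum,
the per-individual proportion of heterozygous genotypes (PHG) -- which
low-depth sequencing depresses below the Mendelian 0.5 by the het-miscall
probability 1/2**(k-1) -- and a standardized genomic relatedness score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING


@dataclass
class MarkerMatrix:
    """Markers x individuals genotype codes with physical coordinates.

    ``table`` has columns chrom, pos (sorted), ``codes`` is int8
    (n_markers, n_individuals) in {0,1,2,-1}, ``individuals`` the sample ids.
    Parent A's allele anchors code 0.
    """

    table: pd.DataFrame
    codes: np.ndarray
    individuals: list[str]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        t = self.table[["chrom", "pos"]]
        if not t.equals(t.sort_values(["chrom", "pos"], kind="mergesort")):
            raise ValueError("markers must be sorted by (chrom, pos)")

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))


def het_miscall_prob(k: int) -> float:
    """Probability that a heterozygote is called homozygous at depth k.

    All k reads must show the same of the two alleles: 2*(1/2)**k = 1/2**(k-1).
    """
    if k < 1 or int(k) != k:
        raise ValueError("depth k must be a positive integer")
    return 1.0 / 2 ** (k - 1)


def expected_phg(k: int, pe: float = 0.5) -> float:
    """Expected observed het proportion per F2 individual at depth k:
    pe * (1 - pm) with pm = 1/2**(k-1)."""
    return pe * (1.0 - het_miscall_prob(k))


def read_vcf(path, samples: list[str] | None = None):
    """Load a VCF into a variant table.

    Returns a DataFrame with chrom, pos, ref, alt (list) and per-sample
    genotype strings like "0/1" ("./." when missing), plus a parallel
    depth DataFrame (DP or summed AD; NaN when absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = samples or list(vcf.samples)
    idx = [vcf.samples.index(s) for s in names]
    rows, gts, dps = [], [], []
    for var in vcf:
        rows.append((var.CHROM, var.POS, var.REF, tuple(var.ALT)))
        g = var.genotypes
        gts.append(tuple(
            "./." if g[i][0] < 0 else f"{g[i][0]}/{g[i][1]}" for i in idx))
        depth = var.format("DP")
        if depth is None:
            ad = var.format("AD")
            depth = ad if ad is not None else None
        if depth is not None:
            depth = np.asarray(depth, dtype=float).reshape(len(vcf.samples), -1)
            depth = np.where(depth < 0, np.nan, depth).sum(axis=1)
        dps.append(tuple(float(depth[i]) if depth is not None else np.nan
                         for i in idx))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gt = pd.DataFrame(gts, columns=names)
    dp = pd.DataFrame(dps, columns=names)
    return table, gt, dp


def select_markers(variants: pd.DataFrame, genotypes: pd.DataFrame,
                   parent_a: str, parent_b: str,
                   maf_min: float = 0.3) -> MarkerMatrix:
    """Apply the marker-selection criteria and encode genotypes.

    Keeps variants that are (1) diallelic, (2) homozygous in parent A,
    (3) of F2 minor allele frequency >= ``maf_min``; additionally parent B
    must be homozygous for the other allele so that codes 0/2 are anchored
    unambiguously.  Genotypes are re-coded with parent A's allele as 0.
    """
    for p in (parent_a, parent_b):
        if p not in genotypes.columns:
            raise ValueError(f"parent sample {p!r} missing from genotype table")
    f2_ids = [c for c in genotypes.columns if c not in (parent_a, parent_b)]

    def parse(gt: str):
        if gt in ("./.", ".", ""):
            return None
        a, b = gt.replace("|", "/").split("/")
        return int(a), int(b)

    kept_rows, kept_codes = [], []
    for i in range(len(variants)):
        alt = variants["alt"].iloc[i]
        alt = list(alt) if isinstance(alt, (list, tuple)) else [alt]
        if len(alt) != 1:  # criterion 1: diallelic
            continue
        pa = parse(genotypes[parent_a].iloc[i])
        pb = parse(genotypes[parent_b].iloc[i])
        if pa is None or pa[0] != pa[1]:  # criterion 2: parent A homozygous
            continue
        if pb is None or pb[0] != pb[1] or pb[0] == pa[0]:
            continue  # parent B homozygous for the other allele
        a_allele = pa[0]
        codes = np.full(len(f2_ids), MISSING, dtype=np.int8)
        for j, s in enumerate(f2_ids):
            g = parse(genotypes[s].iloc[i])
            if g is None:
                continue
            codes[j] = (g[0] != a_allele) + (g[1] != a_allele)
        nz = codes != MISSING
        if nz.sum() == 0:
            continue
        # criterion 3: F2 minor allele frequency on allele counts
        n0 = int((codes == 0).sum())
        n1 = int((codes == 1).sum())
        freq_a = (2 * n0 + n1) / (2 * nz.sum())
        if min(freq_a, 1 - freq_a) < maf_min:
            continue
        kept_rows.append(i)
        kept_codes.append(codes)

    table = variants.iloc[kept_rows][["chrom", "pos"]].reset_index(drop=True)
    codes = (np.vstack(kept_codes) if kept_codes
             else np.empty((0, len(f2_ids)), dtype=np.int8))
    order = table.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return MarkerMatrix(table.iloc[order].reset_index(drop=True), codes[order],
                        f2_ids)


def compute_marker_stats(matrix: MarkerMatrix) -> pd.DataFrame:
    """Per-marker MAF (allele-count convention) and missing fraction."""
    if matrix.n_markers == 0:
        raise ValueError("empty marker matrix")
    c = matrix.codes
    n0 = (c == 0).sum(axis=1)
    n1 = (c == 1).sum(axis=1)
    nm = (c == MISSING).sum(axis=1)
    nn = matrix.n_individuals - nm
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = (2 * n0 + n1) / (2 * nn)
    maf = np.minimum(freq, 1 - freq)
    return pd.DataFrame({
        "chrom": matrix.table["chrom"], "pos": matrix.table["pos"],
        "maf": maf, "missing_frac": nm / matrix.n_individuals,
    })


def compute_individual_qc(matrix: MarkerMatrix, depth_k: int | None = None) -> pd.DataFrame:
    """Per-individual PHG and missing fraction, with the depth-model
    prediction attached when ``depth_k`` is given."""
    c = matrix.codes
    nm = (c == MISSING).sum(axis=0)
    nn = matrix.n_markers - nm
    with np.errstate(invalid="ignore", divide="ignore"):
        phg = (c == 1).sum(axis=0) / nn
    out = pd.DataFrame({
        "individual": matrix.individuals,
        "phg": np.where(nn > 0, phg, np.nan),
        "missing_frac": nm / matrix.n_markers,
        "all_missing": nn == 0,
    })
    if depth_k is not None:
        out.attrs["predicted_phg"] = expected_phg(depth_k)
        out.attrs["het_miscall_prob"] = het_miscall_prob(depth_k)
    return out


def relatedness_scores(matrix: MarkerMatrix):
    """Genomic relationship matrix and standardized off-diagonal scores.

    VanRaden-style: dosages centered by 2p and the cross-product scaled by
    sum 2p(1-p); missing dosages contribute zero after centering.  The
    relatedness score standardizes the off-diagonal coefficients to
    mean 0, sd 1 over all pairs.
    """
    if matrix.n_individuals < 3:
        raise ValueError("need at least 3 individuals")
    c = matrix.codes.astype(float)
    c[matrix.codes == MISSING] = np.nan
    p = np.nanmean(c, axis=1) / 2.0
    keep = (p > 0) & (p < 1) & ~np.isnan(p)
    if keep.sum() == 0:
        raise ValueError("no polymorphic markers")
    z = c[keep] - 2 * p[keep, None]
    z = np.nan_to_num(z, nan=0.0)
    denom = float(np.sum(2 * p[keep] * (1 - p[keep])))
    grm = z.T @ z / denom
    iu = np.triu_indices(matrix.n_individuals, k=1)
    off = grm[iu]
    if off.std() == 0:
        raise ValueError("degenerate relationship matrix")
    standardized = (off - off.mean()) / off.std()
    pairs = pd.DataFrame({
        "i": np.asarray(matrix.individuals)[iu[0]],
        "j": np.asarray(matrix.individuals)[iu[1]],
        "coefficient": off, "score": standardized,
    })
    return grm, pairs


# ---------------------------------------------------------------------------
# TSV dialect: chrom pos ref alt sample1..sampleN with codes {0,1,2,NA}

def write_marker_tsv(matrix: MarkerMatrix, path) -> None:
    df = matrix.table[["chrom", "pos"]].copy()
    if "ref" not in df:
        df["ref"], df["alt"] = "A", "B"
    codes = matrix.codes.astype(object)
    codes[matrix.codes == MISSING] = "NA"
    for j, s in enumerate(matrix.individuals):
        df[s] = codes[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_marker_tsv(path) -> MarkerMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     keep_default_na=False, na_values=["NA"])
    meta = [c for c in ("chrom", "pos", "ref", "alt") if c in df.columns]
    samples = [c for c in df.columns if c not in meta]
    codes = df[samples].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    table = df[["chrom", "pos"]].reset_index(drop=True)
    return MarkerMatrix(table, codes, samples)
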