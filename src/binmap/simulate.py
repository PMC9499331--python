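"""Synthetic F2 / F2:3 data generation.

Emulates the statistical structure of a low-depth whole-genome-resequenced
F2 intercross: crossovers drawn from a no-interference (Poisson) meiosis
model, nonuniform marker density along chromosomes, a piecewise cM/Mb
recombination landscape (dense recombining distal regions, a suppressed
pericentromeric region), per-marker low-depth read sampling that miscalls
heterozygotes with probability 1/2**(k-1), missing data at zero depth, a
pleiotropic QTL driving ordinal traits scored on F2:3 line means, and an
optional mis-assembled segment whose physical coordinates sit on the wrong
chromosome.

Genotype codes throughout: 0 = parent-A homozygote, 1 = heterozygote,
2 = parent-B homozygote, -1 = missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class ChromSpec:
    """One chromosome: physical length in bp and genetic length in cM."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be positive")
        if self.length_cm < 0:
            raise ValueError(f"chromosome {self.name}: genetic length must be >= 0")


@dataclass
class MapSpec:
    """Genome layout for the simulator.

    ``recomb_profile`` maps chromosome name to a list of
    ``(start_bp, end_bp, weight)`` pieces tiling the chromosome; weights are
    relative cM/Mb and are rescaled so the chromosome's genetic length matches
    ``length_cm``.  ``marker_density`` has the same piecewise form with weights
    in relative markers/Mb.  Omitted chromosomes get a uniform profile.
    """

    chromosomes: list[ChromSpec]
    recomb_profile: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    marker_density: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for prof in (self.recomb_profile, self.marker_density):
            for name, pieces in prof.items():
                chrom = self.chrom(name)
                self._check_tiling(chrom, pieces)

    @staticmethod
    def _check_tiling(chrom: ChromSpec, pieces):
        pos = 0
        for start, end, w in pieces:
            if start != pos or end <= start:
                raise ValueError(f"profile pieces must tile chromosome {chrom.name}")
            if w < 0:
                raise ValueError("profile weights must be >= 0")
            pos = end
        if pos != chrom.length_bp:
            raise ValueError(f"profile pieces must tile chromosome {chrom.name}")

    def chrom(self, name: str) -> ChromSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def phys_to_gen(self, name: str, pos_bp) -> np.ndarray:
        """Map physical bp to genetic cM through the recombination profile."""
        chrom = self.chrom(name)
        pos_bp = np.asarray(pos_bp, dtype=float)
        if np.any(pos_bp < 0) or np.any(pos_bp > chrom.length_bp):
            raise ValueError(f"position outside chromosome {name}")
        pieces = self.recomb_profile.get(name)
        if not pieces:
            return pos_bp / chrom.length_bp * chrom.length_cm
        starts = np.array([p[0] for p in pieces], dtype=float)
        ends = np.array([p[1] for p in pieces], dtype=float)
        weights = np.array([p[2] for p in pieces], dtype=float)
        raw = weights * (ends - starts)
        total = raw.sum()
        if total == 0:
            return np.zeros_like(pos_bp)
        cum = np.concatenate([[0.0], np.cumsum(raw)]) / total * chrom.length_cm
        idx = np.clip(np.searchsorted(ends, pos_bp, side="right"), 0, len(pieces) - 1)
        frac = (pos_bp - starts[idx]) / (ends[idx] - starts[idx])
        return cum[idx] + frac * (cum[idx + 1] - cum[idx])


@dataclass(frozen=True)
class DepthModel:
    """Per-marker per-individual sequencing depth model.

    mode ``"fixed"`` uses depth k everywhere; ``"poisson"`` draws depth from
    Poisson(lam).  ``base_error`` is the per-read allele error probability.
    """

    mode: str = "fixed"
    k: int = 2
    lam: float = 2.0
    base_error: float = 0.0

    def __post_init__(self):
        if self.mode not in ("fixed", "poisson"):
            raise ValueError("mode must be 'fixed' or 'poisson'")
        if self.k < 0 or self.lam < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")


@dataclass(frozen=True)
class QTLSpec:
    """A single QTL: position, additive (a) and dominance (d) effects on the
    F2 scale, residual SD of the F2:3 line means, and an optional ordinal
    ceiling used when clipping simulated means to a scoring scale."""

    chromosome: str
    position_cm: float
    a: float
    d: float = 0.0
    residual_sd: float = 1.0
    mu: float = 0.0
    ordinal_max: float | None = None

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


class TrueGenotypeMatrix:
    """Latent F2 genotypes plus the crossover record that generated them.

    ``codes`` is (n_markers, n_individuals) int8 in {0,1,2}.  ``markers`` is a
    DataFrame with columns chrom, pos (reported physical coordinates) and
    sim_chrom, sim_cm (the coordinates genotypes were actually drawn at; they
    differ only for mis-assembled segments).  The crossover record stores, per
    individual, chromosome and gamete, the genetic crossover positions and the
    gamete's starting allele, so the genotype at any genetic position can be
    reconstructed exactly.
    """

    def __init__(self, markers: pd.DataFrame, codes: np.ndarray,
                 crossovers: dict, map_spec: MapSpec):
        self.markers = markers.reset_index(drop=True)
        self.codes = np.asarray(codes, dtype=np.int8)
        self.crossovers = crossovers
        self.map_spec = map_spec
        if self.codes.shape[0] != len(self.markers):
            raise ValueError("codes/markers shape mismatch")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]

    def genotype_at(self, chrom: str, cm: float) -> np.ndarray:
        """True genotype codes of every individual at an arbitrary cM position."""
        n = self.n_individuals
        out = np.empty(n, dtype=np.int8)
        for i in range(n):
            alleles = 0
            for start_allele, xovers in self.crossovers[i][chrom]:
                flips = int(np.searchsorted(xovers, cm))
                alleles += (start_allele + flips) % 2
            out[i] = alleles
        return out


def sample_crossovers(genetic_length_cm: float, rng, n_gametes: int = 1) -> list[np.ndarray]:
    """Crossover positions (cM) for ``n_gametes`` meiotic products.

    Counts are Poisson(L/100) and positions uniform on (0, L): the
    no-interference model underlying the Haldane map function.
    """
    if genetic_length_cm < 0:
        raise ValueError("genetic length must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    counts = rng.poisson(genetic_length_cm / 100.0, size=n_gametes)
    return [np.sort(rng.uniform(0.0, genetic_length_cm, size=c)) for c in counts]


def draw_marker_positions(map_spec: MapSpec, n_markers: int, seed) -> pd.DataFrame:
    """Draw marker physical positions along the genome from the density profile.

    Markers are apportioned to chromosomes/pieces proportionally to
    density x physical length, placed uniformly within each piece, and sorted.
    """
    rng = np.random.default_rng(seed)
    rows = []
    # weight per chromosome = sum of density*length over its pieces
    weights = []
    piecelists = []
    for chrom in map_spec.chromosomes:
        pieces = map_spec.marker_density.get(chrom.name) or [(0, chrom.length_bp, 1.0)]
        w = sum(p[2] * (p[1] - p[0]) for p in pieces)
        weights.append(w)
        piecelists.append(pieces)
    weights = np.array(weights, dtype=float)
    counts = rng.multinomial(n_markers, weights / weights.sum())
    for chrom, pieces, n_c in zip(map_spec.chromosomes, piecelists, counts):
        pw = np.array([p[2] * (p[1] - p[0]) for p in pieces], dtype=float)
        if pw.sum() == 0:
            continue
        sub = rng.multinomial(n_c, pw / pw.sum())
        pos = np.concatenate([
            rng.uniform(p[0], p[1], size=m) for p, m in zip(pieces, sub)
        ]) if n_c else np.empty(0)
        pos = np.unique(pos.astype(np.int64))
        rows.append(pd.DataFrame({"chrom": chrom.name, "pos": pos}))
    df = pd.concat(rows, ignore_index=True)
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df["sim_chrom"] = df["chrom"]
    df["sim_cm"] = np.nan
    for chrom in map_spec.chromosomes:
        m = df["chrom"] == chrom.name
        df.loc[m, "sim_cm"] = map_spec.phys_to_gen(chrom.name, df.loc[m, "pos"].to_numpy())
    return df


def simulate_f2_genotypes(map_spec: MapSpec, n_individuals: int,
                          markers: pd.DataFrame, seed,
                          distortion: tuple | None = None) -> TrueGenotypeMatrix:
    """Simulate true F2 genotypes at the given markers.

    Each individual is formed from two independent gametes per chromosome;
    a gamete's allele at genetic position g is its starting allele flipped
    once per crossover below g.  Markers carry ``sim_chrom``/``sim_cm``
    columns (added here from chrom/pos if absent) giving the genetic
    coordinates genotypes are drawn at.

    ``distortion`` = (chrom, cm, (w0, w1, w2)) applies viability selection
    at one locus: an individual of genotype g there survives with relative
    fitness w_g (rejected individuals are redrawn), producing segregation
    distortion in the linked region.
    """
    rng = np.random.default_rng(seed)
    if distortion is not None:
        map_spec.chrom(distortion[0])
        w = np.asarray(distortion[2], dtype=float)
        if np.any(w < 0) or w.max() <= 0:
            raise ValueError("fitness weights must be >= 0 with a positive maximum")
        w = w / w.max()
    markers = markers.copy().reset_index(drop=True)
    if "sim_chrom" not in markers:
        markers["sim_chrom"] = markers["chrom"]
    if "sim_cm" not in markers:
        markers["sim_cm"] = np.nan
        for chrom in map_spec.chromosomes:
            m = markers["sim_chrom"] == chrom.name
            markers.loc[m, "sim_cm"] = map_spec.phys_to_gen(
                chrom.name, markers.loc[m, "pos"].to_numpy())
    known = {c.name for c in map_spec.chromosomes}
    if not set(markers["sim_chrom"]).issubset(known):
        raise ValueError("markers reference unknown chromosomes")

    codes = np.zeros((len(markers), n_individuals), dtype=np.int8)
    crossovers: dict[int, dict[str, list]] = {i: {} for i in range(n_individuals)}
    for chrom in map_spec.chromosomes:
        sel = (markers["sim_chrom"] == chrom.name).to_numpy()
        cm = markers.loc[sel, "sim_cm"].to_numpy()
        distorted_here = distortion is not None and distortion[0] == chrom.name
        for i in range(n_individuals):
            while True:
                gametes = []
                alleles = np.zeros(sel.sum(), dtype=np.int8)
                for _ in range(2):
                    xov = sample_crossovers(chrom.length_cm, rng)[0]
                    start = int(rng.integers(0, 2))
                    gametes.append((start, xov))
                    flips = np.searchsorted(xov, cm)
                    alleles += (start + flips) % 2
                if not distorted_here:
                    break
                g = sum((s + int(np.searchsorted(x, distortion[1]))) % 2
                        for s, x in gametes)
                if rng.random() < w[g]:
                    break
            crossovers[i][chrom.name] = gametes
            codes[sel, i] = alleles
    return TrueGenotypeMatrix(markers, codes, crossovers, map_spec)


def simulate_unlinked_f2_codes(n_markers: int, n_individuals: int, seed) -> np.ndarray:
    """True genotype codes at unlinked markers: iid 1:2:1 per marker per
    individual (two independent Bernoulli(1/2) alleles)."""
    rng = np.random.default_rng(seed)
    return rng.binomial(2, 0.5, size=(n_markers, n_individuals)).astype(np.int8)


def apply_sequencing_model(true, depth_model: DepthModel, seed) -> np.ndarray:
    """Push true genotypes through the low-depth read-sampling caller.

    Depth k is drawn per marker per individual; k=0 yields missing.  For a
    heterozygote the k read alleles are iid uniform over the two parental
    alleles, and the call is heterozygous only if both alleles are seen --
    hence the miscall probability 2*(1/2)**k = 1/2**(k-1).  Homozygotes are
    read correctly apart from per-read errors at rate ``base_error``.
    ``true`` is a TrueGenotypeMatrix or a bare code matrix.  Returns an int8
    matrix with -1 for missing.
    """
    rng = np.random.default_rng(seed)
    true_codes = true.codes if hasattr(true, "codes") else np.asarray(true, dtype=np.int8)
    shape = true_codes.shape
    if depth_model.mode == "fixed":
        depth = np.full(shape, depth_model.k, dtype=np.int64)
    else:
        depth = rng.poisson(depth_model.lam, size=shape)

    obs = np.full(shape, MISSING, dtype=np.int8)
    covered = depth > 0
    het = (true_codes == 1) & covered
    hom = (true_codes != 1) & covered

    # heterozygote: count of parent-B reads out of k fair draws
    nb = rng.binomial(depth[het], 0.5)
    het_call = np.where(nb == 0, 0, np.where(nb == depth[het], 2, 1)).astype(np.int8)
    obs[het] = het_call

    if depth_model.base_error == 0:
        obs[hom] = true_codes[hom]
    else:
        # per-read flips at base_error; both alleles seen -> spurious het
        nerr = rng.binomial(depth[hom], depth_model.base_error)
        k = depth[hom]
        truth = true_codes[hom]
        call = np.where(nerr == 0, truth,
                        np.where(nerr == k, 2 - truth, 1)).astype(np.int8)
        obs[hom] = call
    return obs


def simulate_f23_phenotypes(true: TrueGenotypeMatrix, qtl: QTLSpec, seed,
                            clip_ordinal: bool = False) -> pd.DataFrame:
    """F2:3 line means under a single-QTL model.

    line mean = mu + x*a + z*d + eps with x in {-1,0,+1} from the F2 parent's
    QTL genotype (+1 = parent-B homozygote) and z = 1/2 for heterozygous F2
    parents: an F3 family from a het segregates 1:2:1, so the family-mean
    dominance deviation is halved.  eps ~ N(0, residual_sd^2).
    """
    rng = np.random.default_rng(seed)
    g = true.genotype_at(qtl.chromosome, qtl.position_cm)
    x = g.astype(float) - 1.0
    z = np.where(g == 1, 0.5, 0.0)
    y = qtl.mu + x * qtl.a + z * qtl.d + rng.normal(0, qtl.residual_sd, size=g.shape)
    if clip_ordinal and qtl.ordinal_max is not None:
        y = np.clip(np.round(y), 0, qtl.ordinal_max)
    return pd.DataFrame({
        "line_id": [f"F{i+1:03d}" for i in range(len(y))],
        "value": y,
        "qtl_genotype": g,
    })


def qtl_pve(a: float, d: float, residual_sd: float) -> float:
    """Model-implied PVE of a QTL on F2:3 line means.

    Var(x) = 1/2 under the 1:2:1 F2 ratio; Var(z*d) = d^2/16 with z in
    {0, 1/2}; so PVE = (a^2/2 + d^2/16) / (a^2/2 + d^2/16 + residual_sd^2).
    """
    gvar = a * a / 2.0 + d * d / 16.0
    return gvar / (gvar + residual_sd * residual_sd)


def additive_effect_for_pve(pve: float, residual_sd: float, d: float = 0.0) -> float:
    """Additive effect giving the requested model PVE at fixed noise (d first)."""
    if not 0 < pve < 1:
        raise ValueError("pve must be in (0,1)")
    gvar = pve / (1 - pve) * residual_sd ** 2
    a2 = 2.0 * (gvar - d * d / 16.0)
    if a2 < 0:
        raise ValueError("dominance effect alone exceeds the requested PVE")
    return float(np.sqrt(a2))


def simulate_misassembly(map_spec: MapSpec, markers: pd.DataFrame,
                         source_chrom: str, segment: tuple[int, int],
                         target_chrom: str, target_cm: float | None = None,
                         truth: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Make a physical segment mis-assembled: genetically on the wrong chromosome.

    Markers whose reported physical coordinates fall inside ``segment`` on
    ``source_chrom`` keep those (wrong) coordinates but have their simulation
    home moved to ``target_chrom`` at ``target_cm`` (default: target mid-point),
    so their genotypes co-segregate with the target chromosome.  The truth
    record retains the correct home for downstream checks.
    """
    start, end = segment
    src = map_spec.chrom(source_chrom)
    map_spec.chrom(target_chrom)
    if not (0 <= start <= end <= src.length_bp):
        raise ValueError("segment outside source chromosome")
    truth = dict(truth or {"segments": []})
    for seg in truth["segments"]:
        if seg["source_chrom"] == source_chrom and not (
                end <= seg["start"] or start >= seg["end"]):
            raise ValueError("overlapping mis-assembly segments")
    out = markers.copy().reset_index(drop=True)
    if "sim_chrom" not in out:
        out["sim_chrom"] = out["chrom"]
        out["sim_cm"] = np.nan
        for chrom in map_spec.chromosomes:
            m = out["sim_chrom"] == chrom.name
            out.loc[m, "sim_cm"] = map_spec.phys_to_gen(
                chrom.name, out.loc[m, "pos"].to_numpy())
    if target_cm is None:
        target_cm = map_spec.chrom(target_chrom).length_cm / 2.0
    hit = ((out["chrom"] == source_chrom) & (out["pos"] >= start)
           & (out["pos"] < end)).to_numpy()
    if hit.any():
        # preserve marker order within the segment on a tight local cM scale
        seg_pos = out.loc[hit, "pos"].to_numpy()
        width_cm = 1e-6
        rel = (seg_pos - start) / max(end - start, 1) * width_cm
        out.loc[hit, "sim_chrom"] = target_chrom
        out.loc[hit, "sim_cm"] = target_cm + rel
    truth["segments"] = truth["segments"] + [{
        "source_chrom": source_chrom, "start": int(start), "end": int(end),
        "target_chrom": target_chrom, "target_cm": float(target_cm),
        "n_markers": int(hit.sum()),
    }]
    return out, truth


DEFAULT_SPEC = MapSpec(
    chromosomes=[ChromSpec(f"chr{i+1}", 80_000_000, 150.0) for i in range(3)],
    recomb_profile={
        f"chr{i+1}": [(0, 20_000_000, 5.0),
                      (20_000_000, 60_000_000, 0.3),
                      (60_000_000, 80_000_000, 6.0)]
        for i in range(3)
    },
    marker_density={
        f"chr{i+1}": [(0, 20_000_000, 3.0),
                      (20_000_000, 60_000_000, 0.5),
                      (60_000_000, 80_000_000, 3.0)]
        for i in range(3)
    },
)


def simulate_dataset(map_spec: MapSpec | None = None, n_individuals: int = 200,
                     n_markers: int = 20_000, depth_model: DepthModel | None = None,
                     qtls: list[QTLSpec] | None = None, seed: int = 0,
                     misassembly: dict | None = None):
    """One-call generator for a complete synthetic study.

    Returns (marker_table, observed_codes, truth) where marker_table carries
    chrom/pos (+ simulation home), observed_codes is the post-sequencing
    genotype matrix, and truth holds the latent genotypes, crossovers,
    phenotypes and any mis-assembly record.
    """
    map_spec = map_spec or DEFAULT_SPEC
    depth_model = depth_model or DepthModel()
    rng = np.random.default_rng(seed)
    markers = draw_marker_positions(map_spec, n_markers, rng.integers(2**31))
    mis_truth = None
    if misassembly:
        markers, mis_truth = simulate_misassembly(
            map_spec, markers, misassembly["source_chrom"],
            (misassembly["start"], misassembly["end"]),
            misassembly["target_chrom"], misassembly.get("target_cm"))
    true = simulate_f2_genotypes(map_spec, n_individuals, markers,
                                 rng.integers(2**31))
    observed = apply_sequencing_model(true, depth_model, rng.integers(2**31))
    phenos = {}
    for i, q in enumerate(qtls or []):
        key = f"trait{i+1}_{q.chromosome}:{q.position_cm}"
        phenos[key] = simulate_f23_phenotypes(true, q, rng.integers(2**31))
    truth = {"true": true, "phenotypes": phenos, "misassembly": mis_truth}
    return true.markers, observed, truth


def write_truth_json(path, truth: dict) -> None:
    """Serialize the portable part of a truth record (crossovers, QTL
    genotypes, mis-assembly) to JSON."""
    true: TrueGenotypeMatrix = truth["true"]
    payload = {
        "misassembly": truth.get("misassembly"),
        "crossovers": {
            str(i): {c: [[s, list(map(float, x))] for s, x in g]
                     for c, g in true.crossovers[i].items()}
            for i in range(true.n_individuals)
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
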