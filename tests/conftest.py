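import numpy as np
import pandas as pd
import pytest

from binmap import bins as bins_mod
from binmap import linkage, markers, simulate, windows


def make_bin(bin_id, chrom, start, end, genotypes, step=10_000):
    return bins_mod.Bin(
        id=bin_id, chrom=chrom, start=int(start), end=int(end),
        anchors=np.arange(start + step // 2, end, step),
        genotypes=np.asarray(genotypes, dtype=np.int8),
    )


def bin_level_map(seed, n_individuals=172, n_chrom=3, length_cm=150.0,
                  n_bins_per_chrom=150, length_bp=100_000_000):
    """Simulate true F2 genotypes at evenly spaced loci and treat each locus
    as a recombination bin; build the genetic map from them.

    A fast stand-in for the full window/bin pipeline when only the map and
    genotypes matter (QTL analyses, null simulations).
    """
    spec = simulate.MapSpec([
        simulate.ChromSpec(f"c{i+1}", length_bp, length_cm)
        for i in range(n_chrom)
    ])
    frames = [pd.DataFrame({
        "chrom": f"c{i+1}",
        "pos": np.linspace(0, length_bp, n_bins_per_chrom + 1).astype(np.int64),
    }) for i in range(n_chrom)]
    mk = pd.concat(frames, ignore_index=True)
    true = simulate.simulate_f2_genotypes(spec, n_individuals, mk, seed)
    bin_list = [
        make_bin(f"b{j}", mk["chrom"].iloc[j], mk["pos"].iloc[j],
                 mk["pos"].iloc[j] + 10_000, true.codes[j].copy())
        for j in range(len(mk))
    ]
    gmap = linkage.build_map(bin_list)
    return spec, true, gmap


def run_pipeline(seed, n_individuals=200, n_markers=20_000, depth_k=2,
                 misassembly=None, map_spec=None):
    """Full pipeline on a synthetic genome: simulate -> window scan ->
    bin partition -> distortion filter -> map construction."""
    spec = map_spec or simulate.DEFAULT_SPEC
    table, observed, truth = simulate.simulate_dataset(
        spec, n_individuals, n_markers,
        simulate.DepthModel("fixed", k=depth_k), seed=seed,
        misassembly=misassembly)
    ids = [f"F{i+1:03d}" for i in range(n_individuals)]
    mm = markers.MarkerMatrix(table[["chrom", "pos"]], observed, ids)
    lengths = {c.name: c.length_bp for c in spec.chromosomes}
    tracks = windows.scan_genome(mm, lengths)
    all_bins = []
    for track in tracks.values():
        all_bins.extend(bins_mod.partition_bins(track))
    kept = bins_mod.filter_distorted(all_bins)
    # build_map corrects/merges in place: give it copies so the bin tables
    # above stay pristine
    import copy
    gmap = linkage.build_map(copy.deepcopy(kept))
    return {"spec": spec, "markers": table, "observed": observed,
            "truth": truth, "matrix": mm, "tracks": tracks,
            "bins": all_bins, "kept": kept, "map": gmap,
            "chrom_lengths": lengths}


@pytest.fixture(scope="session")
def pipeline_run():
    """One shared end-to-end run of the default synthetic study."""
    return run_pipeline(seed=2024)
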