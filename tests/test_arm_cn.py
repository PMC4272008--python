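"""Arm/chromosome CN calling against a normalizer reference set."""

import numpy as np
import pytest

from sccnv.arm_cn import build_normalizer, call_arm_cn
from sccnv.profile import SampleProfile
from sccnv.qc import mapd
from sccnv.simulate import (CNVTruth, noise_for_binmap, simulate_bin_counts,
                            simulate_population)


def _profile(bm, counts, sample="s"):
    counts = np.asarray(counts)
    return SampleProfile(sample, counts, counts == 0)


def _uniform_counts(bm, per_bin=800):
    return np.full(len(bm), per_bin)


def test_single_reference_equals_its_own_fractions(hg_map):
    bm, _, arms = hg_map
    prof = _profile(bm, _uniform_counts(bm))
    nz1 = build_normalizer([prof], bm, arms)
    nz2 = build_normalizer([prof, prof, prof], bm, arms)  # median idempotent
    assert np.allclose(nz1.table["ref_fraction"], nz2.table["ref_fraction"])
    assert nz1.table["ref_fraction"].sum() == pytest.approx(2.0)  # arms + chroms


def test_normalizer_recovers_generative_weights(hg_map):
    bm, _, arms = hg_map
    nm = noise_for_binmap("bulk", bm, gc_bias=False)
    refs = [simulate_bin_counts(bm, CNVTruth(), [], nm, seed=i).to_profile(bm)
            for i in range(5)]
    nz = build_normalizer(refs, bm, arms)
    w = bm.df["n_mappable"].to_numpy(float)
    w = w / w.sum()
    chroms = bm.df["chrom"].to_numpy()
    for chrom in ("chr1", "chr18"):
        truth_frac = w[chroms == chrom].sum()
        got = nz.table[(nz.table["chrom"] == chrom) &
                       (nz.table["arm"] == "*")]["ref_fraction"].iloc[0]
        assert got == pytest.approx(truth_frac, rel=0.02)


def test_sample_identical_to_normalizer_is_diploid(hg_map):
    bm, _, arms = hg_map
    prof = _profile(bm, _uniform_counts(bm))
    nz = build_normalizer([prof], bm, arms)
    res = call_arm_cn(prof, nz, bm, arms, "female")
    autos = res.table[res.table["chrom"] != "chrX"]
    assert (autos["cn_int"] == 2).all()


def test_call_is_depth_invariant(hg_map):
    bm, _, arms = hg_map
    nz = build_normalizer([_profile(bm, _uniform_counts(bm))], bm, arms)
    counts = np.random.default_rng(0).poisson(500, len(bm))
    a = call_arm_cn(_profile(bm, counts), nz, bm, arms).table["cn_float"]
    b = call_arm_cn(_profile(bm, counts * 9), nz, bm, arms).table["cn_float"]
    assert np.allclose(a, b)


def test_simulated_trisomy_called_cn3(hg_map):
    bm, _, arms = hg_map
    nm = noise_for_binmap("mda_like", bm)
    L18 = int(bm.df[bm.df["chrom"] == "chr18"]["end"].max())
    truth = CNVTruth().add("chr18", 0, L18, 3)
    refs = [simulate_bin_counts(bm, CNVTruth(), [], nm, seed=50 + i,
                                sample_id=f"ref{i}").to_profile(bm)
            for i in range(5)]
    nz = build_normalizer(refs, bm, arms)
    cns = []
    tried = kept = 0
    while kept < 9:
        tried += 1
        cell = simulate_bin_counts(bm, truth, [True], nm, seed=200 + tried)
        prof = cell.to_profile(bm)
        if not mapd(prof, bm).passed:
            continue
        kept += 1
        res = call_arm_cn(prof, nz, bm, arms, "female")
        cns.append(res.chrom_cn("chr18")["cn_float"])
        others = res.table[(res.table["arm"] == "*") &
                           (res.table["chrom"] != "chr18") &
                           (res.table["chrom"] != "chrX")]
        assert (others["cn_int"] == 2).mean() > 0.9
    assert all(round(c) == 3 for c in cns)
    assert np.mean(cns) == pytest.approx(3.0, abs=0.15)


def test_male_x_called_single_copy(hg_map):
    bm, _, arms = hg_map
    chroms = bm.df["chrom"].to_numpy()
    female = _uniform_counts(bm)
    nz = build_normalizer([_profile(bm, female)], bm, arms, ref_sex="female")
    male = female.copy()
    male[chroms == "chrX"] = 400  # X at half autosomal depth
    res = call_arm_cn(_profile(bm, male), nz, bm, arms, "male")
    x_arms = res.table[(res.table["chrom"] == "chrX") &
                       (res.table["arm"] != "*")]
    assert (x_arms["cn_int"] == 1).all()


@pytest.mark.parametrize("fraction,expected", [(0.0, 2.0), (0.3, 2.6), (1.0, 4.0)])
def test_pool_cn_is_cell_fraction_weighted(hg_map, fraction, expected):
    bm, _, arms = hg_map
    nm = noise_for_binmap("mda_like", bm)
    nz = build_normalizer(
        [simulate_bin_counts(bm, CNVTruth(), [], nm, seed=77 + i).to_profile(bm)
         for i in range(3)], bm, arms)
    truth = CNVTruth()
    if fraction > 0:
        truth.add("chr1", 125_000_000, 249_250_000, 4, cell_fraction=fraction)
    _, pools = simulate_population(0, truth, nm, bm, pool_sizes=[100], seed=9)
    res = call_arm_cn(pools[0].to_profile(bm), nz, bm, arms, pool=True)
    q = res.table[(res.table["chrom"] == "chr1") & (res.table["arm"] == "q")]
    assert q["cn_float"].iloc[0] == pytest.approx(expected, abs=0.25)
    assert np.isnan(q["cn_int"].iloc[0])


def test_integer_cn_recovery_across_cells(hg_map_small):
    """CN in {1,2,3,4} per arm recovered >=95% under MDA-like noise with QC."""
    bm, _, arms = hg_map_small
    nm = noise_for_binmap("mda_like", bm)
    nz = build_normalizer(
        [simulate_bin_counts(bm, CNVTruth(), [], nm, seed=300 + i).to_profile(bm)
         for i in range(5)], bm, arms)
    L2 = int(bm.df[bm.df["chrom"] == "chr2"]["end"].max())
    L7 = int(bm.df[bm.df["chrom"] == "chr7"]["end"].max())
    correct = total = 0
    seed = 0
    while total < 60:
        seed += 1
        truth = CNVTruth()
        want = {"chr2": 2, "chr7": 2}
        if seed % 4 in (1, 2):
            want["chr2"] = [1, 3][seed % 2]
            truth.add("chr2", 0, L2, want["chr2"])
        if seed % 4 in (2, 3):
            want["chr7"] = 4 if seed % 3 else 1
            truth.add("chr7", 0, L7, want["chr7"])
        cell = simulate_bin_counts(bm, truth, [True] * len(truth.events), nm,
                                   seed=4000 + seed)
        prof = cell.to_profile(bm)
        if not mapd(prof, bm).passed:
            continue
        res = call_arm_cn(prof, nz, bm, arms, "female")
        for chrom, cn in want.items():
            total += 1
            if res.chrom_cn(chrom)["cn_int"] == cn:
                correct += 1
    assert correct / total >= 0.95
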