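"""Circular binary segmentation: oracle equivalence, detection, null control."""

import numpy as np
import pytest
from scipy.stats import ttest_ind

from sccnv.cbs import (CBSParams, cbs_segment, lag1_sd, max_t_statistic,
                       segment_sample)
from sccnv.profile import SampleProfile
from conftest import toy_binmap


def brute_force_max_t(x, min_width):
    """Independent oracle: scipy two-sample t over every circular arc."""
    n = len(x)
    best = (-np.inf, None, None)
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            arc = x[i:j]
            rest = np.concatenate([x[:i], x[j:]])
            t = abs(ttest_ind(arc, rest, equal_var=True).statistic)
            if t > best[0] + 1e-9:
                best = (t, i, j)
    return best


def test_constant_vector_single_segment():
    segs = cbs_segment(np.full(100, 0.3))
    assert segs == [(0, 99, pytest.approx(0.3))]


def test_short_vector_never_split():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 8)  # 8 < 2 * min_width
    segs = cbs_segment(x, CBSParams(min_width=5))
    assert len(segs) == 1
    assert segs[0][2] == pytest.approx(x.mean())


def test_rejects_non_finite_input():
    with pytest.raises(ValueError):
        cbs_segment(np.array([0.0, np.nan, 1.0] * 10))


def test_max_t_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    for n in (12, 20, 30):
        x = rng.normal(0, 1, n)
        x[n // 2:] += 1.5
        t2, i, j = max_t_statistic(x, 5)
        t_oracle, i_o, j_o = brute_force_max_t(x, 5)
        assert np.sqrt(t2) == pytest.approx(t_oracle, rel=1e-9)
        assert (i, j) == (i_o, j_o)


def test_planted_changepoint_selection_equals_bruteforce():
    """Whenever a split is made, the arc chosen is the brute-force max-t arc."""
    rng = np.random.default_rng(8)
    made = 0
    for _ in range(20):
        n = 24
        cp = int(rng.integers(8, 16))
        x = rng.normal(0, 0.3, n)
        x[cp:] += 1.0
        t2, i, j = max_t_statistic(x, 5)
        t_o, i_o, j_o = brute_force_max_t(x, 5)
        assert np.sqrt(t2) == pytest.approx(t_o, rel=1e-9)
        assert (i, j) == (i_o, j_o)
        segs = cbs_segment(x, CBSParams(min_width=5, nperm=500, seed=1))
        if len(segs) > 1:
            made += 1
            # the first breakpoint set contains the oracle's split points
            bps = {s for s, _, _ in segs[1:]}
            oracle_bps = {b for b in (i_o, j_o) if 0 < b < n}
            assert oracle_bps & bps
    assert made >= 15


def test_step_vector_detection_rate():
    """50+50 step of height 1 at noise sd 0.1 is essentially always split,
    and the clean two-segment solution (breakpoint within +/-2 bins of the
    brute-force maximal split, means near {0,1}) dominates; occasional extra
    splits reflect the alpha=0.02 per-interval false-split rate."""
    split = clean = 0
    n_seeds = 100
    for s in range(n_seeds):
        rng = np.random.default_rng(1000 + s)
        x = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(1, 0.1, 50)])
        segs = cbs_segment(x, CBSParams(seed=s))
        if len(segs) > 1:
            split += 1
        if len(segs) == 2:
            _, i_o, j_o = brute_force_max_t(x, 5)
            oracle_bp = i_o if i_o > 0 else j_o
            if abs(segs[1][0] - oracle_bp) <= 2 and abs(segs[0][2]) < 0.06 \
                    and abs(segs[1][2] - 1) < 0.06:
                clean += 1
    assert split >= 99
    assert clean >= 90


def test_type_i_error_controlled_under_null():
    """On pure noise the per-chromosome split rate stays near alpha."""
    alpha = 0.05
    n_chroms = 60
    splits = 0
    params = CBSParams(alpha=alpha, nperm=200, undo_splits="none", seed=7)
    for c in range(n_chroms):
        rng = np.random.default_rng(5000 + c)
        segs = cbs_segment(rng.normal(0, 1, 60), params, chrom_idx=c)
        if len(segs) > 1:
            splits += 1
    bound = alpha * n_chroms + 2 * np.sqrt(n_chroms * alpha * (1 - alpha))
    assert splits <= bound


def test_sd_undo_removes_marginal_breakpoints():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 0.2, 80)
    x[40:] += 0.1  # well below 1 sd: should be undone even if split
    with_undo = cbs_segment(x, CBSParams(seed=3, undo_splits="sdundo"))
    assert len(with_undo) == 1
    # a 5-sd step survives undo
    y = rng.normal(0, 0.2, 80)
    y[40:] += 1.0
    segs = cbs_segment(y, CBSParams(seed=3))
    assert len(segs) == 2


def test_determinism_same_seed_same_segments():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 0.3, 120)
    x[30:50] += 0.8
    a = cbs_segment(x, CBSParams(seed=11))
    b = cbs_segment(x, CBSParams(seed=11))
    assert a == b


def test_segment_sample_partition_and_mean_properties(hg_map):
    bm, _, _ = hg_map
    rng = np.random.default_rng(6)
    n = len(bm)
    log2 = rng.normal(0, 0.15, n)
    sl = bm.chrom_slices()["chr3"]
    log2[sl.start + 40 : sl.start + 50] += 0.585  # spiked 10-bin gain
    prof = SampleProfile("s", np.full(n, 800), np.zeros(n, bool))
    prof.ncnr = 2.0 ** log2
    prof.log2_ncnr = log2
    segset = segment_sample(prof, bm, CBSParams(seed=2))
    df = segset.df
    # partition: per chromosome, segments tile [chrom start, chrom end]
    for chrom, sub in df.groupby("chrom", sort=False):
        csl = bm.chrom_slices()[chrom]
        assert sub["start_bp"].iloc[0] == bm.df["start"].iloc[csl.start]
        assert sub["end_bp"].iloc[-1] == bm.df["end"].iloc[csl.stop - 1]
        assert (sub["start_bp"].to_numpy()[1:] == sub["end_bp"].to_numpy()[:-1]).all()
    # mean property: seg_mean equals the mean of member unmasked values
    for row in df.itertuples(index=False):
        vals = log2[row.start_bin : row.end_bin + 1]
        assert row.seg_mean == pytest.approx(vals.mean(), abs=1e-9)
    # exactly one chromosome carries extra segments
    seg_counts = df.groupby("chrom").size()
    assert seg_counts["chr3"] == 3
    assert (seg_counts.drop("chr3") == 1).sum() >= len(seg_counts) - 3


def test_lag1_sd_estimates_noise_despite_steps():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 0.2, 400)
    x[200:] += 5.0
    assert lag1_sd(x) == pytest.approx(0.2, rel=0.15)
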