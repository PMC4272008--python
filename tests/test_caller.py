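"""Five-criteria CNV calling, clonal sharing, and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from sccnv.caller import (CallingParams, call_cnvs, find_clonal, sharing_null)
from sccnv.cbs import SegmentSet
from sccnv.genome import CentromereTable
from conftest import toy_binmap


def _segset(means, n_bins_list, bin_size=460_000, sample="s1", chrom="chr1"):
    starts_bin = np.concatenate([[0], np.cumsum(n_bins_list)[:-1]])
    rows = []
    for mean, nb, sb in zip(means, n_bins_list, starts_bin):
        rows.append({
            "chrom": chrom, "start_bin": int(sb), "end_bin": int(sb + nb - 1),
            "n_bins": int(nb), "seg_mean": mean,
            "start_bp": int(sb * bin_size), "end_bp": int((sb + nb) * bin_size),
        })
    return SegmentSet(sample, pd.DataFrame(rows))


WORKED = dict(means=[0.0, 0.585, 0.0], n_bins=[10, 5, 15])


def test_worked_example_one_cn3_gain():
    """Means {0, 0.585, 0}, 5-bin/2.3 Mb event: MAD 0, s 0.338, Phi 0.958."""
    segs = _segset(WORKED["means"], WORKED["n_bins"])
    calls = call_cnvs(segs, toy_binmap(30), CentromereTable([]))
    assert len(calls) == 1
    c = calls.iloc[0]
    assert c["direction"] == "gain"
    assert c["seg_dist"] == pytest.approx(0.585)
    assert c["z_cdf"] == pytest.approx(norm.cdf(0.585 / np.std([0, 0.585, 0], ddof=1)))
    assert c["z_cdf"] == pytest.approx(0.9584, abs=2e-4)
    assert c["cn_int"] == 3 and not c["equivocal"]


def test_three_bin_event_fails_span_criterion():
    segs = _segset([0.0, 0.585, 0.0], [10, 3, 15])
    calls = call_cnvs(segs, toy_binmap(28), CentromereTable([]))
    assert calls.empty


def test_sub_megabase_event_fails_size_criterion():
    segs = _segset([0.0, 0.585, 0.0], [10, 5, 15], bin_size=150_000)
    calls = call_cnvs(segs, toy_binmap(30, bin_size=150_000), CentromereTable([]))
    assert calls.empty


def test_centromere_overlap_filters_call():
    segs = _segset(WORKED["means"], WORKED["n_bins"])
    # event spans bp [4.6 Mb, 6.9 Mb); centromere overlapping by 1 bp kills it
    cens = CentromereTable([("chr1", 6_899_999, 7_100_000)])
    assert call_cnvs(segs, toy_binmap(30), cens).empty
    clear = CentromereTable([("chr1", 6_900_000, 7_100_000)])
    assert len(call_cnvs(segs, toy_binmap(30), clear)) == 1


def test_z_criterion_identical_to_one_tail_pvalue_form():
    """Phi(d/s) >= 0.9 is the same rule as upper-tail p = 1-Phi(d/s) < 0.1."""
    segs = _segset([0.0, 0.3, -0.1, 0.585, 0.05], [10, 6, 8, 5, 10])
    means = np.array([0.0, 0.3, -0.1, 0.585, 0.05])
    M = np.median(means)
    s = np.std(means, ddof=1)
    dist = np.abs(means - M)
    by_cdf = norm.cdf(dist / s) >= 0.9
    by_pval = (1 - norm.cdf(dist / s)) < 0.1
    assert (by_cdf == by_pval).all()
    calls = call_cnvs(segs, toy_binmap(39), CentromereTable([]))
    for row in calls.itertuples(index=False):
        assert row.z_cdf >= 0.9


def test_call_count_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    means = rng.normal(0, 0.2, 12).tolist() + [0.7, -0.8]
    nb = [6] * 14
    segs = _segset(means, nb)
    bm = toy_binmap(sum(nb))
    base = len(call_cnvs(segs, bm, CentromereTable([]), CallingParams()))
    for params in (CallingParams(mad_multiplier=3),
                   CallingParams(z_cdf_threshold=0.95),
                   CallingParams(min_bins=7),
                   CallingParams(min_size_bp=3_000_000)):
        assert len(call_cnvs(segs, bm, CentromereTable([]), params)) <= base


def test_calls_satisfy_all_criteria_post_hoc():
    rng = np.random.default_rng(1)
    means = rng.normal(0, 0.25, 20)
    segs = _segset(means.tolist(), [6] * 20)
    params = CallingParams()
    calls = call_cnvs(segs, toy_binmap(120), CentromereTable([]), params)
    M = np.median(means)
    mad = np.median(np.abs(means - M))
    s = np.std(means, ddof=1)
    for row in calls.itertuples(index=False):
        assert row.seg_dist >= params.mad_multiplier * mad
        assert norm.cdf(row.seg_dist / s) >= params.z_cdf_threshold
        assert row.n_bins >= params.min_bins
        assert row.size_bp >= params.min_size_bp


def test_degenerate_zero_spread_segments():
    segs = _segset([0.0, 0.0, 0.0], [10, 10, 10])
    assert call_cnvs(segs, toy_binmap(30), CentromereTable([])).empty


def test_male_sex_compartment_separate():
    df1 = _segset([0.0, 0.585, 0.0], [10, 5, 15], chrom="chr1").df
    dfx = _segset([0.0, 0.0, 1.0], [10, 10, 10], chrom="chrX").df
    segs = SegmentSet("s1", pd.concat([df1, dfx], ignore_index=True))
    calls = call_cnvs(segs, toy_binmap(60), CentromereTable([]),
                      sample_sex="male")
    autos = calls[calls["compartment"] == "autosomal"]
    assert set(autos["chrom"]) == {"chr1"}
    sex = calls[calls["compartment"] == "sex"]
    assert len(sex) == 1
    row = sex.iloc[0]
    # male sex baseline is 1 copy; X median is 0, so 2^1 rounds to CN 2
    assert row["chrom"] == "chrX" and row["cn_int"] == 2


# --- clonal sharing ---------------------------------------------------------


def _call_row(sample, chrom, b0, b1, direction, bin_size=460_000):
    return {
        "sample_id": sample, "chrom": chrom, "start_bp": b0 * bin_size,
        "end_bp": (b1 + 1) * bin_size, "size_bp": (b1 - b0 + 1) * bin_size,
        "n_bins": b1 - b0 + 1, "start_bin": b0, "end_bin": b1,
        "direction": direction, "seg_mean": 0.6 if direction == "gain" else -1.0,
        "seg_dist": 0.6, "z_cdf": 0.99, "cn_int": 3 if direction == "gain" else 1,
        "compartment": "autosomal", "equivocal": False,
    }


def test_two_bin_overlap_defines_clonal_event(small_binmap):
    calls = pd.DataFrame([_call_row("a", "chr1", 5, 10, "loss"),
                          _call_row("b", "chr1", 9, 14, "loss")])
    events = find_clonal(calls, small_binmap)
    assert len(events) == 1
    ev = events[0]
    assert ev.n_shared_bins == 2 and ev.samples == ["a", "b"]
    assert ev.direction == "loss"


def test_one_bin_overlap_is_not_clonal(small_binmap):
    calls = pd.DataFrame([_call_row("a", "chr1", 5, 10, "loss"),
                          _call_row("b", "chr1", 10, 14, "loss")])
    assert find_clonal(calls, small_binmap) == []


def test_opposite_directions_never_clonal(small_binmap):
    calls = pd.DataFrame([_call_row("a", "chr1", 5, 10, "gain"),
                          _call_row("b", "chr1", 6, 11, "loss")])
    assert find_clonal(calls, small_binmap) == []


def test_same_sample_overlap_not_clonal(small_binmap):
    calls = pd.DataFrame([_call_row("a", "chr1", 5, 10, "loss"),
                          _call_row("a", "chr1", 6, 11, "loss")])
    assert find_clonal(calls, small_binmap) == []


def test_sharing_null_identical_calls_small_p(hg_map):
    bm, _, _ = hg_map
    calls = pd.DataFrame([_call_row("a", "chr2", 600, 605, "gain"),
                          _call_row("b", "chr2", 600, 605, "gain")])
    p = sharing_null(calls, bm, n_perm=200, seed=1)
    assert p <= 1 / 200


def test_sharing_null_matches_analytic_overlap_probability(hg_map):
    """Two random 5-bin calls: chance of a >=2-bin overlap is tiny and known.

    With one observed clonal event, the permutation p-value estimates the
    probability that two uniformly re-placed length-5 calls overlap in >= 2
    bins: 7 relative offsets out of ~total_slots placements, ~0.0012 on a
    6,000-bin genome.
    """
    bm, _, _ = hg_map
    calls = pd.DataFrame([_call_row("a", "chr2", 600, 604, "gain"),
                          _call_row("b", "chr2", 602, 606, "gain")])
    slots = {c: sl.stop - sl.start - 4 for c, sl in bm.chrom_slices().items()}
    p_analytic = 7 / sum(slots.values())
    p_emp = sharing_null(calls, bm, n_perm=1000, seed=5)
    assert 1 / 1001 <= p_emp <= 6 * p_analytic  # Monte-Carlo band around 0.0012


def test_sharing_null_no_second_sample_gives_p1(hg_map):
    bm, _, _ = hg_map
    calls = pd.DataFrame([_call_row("a", "chr2", 600, 605, "gain")])
    assert sharing_null(calls, bm, n_perm=50, seed=1) == 1.0
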