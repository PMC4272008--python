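"""Rule-based CNV calling on CBS segments, and clonal-event detection.

A segment j is called a CNV when, within its compartment (autosomes; for
male samples the sex chromosomes form a separate compartment), with
M = median segment mean and Seg.dist_j = |Seg.mean_j - M|:

1. Seg.dist_j >= 2 * MAD, where MAD is the median of Seg.dist over segments;
2. Phi(Seg.dist_j / sd(Seg.mean)) >= 0.9 (equivalently the one-tail Z-test
   p-value is < 0.1), with sd the n-1 sample SD of segment means;
3. the segment spans >= 4 genomic bins;
4. the segment spans >= 1 Mb;
5. the segment does not overlap an annotated centromere.

Called segments get an integer CN: round(baseline * 2^(Seg.mean - M)) with
baseline 2 for autosomes and the female X, 1 per sex chromosome copy for
males.  Calls rounding back to baseline are retained but flagged equivocal.
Clonal events are same-direction calls from different samples sharing at
least two genomic bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .arm_cn import _is_sex
from .cbs import SegmentSet
from .genome import BinMap, CentromereTable


@dataclass
class CallingParams:
    mad_multiplier: float = 2.0
    z_cdf_threshold: float = 0.9
    min_bins: int = 4
    min_size_bp: int = 1_000_000
    centromere_filter: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.z_cdf_threshold < 1:
            raise ValueError("z_cdf_threshold must be in (0.5, 1)")
        if min(self.mad_multiplier, self.min_bins, self.min_size_bp) <= 0:
            raise ValueError("calling parameters must be positive")


CALL_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "size_bp",
                "n_bins", "start_bin", "end_bin", "direction", "seg_mean",
                "seg_dist", "z_cdf", "cn_int", "compartment", "equivocal"]


def _overlaps_centromere(chrom: str, start: int, end: int,
                         centromeres: CentromereTable) -> bool:
    cen = centromeres.get(chrom)
    if cen is None:
        return False
    cs, ce = cen
    return start < ce and cs < end


def call_cnvs(segset: SegmentSet, binmap: BinMap,
              centromeres: CentromereTable | None = None,
              params: CallingParams | None = None,
              sample_sex: str = "unknown") -> pd.DataFrame:
    """Apply the five calling criteria; returns a calls DataFrame."""
    params = params or CallingParams()
    centromeres = centromeres or CentromereTable([])
    df = segset.df
    if df.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    sex_seg = df["chrom"].map(_is_sex).to_numpy()
    split_sex = sample_sex == "male"
    compartments = (
        [("autosomal", ~sex_seg), ("sex", sex_seg)] if split_sex
        else [("autosomal", np.ones(len(df), bool))]
    )
    calls = []
    for comp_name, sel in compartments:
        sub = df[sel]
        if len(sub) < 2:
            continue
        means = sub["seg_mean"].to_numpy(float)
        M = float(np.median(means))
        dist = np.abs(means - M)
        mad = float(np.median(dist))
        s = float(np.std(means, ddof=1))
        if s > 0:
            z_cdf = norm.cdf(dist / s)
        else:
            # degenerate spread: any nonzero distance is infinitely many SDs out
            z_cdf = np.where(dist > 0, 1.0, 0.5)
        baseline = 1.0 if comp_name == "sex" else 2.0
        for row, dist_j, z_j in zip(sub.itertuples(index=False), dist, z_cdf):
            size_bp = row.end_bp - row.start_bp
            if dist_j < params.mad_multiplier * mad:
                continue
            if z_j < params.z_cdf_threshold:
                continue
            if row.n_bins < params.min_bins or size_bp < params.min_size_bp:
                continue
            if params.centromere_filter and _overlaps_centromere(
                    row.chrom, row.start_bp, row.end_bp, centromeres):
                continue
            if dist_j == 0:
                continue  # exactly at the median: no direction, not an event
            cn_float = baseline * 2.0 ** (row.seg_mean - M)
            cn_int = int(np.floor(cn_float + 0.5))
            calls.append({
                "sample_id": segset.sample_id,
                "chrom": row.chrom,
                "start_bp": row.start_bp,
                "end_bp": row.end_bp,
                "size_bp": size_bp,
                "n_bins": row.n_bins,
                "start_bin": row.start_bin,
                "end_bin": row.end_bin,
                "direction": "gain" if row.seg_mean > M else "loss",
                "seg_mean": row.seg_mean,
                "seg_dist": dist_j,
                "z_cdf": float(z_j),
                "cn_int": cn_int,
                "compartment": comp_name,
                "equivocal": cn_int == int(baseline),
            })
    return pd.DataFrame(calls, columns=CALL_COLUMNS)


def write_calls_bed(calls: pd.DataFrame, path: str) -> None:
    """BED6: name = sample:direction, score = round(1000 * z_cdf)."""
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            score = int(round(1000 * row.z_cdf))
            fh.write(f"{row.chrom}\t{row.start_bp}\t{row.end_bp}\t"
                     f"{row.sample_id}:{row.direction}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# clonal events
# ---------------------------------------------------------------------------


@dataclass
class ClonalEvent:
    chrom: str
    start_bp: int
    end_bp: int
    n_shared_bins: int
    direction: str
    samples: list[str]
    member_indices: list[int] = field(default_factory=list)


def _bin_overlap(a, b) -> int:
    """Shared genomic bins between two calls (inclusive bin-index ranges)."""
    if a.chrom != b.chrom:
        return 0
    lo = max(a.start_bin, b.start_bin)
    hi = min(a.end_bin, b.end_bin)
    return max(0, hi - lo + 1)


def find_clonal(calls: pd.DataFrame, binmap: BinMap,
                min_shared_bins: int = 2) -> list[ClonalEvent]:
    """Connected components of same-direction cross-sample calls sharing
    >= ``min_shared_bins`` genomic bins.

    The reported interval is the bounding span of the pairwise shared
    regions within the component (the locus common to the linked pairs).
    """
    recs = list(calls.itertuples(index=False))
    n = len(recs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    links: dict[tuple[int, int], tuple[int, int]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = recs[i], recs[j]
            if a.sample_id == b.sample_id or a.direction != b.direction:
                continue
            ov = _bin_overlap(a, b)
            if ov >= min_shared_bins:
                links[(i, j)] = (max(a.start_bin, b.start_bin),
                                 min(a.end_bin, b.end_bin))
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for (i, j) in links:
        for k in (i, j):
            groups.setdefault(find(k), [])
    for k in range(n):
        root = find(k)
        if root in groups and k not in groups[root]:
            groups[root].append(k)
    starts = binmap.df["start"].to_numpy()
    ends = binmap.df["end"].to_numpy()
    events = []
    for members in groups.values():
        samples = sorted({recs[k].sample_id for k in members})
        if len(samples) < 2:
            continue
        shared = [links[(i, j)] for (i, j) in links
                  if find(i) == find(members[0])]
        lo = min(s for s, _ in shared)
        hi = max(e for _, e in shared)
        events.append(ClonalEvent(
            chrom=recs[members[0]].chrom,
            start_bp=int(starts[lo]),
            end_bp=int(ends[hi]),
            n_shared_bins=hi - lo + 1,
            direction=recs[members[0]].direction,
            samples=samples,
            member_indices=sorted(members),
        ))
    events.sort(key=lambda e: (e.chrom, e.start_bp))
    return events


def clonal_events_frame(events: list[ClonalEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {"chrom": e.chrom, "start_bp": e.start_bp, "end_bp": e.end_bp,
         "n_shared_bins": e.n_shared_bins, "direction": e.direction,
         "n_samples": len(e.samples), "samples": ",".join(e.samples)}
        for e in events
    ], columns=["chrom", "start_bp", "end_bp", "n_shared_bins", "direction",
                "n_samples", "samples"])


def sharing_null(calls: pd.DataFrame, binmap: BinMap, n_perm: int = 1000,
                 seed: int = 0, min_shared_bins: int = 2) -> float:
    """Permutation p-value for the observed number of clonal events.

    Each sample's calls are re-placed uniformly at random as equal-bin-length
    intervals within chromosomes (chromosome chosen with probability
    proportional to the number of valid start bins), preserving per-sample
    call counts, sizes and directions.  p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    samples = calls["sample_id"].unique()
    if len(samples) < 2 or calls.groupby("sample_id").size().min() < 1:
        return 1.0
    obs = len(find_clonal(calls, binmap, min_shared_bins))
    rng = np.random.default_rng(seed)
    chrom_ranges = [(chrom, sl.start, sl.stop)
                    for chrom, sl in binmap.chrom_slices().items()]
    exceed = 0
    for _ in range(n_perm):
        rows = []
        for rec in calls.itertuples(index=False):
            length = rec.end_bin - rec.start_bin + 1
            slots = np.array([max(0, stop - start - length + 1)
                              for _, start, stop in chrom_ranges])
            total = slots.sum()
            if total == 0:
                rows.append(rec._asdict())
                continue
            c = rng.choice(len(chrom_ranges), p=slots / total)
            chrom, start, _ = chrom_ranges[c]
            offset = int(rng.integers(0, slots[c]))
            d = rec._asdict()
            d["chrom"] = chrom
            d["start_bin"] = start + offset
            d["end_bin"] = start + offset + length - 1
            rows.append(d)
        perm_calls = pd.DataFrame(rows)
        if len(find_clonal(perm_calls, binmap, min_shared_bins)) >= obs:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)
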