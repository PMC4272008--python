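"""Circular binary segmentation (CBS) with permutation p-values and sd-undo.

CBS recursively splits a chromosome's log2 copy-number-ratio vector.  The
interval under test is treated as a circle; every arc whose length and
complement are both >= ``min_width`` is scored with the absolute two-sample
t statistic (pooled variance) comparing arc mean vs complement mean.  The
maximal |t| is referred to a permutation null: the interval's values are
randomly permuted ``nperm`` times and the fraction of permutations whose
maximal |t| reaches the observed one is the p-value.  If p <= alpha the
argmax arc's breakpoints are placed (two for an interior arc, one for an arc
touching the interval edge) and the procedure recurses on the sub-intervals.
Finally "sd-undo" pruning removes breakpoints whose flanking segment means
differ by less than ``undo_sd`` times a robust noise SD estimated from
lag-one differences.

The permutation loop stops early, deterministically, once the exceedance
count is larger than alpha * nperm: the count only grows with further
permutations, so the accept/reject decision at level alpha is already that
of the full run.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinMap
from .profile import SampleProfile

_EPS = 1e-12


@dataclass
class CBSParams:
    alpha: float = 0.02
    nperm: int = 1000
    undo_splits: str = "sdundo"  # or "none"
    undo_sd: float = 1.0
    min_width: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.nperm < 100:
            raise ValueError("nperm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class SegmentSet:
    """Ordered segments per chromosome; partitions each chromosome's bins.

    ``df`` columns: chrom, start_bin, end_bin (inclusive bin-row indices into
    the bin map), n_bins (unmasked bins in the segment), seg_mean (mean
    log2 nCNR over unmasked member bins), start_bp, end_bp.
    """

    sample_id: str
    df: pd.DataFrame
    params: CBSParams = field(default_factory=CBSParams)
    noise_sd_estimate: float = float("nan")

    def __len__(self) -> int:
        return len(self.df)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\talpha={self.params.alpha}\t"
                     f"nperm={self.params.nperm}\tundo_sd={self.params.undo_sd}\t"
                     f"min_width={self.params.min_width}\tseed={self.params.seed}\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str) -> "SegmentSet":
        sample_id = path
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for kv in first[1:].strip().split("\t"):
                    key, _, val = kv.partition("=")
                    if key == "sample_id":
                        sample_id = val
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(sample_id, df)


# ---------------------------------------------------------------------------
# max-t statistic over circular arcs
# ---------------------------------------------------------------------------


def _t2_for_arcs(S: np.ndarray, Q: np.ndarray, n: int, k: int) -> np.ndarray:
    """Squared t for all arcs of length k.  S: (B, n+1) prefix sums, Q: (B,)."""
    m = n - k
    A = S[:, k:] - S[:, :-k]  # (B, n-k+1) arc sums, start i = 0..n-k
    tot = S[:, -1:]
    B_sum = tot - A
    d = A / k - B_sum / m
    ssw = Q[:, None] - A * A / k - B_sum * B_sum / m
    denom = np.maximum(ssw, _EPS) * ((1.0 / k + 1.0 / m) / max(n - 2, 1))
    return d * d / denom


def max_t_statistic(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Max |t| over valid arcs of one vector; returns (t2, i, j) for arc (i, j].

    Ties broken by smallest i, then smallest j.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])[None, :]
    Q = np.array([float(np.dot(x, x))])
    best_t2, best_i, best_j = -np.inf, -1, -1
    for k in range(min_width, n - min_width + 1):
        t2 = _t2_for_arcs(S, Q, n, k)[0]
        top = float(t2.max())
        # complementary arcs share |t| exactly in theory but not in floats:
        # break ties (within relative tolerance) toward the smallest (i, j)
        tol = 1e-9 * (1.0 + abs(top))
        idx = int(np.flatnonzero(t2 >= top - tol)[0])
        val = float(t2[idx])
        i, j = idx, idx + k
        if val > best_t2 + 1e-9 * (1.0 + abs(val)) or (
            val >= best_t2 - 1e-9 * (1.0 + abs(val)) and (i, j) < (best_i, best_j)
        ):
            best_t2, best_i, best_j = max(val, best_t2), i, j
    return best_t2, best_i, best_j


def _max_t_batch(X: np.ndarray, min_width: int) -> np.ndarray:
    """Max squared t per row of X (B, n) over all valid arcs."""
    B, n = X.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(X, axis=1)], axis=1)
    Q = np.einsum("ij,ij->i", X, X)
    best = np.full(B, -np.inf)
    for k in range(min_width, n - min_width + 1):
        t2 = _t2_for_arcs(S, Q, n, k)
        np.maximum(best, t2.max(axis=1), out=best)
    return best


def _perm_decision(x: np.ndarray, t2_obs: float, params: CBSParams,
                   rng: np.random.Generator) -> tuple[float, bool]:
    """Permutation p-value with deterministic early stopping.

    Returns (p_estimate, significant).  ``significant`` equals the full-run
    decision p <= alpha; the p estimate uses the permutations actually drawn.
    """
    limit = params.alpha * params.nperm
    count, done = 0, 0
    block = 64
    while done < params.nperm:
        b = min(block, params.nperm - done)
        P = rng.permuted(np.broadcast_to(x, (b, len(x))).copy(), axis=1)
        t2s = _max_t_batch(P, params.min_width)
        count += int((t2s >= t2_obs - _EPS).sum())
        done += b
        if count > limit:
            return count / done, False
        block = min(block * 4, 1024)
    return count / params.nperm, count <= limit


def _rng_for_path(params: CBSParams, sample_key: int, chrom_idx: int,
                  path: tuple[int, ...]) -> np.random.Generator:
    ss = np.random.SeedSequence([params.seed, sample_key, chrom_idx, *path])
    return np.random.default_rng(ss)


def _find_breakpoints(x: np.ndarray, params: CBSParams, sample_key: int,
                      chrom_idx: int, lo: int, hi: int,
                      path: tuple[int, ...]) -> list[int]:
    n = hi - lo
    if n < 2 * params.min_width:
        return []
    t2_obs, i, j = max_t_statistic(x[lo:hi], params.min_width)
    if not np.isfinite(t2_obs) or t2_obs <= 0:
        return []
    rng = _rng_for_path(params, sample_key, chrom_idx, path)
    _, significant = _perm_decision(x[lo:hi], t2_obs, params, rng)
    if not significant:
        return []
    cuts = [c for c in (i, j) if 0 < c < n]
    if not cuts:
        return []
    bps = [lo + c for c in cuts]
    bounds = [lo, *bps, hi]
    out = list(bps)
    for child, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        out += _find_breakpoints(x, params, sample_key, chrom_idx, a, b,
                                 path + (child,))
    return sorted(set(out))


def lag1_sd(x: np.ndarray) -> float:
    """Robust noise SD from lag-1 differences: 1.4826 * MAD(diff) / sqrt(2)."""
    d = np.diff(np.asarray(x, dtype=float))
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def _sd_undo(x: np.ndarray, bps: list[int], undo_sd: float, sd: float) -> list[int]:
    """Remove breakpoints whose flanking segment means differ < undo_sd * sd."""
    bps = sorted(bps)
    while bps:
        bounds = [0, *bps, len(x)]
        means = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        gaps = [abs(means[k + 1] - means[k]) for k in range(len(bps))]
        k_min = int(np.argmin(gaps))
        if gaps[k_min] < undo_sd * sd:
            bps.pop(k_min)
        else:
            break
    return bps


def cbs_segment(values: np.ndarray, params: CBSParams | None = None,
                sample_key: int = 0, chrom_idx: int = 0
                ) -> list[tuple[int, int, float]]:
    """Segment one chromosome's unmasked log2 ratios.

    Returns inclusive (start, end, mean) triples over positions of ``values``.
    """
    params = params or CBSParams()
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        return []
    if not np.isfinite(x).all():
        raise ValueError("non-finite values passed to cbs_segment")
    bps = _find_breakpoints(x, params, sample_key, chrom_idx, 0, len(x), ())
    if params.undo_splits == "sdundo" and bps:
        bps = _sd_undo(x, bps, params.undo_sd, lag1_sd(x))
    bounds = [0, *bps, len(x)]
    return [(a, b - 1, float(x[a:b].mean()))
            for a, b in zip(bounds[:-1], bounds[1:])]


def _sample_key(sample_id: str) -> int:
    return zlib.crc32(sample_id.encode("utf-8"))


def segment_sample(profile: SampleProfile, binmap: BinMap,
                   params: CBSParams | None = None) -> SegmentSet:
    """Genome-wide segmentation of a normalized profile, per chromosome.

    Segmentation runs on unmasked bins only; masked bins are assigned to the
    enclosing segment's bp span so segments tile each chromosome.
    """
    params = params or CBSParams()
    if profile.log2_ncnr is None:
        raise ValueError("profile must be GC-normalized before segmentation")
    key = _sample_key(profile.sample_id)
    starts = binmap.df["start"].to_numpy()
    ends = binmap.df["end"].to_numpy()
    rows = []
    noise_sds = []
    for c_idx, (chrom, sl) in enumerate(binmap.chrom_slices().items()):
        rows_idx = np.arange(sl.start, sl.stop)
        keep = ~profile.mask[sl] & np.isfinite(profile.log2_ncnr[sl])
        um = rows_idx[keep]  # bin-map rows of unmasked bins, in order
        if um.size == 0:
            continue
        x = profile.log2_ncnr[um]
        noise_sds.append(lag1_sd(x))
        segs = cbs_segment(x, params, sample_key=key, chrom_idx=c_idx)
        for s_idx, (a, b, mean) in enumerate(segs):
            first_row = int(um[a])
            last_row = int(um[b])
            # tile the chromosome: first segment starts at the chromosome's
            # first bin; each segment ends where the next one's first
            # unmasked bin starts
            start_bp = int(starts[sl.start]) if s_idx == 0 else int(starts[first_row])
            if s_idx + 1 < len(segs):
                next_first = int(um[segs[s_idx + 1][0]])
                end_bp = int(starts[next_first])
                last_row_tiled = next_first - 1
            else:
                end_bp = int(ends[sl.stop - 1])
                last_row_tiled = sl.stop - 1
            rows.append({
                "chrom": chrom,
                "start_bin": sl.start if s_idx == 0 else first_row,
                "end_bin": last_row_tiled,
                "n_bins": b - a + 1,
                "seg_mean": mean,
                "start_bp": start_bp,
                "end_bp": end_bp,
            })
    df = pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin", "n_bins",
                                     "seg_mean", "start_bp", "end_bp"])
    noise = float(np.median(noise_sds)) if noise_sds else float("nan")
    return SegmentSet(profile.sample_id, df, params, noise_sd_estimate=noise)
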