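"""MAPD amplification-quality statistic and sample gating.

MAPD (median absolute pairwise difference) is the median of
|log2 nCNR_{i+1} - log2 nCNR_i| over neighboring bin pairs.  It measures
bin-to-bin amplification noise and, unlike a standard deviation across bins,
is nearly insensitive to real CNVs, which shift a contiguous block of bins
but only touch two adjacent-bin differences.  Samples with MAPD above a
threshold (default 0.45) are excluded from genome-wide CNV calling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import BinMap
from .profile import SampleProfile

DEFAULT_MAPD_THRESHOLD = 0.45


@dataclass
class QCResult:
    sample_id: str
    mapd: float
    n_pairs: int
    threshold: float
    passed: bool


def adjacent_pair_differences(log2_ncnr: np.ndarray, mask: np.ndarray,
                              binmap: BinMap) -> np.ndarray:
    """|log2 nCNR| differences over genomically adjacent unmasked bin pairs.

    Pairs spanning a chromosome boundary or touching a masked bin are
    excluded; a masked bin between two unmasked bins breaks the pair.
    """
    diffs = []
    for sl in binmap.chrom_slices().values():
        vals = log2_ncnr[sl]
        ok = ~mask[sl] & np.isfinite(vals)
        pair_ok = ok[:-1] & ok[1:]
        if pair_ok.any():
            diffs.append(np.abs(np.diff(vals))[pair_ok])
    if not diffs:
        return np.empty(0)
    return np.concatenate(diffs)


def mapd(profile: SampleProfile, binmap: BinMap,
         threshold: float = DEFAULT_MAPD_THRESHOLD) -> QCResult:
    """MAPD of a normalized profile; even pair counts use the midpoint median."""
    if profile.log2_ncnr is None:
        raise ValueError("profile must be GC-normalized before MAPD")
    diffs = adjacent_pair_differences(profile.log2_ncnr, profile.mask, binmap)
    if len(diffs) < 2:
        raise ValueError(
            f"{profile.sample_id}: only {len(diffs)} valid adjacent-bin pairs; "
            "MAPD undefined")
    value = float(np.median(diffs))
    return QCResult(profile.sample_id, value, len(diffs), threshold,
                    value <= threshold)


def mapd_vs_binsize(profiles_by_binmap: list[tuple[SampleProfile, BinMap]],
                    threshold: float = DEFAULT_MAPD_THRESHOLD) -> pd.DataFrame:
    """One QC row per bin map for the same sample counted at several bin sizes.

    Columns: n_bins, mean_reads_per_bin, mapd, n_pairs, passed.
    """
    rows = []
    for prof, bm in profiles_by_binmap:
        res = mapd(prof, bm, threshold)
        keep = prof.unmasked()
        rows.append({
            "sample_id": prof.sample_id,
            "n_bins": len(bm),
            "mean_reads_per_bin": float(prof.rpb[keep].mean()),
            "mapd": res.mapd,
            "n_pairs": res.n_pairs,
            "passed": res.passed,
        })
    return pd.DataFrame(rows)


def poisson_mapd_floor(lam: float) -> float:
    """Closed-form MAPD of a pure-Poisson profile at mean ``lam`` reads/bin.

    Adjacent log2-ratio differences are approximately normal with variance
    2/(lam ln^2 2); the median absolute value of a N(0, s^2) variate is
    0.6745 s.
    """
    return 0.6745 * np.sqrt(2.0 / lam) / np.log(2.0)
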