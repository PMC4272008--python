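"""Per-sample bin-count profiles: read counting, median-ratio and GC
normalization.

The per-bin pipeline is: reads-per-bin RPB_i -> copy-number ratio
CNR_i = RPB_i / median(RPB) -> GC-normalized ratio nCNR_i obtained by
dividing CNR by a robust locally weighted (lowess) fit of CNR on per-bin GC
and re-centering the median at 1.  Downstream stages (MAPD QC, segmentation,
calling) operate on log2 nCNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinMap

GC_FIT_FLOOR = 0.05
MIN_BINS_FOR_FIT = 50
MIN_DISTINCT_GC = 10


@dataclass
class ReadPlacements:
    """Deduplicated 5'-start read placements for one sample."""

    sample_id: str
    chrom: np.ndarray  # dtype object/str
    pos5: np.ndarray  # int
    strand: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.pos5)

    @classmethod
    def from_tsv(cls, path: str, sample_id: str | None = None) -> "ReadPlacements":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "strand"], comment="#")
        return cls(sample_id or path, df["chrom"].to_numpy(),
                   df["pos"].to_numpy(np.int64), df["strand"].to_numpy())

    @classmethod
    def from_alignments(cls, path: str, sample_id: str | None = None) -> "ReadPlacements":
        """Load mapped, primary, non-duplicate alignments from SAM/BAM/CRAM.

        The 5' start is ``reference_start`` for forward reads and
        ``reference_end - 1`` for reverse reads.
        """
        import pysam

        chroms, positions, strands = [], [], []
        with pysam.AlignmentFile(path) as af:
            for aln in af.fetch(until_eof=True):
                if (aln.is_unmapped or aln.is_secondary or aln.is_supplementary
                        or aln.is_duplicate):
                    continue
                chroms.append(aln.reference_name)
                if aln.is_reverse:
                    positions.append(aln.reference_end - 1)
                    strands.append("-")
                else:
                    positions.append(aln.reference_start)
                    strands.append("+")
        return cls(sample_id or path, np.asarray(chroms, dtype=object),
                   np.asarray(positions, dtype=np.int64),
                   np.asarray(strands, dtype=object))


@dataclass
class SampleProfile:
    """Per-bin counts and normalized copy-number ratios for one sample.

    Arrays are aligned with the rows of the bin map. ``mask`` marks bins
    excluded from all statistics (zero-count bins, all-N bins). ``log2_ncnr``
    is NaN on masked bins.
    """

    sample_id: str
    rpb: np.ndarray
    mask: np.ndarray
    cnr: np.ndarray | None = None
    ncnr: np.ndarray | None = None
    log2_ncnr: np.ndarray | None = None
    gc_model: str = ""
    n_dropped_reads: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return int(self.rpb.sum())

    def unmasked(self) -> np.ndarray:
        return ~self.mask

    def to_frame(self, binmap: BinMap) -> pd.DataFrame:
        df = binmap.df[["chrom", "start", "end"]].copy()
        df["rpb"] = self.rpb
        df["cnr"] = self.cnr if self.cnr is not None else np.nan
        df["ncnr"] = self.ncnr if self.ncnr is not None else np.nan
        df["log2_ncnr"] = self.log2_ncnr if self.log2_ncnr is not None else np.nan
        df["mask"] = self.mask.astype(int)
        return df

    def write_tsv(self, binmap: BinMap, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\tgc_model={self.gc_model}\n")
            self.to_frame(binmap).to_csv(fh, sep="\t", index=False,
                                         float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str) -> "SampleProfile":
        sample_id, gc_model = path, ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for kv in first[1:].strip().split("\t"):
                    key, _, val = kv.partition("=")
                    if key == "sample_id":
                        sample_id = val
                    elif key == "gc_model":
                        gc_model = val
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        prof = cls(sample_id, df["rpb"].to_numpy(float),
                   df["mask"].to_numpy(bool), gc_model=gc_model)
        for col in ("cnr", "ncnr", "log2_ncnr"):
            if col in df and df[col].notna().any():
                setattr(prof, col, df[col].to_numpy(float))
        return prof


def count_reads(placements: ReadPlacements, binmap: BinMap) -> SampleProfile:
    """Assign each read to the bin containing its 5' start (strand-free).

    Reads on chromosomes absent from the bin map, or upstream of the first
    bin / past the last bin end of their chromosome, are dropped and tallied
    in ``n_dropped_reads``.
    """
    rpb = np.zeros(len(binmap), dtype=np.int64)
    dropped = 0
    slices = binmap.chrom_slices()
    starts = binmap.df["start"].to_numpy()
    ends = binmap.df["end"].to_numpy()
    chrom_arr = np.asarray(placements.chrom)
    for chrom in pd.unique(chrom_arr):
        pos = placements.pos5[chrom_arr == chrom]
        sl = slices.get(str(chrom))
        if sl is None:
            dropped += len(pos)
            continue
        cs, ce = starts[sl], ends[sl]
        idx = np.searchsorted(cs, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ce[np.clip(idx, 0, len(ce) - 1)])
        dropped += int((~ok).sum())
        np.add.at(rpb, sl.start + idx[ok], 1)
    mask = (rpb == 0) | binmap.df["gc"].isna().to_numpy()
    return SampleProfile(placements.sample_id, rpb, mask,
                         n_dropped_reads=dropped)


def compute_cnr(profile: SampleProfile) -> SampleProfile:
    """CNR_i = RPB_i / median(RPB over unmasked bins)."""
    keep = profile.unmasked()
    if not keep.any():
        raise ValueError(f"{profile.sample_id}: no unmasked bins")
    med = float(np.median(profile.rpb[keep]))
    if med <= 0:
        raise ValueError(f"{profile.sample_id}: zero median reads per bin "
                         "(catastrophic dropout)")
    profile.cnr = profile.rpb / med
    return profile


def _quantile_gc_fit(cnr: np.ndarray, gc: np.ndarray, n_groups: int = 20) -> np.ndarray:
    """Fallback GC model: median CNR within GC-quantile groups."""
    ranks = pd.qcut(gc, q=min(n_groups, len(np.unique(gc))), labels=False,
                    duplicates="drop")
    fitted = np.empty_like(cnr)
    for g in np.unique(ranks):
        sel = ranks == g
        fitted[sel] = np.median(cnr[sel])
    return fitted


def gc_normalize(profile: SampleProfile, binmap: BinMap,
                 span: float = 0.3, robust_iters: int = 2) -> SampleProfile:
    """Divide CNR by a lowess fit of CNR on GC; re-center the median at 1.

    Falls back to GC-quantile median normalization if the lowess fit is
    degenerate (fitted <= 0 on more than 10% of bins), and to the identity if
    there are too few bins or too little GC spread to fit at all.
    """
    if profile.cnr is None:
        raise ValueError("compute_cnr must run before gc_normalize")
    keep = profile.unmasked()
    gc = binmap.df["gc"].to_numpy(float)
    cnr = profile.cnr
    fit_keep = keep & np.isfinite(gc)
    if fit_keep.sum() < MIN_BINS_FOR_FIT or \
            len(np.unique(gc[fit_keep])) < MIN_DISTINCT_GC:
        profile.gc_model = "identity"
        ncnr = cnr.copy()
    else:
        fitted = lowess(cnr[fit_keep], gc[fit_keep], frac=span, it=robust_iters,
                        xvals=gc[fit_keep])
        if (fitted <= 0).mean() > 0.10:
            fitted = _quantile_gc_fit(cnr[fit_keep], gc[fit_keep])
            profile.gc_model = "gc_quantile_median(20)"
        else:
            profile.gc_model = f"lowess(span={span},it={robust_iters})"
        ncnr = cnr.copy()
        ncnr[fit_keep] = cnr[fit_keep] / np.maximum(fitted, GC_FIT_FLOOR)
    med = np.median(ncnr[keep])
    if med <= 0:
        raise ValueError(f"{profile.sample_id}: degenerate normalized profile")
    ncnr = ncnr / med
    profile.ncnr = ncnr
    log2 = np.full_like(ncnr, np.nan)
    pos = keep & (ncnr > 0)
    log2[pos] = np.log2(ncnr[pos])
    profile.log2_ncnr = log2
    return profile


def normalize_counts(rpb: np.ndarray, binmap: BinMap, sample_id: str = "sample",
                     **gc_kwargs) -> SampleProfile:
    """Convenience: bin counts -> fully normalized profile."""
    rpb = np.asarray(rpb)
    mask = (rpb == 0) | binmap.df["gc"].isna().to_numpy()
    prof = SampleProfile(sample_id, rpb.astype(np.int64), mask)
    return gc_normalize(compute_cnr(prof), binmap, **gc_kwargs)
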