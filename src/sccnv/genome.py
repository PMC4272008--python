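"""Reference-genome model: equal-read bins, GC content, centromere/arm tables.

Low-coverage single-cell CNV analysis counts reads in genomic bins that each
contain the same number of uniquely mappable read start positions
("equal-read" bins), so that under uniform coverage every bin has the same
expected count regardless of local mappability.  This module builds such a
bin map from a reference sequence, annotates per-bin GC content, and reads
and writes the associated plain-text tables (bin map TSV, centromere BED).

Coordinates are 0-based half-open throughout, BED style.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")

BINMAP_COLUMNS = ["chrom", "start", "end", "n_mappable", "gc"]


@dataclass
class ReferenceGenome:
    """Ordered set of named chromosome sequences over {A,C,G,T,N}."""

    chromosomes: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, seq in self.chromosomes:
            if not seq:
                raise ValueError(f"empty sequence for {name}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True)
        return cls([(name, str(fa[name][:])) for name in fa.keys()])

    def to_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass
class BinMap:
    """Ordered equal-read bins with mappable-position counts and GC fraction.

    ``df`` columns: chrom, start, end, n_mappable, gc (NaN for all-N bins).
    Bins are sorted by (chromosome order, start), half-open, non-overlapping,
    and never span a chromosome boundary.
    """

    df: pd.DataFrame
    read_length: int
    total_bins_requested: int
    chrom_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.chrom_order:
            self.chrom_order = list(dict.fromkeys(self.df["chrom"]))
        self.validate()

    def validate(self) -> None:
        df = self.df
        if list(df.columns[:5]) != BINMAP_COLUMNS:
            raise ValueError(f"binmap columns must be {BINMAP_COLUMNS}")
        if (df["start"] < 0).any():
            raise ValueError("negative bin start")
        if (df["end"] <= df["start"]).any():
            raise ValueError("bins must have positive length")
        gc = df["gc"].to_numpy(float)
        ok = np.isnan(gc) | ((gc >= 0.0) & (gc <= 1.0))
        if not ok.all():
            raise ValueError("gc outside [0,1]")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping or unsorted bins on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    def chrom_slices(self) -> dict[str, slice]:
        """Row-range of each chromosome, in chromosome order."""
        out: dict[str, slice] = {}
        chroms = self.df["chrom"].to_numpy()
        for chrom in self.chrom_order:
            idx = np.flatnonzero(chroms == chrom)
            if idx.size:
                out[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def bin_sizes(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()


@dataclass
class CentromereTable:
    """One centromere interval per chromosome (0-based half-open)."""

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        chroms = [c for c, _, _ in self.entries]
        if len(set(chroms)) != len(chroms):
            raise ValueError("at most one centromere entry per chromosome")

    def get(self, chrom: str) -> tuple[int, int] | None:
        for c, s, e in self.entries:
            if c == chrom:
                return (s, e)
        return None

    @classmethod
    def from_bed(cls, path: str) -> "CentromereTable":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{ln}: need >=3 BED columns")
                rows.append((parts[0], int(parts[1]), int(parts[2])))
        return cls(rows)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.entries:
                fh.write(f"{c}\t{s}\t{e}\n")


@dataclass
class ArmTable:
    """Chromosome arms (p before, q after the centromere)."""

    arms: list[tuple[str, str, int, int]]  # (chrom, 'p'|'q', start, end)

    def for_chrom(self, chrom: str) -> list[tuple[str, int, int]]:
        return [(a, s, e) for c, a, s, e in self.arms if c == chrom]

    @classmethod
    def from_centromeres(
        cls, centromeres: CentromereTable, chrom_lengths: dict[str, int]
    ) -> "ArmTable":
        arms = []
        for chrom, length in chrom_lengths.items():
            cen = centromeres.get(chrom)
            if cen is None:
                arms.append((chrom, "q", 0, length))
                continue
            cs, ce = cen
            if cs > 0:
                arms.append((chrom, "p", 0, cs))
            if ce < length:
                arms.append((chrom, "q", ce, length))
        return cls(arms)


# ---------------------------------------------------------------------------
# mappability and bin construction
# ---------------------------------------------------------------------------


def mappable_positions(ref: ReferenceGenome, read_length: int) -> dict[str, np.ndarray]:
    """Uniquely mappable read start positions per chromosome.

    A position is mappable iff its forward-strand ``read_length``-mer contains
    no N and occurs exactly once among all forward and reverse-complement
    ``read_length``-mers of the genome.  This models exact unique alignment of
    error-free reads; a palindromic k-mer is its own reverse complement and is
    therefore never unique.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    counts: dict[bytes, int] = {}
    encoded: list[tuple[str, bytes]] = []
    for name, seq in ref.chromosomes:
        if len(seq) < read_length:
            raise ValueError(f"chromosome {name} shorter than read_length")
        b = seq.encode("ascii").upper()
        encoded.append((name, b))
        rc = b.translate(_COMPLEMENT)[::-1]
        for strand in (b, rc):
            for i in range(len(strand) - read_length + 1):
                kmer = strand[i : i + read_length]
                if b"N" in kmer:
                    continue
                counts[kmer] = counts.get(kmer, 0) + 1
    out: dict[str, np.ndarray] = {}
    for name, b in encoded:
        pos = [
            i
            for i in range(len(b) - read_length + 1)
            if counts.get(b[i : i + read_length], 0) == 1
        ]
        out[name] = np.asarray(pos, dtype=np.int64)
    return out


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights; ties go to earlier entries."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("nonpositive weights")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        # stable argsort descending on fractional part -> earlier chrom wins ties
        frac = quota - base
        order = np.argsort(-frac, kind="stable")
        base[order[:rem]] += 1
    return base


def build_equal_read_bins(
    ref: ReferenceGenome,
    read_length: int,
    total_bins: int,
    mappable: dict[str, np.ndarray] | None = None,
) -> BinMap:
    """Partition the genome into ``total_bins`` bins of equal mappable-position
    content.

    Bins are allocated across chromosomes proportionally to their uniquely
    mappable position counts (largest-remainder rounding), then each
    chromosome's ordered mappable positions are split into consecutive runs of
    equal size (+/-1, earlier bins take the remainder).  A bin starts at its
    first mappable position and ends where the next bin starts (the last bin
    ends at the chromosome end), so unmappable gaps are absorbed into the
    preceding bin.
    """
    if total_bins < len(ref.chromosomes):
        raise ValueError("total_bins must be >= number of chromosomes")
    if mappable is None:
        mappable = mappable_positions(ref, read_length)
    names = ref.names
    counts = np.array([len(mappable[c]) for c in names])
    usable = counts > 0
    for name, n in zip(names, counts):
        if n == 0:
            warnings.warn(f"chromosome {name} has no mappable positions; 0 bins")
    if counts.sum() < total_bins:
        raise ValueError("genome has fewer mappable positions than requested bins")
    alloc = np.zeros(len(names), dtype=int)
    alloc[usable] = _largest_remainder(counts[usable], total_bins)
    rows = []
    for name, n_bins_c in zip(names, alloc):
        if n_bins_c == 0:
            continue
        pos = mappable[name]
        n = len(pos)
        base, extra = divmod(n, n_bins_c)
        sizes = np.full(n_bins_c, base, dtype=int)
        sizes[:extra] += 1
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        chrom_len = ref.length(name)
        for k in range(n_bins_c):
            first = int(pos[bounds[k]])
            end = int(pos[bounds[k + 1]]) if k + 1 < n_bins_c else chrom_len
            rows.append((name, first, end, int(sizes[k]), np.nan))
    df = pd.DataFrame(rows, columns=BINMAP_COLUMNS)
    binmap = BinMap(df, read_length=read_length, total_bins_requested=total_bins,
                    chrom_order=names)
    return compute_bin_gc(ref, binmap)


def compute_bin_gc(ref: ReferenceGenome, binmap: BinMap) -> BinMap:
    """Annotate each bin with GC fraction over non-N bases (NaN if all N)."""
    gcs = []
    seqs = {name: seq.upper() for name, seq in ref.chromosomes}
    for row in binmap.df.itertuples(index=False):
        seq = seqs[row.chrom][row.start : row.end]
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            gcs.append(np.nan)
        else:
            gcs.append((seq.count("G") + seq.count("C")) / acgt)
    df = binmap.df.copy()
    df["gc"] = gcs
    return BinMap(df, binmap.read_length, binmap.total_bins_requested,
                  list(binmap.chrom_order))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_binmap(binmap: BinMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#read_length={binmap.read_length}\t"
                 f"total_bins_requested={binmap.total_bins_requested}\n")
        binmap.df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_binmap(path: str) -> BinMap:
    read_length, requested = 50, 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for kv in first[1:].strip().split("\t"):
                key, _, val = kv.partition("=")
                if key == "read_length":
                    read_length = int(val)
                elif key == "total_bins_requested":
                    requested = int(val)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    for i, row in enumerate(df.itertuples(index=False), 1):
        if row.end <= row.start or row.n_mappable <= 0:
            raise ValueError(f"{path}: malformed bin at data row {i}")
    try:
        return BinMap(df[BINMAP_COLUMNS], read_length, requested)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
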