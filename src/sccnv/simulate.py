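"""Synthetic single-cell WGA data: references, bin counts, noise, populations.

Two levels of simulation are provided.

* Sequence level (``simulate_reference``): small FASTA genomes with a
  controlled GC track, N-run centromeres and optional duplicated blocks, for
  exercising bin construction and mappability on kb-to-Mb genomes.

* Bin level (``hg19_like_binmap`` + ``simulate_bin_counts``): a bin map with
  human-genome chromosome-length proportions (22 autosomes + X; ~506 kb bins
  at 6,000 bins genome-wide) and per-bin read counts drawn as
  Poisson(T * w_i * g(GC_i) * (CN_i/2) * b_i), where w_i is the mappability
  weight, g a quadratic GC response, and b an AR(1) lognormal amplification
  bias.  This reproduces the phenomenology of whole-genome amplification:
  unamplified ("bulk") DNA is Poisson-limited, PCR-based WGA (GenomePlex-like)
  adds moderate short-range bias, and MDA-like amplification adds strong,
  longer-range bias.  The adjacent-bin bias correlation rho and per-bin bias
  SD are derived from a genomic correlation length, so coarser bins average
  out more bias and MAPD falls with increasing bin size, as observed for real
  WGA libraries, while bulk MAPD is bin-size independent.

All randomness flows through numpy SeedSequences derived from the caller's
seed; identical (spec, seed) pairs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import ArmTable, BinMap, CentromereTable, ReferenceGenome
from .profile import SampleProfile, normalize_counts
from .qc import mapd, poisson_mapd_floor

import pandas as pd

DEFAULT_TOTAL_READS = 5_000_000  # ~5M pass-filter reads per sample

# hg19 chromosome lengths (Mb) and approximate centromere midpoint fractions.
# Public assembly constants; acrocentric chromosomes have near-terminal
# p arms.
_HG19_CHROMS: list[tuple[str, float, float]] = [
    ("chr1", 249.25, 0.50), ("chr2", 243.20, 0.38), ("chr3", 198.02, 0.46),
    ("chr4", 191.15, 0.26), ("chr5", 180.92, 0.27), ("chr6", 171.12, 0.35),
    ("chr7", 159.14, 0.38), ("chr8", 146.36, 0.31), ("chr9", 141.21, 0.35),
    ("chr10", 135.53, 0.30), ("chr11", 135.01, 0.40), ("chr12", 133.85, 0.27),
    ("chr13", 115.17, 0.16), ("chr14", 107.35, 0.16), ("chr15", 102.53, 0.19),
    ("chr16", 90.35, 0.41), ("chr17", 81.20, 0.30), ("chr18", 78.08, 0.22),
    ("chr19", 59.13, 0.42), ("chr20", 63.03, 0.44), ("chr21", 48.13, 0.27),
    ("chr22", 51.30, 0.29), ("chrX", 155.27, 0.39),
]


# ---------------------------------------------------------------------------
# specs and noise models
# ---------------------------------------------------------------------------


@dataclass
class SimGenomeSpec:
    """Desk-scale sequence-level genome description."""

    chrom_lengths: list[int]
    gc_mean: float = 0.41
    gc_amplitude: float = 0.08
    gc_wavelength: int = 20_000
    centromere_fraction: float = 0.45
    centromere_length_fraction: float = 0.02
    duplicated_block_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chrom_lengths) < 10_000:
            raise ValueError("chromosomes must be >= 10 kb")
        if not 0 < self.gc_mean < 1:
            raise ValueError("gc_mean must be in (0,1)")


@dataclass
class NoiseModel:
    """Per-bin amplification/sequencing noise parameters.

    ``sigma`` is the stationary SD of the AR(1) log-bias (natural log) at the
    bin scale; ``rho`` its adjacent-bin autocorrelation; ``total_reads`` the
    sequencing budget T; ``gc_coeffs`` (c1, c2) the linear/quadratic GC
    response around GC 0.45.
    """

    kind: str = "bulk"  # bulk | genomeplex_like | mda_like
    sigma: float = 0.0
    rho: float = 0.0
    total_reads: int = DEFAULT_TOTAL_READS
    gc_coeffs: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "bulk" and self.sigma != 0:
            raise ValueError("bulk noise has sigma = 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0,1)")


# WGA-chemistry presets: (sigma0, correlation length bp).  sigma0 is the
# log-bias SD of the underlying bias field at scales below its correlation
# length; per-bin sigma and rho follow from the bin size.  Correlation
# lengths sit below the finest bin scale in use (~54 kb) so bin averaging
# dilutes the bias and MAPD rises as bins shrink, as real WGA libraries do;
# sigma0 inverts the closed-form MAPD approximation at the characteristic
# single-cell MAPD of each chemistry (0.20 GenomePlex-like, 0.45 MDA-like)
# with ~830 reads/bin on ~506 kb bins.
_KIND_PRESETS: dict[str, tuple[float, float]] = {
    "bulk": (0.0, 1.0),
    "genomeplex_like": (0.820, 15_000.0),
    "mda_like": (1.335, 30_000.0),
}

DEFAULT_GC_COEFFS = (0.5, -3.0)  # mild tilt + concave response, peak near 0.45


def noise_for_binmap(kind: str, binmap: BinMap,
                     total_reads: int = DEFAULT_TOTAL_READS,
                     gc_bias: bool = True) -> NoiseModel:
    """Derive per-bin (sigma, rho) for a WGA kind at this bin scale.

    The underlying bias field has correlation length ell and small-scale log
    SD sigma0; averaging over bins of width w gives per-bin variance
    sigma0^2 * min(1, ell/w) and adjacent-bin correlation exp(-w/ell).
    """
    sigma0, ell = _KIND_PRESETS[kind]
    w = float(np.median(binmap.bin_sizes()))
    sigma = sigma0 * np.sqrt(min(1.0, ell / w))
    rho = float(np.exp(-w / ell)) if sigma0 > 0 else 0.0
    return NoiseModel(kind=kind, sigma=float(sigma), rho=rho,
                      total_reads=total_reads,
                      gc_coeffs=DEFAULT_GC_COEFFS if gc_bias else (0.0, 0.0))


def expected_mapd(sigma: float, rho: float, lam: float) -> float:
    """Closed-form MAPD approximation for AR(1) lognormal bias + Poisson."""
    ln2 = np.log(2.0)
    var_diff = 2.0 * (1.0 - rho) * sigma**2 / ln2**2 + 2.0 / (lam * ln2**2)
    return 0.6745 * float(np.sqrt(var_diff))


@dataclass
class CNVTruth:
    """Ground-truth CNV events with per-event cell fractions.

    Events: (chrom, start_bp, end_bp, cn, cell_fraction); whole-chromosome
    events use the full chromosome span.  Events must not overlap within a
    cell.
    """

    events: list[dict] = field(default_factory=list)
    ploidy_baseline: int = 2

    def add(self, chrom: str, start_bp: int, end_bp: int, cn: int,
            cell_fraction: float = 1.0) -> "CNVTruth":
        if cn < 0 or not 0 < cell_fraction <= 1:
            raise ValueError("cn >= 0 and cell_fraction in (0,1] required")
        for ev in self.events:
            if ev["chrom"] == chrom and start_bp < ev["end_bp"] \
                    and ev["start_bp"] < end_bp:
                raise ValueError("overlapping truth events")
        self.events.append({"chrom": chrom, "start_bp": start_bp,
                            "end_bp": end_bp, "cn": cn,
                            "cell_fraction": cell_fraction})
        return self

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "CNVTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(events=d["events"], ploidy_baseline=d["ploidy_baseline"])

    def event_bins(self, binmap: BinMap, event_idx: int) -> np.ndarray:
        """Bin-map row indices overlapping an event by >= 1 bp."""
        ev = self.events[event_idx]
        df = binmap.df
        sel = (df["chrom"] == ev["chrom"]) & (df["start"] < ev["end_bp"]) & \
              (df["end"] > ev["start_bp"])
        return np.flatnonzero(sel.to_numpy())


@dataclass
class SimSample:
    sample_id: str
    counts: np.ndarray
    noise: NoiseModel
    seed: int
    carried: list[bool] = field(default_factory=list)

    def to_profile(self, binmap: BinMap) -> SampleProfile:
        return normalize_counts(self.counts, binmap, sample_id=self.sample_id)


# ---------------------------------------------------------------------------
# sequence-level reference simulation
# ---------------------------------------------------------------------------


def simulate_reference(spec: SimGenomeSpec
                       ) -> tuple[ReferenceGenome, CentromereTable, ArmTable]:
    """Generate a small FASTA-style genome with GC track and N centromeres."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xFA57A]))
    chroms: list[tuple[str, str]] = []
    cen_entries = []
    bases_at = np.frombuffer(b"AT", dtype="S1")
    bases_gc = np.frombuffer(b"GC", dtype="S1")
    for c_idx, length in enumerate(spec.chrom_lengths):
        name = f"chr{c_idx + 1}"
        x = np.arange(length)
        track = spec.gc_mean + spec.gc_amplitude * np.sin(
            2 * np.pi * x / spec.gc_wavelength + c_idx)
        track = np.clip(track, 0.05, 0.95)
        is_gc = rng.random(length) < track
        which = rng.integers(0, 2, size=length)
        seq = np.where(is_gc, bases_gc[which], bases_at[which])
        cen_len = max(1, int(length * spec.centromere_length_fraction))
        cen_start = int(length * spec.centromere_fraction)
        cen_end = min(length, cen_start + cen_len)
        seq[cen_start:cen_end] = b"N"
        if spec.duplicated_block_fraction > 0:
            blk = max(60, int(length * spec.duplicated_block_fraction))
            src = int(rng.integers(0, max(1, cen_start - blk)))
            dst = min(length - blk, cen_end + int(
                rng.integers(0, max(1, length - cen_end - blk))))
            seq[dst:dst + blk] = seq[src:src + blk]
        chroms.append((name, seq.tobytes().decode("ascii")))
        cen_entries.append((name, cen_start, cen_end))
    ref = ReferenceGenome(chroms)
    cens = CentromereTable(cen_entries)
    arms = ArmTable.from_centromeres(cens, {n: len(s) for n, s in chroms})
    return ref, cens, arms


# ---------------------------------------------------------------------------
# bin-level simulation at human scale
# ---------------------------------------------------------------------------


def hg19_like_binmap(total_bins: int = 6000, seed: int = 0,
                     include_x: bool = True
                     ) -> tuple[BinMap, CentromereTable, ArmTable]:
    """Bin map with human chromosome-length proportions and a smooth GC track.

    Bins are equal-sized within each chromosome (uniform mappability), with
    n_mappable shares +/-1; GC follows a long-wavelength sinusoid plus seeded
    jitter around 0.41, mimicking isochore-scale GC variation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB17]))
    chroms = [c for c in _HG19_CHROMS if include_x or c[0] != "chrX"]
    lengths = {name: int(mb * 1e6) for name, mb, _ in chroms}
    weights = np.array([lengths[name] for name, _, _ in chroms], dtype=float)
    from .genome import _largest_remainder
    alloc = _largest_remainder(weights, total_bins)
    reads_per_bin_pos = 100  # nominal mappable positions per bin
    rows = []
    cen_entries = []
    for (name, _, cen_frac), n_bins_c in zip(chroms, alloc):
        L = lengths[name]
        edges = np.linspace(0, L, n_bins_c + 1).astype(np.int64)
        mid = (edges[:-1] + edges[1:]) / 2
        gc = (0.41 + 0.045 * np.sin(2 * np.pi * mid / 35e6 + hash(name) % 7)
              + rng.normal(0, 0.012, size=n_bins_c))
        gc = np.clip(gc, 0.30, 0.60)
        n_map = np.full(n_bins_c, reads_per_bin_pos)
        for k in range(n_bins_c):
            rows.append((name, int(edges[k]), int(edges[k + 1]),
                         int(n_map[k]), float(gc[k])))
        cen_mid = int(L * cen_frac)
        cen_entries.append((name, cen_mid - 1_500_000, cen_mid + 1_500_000))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_mappable", "gc"])
    binmap = BinMap(df, read_length=50, total_bins_requested=total_bins,
                    chrom_order=[name for name, _, _ in chroms])
    cens = CentromereTable(cen_entries)
    arms = ArmTable.from_centromeres(cens, lengths)
    return binmap, cens, arms


def _bin_cn(binmap: BinMap, truth: CNVTruth, carried: list[bool]) -> np.ndarray:
    """Per-bin expected CN given which truth events this cell carries.

    Bins partially overlapped by an event get a proportionally interpolated
    CN (an event ending mid-bin changes only part of the bin's material).
    """
    base = float(truth.ploidy_baseline)
    cn = np.full(len(binmap), base)
    starts = binmap.df["start"].to_numpy()
    ends = binmap.df["end"].to_numpy()
    chroms = binmap.df["chrom"].to_numpy()
    for ev, carry in zip(truth.events, carried):
        if not carry:
            continue
        sel = (chroms == ev["chrom"]) & (starts < ev["end_bp"]) & \
              (ends > ev["start_bp"])
        idx = np.flatnonzero(sel)
        ov = (np.minimum(ends[idx], ev["end_bp"])
              - np.maximum(starts[idx], ev["start_bp"]))
        frac = ov / (ends[idx] - starts[idx])
        cn[idx] = base + (ev["cn"] - base) * frac
    return cn


def _ar1_bias(binmap: BinMap, sigma: float, rho: float,
              rng: np.random.Generator) -> np.ndarray:
    """exp(AR(1)) bias, restarted per chromosome, renormalized to mean 1."""
    if sigma == 0:
        return np.ones(len(binmap))
    x = np.empty(len(binmap))
    for sl in binmap.chrom_slices().values():
        n = sl.stop - sl.start
        e = rng.normal(0.0, sigma, size=n)
        z = np.empty(n)
        z[0] = e[0]
        c = np.sqrt(1.0 - rho**2)
        for i in range(1, n):
            z[i] = rho * z[i - 1] + c * e[i]
        x[sl] = z
    b = np.exp(x)
    return b / b.mean()


def _gc_response(gc: np.ndarray, coeffs: tuple[float, float]) -> np.ndarray:
    c1, c2 = coeffs
    g = 1.0 + c1 * (gc - 0.45) + c2 * (gc - 0.45) ** 2
    g = np.maximum(g, 0.1)
    return g / g.mean()


def simulate_bin_counts(binmap: BinMap, truth: CNVTruth,
                        cell_carries_event: list[bool], noise: NoiseModel,
                        seed: int, sample_id: str = "sim") -> SimSample:
    """One cell's bin counts: Poisson(T * w * g(GC) * (CN/2) * bias)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE11]))
    lam = expected_counts(binmap, truth, cell_carries_event, noise, rng)
    counts = rng.poisson(lam)
    return SimSample(sample_id, counts.astype(np.int64), noise, seed,
                     list(cell_carries_event))


def expected_counts(binmap: BinMap, truth: CNVTruth,
                    cell_carries_event: list[bool], noise: NoiseModel,
                    rng: np.random.Generator) -> np.ndarray:
    w = binmap.df["n_mappable"].to_numpy(float)
    w = w / w.sum()
    gc = np.nan_to_num(binmap.df["gc"].to_numpy(float), nan=0.45)
    g = _gc_response(gc, noise.gc_coeffs)
    cn = _bin_cn(binmap, truth, cell_carries_event)
    b = _ar1_bias(binmap, noise.sigma, noise.rho, rng)
    lam = noise.total_reads * w * g * (cn / truth.ploidy_baseline) * b
    if not np.isfinite(lam).all() or (lam < 0).any():
        raise ValueError("invalid expected counts from simulation spec")
    return lam


def calibrate_noise(target_mapd: float, total_reads: int, binmap: BinMap,
                    rho: float, gc_coeffs: tuple[float, float] = (0.0, 0.0),
                    kind: str = "genomeplex_like", seed: int = 0,
                    tol: float = 0.01, n_probe: int = 2,
                    max_iter: int = 30) -> float:
    """Bisect sigma so simulated euploid cells hit ``target_mapd``.

    MAPD is measured through the real pipeline (median-ratio + GC
    normalization) on ``n_probe`` fixed-seed cells per evaluation.  Targets
    below the Poisson floor are rejected.
    """
    lam = total_reads / len(binmap)
    floor = poisson_mapd_floor(lam)
    if target_mapd < floor:
        raise ValueError(f"target MAPD {target_mapd} below Poisson floor "
                         f"{floor:.4f} at {lam:.0f} reads/bin")
    truth = CNVTruth()

    def measure(sigma: float) -> float:
        vals = []
        for r in range(n_probe):
            nm = NoiseModel(kind=kind, sigma=sigma, rho=rho,
                            total_reads=total_reads, gc_coeffs=gc_coeffs)
            s = simulate_bin_counts(binmap, truth, [], nm,
                                    seed=int(np.random.SeedSequence(
                                        [seed, 0xCA1, r]).generate_state(1)[0]
                                        % 2**31))
            vals.append(mapd(s.to_profile(binmap), binmap).mapd)
        return float(np.mean(vals))

    ln2 = np.log(2.0)
    guess2 = ((target_mapd / 0.6745) ** 2 - 2.0 / (lam * ln2**2)) * ln2**2 \
        / (2.0 * (1.0 - rho))
    lo, hi = 0.0, max(0.05, 4.0 * np.sqrt(max(guess2, 1e-6)))
    while measure(hi) < target_mapd:
        hi *= 2.0
        if hi > 20:
            raise ValueError("cannot reach target MAPD")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        got = measure(mid)
        if abs(got - target_mapd) < tol:
            return mid
        if got < target_mapd:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_population(n_cells: int, truth: CNVTruth, noise: NoiseModel,
                        binmap: BinMap, pool_sizes: list[int] | None = None,
                        seed: int = 0) -> tuple[list[SimSample], list[SimSample]]:
    """Independent cells (each carrying each event w.p. its cell fraction)
    plus pooled samples that average member expectations under one shared
    sequencing budget T before Poisson sampling."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA0]))
    cells = []
    for c in range(n_cells):
        carried = [bool(rng.random() < ev["cell_fraction"])
                   for ev in truth.events]
        cells.append(simulate_bin_counts(
            binmap, truth, carried, noise,
            seed=int(rng.integers(0, 2**31)), sample_id=f"cell{c:03d}"))
    pools = []
    for p_idx, m in enumerate(pool_sizes or []):
        lam = np.zeros(len(binmap))
        prng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0, p_idx]))
        for _ in range(m):
            carried = [bool(prng.random() < ev["cell_fraction"])
                       for ev in truth.events]
            lam += expected_counts(binmap, truth, carried, noise, prng)
        lam /= m  # shared budget: pool sequenced to the same depth as a cell
        counts = prng.poisson(lam)
        pools.append(SimSample(f"pool{m}_{p_idx}", counts.astype(np.int64),
                               noise, seed, []))
    return cells, pools


def power_experiment(binmap: BinMap, centromeres: CentromereTable,
                     event_chrom: str, event_start_bp: int, event_size_bp: int,
                     event_cn: int, noise: NoiseModel, n_reps: int,
                     cbs_params=None, calling_params=None, seed: int = 0,
                     mapd_threshold: float = 0.45,
                     min_overlap_bins: int = 2) -> dict:
    """Detection sensitivity for one planted CNV across replicate cells.

    A replicate counts as detected when a call of the correct direction
    overlaps the truth interval in >= ``min_overlap_bins`` bins.  Replicates
    failing the MAPD gate are excluded from the denominator (they would not
    enter CNV analysis), and tallied separately.
    """
    from .caller import CallingParams, call_cnvs
    from .cbs import CBSParams, segment_sample

    cbs_params = cbs_params or CBSParams()
    calling_params = calling_params or CallingParams()
    truth = CNVTruth().add(event_chrom, event_start_bp,
                           event_start_bp + event_size_bp, event_cn)
    truth_bins = truth.event_bins(binmap, 0)
    direction = "gain" if event_cn > truth.ploidy_baseline else "loss"
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFEED]))
    detected = analyzed = failed_qc = 0
    for r in range(n_reps):
        cell = simulate_bin_counts(binmap, truth, [True], noise,
                                   seed=int(rng.integers(0, 2**31)),
                                   sample_id=f"rep{r:03d}")
        prof = cell.to_profile(binmap)
        if mapd(prof, binmap, mapd_threshold).passed is False:
            failed_qc += 1
            continue
        analyzed += 1
        params_r = replace_seed(cbs_params, seed + r)
        segs = segment_sample(prof, binmap, params_r)
        calls = call_cnvs(segs, binmap, centromeres, calling_params)
        for call in calls.itertuples(index=False):
            if call.direction != direction or call.chrom != event_chrom:
                continue
            ov = np.intersect1d(truth_bins,
                                np.arange(call.start_bin, call.end_bin + 1))
            if len(ov) >= min_overlap_bins:
                detected += 1
                break
    sensitivity = detected / analyzed if analyzed else float("nan")
    return {"sensitivity": sensitivity, "n_detected": detected,
            "n_analyzed": analyzed, "n_failed_qc": failed_qc,
            "n_reps": n_reps}


def replace_seed(cbs_params, seed: int):
    from dataclasses import replace
    return replace(cbs_params, seed=seed)
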