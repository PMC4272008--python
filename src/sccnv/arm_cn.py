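"""Chromosome- and arm-level integer copy-number calling.

Arm CN is estimated from the fraction of a sample's reads falling on each
chromosome arm, normalized to a "normalizer reference set": the median
per-arm read fraction across a panel of euploid reference cells amplified
with the same chemistry.  Autosomal ratios are rescaled so the autosomal
median sits at CN 2; sex-chromosome CN is taken relative to the autosomes
within the sample.  Pooled multi-cell samples report the unrounded CN, which
for a mosaic event approximates the cell-fraction-weighted mean CN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ArmTable, BinMap
from .profile import SampleProfile

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


def _is_sex(chrom: str) -> bool:
    return chrom in SEX_CHROMS


def assign_bins_to_arms(binmap: BinMap, arms: ArmTable) -> pd.Series:
    """Arm label ('p'/'q') per bin, by bin midpoint; '' if no arm contains it."""
    labels = np.full(len(binmap), "", dtype=object)
    df = binmap.df
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    for chrom, sl in binmap.chrom_slices().items():
        for arm, s, e in arms.for_chrom(chrom):
            sel = (mid[sl] >= s) & (mid[sl] < e)
            labels[np.arange(sl.start, sl.stop)[sel]] = arm
    # bins straddling the centromere midpoint-wise outside both arms: attach
    # to the nearer arm so every bin contributes to exactly one arm fraction
    for chrom, sl in binmap.chrom_slices().items():
        arm_list = arms.for_chrom(chrom)
        if not arm_list:
            continue
        for i in range(sl.start, sl.stop):
            if labels[i] == "":
                d = [(min(abs(mid[i] - s), abs(mid[i] - e)), a)
                     for a, s, e in arm_list]
                labels[i] = min(d)[1]
    return pd.Series(labels, name="arm")


def _fractions(profile: SampleProfile, binmap: BinMap,
               arm_labels: pd.Series) -> pd.DataFrame:
    """Read fraction per (chrom, arm) and per chromosome (arm='*')."""
    df = pd.DataFrame({
        "chrom": binmap.df["chrom"].to_numpy(),
        "arm": arm_labels.to_numpy(),
        "rpb": profile.rpb,
    })
    total = df["rpb"].sum()
    if total <= 0:
        raise ValueError(f"{profile.sample_id}: no reads")
    arm_frac = df.groupby(["chrom", "arm"], sort=False)["rpb"].sum() / total
    chrom_frac = df.groupby("chrom", sort=False)["rpb"].sum() / total
    chrom_frac.index = pd.MultiIndex.from_product([chrom_frac.index, ["*"]],
                                                  names=["chrom", "arm"])
    return pd.concat([arm_frac, chrom_frac]).rename("fraction").reset_index()


@dataclass
class NormalizerReference:
    """Median per-arm read fractions of euploid reference samples.

    ``table`` columns: chrom, arm ('p'/'q'/'*' for whole chromosome),
    ref_fraction, ref_cn, usable.
    """

    table: pd.DataFrame
    n_reference_samples: int
    ref_sex: str = "female"
    source: str = ""

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#n_reference_samples={self.n_reference_samples}\t"
                     f"ref_sex={self.ref_sex}\tsource={self.source}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def read_tsv(cls, path: str) -> "NormalizerReference":
        n_ref, sex, source = 1, "female", ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for kv in first[1:].strip().split("\t"):
                    key, _, val = kv.partition("=")
                    if key == "n_reference_samples":
                        n_ref = int(val)
                    elif key == "ref_sex":
                        sex = val
                    elif key == "source":
                        source = val
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(df, n_ref, sex, source)


def build_normalizer(reference_profiles: list[SampleProfile], binmap: BinMap,
                     arms: ArmTable, ref_sex: str = "female",
                     source: str = "") -> NormalizerReference:
    """Median per-arm (and per-chromosome) read fractions across references."""
    if not reference_profiles:
        raise ValueError("need at least one reference profile")
    labels = assign_bins_to_arms(binmap, arms)
    tables = [_fractions(p, binmap, labels) for p in reference_profiles]
    merged = tables[0][["chrom", "arm"]].copy()
    stack = np.column_stack([t["fraction"].to_numpy() for t in tables])
    merged["ref_fraction"] = np.median(stack, axis=1)
    ref_cn = []
    for chrom in merged["chrom"]:
        if _is_sex(chrom):
            ref_cn.append(1 if ref_sex == "male" else 2)
        else:
            ref_cn.append(2)
    merged["ref_cn"] = ref_cn
    merged["usable"] = merged["ref_fraction"] > 0
    return NormalizerReference(merged, len(reference_profiles), ref_sex, source)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class ArmCNResult:
    """Per-arm and per-chromosome CN estimates for one sample.

    ``table`` columns: chrom, arm, cn_ratio (sample/reference fraction ratio),
    cn_float (unrounded copies), cn_int (NaN in pool mode or unusable arms).
    """

    sample_id: str
    table: pd.DataFrame
    sample_sex: str
    pool_mode: bool = False

    def chrom_cn(self, chrom: str) -> pd.Series:
        sel = self.table[(self.table["chrom"] == chrom) &
                         (self.table["arm"] == "*")]
        return sel.iloc[0]

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample_id={self.sample_id}\tsex={self.sample_sex}\t"
                     f"pool={int(self.pool_mode)}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def call_arm_cn(sample: SampleProfile, normalizer: NormalizerReference,
                binmap: BinMap, arms: ArmTable, sample_sex: str = "unknown",
                pool: bool = False) -> ArmCNResult:
    """Integer (or pooled unrounded) CN per chromosome arm.

    Raw ratio r_a = sample fraction / reference fraction per arm; the
    autosomal median of r_a defines the within-sample scale s.  Autosomes:
    cn_float = 2 r_a / s.  Sex chromosomes: cn_float = ref_cn * r_a / s, i.e.
    relative to the autosomes within the sample.  cn_int rounds half away
    from zero; pool mode leaves CN unrounded (mosaic pools are non-integer).
    """
    labels = assign_bins_to_arms(binmap, arms)
    frac = _fractions(sample, binmap, labels)
    merged = normalizer.table.merge(frac, on=["chrom", "arm"], how="left")
    merged["fraction"] = merged["fraction"].fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(merged["usable"],
                         merged["fraction"] / merged["ref_fraction"], np.nan)
    is_sex = merged["chrom"].map(_is_sex).to_numpy()
    is_arm_row = (merged["arm"] != "*").to_numpy()
    auto_arms = ~is_sex & is_arm_row & np.isfinite(ratio)
    if not auto_arms.any():
        raise ValueError("no usable autosomal arms to set the sample scale")
    scale = float(np.median(ratio[auto_arms]))
    if scale <= 0:
        raise ValueError(f"{sample.sample_id}: nonpositive autosomal scale")
    baseline = np.where(is_sex, merged["ref_cn"].to_numpy(float), 2.0)
    cn_float = baseline * ratio / scale
    out = merged[["chrom", "arm"]].copy()
    out["cn_ratio"] = ratio / scale
    out["cn_float"] = cn_float
    out["cn_int"] = np.where(np.isfinite(cn_float),
                             _round_half_away(np.asarray(cn_float)), np.nan)
    if pool:
        out["cn_int"] = np.nan
    return ArmCNResult(sample.sample_id, out, sample_sex, pool_mode=pool)
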