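"""End-to-end orchestration: count -> normalize -> QC -> arm CN -> segment
-> call -> clonal, driven by a JSON config and a sample manifest.

QC-failed samples (MAPD above threshold) are excluded from segmentation and
CNV calling but still reported.  Every output table is stamped with the
parameters and seeds used, and reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .arm_cn import NormalizerReference, build_normalizer, call_arm_cn
from .caller import (CallingParams, call_cnvs, clonal_events_frame,
                     find_clonal, write_calls_bed)
from .cbs import CBSParams, segment_sample
from .genome import ArmTable, BinMap, CentromereTable, read_binmap
from .profile import ReadPlacements, SampleProfile, count_reads, gc_normalize, compute_cnr
from .qc import DEFAULT_MAPD_THRESHOLD, mapd

log = logging.getLogger("sccnv")


@dataclass
class ManifestEntry:
    sample_id: str
    path: str
    sex: str = "unknown"
    role: str = "cell"  # cell | pool | reference | bulk
    kind: str = "counts"  # counts | placements | sam


@dataclass
class PipelineConfig:
    binmap_path: str
    out_dir: str
    centromeres_path: str | None = None
    arms: ArmTable | None = None
    manifest: list[ManifestEntry] = field(default_factory=list)
    mapd_threshold: float = DEFAULT_MAPD_THRESHOLD
    cbs: CBSParams = field(default_factory=CBSParams)
    calling: CallingParams = field(default_factory=CallingParams)
    seed: int = 0
    clonal_nperm: int = 0  # 0 disables the sharing-null permutation test

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        manifest = [ManifestEntry(**m) for m in d.pop("manifest", [])]
        cbs = CBSParams(**d.pop("cbs", {}))
        calling = CallingParams(**d.pop("calling", {}))
        return cls(manifest=manifest, cbs=cbs, calling=calling, **d)


def _load_profile(entry: ManifestEntry, binmap: BinMap) -> SampleProfile:
    if entry.kind == "counts":
        df = pd.read_csv(entry.path, sep="\t", comment="#")
        col = "rpb" if "rpb" in df.columns else df.columns[-1]
        rpb = df[col].to_numpy(np.int64)
        if len(rpb) != len(binmap):
            raise ValueError(f"{entry.sample_id}: {len(rpb)} counts for "
                             f"{len(binmap)}-bin map")
        mask = (rpb == 0) | binmap.df["gc"].isna().to_numpy()
        return SampleProfile(entry.sample_id, rpb, mask)
    if entry.kind == "placements":
        pl = ReadPlacements.from_tsv(entry.path, entry.sample_id)
    elif entry.kind == "sam":
        pl = ReadPlacements.from_alignments(entry.path, entry.sample_id)
    else:
        raise ValueError(f"unknown input kind {entry.kind!r}")
    return count_reads(pl, binmap)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a dict of output DataFrames (also written)."""
    t0 = time.time()
    os.makedirs(config.out_dir, exist_ok=True)
    binmap = read_binmap(config.binmap_path)
    centromeres = (CentromereTable.from_bed(config.centromeres_path)
                   if config.centromeres_path else CentromereTable([]))
    arms = config.arms or ArmTable.from_centromeres(
        centromeres,
        {c: int(binmap.df[binmap.df["chrom"] == c]["end"].max())
         for c in binmap.chrom_order})

    profiles: dict[str, SampleProfile] = {}
    qc_rows = []
    for entry in config.manifest:
        try:
            prof = _load_profile(entry, binmap)
            prof = gc_normalize(compute_cnr(prof), binmap)
        except Exception as exc:
            raise RuntimeError(
                f"stage=normalize sample={entry.sample_id}: {exc}") from exc
        res = mapd(prof, binmap, config.mapd_threshold)
        qc_rows.append({"sample_id": entry.sample_id, "role": entry.role,
                        "mapd": res.mapd, "n_pairs": res.n_pairs,
                        "passed": res.passed})
        profiles[entry.sample_id] = prof
        prof.write_tsv(binmap, os.path.join(config.out_dir,
                                            f"{entry.sample_id}.profile.tsv"))
    qc_table = pd.DataFrame(qc_rows)
    qc_table.to_csv(os.path.join(config.out_dir, "qc.tsv"), sep="\t",
                    index=False, float_format="%.6g")

    refs = [profiles[e.sample_id] for e in config.manifest
            if e.role == "reference"]
    normalizer = None
    arm_tables = []
    if refs:
        ref_sexes = {e.sex for e in config.manifest if e.role == "reference"}
        normalizer = build_normalizer(refs, binmap, arms,
                                      ref_sex=ref_sexes.pop() if len(ref_sexes) == 1
                                      else "female")
        normalizer.write_tsv(os.path.join(config.out_dir, "normalizer.tsv"))
        for entry in config.manifest:
            if entry.role == "reference":
                continue
            res = call_arm_cn(profiles[entry.sample_id], normalizer, binmap,
                              arms, entry.sex, pool=(entry.role == "pool"))
            t = res.table.copy()
            t.insert(0, "sample_id", entry.sample_id)
            arm_tables.append(t)
    arm_cn_table = (pd.concat(arm_tables, ignore_index=True)
                    if arm_tables else pd.DataFrame())
    if not arm_cn_table.empty:
        arm_cn_table.to_csv(os.path.join(config.out_dir, "arm_cn.tsv"),
                            sep="\t", index=False, float_format="%.6g")

    passed = {r["sample_id"] for r in qc_rows if r["passed"]}
    all_calls = []
    for entry in config.manifest:
        if entry.role in ("reference",) or entry.sample_id not in passed:
            continue
        try:
            segs = segment_sample(profiles[entry.sample_id], binmap, config.cbs)
            segs.write_tsv(os.path.join(config.out_dir,
                                        f"{entry.sample_id}.segments.tsv"))
            calls = call_cnvs(segs, binmap, centromeres, config.calling,
                              entry.sex)
        except Exception as exc:
            raise RuntimeError(
                f"stage=segment/call sample={entry.sample_id}: {exc}") from exc
        if not calls.empty:
            all_calls.append(calls)
    from .caller import CALL_COLUMNS
    calls_table = (pd.concat(all_calls, ignore_index=True) if all_calls
                   else pd.DataFrame(columns=CALL_COLUMNS))
    calls_path = os.path.join(config.out_dir, "calls.tsv")
    calls_table.to_csv(calls_path, sep="\t", index=False, float_format="%.6g")
    if not calls_table.empty:
        write_calls_bed(calls_table, os.path.join(config.out_dir, "calls.bed"))

    clonal = find_clonal(calls_table, binmap) if not calls_table.empty else []
    clonal_table = clonal_events_frame(clonal)
    clonal_table.to_csv(os.path.join(config.out_dir, "clonal.tsv"), sep="\t",
                        index=False)

    summary = summarize_cohort(calls_table, clonal, qc_table)
    summary.to_csv(os.path.join(config.out_dir, "summary.tsv"), sep="\t",
                   index=False, float_format="%.6g")
    with open(os.path.join(config.out_dir, "run.json"), "w") as fh:
        json.dump({"version": __version__, "seed": config.seed,
                   "mapd_threshold": config.mapd_threshold,
                   "cbs": vars(config.cbs), "calling": vars(config.calling),
                   "n_samples": len(config.manifest),
                   "elapsed_s": None}, fh, indent=1)
    log.info("pipeline done in %.1f s", time.time() - t0)
    return {"qc": qc_table, "arm_cn": arm_cn_table, "calls": calls_table,
            "clonal": clonal_table, "summary": summary,
            "normalizer": normalizer}


def summarize_cohort(calls: pd.DataFrame, clonal_events,
                     qc: pd.DataFrame) -> pd.DataFrame:
    """Per-sample call counts plus the cohort clonal fraction."""
    clonal_rows: set[int] = set()
    for ev in clonal_events:
        clonal_rows.update(ev.member_indices)
    rows = []
    n_clonal_calls = 0
    for sample_id in qc["sample_id"]:
        if calls.empty:
            sub = pd.DataFrame()
            row_pos = np.empty(0, dtype=int)
        else:
            sel = (calls["sample_id"] == sample_id).to_numpy()
            sub = calls[sel]
            row_pos = np.flatnonzero(sel)
        n = len(sub)
        gains = int((sub["direction"] == "gain").sum()) if n else 0
        in_clonal = sum(1 for p in row_pos if int(p) in clonal_rows)
        n_clonal_calls += in_clonal
        rows.append({
            "sample_id": sample_id,
            "n_calls": n,
            "n_gains": gains,
            "n_losses": n - gains,
            "median_size_bp": float(sub["size_bp"].median()) if n else np.nan,
            "n_clonal_calls": in_clonal,
        })
    out = pd.DataFrame(rows)
    total = out["n_calls"].sum()
    out.attrs["clonal_fraction"] = (n_clonal_calls / total) if total else 0.0
    out["cohort_clonal_fraction"] = out.attrs["clonal_fraction"]
    return out
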