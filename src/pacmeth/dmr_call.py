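"""Aggregation of per-CpG tests into differentially methylated regions.

A DMR is a run of CpGs with coordinated group differences: candidate
regions are seeded from CpGs with p <= 0.01 lying within 100 bp of the
next significant CpG, merged when closer than 100 bp, and kept when at
least 50 bp long, containing >= 3 CpGs of which >= 50% are significant.
Direction (hyper/hypo) follows the sign of the mean per-CpG difference
(exposed - reference).
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["call_dmrs", "classify_directions", "write_regions_bed", "read_regions_bed"]

logger = logging.getLogger(__name__)

REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_cpg",
    "n_sig",
    "frac_sig",
    "mean_diff",
    "area_stat",
    "direction",
]


def call_dmrs(
    dml: pd.DataFrame,
    p_threshold: float = 0.01,
    min_len: int = 50,
    min_cpg: int = 3,
    pct_sig: float = 0.5,
    merge_dist: int = 100,
) -> pd.DataFrame:
    """Call DMRs from a per-CpG differential methylation table.

    ``dml`` must be sorted by (chrom, pos) and carry columns chrom, pos,
    diff, wald, pvalue. Candidate regions are maximal runs of significant
    CpGs (p <= ``p_threshold``) whose consecutive significant members are
    <= ``merge_dist`` bp apart (intervening non-significant CpGs are
    included); boundaries are the half-open interval [first_pos - 1,
    last_pos); candidates closer than ``merge_dist`` are merged and the
    filters and statistics recomputed on the merged region.
    """
    required = {"chrom", "pos", "diff", "wald", "pvalue"}
    missing = required - set(dml.columns)
    if missing:
        raise ValueError(f"dml table missing columns: {sorted(missing)}")
    chrom_pos = dml[["chrom", "pos"]]
    if not chrom_pos.equals(
        chrom_pos.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    ):
        raise ValueError("dml table must be sorted by (chrom, pos)")

    regions = []
    ties = 0
    for chrom, sub in dml.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        pval = sub["pvalue"].to_numpy()
        diff = sub["diff"].to_numpy()
        wald = sub["wald"].to_numpy()
        sig_idx = np.flatnonzero(pval <= p_threshold)
        if sig_idx.size == 0:
            continue
        # seed: runs of significant CpGs with gaps <= merge_dist
        breaks = np.flatnonzero(np.diff(pos[sig_idx]) > merge_dist)
        runs = np.split(sig_idx, breaks + 1)
        cands = [(int(pos[r[0]]) - 1, int(pos[r[-1]])) for r in runs]
        # merge candidates separated by < merge_dist
        merged = [list(cands[0])]
        for s, e in cands[1:]:
            if s - merged[-1][1] < merge_dist:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for start, end in merged:
            inside = (pos > start) & (pos <= end)
            n_cpg = int(inside.sum())
            n_sig = int((pval[inside] <= p_threshold).sum())
            frac_sig = n_sig / n_cpg
            if end - start < min_len or n_cpg < min_cpg or frac_sig < pct_sig:
                continue
            mean_diff = float(diff[inside].mean())
            if mean_diff == 0:
                ties += 1
            regions.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_cpg": n_cpg,
                    "n_sig": n_sig,
                    "frac_sig": frac_sig,
                    "mean_diff": mean_diff,
                    "area_stat": float(wald[inside].sum()),
                    "direction": "hyper" if mean_diff > 0 else "hypo",
                }
            )
    if ties:
        logger.info("call_dmrs: %d regions with mean_diff == 0 classified hypo", ties)
    out = pd.DataFrame(regions, columns=REGION_COLUMNS)
    _validate_regions(out, min_len=min_len, min_cpg=min_cpg, pct_sig=pct_sig)
    return out


def _validate_regions(regions: pd.DataFrame, min_len: int, min_cpg: int, pct_sig: float) -> None:
    if regions.empty:
        return
    assert ((regions["end"] - regions["start"]) >= min_len).all()
    assert (regions["n_cpg"] >= min_cpg).all()
    assert (regions["frac_sig"] >= pct_sig).all()
    hyper = regions["direction"] == "hyper"
    assert (regions.loc[hyper, "mean_diff"] > 0).all()
    assert (regions.loc[~hyper, "mean_diff"] <= 0).all()


class DirectionSummary(NamedTuple):
    n_hyper: int
    n_hypo: int
    pct_hyper: float
    pct_hypo: float


def classify_directions(regions: pd.DataFrame) -> DirectionSummary:
    """Count hyper/hypomethylated regions and their percentages (2 dp)."""
    if regions.empty:
        logger.warning("classify_directions: empty region set")
        return DirectionSummary(0, 0, 0.0, 0.0)
    n_hyper = int((regions["direction"] == "hyper").sum())
    n_hypo = len(regions) - n_hyper
    total = len(regions)
    return DirectionSummary(
        n_hyper,
        n_hypo,
        round(100.0 * n_hyper / total, 2),
        round(100.0 * n_hypo / total, 2),
    )


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """BED6+3: name=direction, score=round(1000*frac_sig), then n_cpg,
    mean_diff, area_stat."""
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t"
                f"{int(round(1000 * r.frac_sig))}\t.\t{r.n_cpg}\t"
                f"{r.mean_diff:.6g}\t{r.area_stat:.6g}\n"
            )


def read_regions_bed(path) -> pd.DataFrame:
    """Read regions written by :func:`write_regions_bed` (or any BED3+)."""
    df = pd.read_csv(path, sep="\t", header=None)
    out = pd.DataFrame({"chrom": df[0], "start": df[1].astype(int), "end": df[2].astype(int)})
    if df.shape[1] >= 4:
        out["direction"] = df[3]
    if df.shape[1] >= 9:
        out["n_cpg"] = df[6].astype(int)
        out["mean_diff"] = df[7].astype(float)
        out["area_stat"] = df[8].astype(float)
    return out
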