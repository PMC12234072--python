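"""Reading, writing and preprocessing of per-cytosine methylation counts.

Implements the preprocessing applied to Bismark methylation calls before
differential-methylation testing: strand merging of CpG dyads, coverage
filtering (low/high/percentile), median-based coverage normalization to
guard against PCR bias, per-group uniting of loci, and a lane
overdispersion diagnostic.

Coordinates are 1-based positions in :class:`CpGCountTable` (matching the
Bismark dialects) and converted to 0-based half-open intervals only at the
region/BED boundary.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CpGCountTable",
    "UnitedMatrix",
    "QCReport",
    "read_bismark_coverage",
    "write_bismark_coverage",
    "destrand",
    "filter_by_coverage",
    "normalize_coverage",
    "unite",
    "lane_overdispersion",
]

_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_total"]


@dataclass
class CpGCountTable:
    """Per-sample methylation counts at individual cytosines.

    ``data`` holds columns chrom, pos (1-based), strand ('+'/'-'),
    n_meth, n_total, sorted by (chrom, pos) with no duplicate
    (chrom, pos, strand).
    """

    sample_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != _COLUMNS:
            df = df.loc[:, _COLUMNS]
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)
        if (df["n_meth"] > df["n_total"]).any() or (df["n_meth"] < 0).any():
            raise ValueError("methylated count must satisfy 0 <= n_meth <= n_total")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) record")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class UnitedMatrix:
    """Loci x samples methylation count matrix after per-group uniting.

    ``loci`` has columns chrom, pos, strand (always '+' after destranding);
    ``samples`` has columns sample_id, group, lane; ``n_meth``/``n_total``
    are float arrays of shape (n_loci, n_samples) with NaN for missing.
    """

    loci: pd.DataFrame
    samples: pd.DataFrame
    n_meth: np.ndarray
    n_total: np.ndarray

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def percent_methylation(self) -> np.ndarray:
        """Per-locus, per-sample percent methylation (NaN where missing)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.n_meth / self.n_total

    def group_index(self, group: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["group"] == group).to_numpy())
        if idx.size == 0:
            raise KeyError(f"group {group!r} not present in matrix")
        return idx

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# pacmeth united matrix\n")
            fh.write("# samples: " + ",".join(self.samples["sample_id"]) + "\n")
            fh.write("# groups: " + ",".join(self.samples["group"]) + "\n")
            fh.write("# lanes: " + ",".join(str(l) for l in self.samples["lane"]) + "\n")
            cols = ["chrom", "pos", "strand"]
            for sid in self.samples["sample_id"]:
                cols += [f"{sid}.meth", f"{sid}.total"]
            fh.write("\t".join(cols) + "\n")
            wide = self.loci.copy()
            for j, sid in enumerate(self.samples["sample_id"]):
                wide[f"{sid}.meth"] = self.n_meth[:, j]
                wide[f"{sid}.total"] = self.n_total[:, j]
            wide.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "UnitedMatrix":
        meta = {}
        n_meta = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_meta += 1
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
        samples = pd.DataFrame(
            {
                "sample_id": meta["samples"].split(","),
                "group": meta["groups"].split(","),
                "lane": [int(x) for x in meta["lanes"].split(",")],
            }
        )
        df = pd.read_csv(path, sep="\t", skiprows=n_meta + 1, header=None, na_values="NA")
        ncol = 3 + 2 * len(samples)
        if df.shape[1] != ncol:
            raise ValueError(f"expected {ncol} columns, found {df.shape[1]}")
        loci = df.iloc[:, :3].copy()
        loci.columns = ["chrom", "pos", "strand"]
        n_meth = df.iloc[:, 3::2].to_numpy(dtype=float)
        n_total = df.iloc[:, 4::2].to_numpy(dtype=float)
        return cls(loci=loci, samples=samples, n_meth=n_meth, n_total=n_total)


@dataclass
class QCReport:
    """Per-sample coverage medians and scaling factors, plus lane lambda."""

    median_coverage: dict = field(default_factory=dict)
    scaling_factors: dict = field(default_factory=dict)
    lane_lambda: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "median_coverage": self.median_coverage,
                    "scaling_factors": self.scaling_factors,
                    "lane_lambda": self.lane_lambda,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# file formats


def read_bismark_coverage(path, sample_id: str | None = None) -> CpGCountTable:
    """Read a Bismark coverage file (or 7-column cytosine report).

    Coverage dialect: chrom, start, end, %methylation, count_methylated,
    count_unmethylated (1-based inclusive, strand-less; strand set to '+').
    Cytosine-report dialect: chrom, pos, strand, count_methylated,
    count_unmethylated, context, trinucleotide.

    The percent column is cross-checked against the counts; on a
    disagreement beyond 0.01 a warning is emitted and the counts win.
    """
    if sample_id is None:
        sample_id = str(path).rsplit("/", 1)[-1].split(".")[0]
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    except pd.errors.EmptyDataError:
        return CpGCountTable(sample_id, pd.DataFrame(columns=_COLUMNS))
    ncol = df.shape[1]
    if ncol == 6:
        try:
            chrom = df[0].astype(str)
            pos = df[1].astype(int)
            end = df[2].astype(int)
            pct = df[3].astype(float)
            n_meth = df[4].astype(int)
            n_unmeth = df[5].astype(int)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed line {_first_bad_line(df)}: {exc}") from exc
        if (end < pos).any():
            raise ValueError(f"{path}: malformed line {int((end < pos).idxmax()) + 1}: end < start")
        n_total = n_meth + n_unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            implied = np.where(n_total > 0, 100.0 * n_meth / np.maximum(n_total, 1), 0.0)
        bad = np.abs(implied - pct.to_numpy()) > 0.01
        if bad.any():
            warnings.warn(
                f"{path}: percent column disagrees with counts at "
                f"{int(bad.sum())} records; counts take precedence",
                stacklevel=2,
            )
        out = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "strand": "+", "n_meth": n_meth, "n_total": n_total}
        )
    elif ncol == 7:
        try:
            out = pd.DataFrame(
                {
                    "chrom": df[0].astype(str),
                    "pos": df[1].astype(int),
                    "strand": df[2].astype(str),
                    "n_meth": df[3].astype(int),
                    "n_total": df[3].astype(int) + df[4].astype(int),
                }
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: malformed line {_first_bad_line(df)}: {exc}") from exc
        if not out["strand"].isin(["+", "-"]).all():
            bad_ln = int((~out["strand"].isin(["+", "-"])).idxmax()) + 1
            raise ValueError(f"{path}: malformed line {bad_ln}: strand must be + or -")
    else:
        raise ValueError(f"{path}: expected 6 or 7 columns, found {ncol}")
    return CpGCountTable(sample_id, out)


def _first_bad_line(df: pd.DataFrame) -> int:
    for i, row in df.iterrows():
        try:
            int(row[1]), float(row[3] if df.shape[1] == 6 else row[3])
        except (ValueError, TypeError):
            return int(i) + 1
    return 1


def write_bismark_coverage(table: CpGCountTable, path) -> None:
    """Write a 6-column Bismark coverage file (destranded tables only)."""
    df = table.data
    n_unmeth = df["n_total"] - df["n_meth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(df["n_total"] > 0, 100.0 * df["n_meth"] / np.maximum(df["n_total"], 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"],
            "pct": [f"{x:.6g}" for x in pct],
            "n_meth": df["n_meth"],
            "n_unmeth": n_unmeth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def destrand(table: CpGCountTable) -> CpGCountTable:
    """Merge CpG dyad strands: a '-' record at pos p+1 joins the '+' record
    at p; an orphan '-' record is re-anchored to the '+' strand at p-1.
    Total methylated and total read counts are conserved."""
    df = table.data
    if df.empty:
        return CpGCountTable(table.sample_id, df.copy())
    anchor = np.where(df["strand"] == "-", df["pos"] - 1, df["pos"])
    merged = (
        df.assign(pos=anchor)
        .groupby(["chrom", "pos"], as_index=False, sort=True)[["n_meth", "n_total"]]
        .sum()
    )
    merged.insert(2, "strand", "+")
    return CpGCountTable(table.sample_id, merged[_COLUMNS])


def filter_by_coverage(
    table: CpGCountTable, lo: int = 5, hi: int = 100, high_percentile: float = 99.9
) -> CpGCountTable:
    """Keep records with lo <= n_total <= min(hi, per-sample percentile cap).

    The cap is the nearest-rank ``high_percentile`` of this sample's
    pre-filter totals, removing PCR-duplicate-like coverage outliers.
    """
    if lo > hi:
        raise ValueError("lo must be <= hi")
    df = table.data
    if df.empty:
        return CpGCountTable(table.sample_id, df.copy())
    totals = np.sort(df["n_total"].to_numpy())
    # nearest-rank; the small epsilon guards binary rounding of q/100 * n
    rank = max(1, math.ceil(high_percentile * len(totals) / 100.0 - 1e-9))
    cap = int(totals[min(rank, len(totals)) - 1])
    hi_eff = min(hi, cap)
    keep = (df["n_total"] >= lo) & (df["n_total"] <= hi_eff)
    return CpGCountTable(table.sample_id, df.loc[keep].reset_index(drop=True))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def normalize_coverage(tables: list[CpGCountTable]) -> tuple[list[CpGCountTable], QCReport]:
    """Scale each sample's coverage toward the median of per-sample medians.

    f_s = median-of-medians / sample median; totals are rescaled and
    rounded, methylated counts follow proportionally so the methylation
    proportion is preserved to within one read.
    """
    if len(tables) < 2:
        raise ValueError("normalization needs at least 2 samples")
    medians = {t.sample_id: float(np.median(t.data["n_total"])) for t in tables}
    if any(m == 0 for m in medians.values()):
        raise ValueError("zero median coverage in at least one sample")
    target = float(np.median(list(medians.values())))
    factors = {sid: target / m for sid, m in medians.items()}
    out = []
    for t in tables:
        f = factors[t.sample_id]
        df = t.data.copy()
        old_total = df["n_total"].to_numpy(dtype=float)
        new_total = np.maximum(_round_half_up(f * old_total), 1).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            new_meth = _round_half_up(df["n_meth"].to_numpy() * new_total / np.maximum(old_total, 1))
        df["n_total"] = new_total
        df["n_meth"] = np.clip(new_meth, 0, new_total).astype(int)
        out.append(CpGCountTable(t.sample_id, df))
    report = QCReport(median_coverage=medians, scaling_factors=factors)
    return out, report


def unite(
    tables: list[CpGCountTable],
    sample_sheet: pd.DataFrame,
    min_group_fraction: float = 0.8,
) -> UnitedMatrix:
    """Merge samples on shared loci covered in >= ``min_group_fraction`` of
    samples of every group (ceiling rule: 4 of 5 passes at 0.8).

    ``sample_sheet`` needs columns sample_id, group, lane; every table's
    sample must appear in it.
    """
    sheet = sample_sheet.reset_index(drop=True)
    known = set(sheet["sample_id"])
    ids = [t.sample_id for t in tables]
    unknown = [s for s in ids if s not in known]
    if unknown:
        raise ValueError(f"samples missing from sample sheet: {unknown}")
    sheet = sheet[sheet["sample_id"].isin(ids)].reset_index(drop=True)
    order = {sid: i for i, sid in enumerate(sheet["sample_id"])}
    tables = sorted(tables, key=lambda t: order[t.sample_id])

    frames = []
    for t in tables:
        df = t.data[["chrom", "pos", "n_meth", "n_total"]].copy()
        df["sample_id"] = t.sample_id
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    meth = long.pivot_table(index=["chrom", "pos"], columns="sample_id", values="n_meth")
    total = long.pivot_table(index=["chrom", "pos"], columns="sample_id", values="n_total")
    meth = meth.reindex(columns=sheet["sample_id"])
    total = total.reindex(columns=sheet["sample_id"])

    covered = total.notna().to_numpy()
    keep = np.ones(len(total), dtype=bool)
    for group, members in sheet.groupby("group").groups.items():
        cols = sheet.index.get_indexer(members)
        need = math.ceil(min_group_fraction * len(cols))
        keep &= covered[:, cols].sum(axis=1) >= need
    meth = meth.loc[keep]
    total = total.loc[keep]
    loci = meth.index.to_frame(index=False)
    loci["strand"] = "+"
    return UnitedMatrix(
        loci=loci[["chrom", "pos", "strand"]],
        samples=sheet[["sample_id", "group", "lane"]],
        n_meth=meth.to_numpy(dtype=float),
        n_total=total.to_numpy(dtype=float),
    )


def lane_overdispersion(matrix: UnitedMatrix) -> float:
    """Lane batch-effect diagnostic lambda.

    For each locus, the methylation level of each sequencing lane is the
    pooled proportion over that lane's samples; lambda is the mean over
    loci of [variance of the lane levels] / [their expected binomial
    sampling variance]. Values near 1 indicate no lane effect; loci whose
    pooled methylation is 0 or 1 (zero expected variance) are excluded.
    """
    lanes = matrix.samples["lane"].to_numpy()
    uniq = np.unique(lanes)
    if uniq.size < 2:
        raise ValueError("lane overdispersion needs >= 2 lanes")
    X = np.nan_to_num(matrix.n_meth)
    N = np.nan_to_num(matrix.n_total)
    lane_meth = np.stack([X[:, lanes == l].sum(axis=1) for l in uniq], axis=1)
    lane_total = np.stack([N[:, lanes == l].sum(axis=1) for l in uniq], axis=1)
    ok = (lane_total > 0).all(axis=1)
    lane_meth, lane_total = lane_meth[ok], lane_total[ok]
    p_lane = lane_meth / lane_total
    p_bar = lane_meth.sum(axis=1) / lane_total.sum(axis=1)
    obs_var = p_lane.var(axis=1, ddof=1)
    exp_var = (p_bar * (1 - p_bar))[:, None] / lane_total
    exp_var = exp_var.mean(axis=1)
    usable = exp_var > 0
    if not usable.any():
        raise ValueError("no locus with nonzero expected lane variance")
    return float((obs_var[usable] / exp_var[usable]).mean())
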