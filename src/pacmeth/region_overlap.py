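"""Region-set intersection, Venn counts, gene annotation, and the
slot-based permutation null for overlap significance.

The permutation null treats the genome as M = round(G / L) interchangeable
region slots (G = genome length, L = mean DMR length, default
round(1.3e9 / 400) = 3,250,000): each DMR set is a uniform
without-replacement draw of slots, and two sets overlap where they share a
slot. The intersection size of independent uniform slot subsets of sizes a
and b is exactly Hypergeometric(M, a, b) — the null is therefore sampled
from that distribution directly (and for triples from the nested
conditional hypergeometric), which is distributionally identical to
materialising the slot draws but O(rounds) instead of O(rounds x M).
Empirical p-values use the add-one convention (1 + #{null >= obs}) /
(1 + R), so p is never exactly zero at finite R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SlotNull",
    "OverlapResult",
    "count_overlaps",
    "venn_counts",
    "shared_percentage",
    "slot_permutation_test",
    "overlap_difference_test",
    "annotate_dmrs",
    "read_gene_annotation",
    "merge_regions",
]


@dataclass
class SlotNull:
    """Slot-permutation null configuration."""

    genome_size: float = 1.3e9
    mean_length: float = 400.0
    rounds: int = 10_000
    seed: int = 0

    @property
    def n_slots(self) -> int:
        return int(round(self.genome_size / self.mean_length))

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.n_slots < 1:
            raise ValueError("slot count must be >= 1")


@dataclass
class OverlapResult:
    observed: float
    null_mean: float
    pvalue: float
    rounds: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "pvalue": self.pvalue,
            "rounds": self.rounds,
        }


# ---------------------------------------------------------------------------
# interval operations (half-open, 0-based)


def _as_frame(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions[["chrom", "start", "end"]]
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def merge_regions(regions) -> pd.DataFrame:
    """Merge overlapping/abutting-free intervals within a set (half-open:
    [0,100) and [100,200) stay separate)."""
    df = _as_frame(regions).sort_values(["chrom", "start", "end"])
    rows = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _trees(regions: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in regions.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"]) if e > s
        )
    return trees


def count_overlaps(regions_a, regions_b, mode: str = "first") -> int:
    """Overlap count between two region sets (>= 1 bp, half-open).

    ``mode='first'``: number of regions in A overlapping any region of B
    (the asymmetric convention behind the reported shared-DMR counts).
    ``mode='events'``: distinct overlap events after merging each set
    internally (symmetric).
    """
    A = _as_frame(regions_a)
    B = _as_frame(regions_b)
    if mode == "events":
        A, B = merge_regions(A), merge_regions(B)
    trees = _trees(B)
    n = 0
    for r in A.itertuples(index=False):
        t = trees.get(r.chrom)
        if t is not None and t.overlaps(int(r.start), int(r.end)):
            n += 1
    return n


def venn_counts(sets: dict[str, "pd.DataFrame"]) -> dict[tuple[str, ...], int]:
    """Membership-class counts for up to three region sets.

    Regions from all sets are clustered into connected overlap components;
    each component contributes one count to the class given by the set
    names it touches. Class counts therefore sum to the number of distinct
    (merged) regions across sets.
    """
    frames = []
    for name, regions in sets.items():
        df = merge_regions(regions).copy()
        df["set"] = name
        frames.append(df)
    allr = pd.concat(frames, ignore_index=True).sort_values(["chrom", "start", "end"])
    counts: dict[tuple[str, ...], int] = {}
    for _, sub in allr.groupby("chrom", sort=True):
        comp_sets: set[str] = set()
        comp_end = None
        for r in sub.itertuples(index=False):
            if comp_end is None or r.start >= comp_end:
                if comp_end is not None:
                    key = tuple(sorted(comp_sets))
                    counts[key] = counts.get(key, 0) + 1
                comp_sets = {r.set}
                comp_end = r.end
            else:
                comp_sets.add(r.set)
                comp_end = max(comp_end, r.end)
        if comp_end is not None:
            key = tuple(sorted(comp_sets))
            counts[key] = counts.get(key, 0) + 1
    return counts


def shared_percentage(shared: int, set_sizes: list[int]) -> float:
    """100 x shared / sum(set sizes), to 2 decimals."""
    total = sum(set_sizes)
    if total <= 0 or any(s <= 0 for s in set_sizes):
        raise ValueError("set sizes must be positive")
    return round(100.0 * shared / total, 2)


# ---------------------------------------------------------------------------
# slot permutation null


def _null_overlaps(set_sizes: tuple[int, ...], null: SlotNull, rng) -> np.ndarray:
    M = null.n_slots
    if any(s > M for s in set_sizes):
        raise ValueError(f"set size exceeds slot count M={M}")
    if len(set_sizes) == 2:
        a, b = set_sizes
        return rng.hypergeometric(a, M - a, b, size=null.rounds)
    if len(set_sizes) == 3:
        a, b, c = set_sizes
        k = rng.hypergeometric(a, M - a, b, size=null.rounds)
        pos = k > 0
        out = np.zeros(null.rounds, dtype=np.int64)
        if pos.any():
            out[pos] = rng.hypergeometric(k[pos], M - k[pos], c)
        return out
    raise ValueError("slot null supports 2 or 3 sets")


def slot_permutation_test(
    set_sizes: tuple[int, ...], observed: int, null: SlotNull
) -> OverlapResult:
    """One-sided upper-tail permutation p for the observed overlap count
    between 2 (or 3) region sets under the slot null."""
    rng = np.random.default_rng(null.seed)
    sims = _null_overlaps(tuple(set_sizes), null, rng)
    p = (1.0 + np.count_nonzero(sims >= observed)) / (1.0 + null.rounds)
    return OverlapResult(
        observed=observed, null_mean=float(sims.mean()), pvalue=float(p), rounds=null.rounds
    )


def overlap_difference_test(
    set_sizes: tuple[int, int, int],
    observed_ab: int,
    observed_ac: int,
    null: SlotNull,
) -> OverlapResult:
    """Two-sided permutation p for D = overlap(A,B) - overlap(A,C).

    Under the slot null the two overlaps are independent hypergeometrics
    (the intersection law depends on A only through its size).
    """
    a, b, c = set_sizes
    rng = np.random.default_rng(null.seed)
    ab = _null_overlaps((a, b), null, rng)
    ac = _null_overlaps((a, c), null, rng)
    d = ab.astype(np.int64) - ac.astype(np.int64)
    d_obs = observed_ab - observed_ac
    p = (1.0 + np.count_nonzero(np.abs(d) >= abs(d_obs))) / (1.0 + null.rounds)
    return OverlapResult(
        observed=d_obs, null_mean=float(d.mean()), pvalue=float(p), rounds=null.rounds
    )


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path, feature: str = "gene") -> pd.DataFrame:
    """Read gene bodies from BED (0-based half-open) or GFF3 (1-based
    inclusive, converted). Returns columns chrom, start, end, gene."""
    path = str(path)
    rows = []
    if path.endswith((".gff", ".gff3")):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != feature:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{f[3]}-{f[4]}"
                rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
    else:
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track", "browser")) or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                rows.append((f[0], int(f[1]), int(f[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def annotate_dmrs(regions, genes: pd.DataFrame) -> list[list[str]]:
    """Genes whose bodies overlap each region by >= 1 bp (possibly empty,
    sorted by gene start within a region)."""
    R = _as_frame(regions)
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), g) for s, e, g in zip(sub["start"], sub["end"], sub["gene"])
        )
    out = []
    for r in R.itertuples(index=False):
        t = trees.get(r.chrom)
        if t is None:
            out.append([])
        else:
            hits = sorted(t.overlap(int(r.start), int(r.end)), key=lambda iv: (iv.begin, iv.data))
            out.append([iv.data for iv in hits])
    return out
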