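"""Synthetic methylome and contaminant-profile generator.

Emulates the statistical structure the downstream analysis assumes: a toy
genome of clustered CpG dyads, planted differentially methylated regions
(DMRs) with a configurable hyper:hypo mix and effect size, per-sample
negative-binomial coverage (~15x) with beta-binomial methylated counts
around a bimodal baseline targeting a global methylation fraction of
~0.67, round-robin sequencing lanes, and per-bird polycyclic aromatic
compound (PAC) concentration tables whose site LMW:HMW composition is
calibrated to target mean ratios.

Everything is deterministic for a fixed seed, so downstream modules are
testable against known ground truth without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meth_io import CpGCountTable

__all__ = [
    "CpGMap",
    "PlantedDMR",
    "SiteProfile",
    "generate_genome_layout",
    "plant_dmrs",
    "generate_methylomes",
    "generate_pac_table",
    "default_site_profiles",
    "write_planted_bed",
    "PAC_COMPOUNDS",
]


@dataclass
class CpGMap:
    """Plus-strand C positions of CpG dyads on one chromosome (1-based)."""

    chrom: str
    positions: np.ndarray
    chrom_length: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=int)
        if pos.size:
            if not (np.diff(pos) >= 2).all():
                raise ValueError("CpG dyads must be strictly increasing and >= 2 bp apart")
            if pos[0] < 1 or pos[-1] > self.chrom_length - 1:
                raise ValueError("CpG position outside [1, chrom_length - 1]")
        self.positions = pos


@dataclass
class PlantedDMR:
    """Ground-truth differentially methylated interval (0-based half-open).

    ``delta`` is the signed methylation-proportion shift applied to the
    exposed group inside the interval (positive = hypermethylated).
    """

    chrom: str
    start: int
    end: int
    delta: float

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SiteProfile:
    """Target composition of one collection site's PAC burden.

    ``lmw_hmw_ratio`` is the target site mean of per-bird LMW:HMW
    concentration ratios; ``mean_usepa`` the target mean of the summed 16
    USEPA priority PACs (ng/g), or None to leave parents uncalibrated.
    ``tail_fraction`` birds carry a ``tail_multiplier``-fold LMW burden,
    modelling episodic acute petrogenic exposure (oil-spill-like sites).
    """

    name: str
    lmw_hmw_ratio: float
    n_birds: int
    mean_usepa: float | None = None
    tail_fraction: float = 0.0
    tail_multiplier: float = 10.0
    sigma: float = 0.4
    bird_sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.lmw_hmw_ratio <= 0:
            raise ValueError("lmw_hmw_ratio must be > 0")
        if self.n_birds < 1:
            raise ValueError("n_birds must be >= 1")


def default_site_profiles() -> list[SiteProfile]:
    """The four study sites with their reported mean LMW:HMW ratios,
    mean USEPA16 burdens (ng/g lipid weight) and sample sizes."""
    return [
        SiteProfile("REFERENCE", 3.66, 21, mean_usepa=1.89),
        SiteProfile("SPILL", 4.99, 14, mean_usepa=40.71, tail_fraction=0.3),
        SiteProfile("SHIP", 1.81, 16, mean_usepa=11.77),
        SiteProfile("SEEP", 0.63, 28, mean_usepa=93.67),
    ]


# ---------------------------------------------------------------------------
# genome layout


def generate_genome_layout(
    n_chrom: int,
    chrom_length: int,
    n_cpg: int,
    cluster_spacing: int = 50,
    seed: int = 0,
) -> list[CpGMap]:
    """Place ``n_cpg`` CpG dyads per chromosome in clusters of ~5 so that
    runs of >=3 CpGs within 100 bp exist (DMR-callable territory)."""
    if n_cpg * 2 > chrom_length:
        raise ValueError(
            f"infeasible CpG density: {n_cpg} dyads need >= {n_cpg * 2} bp, "
            f"chromosome is {chrom_length} bp"
        )
    rng = np.random.default_rng(seed)
    maps = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        if n_cpg == 0:
            maps.append(CpGMap(chrom, np.array([], dtype=int), chrom_length))
            continue
        gap_hi = max(3, cluster_spacing)
        # within-cluster gaps in [2, gap_hi]; every ~5th gap is a large
        # between-cluster jump taken from the remaining slack
        gaps = rng.integers(2, gap_hi + 1, size=n_cpg - 1) if n_cpg > 1 else np.array([], int)
        n_clusters = max(1, n_cpg // 5)
        slack = chrom_length - 2 - (1 + int(gaps.sum()))
        if slack < 0:
            raise ValueError("infeasible CpG density for requested cluster spacing")
        # distribute the slack over leading offset, between-cluster jumps
        # and a trailing margin (stars and bars)
        n_jumps = min(n_clusters - 1, max(0, n_cpg - 1))
        bins = n_jumps + 2
        parts = rng.multinomial(slack, np.full(bins, 1.0 / bins))
        gaps = gaps.astype(int)
        if n_jumps > 0:
            jump_idx = rng.choice(n_cpg - 1, size=n_jumps, replace=False)
            gaps[jump_idx] += parts[1:-1]
        start = 1 + int(parts[0])
        pos = start + np.concatenate([[0], np.cumsum(gaps)]) if n_cpg > 1 else np.array([start])
        pos = pos[pos <= chrom_length - 1]
        if len(pos) < n_cpg:
            raise ValueError("could not place all CpGs inside the chromosome")
        maps.append(CpGMap(chrom, pos.astype(int), chrom_length))
    return maps


# ---------------------------------------------------------------------------
# planted DMRs


def plant_dmrs(
    cpg_maps: list[CpGMap],
    n_dmr: int,
    mean_length: float = 400.0,
    delta: float = 0.25,
    hyper_fraction: float = 0.5,
    min_cpg: int = 3,
    seed: int = 0,
    max_tries: int = 200,
) -> list[PlantedDMR]:
    """Plant ``n_dmr`` mutually non-overlapping DMR intervals.

    Lengths are Gamma(shape=4) with the requested mean (truncated at 50 bp);
    each interval must contain >= ``min_cpg`` CpGs. Direction is hyper with
    probability ``hyper_fraction`` and the signed delta follows.
    """
    if not 0 <= hyper_fraction <= 1:
        raise ValueError("hyper_fraction must be in [0, 1]")
    if n_dmr == 0:
        return []
    rng = np.random.default_rng(seed)
    placed: list[PlantedDMR] = []
    used: dict[str, list[tuple[int, int]]] = {m.chrom: [] for m in cpg_maps}
    eligible = [m for m in cpg_maps if len(m.positions) >= min_cpg]
    if not eligible:
        raise ValueError("cannot place DMRs: no chromosome has enough CpGs")
    weights = np.array([len(m.positions) for m in eligible], dtype=float)
    weights /= weights.sum()
    for _ in range(n_dmr):
        ok = False
        for _try in range(max_tries):
            m = eligible[rng.choice(len(eligible), p=weights)]
            length = max(50, int(round(rng.gamma(4.0, mean_length / 4.0))))
            anchor = int(m.positions[rng.integers(0, len(m.positions))])
            start = max(0, anchor - length // 2)
            end = min(m.chrom_length, start + length)
            if end - start < 50:
                continue
            inside = np.count_nonzero((m.positions > start) & (m.positions <= end))
            if inside < min_cpg:
                continue
            if any(start < e and s < end for s, e in used[m.chrom]):
                continue
            sign = 1.0 if rng.random() < hyper_fraction else -1.0
            placed.append(PlantedDMR(m.chrom, start, end, sign * abs(delta)))
            used[m.chrom].append((start, end))
            ok = True
            break
        if not ok:
            raise ValueError(
                f"cannot place {n_dmr} non-overlapping DMRs with >= {min_cpg} CpGs "
                f"and length >= 50 bp after {max_tries} tries (placed {len(placed)})"
            )
    return placed


def write_planted_bed(dmrs: list[PlantedDMR], path) -> None:
    """BED6: name = direction, score = 1000 * |delta|."""
    with open(path, "w") as fh:
        for d in sorted(dmrs, key=lambda d: (d.chrom, d.start)):
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t"
                f"{int(round(1000 * abs(d.delta)))}\t.\n"
            )


# ---------------------------------------------------------------------------
# methylomes

# bimodal vertebrate CpG methylation: mostly-methylated and mostly-
# unmethylated components; mixture weight solves the global mean
_BETA_HI = (5.0, 0.5)
_BETA_LO = (0.5, 5.0)


def _mixture_weight(target: float) -> float:
    m_hi = _BETA_HI[0] / sum(_BETA_HI)
    m_lo = _BETA_LO[0] / sum(_BETA_LO)
    w = (target - m_lo) / (m_hi - m_lo)
    if not 0.0 <= w <= 1.0:
        raise ValueError(
            f"global methylation target {target} outside the achievable "
            f"range [{m_lo:.3f}, {m_hi:.3f}] of the baseline mixture"
        )
    return w


def generate_methylomes(
    cpg_maps: list[CpGMap],
    dmrs: list[PlantedDMR],
    n_per_group: tuple[int, int] = (8, 8),
    group_names: tuple[str, str] = ("REFERENCE", "EXPOSED"),
    coverage_mean: float = 15.0,
    coverage_size: float = 10.0,
    dispersion: float = 0.05,
    global_meth: float = 0.67,
    baseline: float | None = None,
    n_lanes: int = 3,
    lane_offset: float = 0.0,
    seed: int = 0,
) -> tuple[list[CpGCountTable], pd.DataFrame]:
    """Simulate per-sample CpG count tables plus a sample sheet.

    Coverage ~ NegBin(mean=coverage_mean, size=coverage_size); methylated
    counts are beta-binomial with dispersion ``dispersion`` around a
    per-locus baseline (fixed ``baseline`` if given, else the bimodal
    mixture hitting ``global_meth``). Exposed samples are shifted by each
    planted DMR's delta inside its interval, clipped to [0, 1]; planted
    intervals draw their baseline from an intermediate-methylation band so
    the shift is realizable. Lanes are assigned round-robin; a nonzero
    ``lane_offset`` adds a centered per-lane shift for batch-effect tests.
    """
    if coverage_mean < 1:
        raise ValueError("coverage_mean must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)

    chrom_arr, pos_arr, base_arr, delta_arr = [], [], [], []
    for m in cpg_maps:
        n = len(m.positions)
        if baseline is not None:
            if not 0.0 <= baseline <= 1.0:
                raise ValueError("baseline must be in [0, 1]")
            base = np.full(n, float(baseline))
        else:
            w = _mixture_weight(global_meth)
            hi = rng.random(n) < w
            base = np.where(
                hi,
                rng.beta(*_BETA_HI, size=n),
                rng.beta(*_BETA_LO, size=n),
            )
        delta = np.zeros(n)
        for d in (d for d in dmrs if d.chrom == m.chrom):
            inside = (m.positions > d.start) & (m.positions <= d.end)
            if baseline is None and inside.any():
                # regulatory-region band: effect survives [0,1] clipping
                lo_b = max(0.25, -d.delta) + 0.05
                hi_b = min(0.75, 1.0 - d.delta) - 0.05
                b0 = rng.uniform(lo_b, hi_b)
                base[inside] = np.clip(
                    b0 + rng.uniform(-0.08, 0.08, size=int(inside.sum())), 0.02, 0.98
                )
            delta[inside] = d.delta
        chrom_arr.append(np.repeat(m.chrom, n))
        pos_arr.append(m.positions)
        base_arr.append(base)
        delta_arr.append(delta)
    chrom = np.concatenate(chrom_arr) if chrom_arr else np.array([], dtype=str)
    pos = np.concatenate(pos_arr) if pos_arr else np.array([], dtype=int)
    base = np.concatenate(base_arr) if base_arr else np.array([])
    delta = np.concatenate(delta_arr) if delta_arr else np.array([])
    n_loci = len(pos)

    nb_p = coverage_size / (coverage_size + coverage_mean)
    lane_shift = (
        lane_offset * (np.arange(n_lanes) - (n_lanes - 1) / 2.0) / max(1, (n_lanes - 1) / 2.0)
        if n_lanes > 1
        else np.zeros(1)
    )

    tables, rows = [], []
    sample_index = 0
    for gi, (gname, gsize) in enumerate(zip(group_names, n_per_group)):
        exposed = gi == 1
        for k in range(gsize):
            sid = f"{gname}_{k + 1:02d}"
            lane = sample_index % n_lanes
            p = np.clip(base + (delta if exposed else 0.0) + lane_shift[lane], 0.0, 1.0)
            N = rng.negative_binomial(coverage_size, nb_p, size=n_loci)
            if dispersion > 0:
                a = p * (1 - dispersion) / dispersion
                b = (1 - p) * (1 - dispersion) / dispersion
                # boundary p in {0,1} degenerates to a point mass
                interior = (p > 0) & (p < 1)
                pj = p.copy()
                if interior.any():
                    pj[interior] = rng.beta(a[interior], b[interior])
            else:
                pj = p
            X = rng.binomial(N, pj)
            keep = N > 0
            tables.append(
                CpGCountTable(
                    sid,
                    pd.DataFrame(
                        {
                            "chrom": chrom[keep],
                            "pos": pos[keep],
                            "strand": "+",
                            "n_meth": X[keep],
                            "n_total": N[keep],
                        }
                    ),
                )
            )
            rows.append({"sample_id": sid, "group": gname, "lane": lane})
            sample_index += 1
    return tables, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PAC tables

# (name, rings, alkylated, heterocyclic, usepa16, reference-scale mean ng/g)
PAC_COMPOUNDS: list[tuple[str, int, bool, bool, bool, float]] = [
    # parent LMW (2-3 rings)
    ("naphthalene", 2, False, False, True, 0.70),
    ("acenaphthylene", 3, False, False, True, 0.05),
    ("acenaphthene", 3, False, False, True, 0.10),
    ("fluorene", 3, False, False, True, 0.25),
    ("phenanthrene", 3, False, False, True, 0.65),
    ("anthracene", 3, False, False, True, 0.14),
    # alkylated LMW
    ("C1-naphthalenes", 2, True, False, False, 90.0),
    ("C2-naphthalenes", 2, True, False, False, 110.0),
    ("C3-naphthalenes", 2, True, False, False, 55.0),
    ("C1-phenanthrenes", 3, True, False, False, 25.0),
    ("C2-phenanthrenes", 3, True, False, False, 14.5),
    # parent HMW (4-6 rings)
    ("fluoranthene", 4, False, False, True, 0.010),
    ("pyrene", 4, False, False, True, 0.012),
    ("benz[a]anthracene", 4, False, False, True, 0.004),
    ("chrysene", 4, False, False, True, 0.006),
    ("benzo[b]fluoranthene", 5, False, False, True, 0.003),
    ("benzo[k]fluoranthene", 5, False, False, True, 0.002),
    ("benzo[a]pyrene", 5, False, False, True, 0.003),
    ("indeno[1,2,3-cd]pyrene", 6, False, False, True, 0.002),
    ("dibenz[a,h]anthracene", 5, False, False, True, 0.001),
    ("benzo[ghi]perylene", 6, False, False, True, 0.002),
    # alkylated HMW
    ("C1-fluoranthenes/pyrenes", 4, True, False, False, 45.0),
    ("C1-chrysenes", 4, True, False, False, 24.0),
    ("C2-chrysenes", 4, True, False, False, 12.0),
    # heterocyclic
    ("dibenzothiophene", 3, False, True, False, 0.05),
    ("C1-dibenzothiophenes", 3, True, True, False, 10.0),
    ("C2-dibenzothiophenes", 3, True, True, False, 7.8),
]


def generate_pac_table(profiles: list[SiteProfile], seed: int = 0) -> pd.DataFrame:
    """Per-bird, per-compound lognormal PAC concentrations.

    Bird-level LMW and HMW burdens vary lognormally (plus an optional
    heavy-tail mixture on the LMW side); the site's HMW mass is then scaled
    so the realized site mean LMW:HMW ratio equals the profile target, and
    parent compounds are scaled so the mean summed USEPA16 matches
    ``mean_usepa`` when given. Heterocyclics are excluded from the ratio.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rng = np.random.default_rng(seed)
    comp = pd.DataFrame(
        PAC_COMPOUNDS,
        columns=["compound", "rings", "alkylated", "heterocyclic", "usepa16", "ref_mean"],
    )
    is_lmw = (comp["rings"] <= 3) & ~comp["heterocyclic"]
    is_hmw = (comp["rings"] >= 4) & ~comp["heterocyclic"]
    frames = []
    for prof in profiles:
        nb, nc = prof.n_birds, len(comp)
        sig = prof.sigma
        conc = comp["ref_mean"].to_numpy()[None, :] * rng.lognormal(
            -0.5 * sig**2, sig, size=(nb, nc)
        )
        # bird-level composition effects
        bs = prof.bird_sigma
        lmw_eff = rng.lognormal(-0.5 * bs**2, bs, size=nb)
        hmw_eff = rng.lognormal(-0.5 * bs**2, bs, size=nb)
        if prof.tail_fraction > 0:
            tail = rng.random(nb) < prof.tail_fraction
            lmw_eff = np.where(tail, lmw_eff * prof.tail_multiplier, lmw_eff)
        conc[:, is_lmw.to_numpy()] *= lmw_eff[:, None]
        conc[:, is_hmw.to_numpy()] *= hmw_eff[:, None]
        # calibrate the site composition to the profile targets
        if prof.mean_usepa is not None:
            usepa_sum = conc[:, comp["usepa16"].to_numpy()].sum(axis=1)
            conc[:, comp["usepa16"].to_numpy()] *= prof.mean_usepa / usepa_sum.mean()
        lmw_sum = conc[:, is_lmw.to_numpy()].sum(axis=1)
        hmw_sum = conc[:, is_hmw.to_numpy()].sum(axis=1)
        ratios = lmw_sum / hmw_sum
        conc[:, is_hmw.to_numpy()] *= ratios.mean() / prof.lmw_hmw_ratio
        for b in range(nb):
            frames.append(
                pd.DataFrame(
                    {
                        "bird_id": f"{prof.name}_{b + 1:02d}",
                        "site": prof.name,
                        "compound": comp["compound"],
                        "rings": comp["rings"],
                        "alkylated": comp["alkylated"],
                        "heterocyclic": comp["heterocyclic"],
                        "usepa16": comp["usepa16"],
                        "concentration": conc[b],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
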