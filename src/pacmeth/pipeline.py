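"""End-to-end orchestration: simulate -> unite -> DML -> DMR -> overlap ->
site statistics, with a serialized config, per-stage seeds, logging and a
checksummed output manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diff_meth, dmr_call, meth_io, region_overlap, simulate, site_stats

__all__ = ["RunConfig", "run_all"]

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets so stages rerun alone reproduce themselves
_STAGE_SEEDS = {"genome": 11, "dmrs": 23, "methylomes": 37, "pac": 53, "overlap": 71}


@dataclass
class RunConfig:
    """Configuration of one reproducible synthetic analysis run."""

    out_dir: str = "pacmeth_run"
    seed: int = 0
    # genome / simulation scale
    n_chrom: int = 2
    chrom_length: int = 300_000
    n_cpg_per_chrom: int = 1_500
    cluster_spacing: int = 50
    # planted effects
    n_dmr: int = 40
    dmr_mean_length: float = 400.0
    dmr_delta: float = 0.25
    hyper_fraction: float = 0.1
    site_dmr_prob: float = 0.6
    # sequencing design
    reference_group: str = "REFERENCE"
    exposed_groups: tuple[str, ...] = ("SPILL", "SHIP", "SEEP")
    n_per_group: dict = field(
        default_factory=lambda: {"REFERENCE": 8, "SPILL": 8, "SHIP": 8, "SEEP": 8}
    )
    coverage_mean: float = 15.0
    coverage_size: float = 10.0
    dispersion: float = 0.05
    global_meth: float = 0.67
    n_lanes: int = 3
    # thresholds (analysis defaults)
    lo_count: int = 5
    hi_count: int = 100
    high_percentile: float = 99.9
    min_group_fraction: float = 0.8
    p_threshold: float = 0.01
    fdr_threshold: float = 0.05
    min_len: int = 50
    min_cpg: int = 3
    pct_sig: float = 0.5
    merge_dist: int = 100
    covariate: str | None = None
    # overlap null
    genome_size: float | None = None  # None -> actual simulated genome size
    mean_region_length: float = 400.0
    rounds: int = 10_000

    def validate(self) -> None:
        if not 0 < self.min_group_fraction <= 1:
            raise ValueError("min_group_fraction must be in (0, 1]")
        if not 0 < self.p_threshold < 1 or not 0 < self.fdr_threshold < 1:
            raise ValueError("thresholds must be in (0, 1)")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.reference_group in self.exposed_groups:
            raise ValueError("reference group cannot also be exposed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "exposed_groups" in data:
            data["exposed_groups"] = tuple(data["exposed_groups"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["exposed_groups"] = list(self.exposed_groups)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run every stage and return the output directory.

    Outputs: sim/ (coverage files, sample sheet, planted DMR BED, PAC
    table), united matrices, DML and DMR tables per comparison, overlap
    and statistics JSON, manifest.json with a sha256 per output file.
    Rerunning with the same config and seed reproduces identical
    checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    stage = "setup"
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "sim").mkdir(exist_ok=True)
        config.to_yaml(out / "config.yaml")
        log: dict = {"stages": {}}

        # --- simulate -----------------------------------------------------
        stage = "simulate"
        rng = np.random.default_rng(config.seed)
        base = int(rng.integers(0, 2**31 - 1))
        maps = simulate.generate_genome_layout(
            config.n_chrom,
            config.chrom_length,
            config.n_cpg_per_chrom,
            config.cluster_spacing,
            seed=(base + _STAGE_SEEDS["genome"]) % 2**31,
        )
        pool = simulate.plant_dmrs(
            maps,
            config.n_dmr,
            mean_length=config.dmr_mean_length,
            delta=config.dmr_delta,
            hyper_fraction=config.hyper_fraction,
            seed=(base + _STAGE_SEEDS["dmrs"]) % 2**31,
        )
        assign_rng = np.random.default_rng((base + _STAGE_SEEDS["dmrs"] + 1) % 2**31)
        site_dmrs = {
            site: [d for d in pool if assign_rng.random() < config.site_dmr_prob]
            for site in config.exposed_groups
        }
        simulate.write_planted_bed(pool, out / "sim" / "planted_dmrs.bed")

        all_tables: dict[str, list] = {}
        sheets = []
        for gi, site in enumerate(config.exposed_groups):
            tables, sheet = simulate.generate_methylomes(
                maps,
                site_dmrs[site],
                n_per_group=(
                    config.n_per_group[config.reference_group],
                    config.n_per_group[site],
                ),
                group_names=(config.reference_group, site),
                coverage_mean=config.coverage_mean,
                coverage_size=config.coverage_size,
                dispersion=config.dispersion,
                global_meth=config.global_meth,
                n_lanes=config.n_lanes,
                seed=(base + _STAGE_SEEDS["methylomes"] + gi) % 2**31,
            )
            # the reference site is simulated once, with the first comparison
            if gi == 0:
                keep = tables
                sheets.append(sheet)
            else:
                keep = [t for t in tables if not t.sample_id.startswith(config.reference_group)]
                sheets.append(sheet[sheet["group"] == site])
            all_tables[site] = tables
            for t in keep:
                meth_io.write_bismark_coverage(t, out / "sim" / f"{t.sample_id}.cov")
        sheet_all = pd.concat(sheets, ignore_index=True).drop_duplicates("sample_id")
        sheet_all.to_csv(out / "sim" / "sample_sheet.tsv", sep="\t", index=False)
        pac = simulate.generate_pac_table(
            [
                p
                for p in simulate.default_site_profiles()
                if p.name in (config.reference_group, *config.exposed_groups)
            ],
            seed=(base + _STAGE_SEEDS["pac"]) % 2**31,
        )
        pac.to_csv(out / "sim" / "pac_table.tsv", sep="\t", index=False, float_format="%.6g")
        log["stages"]["simulate"] = {
            "n_loci": sum(len(m.positions) for m in maps),
            "n_planted_dmrs": len(pool),
            "n_samples": int(len(sheet_all)),
        }

        # --- per-comparison unite / DML / DMR ------------------------------
        dmr_sets: dict[str, pd.DataFrame] = {}
        direction: dict[str, dict] = {}
        for site in config.exposed_groups:
            stage = f"unite[{site}]"
            tables = all_tables[site]
            tables = [
                meth_io.filter_by_coverage(
                    meth_io.destrand(t), config.lo_count, config.hi_count, config.high_percentile
                )
                for t in tables
            ]
            tables, qc = meth_io.normalize_coverage(tables)
            sheet = sheet_all[sheet_all["sample_id"].isin([t.sample_id for t in tables])]
            matrix = meth_io.unite(tables, sheet, config.min_group_fraction)
            if config.n_lanes >= 2:
                qc.lane_lambda = meth_io.lane_overdispersion(matrix)
            matrix.to_tsv(out / f"united_{site}.tsv")
            qc.to_json(out / f"qc_{site}.json")
            log["stages"][f"unite[{site}]"] = {"n_loci": matrix.n_loci}

            stage = f"dml[{site}]"
            dml = diff_meth.dml_test(
                matrix, site, config.reference_group, covariate=config.covariate
            )
            dml.to_csv(out / f"dml_{site}.tsv", sep="\t", index=False, float_format="%.6g")
            log["stages"][f"dml[{site}]"] = {
                "n_loci": len(dml),
                "n_fdr_sig": int((dml["qvalue"] < config.fdr_threshold).sum()),
            }

            stage = f"dmr[{site}]"
            regions = dmr_call.call_dmrs(
                dml,
                p_threshold=config.p_threshold,
                min_len=config.min_len,
                min_cpg=config.min_cpg,
                pct_sig=config.pct_sig,
                merge_dist=config.merge_dist,
            )
            dmr_call.write_regions_bed(regions, out / f"dmrs_{site}.bed")
            dmr_sets[site] = regions
            direction[site] = dmr_call.classify_directions(regions)._asdict()
            log["stages"][f"dmr[{site}]"] = {"n_dmrs": len(regions), **direction[site]}

        # --- overlap ------------------------------------------------------
        stage = "overlap"
        genome_size = config.genome_size or config.n_chrom * config.chrom_length
        null = region_overlap.SlotNull(
            genome_size=genome_size,
            mean_length=config.mean_region_length,
            rounds=config.rounds,
            seed=(base + _STAGE_SEEDS["overlap"]) % 2**31,
        )
        sites = list(config.exposed_groups)
        overlap_report: dict = {"slots": null.n_slots, "pairwise": {}, "venn": {}}
        sizes = {s: len(dmr_sets[s]) for s in sites}
        for a, b in [(x, y) for i, x in enumerate(sites) for y in sites[i + 1 :]]:
            obs = region_overlap.count_overlaps(dmr_sets[a], dmr_sets[b])
            entry = {
                "observed": obs,
                "shared_pct": region_overlap.shared_percentage(obs, [sizes[a], sizes[b]])
                if sizes[a] and sizes[b]
                else None,
            }
            if min(sizes[a], sizes[b]) > 0:
                res = region_overlap.slot_permutation_test((sizes[a], sizes[b]), obs, null)
                entry.update(null_mean=res.null_mean, pvalue=res.pvalue)
            overlap_report["pairwise"][f"{a}-{b}"] = entry
        if len(sites) == 3:
            venn = region_overlap.venn_counts({s: dmr_sets[s] for s in sites})
            overlap_report["venn"] = {"+".join(k): v for k, v in venn.items()}
        with open(out / "overlap.json", "w") as fh:
            json.dump(overlap_report, fh, indent=2)
        log["stages"]["overlap"] = {"pairs": len(overlap_report["pairwise"])}

        # --- site statistics ----------------------------------------------
        stage = "stats"
        slots = null.n_slots
        stats_report: dict = {"dmr_counts": sizes, "direction": direction, "chisq": {}}
        for a, b in [(x, y) for i, x in enumerate(sites) for y in sites[i + 1 :]]:
            chi2, p = site_stats.two_prop_chisq(sizes[a], sizes[b], slots)
            stats_report["chisq"][f"{a}-{b}"] = {"chi2": chi2, "pvalue": p}
        ratios = {}
        groups = {}
        for s in pac["site"].unique():
            mean_ratio, per_bird = site_stats.lmw_hmw_ratio(pac, s)
            ratios[s] = mean_ratio
            groups[s] = per_bird.to_numpy()
        stats_report["lmw_hmw_ratio"] = ratios
        exposed_present = [s for s in sites if s in groups]
        if len(exposed_present) >= 2:
            h, p = site_stats.kruskal_wallis([groups[s] for s in exposed_present])
            stats_report["kruskal_wallis"] = {"H": h, "pvalue": p, "df": len(exposed_present) - 1}
            stats_report["pairwise_wilcoxon_bh"] = (
                site_stats.pairwise_wilcoxon_bh({s: groups[s] for s in exposed_present})
                .round(6)
                .to_dict()
            )
        with open(out / "site_stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=2, ensure_ascii=False)
        log["stages"]["stats"] = {"sites": len(ratios)}

        # --- manifest -----------------------------------------------------
        stage = "manifest"
        # config.yaml echoes the input (including out_dir) and is excluded
        files = sorted(
            p
            for p in out.rglob("*")
            if p.is_file() and p.name not in ("manifest.json", "config.yaml")
        )
        manifest = {
            "seed": config.seed,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
            "log": log,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:  # surface which stage failed
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
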