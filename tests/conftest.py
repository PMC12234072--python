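import numpy as np
import pandas as pd
import pytest

from pacmeth import diff_meth, meth_io, simulate


def make_table(records, sample_id="s1"):
    """CpGCountTable from (chrom, pos, strand, n_meth, n_total) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "strand", "n_meth", "n_total"])
    return meth_io.CpGCountTable(sample_id, df)


def simulate_comparison(
    seed=0,
    n_cpg=2000,
    chrom_length=300_000,
    n_dmr=0,
    delta=0.25,
    hyper_fraction=0.5,
    min_cpg=3,
    n_per_group=(8, 8),
    dispersion=0.05,
    coverage_mean=15.0,
    preprocess=True,
    **meth_kwargs,
):
    """One reference-vs-exposed synthetic comparison, ready for dml_test."""
    maps = simulate.generate_genome_layout(1, chrom_length, n_cpg, 50, seed=seed)
    dmrs = (
        simulate.plant_dmrs(
            maps, n_dmr, delta=delta, hyper_fraction=hyper_fraction, min_cpg=min_cpg,
            seed=seed + 1,
        )
        if n_dmr
        else []
    )
    tables, sheet = simulate.generate_methylomes(
        maps,
        dmrs,
        n_per_group=n_per_group,
        dispersion=dispersion,
        coverage_mean=coverage_mean,
        seed=seed + 2,
        **meth_kwargs,
    )
    if preprocess:
        tables = [meth_io.filter_by_coverage(meth_io.destrand(t)) for t in tables]
        tables, _ = meth_io.normalize_coverage(tables)
    matrix = meth_io.unite(tables, sheet)
    return maps, dmrs, matrix


@pytest.fixture(scope="session")
def null_dml():
    """DML results on a null comparison (no planted DMRs)."""
    _, _, matrix = simulate_comparison(seed=11, n_cpg=2000)
    return diff_meth.dml_test(matrix, "EXPOSED", "REFERENCE")


def region_frame(rows):
    """Region DataFrame from (chrom, start, end) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def overlaps_planted(regions, dmr):
    return bool(
        (
            (regions["chrom"] == dmr.chrom)
            & (regions["start"] < dmr.end)
            & (regions["end"] > dmr.start)
        ).any()
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
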