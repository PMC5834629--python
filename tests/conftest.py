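import numpy as np
import pandas as pd
import pytest

from omicsmr.ldpanel import LdPanel
from omicsmr.simulate import SimConfig, make_fixture, simulate_study_set
from omicsmr.summary_io import SNP_COLUMNS
from scipy import stats


def make_snp_table(rows):
    """Build a SNP table from (snp_id, chrom, bp, a1, a2, freq, beta, se, n) tuples."""
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "bp", "a1", "a2", "freq", "beta", "se", "n"])
    z2 = (df["beta"] / df["se"]) ** 2
    df["logp"] = stats.chi2.logsf(z2, df=1)
    df["pvalue"] = np.exp(df["logp"])
    return df[SNP_COLUMNS]


def random_snp_table(rng, n_snps=20, chrom="1", bp_start=1_000_000):
    rows = []
    for i in range(n_snps):
        rows.append((
            f"rs{i + 1}", chrom, bp_start + i * 1000, "A", "G",
            float(rng.uniform(0.05, 0.95)),
            float(rng.normal(0, 0.1)),
            float(rng.uniform(0.01, 0.05)),
            int(rng.integers(500, 5000)),
        ))
    return make_snp_table(rows)


def panel_from_dosages(dosages, chrom="1", bp_start=1_000_000, a1="A", a2="G"):
    dosages = np.asarray(dosages, dtype=float)
    snps = [(f"rs{j + 1}", chrom, bp_start + j * 1000, a1, a2) for j in range(dosages.shape[1])]
    return LdPanel(snps=snps, dosages=dosages)


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory):
    d = tmp_path_factory.mktemp("golden")
    paths = make_fixture(d, seed=7)
    return d, paths


@pytest.fixture(scope="session")
def mediation_set():
    return simulate_study_set(SimConfig(
        model="mediation", seed=11, b_zm=0.5, b_me=0.6, b_et=0.5,
        n_mqtl=2000, n_eqtl=2000, n_gwas=2000, n_panel=1000, n_snps=30,
    ))
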