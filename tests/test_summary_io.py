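import math
from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omicsmr.ldpanel import LdPanel
from omicsmr.summary_io import (
    CisSummary,
    FormatError,
    EmptyIntersectionError,
    ProbeInfo,
    beta_from_z,
    filter_probes,
    flag_inconsistent_pvalues,
    harmonize,
    meta_fixed,
    qtl_variance_explained,
    read_gwas_ma,
    read_probe_annotations,
    read_qtl_flat,
    write_gwas_ma,
    write_qtl_flat,
)

from conftest import make_snp_table, panel_from_dosages, random_snp_table


# ---------------------------------------------------------------------- .ma


class TestReadGwasMa:
    def test_three_valid_rows(self, tmp_path):
        p = tmp_path / "toy.ma"
        p.write_text(
            "SNP A1 A2 freq b se p N\n"
            "rs1 A G 0.3 0.1 0.02 1e-6 10000\n"
            "rs2 C T 0.5 -0.05 0.01 2e-7 10000\n"
            "rs3 G A 0.12 0.0 0.03 1.0 9000\n"
        )
        df = read_gwas_ma(p)
        assert len(df) == 3
        assert list(df["snp_id"]) == ["rs1", "rs2", "rs3"]
        assert df.attrs["report"]["rejected"] == 0

    def test_zero_se_rejected(self, tmp_path):
        p = tmp_path / "bad.ma"
        p.write_text("SNP A1 A2 freq b se p N\nrs1 A G 0.3 0.1 0.0 1e-6 10000\n")
        df = read_gwas_ma(p)
        assert len(df) == 0
        assert df.attrs["report"]["rejected"] == 1

    def test_non_numeric_beta_rejected(self, tmp_path):
        p = tmp_path / "bad.ma"
        p.write_text(
            "SNP A1 A2 freq b se p N\n"
            "rs1 A G 0.3 oops 0.01 1e-6 10000\n"
            "rs2 A G 0.3 0.1 0.01 1e-6 10000\n"
        )
        df = read_gwas_ma(p)
        assert len(df) == 1
        assert df.attrs["report"]["rejected"] == 1

    def test_missing_header_is_format_error(self, tmp_path):
        p = tmp_path / "nohdr.ma"
        p.write_text("rs1 A G 0.3 0.1 0.01 1e-6 10000\n")
        with pytest.raises(FormatError):
            read_gwas_ma(p)

    def test_round_trip_100_records(self, tmp_path):
        rng = np.random.default_rng(42)
        df = random_snp_table(rng, n_snps=100)
        path = tmp_path / "rt.ma"
        write_gwas_ma(df, path)
        back = read_gwas_ma(path)
        assert len(back) == 100
        for col in ("freq", "beta", "se", "pvalue"):
            np.testing.assert_allclose(back[col], df[col], rtol=1e-6)
        assert list(back["n"]) == list(df["n"])
        assert list(back["a1"]) == list(df["a1"])


# ------------------------------------------------------------------ QTL flat


def _write_flat(path, rows):
    with open(path, "w") as fh:
        fh.write("ProbeID\tSNP\tChr\tBP\tA1\tA2\tfreq\tb\tse\tp\tN\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


class TestReadQtlFlat:
    ANN = {
        "cg1": ProbeInfo("cg1", "methylation", "1", 1_000_000),
        "cg2": ProbeInfo("cg2", "methylation", "1", 2_000_000),
    }

    def test_window_rule_excludes_distant_snp(self, tmp_path):
        p = tmp_path / "q.txt"
        _write_flat(p, [
            ("cg1", "rs1", "1", 1_100_000, "A", "G", 0.3, 0.1, 0.02, 1e-6, 600),
            ("cg1", "rs2", "1", 1_600_000, "A", "G", 0.3, 0.1, 0.02, 1e-6, 600),
        ])
        out = read_qtl_flat(p, self.ANN, window_bp=500_000)
        assert list(out["cg1"].records["snp_id"]) == ["rs1"]

    def test_two_probes_grouping(self, tmp_path):
        p = tmp_path / "q.txt"
        _write_flat(p, [
            ("cg1", "rs1", "1", 1_000_100, "A", "G", 0.3, 0.1, 0.02, 1e-6, 600),
            ("cg1", "rs2", "1", 1_000_200, "A", "G", 0.3, 0.1, 0.02, 1e-6, 600),
            ("cg2", "rs3", "1", 2_000_100, "A", "G", 0.3, 0.1, 0.02, 1e-6, 600),
            ("cg2", "rs4", "1", 2_000_200, "A", "G", 0.3, 0.1, 0.02, 1e-6, 600),
        ])
        out = read_qtl_flat(p, self.ANN, window_bp=500_000)
        assert set(out) == {"cg1", "cg2"}
        assert len(out["cg1"]) == 2 and len(out["cg2"]) == 2

    def test_unannotated_probe_skipped(self, tmp_path):
        p = tmp_path / "q.txt"
        _write_flat(p, [("cgX", "rs1", "1", 1_000_100, "A", "G", 0.3, 0.1, 0.02, 1e-6, 600)])
        out = read_qtl_flat(p, self.ANN, window_bp=500_000)
        assert out == {}

    def test_round_trip(self, tmp_path, mediation_set):
        path = tmp_path / "rt.txt"
        write_qtl_flat(mediation_set.mqtl, path)
        ann = {p.probe_id: p for p in mediation_set.annotations.values()}
        back = read_qtl_flat(path, ann, window_bp=mediation_set.mqtl["cg1"].window_bp)
        orig = mediation_set.mqtl["cg1"].records
        got = back["cg1"].records
        assert len(got) == len(orig)
        for col in ("freq", "beta", "se", "pvalue"):
            np.testing.assert_allclose(got[col], orig[col], rtol=1e-6)

    def test_gzip_transparent(self, tmp_path):
        import gzip
        p = tmp_path / "q.txt.gz"
        content = ("ProbeID\tSNP\tChr\tBP\tA1\tA2\tfreq\tb\tse\tp\tN\n"
                   "cg1\trs1\t1\t1000100\tA\tG\t0.3\t0.1\t0.02\t1e-6\t600\n")
        with gzip.open(p, "wt") as fh:
            fh.write(content)
        out = read_qtl_flat(p, self.ANN, window_bp=500_000)
        assert len(out["cg1"]) == 1


def test_probe_annotation_round_trip(tmp_path):
    from omicsmr.summary_io import write_probe_annotations
    probes = [ProbeInfo("cg1", "methylation", "1", 123, "", "unknown"),
              ProbeInfo("e1", "expression", "2", 456, "GENE1", "+")]
    path = tmp_path / "probes.txt"
    write_probe_annotations(probes, path)
    back = read_probe_annotations(path)
    assert back["cg1"] == probes[0]
    assert back["e1"] == probes[1]


# ---------------------------------------------------------------- harmonize


def _simple_panel(sign_alleles=("A", "G")):
    rng = np.random.default_rng(0)
    dos = rng.integers(0, 3, size=(50, 3)).astype(float)
    snps = [("rs1", "1", 1000, sign_alleles[0], sign_alleles[1]),
            ("rs2", "1", 2000, "A", "G"),
            ("rs3", "1", 3000, "A", "G")]
    return LdPanel(snps=snps, dosages=dos)


class TestHarmonize:
    def test_allele_flip(self):
        exp = make_snp_table([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.02, 500)])
        out = make_snp_table([("rs1", "1", 1000, "G", "A", 0.7, 0.25, 0.05, 800)])
        panel = _simple_panel()
        h = harmonize(exp, out, panel, max_freq_diff=1.0)
        assert h.outcome.loc[0, "beta"] == pytest.approx(-0.25)
        assert h.outcome.loc[0, "freq"] == pytest.approx(0.3)
        assert h.outcome.loc[0, "a1"] == "A"

    def test_strand_ambiguous_removed(self):
        exp = make_snp_table([
            ("rs1", "1", 1000, "A", "T", 0.3, 0.1, 0.02, 500),
            ("rs2", "1", 2000, "A", "G", 0.3, 0.1, 0.02, 500),
        ])
        out = exp.copy()
        panel = _simple_panel(("A", "T"))
        h = harmonize(exp, out, panel, max_freq_diff=1.0)
        assert list(h.exposure["snp_id"]) == ["rs2"]
        assert h.report["strand_ambiguous"] == 1

    def test_freq_mismatch_removed(self):
        exp = make_snp_table([("rs1", "1", 1000, "A", "G", 0.10, 0.1, 0.02, 500),
                              ("rs2", "1", 2000, "A", "G", 0.35, 0.1, 0.02, 500)])
        out = make_snp_table([("rs1", "1", 1000, "A", "G", 0.35, 0.1, 0.02, 500),
                              ("rs2", "1", 2000, "A", "G", 0.35, 0.1, 0.02, 500)])
        # panel frequencies compatible with 0.35
        dos = np.full((50, 3), 0.0)
        dos[:35, :] = 1.0
        panel = LdPanel(snps=[("rs1", "1", 1000, "A", "G"), ("rs2", "1", 2000, "A", "G"),
                              ("rs3", "1", 3000, "A", "G")], dosages=dos)
        h = harmonize(exp, out, panel)
        assert list(h.exposure["snp_id"]) == ["rs2"]  # 0.25 > 0.2 threshold
        assert h.report["freq_mismatch"] == 1

    def test_empty_intersection_raises(self):
        exp = make_snp_table([("rsX", "1", 1000, "A", "G", 0.3, 0.1, 0.02, 500)])
        out = make_snp_table([("rsY", "1", 1000, "A", "G", 0.3, 0.1, 0.02, 500)])
        with pytest.raises(EmptyIntersectionError):
            harmonize(exp, out, _simple_panel())

    def test_idempotent(self, mediation_set):
        exp = mediation_set.mqtl["cg1"].records
        out = mediation_set.gwas
        panel = mediation_set.panel
        h1 = harmonize(exp, out, panel)
        h2 = harmonize(h1.exposure, h1.outcome, panel)
        pd.testing.assert_frame_equal(h1.exposure, h2.exposure)
        pd.testing.assert_frame_equal(h1.outcome, h2.outcome)

    def test_panel_sign_flips_when_panel_counts_other_allele(self):
        exp = make_snp_table([("rs1", "1", 1000, "G", "A", 0.6, 0.1, 0.02, 500)])
        out = exp.copy()
        dos = np.zeros((50, 3))
        dos[:40] = 1.0  # panel A-allele freq 0.4 -> G-allele freq 0.6, consistent
        panel = LdPanel(snps=[("rs1", "1", 1000, "A", "G"), ("rs2", "1", 2000, "A", "G"),
                              ("rs3", "1", 3000, "A", "G")], dosages=dos)
        h = harmonize(exp, out, panel)
        assert h.panel_sign[0] == -1


def test_allele_flip_involution():
    rng = np.random.default_rng(1)
    df = random_snp_table(rng, 10)
    flipped = df.copy()
    flipped["beta"] = -flipped["beta"]
    flipped["freq"] = 1.0 - flipped["freq"]
    flipped[["a1", "a2"]] = flipped[["a2", "a1"]].to_numpy()
    back = flipped.copy()
    back["beta"] = -back["beta"]
    back["freq"] = 1.0 - back["freq"]
    back[["a1", "a2"]] = back[["a2", "a1"]].to_numpy()
    pd.testing.assert_frame_equal(back, df)


# ---------------------------------------------------------------- beta_from_z


class TestBetaFromZ:
    def test_zero_z(self):
        beta, se = beta_from_z(0.0, 0.5, 1000)
        assert beta == 0.0
        assert se == pytest.approx(1.0 / math.sqrt(500.0), rel=1e-12)

    @pytest.mark.parametrize("z,freq,n", [(1.5, 0.3, 500), (-4.2, 0.07, 20000), (0.01, 0.5, 100)])
    def test_ratio_identity(self, z, freq, n):
        beta, se = beta_from_z(z, freq, n)
        assert beta / se == pytest.approx(z, rel=1e-14)

    def test_high_precision_oracle(self):
        # 50-digit decimal evaluation of the same formula
        getcontext().prec = 50
        zd, fd, nd = Decimal(5), Decimal("0.2"), Decimal(10000)
        se_d = 1 / (2 * fd * (1 - fd) * (nd + zd * zd)).sqrt()
        beta, se = beta_from_z(5.0, 0.2, 10000)
        assert se == pytest.approx(float(se_d), rel=1e-12)
        assert beta == pytest.approx(float(zd * se_d), rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            beta_from_z(1.0, 0.0, 100)
        with pytest.raises(ValueError):
            beta_from_z(1.0, 1.2, 100)


# ---------------------------------------------------------------- meta_fixed


class TestMetaFixed:
    def test_equal_se_equal_weight(self):
        a = make_snp_table([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.05, 500)])
        b = make_snp_table([("rs1", "1", 1000, "A", "G", 0.3, 0.3, 0.05, 500)])
        m = meta_fixed(a, b)
        assert m.loc[0, "beta"] == pytest.approx(0.2)
        assert m.loc[0, "se"] == pytest.approx(0.05 / math.sqrt(2.0))
        assert m.loc[0, "n"] == 1000

    def test_single_cohort_snp_dropped(self):
        a = make_snp_table([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.05, 500),
                            ("rs2", "1", 2000, "A", "G", 0.3, 0.1, 0.05, 500)])
        b = make_snp_table([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.05, 500)])
        m = meta_fixed(a, b)
        assert list(m["snp_id"]) == ["rs1"]

    def test_against_wls_oracle(self):
        rng = np.random.default_rng(7)
        a = random_snp_table(rng, 15)
        b = a.copy()
        b["beta"] = rng.normal(0, 0.1, 15)
        b["se"] = rng.uniform(0.01, 0.05, 15)
        m = meta_fixed(a, b)
        for i in range(15):
            # independently coded weighted least squares on the two estimates
            y = np.array([a.loc[i, "beta"], b.loc[i, "beta"]])
            w = np.array([a.loc[i, "se"], b.loc[i, "se"]]) ** -2.0
            X = np.ones((2, 1))
            xtwx = (X.T * w) @ X
            est = np.linalg.solve(xtwx, (X.T * w) @ y).item()
            se = np.sqrt(np.linalg.inv(xtwx)).item()
            assert m.loc[i, "beta"] == pytest.approx(est, rel=1e-10)
            assert m.loc[i, "se"] == pytest.approx(se, rel=1e-10)

    def test_meta_variance_never_exceeds_smaller_input(self):
        rng = np.random.default_rng(8)
        a = random_snp_table(rng, 30)
        b = a.copy()
        b["se"] = rng.uniform(0.01, 0.2, 30)
        m = meta_fixed(a, b)
        assert (m["se"] <= np.minimum(a["se"], b["se"]) + 1e-15).all()

    def test_mismatched_alleles_raise(self):
        a = make_snp_table([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.05, 500)])
        b = make_snp_table([("rs1", "1", 1000, "G", "A", 0.7, -0.1, 0.05, 500)])
        with pytest.raises(ValueError):
            meta_fixed(a, b)


# ------------------------------------------------------------- filter_probes


def _cis(probe_id, chrom, bp, snp_rows):
    probe = ProbeInfo(probe_id, "methylation", chrom, bp)
    return CisSummary(probe, make_snp_table(snp_rows), window_bp=500_000)


class TestFilterProbes:
    def test_weak_instrument_probe_removed(self):
        # best p computed from z: choose beta/se so that p ~ 1e-7
        z = stats.norm.isf(1e-7 / 2)
        data = {"cg1": _cis("cg1", "1", 1_000_000,
                            [("rs1", "1", 1_000_100, "A", "G", 0.3, z * 0.02, 0.02, 600)])}
        out, report = filter_probes(data, min_instrument_p=5e-8)
        assert out == {}
        assert report["probes_no_instrument"] == 1

    def test_mhc_probe_removed(self):
        z = 10.0
        data = {"cg1": _cis("cg1", "6", 30_000_000,
                            [("rs1", "6", 30_000_100, "A", "G", 0.3, z * 0.02, 0.02, 600)])}
        out, report = filter_probes(data)
        assert out == {}
        assert report["probes_mhc"] == 1

    def test_maf_filter_applied_first(self):
        # only instrument-grade SNP has MAF below threshold -> probe loses its instrument
        data = {"cg1": _cis("cg1", "1", 1_000_000, [
            ("rs1", "1", 1_000_100, "A", "G", 0.005, 0.5, 0.02, 600),
            ("rs2", "1", 1_000_200, "A", "G", 0.3, 0.01, 0.02, 600),
        ])}
        out, report = filter_probes(data, min_maf=0.01)
        assert out == {}
        assert report["snps_maf_removed"] == 1
        assert report["probes_no_instrument"] == 1

    def test_report_matches_enumeration(self):
        rng = np.random.default_rng(5)
        data = {}
        expected_kept = []
        for i in range(40):
            chrom = "6" if i % 5 == 0 else "1"
            bp = 30_000_000 if chrom == "6" else 1_000_000
            strong = i % 3 == 0
            beta = 0.5 if strong else 0.01
            freq = 0.005 if i % 7 == 0 else float(rng.uniform(0.1, 0.9))
            pid = f"cg{i}"
            data[pid] = _cis(pid, chrom, bp, [(f"rs{i}", chrom, bp + 100, "A", "G", freq, beta, 0.02, 600)])
            # brute-force expectation
            maf_ok = min(freq, 1 - freq) >= 0.01
            z2 = (beta / 0.02) ** 2
            p = stats.chi2.sf(z2, 1)
            if maf_ok and p < 5e-8 and not (chrom == "6" and 25e6 <= bp <= 34e6):
                expected_kept.append(pid)
        out, report = filter_probes(data)
        assert sorted(out) == sorted(expected_kept)
        assert report["kept"] == len(expected_kept)


# --------------------------------------------------- qtl_variance_explained


class TestVarianceExplained:
    def test_zero(self):
        assert qtl_variance_explained(0.0, 100) == 0.0

    def test_direct_value(self):
        assert qtl_variance_explained(10.0, 1000) == pytest.approx(100.0 / 1098.0, rel=1e-12)

    def test_monotone_in_abs_z(self):
        vals = [qtl_variance_explained(z, 500) for z in (0.5, 1, 2, 4, 8)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            qtl_variance_explained(1.0, 2)

    def test_matches_regression_simulation(self):
        # mean |r2_formula - empirical r2| over 200 replicate regressions
        rng = np.random.default_rng(3)
        n, b = 2000, 0.12
        errs = []
        for _ in range(200):
            g = rng.binomial(2, 0.3, n).astype(float)
            gs = (g - g.mean()) / g.std()
            y = b * gs + rng.standard_normal(n) * math.sqrt(1 - b * b)
            r = np.corrcoef(g, y)[0, 1]
            z = r * math.sqrt((n - 2) / (1 - r * r))
            errs.append(abs(qtl_variance_explained(z, n) - r * r))
        assert np.mean(errs) < 0.005


def test_flag_inconsistent_pvalues():
    df = make_snp_table([("rs1", "1", 1000, "A", "G", 0.3, 0.1, 0.02, 500)])
    bad = df.copy()
    bad.loc[0, "logp"] = math.log(0.5)  # stored p wildly off the z-implied one
    bad.loc[0, "pvalue"] = 0.5
    assert not flag_inconsistent_pvalues(df).any()
    assert flag_inconsistent_pvalues(bad).all()
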