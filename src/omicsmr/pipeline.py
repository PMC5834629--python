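"""Three-step integration: methylome -> transcriptome (M2T / T2M), omics -> trait,
triplet combination, and descriptive statistics of the resulting map."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from omicsmr.ldpanel import LdPanel, ld_matrix
from omicsmr.smr import (
    HeidiParams,
    SmrResult,
    STATUS_HEIDI_INSUFFICIENT,
    STATUS_NO_INSTRUMENT,
    STATUS_OK,
    heidi_cov,
    heidi_test,
    select_heidi_snps,
    select_instrument,
    smr_multi,
    smr_test,
)
from omicsmr.summary_io import CisSummary, EmptyIntersectionError, ProbeInfo, harmonize, qtl_variance_explained

logger = logging.getLogger(__name__)

ASSOC_COLUMNS = [
    "exposure_id", "outcome_id", "exposure_chrom", "exposure_bp", "outcome_bp",
    "instrument", "b_xy", "se_xy", "p_smr", "p_heidi", "n_heidi_snps", "status",
    "p_smr_multi", "n_multi_snps", "bonferroni_pass", "heidi_pass",
]


@dataclass
class PipelineConfig:
    """Thresholds and windows for the integrative scans (all configurable)."""

    p_instrument: float = 5e-8
    alpha: float = 0.05
    heidi_threshold: float = 0.01
    pair_window_bp: int = 2_000_000
    heidi: HeidiParams = field(default_factory=HeidiParams)
    strict_missing_heidi: bool = True  # HEIDI-not-run counts as not passing
    run_multi: bool = False
    multi_window_bp: int = 500_000
    multi_r2_prune: float = 0.9

    def to_dict(self) -> dict:
        return asdict(self)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise alpha divided by the realized number of tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return alpha / n_tests


def analyze_pair(
    exposure: CisSummary,
    outcome: pd.DataFrame,
    panel: LdPanel,
    cfg: PipelineConfig,
    outcome_id: str,
) -> SmrResult:
    """SMR + HEIDI (+ optional multi-SNP SMR) for one exposure probe against one outcome.

    ``outcome`` is a plain SNP table (a trait GWAS, or another probe's cis
    records).  Harmonization failures and absent instruments both yield
    status ``no_instrument``.
    """
    res = SmrResult(exposure_id=exposure.probe.probe_id, outcome_id=outcome_id, instrument=None)
    try:
        h = harmonize(exposure.records, outcome, panel)
    except EmptyIntersectionError:
        res.status = STATUS_NO_INSTRUMENT
        return res
    top = select_instrument(h.exposure, cfg.p_instrument)
    if top is None:
        res.status = STATUS_NO_INSTRUMENT
        return res
    exp_ix = h.exposure.set_index("snp_id", drop=False)
    out_ix = h.outcome.set_index("snp_id", drop=False)
    sign_ix = pd.Series(h.panel_sign, index=h.exposure["snp_id"])
    res.instrument = top["snp_id"]
    res.b_xy, res.se_xy, res.p_smr = smr_test(top, out_ix.loc[top["snp_id"]])
    z2 = (res.b_xy / res.se_xy) ** 2 if res.se_xy > 0 else 0.0
    res.logp_smr = float(stats.chi2.logsf(z2, df=1))
    res.status = STATUS_OK

    ids = select_heidi_snps(h.exposure, panel, top["snp_id"], cfg.heidi)
    res.n_heidi_snps = len(ids) - 1
    if res.n_heidi_snps < cfg.heidi.min_snps:
        res.p_heidi = None
        res.status = STATUS_HEIDI_INSUFFICIENT
    else:
        R = ld_matrix(panel, ids, signs=sign_ix.loc[ids].to_numpy())
        ctx = heidi_cov(exp_ix.loc[ids].reset_index(drop=True),
                        out_ix.loc[ids].reset_index(drop=True), R,
                        p_eligible=cfg.heidi.p_eligible)
        res.p_heidi = heidi_test(ctx, cfg.heidi.min_snps)

    if cfg.run_multi:
        cis_h = CisSummary(probe=exposure.probe, records=h.exposure, window_bp=exposure.window_bp)
        res.p_smr_multi, res.n_multi_snps = smr_multi(
            cis_h, h.outcome, panel,
            p_instrument=cfg.p_instrument,
            window_bp=cfg.multi_window_bp,
            r2_prune=cfg.multi_r2_prune,
        )
    return res


def _results_to_table(results: list[tuple[SmrResult, ProbeInfo, Optional[int]]], cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for res, exp_probe, outcome_bp in results:
        rows.append({
            "exposure_id": res.exposure_id,
            "outcome_id": res.outcome_id,
            "exposure_chrom": exp_probe.chrom,
            "exposure_bp": exp_probe.bp,
            "outcome_bp": outcome_bp if outcome_bp is not None else -1,
            "instrument": res.instrument,
            "b_xy": res.b_xy,
            "se_xy": res.se_xy,
            "p_smr": res.p_smr,
            "p_heidi": res.p_heidi if res.p_heidi is not None else np.nan,
            "n_heidi_snps": res.n_heidi_snps,
            "status": res.status,
            "p_smr_multi": res.p_smr_multi if res.p_smr_multi is not None else np.nan,
            "n_multi_snps": res.n_multi_snps,
        })
    df = pd.DataFrame(rows, columns=ASSOC_COLUMNS[:-2])
    tested = df["status"].isin([STATUS_OK, STATUS_HEIDI_INSUFFICIENT]) & df["p_smr"].notna()
    n_tests = int(tested.sum())
    thresh = bonferroni_threshold(cfg.alpha, n_tests) if n_tests else math.nan
    df["bonferroni_pass"] = tested & (df["p_smr"] < thresh)
    if cfg.strict_missing_heidi:
        df["heidi_pass"] = df["p_heidi"].notna() & (df["p_heidi"] >= cfg.heidi_threshold)
    else:
        df["heidi_pass"] = df["p_heidi"].isna() | (df["p_heidi"] >= cfg.heidi_threshold)
    df.attrs["n_tests"] = n_tests
    df.attrs["bonferroni_threshold"] = thresh
    return df


def _run_pairwise(
    exposure_map: dict[str, CisSummary],
    outcome_map: dict[str, CisSummary],
    panel: LdPanel,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    results = []
    for eid in sorted(exposure_map):
        exp = exposure_map[eid]
        for oid in sorted(outcome_map):
            out = outcome_map[oid]
            if out.probe.chrom != exp.probe.chrom:
                continue
            if abs(out.probe.bp - exp.probe.bp) > cfg.pair_window_bp:
                continue
            res = analyze_pair(exp, out.records, panel, cfg, outcome_id=oid)
            results.append((res, exp.probe, out.probe.bp))
    if not results:
        logger.warning("pairwise scan produced no exposure-outcome pairs within %d bp", cfg.pair_window_bp)
        df = pd.DataFrame(columns=ASSOC_COLUMNS)
        df.attrs["n_tests"] = 0
        return df
    return _results_to_table(results, cfg)


def run_m2t(mqtl: dict[str, CisSummary], eqtl: dict[str, CisSummary], panel: LdPanel,
            cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Methylome-to-transcriptome scan: DNAm probes as exposure, genes within
    the pair window as outcomes, top mQTL as instrument."""
    return _run_pairwise(mqtl, eqtl, panel, cfg)


def run_t2m(eqtl: dict[str, CisSummary], mqtl: dict[str, CisSummary], panel: LdPanel,
            cfg: PipelineConfig = PipelineConfig()) -> pd.DataFrame:
    """Reverse scan: expression as exposure, DNAm as outcome, top eQTL as instrument."""
    return _run_pairwise(eqtl, mqtl, panel, cfg)


def overlap_report(m2t: pd.DataFrame, t2m: pd.DataFrame, passing_only: bool = True) -> dict:
    """Pairs found by both directions, M2T-only, and T2M-only (as (dnam, gene) sets)."""
    def pairs(df, swap):
        if passing_only and len(df):
            df = df[df["bonferroni_pass"] & df["heidi_pass"]]
        if swap:
            return {(o, e) for e, o in zip(df["exposure_id"], df["outcome_id"])}
        return set(zip(df["exposure_id"], df["outcome_id"]))

    a, b = pairs(m2t, swap=False), pairs(t2m, swap=True)
    return {"both": a & b, "m2t_only": a - b, "t2m_only": b - a}


def run_omics_trait(qtl: dict[str, CisSummary], gwas: pd.DataFrame, panel: LdPanel,
                    cfg: PipelineConfig = PipelineConfig(), trait: str = "trait") -> pd.DataFrame:
    """Probe-vs-trait scan; Bonferroni over the realized probe count.

    Disease GWAS with log odds-ratio betas pass through unchanged -- b_xy is
    then on the log-OR scale.
    """
    results = []
    for pid in sorted(qtl):
        cs = qtl[pid]
        res = analyze_pair(cs, gwas, panel, cfg, outcome_id=trait)
        results.append((res, cs.probe, None))
    if not results:
        logger.warning("omics-trait scan received no probes")
        df = pd.DataFrame(columns=ASSOC_COLUMNS)
        df.attrs["n_tests"] = 0
        return df
    return _results_to_table(results, cfg)


def combine_triplets(m2t: pd.DataFrame, m2trait: pd.DataFrame, t2trait: pd.DataFrame) -> pd.DataFrame:
    """DNAm-gene-trait triplets where all three tests pass both filters."""
    cols = ["dnam_probe", "gene_probe", "trait", "b_m2t", "p_smr_m2t", "p_heidi_m2t",
            "b_m2trait", "p_smr_m2trait", "p_heidi_m2trait",
            "b_t2trait", "p_smr_t2trait", "p_heidi_t2trait"]
    if not (len(m2t) and len(m2trait) and len(t2trait)):
        return pd.DataFrame(columns=cols)

    def passing(df):
        return df[df["bonferroni_pass"] & df["heidi_pass"]]

    a = passing(m2t).rename(columns={"exposure_id": "dnam_probe", "outcome_id": "gene_probe"})
    b = passing(m2trait).rename(columns={"exposure_id": "dnam_probe", "outcome_id": "trait"})
    c = passing(t2trait).rename(columns={"exposure_id": "gene_probe", "outcome_id": "trait"})
    j = a.merge(b, on="dnam_probe", suffixes=("_m2t", "_m2trait"))
    j = j.merge(c.rename(columns={"b_xy": "b_t2trait", "p_smr": "p_smr_t2trait", "p_heidi": "p_heidi_t2trait"}),
                on=["gene_probe", "trait"])
    out = pd.DataFrame({
        "dnam_probe": j["dnam_probe"],
        "gene_probe": j["gene_probe"],
        "trait": j["trait"],
        "b_m2t": j["b_xy_m2t"],
        "p_smr_m2t": j["p_smr_m2t"],
        "p_heidi_m2t": j["p_heidi_m2t"],
        "b_m2trait": j["b_xy_m2trait"],
        "p_smr_m2trait": j["p_smr_m2trait"],
        "p_heidi_m2trait": j["p_heidi_m2trait"],
        "b_t2trait": j["b_t2trait"],
        "p_smr_t2trait": j["p_smr_t2trait"],
        "p_heidi_t2trait": j["p_heidi_t2trait"],
    })
    return out.sort_values(["dnam_probe", "gene_probe", "trait"]).reset_index(drop=True)


def nearest_gene_stats(
    m2t: pd.DataFrame,
    annotations: dict[str, ProbeInfo],
    restrict_to_tested_nearest: bool = False,
) -> tuple[float, float, float]:
    """Proportions of DNAm probes whose significant genes include the nearest
    gene, a distal gene, or both.

    The nearest gene of a DNAm probe is the expression probe (from
    ``annotations``) on the same chromosome with minimal |bp difference|
    (ties toward smaller bp).  In restricted mode, probes whose nearest gene
    never entered the scan are dropped.
    """
    sig = m2t[m2t["bonferroni_pass"] & m2t["heidi_pass"]]
    if len(sig) == 0:
        raise ValueError("no significant DNAm-gene associations to classify")
    genes = [p for p in annotations.values() if p.kind == "expression"]
    by_chrom: dict[str, list[ProbeInfo]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tested_genes = set(m2t["outcome_id"])

    n_nearest = n_distal = n_both = n_total = 0
    skipped_no_gene = 0
    for dnam, grp in sig.groupby("exposure_id"):
        chrom = grp["exposure_chrom"].iloc[0]
        bp = int(grp["exposure_bp"].iloc[0])
        cands = by_chrom.get(chrom, [])
        if not cands:
            skipped_no_gene += 1
            continue
        nearest = min(cands, key=lambda g: (abs(g.bp - bp), g.bp))
        if restrict_to_tested_nearest and nearest.probe_id not in tested_genes:
            continue
        sig_genes = set(grp["outcome_id"])
        has_nearest = nearest.probe_id in sig_genes
        has_distal = bool(sig_genes - {nearest.probe_id})
        n_total += 1
        n_nearest += has_nearest
        n_distal += has_distal
        n_both += has_nearest and has_distal
    if skipped_no_gene:
        logger.warning("nearest_gene_stats: %d probe(s) had no annotated gene on their chromosome", skipped_no_gene)
    if n_total == 0:
        raise ValueError("no DNAm probe with a classifiable nearest gene")
    return n_nearest / n_total, n_distal / n_total, n_both / n_total


def direction_concordance(m2t: pd.DataFrame) -> float:
    """Fraction of within-gene DNAm-probe pairs whose b_xy signs agree,
    over genes with at least two significantly associated DNAm probes."""
    sig = m2t[m2t["bonferroni_pass"] & m2t["heidi_pass"]]
    agree = total = 0
    for _, grp in sig.groupby("outcome_id"):
        s = np.sign(grp["b_xy"].to_numpy())
        k = len(s)
        if k < 2:
            continue
        pos = int((s > 0).sum())
        neg = k - pos
        agree += pos * (pos - 1) // 2 + neg * (neg - 1) // 2
        total += k * (k - 1) // 2
    if total == 0:
        raise ValueError("no gene with >= 2 associated DNAm probes")
    return agree / total


def variance_comparison(z_e: float, n_e: int, z_m: float, n_m: int) -> tuple[float, float]:
    """Difference in SNP-explained variance between two QTL layers and a
    two-sided p-value from Fisher-z transformed correlations (variances
    1/(n-3))."""
    if n_e <= 3 or n_m <= 3:
        raise ValueError("sample sizes must exceed 3")
    r2_e = qtl_variance_explained(z_e, n_e)
    r2_m = qtl_variance_explained(z_m, n_m)
    delta = r2_e - r2_m
    fz = math.atanh(math.sqrt(r2_e)) - math.atanh(math.sqrt(r2_m))
    se = math.sqrt(1.0 / (n_e - 3) + 1.0 / (n_m - 3))
    p = 2.0 * stats.norm.sf(abs(fz) / se)
    return delta, float(min(p, 1.0))


def write_assoc_table(df: pd.DataFrame, path) -> None:
    """Tab-delimited output with stable column order."""
    out = df.reindex(columns=ASSOC_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
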