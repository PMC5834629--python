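"""Reading, harmonizing, filtering and meta-analysing association summary statistics.

SNP association tables are pandas DataFrames with one row per SNP and columns

    snp_id, chrom, bp, a1, a2, freq, beta, se, pvalue, logp, n

where ``a1`` is the effect allele, ``freq`` its frequency, ``beta`` the
per-allele effect in SD units (quantitative) or log odds-ratio (disease),
and ``logp`` the natural-log p-value kept alongside ``pvalue`` so that
extreme associations (p underflowing a double) stay ordered.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["snp_id", "chrom", "bp", "a1", "a2", "freq", "beta", "se", "pvalue", "logp", "n"]

#: complementary-allele pairs that cannot be strand-resolved from summary data
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


class EmptyIntersectionError(ValueError):
    """Raised when harmonization leaves no SNP shared by all sources."""


@dataclass(frozen=True)
class ProbeInfo:
    """Annotation of a single expression or methylation probe."""

    probe_id: str
    kind: str  # "expression" | "methylation"
    chrom: str
    bp: int
    gene: str = ""
    strand: str = "unknown"  # "+", "-", "unknown"


@dataclass
class CisSummary:
    """A probe together with the SNP summary records in its cis window."""

    probe: ProbeInfo
    records: pd.DataFrame
    window_bp: int

    def __post_init__(self) -> None:
        recs = self.records
        if len(recs) and recs["snp_id"].duplicated().any():
            dup = recs.loc[recs["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate SNP {dup!r} in cis summary of {self.probe.probe_id}")

    def __len__(self) -> int:
        return len(self.records)


def _logp_from_zsq(zsq: np.ndarray) -> np.ndarray:
    return stats.chi2.logsf(zsq, df=1)


def _finalize_snp_table(df: pd.DataFrame) -> pd.DataFrame:
    """Compute logp from z (robust to p underflow) and order columns."""
    z2 = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) ** 2
    with np.errstate(divide="ignore"):
        file_logp = np.log(df["pvalue"].to_numpy(float))
    z_logp = _logp_from_zsq(z2)
    # Trust the file's p unless it underflowed; then fall back to the z-based value.
    logp = np.where(np.isfinite(file_logp), file_logp, z_logp)
    df = df.assign(logp=logp)
    return df[SNP_COLUMNS].reset_index(drop=True)


def flag_inconsistent_pvalues(df: pd.DataFrame, orders: float = 2.0) -> np.ndarray:
    """Boolean mask of rows whose stored p disagrees with chi2_1((beta/se)^2).

    Disagreement beyond ``orders`` orders of magnitude usually indicates a
    mangled column or a p-value computed on a different test statistic.
    """
    z2 = (df["beta"].to_numpy(float) / df["se"].to_numpy(float)) ** 2
    expected = _logp_from_zsq(z2) / math.log(10.0)
    observed = df["logp"].to_numpy(float) / math.log(10.0)
    return np.abs(expected - observed) > orders


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gwas_ma(path) -> pd.DataFrame:
    """Read a GCTA-COJO ``.ma`` file (``SNP A1 A2 freq b se p N``).

    Whitespace-delimited with a mandatory header.  Lines with non-numeric
    fields, se <= 0, freq outside (0, 1) or p outside (0, 1] are rejected;
    the reject count is logged and stored in ``df.attrs["report"]``.
    The returned table has ``chrom == ""`` and ``bp == -1`` because the
    format carries no positions; they are filled in during harmonization
    when a reference panel is available.
    """
    rows = []
    rejected = 0
    with _open_text(path) as fh:
        header = fh.readline().split()
        if [c.upper() for c in header] != ["SNP", "A1", "A2", "FREQ", "B", "SE", "P", "N"]:
            raise FormatError(f"{path}: expected header 'SNP A1 A2 freq b se p N', got {header!r}")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 8:
                rejected += 1
                continue
            snp, a1, a2, f, b, se, p, n = parts
            try:
                f, b, se, p = float(f), float(b), float(se), float(p)
                n = int(float(n))
            except ValueError:
                rejected += 1
                continue
            if se <= 0 or not (0 < f < 1) or not (0 <= p <= 1) or n <= 0:
                rejected += 1
                continue
            rows.append((snp, "", -1, a1.upper(), a2.upper(), f, b, se, p, np.nan, n))
    if rejected:
        logger.warning("read_gwas_ma(%s): rejected %d invalid line(s)", path, rejected)
    df = pd.DataFrame(rows, columns=SNP_COLUMNS)
    df = _finalize_snp_table(df)
    df.attrs["report"] = {"rejected": rejected, "kept": len(df)}
    return df


def write_gwas_ma(df: pd.DataFrame, path) -> None:
    """Write a SNP table in GCTA-COJO ``.ma`` format (positions are dropped)."""
    out = df[["snp_id", "a1", "a2", "freq", "beta", "se", "pvalue", "n"]].copy()
    out.columns = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_probe_annotations(path) -> dict[str, ProbeInfo]:
    """Read tab-delimited probe annotations: ``ProbeID Kind Chr BP Gene Strand``."""
    ann: dict[str, ProbeInfo] = {}
    with _open_text(path) as fh:
        header = fh.readline().split()
        if [c.lower() for c in header] != ["probeid", "kind", "chr", "bp", "gene", "strand"]:
            raise FormatError(f"{path}: expected header 'ProbeID Kind Chr BP Gene Strand'")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6 or not parts[0]:
                continue
            pid, kind, chrom, bp, gene, strand = parts[:6]
            if pid in ann:
                raise FormatError(f"{path}: duplicate probe id {pid!r}")
            ann[pid] = ProbeInfo(pid, kind, chrom, int(bp), gene, strand if strand in "+-" else "unknown")
    return ann


def write_probe_annotations(annotations: Iterable[ProbeInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("ProbeID\tKind\tChr\tBP\tGene\tStrand\n")
        for p in annotations:
            fh.write(f"{p.probe_id}\t{p.kind}\t{p.chrom}\t{p.bp}\t{p.gene}\t{p.strand}\n")


def read_qtl_flat(path, annotations: dict[str, ProbeInfo], window_bp: int) -> dict[str, CisSummary]:
    """Read probe-wise QTL summaries from the tab-delimited flat format.

    Header: ``ProbeID SNP Chr BP A1 A2 freq b se p N``.  Records are grouped
    by probe and restricted to the probe's chromosome within ``window_bp``
    of the probe position.  Probes absent from ``annotations`` are skipped
    (counted in the log); gzip input is accepted transparently.
    """
    expected = ["probeid", "snp", "chr", "bp", "a1", "a2", "freq", "b", "se", "p", "n"]
    with _open_text(path) as fh:
        header = fh.readline().split()
        if [c.lower() for c in header] != expected:
            raise FormatError(f"{path}: expected header 'ProbeID SNP Chr BP A1 A2 freq b se p N'")
        df = pd.read_csv(
            fh,
            sep="\t",
            names=["probe_id", "snp_id", "chrom", "bp", "a1", "a2", "freq", "beta", "se", "pvalue", "n"],
            dtype={"probe_id": str, "snp_id": str, "chrom": str, "a1": str, "a2": str},
        )
    rejected = int((~((df["se"] > 0) & (df["freq"] > 0) & (df["freq"] < 1))).sum())
    df = df[(df["se"] > 0) & (df["freq"] > 0) & (df["freq"] < 1)]
    if rejected:
        logger.warning("read_qtl_flat(%s): rejected %d invalid record(s)", path, rejected)
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()

    unknown_probes = 0
    out: dict[str, CisSummary] = {}
    for pid, grp in df.groupby("probe_id", sort=True):
        info = annotations.get(pid)
        if info is None:
            unknown_probes += 1
            continue
        grp = grp[(grp["chrom"] == info.chrom) & ((grp["bp"] - info.bp).abs() <= window_bp)]
        recs = _finalize_snp_table(grp.drop(columns=["probe_id"]).assign(logp=np.nan))
        out[pid] = CisSummary(probe=info, records=recs, window_bp=window_bp)
    if unknown_probes:
        logger.warning("read_qtl_flat(%s): skipped %d unannotated probe(s)", path, unknown_probes)
    return out


def write_qtl_flat(data: dict[str, CisSummary], path) -> None:
    """Write probe-wise summaries in the flat format consumed by :func:`read_qtl_flat`."""
    frames = []
    for pid in sorted(data):
        cs = data[pid]
        f = cs.records[["snp_id", "chrom", "bp", "a1", "a2", "freq", "beta", "se", "pvalue", "n"]].copy()
        f.insert(0, "probe_id", pid)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["probe_id", "snp_id", "chrom", "bp", "a1", "a2", "freq", "beta", "se", "pvalue", "n"]
    )
    out.columns = ["ProbeID", "SNP", "Chr", "BP", "A1", "A2", "freq", "b", "se", "p", "N"]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonization


@dataclass
class Harmonized:
    """SNPs shared by exposure, outcome and LD panel, aligned to the exposure's effect allele.

    ``panel_idx`` are column indices into the panel's dosage matrix and
    ``panel_sign`` is +1 where the panel's counted allele equals the
    exposure effect allele, -1 where it is the other allele (so that
    dosage correlations carry the harmonized sign convention).
    """

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    panel_idx: np.ndarray
    panel_sign: np.ndarray
    report: dict = field(default_factory=dict)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame, panel, *, max_freq_diff: float = 0.2,
              drop_ambiguous: bool = True) -> Harmonized:
    """Align outcome and panel to the exposure's effect alleles.

    Keeps only SNPs present in all three sources whose allele pairs agree.
    Outcome records with swapped A1/A2 get ``beta`` negated and ``freq``
    complemented.  Strand-ambiguous SNPs (A/T, C/G) and SNPs whose effect
    allele frequency differs by more than ``max_freq_diff`` between any two
    sources are removed.  The report counts every exclusion reason.
    """
    report = {
        "not_in_all_sources": 0,
        "allele_mismatch": 0,
        "strand_ambiguous": 0,
        "freq_mismatch": 0,
        "kept": 0,
    }
    panel_pos = {sid: j for j, sid in enumerate(panel.snp_ids)}
    out_ix = outcome.set_index("snp_id", drop=False)
    if out_ix.index.duplicated().any():
        raise ValueError("duplicate snp_id in outcome table")

    shared = [sid for sid in exposure["snp_id"] if sid in out_ix.index and sid in panel_pos]
    report["not_in_all_sources"] = len(exposure) - len(shared)
    panel_freq_all = panel.allele_freqs()

    exp_rows, out_rows, idxs, signs = [], [], [], []
    exp_ix = exposure.set_index("snp_id", drop=False)
    for sid in shared:
        e = exp_ix.loc[sid]
        o = out_ix.loc[sid]
        ea1, ea2 = e["a1"], e["a2"]
        if drop_ambiguous and frozenset((ea1, ea2)) in AMBIGUOUS_PAIRS:
            report["strand_ambiguous"] += 1
            continue
        j = panel_pos[sid]
        pa1, pa2 = panel.snps[j][3].upper(), panel.snps[j][4].upper()
        if {o["a1"], o["a2"]} != {ea1, ea2} or {pa1, pa2} != {ea1, ea2}:
            report["allele_mismatch"] += 1
            continue
        o = o.copy()
        if o["a1"] != ea1:  # swapped alleles: flip effect direction and frequency
            o["beta"] = -o["beta"]
            o["freq"] = 1.0 - o["freq"]
            o["a1"], o["a2"] = ea1, ea2
        sign = 1 if pa1 == ea1 else -1
        pfreq = panel_freq_all[j] if sign == 1 else 1.0 - panel_freq_all[j]
        freqs = [e["freq"], o["freq"], pfreq]
        if max(freqs) - min(freqs) > max_freq_diff:
            report["freq_mismatch"] += 1
            continue
        e = e.copy()
        if e["bp"] < 0:  # fill unknown positions from the panel (e.g. .ma input)
            e["chrom"], e["bp"] = panel.snps[j][1], panel.snps[j][2]
        if o["bp"] < 0:
            o["chrom"], o["bp"] = panel.snps[j][1], panel.snps[j][2]
        exp_rows.append(e)
        out_rows.append(o)
        idxs.append(j)
        signs.append(sign)

    if not exp_rows:
        raise EmptyIntersectionError("no SNP survives harmonization across exposure, outcome and panel")
    report["kept"] = len(exp_rows)
    exp_df = pd.DataFrame(exp_rows).reset_index(drop=True)[SNP_COLUMNS]
    out_df = pd.DataFrame(out_rows).reset_index(drop=True)[SNP_COLUMNS]
    return Harmonized(exp_df, out_df, np.asarray(idxs, dtype=int), np.asarray(signs, dtype=int), report)


# ---------------------------------------------------------------------------
# scalar transforms


def beta_from_z(z: float, freq: float, n: int) -> tuple[float, float]:
    """Recover (beta, se) in phenotype-SD units from a z-statistic.

    se = 1 / sqrt(2 freq (1-freq) (n + z^2)), beta = z * se, so that
    beta/se reproduces z exactly.
    """
    if not 0 < freq < 1:
        raise ValueError(f"freq must be in (0,1), got {freq}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    se = 1.0 / math.sqrt(2.0 * freq * (1.0 - freq) * (n + z * z))
    return z * se, se


def qtl_variance_explained(z: float, n: int) -> float:
    """Phenotypic variance explained by one SNP from its z-statistic: z^2/(z^2+n-2)."""
    if n <= 2:
        raise ValueError(f"n must be > 2, got {n}")
    return z * z / (z * z + n - 2)


def meta_fixed(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance fixed-effect meta-analysis of two harmonized cohorts.

    SNPs present in only one cohort are dropped: carrying over a
    single-cohort estimate would mix standard errors of different scales.
    """
    m = a.merge(b, on="snp_id", suffixes=("_a", "_b"))
    if len(m) == 0:
        return a.iloc[0:0][SNP_COLUMNS].copy()
    mismatch = (m["a1_a"] != m["a1_b"]) | (m["a2_a"] != m["a2_b"])
    if mismatch.any():
        raise ValueError("meta_fixed requires inputs harmonized to the same effect alleles")
    wa = 1.0 / m["se_a"] ** 2
    wb = 1.0 / m["se_b"] ** 2
    beta = (m["beta_a"] * wa + m["beta_b"] * wb) / (wa + wb)
    se = (wa + wb) ** -0.5
    z2 = (beta / se) ** 2
    logp = _logp_from_zsq(z2.to_numpy())
    freq = (m["freq_a"] * m["n_a"] + m["freq_b"] * m["n_b"]) / (m["n_a"] + m["n_b"])
    return pd.DataFrame(
        {
            "snp_id": m["snp_id"],
            "chrom": m["chrom_a"],
            "bp": m["bp_a"],
            "a1": m["a1_a"],
            "a2": m["a2_a"],
            "freq": freq,
            "beta": beta,
            "se": se,
            "pvalue": np.exp(logp),
            "logp": logp,
            "n": m["n_a"] + m["n_b"],
        }
    ).reset_index(drop=True)


def filter_probes(
    data: dict[str, CisSummary],
    min_instrument_p: float = 5e-8,
    mhc: tuple[str, int, int] = ("6", 25_000_000, 34_000_000),
    min_maf: float = 0.01,
) -> tuple[dict[str, CisSummary], dict]:
    """Apply the study-level QC filters to a probe -> cis-summary mapping.

    Order: per-SNP MAF filter first, then drop probes with no remaining SNP
    at p < ``min_instrument_p``, then drop probes inside the MHC region
    (chr6:25-34 Mb on GRCh37 by default).  Returns the surviving mapping and
    a per-rule count report.
    """
    report = {"snps_maf_removed": 0, "probes_no_instrument": 0, "probes_mhc": 0, "kept": 0}
    mhc_chrom, mhc_start, mhc_end = mhc
    log_thresh = math.log(min_instrument_p)
    out: dict[str, CisSummary] = {}
    for pid, cs in data.items():
        recs = cs.records
        maf = np.minimum(recs["freq"], 1.0 - recs["freq"])
        keep = maf >= min_maf
        report["snps_maf_removed"] += int((~keep).sum())
        recs = recs[keep].reset_index(drop=True)
        if len(recs) == 0 or not (recs["logp"] < log_thresh).any():
            report["probes_no_instrument"] += 1
            continue
        p = cs.probe
        if str(p.chrom).removeprefix("chr") == str(mhc_chrom).removeprefix("chr") and mhc_start <= p.bp <= mhc_end:
            report["probes_mhc"] += 1
            continue
        out[pid] = CisSummary(probe=p, records=recs, window_bp=cs.window_bp)
    report["kept"] = len(out)
    return out, report
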