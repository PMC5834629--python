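"""Coupled genotype/DNAm/expression/trait simulator.

Generates three independent finite samples (mQTL, eQTL, GWAS studies) plus an
LD reference panel observing the same SNPs, under one of four generating
models:

* ``mediation``  -- SNP -> DNAm -> expression -> trait chain,
* ``pleiotropy`` -- one shared causal variant directly affecting every layer
  with marginal effects matched to the mediation chain,
* ``linkage``    -- two causal variants in LD, one driving the molecular
  layers and the other the trait,
* ``null``       -- no genetic effects anywhere.

Phenotypes are built with unit variance by construction (effect b and
residual sd sqrt(1-b^2)), so path coefficients are in SD units and the
implied exposure-on-outcome effects are exact products of path coefficients.
Per-study marginal (single-SNP) regressions yield the summary statistics, the
way real QTL/GWAS summary data arise.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from omicsmr.ldpanel import LdPanel, write_plink
from omicsmr.summary_io import (
    SNP_COLUMNS,
    CisSummary,
    ProbeInfo,
    write_gwas_ma,
    write_probe_annotations,
    write_qtl_flat,
)


@dataclass
class SimConfig:
    model: str = "mediation"  # mediation | pleiotropy | linkage | null
    n_mqtl: int = 1000
    n_eqtl: int = 1000
    n_gwas: int = 1000
    n_panel: int = 500
    n_snps: int = 30
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_decay: float = 0.8  # adjacent-SNP correlation of the latent Gaussians
    b_zm: float = 0.3  # SNP -> DNAm path (SD units per standardized genotype)
    b_me: float = 0.5  # DNAm -> expression path
    b_et: float = 0.4  # expression -> trait path
    b_zx2: float = 0.0  # second-variant -> trait effect (linkage model)
    linkage_r2: float = 0.2  # target LD r^2 between the two causal variants
    causal_index: Optional[int] = None  # default: middle SNP
    disease: bool = False  # liability-threshold binary trait with log-OR summaries
    prevalence: float = 0.1
    sample_overlap: float = 0.0  # robustness knob only; SMR assumes 0
    chrom: str = "1"
    bp_start: int = 1_000_000
    bp_step: int = 1_000
    seed: int = 0

    def validate(self) -> None:
        if self.model not in {"mediation", "pleiotropy", "linkage", "null"}:
            raise ValueError(f"unknown model {self.model!r}")
        for name in ("n_mqtl", "n_eqtl", "n_gwas", "n_panel"):
            if getattr(self, name) < 10:
                raise ValueError(f"{name} must be >= 10")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must be in [0, 1)")
        if self.model == "linkage":
            if self.b_zx2 == 0:
                raise ValueError("linkage model needs a nonzero second-variant effect b_zx2")
            if not 0 < self.linkage_r2 < 1:
                raise ValueError("linkage_r2 must be in (0, 1)")
        for b in (self.b_zm, self.b_me, self.b_et, self.b_zx2):
            if abs(b) >= 1:
                raise ValueError("path coefficients must lie in (-1, 1) for unit-variance construction")


@dataclass
class SimTruth:
    """Generating parameters exposed for recovery tests."""

    model: str
    causal_index: int
    causal_index2: Optional[int]
    causal_snp: str
    causal_snp2: Optional[str]
    b_xy: dict[str, float]  # implied exposure-on-outcome effects per pair
    expected_r2: dict[str, float]  # top-SNP variance explained per layer
    seed: int

    def to_manifest(self) -> str:
        lines = [f"model\t{self.model}", f"causal_index\t{self.causal_index}",
                 f"causal_snp\t{self.causal_snp}", f"seed\t{self.seed}"]
        if self.causal_index2 is not None:
            lines += [f"causal_index2\t{self.causal_index2}", f"causal_snp2\t{self.causal_snp2}"]
        for k, v in self.b_xy.items():
            lines.append(f"b_xy[{k}]\t{v:.10g}")
        for k, v in self.expected_r2.items():
            lines.append(f"r2[{k}]\t{v:.10g}")
        return "\n".join(lines) + "\n"


@dataclass
class SimStudySet:
    mqtl: dict[str, CisSummary]
    eqtl: dict[str, CisSummary]
    gwas: pd.DataFrame
    panel: LdPanel
    truth: SimTruth
    annotations: dict[str, ProbeInfo]
    config: SimConfig


def _draw_mafs(cfg: SimConfig, rng) -> np.ndarray:
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, size=cfg.n_snps)


def _snp_meta(cfg: SimConfig, prefix: str = "rs") -> list[tuple[str, str, int, str, str]]:
    return [
        (f"{prefix}{i + 1}", cfg.chrom, cfg.bp_start + i * cfg.bp_step, "A", "G")
        for i in range(cfg.n_snps)
    ]


def simulate_genotypes(n: int, cfg: SimConfig, rng=None, mafs: Optional[np.ndarray] = None) -> tuple[np.ndarray, list]:
    """Hardy-Weinberg dosages with AR(1) LD between adjacent SNPs.

    Two latent Gaussian haplotypes per individual follow an AR(1) process
    with parameter ``ld_decay``; thresholding each at the MAF quantile gives
    alleles, and their sum the dosage.  Returns (n x n_snps dosage matrix,
    snp metadata).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    if mafs is None:
        mafs = _draw_mafs(cfg, rng)
    p = cfg.n_snps
    rho = cfg.ld_decay
    thresh = stats.norm.ppf(mafs)
    dosage = np.zeros((n, p))
    for _hap in range(2):
        z = np.empty((n, p))
        z[:, 0] = rng.standard_normal(n)
        if p > 1:
            eps = rng.standard_normal((n, p - 1))
            scale = math.sqrt(1.0 - rho * rho)
            for j in range(1, p):
                z[:, j] = rho * z[:, j - 1] + scale * eps[:, j - 1]
        dosage += (z < thresh).astype(float)
    return dosage, _snp_meta(cfg)


def marginal_summaries(G: np.ndarray, y: np.ndarray, snp_meta: list) -> pd.DataFrame:
    """Per-SNP simple-regression summary statistics (the QTL/GWAS estimator).

    Monomorphic SNPs in this sample are dropped.
    """
    n = len(y)
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    keep = sxx > 0
    sxy = yc @ Gc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        syy = float(yc @ yc)
        resid_ss = syy - beta * sxy
        se = np.sqrt(np.maximum(resid_ss, 0.0) / (n - 2) / sxx)
    z2 = np.where(se > 0, (beta / se) ** 2, np.inf)
    logp = stats.chi2.logsf(z2, df=1)
    freq = G.mean(axis=0) / 2.0
    rows = pd.DataFrame({
        "snp_id": [m[0] for m in snp_meta],
        "chrom": [m[1] for m in snp_meta],
        "bp": [m[2] for m in snp_meta],
        "a1": [m[3] for m in snp_meta],
        "a2": [m[4] for m in snp_meta],
        "freq": freq,
        "beta": beta,
        "se": se,
        "pvalue": np.exp(logp),
        "logp": logp,
        "n": n,
    })
    rows = rows[keep & (rows["se"] > 0) & (rows["freq"] > 0) & (rows["freq"] < 1)]
    return rows.reset_index(drop=True)[SNP_COLUMNS]


def _logistic_summaries(G: np.ndarray, y: np.ndarray, snp_meta: list, iters: int = 25) -> pd.DataFrame:
    """Per-SNP logistic regression (IRLS) giving log odds-ratio summaries."""
    n = len(y)
    rows = []
    for j, meta in enumerate(snp_meta):
        g = G[:, j]
        if g.std() == 0:
            continue
        X = np.column_stack([np.ones(n), g])
        b = np.zeros(2)
        for _ in range(iters):
            eta = X @ b
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            if w.max() < 1e-12:
                break
            H = X.T @ (X * w[:, None])
            grad = X.T @ (y - mu)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None])
        cov = np.linalg.inv(H)
        beta, se = b[1], math.sqrt(cov[1, 1])
        z2 = (beta / se) ** 2
        logp = float(stats.chi2.logsf(z2, df=1))
        rows.append((meta[0], meta[1], meta[2], meta[3], meta[4],
                     g.mean() / 2.0, beta, se, math.exp(logp), logp, n))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def _phenotypes(cfg: SimConfig, G: np.ndarray, mafs: np.ndarray, rng, c1: int, c2: Optional[int]):
    """Return (m, x, y) with unit variance by construction."""
    n = G.shape[0]
    sd1 = math.sqrt(2.0 * mafs[c1] * (1.0 - mafs[c1]))
    g1 = (G[:, c1] - 2.0 * mafs[c1]) / sd1

    def layer(parent, b):
        return b * parent + math.sqrt(1.0 - b * b) * rng.standard_normal(n)

    if cfg.model == "mediation":
        m = layer(g1, cfg.b_zm)
        x = layer(m, cfg.b_me)
        y = layer(x, cfg.b_et)
    elif cfg.model == "pleiotropy":
        # direct effects sized to match the mediation chain's marginals
        m = layer(g1, cfg.b_zm)
        x = layer(g1, cfg.b_zm * cfg.b_me)
        y = layer(g1, cfg.b_zm * cfg.b_me * cfg.b_et)
    elif cfg.model == "linkage":
        sd2 = math.sqrt(2.0 * mafs[c2] * (1.0 - mafs[c2]))
        g2 = (G[:, c2] - 2.0 * mafs[c2]) / sd2
        m = layer(g1, cfg.b_zm)
        x = layer(g1, cfg.b_zm * cfg.b_me)
        y = layer(g2, cfg.b_zx2)
    else:  # null
        m = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
    return m, x, y


def _truth(cfg: SimConfig, snp_meta, c1: int, c2: Optional[int]) -> SimTruth:
    if cfg.model == "mediation":
        b_xy = {"m->x": cfg.b_me, "m->y": cfg.b_me * cfg.b_et, "x->y": cfg.b_et}
        r2 = {"m": cfg.b_zm**2, "x": (cfg.b_zm * cfg.b_me) ** 2, "y": (cfg.b_zm * cfg.b_me * cfg.b_et) ** 2}
    elif cfg.model == "pleiotropy":
        b_xy = {"m->x": cfg.b_me, "m->y": cfg.b_me * cfg.b_et, "x->y": cfg.b_et}
        r2 = {"m": cfg.b_zm**2, "x": (cfg.b_zm * cfg.b_me) ** 2, "y": (cfg.b_zm * cfg.b_me * cfg.b_et) ** 2}
    elif cfg.model == "linkage":
        b_xy = {"m->y": 0.0, "x->y": 0.0}
        r2 = {"m": cfg.b_zm**2, "x": (cfg.b_zm * cfg.b_me) ** 2, "y": cfg.b_zx2**2}
    else:
        b_xy = {"m->x": 0.0, "m->y": 0.0, "x->y": 0.0}
        r2 = {"m": 0.0, "x": 0.0, "y": 0.0}
    return SimTruth(
        model=cfg.model,
        causal_index=c1,
        causal_index2=c2,
        causal_snp=snp_meta[c1][0],
        causal_snp2=snp_meta[c2][0] if c2 is not None else None,
        b_xy=b_xy,
        expected_r2=r2,
        seed=cfg.seed,
    )


def _linkage_partner(cfg: SimConfig, c1: int) -> int:
    """Pick the second causal SNP at the AR(1) lag whose latent correlation
    approximates the requested r^2."""
    rho = max(cfg.ld_decay, 1e-6)
    lag = max(1, round(math.log(math.sqrt(cfg.linkage_r2)) / math.log(rho)))
    c2 = c1 + lag if c1 + lag < cfg.n_snps else c1 - lag
    if not 0 <= c2 < cfg.n_snps:
        raise ValueError("n_snps too small for the requested linkage LD")
    return c2


def simulate_study_set(cfg: SimConfig, out_dir=None, probe_suffix: str = "1") -> SimStudySet:
    """Simulate the full study set: mQTL, eQTL and GWAS summary statistics
    from three disjoint samples, plus an LD panel and the generating truth.

    With ``out_dir``, also writes mqtl/eqtl flat files, a GWAS ``.ma`` file,
    a PLINK panel, probe annotations and a truth manifest.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_meta, rng_m, rng_e, rng_g, rng_p = [np.random.default_rng(s) for s in ss.spawn(5)]
    mafs = _draw_mafs(cfg, rng_meta)
    snp_meta = _snp_meta(cfg)
    c1 = cfg.causal_index if cfg.causal_index is not None else cfg.n_snps // 2
    c2 = _linkage_partner(cfg, c1) if cfg.model == "linkage" else None

    def study(n, rng, layer):
        G, _ = simulate_genotypes(n, cfg, rng=rng, mafs=mafs)
        m, x, y = _phenotypes(cfg, G, mafs, rng, c1, c2)
        pheno = {"m": m, "x": x, "y": y}[layer]
        if layer == "y" and cfg.disease:
            cases = (pheno > stats.norm.isf(cfg.prevalence)).astype(float)
            return _logistic_summaries(G, cases, snp_meta)
        return marginal_summaries(G, pheno, snp_meta)

    mqtl_df = study(cfg.n_mqtl, rng_m, "m")
    eqtl_df = study(cfg.n_eqtl, rng_e, "x")
    gwas_df = study(cfg.n_gwas, rng_g, "y")
    G_panel, _ = simulate_genotypes(cfg.n_panel, cfg, rng=rng_p, mafs=mafs)
    panel = LdPanel(snps=snp_meta, dosages=G_panel)

    center_bp = snp_meta[cfg.n_snps // 2][2]
    window = (cfg.n_snps + 1) * cfg.bp_step
    m_probe = ProbeInfo(f"cg{probe_suffix}", "methylation", cfg.chrom, center_bp, "", "unknown")
    e_probe = ProbeInfo(f"expr{probe_suffix}", "expression", cfg.chrom, center_bp + cfg.bp_step // 2,
                        f"GENE{probe_suffix}", "+")
    mqtl = {m_probe.probe_id: CisSummary(m_probe, mqtl_df, window)}
    eqtl = {e_probe.probe_id: CisSummary(e_probe, eqtl_df, window)}
    truth = _truth(cfg, snp_meta, c1, c2)
    annotations = {m_probe.probe_id: m_probe, e_probe.probe_id: e_probe}
    out = SimStudySet(mqtl=mqtl, eqtl=eqtl, gwas=gwas_df, panel=panel, truth=truth,
                      annotations=annotations, config=cfg)
    if out_dir is not None:
        write_study_set(out, out_dir)
    return out


def write_study_set(data: SimStudySet, out_dir) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mqtl": os.path.join(out_dir, "mqtl.flat.txt"),
        "eqtl": os.path.join(out_dir, "eqtl.flat.txt"),
        "gwas": os.path.join(out_dir, "gwas.ma"),
        "panel": os.path.join(out_dir, "panel"),
        "annotations": os.path.join(out_dir, "probes.txt"),
        "truth": os.path.join(out_dir, "truth.txt"),
    }
    write_qtl_flat(data.mqtl, paths["mqtl"])
    write_qtl_flat(data.eqtl, paths["eqtl"])
    write_gwas_ma(data.gwas, paths["gwas"])
    write_plink(data.panel, paths["panel"])
    write_probe_annotations(data.annotations.values(), paths["annotations"])
    with open(paths["truth"], "w") as fh:
        fh.write(data.truth.to_manifest())
    return paths


# ---------------------------------------------------------------------------
# deterministic multi-block fixture for golden tests


TOY_COLLAPSE_MAP = {
    # toy subset of a raw-state -> category collapse (raw labels left of tab)
    "1_TssA": "TssA", "2_PromU": "Prom", "3_PromD1": "Prom", "10_TxEnh5": "TxEn",
    "13_EnhA1": "EnhA", "14_EnhA2": "EnhA", "17_EnhW1": "EnhW",
    "21_Het": "Het", "24_ReprPC": "ReprPC", "25_Quies": "Quies",
}


def make_fixture(dir_path, seed: int = 0) -> dict[str, str]:
    """Write a small deterministic fixture tree with every input format.

    Two SNP blocks on chr1: a mediation block carrying the planted
    DNAm -> gene -> trait triplet, and a null block 8 Mb away.  Emits mqtl
    and eqtl flat files, a GWAS ``.ma`` file, a PLINK panel, probe
    annotations, a toy chromatin-state BED + collapse map, and a truth
    manifest.
    """
    os.makedirs(dir_path, exist_ok=True)
    base = SimConfig(
        model="mediation", n_mqtl=1200, n_eqtl=1200, n_gwas=1200, n_panel=500,
        n_snps=20, maf_range=(0.2, 0.5), ld_decay=0.88,
        b_zm=0.6, b_me=0.7, b_et=0.6, seed=seed,
        chrom="1", bp_start=1_000_000, bp_step=1_000,
    )
    block_a = simulate_study_set(base, probe_suffix="01")
    block_b = simulate_study_set(
        replace(base, model="null", seed=seed + 1, bp_start=9_000_000), probe_suffix="02",
    )
    # second block SNP ids must not collide
    def rename_block_b(df):
        df = df.copy()
        df["snp_id"] = df["snp_id"].str.replace("rs", "rsb", regex=False)
        return df

    for cs in list(block_b.mqtl.values()) + list(block_b.eqtl.values()):
        cs.records = rename_block_b(cs.records)
    block_b.gwas = rename_block_b(block_b.gwas)
    b_snps = [(f"rsb{s[0][2:]}", s[1], s[2], s[3], s[4]) for s in block_b.panel.snps]
    block_b.panel = LdPanel(snps=b_snps, dosages=block_b.panel.dosages)

    mqtl = {**block_a.mqtl, **block_b.mqtl}
    eqtl = {**block_a.eqtl, **block_b.eqtl}
    gwas = pd.concat([block_a.gwas, block_b.gwas], ignore_index=True)
    panel = LdPanel(
        snps=block_a.panel.snps + block_b.panel.snps,
        dosages=np.hstack([block_a.panel.dosages, block_b.panel.dosages]),
    )
    annotations = {**block_a.annotations, **block_b.annotations}

    paths = {
        "mqtl": os.path.join(dir_path, "mqtl.flat.txt"),
        "eqtl": os.path.join(dir_path, "eqtl.flat.txt"),
        "gwas": os.path.join(dir_path, "gwas.ma"),
        "panel": os.path.join(dir_path, "panel"),
        "annotations": os.path.join(dir_path, "probes.txt"),
        "bed": os.path.join(dir_path, "states.bed"),
        "collapse_map": os.path.join(dir_path, "collapse_map.txt"),
        "truth": os.path.join(dir_path, "truth.txt"),
    }
    write_qtl_flat(mqtl, paths["mqtl"])
    write_qtl_flat(eqtl, paths["eqtl"])
    write_gwas_ma(gwas, paths["gwas"])
    write_plink(panel, paths["panel"])
    write_probe_annotations(annotations.values(), paths["annotations"])

    with open(paths["collapse_map"], "w") as fh:
        for raw, cat in TOY_COLLAPSE_MAP.items():
            fh.write(f"{raw}\t{cat}\n")
    with open(paths["bed"], "w") as fh:
        # cover the mediation-block probes with an enhancer, the null block with quiescent
        fh.write("1\t995000\t1015000\t13_EnhA1\n")
        fh.write("1\t1015000\t1030000\t2_PromU\n")
        fh.write("1\t8995000\t9030000\t25_Quies\n")
    with open(paths["truth"], "w") as fh:
        fh.write("# block A (planted mediation triplet)\n")
        fh.write(block_a.truth.to_manifest())
        fh.write("# block B (null)\n")
        fh.write(block_b.truth.to_manifest())
    return paths


def tree_checksum(dir_path) -> str:
    """SHA256 over the sorted file names and contents of a fixture tree."""
    h = hashlib.sha256()
    for root, _dirs, files in sorted(os.walk(dir_path)):
        for name in sorted(files):
            full = os.path.join(root, name)
            h.update(os.path.relpath(full, dir_path).encode())
            with open(full, "rb") as fh:
                h.update(fh.read())
    return h.hexdigest()
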