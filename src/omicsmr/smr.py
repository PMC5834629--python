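"""Core tests: SMR ratio test, HEIDI heterogeneity test, multi-SNP set test.

The ratio estimate b_xy = b_zy / b_zx uses one genetic instrument shared by
an exposure study (mQTL/eQTL) and an outcome study (eQTL/GWAS).  Its Wald
statistic has the closed form

    T_SMR = z_zy^2 z_zx^2 / (z_zy^2 + z_zx^2),   z = beta / se,

which is the first-order Delta-method variance rearranged.  HEIDI compares
b_xy estimated at LD-linked SNPs against the top instrument: under a single
shared causal variant the ratios agree, under linkage they do not.  Both
HEIDI and the multi-SNP test reduce to upper-tail probabilities of a
weighted sum of 1-df chi-squares, evaluated by saddlepoint approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from omicsmr.ldpanel import LdPanel, ld_matrix
from omicsmr.summary_io import CisSummary

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_INSTRUMENT = "no_instrument"
STATUS_HEIDI_INSUFFICIENT = "heidi_insufficient_snps"


class DegenerateWeightsError(ValueError):
    """All quadratic-form weights are zero after clipping."""


class WeakInstrumentError(ValueError):
    """A HEIDI SNP fails the exposure-significance eligibility bound."""


@dataclass
class HeidiParams:
    """Tuning knobs for HEIDI SNP selection and the heterogeneity test."""

    p_eligible: float = 1.57e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20
    min_snps: int = 3  # minimum non-instrument SNPs for the test to run


@dataclass
class SmrResult:
    """One exposure-outcome SMR + HEIDI result."""

    exposure_id: str
    outcome_id: str
    instrument: Optional[str]
    b_xy: float = math.nan
    se_xy: float = math.nan
    p_smr: float = math.nan
    logp_smr: float = math.nan
    p_heidi: Optional[float] = None
    n_heidi_snps: int = 0
    status: str = STATUS_OK
    p_smr_multi: Optional[float] = None
    n_multi_snps: int = 0


@dataclass
class HeidiContext:
    """Difference vector d, its covariance V and the null mixture weights."""

    snp_ids: list
    d: np.ndarray
    V: np.ndarray
    weights: np.ndarray = field(default=None)


def _records_of(cis) -> pd.DataFrame:
    return cis.records if isinstance(cis, CisSummary) else cis


def select_instrument(cis, p_threshold: float = 5e-8):
    """Top associated SNP at p < ``p_threshold``; None when no SNP qualifies.

    Ties on p are broken deterministically: smaller bp, then snp_id.
    """
    recs = _records_of(cis)
    if len(recs) == 0:
        return None
    log_thresh = math.log(p_threshold)
    elig = recs[recs["logp"] < log_thresh]
    if len(elig) == 0:
        return None
    elig = elig.sort_values(["logp", "bp", "snp_id"], kind="mergesort")
    return elig.iloc[0]


def smr_test(zx, zy) -> tuple[float, float, float]:
    """SMR ratio test at one instrument: returns (b_xy, se_xy, p_smr).

    ``zx``/``zy`` are the instrument's exposure/outcome records (rows of a
    SNP table); they must refer to the same SNP with aligned alleles.
    """
    if zx["snp_id"] != zy["snp_id"]:
        raise ValueError(f"instrument mismatch: {zx['snp_id']!r} vs {zy['snp_id']!r}")
    if (zx["a1"], zx["a2"]) != (zy["a1"], zy["a2"]):
        raise ValueError(f"alleles not aligned for {zx['snp_id']!r}; harmonize first")
    z_zx = zx["beta"] / zx["se"]
    z_zy = zy["beta"] / zy["se"]
    b_xy = zy["beta"] / zx["beta"]
    t_smr = smr_statistic(z_zx, z_zy)
    se_xy = abs(b_xy) / math.sqrt(t_smr) if t_smr > 0 else math.inf
    return b_xy, se_xy, float(stats.chi2.sf(t_smr, df=1))


def smr_statistic(z_zx: float, z_zy: float) -> float:
    """Closed-form Delta-method Wald statistic of the ratio estimate."""
    zx2, zy2 = z_zx * z_zx, z_zy * z_zy
    if zx2 + zy2 == 0:
        return 0.0
    return zy2 * zx2 / (zy2 + zx2)


def select_heidi_snps(cis, panel: LdPanel, instrument: str, params: HeidiParams = HeidiParams(),
                      signs=None) -> list[str]:
    """SNPs entering HEIDI, ordered: instrument first, then up to ``max_snps``
    eligible SNPs ranked by exposure significance.

    Eligibility: exposure p < ``p_eligible`` and LD r^2 against the
    instrument within [``r2_min``, ``r2_max``] (pruning SNPs in LD too
    strong -- near-duplicates of the instrument -- or too weak to share its
    signal).
    """
    recs = _records_of(cis)
    if instrument not in set(recs["snp_id"]):
        raise ValueError(f"instrument {instrument!r} not among candidate records")
    cand = recs[(recs["logp"] < math.log(params.p_eligible)) & (recs["snp_id"] != instrument)]
    if len(cand) == 0:
        return [instrument]
    ids = [instrument] + list(cand["snp_id"])
    R = ld_matrix(panel, ids)
    r2 = R[0, 1:] ** 2
    ok = (r2 >= params.r2_min) & (r2 <= params.r2_max)
    cand = cand[ok].sort_values(["logp", "bp", "snp_id"], kind="mergesort")
    return [instrument] + list(cand["snp_id"].head(params.max_snps))


def heidi_cov(exposure: pd.DataFrame, outcome: pd.DataFrame, R: np.ndarray,
              p_eligible: float = 1.57e-3) -> HeidiContext:
    """Build the HEIDI difference vector and its Delta-method covariance.

    Row 0 of ``exposure``/``outcome``/``R`` is the top instrument.  With the
    two studies independent, the covariance between ratio estimates at SNPs
    i and j is

        cov_ij = R_ij se_zy(i) se_zy(j) / (b_zx(i) b_zx(j))
               + R_ij b_zy(i) b_zy(j) se_zx(i) se_zx(j) / (b_zx(i)^2 b_zx(j)^2)

    and V is the covariance of d_i = b_xy(i) - b_xy(0) obtained by the usual
    difference contrast.  Raises :class:`WeakInstrumentError` if any SNP's
    exposure association fails the eligibility bound (the Delta expansion
    is unreliable for weak instruments).
    """
    b_zx = exposure["beta"].to_numpy(float)
    se_zx = exposure["se"].to_numpy(float)
    b_zy = outcome["beta"].to_numpy(float)
    se_zy = outcome["se"].to_numpy(float)
    m = len(b_zx)
    if not (len(b_zy) == m and R.shape == (m, m)):
        raise ValueError("exposure, outcome and R must be aligned")
    z_zx2 = (b_zx / se_zx) ** 2
    min_z2 = stats.chi2.isf(p_eligible, df=1)
    if np.any(z_zx2 < min_z2 * (1 - 1e-12)):
        weak = exposure["snp_id"].to_numpy()[z_zx2 < min_z2 * (1 - 1e-12)]
        raise WeakInstrumentError(f"exposure z below eligibility for SNP(s): {list(weak)!r}")

    b_xy = b_zy / b_zx
    term1 = R * np.outer(se_zy, se_zy) / np.outer(b_zx, b_zx)
    term2 = R * np.outer(b_zy, b_zy) * np.outer(se_zx, se_zx) / np.outer(b_zx**2, b_zx**2)
    C = term1 + term2
    d = b_xy[1:] - b_xy[0]
    V = C[1:, 1:] - C[1:, [0]] - C[[0], 1:] + C[0, 0]
    V = (V + V.T) / 2.0

    sd = np.sqrt(np.diag(V))
    corr = V / np.outer(sd, sd)
    w = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return HeidiContext(snp_ids=list(exposure["snp_id"]), d=d, V=V, weights=w)


def heidi_test(ctx: HeidiContext, min_snps: int = 3) -> Optional[float]:
    """HEIDI p-value; None when fewer than ``min_snps`` non-instrument SNPs.

    Each difference is standardized, the statistic is the sum of squared
    standardized differences, and the null is the matching weighted
    chi-square mixture (weights = eigenvalues of the correlation matrix of
    d, so that LD-induced dependence is accounted for).
    """
    m = len(ctx.d)
    if m < min_snps:
        return None
    z_d = ctx.d / np.sqrt(np.diag(ctx.V))
    t = float(np.sum(z_d**2))
    return quadform_pvalue(ctx.weights, t)


def quadform_pvalue(weights, t: float, clip_rel: float = 1e-8) -> float:
    """Upper-tail probability of sum_k lambda_k chi2_1 at ``t``.

    Uses Kuonen's saddlepoint approximation (Lugannani-Rice form), with an
    exact chi-square shortcut when all weights are equal and a Satterthwaite
    moment-matched fallback when the saddlepoint solve fails (logged).
    """
    lam = np.asarray(weights, dtype=float)
    if np.any(lam < 0):
        raise ValueError("weights must be nonnegative")
    lam = lam[lam > clip_rel * (lam.max() if lam.size else 0.0)]
    if lam.size == 0:
        raise DegenerateWeightsError("all quadratic-form weights are zero after clipping")
    if t <= 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(min(max(stats.chi2.sf(t / lam[0], df=lam.size), 5e-324), 1.0))
    # scale for conditioning; the tail probability is scale-invariant
    scale = lam.max()
    lam = lam / scale
    t = t / scale
    p = _kuonen_saddlepoint(lam, t)
    if p is None:
        logger.info("quadform_pvalue: saddlepoint solve failed, using Satterthwaite fallback")
        p = _satterthwaite(lam, t)
    return float(min(max(p, 5e-324), 1.0))


def _kuonen_saddlepoint(lam: np.ndarray, t: float) -> Optional[float]:
    mean = lam.sum()
    if abs(t - mean) < 1e-10 * mean:
        return None  # saddlepoint at 0 is singular; moment-matched fallback

    def Kp(z):
        return np.sum(lam / (1.0 - 2.0 * z * lam))

    upper = 1.0 / (2.0 * lam.max())
    if t > mean:  # root in (0, upper)
        lo = 0.0
        hi = upper * (1 - 1e-12)
        # K' -> +inf as z -> upper, so the bracket is valid unless t <= mean
    else:  # root in (-inf, 0); K' -> 0+ as z -> -inf
        hi = 0.0
        lo = -1.0
        for _ in range(200):
            if Kp(lo) < t:
                break
            lo *= 2.0
        else:
            return None
    try:
        zhat = optimize.brentq(lambda z: Kp(z) - t, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    except (ValueError, RuntimeError):
        return None
    u = 1.0 - 2.0 * zhat * lam
    if np.any(u <= 0):
        return None
    K = -0.5 * np.sum(np.log(u))
    Kpp = 2.0 * np.sum(lam**2 / u**2)
    arg = 2.0 * (zhat * t - K)
    if arg < 0 or Kpp <= 0:
        return None
    w = math.copysign(math.sqrt(arg), zhat)
    v = zhat * math.sqrt(Kpp)
    if abs(w) < 1e-6 or v == 0:
        return None
    return float(stats.norm.sf(w + math.log(v / w) / w))


def _satterthwaite(lam: np.ndarray, t: float) -> float:
    s1, s2 = lam.sum(), np.sum(lam**2)
    scale = s2 / s1
    df = s1 * s1 / s2
    return float(stats.chi2.sf(t / scale, df=df))


def smr_multi(
    exposure, outcome: pd.DataFrame, panel: LdPanel, *,
    p_instrument: float = 5e-8,
    window_bp: int = 500_000,
    r2_prune: float = 0.9,
) -> tuple[Optional[float], int]:
    """Multi-SNP SMR set test: returns (p, number of SNPs combined).

    All exposure SNPs at p < ``p_instrument`` within ``window_bp`` of the
    probe are retained after removing SNPs in very high LD (r^2 >
    ``r2_prune``) with the top SNP; the statistic T = sum_i z_i^2 over the
    per-SNP ratio z-scores is referred to the weighted chi-square mixture
    with weights the eigenvalues of the LD correlation matrix.  Returns
    (None, 0) when no SNP qualifies.
    """
    recs = _records_of(exposure)
    if isinstance(exposure, CisSummary):
        near = (recs["bp"] - exposure.probe.bp).abs() <= window_bp
        recs = recs[near]
    top = select_instrument(recs, p_instrument)
    if top is None:
        return None, 0
    elig = recs[recs["logp"] < math.log(p_instrument)]
    ids = [top["snp_id"]] + [s for s in elig["snp_id"] if s != top["snp_id"]]
    R = ld_matrix(panel, ids)
    keep = [0] + [k for k in range(1, len(ids)) if R[0, k] ** 2 <= r2_prune]
    ids = [ids[k] for k in keep]
    R = R[np.ix_(keep, keep)]

    out_ix = outcome.set_index("snp_id")
    exp_ix = recs.set_index("snp_id", drop=False)
    zsq = []
    for sid in ids:
        e, o = exp_ix.loc[sid], out_ix.loc[sid]
        zsq.append(smr_statistic(e["beta"] / e["se"], o["beta"] / o["se"]))
    t = float(np.sum(zsq))
    lam = np.clip(np.linalg.eigvalsh(R), 0.0, None)
    return quadform_pvalue(lam, t), len(ids)
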