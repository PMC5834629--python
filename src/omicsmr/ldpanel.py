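"""LD reference panel: PLINK bed/bim/fam I/O and dosage correlation matrices.

The bed codec implements the SNP-major v1.00 layout directly (magic bytes
``6c 1b 01``; two bits per genotype: 00 = hom A1, 01 = missing, 10 = het,
11 = hom A2).  Dosages count copies of the bim A1 allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit genotype code -> A1-allele dosage
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class MonomorphicSnpError(ValueError):
    """Correlation requested for a SNP with zero dosage variance in the panel."""


@dataclass
class LdPanel:
    """Reference genotypes used only to estimate inter-SNP correlations.

    ``snps`` is an ordered list of ``(snp_id, chrom, bp, allele_a, allele_b)``
    where ``allele_a`` is the allele counted by ``dosages`` (samples x snps,
    values 0/1/2 with NaN for missing).
    """

    snps: list[tuple[str, str, int, str, str]]
    dosages: np.ndarray
    _id_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage matrix must be samples x snps matching the snp list")
        self._id_index = {s[0]: j for j, s in enumerate(self.snps)}
        if len(self._id_index) != len(self.snps):
            raise ValueError("duplicate snp_id in panel")

    @property
    def samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return [s[0] for s in self.snps]

    def index_of(self, snp_id: str) -> int:
        return self._id_index[snp_id]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of allele_a per SNP, ignoring missing genotypes."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def qc(self, max_missing: float = 0.05) -> "LdPanel":
        """Drop SNPs with missingness above ``max_missing``."""
        keep = self.missingness() <= max_missing
        if keep.all():
            return self
        dropped = int((~keep).sum())
        logger.info("panel QC: dropped %d SNP(s) with missingness > %g", dropped, max_missing)
        snps = [s for s, k in zip(self.snps, keep) if k]
        return LdPanel(snps=snps, dosages=self.dosages[:, keep])

    def subset(self, snp_ids) -> "LdPanel":
        idx = [self.index_of(s) for s in snp_ids]
        return LdPanel(snps=[self.snps[j] for j in idx], dosages=self.dosages[:, idx])


def read_plink(prefix, max_missing: float = 0.05) -> LdPanel:
    """Read a PLINK bed/bim/fam fileset given its path prefix; applies missingness QC."""
    prefix = str(prefix)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    with open(prefix + ".fam") as fh:
        n_samples = sum(1 for line in fh if line.strip())
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed: not a SNP-major PLINK v1.00 bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n_samples + 3) // 4
    if raw.size != bytes_per_snp * len(bim):
        raise ValueError(f"{prefix}.bed: size inconsistent with {n_samples} samples x {len(bim)} SNPs")
    raw = raw.reshape(len(bim), bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(len(bim), -1)[:, :n_samples]
    dosages = _CODE_TO_DOSAGE[codes].T  # samples x snps
    snps = list(bim[["snp_id", "chrom", "bp", "a1", "a2"]].itertuples(index=False, name=None))
    return LdPanel(snps=snps, dosages=dosages).qc(max_missing)


def write_plink(panel: LdPanel, prefix) -> None:
    """Write a panel as PLINK bed/bim/fam (SNP-major v1.00)."""
    prefix = str(prefix)
    with open(prefix + ".fam", "w") as fh:
        for i in range(panel.samples):
            fh.write(f"F{i + 1} I{i + 1} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for snp_id, chrom, bp, a1, a2 in panel.snps:
            fh.write(f"{chrom}\t{snp_id}\t0\t{bp}\t{a1}\t{a2}\n")
    n = panel.samples
    pad = (-n) % 4
    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(len(panel.snps)):
            col = panel.dosages[:, j]
            codes = np.array(
                [1 if np.isnan(d) else dosage_to_code[float(d)] for d in col] + [0] * pad,
                dtype=np.uint8,
            ).reshape(-1, 4)
            packed = codes[:, 0] | (codes[:, 1] << 2) | (codes[:, 2] << 4) | (codes[:, 3] << 6)
            fh.write(packed.astype(np.uint8).tobytes())


def ld_matrix(
    panel: LdPanel,
    snp_ids,
    signs=None,
    psd_tol: float = 1e-8,
) -> np.ndarray:
    """Pairwise-complete Pearson correlation of dosages for ``snp_ids``.

    ``signs`` (+1/-1 per SNP) flips rows/columns whose panel counted allele
    is the other allele under the harmonized convention.  The result is
    symmetrized, given a unit diagonal, and repaired to positive
    semi-definiteness by clipping eigenvalues below ``-psd_tol * max_eig``
    (clip magnitude logged) -- pairwise-complete correlations of
    missing-containing data need not be PSD.
    """
    idx = [panel.index_of(s) for s in snp_ids]
    sub = panel.dosages[:, idx]
    sd = np.nanstd(sub, axis=0)
    for k, s in enumerate(snp_ids):
        if sd[k] == 0 or np.isnan(sd[k]):
            raise MonomorphicSnpError(f"SNP {s!r} is monomorphic in the LD panel")
    if np.isnan(sub).any():
        R = pd.DataFrame(sub).corr(min_periods=2).to_numpy()
    else:
        R = np.corrcoef(sub, rowvar=False)
        R = np.atleast_2d(R)
    if signs is not None:
        signs = np.asarray(signs, dtype=float)
        R = R * np.outer(signs, signs)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    # PSD repair
    w, U = np.linalg.eigh(R)
    floor = -psd_tol * max(w.max(), 1.0)
    if w.min() < floor:
        clipped = np.clip(w, 0.0, None)
        logger.info("ld_matrix: clipped eigenvalues by %.3g to restore PSD", float(-w.min()))
        R = (U * clipped) @ U.T
        R = (R + R.T) / 2.0
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)
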