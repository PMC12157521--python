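"""Genotype import, quality control, imputation, and standardization.

Genotypes are held as an ``n x p`` double-precision dosage matrix with
entries in ``{0, 1, 2, NaN}`` (NaN marks a missing hard call).  Allele
coding conventions:

* VCF: the dosage counts ALT alleles in the GT field, so ``0/1 -> 1`` and
  ``1|1 -> 2``; ``./.`` is missing.  Multi-allelic records are rejected and
  must be split upstream.
* binary PLINK: the dosage counts A2 alleles (column 6 of the .bim file)
  regardless of which allele is major — the ``--keep-allele-order``
  convention.  The counted allele is stored as ``alt`` so that PLINK and
  VCF imports of the same data produce identical matrices.

Coordinates are 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "GenotypeIOError",
    "EmptyPanelError",
    "read_plink",
    "read_vcf",
    "qc_filter",
    "impute_and_standardize",
    "hwe_chisq_pvalue",
]

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

PLINK_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (SNP-major): 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2.
# Dosage counts A2 alleles.
_PLINK_CODE_TO_DOSAGE = np.array([0.0, np.nan, 1.0, 2.0])


class GenotypeIOError(ValueError):
    """Malformed or unreadable genotype input."""


class EmptyPanelError(ValueError):
    """Every variant was removed by quality control."""


@dataclass
class GenotypeMatrix:
    """Hard-call dosage matrix with per-variant metadata.

    Attributes
    ----------
    values:
        ``n x p`` float array over ``{0, 1, 2, NaN}``.
    samples:
        ``n`` sample identifiers.
    variants:
        DataFrame with columns ``chrom, pos, id, ref, alt`` (one row per
        column of ``values``); ``alt`` is the counted allele.
    """

    values: np.ndarray
    samples: list[str]
    variants: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x variants)")
        n, p = self.values.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample ids for {n} rows")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant records for {p} columns")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must lie in {0, 1, 2}")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Column subset preserving order."""
        return GenotypeMatrix(
            values=self.values[:, index],
            samples=list(self.samples),
            variants=self.variants.iloc[np.asarray(index)].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# binary PLINK
# ---------------------------------------------------------------------------

def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a binary PLINK ``.bed/.bim/.fam`` triplet.

    Dosages count A2 alleles (the last .bim column) even when A2 is the
    major allele.  ``ref`` is set to A1 and ``alt`` to A2 so that the
    counted allele is always ``alt``.
    """
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(f".{ext}") for ext in ("bed", "bim", "fam")}
    for ext, path in paths.items():
        if not path.exists():
            raise GenotypeIOError(f"missing PLINK input file: {path}")

    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise GenotypeIOError(f"{paths['fam']}: expected 6 whitespace-delimited columns")
    samples = list(fam.iloc[:, 1])

    bim = pd.read_csv(
        paths["bim"], sep=r"\s+", header=None, dtype=str,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(np.int64),
            "id": bim["id"],
            "ref": bim["a1"],
            "alt": bim["a2"],
        }
    )

    n, p = len(samples), len(variants)
    raw = np.fromfile(paths["bed"], dtype=np.uint8)
    if raw[:3].tobytes() != PLINK_BED_MAGIC:
        raise GenotypeIOError(
            f"{paths['bed']}: bad magic bytes {raw[:3].tobytes()!r}; "
            "expected SNP-major PLINK v1.00"
        )
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * p:
        raise GenotypeIOError(
            f"{paths['bed']}: {body.size} data bytes, expected {bytes_per_variant * p} "
            f"for n={n}, p={p}"
        )
    blocks = body.reshape(p, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((p, bytes_per_variant * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
    dosages = _PLINK_CODE_TO_DOSAGE[codes[:, :n]].T  # n x p
    return GenotypeMatrix(values=dosages, samples=samples, variants=variants)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (optionally gzipped) into a dosage matrix.

    Dosage is the ALT-allele count in the GT field; phase separators are
    ignored and half-calls are treated as missing.  Records with more than
    one ALT allele raise, instructing the user to split multi-allelics.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"missing VCF input file: {path}")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows: list[dict] = []
    columns: list[np.ndarray] = []
    for record in vcf:
        if len(record.ALT) != 1:
            raise GenotypeIOError(
                f"{record.CHROM}:{record.POS} has ALT alleles {record.ALT}; "
                "multi-allelic records must be split prior to analysis "
                "(e.g. `bcftools norm -m-`)"
            )
        geno = np.array([g[:2] for g in record.genotypes], dtype=np.int64)
        if (geno > 1).any():
            raise GenotypeIOError(
                f"{record.CHROM}:{record.POS}: GT references allele index > 1; "
                "multi-allelic records must be split prior to analysis"
            )
        dosage = geno.sum(axis=1).astype(np.float64)
        dosage[(geno < 0).any(axis=1)] = np.nan  # ./., half-calls
        columns.append(dosage)
        rows.append(
            {
                "chrom": record.CHROM,
                "pos": record.POS,
                "id": record.ID or f"{record.CHROM}:{record.POS}",
                "ref": record.REF,
                "alt": record.ALT[0],
            }
        )
    vcf.close()
    if not rows:
        raise GenotypeIOError(f"{path}: no variant records")
    values = np.column_stack(columns)
    return GenotypeMatrix(values=values, samples=samples, variants=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def hwe_chisq_pvalue(n_ref_hom: np.ndarray, n_het: np.ndarray, n_alt_hom: np.ndarray) -> np.ndarray:
    """Pearson 1-df chi-square Hardy-Weinberg test p-value, vectorized.

    Observed genotype counts are compared against the HWE expectations
    ``n*(p^2, 2pq, q^2)`` at the estimated allele frequency.  Monomorphic
    columns have no degrees of freedom and return p = 1.
    """
    n_ref_hom = np.asarray(n_ref_hom, dtype=np.float64)
    n_het = np.asarray(n_het, dtype=np.float64)
    n_alt_hom = np.asarray(n_alt_hom, dtype=np.float64)
    n = n_ref_hom + n_het + n_alt_hom
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (n_het + 2.0 * n_alt_hom) / (2.0 * n)  # alt-allele frequency
        p = 1.0 - q
        expected = np.stack([n * p * p, n * 2.0 * p * q, n * q * q])
        observed = np.stack([n_ref_hom, n_het, n_alt_hom])
        chisq = np.where(
            expected > 0, (observed - expected) ** 2 / expected, 0.0
        ).sum(axis=0)
    pvals = stats.chi2.sf(chisq, df=1)
    return np.where((q <= 0) | (q >= 1) | (n == 0), 1.0, pvals)


def qc_filter(
    G: GenotypeMatrix, maf_min: float = 0.01, hwe_p_min: float = 1e-6
) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` and HWE chi-square p >= ``hwe_p_min``.

    MAF and genotype counts are computed on non-missing entries only.
    Raises :class:`EmptyPanelError` if every variant is removed.
    """
    if G.n_samples < 2:
        raise ValueError("QC requires at least 2 samples")
    values = G.values
    observed = ~np.isnan(values)
    n_obs = observed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(values, axis=0) / (2.0 * np.maximum(n_obs, 1))
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    n_ref_hom = ((values == 0) & observed).sum(axis=0)
    n_het = ((values == 1) & observed).sum(axis=0)
    n_alt_hom = ((values == 2) & observed).sum(axis=0)
    hwe_p = hwe_chisq_pvalue(n_ref_hom, n_het, n_alt_hom)

    keep = (n_obs > 0) & (maf >= maf_min) & (hwe_p >= hwe_p_min)
    if not keep.any():
        raise EmptyPanelError(
            f"QC removed all {G.n_variants} variants "
            f"(maf_min={maf_min}, hwe_p_min={hwe_p_min})"
        )
    return G.take_variants(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# imputation and standardization
# ---------------------------------------------------------------------------

def impute_and_standardize(G: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing entries, then standardize each column.

    Missing dosages are replaced by the column mean of the observed
    entries; each column is then shifted and scaled to mean 0 and variance
    1 with divisor ``n`` (not ``n - 1``), so that ``X.T @ X / n`` has an
    exactly unit diagonal.

    Returns a dense ``n x p`` float array.  Raises if a column is entirely
    missing or has zero variance after imputation (run :func:`qc_filter`
    first).
    """
    X = G.values.copy()
    missing = np.isnan(X)
    if missing.all(axis=0).any():
        j = int(np.flatnonzero(missing.all(axis=0))[0])
        raise ValueError(f"variant {G.variants['id'].iloc[j]!r} is entirely missing")
    col_mean = np.nanmean(X, axis=0)
    X[missing] = np.broadcast_to(col_mean, X.shape)[missing]
    X -= X.mean(axis=0)
    sd = X.std(axis=0)  # divisor n
    zero = sd == 0
    if zero.any():
        j = int(np.flatnonzero(zero)[0])
        raise ValueError(
            f"variant {G.variants['id'].iloc[j]!r} has zero variance; "
            "remove monomorphic variants with qc_filter before standardizing"
        )
    X /= sd
    return X
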