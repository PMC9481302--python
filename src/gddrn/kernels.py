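"""Genomic relationship kernels.

SNP quality control, the VanRaden method-1 genomic relationship matrix
(GRM), and the Hadamard genomic x environmental-covariate interaction
kernel ``GW = (Zg G Zg') o Omega`` that carries the reaction-norm
genotype-by-environment covariance: two plots are highly covariant for
the interaction effect only when both their genotypes are related *and*
their environments are similar in EC space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "qc_snps",
    "allele_frequencies",
    "build_grm",
    "build_gw_kernel",
    "read_vcf_genotypes",
]


def read_vcf_genotypes(path) -> pd.DataFrame:
    """Read biallelic genotypes from a VCF into -1/0/1 coding.

    Homozygous reference maps to -1, heterozygous to 0, homozygous
    alternate to +1; missing calls to NaN.  Multi-allelic records are
    skipped.  Rows are samples (lines), columns are variant IDs (or
    ``CHROM:POS`` when the ID field is empty).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        coded = np.select(
            [gt == 0, gt == 1, gt == 3], [-1.0, 0.0, 1.0], default=np.nan
        )
        rows.append(coded)
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
    if not rows:
        raise ValueError(f"no biallelic variants found in {path}")
    return pd.DataFrame(
        np.asarray(rows).T, index=pd.Index(samples, name="line_id"), columns=ids
    )


def allele_frequencies(geno: pd.DataFrame) -> pd.Series:
    """Frequency of the +1-coded allele per SNP from non-missing calls.

    Genotypes are coded -1/0/1 (missing as NaN); the mean call equals
    ``2p - 1`` where ``p`` is the +1-allele frequency.
    """
    return (geno.mean(axis=0, skipna=True) + 1.0) / 2.0


def qc_snps(
    geno: pd.DataFrame,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
) -> pd.DataFrame:
    """Remove SNPs with MAF below ``maf_min`` or call rate below ``call_rate_min``.

    Both thresholds are strict ("lower than"): a SNP exactly at the
    threshold is kept.  Removal reasons are recorded per SNP in
    ``result.attrs["qc_removed"]``.
    """
    if geno.shape[1] == 0 or geno.shape[0] == 0:
        raise ValueError("empty genotype matrix")
    p = allele_frequencies(geno)
    maf = np.minimum(p, 1.0 - p)
    call_rate = geno.notna().mean(axis=0)
    removed: dict[str, str] = {}
    keep = []
    for snp in geno.columns:
        if not np.isfinite(maf[snp]) or maf[snp] < maf_min:
            removed[str(snp)] = f"MAF {maf[snp]:.4f} < {maf_min}"
        elif call_rate[snp] < call_rate_min:
            removed[str(snp)] = f"call rate {call_rate[snp]:.4f} < {call_rate_min}"
        else:
            keep.append(snp)
    if not keep:
        raise ValueError("quality control removed every SNP")
    out = geno[keep].copy()
    out.attrs["qc_removed"] = removed
    return out


def build_grm(geno: pd.DataFrame, jitter: float = 0.0) -> pd.DataFrame:
    """VanRaden method-1 genomic relationship matrix.

    ``G = Z Z' / (2 sum_i p_i (1 - p_i))`` with ``Z = M - P`` where
    ``M`` is the -1/0/1 call matrix and column i of ``P`` is filled with
    ``2 (p_i - 0.5)``, ``p_i`` being the +1-allele sample frequency.
    Missing calls are imputed to the per-SNP mean of observed codes
    (equivalently, they contribute 0 to ``Z``).  With sample
    frequencies the columns of ``Z`` are centered, so ``G 1 = 0``.

    The mean diagonal ``d(G)`` equals one plus the average genomic
    inbreeding coefficient; for near-fully-inbred line material it sits
    well above 1.
    """
    p = allele_frequencies(geno).to_numpy(dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs are monomorphic: GRM denominator is zero")
    M = geno.to_numpy(dtype=float)
    center = 2.0 * (p - 0.5)
    Z = M - center  # broadcast over columns
    Z = np.where(np.isnan(Z), 0.0, Z)  # mean imputation -> zero contribution
    G = Z @ Z.T / denom
    if jitter:
        G = G + jitter * np.eye(G.shape[0])
    return pd.DataFrame(G, index=geno.index, columns=geno.index)


def build_gw_kernel(
    G: pd.DataFrame,
    obs_line: pd.Series,
    omega: pd.DataFrame,
    max_dense: int = 6000,
) -> pd.DataFrame:
    """Observation-level interaction kernel ``(Zg G Zg') o Omega``.

    Parameters
    ----------
    G : line x line GRM.
    obs_line : maps observation id (index) to line id (values).
    omega : observation x observation environmental kernel, indexed
        identically to ``obs_line.index``.

    The Hadamard (cell-by-cell) product of two PSD matrices is PSD by
    the Schur product theorem, so the result is a valid covariance
    kernel.  Materialized dense; refuses above ``max_dense``
    observations.
    """
    n = len(obs_line)
    if n > max_dense:
        raise ValueError(f"n = {n} observations exceeds dense cap {max_dense}")
    if list(omega.index) != list(obs_line.index):
        omega = omega.loc[obs_line.index, obs_line.index]
    unknown = sorted(set(obs_line) - set(G.index))
    if unknown:
        raise ValueError(f"observations map to lines absent from G: {unknown}")
    line_pos = pd.Index(G.index).get_indexer(obs_line.values)
    Gobs = G.to_numpy(dtype=float)[np.ix_(line_pos, line_pos)]
    gw = Gobs * omega.to_numpy(dtype=float)
    return pd.DataFrame(gw, index=obs_line.index, columns=obs_line.index)
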