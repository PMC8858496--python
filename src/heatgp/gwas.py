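"""Mixed linear model association and multi-trait meta-analysis.

``run_mlma`` is the standard MLMA scheme: variance components of the null
model y = Xb + g + e (g ~ N(0, G sg2)) are estimated once by GREML on the
array-SNP GRM, then every sequence SNP is tested by generalised least
squares with V = G sg2 + I se2 held fixed.  Computations run in the GRM
eigenbasis, so testing is a whitened ordinary regression, vectorised over
SNP chunks.  Two-sided p-values use the normal approximation (t^2 ~
chi-square with 1 df), the large-n convention of MLMA tools.

``meta_multitrait`` combines the three slope-trait GWAS into one
chi-square statistic per SNP: chi2 = t' V^-1 t where t is the vector of
signed t-statistics and V their correlation matrix estimated over all
SNPs (with a polygenic trait the genome-wide bulk is effectively null).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from heatgp.errors import DataError
from heatgp.kinship import GrmMatrix, estimate_greml

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["chromosome", "snp_id", "position_bp", "effect_allele",
                "beta", "se", "t", "p", "neg_log10_p"]


def run_mlma(
    phenotype,
    genotypes,
    grm: GrmMatrix,
    covariates=None,
    variance_components=None,
    chunk_size: int = 4096,
) -> pd.DataFrame:
    """Single-trait mixed-model association for every SNP in ``genotypes``.

    Parameters
    ----------
    phenotype
        Per-individual trait values aligned with ``genotypes`` rows (e.g.
        slope trait deviations from the reaction-norm stage).
    genotypes
        GenotypeMatrix of the SNPs to test (typically the sequence tier).
    grm
        Relationship matrix of the same individuals (typically built from
        the array tier); defines the polygenic covariance of the null model.
    covariates
        Optional extra fixed-effect columns (e.g. 0/1 breed indicator).
    variance_components
        Optional (sigma_g2, sigma_e2) pair; when absent they are estimated
        by GREML on the null model.  Passing (0, se2) reduces the test to
        ordinary least squares.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n != genotypes.n_individuals or n != grm.n:
        raise DataError("phenotype, genotypes and GRM sizes do not match")
    if not np.array_equal(genotypes.individual_ids, grm.individual_ids):
        raise DataError("genotype and GRM individual orders differ")

    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float).reshape(n, -1)])

    if variance_components is None:
        vc = estimate_greml(y, grm, covariates)
        sg, se = vc.sigma_g2, vc.sigma_e2
    else:
        sg, se = map(float, variance_components)

    lam, U = grm.eigen()
    d = sg * lam + se
    w = 1.0 / np.sqrt(d)                       # whitening weights in eigenbasis
    yw = (U.T @ y) * w
    Xw = (U.T @ X) * w[:, None]
    Q, _ = np.linalg.qr(Xw)
    yr = yw - Q @ (Q.T @ yw)

    m = genotypes.n_snps
    beta = np.zeros(m)
    se_b = np.full(m, np.nan)
    flagged = np.zeros(m, dtype=bool)
    dos = genotypes.dosages
    for start in range(0, m, chunk_size):
        stop = min(start + chunk_size, m)
        Gc = dos[:, start:stop].astype(np.float64)
        var0 = Gc.var(axis=0)
        Gw = (U.T @ Gc) * w[:, None]
        Gr = Gw - Q @ (Q.T @ Gw)
        ss = np.einsum("ij,ij->j", Gr, Gr)
        ok = (var0 > 0) & (ss > 0)
        num = Gr.T @ yr
        with np.errstate(divide="ignore", invalid="ignore"):
            beta[start:stop] = np.where(ok, num / ss, 0.0)
            se_b[start:stop] = np.where(ok, 1.0 / np.sqrt(ss), np.nan)
        flagged[start:stop] = ~ok

    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(flagged, 0.0, beta / se_b)
    p = np.where(flagged, 1.0, 2.0 * stats.norm.sf(np.abs(t)))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if flagged.any():
        logger.info("%d SNPs with zero variance flagged (p set to 1)", int(flagged.sum()))

    out = genotypes.snp_map[["chromosome", "snp_id", "position_bp", "alt_allele"]].copy()
    out = out.rename(columns={"alt_allele": "effect_allele"})
    out["beta"] = beta
    out["se"] = se_b
    out["t"] = t
    out["p"] = p
    out["neg_log10_p"] = -np.log10(p)
    out["flagged"] = flagged
    return out


def genomic_inflation(results: pd.DataFrame) -> float:
    """Genomic-control lambda: median chi-square over its null median."""
    t = results["t"].to_numpy(dtype=float)
    if "flagged" in results.columns:
        t = t[~results["flagged"].to_numpy(dtype=bool)]
    chi2 = t**2
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))


def meta_multitrait(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Multi-trait meta-analysis of aligned single-trait GWAS tables.

    All inputs must carry identical SNP sets in identical order.  The
    statistic is chi2 = t' V^-1 t with V the correlation matrix of the
    per-trait signed t-values across all SNPs; df = number of traits.
    """
    if len(results) < 2:
        raise DataError("meta-analysis needs at least two trait results")
    base = results[0]["snp_id"].to_numpy()
    for r in results[1:]:
        if not np.array_equal(r["snp_id"].to_numpy(), base):
            raise DataError("SNP sets/order differ across trait results")
    T = np.column_stack([r["t"].to_numpy(dtype=float) for r in results])
    V = np.corrcoef(T, rowvar=False)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e8:
        raise DataError("t-statistic correlation matrix is singular: the trait "
                        "results are collinear (duplicated traits?)")
    Vinv = np.linalg.inv(V)
    chi2 = np.einsum("ij,jk,ik->i", T, Vinv, T)
    df = T.shape[1]
    p = np.clip(stats.chi2.sf(chi2, df), np.finfo(float).tiny, 1.0)
    out = results[0][["chromosome", "snp_id", "position_bp"]].copy()
    out["chi2"] = chi2
    out["df"] = df
    out["p"] = p
    out["neg_log10_p"] = -np.log10(p)
    for k, r in enumerate(results, start=1):
        out[f"t{k}"] = r["t"].to_numpy()
    return out
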