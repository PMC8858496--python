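"""Validation of genomic predictions.

Accuracy is the Pearson correlation between GBV and trait-deviation
phenotypes in the validation cows, divided by the square root of the
trait's genomic heritability (so a perfect predictor of the additive
merit scores 1).  Its standard error is the sample SD of the accuracies
over the two random validation subsets divided by sqrt(2).  Dispersion
bias is the regression coefficient of phenotype on GBV (1.0 = unbiased,
> 1 deflated, < 1 inflated predictions).  The LR-method check regresses
GBV from the whole reference set on GBV from a reduced one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from heatgp.errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    trait: str
    method: str
    accuracy: float
    accuracy_se: float
    bias_b: float
    n_subsets: int
    subset_accuracies: list


@dataclass
class LrReport:
    corr_whole_partial: float
    b_w_p: float


def _aligned(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("vector length mismatch")
    return a, b


def prediction_accuracy(gbv, phen, h2: float) -> float:
    """Pearson r between GBV and phenotype, scaled by 1/sqrt(h2)."""
    if not 0.0 < h2 <= 1.0:
        raise ConfigError(f"h2 must be in (0, 1], got {h2}")
    g, p = _aligned(gbv, phen)
    if g.size < 3:
        raise DataError("need at least 3 individuals")
    if np.std(g) == 0 or np.std(p) == 0:
        raise DataError("zero-variance GBV or phenotype")
    r = float(np.corrcoef(g, p)[0, 1])
    return r / float(np.sqrt(h2))


def accuracy_se(subset_accuracies) -> float:
    """SE of the accuracy: sample SD over subsets / sqrt(n_subsets)."""
    acc = np.asarray(subset_accuracies, dtype=float)
    if acc.size < 2:
        raise DataError("need at least 2 validation subsets")
    return float(np.std(acc, ddof=1) / np.sqrt(acc.size))


def dispersion_bias(phen, gbv) -> float:
    """OLS slope of phenotype on GBV; 1.0 means no dispersion bias."""
    p, g = _aligned(phen, gbv)
    vg = np.var(g)
    if vg == 0:
        raise DataError("zero-variance GBV")
    return float(np.cov(p, g, ddof=0)[0, 1] / vg)


def lr_consistency(gbv_whole, gbv_partial) -> LrReport:
    """LR-method check: correlation and slope of whole-data GBV on
    partial-data GBV over the same individuals (both near 1 when the
    predictions are consistent and undispersed)."""
    if isinstance(gbv_whole, pd.Series) and isinstance(gbv_partial, pd.Series):
        if not gbv_whole.index.equals(gbv_partial.index):
            raise DataError("whole/partial GBV cover different individuals")
    w, p = _aligned(np.asarray(gbv_whole), np.asarray(gbv_partial))
    vp = np.var(p)
    if vp == 0:
        raise DataError("zero-variance partial GBV")
    corr = float(np.corrcoef(w, p)[0, 1])
    slope = float(np.cov(w, p, ddof=0)[0, 1] / vp)
    return LrReport(corr_whole_partial=corr, b_w_p=slope)


def sign_concordance(results_a: pd.DataFrame, results_b: pd.DataFrame,
                     p_cutoff: float = 0.001) -> float:
    """Fraction of jointly significant SNPs with the same effect direction.

    SNPs with p < ``p_cutoff`` in both GWAS tables are compared on
    sign(beta); zero effects carry no sign and are excluded (logged).
    """
    a = results_a.set_index("snp_id")
    b = results_b.set_index("snp_id")
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise DataError("no shared SNPs between the two GWAS tables")
    a, b = a.loc[shared], b.loc[shared]
    sig = (a["p"].to_numpy() < p_cutoff) & (b["p"].to_numpy() < p_cutoff)
    if not sig.any():
        raise DataError(f"no SNP significant at p < {p_cutoff} in both sets")
    sa = np.sign(a["beta"].to_numpy()[sig])
    sb = np.sign(b["beta"].to_numpy()[sig])
    has_sign = (sa != 0) & (sb != 0)
    dropped = int((~has_sign).sum())
    if dropped:
        logger.info("excluded %d SNPs with zero effect (no sign)", dropped)
    if not has_sign.any():
        raise DataError("all jointly significant SNPs have zero effects")
    return float(np.mean(sa[has_sign] == sb[has_sign]))


def validation_report(trait: str, method: str, gbv: pd.Series, phen: pd.Series,
                      subsets: tuple, h2: float) -> ValidationReport:
    """Assemble the per-trait, per-method validation summary.

    ``subsets`` holds the id arrays of the two random validation subsets;
    accuracy is computed per subset and pooled: the reported accuracy is
    over the full validation set, the SE over the subset accuracies.
    Bias is computed on the full set.
    """
    accs = []
    for ids in subsets:
        accs.append(prediction_accuracy(gbv.loc[ids], phen.loc[ids], h2))
    all_ids = np.concatenate([np.asarray(s) for s in subsets])
    acc = prediction_accuracy(gbv.loc[all_ids], phen.loc[all_ids], h2)
    bias = dispersion_bias(phen.loc[all_ids], gbv.loc[all_ids])
    return ValidationReport(trait=trait, method=method, accuracy=acc,
                            accuracy_se=accuracy_se(accs), bias_b=bias,
                            n_subsets=len(subsets), subset_accuracies=accs)
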