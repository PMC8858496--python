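"""Heat-tolerance phenotypes from test-day records.

A cow's heat tolerance is summarised by the intercept and slope of her
yield reaction norm on the thresholded temperature-humidity index (THI):
the intercept is her mean yield level, the slope her rate of yield change
per unit of scaled THI above the heat-stress threshold (THI 60 by
default; records below it are set to the threshold).

The derivation runs in two stages, matching routine-evaluation practice:

1. adjust yields for fixed effects (herd-test-day, parity) by least
   squares;
2. fit a two-random-effects-per-cow mixed model (random intercept and
   random slope on the order-1 Legendre THI basis, plus residual), at
   supplied or EM-REML-estimated variance components.

The per-cow intercept/slope solutions are the trait deviations (TD); a
bull's phenotype is the unweighted mean of his daughters' TDs (daughter
trait deviations, DTD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from heatgp.errors import ConfigError, ConvergenceError, DataError
from heatgp.simdata import scaled_thi

logger = logging.getLogger(__name__)


@dataclass
class TraitDeviation:
    cow_id: str
    intercept_td: float
    slope_td: float
    n_records: int


@dataclass
class BullRecord:
    """Bull phenotype: daughter-average TDs with count p and weight w."""

    bull_id: str
    dtd_intercept: float
    dtd_slope: float
    p: int
    w: float = float("nan")


def threshold_thi(thi, threshold: float = 60.0):
    """Thresholded THI: max(thi, threshold).

    Yield is flat in THI below the heat-stress onset, so values below the
    threshold are mapped onto it.  Idempotent and monotone non-decreasing.
    """
    return np.maximum(thi, threshold)


def thi_basis(thi, threshold: float = 60.0, thi_max: float = 85.0):
    """Order-1 Legendre covariate: thresholded THI rescaled to [-1, 1]."""
    return scaled_thi(thi, threshold, thi_max)


def _adjust_fixed_effects(records: pd.DataFrame) -> np.ndarray:
    """Least-squares adjustment of yield for herd-test-day and parity.

    Returns the residual of yield on the categorical fixed effects (the
    first level of each factor after the first is the reference; an
    intercept column makes the design full-rank up to the usual factor
    aliasing, which lsmr handles as a minimum-norm solution).
    """
    y = records["yield"].to_numpy(dtype=float)
    n = len(y)
    cols = []
    cols.append(sp.csr_matrix(np.ones((n, 1))))
    for factor in ("herd_test_day", "parity"):
        codes, uniques = pd.factorize(records[factor], sort=True)
        if len(uniques) > 1:
            mat = sp.csr_matrix(
                (np.ones(n), (np.arange(n), codes)), shape=(n, len(uniques)))
            cols.append(mat[:, 1:])
    X = sp.hstack(cols, format="csr")
    sol = spla.lsmr(X, y, atol=1e-10, btol=1e-10, maxiter=2000)
    beta = sol[0]
    return y - X @ beta


def _per_cow_stats(t: np.ndarray, y: np.ndarray, cow_codes: np.ndarray, n_cows: int):
    """Sufficient statistics per cow for the 2x2 random-regression model."""
    ones = np.ones_like(t)
    ztz = np.zeros((n_cows, 2, 2))
    np.add.at(ztz[:, 0, 0], cow_codes, ones)
    np.add.at(ztz[:, 0, 1], cow_codes, t)
    np.add.at(ztz[:, 1, 1], cow_codes, t * t)
    ztz[:, 1, 0] = ztz[:, 0, 1]
    zty = np.zeros((n_cows, 2))
    np.add.at(zty[:, 0], cow_codes, y)
    np.add.at(zty[:, 1], cow_codes, t * y)
    yty = np.zeros(n_cows)
    np.add.at(yty, cow_codes, y * y)
    counts = ztz[:, 0, 0].astype(int)
    return ztz, zty, yty, counts


def _inv2(M: np.ndarray) -> np.ndarray:
    """Batched 2x2 inverse."""
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    inv = np.empty_like(M)
    inv[:, 0, 0] = M[:, 1, 1]
    inv[:, 1, 1] = M[:, 0, 0]
    inv[:, 0, 1] = -M[:, 0, 1]
    inv[:, 1, 0] = -M[:, 1, 0]
    return inv / det[:, None, None]


def fit_reaction_norm(
    records: pd.DataFrame,
    variance_config: dict | None = None,
    threshold: float = 60.0,
    thi_max: float | None = None,
    min_records: int = 4,
    min_distinct_above: int = 2,
) -> pd.DataFrame:
    """Derive per-cow intercept and slope trait deviations.

    Parameters
    ----------
    records
        Test-day table with columns cow_id, herd_test_day, parity, thi,
        yield (dim/age_days are carried but not used at this scale).
    variance_config
        Optional dict with keys ``cov_u`` (2x2 covariance of the cow
        intercept/slope random effects) and ``sigma_e2``.  When absent,
        components are estimated by EM-REML (relative tolerance 1e-6).
    threshold, thi_max
        THI threshold and upper end of the basis-orthogonalisation range;
        thi_max defaults to the maximum observed THI.

    Returns
    -------
    DataFrame with columns cow_id, intercept_td, slope_td, n_records.
    """
    required = {"cow_id", "herd_test_day", "parity", "thi", "yield"}
    if not required <= set(records.columns):
        raise DataError(f"test-day table missing columns: {sorted(required - set(records.columns))}")
    if thi_max is None:
        thi_max = float(records["thi"].max())
    if thi_max <= threshold:
        raise ConfigError("all THI at or below the threshold: slope unidentifiable")

    y_adj = _adjust_fixed_effects(records)
    t = thi_basis(records["thi"].to_numpy(dtype=float), threshold, thi_max)

    cow_codes, cow_ids = pd.factorize(records["cow_id"])
    n_cows = len(cow_ids)
    ztz, zty, yty, counts = _per_cow_stats(t, y_adj, cow_codes, n_cows)

    # identifiability screen: enough records and distinct suprathreshold THI
    thi_arr = records["thi"].to_numpy(dtype=float)
    above = thi_arr > threshold
    distinct = np.zeros(n_cows, dtype=int)
    df_above = pd.DataFrame({"c": cow_codes[above], "t": np.round(thi_arr[above], 9)})
    if len(df_above):
        distinct_counts = df_above.groupby("c")["t"].nunique()
        distinct[distinct_counts.index.to_numpy()] = distinct_counts.to_numpy()
    keep = (counts >= min_records) & (distinct >= min_distinct_above)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d cows below the record/identifiability threshold", n_dropped)
    if not keep.any():
        raise DataError("no cow passes the identifiability screen")

    ztz, zty, yty, counts = ztz[keep], zty[keep], yty[keep], counts[keep]
    cow_ids = np.asarray(cow_ids, dtype=object)[keep]
    n_rec_total = int(counts.sum())

    if variance_config and "cov_u" in variance_config:
        S0 = np.asarray(variance_config["cov_u"], dtype=float)
        se2 = float(variance_config["sigma_e2"])
        if se2 <= 0 or np.linalg.det(S0) < 0 or S0[0, 0] < 0:
            raise ConfigError("non-positive variance components supplied")
        u = _blup_solutions(ztz, zty, S0, se2)[0]
    else:
        S0, se2, u = _em_reml_random_regression(ztz, zty, yty, n_rec_total)

    return pd.DataFrame({
        "cow_id": cow_ids,
        "intercept_td": u[:, 0],
        "slope_td": u[:, 1],
        "n_records": counts,
    })


def _blup_solutions(ztz, zty, S0, se2):
    """Posterior mean and covariance of (intercept, slope) per cow."""
    S0inv = np.linalg.inv(S0 + 1e-12 * np.eye(2))
    prec = ztz / se2 + S0inv[None, :, :]
    C = _inv2(prec)
    u = np.einsum("nij,nj->ni", C, zty) / se2
    return u, C


def _em_reml_random_regression(ztz, zty, yty, n_rec_total,
                               tol: float = 1e-6, max_iter: int = 500):
    """EM-REML for the per-cow random-regression variance components.

    Fixed effects were removed beforehand, so the model is y = Z u + e with
    u_i ~ N(0, S0) i.i.d. across cows; the EM updates are the classic
    mixed-model ones on per-cow 2x2 sufficient statistics.
    """
    n_cows = ztz.shape[0]
    mean_diag = max(float(np.mean(yty / np.maximum(ztz[:, 0, 0], 1))), 1e-6)
    S0 = np.eye(2) * mean_diag / 2
    se2 = mean_diag / 2
    floor = 1e-12 * mean_diag
    for it in range(max_iter):
        u, C = _blup_solutions(ztz, zty, S0, se2)
        S0_new = (np.einsum("ni,nj->ij", u, u) + C.sum(axis=0)) / n_cows
        # residual: sum ||y_i - Z_i u_i||^2 + tr(Z_i C_i Z_i')
        fit = np.einsum("ni,nij,nj->n", u, ztz, u)
        cross = np.einsum("ni,ni->n", u, zty)
        rss = float(np.sum(yty - 2 * cross + fit))
        tr = float(np.einsum("nij,nji->", C, ztz))
        se2_new = max((rss + tr) / n_rec_total, floor)
        S0_new = S0_new + floor * np.eye(2)
        delta = (abs(se2_new - se2) / max(se2, floor)
                 + float(np.max(np.abs(S0_new - S0)) / max(np.max(np.abs(S0)), floor)))
        S0, se2 = S0_new, se2_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(f"EM-REML did not converge in {max_iter} iterations")
    u, _ = _blup_solutions(ztz, zty, S0, se2)
    return S0, se2, u


def bull_dtd(tds: pd.DataFrame, sire_links: pd.DataFrame,
             h2: float | None = None, c: float = 0.2) -> pd.DataFrame:
    """Average daughters' trait deviations into bull records (DTD).

    ``sire_links`` maps cow_id -> sire_id (one sire per daughter).  Bulls
    without any daughter in ``tds`` are omitted (logged).  When ``h2`` is
    given, the residual weight w = (1 - h2) / (c h2 + (4 - h2)/p) is filled
    per bull from his daughter count p.
    """
    links = sire_links[["cow_id", "sire_id"]].drop_duplicates()
    if links["cow_id"].duplicated().any():
        raise DataError("a daughter has more than one sire in sire_links")
    merged = tds.merge(links, on="cow_id", how="inner")
    n_bulls_all = links["sire_id"].nunique()
    grouped = merged.groupby("sire_id", sort=True).agg(
        dtd_intercept=("intercept_td", "mean"),
        dtd_slope=("slope_td", "mean"),
        p=("cow_id", "count"),
    ).reset_index().rename(columns={"sire_id": "bull_id"})
    if len(grouped) < n_bulls_all:
        logger.info("omitted %d bulls with zero phenotyped daughters",
                    n_bulls_all - len(grouped))
    if h2 is not None:
        from heatgp.predict import bull_weight
        grouped["w"] = [bull_weight(h2, c, p) for p in grouped["p"]]
    else:
        grouped["w"] = np.nan
    return grouped
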