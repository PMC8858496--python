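"""Genomic prediction: BayesR, BayesRC and GBLUP.

BayesR models the phenotype as y = Xb + Wv + e with W the centred dosage
matrix and each SNP effect drawn from a four-component normal mixture
with variances {0, 1e-4, 1e-3, 1e-2} x sigma_v2.  Residuals are
heteroscedastic, e ~ N(0, sigma_e2 * diag(1/w_i)) — for a bull reference
set w_i is the daughter-count weight of :func:`bull_weight`.  BayesRC is
the same model with a separate mixture-proportion vector per SNP
annotation class (here: standard array SNPs vs prioritised "top SNPs").

The Gibbs sampler integrates the SNP effect analytically when drawing its
class indicator, then draws the effect from its conditional normal;
mixture proportions come from Dirichlet conditionals, and both variance
components from scaled inverse chi-square conditionals with flat priors.
Chains run sequentially with seeds seed+chain and are pooled post
burn-in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from heatgp.errors import ConfigError, DataError
from heatgp.kinship import GrmMatrix, VarianceComponents, reml_multi_kernel
from heatgp.simdata import MIXTURE_CLASS_SCALARS

logger = logging.getLogger(__name__)


def bull_weight(h2: float, c: float = 0.2, p: int = 1) -> float:
    """Residual weight of a bull phenotype built from p daughter records.

    w = (1 - h2) / (c * h2 + (4 - h2) / p), where c is the proportion of
    genetic variance not captured by the SNPs (0.2 by default) and p the
    bull's daughter count.  Larger p -> smaller residual variance of the
    daughter average -> larger weight.
    """
    if not 0.0 < h2 < 1.0:
        raise ConfigError(f"h2 must be in (0, 1), got {h2}")
    if p < 1:
        raise ConfigError(f"daughter count p must be >= 1, got {p}")
    return (1.0 - h2) / (c * h2 + (4.0 - h2) / p)


@dataclass
class MixtureSpec:
    class_scalars: tuple = MIXTURE_CLASS_SCALARS
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self):
        if len(self.class_scalars) != 4 or list(self.class_scalars) != sorted(self.class_scalars):
            raise ConfigError("class_scalars must be the 4 ordered mixture scalars")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ConfigError("dirichlet_alpha must be positive")


@dataclass
class McmcConfig:
    n_chains: int = 5
    n_iter: int = 40_000
    burn_in: int = 20_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.n_chains < 1:
            raise ConfigError("need at least one chain")


@dataclass
class PosteriorSummary:
    """Pooled posterior summaries of a BayesR/BayesRC fit."""

    snp_ids: np.ndarray
    snp_effect_mean: np.ndarray          # (m,)
    class_prob: np.ndarray               # (m, 4), rows sum to 1
    fixed_effects: np.ndarray            # (p,)
    sigma_v2_mean: float
    sigma_e2_mean: float
    mixture_proportions_mean: np.ndarray  # (n_annot, 4)
    annotation: np.ndarray               # (m,) int class index
    ref_freq: np.ndarray                 # (m,) allele freq used for centring
    chain_diagnostics: pd.DataFrame = field(default=None, repr=False)
    traces: dict = field(default_factory=dict, repr=False)


@njit(cache=True)
def _gibbs_chain(y, W, X, wts, annot, n_annot, scalars, alpha,
                 n_iter, burn_in, thin, seed,
                 sv2_init, se2_init, pi_init, forced_class,
                 update_sv2, update_se2, update_pi):
    np.random.seed(seed)
    n, m = W.shape
    p = X.shape[1]
    n4 = 4

    cx = np.zeros(p)
    for l in range(p):
        s = 0.0
        for i in range(n):
            s += wts[i] * X[i, l] * X[i, l]
        cx[l] = s
    cj = np.zeros(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += wts[i] * W[i, j] * W[i, j]
        cj[j] = s

    beta = np.zeros(p)
    v = np.zeros(m)
    e = y.copy()
    sv2 = sv2_init
    se2 = se2_init
    pi = pi_init.copy()

    eff_sum = np.zeros(m)
    class_sum = np.zeros((m, n4))
    beta_sum = np.zeros(p)
    pi_sum = np.zeros((n_annot, n4))
    sv2_sum = 0.0
    se2_sum = 0.0
    n_post = 0

    n_trace = (n_iter - burn_in + thin - 1) // thin
    sv2_trace = np.zeros(n_trace)
    se2_trace = np.zeros(n_trace)
    pi_trace = np.zeros((n_trace, n_annot, n4))
    i_trace = 0

    lw = np.zeros(n4)
    mks = np.zeros(n4)
    Vks = np.zeros(n4)
    status = 0

    for it in range(n_iter):
        post = it >= burn_in
        # ---- fixed effects
        for l in range(p):
            u = 0.0
            for i in range(n):
                u += wts[i] * X[i, l] * e[i]
            u += cx[l] * beta[l]
            mean = u / cx[l]
            bnew = mean + np.sqrt(se2 / cx[l]) * np.random.normal()
            diff = beta[l] - bnew
            if diff != 0.0:
                for i in range(n):
                    e[i] += X[i, l] * diff
            beta[l] = bnew

        # ---- SNP effects with integrated class indicators
        counts = np.zeros((n_annot, n4))
        S_v = 0.0
        q_v = 0
        for j in range(m):
            u = 0.0
            for i in range(n):
                u += wts[i] * W[i, j] * e[i]
            u += cj[j] * v[j]
            a = annot[j]
            lw[0] = np.log(pi[a, 0] + 1e-300)
            mks[0] = 0.0
            Vks[0] = 0.0
            maxlw = lw[0]
            for k in range(1, n4):
                sk = scalars[k] * sv2
                Vk = 1.0 / (cj[j] / se2 + 1.0 / sk)
                mk = Vk * u / se2
                lw[k] = np.log(pi[a, k] + 1e-300) + 0.5 * (np.log(Vk) - np.log(sk)) \
                    + 0.5 * mk * mk / Vk
                mks[k] = mk
                Vks[k] = Vk
                if lw[k] > maxlw:
                    maxlw = lw[k]
            if forced_class[j] >= 0:
                ksel = forced_class[j]
            else:
                tot = 0.0
                for k in range(n4):
                    lw[k] = np.exp(lw[k] - maxlw)
                    tot += lw[k]
                rdraw = np.random.random() * tot
                ksel = n4 - 1
                acc = 0.0
                for k in range(n4):
                    acc += lw[k]
                    if rdraw <= acc:
                        ksel = k
                        break
            if ksel == 0:
                vnew = 0.0
            else:
                vnew = mks[ksel] + np.sqrt(Vks[ksel]) * np.random.normal()
                S_v += vnew * vnew / scalars[ksel]
                q_v += 1
            diff = v[j] - vnew
            if diff != 0.0:
                for i in range(n):
                    e[i] += W[i, j] * diff
            v[j] = vnew
            counts[a, ksel] += 1.0
            if post:
                class_sum[j, ksel] += 1.0

        # ---- mixture proportions per annotation class (Dirichlet)
        if update_pi:
            for a in range(n_annot):
                tot = 0.0
                for k in range(n4):
                    g = np.random.gamma(alpha[k] + counts[a, k], 1.0)
                    pi[a, k] = g
                    tot += g
                for k in range(n4):
                    pi[a, k] /= tot

        # ---- variance components (scaled inverse chi-square, flat priors)
        if update_sv2 and q_v >= 3:
            sv2 = S_v / np.random.chisquare(q_v - 2)
            if sv2 < 1e-12:
                sv2 = 1e-12
        if update_se2:
            Se = 0.0
            for i in range(n):
                Se += wts[i] * e[i] * e[i]
            se2 = Se / np.random.chisquare(n - 2)
            if se2 < 1e-12:
                se2 = 1e-12
        if not np.isfinite(se2) or not np.isfinite(sv2):
            status = 1
            break

        # periodic residual refresh against numerical drift
        if (it + 1) % 1000 == 0:
            e = y - X @ beta - W @ v

        if post:
            n_post += 1
            for j in range(m):
                eff_sum[j] += v[j]
            for l in range(p):
                beta_sum[l] += beta[l]
            sv2_sum += sv2
            se2_sum += se2
            for a in range(n_annot):
                for k in range(n4):
                    pi_sum[a, k] += pi[a, k]
            if (it - burn_in) % thin == 0:
                sv2_trace[i_trace] = sv2
                se2_trace[i_trace] = se2
                for a in range(n_annot):
                    for k in range(n4):
                        pi_trace[i_trace, a, k] = pi[a, k]
                i_trace += 1

    return (eff_sum, class_sum, beta_sum, pi_sum, sv2_sum, se2_sum, n_post,
            sv2_trace[:i_trace], se2_trace[:i_trace], pi_trace[:i_trace], status)


def _as_matrix(genotypes, center_freq):
    """Centred dosage matrix and metadata from a GenotypeMatrix or ndarray."""
    if hasattr(genotypes, "dosages"):
        freq = genotypes.allele_freq if center_freq is None else np.asarray(center_freq, float)
        W = genotypes.dosages.astype(np.float64) - 2.0 * freq
        return np.ascontiguousarray(W), genotypes.snp_ids, freq
    W = np.asarray(genotypes, dtype=np.float64)
    freq = W.mean(axis=0) / 2.0 if center_freq is None else np.asarray(center_freq, float)
    return np.ascontiguousarray(W - 2.0 * freq), \
        np.array([f"snp{j}" for j in range(W.shape[1])], dtype=object), freq


def fit_bayesr(
    y,
    genotypes,
    weights=None,
    covariates=None,
    mixture: MixtureSpec | None = None,
    mcmc: McmcConfig | None = None,
    annotation=None,
    center_freq=None,
    forced_class=None,
    initial=None,
    update_sigma_v2: bool = True,
    update_sigma_e2: bool = True,
    update_proportions: bool = True,
) -> PosteriorSummary:
    """Fit the BayesR mixture model by Gibbs sampling.

    Parameters
    ----------
    y
        Reference phenotypes (e.g. bull daughter trait deviations).
    genotypes
        GenotypeMatrix of the reference individuals, or a raw dosage
        matrix; columns are centred internally (``center_freq`` overrides
        the centring frequencies, and is stored for later prediction).
    weights
        Positive residual weights w_i (residual variance sigma_e2 / w_i);
        defaults to 1.
    annotation
        Optional per-SNP integer class for BayesRC-style separate mixture
        proportions; ``fit_bayesrc`` is the friendlier entry point.
    forced_class, initial, update_*
        Testing hooks: pin class memberships, set starting values, or
        freeze hyperparameters so the sampler targets a fixed-variance
        conditional posterior.
    """
    mixture = mixture or MixtureSpec()
    mcmc = mcmc or McmcConfig()
    y = np.asarray(y, dtype=float)
    n = y.size
    W, snp_ids, freq = _as_matrix(genotypes, center_freq)
    if W.shape[0] != n:
        raise DataError("phenotype and genotype row counts differ")
    m = W.shape[1]

    wts = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (wts <= 0).any():
        raise DataError("residual weights must be positive")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float).reshape(n, -1)])
    annot = np.zeros(m, dtype=np.int64) if annotation is None else \
        np.asarray(annotation, dtype=np.int64)
    n_annot = int(annot.max()) + 1
    forced = np.full(m, -1, dtype=np.int64) if forced_class is None else \
        np.asarray(forced_class, dtype=np.int64)

    vary = float(np.var(y))
    init = {"sigma_v2": vary if vary > 0 else 1.0,
            "sigma_e2": vary / 2 if vary > 0 else 1.0,
            "pi": np.tile(np.array([0.9, 0.05, 0.03, 0.02]), (n_annot, 1))}
    if initial:
        init.update(initial)
    pi0 = np.asarray(init["pi"], dtype=float).reshape(n_annot, 4)

    scalars = np.asarray(mixture.class_scalars, dtype=float)
    alpha = np.asarray(mixture.dirichlet_alpha, dtype=float)

    eff = np.zeros(m)
    cls = np.zeros((m, 4))
    bet = np.zeros(X.shape[1])
    pim = np.zeros((n_annot, 4))
    sv2_tot = se2_tot = 0.0
    n_tot = 0
    diags = []
    traces = {"sigma_v2": [], "sigma_e2": [], "proportions": []}
    for chain in range(mcmc.n_chains):
        out = _gibbs_chain(
            y, W, X, wts, annot, n_annot, scalars, alpha,
            mcmc.n_iter, mcmc.burn_in, mcmc.thin, int(mcmc.seed + chain),
            float(init["sigma_v2"]), float(init["sigma_e2"]), pi0, forced,
            update_sigma_v2, update_sigma_e2, update_proportions)
        (e_s, c_s, b_s, p_s, sv_s, se_s, n_post, sv_tr, se_tr, pi_tr, status) = out
        if status != 0:
            raise DataError(f"chain {chain}: residual variance diverged; "
                            "check weights and phenotype scaling")
        eff += e_s
        cls += c_s
        bet += b_s
        pim += p_s
        sv2_tot += sv_s
        se2_tot += se_s
        n_tot += n_post
        diags.append({"chain": chain, "sigma_v2_mean": sv_s / n_post,
                      "sigma_e2_mean": se_s / n_post,
                      "prop_nonzero": float(c_s[:, 1:].sum() / c_s.sum())})
        traces["sigma_v2"].append(sv_tr)
        traces["sigma_e2"].append(se_tr)
        traces["proportions"].append(pi_tr)

    return PosteriorSummary(
        snp_ids=snp_ids,
        snp_effect_mean=eff / n_tot,
        class_prob=cls / cls.sum(axis=1, keepdims=True),
        fixed_effects=bet / n_tot,
        sigma_v2_mean=sv2_tot / n_tot,
        sigma_e2_mean=se2_tot / n_tot,
        mixture_proportions_mean=pim / n_tot,
        annotation=annot,
        ref_freq=freq,
        chain_diagnostics=pd.DataFrame(diags),
        traces=traces,
    )


def fit_bayesrc(
    y,
    genotypes,
    weights=None,
    covariates=None,
    classes=None,
    mixture: MixtureSpec | None = None,
    mcmc: McmcConfig | None = None,
    **kwargs,
) -> PosteriorSummary:
    """BayesRC: BayesR with per-annotation-class mixture proportions.

    ``classes`` maps each SNP to an annotation class, as an integer array
    aligned with the SNPs, or a mapping snp_id -> {'I', 'II', ...}.  Every
    fitted SNP must be covered; empty classes are dropped with a warning.
    """
    if classes is None:
        raise ConfigError("BayesRC needs a class assignment; use fit_bayesr otherwise")
    if hasattr(genotypes, "snp_ids"):
        snp_ids = genotypes.snp_ids
    else:
        snp_ids = np.array([f"snp{j}" for j in range(np.asarray(genotypes).shape[1])])
    if isinstance(classes, dict):
        labels = sorted(set(classes.values()))
        missing = [s for s in snp_ids if s not in classes]
        if missing:
            raise DataError(f"class assignment does not cover all SNPs: {missing[:5]}")
        annot = np.array([labels.index(classes[s]) for s in snp_ids], dtype=np.int64)
    else:
        annot = np.asarray(classes, dtype=np.int64)
        if annot.size != len(snp_ids):
            raise DataError("class assignment length does not match SNP count")
    # drop empty classes, re-index contiguously
    present = np.unique(annot)
    if present.size < annot.max() + 1:
        logger.warning("empty annotation classes ignored: %s",
                       sorted(set(range(int(annot.max()) + 1)) - set(present.tolist())))
    remap = {c: i for i, c in enumerate(present.tolist())}
    annot = np.array([remap[a] for a in annot], dtype=np.int64)
    return fit_bayesr(y, genotypes, weights=weights, covariates=covariates,
                      mixture=mixture, mcmc=mcmc, annotation=annot, **kwargs)


def predict_gbv(posterior: PosteriorSummary, genotypes) -> pd.Series:
    """Genomic breeding values: centred validation dosages x effect means.

    Validation columns are centred with the reference-set allele
    frequencies stored in the posterior (prediction never peeks at
    validation frequencies).  Fixed effects are excluded.
    """
    if hasattr(genotypes, "dosages"):
        if not np.array_equal(genotypes.snp_ids, posterior.snp_ids):
            raise DataError("SNP set mismatch between posterior and genotypes")
        W = genotypes.dosages.astype(np.float64) - 2.0 * posterior.ref_freq
        ids = genotypes.individual_ids
    else:
        W = np.asarray(genotypes, dtype=np.float64) - 2.0 * posterior.ref_freq
        ids = np.arange(W.shape[0])
    return pd.Series(W @ posterior.snp_effect_mean, index=ids, name="gbv")


def fit_gblup(
    y: pd.Series,
    weights=None,
    grms: list | GrmMatrix = None,
    covariates=None,
) -> tuple[pd.Series, list[VarianceComponents]]:
    """GBLUP with one or two genomic relationship kernels.

    ``y`` is indexed by individual id over the reference set; each GRM
    must cover the union of reference and prediction individuals.  REML
    variance components (with weighted residual) are estimated on the
    reference rows, then genetic values are BLUP-predicted for every
    individual in the kernels: g_hat = sum_k s_k K_k[:, ref] V^-1 (y - Xb).

    Returns (GBV series over all kernel individuals, per-kernel variance
    components; the residual appears in each component's sigma_e2).
    """
    if grms is None:
        raise ConfigError("at least one GRM is required")
    kernels = [grms] if isinstance(grms, GrmMatrix) else list(grms)
    all_ids = kernels[0].individual_ids
    for K in kernels[1:]:
        if not np.array_equal(K.individual_ids, all_ids):
            raise DataError("kernel dimension mismatch: GRMs cover different individuals")
    if not isinstance(y, pd.Series):
        raise DataError("y must be a pandas Series indexed by individual id")
    ref_ids = y.index.to_numpy()
    lookup = pd.Index(all_ids)
    ref_idx = lookup.get_indexer(ref_ids)
    if (ref_idx < 0).any():
        raise DataError("reference individuals missing from the kernels")

    yv = y.to_numpy(dtype=float)
    n = yv.size
    K_refs = [K.values[np.ix_(ref_idx, ref_idx)] for K in kernels]
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float).reshape(n, -1)])
    wts = None if weights is None else np.asarray(weights, dtype=float)

    sks, se2, ll = reml_multi_kernel(yv, K_refs, covariates=covariates, weights=wts)

    Dw = np.ones(n) if wts is None else 1.0 / wts
    V = np.diag(se2 * Dw)
    for s, Kr in zip(sks, K_refs):
        V += s * Kr
    Vinv = np.linalg.inv(V)
    bhat = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ yv)
    alphav = Vinv @ (yv - X @ bhat)
    gbv = np.zeros(len(all_ids))
    for s, K in zip(sks, kernels):
        gbv += s * (K.values[:, ref_idx] @ alphav)

    total = sum(sks) + se2
    comps = [VarianceComponents(sigma_g2=s, sigma_e2=se2,
                                h2=s / total, se_h2=float("nan"), loglik=ll)
             for s in sks]
    return pd.Series(gbv, index=all_ids, name="gbv"), comps
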