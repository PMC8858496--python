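"""Genomic relationship matrices and REML variance components.

The GRM follows VanRaden's first method: G = Z Z' / (2 sum_j p_j (1 - p_j))
with Z the column-centred dosage matrix and p_j the observed allele
frequencies.  Genomic heritability is estimated by average-information
REML with EM fallback; for the single-GRM model the GRM is eigendecomposed
once, making every REML iteration O(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heatgp.errors import ConvergenceError, DataError

logger = logging.getLogger(__name__)


@dataclass
class GrmMatrix:
    values: np.ndarray
    individual_ids: np.ndarray
    n_snps_used: int
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise DataError("GRM shape does not match individual_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise DataError("GRM is not symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigen(self):
        """Cached eigendecomposition (ascending eigenvalues)."""
        if self._eig is None:
            lam, U = np.linalg.eigh(self.values)
            self._eig = (np.maximum(lam, 0.0), U)
        return self._eig

    def align(self, ids) -> "GrmMatrix":
        """Sub-matrix for the given individual order."""
        lookup = pd.Index(self.individual_ids)
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [i for i, j in zip(ids, idx) if j < 0]
            raise DataError(f"individuals absent from GRM: {missing[:5]}")
        return GrmMatrix(self.values[np.ix_(idx, idx)],
                         self.individual_ids[idx], self.n_snps_used)


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    trajectory: list = field(default_factory=list, repr=False)


def build_grm(genotypes, snp_subset=None) -> GrmMatrix:
    """VanRaden method-1 GRM from a genotype matrix.

    ``snp_subset`` is an optional list of SNP ids (or boolean/index mask);
    every SNP used must be polymorphic in the sample — a monomorphic SNP
    raises an error naming it.
    """
    g = genotypes if snp_subset is None else _subset(genotypes, snp_subset)
    if g.n_individuals < 2:
        raise DataError("GRM needs at least 2 individuals")
    p = g.allele_freq
    mono = np.flatnonzero((p <= 0) | (p >= 1))
    if mono.size:
        raise DataError(f"monomorphic SNP in GRM subset: {g.snp_ids[mono[0]]}")
    Z = g.centered()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = (Z @ Z.T) / denom
    return GrmMatrix(G, g.individual_ids, g.n_snps)


def _subset(genotypes, snp_subset):
    arr = np.asarray(snp_subset)
    if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
        return genotypes.subset_snps(mask=np.flatnonzero(arr) if arr.dtype == bool else arr)
    return genotypes.subset_snps(snp_ids=list(arr))


def write_grm_text(grm: GrmMatrix, prefix: str) -> None:
    """Plain-text lower-triangle GRM (GCTA .grm.gz layout, uncompressed)."""
    rows = []
    for i in range(grm.n):
        for j in range(i + 1):
            rows.append((i + 1, j + 1, grm.n_snps_used, grm.values[i, j]))
    pd.DataFrame(rows).to_csv(f"{prefix}.grm.txt", sep="\t", header=False, index=False,
                              float_format="%.10g")
    pd.DataFrame({"fid": grm.individual_ids, "iid": grm.individual_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False)


def read_grm_text(prefix: str) -> GrmMatrix:
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].to_numpy(dtype=object)
    n = len(ids)
    tri = pd.read_csv(f"{prefix}.grm.txt", sep="\t", header=None)
    G = np.zeros((n, n))
    i = tri[0].to_numpy() - 1
    j = tri[1].to_numpy() - 1
    G[i, j] = tri[3].to_numpy()
    G[j, i] = tri[3].to_numpy()
    return GrmMatrix(G, ids, int(tri[2].iloc[0]))


def write_grm_gcta_bin(grm: GrmMatrix, prefix: str) -> None:
    """GCTA-compatible binary triplets (grm.bin, grm.N.bin, grm.id)."""
    tri = grm.values[np.tril_indices(grm.n)]
    tri.astype(np.float32).tofile(f"{prefix}.grm.bin")
    np.full(tri.size, grm.n_snps_used, dtype=np.float32).tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": grm.individual_ids, "iid": grm.individual_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# single-GRM REML in the eigenbasis


def _profile_terms(lam, ystar, Xstar, sg, se):
    """Quantities of the restricted likelihood at (sg, se) in the eigenbasis."""
    d = sg * lam + se
    dinv = 1.0 / d
    B = Xstar.T @ (Xstar * dinv[:, None])
    Binv = np.linalg.inv(B)
    xdy = Xstar.T @ (ystar * dinv)
    # P y in the eigenbasis
    r = ystar * dinv - (Xstar * dinv[:, None]) @ (Binv @ xdy)
    yPy = float(ystar @ r)
    logdet = float(np.sum(np.log(d)))
    s, logdetB = np.linalg.slogdet(B)
    ll = -0.5 * (logdet + logdetB + yPy)
    return d, dinv, Binv, r, ll


def _apply_P(v, dinv, Xstar, Binv):
    return v * dinv - (Xstar * dinv[:, None]) @ (Binv @ (Xstar.T @ (v * dinv)))


def estimate_greml(
    phenotype,
    grm: GrmMatrix,
    covariates=None,
    tol: float = 1e-6,
    max_iter: int = 200,
    method: str = "ai",
) -> VarianceComponents:
    """GREML: REML variance components for y = Xb + g + e, g ~ N(0, G sg2).

    The GRM is eigendecomposed once; each iteration is O(n p^2).  Updates
    are average-information steps with fallback to EM whenever an AI step
    would leave the parameter space or decrease the restricted likelihood
    (``method='em'`` forces pure EM).  The standard error of h2 comes from
    the inverse AI matrix by the delta method.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n != grm.n:
        raise DataError("phenotype length does not match GRM")
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float).reshape(n, -1)])

    lam, U = grm.eigen()
    ystar = U.T @ y
    Xstar = U.T @ X

    vary = float(np.var(y))
    if vary <= 0:
        raise DataError("phenotype has zero variance")
    floor = 1e-8 * vary
    sg, se = vary / 2, vary / 2

    trajectory = []
    ll_prev = -np.inf
    converged = False
    AI = None
    for it in range(1, max_iter + 1):
        d, dinv, Binv, r, ll = _profile_terms(lam, ystar, Xstar, sg, se)
        # scores
        trPG = float(np.sum(lam * dinv)) - float(
            np.trace(Binv @ (Xstar.T @ (Xstar * (lam * dinv**2)[:, None]))))
        trP = float(np.sum(dinv)) - float(
            np.trace(Binv @ (Xstar.T @ (Xstar * (dinv**2)[:, None]))))
        yPGPy = float(r @ (lam * r))
        yPPy = float(r @ r)
        score = np.array([-0.5 * (trPG - yPGPy), -0.5 * (trP - yPPy)])
        # average information
        PGr = _apply_P(lam * r, dinv, Xstar, Binv)
        Pr = _apply_P(r, dinv, Xstar, Binv)
        AI = 0.5 * np.array([
            [float((lam * r) @ PGr), float((lam * r) @ Pr)],
            [float(r @ PGr), float(r @ Pr)],
        ])
        AI = 0.5 * (AI + AI.T)

        em_step = np.array([
            (sg**2 * yPGPy + (sg * n - sg**2 * trPG)) / n,
            (se**2 * yPPy + (se * n - se**2 * trP)) / n,
        ])
        step_type = "em"
        new = em_step
        if method == "ai":
            try:
                delta = np.linalg.solve(AI, score)
                cand = np.maximum(np.array([sg, se]) + delta, floor)
                ll_cand = _profile_terms(lam, ystar, Xstar, cand[0], cand[1])[4]
                if ll_cand >= ll - 1e-10:
                    new, step_type = cand, "ai"
            except np.linalg.LinAlgError:
                pass
        new = np.maximum(new, floor)
        trajectory.append({"iter": it, "step": step_type, "loglik": ll,
                           "sigma_g2": sg, "sigma_e2": se})
        rel = np.max(np.abs(new - [sg, se]) / np.maximum([sg, se], floor))
        abschange = np.max(np.abs(new - [sg, se])) / vary
        sg, se = float(new[0]), float(new[1])
        if rel < tol or abschange < tol * 1e-2:
            converged = True
            break
        ll_prev = ll

    if not converged:
        raise ConvergenceError(
            f"GREML did not converge in {max_iter} iterations", trajectory=trajectory)

    _, _, _, _, ll = _profile_terms(lam, ystar, Xstar, sg, se)
    h2 = sg / (sg + se)
    # delta-method SE from the inverse AI matrix at the optimum
    try:
        C = np.linalg.inv(AI)
        grad = np.array([se, -sg]) / (sg + se) ** 2
        se_h2 = float(np.sqrt(max(grad @ C @ grad, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    return VarianceComponents(sigma_g2=sg, sigma_e2=se, h2=float(h2), se_h2=se_h2,
                              loglik=ll, n_iter=len(trajectory), converged=True,
                              trajectory=trajectory)


# ---------------------------------------------------------------------------
# general multi-kernel REML (used by two-GRM GBLUP and weighted residuals)


def reml_multi_kernel(
    y,
    kernels: list,
    covariates=None,
    weights=None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[list, float, float]:
    """AI-REML with EM fallback for V = sum_k sk2 K_k + se2 diag(1/w).

    Returns ([sk2 per kernel], se2, loglik).  Dense O(n^3) per iteration;
    intended for reference-set sizes (hundreds to a few thousand).  A
    singular AI matrix (e.g. proportional kernels) falls back to EM, which
    still converges on the identifiable total.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float).reshape(n, -1)])
    Dw = np.ones(n) if weights is None else 1.0 / np.asarray(weights, dtype=float)
    Ks = [np.asarray(K, dtype=float) for K in kernels]
    for K in Ks:
        if K.shape != (n, n):
            raise DataError("kernel dimension mismatch with phenotype")

    vary = float(np.var(y))
    floor = 1e-8 * max(vary, 1e-12)
    nk = len(Ks)
    theta = np.full(nk + 1, vary / (nk + 1))

    def build(theta):
        V = np.diag(theta[-1] * Dw)
        for s, K in zip(theta[:-1], Ks):
            V += s * K
        Vinv = np.linalg.inv(V)
        B = X.T @ Vinv @ X
        Binv = np.linalg.inv(B)
        P = Vinv - Vinv @ X @ Binv @ X.T @ Vinv
        Py = P @ y
        sV, ldV = np.linalg.slogdet(V)
        sB, ldB = np.linalg.slogdet(B)
        ll = -0.5 * (ldV + ldB + float(y @ Py))
        return P, Py, ll

    As = Ks + [np.diag(Dw)]
    ll = -np.inf
    for it in range(1, max_iter + 1):
        P, Py, ll = build(theta)
        score = np.empty(nk + 1)
        APy = [A @ Py for A in As]
        for k, A in enumerate(As):
            score[k] = -0.5 * (float(np.sum(P * A)) - float(Py @ APy[k]))
        AI = np.empty((nk + 1, nk + 1))
        PAPy = [P @ v for v in APy]
        for k in range(nk + 1):
            for l in range(k, nk + 1):
                AI[k, l] = AI[l, k] = 0.5 * float(APy[k] @ PAPy[l])

        em = np.empty(nk + 1)
        for k, A in enumerate(As):
            trPA = float(np.sum(P * A))
            yPAPy = float(Py @ APy[k])
            em[k] = (theta[k] ** 2 * yPAPy + (theta[k] * n - theta[k] ** 2 * trPA)) / n
        candidates = [np.maximum(em, floor)]
        try:
            delta = np.linalg.solve(AI, score)
            candidates.append(np.maximum(theta + delta, floor))
        except np.linalg.LinAlgError:
            pass
        # boundary projection: a persistently negative score on a small
        # component means the optimum sits at zero — EM alone only crawls
        # there geometrically
        at_boundary = (score < 0) & (candidates[0] < 0.05 * vary)
        if at_boundary.any():
            proj = candidates[0].copy()
            proj[at_boundary] = floor
            candidates.append(proj)
        lls = []
        for cand in candidates:
            try:
                lls.append(build(cand)[2])
            except np.linalg.LinAlgError:
                lls.append(-np.inf)
        best = int(np.argmax(lls))
        # never move below the current likelihood: fall back to EM if needed
        new = candidates[best] if lls[best] >= ll - 1e-10 else candidates[0]
        rel = np.max(np.abs(new - theta) / np.maximum(theta, floor))
        abschange = np.max(np.abs(new - theta)) / max(vary, floor)
        theta = new
        if rel < tol or abschange < tol * 1e-2:
            break
    else:
        raise ConvergenceError(f"multi-kernel REML did not converge in {max_iter} iterations")
    _, _, ll = build(theta)
    return list(map(float, theta[:-1])), float(theta[-1]), float(ll)
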