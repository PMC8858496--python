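"""Synthetic dairy populations with the structure the analysis assumes.

The generator emulates the features of a national dairy data set that the
downstream analysis relies on: two genetically divergent breeds (plus
crossbreds) genotyped on a dense "sequence" SNP set containing a sparser
"array" subset; QTL effects drawn from a four-component normal mixture;
cow-level milk yield declining linearly in the temperature-humidity index
(THI) above a threshold; and bulls whose phenotypes are averages over
variable numbers of phenotyped daughters.

Breed divergence follows a Balding-Nichols model: both breeds' allele
frequencies are beta-perturbations of a shared ancestral frequency with a
single differentiation parameter ``fst``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from heatgp.errors import ConfigError, DataError

# class labels and variances of the SNP-effect mixture: zero, small,
# medium and large effects with variance scalar x sigma_v2
MIXTURE_CLASS_SCALARS = (0.0, 1e-4, 1e-3, 1e-2)
MIXTURE_CLASS_NAMES = ("zero", "small", "medium", "large")

SNP_MAP_COLUMNS = ["snp_id", "chromosome", "position_bp", "ref_allele", "alt_allele", "tier"]


def validate_snp_map(snp_map: pd.DataFrame) -> None:
    """Check SNP-map invariants: unique ids, sorted increasing positions."""
    missing = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise DataError(f"SNP map missing columns: {missing}")
    if snp_map["snp_id"].duplicated().any():
        raise DataError("duplicate snp_id in SNP map")
    for chrom, grp in snp_map.groupby("chromosome", sort=False):
        pos = grp["position_bp"].to_numpy()
        if not np.all(np.diff(pos) > 0):
            raise DataError(f"positions not strictly increasing on chromosome {chrom}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with its marker map.

    ``dosages`` holds allele counts in {0, 1, 2} (stored as int8 to keep
    dense sequence-density matrices small); ``snp_map`` carries chromosome,
    bp position and the array/sequence tier label per SNP.
    """

    dosages: np.ndarray                      # (n, m) int8 or float
    snp_map: pd.DataFrame                    # columns SNP_MAP_COLUMNS
    individual_ids: np.ndarray               # (n,) str
    breed: np.ndarray                        # (n,) str in {A, B, cross}

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.breed = np.asarray(self.breed, dtype=object)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise DataError("individual_ids length does not match dosage rows")
        if len(self.snp_map) != m:
            raise DataError("snp_map length does not match dosage columns")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    @property
    def allele_freq(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (column mean / 2)."""
        return self.dosages.mean(axis=0, dtype=np.float64) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def snp_indexer(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Column indices for the given SNP ids; error on unknown ids."""
        lookup = pd.Index(self.snp_map["snp_id"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            bad = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise DataError(f"SNPs not present in genotype matrix: {bad[:5]}")
        return idx

    def subset_snps(self, snp_ids=None, mask=None) -> "GenotypeMatrix":
        if mask is None:
            mask = self.snp_indexer(snp_ids)
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            snp_map=self.snp_map.iloc[np.atleast_1d(mask)].reset_index(drop=True),
            individual_ids=self.individual_ids,
            breed=self.breed,
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = pd.Index(self.individual_ids)
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            bad = [s for s, i in zip(ids, idx) if i < 0]
            raise DataError(f"individuals not present in genotype matrix: {bad[:5]}")
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            snp_map=self.snp_map,
            individual_ids=self.individual_ids[idx],
            breed=self.breed[idx],
        )

    def tier(self, tier: str) -> "GenotypeMatrix":
        """Subset to one tier ('array' or 'sequence'); 'sequence' = all SNPs."""
        if tier == "sequence":
            return self
        mask = np.flatnonzero((self.snp_map["tier"] == tier).to_numpy())
        if mask.size == 0:
            raise DataError(f"no SNPs in tier {tier!r}")
        return self.subset_snps(mask=mask)

    def centered(self, freq: np.ndarray | None = None, dtype=np.float64) -> np.ndarray:
        """Column-centred dosage matrix; centre at 2*freq (observed if None)."""
        p = self.allele_freq if freq is None else np.asarray(freq, dtype=np.float64)
        return self.dosages.astype(dtype) - 2.0 * p


@dataclass
class TrueGeneticModel:
    """Ground truth of a simulated pair of traits (yield intercept & slope).

    The same QTL are pleiotropic for both traits; effect sizes are drawn
    independently per trait from the class variance of the QTL's mixture
    class.  Non-QTL SNPs have effect exactly zero.
    """

    individual_ids: np.ndarray
    qtl_indices: np.ndarray                  # indices into the SNP map
    class_of_qtl: np.ndarray                 # labels from MIXTURE_CLASS_NAMES[1:]
    effects_intercept: np.ndarray            # (m,) full-length vectors
    effects_slope: np.ndarray
    sigma_v2_intercept: float
    sigma_v2_slope: float
    tbv_intercept: np.ndarray                # (n,) true breeding values
    tbv_slope: np.ndarray

    @property
    def qtl_effects(self) -> np.ndarray:
        """Slope-trait effects at the QTL (the heat-tolerance trait)."""
        return self.effects_slope[self.qtl_indices]


@dataclass
class StudyDesign:
    """Discovery / reference / validation split of a population.

    Invariants: discovery and reference are disjoint; no reference bull
    sires a discovery cow; no validation cow is a daughter of a reference
    bull; each validation set is partitioned into two near-equal subsets.
    """

    scenario: int
    discovery_ids: np.ndarray
    reference_ids: np.ndarray
    validation_sets: dict                    # name -> (subset_a ids, subset_b ids)

    def validation_ids(self, name: str) -> np.ndarray:
        a, b = self.validation_sets[name]
        return np.concatenate([a, b])

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, "discovery", "") for i in self.discovery_ids]
        rows += [(i, "reference", "") for i in self.reference_ids]
        for name, (a, b) in self.validation_sets.items():
            rows += [(i, f"validation:{name}", "subset1") for i in a]
            rows += [(i, f"validation:{name}", "subset2") for i in b]
        return pd.DataFrame(rows, columns=["individual_id", "role", "subset"])


@dataclass
class Population:
    """A simulated population: analysis genotypes plus pedigree metadata.

    ``individuals`` has one row per genotyped animal (individual_id, breed,
    sex, sire_id — empty string when unknown).  Daughters used only to form
    bull phenotypes are not genotyped and appear in the test-day tables,
    not here.
    """

    genotypes: GenotypeMatrix
    individuals: pd.DataFrame

    def sire_links(self) -> pd.DataFrame:
        df = self.individuals
        return df.loc[df["sire_id"] != "", ["individual_id", "sire_id"]]


# ---------------------------------------------------------------------------
# genotype simulation


def _draw_positions(rng, length_bp: int, n: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.2) + 16))
    while pos.size < n:
        extra = rng.integers(1, length_bp + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    keep = np.sort(rng.choice(pos.size, size=n, replace=False))
    return pos[keep]


def _breed_freqs(rng, ancestral: np.ndarray, fst: float) -> np.ndarray:
    """Balding-Nichols perturbation of ancestral frequencies for one breed."""
    if fst == 0:
        return ancestral.copy()
    theta = (1.0 - fst) / fst
    a = np.maximum(ancestral * theta, 1e-8)
    b = np.maximum((1.0 - ancestral) * theta, 1e-8)
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def _smooth_breed_freqs(rng, ancestral: np.ndarray, fst: float,
                        rho: np.ndarray) -> np.ndarray:
    """Balding-Nichols frequencies with spatially smooth perturbations.

    The per-SNP beta draw is taken through a Gaussian copula with the same
    AR(1) correlation as the haplotypes, so breed-specific frequency
    deviations vary smoothly along the chromosome and local LD survives
    the breed divergence.  Marginally identical to ``_breed_freqs``.
    """
    if fst == 0:
        return ancestral.copy()
    from scipy.stats import beta as _beta, norm as _norm
    theta = (1.0 - fst) / fst
    a = np.maximum(ancestral * theta, 1e-8)
    b = np.maximum((1.0 - ancestral) * theta, 1e-8)
    u = _norm.cdf(_ar1_gametes(rng, 1, rho)[0].astype(np.float64))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return np.clip(_beta.ppf(u, a, b), 1e-6, 1.0 - 1e-6)


def _ar1_gametes(rng, n_gametes: int, rho: np.ndarray) -> np.ndarray:
    """Latent AR(1) Gaussians along a chromosome, one row per gamete.

    ``rho[j]`` is the latent correlation between SNP j-1 and j; rho[0] is
    ignored.  Thresholding column j at Phi^-1(p_j) yields alleles whose
    LD decays exponentially with distance (a Gaussian-copula haplotype
    model).
    """
    m = rho.size
    z = np.empty((n_gametes, m), dtype=np.float32)
    z[:, 0] = rng.standard_normal(n_gametes)
    innov = rng.standard_normal((n_gametes, m - 1)).astype(np.float32) if m > 1 else None
    sq = np.sqrt(1.0 - rho**2).astype(np.float32)
    for j in range(1, m):
        z[:, j] = rho[j] * z[:, j - 1] + sq[j] * innov[:, j - 1]
    return z


def simulate_genotypes(
    n_per_breed: Mapping[str, int],
    map_config: Mapping[str, int] | None = None,
    fst: float = 0.1,
    seed: int = 0,
    maf_floor: float = 0.005,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    ld_decay_bp: float = 100_000.0,
    max_regen_rounds: int = 20,
) -> GenotypeMatrix:
    """Simulate dosage genotypes for two diverged breeds and crossbreds.

    Per SNP an ancestral frequency is drawn uniformly on ``ancestral_range``
    and perturbed per breed by a Balding-Nichols beta distribution with
    differentiation ``fst``.  Gametes are Gaussian-copula haplotypes: a
    latent AR(1) Gaussian along each chromosome (correlation
    exp(-distance/ld_decay_bp) between neighbours) is thresholded at each
    SNP's breed frequency, so linkage disequilibrium decays exponentially
    with distance — the feature that lets array SNPs tag sequence-tier
    causal variants.  Pure-breed dosages sum two same-breed gametes;
    crossbreds one gamete from each breed.  Columns whose pooled
    minor-allele frequency is <= ``maf_floor`` are re-thresholded at a
    fresh, more central frequency (same latent haplotypes), and dropped
    if still failing after ``max_regen_rounds``.

    Parameters
    ----------
    n_per_breed
        Mapping with keys among {'A', 'B', 'cross'} giving individual counts.
    map_config
        Keys n_chrom, chrom_length_bp, n_array_snps, n_sequence_snps.
    fst
        Balding-Nichols differentiation between the two breeds, in [0, 1).
    ld_decay_bp
        Distance at which latent haplotype correlation falls to 1/e;
        0 gives fully independent SNPs.
    """
    from scipy.stats import norm as _norm

    cfg = {"n_chrom": 5, "chrom_length_bp": 10_000_000,
           "n_array_snps": 3_000, "n_sequence_snps": 30_000}
    if map_config:
        cfg.update(map_config)
    if not 0.0 <= fst < 1.0:
        raise ConfigError(f"fst must be in [0, 1), got {fst}")
    if cfg["n_chrom"] < 1:
        raise ConfigError("need at least one chromosome")
    if cfg["n_array_snps"] > cfg["n_sequence_snps"]:
        raise ConfigError("n_array_snps must be <= n_sequence_snps")
    counts = {k: int(n_per_breed.get(k, 0)) for k in ("A", "B", "cross")}
    nA, nB, nX = counts["A"], counts["B"], counts["cross"]
    if nA + nB + nX == 0:
        raise ConfigError("empty population: all breed counts are zero")

    rng = np.random.default_rng(seed)
    n_chrom, m = cfg["n_chrom"], cfg["n_sequence_snps"]
    per_chrom = np.full(n_chrom, m // n_chrom)
    per_chrom[: m % n_chrom] += 1

    chrom_blocks, pos_blocks, dose_blocks, keep_blocks = [], [], [], []
    for c in range(n_chrom):
        mc = int(per_chrom[c])
        pos = _draw_positions(rng, cfg["chrom_length_bp"], mc)
        if ld_decay_bp > 0:
            # ancestral frequencies vary smoothly along the chromosome so
            # tightly linked SNPs have matching frequencies and can reach
            # high r^2 (a Pearson correlation of 0/1 indicators is capped
            # when frequencies differ)
            rho_f = np.exp(-np.diff(pos, prepend=pos[0]) / ld_decay_bp)
            rho_f[0] = 0.0
            latent_f = _ar1_gametes(rng, 1, rho_f)[0].astype(np.float64)
            lo, hi = ancestral_range
            anc = lo + (hi - lo) * _norm.cdf(latent_f)
        else:
            anc = rng.uniform(*ancestral_range, size=mc)
        if ld_decay_bp > 0:
            rho = np.exp(-np.diff(pos, prepend=pos[0]) / ld_decay_bp)
            rho[0] = 0.0
        else:
            rho = np.zeros(mc)
        if ld_decay_bp > 0:
            pa = _smooth_breed_freqs(rng, anc, fst, rho)
            pb = _smooth_breed_freqs(rng, anc, fst, rho)
        else:
            pa = _breed_freqs(rng, anc, fst)
            pb = _breed_freqs(rng, anc, fst)

        # gamete pools: A needs 2 per A individual + 1 per crossbred
        zA = _ar1_gametes(rng, 2 * nA + nX, rho) if (nA or nX) else None
        zB = _ar1_gametes(rng, 2 * nB + nX, rho) if (nB or nX) else None

        def assemble(pa, pb, cols=slice(None)):
            blocks = []
            ta = _norm.ppf(pa[cols]).astype(np.float32)
            tb = _norm.ppf(pb[cols]).astype(np.float32)
            if nA:
                al = zA[: 2 * nA, cols] < ta
                blocks.append(al[0::2].astype(np.int8) + al[1::2].astype(np.int8))
            if nB:
                bl = zB[: 2 * nB, cols] < tb
                blocks.append(bl[0::2].astype(np.int8) + bl[1::2].astype(np.int8))
            if nX:
                xa = zA[2 * nA:, cols] < ta
                xb = zB[2 * nB:, cols] < tb
                blocks.append(xa.astype(np.int8) + xb.astype(np.int8))
            return np.vstack(blocks)

        dos = assemble(pa, pb)
        # re-threshold columns failing the MAF floor at fresh central freqs
        for _ in range(max_regen_rounds):
            freq = dos.mean(axis=0) / 2.0
            bad = np.flatnonzero(np.minimum(freq, 1 - freq) <= maf_floor)
            if bad.size == 0:
                break
            anc_new = rng.uniform(0.2, 0.8, size=bad.size)
            pa[bad] = _breed_freqs(rng, anc_new, fst)
            pb[bad] = _breed_freqs(rng, anc_new, fst)
            dos[:, bad] = assemble(pa, pb, cols=bad)
        freq = dos.mean(axis=0) / 2.0
        keep = np.minimum(freq, 1 - freq) > maf_floor
        chrom_blocks.append(np.full(mc, c + 1)[keep])
        pos_blocks.append(pos[keep])
        dose_blocks.append(dos[:, keep])
        keep_blocks.append(keep)

    chrom = np.concatenate(chrom_blocks)
    pos = np.concatenate(pos_blocks)
    dosages = np.hstack(dose_blocks)
    m_kept = dosages.shape[1]
    tier = np.full(m_kept, "sequence", dtype=object)
    array_idx = np.unique(np.linspace(0, m_kept - 1, cfg["n_array_snps"]).round().astype(int))
    tier[array_idx] = "array"
    alleles = rng.choice(list("ACGT"), size=(m_kept, 2))

    snp_map = pd.DataFrame({
        "snp_id": [f"chr{c}:{p}" for c, p in zip(chrom, pos)],
        "chromosome": chrom.astype(int),
        "position_bp": pos.astype(int),
        "ref_allele": alleles[:, 0],
        "alt_allele": alleles[:, 1],
        "tier": tier,
    })
    validate_snp_map(snp_map)

    breed_labels = np.concatenate([
        np.full(nA, "A"), np.full(nB, "B"), np.full(nX, "cross")]).astype(object)
    ids = np.array([f"{b}{i:06d}" for i, b in enumerate(breed_labels)], dtype=object)
    return GenotypeMatrix(dosages, snp_map, ids, breed_labels)


# ---------------------------------------------------------------------------
# QTL effects


def sigma_v2_for_target_variance(
    genotypes: GenotypeMatrix,
    mixture_proportions: Sequence[float],
    target_genetic_variance: float,
) -> float:
    """Scale sigma_v2 so the expected breeding-value variance hits a target.

    E[var(TBV)] = sum_j 2 p_j (1-p_j) * sum_k pi_k c_k sigma_v2, so invert
    for sigma_v2 given the observed allele frequencies.
    """
    p = genotypes.allele_freq
    het = float(np.sum(2.0 * p * (1.0 - p)))
    mix = float(np.dot(mixture_proportions, MIXTURE_CLASS_SCALARS))
    if het * mix <= 0:
        raise ConfigError("mixture has no non-zero component or no polymorphic SNPs")
    return target_genetic_variance / (het * mix)


def simulate_effects(
    genotypes: GenotypeMatrix,
    mixture_proportions: Sequence[float] = (0.99, 0.006, 0.003, 0.001),
    sigma_v2: float = 1.0,
    seed: int = 0,
    sigma_v2_intercept: float | None = None,
    qtl_candidates: np.ndarray | None = None,
) -> TrueGeneticModel:
    """Draw SNP effects from the four-component normal mixture.

    Each SNP is assigned a class with the given proportions; class-k effects
    are N(0, c_k * sigma_v2) with c = (0, 1e-4, 1e-3, 1e-2).  Intercept- and
    slope-trait effects share QTL and classes but are drawn independently.
    ``qtl_candidates`` restricts which SNP indices may be non-zero (the
    mixture is applied to candidates only; all others are class zero).
    """
    pi = np.asarray(mixture_proportions, dtype=float)
    if (pi < 0).any():
        raise ConfigError("mixture proportions must be non-negative")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ConfigError("mixture proportions must sum to 1")
    if sigma_v2 <= 0:
        raise ConfigError("sigma_v2 must be positive")
    if sigma_v2_intercept is None:
        sigma_v2_intercept = sigma_v2

    rng = np.random.default_rng(seed)
    m = genotypes.n_snps
    classes = np.zeros(m, dtype=np.int64)
    cand = np.arange(m) if qtl_candidates is None else np.asarray(qtl_candidates)
    classes[cand] = rng.choice(4, size=cand.size, p=pi)

    scalars = np.asarray(MIXTURE_CLASS_SCALARS)
    sd_slope = np.sqrt(scalars[classes] * sigma_v2)
    sd_int = np.sqrt(scalars[classes] * sigma_v2_intercept)
    eff_slope = rng.standard_normal(m) * sd_slope
    eff_int = rng.standard_normal(m) * sd_int

    qtl = np.flatnonzero(classes > 0)
    Z = genotypes.centered()
    return TrueGeneticModel(
        individual_ids=genotypes.individual_ids,
        qtl_indices=qtl,
        class_of_qtl=np.asarray(MIXTURE_CLASS_NAMES)[classes[qtl]],
        effects_intercept=eff_int,
        effects_slope=eff_slope,
        sigma_v2_intercept=float(sigma_v2_intercept),
        sigma_v2_slope=float(sigma_v2),
        tbv_intercept=Z @ eff_int,
        tbv_slope=Z @ eff_slope,
    )


# ---------------------------------------------------------------------------
# test-day records


DEFAULT_CLIMATE = {"thi_min": 40.0, "thi_max": 85.0, "threshold": 60.0}
DEFAULT_TESTDAY_DESIGN = {
    "records_per_cow": 8,
    "herds": 40,
    "test_days_per_herd": 12,
    "residual_sd": 1.0,
    "herd_sd": 0.5,
    "env_intercept_sd": 1.0,
    "env_slope_sd": 0.5,
    "env_corr": 0.0,
    "mean_yield": 20.0,
    "parity_effects": (0.0, 0.4, 0.6),
}


def scaled_thi(thi, threshold: float = 60.0, thi_max: float = 85.0):
    """Thresholded THI mapped to the order-1 Legendre domain [-1, 1].

    THI below the threshold is set to the threshold, then the interval
    [threshold, thi_max] is affinely mapped onto [-1, 1].
    """
    t = np.maximum(np.asarray(thi, dtype=float), threshold)
    return 2.0 * (t - threshold) / (thi_max - threshold) - 1.0


def simulate_test_days(
    model: TrueGeneticModel,
    climate: Mapping[str, float] | None = None,
    design: Mapping | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate test-day yield records for the cows in ``model``.

    yield = mean + herd-test-day effect + parity effect
            + (intercept TBV + environmental intercept)
            + (slope TBV + environmental slope) * t(THI) + residual,

    with t(.) the thresholded THI rescaled to [-1, 1] (``scaled_thi``).
    THI is drawn uniformly over [thi_min, thi_max] per record.
    """
    clim = dict(DEFAULT_CLIMATE)
    if climate:
        clim.update(climate)
    des = dict(DEFAULT_TESTDAY_DESIGN)
    if design:
        des.update(design)
    if clim["thi_max"] <= clim["threshold"]:
        raise ConfigError("thi_max must exceed the THI threshold; the slope "
                          "is unidentifiable when all THI fall below it")
    n_rec = int(des["records_per_cow"])
    if n_rec < 2:
        raise ConfigError("need >= 2 records per cow for slope identifiability")

    rng = np.random.default_rng(seed)
    ids = model.individual_ids
    n = len(ids)

    # cow-level environmental deviations, bivariate normal
    rho = float(des["env_corr"])
    si, ss = float(des["env_intercept_sd"]), float(des["env_slope_sd"])
    cov = np.array([[si**2, rho * si * ss], [rho * si * ss, ss**2]])
    env = rng.multivariate_normal([0.0, 0.0], cov, size=n) if (si > 0 or ss > 0) else np.zeros((n, 2))

    herd_of_cow = rng.integers(0, des["herds"], size=n)
    n_htd = des["herds"] * des["test_days_per_herd"]
    htd_effect = rng.normal(0.0, des["herd_sd"], size=n_htd)
    parity = rng.integers(1, len(des["parity_effects"]) + 1, size=n)
    age_days = rng.integers(700, 3000, size=n)
    par_eff = np.asarray(des["parity_effects"])

    rows_cow = np.repeat(np.arange(n), n_rec)
    thi = rng.uniform(clim["thi_min"], clim["thi_max"], size=n * n_rec)
    t = scaled_thi(thi, clim["threshold"], clim["thi_max"])
    day = rng.integers(0, des["test_days_per_herd"], size=n * n_rec)
    htd_idx = herd_of_cow[rows_cow] * des["test_days_per_herd"] + day
    dim = rng.integers(5, 306, size=n * n_rec)

    cow_int = model.tbv_intercept + env[:, 0]
    cow_slope = model.tbv_slope + env[:, 1]
    resid = rng.normal(0.0, des["residual_sd"], size=n * n_rec) if des["residual_sd"] > 0 else 0.0
    y = (des["mean_yield"] + htd_effect[htd_idx] + par_eff[parity[rows_cow] - 1]
         + cow_int[rows_cow] + cow_slope[rows_cow] * t + resid)

    return pd.DataFrame({
        "cow_id": ids[rows_cow],
        "herd_test_day": [f"h{h // des['test_days_per_herd']}d{h % des['test_days_per_herd']}" for h in htd_idx],
        "parity": parity[rows_cow],
        "dim": dim,
        "age_days": age_days[rows_cow],
        "thi": thi,
        "yield": y,
    })


# ---------------------------------------------------------------------------
# study design


def make_study_design(population: Population, scenario: int = 1, seed: int = 0,
                      discovery_fraction: float = 0.8,
                      n_validation_subsets: int = 2) -> StudyDesign:
    """Split a population into discovery / reference / validation sets.

    Scenario 1: discovery = breed-A cows, reference = breed-A bulls,
    validation = remaining cows per breed.  Scenario 2 pools breed A and B
    cows in discovery; scenario 3 pools breed A and B bulls in reference.
    Bulls siring any discovery cow are excluded from the reference, and
    cows whose sire is a reference bull are excluded from validation, so
    the three sets are mutually independent.
    """
    if scenario not in (1, 2, 3):
        raise ConfigError(f"scenario must be 1, 2 or 3, got {scenario}")
    rng = np.random.default_rng(seed)
    ind = population.individuals
    if not {"individual_id", "breed", "sex", "sire_id"} <= set(ind.columns):
        raise DataError("individuals table needs individual_id, breed, sex, sire_id")

    cows = ind[ind["sex"] == "F"]
    bulls = ind[ind["sex"] == "M"]

    disc_breeds = {1: ("A",), 2: ("A", "B"), 3: ("A",)}[scenario]
    ref_breeds = {1: ("A",), 2: ("A",), 3: ("A", "B")}[scenario]

    disc_pool = cows[cows["breed"].isin(disc_breeds)]
    n_disc = int(round(discovery_fraction * len(disc_pool)))
    disc_ids = rng.permutation(disc_pool["individual_id"].to_numpy())[:n_disc]
    disc_set = set(disc_ids)

    sires_of_disc = set(ind.set_index("individual_id").loc[list(disc_set), "sire_id"]) - {""}
    ref_pool = bulls[bulls["breed"].isin(ref_breeds)]
    ref_ids = ref_pool.loc[~ref_pool["individual_id"].isin(sires_of_disc),
                           "individual_id"].to_numpy()
    if ref_ids.size == 0:
        raise DataError("impossible design: every eligible bull sires a discovery cow")
    ref_set = set(ref_ids)

    validation_sets = {}
    for breed, grp in cows.groupby("breed"):
        pool = grp[~grp["individual_id"].isin(disc_set)]
        pool = pool[~pool["sire_id"].isin(ref_set)]
        vids = rng.permutation(pool["individual_id"].to_numpy())
        if vids.size < n_validation_subsets:
            continue
        half = (vids.size + 1) // 2
        validation_sets[str(breed)] = (np.sort(vids[:half]), np.sort(vids[half:]))
    if not validation_sets:
        raise DataError("impossible design: no validation cows satisfy the "
                        "independence constraints")

    design = StudyDesign(scenario=scenario,
                         discovery_ids=np.sort(disc_ids),
                         reference_ids=np.sort(ref_ids),
                         validation_sets=validation_sets)
    check_design_invariants(design, population)
    return design


def check_design_invariants(design: StudyDesign, population: Population) -> None:
    """Raise DataError if any independence invariant is violated."""
    ind = population.individuals.set_index("individual_id")
    disc, ref = set(design.discovery_ids), set(design.reference_ids)
    if disc & ref:
        raise DataError("discovery and reference sets overlap")
    if any(ind.loc[list(disc), "sire_id"].isin(ref)):
        raise DataError("a reference bull sires a discovery cow")
    for name, (a, b) in design.validation_sets.items():
        vids = np.concatenate([a, b])
        if abs(len(a) - len(b)) > 1:
            raise DataError(f"validation subsets of {name} differ by more than 1")
        if len(set(vids)) != len(vids) or set(vids) & disc:
            raise DataError(f"validation set {name} overlaps discovery or itself")
        if any(ind.loc[list(vids), "sire_id"].isin(ref)):
            raise DataError(f"a validation cow in {name} is a daughter of a reference bull")


# ---------------------------------------------------------------------------
# whole-population convenience generator


def sire_daughter_dosages(bull_dosages: np.ndarray, breed_freq: np.ndarray,
                          n_daughters: int, rng) -> np.ndarray:
    """Daughter dosages: one gamete from the sire, one from the breed pool."""
    p_sire = np.asarray(bull_dosages, dtype=float) / 2.0
    return (rng.binomial(1, p_sire, size=(n_daughters, p_sire.size))
            + rng.binomial(1, breed_freq, size=(n_daughters, breed_freq.size))).astype(np.int8)


@dataclass
class SimulatedStudy:
    """Bundle returned by :func:`simulate_population`.

    Holds the analysis genotypes, ground-truth genetic models per trait,
    test-day tables per trait (cows and bull daughters), the pedigree of
    the phenotyped daughters, and the realised heritability inputs.
    """

    population: Population
    models: dict                      # trait -> TrueGeneticModel (analysis individuals)
    test_days: dict                   # trait -> DataFrame (cows + daughters)
    daughter_pedigree: pd.DataFrame   # daughter cow_id -> sire bull id
    target_h2_slope: float
    climate: dict
    testday_design: dict


def simulate_population(
    n_discovery_cows: int = 2_000,
    n_reference_bulls: int = 400,
    daughters_per_bull: int = 50,
    n_validation_cows: int = 400,
    map_config: Mapping[str, int] | None = None,
    fst: float = 0.1,
    mixture_proportions: Sequence[float] = (0.99, 0.006, 0.003, 0.001),
    h2_slope: float = 0.25,
    h2_intercept: float = 0.35,
    genetic_variance_slope: float = 0.25,
    genetic_variance_intercept: float = 1.0,
    traits: Sequence[str] = ("milk", "fat", "protein"),
    climate: Mapping[str, float] | None = None,
    testday_design: Mapping | None = None,
    validation_breeds: Mapping[str, int] | None = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a complete study population at desk scale.

    Discovery cows and validation cows are unrelated breed-A (plus optional
    breed-B / crossbred validation groups); reference bulls are breed-A
    males whose phenotypes will come from ``daughters_per_bull`` simulated,
    non-genotyped daughters each.  Daughter genotypes are realised only at
    the QTL columns (that is all their breeding values depend on), keeping
    memory at sequence density manageable.

    The per-trait QTL set is shared across traits (pleiotropy) while effect
    sizes are trait-specific.  Environmental variances are set so the
    cow-level slope and intercept heritabilities equal ``h2_slope`` and
    ``h2_intercept`` in expectation.
    """
    rng = np.random.default_rng(seed)
    extra_val = dict(validation_breeds or {})
    n_B = extra_val.get("B", 0)
    n_cross = extra_val.get("cross", 0)
    n_A = n_discovery_cows + n_reference_bulls + n_validation_cows

    geno = simulate_genotypes(
        {"A": n_A, "B": n_B, "cross": n_cross},
        map_config=map_config, fst=fst,
        seed=int(rng.integers(2**31 - 1)))

    sex = np.full(geno.n_individuals, "F", dtype=object)
    is_A = geno.breed == "A"
    a_idx = np.flatnonzero(is_A)
    bull_rows = a_idx[n_discovery_cows: n_discovery_cows + n_reference_bulls]
    sex[bull_rows] = "M"
    individuals = pd.DataFrame({
        "individual_id": geno.individual_ids,
        "breed": geno.breed,
        "sex": sex,
        "sire_id": "",
    })
    pop = Population(genotypes=geno, individuals=individuals)

    sv2_slope = sigma_v2_for_target_variance(geno, mixture_proportions, genetic_variance_slope)
    sv2_int = sigma_v2_for_target_variance(geno, mixture_proportions, genetic_variance_intercept)

    # environmental cow-level variances solve h2 = sigma_g2 / (sigma_g2 + sigma_env2)
    env_slope_sd = float(np.sqrt(genetic_variance_slope * (1 - h2_slope) / h2_slope))
    env_int_sd = float(np.sqrt(genetic_variance_intercept * (1 - h2_intercept) / h2_intercept))
    des = dict(DEFAULT_TESTDAY_DESIGN)
    des.update({"env_slope_sd": env_slope_sd, "env_intercept_sd": env_int_sd})
    if testday_design:
        des.update(testday_design)
    clim = dict(DEFAULT_CLIMATE)
    if climate:
        clim.update(climate)

    models, test_days = {}, {}
    ped_rows = []
    breed_freq = geno.allele_freq
    bull_ids = geno.individual_ids[bull_rows]
    for trait in traits:
        model = simulate_effects(
            geno, mixture_proportions, sigma_v2=sv2_slope,
            sigma_v2_intercept=sv2_int,
            seed=int(rng.integers(2**31 - 1)))
        models[trait] = model

        td_analysis = simulate_test_days(model, clim, des, seed=int(rng.integers(2**31 - 1)))

        # daughters of reference bulls: genotypes realised at QTL columns only
        qtl = model.qtl_indices
        eff_s = model.effects_slope[qtl]
        eff_i = model.effects_intercept[qtl]
        centre = 2.0 * breed_freq[qtl]
        d_ids, d_tbv_s, d_tbv_i = [], [], []
        for b_row, b_id in zip(bull_rows, bull_ids):
            dos = sire_daughter_dosages(geno.dosages[b_row, qtl], breed_freq[qtl],
                                        daughters_per_bull, rng)
            zc = dos.astype(float) - centre
            d_tbv_s.append(zc @ eff_s)
            d_tbv_i.append(zc @ eff_i)
            ids = [f"D_{trait[:1]}_{b_id}_{k}" for k in range(daughters_per_bull)]
            d_ids.extend(ids)
            ped_rows.extend((i, b_id, trait) for i in ids)
        d_model = TrueGeneticModel(
            individual_ids=np.asarray(d_ids, dtype=object),
            qtl_indices=qtl, class_of_qtl=model.class_of_qtl,
            effects_intercept=model.effects_intercept,
            effects_slope=model.effects_slope,
            sigma_v2_intercept=model.sigma_v2_intercept,
            sigma_v2_slope=model.sigma_v2_slope,
            tbv_intercept=np.concatenate(d_tbv_i),
            tbv_slope=np.concatenate(d_tbv_s),
        )
        td_daughters = simulate_test_days(d_model, clim, des, seed=int(rng.integers(2**31 - 1)))
        test_days[trait] = pd.concat([td_analysis, td_daughters], ignore_index=True)

    ped = pd.DataFrame(ped_rows, columns=["cow_id", "sire_id", "trait"])
    return SimulatedStudy(
        population=pop, models=models, test_days=test_days,
        daughter_pedigree=ped, target_h2_slope=h2_slope,
        climate=clim, testday_design=des)
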