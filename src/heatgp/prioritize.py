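"""Selection of informative "top SNPs" from GWAS results.

Selection proceeds in the order: significance-thresholded sliding-window
election, then LD pruning (MAF filtering is assumed already applied when
genotypes were loaded).  Windows are 100 kb advanced by 50 kb, anchored at
bp 1 of each chromosome; within a window the single most significant SNP
is elected iff it passes the -log10(p) threshold.  LD pruning mirrors
PLINK's ``--indep-pairwise 50 5 0.95`` geometry: within 50-SNP windows
advanced by 5 SNPs, one member of every pair with dosage r^2 above the
cut-off is removed, iterating to a fixed point.  Within a violating pair
the less significant SNP is removed (ties: the one at larger bp), keeping
the selection's intent of retaining the strongest signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heatgp.errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    window_bp: int = 100_000
    step_bp: int = 50_000
    neg_log10_threshold: float = 3.0
    ld_r2_max: float = 0.95
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    maf_min: float = 0.005

    def __post_init__(self):
        if not (0 < self.step_bp <= self.window_bp):
            raise ConfigError("need 0 < step_bp <= window_bp")
        if not (0 < self.ld_r2_max <= 1):
            raise ConfigError("need 0 < ld_r2_max <= 1")


@dataclass
class TopSnpSet:
    snp_ids: list
    source: str                      # 'single_trait' or 'meta'
    config: SelectionConfig
    n_before_prune: int
    n_after_prune: int

    def __post_init__(self):
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise DataError("top-SNP set contains duplicates")
        if self.n_after_prune > self.n_before_prune:
            raise DataError("n_after_prune exceeds n_before_prune")

    def __len__(self):
        return len(self.snp_ids)

    def write(self, path, provenance_path=None):
        with open(path, "w") as fh:
            fh.writelines(f"{s}\n" for s in self.snp_ids)
        if provenance_path:
            with open(provenance_path, "w") as fh:
                fh.write(f"source\t{self.source}\n")
                fh.write(f"n_before_prune\t{self.n_before_prune}\n")
                fh.write(f"n_after_prune\t{self.n_after_prune}\n")
                for k, v in vars(self.config).items():
                    fh.write(f"{k}\t{v}\n")


def maf_filter(genotypes, maf_min: float = 0.005):
    """Retain SNPs with minor-allele frequency strictly above ``maf_min``."""
    keep = genotypes.maf() > maf_min
    if not keep.any():
        raise DataError("MAF filter removed every SNP")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("MAF filter removed %d of %d SNPs", n_removed, keep.size)
    return genotypes.subset_snps(mask=np.flatnonzero(keep))


def select_window_top_snps(
    gwas: pd.DataFrame,
    snp_map: pd.DataFrame | None = None,
    config: SelectionConfig | None = None,
    source: str = "single_trait",
) -> TopSnpSet:
    """Elect the most significant SNP per sliding window, thresholded.

    ``gwas`` must carry snp_id, chromosome, position_bp and neg_log10_p
    (single-trait or meta-analysis output both qualify).  Windows are
    1-based inclusive [start, start + window_bp - 1] anchored at bp 1,
    advancing by step_bp until the window start exceeds the last SNP
    position on the chromosome.  The union over windows is deduplicated
    preserving map order.  Window ties elect the smaller bp.
    """
    config = config or SelectionConfig()
    df = gwas if snp_map is None else gwas.merge(
        snp_map[["snp_id", "chromosome", "position_bp"]], on="snp_id", how="inner")
    for col in ("snp_id", "chromosome", "position_bp", "neg_log10_p"):
        if col not in df.columns:
            raise DataError(f"GWAS table missing column {col}")

    chrom = df["chromosome"].to_numpy()
    pos = df["position_bp"].to_numpy()
    order_check = np.lexsort((pos, chrom))
    if not np.array_equal(order_check, np.arange(len(df))):
        raise DataError("GWAS table / map not sorted by (chromosome, position)")

    selected: list[str] = []
    seen = set()
    score = df["neg_log10_p"].to_numpy(dtype=float)
    ids = df["snp_id"].to_numpy()
    for c in pd.unique(chrom):
        mask = chrom == c
        cpos = pos[mask]
        cscore = score[mask]
        cids = ids[mask]
        last = int(cpos[-1])
        start = 1
        while start <= last:
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, start + config.window_bp - 1, side="right")
            if hi > lo:
                w_score = cscore[lo:hi]
                best = lo + int(np.argmax(w_score))  # argmax takes first = smaller bp on ties
                if cscore[best] >= config.neg_log10_threshold and cids[best] not in seen:
                    seen.add(cids[best])
            start += config.step_bp
    # map order = input order (already sorted)
    selected = [s for s in ids if s in seen]
    return TopSnpSet(snp_ids=selected, source=source, config=config,
                     n_before_prune=len(selected), n_after_prune=len(selected))


def ld_prune(
    genotypes,
    candidate_ids,
    config: SelectionConfig | None = None,
    scores=None,
    source: str = "single_trait",
) -> TopSnpSet:
    """Remove one SNP of every pair in strong LD among the candidates.

    LD is the squared Pearson correlation of dosages over the supplied
    individuals (the discovery set).  Windows of ``ld_window_snps``
    map-ordered candidates advance by ``ld_step_snps``; violating pairs
    are resolved by removing the SNP with the smaller score (``scores``
    maps snp_id -> -log10 p; missing scores count as 0), ties by removing
    the larger bp.  Pruning iterates until no window contains a violating
    pair.
    """
    config = config or SelectionConfig()
    candidate_ids = list(candidate_ids)
    idx = genotypes.snp_indexer(candidate_ids)  # errors on absent candidates
    sub = genotypes.subset_snps(mask=idx)
    order = np.lexsort((sub.snp_map["position_bp"].to_numpy(),
                        sub.snp_map["chromosome"].to_numpy()))
    sub = sub.subset_snps(mask=order)
    ids = list(sub.snp_ids)
    m = len(ids)
    score = np.array([0.0 if scores is None else float(scores.get(s, 0.0)) for s in ids])

    Z = sub.dosages.astype(np.float64)
    Z = Z - Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z /= sd
    R2 = (Z.T @ Z / Z.shape[0]) ** 2

    alive = np.ones(m, dtype=bool)
    W, S = config.ld_window_snps, config.ld_step_snps
    changed = True
    while changed:
        changed = False
        surv = np.flatnonzero(alive)
        for start in range(0, max(len(surv) - 1, 1), S):
            win = surv[start:start + W]
            if win.size < 2:
                continue
            block = R2[np.ix_(win, win)]
            iu, ju = np.triu_indices(win.size, k=1)
            viol = block[iu, ju] > config.ld_r2_max
            if not viol.any():
                continue
            k = int(np.flatnonzero(viol)[0])
            a, b = win[iu[k]], win[ju[k]]
            # drop the less significant; tie -> larger bp (b, the later one)
            drop = a if score[a] < score[b] else b
            alive[drop] = False
            changed = True
            break  # windows shift after a removal; rescan

    kept = [ids[i] for i in range(m) if alive[i]]
    return TopSnpSet(snp_ids=kept, source=source, config=config,
                     n_before_prune=m, n_after_prune=len(kept))
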