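"""Top-SNP selection: MAF filter, sliding windows, LD pruning."""

import numpy as np
import pandas as pd
import pytest

from heatgp.errors import DataError
from heatgp.prioritize import SelectionConfig, ld_prune, maf_filter, select_window_top_snps
from tests.conftest import make_genotypes


class TestMafFilter:
    def test_boundary_frequency_removed_strictly(self):
        g = make_genotypes(1000, 5, seed=40)
        # force SNP 0 to frequency exactly 0.005: 10 alt alleles in 2000
        g.dosages[:, 0] = 0
        g.dosages[:10, 0] = 1
        out = maf_filter(g, 0.005)
        assert "s0" not in out.snp_ids

    def test_common_snp_retained(self, small_genotypes):
        out = maf_filter(small_genotypes, 0.005)
        assert "s0" in out.snp_ids

    def test_matches_enumeration_oracle(self):
        g = make_genotypes(400, 200, seed=41, freq_range=(0.001, 0.2))
        out = maf_filter(g, 0.05)
        freqs = g.allele_freq
        expect = [s for s, f in zip(g.snp_ids, freqs) if min(f, 1 - f) > 0.05]
        assert list(out.snp_ids) == expect

    def test_all_removed_is_error(self):
        g = make_genotypes(50, 10, seed=42)
        with pytest.raises(DataError):
            maf_filter(g, 0.49999 if g.maf().max() < 0.49999 else 0.5)


def _gwas_table(chrom, pos, score):
    return pd.DataFrame({
        "chromosome": chrom, "snp_id": [f"c{c}p{p}" for c, p in zip(chrom, pos)],
        "position_bp": pos, "neg_log10_p": score,
    })


def brute_force_windows(df, config):
    """Materialise every window explicitly; independent of the implementation."""
    chosen = []
    for c in sorted(df["chromosome"].unique()):
        sub = df[df["chromosome"] == c]
        last = sub["position_bp"].max()
        start = 1
        while start <= last:
            inside = sub[(sub["position_bp"] >= start)
                         & (sub["position_bp"] <= start + config.window_bp - 1)]
            if len(inside):
                best = inside.sort_values(["neg_log10_p", "position_bp"],
                                          ascending=[False, True]).iloc[0]
                if best["neg_log10_p"] >= config.neg_log10_threshold:
                    chosen.append(best["snp_id"])
            start += config.step_bp
    seen, out = set(), []
    for s in df["snp_id"]:
        if s in chosen and s not in seen:
            seen.add(s)
            out.append(s)
    return out


class TestWindowSelection:
    def test_hand_enumerated_example(self):
        """Windows [1,100k] and [50k+1,150k] both elect the 60-kb SNP; the
        120-kb SNP fails the threshold."""
        df = _gwas_table([1, 1, 1], [10_000, 60_000, 120_000], [4.0, 5.0, 1.0])
        out = select_window_top_snps(df, config=SelectionConfig(neg_log10_threshold=3))
        assert out.snp_ids == ["c1p60000"]

    def test_all_below_threshold_gives_empty_set(self):
        df = _gwas_table([1, 1], [5_000, 80_000], [1.0, 2.5])
        out = select_window_top_snps(df, config=SelectionConfig(neg_log10_threshold=3))
        assert len(out) == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(5, 200)
        chrom = np.sort(rng.integers(1, 4, m))
        pos = np.concatenate([
            np.sort(rng.choice(np.arange(1, 400_000), np.sum(chrom == c), replace=False))
            for c in np.unique(chrom)])
        df = _gwas_table(chrom, pos, rng.uniform(0, 6, m))
        cfg = SelectionConfig(neg_log10_threshold=float(rng.uniform(1, 4)))
        out = select_window_top_snps(df, config=cfg)
        assert out.snp_ids == brute_force_windows(df, cfg)

    def test_subthreshold_snps_are_irrelevant(self):
        rng = np.random.default_rng(77)
        df = _gwas_table(np.ones(50, int),
                         np.sort(rng.choice(np.arange(1, 500_000), 50, replace=False)),
                         rng.uniform(0, 6, 50))
        cfg = SelectionConfig(neg_log10_threshold=3)
        full = select_window_top_snps(df, config=cfg)
        reduced = select_window_top_snps(
            df[df["neg_log10_p"] >= 3].reset_index(drop=True), config=cfg)
        assert full.snp_ids == reduced.snp_ids

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(78)
        df = _gwas_table(np.ones(120, int),
                         np.sort(rng.choice(np.arange(1, 800_000), 120, replace=False)),
                         rng.uniform(0, 5, 120))
        sizes = [len(select_window_top_snps(
            df, config=SelectionConfig(neg_log10_threshold=t)))
            for t in (1.0, 2.0, 3.0, 4.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_unsorted_map_rejected(self):
        df = _gwas_table([1, 1], [200, 100], [4.0, 4.0])
        with pytest.raises(DataError, match="sorted"):
            select_window_top_snps(df, config=SelectionConfig())


def brute_force_prune(g, ids, config, scores):
    """Independent fixed-point re-implementation of the pruning rule."""
    sub = g.subset_snps(snp_ids=ids)
    order = np.lexsort((sub.snp_map["position_bp"], sub.snp_map["chromosome"]))
    ids = [sub.snp_ids[i] for i in order]
    Z = sub.dosages.astype(float)[:, order]
    R = np.corrcoef(Z, rowvar=False) ** 2
    alive = list(range(len(ids)))
    while True:
        removed = None
        surv = alive
        for start in range(0, max(len(surv) - 1, 1), config.ld_step_snps):
            win = surv[start:start + config.ld_window_snps]
            for ai in range(len(win)):
                for bi in range(ai + 1, len(win)):
                    a, b = win[ai], win[bi]
                    if R[a, b] > config.ld_r2_max:
                        sa = scores.get(ids[a], 0.0)
                        sb = scores.get(ids[b], 0.0)
                        removed = a if sa < sb else b
                        break
                if removed is not None:
                    break
            if removed is not None:
                break
        if removed is None:
            return [ids[i] for i in alive]
        alive = [i for i in alive if i != removed]


class TestLdPrune:
    def test_duplicated_column_keeps_exactly_one(self):
        g = make_genotypes(100, 10, seed=50)
        g.dosages[:, 4] = g.dosages[:, 3]
        out = ld_prune(g, list(g.snp_ids), scores={"s3": 5.0, "s4": 1.0})
        assert "s3" in out.snp_ids and "s4" not in out.snp_ids
        assert out.n_after_prune == 9

    def test_orthogonal_snps_all_survive(self):
        g = make_genotypes(500, 30, seed=51)
        out = ld_prune(g, list(g.snp_ids))
        assert len(out) == 30

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(10, 60))
        g = make_genotypes(80, m, seed=seed + 100)
        # plant correlated pairs
        for _ in range(m // 4):
            a, b = rng.choice(m, 2, replace=False)
            g.dosages[:, b] = g.dosages[:, a]
        scores = {s: float(rng.uniform(0, 5)) for s in g.snp_ids}
        cfg = SelectionConfig(ld_r2_max=0.8, ld_window_snps=10, ld_step_snps=3)
        ours = ld_prune(g, list(g.snp_ids), config=cfg, scores=scores)
        assert ours.snp_ids == brute_force_prune(g, list(g.snp_ids), cfg, scores)

    def test_postcondition_no_violating_pair_in_any_window(self):
        rng = np.random.default_rng(60)
        g = make_genotypes(60, 50, seed=61)
        for _ in range(15):
            a, b = rng.choice(50, 2, replace=False)
            g.dosages[:, b] = g.dosages[:, a]
        cfg = SelectionConfig(ld_r2_max=0.9, ld_window_snps=12, ld_step_snps=4)
        out = ld_prune(g, list(g.snp_ids), config=cfg)
        sub = g.subset_snps(snp_ids=out.snp_ids)
        Z = sub.dosages.astype(float)
        R = np.corrcoef(Z, rowvar=False) ** 2
        surv = list(range(len(out.snp_ids)))
        for start in range(0, max(len(surv) - 1, 1), cfg.ld_step_snps):
            win = surv[start:start + cfg.ld_window_snps]
            for i in range(len(win)):
                for j in range(i + 1, len(win)):
                    assert R[win[i], win[j]] <= cfg.ld_r2_max

    def test_absent_candidate_named_in_error(self, small_genotypes):
        with pytest.raises(DataError, match="nope"):
            ld_prune(small_genotypes, ["s0", "nope"])
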