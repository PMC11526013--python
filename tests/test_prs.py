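import numpy as np
import pandas as pd
import pytest

from dxprs.datatypes import SummaryStats
from dxprs.prs import (
    EmptyPanelError,
    PRSConfig,
    clump,
    filter_sumstats,
    reconcile_alleles,
    score,
)
from dxprs.simulate import SimConfig, simulate_cohort

from conftest import make_genotypes


def make_ss(rows):
    """SummaryStats from (id, chr, pos, a1, a2, beta, se, p, freq) tuples."""
    cols = ["variant_id", "chromosome", "position", "allele_effect", "allele_other",
            "effect_size", "se", "p", "frequency_effect_allele"]
    return SummaryStats(pd.DataFrame(rows, columns=cols))


class TestFilterSumstats:
    def test_mhc_boundaries(self):
        ss = make_ss(
            [
                ("in_mhc", "6", 30_000_000, "A", "G", 0.1, 0.01, 0.01, 0.2),
                ("before_mhc", "6", 24_999_999, "A", "G", 0.1, 0.01, 0.01, 0.2),
                ("other_chrom", "7", 30_000_000, "A", "G", 0.1, 0.01, 0.01, 0.2),
            ]
        )
        kept = filter_sumstats(ss, PRSConfig())
        assert list(kept.table["variant_id"]) == ["before_mhc", "other_chrom"]

    def test_maf_strictly_above(self):
        ss = make_ss(
            [
                ("at_cut", "1", 100, "A", "G", 0.1, 0.01, 0.01, 0.01),
                ("above", "1", 200, "A", "G", 0.1, 0.01, 0.01, 0.011),
                ("high_freq", "1", 300, "A", "G", 0.1, 0.01, 0.01, 0.995),
            ]
        )
        kept = filter_sumstats(ss, PRSConfig())
        assert list(kept.table["variant_id"]) == ["above"]

    def test_empty_panel_error(self):
        ss = make_ss([("v", "6", 26_000_000, "A", "G", 0.1, 0.01, 0.01, 0.2)])
        with pytest.raises(EmptyPanelError):
            filter_sumstats(ss, PRSConfig())


def clump_oracle(ss, G, cfg):
    """Brute-force greedy clumping, straight from the rule."""
    t = ss.table
    X = np.array(G.dosages)
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    col = {v: j for j, v in enumerate(G.variants["variant_id"])}
    remaining = [
        i for i in sorted(
            range(len(t)),
            key=lambda i: (t["p"][i], t["chromosome"][i], t["position"][i]),
        )
        if t["variant_id"][i] in col
    ]
    index = []
    while remaining:
        i = remaining.pop(0)
        index.append(t["variant_id"][i])
        survivors = []
        for j in remaining:
            same = t["chromosome"][j] == t["chromosome"][i]
            near = abs(t["position"][j] - t["position"][i]) <= cfg.clump_window_kb * 1000
            if same and near:
                r = np.corrcoef(X[:, col[t["variant_id"][i]]], X[:, col[t["variant_id"][j]]])[0, 1]
                if r * r >= cfg.clump_r2:
                    continue
            survivors.append(j)
        remaining = survivors
    return sorted(index)


class TestClump:
    def test_correlated_pair_most_significant_wins(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.4, 200).astype(float)
        G = make_genotypes(np.column_stack([a, a]), position=[1000, 11_000])
        ss = make_ss(
            [
                ("v0", "1", 1000, "A", "G", 0.2, 0.02, 1e-8, 0.4),
                ("v1", "1", 11_000, "A", "G", 0.1, 0.02, 1e-4, 0.4),
            ]
        )
        kept, _ = clump(ss, G, PRSConfig())
        assert list(kept.table["variant_id"]) == ["v0"]

    def test_outside_window_both_survive(self):
        rng = np.random.default_rng(0)
        a = rng.binomial(2, 0.4, 200).astype(float)
        G = make_genotypes(np.column_stack([a, a]), position=[1000, 601_000])
        ss = make_ss(
            [
                ("v0", "1", 1000, "A", "G", 0.2, 0.02, 1e-8, 0.4),
                ("v1", "1", 601_000, "A", "G", 0.1, 0.02, 1e-4, 0.4),
            ]
        )
        kept, _ = clump(ss, G, PRSConfig())
        assert list(kept.table["variant_id"]) == ["v0", "v1"]

    def test_absent_variant_logged_not_fatal(self):
        rng = np.random.default_rng(0)
        G = make_genotypes(rng.binomial(2, 0.4, (50, 1)).astype(float), position=[1000])
        ss = make_ss(
            [
                ("v0", "1", 1000, "A", "G", 0.2, 0.02, 1e-8, 0.4),
                ("ghost", "1", 2000, "A", "G", 0.1, 0.02, 1e-4, 0.4),
            ]
        )
        kept, skipped = clump(ss, G, PRSConfig())
        assert skipped == ["ghost"]
        assert list(kept.table["variant_id"]) == ["v0"]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, seed):
        """15-variant LD-block fixture equals the literal greedy rule."""
        rng = np.random.default_rng(seed)
        n = 300
        cols, rows = [], []
        pos = 0
        for b in range(5):
            base = rng.binomial(2, rng.uniform(0.2, 0.5), n).astype(float)
            for k in range(3):
                pos += rng.integers(5_000, 400_000)
                noisy = base.copy()
                flip = rng.random(n) < rng.uniform(0.0, 0.4)
                noisy[flip] = rng.binomial(2, 0.5, flip.sum())
                cols.append(noisy)
                rows.append(
                    (f"v{b}_{k}", "1", int(pos), "A", "G",
                     rng.normal(0, 0.1), 0.02, float(rng.uniform(1e-8, 0.5)), 0.4)
                )
        G = make_genotypes(
            np.column_stack(cols), position=[r[2] for r in rows]
        )
        G.variants["variant_id"] = [r[0] for r in rows]
        ss = make_ss(rows)
        cfg = PRSConfig()
        kept, _ = clump(ss, G, cfg)
        assert sorted(kept.table["variant_id"]) == clump_oracle(ss, G, cfg)

    def test_indices_mutually_independent(self):
        rng = np.random.default_rng(9)
        _, _, ss, _ = (None, None, None, None)
        G, state, ss, _ = simulate_cohort(SimConfig(n_individuals=300, n_variants=100, n_causal=20, seed=3))
        cfg = PRSConfig()
        kept, _ = clump(ss, G, cfg)
        col = {v: j for j, v in enumerate(G.variants["variant_id"])}
        X = np.nan_to_num(G.dosages)
        t = kept.table
        for i in range(len(t)):
            for j in range(i + 1, len(t)):
                if t["chromosome"][i] != t["chromosome"][j]:
                    continue
                if abs(t["position"][i] - t["position"][j]) > cfg.clump_window_kb * 1000:
                    continue
                r = np.corrcoef(X[:, col[t["variant_id"][i]]], X[:, col[t["variant_id"][j]]])[0, 1]
                assert r * r < cfg.clump_r2


class TestScore:
    def test_hand_arithmetic(self):
        G = make_genotypes([[0, 1, 2]])
        ss = make_ss(
            [
                ("v0", "1", 1000, "A", "G", 0.1, 0.01, 0.01, 0.3),
                ("v1", "1", 2000, "A", "G", -0.2, 0.01, 0.01, 0.3),
                ("v2", "1", 3000, "A", "G", 0.3, 0.01, 0.01, 0.3),
            ]
        )
        vec = score(G, ss, PRSConfig())
        assert vec.raw[0] == pytest.approx(0.4, abs=1e-12)

    def test_zero_effects_zero_scores(self):
        rng = np.random.default_rng(1)
        G = make_genotypes(rng.binomial(2, 0.4, (10, 2)).astype(float))
        ss = make_ss(
            [
                ("v0", "1", 1000, "A", "G", 0.0, 0.01, 0.01, 0.3),
                ("v1", "1", 2000, "A", "G", 0.0, 0.01, 0.01, 0.3),
            ]
        )
        assert np.allclose(score(G, ss, PRSConfig()).raw, 0.0)

    def test_matches_naive_loop(self):
        """50-individual fixture equals a per-individual python loop to 1e-12."""
        rng = np.random.default_rng(2)
        n, m = 50, 12
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        d[rng.random((n, m)) < 0.1] = np.nan
        G = make_genotypes(d)
        rows = [
            (f"v{j}", "1", (j + 1) * 1000, "A", "G",
             rng.normal(), 0.02, float(rng.uniform(0.001, 0.2)), 0.4)
            for j in range(m)
        ]
        ss = make_ss(rows)
        cfg = PRSConfig()
        vec = score(G, ss, cfg)
        freq = G.allele_frequencies()
        for i in range(n):
            expected = 0.0
            for j in range(m):
                if rows[j][7] > cfg.p_threshold:
                    continue
                dos = d[i, j]
                if np.isnan(dos):
                    dos = 2 * freq[j]
                expected += dos * rows[j][5]
            assert vec.raw[i] == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        n, m = 20, 8
        d = rng.binomial(2, 0.4, (n, m)).astype(float)
        G = make_genotypes(d)
        rows = [
            (f"v{j}", "1", (j + 1) * 1000, "A", "G", rng.normal(), 0.02, 0.01, 0.4)
            for j in range(m)
        ]
        ss = make_ss(rows)
        perm = rng.permutation(m)
        ss_perm = SummaryStats(ss.table.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(
            score(G, ss, PRSConfig()).raw, score(G, ss_perm, PRSConfig()).raw, atol=1e-12
        )

    def test_z_standardisation(self):
        rng = np.random.default_rng(4)
        G = make_genotypes(rng.binomial(2, 0.4, (40, 5)).astype(float))
        rows = [
            (f"v{j}", "1", (j + 1) * 1000, "A", "G", rng.normal(), 0.02, 0.01, 0.4)
            for j in range(5)
        ]
        vec = score(G, make_ss(rows), PRSConfig())
        assert abs(vec.z.sum()) < 1e-9 * len(vec.z)
        assert abs(vec.z.var() - 1) < 1e-9

    def test_lower_threshold_never_adds_variants(self):
        rng = np.random.default_rng(5)
        G = make_genotypes(rng.binomial(2, 0.4, (30, 10)).astype(float))
        rows = [
            (f"v{j}", "1", (j + 1) * 1000, "A", "G", rng.normal(), 0.02,
             float(rng.uniform(1e-6, 1.0)), 0.4)
            for j in range(10)
        ]
        ss = make_ss(rows)
        counts = [
            score(G, ss, PRSConfig(p_threshold=p)).n_variants
            for p in (0.5, 0.05, 0.005)
            if any(r[7] <= p for r in rows)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_allele_flip_with_negated_effect_invariant(self):
        rng = np.random.default_rng(6)
        G = make_genotypes(rng.binomial(2, 0.4, (25, 2)).astype(float))
        rows = [
            ("v0", "1", 1000, "A", "G", 0.3, 0.02, 0.01, 0.4),
            ("v1", "1", 2000, "A", "G", -0.2, 0.02, 0.01, 0.4),
        ]
        flipped = [
            ("v0", "1", 1000, "G", "A", -0.3, 0.02, 0.01, 0.6),
            ("v1", "1", 2000, "A", "G", -0.2, 0.02, 0.01, 0.4),
        ]
        a = score(G, make_ss(rows), PRSConfig())
        b = score(G, make_ss(flipped), PRSConfig())
        np.testing.assert_allclose(a.raw, b.raw, atol=1e-12)

    def test_palindromic_without_frequency_rejected(self):
        rng = np.random.default_rng(7)
        G = make_genotypes(rng.binomial(2, 0.4, (25, 1)).astype(float))
        G.variants.loc[0, ["allele_effect", "allele_other"]] = ["A", "T"]
        rows = [("v0", "1", 1000, "A", "T", 0.3, 0.02, 0.01, np.nan)]
        with pytest.raises(EmptyPanelError):
            score(G, make_ss(rows), PRSConfig())

    def test_reconcile_alleles(self):
        assert reconcile_alleles("A", "G", "A", "G") == 1
        assert reconcile_alleles("A", "G", "G", "A") == -1
        assert reconcile_alleles("A", "G", "A", "C") is None
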