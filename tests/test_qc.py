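import itertools
import math

import numpy as np
import pytest

from dxprs.qc import (
    QCThresholds,
    hwe_test,
    ld_prune,
    ld_r2,
    pca_cluster,
    relatedness_filter,
    relatedness_matrix,
    snp_qc,
)

from conftest import make_genotypes


def hwe_exact_oracle(n_AA, n_Aa, n_aa):
    """Exact HWE p by literal enumeration of the conditional distribution,
    in exact rational arithmetic."""
    from fractions import Fraction

    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa

    def prob(het):
        hom_a = (n_a - het) // 2
        hom_A = n - het - hom_a
        num = (
            math.factorial(n) * 2**het * math.factorial(n_a) * math.factorial(2 * n - n_a)
        )
        den = (
            math.factorial(hom_A) * math.factorial(het) * math.factorial(hom_a)
            * math.factorial(2 * n)
        )
        return Fraction(num, den)

    hets = range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_Aa]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHWE:
    @pytest.mark.parametrize(
        "counts",
        [(0, 2, 0), (0, 5, 0), (0, 10, 0), (25, 50, 25), (5, 10, 85), (1, 1, 1), (3, 0, 3)],
    )
    def test_matches_enumeration(self, counts):
        assert hwe_test(*counts) == pytest.approx(hwe_exact_oracle(*counts), rel=1e-9)

    def test_enumeration_grid(self):
        """Full agreement with enumeration across all tables of size <= 12."""
        for n in (2, 5, 8, 12):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    assert hwe_test(n_AA, n_Aa, n_aa) == pytest.approx(
                        hwe_exact_oracle(n_AA, n_Aa, n_aa), rel=1e-9
                    )

    def test_monomorphic_p_one(self):
        assert hwe_test(0, 0, 40) == 1.0
        assert hwe_test(40, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 2, 3)

    def test_large_total(self):
        # all-heterozygote excess at n=200 is a vanishing tail probability
        assert hwe_test(0, 200, 0) < 1e-30


class TestSnpQC:
    def test_maf_threshold_semantics(self):
        rng = np.random.default_rng(0)
        n = 1000
        d = np.column_stack(
            [
                rng.binomial(2, 0.049, n),  # below MAF cut
                rng.binomial(2, 0.3, n),    # clean
            ]
        ).astype(float)
        # force exact frequencies: 0.049 and 0.3 ok statistically; set exact
        G = make_genotypes(d)
        kept, fails = snp_qc(G, QCThresholds())
        freqs = G.allele_frequencies()
        for j, f in enumerate(freqs):
            vid = f"v{j}"
            if min(f, 1 - f) < 0.05:
                assert vid in set(fails["variant_id"])
            else:
                assert vid in set(kept.variants["variant_id"])

    def test_missingness_and_hwe_filters(self):
        rng = np.random.default_rng(1)
        n = 400
        clean = rng.binomial(2, 0.4, n).astype(float)
        gappy = clean.copy()
        gappy[: int(0.06 * n)] = np.nan  # 6% missing
        het = np.ones(n)  # all heterozygotes: extreme HWE violation
        G = make_genotypes(np.column_stack([clean, gappy, het]))
        kept, fails = snp_qc(G, QCThresholds())
        reasons = dict(zip(fails["variant_id"], fails["reasons"]))
        assert "missingness" in reasons["v1"]
        assert "hwe" in reasons["v2"]
        assert list(kept.variants["variant_id"]) == ["v0"]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, rng.uniform(0.02, 0.5, 30), size=(300, 30)).astype(float)
        G = make_genotypes(d)
        thr = QCThresholds()
        once, _ = snp_qc(G, thr)
        twice, fails2 = snp_qc(once, thr)
        assert list(twice.variants["variant_id"]) == list(once.variants["variant_id"])
        assert len(fails2) == 0


class TestLdR2:
    def test_identical_and_flipped(self):
        x = np.array([0, 1, 2, 0, 1])
        assert ld_r2(x, x) == pytest.approx(1.0)
        assert ld_r2(np.array([0, 1, 2, 0]), np.array([2, 1, 0, 2])) == pytest.approx(1.0)

    def test_hand_computed_pair(self):
        x = np.array([0, 1, 2, 1, 0, 2], float)
        y = np.array([1, 1, 2, 0, 0, 1], float)
        r = np.corrcoef(x, y)[0, 1]
        assert ld_r2(x, y) == pytest.approx(r * r, rel=1e-12)

    def test_zero_variance_signals_zero(self):
        assert ld_r2(np.array([1, 1, 1, 1]), np.array([0, 1, 2, 0])) == 0.0

    def test_complete_pairs_only(self):
        x = np.array([0, 1, 2, np.nan, 1])
        y = np.array([0, 1, 2, 0, np.nan])
        assert ld_r2(x, y) == pytest.approx(1.0)


def ld_prune_oracle(G, thr):
    """Literal re-implementation of the window walk for small inputs."""
    freq = G.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    X = np.array(G.dosages)
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    chrom = G.variants["chromosome"].to_numpy()
    keep = np.ones(G.n_variants, bool)
    for c in dict.fromkeys(chrom):
        idx = [j for j in range(G.n_variants) if chrom[j] == c]
        start = 0
        while True:
            window = idx[start : start + thr.prune_window]
            changed = True
            while changed:
                changed = False
                for a, b in itertools.combinations([j for j in window if keep[j]], 2):
                    sa, sb = X[:, a], X[:, b]
                    if sa.std() == 0 or sb.std() == 0:
                        continue
                    r = np.corrcoef(sa, sb)[0, 1]
                    if r * r > thr.prune_r2:
                        drop = b if (maf[b] < maf[a] or maf[a] == maf[b]) else a
                        keep[drop] = False
                        changed = True
                        break
            if start + thr.prune_window >= len(idx):
                break
            start += thr.prune_step
    return np.flatnonzero(keep)


class TestLdPrune:
    def test_perfect_pair_one_survives(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.4, 100).astype(float)
        G = make_genotypes(np.column_stack([a, a]))
        kept = ld_prune(G, QCThresholds(prune_window=10, prune_step=5))
        assert len(kept) == 1

    def test_independent_all_survive(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.5, size=(4000, 10)).astype(float)
        G = make_genotypes(d)
        kept = ld_prune(G, QCThresholds(prune_window=10, prune_step=5))
        assert len(kept) == 10

    def test_unsorted_rejected(self):
        G = make_genotypes(np.zeros((5, 3)) + 1.0, position=[30, 10, 20])
        with pytest.raises(ValueError, match="sorted"):
            ld_prune(G, QCThresholds(prune_window=3, prune_step=1))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        """Constructed LD blocks: pruning equals the literal greedy rule."""
        rng = np.random.default_rng(seed)
        blocks = []
        for _ in range(4):
            base = rng.binomial(2, rng.uniform(0.2, 0.5), 120).astype(float)
            for _ in range(5):
                noisy = base.copy()
                flip = rng.random(120) < 0.1
                noisy[flip] = rng.binomial(2, 0.5, flip.sum())
                blocks.append(noisy)
        G = make_genotypes(np.column_stack(blocks))
        thr = QCThresholds(prune_window=8, prune_step=3)
        np.testing.assert_array_equal(ld_prune(G, thr), ld_prune_oracle(G, thr))


@pytest.fixture(scope="module")
def family_matrix():
    """5000-variant panel, 50 unrelated individuals plus a planted duplicate
    (of row 1) and a child of row 0 sharing one allele per locus."""
    rng = np.random.default_rng(5)
    m = 5000
    f = rng.uniform(0.1, 0.5, m)
    hap = lambda: (rng.random(m) < f).astype(float)  # noqa: E731
    parents = np.array([hap() + hap() for _ in range(50)])
    p_h1, p_h2 = hap(), hap()
    parents[0] = p_h1 + p_h2
    transmitted = np.where(rng.random(m) < 0.5, p_h1, p_h2)
    child = transmitted + hap()
    dosages = np.vstack([parents, parents[1], child])  # row 50 duplicates row 1
    return make_genotypes(dosages), [f"i{k}" for k in range(52)]


class TestRelatedness:

    def test_scale_brackets(self, family_matrix):
        G, _ = family_matrix
        A = relatedness_matrix(G)
        assert np.allclose(A, A.T)
        assert np.allclose(np.diag(A), 1.0)
        assert A[1, 50] > 0.98                     # duplicate
        assert abs(A[0, 51] - 0.5) < 0.1           # parent-child
        assert abs(A[2, 3]) < 0.1                  # unrelated
    def test_filter_removes_one_per_pair(self, family_matrix):
        G, _ = family_matrix
        A = relatedness_matrix(G)
        kept, log = relatedness_filter(A, QCThresholds(), seed=123)
        assert len(kept) == 50
        sub = A[np.ix_(kept, kept)]
        np.fill_diagonal(sub, 0.0)
        assert sub.max() <= 0.1875
        kept2, _ = relatedness_filter(A, QCThresholds(), seed=123)
        np.testing.assert_array_equal(kept, kept2)

    def test_clique_of_three(self):
        A = np.full((3, 3), 0.6)
        np.fill_diagonal(A, 1.0)
        for seed in range(8):
            kept, _ = relatedness_filter(A, QCThresholds(), seed=seed)
            assert len(kept) == 1

    def test_no_pairs_identity(self):
        A = np.eye(4)
        kept, log = relatedness_filter(A, QCThresholds(), seed=0)
        assert list(kept) == [0, 1, 2, 3] and len(log) == 0


class TestPCACluster:
    def test_keeps_exact_fraction(self):
        rng = np.random.default_rng(6)
        d = rng.binomial(2, 0.4, size=(57, 40)).astype(float)
        res = pca_cluster(make_genotypes(d), QCThresholds())
        assert len(res.kept) == math.ceil(0.9 * 57)

    def test_minority_population_over_removed(self):
        rng = np.random.default_rng(7)
        m = 300
        f_major = rng.uniform(0.2, 0.8, m)
        f_minor = np.clip(f_major + rng.choice([-0.35, 0.35], m), 0.05, 0.95)
        n_major, n_minor = 190, 10
        d = np.vstack(
            [
                rng.binomial(2, f_major, size=(n_major, m)),
                rng.binomial(2, f_minor, size=(n_minor, m)),
            ]
        ).astype(float)
        res = pca_cluster(make_genotypes(d), QCThresholds())
        removed = set(range(200)) - set(res.kept)
        minority_removed = sum(1 for i in removed if i >= n_major)
        assert minority_removed / len(removed) > n_minor / 200  # over-represented
        assert minority_removed >= 8

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.3, size=(50, 30)).astype(float)
        res = pca_cluster(make_genotypes(d), QCThresholds())
        gram = res.scores.T @ res.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_constant_matrix_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            pca_cluster(make_genotypes(np.ones((20, 10))), QCThresholds())
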