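"""Per-site Fisher test, BH adjustment, global shift and gene-level rules.

The oracles here are independent of the implementation path: the Fisher p
is recomputed by exhaustive hypergeometric enumeration, BH by a hand-written
step-up, and the signed-rank p by exact enumeration of all sign patterns.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from editscope import differential_editing as de


# ------------------------------------------------------------------- oracles

def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p for [[a, b], [c, d]] by enumerating every table
    with the same margins and summing probabilities <= the observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d
    observed = stats.hypergeom.pmf(a, n, col1, row1)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        prob = stats.hypergeom.pmf(x, n, col1, row1)
        if prob <= observed * (1 + 1e-9):
            p += prob
    return min(p, 1.0)


def bh_step_up(p):
    """Independent Benjamini-Hochberg: sort, take cumulative minima of
    m * p_(i) / i from the largest rank down, undo the sort."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def signed_rank_exact(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    of the absolute-difference ranks (no ties, no zeros)."""
    absd = np.abs(diffs)
    ranks = stats.rankdata(absd)
    w_plus = ranks[diffs > 0].sum()
    n = len(diffs)
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if min(w, total - w) <= w_obs:
            count += 1
    return count / 2**n


# --------------------------------------------------------------- per-site test

class TestPerSiteTest:
    def test_identical_tables_p_one(self):
        assert de.per_site_test(3, 7, 3, 7) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        p = de.per_site_test(0, 10, 10, 0)
        assert p == pytest.approx(fisher_enumeration(0, 10, 10, 0), rel=1e-9)

    def test_degenerate_margins_return_one(self):
        assert de.per_site_test(0, 10, 0, 12) == 1.0
        assert de.per_site_test(5, 0, 3, 0) == 1.0

    @pytest.mark.parametrize(
        "table",
        [(1, 9, 5, 5), (2, 8, 8, 2), (4, 4, 1, 7), (0, 5, 3, 3), (6, 1, 2, 9)],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        assert de.per_site_test(*table) == pytest.approx(
            fisher_enumeration(*table), rel=1e-9
        )


# ----------------------------------------------------------------------- BH

class TestBH:
    def test_textbook_example(self):
        q = de.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.37]) == pytest.approx([0.37])

    def test_empty_input(self):
        assert de.bh_adjust([]).size == 0

    def test_matches_independent_step_up(self):
        rng = np.random.default_rng(0)
        p = rng.random(1000)
        assert de.bh_adjust(p) == pytest.approx(bh_step_up(p), abs=1e-12)

    def test_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        q = de.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


# -------------------------------------------------------------- global shift

class TestGlobalShift:
    def test_no_change_direction_none_p_one(self):
        rates = [0.1, 0.2, 0.3]
        shift = de.global_shift(rates, rates, paired=True)
        assert shift.direction == "none" and shift.p_value == 1.0

    def test_uniform_decrease_detected(self):
        rng = np.random.default_rng(2)
        a = rng.beta(2, 5, 200)
        b = np.clip(a - 0.1, 0, 1)
        shift = de.global_shift(a, b, paired=True)
        assert shift.direction == "decrease" and shift.p_value < 1e-6

    def test_paired_p_matches_exact_sign_flip_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.random(10)
            b = a + rng.normal(0, 0.2, 10)
            shift = de.global_shift(a, b, paired=True)
            assert shift.p_value == pytest.approx(
                signed_rank_exact(b - a), rel=1e-9
            )

    def test_unpaired_uses_mann_whitney(self):
        rng = np.random.default_rng(4)
        a = rng.beta(2, 5, 80)
        b = rng.beta(5, 2, 60)
        shift = de.global_shift(a, b, paired=False)
        ref = stats.mannwhitneyu(b, a, alternative="two-sided")
        assert shift.statistic == pytest.approx(ref.statistic)
        assert shift.p_value == pytest.approx(ref.pvalue)
        assert shift.direction == "increase"

    def test_null_calibration(self):
        """With equal true rates the per-site q <= 0.05 fraction stays at or
        below the nominal level (Fisher is conservative at finite depth)."""
        rng = np.random.default_rng(5)
        n, depth = 800, 60
        rates = rng.beta(2, 5, n)
        alt_a = rng.binomial(depth, rates)
        alt_b = rng.binomial(depth, rates)
        p = [
            de.per_site_test(aa, depth - aa, ab, depth - ab)
            for aa, ab in zip(alt_a, alt_b)
        ]
        q = de.bh_adjust(p)
        se = np.sqrt(0.05 * 0.95 / n)
        assert (q <= 0.05).mean() <= 0.05 + 2 * se


# --------------------------------------------------------- gene-level rules

def comparison_frame():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g2", "g3"],
            "q_value": [0.01, 0.9, 0.06, 0.04],
        }
    )


class TestGeneVariation:
    def test_any_significant_site_flags_gene(self):
        flagged = de.gene_variation(comparison_frame(), q_threshold=0.05)
        assert list(flagged["gene_id"]) == ["g1", "g3"]
        assert flagged["min_q"].tolist() == [0.01, 0.04]

    def test_min_q_above_threshold_not_flagged(self):
        flagged = de.gene_variation(comparison_frame(), q_threshold=0.05)
        assert "g2" not in set(flagged["gene_id"])

    def test_matches_brute_force_min_q_scan(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            {
                "gene_id": rng.choice([f"g{i}" for i in range(30)], 300),
                "q_value": rng.random(300),
            }
        )
        flagged = set(de.gene_variation(frame, 0.1)["gene_id"])
        brute = {
            gene
            for gene in frame["gene_id"].unique()
            if frame.loc[frame["gene_id"] == gene, "q_value"].min() <= 0.1
        }
        assert flagged == brute


class TestOverlapDysregulated:
    @staticmethod
    def de_table(rows):
        return pd.DataFrame(rows, columns=["gene_id", "fold_change", "fdr"])

    def test_basic_overlap(self):
        a = self.de_table(
            [("g1", 3, 0.01), ("g2", 0.2, 0.01), ("g3", 4, 0.01), ("g4", 3, 0.5)]
        )
        b = self.de_table(
            [("g2", 5, 0.01), ("g3", 0.1, 0.02), ("g4", 8, 0.01), ("g5", 8, 0.01)]
        )
        shared, n_shared, n_a = de.overlap_dysregulated(a, b)
        assert shared == {"g2", "g3"}
        assert (n_shared, n_a) == (2, 3)

    def test_down_regulation_counts_symmetrically(self):
        a = self.de_table([("g1", 0.4, 0.01)])  # |log2 0.4| > 1
        b = self.de_table([("g1", 3.0, 0.01)])
        shared, n_shared, _ = de.overlap_dysregulated(a, b)
        assert shared == {"g1"}

    def test_disjoint_selections(self):
        a = self.de_table([("g1", 4, 0.01)])
        b = self.de_table([("g2", 4, 0.01)])
        shared, n_shared, n_a = de.overlap_dysregulated(a, b)
        assert (shared, n_shared, n_a) == (set(), 0, 1)

    def test_duplicate_gene_ids_rejected(self):
        a = self.de_table([("g1", 4, 0.01), ("g1", 2, 0.1)])
        b = self.de_table([("g2", 4, 0.01)])
        with pytest.raises(ValueError, match="g1"):
            de.overlap_dysregulated(a, b)

    def test_planted_shared_and_private_genes_recovered(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(60)]
        shared_hits = set(genes[:10])
        a_only, b_only = set(genes[10:20]), set(genes[20:30])

        def table(hits):
            rows = []
            for g in genes:
                if g in hits:
                    fc = rng.choice([4.0, 0.2])
                    fdr = 0.01
                else:
                    fc = rng.uniform(0.8, 1.2)
                    fdr = 0.5
                rows.append((g, fc, fdr))
            return pd.DataFrame(rows, columns=["gene_id", "fold_change", "fdr"])

        shared, n_shared, n_a = de.overlap_dysregulated(
            table(shared_hits | a_only), table(shared_hits | b_only)
        )
        assert shared == shared_hits
        assert (n_shared, n_a) == (10, 20)


def test_compare_sites_joins_and_tests():
    """compare_sites joins on position, restricts to informative depth in
    both conditions and produces BH-monotone q values."""
    a = pd.DataFrame(
        {
            "contig": ["c1"] * 3,
            "pos": [1, 2, 3],
            "gene_id": ["g1", "g1", "g2"],
            "n_ref": [20, 30, 4],
            "n_alt": [10, 2, 2],
        }
    )
    b = pd.DataFrame(
        {
            "contig": ["c1"] * 3,
            "pos": [1, 2, 4],
            "n_ref": [28, 30, 10],
            "n_alt": [2, 2, 10],
        }
    )
    out = de.compare_sites(a, b, min_depth=10)
    assert list(out["pos"]) == [1, 2]  # pos 3 under-covered, pos 4 unmatched
    assert out.loc[0, "delta"] == pytest.approx(2 / 30 - 10 / 30)
    assert out.loc[1, "p_value"] == pytest.approx(1.0)
    assert (out["q_value"] >= out["p_value"].min()).all()
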