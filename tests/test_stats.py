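"""Association statistics: chi-squared, phi, PCA, logistic regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgtrait.annotation_io import Cohort
from pgtrait.association_stats import (
    TwoByTwo,
    absence_pca,
    chisq_association,
    hosmer_lemeshow,
    pg_absence_regression,
    phi_correlation,
)
from pgtrait.synthetic_data import generate_covariate_cohort

from conftest import make_record


class TestChiSquared:
    def test_gh23_bacteria_association_is_strong(self):
        # GH23 presence vs Bacteria membership, from the reported distribution
        res = chisq_association(TwoByTwo(1224, 174, 5, 241))
        assert res.p_value < 1e-7

    def test_perfect_independence(self):
        res = chisq_association(TwoByTwo(10, 10, 10, 10))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_photosynthetic_eukaryote_comparison(self):
        # 5/7 photosynthetic vs 3/35 non-photosynthetic eukaryotes with >=1 gene
        res = chisq_association(TwoByTwo(5, 2, 3, 32))
        assert res.p_value <= 1e-3

    def test_zero_margin_undefined(self):
        res = chisq_association(TwoByTwo(0, 0, 5, 5))
        assert res.statistic is None and res.p_value is None

    @given(
        st.tuples(
            st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry_under_transposition_and_swaps(self, cells):
        a, b, c, d = cells
        t = TwoByTwo(a, b, c, d)
        variants = [TwoByTwo(a, c, b, d), TwoByTwo(c, d, a, b), TwoByTwo(b, a, d, c)]
        base = chisq_association(t)
        for v in variants:
            other = chisq_association(v)
            if base.statistic is None or other.statistic is None:
                continue
            assert other.statistic == pytest.approx(base.statistic, abs=1e-9)


class TestPhi:
    def test_matches_bruteforce_pearson_on_reported_counts(self):
        t = TwoByTwo(84, 5, 0, 1279)
        x = np.array([1] * 89 + [0] * 1279)
        y = np.array([1] * 84 + [0] * 5 + [0] * 1279)
        assert phi_correlation(t) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        assert phi_correlation(t) == pytest.approx(0.9696, abs=5e-5)

    def test_identical_indicators(self):
        assert phi_correlation(TwoByTwo(7, 0, 0, 13)) == pytest.approx(1.0)

    def test_zero_margin_undefined(self):
        assert phi_correlation(TwoByTwo(5, 5, 0, 0)) is None

    @given(
        st.tuples(
            st.integers(0, 200),
            st.integers(0, 200),
            st.integers(0, 200),
            st.integers(0, 200),
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_closed_form_equals_expanded_pearson(self, cells):
        a, b, c, d = cells
        t = TwoByTwo(a, b, c, d)
        phi = phi_correlation(t)
        x = np.array([1] * (a + b) + [0] * (c + d), dtype=float)
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d, dtype=float)
        if phi is None:
            assert x.std() == 0 or y.std() == 0
        else:
            assert phi == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)


def _absence_cohort(n, coupler, seed):
    """Cohort where GT51 absence coincides with PG absence; others random."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        pg_absent = rng.random() < 0.3
        counts = {
            f: int(rng.random() < 0.6)
            for f in ("GT28", "GH23", "GH25", "GH73", "GH102", "GH103", "GH104")
        }
        counts["GT51"] = 0 if (pg_absent if coupler else rng.random() < 0.3) else 1
        records.append(
            make_record(
                f"g{i}",
                counts=counts,
                pg_status="absent" if pg_absent else "present",
            )
        )
    return Cohort(records)


class TestAbsencePCA:
    def test_loadings_orthonormal(self):
        res = absence_pca(_absence_cohort(200, coupler=True, seed=1))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_perfectly_correlated_columns_load_equally(self):
        res = absence_pca(_absence_cohort(300, coupler=True, seed=2))
        l_gt51 = res.loadings.loc["GT51", "PC1"]
        l_pg = res.loadings.loc["PG", "PC1"]
        assert abs(abs(l_gt51) - abs(l_pg)) < 1e-8

    def test_coupled_pair_separates_from_noise_on_pc1(self):
        for seed in range(3):
            res = absence_pca(_absence_cohort(400, coupler=True, seed=seed))
            pc1 = res.loadings["PC1"].abs()
            coupled = min(pc1["GT51"], pc1["PG"])
            others = pc1.drop(["GT51", "PG"]).max()
            assert coupled > others

    def test_constant_column_dropped_with_warning(self):
        cohort = _absence_cohort(50, coupler=True, seed=3)
        # force GH104 constant
        records = [
            make_record(
                f"h{i}",
                counts={**r.family_counts, "GH104": 1},
                pg_status=r.pg_status,
            )
            for i, r in enumerate(cohort)
        ]
        with pytest.warns(UserWarning, match="GH104"):
            res = absence_pca(Cohort(records))
        assert "GH104" in res.dropped


class TestRegression:
    def test_parameter_recovery_ci_coverage(self):
        """Wald 95% CIs should cover a true OR of 5 in >=90% of replicates."""
        true_or = 5.0
        covered = 0
        n_rep = 60
        for seed in range(n_rep):
            cohort = generate_covariate_cohort(
                n=2000, odds_ratios=(true_or, 2.0, 2.0), seed=seed
            )
            rep = pg_absence_regression(cohort)
            r = rep["gc_below_cutoff"]
            covered += r.ci_low <= true_or <= r.ci_high
        assert covered >= 0.9 * n_rep

    def test_independent_predictor_or_near_one(self):
        cohort = generate_covariate_cohort(
            n=4000, odds_ratios=(1.0, 3.0, 3.0), baseline_logodds=-2.0, seed=9
        )
        rep = pg_absence_regression(cohort)
        r = rep["gc_below_cutoff"]
        assert r.ci_low <= 1.0 <= r.ci_high

    def test_type_one_error_calibrated_under_permutation(self):
        """With the outcome shuffled, ~5% of predictor p-values fall below .05."""
        rng = np.random.default_rng(7)
        hits = total = 0
        base = generate_covariate_cohort(n=400, seed=3)
        statuses = [r.pg_status for r in base]
        for _ in range(200):
            perm = rng.permutation(len(statuses))
            records = [
                make_record(
                    f"p{i}",
                    counts={"GT28": 1},
                    pg_status=statuses[perm[i]],
                    lifestyle=r.lifestyle,
                    gc_percent=r.gc_percent,
                    genome_size_mb=r.genome_size_mb,
                )
                for i, r in enumerate(base)
            ]
            rep = pg_absence_regression(Cohort(records))
            for res in rep.per_predictor.values():
                if res.p_value is not None:
                    total += 1
                    hits += res.p_value < 0.05
        assert total > 400
        assert 0.02 <= hits / total <= 0.09

    def test_complete_separation_flagged(self):
        records = []
        for i in range(60):
            absent = i < 30
            records.append(
                make_record(
                    f"s{i}",
                    counts={"GT28": 1},
                    pg_status="absent" if absent else "present",
                    lifestyle="obligate_intracellular" if absent else "free_living",
                    gc_percent=40.0 if absent else 60.0,
                    genome_size_mb=1.0 if absent else 3.0,
                )
            )
        rep = pg_absence_regression(Cohort(records))
        assert any(r.separated for r in rep.per_predictor.values())

    def test_hosmer_lemeshow_reasonable_under_true_model(self):
        cohort = generate_covariate_cohort(n=2000, seed=5)
        rep = pg_absence_regression(cohort)
        assert rep.hosmer_lemeshow_p is None or rep.hosmer_lemeshow_p > 0.001
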