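"""ANOVA screen, univariate cycle fits and backward elimination.

The elimination path is cross-checked against an independent re-implementation
that scores terms by partial-F refits (numpy pinv + scipy F distribution)
instead of the production t-value route.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from litternh3 import (
    DesignGrid,
    FittedModel,
    PUBLISHED_RESPONSE_MODELS,
    anova_interaction,
    fit_polynomial_backward,
    fit_univariate_cycle,
    simulate_responses,
)

# ---------------------------------------------------------------------------
# independent partial-F backward-elimination oracle
# ---------------------------------------------------------------------------

_DEG = {"1": 0, "T": 1, "T2": 2, "T3": 3, "C": 1, "C2": 2, "C3": 3}
_ORD = ("1", "T", "T2", "T3", "C", "C2", "C3")


def _col(term, T, C):
    if term == "1":
        return np.ones(len(T))
    base, power = term[0], int(term[1:] or 1)
    return (T if base == "T" else C) ** power


def _sse(terms, T, C, y):
    if not terms:
        return float(y @ y)
    X = np.column_stack([_col(t, T, C) for t in terms])
    beta = np.linalg.pinv(X) @ y
    r = y - X @ beta
    return float(r @ r)


def oracle_backward(df, alpha=0.05, candidates=_ORD):
    """Greedy hierarchical elimination scored by partial-F refits."""
    T = df["temperature"].to_numpy(float)
    C = df["cycle"].to_numpy(float)
    y = df["response"].to_numpy(float)
    scale = max(float(y @ y), 1e-300)
    terms = [t for t in _ORD if t in candidates]
    while terms:
        perfect = _sse(terms, T, C, y) <= 1e-12 * scale
        if perfect:
            eligible = list(terms)
        else:
            eligible = [
                t for t in terms
                if t == "1"
                or not any(u[0] == t[0] and _DEG[u] > _DEG[t] for u in terms)
            ]
        s_full = _sse(terms, T, C, y)
        dof = len(y) - len(terms)
        pvals = {}
        for t in eligible:
            s_red = _sse([u for u in terms if u != t], T, C, y)
            if perfect:
                pvals[t] = 1.0 if s_red <= 1e-12 * scale else 0.0
            else:
                F = max((s_red - s_full) / (s_full / dof), 0.0)
                pvals[t] = float(scipy.stats.f.sf(F, 1, dof))
        over = [(t, p) for t, p in pvals.items() if p > alpha]
        if not over:
            break
        worst = max(over, key=lambda tp: (tp[1], _DEG[tp[0]], _ORD.index(tp[0])))[0]
        terms.remove(worst)
    return tuple(terms)


def _random_dataset(rng):
    n = 24
    T = rng.uniform(25, 40, n)
    C = rng.integers(1, 7, n).astype(float)
    k = rng.integers(0, 4)
    terms = list(rng.choice(_ORD, size=k, replace=False)) if k else []
    coefs = {t: rng.normal(0, 1) / (30.0 ** _DEG[t]) for t in terms}
    y = sum(c * _col(t, T, C) for t, c in coefs.items()) if coefs else np.zeros(n)
    y = y + rng.normal(0, 0.5, n)
    return pd.DataFrame({"temperature": T, "cycle": C, "response": y})


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

class TestAnovaInteraction:
    def _toy(self):
        # 2 cycles × 2 temperatures × 2 replicates, hand-computable sums of squares
        rows = []
        values = {(1, 25): (10, 12), (1, 30): (14, 16), (2, 25): (20, 18), (2, 30): (22, 26)}
        for (c, t), ys in values.items():
            for rep, y in enumerate(ys, start=1):
                rows.append({"cycle": c, "temperature": t, "replicate": rep, "response": y})
        return pd.DataFrame(rows)

    def test_balanced_2x2_matches_hand_computation(self):
        # hand values: SS_cycle = 144.5, SS_temp = 40.5, SS_int = 0.5, SSE = 14 (df 4)
        table = anova_interaction(self._toy()).table
        assert table.loc["cycle", "ss"] == pytest.approx(144.5, abs=1e-10)
        assert table.loc["temperature", "ss"] == pytest.approx(40.5, abs=1e-10)
        assert table.loc["interaction", "ss"] == pytest.approx(0.5, abs=1e-10)
        assert table.loc["residual", "ss"] == pytest.approx(14.0, abs=1e-10)
        f_int = (0.5 / 1) / (14.0 / 4)
        assert table.loc["interaction", "F"] == pytest.approx(f_int, abs=1e-10)
        assert table.loc["interaction", "p"] == pytest.approx(
            scipy.stats.f.sf(f_int, 1, 4), abs=1e-12
        )

    def test_strong_product_interaction_detected(self):
        rng = np.random.default_rng(2)
        rows = [
            {"cycle": c, "temperature": t, "response": 0.5 * c * t + rng.normal(0, 0.5)}
            for c in (1, 2, 3) for t in (25, 30, 35, 40) for _ in range(3)
        ]
        assert anova_interaction(pd.DataFrame(rows)).p_value("interaction") < 0.05

    def test_additive_truth_has_nominal_type_one_error(self):
        # under an additive truth the interaction test should reject ~5% of the time
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 2000
        c = np.repeat([1, 2, 3, 4], 8)
        t = np.tile(np.repeat([25, 30, 35, 40], 2), 4)
        for _ in range(n_sim):
            y = 0.3 * t + 1.5 * c + rng.normal(0, 1.0, c.size)
            df = pd.DataFrame({"cycle": c, "temperature": t, "response": y})
            if anova_interaction(df).p_value("interaction") < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)

    def test_single_replicate_is_untestable(self):
        df = pd.DataFrame(
            [{"cycle": c, "temperature": t, "response": c + t} for c in (1, 2) for t in (25, 30)]
        )
        with pytest.raises(ValueError, match="single\\s+replicate"):
            anova_interaction(df)


# ---------------------------------------------------------------------------
# univariate per-temperature cycle fits
# ---------------------------------------------------------------------------

class TestUnivariateCycleFit:
    @pytest.mark.parametrize(
        "coef, cycles",
        [
            ((31.90, -1.17), range(1, 7)),        # linear moisture profile
            ((8.67, 0.08, -0.02), range(1, 7)),   # quadratic pH profile
            ((42.91, -8.69, 1.22), range(1, 5)),  # quadratic moisture profile
        ],
    )
    def test_noiseless_exact_recovery(self, coef, cycles):
        c = np.array(list(cycles), dtype=float)
        y = sum(b * c**k for k, b in enumerate(coef))
        model = fit_univariate_cycle(c, y, max_degree=2)
        expected_terms = ("1", "C", "C2")[: len(coef)]
        assert model.retained_terms == expected_terms
        for k, term in enumerate(expected_terms):
            assert model.coefficients[term] == pytest.approx(coef[k], abs=1e-8)
        assert model.r2 == pytest.approx(1.0)
        assert model.see == pytest.approx(0.0, abs=1e-10)

    def test_constant_response_collapses_to_intercept(self):
        model = fit_univariate_cycle(np.arange(1, 7), np.full(6, 5.0))
        assert model.retained_terms == ("1",)
        assert model.coefficients["1"] == pytest.approx(5.0)
        assert model.r2 == 0.0

    def test_insignificant_quadratic_dropped(self):
        rng = np.random.default_rng(4)
        c = np.repeat(np.arange(1, 7), 3).astype(float)
        y = 30.0 - 1.2 * c + rng.normal(0, 0.4, c.size)
        model = fit_univariate_cycle(c, y, max_degree=2)
        assert model.retained_terms == ("1", "C")
        assert all(p <= 0.05 for t, p in model.p_values.items() if t != "1")

    def test_requires_enough_distinct_cycles(self):
        with pytest.raises(ValueError, match="distinct cycle"):
            fit_univariate_cycle([1, 1, 2, 2], [1.0, 1.1, 2.0, 2.1], max_degree=2)


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

class TestBackwardElimination:
    @pytest.mark.parametrize("key", list(PUBLISHED_RESPONSE_MODELS))
    def test_noiseless_published_models_recovered_exactly(self, key):
        truth = PUBLISHED_RESPONSE_MODELS[key]
        df = simulate_responses(truth, DesignGrid(key[1]), seed=0)
        model = fit_polynomial_backward(df)
        assert set(model.retained_terms) == set(truth)
        for term, coef in truth.items():
            assert model.coefficients[term] == pytest.approx(coef, abs=1e-8)
        assert not model.has_intercept
        assert model.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "truth", [{"T": 2.0}, {"T2": 1e-3, "C2": 0.5}, {"1": 4.0, "C": 1.0}]
    )
    def test_noiseless_nonstandard_generators_recovered(self, truth, wood_grid):
        df = simulate_responses(truth, wood_grid, seed=0)
        model = fit_polynomial_backward(df)
        assert set(model.retained_terms) == set(truth)
        for term, coef in truth.items():
            assert model.coefficients[term] == pytest.approx(coef, abs=1e-8)

    def test_pure_noise_with_tiny_alpha_returns_null_model(self, wood_grid):
        rng = np.random.default_rng(9)
        df = simulate_responses({"T": 0.0}, wood_grid, seed=0)
        df["response"] = rng.normal(0, 1, len(df))
        model = fit_polynomial_backward(df, alpha=1e-12)
        assert model.retained_terms == ()
        assert model.warnings

    def test_retained_terms_all_significant(self, coffee_grid):
        truth = PUBLISHED_RESPONSE_MODELS[("generation", "coffee_husks")]
        df = simulate_responses(truth, coffee_grid, noise_frac_of_mean=0.05, seed=21)
        model = fit_polynomial_backward(df)
        # termination contract: every testable retained term is significant
        # (a lower power shielded by its higher power is not testable)
        from litternh3.modeling import _highest_powers

        eligible = _highest_powers(list(model.retained_terms), test_intercept=True)
        assert all(model.p_values[t] <= 0.05 for t in eligible)
        assert len(model.retained_terms) <= len(model.candidate_terms)

    def test_matches_partial_f_oracle_on_random_datasets(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            df = _random_dataset(rng)
            model = fit_polynomial_backward(df)
            assert tuple(model.retained_terms) == oracle_backward(df)

    def test_rank_deficiency_reported(self, wood_grid):
        df = simulate_responses({"C": 1.0}, wood_grid, seed=0)
        df["temperature"] = 30.0  # constant T makes T powers collinear with 1
        with pytest.raises(ValueError, match="collinear"):
            fit_polynomial_backward(df)

    def test_needs_more_rows_than_terms(self):
        df = pd.DataFrame(
            {"temperature": [25.0, 30, 35, 40], "cycle": [1.0, 2, 3, 4], "response": [1.0, 2, 3, 4]}
        )
        with pytest.raises(ValueError, match="observations"):
            fit_polynomial_backward(df)


class TestFittedModelRoundTrip:
    def test_json_round_trip(self, tmp_path, wood_grid):
        truth = PUBLISHED_RESPONSE_MODELS[("emission", "wood_shavings")]
        df = simulate_responses(truth, wood_grid, noise_frac_of_mean=0.05, seed=5)
        model = fit_polynomial_backward(df)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedModel.from_json(str(path))
        assert back == model

    def test_coefficient_table_layout(self, wood_grid):
        truth = PUBLISHED_RESPONSE_MODELS[("generation", "wood_shavings")]
        df = simulate_responses(truth, wood_grid, seed=1)
        table = fit_polynomial_backward(df).coefficient_table()
        assert list(table.columns) == ["term", "coefficient", "se", "p"]
        assert len(table) == 3
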