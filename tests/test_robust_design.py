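"""Robust-design likelihood: closed-form checks, exhaustive enumeration
oracles, nesting monotonicity, and joint-fit behaviour."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patchdemog import robust_design as rd
from patchdemog import synthetic_data as sd

from conftest import uniform_truth


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def huggins_prob(h, p, c):
    """Naive conditional probability of one within-session history."""
    j = h.index(1)
    pr = (1 - p) ** j * p
    for m in h[j + 1:]:
        pr *= c if m else (1 - c)
    return pr / (1 - (1 - p) ** len(h))


def open_prob(h, phi, lam, ps):
    """Naive conditional probability of one collapsed history: explicit sum
    over entry session b and last-alive session d."""
    T = len(h)
    e = [lam**t for t in range(T)]
    b_raw = [1.0] + [e[t] - phi * e[t - 1] for t in range(1, T)]
    b_mass = [max(x, 0.0) for x in b_raw]
    beta = [x / sum(b_mass) for x in b_mass]
    first = h.index(1)
    last = T - 1 - h[::-1].index(1)

    def joint(hh, b, d):
        pr = beta[b] * phi ** (d - b) * ((1 - phi) if d < T - 1 else 1.0)
        for t in range(b, d + 1):
            pr *= ps[t] if hh[t] else (1 - ps[t])
        return pr

    num = sum(
        joint(h, b, d)
        for b in range(first + 1)
        for d in range(last, T)
    )
    p0 = sum(
        joint([0] * T, b, d) for b in range(T) for d in range(b, T)
    )
    return num / (1 - p0)


def all_histories(length):
    return [list(h) for h in itertools.product([0, 1], repeat=length) if any(h)]


# ---------------------------------------------------------------------------
# parameter counting and structures
# ---------------------------------------------------------------------------

class TestCountParameters:
    def test_table_structure_counts(self):
        structures = rd.table1_structures()
        expected = {"I1": 22, "I2": 24, "I3": 23, "I4": 23, "I5": 28,
                    "I6": 28, "I7": 27, "I8": 27, "I9": 32}
        for name, k in expected.items():
            assert rd.count_parameters(structures[name], 6, 5, 2) == k

    def test_constant_detection_block(self):
        s = rd.RDParameterStructure(
            "constant", "constant", p_factors=frozenset(), c_factors=frozenset()
        )
        assert rd.count_parameters(s, 6, 5) == 4


class TestPstar:
    def test_closed_forms(self):
        assert rd.pstar([0.5, 0.5]) == pytest.approx(0.75)
        assert rd.pstar([0.0] * 4) == 0.0
        assert rd.pstar([0.2] * 5) == pytest.approx(1 - 0.8**5)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_each_argument(self, ps):
        base = rd.pstar(ps)
        bumped = list(ps)
        bumped[0] = min(bumped[0] + 0.1, 1.0)
        assert rd.pstar(bumped) >= base - 1e-12


# ---------------------------------------------------------------------------
# within-session likelihood
# ---------------------------------------------------------------------------

class TestHugginsLoglik:
    def test_single_occasion_saturates(self):
        assert rd.huggins_session_loglik(
            [[1], [1], [1]], 0.3, 0.6
        ) == pytest.approx(0.0, abs=1e-12)

    def test_empty_session_no_information(self):
        assert rd.huggins_session_loglik([], 0.3, 0.6) == 0.0

    def test_conditional_probabilities_sum_to_one(self):
        p, c = 0.3, 0.6
        total = sum(huggins_prob(h, p, c) for h in all_histories(5))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        p, c = 0.3, 0.6
        hists = all_histories(5)[::3]
        impl = rd.huggins_session_loglik(hists, p, c)
        oracle = sum(np.log(huggins_prob(h, p, c)) for h in hists)
        assert impl == pytest.approx(oracle, abs=1e-10)

    def test_p_equals_c_is_classical_m0(self):
        """With no behavioural response the conditional likelihood must be
        the M0 conditional likelihood: iid Bernoulli(p) given >= 1 capture."""
        p = 0.37
        for h in all_histories(4):
            impl = rd.huggins_session_loglik([h], p, p)
            n1 = sum(h)
            m0 = n1 * np.log(p) + (4 - n1) * np.log(1 - p) - np.log(1 - (1 - p) ** 4)
            assert impl == pytest.approx(m0, abs=1e-12)


class TestHugginsAbundance:
    def test_closed_form(self):
        est = rd.huggins_abundance(3, 0.75)
        assert est.n_hat == pytest.approx(4.0)
        assert est.ci_low >= 3.0

    def test_perfect_detection_collapses(self):
        est = rd.huggins_abundance(7, 1.0)
        assert est.n_hat == 7.0
        assert est.se == 0.0
        assert (est.ci_low, est.ci_high) == (7.0, 7.0)

    def test_unstable_flag(self):
        assert rd.huggins_abundance(5, 0.001).unstable

    def test_lower_ci_never_below_count(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.integers(1, 40)
            ps = rng.uniform(0.05, 0.99)
            est = rd.huggins_abundance(int(m), ps, rng.uniform(0, 0.01))
            assert est.ci_low >= m - 1e-9
            assert est.ci_low <= est.n_hat <= est.ci_high + 1e-9


# ---------------------------------------------------------------------------
# open process
# ---------------------------------------------------------------------------

class TestEntryDistribution:
    def test_growth_balancing_survival_means_no_recruitment(self):
        beta, pen = rd.entry_distribution(0.7, 0.7, 5)
        assert np.allclose(beta, [1, 0, 0, 0, 0])
        assert pen == 0.0

    def test_stationary_arithmetic(self):
        beta, _ = rd.entry_distribution(0.5, 1.0, 3)
        assert np.allclose(beta, [0.5, 0.25, 0.25])

    def test_declining_population_floors_with_penalty(self):
        beta, pen = rd.entry_distribution(0.9, 0.5, 4)
        assert (beta >= 0).all()
        assert beta.sum() == pytest.approx(1.0)
        assert pen > 0

    def test_matches_generator_entry_fractions(self):
        """Realised entry fractions in a large simulation match beta."""
        phi, n1 = 0.6, 5000
        imm = (1.0 - phi) * n1  # stationary, lambda = 1
        truth = uniform_truth(n1=n1, phi=phi, imm_rate=imm, n_patches=2, p=0.5, c=0.5)
        roster = sd.simulate_population(truth, seed=21)
        entries = np.zeros(5)
        for ind in roster.individuals:
            entries[ind.entry_session - 1] += 1
        beta, _ = rd.entry_distribution(phi, 1.0, 5)
        assert np.allclose(entries / entries.sum(), beta, atol=0.01)


class TestOpenLoglik:
    def test_conditional_probabilities_sum_to_one(self):
        phi, lam, ps = 0.6, 1.1, [0.4] * 4
        total = sum(
            np.exp(rd.open_history_loglik([h], phi, lam, ps))
            for h in all_histories(4)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_enumeration_oracle(self):
        phi, lam, ps = 0.55, 0.95, [0.3, 0.5, 0.4, 0.6]
        hists = all_histories(4)
        impl = rd.open_history_loglik(hists, phi, lam, ps)
        oracle = sum(np.log(open_prob(h, phi, lam, ps)) for h in hists)
        assert impl == pytest.approx(oracle, abs=1e-8)

    def test_closed_population_limit(self):
        """phi -> 1, lambda = 1: everyone enters at session 1 and never
        leaves, so the model reduces to independent Bernoulli sessions
        conditioned on detection."""
        phi, ps = 1 - 1e-10, [0.35, 0.5, 0.25, 0.6]
        for h in all_histories(4):
            impl = rd.open_history_loglik([h], phi, 1.0, ps)
            bern = np.prod([ps[t] if h[t] else 1 - ps[t] for t in range(4)])
            cond = bern / (1 - np.prod([1 - q for q in ps]))
            assert impl == pytest.approx(np.log(cond), abs=1e-6)

    @given(
        st.floats(0.2, 0.9),
        st.floats(0.5, 1.5),
        st.lists(st.floats(0.1, 0.9), min_size=3, max_size=4),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_normalization_property(self, phi, lam, ps):
        total = sum(
            np.exp(rd.open_history_loglik([h], phi, lam, ps))
            for h in all_histories(len(ps))
        )
        # penalty-free region only: the floored entry distribution is not a
        # probability model for lam < phi, so normalisation holds when pen=0
        _, pen = rd.entry_distribution(phi, lam, len(ps))
        if pen == 0:
            assert total == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# joint fitting
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def simulated_fit():
    truth = uniform_truth(n1=40, phi=0.6, p=0.4, c=0.4)
    roster, data = sd.simulate_dataset(truth, seed=1)
    struct = rd.RDParameterStructure(
        "constant", "constant", p_factors=frozenset(), c_factors=frozenset()
    )
    return roster, data, rd.fit(data, struct, n_random_starts=2, seed=0)


class TestFit:
    def test_recovers_truth_roughly(self, simulated_fit):
        _, _, f = simulated_fit
        assert f.converged
        phi_hat = f.phi_table["estimate"].iloc[0]
        lam_hat = f.lambda_table["estimate"].iloc[0]
        assert abs(phi_hat - 0.6) < 0.1
        assert abs(lam_hat - 1.0) < 0.1

    def test_real_scale_ranges(self, simulated_fit):
        _, _, f = simulated_fit
        assert ((f.phi_table["estimate"] > 0) & (f.phi_table["estimate"] < 1)).all()
        assert (f.lambda_table["estimate"] > 0).all()
        for a in f.abundances:
            assert a.ci_low >= a.m_t1 - 1e-9
            assert a.ci_low <= a.n_hat <= a.ci_high + 1e-9

    def test_nested_structures_monotone_loglik(self):
        """I1 (constant) is nested in I3 (landscape phi) is nested in I7
        (patch phi): the maximised log-likelihood must not decrease."""
        truth = uniform_truth(n1=30, phi=0.6, p=0.5, c=0.5)
        _, data = sd.simulate_dataset(truth, seed=5)
        det = dict(p_factors=frozenset(), c_factors=frozenset())
        lls = [
            rd.fit(data, rd.RDParameterStructure(f, "constant", **det),
                   n_random_starts=2, seed=0).loglik
            for f in ("constant", "landscape", "patch")
        ]
        assert lls[0] <= lls[1] + 1e-6 <= lls[2] + 2e-6

    def test_fit_all_nine_structures_weights_sum_to_one(self):
        truth = uniform_truth(n1=25, phi=0.6, p=0.5, c=0.5)
        _, data = sd.simulate_dataset(truth, seed=9)
        tab, fits = rd.fit_all(data, n_random_starts=0, seed=0)
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert len(tab) == 9
        expected_k = {"I1": 22, "I2": 24, "I3": 23, "I4": 23, "I5": 28,
                      "I6": 28, "I7": 27, "I8": 27, "I9": 32}
        for _, row in tab.iterrows():
            assert row["K"] == expected_k[row["model"]]

    def test_model_average_within_range(self):
        truth = uniform_truth(n1=30, phi=0.6, p=0.5, c=0.5)
        _, data = sd.simulate_dataset(truth, seed=13)
        det = dict(p_factors=frozenset(), c_factors=frozenset())
        structures = {
            "I1": rd.RDParameterStructure("constant", "constant", **det, name="I1"),
            "I2": rd.RDParameterStructure("landscape", "landscape", **det, name="I2"),
            "I3": rd.RDParameterStructure("landscape", "constant", **det, name="I3"),
        }
        tab, fits = rd.fit_all(data, structures, n_random_starts=1, seed=0)
        avg = rd.model_average_demography(tab, fits)
        usable = [fits[m] for m in tab["model"]]
        for _, row in avg.abundance.iterrows():
            per_model = [
                a.n_hat for f in usable for a in f.abundances
                if a.patch_id == row["patch_id"] and a.session == row["session"]
            ]
            assert min(per_model) - 1e-9 <= row["n_hat"] <= max(per_model) + 1e-9
            assert row["ci_low"] >= row["m_t1"] - 1e-9
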