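"""Generator truth: reproducibility, accounting identity, and expectations."""

import numpy as np
import pytest

from patchdemog import synthetic_data as sd
from patchdemog import capture_data as cd

from conftest import uniform_truth


class TestDensitySimulation:
    def test_seeded_runs_reproducible(self):
        truth = sd.density_truth_study_default()
        a = sd.simulate_density(truth, seed=4)
        b = sd.simulate_density(truth, seed=4)
        c = sd.simulate_density(truth, seed=5)
        assert a == b
        assert a != c

    def test_degenerate_slope_is_constant_poisson(self):
        truth = sd.DensityTruth(
            components={
                50: sd.DensityComponentTruth("linear", a=np.log(6.0), b=0.0),
                30: sd.DensityComponentTruth("constant", a=-np.inf),
                10: sd.DensityComponentTruth("constant", a=-np.inf),
            },
            n_patches={50: 3000, 30: 2, 10: 2},
            area_range_ha={50: (1, 100), 30: (1, 100), 10: (1, 100)},
        )
        recs = [r for r in sd.simulate_density(truth, seed=2)
                if r.landscape_class == 50]
        counts = np.array([r.count for r in recs])
        assert counts.mean() == pytest.approx(6.0, abs=3 * np.sqrt(6.0 / len(counts)))
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.1)

    def test_structural_zero_landscape(self):
        truth = sd.density_truth_study_default()
        recs = sd.simulate_density(truth, seed=8)
        assert all(r.count == 0 for r in recs if r.landscape_class == 10)

    def test_landscape_means_match_study_values(self):
        """Default truth reproduces the surveyed mean densities (12.9 at 50%,
        8.9 at 30%) within Monte-Carlo error; checked at inflated patch
        numbers to shrink that error."""
        base = sd.density_truth_study_default()
        truth = sd.DensityTruth(
            components=base.components,
            n_patches={50: 2000, 30: 2000, 10: 2},
            area_range_ha=base.area_range_ha,
        )
        recs = sd.simulate_density(truth, seed=12)
        for ls, target, sdev in ((50, 12.9, 9.6), (30, 8.9, 5.5)):
            counts = [r.count for r in recs if r.landscape_class == ls]
            sem = sdev / np.sqrt(len(counts))
            assert np.mean(counts) == pytest.approx(target, abs=4 * sem)


class TestPopulationSimulation:
    def test_seeded_reproducibility(self):
        truth = uniform_truth(n1=20)
        r1 = sd.simulate_population(truth, seed=3)
        r2 = sd.simulate_population(truth, seed=3)
        r3 = sd.simulate_population(truth, seed=4)
        assert [i.individual_id for i in r1.individuals] == [
            i.individual_id for i in r2.individuals
        ]
        assert [(i.entry_session, i.exit_session) for i in r1.individuals] == [
            (i.entry_session, i.exit_session) for i in r2.individuals
        ]
        assert [(i.entry_session, i.exit_session) for i in r1.individuals] != [
            (i.entry_session, i.exit_session) for i in r3.individuals
        ]

    def test_closed_immortal_population_constant(self):
        truth = uniform_truth(n1=15, phi=0.999999, imm_rate=0.0, n_patches=2)
        # phi must be < 1 by type contract; use a value that cannot flip
        roster = sd.simulate_population(truth, seed=1)
        counts = roster.alive_counts()
        assert (counts == 15).all()

    def test_survival_expectation(self):
        n1, reps = 1000, 200
        survivors = [
            sd.simulate_population(
                uniform_truth(n1=n1, phi=0.5, imm_rate=0.0, n_patches=2), seed=s
            ).alive_counts()[:, 1].sum() / 2
            for s in range(reps)
        ]
        se = np.sqrt(n1 * 0.25) / np.sqrt(reps)
        assert np.mean(survivors) == pytest.approx(500, abs=4 * se)

    def test_immigrant_poisson_expectation(self):
        truth = uniform_truth(n1=5, phi=0.6, imm_rate=2.0, n_patches=2)
        totals = [
            sd.simulate_population(truth, seed=s).immigrant_arrivals().sum(axis=1)
            for s in range(200)
        ]
        # 4 intervals x rate 2 = 8 expected immigrants per patch
        assert np.mean(totals) == pytest.approx(8.0, abs=4 * np.sqrt(8 / 400))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_accounting_identity_exact(self, seed):
        """adults(t+1) = surviving adults(t) + matured young(t) + immigrants,
        exactly, for every patch and interval of every replicate."""
        truth = uniform_truth(
            n1=20, phi=0.55, imm_rate=3.0, young_rate=2.0, n_patches=4
        )
        roster = sd.simulate_population(truth, seed=seed)
        d = truth.design()
        idx = {pid: i for i, pid in enumerate(d.patch_ids)}
        T = d.n_primary
        adults = roster.alive_counts(adults_only=True)
        imm = roster.immigrant_arrivals()
        for i in range(d.n_patches):
            for t in range(1, T):
                surv_adults = sum(
                    1 for ind in roster.individuals
                    if idx[ind.patch_id] == i and ind.alive(t) and ind.alive(t + 1)
                    and ind.is_adult(t)
                )
                matured = sum(
                    1 for ind in roster.individuals
                    if idx[ind.patch_id] == i and ind.origin == "born"
                    and ind.entry_session == t and ind.alive(t + 1)
                )
                assert adults[i, t] == surv_adults + matured + imm[i, t - 1]

    def test_realized_growth_matches_stationary_truth(self):
        """imm_rate = (1-phi) * N1 keeps the adult population stationary:
        realized lambda averages 1 over replicates."""
        truth = uniform_truth(n1=200, phi=0.6, n_patches=2)
        lams = [
            np.nanmean(sd.simulate_population(truth, seed=s).realized_lambda())
            for s in range(60)
        ]
        assert np.mean(lams) == pytest.approx(1.0, abs=0.02)


class TestDetectionSimulation:
    def test_perfect_detection_includes_everyone(self):
        truth = uniform_truth(n1=30, phi=0.7, imm_rate=2.0, p=1.0, c=1.0,
                              n_patches=2)
        roster, data = sd.simulate_dataset(truth, seed=6)
        assert len(data) == len(roster.individuals)
        m = cd.mt1_per_session(data)
        assert np.array_equal(m.values, roster.alive_counts())

    def test_zero_detection_empty_dataset(self):
        truth = uniform_truth(n1=30, p=0.0, c=0.0, n_patches=2)
        _, data = sd.simulate_dataset(truth, seed=6)
        assert len(data) == 0

    def test_no_behavioural_response_matches_closed_form(self):
        """With p = c the per-session detection fraction is 1-(1-p)^K."""
        p, K = 0.3, 5
        truth = uniform_truth(n1=10_000, phi=0.9, imm_rate=0.0, p=p, c=p,
                              n_patches=1, T=2)
        roster, data = sd.simulate_dataset(truth, seed=14)
        m = cd.mt1_per_session(data)
        expected = 1 - (1 - p) ** K
        frac = m.loc["p1", 1] / 10_000
        assert frac == pytest.approx(expected, abs=4 * np.sqrt(expected / 10_000))

    def test_age_recorded_from_maturity(self):
        truth = uniform_truth(n1=5, phi=0.7, imm_rate=1.0, young_rate=3.0,
                              p=1.0, c=1.0, n_patches=2)
        roster, data = sd.simulate_dataset(truth, seed=2)
        born_entry = {
            i.individual_id: i.entry_session
            for i in roster.individuals if i.origin == "born"
        }
        saw_young = 0
        for rec in data.records:
            if rec.individual_id in born_entry:
                t0 = born_entry[rec.individual_id]
                ages = {a for a in rec.age[t0 - 1] if a is not None}
                assert ages == {cd.YOUNG}
                saw_young += 1
        assert saw_young > 0
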