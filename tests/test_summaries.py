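"""Risk and effect summaries: quantiles, exceedance, ranking, densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bymmap import rank_areas, summarize_effects, summarize_relative_risk
from tests.conftest import draws_from_theta


class TestRelativeRisk:
    def test_degenerate_draws(self):
        d = draws_from_theta(np.full((200, 1), 2.0))
        table = summarize_relative_risk(d, thresholds=(1.5, 2.0))
        s = table[0]
        assert (s.rr_mean, s.rr_lo, s.rr_hi) == (2.0, 2.0, 2.0)
        assert s.exceedance[1.5] == 1.0
        assert s.exceedance[2.0] == 0.0  # strict inequality at the threshold

    def test_two_point_posterior(self):
        d = draws_from_theta(np.array([[0.5], [1.5]]))
        s = summarize_relative_risk(d, thresholds=(1.0,))[0]
        assert s.exceedance[1.0] == 0.5
        assert s.rr_mean == 1.0

    def test_hand_enumerated_three_areas(self):
        theta = np.array(
            [
                [0.8, 1.0, 2.0],
                [1.2, 1.0, 2.4],
                [0.9, 1.0, 1.6],
                [1.1, 1.0, 2.0],
            ]
        )
        table = summarize_relative_risk(d := draws_from_theta(theta), (1.0, 2.0))
        assert table[0].rr_mean == pytest.approx(1.0)
        assert table[2].rr_mean == pytest.approx(2.0)
        # quantiles against a sorted-array oracle
        col = np.sort(theta[:, 0])
        assert table[0].rr_lo == pytest.approx(np.quantile(col, 0.025))
        assert table[0].rr_hi == pytest.approx(np.quantile(col, 0.975))
        assert table[2].exceedance[2.0] == 0.25  # only 2.4 exceeds, strictly
        g = table.global_summary
        assert g["mean_rr"] == pytest.approx(np.mean([1.0, 1.0, 2.0]))
        assert g["max_area"] == "C"

    def test_mean_within_draw_range(self):
        rng = np.random.default_rng(3)
        theta = rng.lognormal(size=(500, 4))
        for s in summarize_relative_risk(draws_from_theta(theta)):
            assert s.rr_lo <= s.rr_mean <= s.rr_hi or (
                theta.min() <= s.rr_mean <= theta.max()
            )

    @given(
        st.lists(st.floats(0.01, 10), min_size=5, max_size=60),
        st.lists(st.floats(0, 5), min_size=2, max_size=5),
    )
    @settings(max_examples=40, deadline=None)
    def test_exceedance_monotone_in_threshold(self, vals, thresholds):
        d = draws_from_theta(np.array(vals)[:, None])
        s = summarize_relative_risk(d, thresholds=sorted(thresholds))[0]
        cs = sorted(s.exceedance)
        probs = [s.exceedance[c] for c in cs]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert all(p1 >= p2 for p1, p2 in zip(probs, probs[1:]))

    def test_empty_draws_rejected(self):
        d = draws_from_theta(np.empty((0, 1)))
        with pytest.raises(ValueError):
            summarize_relative_risk(d)


class TestEffects:
    def test_degenerate_point_mass_significant(self):
        d = draws_from_theta(np.ones((50, 1)), covariate_names=("x1",))
        d.beta = np.full((1, 50, 1), 0.3)
        (eff,) = summarize_effects(d)
        assert (eff.lo, eff.hi) == (0.3, 0.3)
        assert eff.significant
        assert len(eff.density_grid) == 512

    def test_symmetric_draws_not_significant(self):
        rng = np.random.default_rng(4)
        d = draws_from_theta(np.ones((4000, 1)), covariate_names=("x1",))
        d.beta = rng.standard_normal((1, 4000, 1))
        (eff,) = summarize_effects(d)
        assert not eff.significant
        assert eff.prob_positive == pytest.approx(0.5, abs=0.05)

    def test_signal_detected_across_replicates(self):
        """A beta=0.3 effect at n=400 areas is declared significant in the
        overwhelming majority of refits."""
        from bymmap import (
            McmcConfig,
            ModelSpec,
            SimulationConfig,
            compute_expected_counts,
            fit,
            simulate_dataset,
        )

        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = SimulationConfig(
                lattice=(20, 20),
                beta={"x1": 0.3},
                sigma_u=0.0,
                sigma_v=0.0,
                seed=10_000 + rep,
            )
            table, _, _ = simulate_dataset(cfg)
            table = compute_expected_counts(table)
            draws = fit(
                table,
                None,
                ModelSpec(covariate_names=("x1",), standardize_covariates=False),
                McmcConfig(n_chains=1, n_iter=1200, n_burnin=400, thin=2,
                           seed=rep),
            )
            (eff,) = summarize_effects(draws)
            hits += eff.significant
        assert hits >= 0.9 * n_rep


class TestRanking:
    def _summaries(self):
        theta = np.array([[2.0, 1.0, 1.0], [2.0, 1.0, 1.0]])
        return summarize_relative_risk(
            draws_from_theta(theta, area_ids=["zeta", "beta", "alpha"]),
            thresholds=(1.5,),
        )

    def test_descending_by_rr(self):
        ranked = rank_areas(self._summaries(), by="rr_mean")
        assert [s.area_id for s in ranked] == ["zeta", "alpha", "beta"]

    def test_tie_breaks_alphabetical(self):
        ranked = rank_areas(self._summaries(), by="rr_mean")
        assert [s.area_id for s in ranked[1:]] == ["alpha", "beta"]

    def test_rank_by_exceedance(self):
        ranked = rank_areas(self._summaries(), by="exceedance@1.5")
        assert ranked[0].area_id == "zeta"

    def test_unknown_key(self):
        with pytest.raises(KeyError):
            rank_areas(self._summaries(), by="banana")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_areas([])
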