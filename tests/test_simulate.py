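"""Synthetic panels: ground-truth scores, label noise, ranking recovery."""

import numpy as np
import pytest

from promethee2 import (
    DomainError,
    PanelSpec,
    aggregate_panel,
    recovery_experiment,
    simulate_expert_panel,
    simulate_true_scores,
)


class TestTrueScores:
    def test_two_alternatives_hit_the_scale_endpoints(self):
        spec = PanelSpec(n_alternatives=2, n_criteria=1, n_experts=1,
                         latent_utilities=(1.0, 0.0), criterion_loadings=(1.0,),
                         noise=0.0)
        dm, truth = simulate_true_scores(spec)
        assert list(dm.scores[:, 0]) == [1.000, 0.000]
        assert truth == {"A1": 1, "A2": 2}

    def test_zero_loading_gives_a_degenerate_column(self):
        spec = PanelSpec(n_alternatives=3, n_criteria=2, n_experts=1,
                         criterion_loadings=(1.0, 0.0), noise=0.0)
        dm, _ = simulate_true_scores(spec)
        col = dm.scores[:, 1]
        assert np.all(col == col[0])

    def test_equally_spaced_utilities_snap_to_nearest_scale_values(self):
        # brute-force nearest over {0, .25, .333, .666, 1}: 0.75 and 0.5 both
        # land on 0.666, 0.25 on 0.250, endpoints exact
        spec = PanelSpec(n_alternatives=5, n_criteria=1, n_experts=1,
                         latent_utilities=(1.0, 0.75, 0.5, 0.25, 0.0),
                         criterion_loadings=(1.0,), noise=0.0)
        dm, _ = simulate_true_scores(spec)
        assert list(dm.scores[:, 0]) == [1.000, 0.666, 0.666, 0.250, 0.000]

    def test_tied_utilities_share_a_ground_truth_rank(self):
        spec = PanelSpec(n_alternatives=3, n_criteria=1, n_experts=1,
                         latent_utilities=(0.8, 0.8, 0.1), noise=0.0)
        _, truth = simulate_true_scores(spec)
        assert truth == {"A1": 1, "A2": 1, "A3": 3}

    def test_non_finite_utilities_rejected(self):
        with pytest.raises(DomainError):
            PanelSpec(n_alternatives=2, n_criteria=1, n_experts=1,
                      latent_utilities=(np.inf, 0.0))

    def test_invalid_noise_rejected(self):
        with pytest.raises(DomainError):
            PanelSpec(noise=1.5)


class TestExpertPanel:
    def test_noiseless_panel_is_unanimous_and_recovers_the_matrix(self):
        spec = PanelSpec(n_alternatives=4, n_criteria=2, n_experts=10, noise=0.0)
        panel = simulate_expert_panel(spec)
        true_dm, _ = simulate_true_scores(spec)
        per_cell = panel.responses.groupby(["alternative", "criterion"])["label"].nunique()
        assert (per_cell == 1).all()
        agg = aggregate_panel(panel, method="mode", criteria=list(true_dm.criteria))
        assert np.array_equal(agg.scores, true_dm.scores)

    def test_same_seed_reproduces_the_panel(self):
        spec = PanelSpec(n_alternatives=5, n_criteria=2, n_experts=8,
                         noise=0.4, seed=123)
        p1 = simulate_expert_panel(spec)
        p2 = simulate_expert_panel(spec)
        assert p1.responses.equals(p2.responses)

    def test_different_seeds_differ(self):
        s1 = PanelSpec(n_alternatives=5, n_criteria=2, n_experts=8, noise=0.4, seed=1)
        s2 = PanelSpec(n_alternatives=5, n_criteria=2, n_experts=8, noise=0.4, seed=2)
        assert not simulate_expert_panel(s1).responses.equals(
            simulate_expert_panel(s2).responses
        )

    def test_full_noise_concentrates_on_adjacent_labels(self):
        """With noise 1 every response slips one step, so a middle label's
        mass splits ~50/50 between its two neighbours and the true label
        disappears; at the scale ends the clamped step stays put."""
        spec = PanelSpec(n_alternatives=3, n_criteria=1, n_experts=2000,
                         latent_utilities=(1.0, 0.5, 0.0),
                         criterion_loadings=(1.0,), noise=1.0, seed=7)
        panel = simulate_expert_panel(spec)
        # true labels: A1 High, A2 Average (0.5 snaps to 0.666), A3 Null
        counts = (
            panel.responses.groupby(["alternative", "label"]).size().unstack(fill_value=0)
            / spec.n_experts
        )
        mid = counts.loc["A2"]
        assert mid.get("Average", 0) == 0
        assert mid["High"] == pytest.approx(0.5, abs=0.05)
        assert mid["Low"] == pytest.approx(0.5, abs=0.05)
        top = counts.loc["A1"]  # clamp: up-steps stay at High
        assert top["High"] == pytest.approx(0.5, abs=0.05)
        assert top["Average"] == pytest.approx(0.5, abs=0.05)


class TestRecovery:
    def test_noiseless_recovery_is_perfect(self):
        spec = PanelSpec(n_alternatives=4, n_criteria=3, n_experts=10,
                         noise=0.0, seed=11)
        res = recovery_experiment(spec, replicates=5)
        assert res.recovery_fraction == 1.0
        # m=4 evenly spaced utilities snap injectively (1, .666, .333, 0),
        # so the latent order is fully resolved and tau is exactly 1
        assert res.mean_tau == pytest.approx(1.0)

    def test_noiseless_recovery_with_tied_utilities(self):
        spec = PanelSpec(n_alternatives=3, n_criteria=2, n_experts=5,
                         latent_utilities=(0.9, 0.9, 0.0), noise=0.0)
        res = recovery_experiment(spec, replicates=3)
        assert res.recovery_fraction == 1.0

    def test_monte_carlo_at_study_conditions(self):
        """Frozen from a first brute-force run: 5 alternatives, 3 criteria,
        72 experts, adjacent-label noise 0.3, 200 replicates, seed 1. The
        modal label over 72 experts is a strong estimator, so recovery stays
        perfect; tau is capped at 9/sqrt(90) because the scale merges the two
        middle utilities."""
        spec = PanelSpec(n_alternatives=5, n_criteria=3, n_experts=72,
                         noise=0.3, seed=1)
        res = recovery_experiment(spec, replicates=200)
        assert res.recovery_fraction == pytest.approx(1.0)
        assert res.mean_tau == pytest.approx(0.948683, abs=1e-6)

    def test_mean_tau_degrades_monotonically_with_noise(self):
        taus = []
        for noise in (0.0, 0.5, 0.8):
            spec = PanelSpec(n_alternatives=5, n_criteria=3, n_experts=72,
                             noise=noise, seed=1)
            taus.append(recovery_experiment(spec, replicates=50).mean_tau)
        for lo, hi in zip(taus[1:], taus[:-1]):
            assert lo <= hi + 0.05  # Monte-Carlo slack

    def test_recovery_is_seed_deterministic(self):
        spec = PanelSpec(n_alternatives=5, n_criteria=2, n_experts=12,
                         noise=0.6, seed=42)
        r1 = recovery_experiment(spec, replicates=20)
        r2 = recovery_experiment(spec, replicates=20)
        assert r1.recovery_fraction == r2.recovery_fraction
        assert r1.taus == r2.taus

    def test_zero_replicates_rejected(self):
        with pytest.raises(DomainError):
            recovery_experiment(PanelSpec(), replicates=0)
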