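import numpy as np
import pandas as pd
import pytest

from vogquant.synth import (
    ConstructModel,
    FieldParams,
    RLUCondition,
    assign_labels,
    simulate_field,
    simulate_flow_events,
    simulate_rlu_table,
)


def small_params(**kwargs):
    defaults = dict(width_px=128, height_px=128, n_z=3, seed=0)
    defaults.update(kwargs)
    return FieldParams(**defaults)


class TestAssignLabels:
    def test_gag_anchored_copy_numbers_exceed_packaging_floor(self):
        c = ConstructModel(name="optiGag", channel="green")
        labels = assign_labels(5000, [c], seed=0)
        assert labels["copies_green"].mean() >= 1500

    def test_pol_to_gag_ratio(self):
        c = ConstructModel(
            name="psPAX2", channel="green", in_label_mode="pol_anchored",
            gag_copy_mean=2000.0, gag_copy_cv=0.0,
        )
        labels = assign_labels(100, [c], seed=0)
        assert (labels["copies_green"] == 100).all()  # 2000 / 20

    def test_certain_incorporation_labels_everything(self):
        cons = [
            ConstructModel(name="a", channel="green", incorporation_prob=1.0),
            ConstructModel(name="b", channel="red", incorporation_prob=1.0),
        ]
        labels = assign_labels(500, cons, seed=1)
        assert ((labels["copies_green"] > 0) & (labels["copies_red"] > 0)).all()

    @pytest.mark.parametrize("p", [0.25, 0.5, 0.7, 0.95])
    def test_marginals_match_closed_form(self, p):
        n = 10_000
        cons = [
            ConstructModel(name="a", channel="green", incorporation_prob=p),
            ConstructModel(name="b", channel="red", incorporation_prob=p),
        ]
        labels = assign_labels(n, cons, seed=2)
        either = ((labels["copies_green"] > 0) | (labels["copies_red"] > 0)).mean()
        expected = 1 - (1 - p) ** 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(either - expected) < 3 * se

    def test_complement_rule_at_070(self):
        # two independent constructs at 0.7: P(>=1 label) = 1 - 0.3^2 = 0.91
        cons = [
            ConstructModel(name="a", channel="green", incorporation_prob=0.7),
            ConstructModel(name="b", channel="red", incorporation_prob=0.7),
        ]
        labels = assign_labels(10_000, cons, seed=3)
        either = ((labels["copies_green"] > 0) | (labels["copies_red"] > 0)).mean()
        assert abs(either - 0.91) < 3 * np.sqrt(0.91 * 0.09 / 10_000)

    def test_duplicate_channels_rejected(self):
        cons = [ConstructModel(name="a", channel="green"), ConstructModel(name="b", channel="green")]
        with pytest.raises(ValueError):
            assign_labels(10, cons)


class TestSimulateField:
    def test_empty_field(self):
        params = small_params(particle_density=0.0)
        field, truth = simulate_field(params, [ConstructModel(name="c", channel="green")])
        assert len(truth) == 0
        # image is background plus noise only
        assert field.data.mean() == pytest.approx(params.background_level, rel=0.05)

    def test_particle_count_matches_poisson_mean(self):
        params = small_params(particle_density=0.05)
        lam = params.particle_density * params.area_um2
        counts = [
            len(simulate_field(small_params(particle_density=0.05, seed=s),
                               [ConstructModel(name="c", channel="green")])[1])
            for s in range(100)
        ]
        se = np.sqrt(lam / 100)
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_ground_truth_consistency(self, standard_field):
        params, field, truth = standard_field
        assert (truth.x_um >= 0).all() and (truth.x_um <= field.width_um).all()
        assert (truth.y_um >= 0).all() and (truth.y_um <= field.height_um).all()
        labeled = truth.copies_green > 0
        assert (truth.loc[labeled, "photons_green"] > 0).all()
        assert (truth.loc[~labeled, "photons_green"] == 0).all()
        # only mature particles take up the immunostain
        assert (truth.loc[truth.mature, "photons_farred"] > 0).all()
        assert (truth.loc[~truth.mature, "photons_farred"] == 0).all()

    def test_rendered_flux_matches_photons(self):
        # noise-free rendering: integrated image equals expected photons
        # (stack deep enough to hold the axial PSF support)
        params = small_params(n_z=9, particle_density=0.002, background_level=0.0,
                              read_noise_sd=0.0, seed=7)
        field, truth = simulate_field(params, [ConstructModel(name="c", channel="green")])
        assert len(truth) > 0
        total_photons = truth["photons_green"].sum()
        rendered = float(field.channel("green").sum())
        # Poisson shot noise on the total plus kernel-tail truncation
        assert rendered == pytest.approx(total_photons, rel=0.05)

    def test_seed_reproducibility(self):
        cons = [ConstructModel(name="c", channel="green")]
        f1, t1 = simulate_field(small_params(seed=9), cons)
        f2, t2 = simulate_field(small_params(seed=9), cons)
        np.testing.assert_array_equal(f1.data, f2.data)
        pd.testing.assert_frame_equal(t1, t2)
        f3, _ = simulate_field(small_params(seed=10), cons)
        assert not np.array_equal(f1.data, f3.data)

    def test_density_cap_refused(self):
        params = small_params(particle_density=200.0)
        with pytest.raises(ValueError, match="cap"):
            simulate_field(params, [ConstructModel(name="c", channel="green")])

    def test_dual_label_fraction_overrides_marginals(self):
        cons = [
            ConstructModel(name="a", channel="green"),
            ConstructModel(name="b", channel="red"),
        ]
        params = small_params(particle_density=0.5, seed=4)
        _, truth = simulate_field(params, cons, dual_label_fraction=0.85)
        both = (truth.copies_green > 0) & (truth.copies_red > 0)
        neither = (truth.copies_green == 0) & (truth.copies_red == 0)
        assert (both | neither).all()
        n = len(truth)
        assert abs(both.mean() - 0.85) < 3 * np.sqrt(0.85 * 0.15 / n)


class TestSimulateFlowEvents:
    def test_no_infection_means_all_negative(self):
        ev = simulate_flow_events(2000, 0.0, seed=0)
        assert not ev.true_infected.any()

    def test_mixture_midpoint_splits_evenly(self):
        ev = simulate_flow_events(20_000, 0.5, separation=4.0, seed=1)
        neg_mean, sd = 1.0, 0.4
        midpoint = 10 ** (neg_mean + 2.0 * sd)  # halfway between component means
        frac = (ev.fluor > midpoint).mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 20_000) + 0.01

    def test_doublets_have_inflated_width(self):
        ev = simulate_flow_events(20_000, 0.3, seed=2, doublet_fraction=0.1)
        ratio = ev["FSC-W"] / ev["FSC-H"]
        assert ratio[ev.is_doublet].median() > 1.8
        assert abs(ratio[~ev.is_doublet].median() - 1.0) < 0.05

    def test_condition_labels_support_infection_designs(self):
        conditions = ["negative", "unlabeled_IN", "sfGFP_IN", "mNeonG_IN", "mRuby3_IN"]
        tables = [
            simulate_flow_events(100, 0.0 if c == "negative" else 0.7, seed=i, condition=c)
            for i, c in enumerate(conditions)
        ]
        combined = pd.concat(tables)
        assert set(combined.condition) == set(conditions)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_flow_events(0, 0.5)
        with pytest.raises(ValueError):
            simulate_flow_events(10, 1.5)


class TestSimulateRLU:
    def test_zero_noise_is_exact(self):
        conds = [RLUCondition("optiGag", rlu_per_p24=1e4, p24_ng=2.0)]
        table = simulate_rlu_table(conds, seed=0, noise_cv=0.0, background_rlu=500.0)
        assert (table.rlu == 500.0 + 2e4).all()

    def test_rtg_condition_sits_at_background(self):
        conds = [
            RLUCondition("RTG", rlu_per_p24=0.0, p24_ng=2.0),
            RLUCondition("optiGag", rlu_per_p24=1e4, p24_ng=2.0),
        ]
        table = simulate_rlu_table(conds, seed=1, n_replicates=50, background_rlu=500.0)
        rtg = table[table.condition == "RTG"].rlu
        assert rtg.mean() == pytest.approx(500.0, rel=0.15)
        assert table[table.condition == "optiGag"].rlu.mean() > 10 * rtg.mean()

    def test_signal_linear_in_p24(self):
        conds = [
            RLUCondition("x1", rlu_per_p24=1e4, p24_ng=1.0),
            RLUCondition("x2", rlu_per_p24=1e4, p24_ng=2.0),
        ]
        table = simulate_rlu_table(conds, seed=2, n_replicates=200, background_rlu=500.0)
        means = table.groupby("condition").rlu.mean()
        assert (means["x2"] - 500) == pytest.approx(2 * (means["x1"] - 500), rel=0.1)
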