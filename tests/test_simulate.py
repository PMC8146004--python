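"""Droplet partitioning simulator: Poisson occupancy, noise, determinism."""

import numpy as np
import pytest
from scipy import stats

from ddfetal import (
    MaternalContext,
    SimulationParams,
    builtin_registry,
    channel_lambdas,
    expected_counts,
    simulate_ntc,
    simulate_well,
)
from ddfetal.assays import Channel
from ddfetal.scenarios import SCENARIOS, params_for_scenario


def _params(cc_ctx, **kw):
    defaults = dict(ctx=cc_ctx, fetal_genotype="C/c", seed=11)
    defaults.update(kw)
    return SimulationParams(**defaults)


class TestParams:
    def test_non_mendelian_fetus_rejected(self, registry):
        ctx = MaternalContext(registry["RHCE_rs676785"], "c/c")
        with pytest.raises(ValueError, match="Mendelian"):
            SimulationParams(ctx=ctx, fetal_genotype="C/C")

    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_droplets", 0),
            ("maternal_genomes_per_droplet", 0.0),
            ("fetal_fraction_true", -0.1),
            ("rain_prob", 1.5),
            ("false_positive_rate", -1e-3),
            ("detection_dropout", 2.0),
        ],
    )
    def test_invalid_params_rejected(self, cc_ctx, field, value):
        with pytest.raises(ValueError):
            _params(cc_ctx, **{field: value})

    def test_channel_lambdas_snp(self, cc_ctx):
        # mother c/c, fetus C/c: FAM (c) sees 2 + f maternal-allele copies,
        # HEX (C) sees f fetal copies, all times lambda_m
        p = _params(cc_ctx, maternal_genomes_per_droplet=0.04, fetal_fraction_true=0.1)
        lams = channel_lambdas(p)
        assert lams[Channel.FAM] == pytest.approx(0.04 * 2.1)
        assert lams[Channel.HEX] == pytest.approx(0.04 * 0.1)

    def test_channel_lambdas_total_dna_control(self, rhd_ctx):
        # beta-globin counts 2 copies from every genome, fetal included
        p = SimulationParams(
            ctx=rhd_ctx, fetal_genotype="RHD+/RHD-", seed=0,
            maternal_genomes_per_droplet=0.05, fetal_fraction_true=0.2,
        )
        lams = channel_lambdas(p)
        assert lams[Channel.HEX] == pytest.approx(2 * 0.05 * 1.2)
        assert lams[Channel.FAM] == pytest.approx(0.05 * 0.2)


class TestSimulateWell:
    def test_fixed_seed_reproducible(self, cc_ctx):
        p = _params(cc_ctx)
        a, b = simulate_well(p), simulate_well(p)
        np.testing.assert_array_equal(a.ch1_amplitude, b.ch1_amplitude)
        np.testing.assert_array_equal(a.ch2_amplitude, b.ch2_amplitude)
        np.testing.assert_array_equal(a.ch1_molecules, b.ch1_molecules)

    def test_no_fetal_dna_no_fetus_specific_positives(self, cc_ctx):
        p = _params(cc_ctx, fetal_genotype="c/c", fetal_fraction_true=0.0,
                    false_positive_rate=0.0)
        table = simulate_well(p)
        assert int(table.ch2_latent_pos.sum()) == 0  # HEX = C channel

    def test_latent_classes_partition_droplets(self, positive_well):
        _, table = positive_well
        p1, p2 = table.ch1_latent_pos, table.ch2_latent_pos
        counts = [
            int((p1 & p2).sum()), int((p1 & ~p2).sum()),
            int((~p1 & p2).sum()), int((~p1 & ~p2).sum()),
        ]
        assert sum(counts) == table.n_droplets

    def test_dropout_suppresses_positives(self, cc_ctx):
        p = _params(cc_ctx, detection_dropout=1.0, false_positive_rate=0.0)
        table = simulate_well(p)
        assert int(table.ch1_latent_pos.sum()) == 0
        assert int(table.ch2_latent_pos.sum()) == 0


class TestExpectedCounts:
    def test_zero_load_zero_noise(self, cc_ctx):
        p = _params(cc_ctx, fetal_genotype="c/c", fetal_fraction_true=0.0,
                    false_positive_rate=0.0)
        assert expected_counts(p)["HEX"] == 0.0

    def test_noise_only_channel(self, cc_ctx):
        # expected NTC-like false positives: n * fp
        p = _params(cc_ctx, fetal_genotype="c/c", fetal_fraction_true=0.0,
                    n_droplets=15_000, false_positive_rate=1.5e-4)
        assert expected_counts(p)["HEX"] == pytest.approx(2.25)

    def test_closed_form_value(self, cc_ctx):
        # occupancy 0.05 over 10,000 droplets -> 10,000*(1-e^-0.05)
        p = _params(cc_ctx, fetal_genotype="c/c", fetal_fraction_true=0.0,
                    maternal_genomes_per_droplet=0.025, n_droplets=10_000,
                    false_positive_rate=0.0)
        assert expected_counts(p)["FAM"] == pytest.approx(487.7058, abs=0.01)

    def test_monotone_in_fetal_fraction(self, cc_ctx):
        values = [
            expected_counts(_params(cc_ctx, fetal_fraction_true=f))["HEX"]
            for f in (0.0, 0.05, 0.1, 0.2, 0.3)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_simulation_matches_expectation(self, cc_ctx):
        """Latent positive counts fall in the 99.9% binomial band of the
        closed form (single 50k-droplet well per channel)."""
        p = _params(cc_ctx, n_droplets=50_000, seed=99)
        table = simulate_well(p)
        exp = expected_counts(p)
        for ch, latent in (("FAM", table.ch1_latent_pos), ("HEX", table.ch2_latent_pos)):
            lo, hi = stats.binom.interval(0.999, p.n_droplets, exp[ch] / p.n_droplets)
            assert lo <= int(latent.sum()) <= hi


class TestSimulateNtc:
    def test_no_noise_no_positives(self):
        table = simulate_ntc(n_droplets=5000, false_positive_rate=0.0, seed=1)
        assert int(table.ch1_latent_pos.sum()) == 0
        assert int(table.ch2_latent_pos.sum()) == 0

    def test_reproducible(self):
        a = simulate_ntc(seed=5)
        b = simulate_ntc(seed=5)
        np.testing.assert_array_equal(a.ch1_amplitude, b.ch1_amplitude)

    def test_false_positives_stay_below_qc_limit(self):
        """At the realistic noise rate a clean NTC shows 0-4 positives per
        channel (20 seeds, 15,646 droplets)."""
        for seed in range(20):
            table = simulate_ntc(n_droplets=15_646, false_positive_rate=1.5e-5, seed=seed)
            assert int(table.ch1_latent_pos.sum()) <= 4
            assert int(table.ch2_latent_pos.sum()) <= 4

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            simulate_ntc(n_droplets=0)
        with pytest.raises(ValueError):
            simulate_ntc(false_positive_rate=1.5)


def test_scenario_inversion_hits_target_counts():
    """params_for_scenario solves lambda_m so the maternal channel's
    expected positives equal the requested target, for every scenario."""
    from ddfetal.assays import maternal_channel

    for scen in SCENARIOS:
        p = params_for_scenario(scen, fetal_fraction=0.12, maternal_positives=800,
                                false_positive_rate=0.0)
        exp = expected_counts(p)
        assert exp[maternal_channel(p.ctx).value] == pytest.approx(800, rel=1e-9)
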