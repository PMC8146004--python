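"""Amplitude thresholding and droplet tallying."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddfetal import ChannelCutoffs, ClassifiedCounts, DropletTable, auto_threshold, classify
from ddfetal.classify import InsufficientDataError, auto_cutoffs


def _two_means_oracle(x):
    """Brute-force 1-D two-means over every ordered split point."""
    x = np.sort(np.asarray(x, float))
    best = (np.inf, None)
    for k in range(1, len(x)):
        left, right = x[:k], x[k:]
        ss = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if ss < best[0]:
            best = (ss, 0.5 * (left.mean() + right.mean()))
    return best[1]


class TestAutoThreshold:
    def test_two_clouds_bimodal_midpoint(self):
        rng = np.random.default_rng(42)
        amps = np.concatenate([
            rng.normal(1000, 150, 9000), rng.normal(8000, 400, 1000)
        ])
        result = auto_threshold(amps)
        assert result.bimodal
        assert result.cutoff == pytest.approx(4500, abs=150)

    def test_matches_brute_force_two_means(self):
        rng = np.random.default_rng(3)
        amps = np.concatenate([rng.normal(1000, 150, 400), rng.normal(8000, 400, 100)])
        result = auto_threshold(amps)
        assert result.bimodal
        assert result.cutoff == pytest.approx(_two_means_oracle(amps), abs=1e-9)

    def test_single_cloud_unimodal_fallback_above_all(self):
        rng = np.random.default_rng(12)
        amps = rng.normal(1000, 150, 15_000)
        result = auto_threshold(amps)
        assert not result.bimodal
        assert result.cutoff > amps.max()

    def test_constant_amplitudes_degenerate(self):
        result = auto_threshold(np.full(500, 1000.0))
        assert not result.bimodal
        assert result.cutoff == pytest.approx(1000.0)

    def test_too_few_droplets(self):
        with pytest.raises(InsufficientDataError):
            auto_threshold(np.arange(50, dtype=float))


SIX_DROPLETS = DropletTable(
    ch1_amplitude=np.array([500, 9000, 950, 8800, 400, 700], float),
    ch2_amplitude=np.array([900, 800, 8500, 9100, 300, 600], float),
    well_id="six",
)


class TestClassify:
    def test_six_droplet_example(self):
        counts = classify(SIX_DROPLETS, ChannelCutoffs(4500, 4500))
        assert (counts.n_ch1_pos, counts.n_ch2_pos) == (2, 2)
        assert counts.n_double_pos == 1
        assert counts.n_neg == 3
        assert counts.n_total == 6

    def test_all_below_cutoffs(self):
        counts = classify(SIX_DROPLETS, ChannelCutoffs(10_000, 10_000))
        assert counts.n_neg == counts.n_total == 6
        assert counts.n_ch1_pos == counts.n_ch2_pos == 0

    def test_tie_classifies_negative(self):
        table = DropletTable(np.array([4500.0]), np.array([4501.0]))
        counts = classify(table, ChannelCutoffs(4500, 4500))
        assert counts.n_ch1_pos == 0 and counts.n_ch2_pos == 1

    def test_matches_per_droplet_loop(self):
        rng = np.random.default_rng(8)
        table = DropletTable(rng.uniform(0, 10_000, 1000), rng.uniform(0, 10_000, 1000))
        cutoffs = ChannelCutoffs(4200.0, 5100.0)
        counts = classify(table, cutoffs)
        n1 = n2 = nd = nn = 0
        for a1, a2 in zip(table.ch1_amplitude, table.ch2_amplitude):
            p1, p2 = a1 > cutoffs.ch1_cutoff, a2 > cutoffs.ch2_cutoff
            n1 += p1
            n2 += p2
            nd += p1 and p2
            nn += not p1 and not p2
        assert (counts.n_ch1_pos, counts.n_ch2_pos, counts.n_double_pos, counts.n_neg) == (
            n1, n2, nd, nn,
        )

    @given(st.integers(0, 2**31 - 1), st.floats(100, 9000), st.floats(100, 9000))
    def test_conservation_and_order_invariance(self, seed, cut1, cut2):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 400))
        table = DropletTable(rng.uniform(0, 10_000, n), rng.uniform(0, 10_000, n), "h")
        cutoffs = ChannelCutoffs(cut1, cut2)
        counts = classify(table, cutoffs)
        assert counts.n_ch1_pos + counts.n_ch2_pos - counts.n_double_pos + counts.n_neg == n
        perm = rng.permutation(n)
        shuffled = DropletTable(table.ch1_amplitude[perm], table.ch2_amplitude[perm], "h")
        again = classify(shuffled, cutoffs)
        assert (again.n_ch1_pos, again.n_ch2_pos, again.n_double_pos) == (
            counts.n_ch1_pos, counts.n_ch2_pos, counts.n_double_pos,
        )

    @given(st.integers(0, 2**31 - 1))
    def test_raising_cutoff_never_gains_positives(self, seed):
        rng = np.random.default_rng(seed)
        table = DropletTable(rng.uniform(0, 10_000, 300), rng.uniform(0, 10_000, 300))
        lo, hi = sorted(rng.uniform(100, 9900, 2))
        n_lo = classify(table, ChannelCutoffs(lo, 5000)).n_ch1_pos
        n_hi = classify(table, ChannelCutoffs(hi, 5000)).n_ch1_pos
        assert n_hi <= n_lo


class TestClassifiedCounts:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError, match="conservation"):
            ClassifiedCounts("w", n_total=100, n_ch1_pos=10, n_ch2_pos=10,
                             n_double_pos=0, n_neg=90)

    def test_double_pos_bounded(self):
        with pytest.raises(ValueError, match="n_double_pos"):
            ClassifiedCounts("w", n_total=10, n_ch1_pos=2, n_ch2_pos=3,
                             n_double_pos=3, n_neg=8)


def test_auto_cutoffs_on_simulated_well(positive_well):
    """Auto thresholds on a realistic well recover the latent classes of
    both channels up to rain droplets, which straddle the cut-off line."""
    params, table = positive_well
    cutoffs, diag = auto_cutoffs(table)
    assert cutoffs.ch1_method == cutoffs.ch2_method == "auto"
    counts = classify(table, cutoffs)
    # maternal channel is dense enough to split; fetal channel may be
    # unimodal but the fallback line still lies below the positive cloud
    assert diag["FAM"].bimodal
    for tally, latent in (
        (counts.n_ch1_pos, int(table.ch1_latent_pos.sum())),
        (counts.n_ch2_pos, int(table.ch2_latent_pos.sum())),
    ):
        # ~1% of positives are rain, roughly half landing below the line
        assert abs(tally - latent) <= max(3, round(0.015 * latent))
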