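"""Dye-swap averaging, background fitting, probe selection, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from compchip import (
    BackgroundModel,
    aggregate_to_locus,
    fit_background_normal,
    geometric_average_dyeswap,
    normalize_to_background,
    select_signal_probes,
)


class TestGeometricAverage:
    def test_examples(self):
        assert geometric_average_dyeswap(4.0, 1.0) == pytest.approx(2.0)
        assert geometric_average_dyeswap(3.7, 3.7) == pytest.approx(3.7)

    def test_matches_log_mean_oracle(self):
        rng = np.random.default_rng(0)
        a, b = rng.lognormal(0, 1, 100), rng.lognormal(0, 1, 100)
        oracle = np.exp((np.log(a) + np.log(b)) / 2)
        np.testing.assert_allclose(geometric_average_dyeswap(a, b), oracle,
                                   atol=1e-12, rtol=1e-12)

    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.01, 100))
    def test_symmetric_and_scale_equivariant(self, a, b, c):
        assert geometric_average_dyeswap(a, b) == pytest.approx(
            geometric_average_dyeswap(b, a))
        assert geometric_average_dyeswap(a * c, b * c) == pytest.approx(
            c * geometric_average_dyeswap(a, b), rel=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_average_dyeswap(0.0, 1.0)
        with pytest.raises(ValueError):
            geometric_average_dyeswap(2.0, -1.0)


class TestBackgroundFit:
    def test_pure_normal(self):
        rng = np.random.default_rng(0)
        bg = fit_background_normal(rng.normal(0.1, 0.3, 100_000))
        assert bg.mu_log2 == pytest.approx(0.1, rel=0.02)
        assert bg.sigma_log2 == pytest.approx(0.3, rel=0.02)

    def test_contaminated_mixture(self):
        """Background recovered despite a 5% signal component at -3."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(0, 0.25, 9500),
                                rng.normal(-3, 0.25, 500)])
            bg = fit_background_normal(x)
            assert abs(bg.mu_log2) < 0.02
            assert bg.sigma_log2 == pytest.approx(0.25, rel=0.05)

    def test_right_signal_orientation_mirrors(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.25, 9500), rng.normal(3, 0.25, 500)])
        bg = fit_background_normal(x, signal_side="right")
        assert abs(bg.mu_log2) < 0.02

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_background_normal(np.ones(500))
        with pytest.raises(ValueError):
            fit_background_normal(np.zeros(10))  # too few values


class TestSelectSignalProbes:
    def test_null_selects_almost_nothing(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.3, 10_000)
        bg = fit_background_normal(x)
        sel = select_signal_probes(x, bg, fdr=0.05)
        assert len(sel) / len(x) <= 0.01

    def test_mixture_recall_and_fdr(self):
        """5% signal at -4 sigma: recall >= 0.9, empirical FDR <= 0.10."""
        recalls, fdrs = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n_sig = 500
            bg_vals = rng.normal(0, 0.3, 9500)
            sig_vals = rng.normal(-4 * 0.3, 0.3, n_sig)
            x = np.concatenate([bg_vals, sig_vals])
            is_sig = np.zeros(len(x), dtype=bool)
            is_sig[-n_sig:] = True
            bg = fit_background_normal(x)
            sel = select_signal_probes(x, bg, fdr=0.05)
            hit = is_sig[sel]
            recalls.append(hit.sum() / n_sig)
            fdrs.append(0.0 if len(sel) == 0 else (~hit).sum() / len(sel))
        # closed-form power: the BH threshold lands near p ~ 2e-3 (z ~ -2.85),
        # so recall for a -4 sigma component of equal spread is Phi(1.15) ~ 0.87
        assert np.mean(recalls) >= 0.85
        assert np.mean(fdrs) <= 0.10

    def test_empty_input_rejected(self):
        bg = BackgroundModel(0.0, 0.3)
        with pytest.raises(ValueError):
            select_signal_probes(np.array([]), bg)


class TestNormalize:
    def test_background_maps_to_unity(self):
        bg = BackgroundModel(mu_log2=0.7, sigma_log2=0.3)
        assert normalize_to_background(2.0 ** 0.7, bg) == pytest.approx(1.0)
        assert normalize_to_background(2.0, BackgroundModel(0.0, 0.3)) == 2.0

    def test_background_batch_geometric_mean_near_one(self):
        rng = np.random.default_rng(5)
        ratios = 2.0 ** rng.normal(0.4, 0.3, 20_000)
        bg = fit_background_normal(np.log2(ratios))
        normed = normalize_to_background(ratios, bg)
        geo_mean = np.exp(np.mean(np.log(normed)))
        assert geo_mean == pytest.approx(1.0, rel=0.01)


def _probe_frame(rows):
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end",
                                       "time_min", "value"])


class TestAggregate:
    def test_single_probe_passthrough(self):
        probes = _probe_frame([("p1", "chr1", 10, 70, t, v)
                               for t, v in [(0, 1.0), (5, 2.0), (10, 3.0)]])
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                              "name": ["L1"]})
        (series,) = aggregate_to_locus(probes, peaks)
        np.testing.assert_allclose(series.values, [1.0, 2.0, 3.0])

    def test_two_probes_averaged(self):
        rows = []
        for pid, v in [("p1", 1.0), ("p2", 3.0)]:
            rows += [(pid, "chr1", 10, 70, t, v) for t in (0, 5, 10)]
        (series,) = aggregate_to_locus(
            _probe_frame(rows),
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}))
        np.testing.assert_allclose(series.values, [2.0, 2.0, 2.0])

    def test_membership_matches_bruteforce_overlap(self):
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 950, 80)
        probes = _probe_frame([
            (f"p{i}", "chr1", s, s + 50, 0.0, 1.0) for i, s in enumerate(starts)
        ])
        pk_starts = rng.integers(0, 900, 12)
        peaks = pd.DataFrame({"chrom": "chr1", "start": pk_starts,
                              "end": pk_starts + 100,
                              "name": [f"L{j}" for j in range(12)]})
        # brute force: per-pair half-open interval overlap
        expected = {}
        for j in range(12):
            members = {f"p{i}" for i, s in enumerate(starts)
                       if s < peaks["end"][j] and s + 50 > peaks["start"][j]}
            if members:
                expected[f"L{j}"] = len(members)
        series = aggregate_to_locus(probes, peaks)
        got = {s.locus_id for s in series}
        assert got == set(expected)
        # per-peak member counts agree via the mean of distinct values
        probes2 = probes.copy()
        probes2["value"] = np.arange(len(probes2), dtype=float)
        for s in aggregate_to_locus(probes2, peaks):
            members = [i for i, st_ in enumerate(starts)
                       if st_ < int(peaks.set_index("name").loc[s.locus_id, "end"])
                       and st_ + 50 > int(peaks.set_index("name").loc[s.locus_id, "start"])]
            assert s.values[0] == pytest.approx(np.mean(members))

    def test_empty_peak_skipped(self, caplog):
        probes = _probe_frame([("p1", "chr1", 10, 70, 0.0, 1.0)])
        peaks = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100],
                              "name": ["empty"]})
        assert aggregate_to_locus(probes, peaks) == []
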