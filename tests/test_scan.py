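"""Sliding-window Z tracks, covariance-corrected combination, regions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import laibench as lb
from laibench.scan import WindowTrack
from conftest import make_calls


def _panel(n, chrom="1", spacing_bp=10_000):
    return lb.SitePanel(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": (np.arange(n) + 1) * spacing_bp,
                "cm": (np.arange(n) + 1) * spacing_bp / 1e6,
                "ref": "A",
                "alt": "G",
                "maf": 0.3,
                "info": 1.0,
            }
        )
    )


def _track(z, method="m", chrom=None, pos=None):
    z = np.asarray(z, float)
    return WindowTrack(
        method,
        chrom if chrom is not None else np.full(len(z), "1", dtype=object),
        pos if pos is not None else (np.arange(len(z)) + 1) * 100_000,
        z,
        np.isnan(z),
    )


class TestSnpMeans:
    def test_trivial_means(self):
        calls = make_calls([[1, 1, 1], [1, 0, -1]], ["a.0", "a.1"])
        m = lb.snp_mean_ancestry(calls, min_call_rate=0.5)
        assert np.allclose(m, [1.0, 0.5, 1.0])

    def test_low_call_rate_missing(self):
        calls = make_calls([[1, -1], [1, -1], [0, -1], [0, 1]])
        m = lb.snp_mean_ancestry(calls, min_call_rate=0.5)
        assert m[0] == 0.5 and np.isnan(m[1])


class TestWindowZ:
    def test_constant_track_all_masked_with_warning(self, caplog):
        panel = _panel(100)
        with caplog.at_level("WARNING", logger="laibench"):
            track = lb.window_z(np.full(100, 0.2), panel, lb.ScanConfig(window=11))
        assert track.masked.all()
        assert any("zero spread" in r.message for r in caplog.records)

    def test_outlier_window_attains_max_abs_z(self):
        rng = np.random.default_rng(0)
        n = 400
        panel = _panel(n)
        means = 0.2 + rng.normal(0, 0.01, n)
        means[200:251] += 0.1
        track = lb.window_z(means, panel, lb.ScanConfig())
        lead = np.nanargmax(np.abs(track.z))
        assert 200 <= lead + 25 <= 251  # lead window centered inside the bump

    def test_short_chromosome_warns_and_masks(self, caplog):
        panel = _panel(10)
        with caplog.at_level("WARNING", logger="laibench"):
            track = lb.window_z(np.linspace(0.1, 0.3, 10), panel, lb.ScanConfig(window=51))
        assert track.n_windows == 0

    def test_masked_regions_are_excluded(self):
        rng = np.random.default_rng(1)
        n = 400
        panel = _panel(n)
        means = 0.2 + rng.normal(0, 0.02, n)
        masks = lb.MaskRegions(
            pd.DataFrame({"chrom": ["1"], "start": [1_000_000], "end": [2_000_000]})
        )
        track = lb.window_z(means, panel, lb.ScanConfig(), masks)
        in_mask = masks.contains("1", track.lead_pos)
        assert track.masked[in_mask].all()

    def test_null_windows_selfnormalized(self):
        rng = np.random.default_rng(2)
        panel = _panel(3000)
        means = 0.2 + rng.normal(0, 0.02, 3000)
        track = lb.window_z(means, panel, lb.ScanConfig())
        z = track.z[~track.masked]
        assert abs(np.std(z, ddof=1) - 1) < 1e-9  # exact by construction
        assert abs(np.mean(z)) < 0.1


class TestCombineZ:
    def test_identity_sigma_reduces_to_stouffer(self):
        tracks = [_track(np.ones(4), m) for m in "abcde"]
        comb, _ = lb.combine_z(tracks, sigma=np.eye(5))
        assert np.allclose(comb.z, np.sqrt(5))

    def test_perfect_correlation_is_identity(self):
        z = np.array([1.3, -0.2, 2.0])
        tracks = [_track(z, m) for m in "abcde"]
        comb, _ = lb.combine_z(tracks, sigma=np.ones((5, 5)))
        assert np.allclose(comb.z, z)

    def test_two_methods_half_correlation(self):
        tracks = [_track([2.0, 2.0], "a"), _track([2.0, 2.0], "b")]
        comb, _ = lb.combine_z(tracks, sigma=np.array([[1, 0.5], [0.5, 1]]))
        assert np.allclose(comb.z, 4 / np.sqrt(3), atol=1e-9)

    def test_estimated_sigma_from_identical_tracks_is_identity(self):
        # window_z output is self-normalized (unit SD), so identical tracks
        # combine to themselves when Sigma is estimated from them
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 500)
        z = (z - 0.1) / np.std(z - 0.1, ddof=1)
        tracks = [_track(z, m) for m in "abc"]
        comb, sigma = lb.combine_z(tracks)
        assert np.allclose(comb.z, z, atol=1e-9)
        assert np.allclose(sigma, np.cov(np.vstack([z] * 3)))

    def test_masked_window_propagates(self):
        za = np.array([1.0, np.nan, 1.0, 0.5, -0.3, 0.8])
        zb = np.array([1.0, 1.0, 1.0, 0.2, -0.1, 0.4])
        comb, _ = lb.combine_z([_track(za, "a"), _track(zb, "b")])
        assert comb.masked[1] and np.isnan(comb.z[1])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="shared window grid"):
            lb.combine_z([_track([1.0, 2.0]), _track([1.0, 2.0, 3.0])])


class TestPValues:
    @given(z=st.floats(-6, 6), n=st.integers(1, 50))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_z_p_round_trip(self, z, n):
        for side in ("two-sided", "one-sided"):
            p = lb.z_to_p(abs(z), side)
            if p <= 0 or p >= 1:
                continue
            back = lb.p_to_z_threshold(p * n, n, side)
            assert abs(back - abs(z)) < 1e-9

    def test_zero_z_two_sided_is_one(self):
        assert lb.z_to_p(0.0) == pytest.approx(1.0)

    def test_full_alpha_threshold_is_zero(self):
        assert lb.p_to_z_threshold(1.0, 1, "one-sided") == 0.0


class TestRegions:
    def test_single_window_region(self):
        z = np.zeros(50)
        z[20] = 4.0
        regions = lb.call_candidate_regions(_track(z), lb.ScanConfig())
        assert len(regions) == 1
        assert regions.iloc[0]["lead_pos"] == 21 * 100_000
        assert regions.iloc[0]["sign"] == 1

    def test_distant_clusters_stay_separate(self):
        z = np.zeros(200)
        z[10:13] = 3.5
        z[150:152] = -4.0  # 14 Mb away on the 100 kb grid
        regions = lb.call_candidate_regions(_track(z), lb.ScanConfig())
        assert len(regions) == 2
        assert regions["sign"].tolist() == [1, -1]

    def test_no_lead_snp_inside_mask(self):
        rng = np.random.default_rng(4)
        panel = _panel(2000)
        means = 0.2 + rng.normal(0, 0.02, 2000)
        masks = lb.MaskRegions(
            pd.DataFrame({"chrom": ["1"], "start": [5_000_000], "end": [9_000_000]})
        )
        cfg = lb.ScanConfig(z_threshold=1.0)  # permissive: many regions
        track = lb.window_z(means, panel, cfg, masks)
        regions = lb.call_candidate_regions(track, cfg)
        assert len(regions) > 0
        assert not masks.contains("1", regions["lead_pos"].to_numpy()).any()


class TestReplication:
    def test_discovery_track_replicates_itself(self):
        z = np.zeros(100)
        z[40:45] = 3.5
        track = _track(z)
        cfg = lb.ScanConfig(replication_z=3.0)
        regions = lb.call_candidate_regions(track, cfg)
        rep = lb.replicate(regions, track, cfg)
        assert rep["replicated"].all()

    def test_sign_flipped_track_never_replicates(self):
        z = np.zeros(100)
        z[40:45] = 3.5
        cfg = lb.ScanConfig(replication_z=1.0)
        regions = lb.call_candidate_regions(_track(z), cfg)
        flipped = _track(-z)
        rep = lb.replicate(regions, flipped, cfg)
        assert not rep["replicated"].any()


class TestLowAncestryDiagnostic:
    def _setup(self, subset_has_deviation):
        n = 200
        panel = _panel(n)
        inds = [f"i{k}" for k in range(10)]
        haps = [f"{i}.{j}" for i in inds for j in (0, 1)]
        labels = np.zeros((20, n), np.int8)
        window = slice(100 - 25, 100 + 26)
        for k, i in enumerate(inds):
            high = k >= 5
            if high or subset_has_deviation:
                labels[2 * k, window] = 1
                labels[2 * k + 1, window] = 1
        calls = make_calls(labels, haps)
        ref = pd.Series({i: (0.05 if k < 5 else 0.3) for k, i in enumerate(inds)})
        regions = pd.DataFrame({"chrom": ["1"], "lead_pos": [panel.sites['pos'].iloc[100]]})
        return calls, regions, panel, ref

    def test_selection_consistent_when_subset_flat(self):
        calls, regions, panel, ref = self._setup(subset_has_deviation=False)
        out = lb.low_ancestry_diagnostic(calls, regions, panel, ref)
        assert out.iloc[0]["classification"] == "selection-consistent"
        assert abs(out.iloc[0]["deviation_subset"]) < 0.01

    def test_misclassification_suspect_when_subset_matches_full(self):
        calls, regions, panel, ref = self._setup(subset_has_deviation=True)
        out = lb.low_ancestry_diagnostic(calls, regions, panel, ref)
        assert out.iloc[0]["classification"] == "misclassification-suspect"
        assert out.iloc[0]["deviation_subset"] == pytest.approx(
            out.iloc[0]["deviation_full"], rel=0.05
        )

    def test_shifted_source_frequencies_inflate_subset_deviation(self):
        """Misspecified sources create spurious local deviations visible in
        the low-ancestry subset, where true selection signal is absent."""
        cfg = lb.SimulationConfig(n_admixed=60, sites_per_chrom=2000, seed=70)
        co = lb.simulate_cohort(cfg)
        truth_gp = lb.global_proportions(co.truth_calls)
        cutoff = float(truth_gp.quantile(0.2))  # ensure a non-empty subset
        fh = lb.estimate_frequencies(co.source_hg)
        ff = lb.estimate_frequencies(co.source_farmer)
        matched = lb.call_hmm(co.panel, co.admixed, fh, ff)
        shifted = lb.call_hmm(co.panel, co.admixed, fh, 0.6 * ff + 0.4 * fh)
        pos = co.panel.sites["pos"].to_numpy()
        slices = co.panel.chrom_slices()
        regions = pd.DataFrame(
            {
                "chrom": list(slices),
                "lead_pos": [pos[sl][len(pos[sl]) // 2] for sl in slices.values()],
            }
        )
        devs = {}
        for name, calls in (("matched", matched), ("shifted", shifted)):
            out = lb.low_ancestry_diagnostic(calls, regions, co.panel, truth_gp, cutoff)
            devs[name] = np.abs(out["deviation_subset"]).mean()
        assert devs["shifted"] > devs["matched"]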