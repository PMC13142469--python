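"""Caller correctness: HMM exactness, mismatch rules, rephasing, recoding."""

import itertools

import numpy as np
import pandas as pd
import pytest

import laibench as lb
from conftest import make_calls


def _panel(cm, chrom="1"):
    cm = np.asarray(cm, float)
    return lb.SitePanel(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": (np.arange(len(cm)) + 1) * 10_000,
                "cm": cm,
                "ref": "A",
                "alt": "G",
                "maf": 0.3,
                "info": 1.0,
            }
        )
    )


def _enumerate_posteriors(cm, alleles, fh, ff, T=35.0, p=0.2, eps=1e-3):
    """Brute-force marginal HG posteriors over all 2^n hidden paths."""
    n = len(cm)
    d = np.diff(cm)
    qf = 1 - np.exp(-T * p * d / 100)
    qh = 1 - np.exp(-T * (1 - p) * d / 100)
    fh = np.clip(fh, eps, 1 - eps)
    ff = np.clip(ff, eps, 1 - eps)

    def emis(state, a, j):
        if a < 0:
            return 1.0
        f = fh[j] if state == 1 else ff[j]
        return f if a == 1 else 1 - f

    tot = 0.0
    marg = np.zeros(n)
    for path in itertools.product([0, 1], repeat=n):
        pr = (p if path[0] == 1 else 1 - p) * emis(path[0], alleles[0], 0)
        for j in range(1, n):
            if path[j - 1] == 0:
                pr *= qf[j - 1] if path[j] == 1 else 1 - qf[j - 1]
            else:
                pr *= qh[j - 1] if path[j] == 0 else 1 - qh[j - 1]
            pr *= emis(path[j], alleles[j], j)
        tot += pr
        marg += pr * np.array(path)
    return marg / tot


class TestHmm:
    @pytest.mark.parametrize("n_sites,seed", [(2, 0), (6, 1), (10, 2), (12, 3)])
    def test_posteriors_match_exhaustive_enumeration(self, n_sites, seed):
        rng = np.random.default_rng(seed)
        cm = np.sort(rng.uniform(0, 15, n_sites))
        panel = _panel(cm)
        fh = rng.uniform(0.02, 0.98, n_sites)
        ff = rng.uniform(0.02, 0.98, n_sites)
        alleles = rng.integers(0, 2, (1, n_sites)).astype(np.int8)
        if n_sites >= 6:
            alleles[0, 3] = -1  # missing site emits nothing
        post = lb.hmm_posterior_hg(panel, lb.GenotypeMatrix(["a.0"], alleles, {"a": 1}), fh, ff)
        expect = _enumerate_posteriors(cm, alleles[0], fh, ff)
        assert np.max(np.abs(post[0] - expect)) < 1e-9

    def test_uninformative_emission_returns_prior(self):
        panel = _panel([0.0])
        gm = lb.GenotypeMatrix(["a.0"], np.array([[1]], np.int8), {"a": 1})
        post = lb.hmm_posterior_hg(panel, gm, np.array([0.4]), np.array([0.4]))
        assert abs(post[0, 0] - 0.2) < 1e-12

    def test_correct_state_has_higher_mean_posterior(self, default_cohort):
        co = default_cohort
        post = lb.hmm_posterior_hg(
            co.panel,
            co.admixed,
            lb.estimate_frequencies(co.source_hg),
            lb.estimate_frequencies(co.source_farmer),
        )
        truth_hg = co.truth_calls.labels == 1
        assert post[truth_hg].mean() > post[~truth_hg].mean()

    def test_stored_posterior_is_of_assigned_label(self, default_cohort):
        co = default_cohort
        calls = lb.call_hmm(
            co.panel,
            co.admixed,
            lb.estimate_frequencies(co.source_hg),
            lb.estimate_frequencies(co.source_farmer),
        )
        assert np.all(calls.posterior >= 0.5 - 1e-6)


class TestMismatch:
    def test_separable_sources_recovered_exactly(self):
        # fixed differences at every site, noise-free target
        n = 60
        panel = _panel(np.linspace(0, 5, n))
        hg = lb.GenotypeMatrix(["h0.0", "h0.1"], np.ones((2, n), np.int8), {"h0": 2})
        fa = lb.GenotypeMatrix(["f0.0", "f0.1"], np.zeros((2, n), np.int8), {"f0": 2})
        truth = np.zeros((1, n), np.int8)
        truth[0, : n // 2] = 1
        gm = lb.GenotypeMatrix(["a.0"], truth.copy(), {"a": 1})
        cfg = lb.MismatchConfig(span_bp=100_000, step_bp=50_000, min_sites=3)
        calls = lb.call_mismatch(panel, gm, hg, fa, cfg)
        ok = calls.labels[0] != -1
        assert ok.any()
        # exact away from the ancestry switch (window-grid resolution there)
        pos = panel.sites["pos"].to_numpy()
        switch_pos = pos[n // 2]
        far = np.abs(pos - switch_pos) > cfg.span_bp
        assert np.array_equal(calls.labels[0][ok & far], truth[0][ok & far])
        assert np.mean(calls.labels[0][ok] == truth[0][ok]) > 0.9

    def test_tie_breaks_to_farmer_majority(self):
        n = 20
        panel = _panel(np.linspace(0, 2, n))
        same = np.ones((2, n), np.int8)
        hg = lb.GenotypeMatrix(["h0.0", "h0.1"], same.copy(), {"h0": 2})
        fa = lb.GenotypeMatrix(["f0.0", "f0.1"], same.copy(), {"f0": 2})
        gm = lb.GenotypeMatrix(["a.0"], same[:1].copy(), {"a": 1})
        cfg = lb.MismatchConfig(span_bp=100_000, step_bp=100_000, min_sites=3)
        calls = lb.call_mismatch(panel, gm, hg, fa, cfg)
        assert np.all(calls.labels[0] == lb.LABEL_FARMER)

    def test_empty_source_panel_rejected(self, tiny_panel):
        gm = lb.GenotypeMatrix(["a.0"], np.zeros((1, 5), np.int8), {"a": 1})
        empty = lb.GenotypeMatrix([], np.zeros((0, 5), np.int8), {})
        with pytest.raises(ValueError, match="empty source"):
            lb.call_mismatch(tiny_panel, gm, empty, gm)

    def test_accuracy_on_default_simulation(self, default_cohort):
        # pilot-frozen floors at the generator's default divergence (F_st=0.1):
        # frequency-only emission bounds the mismatch caller well below the
        # HMM, but both must beat these margins
        co = default_cohort
        cfg = lb.MismatchConfig(span_bp=10_000_000, step_bp=5_000_000, min_sites=10)
        mm = lb.call_mismatch(co.panel, co.admixed, co.source_hg, co.source_farmer, cfg)
        hm = lb.call_hmm(
            co.panel,
            co.admixed,
            lb.estimate_frequencies(co.source_hg),
            lb.estimate_frequencies(co.source_farmer),
        )
        truth = co.truth_calls.labels
        assert np.mean(mm.labels == truth) > 0.55
        assert np.mean(hm.labels == truth) > 0.72

    def test_accuracy_improves_with_divergence(self):
        cfg = lb.SimulationConfig(n_admixed=10, f_st=0.3, seed=21)
        co = lb.simulate_cohort(cfg)
        mc = lb.MismatchConfig(span_bp=10_000_000, step_bp=5_000_000, min_sites=10)
        mm = lb.call_mismatch(co.panel, co.admixed, co.source_hg, co.source_farmer, mc)
        assert np.mean(mm.labels == co.truth_calls.labels) > 0.8


class TestRecode:
    def test_path_codes_map_to_sources(self):
        out = lb.recode_paths(np.array([1, 2, 3, 4, 5, 6]))
        assert out.tolist() == [0, 0, 1, 1, 0, 0]

    def test_all_hg_proximal(self):
        assert np.all(lb.recode_paths(np.full(10, 3)) == 1)

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="unknown path code 7"):
            lb.recode_paths(np.array([1, 7]))

    def test_missing_passes_through(self):
        assert lb.recode_paths(np.array([-1, 4])).tolist() == [-1, 1]


class TestChromosomeBias:
    def test_forced_arithmetic(self):
        panel = lb.SitePanel(
            pd.concat(
                [
                    _panel([0, 1, 2], chrom="1").sites,
                    _panel([0, 1, 2], chrom="2").sites,
                ]
            ).reset_index(drop=True)
        )
        means = np.array([0.3, 0.3, 0.3, 0.1, 0.1, 0.1])
        out = lb.correct_chromosome_bias(means, panel)
        assert np.allclose(out, [0.2] * 6)
        assert np.allclose(out[:3], means[:3] - 0.1)

    def test_balanced_input_identity(self, tiny_panel):
        means = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        assert np.allclose(lb.correct_chromosome_bias(means, tiny_panel), means)

    def test_chromosome_means_equal_genome_mean(self, default_cohort):
        co = default_cohort
        means = lb.snp_mean_ancestry(co.truth_calls)
        out = lb.correct_chromosome_bias(means, co.panel)
        genome = np.nanmean(out)
        for _, sl in co.panel.chrom_slices().items():
            assert abs(np.nanmean(out[sl]) - genome) < 1e-12


class TestUnkink:
    def test_canonical_kink_fixed_exactly(self):
        calls = make_calls([[1, 1, 0, 0], [0, 0, 1, 1]], ["a.0", "a.1"])
        panel = _panel([0, 1, 2, 3])
        assert lb.count_switches(calls, panel) == 2
        out = lb.unkink(calls)
        assert out.labels[0].tolist() == [1, 1, 1, 1]
        assert out.labels[1].tolist() == [0, 0, 0, 0]
        assert lb.count_switches(out, panel) == 0

    def test_no_opposite_switches_identity(self):
        calls = make_calls([[1, 0, 0, 1], [0, 0, 1, 1]], ["a.0", "a.1"])
        out = lb.unkink(calls)
        assert np.array_equal(out.labels, calls.labels)

    def test_never_increases_switches_and_recovers_truth_floor(self):
        # phase-scrambled truth: unkinking must not undershoot the true
        # switch count (100 seeded replicates).  A phase switch landing in
        # the same inter-SNP interval as a true ancestry switch erases that
        # switch before any rephasing; the dense grid makes this rare.
        from laibench.simulate import build_panel, lay_tracts, truth_calls

        n_ok_floor = 0
        for seed in range(100):
            cfg = lb.SimulationConfig(
                n_admixed=2, n_chrom=1, sites_per_chrom=5000, chrom_length_cm=100, seed=seed
            )
            panel = build_panel(cfg)
            tr = lay_tracts(cfg, np.random.default_rng(seed))
            truth = truth_calls(tr, panel, tr.haplotypes())
            scrambled = lb.phase_scramble_calls(
                truth, panel, 0.01, np.random.default_rng(seed + 500)
            )
            out = lb.unkink(scrambled)
            before = lb.count_switches(scrambled, panel)
            after = lb.count_switches(out, panel)
            assert after <= before
            n_ok_floor += after >= lb.count_switches(truth, panel)
        assert n_ok_floor >= 95

    def test_ploidy_one_passes_through(self):
        calls = make_calls([[1, 0, 1]], ["m.0"])
        out = lb.unkink(calls, {"m": 1})
        assert np.array_equal(out.labels, calls.labels)


class TestMaleX:
    def test_dedup_keeps_one_haplotype_per_male(self):
        calls = make_calls(
            [[1, 0], [1, 0], [0, 1], [1, 1]], ["m.0", "m.1", "f.0", "f.1"]
        )
        out = lb.dedup_male_x(calls, {"m": 1, "f": 2})
        assert out.haplotypes == ["m.0", "f.0", "f.1"]

    def test_all_female_identity(self):
        calls = make_calls([[1, 0], [0, 1]], ["f.0", "f.1"])
        out = lb.dedup_male_x(calls, {"f": 2})
        assert out.haplotypes == calls.haplotypes

    def test_idempotent(self):
        calls = make_calls([[1], [1], [0]], ["m.0", "m.1", "f.0"])
        once = lb.dedup_male_x(calls, {"m": 1, "f": 2})
        twice = lb.dedup_male_x(once, {"m": 1, "f": 2})
        assert once.haplotypes == twice.haplotypes

    def test_pseudodiploid_round_trip(self):
        gm = lb.GenotypeMatrix(["m.0", "f.0", "f.1"], np.array([[1, 0], [0, 1], [1, 1]], np.int8), {"m": 1, "f": 2})
        enc = lb.encode_pseudodiploid(gm)
        assert enc.haplotypes == ["m.0", "m.1", "f.0", "f.1"]
        assert np.array_equal(enc.alleles[0], enc.alleles[1])
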