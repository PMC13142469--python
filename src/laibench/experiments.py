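"""Pre-configured study harnesses tying the pipeline stages together.

Each function runs one of the package's benchmark experiments end to end at a
desk-scale study size (documented in docs/methods.md) and returns plain
dictionaries/ DataFrames, so the test suite and the acceptance script execute
exactly the same conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bench, engines, scan, tracts
from .io import apply_posterior_filter
from .simulate import (
    SelectionLocus,
    SimulationConfig,
    lay_tracts,
    simulate_cohort,
)

__all__ = [
    "tract_recovery",
    "scan_cohort_config",
    "run_scan",
    "scan_power_experiment",
    "null_calibration",
    "source_imbalance_experiment",
]


# ---------------------------------------------------------------------------
# tract-length dating
# ---------------------------------------------------------------------------


def tract_recovery(
    seed: int,
    T: float = 35.0,
    p_hg: float = 0.2,
    n_haplotypes: int = 200,
    n_chrom: int = 35,
    chrom_length_cm: float = 150.0,
    min_length_cm: float = 10.0,
) -> tracts.TractFit:
    """Lay truth tracts at known T and refit it from HG tracts >= the cutoff."""
    cfg = SimulationConfig(
        n_admixed=n_haplotypes // 2,
        T=T,
        p_hg=p_hg,
        n_chrom=n_chrom,
        chrom_length_cm=chrom_length_cm,
        seed=seed,
    )
    truth = lay_tracts(cfg, np.random.default_rng(seed))
    table = tracts.truth_tract_table(truth)
    hg = table[table["label"] == 1]
    return tracts.fit_single_pulse(
        hg, p_pop=p_hg, min_length_cm=min_length_cm, chrom_length_cm=chrom_length_cm
    )


# ---------------------------------------------------------------------------
# deviation scan
# ---------------------------------------------------------------------------

#: injected deviations for the power study: +0.15 on chromosome 2,
#: -0.15 on chromosome 4, both at 31 cM with a 5 cM linear-taper radius
SCAN_LOCI = (
    SelectionLocus("2", 31.0, +0.15, 5.0),
    SelectionLocus("4", 31.0, -0.15, 5.0),
)


def scan_cohort_config(
    seed: int, selection: bool = True, n_admixed: int = 150
) -> SimulationConfig:
    """Scan study conditions: 5 chromosomes x 10,000 SNPs x 62 cM (the
    discovery data's ~160 SNP/cM density), balanced 48v48 source panels so the
    scan is tested apart from source-imbalance bias."""
    return SimulationConfig(
        n_admixed=n_admixed,
        n_source_hg=48,
        n_source_farmer=48,
        n_chrom=5,
        sites_per_chrom=10_000,
        chrom_length_cm=62.0,
        selection_loci=SCAN_LOCI if selection else (),
        seed=seed,
    )


def run_scan(cohort, scan_config: scan.ScanConfig | None = None):
    """Call ancestry with both engines, build window-Z tracks, and combine.

    The HMM track is posterior-filtered at 0.9 (it reports calibrated
    posteriors); the mismatch pseudo-posterior is a margin, not a calibrated
    probability, so that track is left unfiltered.
    """
    scfg = scan_config or scan.ScanConfig()
    fh = engines.estimate_frequencies(cohort.source_hg)
    ff = engines.estimate_frequencies(cohort.source_farmer)
    hmm_calls = apply_posterior_filter(
        engines.call_hmm(cohort.panel, cohort.admixed, fh, ff, dtype=np.float32), 0.9
    )
    mm_calls = engines.call_mismatch(
        cohort.panel,
        cohort.admixed,
        cohort.source_hg,
        cohort.source_farmer,
        engines.MismatchConfig(span_bp=2_000_000, step_bp=500_000, min_sites=100),
    )
    tracks = [
        scan.window_z(scan.snp_mean_ancestry(c), cohort.panel, scfg, None, name)
        for c, name in ((hmm_calls, "hmm"), (mm_calls, "mismatch"))
    ]
    combined, sigma = scan.combine_z(tracks)
    return tracks, combined, sigma


def _match_locus(regions: pd.DataFrame, locus: SelectionLocus, slop_bp: int = 6_000_000):
    """The region (if any) whose lead SNP covers the injected locus."""
    pos_bp = locus.pos_cm * 1e6  # simulator map is 1 cM/Mb
    hit = regions[
        (regions["chrom"] == locus.chrom)
        & ((regions["lead_pos"] - pos_bp).abs() <= slop_bp)
    ]
    return None if hit.empty else hit.iloc[(hit["lead_pos"] - pos_bp).abs().argmin()]


def scan_power_experiment(seed: int, scan_config: scan.ScanConfig | None = None) -> dict:
    """Discovery + replication on two independently simulated cohorts.

    Returns detection flags (both injected loci found with the right sign),
    the count of null (spurious) regions, and replication verdicts under the
    2 Mb / matching-sign rule.
    """
    scfg = scan_config or scan.ScanConfig()
    disc = simulate_cohort(scan_cohort_config(seed))
    _, combined, _ = run_scan(disc, scfg)
    regions = scan.call_candidate_regions(combined, scfg)

    detected, signs_ok = [], []
    matched_leads = []
    for locus in SCAN_LOCI:
        m = _match_locus(regions, locus)
        detected.append(m is not None)
        signs_ok.append(m is not None and m["sign"] == np.sign(locus.delta))
        if m is not None:
            matched_leads.append(m["lead_pos"])
    n_null = 0
    for _, reg in regions.iterrows():
        if not any(
            reg["chrom"] == l.chrom and abs(reg["lead_pos"] - l.pos_cm * 1e6) <= 6_000_000
            for l in SCAN_LOCI
        ):
            n_null += 1

    rep = simulate_cohort(scan_cohort_config(seed + 10_000))
    _, rep_combined, _ = run_scan(rep, scfg)
    verdicts = scan.replicate(regions, rep_combined, scfg)
    rep_ok = []
    for locus in SCAN_LOCI:
        m = _match_locus(verdicts, locus)
        rep_ok.append(bool(m is not None and m["replicated"]))
    return {
        "regions": verdicts,
        "both_detected": all(detected) and all(signs_ok),
        "n_null_regions": int(n_null),
        "both_replicated": all(rep_ok),
    }


def null_calibration(seed: int, n_admixed: int = 100) -> dict:
    """Combined-Z mean/SD over unmasked windows with no selection injected."""
    cohort = simulate_cohort(scan_cohort_config(seed, selection=False, n_admixed=n_admixed))
    _, combined, sigma = run_scan(cohort)
    z = combined.z[~combined.masked]
    return {"mean": float(np.mean(z)), "sd": float(np.std(z, ddof=1)), "n_windows": len(z)}


# ---------------------------------------------------------------------------
# source imbalance / posterior filtering
# ---------------------------------------------------------------------------


def source_imbalance_experiment(seeds: list[int]) -> pd.DataFrame:
    """Engine bias with unbalanced (48v7) vs balanced (7v7) source panels.

    One cohort per seed (48 HG / 7 farmer sources available); each engine runs
    with the full unbalanced HG panel and with a 7-individual subsample, and
    the HMM additionally with posterior filtering at 0.9.  Bias is the mean
    signed error of per-individual HG fractions vs truth; delta the mean
    absolute error.
    """
    rows = []
    for seed in seeds:
        cohort = simulate_cohort(
            SimulationConfig(n_admixed=30, n_chrom=3, sites_per_chrom=3000,
                             chrom_length_cm=100.0, seed=seed)
        )
        truth = bench.global_proportions(cohort.truth_calls)
        rng = np.random.default_rng(seed)
        sub7 = list(rng.choice(cohort.source_hg.individuals, size=7, replace=False))
        hg_panels = {
            "48v7": cohort.source_hg,
            "7v7": cohort.source_hg.subset_haplotypes(
                [f"{i}.{k}" for i in sub7 for k in (0, 1)]
            ),
        }
        ff = engines.estimate_frequencies(cohort.source_farmer)
        for design, hg_panel in hg_panels.items():
            fh = engines.estimate_frequencies(hg_panel)
            calls = {
                "hmm": engines.call_hmm(cohort.panel, cohort.admixed, fh, ff),
                "mismatch": engines.call_mismatch(
                    cohort.panel,
                    cohort.admixed,
                    hg_panel,
                    cohort.source_farmer,
                    engines.MismatchConfig(
                        span_bp=5_000_000, step_bp=2_500_000, min_sites=20
                    ),
                ),
            }
            calls["hmm_filtered"] = apply_posterior_filter(calls["hmm"], 0.9)
            for name, c in calls.items():
                est = bench.global_proportions(c)
                st = bench.compare_to_reference(est, truth)
                rows.append(
                    {
                        "seed": seed,
                        "design": design,
                        "engine": name,
                        "bias": float((est - truth.loc[est.index]).mean()),
                        "delta": st.delta,
                        "r": st.r,
                    }
                )
    return pd.DataFrame(rows)
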