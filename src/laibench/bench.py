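"""Global-ancestry benchmarking: per-individual proportions, agreement with a
reference estimator, and the source-panel subsampling experiment."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LABEL_HG, LABEL_MISSING, AncestryCalls, individual_of
from . import engines

logger = logging.getLogger("laibench")

__all__ = [
    "ComparisonStats",
    "global_proportions",
    "compare_to_reference",
    "subsample_experiment",
    "select_optimal",
]


@dataclass(frozen=True)
class ComparisonStats:
    """Agreement between per-individual ancestry estimates and a reference.

    r / rho: Pearson and Spearman correlations; beta: OLS slope of the method
    on the reference (reference on the x-axis); delta: mean absolute
    per-individual difference (mean signed difference when ``signed``).
    """

    r: float
    rho: float
    beta: float
    delta: float
    n: int


def global_proportions(calls: AncestryCalls, fixed_denominator: bool = False) -> pd.Series:
    """Genome-wide hunter-gatherer fraction per individual.

    The denominator is the individual's non-missing haplotype-site calls
    (posterior filtering creates missingness); ``fixed_denominator`` divides
    by the full panel size instead.
    """
    rows_by_ind: dict[str, list[int]] = {}
    for i, h in enumerate(calls.haplotypes):
        rows_by_ind.setdefault(individual_of(h), []).append(i)
    out = {}
    for ind, rows in rows_by_ind.items():
        lab = calls.labels[rows]
        n_hg = int(np.sum(lab == LABEL_HG))
        denom = lab.size if fixed_denominator else int(np.sum(lab != LABEL_MISSING))
        out[ind] = n_hg / denom if denom else np.nan
    return pd.Series(out, name="hg_fraction")


def compare_to_reference(
    method_estimates: pd.Series, reference_estimates: pd.Series, signed: bool = False
) -> ComparisonStats:
    """R / rho / OLS slope / mean (absolute) difference on paired individuals.

    Individuals missing from either side are dropped with a logged count.
    """
    common = method_estimates.index.intersection(reference_estimates.index)
    dropped = (
        len(method_estimates.index.union(reference_estimates.index)) - len(common)
    )
    if dropped:
        logger.info("compare_to_reference: dropped %d unpaired individuals", dropped)
    m = method_estimates.loc[common].to_numpy(float)
    r = reference_estimates.loc[common].to_numpy(float)
    ok = ~np.isnan(m) & ~np.isnan(r)
    m, r = m[ok], r[ok]
    diff = m - r
    delta = float(np.mean(diff)) if signed else float(np.mean(np.abs(diff)))
    if len(m) < 2 or np.ptp(r) == 0 or np.ptp(m) == 0:
        return ComparisonStats(np.nan, np.nan, np.nan, delta, len(m))
    pearson = float(stats.pearsonr(m, r).statistic)
    rho = float(stats.spearmanr(m, r).statistic)
    beta = float(np.polyfit(r, m, 1)[0])
    return ComparisonStats(pearson, rho, beta, delta, len(m))


def subsample_experiment(
    cohort,
    hg_sizes: list[int],
    seeds: list[int],
    engine: str = "hmm",
    posterior_min: float | None = None,
    reference: pd.Series | None = None,
    mismatch_config: engines.MismatchConfig | None = None,
    hmm_config: engines.HmmConfig | None = None,
) -> pd.DataFrame:
    """Rerun an engine with down-sampled hunter-gatherer source panels.

    For each requested size and seed, source individuals are drawn without
    replacement, the engine reruns on the cohort, and agreement statistics
    against the simulation truth (or a supplied reference) are tabulated.
    """
    from .io import apply_posterior_filter

    ref = reference if reference is not None else global_proportions(cohort.truth_calls)
    rows = []
    all_inds = cohort.source_hg.individuals
    for size in hg_sizes:
        if size > len(all_inds):
            raise ValueError(f"requested {size} hunter-gatherer sources, have {len(all_inds)}")
        for seed in seeds:
            rng = np.random.default_rng(seed)
            chosen = (
                all_inds
                if size == len(all_inds)
                else list(rng.choice(all_inds, size=size, replace=False))
            )
            haps = [f"{i}.{k}" for i in chosen for k in (0, 1)]
            sub = cohort.source_hg.subset_haplotypes(haps)
            if engine == "hmm":
                calls = engines.call_hmm(
                    cohort.panel,
                    cohort.admixed,
                    engines.estimate_frequencies(sub),
                    engines.estimate_frequencies(cohort.source_farmer),
                    hmm_config,
                )
            elif engine == "mismatch":
                calls = engines.call_mismatch(
                    cohort.panel, cohort.admixed, sub, cohort.source_farmer, mismatch_config
                )
            else:
                raise ValueError(f"unknown engine {engine!r}")
            if posterior_min is not None:
                calls = apply_posterior_filter(calls, posterior_min)
            st = compare_to_reference(global_proportions(calls), ref)
            rows.append(
                {
                    "hg_size": size,
                    "seed": seed,
                    "engine": engine,
                    "r": st.r,
                    "rho": st.rho,
                    "beta": st.beta,
                    "delta": st.delta,
                    "n": st.n,
                }
            )
    return pd.DataFrame(rows)


def select_optimal(table: pd.DataFrame) -> pd.Series:
    """Recommended source size: minimal mean delta, ties broken by maximal R."""
    agg = table.groupby("hg_size").agg(delta=("delta", "mean"), r=("r", "mean"))
    agg = agg.sort_values(["delta", "r"], ascending=[True, False])
    best = agg.index[0]
    return pd.Series({"hg_size": best, "delta": agg.iloc[0]["delta"], "r": agg.iloc[0]["r"]})
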