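"""Agreement between ancestry-call tracks in genomic bins.

Population-level concordance averages the hunter-gatherer indicator over all
haplotypes in fixed-width bins and correlates the binned tracks between
methods; individual-level concordance does the same per individual and
averages correlations over method pairs.  Bins are half-open, anchored at
position 1 of each chromosome; zero-variance tracks yield missing values
rather than NaN propagation.
"""

from __future__ import annotations

import logging
import itertools

import numpy as np
import pandas as pd

from .io import AncestryCalls, SitePanel, individual_of

logger = logging.getLogger("laibench")

__all__ = [
    "bin_ancestry",
    "pairwise_population_correlation",
    "individual_level_correlation",
    "STANDARD_BIN_WIDTHS",
]

#: the benchmark's standard bin widths (bp)
STANDARD_BIN_WIDTHS = (10_000, 100_000, 1_000_000, 100_000_000)


def _bin_ids(panel: SitePanel, width_bp: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-site bin index plus the bin table (chrom, start)."""
    chrom = panel.sites["chrom"].to_numpy()
    pos = panel.sites["pos"].to_numpy()
    start = ((pos - 1) // width_bp) * width_bp + 1
    ccodes, cuniq = pd.factorize(chrom)
    combined = ccodes.astype(np.int64) * (start.max() + 1) + start
    uniq, inverse = np.unique(combined, return_inverse=True)
    first = np.zeros(len(uniq), dtype=int)
    first[inverse[::-1]] = np.arange(len(combined))[::-1]
    table = pd.DataFrame({"chrom": chrom[first], "start": start[first]})
    return table, inverse


def bin_ancestry(
    calls: AncestryCalls,
    panel: SitePanel,
    width_bp: int,
    per_individual: bool = False,
) -> pd.DataFrame:
    """Mean hunter-gatherer fraction in fixed-width bins.

    Population level: one ``mean`` column averaging all haplotype-site calls.
    ``per_individual``: one column per individual.  Empty bins are NaN.
    """
    table, inverse = _bin_ids(panel, width_bp)
    ind = calls.hg_indicator()  # (n_hap, n_sites) with NaN missing
    n_bins = len(table)

    def _binned(mat: np.ndarray) -> np.ndarray:
        ok = ~np.isnan(mat)
        num = np.zeros(n_bins)
        den = np.zeros(n_bins)
        np.add.at(num, np.broadcast_to(inverse, mat.shape)[ok], mat[ok])
        np.add.at(den, np.broadcast_to(inverse, mat.shape)[ok], 1.0)
        with np.errstate(invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    out = table.copy()
    if per_individual:
        rows_by_ind: dict[str, list[int]] = {}
        for i, h in enumerate(calls.haplotypes):
            rows_by_ind.setdefault(individual_of(h), []).append(i)
        for ind_id, rows in rows_by_ind.items():
            out[ind_id] = _binned(ind[rows])
    else:
        out["mean"] = _binned(ind)
    return out


def pairwise_population_correlation(
    tracks: dict[str, AncestryCalls], panel: SitePanel, width_bp: int
) -> pd.DataFrame:
    """Method x method Pearson matrix of binned population ancestry.

    Each pair is correlated over bins non-missing in both tracks; the matrix
    is symmetric with unit diagonal.
    """
    binned = {
        name: bin_ancestry(c, panel, width_bp)["mean"].to_numpy()
        for name, c in tracks.items()
    }
    names = list(binned)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        x, y = binned[a], binned[b]
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def individual_level_correlation(
    tracks: dict[str, AncestryCalls], panel: SitePanel, width_bp: int
) -> pd.Series:
    """Per-individual mean Pearson correlation over method pairs in bins.

    Individuals with zero ancestry variance in a track yield an undefined
    correlation for the pairs involving it; these are skipped with a logged
    count, and individuals with no defined pair at all are missing.
    """
    names = list(tracks)
    binned = {
        name: bin_ancestry(c, panel, width_bp, per_individual=True)
        for name, c in tracks.items()
    }
    individuals = [
        c for c in binned[names[0]].columns if c not in ("chrom", "start")
    ]
    out = {}
    n_undefined = 0
    for ind in individuals:
        rs = []
        for a, b in itertools.combinations(names, 2):
            x = binned[a][ind].to_numpy()
            y = binned[b][ind].to_numpy()
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                n_undefined += 1
                continue
            rs.append(float(np.corrcoef(x[ok], y[ok])[0, 1]))
        out[ind] = float(np.mean(rs)) if rs else np.nan
    if n_undefined:
        logger.info(
            "individual_level_correlation: %d undefined pair correlations skipped",
            n_undefined,
        )
    return pd.Series(out, name=f"mean_r_{width_bp}bp")
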