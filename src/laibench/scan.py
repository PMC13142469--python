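"""Covariance-corrected sliding-window scan for loci with deviant ancestry.

Per method, the population mean hunter-gatherer ancestry of each SNP is
averaged in 51-SNP sliding windows (step 1) and standardized against the
genome-wide mean and the genome-wide spread of the window statistic, giving a
self-normalized Z track.  Method tracks are combined with a Stouffer-type
statistic corrected for inter-method correlation,

    Z_combined = sum_i Z_i / sqrt(1' Sigma 1),

with Sigma the genome-wide covariance matrix of the method Z tracks.  Windows
over long-range-LD or unmappable-flank masks are excluded.  Candidate regions
exceed |Z| > 3; replication requires a matching-sign window above the
replication threshold within 2 Mb of the discovery lead SNP.  A low-ancestry
subset diagnostic separates selection-consistent signals from likely ancestry
misclassification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import LABEL_MISSING, AncestryCalls, MaskRegions, SitePanel, individual_of

logger = logging.getLogger("laibench")

__all__ = [
    "ScanConfig",
    "WindowTrack",
    "snp_mean_ancestry",
    "window_z",
    "combine_z",
    "z_to_p",
    "p_to_z_threshold",
    "call_candidate_regions",
    "replicate",
    "low_ancestry_diagnostic",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan settings; defaults follow the discovery/replication design."""

    window: int = 51
    step: int = 1
    z_threshold: float = 3.0
    merge_radius_bp: int = 1_000_000
    replication_radius_bp: int = 2_000_000
    replication_z: float = 2.84  # p = 0.05/10 as printed; see p_to_z_threshold
    replication_alpha: float = 0.05
    n_discovery_hits: int = 10
    sidedness: str = "two-sided"
    min_call_rate: float = 0.5
    max_missing_frac: float = 0.2
    denominator: str = "window"  # or "snp": per-SNP SD variant

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.replication_radius_bp <= 0:
            raise ValueError("replication radius must be positive")
        if self.sidedness not in {"two-sided", "one-sided"}:
            raise ValueError("sidedness must be 'two-sided' or 'one-sided'")


@dataclass
class WindowTrack:
    """Per-window Z scores on a fixed grid of lead (central) SNPs."""

    method: str
    chrom: np.ndarray
    lead_pos: np.ndarray
    z: np.ndarray
    masked: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.z)

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            len(self.lead_pos) == len(other.lead_pos)
            and np.array_equal(self.lead_pos, other.lead_pos)
            and np.array_equal(self.chrom, other.chrom)
        )


def snp_mean_ancestry(calls: AncestryCalls, min_call_rate: float = 0.5) -> np.ndarray:
    """Population mean hunter-gatherer fraction per SNP.

    SNPs called in fewer than ``min_call_rate`` of haplotypes are missing.
    """
    n_hg = np.count_nonzero(calls.labels == 1, axis=0)
    n_called = np.count_nonzero(calls.labels != LABEL_MISSING, axis=0)
    with np.errstate(invalid="ignore"):
        means = n_hg / np.maximum(n_called, 1)
    low = n_called < min_call_rate * calls.n_haplotypes
    if low.any():
        logger.info("snp_mean_ancestry: %d SNPs below %.0f%% call rate set missing",
                    int(low.sum()), 100 * min_call_rate)
    means = means.astype(float)
    means[low | (n_called == 0)] = np.nan
    return means


def window_z(
    snp_means: np.ndarray,
    panel: SitePanel,
    config: ScanConfig | None = None,
    masks: MaskRegions | None = None,
    method: str = "",
) -> WindowTrack:
    """Standardized sliding-window ancestry Z track for one method.

    The window statistic is the mean of per-SNP mean ancestries over
    ``config.window`` SNPs; Z subtracts the genome-wide mean of per-SNP means
    (mask-excluded) and divides by the SD of the window statistic over all
    unmasked windows, so the null track is self-normalized.  Windows that
    overlap a mask, fall off a chromosome end, or contain too many missing
    SNPs are masked.
    """
    config = config or ScanConfig()
    snp_means = np.asarray(snp_means, dtype=float)
    W, S = config.window, config.step
    half = W // 2
    pos = panel.sites["pos"].to_numpy()

    snp_masked = np.zeros(panel.n_sites, dtype=bool)
    if masks is not None:
        for chrom, sl in panel.chrom_slices().items():
            snp_masked[sl] = masks.contains(chrom, pos[sl])

    chrom_out, pos_out, stat_out, masked_out = [], [], [], []
    for chrom, sl in panel.chrom_slices().items():
        x = snp_means[sl]
        n = len(x)
        if n < W:
            logger.warning("window_z: chromosome %s has %d < %d SNPs; no windows", chrom, n, W)
            continue
        vals = np.where(np.isnan(x), 0.0, x)
        miss = np.isnan(x).astype(float)
        msk = snp_masked[sl].astype(float)
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        cmiss = np.concatenate([[0.0], np.cumsum(miss)])
        cmask = np.concatenate([[0.0], np.cumsum(msk)])
        starts = np.arange(0, n - W + 1, S)
        wsum = csum[starts + W] - csum[starts]
        wmiss = cmiss[starts + W] - cmiss[starts]
        wmask = cmask[starts + W] - cmask[starts]
        n_ok = W - wmiss
        with np.errstate(invalid="ignore", divide="ignore"):
            wmean = np.where(n_ok > 0, wsum / n_ok, np.nan)
        bad = (wmask > 0) | (wmiss > config.max_missing_frac * W) | (n_ok == 0)
        chrom_out.append(np.full(len(starts), chrom, dtype=object))
        pos_out.append(pos[sl][starts + half])
        stat_out.append(wmean)
        masked_out.append(bad)

    chrom_arr = np.concatenate(chrom_out) if chrom_out else np.array([], dtype=object)
    pos_arr = np.concatenate(pos_out) if pos_out else np.array([], dtype=int)
    stat = np.concatenate(stat_out) if stat_out else np.array([])
    masked = np.concatenate(masked_out) if masked_out else np.array([], dtype=bool)

    genome_mean = np.nanmean(snp_means[~snp_masked]) if panel.n_sites else np.nan
    if config.denominator == "snp":
        sd = np.nanstd(snp_means[~snp_masked], ddof=1)
    else:
        sd = np.nanstd(np.where(masked, np.nan, stat), ddof=1)
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(genome_mean)):
        logger.warning("window_z: zero spread in window statistic; all windows masked")
        masked = np.ones_like(masked)
        z = np.full_like(stat, np.nan)
    else:
        z = (stat - genome_mean) / sd
        z[masked] = np.nan
        masked = masked | np.isnan(z)
        z[masked] = np.nan
    return WindowTrack(method, chrom_arr, pos_arr, z, masked)


def combine_z(
    tracks: list[WindowTrack],
    sigma: np.ndarray | None = None,
    use_correlation: bool = False,
    renormalize_partial: bool = False,
) -> tuple[WindowTrack, np.ndarray]:
    """Covariance-corrected combined Z: sum_i Z_i / sqrt(1' Sigma 1).

    Sigma is estimated genome-wide over windows unmasked in every track
    (covariance by default; correlation behind the flag), floored to positive
    semidefinite if needed.  Windows where any method is masked are masked,
    unless ``renormalize_partial`` renormalizes over the available methods.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two method tracks")
    base = tracks[0]
    for t in tracks[1:]:
        if not t.same_grid(base):
            raise ValueError("tracks are not on a shared window grid")
    Z = np.vstack([t.z for t in tracks])
    masked_each = np.vstack([t.masked for t in tracks])
    complete = ~masked_each.any(axis=0)
    if sigma is None:
        if complete.sum() < len(tracks) + 1:
            raise ValueError("too few jointly unmasked windows to estimate Sigma")
        sigma = np.corrcoef(Z[:, complete]) if use_correlation else np.cov(Z[:, complete])
    sigma = np.asarray(sigma, dtype=float)
    w, V = np.linalg.eigh((sigma + sigma.T) / 2.0)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        logger.warning("combine_z: Sigma eigenvalue floor applied (min %.3g)", w.min())
        sigma = (V * np.maximum(w, 0.0)) @ V.T
    denom = float(np.sqrt(np.ones(len(tracks)) @ sigma @ np.ones(len(tracks))))
    combined = np.full(base.n_windows, np.nan)
    combined[complete] = Z[:, complete].sum(axis=0) / denom
    masked = ~complete
    if renormalize_partial:
        partial = masked_each.any(axis=0) & ~masked_each.all(axis=0)
        for j in np.flatnonzero(partial):
            avail = ~masked_each[:, j]
            d = float(np.sqrt(np.ones(avail.sum()) @ sigma[np.ix_(avail, avail)] @ np.ones(avail.sum())))
            combined[j] = Z[avail, j].sum() / d
        masked = masked_each.all(axis=0)
        combined[masked] = np.nan
    return (
        WindowTrack("combined", base.chrom, base.lead_pos, combined, masked),
        sigma,
    )


def z_to_p(z, sidedness: str = "two-sided"):
    """Normal-tail p-value: two-sided 2(1-Phi(|z|)); one-sided upper 1-Phi(z)."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z)) if sidedness == "two-sided" else stats.norm.sf(z)
    return float(p) if p.ndim == 0 else p


def p_to_z_threshold(alpha: float, n_tests: int = 1, sidedness: str = "one-sided") -> float:
    """Z threshold for a Bonferroni-corrected alpha (inverse of :func:`z_to_p`).

    Returned as a non-negative |Z| threshold (alpha >= the sidedness-appropriate
    ceiling gives 0, i.e. everything passes).
    """
    a = alpha / n_tests
    z = stats.norm.isf(a / 2.0) if sidedness == "two-sided" else stats.norm.isf(a)
    return float(max(z, 0.0))


def call_candidate_regions(track: WindowTrack, config: ScanConfig | None = None) -> pd.DataFrame:
    """Merge supra-threshold windows into candidate regions with lead SNPs.

    Windows with |Z| above the discovery threshold are merged when their lead
    SNPs lie within the merge radius; the region lead is the window with
    maximal |Z|, and positive Z means excess hunter-gatherer ancestry.
    """
    config = config or ScanConfig()
    hits = np.flatnonzero(~track.masked & (np.abs(track.z) > config.z_threshold))
    rows = []
    if len(hits):
        group = [hits[0]]
        for j in hits[1:]:
            if (
                track.chrom[j] == track.chrom[group[-1]]
                and track.lead_pos[j] - track.lead_pos[group[-1]] <= config.merge_radius_bp
            ):
                group.append(j)
            else:
                rows.append(_summarize_region(track, group, config))
                group = [j]
        rows.append(_summarize_region(track, group, config))
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "lead_pos",
            "lead_z",
            "p",
            "sign",
            "n_windows",
        ],
    )


def _summarize_region(track: WindowTrack, group: list[int], config: ScanConfig) -> dict:
    g = np.asarray(group)
    lead = g[np.argmax(np.abs(track.z[g]))]
    zv = float(track.z[lead])
    return {
        "chrom": track.chrom[lead],
        "start_bp": int(track.lead_pos[g].min()),
        "end_bp": int(track.lead_pos[g].max()),
        "lead_pos": int(track.lead_pos[lead]),
        "lead_z": zv,
        "p": z_to_p(zv, config.sidedness),
        "sign": int(np.sign(zv)),
        "n_windows": int(len(g)),
    }


def replicate(
    regions: pd.DataFrame,
    replication_track: WindowTrack,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Replication verdict per discovery region.

    A region replicates iff some unmasked window of the replication track
    within the replication radius of the discovery lead SNP reaches
    |Z| >= the replication threshold with matching sign.
    """
    config = config or ScanConfig()
    out = regions.copy()
    verdicts, best = [], []
    for _, reg in regions.iterrows():
        near = (
            (replication_track.chrom == reg["chrom"])
            & (np.abs(replication_track.lead_pos - reg["lead_pos"]) <= config.replication_radius_bp)
            & ~replication_track.masked
        )
        zs = replication_track.z[near]
        same_sign = zs * reg["sign"] > 0
        if same_sign.any():
            zbest = zs[same_sign][np.argmax(np.abs(zs[same_sign]))]
        elif len(zs):
            zbest = zs[np.argmax(np.abs(zs))]
        else:
            zbest = np.nan
        ok = bool(
            same_sign.any() and np.max(np.abs(zs[same_sign])) >= config.replication_z
        )
        verdicts.append(ok)
        best.append(float(zbest))
    out["replicated"] = verdicts
    out["best_replication_z"] = best
    return out


def low_ancestry_diagnostic(
    calls: AncestryCalls,
    regions: pd.DataFrame,
    panel: SitePanel,
    reference_global: pd.Series,
    cutoff: float = 0.1,
    ratio: float = 0.5,
    window: int = 51,
) -> pd.DataFrame:
    """Selection-vs-misclassification diagnostic on a low-ancestry subset.

    For the full cohort and the subset with reference global ancestry below
    ``cutoff``, the per-region deviation is the mean local hunter-gatherer
    ancestry at the lead window minus that group's genome-wide mean.  Because
    low-ancestry individuals are nearly unaffected by selection on the minor
    ancestry, a region is "selection-consistent" when the subset deviation is
    small relative to the full-cohort deviation (|subset| < |full| * ratio)
    and "misclassification-suspect" otherwise.
    """
    subset_inds = set(reference_global.index[reference_global < cutoff])
    if not subset_inds:
        logger.warning("low_ancestry_diagnostic: no individuals below cutoff %.3g", cutoff)
    hap_groups = {
        "full": list(range(calls.n_haplotypes)),
        "subset": [
            i for i, h in enumerate(calls.haplotypes) if individual_of(h) in subset_inds
        ],
    }
    ind_mat = calls.hg_indicator()
    half = window // 2
    pos = panel.sites["pos"].to_numpy()
    chrom = panel.sites["chrom"].to_numpy()
    rows = []
    for _, reg in regions.iterrows():
        rec = {"chrom": reg["chrom"], "lead_pos": reg["lead_pos"]}
        for name, hrows in hap_groups.items():
            if not hrows:
                rec[f"deviation_{name}"] = np.nan
                continue
            sub = ind_mat[hrows]
            genome = np.nanmean(sub)
            on_chrom = np.flatnonzero(chrom == reg["chrom"])
            center = on_chrom[np.argmin(np.abs(pos[on_chrom] - reg["lead_pos"]))]
            lo = max(center - half, on_chrom[0])
            hi = min(center + half + 1, on_chrom[-1] + 1)
            local = np.nanmean(sub[:, lo:hi])
            rec[f"deviation_{name}"] = float(local - genome)
        ds, df_ = rec.get("deviation_subset"), rec.get("deviation_full")
        if ds is None or df_ is None or np.isnan(ds) or np.isnan(df_):
            rec["classification"] = "undetermined"
        else:
            rec["classification"] = (
                "selection-consistent"
                if abs(ds) < abs(df_) * ratio
                else "misclassification-suspect"
            )
        rows.append(rec)
    return pd.DataFrame(rows)
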