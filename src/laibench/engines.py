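"""In-repo local-ancestry callers and the shared post-processing steps.

Two engines are provided, mirroring the two families of desk-reproducible LAI
approaches: a sliding-window minimum-mismatch caller (assign each window to
the source panel containing the closest haplotype) and a per-haplotype
two-state hidden Markov model with allele-frequency emissions and
admixture-time-scaled transitions.  Both emit SNP-level :class:`AncestryCalls`
so every downstream comparison runs on a single currency.

Post-processing: recoding of external path codes onto the two sources,
per-chromosome bias correction of population mean-ancestry tracks, TRACTOR-style
"unkink" rephasing, and male-X haplotype de-duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import (
    LABEL_FARMER,
    LABEL_HG,
    LABEL_MISSING,
    AncestryCalls,
    GenotypeMatrix,
    SitePanel,
    individual_of,
)

logger = logging.getLogger("laibench")

__all__ = [
    "MismatchConfig",
    "HmmConfig",
    "PATH_RECODE_DEFAULT",
    "call_mismatch",
    "call_hmm",
    "hmm_posterior_hg",
    "estimate_frequencies",
    "recode_paths",
    "correct_chromosome_bias",
    "unkink",
    "count_switches",
    "dedup_male_x",
    "encode_pseudodiploid",
]


@dataclass(frozen=True)
class MismatchConfig:
    """Window-mismatch caller settings.

    ``min_sites`` defaults far below the source tool's recommended 1000
    because the synthetic panels are much sparser than real imputed data;
    ``decision_threshold`` (the tool's mismatch-ratio cut) is tracked as an
    ambiguity diagnostic and does not veto calls.
    """

    span_bp: int = 1_000_000
    step_bp: int = 500_000
    max_sites: int = 2000
    min_sites: int = 50
    decision_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.step_bp > self.span_bp:
            raise ValueError("window step must not exceed span")
        if self.min_sites > self.max_sites:
            raise ValueError("min_sites must not exceed max_sites")


@dataclass(frozen=True)
class HmmConfig:
    """Two-state HMM settings.

    ``ne`` is retained for interface parity with the read-count HMM tool's
    parameterization but the per-haplotype two-state model has no drift term,
    so it does not enter the computation.
    """

    T: float = 35.0
    ne: float = 10_000.0
    p_hg: float = 0.2
    emission: str = "genotype"  # or "read-count"
    read_error: float = 0.0
    freq_clamp: float = 1e-3

    def __post_init__(self) -> None:
        if not 0 < self.p_hg < 1:
            raise ValueError("p_hg must be in (0, 1)")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.emission not in {"genotype", "read-count"}:
            raise ValueError("emission must be 'genotype' or 'read-count'")


# ---------------------------------------------------------------------------
# window-mismatch caller
# ---------------------------------------------------------------------------


def _one_hot(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        (x == 1).astype(np.float32),
        (x == 0).astype(np.float32),
        (x >= 0).astype(np.float32),
    )


def call_mismatch(
    panel: SitePanel,
    genotypes: GenotypeMatrix,
    source_hg: GenotypeMatrix,
    source_farmer: GenotypeMatrix,
    config: MismatchConfig | None = None,
) -> AncestryCalls:
    """Assign each window to the source containing the least-mismatching haplotype.

    Per window and target haplotype the mismatch *fraction* over pairwise
    non-missing sites is minimized over every hunter-gatherer and every farmer
    source haplotype; the window takes the ancestry of the smaller minimum
    (exact ties go to farmer, the majority ancestry, and are counted).  Each
    SNP inherits the label of the window whose center is nearest.  The
    pseudo-posterior is worse/(best+worse), clipped to [0.5, 1].
    """
    config = config or MismatchConfig()
    if source_hg.n_haplotypes == 0 or source_farmer.n_haplotypes == 0:
        raise ValueError("empty source panel")
    n_hap = genotypes.n_haplotypes
    labels = np.full((n_hap, panel.n_sites), LABEL_MISSING, dtype=np.int8)
    posterior = np.full((n_hap, panel.n_sites), np.nan, dtype=np.float32)
    n_tie = 0
    n_windows = 0
    n_ambiguous = 0

    pos_all = panel.sites["pos"].to_numpy()
    for chrom, sl in panel.chrom_slices().items():
        pos = pos_all[sl]
        starts = np.arange(pos[0], pos[-1] + 1, config.step_bp)
        centers, wlab, wpost = [], [], []
        for ws in starts:
            lo = np.searchsorted(pos, ws, side="left")
            hi = np.searchsorted(pos, ws + config.span_bp, side="left")
            centers.append(ws + config.span_bp // 2)
            if hi - lo < config.min_sites:
                wlab.append(np.full(n_hap, LABEL_MISSING, dtype=np.int8))
                wpost.append(np.full(n_hap, np.nan, dtype=np.float32))
                continue
            idx = np.arange(lo, hi)
            if len(idx) > config.max_sites:
                idx = idx[np.linspace(0, len(idx) - 1, config.max_sites).astype(int)]
            cols = sl.start + idx
            t1, t0, tv = _one_hot(genotypes.alleles[:, cols])
            best = {}
            for key, src in (("hg", source_hg), ("farmer", source_farmer)):
                s1, s0, sv = _one_hot(src.alleles[:, cols])
                mism = t1 @ s0.T + t0 @ s1.T
                valid = tv @ sv.T
                with np.errstate(divide="ignore", invalid="ignore"):
                    rate = np.where(valid > 0, mism / valid, np.inf)
                best[key] = rate.min(axis=1)
            b_hg, b_f = best["hg"], best["farmer"]
            lab = np.where(b_hg < b_f, LABEL_HG, LABEL_FARMER).astype(np.int8)
            lab[~np.isfinite(b_hg) & ~np.isfinite(b_f)] = LABEL_MISSING
            n_tie += int(np.sum((b_hg == b_f) & np.isfinite(b_hg)))
            n_windows += n_hap
            worse = np.maximum(b_hg, b_f)
            bsum = np.minimum(b_hg, b_f) + worse
            with np.errstate(divide="ignore", invalid="ignore"):
                post = np.where(bsum > 0, worse / bsum, 0.5)
            post = np.clip(post, 0.5, 1.0).astype(np.float32)
            post[lab == LABEL_MISSING] = np.nan
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(
                    np.minimum(b_hg, b_f) > 0, worse / np.minimum(b_hg, b_f), np.inf
                )
            n_ambiguous += int(np.sum(ratio < config.decision_threshold))
            wlab.append(lab)
            wpost.append(post)
        centers = np.asarray(centers)
        wlab_m = np.stack(wlab, axis=1)  # (n_hap, n_windows)
        wpost_m = np.stack(wpost, axis=1)
        # nearest window center per site
        j = np.searchsorted(centers, pos)
        j = np.clip(j, 0, len(centers) - 1)
        left = np.clip(j - 1, 0, len(centers) - 1)
        use_left = np.abs(pos - centers[left]) <= np.abs(centers[j] - pos)
        nearest = np.where(use_left & (j > 0), left, j)
        labels[:, sl] = wlab_m[:, nearest]
        posterior[:, sl] = wpost_m[:, nearest]

    if n_windows:
        logger.info(
            "call_mismatch: tie frequency %.4g, ambiguous-window frequency %.4g",
            n_tie / n_windows,
            n_ambiguous / n_windows,
        )
    return AncestryCalls(list(genotypes.haplotypes), labels, posterior, "mismatch")


# ---------------------------------------------------------------------------
# two-state HMM caller
# ---------------------------------------------------------------------------


def estimate_frequencies(source: GenotypeMatrix) -> np.ndarray:
    """Per-site allele frequency over non-missing source haplotypes."""
    ok = source.alleles >= 0
    n = ok.sum(axis=0)
    f = np.where(ok, source.alleles, 0).sum(axis=0) / np.maximum(n, 1)
    f = np.where(n == 0, 0.5, f)
    return f.astype(float)


def hmm_posterior_hg(
    panel: SitePanel,
    genotypes: GenotypeMatrix,
    freq_hg: np.ndarray,
    freq_farmer: np.ndarray,
    config: HmmConfig | None = None,
    dtype=np.float64,
) -> np.ndarray:
    """Forward-backward posterior of hunter-gatherer ancestry per haplotype/site.

    Transition between adjacent sites at distance d cM leaves ancestry ``a``
    with probability 1 - exp(-T (1 - p_a) d / 100); emissions are
    Bernoulli(source allele frequency), with the frequency moved toward 0.5 by
    the read error in read-count mode.  Chromosomes are independent chains.
    """
    config = config or HmmConfig()
    eps = config.freq_clamp
    fh = np.clip(freq_hg, eps, 1 - eps)
    ff = np.clip(freq_farmer, eps, 1 - eps)
    if np.any(freq_hg != fh) or np.any(freq_farmer != ff):
        logger.info("call_hmm: source frequencies clamped to [%g, %g]", eps, 1 - eps)
    if config.emission == "read-count":
        e = config.read_error
        fh = fh * (1 - e) + (1 - fh) * e
        ff = ff * (1 - e) + (1 - ff) * e

    n_hap, n_sites = genotypes.alleles.shape
    # emission lookup per site: rows = allele {0, 1, missing}
    emit_f = np.stack([1 - ff, ff, np.ones(n_sites)])
    emit_h = np.stack([1 - fh, fh, np.ones(n_sites)])
    aidx = np.where(genotypes.alleles < 0, 2, genotypes.alleles).astype(np.int8)

    p = config.p_hg
    cm = panel.sites["cm"].to_numpy()
    post_hg = np.empty((n_hap, n_sites), dtype=dtype)
    slices = panel.chrom_slices()
    nmax = max(sl.stop - sl.start for sl in slices.values())
    # time-major working buffers, reused across chromosomes
    E0 = np.empty((nmax, n_hap))
    E1 = np.empty((nmax, n_hap))
    A0 = np.empty((nmax, n_hap))
    A1 = np.empty((nmax, n_hap))
    G = np.empty((nmax, n_hap))
    for chrom, sl in slices.items():
        n = sl.stop - sl.start
        cols = np.arange(sl.start, sl.stop)[:, None]
        at = aidx[:, sl].T
        E0[:n] = emit_f[at, cols]
        E1[:n] = emit_h[at, cols]
        d = np.diff(cm[sl])
        qf = (1.0 - np.exp(-config.T * p * d / 100.0)).tolist()  # leave farmer
        qh = (1.0 - np.exp(-config.T * (1 - p) * d / 100.0)).tolist()  # leave HG
        a0 = (1 - p) * E0[0]
        a1 = p * E1[0]
        s = a0 + a1
        A0[0], A1[0] = a0 / s, a1 / s
        for j in range(1, n):
            q_f, q_h = qf[j - 1], qh[j - 1]
            a0 = (A0[j - 1] * (1 - q_f) + A1[j - 1] * q_h) * E0[j]
            a1 = (A0[j - 1] * q_f + A1[j - 1] * (1 - q_h)) * E1[j]
            s = a0 + a1
            A0[j], A1[j] = a0 / s, a1 / s
        G[n - 1] = A1[n - 1] / (A0[n - 1] + A1[n - 1])
        b0 = np.ones(n_hap)
        b1 = np.ones(n_hap)
        for j in range(n - 2, -1, -1):
            q_f, q_h = qf[j], qh[j]
            e0 = E0[j + 1] * b0
            e1 = E1[j + 1] * b1
            b0 = (1 - q_f) * e0 + q_f * e1
            b1 = q_h * e0 + (1 - q_h) * e1
            s = b0 + b1
            b0, b1 = b0 / s, b1 / s
            G[j] = A1[j] * b1 / (A0[j] * b0 + A1[j] * b1)
        post_hg[:, sl] = G[:n].T
    return post_hg


def call_hmm(
    panel: SitePanel,
    genotypes: GenotypeMatrix,
    freq_hg: np.ndarray,
    freq_farmer: np.ndarray,
    config: HmmConfig | None = None,
    dtype=np.float64,
) -> AncestryCalls:
    """Posterior-decode the two-state HMM into SNP-level ancestry calls.

    The label is the argmax posterior (exact 0.5 ties go to farmer, the
    majority ancestry); the stored posterior is that of the assigned label.
    """
    post_hg = hmm_posterior_hg(panel, genotypes, freq_hg, freq_farmer, config, dtype)
    labels = np.where(post_hg > 0.5, LABEL_HG, LABEL_FARMER).astype(np.int8)
    posterior = np.maximum(post_hg, 1 - post_hg).astype(np.float32)
    return AncestryCalls(list(genotypes.haplotypes), labels, posterior, "hmm")


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

#: external path codes {1..6} onto the two sources: {3, 4} are
#: hunter-gatherer-proximal, {1, 2, 5, 6} farmer-proximal
PATH_RECODE_DEFAULT: dict[int, int] = {
    1: LABEL_FARMER,
    2: LABEL_FARMER,
    3: LABEL_HG,
    4: LABEL_HG,
    5: LABEL_FARMER,
    6: LABEL_FARMER,
}


def recode_paths(raw, mapping: dict[int, int] | None = None):
    """Map integer path codes onto source labels (total mapping; unknown -> error).

    Accepts a plain integer array or an :class:`AncestryCalls` whose labels
    are path codes; missing (-1) passes through.
    """
    mapping = mapping or PATH_RECODE_DEFAULT
    if isinstance(raw, AncestryCalls):
        return AncestryCalls(
            list(raw.haplotypes),
            recode_paths(raw.labels, mapping),
            raw.posterior,
            raw.method or "recoded",
        )
    codes = np.asarray(raw)
    lut = np.full(max(mapping) + 1, -2, dtype=np.int8)
    for k, v in mapping.items():
        lut[k] = v
    out = np.full(codes.shape, LABEL_MISSING, dtype=np.int8)
    known = codes == LABEL_MISSING
    valid = (codes >= 0) & (codes <= max(mapping))
    if not np.all(known | valid):
        bad = codes[~(known | valid)].ravel()[0]
        raise ValueError(f"unknown path code {bad}")
    out[valid] = lut[codes[valid]]
    if np.any(out == -2):
        bad = codes[(out == -2)].ravel()[0]
        raise ValueError(f"unknown path code {bad}")
    out[known] = LABEL_MISSING
    return out


def correct_chromosome_bias(snp_means: np.ndarray, panel: SitePanel) -> np.ndarray:
    """Remove per-chromosome offsets from a population mean-ancestry track.

    Each chromosome's SNP means are shifted by (chromosome mean - genome-wide
    mean), so that afterwards every chromosome mean equals the genome mean.
    """
    snp_means = np.asarray(snp_means, dtype=float)
    out = snp_means.copy()
    genome = np.nanmean(snp_means)
    for chrom, sl in panel.chrom_slices().items():
        out[sl] -= np.nanmean(snp_means[sl]) - genome
    return out


def count_switches(calls: AncestryCalls, panel: SitePanel) -> int:
    """Total ancestry switches between adjacent non-missing calls, all haplotypes."""
    total = 0
    for chrom, sl in panel.chrom_slices().items():
        lab = calls.labels[:, sl]
        a, b = lab[:, :-1], lab[:, 1:]
        total += int(np.sum((a != b) & (a != LABEL_MISSING) & (b != LABEL_MISSING)))
    return total


def unkink(calls: AncestryCalls, ploidy: dict[str, int] | None = None) -> AncestryCalls:
    """TRACTOR-style rephasing: where both haplotypes of a diploid switch
    ancestry simultaneously in opposite directions, swap their label
    assignments from that point on.  Never increases the switch count.

    ``ploidy`` (individual -> 1 or 2) lets ploidy-1 individuals pass through.
    Operates over the whole site axis; chromosome boundaries are irrelevant
    because a swap applied from a boundary onward relabels entire chromosomes
    symmetrically.
    """
    out = calls.copy()
    hap_row = {h: i for i, h in enumerate(calls.haplotypes)}
    for ind in calls.individuals:
        if ploidy is not None and ploidy.get(ind, 2) != 2:
            continue
        h0, h1 = f"{ind}.0", f"{ind}.1"
        if h1 not in hap_row:
            continue
        r0, r1 = hap_row[h0], hap_row[h1]
        l0, l1 = out.labels[r0], out.labels[r1]
        ok = (
            (l0[:-1] != LABEL_MISSING)
            & (l0[1:] != LABEL_MISSING)
            & (l1[:-1] != LABEL_MISSING)
            & (l1[1:] != LABEL_MISSING)
        )
        kink = ok & (l0[:-1] != l0[1:]) & (l1[:-1] != l1[1:]) & (l0[:-1] != l1[:-1])
        if not kink.any():
            continue
        parity = np.zeros(calls.n_sites, dtype=bool)
        parity[1:] = (np.cumsum(kink) % 2).astype(bool)
        new0 = np.where(parity, l1, l0)
        new1 = np.where(parity, l0, l1)
        out.labels[r0], out.labels[r1] = new0, new1
        if out.posterior is not None:
            p0, p1 = out.posterior[r0].copy(), out.posterior[r1].copy()
            out.posterior[r0] = np.where(parity, p1, p0)
            out.posterior[r1] = np.where(parity, p0, p1)
    return out


def dedup_male_x(calls: AncestryCalls, ploidy: dict[str, int]) -> AncestryCalls:
    """Keep exactly one haplotype per ploidy-1 individual (male X de-duplication)."""
    keep = []
    seen: set[str] = set()
    for h in calls.haplotypes:
        ind = individual_of(h)
        if ploidy.get(ind, 2) == 1:
            if ind in seen:
                continue
            seen.add(ind)
        keep.append(h)
    idx = [calls.haplotypes.index(h) for h in keep]
    return AncestryCalls(
        keep,
        calls.labels[idx],
        None if calls.posterior is None else calls.posterior[idx],
        calls.method,
    )


def encode_pseudodiploid(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Duplicate the haploid sequence of ploidy-1 individuals so diploid-only
    engines can process them (undone afterwards with :func:`dedup_male_x`)."""
    names: list[str] = []
    rows: list[np.ndarray] = []
    hap_row = {h: i for i, h in enumerate(genotypes.haplotypes)}
    for ind in genotypes.individuals:
        h0 = f"{ind}.0"
        names.append(h0)
        rows.append(genotypes.alleles[hap_row[h0]])
        if genotypes.ploidy.get(ind, 2) == 1:
            names.append(f"{ind}.1")
            rows.append(genotypes.alleles[hap_row[h0]])
        elif f"{ind}.1" in hap_row:
            names.append(f"{ind}.1")
            rows.append(genotypes.alleles[hap_row[f"{ind}.1"]])
    return GenotypeMatrix(names, np.array(rows, dtype=np.int8), dict(genotypes.ploidy))
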