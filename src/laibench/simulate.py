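"""Synthetic two-way admixed cohorts with known truth tracts.

The generator emulates a single-pulse admixture between two diverged source
populations (hunter-gatherers, the ~20% minor ancestry, and farmers): ancestry
along each haplotype is a two-state Markov jump process in genetic distance
whose switch rate out of ancestry ``a`` is ``T * (1 - p_a) / 100`` per cM, the
stationary approximation to a T-generation pedigree.  Source divergence is a
Balding-Nichols model at a chosen F_ST; ancient-DNA artefacts (genotype error,
phase-switch error, pseudohaploid sampling) are layered on top.  Local
"selection" is injected by resampling truth labels around chosen loci, giving
exact control of the ancestry deviation a scan must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    LABEL_FARMER,
    LABEL_HG,
    AncestryCalls,
    GenotypeMatrix,
    SitePanel,
)

__all__ = [
    "SimulationConfig",
    "SelectionLocus",
    "SourceFrequencies",
    "TruthTracts",
    "SimulatedCohort",
    "simulate_source_frequencies",
    "lay_tracts",
    "inject_selection",
    "emit_genotypes",
    "truth_calls",
    "simulate_cohort",
    "phase_scramble_calls",
    "hudson_fst",
    "switch_rate",
]


def switch_rate(T: float, p_focal: float) -> float:
    """Per-cM rate of leaving an ancestry whose genome-wide proportion is p_focal."""
    return T * (1.0 - p_focal) / 100.0


@dataclass(frozen=True)
class SelectionLocus:
    """A locus with injected ancestry deviation: HG probability becomes
    ``p + delta`` at ``pos_cm``, tapering linearly to ``p`` at ``radius_cm``."""

    chrom: str
    pos_cm: float
    delta: float
    radius_cm: float


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the admixed Neolithic setting: a single admixture pulse
    T=35 generations ago, 20% hunter-gatherer ancestry, and unbalanced source
    panels of 48 hunter-gatherers vs 7 farmers (diploid individuals).
    """

    n_admixed: int = 50
    n_source_hg: int = 48
    n_source_farmer: int = 7
    T: float = 35.0
    p_hg: float = 0.2
    n_chrom: int = 3
    sites_per_chrom: int = 2000
    chrom_length_cm: float = 150.0
    f_st: float = 0.1
    selection_loci: tuple[SelectionLocus, ...] = ()
    genotype_error_rate: float = 1e-3
    phase_switch_rate: float = 0.0  # per cM, per diploid individual
    pseudohaploid: bool = False
    n_males: int = 0  # leading individuals carry one haplotype (X-style)
    seed: int = 0

    def __post_init__(self) -> None:
        # p_hg = 1 is tolerated as a declared degenerate case (single HG tract)
        if not 0 < self.p_hg <= 1:
            raise ValueError("p_hg must be in (0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0 < self.f_st < 1:
            raise ValueError("f_st must be in (0, 1)")
        loci = tuple(
            l if isinstance(l, SelectionLocus) else SelectionLocus(*l)
            for l in self.selection_loci
        )
        self.selection_loci = loci
        for l in loci:
            if abs(l.delta) > min(self.p_hg, 1 - self.p_hg):
                raise ValueError(
                    f"selection delta {l.delta} pushes local ancestry outside (0, 1)"
                )

    @property
    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chrom)]

    @property
    def chrom_length_bp(self) -> int:
        # fixed 1 cM / Mb map
        return int(self.chrom_length_cm * 1e6)


@dataclass
class SourceFrequencies:
    """Per-site allele frequencies: ancestral plus the two source populations."""

    ancestral: np.ndarray
    hg: np.ndarray
    farmer: np.ndarray

    def for_state(self, states: np.ndarray, site_index: np.ndarray) -> np.ndarray:
        f = np.where(states == LABEL_HG, self.hg[site_index], self.farmer[site_index])
        return f


@dataclass
class TruthTracts:
    """Ground-truth ancestry segments; tracts tile each haplotype exactly.

    ``tracts`` columns: hap, chrom, start_cm, end_cm, state (0 farmer, 1 HG).
    """

    tracts: pd.DataFrame
    chrom_length_cm: float

    def __post_init__(self) -> None:
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] | None = None

    def haplotypes(self) -> list[str]:
        return list(dict.fromkeys(self.tracts["hap"]))

    def segments(self, hap: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(end_cm breakpoints, states) for one haplotype chromosome."""
        if self._index is None:
            idx: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
            for (h, c), grp in self.tracts.groupby(["hap", "chrom"], sort=False):
                g = grp.sort_values("start_cm")
                idx[(h, c)] = (g["end_cm"].to_numpy(), g["state"].to_numpy(np.int8))
            self._index = idx
        return self._index[(hap, chrom)]

    def states_at(self, hap: str, chrom: str, cm: np.ndarray) -> np.ndarray:
        ends, states = self.segments(hap, chrom)
        i = np.minimum(np.searchsorted(ends, cm, side="right"), len(states) - 1)
        return states[i]

    def hg_fraction(self) -> float:
        """Length-weighted genome-wide hunter-gatherer fraction."""
        t = self.tracts
        lens = (t["end_cm"] - t["start_cm"]).to_numpy()
        return float(lens[t["state"].to_numpy() == LABEL_HG].sum() / lens.sum())


def simulate_source_frequencies(
    config: SimulationConfig, rng: np.random.Generator
) -> SourceFrequencies:
    """Draw ancestral and source-population allele frequencies.

    Ancestral frequencies are Uniform(0.05, 0.95) (near-fixed sites would make
    the divergence model degenerate, mirroring a MAF-filtered panel); each
    source frequency is Balding-Nichols:
    Beta(f(1-F)/F, (1-f)(1-F)/F) with F = f_st.
    """
    n = config.n_chrom * config.sites_per_chrom
    f = rng.uniform(0.05, 0.95, size=n)
    F = config.f_st
    a = f * (1 - F) / F
    b = (1 - f) * (1 - F) / F
    hg = rng.beta(a, b)
    farmer = rng.beta(a, b)
    return SourceFrequencies(f, hg, farmer)


def lay_tracts(
    config: SimulationConfig,
    rng: np.random.Generator,
    haplotypes: list[str] | None = None,
) -> TruthTracts:
    """Lay ancestry tracts for every haplotype as a two-state Markov jump process.

    Sojourn lengths out of ancestry ``a`` are Exp(T * (1 - p_a) / 100) per cM;
    the initial state is hunter-gatherer with probability ``p_hg``, so the
    expected genome-wide HG fraction is exactly ``p_hg``.
    """
    if haplotypes is None:
        haplotypes = _admixed_haplotype_names(config)
    H = len(haplotypes)
    L = config.chrom_length_cm
    rate = np.array(
        [switch_rate(config.T, 1 - config.p_hg), switch_rate(config.T, config.p_hg)]
    )  # index by state: out-rate of farmer(0), HG(1)
    rows_hap, rows_chrom, rows_start, rows_end, rows_state = [], [], [], [], []
    for chrom in config.chrom_names:
        state = (rng.random(H) < config.p_hg).astype(np.int8)
        pos = np.zeros(H)
        alive = np.arange(H)
        while alive.size:
            r = rate[state[alive]]
            soj = np.full(alive.size, np.inf)
            live = r > 0  # zero rate (degenerate p) => infinite sojourn
            if live.any():
                soj[live] = rng.exponential(1.0 / r[live])
            end = np.minimum(pos[alive] + soj, L)
            rows_hap.append(alive.copy())
            rows_chrom.append(np.full(alive.size, chrom, dtype=object))
            rows_start.append(pos[alive].copy())
            rows_end.append(end)
            rows_state.append(state[alive].copy())
            done = end >= L
            cont = alive[~done]
            pos[cont] = end[~done]
            state[cont] = 1 - state[cont]
            alive = cont
    df = pd.DataFrame(
        {
            "hap": np.array(haplotypes, dtype=object)[np.concatenate(rows_hap)],
            "chrom": np.concatenate(rows_chrom),
            "start_cm": np.concatenate(rows_start),
            "end_cm": np.concatenate(rows_end),
            "state": np.concatenate(rows_state),
        }
    ).sort_values(["hap", "chrom", "start_cm"], kind="stable", ignore_index=True)
    return TruthTracts(df, L)


def _admixed_haplotype_names(config: SimulationConfig) -> list[str]:
    names = []
    for i in range(config.n_admixed):
        ind = f"adm{i}"
        names.append(f"{ind}.0")
        if i >= config.n_males:
            names.append(f"{ind}.1")
    return names


def inject_selection(
    truth: TruthTracts,
    loci: tuple[SelectionLocus, ...],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TruthTracts:
    """Resample truth labels around each locus so the local HG probability is
    ``p + delta`` at the locus, tapering linearly to ``p`` at the radius edge.

    For delta > 0 each haplotype is independently converted to HG with
    probability delta/(1-p) over an interval of half-width Uniform(0, radius);
    marginalising the uniform half-width yields exactly the linear taper.
    delta < 0 converts to farmer with probability -delta/p symmetrically.
    """
    p = config.p_hg
    df = truth.tracts
    haps = truth.haplotypes()
    per_hap: dict[tuple[str, str], list[tuple[float, float, int]]] = {}
    for l in loci:
        if not 0 < p + l.delta < 1:
            raise ValueError(f"locus at {l.chrom}:{l.pos_cm} pushes ancestry outside (0,1)")
        if l.delta == 0:
            continue
        target = LABEL_HG if l.delta > 0 else LABEL_FARMER
        c = l.delta / (1 - p) if l.delta > 0 else -l.delta / p
        convert = rng.random(len(haps)) < c
        half = rng.uniform(0.0, l.radius_cm, size=len(haps))
        for h, conv, w in zip(haps, convert, half):
            if conv:
                per_hap.setdefault((h, l.chrom), []).append(
                    (l.pos_cm - w, l.pos_cm + w, target)
                )
    if not per_hap:
        return TruthTracts(df.copy(), truth.chrom_length_cm)

    keep = []
    new_rows = []
    for (h, c), grp in df.groupby(["hap", "chrom"], sort=False):
        ivs = per_hap.get((h, c))
        if not ivs:
            keep.append(grp)
            continue
        starts = grp["start_cm"].to_numpy()
        ends = grp["end_cm"].to_numpy()
        states = grp["state"].to_numpy(np.int8)
        for a, b, s in ivs:
            a = max(a, 0.0)
            b = min(b, truth.chrom_length_cm)
            starts, ends, states = _overwrite_interval(starts, ends, states, a, b, s)
        new_rows.append(
            pd.DataFrame(
                {"hap": h, "chrom": c, "start_cm": starts, "end_cm": ends, "state": states}
            )
        )
    out = pd.concat(keep + new_rows, ignore_index=True).sort_values(
        ["hap", "chrom", "start_cm"], kind="stable", ignore_index=True
    )
    return TruthTracts(out, truth.chrom_length_cm)


def _overwrite_interval(
    starts: np.ndarray, ends: np.ndarray, states: np.ndarray, a: float, b: float, s: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Set ancestry to ``s`` on [a, b], keeping tracts tiling and merged."""
    ns, ne, st = [], [], []
    for s0, e0, x in zip(starts, ends, states):
        if e0 <= a or s0 >= b:
            ns.append(s0), ne.append(e0), st.append(x)
        else:
            if s0 < a:
                ns.append(s0), ne.append(a), st.append(x)
            if e0 > b:
                ns.append(b), ne.append(e0), st.append(x)
    ns.append(a), ne.append(b), st.append(s)
    order = np.argsort(ns, kind="stable")
    ns = np.asarray(ns)[order]
    ne = np.asarray(ne)[order]
    st = np.asarray(st, dtype=np.int8)[order]
    # merge same-state neighbours
    ks, ke, kt = [ns[0]], [ne[0]], [st[0]]
    for i in range(1, len(ns)):
        if st[i] == kt[-1]:
            ke[-1] = ne[i]
        else:
            ks.append(ns[i]), ke.append(ne[i]), kt.append(st[i])
    return np.asarray(ks), np.asarray(ke), np.asarray(kt, dtype=np.int8)


def build_panel(config: SimulationConfig) -> SitePanel:
    """Evenly spaced SNP grid with a constant 1 cM/Mb genetic map."""
    rows = []
    for chrom in config.chrom_names:
        pos = np.unique(
            np.round(np.linspace(1, config.chrom_length_bp, config.sites_per_chrom))
        ).astype(np.int64)
        cm = pos / 1e6
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "cm": cm,
                    "ref": "A",
                    "alt": "G",
                    "maf": np.nan,
                    "info": 1.0,
                }
            )
        )
    return SitePanel(pd.concat(rows, ignore_index=True))


@dataclass
class SimulatedCohort:
    """Everything a downstream stage needs, with ground truth attached."""

    config: SimulationConfig
    panel: SitePanel
    frequencies: SourceFrequencies
    truth: TruthTracts
    truth_calls: AncestryCalls
    admixed: GenotypeMatrix
    source_hg: GenotypeMatrix
    source_farmer: GenotypeMatrix
    n_phase_switches: dict[str, int] = field(default_factory=dict)


def truth_calls(truth: TruthTracts, panel: SitePanel, haplotypes: list[str]) -> AncestryCalls:
    """Project truth tracts onto the SNP grid as an AncestryCalls track."""
    labels = np.empty((len(haplotypes), panel.n_sites), dtype=np.int8)
    slices = panel.chrom_slices()
    cm = panel.sites["cm"].to_numpy()
    for hi, h in enumerate(haplotypes):
        for chrom, sl in slices.items():
            labels[hi, sl] = truth.states_at(h, chrom, cm[sl])
    return AncestryCalls(haplotypes, labels, None, "truth")


def emit_genotypes(
    truth: TruthTracts,
    frequencies: SourceFrequencies,
    config: SimulationConfig,
    panel: SitePanel,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Draw alleles from tract-conditional source frequencies and add noise.

    Genotype errors flip alleles at ``genotype_error_rate``; phase-switch
    errors swap the two haplotypes of a diploid downstream of points drawn at
    ``phase_switch_rate`` per cM; pseudohaploid mode collapses each diploid to
    one random allele per site.  Returns the matrix and the realized
    phase-switch count per individual.
    """
    haps = truth.haplotypes()
    slices = panel.chrom_slices()
    cm = panel.sites["cm"].to_numpy()
    n_sites = panel.n_sites
    alleles = np.empty((len(haps), n_sites), dtype=np.int8)
    site_index = np.arange(n_sites)
    for hi, h in enumerate(haps):
        states = np.empty(n_sites, dtype=np.int8)
        for chrom, sl in slices.items():
            states[sl] = truth.states_at(h, chrom, cm[sl])
        f = frequencies.for_state(states, site_index)
        alleles[hi] = (rng.random(n_sites) < f).astype(np.int8)
    if config.genotype_error_rate > 0:
        flips = rng.random(alleles.shape) < config.genotype_error_rate
        alleles[flips] = 1 - alleles[flips]

    ploidy: dict[str, int] = {}
    for h in haps:
        ind = h.rsplit(".", 1)[0]
        ploidy[ind] = ploidy.get(ind, 0) + 1

    n_switches: dict[str, int] = {}
    if config.phase_switch_rate > 0:
        hap_row = {h: i for i, h in enumerate(haps)}
        for ind, pl in ploidy.items():
            if pl != 2:
                continue
            total = 0
            parity = np.zeros(n_sites, dtype=bool)
            for chrom, sl in slices.items():
                L = truth.chrom_length_cm
                k = rng.poisson(config.phase_switch_rate * L)
                total += k
                if k:
                    pts = np.sort(rng.uniform(0, L, size=k))
                    counts = np.searchsorted(pts, cm[sl])
                    parity[sl] = (counts % 2).astype(bool)
            n_switches[ind] = total
            if parity.any():
                r0, r1 = hap_row[f"{ind}.0"], hap_row[f"{ind}.1"]
                a0 = alleles[r0].copy()
                alleles[r0, parity] = alleles[r1, parity]
                alleles[r1, parity] = a0[parity]

    if config.pseudohaploid:
        out_names = []
        out_rows = []
        hap_row = {h: i for i, h in enumerate(haps)}
        for ind, pl in ploidy.items():
            out_names.append(f"{ind}.0")
            if pl == 2:
                pick = rng.integers(0, 2, size=n_sites)
                r0, r1 = hap_row[f"{ind}.0"], hap_row[f"{ind}.1"]
                out_rows.append(np.where(pick == 0, alleles[r0], alleles[r1]))
            else:
                out_rows.append(alleles[hap_row[f"{ind}.0"]])
        return (
            GenotypeMatrix(out_names, np.array(out_rows, dtype=np.int8), {k: 1 for k in ploidy}),
            n_switches,
        )
    return GenotypeMatrix(haps, alleles, ploidy), n_switches


def _pure_source_genotypes(
    prefix: str,
    n_individuals: int,
    freqs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    names = [f"{prefix}{i}.{k}" for i in range(n_individuals) for k in (0, 1)]
    alleles = (rng.random((len(names), len(freqs))) < freqs).astype(np.int8)
    if config.genotype_error_rate > 0:
        flips = rng.random(alleles.shape) < config.genotype_error_rate
        alleles[flips] = 1 - alleles[flips]
    return GenotypeMatrix(names, alleles, {f"{prefix}{i}": 2 for i in range(n_individuals)})


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator: frequencies, truth tracts, selection, genotypes.

    Deterministic for a given config (all randomness flows from config.seed).
    """
    rng = np.random.default_rng(config.seed)
    freqs = simulate_source_frequencies(config, rng)
    panel = build_panel(config)
    truth = lay_tracts(config, rng)
    if config.selection_loci:
        truth = inject_selection(truth, config.selection_loci, config, rng)
    tcalls = truth_calls(truth, panel, truth.haplotypes())
    admixed, n_sw = emit_genotypes(truth, freqs, config, panel, rng)
    source_hg = _pure_source_genotypes("hg", config.n_source_hg, freqs.hg, config, rng)
    source_farmer = _pure_source_genotypes(
        "f", config.n_source_farmer, freqs.farmer, config, rng
    )
    # cohort MAF over every simulated haplotype, for the site filters
    all_alleles = np.vstack([admixed.alleles, source_hg.alleles, source_farmer.alleles])
    ok = all_alleles >= 0
    f = np.where(ok, all_alleles, 0).sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
    panel.sites["maf"] = np.minimum(f, 1 - f)
    return SimulatedCohort(
        config, panel, freqs, truth, tcalls, admixed, source_hg, source_farmer, n_sw
    )


def phase_scramble_calls(
    calls: AncestryCalls,
    panel: SitePanel,
    rate_per_cm: float,
    rng: np.random.Generator,
) -> AncestryCalls:
    """Apply phase-switch errors to an ancestry track (for rephasing studies)."""
    out = calls.copy()
    cm = panel.sites["cm"].to_numpy()
    slices = panel.chrom_slices()
    hap_row = {h: i for i, h in enumerate(calls.haplotypes)}
    for ind in calls.individuals:
        h0, h1 = f"{ind}.0", f"{ind}.1"
        if h1 not in hap_row:
            continue
        parity = np.zeros(calls.n_sites, dtype=bool)
        for chrom, sl in slices.items():
            span = cm[sl][-1] - cm[sl][0]
            k = rng.poisson(rate_per_cm * span)
            if k:
                pts = np.sort(rng.uniform(cm[sl][0], cm[sl][-1], size=k))
                parity[sl] = (np.searchsorted(pts, cm[sl]) % 2).astype(bool)
        if parity.any():
            r0, r1 = hap_row[h0], hap_row[h1]
            tmp = out.labels[r0].copy()
            out.labels[r0, parity] = out.labels[r1, parity]
            out.labels[r1, parity] = tmp[parity]
            if out.posterior is not None:
                tmp2 = out.posterior[r0].copy()
                out.posterior[r0, parity] = out.posterior[r1, parity]
                out.posterior[r1, parity] = tmp2[parity]
    return out


def hudson_fst(p1: np.ndarray, p2: np.ndarray) -> float:
    """Hudson-style F_ST from known population allele frequencies."""
    num = (p1 - p2) ** 2
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())
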