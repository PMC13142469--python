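"""Readers, writers and core containers for sites, genotypes, ancestry calls and masks.

Conventions used throughout the package:

* site coordinates are 1-based inclusive base pairs (VCF convention);
* mask intervals are 0-based half-open (BED convention), converted on use;
* ancestry labels are integers: ``0`` = farmer, ``1`` = hunter-gatherer,
  ``-1`` = missing.  Every ancestry proportion reported anywhere in the
  package is a *hunter-gatherer* fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("laibench")

LABEL_FARMER = 0
LABEL_HG = 1
LABEL_MISSING = -1

#: default site filters: strictly greater-than, as printed
DEFAULT_MAF_MIN = 0.01
DEFAULT_INFO_MIN = 0.8
#: default posterior-probability cutoff for ancestry calls (strict >)
DEFAULT_POSTERIOR_MIN = 0.9
#: flank width (bp) added around unmappable regions when building masks
UNMAPPABLE_FLANK_BP = 2_500_000


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SitePanel:
    """Ordered panel of biallelic SNPs shared by all tracks.

    ``sites`` columns: ``chrom`` (str), ``pos`` (int, 1-based bp), ``cm``
    (float, non-decreasing within chromosome), ``ref``, ``alt``, ``maf``
    (minor-allele frequency in [0, 0.5]), ``info`` (imputation quality in
    [0, 1]; NaN when unknown).
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["chrom", "pos", "cm", "ref", "alt", "maf", "info"]
        missing = [c for c in req if c not in self.sites.columns]
        if missing:
            raise ValueError(f"SitePanel missing columns: {missing}")
        self.sites = self.sites.reset_index(drop=True)
        self.sites["chrom"] = self.sites["chrom"].astype(str)
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        # chromosomes must form contiguous blocks, positions strictly increasing
        seen: set[str] = set()
        last_chrom = None
        last_pos = -1
        for i in range(len(chrom)):
            if chrom[i] != last_chrom:
                if chrom[i] in seen:
                    raise ValueError(
                        f"sites not grouped by chromosome at record {i} "
                        f"({chrom[i]}:{pos[i]})"
                    )
                seen.add(chrom[i])
                last_chrom = chrom[i]
                last_pos = -1
            if pos[i] <= last_pos:
                raise ValueError(
                    f"sites not strictly increasing at record {i} "
                    f"({chrom[i]}:{pos[i]} after {chrom[i]}:{last_pos})"
                )
            last_pos = pos[i]
        cm = self.sites["cm"].to_numpy(float)
        for c in seen:
            sel = chrom == c
            vals = cm[sel]
            ok = vals[~np.isnan(vals)]
            if len(ok) > 1 and np.any(np.diff(ok) < 0):
                raise ValueError(f"cM positions decrease within chromosome {c}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice for each chromosome, in panel order."""
        chrom = self.sites["chrom"].to_numpy()
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, len(chrom) + 1):
            if i == len(chrom) or chrom[i] != chrom[start]:
                out[chrom[start]] = slice(start, i)
                start = i
        return out

    def subset(self, index: np.ndarray) -> "SitePanel":
        return SitePanel(self.sites.iloc[np.asarray(index)].reset_index(drop=True))

    def positions(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slices()[chrom]
        return self.sites["pos"].to_numpy()[sl]


@dataclass
class GenotypeMatrix:
    """Phased haplotype alleles, one row per haplotype.

    Haplotypes are named ``<individual>.0`` / ``<individual>.1``; ploidy-1
    individuals (male X, pseudohaploid collapse) contribute a single ``.0``
    row.  Alleles are int8 in {0, 1, -1 (missing)}.
    """

    haplotypes: list[str]
    alleles: np.ndarray
    ploidy: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != len(self.haplotypes):
            raise ValueError("alleles must be (n_haplotypes, n_sites)")
        if not self.ploidy:
            counts: dict[str, int] = {}
            for h in self.haplotypes:
                counts[individual_of(h)] = counts.get(individual_of(h), 0) + 1
            self.ploidy = counts

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(individual_of(h) for h in self.haplotypes))

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.haplotypes), self.alleles[:, np.asarray(index)], dict(self.ploidy)
        )

    def subset_haplotypes(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.haplotypes.index(n) for n in names]
        inds = {individual_of(n) for n in names}
        return GenotypeMatrix(
            list(names),
            self.alleles[idx],
            {k: v for k, v in self.ploidy.items() if k in inds},
        )


@dataclass
class AncestryCalls:
    """Per-haplotype, per-site ancestry labels with optional posteriors.

    The universal currency of the pipeline: every engine and every ingested
    external track is converted to this shape before benchmarking.
    """

    haplotypes: list[str]
    labels: np.ndarray
    posterior: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.haplotypes):
            raise ValueError("labels must be (n_haplotypes, n_sites)")
        if self.posterior is not None:
            self.posterior = np.asarray(self.posterior, dtype=np.float32)
            if self.posterior.shape != self.labels.shape:
                raise ValueError("posterior shape must match labels")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_sites(self) -> int:
        return self.labels.shape[1]

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(individual_of(h) for h in self.haplotypes))

    def hg_indicator(self) -> np.ndarray:
        """Float matrix: 1.0 hunter-gatherer, 0.0 farmer, NaN missing."""
        out = self.labels.astype(float)
        out[self.labels == LABEL_MISSING] = np.nan
        return out

    def copy(self) -> "AncestryCalls":
        return AncestryCalls(
            list(self.haplotypes),
            self.labels.copy(),
            None if self.posterior is None else self.posterior.copy(),
            self.method,
        )


@dataclass
class MaskRegions:
    """Excluded genomic intervals, half-open 0-based [start, end) per BED.

    Intervals are merged within each category on construction.
    """

    regions: pd.DataFrame  # chrom, start, end, category

    def __post_init__(self) -> None:
        req = ["chrom", "start", "end"]
        if any(c not in self.regions.columns for c in req):
            raise ValueError("MaskRegions needs chrom, start, end columns")
        df = self.regions.copy()
        if "category" not in df.columns:
            df["category"] = "mask"
        df["chrom"] = df["chrom"].astype(str)
        merged = []
        for (cat, chrom), grp in df.groupby(["category", "chrom"], sort=False):
            ivs = sorted(zip(grp["start"], grp["end"]))
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e, cat))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e, cat))
        self.regions = pd.DataFrame(
            merged, columns=["chrom", "start", "end", "category"]
        )

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask over 1-based positions ``pos`` on ``chrom``."""
        pos = np.asarray(pos)
        hit = np.zeros(pos.shape, dtype=bool)
        sub = self.regions[self.regions["chrom"] == str(chrom)]
        for s, e in zip(sub["start"], sub["end"]):
            hit |= (pos > s) & (pos <= e)
        return hit

    def with_flanks(self, width_bp: int = UNMAPPABLE_FLANK_BP) -> "MaskRegions":
        df = self.regions.copy()
        df["start"] = np.maximum(df["start"] - width_bp, 0)
        df["end"] = df["end"] + width_bp
        return MaskRegions(df)


def individual_of(haplotype: str) -> str:
    """Individual id of a ``<individual>.<k>`` haplotype name."""
    return haplotype.rsplit(".", 1)[0]


# ---------------------------------------------------------------------------
# VCF / TSV genotypes
# ---------------------------------------------------------------------------


def read_vcf_like(
    path: str | Path, genetic_map: pd.DataFrame | None = None
) -> tuple[SitePanel, GenotypeMatrix]:
    """Read a phased VCF (or the package TSV dialect) into panel + genotypes.

    Haplotypes are labeled ``<sample>.0`` / ``<sample>.1``; ``./.`` genotypes
    become missing alleles.  Unsorted records and unphased non-missing
    genotypes are hard errors — phasing happens upstream of this package.
    """
    path = Path(path)
    if path.suffix in {".tsv", ".txt"}:
        return _read_tsv_genotypes(path, genetic_map)

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    hap_alleles: list[np.ndarray] = []
    ploidy: dict[str, int] = {}
    last: tuple[str, int] | None = None
    for rec_idx, v in enumerate(vcf):
        chrom, pos = str(v.CHROM), int(v.POS)
        if last is not None and chrom == last[0] and pos <= last[1]:
            raise ValueError(
                f"unsorted VCF: record {rec_idx + 1} at {chrom}:{pos} "
                f"follows {last[0]}:{last[1]}"
            )
        last = (chrom, pos)
        alt = v.ALT[0] if v.ALT else "."
        info_score = v.INFO.get("INFO")
        site_alleles = np.full(2 * len(samples), LABEL_MISSING, dtype=np.int8)
        for si, g in enumerate(v.genotypes):
            *alleles_i, phased = g
            if len(alleles_i) == 1:  # haploid record
                ploidy.setdefault(samples[si], 1)
                if alleles_i[0] >= 0:
                    site_alleles[2 * si] = alleles_i[0]
                continue
            ploidy.setdefault(samples[si], 2)
            a0, a1 = alleles_i[0], alleles_i[1]
            if a0 >= 0 and a1 >= 0 and not phased:
                raise ValueError(
                    f"unphased genotype for sample {samples[si]} at {chrom}:{pos}"
                )
            site_alleles[2 * si] = a0 if a0 >= 0 else LABEL_MISSING
            site_alleles[2 * si + 1] = a1 if a1 >= 0 else LABEL_MISSING
        rows.append((chrom, pos, v.REF, alt, np.nan if info_score is None else float(info_score)))
        hap_alleles.append(site_alleles)

    geno = np.array(hap_alleles, dtype=np.int8).T if hap_alleles else np.zeros((2 * len(samples), 0), np.int8)
    hap_names = []
    keep_rows = []
    for si, s in enumerate(samples):
        hap_names.append(f"{s}.0")
        keep_rows.append(2 * si)
        if ploidy.get(s, 2) == 2:
            hap_names.append(f"{s}.1")
            keep_rows.append(2 * si + 1)
    geno = geno[keep_rows]

    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "info"])
    df["maf"] = _minor_allele_frequency(geno)
    df["cm"] = np.nan
    panel = SitePanel(df[["chrom", "pos", "cm", "ref", "alt", "maf", "info"]])
    if genetic_map is not None:
        panel = interpolate_cm(panel, genetic_map)
    gm = GenotypeMatrix(hap_names, geno, ploidy)
    return panel, gm


def _read_tsv_genotypes(
    path: Path, genetic_map: pd.DataFrame | None
) -> tuple[SitePanel, GenotypeMatrix]:
    """Package TSV dialect: chrom, pos, ref, alt[, cm] + one column per haplotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = [c for c in ("chrom", "pos", "ref", "alt", "cm") if c in df.columns]
    hap_cols = [c for c in df.columns if c not in meta]
    geno = df[hap_cols].replace(".", "-1").astype(np.int8).to_numpy().T
    sites = df[meta].copy()
    if "cm" not in sites:
        sites["cm"] = np.nan
    sites["maf"] = _minor_allele_frequency(geno)
    sites["info"] = np.nan
    panel = SitePanel(sites[["chrom", "pos", "cm", "ref", "alt", "maf", "info"]])
    if genetic_map is not None:
        panel = interpolate_cm(panel, genetic_map)
    return panel, GenotypeMatrix(hap_cols, geno)


def _minor_allele_frequency(geno: np.ndarray) -> np.ndarray:
    ok = geno >= 0
    with np.errstate(invalid="ignore"):
        f = np.where(ok, geno, 0).sum(axis=0) / np.maximum(ok.sum(axis=0), 1).astype(float)
    f[ok.sum(axis=0) == 0] = np.nan
    return np.minimum(f, 1.0 - f)


def write_vcf(panel: SitePanel, genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal phased VCF (biallelic SNPs, GT only)."""
    inds = genotypes.individuals
    hap_idx = {h: i for i, h in enumerate(genotypes.haplotypes)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds) + "\n")
        sites = panel.sites
        for j in range(panel.n_sites):
            row = sites.iloc[j]
            info = "." if np.isnan(row["info"]) else f"INFO={row['info']:g}"
            gts = []
            for ind in inds:
                a0 = genotypes.alleles[hap_idx[f"{ind}.0"], j]
                if genotypes.ploidy.get(ind, 2) == 1:
                    gts.append("." if a0 < 0 else str(a0))
                else:
                    a1 = genotypes.alleles[hap_idx[f"{ind}.1"], j]
                    s0 = "." if a0 < 0 else str(a0)
                    s1 = "." if a1 < 0 else str(a1)
                    gts.append(f"{s0}|{s1}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t"
                f"{info}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# msp ancestry-call dialect
# ---------------------------------------------------------------------------

_MSP_CODES = {"FARMER": LABEL_FARMER, "HG": LABEL_HG}


def write_msp_calls(
    calls: AncestryCalls,
    panel: SitePanel,
    path: str | Path,
    posterior_path: str | Path | None = None,
) -> None:
    """Write SNP-level calls in the msp dialect (one degenerate row per SNP).

    Columns: chrom, spos, epos, sgpos, egpos, nsnps, then one label column per
    haplotype; a SNP-level row has spos == epos == the site bp.
    """
    sites = panel.sites
    with open(path, "w") as fh:
        fh.write("#Subpopulation order/codes: FARMER=0\tHG=1\n")
        fh.write(
            "#chm\tspos\tepos\tsgpos\tegpos\tn snps\t" + "\t".join(calls.haplotypes) + "\n"
        )
        for j in range(panel.n_sites):
            row = sites.iloc[j]
            labels = "\t".join(str(int(x)) for x in calls.labels[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['pos']}\t{row['cm']:.6f}\t"
                f"{row['cm']:.6f}\t1\t{labels}\n"
            )
    if posterior_path is not None and calls.posterior is not None:
        pd.DataFrame(calls.posterior.T, columns=calls.haplotypes).assign(
            chrom=sites["chrom"].to_numpy(), pos=sites["pos"].to_numpy()
        ).to_csv(posterior_path, sep="\t", index=False)


def read_msp_calls(
    path: str | Path,
    panel: SitePanel,
    posterior_path: str | Path | None = None,
    method: str = "external",
) -> AncestryCalls:
    """Read an msp-dialect track, expanding window rows to the SNPs they contain.

    A window row labels every panel site with spos <= pos <= epos; sites not
    covered by any row are missing.  Haplotype-count mismatches and unknown
    label codes are hard errors.
    """
    header_haps: list[str] | None = None
    data_rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#chm") or "spos" in line:
                    header_haps = line.split("\t")[6:]
                continue
            data_rows.append(line.split("\t"))
    if header_haps is None:
        raise ValueError(f"{path}: missing msp column header")

    n_hap = len(header_haps)
    labels = np.full((n_hap, panel.n_sites), LABEL_MISSING, dtype=np.int8)
    slices = panel.chrom_slices()
    pos_by_chrom = {c: panel.sites["pos"].to_numpy()[sl] for c, sl in slices.items()}
    for row in data_rows:
        if len(row) != 6 + n_hap:
            raise ValueError(
                f"{path}: row has {len(row) - 6} haplotype columns, header has {n_hap}"
            )
        chrom, spos, epos = str(row[0]), int(float(row[1])), int(float(row[2]))
        codes = np.array([int(x) for x in row[6:]], dtype=np.int8)
        bad = ~np.isin(codes, [LABEL_FARMER, LABEL_HG, LABEL_MISSING])
        if bad.any():
            raise ValueError(f"{path}: unknown label code {codes[bad][0]}")
        if chrom not in slices:
            continue
        pos = pos_by_chrom[chrom]
        lo = np.searchsorted(pos, spos, side="left")
        hi = np.searchsorted(pos, epos, side="right")
        if hi > lo:
            sl = slices[chrom]
            labels[:, sl.start + lo : sl.start + hi] = codes[:, None]

    posterior = None
    if posterior_path is not None:
        pdf = pd.read_csv(posterior_path, sep="\t", dtype={"chrom": str})
        if list(pdf.columns[: n_hap]) != header_haps:
            raise ValueError("posterior sidecar haplotypes do not match msp header")
        posterior = np.full((n_hap, panel.n_sites), np.nan, dtype=np.float32)
        key = pd.MultiIndex.from_frame(panel.sites[["chrom", "pos"]])
        pkey = pd.MultiIndex.from_frame(pdf[["chrom", "pos"]])
        locs = key.get_indexer(pkey)
        ok = locs >= 0
        posterior[:, locs[ok]] = pdf[header_haps].to_numpy().T[:, ok]
    return AncestryCalls(header_haps, labels, posterior, method)


# ---------------------------------------------------------------------------
# maps, masks, reference tables
# ---------------------------------------------------------------------------


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """3-column TSV: chrom, pos (bp), cm."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = ["chrom", "pos", "cm"]
    return df


def interpolate_cm(panel: SitePanel, genetic_map: pd.DataFrame) -> SitePanel:
    """Fill panel cM positions from a genetic map.

    Sites between map points are linearly interpolated; sites beyond the
    mapped range are extrapolated at the chromosome's mean cM/bp rate.
    """
    sites = panel.sites.copy()
    cm = np.full(len(sites), np.nan)
    for chrom, sl in panel.chrom_slices().items():
        gm = genetic_map[genetic_map["chrom"].astype(str) == chrom].sort_values("pos")
        if gm.empty:
            raise ValueError(f"genetic map has no entries for chromosome {chrom}")
        mp = gm["pos"].to_numpy(float)
        mc = gm["cm"].to_numpy(float)
        pos = sites["pos"].to_numpy(float)[sl]
        vals = np.interp(pos, mp, mc)
        if len(mp) > 1:
            rate = (mc[-1] - mc[0]) / (mp[-1] - mp[0])
            below = pos < mp[0]
            above = pos > mp[-1]
            vals[below] = mc[0] - (mp[0] - pos[below]) * rate
            vals[above] = mc[-1] + (pos[above] - mp[-1]) * rate
        cm[sl] = np.maximum.accumulate(np.maximum(vals, 0.0))
    sites["cm"] = cm
    return SitePanel(sites)


def read_masks(path: str | Path, category: str | None = None) -> MaskRegions:
    """Read a BED file of excluded regions (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = ["chrom", "start", "end"] + (["category"] if df.shape[1] > 3 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if category is not None:
        df["category"] = category
    return MaskRegions(df)


def write_masks(masks: MaskRegions, path: str | Path) -> None:
    masks.regions.to_csv(path, sep="\t", header=False, index=False)


def read_reference_ancestry(path: str | Path) -> pd.Series:
    """2-column TSV (individual, hunter-gatherer proportion) -> Series."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["individual", "proportion"][: df.shape[1]]
    return df.set_index("individual")["proportion"].astype(float)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_sites(
    panel: SitePanel,
    genotypes: GenotypeMatrix,
    maf_min: float = DEFAULT_MAF_MIN,
    info_min: float = DEFAULT_INFO_MIN,
) -> tuple[SitePanel, GenotypeMatrix]:
    """Keep sites with MAF > maf_min and INFO > info_min (strict inequalities).

    Sites with unknown INFO (NaN) are judged on MAF alone.  The empty result
    is allowed and logged.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= info_min <= 1:
        raise ValueError("info_min must be in [0, 1]")
    maf = panel.sites["maf"].to_numpy(float)
    info = panel.sites["info"].to_numpy(float)
    keep = np.ones(panel.n_sites, dtype=bool)
    if maf_min > 0:  # a zero threshold is a declared no-op
        keep &= maf > maf_min
    if info_min > 0:
        keep &= np.isnan(info) | (info > info_min)
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        logger.warning("filter_sites: no sites survive maf>%s, info>%s", maf_min, info_min)
    return panel.subset(idx), genotypes.subset_sites(idx)


def apply_posterior_filter(
    calls: AncestryCalls, q: float = DEFAULT_POSTERIOR_MIN
) -> AncestryCalls:
    """Set calls with posterior <= q to missing (strict > keeps a call).

    Tracks without posteriors pass through unchanged with a warning.
    """
    if not 0 <= q <= 1:
        raise ValueError("posterior threshold must be in [0, 1]")
    if calls.posterior is None:
        logger.warning("apply_posterior_filter: track %r has no posteriors", calls.method)
        return calls.copy()
    out = calls.copy()
    drop = ~np.isnan(out.posterior) & (out.posterior <= q) & (out.labels != LABEL_MISSING)
    out.labels[drop] = LABEL_MISSING
    return out
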