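"""Weir-Cockerham FST: per-site components, pairwise matrices, sliding-window
scans, top-quantile outlier windows, and gene intersection.

The two-population diploid estimator decomposes allele-frequency variance
into among-population (a), among-individual-within-population (b) and
within-individual (c) components; theta = a / (a + b + c). Genome-wide and
per-window values use the "weighted" ratio-of-sums form (sum of a over sum
of a+b+c), the convention VCFtools reports. Windows are 50 kb with a 10 kb
step, anchored at position 1 of each chromosome; outlier windows are those
at or above the empirical 99th percentile of defined window values, and
genes are collected when they overlap an outlier-window SNP padded by
+/- 2500 bp (closed intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import MISSING, GeneFeature, GenotypeMatrix, ValidationError


@dataclass
class WcSiteComponents:
    """Per-site a, b, c arrays for one population pair; NaN where unusable."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    usable: np.ndarray  # both pops genotyped

    def theta_per_site(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.usable & (denom > 0), self.a / denom, np.nan)


def wc_components_site(dosages: np.ndarray, labels: np.ndarray,
                       pair: tuple) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one site and one population pair.

    Implements the 1984 two-population diploid estimator (r = 2) from
    per-population sample sizes, alternate-allele frequencies and observed
    heterozygote fractions. NaNs are returned when either population has no
    genotyped member at the site.
    """
    dosages = np.asarray(dosages)
    if dosages.ndim == 1:
        dosages = dosages.reshape(-1, 1)
    comps = wc_components(dosages, labels, pair)
    return float(comps.a[0]), float(comps.b[0]), float(comps.c[0])


def wc_components(dosage: np.ndarray, labels: np.ndarray,
                  pair: tuple) -> WcSiteComponents:
    """Vectorized per-site (a, b, c) for a population pair.

    ``dosage`` is (n_samples, n_sites) with MISSING = -1.
    """
    labels = np.asarray(labels)
    g1, g2 = pair
    r = 2.0
    ns, ps, hs = [], [], []
    for g in (g1, g2):
        sub = dosage[labels == g]
        called = sub != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, ((sub == 1) & called).sum(axis=0) / n, np.nan)
        ns.append(n)
        ps.append(p)
        hs.append(h)
    n1, n2 = ns
    p1, p2 = ps
    h1, h2 = hs
    usable = (n1 > 0) & (n2 > 0)
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - s2 * (r - 1) / r
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    bad = ~usable | (nbar <= 1) | (nc <= 0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return WcSiteComponents(a=a, b=b, c=c, usable=~bad)


def weighted_fst(comps: WcSiteComponents) -> float:
    """Ratio-of-sums FST over usable sites with positive total variance."""
    denom = comps.a + comps.b + comps.c
    ok = comps.usable & np.isfinite(denom) & (denom > 0)
    if not ok.any():
        return float("nan")
    return float(comps.a[ok].sum() / denom[ok].sum())


def pairwise_fst(gm: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Symmetric matrix of weighted pairwise FST between all label pairs.

    Estimates are reported as computed (possibly slightly negative); a
    clipped copy is trivial to derive downstream.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("pairwise FST needs at least 2 groups")
    if counts.min() < 2:
        raise ValidationError("every group needs at least 2 samples")
    mat = pd.DataFrame(0.0, index=uniq, columns=uniq)
    for i, g1 in enumerate(uniq):
        for g2 in uniq[i + 1:]:
            fst = weighted_fst(wc_components(gm.dosage, labels, (g1, g2)))
            mat.loc[g1, g2] = mat.loc[g2, g1] = fst
    return mat


@dataclass
class WindowStat:
    chromosome: str
    start: int   # 1-based closed
    end: int
    sum_a: float
    sum_abc: float
    n_snps: int

    @property
    def fst(self) -> float:
        return self.sum_a / self.sum_abc if self.sum_abc > 0 else float("nan")


def windowed_fst(comps: WcSiteComponents, sites: pd.DataFrame,
                 window: int = 50_000, step: int = 10_000,
                 min_snps: int = 1) -> list[WindowStat]:
    """Sliding-window ratio-of-sums FST.

    Windows are closed intervals anchored at 1, 1+step, 1+2*step, ... per
    chromosome, extending to the last window containing a SNP; windows with
    fewer than ``min_snps`` usable SNPs are omitted. Sites with
    nonpositive total variance are skipped in the sums but not counted.
    """
    out: list[WindowStat] = []
    denom = comps.a + comps.b + comps.c
    ok = comps.usable & np.isfinite(denom) & (denom > 0)
    chrom_arr = sites["chromosome"].to_numpy()
    pos_arr = sites["position"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        m = (chrom_arr == chrom) & ok
        pos = pos_arr[m]
        if pos.size == 0:
            continue
        a = comps.a[m]
        d = denom[m]
        max_start = int(pos.max())  # last anchored start that can hold a SNP
        n_windows = (max_start - 1) // step + 1
        sum_a = np.zeros(n_windows)
        sum_d = np.zeros(n_windows)
        n_snp = np.zeros(n_windows, dtype=int)
        # window starts s = 1 + k*step cover pos iff s <= pos <= s + window - 1
        k_hi = (pos - 1) // step                       # largest k with start <= pos
        k_lo = np.maximum(0, -((window - pos) // step))  # ceil((pos-window)/step)
        for i in range(pos.size):
            ks = np.arange(k_lo[i], k_hi[i] + 1)
            sum_a[ks] += a[i]
            sum_d[ks] += d[i]
            n_snp[ks] += 1
        for k in range(n_windows):
            if n_snp[k] >= min_snps:
                start = 1 + k * step
                out.append(WindowStat(str(chrom), start, start + window - 1,
                                      float(sum_a[k]), float(sum_d[k]),
                                      int(n_snp[k])))
    return out


@dataclass
class OutlierSet:
    threshold_fst: float
    windows: list[WindowStat]
    snp_indices: np.ndarray          # indices into the sites frame
    genes: list[GeneFeature] = field(default_factory=list)


def outliers_and_genes(windows: list[WindowStat], sites: pd.DataFrame,
                       genes: list[GeneFeature], q: float = 0.99,
                       pad: int = 2500) -> OutlierSet:
    """Top-quantile windows, the SNPs inside them, and overlapping genes.

    The threshold is the empirical ``q`` quantile (linear interpolation) of
    defined window FST values; outliers are windows at or above it. SNPs in
    any outlier window are collected once, and genes overlap when their
    closed interval intersects [snp - pad, snp + pad]. Genes are
    deduplicated by id.
    """
    import warnings

    if not windows:
        raise ValidationError("no windows to scan")
    vals = np.array([w.fst for w in windows])
    vals = vals[np.isfinite(vals)]
    if vals.size < 100:
        warnings.warn("fewer than 100 windows; outlier quantile is unstable")
    thr = float(np.quantile(vals, q))
    out_windows = [w for w in windows if np.isfinite(w.fst) and w.fst >= thr]

    chrom_arr = sites["chromosome"].to_numpy()
    pos_arr = sites["position"].to_numpy()
    snp_mask = np.zeros(len(sites), dtype=bool)
    for w in out_windows:
        snp_mask |= (chrom_arr == w.chromosome) & (pos_arr >= w.start) & (pos_arr <= w.end)
    snp_idx = np.flatnonzero(snp_mask)

    hit: dict[str, GeneFeature] = {}
    by_chrom: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for i in snp_idx:
        lo, hi = pos_arr[i] - pad, pos_arr[i] + pad
        for g in by_chrom.get(chrom_arr[i], ()):
            if g.start <= hi and g.end >= lo:
                hit[g.gene_id] = g
    return OutlierSet(threshold_fst=thr, windows=out_windows,
                      snp_indices=snp_idx,
                      genes=sorted(hit.values(), key=lambda g: g.gene_id))
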