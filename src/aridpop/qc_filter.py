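"""Site, genotype and sample quality filtering plus windowed LD pruning.

Default thresholds reproduce a standard short-read resequencing pipeline:
biallelic SNPs with QUAL >= 30, per-genotype GQ >= 20 and DP >= 5, per-site
missingness strictly below 10%, MAF >= 0.05; samples with strictly more than
20% missing genotypes are excluded. LD pruning uses a 50-SNP sliding window
with step 5 and an r-squared threshold of 0.5 (PLINK ``--indep-pairwise``
style), with the lower-MAF member of each correlated pair removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import MISSING, AridpopError, GenotypeMatrix, ValidationError


class ConfigurationError(AridpopError):
    pass


@dataclass
class FilterConfig:
    """Quality-filter thresholds; inclusivity follows the stated rules:

    GQ/DP/QUAL/MAF thresholds are inclusive (``>=`` keeps), while the
    missingness cutoffs are strict (a site at exactly ``max_site_missing``
    is dropped, a sample at exactly ``max_sample_missing`` is kept).
    """

    min_qual: float = 30.0
    min_gq: int = 20
    min_dp: int = 5
    max_site_missing: float = 0.10
    min_maf: float = 0.05
    max_sample_missing: float = 0.20

    def __post_init__(self) -> None:
        for name in ("max_site_missing", "min_maf", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class PruneConfig:
    window_snps: int = 50
    step_snps: int = 5
    r2_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.step_snps > self.window_snps:
            raise ValidationError("step_snps must be <= window_snps")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValidationError("r2_threshold must be in (0, 1]")


@dataclass
class FilterReport:
    """Ledger of how many sites/samples each rule removed."""

    n_input_sites: int = 0
    n_masked_genotypes: int = 0
    dropped_not_biallelic_snp: int = 0
    dropped_qual: int = 0
    dropped_missingness: int = 0
    dropped_maf: int = 0
    n_output_sites: int = 0
    dropped_samples: list[str] = field(default_factory=list)

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("input_sites", self.n_input_sites),
            ("masked_genotypes", self.n_masked_genotypes),
            ("dropped_not_biallelic_snp", self.dropped_not_biallelic_snp),
            ("dropped_qual", self.dropped_qual),
            ("dropped_missingness", self.dropped_missingness),
            ("dropped_maf", self.dropped_maf),
            ("output_sites", self.n_output_sites),
            ("dropped_samples", len(self.dropped_samples)),
        ]


def mask_genotypes(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Set calls with DP < min_dp or GQ < min_gq to MISSING (thresholds inclusive).

    Requires both DP and GQ matrices; refusing to apply a partial filter
    silently is deliberate.
    """
    cfg = cfg or FilterConfig()
    if gm.depth is None or gm.genoqual is None:
        raise ConfigurationError(
            "mask_genotypes requires per-genotype DP and GQ matrices"
        )
    called = gm.dosage != MISSING
    bad = called & ((gm.depth < cfg.min_dp) | (gm.genoqual < cfg.min_gq))
    dosage = np.where(bad, MISSING, gm.dosage)
    return GenotypeMatrix(gm.sample_ids, gm.sites, dosage, gm.depth, gm.genoqual,
                          sort=False)


def filter_sites(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None,
    report: FilterReport | None = None,
) -> GenotypeMatrix:
    """Keep biallelic SNPs with QUAL >= min_qual, missingness < max_site_missing
    (strict), and MAF >= min_maf computed on non-missing calls. Order preserved.
    """
    cfg = cfg or FilterConfig()
    rep = report if report is not None else FilterReport()
    rep.n_input_sites = gm.n_sites
    bial = (gm.sites["biallelic"] & gm.sites["is_snp"]).to_numpy()
    qual = gm.sites["qual"].to_numpy() >= cfg.min_qual
    miss = gm.site_missing_rate() < cfg.max_site_missing
    with np.errstate(invalid="ignore"):
        maf = gm.maf() >= cfg.min_maf
    maf = np.nan_to_num(maf, nan=0.0).astype(bool)
    # attribute each drop to the first failing rule, in pipeline order
    rep.dropped_not_biallelic_snp = int((~bial).sum())
    rep.dropped_qual = int((bial & ~qual).sum())
    rep.dropped_missingness = int((bial & qual & ~miss).sum())
    rep.dropped_maf = int((bial & qual & miss & ~maf).sum())
    keep = bial & qual & miss & maf
    rep.n_output_sites = int(keep.sum())
    return gm.subset_sites(np.flatnonzero(keep))


def filter_samples(
    gm: GenotypeMatrix, cfg: FilterConfig | None = None,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples with missing fraction strictly above max_sample_missing."""
    cfg = cfg or FilterConfig()
    fmiss = gm.sample_missing_rate()
    keep = fmiss <= cfg.max_sample_missing
    dropped = [s for s, k in zip(gm.sample_ids, keep) if not k]
    if not keep.any():
        raise ValidationError("all samples exceed the missingness cutoff")
    if report is not None:
        report.dropped_samples = dropped
    kept_ids = [s for s, k in zip(gm.sample_ids, keep) if k]
    return gm.subset_samples(kept_ids), dropped


R2_UNDEFINED = float("nan")


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Computed over pairwise-complete entries; 0.0 when either vector is
    constant on the complete set; NaN when fewer than 2 complete pairs.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError("dosage vectors differ in length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return R2_UNDEFINED
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    xs -= xs.mean()
    ys -= ys.mean()
    vx = (xs * xs).sum()
    vy = (ys * ys).sum()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = (xs * ys).sum()
    return float(c * c / (vx * vy))


def _window_r2(dos: np.ndarray) -> np.ndarray:
    """Pairwise r^2 matrix for a (k, n_samples) dosage block, MISSING aware."""
    k = dos.shape[0]
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r2 = genotype_r2(dos[i], dos[j])
            out[i, j] = out[j, i] = 0.0 if np.isnan(r2) else r2
    return out


def ld_prune(gm: GenotypeMatrix, cfg: PruneConfig | None = None) -> list[int]:
    """Greedy windowed LD pruning; returns retained site indices (sorted).

    Per chromosome: slide a window of ``window_snps`` consecutive retained
    candidates by ``step_snps``; within a window, while any pair has
    r^2 > threshold, remove the lower-MAF member (tie: the later site).
    Passes repeat until a full sweep removes nothing, which guarantees no
    pair that ever shared a window exceeds the threshold in the final set.
    """
    cfg = cfg or PruneConfig()
    maf = gm.maf()
    retained: list[int] = []
    chrom_arr = gm.sites["chromosome"].to_numpy()
    for chrom in gm.chromosomes():
        idx = np.flatnonzero(chrom_arr == chrom)
        alive = set(idx.tolist())
        changed = True
        while changed:
            changed = False
            cand = [i for i in idx if i in alive]
            start = 0
            while start < len(cand):
                window = cand[start:start + cfg.window_snps]
                if len(window) >= 2:
                    block = gm.dosage[:, window].T
                    r2 = _window_r2(block)
                    local_alive = list(range(len(window)))
                    drop_any = True
                    while drop_any:
                        drop_any = False
                        worst = None
                        for a_i, a in enumerate(local_alive):
                            for b in local_alive[a_i + 1:]:
                                if r2[a, b] > cfg.r2_threshold:
                                    sa, sb = window[a], window[b]
                                    # remove lower MAF; tie -> later site
                                    victim = (b if (maf[sb] < maf[sa]) or
                                              (maf[sb] == maf[sa]) else a)
                                    worst = victim
                                    break
                            if worst is not None:
                                break
                        if worst is not None:
                            alive.discard(window[worst])
                            local_alive.remove(worst)
                            drop_any = True
                            changed = True
                if len(window) < cfg.window_snps:
                    break
                start += cfg.step_snps
        retained.extend(sorted(alive))
    return sorted(retained)
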