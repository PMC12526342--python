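"""Known-truth synthetic data emulating a structured resequencing panel.

The generator mirrors the shape of a multi-deme tree-population study at
desk scale: K discrete demes whose allele frequencies drift from a shared
ancestral frequency under the Balding-Nichols model (deme frequency ~
Beta(p(1-F)/F, (1-p)(1-F)/F) around ancestral p, so Var = p(1-p)F and the
expected pairwise differentiation between demes i and j is ~(F_i + F_j)/2),
optional Dirichlet admixture, clonal duplicates with small genotyping error
and missingness, 15 chromosomes named PC1..PC15, per-genotype DP/GQ and
per-site QUAL fields that can be planted to fail each quality-filter rule,
a four-deme quartet with a controllable introgression fraction, and a toy
gene annotation. Every simulation records its truth (deme memberships,
clone groups, planted failures, introgressed sites) so downstream recovery
is checkable exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (MISSING, GeneFeature, GenotypeMatrix, SampleMeta,
                      ValidationError)

CHROM_PREFIX = "PC"


@dataclass
class QualityConfig:
    """Quality-field model plus planted-failure fractions (of sites/cells)."""

    mean_dp: int = 20
    qual_mean: float = 60.0
    frac_fail_qual: float = 0.0       # sites with QUAL < 30
    frac_fail_missing: float = 0.0    # sites pushed to >= 10% missing calls
    frac_fail_maf: float = 0.0        # sites forced below MAF 0.05
    frac_multiallelic: float = 0.0    # sites given a second ALT allele
    frac_fail_dp: float = 0.0         # cells with DP < 5
    frac_fail_gq: float = 0.0         # cells with GQ < 20


@dataclass
class CloneConfig:
    group_sizes: list[int] = field(default_factory=list)  # total members per group
    error_rate: float = 0.0
    missing_rate: float = 0.0


@dataclass
class QuartetConfig:
    """Four demes on (((P1,P2),P3),O) with per-branch drift and gene flow."""

    n_per_deme: int = 20
    n_snps: int = 10_000
    f_internal: float = 0.05     # root -> (P1,P2,P3) ancestor
    f_split: float = 0.10        # ancestor -> (P1,P2) ancestor and -> P3
    f_tip: float = 0.03          # (P1,P2) ancestor -> P1 and -> P2
    f_outgroup: float = 0.30
    introgression_f: float = 0.0
    donor: str = "P3"
    recipient: str = "P2"
    chromosome: str | None = None  # restrict gene flow to one chromosome


@dataclass
class GeneConfig:
    n_genes_per_chrom: int = 20
    gene_length: int = 2_000
    gap: int = 3_000


@dataclass
class SimConfig:
    seed: int
    n_demes: int = 4
    deme_sizes: list[int] = field(default_factory=lambda: [29, 29, 28, 28])
    bn_f: list[float] = field(default_factory=lambda: [0.02, 0.03, 0.05, 0.12])
    admixture_alpha: float | None = None  # None => pure deme membership
    fis: list[float] | None = None  # per-deme within-deme inbreeding (default 0)
    n_chromosomes: int = 15
    chrom_length_bp: int = 5_000_000
    n_snps: int = 10_000
    freq_range: tuple[float, float] = (0.05, 0.95)
    outlier_region: tuple[str, int, int] | None = None  # planted high-FST span
    clones: CloneConfig = field(default_factory=CloneConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    quartet: QuartetConfig = field(default_factory=QuartetConfig)
    genes: GeneConfig = field(default_factory=GeneConfig)

    def __post_init__(self) -> None:
        if len(self.deme_sizes) != self.n_demes or len(self.bn_f) != self.n_demes:
            raise ValidationError("deme_sizes and bn_f must have n_demes entries")
        for f in self.bn_f:
            if not 0.0 <= f < 1.0:
                raise ValidationError("Balding-Nichols F must be in [0, 1)")


@dataclass
class TruthTable:
    """Everything the generator knows that an analysis should recover."""

    samples: pd.DataFrame                      # sample_id, deme, Q columns
    ancestral_freq: np.ndarray | None = None   # per site
    deme_freqs: np.ndarray | None = None       # n_demes x n_sites
    expected_pairwise_fst: dict | None = None  # (i, j) -> (F_i + F_j)/2
    outlier_site_mask: np.ndarray | None = None
    clone_groups: list[list[str]] | None = None
    quartet: dict | None = None                # f, donor, recipient, site mask
    planted: dict | None = None                # planted-failure indices
    n_genes: int | None = None

    def deme_labels(self) -> np.ndarray:
        return self.samples["deme"].to_numpy()


def _chromosome_names(n: int) -> list[str]:
    return [f"{CHROM_PREFIX}{i}" for i in range(1, n + 1)]


def _site_frame(rng: np.random.Generator, n_snps: int, n_chrom: int,
                chrom_len: int) -> pd.DataFrame:
    """Sites spread round-robin over chromosomes, positions uniform w/o repl."""
    chroms = _chromosome_names(n_chrom)
    per = np.full(n_chrom, n_snps // n_chrom)
    per[: n_snps % n_chrom] += 1
    rows = []
    bases = np.array(list("ACGT"))
    for c, k in zip(chroms, per):
        pos = np.sort(rng.choice(np.arange(1, chrom_len + 1), size=k,
                                 replace=False))
        ref = rng.choice(bases, size=k)
        for p, r in zip(pos, ref):
            alt = rng.choice([b for b in "ACGT" if b != r])
            rows.append((c, int(p), str(r), str(alt), 100.0, True, True))
    return pd.DataFrame(rows, columns=["chromosome", "position", "ref", "alt",
                                       "qual", "biallelic", "is_snp"])


def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     f: float) -> np.ndarray:
    if f == 0.0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    return np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)


def simulate_structured(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """K-deme Balding-Nichols genotypes with optional admixture and a
    planted high-differentiation region.

    Sample ids are S001, S002, ...; Q rows are one-hot deme indicators
    unless ``admixture_alpha`` is set, in which case they are Dirichlet
    draws biased toward the home deme.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = _site_frame(rng, cfg.n_snps, cfg.n_chromosomes, cfg.chrom_length_bp)
    m = len(sites)
    lo, hi = cfg.freq_range
    p_anc = rng.uniform(lo, hi, size=m)
    deme_freqs = np.stack([
        _balding_nichols(rng, p_anc, f) for f in cfg.bn_f
    ])

    outlier_mask = np.zeros(m, dtype=bool)
    if cfg.outlier_region is not None:
        chrom, start, end = cfg.outlier_region
        outlier_mask = ((sites["chromosome"] == chrom)
                        & (sites["position"] >= start)
                        & (sites["position"] <= end)).to_numpy()
        # near-fixed differences: deme 0 low, all others high
        deme_freqs[0, outlier_mask] = 0.02
        deme_freqs[1:, outlier_mask] = 0.98

    n = sum(cfg.deme_sizes)
    demes = np.repeat(np.arange(cfg.n_demes), cfg.deme_sizes)
    if cfg.admixture_alpha is None:
        Q = np.eye(cfg.n_demes)[demes]
    else:
        alpha = np.full(cfg.n_demes, cfg.admixture_alpha)
        Q = np.stack([
            rng.dirichlet(alpha + 5.0 * np.eye(cfg.n_demes)[d]) for d in demes
        ])
    ind_freq = Q @ deme_freqs
    fis = np.zeros(cfg.n_demes) if cfg.fis is None else np.asarray(cfg.fis)
    f_ind = fis[demes][:, None]
    # genotype draws with within-deme inbreeding: het deficit scaled by F_IS
    p = ind_freq
    p_hom_ref = (1 - p) ** 2 + p * (1 - p) * f_ind
    p_het = 2 * p * (1 - p) * (1 - f_ind)
    u = rng.random(p.shape)
    dosage = np.where(u < p_hom_ref, 0,
                      np.where(u < p_hom_ref + p_het, 1, 2)).astype(np.int8)

    ids = [f"S{i + 1:03d}" for i in range(n)]
    sample_df = pd.DataFrame({"sample_id": ids, "deme": demes + 1})
    for k in range(cfg.n_demes):
        sample_df[f"Q{k + 1}"] = Q[:, k]
    exp_fst = {
        (i + 1, j + 1): (cfg.bn_f[i] + cfg.bn_f[j]) / 2.0
        for i in range(cfg.n_demes) for j in range(i + 1, cfg.n_demes)
    }
    truth = TruthTable(samples=sample_df, ancestral_freq=p_anc,
                       deme_freqs=deme_freqs, expected_pairwise_fst=exp_fst,
                       outlier_site_mask=outlier_mask)
    gm = GenotypeMatrix(ids, sites, dosage, sort=False)
    return gm, truth


def add_clones(gm: GenotypeMatrix, truth: TruthTable,
               cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Append clonal copies of the first samples per the clone plan.

    A group size of ``s`` keeps one original and appends ``s - 1`` copies
    named ``<orig>_c<k>``. Copies flip each genotype to a random other
    value with ``error_rate`` and blank cells with ``missing_rate``.
    """
    plan = cfg.clones
    if not plan.group_sizes:
        truth.clone_groups = [[s] for s in gm.sample_ids]
        return gm, truth
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 77)).generate_state(1)[0])
    if len(plan.group_sizes) > gm.n_samples:
        raise ValidationError("more clone groups than source samples")
    new_rows = [gm.dosage]
    new_ids = list(gm.sample_ids)
    groups: list[list[str]] = [[s] for s in gm.sample_ids]
    for gi, size in enumerate(plan.group_sizes):
        src = gm.sample_ids[gi]
        for k in range(1, size):
            row = gm.dosage[gi].copy()
            if plan.error_rate > 0:
                flip = rng.random(row.shape) < plan.error_rate
                delta = rng.integers(1, 3, size=row.shape, dtype=np.int8)
                row = np.where(flip & (row != MISSING),
                               (row + delta) % 3, row).astype(np.int8)
            if plan.missing_rate > 0:
                row = np.where(rng.random(row.shape) < plan.missing_rate,
                               MISSING, row).astype(np.int8)
            cid = f"{src}_c{k}"
            new_ids.append(cid)
            new_rows.append(row[None, :])
            groups[gi].append(cid)
    dosage = np.vstack(new_rows)
    out = GenotypeMatrix(new_ids, gm.sites, dosage, sort=False)
    truth.clone_groups = groups
    extra = pd.DataFrame({
        "sample_id": new_ids[gm.n_samples:],
        "deme": [truth.samples["deme"].iloc[
            gm.sample_ids.index(c.rsplit("_c", 1)[0])] for c in new_ids[gm.n_samples:]],
    })
    truth.samples = pd.concat([truth.samples, extra], ignore_index=True)
    return out, truth


def simulate_quartet(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTable,
                                              dict[str, list[str]]]:
    """Four demes on (((P1,P2),P3),O) with drift per branch and optional
    P3 <-> recipient gene flow on a fraction of sites.

    Returns the genotype matrix, the truth (including the introgressed-site
    mask), and the population assignment mapping group label to sample ids.
    """
    q = cfg.quartet
    rng = np.random.default_rng(cfg.seed)
    sites = _site_frame(rng, q.n_snps, cfg.n_chromosomes, cfg.chrom_length_bp)
    m = len(sites)
    lo, hi = cfg.freq_range
    p = rng.uniform(lo, hi, size=m)
    p_abc = _balding_nichols(rng, p, q.f_internal)
    p_o = _balding_nichols(rng, p, q.f_outgroup)
    p_12 = _balding_nichols(rng, p_abc, q.f_split)
    p_3 = _balding_nichols(rng, p_abc, q.f_split)
    freqs = {
        "P1": _balding_nichols(rng, p_12, q.f_tip),
        "P2": _balding_nichols(rng, p_12, q.f_tip),
        "P3": p_3,
        "O": p_o,
    }

    flow_mask = np.zeros(m, dtype=bool)
    if q.introgression_f > 0:
        eligible = np.ones(m, dtype=bool)
        if q.chromosome is not None:
            eligible = (sites["chromosome"] == q.chromosome).to_numpy()
        idx = np.flatnonzero(eligible)
        n_flow = int(round(q.introgression_f * idx.size))
        chosen = rng.choice(idx, size=n_flow, replace=False)
        flow_mask[chosen] = True
        freqs[q.recipient] = freqs[q.recipient].copy()
        freqs[q.recipient][flow_mask] = freqs[q.donor][flow_mask]

    ids, rows, demes = [], [], []
    groups: dict[str, list[str]] = {}
    for label in ("P1", "P2", "P3", "O"):
        members = [f"{label}_{i + 1:02d}" for i in range(q.n_per_deme)]
        groups[label] = members
        ids.extend(members)
        demes.extend([label] * q.n_per_deme)
        rows.append(rng.binomial(2, np.broadcast_to(freqs[label], (q.n_per_deme, m))))
    dosage = np.vstack(rows).astype(np.int8)
    truth = TruthTable(
        samples=pd.DataFrame({"sample_id": ids, "deme": demes}),
        quartet={"f": q.introgression_f, "donor": q.donor,
                 "recipient": q.recipient, "chromosome": q.chromosome,
                 "site_mask": flow_mask},
    )
    return GenotypeMatrix(ids, sites, dosage, sort=False), truth, groups


def simulate_annotation(cfg: SimConfig) -> list[GeneFeature]:
    """Genes tiled with gaps along every chromosome (deterministic)."""
    g = cfg.genes
    genes = []
    for chrom in _chromosome_names(cfg.n_chromosomes):
        pos = 1
        for i in range(g.n_genes_per_chrom):
            start = pos
            end = start + g.gene_length - 1
            if end > cfg.chrom_length_bp:
                break
            genes.append(GeneFeature(f"{chrom}g{i + 1:04d}", chrom, start, end,
                                     "+" if i % 2 == 0 else "-"))
            pos = end + g.gap + 1
    return genes


def write_gff3(genes: list[GeneFeature], path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([
            g.chromosome, "aridpop_sim", "gene", str(g.start), str(g.end),
            ".", g.strand, ".", f"ID={g.gene_id}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def attach_quality(gm: GenotypeMatrix, cfg: SimConfig
                   ) -> tuple[GenotypeMatrix, TruthTable]:
    """Attach QUAL/DP/GQ fields, planting failures of each filter rule.

    Non-planted sites and cells are guaranteed to pass the default filter
    thresholds (QUAL >= 30, DP >= 5, GQ >= 20, site missingness < 10%);
    planted failures are disjoint across rules and recorded in the returned
    truth's ``planted`` dict:

    - ``qual_sites``: QUAL drawn in [0, 30)
    - ``missing_sites``: >= 10% of calls blanked
    - ``maf_sites``: dosage column rewritten to a single heterozygote
    - ``multiallelic_sites``: a second ALT allele appended
    - ``dp_cells`` / ``gq_cells``: cell index pairs with DP < 5 / GQ < 20
    """
    qc = cfg.quality
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 99)).generate_state(1)[0])
    n, m = gm.dosage.shape
    sites = gm.sites.copy()
    dosage = gm.dosage.copy()

    n_each = {
        "qual": int(round(qc.frac_fail_qual * m)),
        "missing": int(round(qc.frac_fail_missing * m)),
        "maf": int(round(qc.frac_fail_maf * m)),
        "multi": int(round(qc.frac_multiallelic * m)),
    }
    total = sum(n_each.values())
    if total > m:
        raise ValidationError("planted site-failure fractions exceed 1")
    perm = rng.permutation(m)
    cut = np.cumsum([n_each["qual"], n_each["missing"], n_each["maf"],
                     n_each["multi"]])
    qual_sites = np.sort(perm[: cut[0]])
    missing_sites = np.sort(perm[cut[0]: cut[1]])
    maf_sites = np.sort(perm[cut[1]: cut[2]])
    multi_sites = np.sort(perm[cut[2]: cut[3]])

    qual = 30.0 + rng.gamma(4.0, (cfg.quality.qual_mean - 30.0) / 4.0, size=m)
    qual[qual_sites] = rng.uniform(0.0, 29.9, size=qual_sites.size)
    sites["qual"] = qual

    # planted missingness: blank exactly ceil(10% of samples) calls
    n_blank = int(np.ceil(0.10 * n))
    for j in missing_sites:
        rows = rng.choice(n, size=n_blank, replace=False)
        dosage[rows, j] = MISSING

    for j in maf_sites:
        col = np.zeros(n, dtype=np.int8)
        col[rng.integers(0, n)] = 1  # single het: MAF = 1/(2n) < 0.05
        dosage[:, j] = col

    for j in multi_sites:
        ref = sites.at[j, "ref"]
        extra = next(b for b in "ACGT" if b != ref and b != sites.at[j, "alt"])
        sites.at[j, "alt"] = f"{sites.at[j, 'alt']},{extra}"
        sites.at[j, "biallelic"] = False

    depth = np.maximum(rng.poisson(qc.mean_dp, size=(n, m)), 5).astype(np.int32)
    gq = np.minimum(99, (3 * depth + rng.integers(0, 10, size=(n, m)))).astype(np.int32)
    gq = np.maximum(gq, 20)

    cells = rng.permutation(n * m)
    n_dp = int(round(qc.frac_fail_dp * n * m))
    n_gq = int(round(qc.frac_fail_gq * n * m))
    dp_cells = cells[:n_dp]
    gq_cells = cells[n_dp: n_dp + n_gq]
    r, c = np.unravel_index(dp_cells, (n, m))
    depth[r, c] = rng.integers(0, 5, size=n_dp)
    r, c = np.unravel_index(gq_cells, (n, m))
    gq[r, c] = rng.integers(0, 20, size=n_gq)

    called = dosage != MISSING
    depth[~called] = -1
    gq[~called] = -1

    out = GenotypeMatrix(gm.sample_ids, sites, dosage, depth, gq, sort=False)
    truth = TruthTable(samples=pd.DataFrame({"sample_id": gm.sample_ids}),
                       planted={
                           "qual_sites": qual_sites,
                           "missing_sites": missing_sites,
                           "maf_sites": maf_sites,
                           "multiallelic_sites": multi_sites,
                           "dp_cells": np.unravel_index(dp_cells, (n, m)),
                           "gq_cells": np.unravel_index(gq_cells, (n, m)),
                       })
    return out, truth


def simulate_coordinates(truth: TruthTable, cfg: SimConfig,
                         jitter_deg: float = 0.3, n_collisions: int = 0,
                         concentrate_last_deme: bool = True
                         ) -> list[SampleMeta]:
    """Collection coordinates: deme centers in a bounding box with jitter.

    The last deme can be concentrated in the northeast corner of the box
    (tight jitter), mimicking a geographically restricted cluster. The
    first ``n_collisions`` samples of deme 1 share exact coordinates to
    exercise the flower-expansion layout.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 55)).generate_state(1)[0])
    lat_lo, lat_hi, lon_lo, lon_hi = 22.6, 26.1, 51.6, 56.4
    demes = truth.samples["deme"].to_numpy()
    uniq = list(pd.unique(demes))
    centers = {}
    for d in uniq:
        centers[d] = (rng.uniform(lat_lo + 0.5, lat_hi - 0.5),
                      rng.uniform(lon_lo + 0.5, lon_hi - 0.5))
    if concentrate_last_deme and len(uniq) > 1:
        centers[uniq[-1]] = (lat_hi - 0.3, lon_hi - 0.3)
    metas = []
    first_deme_seen = 0
    collision_point = None
    for sid, d in zip(truth.samples["sample_id"], demes):
        clat, clon = centers[d]
        jit = jitter_deg if not (concentrate_last_deme and d == uniq[-1]) else 0.08
        lat = clat + rng.normal(0, jit)
        lon = clon + rng.normal(0, jit)
        if d == uniq[0] and first_deme_seen < n_collisions:
            if collision_point is None:
                collision_point = (lat, lon)
            lat, lon = collision_point
            first_deme_seen += 1
        metas.append(SampleMeta(sample_id=sid, latitude=float(lat),
                                longitude=float(lon), group=str(d)))
    return metas
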