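"""Core data model and file I/O for the pipeline.

All genotype data flow through :class:`GenotypeMatrix`, a samples x sites
matrix of diploid alternate-allele dosages (0, 1, 2, or :data:`MISSING`)
together with per-site records (chromosome, position, alleles, QUAL) and
optional per-genotype depth (DP) and genotype-quality (GQ) matrices.

Coordinate conventions are fixed here once: positions are 1-based and all
intervals (gene features, scan windows) are closed, matching both VCF and
GFF3 native conventions. Chromosome names are opaque strings ordered by
natural sort, so "PC2" < "PC10".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
"""Sentinel dosage for a missing genotype call."""

SITE_COLUMNS = ["chromosome", "position", "ref", "alt", "qual", "biallelic", "is_snp"]


class AridpopError(Exception):
    """Base class for package errors."""


class FormatError(AridpopError):
    """A file did not conform to its declared format."""


class ValidationError(AridpopError):
    """Input data violated an invariant (duplicate ids, bad ploidy, ...)."""


def natural_sort_key(name: str) -> tuple:
    """Sort key treating digit runs as integers, so PC2 sorts before PC10."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name))


@dataclass(frozen=True)
class SiteRecord:
    """One variant site; biallelic SNPs are the analysis substrate."""

    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    site_qual: float
    biallelic: bool = True
    is_snp: bool = True


@dataclass
class SampleMeta:
    """Per-sample metadata: id, collection coordinates, missingness, clone status."""

    sample_id: str
    latitude: float | None = None
    longitude: float | None = None
    group: str | None = None
    f_miss: float | None = None
    clonal_status: str = "unique"  # unique | clonemate | representative


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval from GFF3; 1-based closed coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


class GenotypeMatrix:
    """Diploid dosage matrix with site and sample registries.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers (rows of ``dosage``).
    sites
        DataFrame with columns ``chromosome, position, ref, alt, qual,
        biallelic, is_snp`` (one row per dosage column), or an iterable of
        :class:`SiteRecord`.
    dosage
        ``(n_samples, n_sites)`` integer array with entries in
        ``{0, 1, 2, MISSING}``.
    depth, genoqual
        Optional same-shape per-genotype DP and GQ matrices (``-1`` where
        the call is missing).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        sites: pd.DataFrame | Iterable[SiteRecord],
        dosage: np.ndarray,
        depth: np.ndarray | None = None,
        genoqual: np.ndarray | None = None,
        *,
        sort: bool = True,
    ) -> None:
        self.sample_ids = list(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if not isinstance(sites, pd.DataFrame):
            sites = pd.DataFrame(
                [
                    (s.chromosome, s.position, s.ref_allele, s.alt_allele,
                     s.site_qual, s.biallelic, s.is_snp)
                    for s in sites
                ],
                columns=SITE_COLUMNS,
            )
        self.sites = sites.reset_index(drop=True)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        self.depth = None if depth is None else np.asarray(depth, dtype=np.int32)
        self.genoqual = None if genoqual is None else np.asarray(genoqual, dtype=np.int32)
        self._validate()
        if sort:
            self._sort_sites()

    # ---------------------------------------------------------------- basics
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def _validate(self) -> None:
        if self.dosage.shape != (self.n_samples, self.n_sites):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} != "
                f"({self.n_samples}, {self.n_sites})"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("dosage entries must be in {0,1,2,MISSING}")
        for name, mat in (("depth", self.depth), ("genoqual", self.genoqual)):
            if mat is not None and mat.shape != self.dosage.shape:
                raise ValidationError(f"{name} shape differs from dosage")
        if self.n_sites and (self.sites["position"].to_numpy() < 1).any():
            raise ValidationError("positions must be >= 1")
        dup = self.sites.duplicated(subset=["chromosome", "position"])
        if dup.any():
            raise ValidationError("duplicate (chromosome, position)")

    def _sort_sites(self) -> None:
        keys = list(zip(
            (natural_sort_key(c) for c in self.sites["chromosome"]),
            self.sites["position"],
        ))
        order = sorted(range(len(keys)), key=keys.__getitem__)
        if order != list(range(len(keys))):
            warnings.warn("sites were not sorted; sorting by (chromosome, position)")
            self._take_sites(np.asarray(order, dtype=int), inplace=True)

    def _take_sites(self, idx: np.ndarray, inplace: bool = False):
        sites = self.sites.iloc[idx].reset_index(drop=True)
        dosage = self.dosage[:, idx]
        depth = None if self.depth is None else self.depth[:, idx]
        gq = None if self.genoqual is None else self.genoqual[:, idx]
        if inplace:
            self.sites, self.dosage, self.depth, self.genoqual = sites, dosage, depth, gq
            return self
        return GenotypeMatrix(self.sample_ids, sites, dosage, depth, gq, sort=False)

    def subset_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site indices (order kept)."""
        return self._take_sites(np.asarray(idx, dtype=int))

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample ids, in given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in keep]
        except KeyError as e:
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from None
        return GenotypeMatrix(
            list(keep),
            self.sites,
            self.dosage[rows],
            None if self.depth is None else self.depth[rows],
            None if self.genoqual is None else self.genoqual[rows],
            sort=False,
        )

    # ------------------------------------------------------------ statistics
    def called_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_sites) mask of non-missing calls."""
        return self.dosage != MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing calls (NaN if none)."""
        called = self.called_mask()
        n = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def site_missing_rate(self) -> np.ndarray:
        # direct count/n keeps exact-threshold fractions (e.g. 1 missing in
        # 10) comparable against decimal cutoffs without 1-x rounding
        return (self.dosage == MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=1)

    def site_records(self) -> list[SiteRecord]:
        return [
            SiteRecord(r.chromosome, int(r.position), r.ref, r.alt,
                       float(r.qual), bool(r.biallelic), bool(r.is_snp))
            for r in self.sites.itertuples(index=False)
        ]

    def chromosomes(self) -> list[str]:
        """Chromosome names present, in natural order."""
        return sorted(set(self.sites["chromosome"]), key=natural_sort_key)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_opt = all(
            (a is None) == (b is None) and (a is None or np.array_equal(a, b))
            for a, b in ((self.depth, other.depth), (self.genoqual, other.genoqual))
        )
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.dosage, other.dosage)
            and same_opt
            and self.sites[["chromosome", "position", "ref", "alt"]].equals(
                other.sites[["chromosome", "position", "ref", "alt"]]
            )
            and np.allclose(self.sites["qual"], other.sites["qual"], equal_nan=True)
        )


# ----------------------------------------------------------------------- VCF
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_vcf(path: str | Path, region: str | None = None) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are retained with ``biallelic=False`` so the site
    filter can drop them explicitly; their dosages count copies of the first
    alternate allele and any genotype carrying a higher-numbered allele is
    set to MISSING. Phase separators are accepted and discarded. Haploid or
    polyploid calls raise :class:`ValidationError`.

    Parameters
    ----------
    region
        Optional ``"chrom"`` or ``"chrom:start-end"`` (1-based closed)
        restriction, applied while reading.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as e:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vcf.samples)

    want_chrom = want_lo = want_hi = None
    if region:
        if ":" in region:
            want_chrom, span = region.split(":", 1)
            lo, hi = span.split("-")
            want_lo, want_hi = int(lo), int(hi)
        else:
            want_chrom = region

    fmt_ids = set()
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                fmt_ids.add(h["ID"])
        except KeyError:
            continue
    chroms, poss, refs, alts, quals, bis, snps = [], [], [], [], [], [], []
    dos_rows, dp_rows, gq_rows = [], [], []
    has_dp = has_gq = False
    for var in vcf:
        if want_chrom is not None and var.CHROM != want_chrom:
            continue
        if want_lo is not None and not (want_lo <= var.POS <= want_hi):
            continue
        gts = var.genotypes
        if len(gts) != len(samples):
            raise FormatError(
                f"{var.CHROM}:{var.POS}: {len(gts)} genotype columns, "
                f"expected {len(samples)}"
            )
        dos = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) != 3:  # [a1, a2, phased] for diploid
                raise ValidationError(
                    f"{var.CHROM}:{var.POS} sample {samples[i]}: "
                    f"ploidy {len(g) - 1} call; only diploid data supported"
                )
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0 or a1 > 1 or a2 > 1:
                # missing, or carries a non-first alt allele
                dos[i] = MISSING
            else:
                dos[i] = a1 + a2
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alt_list = var.ALT if var.ALT else ["."]
        alts.append(alt_list[0])
        quals.append(np.nan if var.QUAL is None else float(var.QUAL))
        bis.append(len(alt_list) == 1)
        snps.append(len(var.REF) == 1 and all(len(a) == 1 for a in alt_list))
        dos_rows.append(dos)

        dp = var.format("DP") if "DP" in fmt_ids else None
        gq = var.format("GQ") if "GQ" in fmt_ids else None
        if dp is not None:
            has_dp = True
            dp_rows.append(np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
        else:
            dp_rows.append(np.full(len(samples), -1, dtype=np.int32))
        if gq is not None:
            has_gq = True
            gq_rows.append(np.where(gq[:, 0] < 0, -1, gq[:, 0]).astype(np.int32))
        else:
            gq_rows.append(np.full(len(samples), -1, dtype=np.int32))

    sites = pd.DataFrame(
        {"chromosome": chroms, "position": poss, "ref": refs, "alt": alts,
         "qual": quals, "biallelic": bis, "is_snp": snps},
        columns=SITE_COLUMNS,
    )
    n_sites = len(sites)
    dosage = (np.vstack(dos_rows).T if n_sites else
              np.empty((len(samples), 0), dtype=np.int8))
    depth = np.vstack(dp_rows).T if (n_sites and has_dp) else None
    genoqual = np.vstack(gq_rows).T if (n_sites and has_gq) else None
    return GenotypeMatrix(samples, sites, dosage, depth, genoqual)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF 4.2 file with FORMAT ``GT[:DP][:GQ]``.

    Round-trips losslessly with :func:`read_vcf` for dosage, QUAL, DP and GQ.
    """
    fmt_keys = ["GT"]
    if gm.depth is not None:
        fmt_keys.append("DP")
    if gm.genoqual is not None:
        fmt_keys.append("GQ")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=aridpop",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if "DP" in fmt_keys:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if "GQ" in fmt_keys:
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for chrom in gm.chromosomes():
        max_pos = int(gm.sites.loc[gm.sites["chromosome"] == chrom, "position"].max())
        lines.append(f"##contig=<ID={chrom},length={max_pos + 1000}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    fmt = ":".join(fmt_keys)
    for j, rec in enumerate(gm.sites.itertuples(index=False)):
        qual = "." if np.isnan(rec.qual) else format(rec.qual, "g")
        fields = [rec.chromosome, str(rec.position), ".", rec.ref, rec.alt,
                  qual, "PASS", ".", fmt]
        for i in range(gm.n_samples):
            parts = [_GT_STRINGS[int(gm.dosage[i, j])]]
            if gm.depth is not None:
                v = int(gm.depth[i, j])
                parts.append("." if v < 0 else str(v))
            if gm.genoqual is not None:
                v = int(gm.genoqual[i, j])
                parts.append("." if v < 0 else str(v))
            fields.append(":".join(parts))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------- GFF3
def read_gff3_genes(path: str | Path) -> list[GeneFeature]:
    """Read gene features (type == "gene") from a GFF3 file.

    Coordinates are kept 1-based inclusive as in GFF3. The gene id is taken
    from the ``ID=`` attribute, falling back to ``Name=`` then to
    ``<chrom>:<start>-<end>``.
    """
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise FormatError(f"line {ln}: expected >=8 GFF3 columns")
            if cols[2] != "gene":
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise FormatError(f"line {ln}: non-integer coordinates") from None
            attrs = dict(
                kv.split("=", 1) for kv in (cols[8].split(";") if len(cols) > 8 else [])
                if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name") or f"{cols[0]}:{start}-{end}"
            strand = cols[6] if cols[6] in {"+", "-", "."} else "."
            genes.append(GeneFeature(gid, cols[0], start, end, strand))
    return genes


# ------------------------------------------------------------------ metadata
def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the tab-separated sample metadata table.

    Requires a ``sample_id`` column; ``latitude``, ``longitude``, ``group``
    and ``f_miss`` are optional and unknown columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata file lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def _num(key):
            v = d.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)

        group = d.get("group")
        if group is not None and (isinstance(group, float) and np.isnan(group)):
            group = None
        out.append(SampleMeta(
            sample_id=str(d["sample_id"]),
            latitude=_num("latitude"),
            longitude=_num("longitude"),
            group=None if group is None else str(group).removesuffix(".0"),
            f_miss=_num("f_miss"),
            clonal_status=str(d.get("clonal_status", "unique") or "unique"),
        ))
    return out


def read_populations(path: str | Path) -> dict[str, str]:
    """Read the two-column (sample_id, group) population assignment file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("population file needs two columns (sample_id, group)")
    ids, groups = df.iloc[:, 0], df.iloc[:, 1]
    if ids.duplicated().any():
        raise ValidationError("duplicate sample_id in population file")
    return dict(zip(ids, groups))


def write_populations(assignments: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(assignments), "group": list(assignments.values())}
    ).to_csv(path, sep="\t", index=False)
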