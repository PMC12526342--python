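"""Frequency-based ABBA-BABA (D-statistic) tests with block-jackknife
significance and an f4-ratio admixture-fraction estimate.

For a quartet (((P1, P2), P3), Outgroup) and per-population alternate-allele
frequencies p1, p2, p3, pO at each biallelic site, the expected site-pattern
weights are

    ABBA = (1-p1) p2 p3 (1-pO) + p1 (1-p2)(1-p3) pO
    BABA = p1 (1-p2) p3 (1-pO) + (1-p1) p2 (1-p3) pO
    BBAA = p1 p2 (1-p3)(1-pO) + (1-p1)(1-p2) p3 pO

D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA). Under incomplete lineage
sorting alone D ~ 0; an excess of ABBA indicates gene flow between P2 and
P3 (BABA: P1 and P3). The standard error comes from a leave-one-out block
jackknife over contiguous physical blocks, Z = D/SE, and the f4-ratio
estimates the admixture fraction by splitting P3 into two random halves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MISSING, GenotypeMatrix, ValidationError


@dataclass
class DStatResult:
    quartet: tuple[str, str, str, str]
    abba: float
    baba: float
    bbaa: float
    d: float | None
    se: float | None
    z: float | None
    p: float | None
    f4_ratio: float | None
    n_blocks: int
    n_sites_used: int

    def as_row(self) -> dict:
        p1, p2, p3, o = self.quartet
        return {"P1": p1, "P2": p2, "P3": p3, "outgroup": o,
                "ABBA": self.abba, "BABA": self.baba, "BBAA": self.bbaa,
                "D": self.d, "SE": self.se, "Z": self.z, "p": self.p,
                "f4_ratio": self.f4_ratio, "n_blocks": self.n_blocks,
                "n_sites": self.n_sites_used}


def site_patterns(p1, p2, p3, po) -> tuple:
    """ABBA/BABA/BBAA weights from four allele frequencies (scalar or array)."""
    p1, p2, p3, po = (np.asarray(x, dtype=float) for x in (p1, p2, p3, po))
    abba = (1 - p1) * p2 * p3 * (1 - po) + p1 * (1 - p2) * (1 - p3) * po
    baba = p1 * (1 - p2) * p3 * (1 - po) + (1 - p1) * p2 * (1 - p3) * po
    bbaa = p1 * p2 * (1 - p3) * (1 - po) + (1 - p1) * (1 - p2) * p3 * po
    return abba, baba, bbaa


def _group_freqs(gm: GenotypeMatrix, members: list[str]) -> np.ndarray:
    idx = [gm.sample_ids.index(s) for s in members]
    sub = gm.dosage[idx]
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, alt / (2.0 * n), np.nan)


def _f4(pa, pb, pc, pd) -> np.ndarray:
    return (pa - pb) * (pc - pd)


def _jackknife(per_block_num: np.ndarray, per_block_den: np.ndarray):
    """Delete-one-block jackknife SE of a ratio of sums."""
    B = per_block_num.size
    tot_n, tot_d = per_block_num.sum(), per_block_den.sum()
    loo = (tot_n - per_block_num) / (tot_d - per_block_den)
    mean = loo.mean()
    se = float(np.sqrt((B - 1) / B * ((loo - mean) ** 2).sum()))
    return se


def d_statistic(gm: GenotypeMatrix, groups: dict[str, list[str]],
                quartet: tuple[str, str, str, str],
                block_size_bp: int = 1_000_000,
                seed: int = 0, warn_bbaa: bool = True) -> DStatResult:
    """Genome-wide D with block-jackknife Z and an f4-ratio.

    ``groups`` maps group label to member sample ids; ``quartet`` is
    (P1, P2, P3, Outgroup). Sites with an undefined frequency in any of the
    four populations are skipped. Blocks are contiguous ``block_size_bp``
    spans per chromosome; blocks without informative sites are dropped, and
    with fewer than 2 usable blocks Z and p are None while D is still
    reported. The f4-ratio splits P3 into two seeded random halves (None if
    P3 has fewer than 2 members or its denominator vanishes).
    """
    import warnings

    p1n, p2n, p3n, on = quartet
    for name in quartet:
        if not groups.get(name):
            raise ValidationError(f"quartet population {name!r} is empty")
    if on in (p1n, p2n, p3n):
        raise ValidationError("outgroup must be distinct from P1/P2/P3")

    freqs = {name: _group_freqs(gm, groups[name]) for name in set(quartet)}
    p1, p2, p3, po = (freqs[n] for n in quartet)
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(po)
    abba, baba, bbaa = site_patterns(p1[ok], p2[ok], p3[ok], po[ok])
    sum_abba, sum_baba, sum_bbaa = map(float, (abba.sum(), baba.sum(), bbaa.sum()))
    if warn_bbaa and sum_bbaa < max(sum_abba, sum_baba):
        warnings.warn(
            "BBAA is not the largest pattern sum; the quartet may not match "
            "the population tree"
        )

    denom = sum_abba + sum_baba
    if denom <= 0:
        return DStatResult(quartet, sum_abba, sum_baba, sum_bbaa, None, None,
                           None, None, None, 0, int(ok.sum()))
    d = (sum_abba - sum_baba) / denom

    # physical blocks per chromosome
    chrom = gm.sites["chromosome"].to_numpy()[ok]
    pos = gm.sites["position"].to_numpy()[ok]
    block_key = pd.Series(
        [f"{c}:{(p - 1) // block_size_bp}" for c, p in zip(chrom, pos)]
    )
    num = pd.Series(abba - baba).groupby(block_key.values).sum()
    den = pd.Series(abba + baba).groupby(block_key.values).sum()
    useful = den > 0
    n_blocks = int(useful.sum())
    se = z = p = None
    if n_blocks >= 2:
        se = _jackknife(num[useful].to_numpy(), den[useful].to_numpy())
        if se > 0:
            z = d / se
            p = float(2 * (1 - stats.norm.cdf(abs(z))))

    f4_ratio = _f4_ratio(gm, groups, quartet, ok, seed)
    return DStatResult(quartet, sum_abba, sum_baba, sum_bbaa, float(d), se, z,
                       p, f4_ratio, n_blocks, int(ok.sum()))


def _f4_ratio(gm, groups, quartet, ok, seed) -> float | None:
    p1n, p2n, p3n, on = quartet
    members = list(groups[p3n])
    if len(members) < 2:
        return None
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(members))
    half = len(members) // 2
    p3a = [members[i] for i in perm[:half]]
    p3b = [members[i] for i in perm[half:]]
    f1, f2 = _group_freqs(gm, groups[p1n]), _group_freqs(gm, groups[p2n])
    fa, fb = _group_freqs(gm, p3a), _group_freqs(gm, p3b)
    fo = _group_freqs(gm, groups[on])
    use = ok & np.isfinite(fa) & np.isfinite(fb)
    num = _f4(f1[use], f2[use], fa[use], fo[use]).sum()
    den = _f4(f1[use], fb[use], fa[use], fo[use]).sum()
    if den == 0:
        return None
    return float(num / den)


def per_chromosome_d(gm: GenotypeMatrix, groups: dict[str, list[str]],
                     quartet: tuple[str, str, str, str],
                     block_size_bp: int = 1_000_000, seed: int = 0,
                     z_flag: float = 2.0) -> pd.DataFrame:
    """D-statistic per chromosome, jackknife blocks within each chromosome.

    Chromosomes with |Z| above ``z_flag`` are marked in the ``flagged``
    column (the reporting convention for localized introgression).
    """
    rows = []
    for chrom in gm.chromosomes():
        idx = np.flatnonzero(gm.sites["chromosome"].to_numpy() == chrom)
        sub = gm.subset_sites(idx)
        res = d_statistic(sub, groups, quartet, block_size_bp, seed,
                          warn_bbaa=False)
        row = res.as_row()
        row["chromosome"] = chrom
        row["flagged"] = bool(res.z is not None and res.z > z_flag)
        rows.append(row)
    cols = ["chromosome", "P1", "P2", "P3", "outgroup", "ABBA", "BABA", "BBAA",
            "D", "SE", "Z", "p", "f4_ratio", "n_blocks", "n_sites", "flagged"]
    return pd.DataFrame(rows)[cols]
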