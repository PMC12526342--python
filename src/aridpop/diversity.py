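"""Per-sample and per-group diversity indices with group-difference tests.

Indices: observed heterozygosity Ho (fraction of heterozygous calls among
non-missing calls), unbiased expected heterozygosity He per group, the
inbreeding coefficient F = 1 - Ho/He against the sample's group He, and a
per-sample nucleotide-diversity proxy (heterozygous calls over all loci in
the matrix, missing included in the denominator). Group differences are
tested by one-way ANOVA with Tukey HSD post hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MISSING, GenotypeMatrix, ValidationError


def observed_het(gm: GenotypeMatrix) -> np.ndarray:
    """Per-sample Ho = heterozygous calls / non-missing calls (NaN if none)."""
    if gm.n_sites == 0:
        raise ValidationError("empty genotype matrix")
    het = (gm.dosage == 1).sum(axis=1)
    called = gm.called_mask().sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def expected_het(gm: GenotypeMatrix, labels: np.ndarray) -> dict:
    """Per-group He: mean over sites of unbiased 2p(1-p) * 2n/(2n-1).

    The 2n/(2n-1) factor is Nei's small-sample correction on the allele
    count 2n, making He an unbiased estimate of the population gene
    diversity (the convention of standard genotype toolkits).
    n is the number of genotyped diploids in the group at the site; sites
    with fewer than 2 genotyped members are skipped. A group monomorphic at
    every site has He = 0.
    """
    labels = np.asarray(labels)
    out: dict = {}
    for g in np.unique(labels):
        rows = np.flatnonzero(labels == g)
        if len(rows) < 2:
            raise ValidationError(f"group {g} has fewer than 2 samples")
        sub = gm.dosage[rows]
        called = sub != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        ok = n >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
        he = 2.0 * p * (1.0 - p) * 2 * n / np.maximum(2 * n - 1, 1)
        out[g] = float(he[ok].mean()) if ok.any() else 0.0
    return out


def inbreeding_f(ho: np.ndarray, labels: np.ndarray, he_by_group: dict) -> np.ndarray:
    """Per-sample F = 1 - Ho / He(group); NaN where the group He is 0."""
    he = np.array([he_by_group[g] for g in np.asarray(labels)])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(he > 0, 1.0 - ho / np.where(he == 0, 1, he), np.nan)


def pi_proxy(gm: GenotypeMatrix) -> np.ndarray:
    """Per-sample heterozygous-call fraction over all loci (missing counted)."""
    if gm.n_sites == 0:
        raise ValidationError("empty genotype matrix")
    return (gm.dosage == 1).sum(axis=1) / gm.n_sites


def diversity_table(gm: GenotypeMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Assemble per-sample Ho, pi proxy, group He and F into one table."""
    labels = np.asarray(labels)
    ho = observed_het(gm)
    he = expected_het(gm, labels)
    f = inbreeding_f(ho, labels, he)
    return pd.DataFrame({
        "sample_id": gm.sample_ids,
        "group": labels,
        "Ho": ho,
        "pi_proxy": pi_proxy(gm),
        "He_group": [he[g] for g in labels],
        "F": f,
    })


@dataclass
class GroupTestResult:
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, reject


def group_tests(values: np.ndarray, labels: np.ndarray,
                alpha: float = 0.05) -> GroupTestResult:
    """One-way ANOVA plus Tukey HSD over per-sample values grouped by label.

    Degenerate input (all groups constant and equal) reports F = 0, p = 1
    with no significant pair rather than dividing by zero.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = ~np.isnan(values)
    values, labels = values[ok], labels[ok]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValidationError("need >=2 groups with >=2 members each")
    samples = [values[labels == g] for g in uniq]
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(values) == 0:
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
        tukey = pd.DataFrame(
            [(a, b, 0.0, 1.0, False) for a, b in pairs],
            columns=["group_a", "group_b", "mean_diff", "p_adj", "reject"],
        )
        return GroupTestResult(anova_f=0.0, anova_p=1.0, tukey=tukey)
    f, p = stats.f_oneway(*samples)
    if np.isnan(f):  # zero within-group variance, unequal means
        f, p = np.inf, 0.0
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    tukey.columns = ["group_a", "group_b", "mean_diff", "p_adj", "reject"]
    return GroupTestResult(anova_f=float(f), anova_p=float(p), tukey=tukey)
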