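"""Pairwise relatedness, clone grouping and representative selection.

Relatedness uses the method-of-moments identity-by-descent estimator of
PLINK ``--genome``: observed identity-by-state (IBS) sharing is compared
with its expectation under IBD state 0/1/2 given sample allele frequencies,
with the finite-sample allele-count corrections of the original estimator.
PI_HAT = P(IBD=2) + P(IBD=1)/2. Pairs at PI_HAT >= 0.95 are treated as
clonemates; clonal groups are the connected components of the clonemate
graph (transitive closure) and each multi-member group keeps its
lowest-missingness member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, SampleMeta, ValidationError

LOW_CONFIDENCE_SITES = 100


@dataclass
class RelatednessTable:
    """One row per unordered sample pair with IBS counts and PI_HAT."""

    pairs: pd.DataFrame  # sample_i, sample_j, ibs0, ibs1, ibs2, n_sites, pi_hat, low_confidence

    def lookup(self, a: str, b: str) -> float:
        df = self.pairs
        m = ((df["sample_i"] == a) & (df["sample_j"] == b)) | (
            (df["sample_i"] == b) & (df["sample_j"] == a)
        )
        return float(df.loc[m, "pi_hat"].iloc[0])


@dataclass
class CloneGroups:
    """Partition of samples into clonal groups with one representative each."""

    groups: list[list[str]]
    representatives: dict[int, str] = field(default_factory=dict)

    def group_of(self) -> dict[str, int]:
        return {s: gi for gi, grp in enumerate(self.groups) for s in grp}


def _expectation_terms(gm: GenotypeMatrix) -> tuple[np.ndarray, ...]:
    """Per-site expected IBS probabilities given IBD state, bias-corrected.

    Uses the allele-count corrections of the standard method-of-moments
    estimator; sites with fewer than 2 genotyped diploids or monomorphic
    frequencies contribute nothing (expectation set to 0, matching their
    uninformative IBS contribution).
    """
    called = gm.called_mask()
    n_geno = called.sum(axis=0)
    alt = np.where(called, gm.dosage, 0).sum(axis=0)
    T = 2.0 * n_geno  # total allele count per site
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / T
    q = 1.0 - p
    X = alt.astype(float)           # alt allele count
    Y = T - X                       # ref allele count
    ok = (T >= 4) & (X >= 2) & (Y >= 2)

    def safe(num, den):
        return np.where(ok & (den != 0), num / np.where(den == 0, 1, den), 0.0)

    c1 = safe(T, T - 1)
    c2 = safe(T, T - 2)
    c3 = safe(T, T - 3)
    ax1 = safe(X - 1, X)
    ax2 = safe(X - 2, X)
    ax3 = safe(X - 3, X)
    ay1 = safe(Y - 1, Y)
    ay2 = safe(Y - 2, Y)
    ay3 = safe(Y - 3, Y)

    p = np.where(ok, p, 0.0)
    q = np.where(ok, q, 0.0)
    e00 = 2 * p**2 * q**2 * ax1 * ay1 * c1 * c2 * c3
    e10 = (4 * p**3 * q * ax1 * ax2 + 4 * p * q**3 * ay1 * ay2) * c1 * c2 * c3
    e20 = (p**4 * ax1 * ax2 * ax3 + q**4 * ay1 * ay2 * ay3
           + 4 * p**2 * q**2 * ax1 * ay1) * c1 * c2 * c3
    e11 = (2 * p**2 * q * ax1 + 2 * p * q**2 * ay1) * c1 * c2
    e21 = (p**3 * ax1 * ax2 + q**3 * ay1 * ay2
           + p**2 * q * ax1 + p * q**2 * ay1) * c1 * c2
    e22 = np.where(ok, 1.0, 0.0)
    return e00, e10, e20, e11, e21, e22


def _project_simplex_3(p0: float, p1: float, p2: float) -> tuple[float, float, float]:
    """Euclidean projection of (p0, p1, p2) onto the probability simplex."""
    v = np.array([p0, p1, p2])
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, 4) > (css - 1))[0][-1]
    theta = (css[rho] - 1) / (rho + 1.0)
    w = np.maximum(v - theta, 0)
    return float(w[0]), float(w[1]), float(w[2])


def pairwise_relatedness(gm: GenotypeMatrix) -> RelatednessTable:
    """Method-of-moments IBD estimates for every sample pair.

    Allele frequencies come from the full sample set of ``gm``. Pairs with
    fewer than 100 pairwise-complete informative sites are kept but flagged
    low-confidence with a warning.
    """
    if gm.n_samples < 2:
        raise ValidationError("need at least 2 samples for relatedness")
    e00, e10, e20, e11, e21, e22 = _expectation_terms(gm)
    called = gm.called_mask().astype(np.float64)
    informative = (e22 > 0).astype(np.float64)

    def pairsum(per_site: np.ndarray) -> np.ndarray:
        w = called * per_site[None, :]
        return w @ called.T

    E00, E10, E20 = pairsum(e00), pairsum(e10), pairsum(e20)
    E11, E21 = pairsum(e11), pairsum(e21)
    # observed IBS restricted to informative (polymorphic, well-genotyped) sites
    x = [((gm.dosage == k) & gm.called_mask()).astype(np.float64)
         * informative[None, :] for k in (0, 1, 2)]
    ibs2 = x[0] @ x[0].T + x[1] @ x[1].T + x[2] @ x[2].T
    ibs0 = x[0] @ x[2].T + x[2] @ x[0].T
    ibs1 = x[0] @ x[1].T + x[1] @ x[0].T + x[1] @ x[2].T + x[2] @ x[1].T

    rows = []
    n_low = 0
    ids = gm.sample_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            n_sites = ibs0[i, j] + ibs1[i, j] + ibs2[i, j]
            low = n_sites < LOW_CONFIDENCE_SITES
            n_low += low
            if E00[i, j] > 0 and n_sites > 0:
                p0 = ibs0[i, j] / E00[i, j]
                p1 = (ibs1[i, j] - p0 * E10[i, j]) / E11[i, j] if E11[i, j] > 0 else 0.0
                p2 = (ibs2[i, j] - p0 * E20[i, j] - p1 * E21[i, j]) / n_sites
                p0, p1, p2 = _project_simplex_3(p0, p1, p2)
            else:
                p0 = p1 = 0.0
                p2 = 0.0
            pi_hat = min(1.0, max(0.0, p2 + 0.5 * p1))
            rows.append((ids[i], ids[j], ibs0[i, j], ibs1[i, j], ibs2[i, j],
                         n_sites, pi_hat, bool(low)))
    if n_low:
        warnings.warn(
            f"{n_low} pair(s) had < {LOW_CONFIDENCE_SITES} complete sites; "
            "their PI_HAT is low-confidence"
        )
    df = pd.DataFrame(rows, columns=["sample_i", "sample_j", "ibs0", "ibs1",
                                     "ibs2", "n_sites", "pi_hat",
                                     "low_confidence"])
    return RelatednessTable(df)


def clone_groups(rel: RelatednessTable, threshold: float = 0.95) -> CloneGroups:
    """Connected components of the PI_HAT >= threshold graph; singletons kept."""
    g = nx.Graph()
    df = rel.pairs
    g.add_nodes_from(pd.unique(df[["sample_i", "sample_j"]].values.ravel()))
    hits = df[df["pi_hat"] >= threshold]
    g.add_edges_from(zip(hits["sample_i"], hits["sample_j"]))
    groups = [sorted(c) for c in nx.connected_components(g)]
    groups.sort(key=lambda c: c[0])
    return CloneGroups(groups=groups)


def select_representatives(
    groups: CloneGroups, meta: list[SampleMeta]
) -> list[str]:
    """One sample per group: minimal f_miss, ties broken by smaller id.

    Updates ``clonal_status`` in ``meta`` (representative / clonemate /
    unique) and fills ``groups.representatives``.
    """
    fm = {m.sample_id: m.f_miss for m in meta}
    missing_ids = [s for grp in groups.groups for s in grp if fm.get(s) is None]
    if missing_ids:
        raise ValidationError(
            f"f_miss unknown for {missing_ids[:3]}...; run filter_samples first"
        )
    by_id = {m.sample_id: m for m in meta}
    retained = []
    for gi, grp in enumerate(groups.groups):
        rep = min(grp, key=lambda s: (fm[s], s))
        groups.representatives[gi] = rep
        retained.append(rep)
        for s in grp:
            if len(grp) == 1:
                by_id[s].clonal_status = "unique"
            else:
                by_id[s].clonal_status = "representative" if s == rep else "clonemate"
    return sorted(retained)
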