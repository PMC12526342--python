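"""Linkage-disequilibrium decay: r^2 vs physical distance, smoothed curves,
and the half-decay distance.

Within each chromosome, all SNP pairs up to a maximum separation contribute
(distance, r^2) points; r^2 is the squared dosage correlation restricted to
a sample group. Points are averaged in fixed-width distance bins and a
weighted cubic smoothing spline is fitted to the bin means (weights = bin
pair counts). The half-decay distance is the first distance at which the
fitted curve drops to half of its value nearest distance zero — anchoring
the "maximum" at short range rather than at a possibly wiggly global
maximum, since physical LD decay is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, ValidationError
from .qc_filter import genotype_r2


@dataclass
class LdCurve:
    bins: pd.DataFrame                 # midpoint_bp, mean_r2, n_pairs
    bin_width_bp: int
    fitted_grid: np.ndarray | None = None
    fitted_values: np.ndarray | None = None
    half_decay_bp: float | None = None


def r2_pairs(gm: GenotypeMatrix, group_samples: list[str] | None = None,
             max_dist_bp: int = 300_000) -> np.ndarray:
    """(distance_bp, r^2) rows for all intra-chromosome SNP pairs in range.

    Restricted to ``group_samples`` when given; pairs whose r^2 is
    undefined (fewer than 2 complete genotype pairs) are dropped.
    """
    sub = gm if group_samples is None else gm.subset_samples(group_samples)
    if sub.n_samples < 2:
        raise ValidationError("need at least 2 samples for LD")
    out_d: list[np.ndarray] = []
    out_r: list[np.ndarray] = []
    chrom_arr = sub.sites["chromosome"].to_numpy()
    pos_arr = sub.sites["position"].to_numpy()
    for chrom in sub.chromosomes():
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[idx]
        dos = sub.dosage[:, idx]
        complete = not (dos == MISSING).any()
        if complete and len(idx) >= 2:
            sd = dos.std(axis=0)
            ok_col = sd > 0
            with np.errstate(invalid="ignore"):
                cc = np.corrcoef(dos.astype(float).T) ** 2
            for a in range(len(idx)):
                hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
                for b in range(a + 1, hi):
                    r2 = 0.0 if not (ok_col[a] and ok_col[b]) else float(cc[a, b])
                    out_d.append(np.float64(pos[b] - pos[a]))
                    out_r.append(np.float64(r2))
        else:
            for a in range(len(idx)):
                hi = np.searchsorted(pos, pos[a] + max_dist_bp, side="right")
                for b in range(a + 1, hi):
                    r2 = genotype_r2(dos[:, a], dos[:, b])
                    if np.isnan(r2):
                        continue
                    out_d.append(np.float64(pos[b] - pos[a]))
                    out_r.append(np.float64(r2))
    if not out_d:
        return np.empty((0, 2))
    return np.column_stack([np.asarray(out_d), np.asarray(out_r)])


def bin_curve(pairs: np.ndarray, bin_width_bp: int = 100) -> LdCurve:
    """Average r^2 in fixed-width distance bins starting at 0."""
    if len(pairs) == 0:
        raise ValidationError("no (distance, r^2) pairs to bin")
    dist, r2 = pairs[:, 0], pairs[:, 1]
    k = (dist // bin_width_bp).astype(int)
    df = pd.DataFrame({"k": k, "r2": r2}).groupby("k")["r2"].agg(["mean", "size"])
    bins = pd.DataFrame({
        "midpoint_bp": (df.index.to_numpy() + 0.5) * bin_width_bp,
        "mean_r2": df["mean"].to_numpy(),
        "n_pairs": df["size"].to_numpy(),
    })
    return LdCurve(bins=bins, bin_width_bp=bin_width_bp)


def fit_and_half_decay(curve: LdCurve, spline_df: int = 8) -> LdCurve:
    """Weighted smoothing-spline fit of the binned curve plus half-decay.

    A cubic least-squares B-spline with ``spline_df`` basis functions
    (interior knots at distance quantiles) is fitted to bin means weighted
    by pair counts, evaluated on a grid with the bin width as step, and
    clipped to [0, 1]. The reference maximum is the fitted value at the
    smallest bin; the half-decay distance is the first grid crossing of
    half that value (linear interpolation between grid points), or None if
    the curve never crosses within range.
    """
    from scipy.interpolate import make_lsq_spline

    bins = curve.bins
    if len(bins) < 5:
        raise ValidationError(
            "need at least 5 non-empty bins; consider wider bins"
        )
    x = bins["midpoint_bp"].to_numpy(float)
    y = bins["mean_r2"].to_numpy(float)
    w = np.sqrt(bins["n_pairs"].to_numpy(float))
    k = 3
    n_basis = min(spline_df, len(x) - 1)
    n_basis = max(n_basis, k + 1)
    n_interior = n_basis - (k + 1)
    if n_interior > 0:
        # log-spaced interior knots: LD decay curvature concentrates at
        # short range, so uniform knots under-resolve the initial drop
        interior = np.exp(np.linspace(np.log(x[0] + 1.0), np.log(x[-1]),
                                      n_interior + 2)[1:-1])
        interior = np.clip(interior, x[0] + 1e-9, x[-1] - 1e-9)
    else:
        interior = np.array([])
    t = np.r_[[x[0]] * (k + 1), interior, [x[-1]] * (k + 1)]
    spl = make_lsq_spline(x, y, t, k=k, w=w)
    grid = np.arange(x[0], x[-1] + 0.5 * curve.bin_width_bp, curve.bin_width_bp)
    fitted = np.clip(spl(grid), 0.0, 1.0)

    ref_max = fitted[0]
    target = ref_max / 2.0
    half = None
    below = np.flatnonzero(fitted <= target)
    if below.size:
        i = below[0]
        if i == 0:
            half = float(grid[0])
        else:
            x0, x1 = grid[i - 1], grid[i]
            y0, y1 = fitted[i - 1], fitted[i]
            half = float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0)) if y0 != y1 \
                else float(x1)
    return LdCurve(bins=bins, bin_width_bp=curve.bin_width_bp,
                   fitted_grid=grid, fitted_values=fitted, half_decay_bp=half)


def group_ld_curves(gm: GenotypeMatrix, labels: np.ndarray,
                    max_dist_bp: int = 300_000, bin_width_bp: int = 100,
                    spline_df: int = 8) -> pd.DataFrame:
    """Half-decay summary per group label (NaN where undefined)."""
    labels = np.asarray(labels)
    rows = []
    for g in np.unique(labels):
        members = [s for s, lab in zip(gm.sample_ids, labels) if lab == g]
        pairs = r2_pairs(gm, members, max_dist_bp)
        if len(pairs) == 0:
            rows.append((g, 0, np.nan))
            continue
        curve = fit_and_half_decay(bin_curve(pairs, bin_width_bp), spline_df)
        rows.append((g, len(pairs),
                     np.nan if curve.half_decay_bp is None else curve.half_decay_bp))
    return pd.DataFrame(rows, columns=["group", "n_pairs", "half_decay_bp"])
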