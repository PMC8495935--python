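"""Pairwise linkage disequilibrium between deletions and its decay profile.

LD between two presence/absence sites is r^2, the squared Pearson
correlation of the paired 0/1 vectors over samples nonmissing at *both*
sites (pairwise-complete handling).  The decay profile bins all
intra-chromosome pairs up to a distance cap into fixed-width distance bins
(default 100 bp) and averages r^2 per bin; LD-half is the smallest bin
midpoint at which the binned mean has dropped to half of the profile's
maximum bin mean.  Profiles can be computed on all sites or restricted to
genic / CDS strata via feature overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureOverlap
from .variant_io import GenotypeMatrix

logger = logging.getLogger("svpanel")

DEFAULT_MAX_DIST_BP = 500_000
DEFAULT_BIN_WIDTH_BP = 100


@dataclass
class LDProfile:
    bin_width_bp: int
    bin_mid_distances: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    stratum: str = "all"

    @property
    def max_mean_r2(self) -> float:
        return float(np.max(self.mean_r2)) if self.mean_r2.size else float("nan")

    @property
    def ld_half_bp(self) -> float | None:
        return ld_half(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "bin_mid": self.bin_mid_distances,
                "n_pairs": self.n_pairs,
                "mean_r2": self.mean_r2,
            }
        )

    def rolling_mean(self, window_bins: int = 5) -> np.ndarray:
        """Centered rolling mean over bins, for plotting parity with
        moving-average presentations of the pair cloud."""
        return (
            pd.Series(self.mean_r2)
            .rolling(window_bins, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1 site rows, pairwise-complete.

    Raises ValueError when fewer than 2 shared nonmissing samples remain or
    either site is monomorphic on the shared set (r^2 undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 shared nonmissing samples")
    xs, ys = x[ok], y[ok]
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        raise ValueError("monomorphic site on the shared nonmissing set")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _pair_r2_vector(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """r^2 of one site row against many, pairwise-complete; NaN where
    undefined.  Vectorized over rows of Y."""
    vx = ~np.isnan(x)
    vY = ~np.isnan(Y)
    valid = vx[None, :] & vY
    n = valid.sum(axis=1).astype(float)
    x0 = np.where(np.isnan(x), 0.0, x)
    Y0 = np.where(np.isnan(Y), 0.0, Y)
    sx = valid @ x0
    sy = (Y0 * valid).sum(axis=1)
    sxy = (Y0 * (valid * x0[None, :])).sum(axis=1)
    sxx = valid @ (x0 * x0)
    syy = (Y0 * Y0 * valid).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        r2 = (cov * cov) / (varx * vary)
    r2[(n < 2) | (varx <= 0) | (vary <= 0)] = np.nan
    return r2


def decay_profile(
    matrix: GenotypeMatrix,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
    bin_width_bp: int = DEFAULT_BIN_WIDTH_BP,
    stratum: str = "all",
) -> LDProfile:
    """Distance-binned mean r^2 over all intra-chromosome pairs <= the cap.

    Pair distance is the difference of site starts.  Pairs whose r^2 is
    undefined (monomorphic on the shared nonmissing set) are skipped.
    """
    if max_dist_bp <= 0 or bin_width_bp <= 0:
        raise ValueError("max_dist_bp and bin_width_bp must be > 0")
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    pos = matrix.positions
    for chrom, idx in pos.groupby("chrom", sort=True).indices.items():
        idx = np.asarray(idx)
        starts = pos["start"].to_numpy()[idx]
        order = np.argsort(starts, kind="stable")
        idx, starts = idx[order], starts[order]
        rows = matrix.presence[idx]
        for a in range(len(idx) - 1):
            hi = np.searchsorted(starts, starts[a] + max_dist_bp, side="right")
            if hi <= a + 1:
                continue
            r2 = _pair_r2_vector(rows[a], rows[a + 1 : hi])
            dist = starts[a + 1 : hi] - starts[a]
            ok = ~np.isnan(r2)
            if not ok.any():
                continue
            bins = np.minimum(dist[ok] // bin_width_bp, n_bins - 1).astype(int)
            np.add.at(sums, bins, r2[ok])
            np.add.at(counts, bins, 1)

    has = counts > 0
    mids = (np.arange(n_bins) * bin_width_bp + bin_width_bp / 2.0)[has]
    with np.errstate(invalid="ignore"):
        means = (sums[has] / counts[has])
    if not has.any():
        logger.info("decay_profile: no valid pairs")
    return LDProfile(
        bin_width_bp=bin_width_bp,
        bin_mid_distances=mids,
        mean_r2=means,
        n_pairs=counts[has],
        stratum=stratum,
    )


def ld_half(profile: LDProfile) -> float | None:
    """Smallest bin midpoint where mean r^2 <= half the profile maximum.

    The maximum is the largest bin mean (not necessarily the shortest
    distance bin).  Returns None if the profile never decays to half within
    its support, or is empty.
    """
    if profile.mean_r2.size == 0:
        return None
    half = profile.max_mean_r2 / 2.0
    below = profile.mean_r2 <= half
    if not below.any():
        return None
    return float(profile.bin_mid_distances[np.argmax(below)])


def stratify_sites(
    matrix: GenotypeMatrix,
    overlaps: Sequence[FeatureOverlap],
    stratum: str,
) -> GenotypeMatrix:
    """Sub-matrix of sites in a stratum: all, genic, or cds."""
    if stratum == "all":
        return matrix
    if len(overlaps) != matrix.n_sites:
        raise ValueError("overlaps not aligned with matrix sites")
    if stratum == "genic":
        keep = np.array([o.in_gene for o in overlaps])
    elif stratum == "cds":
        keep = np.array([o.in_cds for o in overlaps])
    else:
        raise ValueError("stratum must be one of 'all', 'genic', 'cds'")
    if not keep.any():
        logger.info("stratify_sites: stratum %r is empty", stratum)
    return matrix.subset_sites(keep)


def plot_ld_decay(profiles: Sequence[LDProfile], path) -> None:
    """Decay curves for one or more strata (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for p in profiles:
        ax.plot(p.bin_mid_distances / 1000.0, p.rolling_mean(), label=p.stratum)
        half = ld_half(p)
        if half is not None:
            ax.axvline(half / 1000.0, linestyle="--", alpha=0.4)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
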