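"""Windowed nucleotide diversity (pi) and the SV/SNP window correlation.

Per-site diversity is the average pairwise difference among nonmissing
calls.  For presence/absence SV sites with c1 carriers and c0 non-carriers
among m nonmissing genotypes:

    pi_site = 2 * c1 * c0 / (m * (m - 1))

For diploid SNP sites the same estimator runs at the allele level: with a
alternate alleles among m = 2 * (nonmissing genotypes) chromosomes,
pi_site = 2 * a * (m - a) / (m * (m - 1)).  Window pi sums site values over
sites whose start falls in the window and divides by the window length in
bp; windows tile each chromosome from position 1 (step = window by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import GenotypeMatrix

logger = logging.getLogger("svpanel")

DEFAULT_WINDOW_BP = 500_000


def site_pi(row: np.ndarray) -> float:
    """Mean pairwise difference among nonmissing presence/absence calls."""
    row = np.asarray(row, dtype=float)
    nonmissing = ~np.isnan(row)
    m = int(nonmissing.sum())
    if m < 2:
        raise ValueError("site_pi needs >= 2 nonmissing calls")
    c1 = int(np.nansum(row))
    c0 = m - c1
    return 2.0 * c1 * c0 / (m * (m - 1))


def site_pi_dosage(row: np.ndarray) -> float:
    """Allele-level pi for one diploid SNP site coded 0/1/2 with NaN missing."""
    row = np.asarray(row, dtype=float)
    nonmissing = ~np.isnan(row)
    if int(nonmissing.sum()) < 1:
        raise ValueError("site has no nonmissing genotypes")
    m = 2 * int(nonmissing.sum())
    if m < 2:
        raise ValueError("site_pi_dosage needs >= 2 alleles")
    a = float(np.nansum(row))
    return 2.0 * a * (m - a) / (m * (m - 1))


def _window_table(
    positions: pd.DataFrame,
    pis: np.ndarray,
    window_bp: int,
    step_bp: int,
    chrom_lengths: dict[str, int] | None,
) -> pd.DataFrame:
    rows = []
    for chrom, grp in positions.assign(pi=pis).groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        length = (chrom_lengths or {}).get(chrom, int(starts.max()) if len(starts) else 0)
        w0 = 1
        while w0 <= length:
            w1 = w0 + window_bp - 1
            sel = (starts >= w0) & (starts <= w1)
            rows.append(
                {
                    "chrom": chrom,
                    "window_start": w0,
                    "window_end": w1,
                    "pi": grp["pi"].to_numpy()[sel].sum() / window_bp,
                    "n_sites": int(sel.sum()),
                }
            )
            w0 += step_bp
    return pd.DataFrame(rows)


def window_pi(
    matrix: GenotypeMatrix,
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int | None = None,
    chrom_lengths: dict[str, int] | None = None,
    kind: str = "presence",
) -> pd.DataFrame:
    """Per-window diversity: columns chrom, window_start, window_end, pi, n_sites.

    ``kind="presence"`` treats rows as 0/1 carrier calls (SVs);
    ``kind="dosage"`` treats rows as 0/1/2 diploid dosages (SNPs).
    Sites with < 2 nonmissing calls are skipped with a log note.  Window
    assignment uses the site *start*; windows tile from position 1 up to the
    chromosome length (largest site start when lengths are not given).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    step_bp = step_bp or window_bp
    if step_bp <= 0:
        raise ValueError("step_bp must be > 0")
    fn = site_pi if kind == "presence" else site_pi_dosage
    pis = np.zeros(matrix.n_sites)
    skipped = 0
    for i in range(matrix.n_sites):
        try:
            pis[i] = fn(matrix.row(i))
        except ValueError:
            skipped += 1
    if skipped:
        logger.info("window_pi: skipped %d site(s) with < 2 nonmissing calls", skipped)
    return _window_table(matrix.positions, pis, window_bp, step_bp, chrom_lengths)


def diversity_correlation(
    win_a: pd.DataFrame, win_b: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation of paired window pi values with two-sided p.

    Windows are matched on (chrom, window_start); both tables must come
    from the same windowing.  Raises on zero variance or < 3 pairs.
    """
    merged = win_a.merge(
        win_b, on=["chrom", "window_start"], suffixes=("_a", "_b")
    )
    x = merged["pi_a"].to_numpy(dtype=float)
    y = merged["pi_b"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 paired windows")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a window-pi vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
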