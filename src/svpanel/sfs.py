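"""Site frequency spectrum and the neutral expectation from Watterson's theta.

For a panel of n genotypes scored presence/absence, each segregating site
contributes one count to the bin equal to its minor-carrier count
(1 .. floor(n/2); for 347 genotypes the last bin is 173).  Under neutrality
the expected number of sites in bin i is theta_w / i, where

    theta_w = S / H(n - 1),    H(m) = sum_{j=1}^{m} 1/j

with S the number of segregating sites.  n counts *genotypes*, matching the
presence/absence coding (a config switch doubles it for the diploid
chromosome-count reading).  The expected curve is the plain unfolded 1/i
form by default; a textbook folded variant (theta_w * (1/i + 1/(n-i)),
halved at i = n/2) is available via ``mode="textbook_folded"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import minor_carrier_count
from .variant_io import GenotypeMatrix


@dataclass
class SiteFrequencySpectrum:
    n_samples: int
    bins: np.ndarray  # 1 .. floor(n/2)
    observed: np.ndarray  # per-bin site counts
    theta_w: float
    expected: np.ndarray  # theta_w / i per bin
    S: int  # segregating sites entering the spectrum
    #: first bin that missingness can distort at some site: with m nonmissing
    #: genotypes the minor-allele identity flips at m/2, so bins >= min(m) -
    #: floor(n/2) may gain or lose sites purely through censoring.  None when
    #: no site is affected (complete data).
    censor_bin: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bins, "observed": self.observed, "expected": self.expected}
        )


def harmonic_number(m: int) -> float:
    """H(m) = sum_{j=1}^{m} 1/j by direct summation."""
    if m < 1:
        raise ValueError("harmonic number needs m >= 1")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator: S divided by the harmonic number H(n-1)."""
    if n < 2:
        raise ValueError("watterson_theta requires n >= 2")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / harmonic_number(n - 1)


def expected_neutral_sfs(
    theta_w: float, bins: np.ndarray, n: int | None = None, mode: str = "paper"
) -> np.ndarray:
    """Expected site count per bin under neutrality.

    ``mode="paper"``: theta_w / i.  ``mode="textbook_folded"``:
    theta_w * (1/i + 1/(n-i)) / (1 + [i == n-i]), which needs ``n``.
    """
    if theta_w < 0:
        raise ValueError("theta_w must be >= 0")
    bins = np.asarray(bins, dtype=float)
    if mode == "paper":
        return theta_w / bins
    if mode == "textbook_folded":
        if n is None:
            raise ValueError("textbook_folded mode needs n")
        same = bins == (n - bins)
        return theta_w * (1.0 / bins + 1.0 / (n - bins)) / (1.0 + same)
    raise ValueError(f"unknown mode {mode!r}")


def observed_sfs(matrix: GenotypeMatrix, svtype: str | None = None) -> np.ndarray:
    """Histogram of minor-carrier counts over bins 1..floor(n/2).

    Sites with minor count 0 (monomorphic on the nonmissing set) contribute
    to no bin.  ``svtype`` restricts to matching sites.
    """
    n = matrix.n_samples
    max_bin = n // 2
    counts = np.zeros(max_bin, dtype=int)
    svtypes = matrix.positions["svtype"].to_numpy()
    for i in range(matrix.n_sites):
        if svtype is not None and svtypes[i] != svtype:
            continue
        c = minor_carrier_count(matrix.row(i))
        if 1 <= c <= max_bin:
            counts[c - 1] += 1
    return counts


def compute_sfs(
    matrix: GenotypeMatrix,
    svtype: str | None = None,
    n_mode: str = "genotypes",
    expected_mode: str = "paper",
) -> SiteFrequencySpectrum:
    """Observed spectrum plus the neutral expectation for one SV class.

    ``n_mode="genotypes"`` uses the panel size directly (the presence/absence
    reading that makes bins run to floor(n/2)); ``"chromosomes"`` doubles it.
    S is the number of sites entering the spectrum (minor count >= 1).
    """
    if n_mode not in ("genotypes", "chromosomes"):
        raise ValueError("n_mode must be 'genotypes' or 'chromosomes'")
    n = matrix.n_samples
    observed = observed_sfs(matrix, svtype=svtype)
    bins = np.arange(1, n // 2 + 1)
    S = int(observed.sum())
    n_theta = n if n_mode == "genotypes" else 2 * n
    theta = watterson_theta(S, n_theta) if S > 0 else 0.0
    expected = expected_neutral_sfs(theta, bins, n=n_theta, mode=expected_mode)
    nonmissing = (~np.isnan(matrix.presence)).sum(axis=1)
    svtypes = matrix.positions["svtype"].to_numpy()
    if svtype is not None:
        nonmissing = nonmissing[svtypes == svtype]
    if nonmissing.size and int(nonmissing.min()) < n:
        censor = max(1, int(nonmissing.min()) - n // 2)
    else:
        censor = None
    return SiteFrequencySpectrum(
        n_samples=n, bins=bins, observed=observed, theta_w=theta,
        expected=expected, S=S, censor_bin=censor,
    )


def sfs_fit_statistic(
    sfs: SiteFrequencySpectrum, min_expected: float = 5.0
) -> tuple[float, float, pd.DataFrame]:
    """Chi-square goodness of fit of the observed spectrum to the 1/i shape.

    The 1/i weights are renormalized over the spectrum's bins so pooled
    expected counts sum to S (a proper multinomial null), then consecutive
    bins are pooled from the left until every pooled expected count is
    >= ``min_expected`` (the remainder tail forms the last pool).  Bins
    above the spectrum's ``censor_bin`` — frequencies no site could reach
    given its nonmissing count — are pooled with the final cell first: near
    the folding boundary the minor-allele identity flips under missingness,
    a censoring artifact a neutrality test must not mistake for misfit.
    Returns (chi2, p, table); the table carries per-bin observed, expected
    and observed/expected ratios on the unpooled bins.
    """
    obs = np.asarray(sfs.observed, dtype=float)
    S = obs.sum()
    if S <= 0:
        raise ValueError("empty spectrum")
    w = 1.0 / sfs.bins.astype(float)
    probs = w / w.sum()
    exp = S * probs

    cut = len(obs)
    if sfs.censor_bin is not None:
        cut = min(cut, int(sfs.censor_bin))
    if cut < 1:
        raise ValueError("censor bin below the first spectrum bin")
    obs_c = np.concatenate([obs[: cut - 1], [obs[cut - 1 :].sum()]])
    exp_c = np.concatenate([exp[: cut - 1], [exp[cut - 1 :].sum()]])

    pooled_obs, pooled_exp = _pool(obs_c, exp_c, min_expected)
    if len(pooled_obs) < 2:
        raise ValueError("fewer than 2 pooled bins; spectrum too small to test")
    chi2, p = stats.chisquare(pooled_obs, pooled_exp)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(exp > 0, obs / exp, np.nan)
    table = pd.DataFrame(
        {"bin": sfs.bins, "observed": obs, "expected_fit": exp, "ratio": ratio}
    )
    return float(chi2), float(p), table


def _pool(obs: np.ndarray, exp: np.ndarray, min_expected: float):
    """Pool consecutive bins left-to-right until each pool's expected count
    reaches ``min_expected``; an undersized final pool merges backwards."""
    p_obs: list[float] = []
    p_exp: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            p_obs.append(acc_o)
            p_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if p_obs:
            p_obs[-1] += acc_o
            p_exp[-1] += acc_e
        else:
            p_obs.append(acc_o)
            p_exp.append(acc_e)
    return np.array(p_obs), np.array(p_exp)


def plot_sfs(sfs: SiteFrequencySpectrum, path, max_bin: int | None = 50) -> None:
    """Observed-vs-expected spectrum bar/line plot (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = max_bin or len(sfs.bins)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(sfs.bins[:k], sfs.observed[:k], color="firebrick", label="observed")
    ax.plot(sfs.bins[:k], sfs.expected[:k], "k--", label=r"expected $\theta_w/i$")
    ax.set_xlabel("minor carrier count")
    ax.set_ylabel("number of sites")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
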