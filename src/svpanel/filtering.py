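"""The SV filter cascade and its per-stage tally.

Stages, in order (each applied to the survivors of the previous one):

1. paired-end support  — keep records with PE support > 3 (i.e. >= 4);
2. precise breakpoint  — keep records flagged PRECISE;
3. break-ends          — drop BND (and unknown-architecture) records;
4. size                — keep 50 bp <= length <= 100,000 bp;
5. missingness         — drop sites with > 20% missing genotypes;
6. minor SV frequency  — keep sites whose minor-carrier frequency is >= 0.05
                         (optional: the site-frequency spectrum and diversity
                         stages use the pre-MAF set).

The tally mirrors the shape of a per-svtype survivors table: one row per
svtype plus a Total row, one column per stage, plus min/max/median size of
the final survivor set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import ABSENT, MISSING, PRESENT, GenotypeMatrix, SVRecord

STAGES = (
    "no_filters",
    "pair_end",
    "precise",
    "bnd",
    "size",
    "missing",
    "maf",
)


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade.

    ``min_pe_support`` is the smallest paired-end support kept ("more than
    3" -> 4).  ``max_missing_fraction`` is strict: a site is removed iff its
    missing fraction exceeds it.  ``min_maf`` keeps sites whose minor-carrier
    frequency is >= the threshold; ``maf_denominator`` selects whether that
    frequency divides by the full panel size ("panel", matching the
    18-of-347 arithmetic) or by the nonmissing count at the site.
    """

    min_pe_support: int = 4
    require_precise: bool = True
    drop_bnd: bool = True
    min_size_bp: int = 50
    max_size_bp: int = 100_000
    max_missing_fraction: float = 0.20
    min_maf: float = 0.05
    maf_denominator: str = "panel"

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_size_bp > self.max_size_bp:
            raise ValueError("min_size_bp > max_size_bp")
        if self.maf_denominator not in ("panel", "nonmissing"):
            raise ValueError("maf_denominator must be 'panel' or 'nonmissing'")


@dataclass
class FilterTally:
    """Per-stage, per-svtype surviving counts plus survivor size summary."""

    counts: pd.DataFrame  # rows: svtypes + Total; columns: STAGES
    size_summary: pd.DataFrame  # rows: svtypes + Total; min/max/median bp

    def to_tsv(self, path) -> None:
        pd.concat([self.counts, self.size_summary], axis=1).to_csv(
            path, sep="\t", index_label="svtype"
        )


# ---------------------------------------------------------------------------
# Site-level helpers (operate on a GenotypeMatrix row or an SVRecord)


def site_missing_fraction(row: np.ndarray) -> float:
    """Fraction of missing entries at a site (NaN in a matrix row)."""
    row = np.asarray(row, dtype=float)
    if row.size == 0:
        raise ValueError("site has no samples")
    return float(np.isnan(row).sum() / row.size)


def minor_carrier_count(row: np.ndarray) -> int:
    """min(#present, #absent) over the nonmissing entries of a site."""
    row = np.asarray(row, dtype=float)
    nonmissing = ~np.isnan(row)
    if not nonmissing.any():
        raise ValueError("all-missing site has no minor carrier count")
    n_present = int(np.nansum(row))
    n_absent = int(nonmissing.sum()) - n_present
    return min(n_present, n_absent)


def maf_threshold_count(n_samples: int, min_maf: float) -> int:
    """Smallest carrier count c with c / n_samples >= min_maf."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return math.ceil(min_maf * n_samples)


def _record_missing_fraction(rec: SVRecord) -> float:
    return rec.n_missing / rec.n_samples


def _record_minor_count(rec: SVRecord) -> int:
    nonmissing = int(np.sum(rec.carriers != MISSING))
    if nonmissing == 0:
        return 0
    present = rec.n_present
    return min(present, nonmissing - present)


def _passes_maf(rec: SVRecord, config: FilterConfig) -> bool:
    minor = _record_minor_count(rec)
    if config.maf_denominator == "panel":
        denom = rec.n_samples
    else:
        denom = int(np.sum(rec.carriers != MISSING))
        if denom == 0:
            return False
    return minor / denom >= config.min_maf


# ---------------------------------------------------------------------------
# The cascade


def filter_cascade(
    records: Sequence[SVRecord],
    config: FilterConfig | None = None,
    apply_maf: bool = True,
) -> tuple[list[SVRecord], FilterTally]:
    """Apply the filter stages in order and tally survivors per stage.

    With ``apply_maf=False`` the minor-frequency stage is skipped (its tally
    column is still reported) and the returned records are the pre-MAF set —
    the set the site-frequency spectrum and diversity analyses use.
    """
    config = config or FilterConfig()
    surviving = list(records)
    stage_sets: dict[str, list[SVRecord]] = {"no_filters": surviving}

    surviving = [r for r in surviving if r.pe_support >= config.min_pe_support]
    stage_sets["pair_end"] = surviving

    if config.require_precise:
        surviving = [r for r in surviving if r.precise]
    stage_sets["precise"] = surviving

    if config.drop_bnd:
        surviving = [r for r in surviving if r.svtype not in ("BND", "unknown")]
    stage_sets["bnd"] = surviving

    surviving = [
        r
        for r in surviving
        if r.length_bp is not None
        and config.min_size_bp <= r.length_bp <= config.max_size_bp
    ]
    stage_sets["size"] = surviving

    surviving = [
        r
        for r in surviving
        if _record_missing_fraction(r) <= config.max_missing_fraction
    ]
    stage_sets["missing"] = surviving

    post_maf = [r for r in surviving if _passes_maf(r, config)]
    stage_sets["maf"] = post_maf
    if apply_maf:
        surviving = post_maf

    tally = _build_tally(stage_sets, surviving)
    return surviving, tally


def _build_tally(
    stage_sets: dict[str, list[SVRecord]], final: list[SVRecord]
) -> FilterTally:
    svtypes = sorted({r.svtype for r in stage_sets["no_filters"]})
    rows = svtypes + ["Total"]
    counts = pd.DataFrame(0, index=rows, columns=list(STAGES), dtype=int)
    for stage in STAGES:
        recs = stage_sets[stage]
        for t in svtypes:
            counts.loc[t, stage] = sum(1 for r in recs if r.svtype == t)
        counts.loc["Total", stage] = len(recs)

    size = pd.DataFrame(
        np.nan, index=rows, columns=["min_bp", "max_bp", "median_bp"]
    )
    for t in rows:
        lens = [
            r.length_bp
            for r in final
            if r.length_bp is not None and (t == "Total" or r.svtype == t)
        ]
        if lens:
            size.loc[t] = [min(lens), max(lens), float(np.median(lens))]
    return FilterTally(counts=counts, size_summary=size)


def matrix_after_filter(records: Sequence[SVRecord]) -> GenotypeMatrix:
    """Convenience: cascade survivors -> presence/absence matrix."""
    from .variant_io import to_binary_matrix

    return to_binary_matrix(records)
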