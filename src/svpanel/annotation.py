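"""Intersect deletions with gene/CDS annotation and summarize per chromosome.

A deletion is "within" a feature if its [start, end] interval intersects the
feature by at least one base (inclusive coordinates); full containment is
available via ``mode="within"``.  Functional-impact classes are parsed from
precomputed snpEff-style ANN strings — the package never predicts impacts
itself, it only ranks what an external annotator wrote.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import FeatureIntervals, GenotypeMatrix

logger = logging.getLogger("svpanel")

IMPACT_SEVERITY = {"high": 4, "moderate": 3, "low": 2, "modifier": 1, "none": 0}


@dataclass
class FeatureOverlap:
    site_id: str
    in_gene: bool
    in_cds: bool
    overlapped_gene_ids: list[str] = field(default_factory=list)
    impact_class: str = "none"


def overlap_features(
    matrix: GenotypeMatrix,
    features: FeatureIntervals,
    mode: str = "any",
) -> list[FeatureOverlap]:
    """Overlap every site with the gene and CDS interval sets.

    ``mode="any"`` flags >=1 bp intersection; ``mode="within"`` requires the
    deletion to be fully contained in a single feature interval.
    Chromosomes absent from the annotation yield in_gene=False and are
    logged once each.
    """
    if mode not in ("any", "within"):
        raise ValueError("mode must be 'any' or 'within'")
    warned: set[str] = set()
    out: list[FeatureOverlap] = []
    pos = matrix.positions
    for i in range(matrix.n_sites):
        chrom = pos["chrom"].iat[i]
        start = int(pos["start"].iat[i])
        end = int(pos["end"].iat[i])
        gene_tree = features.genes.get(chrom)
        cds_tree = features.cds.get(chrom)
        if gene_tree is None and cds_tree is None:
            if chrom not in warned and (features.genes or features.cds):
                logger.warning("chromosome %s absent from annotation", chrom)
                warned.add(chrom)
        gene_hits = _query(gene_tree, start, end, mode)
        cds_hits = _query(cds_tree, start, end, mode)
        out.append(
            FeatureOverlap(
                site_id=matrix.site_ids[i],
                in_gene=bool(gene_hits),
                in_cds=bool(cds_hits),
                overlapped_gene_ids=sorted({h.data for h in gene_hits}),
            )
        )
    return out


def _query(tree, start: int, end: int, mode: str):
    if tree is None:
        return []
    hits = tree.overlap(start, end + 1)  # trees store [start, end+1)
    if mode == "within":
        hits = {h for h in hits if h.begin <= start and end < h.end}
    return list(hits)


def parse_impact(ann_field: str | None) -> str:
    """Highest-severity impact class in a snpEff ANN string.

    ANN entries are comma-separated, pipe-delimited; the impact is the third
    pipe field.  Severity: high > moderate > low > modifier.  Empty or
    unparseable input -> "none".
    """
    if not ann_field:
        return "none"
    best = "none"
    for entry in str(ann_field).split(","):
        parts = entry.split("|")
        if len(parts) < 3:
            continue
        impact = parts[2].strip().lower()
        if impact in IMPACT_SEVERITY and IMPACT_SEVERITY[impact] > IMPACT_SEVERITY[best]:
            best = impact
    if best == "none" and ann_field.strip():
        logger.debug("unparseable ANN field: %.60s", ann_field)
    return best


def per_chromosome_summary(
    matrix: GenotypeMatrix,
    overlaps: Sequence[FeatureOverlap],
    chrom_lengths: dict[str, int] | None = None,
    impacts: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome deletion tally: counts, density, sizes, genic/CDS hits.

    Percentages are of the grand total; density (per 100 kbp) needs
    ``chrom_lengths`` and is NaN where a length is unknown.  ``impacts`` is
    an optional per-site impact-class vector (aligned with matrix rows);
    high+moderate sites are counted per chromosome when given.
    """
    if len(overlaps) != matrix.n_sites:
        raise ValueError("overlaps not aligned with matrix sites")
    if matrix.n_sites == 0:
        return pd.DataFrame(
            columns=[
                "n_deletions", "pct", "per_100kbp", "min_size", "max_size",
                "n_genic", "pct_genic", "n_cds", "pct_cds", "n_impact",
            ]
        )
    pos = matrix.positions
    sizes = (pos["end"] - pos["start"] + 1).to_numpy()
    genic = np.array([o.in_gene for o in overlaps])
    in_cds = np.array([o.in_cds for o in overlaps])
    hit = (
        np.array([i in ("high", "moderate") for i in impacts])
        if impacts is not None
        else np.zeros(matrix.n_sites, dtype=bool)
    )
    total = matrix.n_sites
    rows = []
    for chrom, idx in pos.groupby("chrom", sort=True).indices.items():
        idx = np.asarray(idx)
        n = idx.size
        length = (chrom_lengths or {}).get(chrom)
        rows.append(
            {
                "chrom": chrom,
                "n_deletions": n,
                "pct": 100.0 * n / total,
                "per_100kbp": (100_000.0 * n / length) if length else np.nan,
                "min_size": int(sizes[idx].min()),
                "max_size": int(sizes[idx].max()),
                "n_genic": int(genic[idx].sum()),
                "pct_genic": 100.0 * genic[idx].sum() / total,
                "n_cds": int(in_cds[idx].sum()),
                "pct_cds": 100.0 * in_cds[idx].sum() / total,
                "n_impact": int(hit[idx].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
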