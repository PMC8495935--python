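"""Readers and writers for the file formats the pipeline touches.

Structural-variant (SV) call sets arrive as multi-sample VCFs in the
LUMPY/svtools dialect: each row carries ``SVTYPE``, ``END``/``SVLEN``,
a ``PRECISE``/``IMPRECISE`` breakpoint flag and a paired-end support
count (``PE``), plus per-sample genotypes and read depths.  This module
converts those rows into :class:`SVRecord` objects and then into an
analysis-ready presence/absence matrix (:class:`GenotypeMatrix`), applying
the depth-based genotype mask: a sample whose read depth at a site falls
below ``min_depth`` is treated as missing regardless of its genotype call.

Coordinates are 1-based inclusive throughout (VCF convention).  A genotype
with any alternate allele counts as *present* — heterozygous and homozygous
alternate collapse to a single carrier state, because every downstream
statistic works on presence/absence per genotype, not allele dosage.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("svpanel")

# Carrier states in SVRecord.carriers / GenotypeMatrix.presence
PRESENT = 1
ABSENT = 0
MISSING = -1

#: svtypes with interval semantics; anything else is treated like a
#: break-end (no length, removed by the BND filter stage).
INTERVAL_SVTYPES = ("DEL", "DUP", "INV")

DEFAULT_MIN_DEPTH = 10


@dataclass
class SVRecord:
    """One structural-variant site across the whole sample panel.

    ``carriers`` holds one entry per panel sample: 1 (present), 0 (absent)
    or -1 (missing).  ``depths`` holds the per-sample read depth, with -1
    where no depth field was available.  ``length_bp`` is ``|SVLEN|`` when
    the caller emitted one, otherwise ``end - start + 1``; break-ends carry
    no length (``None``).
    """

    site_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length_bp: int | None
    precise: bool
    pe_support: int
    carriers: np.ndarray
    depths: np.ndarray
    flagged: bool = False

    def __post_init__(self) -> None:
        self.carriers = np.asarray(self.carriers, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.carriers.shape != self.depths.shape:
            raise ValueError(
                f"{self.site_id}: carriers and depths differ in length"
            )
        if self.svtype in INTERVAL_SVTYPES:
            if self.end < self.start:
                raise ValueError(f"{self.site_id}: end < start")
            if self.length_bp is not None and self.length_bp < 1:
                raise ValueError(f"{self.site_id}: nonpositive length")

    @property
    def n_samples(self) -> int:
        return self.carriers.size

    @property
    def n_present(self) -> int:
        return int(np.sum(self.carriers == PRESENT))

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.carriers == MISSING))


@dataclass
class GenotypeMatrix:
    """Sites x samples presence/absence matrix with a missing mask.

    ``presence`` is a float array with entries 0.0 (absent), 1.0 (present)
    and NaN (missing).  ``positions`` is a DataFrame aligned with the rows,
    with columns ``chrom``, ``start``, ``end``, ``svtype``.
    """

    site_ids: list[str]
    sample_ids: list[str]
    presence: np.ndarray
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=float)
        if self.presence.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError("presence shape inconsistent with ids")
        if len(self.positions) != len(self.site_ids):
            raise ValueError("positions inconsistent with site_ids")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.presence) | (self.presence == 0) | (self.presence == 1))
        if bad.any():
            raise ValueError("presence entries must be 0, 1 or NaN")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, i: int) -> np.ndarray:
        return self.presence[i]

    def subset_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            site_ids=[self.site_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            presence=self.presence[index],
            positions=self.positions.iloc[index].reset_index(drop=True),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.presence, index=self.site_ids, columns=self.sample_ids)
        return pd.concat([self.positions.set_axis(df.index), df], axis=1)


@dataclass
class FeatureIntervals:
    """Gene and CDS interval collections keyed by chromosome.

    Intervals are stored 1-based inclusive.  ``cds_outside_gene`` lists CDS
    features that are not contained in any gene interval — reported, not
    enforced, since some annotations do not nest features.
    """

    genes: dict
    cds: dict
    cds_outside_gene: list[str] = field(default_factory=list)

    def n_genes(self) -> int:
        return sum(len(t) for t in self.genes.values())

    def n_cds(self) -> int:
        return sum(len(t) for t in self.cds.values())


# ---------------------------------------------------------------------------
# VCF reading


def _depth_array(variant, n_samples: int) -> np.ndarray:
    """Per-sample depth: FORMAT DP if present, else summed allele depths,
    else -1 (no depth information -> treated as passing the depth mask)."""
    dp = None
    try:
        dp = variant.format("DP")
    except KeyError:
        dp = None
    if dp is not None:
        out = dp[:, 0].astype(np.int64)
        out[out < 0] = -1  # cyvcf2 encodes '.' as a large negative int
        return out
    for tag in ("AD", "DHFFC_AD"):
        try:
            ad = variant.format(tag)
        except KeyError:
            ad = None
        if ad is not None:
            ad = ad.astype(np.int64)
            ad[ad < 0] = 0
            return ad.sum(axis=1)
    return np.full(n_samples, -1, dtype=np.int64)


def _carriers_from_gt_types(gt_types: np.ndarray) -> np.ndarray:
    """cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt."""
    carriers = np.full(gt_types.shape, MISSING, dtype=np.int8)
    carriers[gt_types == 0] = ABSENT
    carriers[(gt_types == 1) | (gt_types == 3)] = PRESENT
    return carriers


def read_sv_vcf(path: str | os.PathLike, min_depth: int = DEFAULT_MIN_DEPTH) -> list[SVRecord]:
    """Read a structural-variant VCF into :class:`SVRecord` objects.

    Applies the depth mask: any genotype whose read depth is below
    ``min_depth`` is set to missing.  Records with an unrecognized SVTYPE
    are retained with ``svtype='unknown'`` and ``flagged=True``; they fall
    to the BND stage of the filter cascade.
    """
    from cyvcf2 import VCF

    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    records: list[SVRecord] = []
    for lineno, v in enumerate(vcf, start=1):
        try:
            svtype = v.INFO.get("SVTYPE")
            flagged = False
            if svtype is None or svtype not in INTERVAL_SVTYPES + ("BND",):
                svtype, flagged = "unknown", True
            start = int(v.POS)
            end_info = v.INFO.get("END")
            svlen = v.INFO.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if end_info is not None:
                end = int(end_info)
            elif svlen is not None and svtype in INTERVAL_SVTYPES:
                end = start + abs(int(svlen)) - 1
            else:
                end = start
            if svtype in INTERVAL_SVTYPES:
                length = abs(int(svlen)) if svlen is not None else end - start + 1
            else:
                length = None
            precise = v.INFO.get("IMPRECISE") is None
            if v.INFO.get("PRECISE") is not None:
                precise = True
            pe = v.INFO.get("PE")
            if isinstance(pe, (tuple, list)):
                pe = pe[0]
            pe = int(pe) if pe is not None else 0

            carriers = _carriers_from_gt_types(np.asarray(v.gt_types))
            depths = _depth_array(v, n)
            low = (depths >= 0) & (depths < min_depth)
            carriers[low] = MISSING

            records.append(
                SVRecord(
                    site_id=f"{v.CHROM}_{start}_{end}_{svtype}",
                    chrom=v.CHROM,
                    start=start,
                    end=end,
                    svtype=svtype,
                    length_bp=length,
                    precise=precise,
                    pe_support=pe,
                    carriers=carriers,
                    depths=depths,
                )
            )
            records[-1].flagged = flagged
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed VCF record at {path} body line {lineno}: {exc}") from exc
    return records


def write_sv_vcf(records: Iterable[SVRecord], sample_ids: Sequence[str],
                 path: str | os.PathLike) -> None:
    """Write SV records as a minimal multi-sample VCF (GT:DP format).

    Present carriers are written 0/1, absent 0/0, missing ./.; a depth of
    -1 (no information) is written as '.'.
    """
    records = list(records)
    chroms: list[str] = []
    for r in records:
        if r.chrom not in chroms:
            chroms.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svpanel\n")
        for c in chroms:
            end = max(r.end for r in records if r.chrom == c)
            fh.write(f"##contig=<ID={c},length={end + 1}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=PE,Number=1,Type=Integer,Description="Paired-end support">\n')
        fh.write('##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoint">\n')
        fh.write('##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoint">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for r in records:
            info = [f"SVTYPE={r.svtype}", f"END={r.end}"]
            if r.length_bp is not None:
                sign = -1 if r.svtype == "DEL" else 1
                info.append(f"SVLEN={sign * r.length_bp}")
            info.append(f"PE={r.pe_support}")
            info.append("PRECISE" if r.precise else "IMPRECISE")
            cols = [r.chrom, str(r.start), r.site_id, "N",
                    f"<{r.svtype if r.svtype in INTERVAL_SVTYPES else 'BND'}>",
                    ".", "PASS", ";".join(info), "GT:DP"]
            for call, dp in zip(r.carriers, r.depths):
                gt = {PRESENT: "0/1", ABSENT: "0/0", MISSING: "./."}[int(call)]
                cols.append(f"{gt}:{dp if dp >= 0 else '.'}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Matrix conversion


def to_binary_matrix(records: Sequence[SVRecord]) -> GenotypeMatrix:
    """Convert SV records into a sites x samples presence/absence matrix.

    Row order follows record order.  Sample ids are positional (records do
    not carry them); attach real ids via the ``sample_ids`` argument of the
    callers that have them.
    """
    records = list(records)
    if not records:
        return GenotypeMatrix([], [], np.zeros((0, 0)), _empty_positions())
    n = records[0].n_samples
    for r in records:
        if r.n_samples != n:
            raise ValueError(
                f"inconsistent sample panels: {r.site_id} has {r.n_samples} "
                f"samples, expected {n}"
            )
    presence = np.empty((len(records), n), dtype=float)
    for i, r in enumerate(records):
        row = r.carriers.astype(float)
        row[r.carriers == MISSING] = np.nan
        presence[i] = row
    positions = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "start": [r.start for r in records],
            "end": [r.end for r in records],
            "svtype": [r.svtype for r in records],
        }
    )
    return GenotypeMatrix(
        site_ids=[r.site_id for r in records],
        sample_ids=[f"S{i:04d}" for i in range(n)],
        presence=presence,
        positions=positions,
    )


def _empty_positions() -> pd.DataFrame:
    return pd.DataFrame({"chrom": [], "start": [], "end": [], "svtype": []})


# ---------------------------------------------------------------------------
# GFF3 gene annotation


def read_gene_annotation(path: str | os.PathLike) -> FeatureIntervals:
    """Read gene and CDS intervals from a GFF3 file.

    Returns 1-based inclusive interval trees keyed by chromosome.  CDS
    features that fall outside every gene interval on their chromosome are
    listed in ``cds_outside_gene`` (reported, not rejected).
    """
    import gffutils
    from intervaltree import IntervalTree

    path = str(path)
    if os.path.getsize(path) == 0 or _gff_is_empty(path):
        return FeatureIntervals(genes={}, cds={})
    try:
        db = gffutils.create_db(
            path, dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:
        raise ValueError(f"cannot parse GFF3 {path}: {exc}") from exc

    genes: dict[str, IntervalTree] = {}
    cds: dict[str, IntervalTree] = {}
    for feat in db.features_of_type("gene"):
        genes.setdefault(feat.seqid, IntervalTree()).addi(
            feat.start, feat.end + 1, feat.id
        )
    outside: list[str] = []
    for feat in db.features_of_type("CDS"):
        cds.setdefault(feat.seqid, IntervalTree()).addi(
            feat.start, feat.end + 1, feat.id
        )
        tree = genes.get(feat.seqid)
        if tree is None or not tree.overlap(feat.start, feat.end + 1):
            outside.append(feat.id)
    if outside:
        logger.warning("%d CDS feature(s) outside any gene interval", len(outside))
    return FeatureIntervals(genes=genes, cds=cds, cds_outside_gene=outside)


def _gff_is_empty(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return False
    return True


# ---------------------------------------------------------------------------
# Sample metadata


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample metadata table (TSV or CSV) with a ``sample_id`` column.

    Missing country/region/race values are normalized to "Unknown".
    Duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata table lacks a sample_id column")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample_id(s): {sorted(set(dup))}")
    for col in ("country", "region", "race"):
        if col not in df.columns:
            df[col] = "Unknown"
        df[col] = df[col].fillna("Unknown").replace("", "Unknown")
    if "cluster" in df.columns:
        df["cluster"] = pd.to_numeric(df["cluster"], errors="coerce").astype("Int64")
    return df.reset_index(drop=True)
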