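"""Synthetic diversity-panel generator with known ground truth.

The generator emulates the statistical structure the pipeline assumes, not
population history: no coalescent, no recombination map.  It produces

* deletion presence/absence sites whose minor-carrier counts follow the
  neutral 1/i spectrum, with carriers placed exchangeably across samples
  (so the cluster-specificity false-positive rate is interpretable);
* a configurable number of planted cluster-specific deletions that place a
  target fraction of their carriers in one focal cluster;
* cluster-informative SNP dosages (per-cluster allele-frequency contrasts)
  that let k-means recover the planted structure;
* per-entry missingness, per-genotype Poisson read depths, and uniform
  genomic positions, so the exported VCFs run through the full pipeline
  unchanged.

Defaults mirror the study design this package targets: 347 genotypes in 8
clusters of sizes 43, 44, 37, 31, 40, 58, 55, 39; 1,000 deletion sites
(950 background + 50 specific); 2,000 SNP sites; ~30x depth; 5% missing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, SVRecord, write_sv_vcf

PAPER_CLUSTER_SIZES = (43, 44, 37, 31, 40, 58, 55, 39)
DEFAULT_GENOME = tuple((f"Chr{i:02d}", 5_000_000) for i in range(1, 11))

#: carrier-count range for planted specific sites.  Cluster-specific
#: deletions are discovered in the minor-frequency-filtered set, where every
#: site occurs in at least 18 of 347 genotypes; the canonical example site
#: has 26 carriers, so [18, 35] brackets that scale while honoring the
#: frequency floor.
SPECIFIC_CARRIER_RANGE = (18, 35)


@dataclass
class SimulationConfig:
    n_samples: int = 347
    k_clusters: int = 8
    cluster_sizes: tuple[int, ...] = PAPER_CLUSTER_SIZES
    n_background_sites: int = 950
    n_specific_sites: int = 50
    specific_dominance: float = 0.9
    theta_scale: float = 1.0
    n_snp_sites: int = 2000
    snp_cluster_separation: float = 0.8
    missing_rate: float = 0.05
    depth_mean: float = 30.0
    min_depth: int = 10
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    ld_block: tuple[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_sizes is None:
            base = self.n_samples // self.k_clusters
            sizes = [base] * self.k_clusters
            for i in range(self.n_samples - base * self.k_clusters):
                sizes[i] += 1
            self.cluster_sizes = tuple(sizes)
        if len(self.cluster_sizes) != self.k_clusters:
            raise ValueError("cluster_sizes length != k_clusters")
        if sum(self.cluster_sizes) != self.n_samples:
            raise ValueError("cluster_sizes must sum to n_samples")
        if any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be positive")
        for name in ("specific_dominance", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.snp_cluster_separation <= 1:
            raise ValueError("snp_cluster_separation must be in [0, 1]")


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated panel."""

    site_labels: list[str]  # "background" or "specific_c<focal>"
    specific_focal: dict[str, int]  # site_id -> 1-based focal cluster
    sample_clusters: np.ndarray  # 1-based planted cluster per sample
    minor_counts: np.ndarray  # generative carrier count per site
    ld_half_bp: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.site_labels, "minor_count": self.minor_counts}
        )


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def _cluster_labels(config: SimulationConfig) -> np.ndarray:
    labels = np.concatenate(
        [np.full(s, c + 1) for c, s in enumerate(config.cluster_sizes)]
    )
    return labels.astype(int)


def _draw_positions(rng, genome, n) -> pd.DataFrame:
    chroms, lengths = zip(*genome)
    lengths = np.asarray(lengths, dtype=float)
    which = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    starts = np.array(
        [rng.integers(1, lengths[w] + 1) for w in which], dtype=np.int64
    )
    sizes = np.clip(
        np.round(rng.lognormal(mean=np.log(900.0), sigma=1.0, size=n)),
        51, 92_000,
    ).astype(np.int64)
    df = pd.DataFrame(
        {
            "chrom": [chroms[w] for w in which],
            "start": starts,
            "end": starts + sizes - 1,
            "svtype": "DEL",
        }
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _neutral_minor_counts(rng, n_sites: int, max_bin: int) -> np.ndarray:
    i = np.arange(1, max_bin + 1)
    p = (1.0 / i) / np.sum(1.0 / i)
    return rng.choice(i, size=n_sites, p=p)


def simulate_panel(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame, pd.DataFrame, SimulatedTruth]:
    """Generate one panel: SV matrix, SNP dosages, positions, metadata, truth.

    Returns ``(sv_matrix, snp_dosage, snp_positions, metadata, truth)``.
    ``snp_dosage`` is sites x samples 0/1/2 with NaN missing.  Background
    SV sites draw a minor-carrier count i with P(i) proportional to 1/i over
    1..floor(n/2) and place the carriers uniformly among the genotypes
    observable at the site; specific sites place round(dominance * total)
    carriers in their focal cluster.  Missingness (independent per entry at
    ``missing_rate``, plus read depth below ``min_depth``) is drawn first,
    and unobservable genotypes are never carriers — so the planted minor
    count is the one the downstream spectrum sees, and the exported VCF
    re-reads into an identical matrix.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    labels = _cluster_labels(config)
    sample_ids = _sample_ids(n)

    n_bg = int(round(config.n_background_sites * config.theta_scale))
    n_sp = config.n_specific_sites
    n_sites = n_bg + n_sp
    positions = _draw_positions(rng, config.genome, n_sites)

    # interleave site roles at random so specific sites are not positionally
    # clustered by construction
    roles = np.array(["background"] * n_bg + ["specific"] * n_sp)
    rng.shuffle(roles)

    # Missingness first: a genotype that cannot be observed at a site (call
    # failure, or read depth below the mask threshold) is never a carrier
    # there — the same convention the permutation null uses.  Carriers are
    # then placed among the observable genotypes, so the generative minor
    # count is the one the analysis sees.
    depths = rng.poisson(config.depth_mean, size=(n_sites, n)).astype(np.int64)
    missing = (rng.random((n_sites, n)) < config.missing_rate) | (
        depths < config.min_depth
    )

    presence = np.zeros((n_sites, n), dtype=float)
    minor_counts = np.zeros(n_sites, dtype=int)
    site_labels: list[str] = []
    specific_focal: dict[str, int] = {}
    max_bin = n // 2
    bg_counts = _neutral_minor_counts(rng, n_sites, max_bin)  # draw for all; used for bg
    cluster_members = [np.flatnonzero(labels == c + 1) for c in range(config.k_clusters)]

    site_ids = [
        f"{positions['chrom'].iat[i]}_{positions['start'].iat[i]}_"
        f"{positions['end'].iat[i]}_DEL"
        for i in range(n_sites)
    ]

    for i in range(n_sites):
        observable = np.flatnonzero(~missing[i])
        if roles[i] == "background":
            c_total = min(int(bg_counts[i]), observable.size)
            carriers = rng.choice(observable, size=c_total, replace=False)
            site_labels.append("background")
        else:
            focal = int(rng.integers(1, config.k_clusters + 1))
            members = np.intersect1d(
                cluster_members[focal - 1], observable, assume_unique=True
            )
            lo, hi = SPECIFIC_CARRIER_RANGE
            hi = min(hi, int(members.size / config.specific_dominance))
            if hi < lo:
                raise ValueError(
                    f"site {site_ids[i]}: cannot place >= {lo} carriers at "
                    f"dominance {config.specific_dominance} in cluster {focal} "
                    f"(observable size {members.size})"
                )
            c_total = int(rng.integers(lo, hi + 1))
            n_focal = int(round(config.specific_dominance * c_total))
            if n_focal > members.size:
                raise ValueError(
                    f"site {site_ids[i]}: {n_focal} carriers exceed focal "
                    f"cluster {focal} observable size {members.size}"
                )
            inside = rng.choice(members, size=n_focal, replace=False)
            outside_pool = np.setdiff1d(observable, cluster_members[focal - 1])
            outside = rng.choice(
                outside_pool, size=c_total - n_focal, replace=False
            )
            carriers = np.concatenate([inside, outside])
            site_labels.append(f"specific_c{focal}")
            specific_focal[site_ids[i]] = focal
        presence[i, carriers] = 1.0
        minor_counts[i] = len(carriers)

    presence[missing] = np.nan

    sv_matrix = GenotypeMatrix(
        site_ids=site_ids,
        sample_ids=sample_ids,
        presence=presence,
        positions=positions,
    )
    sv_matrix._sim_depths = depths  # carried for VCF export

    snp_dosage, snp_positions = _simulate_snps(config, rng, labels)

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "country": [f"Country{c}" for c in labels],
            "region": [f"Region{(c - 1) // 3 + 1}" for c in labels],
            "race": [f"Race{c}" for c in labels],
            "cluster": labels,
        }
    )
    truth = SimulatedTruth(
        site_labels=site_labels,
        specific_focal=specific_focal,
        sample_clusters=labels,
        minor_counts=minor_counts,
    )
    return sv_matrix, snp_dosage, snp_positions, metadata, truth


def _simulate_snps(config: SimulationConfig, rng, labels: np.ndarray):
    """Cluster-informative biallelic SNPs: each site is diagnostic for one
    cluster (round-robin), with alternate-allele frequency 0.5 + sep/2 in
    the focal cluster and 0.5 - sep/2 elsewhere."""
    n = config.n_samples
    n_snp = config.n_snp_sites
    sep = config.snp_cluster_separation
    p_hi = 0.5 + sep / 2.0
    p_lo = 0.5 - sep / 2.0
    dosage = np.empty((n_snp, n), dtype=float)
    for s in range(n_snp):
        focal = s % config.k_clusters + 1
        p = np.where(labels == focal, p_hi, p_lo)
        dosage[s] = rng.binomial(2, p)
    miss = rng.random((n_snp, n)) < config.missing_rate
    dosage[miss] = np.nan
    chroms, lengths = zip(*config.genome)
    which = rng.integers(0, len(chroms), size=n_snp)
    starts = np.array(
        [rng.integers(1, lengths[w] + 1) for w in which], dtype=np.int64
    )
    positions = pd.DataFrame(
        {"chrom": [chroms[w] for w in which], "start": starts}
    )
    return dosage, positions


# ---------------------------------------------------------------------------
# LD-decay generator (block model)


def simulate_ld_decay(
    config: SimulationConfig,
    n_sites: int = 400,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, float]:
    """Deletion matrix with block-structured LD and a known half-distance.

    The single simulated chromosome is tiled by blocks of ``ld_block[0]``
    bp.  Every sample carries one latent binary haplotype per block; a site
    in the block copies the latent state with probability q chosen so that
    same-block site pairs have expected r^2 = ``ld_block[1]``.  Sites in
    different blocks are independent.  For uniformly placed sites the mean
    r^2 at distance d is approximately r2_within * max(0, 1 - d/B), so the
    profile decays to half its maximum at B/2 — returned as the analytic
    half-distance.
    """
    if config.ld_block is None:
        raise ValueError("config.ld_block must be set")
    block_bp, r2_within = config.ld_block
    if not 0 <= r2_within <= 1:
        raise ValueError("within-block r2 must be in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    chrom, length = config.genome[0]
    q = (1.0 + r2_within**0.25) / 2.0

    starts = np.sort(rng.integers(1, length + 1, size=n_sites))
    blocks = (starts - 1) // block_bp
    presence = np.empty((n_sites, n), dtype=float)
    latent: dict[int, np.ndarray] = {}
    for i in range(n_sites):
        b = int(blocks[i])
        if b not in latent:
            latent[b] = rng.integers(0, 2, size=n)
        copy = rng.random(n) < q
        presence[i] = np.where(copy, latent[b], rng.integers(0, 2, size=n))
    positions = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + 100,
            "svtype": "DEL",
        }
    )
    matrix = GenotypeMatrix(
        site_ids=[f"{chrom}_{s}_{s + 100}_DEL" for s in starts],
        sample_ids=_sample_ids(n),
        presence=presence,
        positions=positions,
    )
    return matrix, block_bp / 2.0


# ---------------------------------------------------------------------------
# Panel export (so the CLI pipeline runs on simulated data unchanged)


def matrix_to_records(
    matrix: GenotypeMatrix,
    pe_support: int = 10,
    precise: bool = True,
    depths: np.ndarray | None = None,
) -> list[SVRecord]:
    """Rebuild SVRecord objects from a presence/absence matrix."""
    if depths is None:
        depths = getattr(matrix, "_sim_depths", None)
    records = []
    for i in range(matrix.n_sites):
        row = matrix.row(i)
        carriers = np.where(np.isnan(row), -1, row).astype(np.int8)
        d = (
            depths[i]
            if depths is not None
            else np.full(matrix.n_samples, -1, dtype=np.int64)
        )
        pos = matrix.positions.iloc[i]
        records.append(
            SVRecord(
                site_id=matrix.site_ids[i],
                chrom=pos["chrom"],
                start=int(pos["start"]),
                end=int(pos["end"]),
                svtype=pos["svtype"],
                length_bp=int(pos["end"]) - int(pos["start"]) + 1,
                precise=precise,
                pe_support=pe_support,
                carriers=carriers,
                depths=d,
            )
        )
    return records


def write_snp_vcf(dosage: np.ndarray, positions: pd.DataFrame,
                  sample_ids, path) -> None:
    """Write a biallelic SNP dosage matrix as a minimal VCF."""
    order = positions.sort_values(["chrom", "start"], kind="stable").index
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=svpanel-sim\n")
        for c in positions["chrom"].unique():
            top = int(positions.loc[positions["chrom"] == c, "start"].max())
            fh.write(f"##contig=<ID={c},length={top + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in order:
            row = dosage[i]
            calls = [
                "./." if np.isnan(v) else gt_map[float(v)] for v in row
            ]
            fh.write(
                f"{positions['chrom'].iat[i]}\t{positions['start'].iat[i]}\t"
                f"snp{i}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_panel(
    outdir: str | os.PathLike,
    matrix: GenotypeMatrix,
    snp_dosage: np.ndarray,
    snp_positions: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: SimulatedTruth,
) -> dict[str, str]:
    """Write SV VCF + SNP VCF + metadata TSV + truth TSV; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "sv_vcf": os.path.join(outdir, "panel_sv.vcf"),
        "snp_vcf": os.path.join(outdir, "panel_snp.vcf"),
        "metadata": os.path.join(outdir, "panel_metadata.tsv"),
        "truth": os.path.join(outdir, "panel_truth.tsv"),
    }
    write_sv_vcf(matrix_to_records(matrix), matrix.sample_ids, paths["sv_vcf"])
    write_snp_vcf(snp_dosage, snp_positions, matrix.sample_ids, paths["snp_vcf"])
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    truth.to_frame().assign(site_id=matrix.site_ids).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
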