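"""End-to-end orchestration: filter -> annotate -> SFS -> pi -> LD ->
cluster -> specificity -> window scan, with every stage's table written to
an output directory plus a machine-readable run summary.

The pipeline is a pure function of (inputs, config, seed): reruns with the
same inputs produce identical tables.
"""

from __future__ import annotations

import json
import logging
import os
import sys
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .annotation import overlap_features, per_chromosome_summary
from .diversity import diversity_correlation, window_pi
from .filtering import FilterConfig, filter_cascade
from .ld import decay_profile, ld_half, stratify_sites
from .popstructure import assign_clusters, encode_snp_matrix, pca_coords, read_snp_vcf, silhouette_scan
from .sfs import compute_sfs, sfs_fit_statistic
from .specificity import (
    ClusterSpecificConfig,
    classify_cluster_specific,
    results_to_frame,
    scan_to_frame,
    windowed_abundance_scan,
)
from .variant_io import (
    read_gene_annotation,
    read_metadata,
    read_sv_vcf,
    to_binary_matrix,
    write_sv_vcf,
)

logger = logging.getLogger("svpanel")


@dataclass
class PipelineConfig:
    sv_vcf: str = ""
    snp_vcf: str | None = None
    gff3: str | None = None
    metadata: str | None = None
    chrom_lengths: str | None = None  # two-column TSV chrom<TAB>length
    outdir: str = "svpanel_out"
    min_depth: int = 10
    filter: FilterConfig = field(default_factory=FilterConfig)
    window_bp: int = 500_000
    ld_max_dist_bp: int = 500_000
    ld_bin_width_bp: int = 100
    k_range: tuple[int, int] = (2, 15)
    specificity: ClusterSpecificConfig = field(default_factory=ClusterSpecificConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        spec = ClusterSpecificConfig(**raw.pop("specificity", {}))
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(filter=filt, specificity=spec, **raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _load_chrom_lengths(path: str | None) -> dict[str, int] | None:
    if path is None:
        return None
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split()[:2]
                out[chrom] = int(length)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the summary."""
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    summary: dict = {"version": __version__, "seed": config.seed}
    out = lambda name: os.path.join(config.outdir, name)
    lengths = _load_chrom_lengths(config.chrom_lengths)

    def stage(name):
        logger.info("stage: %s", name)

    # --- filter ---------------------------------------------------------
    stage("filter")
    try:
        records = read_sv_vcf(config.sv_vcf, min_depth=config.min_depth)
        if not records:
            raise ValueError(f"no SV records in {config.sv_vcf}")
        pre_maf, tally = filter_cascade(records, config.filter, apply_maf=False)
        post_maf, _ = filter_cascade(records, config.filter, apply_maf=True)
        tally.to_tsv(out("filter_tally.tsv"))
        sample_ids = _vcf_samples(config.sv_vcf)
        write_sv_vcf(post_maf, sample_ids, out("filtered_sv.vcf"))
        matrix_pre = to_binary_matrix(pre_maf)
        matrix = to_binary_matrix(post_maf)
        matrix_pre.sample_ids = sample_ids
        matrix.sample_ids = sample_ids
        summary["counts_per_stage"] = {
            c: int(tally.counts.loc["Total", c]) for c in tally.counts.columns
        }
    except Exception as exc:
        raise StageError("filter", exc) from exc

    deletions = matrix.subset_sites(
        matrix.positions["svtype"].to_numpy() == "DEL"
    )
    summary["n_deletions_post_maf"] = deletions.n_sites

    # --- annotation -----------------------------------------------------
    overlaps = None
    if config.gff3:
        stage("annotation")
        try:
            features = read_gene_annotation(config.gff3)
            overlaps = overlap_features(deletions, features)
            per_chromosome_summary(deletions, overlaps, lengths).to_csv(
                out("per_chromosome_summary.tsv"), sep="\t"
            )
            summary["n_genic_deletions"] = sum(o.in_gene for o in overlaps)
            summary["n_cds_deletions"] = sum(o.in_cds for o in overlaps)
        except Exception as exc:
            raise StageError("annotation", exc) from exc

    # --- SFS ------------------------------------------------------------
    stage("sfs")
    try:
        spectrum = compute_sfs(matrix_pre)
        spectrum.to_frame().to_csv(out("sfs.tsv"), sep="\t", index=False)
        summary["theta_w"] = spectrum.theta_w
        summary["sfs_S"] = spectrum.S
        try:
            chi2, p, _ = sfs_fit_statistic(spectrum)
            summary["sfs_fit_p"] = p
        except ValueError:
            summary["sfs_fit_p"] = None
    except Exception as exc:
        raise StageError("sfs", exc) from exc

    # --- diversity ------------------------------------------------------
    stage("diversity")
    try:
        win_sv = window_pi(matrix_pre, config.window_bp, chrom_lengths=lengths)
        win_sv.to_csv(out("window_pi_sv.tsv"), sep="\t", index=False)
        if config.snp_vcf:
            dosage, snp_pos, _ = read_snp_vcf(config.snp_vcf)
            win_snp = _window_pi_dosage(
                dosage, snp_pos, config.window_bp, lengths
            )
            win_snp.to_csv(out("window_pi_snp.tsv"), sep="\t", index=False)
            try:
                r, p = diversity_correlation(win_sv, win_snp)
                summary["pi_correlation_r"] = r
                summary["pi_correlation_p"] = p
            except ValueError as exc:
                logger.info("diversity correlation unavailable: %s", exc)
    except Exception as exc:
        raise StageError("diversity", exc) from exc

    # --- LD -------------------------------------------------------------
    stage("ld")
    try:
        frames = []
        summary["ld_half_bp"] = {}
        strata = ["all"] + (["genic", "cds"] if overlaps is not None else [])
        for stratum in strata:
            sub = (
                deletions
                if stratum == "all"
                else stratify_sites(deletions, overlaps, stratum)
            )
            if sub.n_sites < 2:
                summary["ld_half_bp"][stratum] = None
                continue
            prof = decay_profile(
                sub, config.ld_max_dist_bp, config.ld_bin_width_bp, stratum
            )
            frames.append(prof.to_frame())
            summary["ld_half_bp"][stratum] = ld_half(prof)
        if frames:
            import pandas as pd

            pd.concat(frames).to_csv(out("ld_profile.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise StageError("ld", exc) from exc

    # --- population structure ------------------------------------------
    assignment = None
    if config.snp_vcf:
        stage("cluster")
        try:
            dosage, _, snp_samples = read_snp_vcf(config.snp_vcf)
            X = encode_snp_matrix(dosage)
            lo, hi = config.k_range
            widths, chosen = silhouette_scan(
                X, range(lo, hi + 1), seed=config.seed
            )
            assignment = assign_clusters(
                X, chosen, seed=config.seed, sample_ids=snp_samples
            )
            assignment.silhouette_by_k = widths
            assignment.chosen_k = chosen
            coords, var = pca_coords(X)
            assignment.pca_coords = coords
            assignment.pca_variance_fractions = var
            import pandas as pd

            assignment.to_frame().to_csv(out("clusters.tsv"), sep="\t", index=False)
            pd.DataFrame(
                {"k": list(widths), "silhouette": list(widths.values())}
            ).to_csv(out("silhouette.tsv"), sep="\t", index=False)
            pc = pd.DataFrame(
                coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
            )
            pc.insert(0, "sample_id", snp_samples)
            pc.to_csv(out("pca.tsv"), sep="\t", index=False)
            summary["chosen_k"] = chosen
            summary["silhouette_by_k"] = {int(k): v for k, v in widths.items()}
        except Exception as exc:
            raise StageError("cluster", exc) from exc

    # --- cluster specificity -------------------------------------------
    if assignment is not None:
        stage("specificity")
        try:
            cfg = config.specificity
            cfg.seed = config.seed
            results = classify_cluster_specific(deletions, assignment, cfg)
            results_to_frame(results).to_csv(
                out("cluster_specific.tsv"), sep="\t", index=False
            )
            summary["n_cluster_specific"] = sum(r.is_specific for r in results)
            scan = windowed_abundance_scan(
                deletions, assignment, config.window_bp, chrom_lengths=lengths
            )
            scan_to_frame(scan).to_csv(out("window_scan.tsv"), sep="\t", index=False)
            summary["n_significant_windows"] = sum(r.significant for r in scan)
        except Exception as exc:
            raise StageError("specificity", exc) from exc

    with open(out("run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonify)
    with open(out("run_manifest.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "version": __version__,
                "seed": config.seed,
                "config": _config_dict(config),
            },
            fh,
        )
    return summary


def _window_pi_dosage(dosage, positions, window_bp, lengths):
    """Windowed SNP pi straight from a dosage matrix (0/1/2, NaN missing)."""
    import pandas as pd

    from .diversity import _window_table, site_pi_dosage

    pis = np.zeros(len(positions))
    for i in range(len(positions)):
        try:
            pis[i] = site_pi_dosage(dosage[i])
        except ValueError:
            pis[i] = 0.0
    pos = positions.copy()
    return _window_table(pos, pis, window_bp, window_bp, lengths)


def _vcf_samples(path: str) -> list[str]:
    from cyvcf2 import VCF

    return list(VCF(str(path)).samples)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return json.loads(json.dumps(d, default=_jsonify))
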