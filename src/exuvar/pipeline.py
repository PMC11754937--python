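"""End-to-end orchestration: filter -> heritability -> distances -> Mantel
-> GWAS -> cluster comparison, driven by one YAML config.

Each stage writes its outputs under ``outdir`` so any stage can be re-run
from the intermediate files; a JSON manifest records the config, seeds,
input checksums and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import pandas as pd
import yaml

from . import __version__
from .association import mantel_screen
from .cluster_compare import cluster_compare_screen, majority_cluster
from .distances import (
    bray_curtis,
    euclidean_geographic,
    membership_distances,
    ordination_distance,
    pca_distance,
    pcoa,
    select_uncorrelated,
    standardize,
)
from .feature_table import accession_means, filter_pipeline, read_feature_table
from .gwas import (
    allele_difference_distance,
    annotate_flanking,
    call_significant,
    ibs_kinship,
    mlm_scan,
    preprocess,
    read_genotypes,
)
from .heritability import heritability_screen

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    """All stage inputs and thresholds; see the README for the YAML keys."""

    feature_table: str = ""
    annotations: str | None = None
    metadata: str | None = None  # Dataset S1-shaped CSV
    genotypes: str | None = None  # VCF or 0/1 TSV
    gff: str | None = None
    outdir: str = "exuvar_out"
    pseudocount: float = 1e-10
    prevalence_lo: float = 0.10
    prevalence_hi: float = 0.90
    replicate_rule: str = "per_accession"
    n_boot: int = 1000
    seed: int = 0
    n_perm: int = 9999
    mantel_alternative: str = "greater"
    maf_min_accessions: int = 5
    gwas_threshold: float = 7.5
    outlier_sd: float = 4.0
    cluster_a: str = "C1"
    cluster_b: str = "C3"
    anova_runs: int = 1000
    anova_n_down: int = 13
    membership_columns: tuple = ("C1", "C2", "C3", "C4")

    def validate(self) -> None:
        if self.prevalence_lo >= self.prevalence_hi:
            raise ValueError("prevalence_lo must be < prevalence_hi")
        if not self.feature_table:
            raise ValueError("feature_table input is required")
        if self.n_boot < 1 or self.n_perm < 1 or self.anova_runs < 1:
            raise ValueError("resampling counts must be positive")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_STAGE_ORDER = (
    "filter", "heritability", "distances", "mantel", "gwas", "cluster_compare"
)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    A failing stage halts the run with a RuntimeError naming the stage;
    the underlying error (which names the offending sample/feature/SNP)
    is chained as the cause.
    """
    cfg.validate()
    out = pathlib.Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "stages": {},
    }
    for key in ("feature_table", "annotations", "metadata", "genotypes", "gff"):
        p = getattr(cfg, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _checksum(p)}
    try:
        return _run_stages(cfg, out, manifest)
    except Exception as exc:
        failed = next(
            (s for s in _STAGE_ORDER if s not in manifest["stages"]), "unknown"
        )
        raise RuntimeError(f"stage {failed!r} failed: {exc}") from exc


def _run_stages(cfg: PipelineConfig, out: pathlib.Path, manifest: dict) -> dict:
    # --- filter ---------------------------------------------------------
    table = read_feature_table(cfg.feature_table, annotation_path=cfg.annotations)
    filtered, report = filter_pipeline(
        table, pseudocount=cfg.pseudocount, lo=cfg.prevalence_lo,
        hi=cfg.prevalence_hi, replicate_rule=cfg.replicate_rule,
    )
    filtered.rel_abundance.to_csv(out / "filtered_abundance.tsv", sep="\t")
    report.per_mode.rename_axis("mode").to_csv(out / "filter_report.tsv", sep="\t")
    report.removal_reason.rename_axis("feature_id").to_csv(
        out / "filter_reasons.tsv", sep="\t"
    )
    manifest["stages"]["filter"] = {
        "per_mode": report.per_mode.to_dict("index"),
        "log": report.summary_lines(),
    }

    # --- heritability ---------------------------------------------------
    herit = heritability_screen(filtered, n_boot=cfg.n_boot, seed=cfg.seed)
    herit.to_csv(out / "heritability.tsv", sep="\t")
    manifest["stages"]["heritability"] = {
        "n_features": int(len(herit)),
        "n_significant": int(herit["significant"].sum()),
    }

    # --- distances ------------------------------------------------------
    means = accession_means(filtered)
    chem: dict = {"all_compounds": bray_curtis(means)}
    sig_ids = list(herit.index[herit["significant"]])
    if len(sig_ids) >= 2:
        chem["heritable_subset"] = bray_curtis(means, feature_subset=sig_ids)
    fmeta = filtered.feature_meta
    if "npc_pathway" in fmeta.columns:
        for pw, ids in fmeta.groupby("npc_pathway").groups.items():
            ids = [i for i in ids if i in means.columns]
            if len(ids) >= 2:
                chem[f"npc_{str(pw).lower().replace(' ', '_')}"] = bray_curtis(
                    means, feature_subset=ids
                )
    ords = pcoa(chem["all_compounds"], k=3)
    ords.coordinates.to_csv(out / "pcoa_scores.tsv", sep="\t")
    chem["pcoa_axes"] = ordination_distance(ords)

    drivers: dict = {}
    if cfg.metadata:
        meta = pd.read_csv(cfg.metadata, index_col="accession_id")
        meta = meta.loc[means.index]
        drivers["geographic"] = euclidean_geographic(meta[["longitude", "latitude"]])
        memcols = [c for c in cfg.membership_columns if c in meta.columns]
        for name, dm in membership_distances(meta[memcols]).items():
            drivers[f"membership_{name}"] = dm
        env_cols = [
            c for c in meta.columns
            if c not in ("longitude", "latitude", "altitude", *memcols)
        ]
        env = meta[env_cols[:7]]
        life = meta[env_cols[7:14]] if len(env_cols) >= 14 else None
        for label, block in (("environmental", env), ("life_history", life)):
            if block is None or block.shape[1] < 2:
                continue
            keep = select_uncorrelated(block, threshold=0.7)
            z = standardize(block[keep])
            ordn, dmat = pca_distance(z, n_axes=min(3, len(keep)))
            drivers[label] = dmat
            manifest["stages"][f"{label}_pca"] = {
                "variables": keep,
                "variance_fraction_3axes": float(ordn.variance_fraction.sum()),
            }
    if cfg.genotypes:
        gmat = read_genotypes(cfg.genotypes)
        gmat2, traits = preprocess(
            gmat, means, maf_min_accessions=cfg.maf_min_accessions,
            outlier_sd=cfg.outlier_sd,
        )
        drivers["genetic"] = allele_difference_distance(gmat2).reorder(
            list(means.index)
        )
    for name, dm in {**chem, **drivers}.items():
        dm.to_frame().to_csv(out / f"distance_{name}.tsv", sep="\t")
    manifest["stages"]["distances"] = {
        "chemical": sorted(chem), "drivers": sorted(drivers),
    }

    # --- mantel ---------------------------------------------------------
    if drivers:
        screen = mantel_screen(
            chem, drivers, n_perm=cfg.n_perm, seed=cfg.seed,
            alternative=cfg.mantel_alternative,
        )
        screen.to_csv(out / "mantel.tsv", sep="\t", index=False)
        manifest["stages"]["mantel"] = {
            "n_tests": int(len(screen)),
            "n_significant": int((screen["p_adj"] < 0.05).sum()),
        }
    else:
        manifest["stages"]["mantel"] = "skipped: no driver matrices"

    # --- gwas -----------------------------------------------------------
    if cfg.genotypes:
        kin = ibs_kinship(gmat2)
        hits_all = []
        scan_traits = sig_ids if sig_ids else list(means.columns[:5])
        for fid in scan_traits:
            y = traits[fid].loc[kin.labels].to_numpy()
            res = mlm_scan(y, gmat2, kin, trait_id=str(fid))
            hits = call_significant(res, threshold_neglog10p=cfg.gwas_threshold)
            if len(hits):
                hits = hits.assign(trait=str(fid))
                hits_all.append(hits)
        hits_df = (
            pd.concat(hits_all, ignore_index=True)
            if hits_all
            else pd.DataFrame(columns=["chrom", "pos", "neglog10p", "trait"])
        )
        hits_df.to_csv(out / "gwas_hits.tsv", sep="\t", index=False)
        manifest["stages"]["gwas"] = {
            "n_traits": len(scan_traits), "n_hits": int(len(hits_df)),
        }
    else:
        manifest["stages"]["gwas"] = "skipped: no genotypes"
    if cfg.genotypes:
        if cfg.gff and len(hits_df):
            ann = annotate_flanking(hits_df, cfg.gff)
            pd.DataFrame(
                [
                    dict(chrom=h.chrom, pos=h.pos, relation=h.relation,
                         genes=";".join(l["gene_id"] for l in h.loci))
                    for h in ann
                ]
            ).to_csv(out / "gwas_annotation.tsv", sep="\t", index=False)

    # --- cluster comparison --------------------------------------------
    if cfg.metadata:
        memcols = [c for c in cfg.membership_columns if c in meta.columns]
        clusters = majority_cluster(meta[memcols])
        sizes = clusters.value_counts()
        if (
            cfg.cluster_a in sizes and cfg.cluster_b in sizes
            and sizes[cfg.cluster_a] >= cfg.anova_n_down
            and sizes[cfg.cluster_b] >= cfg.anova_n_down
        ):
            cmp_res = cluster_compare_screen(
                means, clusters, cfg.cluster_a, cfg.cluster_b,
                n_down=cfg.anova_n_down, runs=cfg.anova_runs, seed=cfg.seed,
            )
            cmp_res.to_csv(out / "cluster_compare.tsv", sep="\t")
            manifest["stages"]["cluster_compare"] = {
                "n_differential": int(cmp_res["differential"].sum()),
            }
        else:
            manifest["stages"]["cluster_compare"] = "skipped: clusters too small"
    else:
        manifest["stages"]["cluster_compare"] = "skipped: no metadata"

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
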