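"""End-to-end orchestration: config, stage sequencing, logging, report.

Stages run in the method's natural order: build the consensus matrix,
filter sites, per-MAG distances, strain clustering, temporal/group
statistics, trait scan, LD pruning, metabolite-phenotype linkage, gene
mapping and pathway enrichment.  Every stage writes its result table
and logs record counts so the site/sample/MAG funnel is auditable on
any dataset; the run report summarizes the counts.  A stage failure
aborts the run with the stage name, leaves earlier outputs in place and
drops a ``FAILED`` marker file.

All parameters come from a YAML config file; command-line flags
override config values.  Given the same config and seed the outputs
are byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import association, distance, enrichment, group_stats, matrix as mx
from .io import (
    FeatureTable,
    read_feature_table,
    read_gene_table,
    read_sample_metadata,
    read_scaffold_to_bin,
    read_snv_table,
    write_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

log = logging.getLogger("magsnv")


def _read_scan(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    df["skip_reason"] = df["skip_reason"].fillna("")
    return df


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    snv_dir: str = ""
    scaffold_to_bin: str = ""
    genes: str = ""
    pathway_map: str = ""
    metadata: str = ""
    metabolites: str = ""
    phenotypes: str = ""
    output_dir: str = "results"
    seed: int = 0
    # site filters
    presence_min: float = 0.20
    major_max: float = 0.90
    maf_min: float = 0.10
    # distances / clustering
    min_overlap: int = 10
    cluster_height: float | None = 0.5
    cluster_k: int | None = None
    # scans
    fdr: float = 0.05
    r2_threshold: float = 0.9
    min_n: int = 20
    min_class_count: int = 3
    day_numeric: bool = True
    keep_class: str = "SNV"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        for name in (
            "snv_dir", "scaffold_to_bin", "genes", "pathway_map",
            "metadata", "metabolites", "phenotypes",
        ):
            value = getattr(self, name)
            if not value:
                raise FileNotFoundError(f"config field {name!r} is not set")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such path {value!r}")


STAGES = (
    "matrix", "filter", "distance", "cluster", "stats",
    "scan", "prune", "link", "enrich",
)


class _Run:
    """Carries the state between stages; loads prerequisites from disk."""

    def __init__(self, cfg: RunConfig):
        cfg.validate()
        self.cfg = cfg
        self.out = Path(cfg.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.meta = read_sample_metadata(cfg.metadata)
        self.bin_map = read_scaffold_to_bin(cfg.scaffold_to_bin)
        self.genes = read_gene_table(cfg.genes)
        self.pathways = enrichment.read_pathway_map(cfg.pathway_map)
        self.report: dict = {"stages": {}}
        self._matrix = None
        self._geno = None
        self._dists = None
        self._trait_scan = None
        self._group_scan = None

    # ---- lazy prerequisites ------------------------------------------

    @property
    def matrix(self) -> mx.SnvMatrix:
        if self._matrix is None:
            self._matrix = mx.read_snv_matrix(self.out / "matrix.tsv")
        return self._matrix

    @property
    def geno(self) -> mx.BinarySnvGenotypes:
        if self._geno is None:
            self._geno = mx.read_genotypes(self.out / "genotypes.tsv")
        return self._geno

    @property
    def dists(self) -> list[distance.MagDistanceMatrix]:
        if self._dists is None:
            self._dists = [
                distance.read_distance_matrix(p)
                for p in sorted((self.out / "dist").glob("*.tsv"))
            ]
        return self._dists

    @property
    def trait_scan(self) -> pd.DataFrame:
        if self._trait_scan is None:
            self._trait_scan = _read_scan(self.out / "trait_scan.tsv")
        return self._trait_scan

    @property
    def group_scan(self) -> pd.DataFrame:
        if self._group_scan is None:
            self._group_scan = _read_scan(self.out / "group_scan.tsv")
        return self._group_scan

    # ---- stages -------------------------------------------------------

    def stage_matrix(self) -> None:
        cfg = self.cfg
        paths = sorted(Path(cfg.snv_dir).glob("*.tsv"))
        sample_order = {m.sample_id: i for i, m in enumerate(self.meta)}
        paths.sort(key=lambda p: sample_order.get(p.stem, len(sample_order)))
        calls = {p.stem: read_snv_table(p, keep_class=cfg.keep_class) for p in paths}
        self._matrix = mx.build_consensus_matrix(calls, self.bin_map)
        mx.write_snv_matrix(self._matrix, self.out / "matrix.tsv")
        counts = mx.count_snvs_per_sample(self._matrix)
        df = counts.rename_axis("sample_id").reset_index()
        write_table(df, self.out / "snv_counts.tsv")
        self.report["stages"]["matrix"] = {
            "n_samples": self._matrix.n_samples,
            "n_sites": self._matrix.n_sites,
            "n_mags": len(set(self._matrix.site_to_mag.values())),
        }

    def stage_filter(self) -> None:
        cfg = self.cfg
        self._geno = mx.filter_sites(
            self.matrix,
            presence_min=cfg.presence_min,
            major_max=cfg.major_max,
            maf_min=cfg.maf_min,
        )
        mx.write_genotypes(self._geno, self.out / "genotypes.tsv")
        self.report["stages"]["filter"] = dict(self._geno.filter_counts)

    def stage_distance(self) -> None:
        cfg = self.cfg
        (self.out / "dist").mkdir(exist_ok=True)
        mags = sorted(set(self.matrix.site_to_mag.values()))
        self._dists = []
        for mag in mags:
            m = distance.mag_distance_matrix(
                self.matrix, mag, min_overlap=cfg.min_overlap
            )
            self._dists.append(m)
            distance.write_distance_matrix(m, self.out / "dist" / f"{mag}.tsv")
        self.report["stages"]["distance"] = {
            "n_mags": len(mags),
            "n_saturated_pairs": int(sum(m.n_saturated for m in self._dists)),
        }

    def stage_cluster(self) -> None:
        cfg = self.cfg
        rows = []
        enrich_frames = []
        n_failed = 0
        for m in self.dists:
            try:
                norm = distance.normalize_distances(m)
                clustering = distance.cluster_strains(
                    norm, height=cfg.cluster_height, k=cfg.cluster_k
                )
            except ValueError:
                n_failed += 1
                continue
            for sample, label in sorted(clustering.labels.items()):
                rows.append(dict(mag_id=m.mag_id, sample_id=sample, cluster=label))
            for sample in clustering.dropped_samples:
                rows.append(dict(mag_id=m.mag_id, sample_id=sample, cluster="NA"))
            enrich_frames.append(
                distance.strain_time_enrichment(clustering, self.meta)
            )
        write_table(pd.DataFrame(rows), self.out / "clusters.tsv")
        ste = (
            pd.concat(enrich_frames, ignore_index=True)
            if enrich_frames
            else pd.DataFrame()
        )
        write_table(ste, self.out / "strain_time_enrichment.tsv")
        self.report["stages"]["cluster"] = {
            "n_mags_clustered": len(self.dists) - n_failed,
            "n_mags_failed": n_failed,
            "n_enrichment_tests": len(ste),
        }

    def stage_stats(self) -> None:
        scan, skipped = group_stats.mag_group_dissimilarity_scan(self.dists, self.meta)
        write_table(scan, self.out / "group_dissimilarity.tsv")
        gene_tests = group_stats.per_gene_temporal_test(
            self.geno, self.genes, self.meta
        )
        write_table(gene_tests, self.out / "gene_temporal.tsv")
        self.report["stages"]["stats"] = {
            "n_mags_tested": len(scan),
            "n_mags_skipped": len(skipped),
            "n_mags_significant": int((scan["q"] < self.cfg.fdr).sum()) if len(scan) else 0,
            "n_gene_tests": len(gene_tests),
        }

    def stage_scan(self) -> None:
        cfg = self.cfg
        metabolites = read_feature_table(cfg.metabolites)
        self._trait_scan = association.snv_trait_scan(
            self.geno, metabolites, self.meta,
            day_numeric=cfg.day_numeric, min_n=cfg.min_n,
            min_class_count=cfg.min_class_count,
        )
        write_table(self._trait_scan, self.out / "trait_scan.tsv")
        self._group_scan = association.snv_group_scan(
            self.geno, self.meta,
            day_numeric=cfg.day_numeric, min_n=cfg.min_n,
            min_class_count=cfg.min_class_count,
        )
        write_table(self._group_scan, self.out / "group_scan.tsv")
        self.report["stages"]["scan"] = {
            "n_trait_tests": len(self._trait_scan),
            "n_trait_significant": int(
                (self._trait_scan["q"] < cfg.fdr).sum()
            ),
            "n_group_tests": len(self._group_scan),
            "n_group_significant": int((self._group_scan["q"] < cfg.fdr).sum()),
        }

    def stage_prune(self) -> None:
        cfg = self.cfg
        scan = self.trait_scan
        significant = scan[scan["q"] < cfg.fdr].copy()
        pruned = association.ld_prune(significant, self.geno, cfg.r2_threshold)
        write_table(pruned.kept, self.out / "trait_scan_pruned.tsv")
        removals = [
            dict(mag_id=mag, trait_id=trait, kept_site=site,
                 removed_site=rs, r2=r2)
            for (mag, trait, site), removed in sorted(pruned.pruned.items())
            for rs, r2 in removed
        ]
        write_table(
            pd.DataFrame(
                removals,
                columns=["mag_id", "trait_id", "kept_site", "removed_site", "r2"],
            ),
            self.out / "prune_report.tsv",
        )
        self.report["stages"]["prune"] = {
            "n_significant": len(significant),
            "n_independent": pruned.n_kept,
            "n_removed": len(removals),
        }

    def stage_link(self) -> None:
        cfg = self.cfg
        metabolites = read_feature_table(cfg.metabolites)
        phenotypes = read_feature_table(cfg.phenotypes)
        scan = self.trait_scan
        snv_mets = sorted(set(scan.loc[scan["q"] < cfg.fdr, "trait_id"]))
        link, overlap = association.metabolite_phenotype_link(
            metabolites, phenotypes, self.meta,
            snv_metabolites=snv_mets, day_numeric=cfg.day_numeric, fdr=cfg.fdr,
        )
        write_table(link, self.out / "metabolite_phenotype.tsv")
        write_table(
            pd.DataFrame({"metabolite": overlap}), self.out / "overlap_report.tsv"
        )
        self.report["stages"]["link"] = {
            "n_pairs": len(link),
            "n_significant": int((link["q"] < cfg.fdr).sum()),
            "n_overlap_metabolites": len(overlap),
        }

    def stage_enrich(self) -> None:
        cfg = self.cfg
        hits, dist_counts, cds_summary = enrichment.differential_gene_summary(
            self.group_scan, self.genes, self.bin_map, q_threshold=cfg.fdr
        )
        hit_df = pd.DataFrame(
            [
                dict(
                    gene_id=h.gene_id, mag_id=h.mag_id,
                    n_differential_snvs=h.n_differential_snvs,
                    multiple=h.multiple, cog_id=h.cog_id or "",
                )
                for h in hits
            ],
            columns=["gene_id", "mag_id", "n_differential_snvs", "multiple", "cog_id"],
        )
        write_table(hit_df, self.out / "gene_hits.tsv")
        write_table(
            dist_counts.reset_index(), self.out / "gene_hit_distribution.tsv"
        )
        enr = enrichment.pathway_enrichment_per_mag(
            hits, self.genes, self.pathways, self.bin_map
        )
        write_table(enr, self.out / "pathway_enrichment.tsv")
        self.report["stages"]["enrich"] = {
            "n_hit_genes": len(hits),
            "cds_fraction": round(cds_summary["cds_fraction"], 4)
            if cds_summary["n_sites"]
            else None,
            "n_enrichment_tests": len(enr),
            "n_enrichment_significant": int((enr["q"] < cfg.fdr).sum())
            if len(enr)
            else 0,
        }


def run_pipeline(
    cfg: RunConfig, stages: Sequence[str] = STAGES
) -> dict:
    """Execute the requested stages in order and return the run report.

    The report is also written to ``<output_dir>/report.json``.  On a
    stage failure a ``FAILED`` marker naming the stage is left in the
    output directory and :class:`PipelineError` is raised.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {', '.join(unknown)}")
    run = _Run(cfg)
    ordered = [s for s in STAGES if s in stages]
    for stage in ordered:
        log.info("stage %s: starting", stage)
        try:
            getattr(run, f"stage_{stage}")()
        except Exception as exc:
            (run.out / "FAILED").write_text(f"{stage}: {exc}\n")
            raise PipelineError(stage, exc) from exc
        log.info("stage %s: %s", stage, run.report["stages"].get(stage))
    failed_marker = run.out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    run.report["config"] = dataclasses.asdict(cfg)
    with open(run.out / "report.json", "w") as fh:
        json.dump(run.report, fh, indent=1, sort_keys=True)
    return run.report
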