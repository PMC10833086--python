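"""Gene mapping of differential SNVs and per-MAG pathway enrichment.

Differential sites from the group scan are mapped onto CDS intervals
(0-based half-open; a site on the lower bound is inside, on the upper
bound outside).  Per MAG, genes carrying at least one differential SNV
are tested for over-representation in each COG pathway with a
one-sided (enrichment-direction) Fisher exact test against the
background of all COG-annotated genes of that MAG, BH-adjusted across
all (MAG, pathway) pairs.  Genes without a COG id are excluded from
both margins; a gene in several pathways contributes to each table
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io import GeneRecord, SiteKey

__all__ = [
    "map_snvs_to_genes",
    "GeneHitSummary",
    "differential_gene_summary",
    "pathway_enrichment_per_mag",
    "read_pathway_map",
]

MULTIPLE_SNV_CUTOFF = 3  # "multiple differential SNVs" means more than this


def map_snvs_to_genes(
    sites: Sequence[SiteKey], genes: Sequence[GeneRecord]
) -> tuple[dict[SiteKey, list[str]], dict]:
    """Assign every site to the genes whose CDS interval contains it.

    Overlapping genes yield multiple assignments; a site in no gene maps
    to an empty list (intergenic).  The summary reports the fraction of
    sites falling inside at least one CDS.
    """
    by_scaffold: dict[str, list[GeneRecord]] = {}
    for gene in genes:
        by_scaffold.setdefault(gene.scaffold, []).append(gene)
    assignment: dict[SiteKey, list[str]] = {}
    n_in_cds = 0
    for site in sites:
        hits = [
            g.gene_id
            for g in by_scaffold.get(site.scaffold, ())
            if g.contains(site.position)
        ]
        assignment[site] = hits
        if hits:
            n_in_cds += 1
    summary = {
        "n_sites": len(sites),
        "n_in_cds": n_in_cds,
        "cds_fraction": n_in_cds / len(sites) if sites else float("nan"),
    }
    return assignment, summary


@dataclass
class GeneHitSummary:
    gene_id: str
    mag_id: str
    n_differential_snvs: int
    snv_positions: list[int]
    cog_id: str | None = None

    @property
    def multiple(self) -> bool:
        return self.n_differential_snvs > MULTIPLE_SNV_CUTOFF


def differential_gene_summary(
    group_scan: pd.DataFrame,
    genes: Sequence[GeneRecord],
    bin_map: Mapping[str, str],
    q_threshold: float | None = 0.05,
    p_threshold: float | None = None,
) -> tuple[list[GeneHitSummary], pd.Series, dict]:
    """Genes with at least one differential SNV, plus the hit-count histogram.

    A site is differential when its scan q is below ``q_threshold``
    (default) or, in nominal mode, its p is below ``p_threshold``.
    Returns the per-gene summaries, the distribution of per-gene counts,
    and the CDS-fraction summary of the differential sites.
    """
    if (q_threshold is None) == (p_threshold is None):
        raise ValueError("specify exactly one of q_threshold or p_threshold")
    scan = group_scan[group_scan["skip_reason"].fillna("") == ""]
    if q_threshold is not None:
        hits = scan[scan["q"] < q_threshold]
    else:
        hits = scan[scan["p"] < p_threshold]
    diff_sites = [SiteKey.parse(s) for s in hits["site"]]
    assignment, cds_summary = map_snvs_to_genes(diff_sites, genes)

    gene_info = {g.gene_id: g for g in genes}
    per_gene: dict[str, list[int]] = {}
    for site, gene_ids in assignment.items():
        for gid in gene_ids:
            per_gene.setdefault(gid, []).append(site.position)
    summaries = [
        GeneHitSummary(
            gene_id=gid,
            mag_id=bin_map.get(gene_info[gid].scaffold, ""),
            n_differential_snvs=len(positions),
            snv_positions=sorted(positions),
            cog_id=gene_info[gid].cog_id,
        )
        for gid, positions in sorted(per_gene.items())
    ]
    counts = pd.Series(
        [s.n_differential_snvs for s in summaries], dtype=int
    ).value_counts().sort_index()
    counts.name = "n_genes"
    counts.index.name = "n_differential_snvs"
    return summaries, counts, cds_summary


def read_pathway_map(path) -> dict[str, set[str]]:
    """Two-column TSV (cog_id, pathway_id); multiple rows per COG allowed."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=["cog_id", "pathway_id"],
        dtype=str,
    )
    if len(df) and df.iloc[0, 0].lower() == "cog_id":
        df = df.iloc[1:]
    mapping: dict[str, set[str]] = {}
    for cog, pw in zip(df["cog_id"], df["pathway_id"]):
        mapping.setdefault(cog, set()).add(pw)
    return mapping


def pathway_enrichment_per_mag(
    hits: Sequence[GeneHitSummary],
    genes: Sequence[GeneRecord],
    pathway_map: Mapping[str, set[str]],
    bin_map: Mapping[str, str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of hit genes in each pathway per MAG.

    The background of a MAG is its COG-annotated genes.  Pathways with
    no gene in the MAG are skipped.  BH across all tested (MAG,
    pathway) pairs.
    """
    from .association import bh_fdr

    hit_ids = {h.gene_id for h in hits}
    by_mag: dict[str, list[GeneRecord]] = {}
    for gene in genes:
        if gene.cog_id is None:
            continue
        mag = bin_map.get(gene.scaffold)
        if mag is None:
            continue
        by_mag.setdefault(mag, []).append(gene)

    rows = []
    for mag in sorted(by_mag):
        mag_genes = by_mag[mag]
        n_total = len(mag_genes)
        hit_genes = [g for g in mag_genes if g.gene_id in hit_ids]
        k_total = len(hit_genes)
        pathways: dict[str, set[str]] = {}
        for g in mag_genes:
            for pw in pathway_map.get(g.cog_id, ()):
                pathways.setdefault(pw, set()).add(g.gene_id)
        for pw in sorted(pathways):
            in_path = pathways[pw]
            k_in = len(in_path & hit_ids)
            n_in = len(in_path)
            table = [
                [k_in, k_total - k_in],
                [n_in - k_in, (n_total - k_total) - (n_in - k_in)],
            ]
            odds, p = fisher_exact(table, alternative="greater")
            rows.append(
                dict(
                    mag_id=mag,
                    pathway_id=pw,
                    k_hit_in_path=k_in,
                    k_hit_total=k_total,
                    n_genes_in_path=n_in,
                    n_genes_total=n_total,
                    odds_ratio=odds,
                    p=p,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "mag_id", "pathway_id", "k_hit_in_path", "k_hit_total",
            "n_genes_in_path", "n_genes_total", "odds_ratio", "p",
        ],
    )
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df
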