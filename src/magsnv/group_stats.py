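"""Temporal trend tests and transplantation-group comparisons.

The study design has three groups (CON, RMT, RFT) sampled on days 15,
35 and 56.  Day is treated as ordinal for Spearman trend tests and as
categorical for Kruskal-Wallis tests.  "Within-group genomic distance"
means the pairwise K2P distances among samples sharing both group and
day; the group-difference scan compares these pools across the three
groups per MAG, with BH adjustment across MAGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneRecord, SampleMeta
from .matrix import BinarySnvGenotypes
from .distance import MagDistanceMatrix

__all__ = [
    "GroupTestResult",
    "kruskal_test",
    "spearman_trend",
    "within_group_distance_by_day",
    "mag_group_dissimilarity_scan",
    "per_gene_temporal_test",
]


@dataclass
class GroupTestResult:
    unit_id: str
    statistic: float
    p: float
    n_per_level: dict
    test_name: str
    q: float | None = None

    def as_row(self) -> dict:
        return dict(
            unit_id=self.unit_id,
            statistic=self.statistic,
            p=self.p,
            q=self.q,
            n_per_level=";".join(f"{k}={v}" for k, v in self.n_per_level.items()),
            test_name=self.test_name,
        )


def kruskal_test(
    values_by_level: Mapping[object, Sequence[float]], unit_id: str = ""
) -> GroupTestResult:
    """Kruskal-Wallis H across levels (tie-corrected, chi-square p).

    Degenerate input where every value is identical yields H = 0, p = 1.
    """
    levels = [lv for lv in values_by_level if len(values_by_level[lv]) > 0]
    if len(levels) < 2:
        raise ValueError("need at least two non-empty levels")
    groups = [np.asarray(values_by_level[lv], dtype=float) for lv in levels]
    try:
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            h, p = stats.kruskal(*groups)
    except ValueError:  # all values identical
        h, p = 0.0, 1.0
    if np.isnan(h):
        h, p = 0.0, 1.0
    return GroupTestResult(
        unit_id=unit_id,
        statistic=float(h),
        p=float(p),
        n_per_level={lv: len(g) for lv, g in zip(levels, groups)},
        test_name="kruskal",
    )


def spearman_trend(x: Sequence[float], y: Sequence[float]) -> dict:
    """Spearman rank correlation with t-approximation p-value.

    Constant input leaves rho undefined: returns NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant input: Spearman rho undefined")
        return {"rho": float("nan"), "p": float("nan"), "n": len(x)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": len(x)}


@dataclass
class WithinGroupDistanceResult:
    """Per-day within-group distance pools with Kruskal and Spearman tests."""

    mag_id: str
    group: str
    kruskal: GroupTestResult
    spearman_rho: float
    spearman_p: float
    distances_by_day: dict[int, np.ndarray] = field(default_factory=dict)


def _within_pool_distances(
    m: MagDistanceMatrix, samples: Sequence[str]
) -> np.ndarray:
    idx = [m.sample_ids.index(s) for s in samples if s in m.sample_ids]
    vals = []
    for a in range(len(idx) - 1):
        for b in range(a + 1, len(idx)):
            d = m.distance[idx[a], idx[b]]
            if not np.isnan(d):
                vals.append(d)
    return np.asarray(vals, dtype=float)


def within_group_distance_by_day(
    m: MagDistanceMatrix, meta: Sequence[SampleMeta], group: str
) -> WithinGroupDistanceResult:
    """Same-day pairwise distances within one group, tested across days.

    Days represented by fewer than two samples contribute no pairs and
    are excluded (noted through ``n_per_level``).
    """
    by_day: dict[int, list[str]] = {}
    for sm in meta:
        if sm.group == group and sm.sample_id in m.sample_ids:
            by_day.setdefault(sm.day, []).append(sm.sample_id)
    pools = {
        day: _within_pool_distances(m, samples)
        for day, samples in sorted(by_day.items())
        if len(samples) >= 2
    }
    pools = {day: v for day, v in pools.items() if v.size > 0}
    if len(pools) < 2:
        raise ValueError(f"{m.mag_id}/{group}: fewer than 2 days with pairs")
    kw = kruskal_test(pools, unit_id=f"{m.mag_id}/{group}")
    xs = np.concatenate([np.full(v.size, day) for day, v in pools.items()])
    ys = np.concatenate(list(pools.values()))
    if xs.size >= 3:
        sp = spearman_trend(xs, ys)
    else:
        sp = {"rho": float("nan"), "p": float("nan")}
    return WithinGroupDistanceResult(
        mag_id=m.mag_id,
        group=group,
        kruskal=kw,
        spearman_rho=sp["rho"],
        spearman_p=sp["p"],
        distances_by_day=pools,
    )


def mag_group_dissimilarity_scan(
    matrices: Sequence[MagDistanceMatrix],
    meta: Sequence[SampleMeta],
    groups: Sequence[str] = ("CON", "RMT", "RFT"),
) -> tuple[pd.DataFrame, list[str]]:
    """Per-MAG Kruskal of within-group distance pools across groups.

    MAGs lacking distances in every group are skipped and listed.  BH
    adjustment is across the tested MAGs.  The result is sorted by MAG
    id, so it is invariant to input ordering.
    """
    from .association import bh_fdr

    members: dict[str, dict[int, list[str]]] = {g: {} for g in groups}
    for sm in meta:
        if sm.group in members:
            members[sm.group].setdefault(sm.day, []).append(sm.sample_id)

    rows = []
    skipped: list[str] = []
    for m in sorted(matrices, key=lambda x: x.mag_id):
        pools: dict[str, np.ndarray] = {}
        for g in groups:
            vals = [
                _within_pool_distances(m, samples)
                for samples in members[g].values()
                if len(samples) >= 2
            ]
            pool = np.concatenate(vals) if vals else np.array([])
            if pool.size > 0:
                pools[g] = pool
        if len(pools) < len(groups):
            skipped.append(m.mag_id)
            continue
        res = kruskal_test(pools, unit_id=m.mag_id)
        rows.append(res.as_row())
    df = pd.DataFrame(
        rows, columns=["unit_id", "statistic", "p", "q", "n_per_level", "test_name"]
    )
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df, skipped


def per_gene_temporal_test(
    geno: BinarySnvGenotypes,
    genes: Sequence[GeneRecord],
    meta: Sequence[SampleMeta],
    level: str = "gene",
) -> pd.DataFrame:
    """Kruskal across days of per-sample minor-allele load per gene.

    ``level="gene"`` (default) summarizes each gene as the mean of the
    0/1 genotype over the gene's non-missing sites per sample;
    ``level="site"`` tests each SNV inside the gene separately.  Genes
    with no called sites are skipped.
    """
    from .association import bh_fdr

    day_of = {m.sample_id: m.day for m in meta}
    days = np.array([day_of.get(s, np.nan) for s in geno.sample_ids], dtype=float)
    positions = np.array([k.position for k in geno.site_keys])
    scaffolds = np.array([k.scaffold for k in geno.site_keys])

    rows = []
    for gene in genes:
        on = (scaffolds == gene.scaffold) & (positions >= gene.start) & (
            positions < gene.end
        )
        idx = np.flatnonzero(on)
        if idx.size == 0:
            continue
        sub = geno.genotype[idx]  # sites x samples
        if level == "gene":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                load = np.nanmean(sub, axis=0)
            units = [(gene.gene_id, load)]
        elif level == "site":
            units = [(str(geno.site_keys[i]), geno.genotype[i]) for i in idx]
        else:
            raise ValueError(f"unknown level {level!r}")
        for unit_id, values in units:
            ok = ~np.isnan(values) & ~np.isnan(days)
            if ok.sum() == 0:
                continue
            by_day = {
                int(d): values[ok & (days == d)]
                for d in np.unique(days[ok])
            }
            by_day = {d: v for d, v in by_day.items() if v.size > 0}
            if len(by_day) < 2:
                continue
            res = kruskal_test(by_day, unit_id=unit_id)
            row = res.as_row()
            row["gene_id"] = gene.gene_id
            row["n_sites"] = int(idx.size)
            rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=[
            "unit_id", "gene_id", "n_sites", "statistic", "p", "q",
            "n_per_level", "test_name",
        ],
    )
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df
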