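"""SNV-haplotype genomic dissimilarity, strain clustering, enrichment.

Each sample's column over a MAG's ordered SNV sites is treated as a
single pseudo-haplotype sequence.  Pairwise dissimilarity is the Kimura
2-parameter (K2P) substitution-rate estimate computed over
pairwise-complete positions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P the transition fraction (A<->G, C<->T) and Q the transversion
fraction.  The distance is missing when fewer than ``min_overlap``
positions are jointly called, or when a log argument is non-positive
(saturation); saturated pairs are counted, not returned as infinity.

Per MAG, the distance matrix is normalized by its maximum defined entry
and strains are obtained by complete-linkage agglomerative clustering,
cut either at a height on the normalized scale or into k clusters.
Cluster-by-day contingency is scored with Fisher's exact test,
BH-adjusted within the MAG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact

from .io import SampleMeta, write_table
from .matrix import MISSING, SnvMatrix

__all__ = [
    "k2p_distance",
    "MagDistanceMatrix",
    "mag_distance_matrix",
    "normalize_distances",
    "StrainClustering",
    "cluster_strains",
    "strain_time_enrichment",
    "write_distance_matrix",
    "read_distance_matrix",
]


def k2p_distance(
    a: np.ndarray, b: np.ndarray, min_overlap: int = 10
) -> float:
    """K2P distance between two encoded pseudo-haplotypes.

    ``a`` and ``b`` are equal-length int8 arrays (A=0,C=1,G=2,T=3; -1 =
    missing).  Returns NaN when the pairwise-complete overlap is below
    ``min_overlap`` or the estimate is saturated.
    """
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    valid = (a != MISSING) & (b != MISSING)
    n = int(valid.sum())
    if n < min_overlap:
        return float("nan")
    diff = valid & (a != b)
    # transitions are within-purine / within-pyrimidine: same parity of code
    ts = diff & ((a & 1) == (b & 1))
    p = ts.sum() / n
    q = (diff.sum() - ts.sum()) / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0.0 or arg2 <= 0.0:
        return float("nan")
    return float(-0.5 * np.log(arg1) - 0.25 * np.log(arg2))


@dataclass
class MagDistanceMatrix:
    """Pairwise K2P distances between samples over one MAG's sites."""

    mag_id: str
    sample_ids: list[str]
    distance: np.ndarray  # float64, NaN where undefined
    overlap: np.ndarray  # int64, pairwise-complete site counts
    normalized: bool = False
    n_saturated: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.distance)

    def submatrix(self, samples: Sequence[str]) -> "MagDistanceMatrix":
        idx = [self.sample_ids.index(s) for s in samples]
        return MagDistanceMatrix(
            self.mag_id,
            list(samples),
            self.distance[np.ix_(idx, idx)],
            self.overlap[np.ix_(idx, idx)],
            self.normalized,
            self.n_saturated,
        )


def mag_distance_matrix(
    matrix: SnvMatrix,
    mag_id: str,
    samples: Sequence[str] | None = None,
    min_overlap: int = 10,
) -> MagDistanceMatrix:
    """All pairwise K2P distances on one MAG's sites.

    The computation is vectorized over sample pairs but is numerically
    identical to calling :func:`k2p_distance` per pair.
    """
    rows = matrix.sites_of_mag(mag_id)
    if rows.size == 0:
        raise KeyError(f"MAG {mag_id!r} has no sites in the matrix")
    if samples is None:
        samples = list(matrix.sample_ids)
    col_idx = [matrix.sample_ids.index(s) for s in samples]
    if len(col_idx) < 2:
        raise ValueError("need at least two samples")
    cons = matrix.consensus[np.ix_(rows, col_idx)]  # sites x samples

    n = len(col_idx)
    dist = np.full((n, n), np.nan)
    overlap = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(overlap, (cons != MISSING).sum(axis=0))
    n_saturated = 0
    for i in range(n - 1):
        a = cons[:, i : i + 1]
        B = cons[:, i + 1 :]
        valid = (a != MISSING) & (B != MISSING)
        diff = valid & (a != B)
        ts = diff & ((a & 1) == (B & 1))
        nv = valid.sum(axis=0).astype(float)
        nts = ts.sum(axis=0)
        ntv = diff.sum(axis=0) - nts
        with np.errstate(invalid="ignore", divide="ignore"):
            p = nts / nv
            q = ntv / nv
            arg1 = 1.0 - 2.0 * p - q
            arg2 = 1.0 - 2.0 * q
            d = -0.5 * np.log(arg1) - 0.25 * np.log(arg2)
        enough = nv >= min_overlap
        saturated = enough & ((arg1 <= 0) | (arg2 <= 0))
        n_saturated += int(saturated.sum())
        d = np.where(enough & ~saturated, d, np.nan)
        dist[i, i + 1 :] = d
        dist[i + 1 :, i] = d
        overlap[i, i + 1 :] = nv.astype(np.int64)
        overlap[i + 1 :, i] = nv.astype(np.int64)
    defined_diag = overlap.diagonal() >= min_overlap
    diag = np.where(defined_diag, 0.0, np.nan)
    dist[np.diag_indices(n)] = diag
    if n_saturated:
        warnings.warn(f"{mag_id}: {n_saturated} saturated sample pairs set to missing")
    return MagDistanceMatrix(mag_id, list(samples), dist, overlap, False, n_saturated)


def normalize_distances(m: MagDistanceMatrix) -> MagDistanceMatrix:
    """Divide every defined entry by the maximum defined entry.

    An all-zero matrix is returned unchanged (flagged normalized); a
    matrix with no defined entry is an error.
    """
    defined = m.defined()
    if not defined.any():
        raise ValueError(f"{m.mag_id}: no defined distances to normalize")
    dmax = np.nanmax(m.distance)
    dist = m.distance if dmax == 0 else m.distance / dmax
    return MagDistanceMatrix(
        m.mag_id, list(m.sample_ids), dist.copy(), m.overlap.copy(), True, m.n_saturated
    )


@dataclass
class StrainClustering:
    mag_id: str
    labels: dict[str, int]  # sample_id -> cluster (1-based, largest first)
    linkage: np.ndarray  # scipy linkage matrix over the clustered samples
    clustered_samples: list[str]
    dropped_samples: list[str]
    cut_height: float | None = None
    n_clusters: int | None = None

    def labels_for(self, samples: Sequence[str]) -> list[int | None]:
        return [self.labels.get(s) for s in samples]


def cluster_strains(
    m: MagDistanceMatrix,
    height: float | None = None,
    k: int | None = None,
    max_missing_frac: float = 0.5,
) -> StrainClustering:
    """Complete-linkage clustering of a (normalized) distance matrix.

    Samples whose distance is missing to more than ``max_missing_frac``
    of the others are dropped first; if undefined entries remain, the
    sample with the most of them is dropped iteratively.  Cluster labels
    are renumbered by size (largest = 1), ties broken by the smallest
    member sample id, so the labelling is ordering-independent.
    """
    if (height is None) == (k is None):
        raise ValueError("specify exactly one of height= or k=")
    dist = m.distance.copy()
    ids = list(m.sample_ids)

    keep = np.ones(len(ids), dtype=bool)
    off_diag = ~np.eye(len(ids), dtype=bool)
    missing_frac = (np.isnan(dist) & off_diag).sum(axis=1) / max(len(ids) - 1, 1)
    keep &= missing_frac <= max_missing_frac
    while True:
        sub = dist[np.ix_(keep, keep)]
        nan_counts = np.isnan(sub).sum(axis=1)
        if nan_counts.sum() == 0:
            break
        worst = np.flatnonzero(keep)[np.argmax(nan_counts)]
        keep[worst] = False
    clustered = [s for s, k_ in zip(ids, keep) if k_]
    dropped = [s for s, k_ in zip(ids, keep) if not k_]
    if len(clustered) < 2:
        raise ValueError(f"{m.mag_id}: fewer than 2 cluster-eligible samples")

    sub = dist[np.ix_(keep, keep)]
    condensed = squareform(sub, checks=False)
    Z = hierarchy.linkage(condensed, method="complete")
    if height is not None:
        raw = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    # deterministic renumbering: by size desc, then smallest member id
    order: dict[int, tuple[int, str]] = {}
    for lab in np.unique(raw):
        members = [clustered[i] for i in np.flatnonzero(raw == lab)]
        order[int(lab)] = (-len(members), min(members))
    ranking = {lab: r + 1 for r, lab in enumerate(sorted(order, key=order.get))}
    labels = {s: ranking[int(lab)] for s, lab in zip(clustered, raw)}
    return StrainClustering(
        mag_id=m.mag_id,
        labels=labels,
        linkage=Z,
        clustered_samples=clustered,
        dropped_samples=dropped,
        cut_height=height,
        n_clusters=len(ranking) if k is None else k,
    )


def linkage_to_newick(clustering: StrainClustering) -> str:
    """Render the dendrogram as a newick string (heights as branch lengths)."""
    tree = hierarchy.to_tree(clustering.linkage)
    names = clustering.clustered_samples

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def strain_time_enrichment(
    clustering: StrainClustering,
    meta: Sequence[SampleMeta],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher exact cluster-by-day enrichment within one MAG.

    For every (cluster, day) the 2x2 table is membership in the cluster
    versus sampling on that day, among the clustered samples.  P-values
    are BH-adjusted across all tests of the MAG.  Fewer than 2 clusters
    or fewer than 2 day levels yield an empty table.
    """
    from .association import bh_fdr

    day_of = {m.sample_id: m.day for m in meta}
    samples = [s for s in clustering.clustered_samples if s in day_of]
    clusters = sorted(set(clustering.labels[s] for s in samples))
    days = sorted(set(day_of[s] for s in samples))
    if len(clusters) < 2 or len(days) < 2:
        return pd.DataFrame(
            columns=["mag_id", "cluster", "day", "a", "b", "c", "d", "odds_ratio", "p", "q"]
        )
    rows = []
    for cl in clusters:
        for day in days:
            in_cl = np.array([clustering.labels[s] == cl for s in samples])
            on_day = np.array([day_of[s] == day for s in samples])
            a = int((in_cl & on_day).sum())
            b = int((in_cl & ~on_day).sum())
            c = int((~in_cl & on_day).sum())
            d = int((~in_cl & ~on_day).sum())
            odds, p = fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append(
                dict(
                    mag_id=clustering.mag_id,
                    cluster=cl,
                    day=day,
                    a=a,
                    b=b,
                    c=c,
                    d=d,
                    odds_ratio=odds,
                    p=p,
                )
            )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------


def write_distance_matrix(m: MagDistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(m.distance, index=m.sample_ids, columns=m.sample_ids)
    df.index.name = "sample_id"
    write_table(
        df,
        path,
        params={"mag": m.mag_id, "normalized": m.normalized, "saturated": m.n_saturated},
        index=True,
    )


def read_distance_matrix(path: str | Path, mag_id: str = "") -> MagDistanceMatrix:
    with open(path) as fh:
        header = fh.readline()
    normalized = "normalized=True" in header
    if not mag_id and "mag=" in header:
        mag_id = header.split("mag=")[1].split()[0]
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    dist = df.to_numpy(dtype=float)
    overlap = np.zeros_like(dist, dtype=np.int64)
    return MagDistanceMatrix(mag_id, list(df.columns), dist, overlap, normalized)
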