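"""Metagenome-wide SNV association scans with FDR control and LD pruning.

Models follow the study design: for a continuous trait,
``trait ~ SNV + day`` by ordinary least squares with a Wald test on the
SNV coefficient; for a binary trait, maximum-likelihood logistic
regression.  The transplantation-effect scan inverts the model:
``SNV ~ group + day`` with group entered as two indicators (CON as
reference) and an omnibus likelihood-ratio test on the two group terms.
Day is a numeric covariate (15/35/56) by default; a categorical
encoding is available by flag.

Multiple testing is controlled with the Benjamini-Hochberg step-up
procedure, applied jointly across all (site x trait) tests of a scan
("study-wide"); per-trait adjustment is available by flag.  Highly
correlated significant sites (pairwise-complete Pearson r^2 above a
threshold, default 0.9) from the same MAG associated with the same
trait are pruned greedily, keeping the smallest p per correlated set.

Skipped or degenerate fits are reported as records with a
``skip_reason`` (``monomorphic``, ``min_class_count``,
``too_few_samples``, ``separation_or_nonconvergence``) rather than
silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable, SampleMeta, SiteKey
from .matrix import BinarySnvGenotypes

__all__ = [
    "SCAN_COLUMNS",
    "bh_fdr",
    "snv_trait_scan",
    "snv_group_scan",
    "ld_prune",
    "PrunedAssociationSet",
    "genotype_r2",
    "metabolite_phenotype_link",
]

SCAN_COLUMNS = [
    "site", "mag_id", "trait_id", "model", "estimate", "std_error",
    "p", "q", "n_used", "skip_reason",
]

#: logistic fits with any |coefficient| above this are treated as separated
_SEPARATION_BOUND = 15.0
_MAX_LOGIT_ITER = 100
_LOGIT_TOL = 1e-8


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order preserved.

    ``q_i = min_{j: p_(j) >= p_(i)} p_(j) * m / j`` clipped to 1, with m
    counting only the non-missing entries; NaNs pass through in place.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# model fitting primitives
# ---------------------------------------------------------------------------


def _ols_wald(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of every column of Y on X; Wald stats for coefficient 1.

    Returns (beta1, se1, p1) arrays of length Y.shape[1].  A perfect fit
    (zero residual variance) yields p = 0 with a zero standard error.
    """
    n, k = X.shape
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    B = xtx_inv @ (X.T @ Y)  # k x T
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    df = n - k
    if df <= 0:
        bad = np.full(Y.shape[1], np.nan)
        return B[1], bad, bad
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B[1] / se, 0.0)
    p = np.where(
        se > 0,
        2.0 * stats.t.sf(np.abs(t), df),
        np.where(np.abs(B[1]) > 1e-12, 0.0, 1.0),  # exact fit vs constant response
    )
    p = np.where(np.isfinite(B[1]), p, np.nan)
    return B[1], se, p


def _logit_fit(X: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit via statsmodels; None on failure."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.Logit(y, X)
            res = model.fit(disp=0, maxiter=_MAX_LOGIT_ITER, tol=_LOGIT_TOL)
        except Exception:
            return None
    if not res.mle_retvals.get("converged", False):
        return None
    if np.abs(res.params).max() > _SEPARATION_BOUND:
        return None
    return res


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------


def _day_vector(
    meta: Sequence[SampleMeta], sample_ids: Sequence[str], numeric: bool
) -> np.ndarray:
    day_of = {m.sample_id: m.day for m in meta}
    days = np.array([day_of.get(s, np.nan) for s in sample_ids], dtype=float)
    return days


def _day_columns(days: np.ndarray, numeric: bool) -> np.ndarray:
    """Covariate columns for day: one numeric column or L-1 indicators."""
    if numeric:
        return days[:, None]
    levels = np.unique(days[~np.isnan(days)])
    return np.column_stack([(days == lv).astype(float) for lv in levels[1:]])


def snv_trait_scan(
    geno: BinarySnvGenotypes,
    traits: FeatureTable,
    meta: Sequence[SampleMeta],
    covariate_day: bool = True,
    day_numeric: bool = True,
    min_n: int = 20,
    min_class_count: int = 3,
    fdr_per_trait: bool = False,
) -> pd.DataFrame:
    """Associate every filtered SNV with every trait.

    Continuous traits: OLS ``trait ~ SNV (+ day)`` with a Wald p on the
    SNV slope.  Binary traits: logistic regression, separation flagged.
    Returns one record per (site, trait) with a q column (BH across the
    whole scan by default).
    """
    sample_ids = list(geno.sample_ids)
    trait_data = traits.data.reindex(sample_ids)
    Y_all = trait_data.to_numpy(dtype=float)  # samples x traits
    trait_ids = traits.feature_ids
    kinds = [traits.kinds[t] for t in trait_ids]
    days = _day_vector(meta, sample_ids, day_numeric)
    mags = geno.mags()

    cont_idx = [j for j, k in enumerate(kinds) if k == "continuous"]
    bin_idx = [j for j, k in enumerate(kinds) if k == "binary"]

    rows: list[dict] = []
    base_ok = ~np.isnan(days) if covariate_day else np.ones(len(sample_ids), bool)

    for i in range(geno.n_sites):
        g = geno.genotype[i].astype(float)
        site = str(geno.site_keys[i])
        mag = mags[i]
        g_ok = base_ok & ~np.isnan(g)

        def record(trait_j, **kw):
            rows.append(
                dict(
                    site=site,
                    mag_id=mag,
                    trait_id=trait_ids[trait_j],
                    model=kw.get("model", ""),
                    estimate=kw.get("estimate", np.nan),
                    std_error=kw.get("std_error", np.nan),
                    p=kw.get("p", np.nan),
                    n_used=kw.get("n_used", 0),
                    skip_reason=kw.get("skip_reason", ""),
                )
            )

        # --- continuous traits: vectorize over traits complete under g_ok
        if cont_idx:
            Yc = Y_all[:, cont_idx]
            complete = ~np.isnan(Yc[g_ok]).any(axis=0)
            groups = [
                ([cont_idx[j] for j in np.flatnonzero(complete)], None),
            ] + [([cont_idx[j]], True) for j in np.flatnonzero(~complete)]
            for trait_js, needs_own_mask in groups:
                if not trait_js:
                    continue
                if needs_own_mask:
                    mask = g_ok & ~np.isnan(Y_all[:, trait_js[0]])
                else:
                    mask = g_ok
                n = int(mask.sum())
                gm = g[mask]
                n1 = int(gm.sum())
                n0 = n - n1
                reason = None
                if n < min_n:
                    reason = "too_few_samples"
                elif n0 == 0 or n1 == 0:
                    reason = "monomorphic"
                elif min(n0, n1) < min_class_count:
                    reason = "min_class_count"
                if reason:
                    for j in trait_js:
                        record(j, model="linear", n_used=n, skip_reason=reason)
                    continue
                cols = [np.ones(n), gm]
                if covariate_day:
                    cols.append(_day_columns(days[mask], day_numeric))
                X = np.column_stack(cols)
                Y = Y_all[np.ix_(mask, trait_js)]
                beta, se, p = _ols_wald(X, Y)
                for b, s_, pv, j in zip(beta, se, p, trait_js):
                    record(
                        j, model="linear", estimate=float(b), std_error=float(s_),
                        p=float(pv), n_used=n,
                    )

        # --- binary traits: per-pair logistic
        for j in bin_idx:
            mask = g_ok & ~np.isnan(Y_all[:, j])
            n = int(mask.sum())
            gm = g[mask]
            n1 = int(gm.sum())
            n0 = n - n1
            if n < min_n:
                record(j, model="logistic", n_used=n, skip_reason="too_few_samples")
                continue
            if n0 == 0 or n1 == 0:
                record(j, model="logistic", n_used=n, skip_reason="monomorphic")
                continue
            if min(n0, n1) < min_class_count:
                record(j, model="logistic", n_used=n, skip_reason="min_class_count")
                continue
            y = Y_all[mask, j]
            if y.min() == y.max():
                record(j, model="logistic", n_used=n, skip_reason="monomorphic")
                continue
            cols = [np.ones(n), gm]
            if covariate_day:
                cols.append(_day_columns(days[mask], day_numeric))
            X = np.column_stack(cols)
            res = _logit_fit(X, y)
            if res is None:
                record(
                    j, model="logistic", n_used=n,
                    skip_reason="separation_or_nonconvergence",
                )
                continue
            record(
                j, model="logistic", estimate=float(res.params[1]),
                std_error=float(res.bse[1]), p=float(res.pvalues[1]), n_used=n,
            )

    df = pd.DataFrame(rows)
    df = _attach_q(df, per_trait=fdr_per_trait)
    return df[SCAN_COLUMNS]


def _attach_q(df: pd.DataFrame, per_trait: bool) -> pd.DataFrame:
    df = df.copy()
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        return df
    if per_trait:
        df["q"] = np.nan
        for t, sub in df.groupby("trait_id"):
            df.loc[sub.index, "q"] = bh_fdr(sub["p"].to_numpy())
    else:
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def snv_group_scan(
    geno: BinarySnvGenotypes,
    meta: Sequence[SampleMeta],
    groups: Sequence[str] = ("CON", "RMT", "RFT"),
    day_numeric: bool = True,
    min_n: int = 20,
    min_class_count: int = 3,
) -> pd.DataFrame:
    """Logistic scan ``SNV ~ group + day`` with an omnibus group LRT.

    The genotype is the outcome; the first group is the reference and
    the remaining groups enter as indicators.  The reported p is the
    likelihood-ratio test of the group indicators jointly
    (chi-square, len(groups) - 1 df); ``estimate`` is the log-odds of
    the first non-reference group (RMT under the default ordering).
    """
    sample_ids = list(geno.sample_ids)
    group_of = {m.sample_id: m.group for m in meta}
    sample_group = np.array([group_of.get(s, "") for s in sample_ids])
    days = _day_vector(meta, sample_ids, day_numeric)
    mags = geno.mags()
    base_ok = ~np.isnan(days) & np.isin(sample_group, groups)
    indicators = np.column_stack(
        [(sample_group == g).astype(float) for g in groups[1:]]
    )

    reduced_cache: dict[bytes, float | None] = {}
    rows: list[dict] = []
    for i in range(geno.n_sites):
        g = geno.genotype[i].astype(float)
        site = str(geno.site_keys[i])
        mask = base_ok & ~np.isnan(g)
        n = int(mask.sum())
        y = g[mask]
        n1 = int(y.sum())
        n0 = n - n1
        common = dict(site=site, mag_id=mags[i], trait_id="group", model="logistic_lrt")
        if n < min_n:
            rows.append(dict(common, estimate=np.nan, std_error=np.nan, p=np.nan,
                             n_used=n, skip_reason="too_few_samples"))
            continue
        if n0 == 0 or n1 == 0:
            rows.append(dict(common, estimate=np.nan, std_error=np.nan, p=np.nan,
                             n_used=n, skip_reason="monomorphic"))
            continue
        if min(n0, n1) < min_class_count:
            rows.append(dict(common, estimate=np.nan, std_error=np.nan, p=np.nan,
                             n_used=n, skip_reason="min_class_count"))
            continue
        day_cols = _day_columns(days[mask], day_numeric)
        X_full = np.column_stack([np.ones(n), indicators[mask], day_cols])
        full = _logit_fit(X_full, y)
        if full is None:
            rows.append(dict(common, estimate=np.nan, std_error=np.nan, p=np.nan,
                             n_used=n, skip_reason="separation_or_nonconvergence"))
            continue
        key = mask.tobytes() + y.astype(np.int8).tobytes()
        if key not in reduced_cache:
            X_red = np.column_stack([np.ones(n), day_cols])
            red = _logit_fit(X_red, y)
            reduced_cache[key] = None if red is None else float(red.llf)
        llf_red = reduced_cache[key]
        if llf_red is None:
            rows.append(dict(common, estimate=np.nan, std_error=np.nan, p=np.nan,
                             n_used=n, skip_reason="separation_or_nonconvergence"))
            continue
        lrt = max(2.0 * (float(full.llf) - llf_red), 0.0)
        p = float(stats.chi2.sf(lrt, df=len(groups) - 1))
        rows.append(dict(common, estimate=float(full.params[1]),
                         std_error=float(full.bse[1]), p=p, n_used=n, skip_reason=""))
    df = pd.DataFrame(rows)
    df = _attach_q(df, per_trait=False)
    return df[SCAN_COLUMNS]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def genotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1 rows, pairwise complete.

    NaN when fewer than two complete pairs remain or either row is
    constant on the complete pairs.
    """
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        return float("nan")
    x, y = a[ok], b[ok]
    if x.min() == x.max() or y.min() == y.max():
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class PrunedAssociationSet:
    kept: pd.DataFrame
    pruned: dict[tuple[str, str, str], list[tuple[str, float]]] = field(
        default_factory=dict
    )

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def ld_prune(
    records: pd.DataFrame,
    geno: BinarySnvGenotypes,
    r2_threshold: float = 0.9,
) -> PrunedAssociationSet:
    """Greedy LD pruning within each (MAG, trait) stratum.

    Records are ordered by ascending p (ties by site string); the best
    is kept and every remaining record whose genotype r^2 with it
    exceeds the threshold is removed and logged against the kept
    record.  The procedure iterates until the stratum is exhausted.
    """
    site_row = {str(k): i for i, k in enumerate(geno.site_keys)}
    missing = [s for s in records["site"] if s not in site_row]
    if missing:
        raise KeyError(f"site(s) absent from genotypes: {missing[:3]}")

    kept_indices: list[int] = []
    pruned: dict[tuple[str, str, str], list[tuple[str, float]]] = {}
    for (mag, trait), stratum in records.groupby(["mag_id", "trait_id"], sort=True):
        stratum = stratum.sort_values(
            ["p", "site"], kind="stable", na_position="last"
        )
        remaining = list(stratum.index)
        while remaining:
            best = remaining.pop(0)
            kept_indices.append(best)
            best_site = records.at[best, "site"]
            g_best = geno.genotype[site_row[best_site]].astype(float)
            removals = []
            still = []
            for idx in remaining:
                other_site = records.at[idx, "site"]
                r2 = genotype_r2(g_best, geno.genotype[site_row[other_site]].astype(float))
                if not np.isnan(r2) and r2 > r2_threshold:
                    removals.append((other_site, r2))
                else:
                    still.append(idx)
            if removals:
                pruned[(mag, trait, best_site)] = removals
            remaining = still
    kept = records.loc[sorted(kept_indices)].copy()
    return PrunedAssociationSet(kept=kept, pruned=pruned)


# ---------------------------------------------------------------------------
# metabolite-phenotype linkage
# ---------------------------------------------------------------------------


def metabolite_phenotype_link(
    metabolites: FeatureTable,
    phenotypes: FeatureTable,
    meta: Sequence[SampleMeta],
    snv_metabolites: Sequence[str] | None = None,
    covariate_day: bool = True,
    day_numeric: bool = True,
    fdr: float = 0.05,
    min_n: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Associate every metabolite with every phenotype.

    Per pair: ``phenotype ~ metabolite + day`` (OLS for continuous,
    logistic for binary phenotypes) plus the Spearman correlation; BH
    across the scan.  The overlap report lists metabolites significant
    here and also carried in ``snv_metabolites`` (the metabolites with
    a significant SNV association) -- the input of a Sankey-style
    SNV -> metabolite -> phenotype summary.
    """
    shared = [s for s in metabolites.sample_ids if s in set(phenotypes.sample_ids)]
    if len(shared) < min_n:
        raise ValueError("too few shared samples between the two tables")
    M = metabolites.data.reindex(shared)
    P = phenotypes.data.reindex(shared)
    days = _day_vector(meta, shared, day_numeric)

    rows = []
    for phen in phenotypes.feature_ids:
        kind = phenotypes.kinds[phen]
        y_all = P[phen].to_numpy(dtype=float)
        for met in metabolites.feature_ids:
            x_all = M[met].to_numpy(dtype=float)
            mask = ~np.isnan(x_all) & ~np.isnan(y_all)
            if covariate_day:
                mask &= ~np.isnan(days)
            n = int(mask.sum())
            base = dict(metabolite=met, phenotype=phen, model=kind, n_used=n)
            if n < min_n:
                rows.append(dict(base, estimate=np.nan, p=np.nan, rho=np.nan,
                                 skip_reason="too_few_samples"))
                continue
            x, y = x_all[mask], y_all[mask]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(x, y)[0] if x.min() < x.max() else np.nan
            cols = [np.ones(n), x]
            if covariate_day:
                cols.append(_day_columns(days[mask], day_numeric))
            X = np.column_stack(cols)
            if kind == "binary":
                if y.min() == y.max():
                    rows.append(dict(base, estimate=np.nan, p=np.nan, rho=rho,
                                     skip_reason="monomorphic"))
                    continue
                res = _logit_fit(X, y)
                if res is None:
                    rows.append(dict(base, estimate=np.nan, p=np.nan, rho=rho,
                                     skip_reason="separation_or_nonconvergence"))
                    continue
                est, p = float(res.params[1]), float(res.pvalues[1])
            else:
                beta, se, pv = _ols_wald(X, y[:, None])
                est, p = float(beta[0]), float(pv[0])
            rows.append(dict(base, estimate=est, p=p, rho=float(rho), skip_reason=""))
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    significant = sorted(set(df.loc[df["q"] < fdr, "metabolite"]))
    if snv_metabolites is None:
        overlap = significant
    else:
        overlap = sorted(set(significant) & set(snv_metabolites))
    return df, overlap
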