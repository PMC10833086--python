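"""Study-level consensus-base matrix and the biallelic site filters.

The central object is :class:`SnvMatrix`: rows are SNV sites (scaffold +
position + reference base), columns are samples, and each entry is the
consensus base (the base supported by the most reads) where the sample
called the site, or missing otherwise.  Bases are encoded as int8
(A=0, C=1, G=2, T=3; missing = -1) for vectorized downstream work and
rendered as letters only at the file boundary.

:func:`filter_sites` applies the association-scan site filters, in a
fixed order so per-rule removal counts are unambiguous:

1. presence: the site is called in at least ``presence_min`` of samples;
2. biallelic: exactly two distinct bases among the non-missing calls;
3. frequency: the major base accounts for at most ``major_max`` of the
   non-missing calls and the minor base for at least ``maf_min``
   (boundary semantics: "more than 90%" removes strictly above 0.90;
   a minor-allele fraction of exactly 0.10 is kept).

Allele fractions are computed over non-missing samples only.  The minor
base is coded 1 and the major base 0; an exact 50/50 tie is broken
alphabetically (the lower base is coded 0) for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BASES, FormatError, SiteKey, SnvCall, write_table

__all__ = [
    "MISSING",
    "encode_base",
    "decode_base",
    "SnvMatrix",
    "BinarySnvGenotypes",
    "build_consensus_matrix",
    "count_snvs_per_sample",
    "filter_sites",
    "write_snv_matrix",
    "read_snv_matrix",
    "write_genotypes",
    "read_genotypes",
]

MISSING = np.int8(-1)
_BASE_TO_CODE = {b: np.int8(i) for i, b in enumerate(BASES)}
_CODE_TO_BASE = np.array(list(BASES))


def encode_base(base: str) -> np.int8:
    return _BASE_TO_CODE[base]


def decode_base(code: int) -> str:
    return "NA" if code < 0 else _CODE_TO_BASE[code]


@dataclass
class SnvMatrix:
    """Sites x samples consensus-base matrix with missingness."""

    site_keys: list[SiteKey]
    sample_ids: list[str]
    consensus: np.ndarray  # int8, shape (n_sites, n_samples), -1 = missing
    site_to_mag: dict[SiteKey, str]

    def __post_init__(self) -> None:
        self.consensus = np.asarray(self.consensus, dtype=np.int8)
        if self.consensus.shape != (len(self.site_keys), len(self.sample_ids)):
            raise ValueError("consensus shape does not match site/sample lists")

    @property
    def n_sites(self) -> int:
        return len(self.site_keys)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def mag_of_site(self, index: int) -> str:
        return self.site_to_mag[self.site_keys[index]]

    def mags(self) -> np.ndarray:
        """Per-site MAG id, aligned with ``site_keys``."""
        return np.array([self.site_to_mag[k] for k in self.site_keys])

    def sites_of_mag(self, mag_id: str) -> np.ndarray:
        return np.flatnonzero(self.mags() == mag_id)


@dataclass
class BinarySnvGenotypes:
    """Filtered biallelic sites coded 0/1 (NaN = missing) with allele map."""

    site_keys: list[SiteKey]
    sample_ids: list[str]
    genotype: np.ndarray  # float32, shape (n_sites, n_samples), NaN = missing
    allele_map: list[tuple[str, str]]  # (base coded 0, base coded 1) per site
    presence_fraction: np.ndarray
    minor_allele_fraction: np.ndarray
    site_to_mag: dict[SiteKey, str]
    filter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.site_keys)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def site_index(self) -> dict[SiteKey, int]:
        return {k: i for i, k in enumerate(self.site_keys)}

    def mags(self) -> np.ndarray:
        return np.array([self.site_to_mag[k] for k in self.site_keys])

    def as_matrix(self) -> SnvMatrix:
        """Re-express the 0/1 genotypes as a consensus-base matrix."""
        cons = np.full(self.genotype.shape, MISSING, dtype=np.int8)
        for i, (base0, base1) in enumerate(self.allele_map):
            row = self.genotype[i]
            cons[i, row == 0.0] = encode_base(base0)
            cons[i, row == 1.0] = encode_base(base1)
        return SnvMatrix(
            list(self.site_keys), list(self.sample_ids), cons, dict(self.site_to_mag)
        )


def build_consensus_matrix(
    calls_by_sample: Mapping[str, Sequence[SnvCall]],
    bin_map: Mapping[str, str],
) -> SnvMatrix:
    """Merge per-sample SNV calls into the study-level consensus matrix.

    Rows are the union of site keys across samples, in first-appearance
    order (sample order, then call order within a sample).  Calls on
    scaffolds absent from ``bin_map`` are dropped with a warning.  Two
    calls for the same (sample, site) with different consensus bases are
    an error; identical duplicates are idempotent.
    """
    sample_ids = list(calls_by_sample)
    site_order: dict[SiteKey, int] = {}
    entries: list[tuple[int, int, np.int8]] = []
    n_unmapped = 0
    for j, sample in enumerate(sample_ids):
        for call in calls_by_sample[sample]:
            if call.scaffold not in bin_map:
                n_unmapped += 1
                continue
            key = call.site_key
            i = site_order.setdefault(key, len(site_order))
            entries.append((i, j, encode_base(call.con_base)))
    if n_unmapped:
        warnings.warn(
            f"dropped {n_unmapped} calls on scaffolds absent from the bin map"
        )
    consensus = np.full((len(site_order), len(sample_ids)), MISSING, dtype=np.int8)
    for i, j, code in entries:
        if consensus[i, j] != MISSING and consensus[i, j] != code:
            key = next(k for k, idx in site_order.items() if idx == i)
            raise FormatError(
                f"conflicting consensus bases for sample {sample_ids[j]!r} at {key}"
            )
        consensus[i, j] = code
    site_keys = list(site_order)
    site_to_mag = {k: bin_map[k.scaffold] for k in site_keys}
    return SnvMatrix(site_keys, sample_ids, consensus, site_to_mag)


def count_snvs_per_sample(matrix: SnvMatrix) -> pd.Series:
    """Number of non-missing consensus calls per sample."""
    counts = (matrix.consensus != MISSING).sum(axis=0)
    return pd.Series(counts, index=matrix.sample_ids, name="n_snvs")


def filter_sites(
    matrix: SnvMatrix,
    presence_min: float = 0.20,
    major_max: float = 0.90,
    maf_min: float = 0.10,
) -> BinarySnvGenotypes:
    """Apply presence / biallelic / allele-frequency filters and binarize.

    See the module docstring for rule order and boundary semantics.
    ``filter_counts`` on the result records how many sites each rule
    removed.
    """
    for name, value in (
        ("presence_min", presence_min),
        ("major_max", major_max),
        ("maf_min", maf_min),
    ):
        if not 0.0 < value < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {value}")
    if matrix.n_sites == 0:
        raise ValueError("empty SNV matrix")

    cons = matrix.consensus
    n_samples = matrix.n_samples
    base_counts = np.stack([(cons == b).sum(axis=1) for b in range(4)], axis=1)
    n_called = base_counts.sum(axis=1)

    presence = n_called / n_samples
    keep_presence = presence >= presence_min

    n_distinct = (base_counts > 0).sum(axis=1)
    keep_biallelic = keep_presence & (n_distinct == 2)

    major_count = base_counts.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        major_frac = np.where(n_called > 0, major_count / n_called, 0.0)
        # computed from integer counts so the 9-of-10 boundary lands exactly
        minor_frac = np.where(n_called > 0, (n_called - major_count) / n_called, 0.0)
    keep_freq = keep_biallelic & (major_frac <= major_max) & (minor_frac >= maf_min)

    counts = {
        "input": int(matrix.n_sites),
        "removed_presence": int((~keep_presence).sum()),
        "removed_biallelic": int((keep_presence & ~keep_biallelic).sum()),
        "removed_frequency": int((keep_biallelic & ~keep_freq).sum()),
        "retained": int(keep_freq.sum()),
    }

    idx = np.flatnonzero(keep_freq)
    genotype = np.full((len(idx), n_samples), np.nan, dtype=np.float32)
    allele_map: list[tuple[str, str]] = []
    for out_i, i in enumerate(idx):
        present = np.flatnonzero(base_counts[i] > 0)
        b0, b1 = int(present[0]), int(present[1])
        # major base coded 0; exact tie -> alphabetically lower base is major
        if base_counts[i, b1] > base_counts[i, b0]:
            b0, b1 = b1, b0
        allele_map.append((BASES[b0], BASES[b1]))
        row = cons[i]
        genotype[out_i, row == b0] = 0.0
        genotype[out_i, row == b1] = 1.0

    site_keys = [matrix.site_keys[i] for i in idx]
    return BinarySnvGenotypes(
        site_keys=site_keys,
        sample_ids=list(matrix.sample_ids),
        genotype=genotype,
        allele_map=allele_map,
        presence_fraction=presence[idx],
        minor_allele_fraction=minor_frac[idx],
        site_to_mag={k: matrix.site_to_mag[k] for k in site_keys},
        filter_counts=counts,
    )


# ---------------------------------------------------------------------------
# import / export
# ---------------------------------------------------------------------------


def write_snv_matrix(matrix: SnvMatrix, path: str | Path) -> None:
    """Export: rows = "scaffold:position:ref", cells = base letter or NA."""
    cells = np.where(
        matrix.consensus >= 0, _CODE_TO_BASE[np.maximum(matrix.consensus, 0)], "NA"
    )
    df = pd.DataFrame(cells, columns=matrix.sample_ids)
    df.insert(0, "site", [str(k) for k in matrix.site_keys])
    df.insert(1, "mag", [matrix.site_to_mag[k] for k in matrix.site_keys])
    write_table(df, path, params={"n_sites": matrix.n_sites})


def read_snv_matrix(path: str | Path) -> SnvMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    site_keys = [SiteKey.parse(s) for s in df["site"]]
    site_to_mag = dict(zip(site_keys, df["mag"]))
    sample_ids = [c for c in df.columns if c not in ("site", "mag")]
    cells = df[sample_ids].to_numpy(dtype=object)
    consensus = np.full(cells.shape, MISSING, dtype=np.int8)
    for b, code in _BASE_TO_CODE.items():
        consensus[cells == b] = code
    return SnvMatrix(site_keys, sample_ids, consensus, site_to_mag)


def write_genotypes(geno: BinarySnvGenotypes, path: str | Path) -> None:
    with np.errstate(invalid="ignore"):
        codes = np.nan_to_num(geno.genotype, nan=0.0).astype(int).astype(str)
    cells = np.where(np.isnan(geno.genotype), "NA", codes)
    df = pd.DataFrame(cells, columns=geno.sample_ids)
    df.insert(0, "site", [str(k) for k in geno.site_keys])
    df.insert(1, "mag", [geno.site_to_mag[k] for k in geno.site_keys])
    df.insert(2, "allele0", [a for a, _ in geno.allele_map])
    df.insert(3, "allele1", [b for _, b in geno.allele_map])
    write_table(df, path, params=geno.filter_counts)


def read_genotypes(path: str | Path) -> BinarySnvGenotypes:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    site_keys = [SiteKey.parse(s) for s in df["site"]]
    meta_cols = ("site", "mag", "allele0", "allele1")
    sample_ids = [c for c in df.columns if c not in meta_cols]
    cells = df[sample_ids].to_numpy(dtype=object)
    genotype = np.full(cells.shape, np.nan, dtype=np.float32)
    genotype[cells == "0"] = 0.0
    genotype[cells == "1"] = 1.0
    n_called = (~np.isnan(genotype)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        maf = np.nansum(genotype, axis=1) / np.maximum(n_called, 1)
    return BinarySnvGenotypes(
        site_keys=site_keys,
        sample_ids=sample_ids,
        genotype=genotype,
        allele_map=list(zip(df["allele0"], df["allele1"])),
        presence_fraction=n_called / len(sample_ids),
        minor_allele_fraction=np.minimum(maf, 1 - maf),
        site_to_mag=dict(zip(site_keys, df["mag"])),
    )
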