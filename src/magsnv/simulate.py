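"""Synthetic longitudinal strain-level studies with known ground truth.

The generator emulates the statistical structure of a three-arm
neonatal transplantation study: animals in CON / RMT / RFT groups
sampled on days 15, 35 and 56, several MAGs each carrying two (or more)
strain haplotypes over biallelic SNV sites, day-dependent missingness
of consensus calls (coverage improves with age), transplantation-driven
strain replacement in a subset of MAGs, planted linear SNV->metabolite
effects with a day covariate, metabolite->phenotype loadings, and a
planted pathway enrichment among the genes carrying strain-divergent
sites.

Design choices (see docs/methods.md for rationale):

* Strain replacement acts at the whole-MAG level per animal -- the
  dominant strain switches -- not as per-site drift.
* The consensus-error rate substitutes a uniformly random different
  base, occasionally creating tri-allelic sites on purpose so the
  biallelic filter has work to do.
* Planted metabolite effects sit on strain-divergent sites of one MAG
  per metabolite, so the affected sites are mutually correlated -- the
  situation the LD-pruning step exists for.
* All randomness flows from one seed through named substreams, so each
  component can be regenerated independently.

Besides full studies, two focused panels back the calibration and
power analyses of the association scan: :func:`simulate_trait_panel`
(continuous traits with planted slopes) and
:func:`simulate_group_panel` (group-dependent allele shifts on the
logit scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BASES,
    FeatureTable,
    GeneRecord,
    SampleMeta,
    SiteKey,
    SnvCall,
    write_feature_table,
)
from .matrix import MISSING, BinarySnvGenotypes, SnvMatrix, encode_base

__all__ = [
    "SimulationConfig",
    "StudyTruth",
    "SyntheticStudy",
    "simulate_study",
    "null_study",
    "simulate_trait_panel",
    "simulate_group_panel",
]

_BASE_CODES = np.arange(4, dtype=np.int8)
# transition partner of each base code (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)
# the two transversion partners of each base code
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_animals_per_group: int = 12
    groups: tuple = ("CON", "RMT", "RFT")
    days: tuple = (15, 35, 56)
    n_mags: int = 6
    n_scaffolds_per_mag: int = 2
    scaffold_length: int = 10_000
    n_sites_per_mag: int = 200
    n_strains: int = 2
    strain_divergence: float = 0.2
    titv_ratio: float = 2.0
    consensus_error: float = 0.02
    missingness_by_day: tuple = ((15, 0.5), (35, 0.3), (56, 0.2))
    # transplantation-driven replacement
    n_rmt_mags: int = 2
    rmt_replacement_prob: float = 0.8
    # temporal strain turnover (strain 2 takes over with age)
    n_temporal_mags: int = 1
    temporal_strain2_prob_by_day: tuple = ((15, 0.1), (35, 0.6), (56, 0.9))
    baseline_strain2_prob: float = 0.5
    # metabolites and planted SNV effects
    n_metabolites: int = 20
    n_planted_snv_effects: int = 12
    n_effect_metabolites: int = 4
    effect_beta: float = 1.0
    day_gamma: float = 0.02  # per day, on the residual-SD scale
    planted_min_presence: float = 0.5
    # phenotypes
    n_continuous_phenotypes: int = 4
    phenotype_alpha: float = 0.8
    binary_phenotype: bool = True
    binary_intercept: float = 0.0
    binary_slope: float = 1.0
    # genes and pathways
    n_genes_per_mag: int = 200
    gene_length: int = 90
    gene_gap: int = 10
    n_pathways: int = 8
    enriched_pathway_size: int = 10
    enriched_hit_genes: int = 8
    total_hit_genes: int = 20

    def validate(self) -> None:
        for name in (
            "strain_divergence", "consensus_error", "rmt_replacement_prob",
            "baseline_strain2_prob", "planted_min_presence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        per_scaffold = self.n_genes_per_mag // self.n_scaffolds_per_mag
        needed = per_scaffold * (self.gene_length + self.gene_gap)
        if needed > self.scaffold_length:
            raise ValueError("genes do not fit on the configured scaffolds")
        if self.n_rmt_mags + self.n_temporal_mags > self.n_mags:
            raise ValueError("more special MAGs than MAGs")
        n_div = round(self.strain_divergence * self.n_sites_per_mag)
        if self.n_planted_snv_effects > 0:
            n_baseline = self.n_mags - self.n_rmt_mags - self.n_temporal_mags
            if n_baseline <= 0:
                raise ValueError("planted effects need at least one baseline MAG")
            if self.n_planted_snv_effects > n_baseline * n_div:
                raise ValueError(
                    "planted effects reference more divergent sites than exist"
                )


@dataclass
class StudyTruth:
    """Ground truth of a simulated study (JSON-serializable)."""

    config: dict
    samples: list  # [sample_id, animal_id, group, day]
    mags: list
    sites: dict  # mag -> list of [scaffold, position, ref_base]
    haplotypes: dict  # mag -> list of base strings, one per strain
    divergent_sites: dict  # mag -> site indices where strain 2 differs
    strain_assignment: dict  # mag -> {sample_id: strain index (0-based)}
    consensus: dict  # sample -> {mag: base string after consensus error}
    missing_sites: dict  # sample -> {mag: missing site indices}
    planted_effects: list  # {mag, site, metabolite, beta}
    rmt_mags: list
    temporal_mags: list
    enriched: dict  # {mag, pathway, hit_genes, pathway_genes}
    phenotype_spec: list  # {phenotype, metabolite, loading, kind}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def site_key(self, mag: str, index: int) -> SiteKey:
        scaffold, pos, ref = self.sites[mag][index]
        return SiteKey(scaffold, int(pos), ref)

    def consensus_matrix(self) -> "SnvMatrix":
        """The truth consensus matrix (masked entries missing)."""
        sample_ids = [s[0] for s in self.samples]
        site_keys: list[SiteKey] = []
        site_to_mag: dict[SiteKey, str] = {}
        blocks = []
        for mag in self.mags:
            keys = [self.site_key(mag, i) for i in range(len(self.sites[mag]))]
            site_keys.extend(keys)
            site_to_mag.update({k: mag for k in keys})
            block = np.full((len(keys), len(sample_ids)), MISSING, dtype=np.int8)
            for j, sid in enumerate(sample_ids):
                seq = np.frombuffer(
                    self.consensus[sid][mag].encode(), dtype=np.uint8
                )
                codes = np.searchsorted(
                    np.frombuffer(b"ACGT", dtype=np.uint8), seq
                ).astype(np.int8)
                codes[np.array(self.missing_sites[sid][mag], dtype=int)] = MISSING
                block[:, j] = codes
            blocks.append(block)
        consensus = np.concatenate(blocks, axis=0)
        return SnvMatrix(site_keys, sample_ids, consensus, site_to_mag)


@dataclass
class SyntheticStudy:
    """In-memory view of one simulated study plus its ground truth."""

    config: SimulationConfig
    meta: list
    calls_by_sample: dict
    bin_map: dict
    genes: list
    pathway_map: dict
    metabolites: FeatureTable
    phenotypes: FeatureTable
    truth: StudyTruth

    def to_matrix(self) -> SnvMatrix:
        """Consensus matrix built directly from truth (vectorized).

        Identical to reading the emitted per-sample tables back through
        the I/O layer (verified by the round-trip tests).
        """
        return self.truth.consensus_matrix()


def _substreams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _mutate(base: np.int8, rng: np.random.Generator, titv: float) -> np.int8:
    """A different base, transition with probability titv/(titv+1)."""
    if rng.random() < titv / (titv + 1.0):
        return _TRANSITION[base]
    return _TRANSVERSIONS[base][rng.integers(2)]


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticStudy:
    """Generate one complete study; optionally write all input files.

    Deterministic given ``config.seed``.  When ``out_dir`` is given the
    emitted files are exactly the dialects the I/O layer reads, plus
    ``truth.json`` and a ``manifest.json`` listing every path.
    """
    config.validate()
    rngs = _substreams(
        config.seed,
        ["structure", "strains", "assignment", "consensus", "mask",
         "metabolites", "phenotypes"],
    )

    groups = list(config.groups)
    days = list(config.days)
    miss_by_day = dict(config.missingness_by_day)
    temporal_prob = dict(config.temporal_strain2_prob_by_day)

    n_animals = config.n_animals_per_group * len(groups)
    animals = [f"A{i + 1:02d}" for i in range(n_animals)]
    group_of_animal = {
        a: groups[i // config.n_animals_per_group] for i, a in enumerate(animals)
    }
    meta = [
        SampleMeta(f"{a}_d{day}", a, group_of_animal[a], day)
        for a in animals
        for day in days
    ]
    sample_ids = [m.sample_id for m in meta]

    mags = [f"MAG{i + 1:02d}" for i in range(config.n_mags)]
    rmt_mags = mags[: config.n_rmt_mags]
    temporal_mags = mags[config.n_rmt_mags : config.n_rmt_mags + config.n_temporal_mags]
    baseline_mags = mags[config.n_rmt_mags + config.n_temporal_mags :]
    enriched_mag = rmt_mags[0] if rmt_mags else None

    # ---- genomic structure: scaffolds, genes, pathways -------------------
    rng = rngs["structure"]
    bin_map: dict[str, str] = {}
    genes: list[GeneRecord] = []
    pathway_map: dict[str, set[str]] = {}
    genes_by_mag: dict[str, list[GeneRecord]] = {m: [] for m in mags}
    pathways = [f"pw{i + 1:02d}" for i in range(config.n_pathways)]
    for mi, mag in enumerate(mags):
        scaffolds = [f"{mag}_s{j + 1}" for j in range(config.n_scaffolds_per_mag)]
        for sc in scaffolds:
            bin_map[sc] = mag
        per_scaffold = config.n_genes_per_mag // config.n_scaffolds_per_mag
        gi = 0
        for sc in scaffolds:
            for k in range(per_scaffold):
                start0 = k * (config.gene_length + config.gene_gap)
                cog = f"COG{mi + 1:02d}_{gi + 1:03d}"
                gene = GeneRecord(
                    gene_id=f"{mag}_g{gi + 1:03d}",
                    scaffold=sc,
                    start=start0,
                    end=start0 + config.gene_length,
                    strand="+" if gi % 2 == 0 else "-",
                    cog_id=cog,
                    product=f"hypothetical protein {gi + 1}",
                )
                genes.append(gene)
                genes_by_mag[mag].append(gene)
                if mag == enriched_mag and gi < config.enriched_pathway_size:
                    pw = pathways[0]
                else:
                    pw = pathways[1 + gi % (config.n_pathways - 1)]
                pathway_map.setdefault(cog, set()).add(pw)
                gi += 1

    # ---- sites and strain haplotypes ------------------------------------
    n_div = round(config.strain_divergence * config.n_sites_per_mag)
    sites: dict[str, list] = {}
    divergent: dict[str, list] = {}
    haplotypes: dict[str, np.ndarray] = {}  # (n_strains, n_sites) int8
    enriched_truth: dict = {}
    srng = rngs["strains"]
    for mag in mags:
        scaffolds = [f"{mag}_s{j + 1}" for j in range(config.n_scaffolds_per_mag)]
        mag_genes = genes_by_mag[mag]
        positions: list[tuple[str, int]] = []
        div_idx: list[int] = []
        if mag == enriched_mag and n_div > 0:
            # place the divergent sites inside a controlled set of hit genes:
            # some inside the planted pathway, the rest elsewhere
            pathway_genes = mag_genes[: config.enriched_pathway_size]
            in_path = pathway_genes[: config.enriched_hit_genes]
            n_out = config.total_hit_genes - len(in_path)
            out_path = mag_genes[
                config.enriched_pathway_size : config.enriched_pathway_size + n_out
            ]
            hit_genes = in_path + out_path
            taken: dict[str, set[int]] = {sc: set() for sc in scaffolds}
            for si in range(n_div):
                gene = hit_genes[si % len(hit_genes)]
                while True:
                    pos = int(srng.integers(gene.start, gene.end))
                    if pos not in taken[gene.scaffold]:
                        break
                taken[gene.scaffold].add(pos)
                positions.append((gene.scaffold, pos))
                div_idx.append(si)
            for si in range(n_div, config.n_sites_per_mag):
                while True:
                    sc = scaffolds[int(srng.integers(len(scaffolds)))]
                    pos = int(srng.integers(config.scaffold_length))
                    if pos not in taken[sc]:
                        break
                taken[sc].add(pos)
                positions.append((sc, pos))
            enriched_truth = {
                "mag": mag,
                "pathway": pathways[0],
                "hit_genes": [g.gene_id for g in hit_genes],
                "pathway_genes": [g.gene_id for g in pathway_genes],
            }
        else:
            per_scaffold = config.n_sites_per_mag // len(scaffolds)
            extra = config.n_sites_per_mag - per_scaffold * len(scaffolds)
            for j, sc in enumerate(scaffolds):
                n_here = per_scaffold + (1 if j < extra else 0)
                pos = srng.choice(config.scaffold_length, size=n_here, replace=False)
                positions.extend((sc, int(p)) for p in pos)
            div_idx = sorted(
                int(i)
                for i in srng.choice(
                    config.n_sites_per_mag, size=n_div, replace=False
                )
            )
        # canonical site order: by scaffold then position
        order = sorted(range(len(positions)), key=lambda i: positions[i])
        positions = [positions[i] for i in order]
        inv = {old: new for new, old in enumerate(order)}
        div_idx = sorted(inv[i] for i in div_idx)

        n_sites = len(positions)
        refs = srng.integers(4, size=n_sites).astype(np.int8)
        hap = np.empty((config.n_strains, n_sites), dtype=np.int8)
        # strain 1: the reference base half the time, a mutation otherwise
        for i in range(n_sites):
            if srng.random() < 0.5:
                hap[0, i] = refs[i]
            else:
                hap[0, i] = _mutate(refs[i], srng, config.titv_ratio)
        for s in range(1, config.n_strains):
            hap[s] = hap[0]
            idx = div_idx if s == 1 else sorted(
                int(i) for i in srng.choice(n_sites, size=n_div, replace=False)
            )
            for i in idx:
                hap[s, i] = _mutate(hap[0, i], srng, config.titv_ratio)
        sites[mag] = [
            [sc, pos, BASES[refs[i]]] for i, (sc, pos) in enumerate(positions)
        ]
        divergent[mag] = div_idx
        haplotypes[mag] = hap

    # ---- strain assignment per animal / MAG / day ------------------------
    arng = rngs["assignment"]
    assignment: dict[str, dict[str, int]] = {m: {} for m in mags}
    for mag in mags:
        u = {a: arng.random() for a in animals}
        for sm in meta:
            if mag in temporal_mags:
                strain = 1 if u[sm.animal_id] < temporal_prob[sm.day] else 0
            elif mag in rmt_mags:
                switched = (
                    sm.group == "RMT"
                    and u[sm.animal_id] < config.rmt_replacement_prob
                )
                strain = 1 if switched else 0
            else:
                strain = 1 if u[sm.animal_id] < config.baseline_strain2_prob else 0
            assignment[mag][sm.sample_id] = strain

    # ---- consensus sequences, errors, masks ------------------------------
    crng = rngs["consensus"]
    mrng = rngs["mask"]
    consensus: dict[str, dict[str, str]] = {}
    missing: dict[str, dict[str, list]] = {}
    for sm in meta:
        consensus[sm.sample_id] = {}
        missing[sm.sample_id] = {}
        for mag in mags:
            hap = haplotypes[mag][assignment[mag][sm.sample_id]].copy()
            if config.consensus_error > 0:
                flip = crng.random(hap.size) < config.consensus_error
                for i in np.flatnonzero(flip):
                    shift = 1 + int(crng.integers(3))
                    hap[i] = (hap[i] + shift) % 4
            mask = mrng.random(hap.size) < miss_by_day[sm.day]
            consensus[sm.sample_id][mag] = "".join(BASES[b] for b in hap)
            missing[sm.sample_id][mag] = [int(i) for i in np.flatnonzero(mask)]

    # ---- planted SNV -> metabolite effects -------------------------------
    met_rng = rngs["metabolites"]
    planted: list[dict] = []
    if config.n_planted_snv_effects > 0 and config.n_effect_metabolites > 0:
        per_met = -(-config.n_planted_snv_effects // config.n_effect_metabolites)
        met_ids = [f"met{j + 1:03d}" for j in range(config.n_metabolites)]
        effect = 0
        for j in range(config.n_effect_metabolites):
            mag = baseline_mags[j % len(baseline_mags)]
            # candidate divergent sites must survive the site filters on the
            # realized data (called often enough, still biallelic and common
            # after consensus errors), ranked by how often they are called
            presence: dict[int, float] = {}
            usable: dict[int, bool] = {}
            for i in divergent[mag]:
                called = [
                    consensus[s][mag][i]
                    for s in sample_ids
                    if i not in set(missing[s][mag])
                ]
                presence[i] = len(called) / len(sample_ids)
                tally = pd.Series(called).value_counts()
                usable[i] = (
                    len(tally) == 2 and tally.min() / tally.sum() >= 0.10
                )
            ranked = sorted(presence, key=lambda i: (-presence[i], i))
            chosen = [
                i for i in ranked
                if usable[i] and presence[i] >= config.planted_min_presence
            ][:per_met] or ranked[:per_met]
            for i in chosen:
                if effect >= config.n_planted_snv_effects:
                    break
                planted.append(
                    dict(
                        mag=mag,
                        site_index=int(i),
                        site=str(
                            SiteKey(
                                sites[mag][i][0], sites[mag][i][1], sites[mag][i][2]
                            )
                        ),
                        metabolite=met_ids[j],
                        beta=config.effect_beta,
                    )
                )
                effect += 1

    # ---- metabolites -----------------------------------------------------
    met_ids = [f"met{j + 1:03d}" for j in range(config.n_metabolites)]
    day_arr = np.array([sm.day for sm in meta], dtype=float)
    M = met_rng.standard_normal((len(meta), config.n_metabolites))
    M += config.day_gamma * (day_arr - np.mean(days))[:, None]
    for eff in planted:
        j = met_ids.index(eff["metabolite"])
        mag, i = eff["mag"], eff["site_index"]
        alt = haplotypes[mag][1][i]
        carries = np.array(
            [
                haplotypes[mag][assignment[mag][sid]][i] == alt
                for sid in sample_ids
            ],
            dtype=float,
        )
        M[:, j] += eff["beta"] * carries
    metabolites = FeatureTable(
        pd.DataFrame(M, index=sample_ids, columns=met_ids),
        kinds={m: "continuous" for m in met_ids},
    )

    # ---- phenotypes ------------------------------------------------------
    prng = rngs["phenotypes"]
    phen_cols: dict[str, np.ndarray] = {}
    phen_spec: list[dict] = []
    effect_mets = [f"met{j + 1:03d}" for j in range(config.n_effect_metabolites)]
    for k in range(config.n_continuous_phenotypes):
        met = effect_mets[k % len(effect_mets)] if effect_mets else met_ids[k]
        pid = f"phen{k + 1:02d}"
        phen_cols[pid] = (
            config.phenotype_alpha * M[:, met_ids.index(met)]
            + prng.standard_normal(len(meta))
        )
        phen_spec.append(
            dict(phenotype=pid, metabolite=met, loading=config.phenotype_alpha,
                 kind="continuous")
        )
    if config.binary_phenotype:
        met = effect_mets[0] if effect_mets else met_ids[0]
        lin = (
            config.binary_intercept
            + config.binary_slope * M[:, met_ids.index(met)]
        )
        prob = 1.0 / (1.0 + np.exp(-lin))
        phen_cols["phen_bin"] = (prng.random(len(meta)) < prob).astype(float)
        phen_spec.append(
            dict(phenotype="phen_bin", metabolite=met,
                 loading=config.binary_slope, kind="binary")
        )
    phenotypes = FeatureTable(
        pd.DataFrame(phen_cols, index=sample_ids),
        kinds={p["phenotype"]: p["kind"] for p in phen_spec},
    )

    # ---- per-sample SNV calls -------------------------------------------
    calls_by_sample: dict[str, list[SnvCall]] = {}
    for sm in meta:
        calls: list[SnvCall] = []
        for mag in mags:
            seq = consensus[sm.sample_id][mag]
            gone = set(missing[sm.sample_id][mag])
            for i, (sc, pos, ref) in enumerate(sites[mag]):
                if i in gone:
                    continue
                calls.append(SnvCall(sc, pos, ref, seq[i], "SNV"))
        calls_by_sample[sm.sample_id] = calls

    truth = StudyTruth(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        samples=[[m.sample_id, m.animal_id, m.group, m.day] for m in meta],
        mags=mags,
        sites=sites,
        haplotypes={
            m: ["".join(BASES[b] for b in row) for row in haplotypes[m]]
            for m in mags
        },
        divergent_sites=divergent,
        strain_assignment=assignment,
        consensus=consensus,
        missing_sites=missing,
        planted_effects=planted,
        rmt_mags=rmt_mags,
        temporal_mags=temporal_mags,
        enriched=enriched_truth,
        phenotype_spec=phen_spec,
    )
    study = SyntheticStudy(
        config=config,
        meta=meta,
        calls_by_sample=calls_by_sample,
        bin_map=bin_map,
        genes=genes,
        pathway_map=pathway_map,
        metabolites=metabolites,
        phenotypes=phenotypes,
        truth=truth,
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def null_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticStudy:
    """The same study with all planted structure switched off.

    Effects are zeroed, no transplantation replacement, no temporal
    turnover, no enriched pathway -- the input of the type-I-error and
    calibration suites.
    """
    import dataclasses

    cfg = dataclasses.replace(
        config,
        n_rmt_mags=0,
        n_temporal_mags=0,
        n_planted_snv_effects=0,
        n_effect_metabolites=0,
        effect_beta=0.0,
        phenotype_alpha=0.0,
        binary_slope=0.0,
    )
    return simulate_study(cfg, out_dir=out_dir)


def _write_study(study: SyntheticStudy, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    snv_dir = out_dir / "snv"
    snv_dir.mkdir(exist_ok=True)
    manifest: dict[str, object] = {"snv_tables": {}}

    for sid, calls in study.calls_by_sample.items():
        path = snv_dir / f"{sid}.tsv"
        with open(path, "w") as fh:
            fh.write("scaffold\tposition\tref_base\tcon_base\tclass\tposition_coverage\n")
            for c in calls:
                fh.write(
                    f"{c.scaffold}\t{c.position}\t{c.ref_base}\t{c.con_base}\t"
                    f"{c.snv_class}\t.\n"
                )
        manifest["snv_tables"][sid] = str(path.relative_to(out_dir))

    stb = out_dir / "scaffold_to_bin.tsv"
    with open(stb, "w") as fh:
        for sc in sorted(study.bin_map):
            fh.write(f"{sc}\t{study.bin_map[sc]}\n")
    manifest["scaffold_to_bin"] = stb.name

    genes_path = out_dir / "genes.tsv"
    with open(genes_path, "w") as fh:
        fh.write("gene_id\tscaffold\tstart\tend\tstrand\tcog_id\tproduct\n")
        for g in study.genes:
            fh.write(
                f"{g.gene_id}\t{g.scaffold}\t{g.start + 1}\t{g.end}\t{g.strand}\t"
                f"{g.cog_id or ''}\t{g.product or ''}\n"
            )
    manifest["genes"] = genes_path.name

    pw_path = out_dir / "pathways.tsv"
    with open(pw_path, "w") as fh:
        for cog in sorted(study.pathway_map):
            for pw in sorted(study.pathway_map[cog]):
                fh.write(f"{cog}\t{pw}\n")
    manifest["pathways"] = pw_path.name

    meta_path = out_dir / "metadata.tsv"
    with open(meta_path, "w") as fh:
        fh.write("sample_id\tanimal_id\tgroup\tday\n")
        for m in study.meta:
            fh.write(f"{m.sample_id}\t{m.animal_id}\t{m.group}\t{m.day}\n")
    manifest["metadata"] = meta_path.name

    write_feature_table(study.metabolites, out_dir / "metabolites.tsv")
    write_feature_table(study.phenotypes, out_dir / "phenotypes.tsv")
    manifest["metabolites"] = "metabolites.tsv"
    manifest["phenotypes"] = "phenotypes.tsv"

    study.truth.to_json(out_dir / "truth.json")
    manifest["truth"] = "truth.json"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# focused panels for scan calibration and power
# ---------------------------------------------------------------------------


def _panel_meta(n_samples: int, groups=("CON", "RMT", "RFT"), days=(15, 35, 56)):
    meta = []
    per_group = n_samples // len(groups)
    for i in range(n_samples):
        g = groups[min(i // per_group, len(groups) - 1)]
        day = days[i % len(days)]
        meta.append(SampleMeta(f"S{i + 1:03d}", f"S{i + 1:03d}", g, day))
    return meta


def _panel_genotypes(
    g_true: np.ndarray, missingness: float, rng: np.random.Generator,
    mags_per_block: int = 10,
) -> BinarySnvGenotypes:
    n_sites, n_samples = g_true.shape
    geno = g_true.astype(np.float32)
    if missingness > 0:
        mask = rng.random(geno.shape) < missingness
        geno[mask] = np.nan
    site_keys = [SiteKey(f"panel_s{i // 100 + 1}", i % 100 * 10, "A") for i in range(n_sites)]
    site_to_mag = {
        k: f"PMAG{i // mags_per_block + 1:02d}" for i, k in enumerate(site_keys)
    }
    n_called = (~np.isnan(geno)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        maf = np.nansum(geno, axis=1) / np.maximum(n_called, 1)
    return BinarySnvGenotypes(
        site_keys=site_keys,
        sample_ids=[f"S{i + 1:03d}" for i in range(n_samples)],
        genotype=geno,
        allele_map=[("A", "C")] * n_sites,
        presence_fraction=n_called / n_samples,
        minor_allele_fraction=np.minimum(maf, 1 - maf),
        site_to_mag=site_to_mag,
    )


def simulate_trait_panel(
    seed: int,
    n_samples: int = 120,
    n_sites: int = 100,
    n_traits: int = 50,
    n_causal: int = 50,
    beta: float = 1.0,
    missingness: float = 0.2,
    maf_range: tuple = (0.3, 0.5),
    day_gamma: float = 0.02,
):
    """Genotype/trait panel with planted slopes for power analyses.

    The default allele-frequency range covers common variants (MAF
    0.3-0.5), the regime in which single-site effects of one residual
    SD are detectable at study-wide FDR control with ~100 usable
    samples; the calibration suite uses the same panel with all slopes
    zeroed.

    Site ``i`` (for ``i < n_causal``) drives trait ``i`` with slope
    ``beta`` in residual-SD units; traits carry a linear day effect and
    unit Gaussian noise.  The planted effect acts through the complete
    genotype; missingness is applied only to the measured matrix.
    """
    if n_causal > min(n_sites, n_traits):
        raise ValueError("n_causal exceeds the panel dimensions")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    meta = _panel_meta(n_samples)
    days = np.array([m.day for m in meta], dtype=float)
    maf = rng.uniform(*maf_range, size=n_sites)
    g_true = (rng.random((n_sites, n_samples)) < maf[:, None]).astype(float)
    geno = _panel_genotypes(g_true, missingness, rng)
    T = rng.standard_normal((n_samples, n_traits))
    T += day_gamma * (days - days.mean())[:, None]
    for i in range(n_causal):
        T[:, i] += beta * g_true[i]
    trait_ids = [f"trait{j + 1:03d}" for j in range(n_traits)]
    traits = FeatureTable(
        pd.DataFrame(T, index=geno.sample_ids, columns=trait_ids),
        kinds={t: "continuous" for t in trait_ids},
    )
    causal = [
        (str(geno.site_keys[i]), trait_ids[i], beta) for i in range(n_causal)
    ]
    return geno, traits, meta, causal


def simulate_group_panel(
    seed: int,
    n_samples: int = 120,
    n_sites: int = 100,
    n_causal: int = 50,
    log_odds: float = 2.0,
    base_prob: float = 0.3,
    missingness: float = 0.2,
    shifted_group: str = "RMT",
):
    """Genotype panel with a group-dependent allele shift on the logit scale.

    The first ``n_causal`` sites carry allele probability
    ``sigmoid(logit(base_prob) + log_odds)`` in the shifted group and
    ``base_prob`` elsewhere; the remaining sites are null.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    meta = _panel_meta(n_samples)
    in_shift = np.array([m.group == shifted_group for m in meta])
    logit0 = np.log(base_prob / (1 - base_prob))
    p_shift = 1.0 / (1.0 + np.exp(-(logit0 + log_odds)))
    probs = np.full((n_sites, n_samples), base_prob)
    probs[:n_causal, in_shift] = p_shift
    g_true = (rng.random((n_sites, n_samples)) < probs).astype(float)
    geno = _panel_genotypes(g_true, missingness, rng)
    causal = [str(geno.site_keys[i]) for i in range(n_causal)]
    return geno, meta, causal
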