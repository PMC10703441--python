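"""Synthetic input generation with controllable planted structure.

Everything the pipeline consumes can be generated here: block-structured
marker maps with cis-dominated eQTLs, GWAS p-values with Beta(a, 1) signal
planted in the eSNPs of chosen gene sets, overlapping gene-set collections,
directed acyclic regulatory networks with planted hub drivers, paired
species with a 1:1 ortholog core, and expression/trait matrices with a
target driver-trait correlation. All outputs are pure functions of their
configuration: a fixed seed reproduces them byte-identically.

Genomic coordinates are abstracted away — LD blocks are index partitions and
cis-ness is a label — because downstream stages only use block membership
and gene-marker links.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    GeneSetCollection,
    write_expression,
    write_gmt,
    write_json,
    write_network,
    write_trait,
)

__all__ = [
    "ConfigError",
    "PlantedSet",
    "SimConfig",
    "PlannedSet",
    "SharePlan",
    "Bundle",
    "SpeciesPairBundle",
    "stage_rng",
    "gene_ids",
    "gen_genome",
    "gen_gwas",
    "gen_gene_sets",
    "gen_network",
    "gen_expression_trait",
    "gen_bundle",
    "gen_species_pair",
]

DEFAULT_TISSUE = "synthetic"


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


def stage_rng(seed: int, *tags) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed."""
    digest = hashlib.sha256("|".join(str(t) for t in tags).encode()).digest()
    return np.random.default_rng([int(seed), int.from_bytes(digest[:8], "little")])


@dataclass(frozen=True)
class PlantedSet:
    """A gene set with Beta(a, 1)-distributed GWAS signal in its eSNPs.

    ``enrichment_alpha == 1`` is the null (uniform p-values). ``planted_kd``
    optionally names a member gene to wire as a network hub whose
    out-neighborhood is enriched for the set.
    """

    set_id: str
    member_genes: tuple
    enrichment_alpha: float = 1.0
    shared_across_species: bool = False
    planted_kd: str | None = None

    def __post_init__(self):
        if not self.member_genes:
            raise ConfigError(f"planted set {self.set_id!r}: member_genes is empty")
        if not 0.0 < self.enrichment_alpha <= 1.0:
            raise ConfigError(
                f"planted set {self.set_id!r}: enrichment_alpha must be in (0, 1], "
                f"got {self.enrichment_alpha}"
            )
        object.__setattr__(self, "member_genes", tuple(self.member_genes))


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 1000
    n_markers: int = 5000
    block_size: int = 5
    cis_per_gene: int = 2
    trans_fraction: float = 0.1
    n_sets: int = 50
    set_size_range: tuple = (10, 50)
    planted_sets: tuple = ()
    seed: int = 0
    species_tag: str = "human"
    tissue: str = DEFAULT_TISSUE
    # network knobs
    attach_per_node: int = 2
    kd_out_degree: int = 20
    kd_member_fraction: float = 0.6
    # gene-set collection knobs
    overlap_pairs: tuple = ()
    decoys_exclude_planted: bool = False
    # expression knobs (n_samples == 0 disables expression/trait output)
    n_samples: int = 0
    expression_r: float = 0.8
    n_expression_decoys: int = 50

    def __post_init__(self):
        for name in ("n_genes", "n_markers", "block_size", "cis_per_gene"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive count, got {getattr(self, name)}")
        if self.n_sets < 0:
            raise ConfigError(f"n_sets must be >= 0, got {self.n_sets}")
        if self.n_markers < self.block_size:
            raise ConfigError(
                f"n_markers ({self.n_markers}) must be >= block_size ({self.block_size})"
            )
        if not 0.0 <= self.trans_fraction <= 1.0:
            raise ConfigError(f"trans_fraction must be in [0, 1], got {self.trans_fraction}")
        lo, hi = self.set_size_range
        if not (2 <= lo <= hi <= self.n_genes):
            raise ConfigError(
                f"set_size_range {self.set_size_range} must lie within [2, n_genes={self.n_genes}]"
            )
        if self.species_tag not in ("human", "mouse"):
            raise ConfigError(f"species_tag must be 'human' or 'mouse', got {self.species_tag!r}")
        if not 0.0 < self.kd_member_fraction < 1.0:
            raise ConfigError(
                f"kd_member_fraction must be in (0, 1), got {self.kd_member_fraction}"
            )
        if self.cis_per_gene > self.n_markers:
            raise ConfigError("cis_per_gene cannot exceed n_markers")
        object.__setattr__(self, "planted_sets", tuple(self.planted_sets))
        object.__setattr__(self, "overlap_pairs", tuple(tuple(p) for p in self.overlap_pairs))
        universe = set(gene_ids(self))
        for planted in self.planted_sets:
            unknown = sorted(set(planted.member_genes) - universe)
            if unknown:
                raise ConfigError(
                    f"planted set {planted.set_id!r}: genes outside the universe: {unknown[:5]}"
                )
            if planted.planted_kd is not None and planted.planted_kd not in universe:
                raise ConfigError(
                    f"planted set {planted.set_id!r}: planted_kd {planted.planted_kd!r} "
                    "outside the universe"
                )


def gene_ids(config: SimConfig) -> list[str]:
    """Species-convention gene symbols: upper-case (human) or title-case (mouse)."""
    stem = "GENE" if config.species_tag == "human" else "Gene"
    return [f"{stem}{i:05d}" for i in range(config.n_genes)]


def marker_ids(config: SimConfig) -> list[str]:
    return [f"M{i:06d}" for i in range(config.n_markers)]


def gen_genome(config: SimConfig):
    """Markers, LD-block assignment and eQTL map.

    Markers are partitioned into contiguous blocks of ``block_size`` (the
    last block may be smaller). Each gene receives ``cis_per_gene`` distinct
    markers spread evenly along the marker axis, plus
    ``floor(trans_fraction * n_genes)`` random trans gene-marker pairs.
    """
    markers = marker_ids(config)
    genes = gene_ids(config)
    ld = {m: f"B{i // config.block_size:05d}" for i, m in enumerate(markers)}
    rng = stage_rng(config.seed, "genome", config.species_tag)

    records = []
    seen = set()
    for i, gene in enumerate(genes):
        start = (i * config.n_markers) // config.n_genes
        for j in range(config.cis_per_gene):
            marker = markers[(start + j) % config.n_markers]
            if (marker, gene) not in seen:
                seen.add((marker, gene))
                records.append((marker, gene, "cis"))

    n_trans = math.floor(config.trans_fraction * config.n_genes)
    attempts = 0
    added = 0
    while added < n_trans and attempts < 50 * max(n_trans, 1):
        attempts += 1
        gene = genes[int(rng.integers(config.n_genes))]
        marker = markers[int(rng.integers(config.n_markers))]
        if (marker, gene) in seen:
            continue
        seen.add((marker, gene))
        records.append((marker, gene, "trans"))
        added += 1

    fdr = rng.uniform(0.0, 0.05, size=len(records))
    eqtl = pd.DataFrame(
        {
            "MARKER": [r[0] for r in records],
            "GENE": [r[1] for r in records],
            "TISSUE": config.tissue,
            "CIS_TRANS": [r[2] for r in records],
            "FDR": fdr,
        }
    )
    return markers, ld, eqtl


def gen_gwas(eqtl: pd.DataFrame, planted, config: SimConfig) -> pd.DataFrame:
    """GWAS p-values: Uniform(0,1) null with Beta(a, 1) planted in the
    eSNPs of planted-set genes; markers hit by several sets take the
    smallest a. Sampling uses the inverse-CDF transform p = U**(1/a) so the
    a == 1 case is exactly the uniform draw."""
    eqtl_genes = set(eqtl["GENE"])
    alpha_by_marker: dict[str, float] = {}
    for p_set in planted:
        unknown = sorted(set(p_set.member_genes) - eqtl_genes)
        if unknown:
            raise ConfigError(
                f"planted set {p_set.set_id!r}: genes without eQTL records: {unknown[:10]}"
            )
        members = set(p_set.member_genes)
        hit = eqtl.loc[eqtl["GENE"].isin(members), "MARKER"]
        for marker in hit:
            a = alpha_by_marker.get(marker, 1.0)
            alpha_by_marker[marker] = min(a, p_set.enrichment_alpha)

    markers = marker_ids(config)
    rng = stage_rng(config.seed, "gwas", config.species_tag)
    p = rng.uniform(size=len(markers))
    if alpha_by_marker:
        idx = {m: i for i, m in enumerate(markers)}
        for marker, a in alpha_by_marker.items():
            if a < 1.0 and marker in idx:
                p[idx[marker]] = p[idx[marker]] ** (1.0 / a)
    return pd.DataFrame({"MARKER": markers, "PVALUE": p})


def gen_gene_sets(config: SimConfig, exclude=()) -> GeneSetCollection:
    """Random decoy sets, engineered overlap pairs, and the planted sets.

    ``config.overlap_pairs`` holds ``(size_a, size_b, fraction)`` triples;
    each yields a pair sharing exactly ``round(fraction * min(sizes))``
    genes. Decoys avoid *exclude* (and planted members when
    ``decoys_exclude_planted`` is set).
    """
    genes = np.array(gene_ids(config))
    excluded = set(exclude)
    if config.decoys_exclude_planted:
        for p_set in config.planted_sets:
            excluded |= set(p_set.member_genes)
    pool = np.array([g for g in genes if g not in excluded])
    rng = stage_rng(config.seed, "gene_sets", config.species_tag)
    lo, hi = config.set_size_range

    sets: dict[str, tuple] = {}
    descriptions: dict[str, str] = {}
    for k in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        if size > pool.size:
            raise ConfigError(
                f"decoy pool ({pool.size} genes) smaller than requested set size {size}"
            )
        members = rng.choice(pool, size=size, replace=False)
        sets[f"RAND{k:04d}"] = tuple(sorted(members))
        descriptions[f"RAND{k:04d}"] = "random decoy set"

    for k, (size_a, size_b, fraction) in enumerate(config.overlap_pairs, start=1):
        if not 0.0 <= fraction <= 1.0:
            raise ConfigError(f"overlap fraction must be in [0, 1], got {fraction}")
        n_shared = round(fraction * min(size_a, size_b))
        need = size_a + size_b - n_shared
        if need > pool.size:
            raise ConfigError("overlap pair larger than available gene pool")
        draw = rng.choice(pool, size=need, replace=False)
        shared = draw[:n_shared]
        only_a = draw[n_shared:size_a]
        only_b = draw[size_a:]
        sets[f"OVL{k:02d}A"] = tuple(sorted(np.concatenate([shared, only_a])))
        sets[f"OVL{k:02d}B"] = tuple(sorted(np.concatenate([shared, only_b])))
        descriptions[f"OVL{k:02d}A"] = f"engineered overlap pair {k} (fraction {fraction})"
        descriptions[f"OVL{k:02d}B"] = f"engineered overlap pair {k} (fraction {fraction})"

    for p_set in config.planted_sets:
        if p_set.set_id in sets:
            raise ConfigError(f"duplicate set id {p_set.set_id!r}")
        sets[p_set.set_id] = tuple(sorted(p_set.member_genes))
        descriptions[p_set.set_id] = "planted set"

    return GeneSetCollection(sets, descriptions)


def gen_network(config: SimConfig, planted=None) -> pd.DataFrame:
    """Directed acyclic network with planted hub drivers.

    A preferential-attachment DAG is grown over a topological order in which
    planted key drivers come first (and are excluded from the attachment
    pool, so their connectivity is fully controlled). Each planted driver
    then receives ``kd_out_degree`` out-edges of which at least
    ``kd_member_fraction`` point at members of its planted set.
    """
    planted = config.planted_sets if planted is None else tuple(planted)
    genes = gene_ids(config)
    universe = set(genes)
    kd_list = []
    kd_sets: dict[str, PlantedSet] = {}
    for p_set in planted:
        if p_set.planted_kd is None:
            continue
        if p_set.planted_kd not in universe:
            raise ConfigError(
                f"planted_kd {p_set.planted_kd!r} not in the gene universe"
            )
        if p_set.planted_kd not in kd_sets:
            kd_list.append(p_set.planted_kd)
        kd_sets[p_set.planted_kd] = p_set

    rng = stage_rng(config.seed, "network", config.species_tag)
    others = [g for g in genes if g not in kd_sets]
    order = kd_list + [others[i] for i in rng.permutation(len(others))]
    pos = {g: i for i, g in enumerate(order)}
    n_kd = len(kd_list)

    edges: set = set()
    attach_pool: list[int] = []
    for j in range(n_kd, len(order)):
        if j == n_kd:
            attach_pool.append(j)
            continue
        m = min(config.attach_per_node, j - n_kd)
        chosen: set = set()
        guard = 0
        while len(chosen) < m and guard < 100 * m:
            guard += 1
            pick = attach_pool[int(rng.integers(len(attach_pool)))]
            if pick != j:
                chosen.add(pick)
        while len(chosen) < m:
            pick = int(rng.integers(n_kd, j))
            chosen.add(pick)
        for parent in chosen:
            edges.add((order[parent], order[j]))
            attach_pool.append(parent)
            attach_pool.append(j)
        if m == 0:
            attach_pool.append(j)

    for kd in kd_list:
        p_set = kd_sets[kd]
        members = [g for g in p_set.member_genes if g != kd and pos[g] > pos[kd]]
        n_member_edges = math.ceil(config.kd_member_fraction * config.kd_out_degree)
        if len(members) < n_member_edges:
            raise ConfigError(
                f"planted set {p_set.set_id!r} too small for enrichment fraction "
                f"{config.kd_member_fraction} at out-degree {config.kd_out_degree} "
                f"({len(members)} eligible members, {n_member_edges} needed)"
            )
        member_targets = rng.choice(len(members), size=n_member_edges, replace=False)
        targets = {members[int(t)] for t in member_targets}
        non_members = [g for g in order[pos[kd] + 1:]
                       if g not in set(p_set.member_genes) and g not in kd_sets]
        n_fill = config.kd_out_degree - n_member_edges
        if n_fill > 0 and non_members:
            fill_idx = rng.choice(len(non_members), size=min(n_fill, len(non_members)),
                                  replace=False)
            targets |= {non_members[int(t)] for t in fill_idx}
        for target in targets:
            edges.add((kd, target))

    df = pd.DataFrame(sorted(edges), columns=["SRC", "DST"])
    df["WEIGHT"] = 1.0
    return df


def gen_expression_trait(
    kd_genes,
    r_target: float,
    n_samples: int,
    seed: int,
    other_genes=(),
    noise_sd: float | None = None,
):
    """Expression matrix and a trait correlated with each driver gene.

    The trait is the sum of the drivers' (standard-normal) expression plus
    Gaussian noise scaled so the population Pearson correlation with each
    driver equals *r_target* (feasible only when ``r_target**2 <= 1/k`` for
    k drivers). Non-driver genes are independent noise. *noise_sd*
    overrides the derived noise scale (0 gives an exact linear trait).
    """
    kd_genes = list(kd_genes)
    other_genes = [g for g in other_genes if g not in set(kd_genes)]
    if n_samples < 4:
        raise ConfigError(f"n_samples must be >= 4, got {n_samples}")
    if abs(r_target) >= 1.0:
        raise ConfigError(f"|r_target| must be < 1, got {r_target}")
    if not kd_genes:
        raise ConfigError("kd_genes is empty")
    k = len(kd_genes)
    rng = stage_rng(seed, "expression")
    z = rng.standard_normal((k, n_samples))
    sign = 1.0 if r_target >= 0 else -1.0
    if noise_sd is not None:
        trait = sign * (z.sum(axis=0) + noise_sd * rng.standard_normal(n_samples))
    elif r_target == 0.0:
        trait = rng.standard_normal(n_samples)
    else:
        var_noise = 1.0 / r_target**2 - k
        if var_noise < 0:
            raise ConfigError(
                f"|r_target|={abs(r_target)} infeasible for {k} driver genes "
                f"(max 1/sqrt(k) = {1 / math.sqrt(k):.4f})"
            )
        trait = sign * (z.sum(axis=0) + math.sqrt(var_noise) * rng.standard_normal(n_samples))
    noise = rng.standard_normal((len(other_genes), n_samples))
    samples = [f"S{i:04d}" for i in range(n_samples)]
    expr = pd.DataFrame(
        np.vstack([z, noise]) if other_genes else z,
        index=kd_genes + other_genes,
        columns=samples,
    )
    expr.index.name = "GENE"
    return expr, pd.Series(trait, index=samples, name="VALUE")


@dataclass
class Bundle:
    """All pipeline inputs for one species, plus the planted-structure truth."""

    config: SimConfig
    markers: list
    ld: dict
    eqtl: pd.DataFrame
    gwas: pd.DataFrame
    gene_sets: GeneSetCollection
    network: pd.DataFrame
    expression: pd.DataFrame | None = None
    trait: pd.Series | None = None
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
        self.eqtl.to_csv(outdir / "eqtl.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"MARKER": list(self.ld), "BLOCK": list(self.ld.values())}
        ).to_csv(outdir / "ld.tsv", sep="\t", index=False)
        write_gmt(self.gene_sets, outdir / "gene_sets.gmt")
        write_network(self.network, outdir / "network.tsv")
        if self.expression is not None:
            write_expression(self.expression, outdir / "expression.tsv")
        if self.trait is not None:
            write_trait(self.trait, outdir / "trait.tsv")
        write_json(self.truth, outdir / "truth.json")
        return outdir


def _truth_record(config: SimConfig) -> dict:
    return {
        "species_tag": config.species_tag,
        "seed": config.seed,
        "planted_sets": [
            {
                "set_id": p.set_id,
                "member_genes": sorted(p.member_genes),
                "enrichment_alpha": p.enrichment_alpha,
                "shared_across_species": p.shared_across_species,
                "planted_kd": p.planted_kd,
            }
            for p in config.planted_sets
        ],
    }


def gen_bundle(config: SimConfig) -> Bundle:
    """Generate a complete, self-consistent input bundle for one species."""
    markers, ld, eqtl = gen_genome(config)
    gwas = gen_gwas(eqtl, config.planted_sets, config)
    gene_sets = gen_gene_sets(config)
    network = gen_network(config, config.planted_sets)
    expression = trait = None
    kd_genes = [p.planted_kd for p in config.planted_sets if p.planted_kd]
    if config.n_samples > 0 and kd_genes:
        rng = stage_rng(config.seed, "expression_decoys", config.species_tag)
        non_kd = [g for g in gene_ids(config) if g not in set(kd_genes)]
        n_decoys = min(config.n_expression_decoys, len(non_kd))
        decoys = [non_kd[i] for i in sorted(rng.permutation(len(non_kd))[:n_decoys])]
        expression, trait = gen_expression_trait(
            kd_genes, config.expression_r, config.n_samples,
            seed=config.seed, other_genes=decoys,
        )
    return Bundle(
        config=config, markers=markers, ld=ld, eqtl=eqtl, gwas=gwas,
        gene_sets=gene_sets, network=network, expression=expression,
        trait=trait, truth=_truth_record(config),
    )


@dataclass(frozen=True)
class PlannedSet:
    """Blueprint for one planted set inside a species-pair design."""

    set_id: str
    size: int
    enrichment_alpha: float = 0.2
    kd: bool = False


@dataclass(frozen=True)
class SharePlan:
    """Which planted sets are shared across the pair vs species-specific.

    All planned sets draw from disjoint slices of the ortholog core so a
    species-specific set has zero gene overlap with anything planted in the
    other species.
    """

    shared: tuple = ()
    specific_a: tuple = ()
    specific_b: tuple = ()


@dataclass
class SpeciesPairBundle:
    species_a: Bundle
    species_b: Bundle
    ortholog_table: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.species_a.write(outdir / "species_a")
        self.species_b.write(outdir / "species_b")
        self.ortholog_table.to_csv(outdir / "orthologs.tsv", sep="\t", index=False)
        write_json(self.truth, outdir / "truth.json")
        return outdir


def gen_species_pair(
    config_a: SimConfig,
    config_b: SimConfig,
    share_plan: SharePlan,
) -> SpeciesPairBundle:
    """Two complete bundles with an ortholog core and a shared/specific design.

    Shared planted sets are ortholog-identical gene lists (species-specific
    id conventions); specific sets have no counterpart. The truth record
    lists exactly the planned ids.
    """
    ids_a = gene_ids(config_a)
    ids_b = gene_ids(config_b)
    if set(ids_a) & set(ids_b):
        raise ConfigError(
            "gene id collision across species conventions; use distinct species_tag values"
        )
    core = min(len(ids_a), len(ids_b))
    plans = list(share_plan.shared) + list(share_plan.specific_a) + list(share_plan.specific_b)
    need = sum(p.size for p in plans)
    if need > core:
        raise ConfigError(
            f"share plan needs {need} ortholog-core genes but only {core} exist"
        )
    rng = stage_rng(config_a.seed, "share_plan", config_b.seed)
    perm = rng.permutation(core)
    cursor = 0
    slices: dict[str, np.ndarray] = {}
    for plan in plans:
        slices[plan.set_id] = np.sort(perm[cursor:cursor + plan.size])
        cursor += plan.size

    def planted_for(plans_here, shared_flags, ids):
        out = []
        for plan, shared in zip(plans_here, shared_flags):
            members = tuple(ids[i] for i in slices[plan.set_id])
            out.append(PlantedSet(
                set_id=plan.set_id,
                member_genes=members,
                enrichment_alpha=plan.enrichment_alpha,
                shared_across_species=shared,
                planted_kd=members[0] if plan.kd else None,
            ))
        return tuple(out)

    planted_a = planted_for(
        list(share_plan.shared) + list(share_plan.specific_a),
        [True] * len(share_plan.shared) + [False] * len(share_plan.specific_a),
        ids_a,
    )
    planted_b = planted_for(
        list(share_plan.shared) + list(share_plan.specific_b),
        [True] * len(share_plan.shared) + [False] * len(share_plan.specific_b),
        ids_b,
    )
    bundle_a = gen_bundle(dataclasses.replace(config_a, planted_sets=planted_a))
    bundle_b = gen_bundle(dataclasses.replace(config_b, planted_sets=planted_b))
    orthologs = pd.DataFrame({"GENE_A": ids_a[:core], "GENE_B": ids_b[:core]})
    truth = {
        "shared": [p.set_id for p in share_plan.shared],
        "specific_a": [p.set_id for p in share_plan.specific_a],
        "specific_b": [p.set_id for p in share_plan.specific_b],
        "species_a": _truth_record(bundle_a.config),
        "species_b": _truth_record(bundle_b.config),
    }
    return SpeciesPairBundle(species_a=bundle_a, species_b=bundle_b,
                             ortholog_table=orthologs, truth=truth)
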