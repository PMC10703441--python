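"""End-to-end pipeline: mapping -> MSEA -> supersets -> matching -> KDA.

A single YAML-style configuration dictionary drives the whole run. One
master seed governs every stochastic stage through stage-name-keyed
derivation, so re-running an identical configuration reproduces identical
outputs byte for byte. Every stage writes plain TSV/JSON plus a manifest
with the configuration hash and row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .cross_species import OrthologTable, match_supersets
from .kda import (
    RegulatoryNetwork,
    extract_subnetwork,
    flag_gwas_hits,
    kd_trait_correlation,
    kda_test,
)
from .msea import MseaContext, make_grid, msea_test
from .supersets import annotate_set, confirm_supersets, merge_supersets

log = logging.getLogger(__name__)

__all__ = ["PipelineError", "DEFAULT_THRESHOLDS", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_THRESHOLDS = {
    "eqtl_fdr": 0.05,
    "msea_fdr": 0.05,
    "merge_ratio": 0.33,
    "merge_alpha": 0.05,
    "match_jaccard": 0.5,
    "match_one_sided": 0.9,
    "kda_fdr": 0.05,
    "corr_p": 0.05,
}

DEFAULT_GRID = {"n": 10, "f_top": 0.5, "f_bottom": 0.001, "spacing": "log"}

_REQUIRED_SPECIES_KEYS = ("gwas", "eqtl", "ld", "gene_sets")


def stage_seed(seed: int, *tags) -> int:
    digest = hashlib.sha256("|".join(str(t) for t in ("stage", seed, *tags)).encode())
    return int.from_bytes(digest.digest()[:4], "little")


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def validate_config(config: dict, base_dir: str | Path = ".") -> dict:
    """Fill defaults, check thresholds and that every input path is readable."""
    base_dir = Path(base_dir)
    cfg = dict(config)
    cfg["seed"] = int(cfg.get("seed", 0))
    cfg["n_perm"] = int(cfg.get("n_perm", 1000))
    cfg["kappa"] = float(cfg.get("kappa", 1.0))
    cfg["top_kds"] = int(cfg.get("top_kds", 5))
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    for name, value in thresholds.items():
        if name not in DEFAULT_THRESHOLDS:
            raise PipelineError(f"stage 'validate': unknown threshold {name!r}")
        if not 0.0 < float(value) <= 1.0:
            raise PipelineError(
                f"stage 'validate': threshold {name}={value} outside (0, 1]"
            )
    cfg["thresholds"] = {k: float(v) for k, v in thresholds.items()}
    cfg["grid"] = {**DEFAULT_GRID, **cfg.get("grid", {})}
    species = cfg.get("species")
    if not species:
        raise PipelineError("stage 'validate': config has no 'species' section")
    if len(species) > 2:
        raise PipelineError("stage 'validate': at most two species are supported")

    def resolve(path):
        p = Path(path)
        return p if p.is_absolute() else base_dir / p

    for name, spec in species.items():
        for key in _REQUIRED_SPECIES_KEYS:
            if key not in spec:
                raise PipelineError(
                    f"stage 'validate': species {name!r} missing input {key!r}"
                )
        for key in (*_REQUIRED_SPECIES_KEYS, "network", "expression", "trait"):
            if spec.get(key):
                path = resolve(spec[key])
                if not path.is_file():
                    raise PipelineError(
                        f"stage 'validate': species {name!r} input {key!r} not "
                        f"readable: {path}"
                    )
                spec[key] = str(path)
    if len(species) == 2:
        if not cfg.get("orthologs"):
            raise PipelineError(
                "stage 'cross_species': two species configured but no ortholog table"
            )
    for key in ("orthologs", "pathways", "recent_hits", "prior_hits"):
        if cfg.get(key):
            path = resolve(cfg[key])
            if not path.is_file():
                raise PipelineError(
                    f"stage '{'cross_species' if key == 'orthologs' else key}': "
                    f"input file not readable: {path}"
                )
            cfg[key] = str(path)
    return cfg


def _run_species(name: str, spec: dict, cfg: dict, outdir: Path) -> dict:
    """All per-species stages; returns artifacts needed downstream."""
    outdir.mkdir(parents=True, exist_ok=True)
    th = cfg["thresholds"]
    grid = make_grid(
        n=int(cfg["grid"]["n"]), f_top=float(cfg["grid"]["f_top"]),
        f_bottom=float(cfg["grid"]["f_bottom"]), spacing=cfg["grid"]["spacing"],
    )
    counts: dict[str, int] = {}

    def stage(label):
        def decorate(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(
                    f"stage {label!r} failed for species {name!r}: {exc}"
                ) from exc
        return decorate

    def load():
        gwas = io.read_gwas(spec["gwas"])
        eqtl = io.read_eqtls(spec["eqtl"])
        ld = io.read_ld(spec["ld"])
        sets = io.read_gmt(spec["gene_sets"])
        return gwas, eqtl, ld, sets

    gwas, eqtl, ld, sets = stage("load")(load)

    def mapping():
        ctx = MseaContext.from_raw(
            gwas, eqtl, ld, tissue=spec.get("tissue"), fdr_max=th["eqtl_fdr"],
            cis_only=bool(spec.get("cis_only", False)),
        )
        summary = {}
        for set_id in sets:
            esnp = ctx.esnp_set(sets[set_id], set_id)
            summary[set_id] = {
                "n_genes": len(esnp.source_genes),
                "n_esnps": len(esnp.markers),
                "n_unmapped": esnp.n_unmapped,
                "markers": sorted(esnp.markers),
            }
        io.write_json(summary, outdir / "esnp_sets.json")
        return ctx

    ctx = stage("mapping")(mapping)
    counts["background_markers"] = ctx.n_background
    counts["mappable_genes"] = len(ctx.universe)

    null_cache: dict = {}
    seed_msea = stage_seed(cfg["seed"], "msea", name)

    def msea_stage():
        res = msea_test(sets, ctx, grid=grid, n_perm=cfg["n_perm"],
                        seed=seed_msea, kappa=cfg["kappa"], null_cache=null_cache)
        res.to_csv(outdir / "msea.tsv", sep="\t", index=False)
        return res

    msea_res = stage("msea")(msea_stage)
    counts["sets_tested"] = int(msea_res["P"].notna().sum())

    def merge():
        survivors = msea_res[msea_res["FDR"] < th["msea_fdr"]]["SET_ID"].tolist()
        counts["msea_significant"] = len(survivors)
        if not survivors:
            io.write_json([], outdir / "supersets.json")
            return []
        significant = sets.subset(survivors)
        sups = merge_supersets(
            significant, universe_size=len(ctx.universe),
            ratio_min=th["merge_ratio"], alpha=th["merge_alpha"],
        )
        sups = confirm_supersets(
            sups, ctx, grid=grid, n_perm=cfg["n_perm"], seed=seed_msea,
            kappa=cfg["kappa"], fdr_max=th["msea_fdr"], null_cache=null_cache,
        )
        if cfg.get("pathways"):
            pathways = io.read_gmt(cfg["pathways"])
            for sup in sups:
                sup.annotation = [
                    {"label": ann.display(), "n_shared": ann.n_shared,
                     "p": ann.p, "p_adj": ann.p_adj}
                    for ann in annotate_set(sup.genes, pathways,
                                            universe_size=len(ctx.universe))
                ]
        payload = [
            {
                "superset_id": s.superset_id,
                "member_sets": s.member_sets,
                "genes": sorted(s.genes),
                "annotation": s.annotation,
                "retest": s.retest,
                "significant": s.significant,
            }
            for s in sups
        ]
        io.write_json(payload, outdir / "supersets.json")
        return sups

    sups = stage("supersets")(merge)
    counts["supersets"] = len(sups)
    confirmed = {s.superset_id: s.genes for s in sups if s.significant}
    counts["supersets_confirmed"] = len(confirmed)

    artifacts = {"counts": counts, "supersets": confirmed, "outdir": outdir}
    if not spec.get("network"):
        return artifacts

    def kda_stage():
        net = RegulatoryNetwork.from_frame(io.read_network(spec["network"]))
        if not confirmed:
            pd.DataFrame().to_csv(outdir / "kda.tsv", sep="\t", index=False)
            return net, pd.DataFrame()
        res = kda_test(
            confirmed, net, n_perm=cfg["n_perm"],
            seed=stage_seed(cfg["seed"], "kda", name), kappa=cfg["kappa"],
            min_neighbors=int(cfg.get("min_neighbors", 5)),
            fdr_max=th["kda_fdr"],
        )
        res.to_csv(outdir / "kda.tsv", sep="\t", index=False)
        return net, res

    net, kda_res = stage("kda")(kda_stage)
    counts["kda_candidates"] = int(len(kda_res))
    kds = [] if kda_res.empty else (
        kda_res[kda_res["IS_KD"]]["NODE"].drop_duplicates().head(cfg["top_kds"]).tolist()
    )
    counts["key_drivers"] = len(kds)

    def subnet_stage():
        if not kds:
            return None
        sub = extract_subnetwork(kds, net, depth=1)
        recent = io.read_gene_list(cfg["recent_hits"]) if cfg.get("recent_hits") else []
        prior = io.read_gene_list(cfg["prior_hits"]) if cfg.get("prior_hits") else []
        sub = flag_gwas_hits(sub, recent, prior)
        io.write_json(sub.to_dict(), outdir / "subnetwork.json")
        pd.DataFrame({
            "NODE": sub.member_nodes,
            "IS_KD": [n in set(sub.kd_nodes) for n in sub.member_nodes],
            "GWAS_FLAG": [sub.gwas_flags[n] for n in sub.member_nodes],
        }).to_csv(outdir / "subnetwork.nodes.tsv", sep="\t", index=False)
        pd.DataFrame(sub.edges, columns=["SRC", "DST", "WEIGHT"]).to_csv(
            outdir / "subnetwork.edges.tsv", sep="\t", index=False)
        return sub

    stage("subnetwork")(subnet_stage)

    def corr_stage():
        if not (kds and spec.get("expression") and spec.get("trait")):
            return None
        expr = io.read_expression(spec["expression"])
        trait = io.read_trait(spec["trait"])
        corr = kd_trait_correlation(kds, expr, trait, alpha=th["corr_p"])
        corr.to_csv(outdir / "kd_trait_correlation.tsv", sep="\t", index=False)
        return corr

    stage("kd_trait_correlation")(corr_stage)
    return artifacts


def run_pipeline(config: dict, outdir: str | Path, base_dir: str | Path = ".") -> Path:
    """Execute every stage; returns the output directory.

    Any stage error aborts with the stage name; outputs written before the
    failure are preserved.
    """
    cfg = validate_config(config, base_dir)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "n_perm": cfg["n_perm"],
        "thresholds": cfg["thresholds"],
        "species": {},
    }
    results = {}
    for name in sorted(cfg["species"]):
        spec = cfg["species"][name]
        artifacts = _run_species(name, spec, cfg, outdir / name)
        results[name] = artifacts
        manifest["species"][name] = artifacts["counts"]

    if len(results) == 2 and cfg.get("orthologs"):
        name_a, name_b = sorted(results)
        try:
            table = OrthologTable.from_frame(io.read_orthologs(cfg["orthologs"]))
            sets_a = results[name_a]["supersets"]
            sets_b = results[name_b]["supersets"]
            if sets_a and sets_b:
                th = cfg["thresholds"]
                matches, classification = match_supersets(
                    sets_a, sets_b, table,
                    alpha=th["merge_alpha"], ji_min=th["match_jaccard"],
                    one_sided_min=th["match_one_sided"],
                )
                rows = [{
                    "SET_A": m.superset_a, "SET_B": m.superset_b,
                    "N_SHARED": m.n_shared, "JI": m.jaccard,
                    "ONE_SIDED_A": m.one_sided_a, "ONE_SIDED_B": m.one_sided_b,
                    "FET_P_ADJ": m.fet_p_adj, "MATCHED": m.matched,
                    "RULE": m.rule or "none",
                } for m in matches]
                pd.DataFrame(rows).to_csv(outdir / "matches.tsv", sep="\t", index=False)
                io.write_json(
                    {"species_a": name_a, "species_b": name_b, **classification},
                    outdir / "classification.json",
                )
                manifest["cross_species"] = {
                    "pairs_tested": len(matches),
                    "matched_pairs": sum(m.matched for m in matches),
                }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage 'cross_species' failed: {exc}") from exc

    io.write_json(manifest, outdir / "manifest.json")
    io.write_json(cfg, outdir / "config.echo.json")
    return outdir
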