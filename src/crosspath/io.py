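"""Readers and writers for the plain-text interchange formats.

All tabular formats are tab-separated with a header row. Headers are matched
case-insensitively and order-insensitively; extra columns are ignored with a
log line. Gene sets travel as GMT (``set_id<TAB>description<TAB>gene...``).
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "GeneSetCollection",
    "read_tabular",
    "read_gwas",
    "read_eqtls",
    "read_ld",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "read_orthologs",
    "read_expression",
    "write_expression",
    "read_trait",
    "write_trait",
    "read_gene_list",
    "write_json",
    "read_json",
    "GWAS_SCHEMA",
    "EQTL_SCHEMA",
    "LD_SCHEMA",
    "NETWORK_SCHEMA",
    "ORTHOLOG_SCHEMA",
]


class SchemaError(ValueError):
    """A file does not conform to its declared tabular schema."""


GWAS_SCHEMA = {"MARKER": str, "PVALUE": float}
EQTL_SCHEMA = {"MARKER": str, "GENE": str, "TISSUE": str, "CIS_TRANS": str, "FDR": float}
LD_SCHEMA = {"MARKER": str, "BLOCK": str}
NETWORK_SCHEMA = {"SRC": str, "DST": str, "WEIGHT": float}
ORTHOLOG_SCHEMA = {"GENE_A": str, "GENE_B": str}


def read_tabular(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a TSV into a typed frame according to *schema*.

    *schema* maps upper-case column names to ``str`` or ``float``. Missing
    required columns raise :class:`SchemaError`; extra columns are dropped
    with a log line; rows whose numeric fields fail to parse are dropped with
    a logged count. Scientific notation is accepted for floats.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    by_upper: dict[str, str] = {}
    for col in df.columns:
        by_upper.setdefault(col.strip().upper(), col)
    missing = [name for name in schema if name not in by_upper]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")
    extra = [col for col in df.columns if col.strip().upper() not in schema]
    if extra:
        log.info("%s: ignoring extra column(s) %s", path, extra)
    out = pd.DataFrame({name: df[by_upper[name]] for name in schema})
    n_raw = len(out)
    for name, typ in schema.items():
        if typ is float:
            out[name] = pd.to_numeric(out[name], errors="coerce")
        else:
            out[name] = out[name].astype(str).str.strip()
    out = out.dropna().reset_index(drop=True)
    if len(out) < n_raw:
        log.warning("%s: dropped %d row(s) failing type checks", path, n_raw - len(out))
    return out


def read_gwas(path: str | Path) -> pd.DataFrame:
    """GWAS summary statistics: MARKER, PVALUE. Duplicate markers keep min p."""
    df = read_tabular(path, GWAS_SCHEMA)
    if df["MARKER"].duplicated().any():
        n = int(df["MARKER"].duplicated().sum())
        log.warning("%s: %d duplicate marker(s), keeping smallest p-value", path, n)
        df = df.sort_values(["PVALUE", "MARKER"], kind="stable").drop_duplicates("MARKER")
        df = df.sort_index().reset_index(drop=True)
    return df


def read_eqtls(path: str | Path) -> pd.DataFrame:
    """eQTL table: MARKER, GENE, TISSUE, CIS_TRANS, FDR; unique per (marker, gene, tissue)."""
    df = read_tabular(path, EQTL_SCHEMA)
    bad = ~df["FDR"].between(0.0, 1.0)
    if bad.any():
        log.warning("%s: dropped %d row(s) with FDR outside [0,1]", path, int(bad.sum()))
        df = df[~bad]
    df = df.sort_values("FDR", kind="stable").drop_duplicates(["MARKER", "GENE", "TISSUE"])
    return df.sort_index().reset_index(drop=True)


def read_ld(path: str | Path) -> dict[str, str]:
    """LD block assignment: MARKER, BLOCK as a marker -> block mapping."""
    df = read_tabular(path, LD_SCHEMA)
    blocks: dict[str, str] = {}
    for marker, block in zip(df["MARKER"], df["BLOCK"]):
        if marker in blocks and blocks[marker] != block:
            raise SchemaError(f"{path}: marker {marker!r} assigned to multiple LD blocks")
        blocks[marker] = block
    return blocks


class GeneSetCollection(Mapping):
    """An ordered mapping of set id -> frozenset of gene ids, with descriptions."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, frozenset] = {}
        for set_id, genes in sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"gene set {set_id!r} is empty")
            self._sets[str(set_id)] = genes
        self.descriptions = {
            sid: (descriptions or {}).get(sid, "") for sid in self._sets
        }

    def __getitem__(self, set_id: str) -> frozenset:
        return self._sets[set_id]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSetCollection({len(self)} sets)"

    def all_genes(self) -> frozenset:
        out: set = set()
        for genes in self._sets.values():
            out |= genes
        return frozenset(out)

    def subset(self, ids: Iterable[str]) -> "GeneSetCollection":
        ids = list(ids)
        return GeneSetCollection(
            {sid: self._sets[sid] for sid in ids},
            {sid: self.descriptions[sid] for sid in ids},
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, list] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields, got {len(fields)}"
                )
            set_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if set_id in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            if not genes:
                raise SchemaError(f"{path}:{lineno}: set {set_id!r} has no genes")
            sets[set_id] = genes
            descriptions[set_id] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for set_id in collection:
            desc = collection.descriptions.get(set_id, "")
            genes = sorted(collection[set_id])
            handle.write("\t".join([set_id, desc, *genes]) + "\n")


def read_network(path: str | Path) -> pd.DataFrame:
    """Edge list: SRC, DST and optional WEIGHT (default 1.0)."""
    head = pd.read_csv(path, sep="\t", nrows=0)
    has_weight = any(c.strip().upper() == "WEIGHT" for c in head.columns)
    if has_weight:
        return read_tabular(path, NETWORK_SCHEMA)
    df = read_tabular(path, {"SRC": str, "DST": str})
    df["WEIGHT"] = 1.0
    return df


def write_network(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, columns=["SRC", "DST", "WEIGHT"])


def read_orthologs(path: str | Path) -> pd.DataFrame:
    return read_tabular(path, ORTHOLOG_SCHEMA)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression matrix, genes x samples; first column is GENE."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    if first.strip().upper() != "GENE":
        raise SchemaError(f"{path}: first column must be GENE, got {first!r}")
    df = df.set_index(first)
    df.index = df.index.astype(str)
    df.index.name = "GENE"
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="GENE")


def read_trait(path: str | Path) -> pd.Series:
    df = read_tabular(path, {"SAMPLE": str, "VALUE": float})
    return pd.Series(df["VALUE"].to_numpy(), index=df["SAMPLE"].tolist(), name="VALUE")


def write_trait(trait: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"SAMPLE": trait.index, "VALUE": trait.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: str | Path):
    with open(path) as handle:
        return json.load(handle)
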