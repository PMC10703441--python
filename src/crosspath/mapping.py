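"""Bridge from gene space to GWAS marker space.

Gene sets are converted into LD-pruned eSNP sets through tissue-specific
eQTLs. Pruning is performed once on the global eQTL-marker universe and
per-set eSNP sets are intersected with that pruned background, so that every
set is scored against one consistent background.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["EsnpSet", "filter_eqtls", "prune_ld", "map_set_to_esnps", "pvalue_map"]


@dataclass(frozen=True)
class EsnpSet:
    """A gene set's image in marker space after LD pruning."""

    set_id: str
    markers: frozenset
    source_genes: frozenset
    n_unmapped: int


def pvalue_map(gwas) -> dict[str, float]:
    """Normalize a GWAS table (MARKER/PVALUE frame or mapping) to a dict."""
    if isinstance(gwas, Mapping):
        return dict(gwas)
    return dict(zip(gwas["MARKER"], gwas["PVALUE"]))


def filter_eqtls(
    eqtl: pd.DataFrame,
    fdr_max: float = 0.05,
    tissue: str | None = None,
    cis_only: bool = False,
) -> pd.DataFrame:
    """Keep records of *tissue* with FDR strictly below *fdr_max*.

    cis and trans records are pooled by default; ``cis_only=True`` restricts
    to cis. An unknown tissue raises with the available tissue labels. An
    empty result is allowed and returned as an empty frame.
    """
    if not 0.0 < fdr_max <= 1.0:
        raise ValueError(f"fdr_max must be in (0, 1], got {fdr_max}")
    out = eqtl
    if tissue is not None:
        tissues = sorted(set(eqtl["TISSUE"]))
        if tissue not in tissues:
            raise ValueError(f"tissue {tissue!r} not in eQTL table; available: {tissues}")
        out = out[out["TISSUE"] == tissue]
    out = out[out["FDR"] < fdr_max]
    if cis_only:
        out = out[out["CIS_TRANS"].str.lower() == "cis"]
    out = out.drop_duplicates(["MARKER", "GENE"]).reset_index(drop=True)
    return out


def prune_ld(
    markers: Iterable[str],
    gwas,
    ld: Mapping[str, str],
    keep: str = "min_p",
) -> set:
    """Keep exactly one marker per LD block.

    With ``keep='min_p'`` (default) the retained marker is the one with the
    smallest GWAS p-value in its block, ties broken by lexicographically
    smallest marker id. ``keep='first'`` retains the lexicographically
    smallest id regardless of p-value. Markers missing from *ld* or *gwas*
    raise an error naming the offender.
    """
    if keep not in ("min_p", "first"):
        raise ValueError(f"keep must be 'min_p' or 'first', got {keep!r}")
    pmap = pvalue_map(gwas)
    best: dict[str, tuple] = {}
    for marker in markers:
        if marker not in ld:
            raise KeyError(f"marker {marker!r} has no LD block assignment")
        if marker not in pmap:
            raise KeyError(f"marker {marker!r} has no GWAS p-value")
        key = (pmap[marker], marker) if keep == "min_p" else (marker,)
        block = ld[marker]
        if block not in best or key < best[block]:
            best[block] = key
    return {key[-1] for key in best.values()}


def map_set_to_esnps(
    genes: Iterable[str],
    eqtl: pd.DataFrame,
    gwas,
    ld: Mapping[str, str],
    set_id: str = "",
    background: set | None = None,
    keep: str = "min_p",
) -> EsnpSet:
    """Map a gene set to its pruned eSNP set.

    *eqtl* must already be FDR-filtered. If *background* is not given, the
    global pruned background is computed here from every eQTL marker present
    in the GWAS. The resulting markers are the union of the member genes'
    eQTL markers intersected with the pruned background; ``n_unmapped``
    counts member genes contributing no surviving marker.
    """
    genes = frozenset(genes)
    if not genes:
        raise ValueError("gene set is empty")
    pmap = pvalue_map(gwas)
    if background is None:
        universe = {m for m in set(eqtl["MARKER"]) if m in pmap}
        n_dropped = len(set(eqtl["MARKER"])) - len(universe)
        if n_dropped:
            log.info("%d eQTL marker(s) absent from GWAS dropped", n_dropped)
        background = prune_ld(universe, pmap, ld, keep=keep)
    sub = eqtl[eqtl["GENE"].isin(genes)]
    markers: set = set()
    mapped_genes: set = set()
    for marker, gene in zip(sub["MARKER"], sub["GENE"]):
        if marker in background:
            markers.add(marker)
            mapped_genes.add(gene)
    return EsnpSet(
        set_id=set_id,
        markers=frozenset(markers),
        source_genes=genes,
        n_unmapped=len(genes) - len(mapped_genes),
    )
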