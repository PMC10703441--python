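"""Marker-set enrichment analysis.

Each gene set's LD-pruned eSNP set is scored for enrichment of strong GWAS
signal with a modified chi-square statistic summed over a grid of top-signal
quantile cutoffs,

    chi = sum_i (O_i - E_i) / sqrt(E_i + kappa),

where O_i counts set markers ranked above the i-th cutoff in the background
p-value ranking, E_i = |set| * f_i is the expected count, and kappa (default
1) stabilises small sets. Calibration is against eSNP sets mapped from
randomly drawn gene sets of matched size; one-sided p-values come from a
Gaussian fit to the permutation sample (empirical tail optional) and are
BH-adjusted across all tested sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .mapping import EsnpSet, filter_eqtls, prune_ld, pvalue_map

log = logging.getLogger(__name__)

__all__ = [
    "QuantileGrid",
    "make_grid",
    "count_oe",
    "chi_statistic",
    "MseaContext",
    "NullDistribution",
    "null_distribution",
    "msea_test",
]


@dataclass(frozen=True)
class QuantileGrid:
    """Ordered top-signal fractions, strictly decreasing within (0, 1)."""

    fractions: tuple

    def __post_init__(self):
        f = self.fractions
        if len(f) < 2:
            raise ValueError("grid needs at least 2 quantile points")
        if any(not 0.0 < x < 1.0 for x in f):
            raise ValueError("grid fractions must lie in (0, 1)")
        if any(later >= earlier for earlier, later in zip(f[:-1], f[1:])):
            raise ValueError("grid fractions must be strictly decreasing")

    @property
    def n(self) -> int:
        return len(self.fractions)

    def cutoff_ranks(self, n_background: int) -> np.ndarray:
        """Rank cutoffs ceil(f_i * N), guarded against float fuzz."""
        f = np.asarray(self.fractions, dtype=float)
        return np.ceil(np.round(f * n_background, 9)).astype(np.int64)


def make_grid(n: int = 10, f_top: float = 0.5, f_bottom: float = 0.001,
              spacing: str = "log") -> QuantileGrid:
    """Grid of *n* fractions from *f_top* down to *f_bottom* inclusive."""
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not 0.0 < f_bottom < f_top < 1.0:
        raise ValueError(f"need 0 < f_bottom < f_top < 1, got {f_bottom}, {f_top}")
    if spacing == "log":
        fr = np.geomspace(f_top, f_bottom, n)
    elif spacing == "linear":
        fr = np.linspace(f_top, f_bottom, n)
    else:
        raise ValueError(f"spacing must be 'log' or 'linear', got {spacing!r}")
    fr[0], fr[-1] = f_top, f_bottom
    return QuantileGrid(tuple(float(x) for x in fr))


def chi_statistic(o, e, kappa: float = 1.0) -> float:
    """sum_i (O_i - E_i)/sqrt(E_i + kappa); exact, no clipping."""
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    if o.shape != e.shape:
        raise ValueError(f"O and E length mismatch: {o.shape} vs {e.shape}")
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    return float(np.sum((o - e) / np.sqrt(e + kappa)))


def _rank_markers(background, pmap) -> dict[str, int]:
    """1-based rank of each background marker by (p-value, marker id)."""
    order = sorted(background, key=lambda m: (pmap[m], m))
    return {m: i + 1 for i, m in enumerate(order)}


def _counts_from_ranks(ranks_sorted: np.ndarray, n_set: int,
                       grid: QuantileGrid, n_background: int):
    cutoffs = grid.cutoff_ranks(n_background)
    o = np.searchsorted(ranks_sorted, cutoffs, side="right").astype(np.int64)
    e = n_set * np.asarray(grid.fractions, dtype=float)
    return o, e


def count_oe(esnp, gwas, background, grid: QuantileGrid):
    """Observed and expected counts per quantile cutoff.

    *esnp* may be an :class:`~crosspath.mapping.EsnpSet` or a plain marker
    set; markers must be a subset of *background* and every background
    marker must carry a GWAS p-value. Returns ``(O, E)`` vectors; an empty
    set yields zero vectors (callers skip such sets).
    """
    markers = esnp.markers if isinstance(esnp, EsnpSet) else frozenset(esnp)
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    if not markers <= background:
        raise ValueError("eSNP markers are not a subset of the background")
    if not markers:
        n = grid.n
        return np.zeros(n, dtype=np.int64), np.zeros(n, dtype=float)
    pmap = pvalue_map(gwas)
    missing = [m for m in background if m not in pmap]
    if missing:
        raise KeyError(f"background marker {missing[0]!r} has no GWAS p-value")
    rank_of = _rank_markers(background, pmap)
    ranks = np.sort(np.array([rank_of[m] for m in markers], dtype=np.int64))
    return _counts_from_ranks(ranks, len(markers), grid, len(background))


class MseaContext:
    """Precomputed ranking and gene->marker-rank index for fast scoring.

    Built from a GWAS table, an FDR-filtered eQTL table and LD block
    assignments. The global background is the LD-pruned universe of eQTL
    markers present in the GWAS; the permutation universe is every gene with
    at least one background marker.
    """

    def __init__(self, gwas, eqtl: pd.DataFrame, ld, keep: str = "min_p"):
        pmap = pvalue_map(gwas)
        eqtl_markers = set(eqtl["MARKER"])
        in_gwas = {m for m in eqtl_markers if m in pmap}
        dropped = len(eqtl_markers) - len(in_gwas)
        if dropped:
            log.info("MseaContext: %d eQTL marker(s) absent from GWAS dropped", dropped)
        if not in_gwas:
            raise ValueError("no eQTL marker overlaps the GWAS")
        self.background = prune_ld(in_gwas, pmap, ld, keep=keep)
        self.n_background = len(self.background)
        self._rank_of = _rank_markers(self.background, pmap)
        self._marker_by_rank = {r: m for m, r in self._rank_of.items()}

        gene_ranks: dict[str, set] = {}
        for marker, gene in zip(eqtl["MARKER"], eqtl["GENE"]):
            rank = self._rank_of.get(marker)
            if rank is not None:
                gene_ranks.setdefault(gene, set()).add(rank)
        self.universe = sorted(gene_ranks)
        self._gene_index = {g: i for i, g in enumerate(self.universe)}
        lengths = np.array([len(gene_ranks[g]) for g in self.universe], dtype=np.int64)
        self._starts = np.concatenate(([0], np.cumsum(lengths)[:-1]))
        self._lengths = lengths
        self._flat = np.concatenate(
            [np.sort(np.fromiter(gene_ranks[g], dtype=np.int64)) for g in self.universe]
        ) if self.universe else np.empty(0, dtype=np.int64)

    def _gather_ranks(self, gene_idx: np.ndarray) -> np.ndarray:
        """Unique sorted background ranks of the union of the genes' markers."""
        counts = self._lengths[gene_idx]
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64)
        offsets = np.repeat(
            self._starts[gene_idx] - np.concatenate(([0], np.cumsum(counts)[:-1])),
            counts,
        )
        ranks = self._flat[offsets + np.arange(total)]
        return np.unique(ranks)

    def set_ranks(self, genes) -> tuple[np.ndarray, int, int]:
        """(sorted unique ranks, n mapped genes, n unmapped genes) for a gene set."""
        genes = frozenset(genes)
        idx = np.array(
            sorted(self._gene_index[g] for g in genes if g in self._gene_index),
            dtype=np.int64,
        )
        ranks = self._gather_ranks(idx) if idx.size else np.empty(0, dtype=np.int64)
        return ranks, int(idx.size), len(genes) - int(idx.size)

    def esnp_set(self, genes, set_id: str = "") -> EsnpSet:
        ranks, _, n_unmapped = self.set_ranks(genes)
        markers = frozenset(self._marker_by_rank[int(r)] for r in ranks)
        return EsnpSet(set_id=set_id, markers=markers,
                       source_genes=frozenset(genes), n_unmapped=n_unmapped)

    @classmethod
    def from_raw(cls, gwas, eqtl, ld, tissue=None, fdr_max: float = 0.05,
                 cis_only: bool = False, keep: str = "min_p") -> "MseaContext":
        return cls(gwas, filter_eqtls(eqtl, fdr_max=fdr_max, tissue=tissue,
                                      cis_only=cis_only), ld, keep=keep)


@dataclass
class NullDistribution:
    set_size: int
    mean: float
    sd: float
    sample: np.ndarray = field(repr=False)


def null_distribution(
    set_size: int,
    ctx: MseaContext,
    grid: QuantileGrid,
    n_perm: int = 1000,
    seed: int = 0,
    kappa: float = 1.0,
) -> NullDistribution:
    """Permutation null for gene sets of *set_size* mappable genes.

    Draws ``n_perm`` uniform gene sets (without replacement) from the
    mappable gene universe, maps each through the context and computes chi.
    Seeded by ``(seed, set_size)`` so equally-sized sets share one null
    regardless of evaluation order.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    n_universe = len(ctx.universe)
    if set_size >= n_universe:
        raise ValueError(
            f"set_size {set_size} not below mappable universe size {n_universe}"
        )
    rng = np.random.default_rng([seed, set_size])
    fractions = np.asarray(grid.fractions, dtype=float)
    cutoffs = grid.cutoff_ranks(ctx.n_background)
    sample = np.empty(n_perm, dtype=float)
    for j in range(n_perm):
        idx = rng.choice(n_universe, size=set_size, replace=False)
        ranks = ctx._gather_ranks(np.asarray(idx, dtype=np.int64))
        o = np.searchsorted(ranks, cutoffs, side="right")
        e = ranks.size * fractions
        sample[j] = np.sum((o - e) / np.sqrt(e + kappa))
    mean = float(sample.mean())
    sd = float(sample.std(ddof=1))
    if sd == 0.0:
        raise ValueError(
            "degenerate permutation null (sd=0); increase n_perm or the gene universe"
        )
    return NullDistribution(set_size=set_size, mean=mean, sd=sd, sample=sample)


_RESULT_COLUMNS = [
    "SET_ID", "N_GENES", "N_GENES_MAPPED", "N_UNMAPPED", "N_ESNPS",
    "CHI", "NULL_MEAN", "NULL_SD", "Z", "P", "FDR",
]


def msea_test(
    collection: GeneSetCollection,
    ctx: MseaContext,
    grid: QuantileGrid | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    kappa: float = 1.0,
    tail: str = "gaussian",
    null_cache: dict | None = None,
) -> pd.DataFrame:
    """Score every set in *collection*; returns one row per set.

    Sets mapping to zero eSNPs are reported with ``N_ESNPS == 0`` and NaN
    statistics and are excluded from the BH correction. Results are sorted
    by FDR then chi descending. *null_cache* (keyed by mapped set size) may
    be shared across calls with identical context/grid/seed/kappa.
    """
    if tail not in ("gaussian", "empirical"):
        raise ValueError(f"tail must be 'gaussian' or 'empirical', got {tail!r}")
    grid = grid or make_grid()
    cache: dict[int, NullDistribution] = null_cache if null_cache is not None else {}
    rows = []
    for set_id in collection:
        genes = collection[set_id]
        ranks, n_mapped, n_unmapped = ctx.set_ranks(genes)
        row = {
            "SET_ID": set_id,
            "N_GENES": len(genes),
            "N_GENES_MAPPED": n_mapped,
            "N_UNMAPPED": n_unmapped,
            "N_ESNPS": int(ranks.size),
        }
        if ranks.size == 0:
            row.update({k: math.nan for k in ("CHI", "NULL_MEAN", "NULL_SD", "Z", "P", "FDR")})
            log.info("msea: set %s has no surviving eSNPs; skipped", set_id)
            rows.append(row)
            continue
        o, e = _counts_from_ranks(ranks, int(ranks.size), grid, ctx.n_background)
        chi = chi_statistic(o, e, kappa)
        null = cache.get(n_mapped)
        if null is None:
            null = null_distribution(n_mapped, ctx, grid, n_perm=n_perm,
                                     seed=seed, kappa=kappa)
            cache[n_mapped] = null
        z = (chi - null.mean) / null.sd
        if tail == "gaussian":
            p = float(stats.norm.sf(z))
        else:
            p = float((1 + np.sum(null.sample >= chi)) / (n_perm + 1))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        row.update({"CHI": chi, "NULL_MEAN": null.mean, "NULL_SD": null.sd,
                    "Z": z, "P": p, "FDR": math.nan})
        rows.append(row)
    out = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    tested = out["P"].notna()
    if tested.any():
        out.loc[tested, "FDR"] = multipletests(out.loc[tested, "P"], method="fdr_bh")[1]
    out = out.sort_values(["FDR", "CHI"], ascending=[True, False],
                          kind="stable", na_position="last")
    return out.reset_index(drop=True)
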