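"""Redundancy reduction: merge significantly overlapping gene sets.

Significant sets are merged into supersets when they share >33% of genes
(ratio over the smaller set) with a Bonferroni-corrected one-tailed Fisher
exact (hypergeometric) p < 5%. Merging is a single round of pairwise tests
followed by connected components, which makes the outcome independent of
input order. Supersets are re-tested for enrichment and annotated against a
pathway collection via the hypergeometric upper tail.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .io import GeneSetCollection
from .msea import MseaContext, QuantileGrid, msea_test

log = logging.getLogger(__name__)

__all__ = [
    "OverlapTest",
    "Superset",
    "Annotation",
    "fet_overlap",
    "merge_supersets",
    "confirm_supersets",
    "annotate_set",
]


@dataclass(frozen=True)
class OverlapTest:
    set_a: str
    set_b: str
    n_shared: int
    ratio: float
    fet_p: float
    fet_p_adj: float = float("nan")


@dataclass
class Superset:
    superset_id: str
    member_sets: list
    genes: frozenset
    annotation: list = field(default_factory=list)
    retest: dict | None = None
    significant: bool | None = None


def fet_overlap(a, b, universe_size: int, set_a: str = "A", set_b: str = "B") -> OverlapTest:
    """One-tailed Fisher exact (hypergeometric upper tail) overlap test.

    ``fet_p = P(X >= n_shared)`` for X ~ Hypergeom(universe_size, |a|, |b|);
    ``ratio = n_shared / min(|a|, |b|)``.
    """
    a, b = frozenset(a), frozenset(b)
    if universe_size < len(a | b):
        raise ValueError(
            f"universe_size {universe_size} smaller than |A union B| = {len(a | b)}"
        )
    n_shared = len(a & b)
    smaller = min(len(a), len(b))
    ratio = n_shared / smaller if smaller else 0.0
    fet_p = float(hypergeom.sf(n_shared - 1, universe_size, len(a), len(b)))
    return OverlapTest(set_a=set_a, set_b=set_b, n_shared=n_shared,
                       ratio=ratio, fet_p=min(fet_p, 1.0))


def merge_supersets(
    significant: GeneSetCollection,
    universe_size: int,
    ratio_min: float = 0.33,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> list[Superset]:
    """Merge qualifying overlapping sets into supersets (connected components).

    An edge joins two sets when ratio > *ratio_min* AND the Bonferroni
    adjusted FET p (over all pairs tested this round) is < *alpha*
    (``use_adjusted=False`` applies *alpha* to the raw p). Superset ids are
    assigned by decreasing component size, ties by lexicographic member ids.
    """
    ids = sorted(significant)
    if not ids:
        return []
    pairs = list(itertools.combinations(ids, 2))
    n_pairs = len(pairs)
    parent = {sid: sid for sid in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for sid_a, sid_b in pairs:
        test = fet_overlap(significant[sid_a], significant[sid_b],
                           universe_size, sid_a, sid_b)
        p_adj = min(1.0, test.fet_p * n_pairs)
        p_use = p_adj if use_adjusted else test.fet_p
        if test.ratio > ratio_min and p_use < alpha:
            parent[find(sid_a)] = find(sid_b)

    components: dict[str, list] = {}
    for sid in ids:
        components.setdefault(find(sid), []).append(sid)
    ordered = sorted(components.values(), key=lambda ms: (-len(ms), sorted(ms)))
    out = []
    for i, members in enumerate(ordered, start=1):
        members = sorted(members)
        genes = frozenset().union(*(significant[sid] for sid in members))
        out.append(Superset(superset_id=f"SS{i:03d}", member_sets=members, genes=genes))
    return out


def confirm_supersets(
    supersets: list[Superset],
    ctx: MseaContext,
    grid: QuantileGrid | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    kappa: float = 1.0,
    fdr_max: float = 0.05,
    null_cache: dict | None = None,
) -> list[Superset]:
    """Re-score each superset's union gene set; flag FDR survivors.

    Supersets failing ``FDR < fdr_max`` are retained with
    ``significant=False`` (downstream stages exclude them by default).
    """
    if not supersets:
        return []
    collection = GeneSetCollection({s.superset_id: s.genes for s in supersets})
    results = msea_test(collection, ctx, grid=grid, n_perm=n_perm, seed=seed,
                        kappa=kappa, null_cache=null_cache)
    by_id = {row["SET_ID"]: row for row in results.to_dict("records")}
    for sup in supersets:
        row = by_id[sup.superset_id]
        sup.retest = {k: row[k] for k in
                      ("N_ESNPS", "CHI", "NULL_MEAN", "NULL_SD", "Z", "P", "FDR")}
        fdr = row["FDR"]
        sup.significant = bool(fdr == fdr and fdr < fdr_max)  # NaN-safe
    return supersets


@dataclass(frozen=True)
class Annotation:
    label: str
    n_shared: int
    p: float
    p_adj: float
    fallback: bool

    def display(self) -> str:
        return self.label + ("*" if self.fallback else "")


def annotate_set(
    genes,
    pathways: GeneSetCollection,
    universe_size: int,
    max_terms: int = 5,
    alpha: float = 0.05,
    min_shared: int = 5,
    fallback_p: float = 5e-3,
) -> list[Annotation]:
    """Top pathway labels for a gene set by hypergeometric overlap.

    Pathways with Bonferroni-adjusted p < *alpha* (over the pathway count)
    and >= *min_shared* shared genes qualify; the best *max_terms* by raw p
    are returned. If none qualify, the fallback keeps pathways at raw
    p < *fallback_p* with >= *min_shared* shared genes, marked ``fallback``
    (displayed with an asterisk).
    """
    genes = frozenset(genes)
    if not len(pathways):
        raise ValueError("pathway collection is empty")
    n_pathways = len(pathways)
    scored = []
    for pid in pathways:
        pw = pathways[pid]
        n_shared = len(genes & pw)
        if n_shared < min_shared:
            continue
        p = float(hypergeom.sf(n_shared - 1, universe_size, len(genes), len(pw)))
        scored.append((p, pid, n_shared))
    scored.sort(key=lambda t: (t[0], t[1]))
    primary = [
        Annotation(pid, n_shared, p, min(1.0, p * n_pathways), fallback=False)
        for p, pid, n_shared in scored
        if min(1.0, p * n_pathways) < alpha
    ]
    if primary:
        return primary[:max_terms]
    fallback = [
        Annotation(pid, n_shared, p, min(1.0, p * n_pathways), fallback=True)
        for p, pid, n_shared in scored
        if p < fallback_p
    ]
    return fallback[:max_terms]
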