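"""Cross-species superset comparison via 1:1 orthologs.

Gene sets are translated into a common id space through an ortholog table,
then every cross-species superset pair is tested. A pair matches when the
correction-adjusted hypergeometric overlap p-value is below alpha and either
the Jaccard index exceeds 50% (two-sided rule) or one of the one-sided
overlaps exceeds 90% (subset rule). A superset with at least one match is
classified as shared, otherwise species-specific; many-to-one matches are
legitimate, so per-species shared counts may differ.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["OrthologTable", "MatchResult", "translate", "jaccard", "match_supersets"]


class OrthologTable:
    """A 1:1 gene-id correspondence between two species.

    Pairs in which either id occurs more than once are removed during
    construction (with a logged count), leaving a strict bijection.
    """

    def __init__(self, pairs) -> None:
        pairs = list(pairs)
        if not pairs:
            raise ValueError("ortholog table is empty")
        count_a: dict[str, int] = {}
        count_b: dict[str, int] = {}
        for a, b in pairs:
            count_a[a] = count_a.get(a, 0) + 1
            count_b[b] = count_b.get(b, 0) + 1
        kept = [(a, b) for a, b in pairs if count_a[a] == 1 and count_b[b] == 1]
        dropped = len(pairs) - len(kept)
        if dropped:
            log.warning("ortholog table: dropped %d non-1:1 pair(s)", dropped)
        if not kept:
            raise ValueError("ortholog table has no 1:1 pairs after filtering")
        self.a_to_b = dict(kept)
        self.b_to_a = {b: a for a, b in kept}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OrthologTable":
        return cls(zip(df["GENE_A"], df["GENE_B"]))

    def __len__(self) -> int:
        return len(self.a_to_b)


def translate(genes, table: OrthologTable, direction: str = "a_to_b") -> frozenset:
    """Image of the mappable genes under the ortholog bijection.

    Unmappable genes are dropped with a logged count.
    """
    if direction not in ("a_to_b", "b_to_a"):
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    mapping = table.a_to_b if direction == "a_to_b" else table.b_to_a
    genes = frozenset(genes)
    out = frozenset(mapping[g] for g in genes if g in mapping)
    n_lost = len(genes) - len(out)
    if n_lost:
        log.info("translate: %d gene(s) without ortholog dropped", n_lost)
    return out


def jaccard(a, b) -> float:
    """|A and B| / |A or B|; 0 for two empty sets by convention."""
    a, b = frozenset(a), frozenset(b)
    union = len(a | b)
    return len(a & b) / union if union else 0.0


@dataclass(frozen=True)
class MatchResult:
    superset_a: str
    superset_b: str
    n_shared: int
    jaccard: float
    one_sided_a: float
    one_sided_b: float
    fet_p: float
    fet_p_adj: float
    matched: bool
    rule: str | None


def match_supersets(
    sets_a: Mapping,
    sets_b: Mapping,
    table: OrthologTable,
    universe_size: int | None = None,
    alpha: float = 0.05,
    ji_min: float = 0.5,
    one_sided_min: float = 0.9,
    correction: str = "bonferroni",
) -> tuple[list[MatchResult], dict]:
    """Test all cross-species superset pairs in the translated space.

    Species-a sets are translated into species-b ids; species-b sets are
    restricted to their ortholog-mappable core, so one-sided ratios use
    translated sizes. *universe_size* defaults to the ortholog pair count.
    Returns the pair results plus a per-species shared/specific
    classification (shared = at least one match).
    """
    if not sets_a or not sets_b:
        raise ValueError("both superset collections must be non-empty")
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"correction must be 'bonferroni' or 'bh', got {correction!r}")
    if universe_size is None:
        universe_size = len(table)
        log.info("match: using ortholog-mappable universe of %d genes", universe_size)

    trans_a = {sid: translate(genes, table, "a_to_b") for sid, genes in sets_a.items()}
    core_b = {sid: frozenset(g for g in genes if g in table.b_to_a)
              for sid, genes in sets_b.items()}

    raw = []
    for sid_a in sorted(trans_a):
        a = trans_a[sid_a]
        for sid_b in sorted(core_b):
            b = core_b[sid_b]
            n = len(a & b)
            ji = jaccard(a, b)
            os_a = n / len(a) if a else 0.0
            os_b = n / len(b) if b else 0.0
            p = float(hypergeom.sf(n - 1, universe_size, len(a), len(b)))
            raw.append((sid_a, sid_b, n, ji, os_a, os_b, min(p, 1.0)))

    n_pairs = len(raw)
    if correction == "bonferroni":
        adj = [min(1.0, r[6] * n_pairs) for r in raw]
    else:
        adj = list(multipletests([r[6] for r in raw], method="fdr_bh")[1])

    results = []
    for (sid_a, sid_b, n, ji, os_a, os_b, p), p_adj in zip(raw, adj):
        two_sided = ji > ji_min
        one_sided = max(os_a, os_b) > one_sided_min
        matched = p_adj < alpha and (two_sided or one_sided)
        rule = None
        if matched:
            rule = "two_sided" if two_sided else "one_sided"
        results.append(MatchResult(sid_a, sid_b, n, ji, os_a, os_b, p, p_adj,
                                   matched, rule))

    matched_a = {r.superset_a for r in results if r.matched}
    matched_b = {r.superset_b for r in results if r.matched}
    classification = {
        "a": {"shared": sorted(matched_a),
              "specific": sorted(set(sets_a) - matched_a)},
        "b": {"shared": sorted(matched_b),
              "specific": sorted(set(sets_b) - matched_b)},
    }
    return results, classification
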