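"""Key driver analysis on a directed gene-regulatory network.

A candidate node's neighborhood is scored for enrichment of a superset's
member genes with the same (O - E)/sqrt(E + kappa) form used for marker-set
enrichment, applied to a single membership bin: O_w is the summed edge
weight from the candidate to neighbors inside the superset, and
E_w = W_total * |S_net| / |nodes| is its expectation for a random gene set
of the same size drawn from the network. Calibration is by permutation,
Gaussian one-sided p, BH FDR across all (candidate, superset) pairs.

Networks may contain cycles; nothing here assumes acyclicity. Neighborhoods
are undirected by default with in-/out-only modes available.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "RegulatoryNetwork",
    "KdResult",
    "Subnetwork",
    "neighborhood",
    "kd_score",
    "kda_test",
    "extract_subnetwork",
    "flag_gwas_hits",
    "kd_trait_correlation",
]

_MODES = ("undirected", "out", "in")


class RegulatoryNetwork:
    """Directed weighted graph with self-loops removed and parallel edges
    collapsed by maximum weight. Undirected neighbor weights take the max of
    the two directions."""

    def __init__(self, edges: Iterable[tuple]) -> None:
        self._out: dict[str, dict[str, float]] = {}
        self._in: dict[str, dict[str, float]] = {}
        nodes: set = set()
        for edge in edges:
            src, dst = str(edge[0]), str(edge[1])
            w = float(edge[2]) if len(edge) > 2 else 1.0
            if w <= 0:
                raise ValueError(f"edge ({src}, {dst}) has non-positive weight {w}")
            nodes.add(src)
            nodes.add(dst)
            if src == dst:
                continue
            prev = self._out.setdefault(src, {}).get(dst)
            if prev is None or w > prev:
                self._out[src][dst] = w
                self._in.setdefault(dst, {})[src] = w
        self.nodes: list[str] = sorted(nodes)
        self._node_index = {n: i for i, n in enumerate(self.nodes)}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegulatoryNetwork":
        if "WEIGHT" in df.columns:
            return cls(zip(df["SRC"], df["DST"], df["WEIGHT"]))
        return cls(zip(df["SRC"], df["DST"]))

    def to_frame(self) -> pd.DataFrame:
        rows = [(src, dst, w)
                for src in sorted(self._out)
                for dst, w in sorted(self._out[src].items())]
        return pd.DataFrame(rows, columns=["SRC", "DST", "WEIGHT"])

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._node_index

    def edge_count(self) -> int:
        return sum(len(d) for d in self._out.values())

    def neighbor_weights(self, node: str, mode: str = "undirected") -> dict[str, float]:
        """Direct neighbors and the edge weight used toward each."""
        if node not in self._node_index:
            raise KeyError(f"unknown node {node!r}")
        if mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
        out_w = self._out.get(node, {})
        in_w = self._in.get(node, {})
        if mode == "out":
            return dict(out_w)
        if mode == "in":
            return dict(in_w)
        merged = dict(in_w)
        for nbr, w in out_w.items():
            if nbr not in merged or w > merged[nbr]:
                merged[nbr] = w
        return merged


def neighborhood(node: str, net: RegulatoryNetwork, depth: int = 1,
                 mode: str = "undirected") -> frozenset:
    """Nodes reachable within *depth* steps under *mode*, excluding *node*."""
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    seen = {node}
    frontier = {node}
    for _ in range(depth):
        nxt: set = set()
        for u in frontier:
            nxt.update(net.neighbor_weights(u, mode))
        frontier = nxt - seen
        seen |= frontier
        if not frontier:
            break
    return frozenset(seen - {node})


@dataclass
class KdResult:
    node: str
    superset_id: str
    neighborhood_size: int
    overlap_weight: float
    expected_weight: float
    score: float
    p: float = math.nan
    fdr: float = math.nan


def kd_score(
    node: str,
    superset_genes,
    net: RegulatoryNetwork,
    kappa: float = 1.0,
    mode: str = "undirected",
    depth: int = 1,
    superset_id: str = "",
) -> KdResult:
    """Neighborhood-enrichment score of one candidate for one superset.

    ``S_net`` is the superset intersected with the network nodes. For
    depth 1, weights are the direct edge weights; deeper neighborhoods use
    unit weights per member (edge weights to indirect neighbors are
    undefined).
    """
    s_net = frozenset(g for g in superset_genes if g in net)
    if depth == 1:
        weights = net.neighbor_weights(node, mode)
    else:
        weights = {nbr: 1.0 for nbr in neighborhood(node, net, depth, mode)}
    w_total = float(sum(weights.values()))
    o_w = float(sum(w for nbr, w in weights.items() if nbr in s_net))
    e_w = w_total * len(s_net) / net.n_nodes
    score = (o_w - e_w) / math.sqrt(e_w + kappa)
    return KdResult(node=node, superset_id=superset_id,
                    neighborhood_size=len(weights), overlap_weight=o_w,
                    expected_weight=e_w, score=score)


_KDA_COLUMNS = ["NODE", "SUPERSET_ID", "NEIGHBORHOOD_SIZE", "OVERLAP_WEIGHT",
                "EXPECTED_WEIGHT", "SCORE", "NULL_MEAN", "NULL_SD", "Z", "P",
                "FDR", "IS_KD", "RANK"]


def kda_test(
    supersets: Mapping,
    net: RegulatoryNetwork,
    n_perm: int = 1000,
    seed: int = 0,
    kappa: float = 1.0,
    mode: str = "undirected",
    depth: int = 1,
    min_neighbors: int = 5,
    fdr_max: float = 0.05,
    tail: str = "gaussian",
) -> pd.DataFrame:
    """Score every candidate node against every superset.

    Candidates are nodes with at least *min_neighbors* neighbors (smaller
    neighborhoods are skipped, not an error). The null draws ``n_perm``
    random gene sets of size ``|S_net|`` from the network's nodes per
    superset; the same draws calibrate every candidate of that superset.
    Results carry BH FDR across all (candidate, superset) pairs, an
    ``IS_KD`` flag (FDR < *fdr_max*) and a within-superset ``RANK`` by
    (FDR, -score). Fully deterministic under *seed*.
    """
    if tail not in ("gaussian", "empirical"):
        raise ValueError(f"tail must be 'gaussian' or 'empirical', got {tail!r}")
    n_nodes = net.n_nodes
    candidates = []
    for node in net.nodes:
        if depth == 1:
            weights = net.neighbor_weights(node, mode)
        else:
            weights = {nbr: 1.0 for nbr in neighborhood(node, net, depth, mode)}
        if len(weights) < min_neighbors:
            continue
        nbrs = sorted(weights)
        idx = np.array([net._node_index[n] for n in nbrs], dtype=np.int64)
        w = np.array([weights[n] for n in nbrs], dtype=float)
        candidates.append((node, idx, w, float(w.sum())))
    if not candidates:
        log.warning("kda: no candidate has >= %d neighbors", min_neighbors)
        return pd.DataFrame(columns=_KDA_COLUMNS)

    rows = []
    for sup_index, sup_id in enumerate(sorted(supersets)):
        s_net_idx = np.array(
            sorted(net._node_index[g] for g in supersets[sup_id] if g in net),
            dtype=np.int64,
        )
        s = int(s_net_idx.size)
        if s == 0:
            log.info("kda: superset %s has no genes in the network; skipped", sup_id)
            continue
        member = np.zeros(n_nodes, dtype=bool)
        member[s_net_idx] = True

        rng = np.random.default_rng([seed, sup_index])
        null_member = np.zeros((n_perm, n_nodes), dtype=bool)
        for j in range(n_perm):
            null_member[j, rng.choice(n_nodes, size=s, replace=False)] = True

        frac = s / n_nodes
        for node, idx, w, w_total in candidates:
            e_w = w_total * frac
            denom = math.sqrt(e_w + kappa)
            o_w = float(w[member[idx]].sum())
            score = (o_w - e_w) / denom
            o_null = null_member[:, idx].astype(float) @ w
            null_scores = (o_null - e_w) / denom
            null_mean = float(null_scores.mean())
            null_sd = float(null_scores.std(ddof=1))
            if null_sd == 0.0:
                raise ValueError(
                    f"degenerate null (sd=0) for candidate {node!r}, superset "
                    f"{sup_id!r}; increase n_perm"
                )
            z = (score - null_mean) / null_sd
            if tail == "gaussian":
                p = float(stats.norm.sf(z))
            else:
                p = float((1 + np.sum(null_scores >= score)) / (n_perm + 1))
            p = min(max(p, np.finfo(float).tiny), 1.0)
            rows.append({
                "NODE": node, "SUPERSET_ID": sup_id,
                "NEIGHBORHOOD_SIZE": int(idx.size), "OVERLAP_WEIGHT": o_w,
                "EXPECTED_WEIGHT": e_w, "SCORE": score, "NULL_MEAN": null_mean,
                "NULL_SD": null_sd, "Z": z, "P": p,
            })

    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=_KDA_COLUMNS)
    out["FDR"] = multipletests(out["P"], method="fdr_bh")[1]
    out["IS_KD"] = out["FDR"] < fdr_max
    out = out.sort_values(["SUPERSET_ID", "FDR", "SCORE"],
                          ascending=[True, True, False], kind="stable")
    out["RANK"] = out.groupby("SUPERSET_ID").cumcount() + 1
    out = out.sort_values(["FDR", "SCORE"], ascending=[True, False], kind="stable")
    return out.reset_index(drop=True)[_KDA_COLUMNS]


@dataclass
class Subnetwork:
    kd_nodes: list
    member_nodes: list
    edges: list
    gwas_flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kd_nodes": list(self.kd_nodes),
            "member_nodes": list(self.member_nodes),
            "edges": [list(e) for e in self.edges],
            "gwas_flags": dict(self.gwas_flags),
        }


def extract_subnetwork(kds, net: RegulatoryNetwork, depth: int = 1,
                       mode: str = "undirected") -> Subnetwork:
    """Induced subnetwork on the top KDs and their neighborhoods.

    *kds* is a non-empty list of node ids or :class:`KdResult` objects.
    Edges are exactly the network's edges restricted to the collected nodes.
    """
    kd_nodes = [kd.node if isinstance(kd, KdResult) else str(kd) for kd in kds]
    if not kd_nodes:
        raise ValueError("at least one key driver is required")
    members: set = set(kd_nodes)
    for node in kd_nodes:
        members |= neighborhood(node, net, depth=depth, mode=mode)
    member_nodes = sorted(members)
    edges = [(src, dst, w)
             for src in member_nodes
             for dst, w in sorted(net._out.get(src, {}).items())
             if dst in members]
    flags = {node: "none" for node in member_nodes}
    return Subnetwork(kd_nodes=sorted(set(kd_nodes)), member_nodes=member_nodes,
                      edges=edges, gwas_flags=flags)


def flag_gwas_hits(sub: Subnetwork, recent_hits, prior_hits) -> Subnetwork:
    """Flag subnetwork nodes as recent_hit / prior_hit / none.

    Recent hits take precedence over prior hits; hit genes absent from the
    subnetwork are ignored.
    """
    recent = set(recent_hits)
    prior = set(prior_hits)
    flags = {}
    for node in sub.member_nodes:
        if node in recent:
            flags[node] = "recent_hit"
        elif node in prior:
            flags[node] = "prior_hit"
        else:
            flags[node] = "none"
    sub.gwas_flags = flags
    return sub


def kd_trait_correlation(
    genes,
    expression: pd.DataFrame,
    trait: pd.Series,
    method: str = "pearson",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene correlation between expression and a clinical trait.

    Expression is genes x samples; samples must match the trait's index.
    Zero-variance genes (or trait) yield NaN correlations, reported as
    missing rather than raising.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    samples = list(trait.index)
    if len(samples) < 4:
        raise ValueError(f"need >= 4 samples, got {len(samples)}")
    missing = [s for s in samples if s not in expression.columns]
    if missing:
        raise ValueError(f"trait sample(s) absent from expression: {missing[:5]}")
    expr = expression[samples]
    y = trait.to_numpy(dtype=float)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    y_const = np.ptp(y) == 0
    for gene in genes:
        if gene not in expr.index:
            rows.append({"GENE": gene, "R": math.nan, "P": math.nan,
                         "SIGNIFICANT": False, "DIRECTION": 0})
            continue
        x = expr.loc[gene].to_numpy(dtype=float)
        if y_const or np.ptp(x) == 0:
            rows.append({"GENE": gene, "R": math.nan, "P": math.nan,
                         "SIGNIFICANT": False, "DIRECTION": 0})
            continue
        res = corr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        rows.append({"GENE": gene, "R": r, "P": p,
                     "SIGNIFICANT": bool(p < alpha),
                     "DIRECTION": int(np.sign(r))})
    return pd.DataFrame(rows, columns=["GENE", "R", "P", "SIGNIFICANT", "DIRECTION"])
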