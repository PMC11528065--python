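"""Bipartite metabolite-reaction graphs and complex-network measures.

A metabolic model maps to a bipartite directed graph: every metabolite
and every (active) reaction is a node; a reagent m of reaction r
contributes an edge m -> r and a product p an edge r -> p.  With a flux
distribution, edge weights are |flux * stoichiometric coefficient|,
edge direction follows the flux sign, and zero-flux reactions drop out
of the graph entirely.

Global efficiency is the Latora-Marchiori measure: the mean over
ordered node pairs of the reciprocal shortest-path length, with
unreachable pairs contributing zero.  Betweenness here is the raw count
of shortest paths (over all ordered pairs) passing through a node as an
intermediate.  Degree distributions can be fitted with the standard
continuous maximum-likelihood power-law estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ContractError, ValidationError
from .gpr import DeletionState
from .model import MetabolicModel
from .solvers import FluxDistribution, pfba

__all__ = [
    "build_flux_graph",
    "global_efficiency",
    "degree_and_betweenness",
    "cumulative_distribution",
    "PowerLawFit",
    "fit_power_law",
    "gene_removal_efficiency",
    "monte_carlo_removal",
    "compare_efficiency_samples",
    "load_gene_network",
]

_FLUX_EPS = 1e-9


def build_flux_graph(model: MetabolicModel,
                     fluxes: FluxDistribution | None = None,
                     state: DeletionState | None = None) -> nx.DiGraph:
    """Build the bipartite metabolite-reaction digraph.

    Structural mode (``fluxes`` None): all GPR-active reactions enter
    with unit edge weights, reversible reactions in their forward
    orientation.  Flux mode: zero-flux reactions are dropped, weights
    are |flux * coefficient| and direction follows the flux sign.
    """
    if fluxes is not None and fluxes.fluxes is not None \
            and len(fluxes.fluxes) != model.n_reactions:
        raise ContractError("flux vector is misaligned with the model")
    disabled = (model.disabled_reaction_mask(state) if state is not None
                else np.zeros(model.n_reactions, dtype=bool))
    G = nx.DiGraph()
    S = model.S.tocsc()
    for j, rid in enumerate(model.reaction_ids):
        if disabled[j]:
            continue
        if fluxes is not None:
            v = float(fluxes.fluxes[j])
            if abs(v) <= _FLUX_EPS:
                continue
        else:
            v = 1.0
        G.add_node(rid, kind="reaction")
        col = S.getcol(j).tocoo()
        for i, coeff in zip(col.row, col.data):
            mid = model.metabolite_ids[i]
            if mid not in G:
                G.add_node(mid, kind="metabolite")
            weight = abs(v * coeff) if fluxes is not None else 1.0
            consumed = (coeff < 0) if v >= 0 else (coeff > 0)
            if consumed:
                G.add_edge(mid, rid, weight=weight)
            else:
                G.add_edge(rid, mid, weight=weight)
    return G


def global_efficiency(G: nx.Graph, weighted: bool = False) -> float:
    """Mean reciprocal shortest-path length over ordered node pairs.

    Distances default to unweighted hop counts; with ``weighted`` the
    length of an edge is 1/weight, so heavy (high-flux) edges are short.
    Graphs with fewer than two nodes have efficiency 0 by convention.
    """
    N = G.number_of_nodes()
    if N < 2:
        return 0.0
    if weighted:
        H = G.copy()
        for u, v, d in H.edges(data=True):
            d["length"] = 1.0 / d.get("weight", 1.0)
        sp = dict(nx.all_pairs_dijkstra_path_length(H, weight="length"))
    else:
        sp = dict(nx.all_pairs_shortest_path_length(G))
    total = 0.0
    for i, dists in sp.items():
        for j, d in dists.items():
            if i != j and d > 0:
                total += 1.0 / d
    return total / (N * (N - 1))


def _bfs_counts(G: nx.DiGraph, source):
    """Hop distance and number of distinct shortest paths from source."""
    dist = {source: 0}
    nsp = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in G.successors(u):
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nsp[w] = nsp[u]
                    nxt.append(w)
                elif dist[w] == dist[u] + 1:
                    nsp[w] += nsp[u]
        frontier = nxt
    return dist, nsp


def degree_and_betweenness(G: nx.Graph) -> pd.DataFrame:
    """Per-node incident-edge degree and shortest-path betweenness.

    Betweenness counts, over all ordered pairs (s, t), the shortest
    s-t paths on which the node appears as an intermediate vertex.
    Undirected graphs are analysed on their directed double cover,
    counting each unordered pair once.
    """
    directed = G.is_directed()
    D = G if directed else G.to_directed(as_view=True)
    nodes = list(G.nodes)
    bfs = {s: _bfs_counts(D, s) for s in nodes}
    btw = {v: 0 for v in nodes}
    for s in nodes:
        dist_s, nsp_s = bfs[s]
        for t in nodes:
            if t == s or t not in dist_s:
                continue
            if not directed and s > t:
                continue  # count each unordered pair once
            d_st = dist_s[t]
            for v in dist_s:
                if v == s or v == t:
                    continue
                dist_v, nsp_v = bfs[v]
                if t in dist_v and dist_s[v] + dist_v[t] == d_st:
                    btw[v] += nsp_s[v] * nsp_v[t]
    deg = dict(G.degree()) if not directed else {
        v: G.in_degree(v) + G.out_degree(v) for v in nodes}
    return pd.DataFrame({
        "degree": pd.Series(deg),
        "betweenness": pd.Series(btw),
    }).rename_axis("node")


def cumulative_distribution(values) -> pd.DataFrame:
    """Sorted (value, P(X >= value)) table for degrees or edge weights."""
    vals = np.sort(np.asarray(list(values), dtype=float))
    n = vals.size
    uniq = np.unique(vals)
    p_ge = [(vals >= u).sum() / n for u in uniq]
    return pd.DataFrame({"value": uniq, "p_ge": p_ge})


@dataclass(frozen=True)
class PowerLawFit:
    gamma: float
    k_min: float
    n_tail: int


def fit_power_law(degrees, k_min: float = 1.0,
                  continuity_correction: bool = True) -> PowerLawFit:
    """Continuous maximum-likelihood estimate of a power-law exponent.

    gamma = 1 + n / sum(ln(k_i / k_ref)) over observations >= k_min,
    with k_ref = k_min - 1/2 under the discrete-data continuity
    correction (the Clauset et al. recipe) or k_ref = k_min for the
    naive continuous estimator.
    """
    ks = np.asarray([k for k in degrees if k >= k_min], dtype=float)
    if ks.size < 2:
        raise ContractError(
            "power-law fit needs at least 2 observations >= k_min")
    k_ref = k_min - 0.5 if continuity_correction else k_min
    if k_ref <= 0:
        raise ContractError("k_min too small for the chosen estimator")
    denom = np.log(ks / k_ref).sum()
    if denom <= 0:
        raise ContractError(
            "all observations at k_min; estimator diverges - use a larger "
            "sample or a smaller k_min")
    gamma = 1.0 + ks.size / denom
    return PowerLawFit(gamma=float(gamma), k_min=float(k_min),
                       n_tail=int(ks.size))


def gene_removal_efficiency(model: MetabolicModel, genes,
                            mode: str = "structural",
                            weighted: bool = False) -> float:
    """Global efficiency of the metabolite-reaction graph after deleting
    a gene set.

    Structural mode removes GPR-disabled reactions and keeps unit
    weights; flux mode recomputes pFBA under the deletions (returning 0
    when no growth-positive flux state exists) and weights edges by the
    flux distribution.
    """
    if mode not in ("structural", "flux"):
        raise ContractError(f"unknown mode {mode!r}")
    state = DeletionState.from_genes(model, genes)
    if mode == "structural":
        G = build_flux_graph(model, state=state)
    else:
        from .errors import InfeasibleError
        try:
            dist = pfba(model, state, growth_fraction=1.0)
        except InfeasibleError:
            return 0.0
        G = build_flux_graph(model, fluxes=dist, state=state)
    return global_efficiency(G, weighted=weighted)


def monte_carlo_removal(model: MetabolicModel, pool, k: int,
                        n_samples: int = 1000, seed: int = 0,
                        mode: str = "structural") -> dict:
    """Efficiency sample under repeated random k-gene removals.

    Draws ``n_samples`` seeded samples of k distinct genes from the pool
    and evaluates each by ``gene_removal_efficiency``.  The summary
    follows the usual box-plot conventions: quartiles Q1-Q3 and whiskers
    at Q1 - 1.5 IQR and Q3 + 1.5 IQR.
    """
    pool = sorted(pool)
    if len(pool) < k:
        raise ContractError(
            f"pool of {len(pool)} genes cannot supply k={k} draws")
    rng = np.random.default_rng(seed)
    cache: dict[tuple, float] = {}
    samples = np.empty(n_samples)
    for i in range(n_samples):
        draw = tuple(sorted(rng.choice(pool, size=k, replace=False)))
        if draw not in cache:
            cache[draw] = gene_removal_efficiency(model, draw, mode=mode)
        samples[i] = cache[draw]
    q1, med, q3 = np.percentile(samples, [25, 50, 75])
    iqr = q3 - q1
    return {
        "samples": samples,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }


def compare_efficiency_samples(a, b, alternative: str = "two-sided"):
    """Mann-Whitney U test between two efficiency samples.

    Returns (statistic, p_value).  ``alternative="less"`` tests whether
    sample ``a`` is stochastically smaller than ``b``.
    """
    res = mannwhitneyu(np.asarray(a), np.asarray(b), alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def load_gene_network(path, directed: bool = False,
                      restrict_to: MetabolicModel | None = None) -> nx.Graph:
    """Load a gene-interaction edge list (TSV: gene_a, gene_b[, weight]).

    Lines starting with '#' are comments.  With ``restrict_to``, nodes
    absent from the model's gene list are dropped along with their
    edges.
    """
    G = nx.DiGraph() if directed else nx.Graph()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        raw = line.strip()
        if not raw or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValidationError(f"malformed edge row at line {ln}: {line!r}")
        weight = 1.0
        if len(parts) >= 3 and parts[2]:
            try:
                weight = float(parts[2])
            except ValueError:
                raise ValidationError(
                    f"non-numeric weight at line {ln}: {parts[2]!r}")
        G.add_edge(parts[0], parts[1], weight=weight)
    if restrict_to is not None:
        keep = set(restrict_to.gene_ids)
        G.remove_nodes_from([n for n in list(G.nodes) if n not in keep])
    return G
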