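"""Compositionality-aware co-occurrence networks and meta-network statistics.

SparCC-style inference: per Dirichlet resample of the count table the
log-ratio variation matrix T_ab = Var[log(x_a/x_b)] is converted to
basis variances omega by solving the sparse-correlation linear system
(row a: (D-1)*omega_a + sum_{b != a} omega_b = sum_b T_ab), strongly
correlated pairs are iteratively excluded from the system, and
rho_ab = (omega_a + omega_b - T_ab) / (2 sqrt(omega_a omega_b)); the
final estimate is the element-wise median over resamples. Significance
comes from a column-independent permutation null with BH adjustment.

Edges passing |rho| > 0.3 (strict) and FDR q < 0.05 form per-context
networks; merging contexts yields a meta-network with per-edge
provenance, Louvain modules, hub sets (10 highest-degree nodes),
degree-based complexity indices (ABC, GA, Bertz), edge-set Jaccard
similarities, and hypergeometric / binomial taxon-pair enrichment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import CountTable, DataError, TaxonomyTable
from .stats import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def variation_matrix(fractions: np.ndarray) -> np.ndarray:
    """T_ab = Var over samples of log(x_a / x_b); fractions is taxa x samples."""
    logf = np.log(fractions)
    c = np.cov(logf)
    v = np.diag(c)
    t = v[:, None] + v[None, :] - 2.0 * c
    np.fill_diagonal(t, 0.0)
    return t


def basis_correlations(
    t_mat: np.ndarray,
    n_exclusion_iter: int = 10,
    exclusion_thresh: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Solve the basis system for one variation matrix.

    Returns (rho, omega, clipped_flag). Non-positive basis variances are
    replaced by the smallest positive entry of T (flagged). The D=3 case
    is the exact closed form omega_a = (T_ab + T_ac - T_bc) / 2, which
    the general solve reproduces.
    """
    d = t_mat.shape[0]
    if d < 3:
        raise DataError("basis system needs >= 3 taxa")
    m = np.ones((d, d)) + np.eye(d) * (d - 2)
    t_work = t_mat.copy()
    excluded = np.zeros((d, d), dtype=bool)
    flagged = False

    def solve():
        nonlocal flagged
        rhs = t_work.sum(axis=1)
        omega = np.linalg.solve(m, rhs)
        if np.any(omega <= 0):
            pos = t_mat[t_mat > 0]
            fill = pos.min() if pos.size else 1e-6
            omega = np.where(omega <= 0, fill, omega)
            flagged = True
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t_mat) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        return rho, omega

    rho, omega = solve()
    for _ in range(n_exclusion_iter):
        absr = np.abs(rho).copy()
        np.fill_diagonal(absr, 0.0)
        absr[excluded] = 0.0
        a, b = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[a, b] <= exclusion_thresh:
            break
        # degree guard: never disconnect a taxon from the system entirely
        if (~excluded[a]).sum() <= 2 or (~excluded[b]).sum() <= 2:
            break
        excluded[a, b] = excluded[b, a] = True
        m[a, b] = m[b, a] = 0.0
        m[a, a] -= 1.0
        m[b, b] -= 1.0
        t_work[a, b] = t_work[b, a] = 0.0
        rho, omega = solve()
    return rho, omega, flagged


def _sparcc_counts(
    counts: np.ndarray,
    n_resample: int,
    n_exclusion_iter: int,
    exclusion_thresh: float,
    rng: np.random.Generator,
) -> np.ndarray:
    d, n = counts.shape
    rhos = np.empty((n_resample, d, d))
    for r in range(n_resample):
        fracs = np.empty_like(counts, dtype=float)
        for j in range(n):
            fracs[:, j] = rng.dirichlet(counts[:, j] + 1.0)
        t_mat = variation_matrix(fracs)
        rhos[r], _, _ = basis_correlations(t_mat, n_exclusion_iter, exclusion_thresh)
    med = np.median(rhos, axis=0)
    med = (med + med.T) / 2.0
    np.fill_diagonal(med, 1.0)
    return med


def sparcc(
    t: CountTable,
    n_resample: int = 20,
    n_exclusion_iter: int = 10,
    exclusion_thresh: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """SparCC correlation estimate for a count table (taxa x samples).

    Per resample, per-sample taxon fractions are drawn from
    Dirichlet(counts + 1); the returned rho is the element-wise median
    over resamples, as a taxa x taxa DataFrame.
    """
    counts = t.counts.to_numpy(dtype=float)
    if counts.shape[0] < 4:
        raise DataError("sparcc needs >= 4 taxa for a stable basis system")
    rng = np.random.default_rng(seed)
    med = _sparcc_counts(counts, n_resample, n_exclusion_iter, exclusion_thresh, rng)
    return pd.DataFrame(med, index=t.otu_ids, columns=t.otu_ids)


def sparcc_pvalues(
    t: CountTable,
    rho_obs: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
    n_resample: int = 5,
    **sparcc_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation p- and BH q-values for a SparCC correlation matrix.

    Each permutation shuffles every taxon's counts across samples
    independently, destroying all inter-taxon covariation;
    two-sided pseudo-p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm).
    """
    if n_perm < 20:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    counts = t.counts.to_numpy(dtype=float)
    d, n = counts.shape
    rng = np.random.default_rng(seed)
    obs = np.abs(rho_obs.to_numpy(dtype=float))
    n_excl = sparcc_kwargs.pop("n_exclusion_iter", 10)
    thresh = sparcc_kwargs.pop("exclusion_thresh", 0.1)
    exceed = np.zeros((d, d))
    for _ in range(n_perm):
        perm = np.empty_like(counts)
        for i in range(d):
            perm[i] = counts[i, rng.permutation(n)]
        rho_p = _sparcc_counts(perm, n_resample, n_excl, thresh, rng)
        exceed += np.abs(rho_p) >= obs - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    np.fill_diagonal(p, 1.0)
    p = np.minimum(p, p.T)
    iu = np.triu_indices(d, k=1)
    q_flat = bh_adjust(p[iu])
    q = np.ones((d, d))
    q[iu] = q_flat
    q = np.minimum(q, q.T)
    ids = t.otu_ids
    return (pd.DataFrame(p, index=ids, columns=ids), pd.DataFrame(q, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass
class AssocNetwork:
    """Per-context signed association network (undirected, thresholded)."""

    graph: nx.Graph
    context: tuple  # (compartment, age) or ('all', 'all')
    r_threshold: float = 0.3
    fdr: float = 0.05

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"otu_a": a, "otu_b": b, **attrs}
            for a, b, attrs in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def build_network(
    rho: pd.DataFrame,
    q: pd.DataFrame,
    r_threshold: float = 0.3,
    fdr: float = 0.05,
    context: tuple = ("all", "all"),
    tax: TaxonomyTable | None = None,
    p: pd.DataFrame | None = None,
) -> AssocNetwork:
    """Retain edges with |rho| strictly above r_threshold and q below fdr.

    A coefficient exactly at the threshold is excluded. Isolated nodes
    are dropped; node attributes carry kingdom/class/order labels when a
    taxonomy is supplied.
    """
    if list(rho.index) != list(q.index) or list(rho.columns) != list(q.columns):
        raise DataError("rho and q matrices are not aligned")
    g = nx.Graph()
    ids = list(rho.index)
    rarr, qarr = rho.to_numpy(dtype=float), q.to_numpy(dtype=float)
    parr = p.to_numpy(dtype=float) if p is not None else None
    for i, j in itertools.combinations(range(len(ids)), 2):
        r_ij = rarr[i, j]
        if abs(r_ij) > r_threshold and qarr[i, j] < fdr:
            attrs = {"rho": float(r_ij), "q": float(qarr[i, j]),
                     "sign": "pos" if r_ij > 0 else "neg"}
            if parr is not None:
                attrs["p"] = float(parr[i, j])
            g.add_edge(ids[i], ids[j], **attrs)
    if tax is not None:
        for node in g.nodes:
            g.nodes[node]["kingdom"] = tax.kingdom(node)
            g.nodes[node]["class"] = tax.labels("class", [node]).iloc[0]
            g.nodes[node]["order"] = tax.labels("order", [node]).iloc[0]
    return AssocNetwork(graph=g, context=context, r_threshold=r_threshold, fdr=fdr)


@dataclass
class GraphStats:
    node_table: pd.DataFrame  # degree, betweenness, closeness, clustering
    hubs: list
    abc_index: float
    ga_index: float
    bertz_index: float
    n_nodes: int
    n_edges: int


def abc_index(g: nx.Graph) -> float:
    """Atom-bond connectivity: sum over edges of sqrt((du + dv - 2)/(du dv))."""
    deg = dict(g.degree())
    return float(sum(
        math.sqrt((deg[u] + deg[v] - 2) / (deg[u] * deg[v])) for u, v in g.edges
    ))


def ga_index(g: nx.Graph) -> float:
    """Geometric-arithmetic index: sum over edges of 2 sqrt(du dv)/(du + dv)."""
    deg = dict(g.degree())
    return float(sum(
        2.0 * math.sqrt(deg[u] * deg[v]) / (deg[u] + deg[v]) for u, v in g.edges
    ))


def bertz_index(g: nx.Graph) -> float:
    """Degree-sequence information content: 2m log2(2m) - sum_v dv log2 dv."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    total = 2.0 * m * math.log2(2.0 * m)
    return float(total - sum(d * math.log2(d) for _, d in g.degree() if d > 0))


def graph_stats(n: AssocNetwork | nx.Graph, n_hubs: int = 10) -> GraphStats:
    """Standard unweighted node metrics plus hubs and complexity indices.

    Hubs are the ``n_hubs`` highest-degree nodes, ties at the cut broken
    lexicographically by node id.
    """
    g = n.graph if isinstance(n, AssocNetwork) else n
    if g.number_of_nodes() == 0:
        raise DataError("graph_stats on an empty graph")
    deg = dict(g.degree())
    bet = nx.betweenness_centrality(g)
    clo = nx.closeness_centrality(g)
    clu = nx.clustering(g)
    node_table = pd.DataFrame({
        "degree": pd.Series(deg), "betweenness": pd.Series(bet),
        "closeness": pd.Series(clo), "clustering": pd.Series(clu),
    }).sort_index()
    order = sorted(deg, key=lambda v: (-deg[v], str(v)))
    hubs = order[: min(n_hubs, len(order))]
    return GraphStats(
        node_table=node_table, hubs=hubs,
        abc_index=abc_index(g), ga_index=ga_index(g), bertz_index=bertz_index(g),
        n_nodes=g.number_of_nodes(), n_edges=g.number_of_edges(),
    )


# ---------------------------------------------------------------------------
# Meta-network
# ---------------------------------------------------------------------------

@dataclass
class MetaNetwork:
    """Union of context networks with per-edge provenance."""

    graph: nx.Graph  # edge attrs: contexts (list), rhos (list), rho (mean)
    contexts: list

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def merge_meta(networks: list) -> MetaNetwork:
    """Merge per-context networks into one meta-network.

    Edge identity is the unordered OTU pair (sign-agnostic); every
    contributing context is recorded in the edge's provenance together
    with that context's rho, and the edge-level rho is the mean over
    contexts.
    """
    g = nx.Graph()
    contexts = []
    for net in networks:
        contexts.append(net.context)
        for node, attrs in net.graph.nodes(data=True):
            if node not in g:
                g.add_node(node, **attrs)
        for u, v, attrs in net.graph.edges(data=True):
            if g.has_edge(u, v):
                g[u][v]["contexts"].append(net.context)
                g[u][v]["rhos"].append(attrs.get("rho", float("nan")))
            else:
                g.add_edge(u, v, contexts=[net.context], rhos=[attrs.get("rho", float("nan"))])
    for u, v in g.edges:
        rhos = g[u][v]["rhos"]
        g[u][v]["rho"] = float(np.nanmean(rhos))
        g[u][v]["sign"] = "pos" if g[u][v]["rho"] > 0 else "neg"
    return MetaNetwork(graph=g, contexts=contexts)


@dataclass
class ModuleResult:
    membership: dict  # node -> module id
    modularity: float
    composition: pd.DataFrame  # module, context axis ('compartment'|'age'), label, fraction


def detect_modules(m: MetaNetwork, seed: int | None = None, resolution: float = 1.0) -> ModuleResult:
    """Louvain modules of the meta-network plus per-module context makeup.

    The composition table reports, for each module and each compartment
    (and each age), the fraction of that module's edge-context
    provenance entries coming from that compartment/age — the
    within-module association profile across the study design.
    """
    communities = nx.community.louvain_communities(m.graph, seed=seed, resolution=resolution)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(map(str, c))[0] if c else ""))
    membership = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.community.modularity(m.graph, communities) if m.graph.number_of_edges() else 0.0
    rows = []
    for mod_id, comm in enumerate(communities):
        comp_counts: dict = {}
        age_counts: dict = {}
        total = 0
        for u, v, attrs in m.graph.edges(comm, data=True):
            if membership[u] != mod_id or membership[v] != mod_id:
                continue
            for comp, age in attrs["contexts"]:
                comp_counts[comp] = comp_counts.get(comp, 0) + 1
                age_counts[age] = age_counts.get(age, 0) + 1
                total += 1
        for axis, counts in (("compartment", comp_counts), ("age", age_counts)):
            for label, count in sorted(counts.items(), key=lambda kv: str(kv[0])):
                rows.append({
                    "module": mod_id, "axis": axis, "label": label,
                    "count": count, "fraction": count / total if total else 0.0,
                })
    return ModuleResult(membership=membership, modularity=float(q),
                        composition=pd.DataFrame(rows))


def edge_jaccard(
    networks: list,
    display_threshold: float = 0.02,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Edge-set Jaccard similarity between networks + thresholded graph.

    J(A, B) = |E_A & E_B| / |E_A | E_B| on unordered node-pair identity.
    An empty network has J = 0 against every other (with a warning). The
    similarity graph keeps pairs with J strictly above the display
    threshold.
    """
    if len(networks) < 2:
        raise DataError("edge_jaccard needs >= 2 networks")
    names = []
    for i, net in enumerate(networks):
        ctx = getattr(net, "context", None)
        names.append("|".join(map(str, ctx)) if ctx else f"net{i}")
    sets = [net.edge_set() for net in networks]
    for name, s in zip(names, sets):
        if not s:
            logger.warning("network %s has no edges; J defined as 0", name)
    k = len(sets)
    j = np.eye(k)
    for a, b in itertools.combinations(range(k), 2):
        union = sets[a] | sets[b]
        j[a, b] = j[b, a] = (len(sets[a] & sets[b]) / len(union)) if union else 0.0
    mat = pd.DataFrame(j, index=names, columns=names)
    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(range(k), 2):
        if j[a, b] > display_threshold:
            g.add_edge(names[a], names[b], jaccard=float(j[a, b]))
    return mat, g


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # class_a, class_b, k, draws, successes, expected, p, q, flag


def _edge_labels(g: nx.Graph, tax: TaxonomyTable | None, level: str) -> list[tuple]:
    if tax is not None:
        lab = tax.labels(level, list(g.nodes))
        get = lambda n: lab.loc[n]
    else:
        get = lambda n: str(g.nodes[n].get(level, "unclassified"))
    return [(get(u), get(v)) for u, v in g.edges]


def class_enrichment(
    n: AssocNetwork | MetaNetwork,
    tax: TaxonomyTable | None = None,
    level: str = "class",
    fdr: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric over-representation of label-pair associations.

    For a label pair (A, B): population = all edges, draws = edges
    touching A, successes = edges touching B, observed k = edges joining
    A and B; p is the upper-tail hypergeometric probability P(X >= k),
    BH-adjusted over all tested pairs. A pair is flagged
    'overrepresented' when q < fdr and k exceeds its expectation.
    """
    g = n.graph
    edge_labels = _edge_labels(g, tax, level)
    n_e = len(edge_labels)
    if n_e == 0:
        raise DataError("enrichment on a network with no edges")
    labels = sorted({l for pair in edge_labels for l in pair})
    touches = {l: sum(1 for a, b in edge_labels if l in (a, b)) for l in labels}
    rows = []
    for a, b in itertools.combinations_with_replacement(labels, 2):
        if a == b:
            k = sum(1 for x, y in edge_labels if x == a and y == a)
        else:
            k = sum(1 for x, y in edge_labels if {x, y} == {a, b})
        draws, successes = touches[a], touches[b]
        p = float(sps.hypergeom.sf(k - 1, n_e, successes, draws))
        expected = draws * successes / n_e
        rows.append({"class_a": a, "class_b": b, "k": k, "draws": draws,
                     "successes": successes, "expected": expected, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["flag"] = np.where(
        (table["q"] < fdr) & (table["k"] > table["expected"]),
        "overrepresented", "random",
    )
    return EnrichmentResult(table)


def binomial_cooccurrence(
    n: AssocNetwork | MetaNetwork,
    tax: TaxonomyTable | None = None,
    level: str = "class",
) -> pd.DataFrame:
    """Sign-bias (co-occurrence vs co-exclusion) test per label pair.

    Within each label pair the count of positive edges among n_total is
    tested against Binomial(n_total, pi0) with pi0 the global
    positive-edge fraction; the two-sided p doubles the smaller tail
    (capped at 1) and is BH-adjusted across pairs. Pairs with no edges
    are skipped.
    """
    g = n.graph
    signs = [attrs.get("sign", "pos") for _, _, attrs in g.edges(data=True)]
    if not signs:
        raise DataError("sign test on a network with no edges")
    pi0 = signs.count("pos") / len(signs)
    edge_labels = _edge_labels(g, tax, level)
    pair_counts: dict = {}
    for (a, b), sign in zip(edge_labels, signs):
        key = tuple(sorted((a, b)))
        tot, pos = pair_counts.get(key, (0, 0))
        pair_counts[key] = (tot + 1, pos + (sign == "pos"))
    rows = []
    for (a, b), (tot, pos) in sorted(pair_counts.items()):
        lower = float(sps.binom.cdf(pos, tot, pi0))
        upper = float(sps.binom.sf(pos - 1, tot, pi0))
        p = min(1.0, 2.0 * min(lower, upper))
        rows.append({"class_a": a, "class_b": b, "n_total": tot, "n_pos": pos,
                     "pi0": pi0, "p": p})
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    return table


def write_graphml(n: AssocNetwork | MetaNetwork, path) -> None:
    g = n.graph.copy()
    for u, v in g.edges:
        for key in ("contexts", "rhos"):
            if key in g[u][v]:
                g[u][v][key] = ";".join(map(str, g[u][v][key]))
    nx.write_graphml(g, path)
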