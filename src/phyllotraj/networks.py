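"""Covariance-network inference and node-role analysis for OTU tables.

Edges come from stability-selected Pearson correlations of CLR-transformed
abundances: an edge is kept when |r| clears a threshold in a large enough
fraction of sample subsamples, with the sign taken from the full-data
correlation. This is a deterministic, seedable surrogate for sparse
inverse-covariance network inference, exposed behind the same interface so
alternative backends can be swapped in.

Node roles follow the classical within-module degree (Zi) versus
participation coefficient (Pi) plane with thresholds Zi = 2.5 and Pi = 0.62:
network hubs (high/high), module hubs (high/low), connectors (low/high) and
peripherals (low/low). Guild summaries aggregate betweenness centrality,
degree, and the within-module edge fraction per functional guild; network
comparison over time uses a bootstrap-permutation scheme on an edge-weight
correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import greedy_modularity_communities
from scipy import stats

from .table import AbundanceMatrix, OtuTable, TableError, _as_frame

__all__ = [
    "NetworkModel",
    "NodeRoles",
    "GuildSummary",
    "clr_transform",
    "infer_network",
    "detect_modules",
    "zi_pi",
    "guild_summary",
    "compare_networks",
    "class_edge_proportions",
]


def clr_transform(table, pseudocount: float = 1.0) -> AbundanceMatrix:
    """Centered log-ratio transform of counts with a pseudocount; rows sum to 0."""
    df = _as_frame(table)
    vals = np.log(df.to_numpy(dtype=float) + pseudocount)
    vals = vals - vals.mean(axis=1, keepdims=True)
    return AbundanceMatrix(pd.DataFrame(vals, index=df.index, columns=df.columns),
                           "clr")


@dataclass
class NetworkModel:
    """Signed weighted OTU association graph with inference provenance."""

    edges: pd.DataFrame  # source, target, weight, sign, stability
    nodes: list[str]
    params: dict = field(default_factory=dict)
    timepoint: object = None
    modules: dict[str, int] | None = None
    modularity: float | None = None

    def graph(self, weighted: bool = True) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, r in self.edges.iterrows():
            g.add_edge(r["source"], r["target"], weight=float(r["weight"]),
                       absweight=abs(float(r["weight"])), sign=r["sign"],
                       stability=float(r["stability"]))
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_edge_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph(), path)


def infer_network(
    clr: AbundanceMatrix,
    r_thresh: float = 0.35,
    subsample: float = 0.8,
    n_subsamples: int = 50,
    stability: float = 0.8,
    seed: int = 0,
    timepoint=None,
) -> NetworkModel:
    """Stability-selected correlation network on CLR abundances.

    An OTU pair becomes an edge iff |Pearson r| >= ``r_thresh`` in at least
    ``stability`` of ``n_subsamples`` random subsamples of the samples; the
    edge weight and sign come from the full-data correlation.
    """
    x = clr.values.to_numpy(dtype=float)
    n, k = x.shape
    if n < 10:
        raise TableError("need >= 10 samples for network inference")
    n_sub = int(round(subsample * n))
    if n_sub < 3:
        raise TableError("subsample size too small")
    rng = np.random.default_rng(seed)
    # guard constant columns: corrcoef would return NaN
    sd = x.std(axis=0)
    keep_var = sd > 0
    hits = np.zeros((k, k))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=n_sub, replace=False)
        xs = x[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(xs, rowvar=False)
        r = np.nan_to_num(r)
        hits += np.abs(r) >= r_thresh
    freq = hits / n_subsamples
    with np.errstate(invalid="ignore", divide="ignore"):
        r_full = np.nan_to_num(np.corrcoef(x, rowvar=False))
    nodes = clr.values.columns.tolist()
    iu = np.triu_indices(k, 1)
    mask = (freq[iu] >= stability) & keep_var[iu[0]] & keep_var[iu[1]] \
        & (np.abs(r_full[iu]) >= r_thresh)
    rows = []
    for a, b in zip(iu[0][mask], iu[1][mask]):
        w = r_full[a, b]
        rows.append((nodes[a], nodes[b], float(w), "+" if w >= 0 else "-",
                     float(freq[a, b])))
    edges = pd.DataFrame(rows, columns=["source", "target", "weight", "sign",
                                        "stability"])
    params = {"r_thresh": r_thresh, "subsample": subsample,
              "n_subsamples": n_subsamples, "stability": stability, "seed": seed}
    return NetworkModel(edges, nodes, params, timepoint)


def detect_modules(net: NetworkModel, seed: int = 0) -> dict[str, int]:
    """Greedy modularity communities on absolute edge weights.

    Module ids are assigned deterministically in order of each community's
    smallest node id; isolated nodes get their own singleton modules. The
    modularity score is stored on the network model.
    """
    g = net.graph()
    if g.number_of_nodes() == 0:
        raise TableError("empty graph")
    connected = [n for n in g.nodes if g.degree(n) > 0]
    sub = g.subgraph(connected)
    if sub.number_of_edges() > 0:
        comms = greedy_modularity_communities(sub, weight="absweight")
        comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
        q = nx.algorithms.community.modularity(sub, comms, weight="absweight")
    else:
        comms, q = [], 0.0
    modules: dict[str, int] = {}
    mid = 0
    for c in comms:
        for node in c:
            modules[node] = mid
        mid += 1
    for node in sorted(set(g.nodes) - set(modules)):
        modules[node] = mid
        mid += 1
    net.modules = modules
    net.modularity = float(q)
    return modules


@dataclass
class NodeRoles:
    """Zi-Pi role classification of network nodes."""

    table: pd.DataFrame  # module, degree, zi, pi, role
    zi_threshold: float = 2.5
    pi_threshold: float = 0.62
    excluded: list[str] = field(default_factory=list)


def zi_pi(net: NetworkModel, modules: dict[str, int] | None = None) -> NodeRoles:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes each node's within-module degree against its module's
    mean and SD (SD 0 gives Zi = 0); Pi = 1 - sum_m (k_im / k_i)^2. Roles:
    network hub (Zi >= 2.5 and Pi >= 0.62), module hub (Zi >= 2.5, Pi < 0.62),
    connector (Zi < 2.5, Pi >= 0.62), peripheral otherwise. Degree-0 nodes
    are excluded and listed.
    """
    if modules is None:
        modules = net.modules if net.modules is not None else detect_modules(net)
    g = net.graph()
    excluded = [n for n in g.nodes if g.degree(n) == 0]
    nodes = [n for n in g.nodes if g.degree(n) > 0]
    within = {}
    permod: dict[int, list[float]] = {}
    for n in nodes:
        kw = sum(1 for nb in g.neighbors(n) if modules[nb] == modules[n])
        within[n] = kw
        permod.setdefault(modules[n], []).append(kw)
    mod_stats = {m: (np.mean(v), np.std(v)) for m, v in permod.items()}
    rows = []
    for n in nodes:
        mu, sd = mod_stats[modules[n]]
        zi = (within[n] - mu) / sd if sd > 0 else 0.0
        k_i = g.degree(n)
        shares = {}
        for nb in g.neighbors(n):
            shares[modules[nb]] = shares.get(modules[nb], 0) + 1
        pi = 1.0 - sum((c / k_i) ** 2 for c in shares.values())
        if zi >= 2.5 and pi >= 0.62:
            role = "network hub"
        elif zi >= 2.5:
            role = "module hub"
        elif pi >= 0.62:
            role = "connector"
        else:
            role = "peripheral"
        rows.append((n, modules[n], k_i, float(zi), float(pi), role))
    df = pd.DataFrame(rows, columns=["node", "module", "degree", "zi", "pi",
                                     "role"]).set_index("node")
    return NodeRoles(df, excluded=excluded)


@dataclass
class GuildSummary:
    table: pd.DataFrame  # guild x (betweenness/degree/within-module mean, sd)
    timepoint: object = None


def guild_summary(net: NetworkModel, guild_table: pd.DataFrame | pd.Series) -> GuildSummary:
    """Mean +- SD betweenness, degree and within-module edge fraction per guild.

    Betweenness is Brandes' algorithm on the unweighted edge skeleton. Guilds
    with no node in the graph are omitted with a warning.
    """
    guilds = (guild_table["guild"] if isinstance(guild_table, pd.DataFrame)
              else guild_table)
    if net.modules is None:
        detect_modules(net)
    g = net.graph()
    btw = nx.betweenness_centrality(g, normalized=True)
    rows = []
    labeled = [n for n in g.nodes if n in guilds.index]
    if not labeled:
        raise TableError("no network node carries a guild label")
    for guild in sorted(guilds.loc[labeled].dropna().unique()):
        members = [n for n in labeled if guilds[n] == guild]
        if not members:
            warnings.warn(f"guild {guild!r} has no nodes in the graph")
            continue
        b = np.array([btw[n] for n in members])
        d = np.array([g.degree(n) for n in members], dtype=float)
        wfrac = []
        for n in members:
            k = g.degree(n)
            if k == 0:
                wfrac.append(np.nan)
            else:
                kw = sum(1 for nb in g.neighbors(n)
                         if net.modules[nb] == net.modules[n])
                wfrac.append(kw / k)
        wfrac = np.array(wfrac, dtype=float)
        rows.append({
            "guild": guild, "n_nodes": len(members),
            "betweenness_mean": b.mean(), "betweenness_sd": b.std(ddof=0),
            "degree_mean": d.mean(), "degree_sd": d.std(ddof=0),
            "within_module_mean": np.nanmean(wfrac) if len(wfrac) else np.nan,
            "within_module_sd": np.nanstd(wfrac) if len(wfrac) else np.nan,
        })
    return GuildSummary(pd.DataFrame(rows).set_index("guild"), net.timepoint)


# ---------------------------------------------------------------------------
# temporal network comparison
# ---------------------------------------------------------------------------

@dataclass
class NetworkComparison:
    distance: float
    p_value: float
    bootstrap_ci: tuple[float, float]
    n_boot: int
    n_perm: int
    seed: int


def _edge_weight_vector(net: NetworkModel, pair_index: dict) -> np.ndarray:
    v = np.zeros(len(pair_index))
    for _, r in net.edges.iterrows():
        key = (r["source"], r["target"]) if r["source"] < r["target"] \
            else (r["target"], r["source"])
        v[pair_index[key]] = r["weight"]
    return v


def _network_distance(n1: NetworkModel, n2: NetworkModel) -> float:
    nodes = sorted(set(n1.nodes) & set(n2.nodes))
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
    idx = {p: i for i, p in enumerate(pairs)}
    v1 = _edge_weight_vector(n1, idx)
    v2 = _edge_weight_vector(n2, idx)
    if np.all(v1 == v1[0]) or np.all(v2 == v2[0]):
        return 1.0 if not np.array_equal(v1, v2) else 0.0
    rho = stats.spearmanr(v1, v2).statistic
    if np.isnan(rho):
        rho = 0.0
    return float(1.0 - rho)


def compare_networks(
    table_t1: OtuTable | AbundanceMatrix,
    table_t2: OtuTable | AbundanceMatrix,
    n_boot: int = 100,
    n_perm: int = 100,
    seed: int = 0,
    **infer_kw,
) -> NetworkComparison:
    """Bootstrap-permutation comparison of two timepoints' networks.

    The statistic is 1 - Spearman correlation of the edge-weight vectors
    over the union of node pairs. The null permutes sample-to-timepoint
    labels and re-infers both networks; the bootstrap resamples samples
    within each timepoint for a CI on the distance.
    """

    def to_clr(t):
        return t if isinstance(t, AbundanceMatrix) else clr_transform(t)

    c1, c2 = to_clr(table_t1), to_clr(table_t2)
    common = [o for o in c1.values.columns if o in set(c2.values.columns)]
    if len(common) < c1.values.shape[1] or len(common) < c2.values.shape[1]:
        warnings.warn("OTU sets differ; intersecting")
    x1 = c1.values[common]
    x2 = c2.values[common]
    rng = np.random.default_rng(seed)

    def infer(frame, s):
        return infer_network(AbundanceMatrix(frame, "clr"), seed=s, **infer_kw)

    obs = _network_distance(infer(x1, seed), infer(x2, seed))

    pooled = pd.concat([x1, x2])
    n1 = len(x1)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(pooled))
        p1 = pooled.iloc[perm[:n1]]
        p2 = pooled.iloc[perm[n1:]]
        null[b] = _network_distance(infer(p1, seed + 2 + b), infer(p2, seed + 1002 + b))
    p = (int((null >= obs - 1e-12).sum()) + 1) / (n_perm + 1)

    boots = np.empty(n_boot)
    for b in range(n_boot):
        i1 = rng.integers(0, len(x1), size=len(x1))
        i2 = rng.integers(0, len(x2), size=len(x2))
        boots[b] = _network_distance(infer(x1.iloc[i1], seed + 5000 + b),
                                     infer(x2.iloc[i2], seed + 9000 + b))
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return NetworkComparison(float(obs), float(p), ci, n_boot, n_perm, seed)


def class_edge_proportions(net: NetworkModel, taxonomy: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Proportion of edges per unordered Class pair and sign; sums to 1.

    Unlabeled nodes are pooled into "Unknown".
    """
    classes = (taxonomy["Class"] if isinstance(taxonomy, pd.DataFrame)
               else taxonomy)
    if net.n_edges == 0:
        raise TableError("network has no edges")
    counts: dict[tuple[str, str, str], int] = {}
    for _, r in net.edges.iterrows():
        ca = str(classes.get(r["source"], "Unknown") or "Unknown")
        cb = str(classes.get(r["target"], "Unknown") or "Unknown")
        key = tuple(sorted((ca, cb))) + (r["sign"],)
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    rows = [{"class_a": a, "class_b": b, "sign": s, "proportion": c / total}
            for (a, b, s), c in sorted(counts.items())]
    return pd.DataFrame(rows)
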