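"""Co-occurrence network inference for genus-level communities.

Edges are Spearman rank correlations between genus relative-abundance
profiles across a group's samples, retained only when |rho| >= 0.65 and the
Benjamini-Hochberg adjusted p (q) is < 0.05.  The FDR family is one network
build: all candidate pairs of that group x mode.  Cross-domain networks
consider bacterium-fungus pairs only and are bipartite by construction.

Bacterial genera enter a network if they occur (nonzero) in at least five
of the group's samples and have mean relative abundance >= 0.05% there;
fungal genera only need mean relative abundance >= 0.001% (fungal tables
are sparser, so the occurrence gate is waived).

Community detection maximises Newman-Girvan modularity on the unweighted,
sign-ignored graph with the seeded Louvain heuristic; edge signs are kept
for reporting only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import RelAbundanceTable

__all__ = [
    "CoNetwork",
    "TopologySummary",
    "filter_genera",
    "spearman_matrix",
    "bh_fdr",
    "build_network",
    "detect_modules",
    "topology",
    "network_from_tables",
    "write_edge_list",
]

RHO_MIN = 0.65
Q_MAX = 0.05
OCCURRENCE_MIN = 5
BACTERIAL_MEAN_RA_MIN = 5e-4
FUNGAL_MEAN_RA_MIN = 1e-5

MODES = ("bacteria", "fungi", "cross_domain")


@dataclass
class CoNetwork:
    """Weighted signed co-occurrence graph of genera.

    ``graph`` nodes carry a ``domain`` attribute; edges carry ``rho``,
    ``q`` and ``sign``.  Isolated nodes are dropped at build time.
    """

    graph: nx.Graph
    group: str
    mode: str
    modules: dict | None = None
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, attr in self.graph.edges(data=True):
            a2, b2 = sorted((a, b))
            rows.append(
                {
                    "taxon_a": a2,
                    "taxon_b": b2,
                    "rho": attr["rho"],
                    "q": attr["q"],
                    "sign": attr["sign"],
                    "module_a": (self.modules or {}).get(a2),
                    "module_b": (self.modules or {}).get(b2),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["taxon_a", "taxon_b", "rho", "q", "sign", "module_a", "module_b"],
        ).sort_values(["taxon_a", "taxon_b"]).reset_index(drop=True)


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    clustering_coefficient: float
    density: float
    diameter: float
    avg_path_length: float
    modularity: float | None
    n_modules: int | None
    pct_positive_edges: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# filtering, correlation, FDR
# ---------------------------------------------------------------------------

def filter_genera(r: RelAbundanceTable, samples, domain: str,
                  occurrence_min: int = OCCURRENCE_MIN,
                  bacterial_mean_ra_min: float = BACTERIAL_MEAN_RA_MIN,
                  fungal_mean_ra_min: float = FUNGAL_MEAN_RA_MIN) -> list:
    """Genera passing the per-domain prevalence/abundance gates within the
    group's samples."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample group")
    sub = r.values[samples]
    mean_ra = sub.mean(axis=1)
    if domain == "bacteria":
        occ = (sub > 0).sum(axis=1)
        keep = (occ >= occurrence_min) & (mean_ra >= bacterial_mean_ra_min)
    elif domain == "fungi":
        keep = mean_ra >= fungal_mean_ra_min
    else:
        raise ValueError(f"unknown domain {domain!r}")
    return list(sub.index[keep])


def spearman_matrix(values: pd.DataFrame):
    """Tie-corrected Spearman rho and two-sided p (t approximation) for all
    unordered genus pairs of a taxa x samples table.

    Genera with constant profiles yield undefined correlations; their
    entries are NaN and a warning lists them.
    """
    if values.shape[1] < 4:
        raise ValueError("need at least 4 samples for correlation")
    arr = values.to_numpy(dtype=float)
    n = arr.shape[0]
    constant = arr.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"constant genera excluded from the correlation family: "
            f"{list(values.index[constant])}"
        )
    ok = ~constant
    rho = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    sub = arr[ok]
    if sub.shape[0] >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_sub, p_sub = stats.spearmanr(sub.T)
        if np.ndim(r_sub) == 0:  # scipy collapses two variables to scalars
            r_sub = np.array([[1.0, r_sub], [r_sub, 1.0]])
            p_sub = np.array([[1.0, p_sub], [p_sub, 1.0]])
        rho[np.ix_(ok, ok)] = r_sub
        p[np.ix_(ok, ok)] = p_sub
    np.fill_diagonal(rho, 1.0)
    idx = values.index
    return (pd.DataFrame(rho, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values:
    ``q_(i) = min_{j >= i} (m * p_(j) / j)``, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_network(rho: pd.DataFrame, p: pd.DataFrame, mode: str, group: str,
                  domains, rho_min: float = RHO_MIN,
                  q_max: float = Q_MAX) -> CoNetwork:
    """Gate correlations into a network.

    ``domains`` maps taxon id -> domain.  For ``mode='cross_domain'`` the
    FDR family is the bacterium-fungus pairs only and within-domain pairs
    can never become edges.  Isolated nodes are dropped.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    domains = dict(domains)
    taxa = list(rho.index)
    pairs = []
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            if mode == "cross_domain":
                if domains[a] == domains[b]:
                    continue
            else:
                if domains[a] != mode or domains[b] != mode:
                    continue
            pv = p.loc[a, b]
            if np.isnan(pv):
                continue  # undefined correlation: excluded from the family
            pairs.append((a, b, float(rho.loc[a, b]), float(pv)))
    g = nx.Graph()
    if pairs:
        q = bh_fdr([pr[3] for pr in pairs])
        for (a, b, r_ab, _), q_ab in zip(pairs, q):
            if abs(r_ab) >= rho_min and q_ab < q_max:
                g.add_edge(a, b, rho=r_ab, q=float(q_ab),
                           sign="positive" if r_ab > 0 else "negative")
    for n in g.nodes:
        g.nodes[n]["domain"] = domains[n]
    return CoNetwork(graph=g, group=group, mode=mode)


def detect_modules(net: CoNetwork, seed: int = 0):
    """Louvain partition of the unweighted graph plus its Newman-Girvan
    modularity Q.  Deterministic under ``seed``; stores the result on the
    network.  An edgeless network has undefined Q (flagged, ``None``)."""
    if net.n_edges == 0:
        warnings.warn(f"{net.group}/{net.mode}: edgeless network, modularity undefined")
        net.modules, net.modularity = {}, None
        return {}, None
    comms = nx.community.louvain_communities(net.graph, weight=None, seed=seed)
    q = nx.community.modularity(net.graph, comms, weight=None)
    modules = {}
    for k, comm in enumerate(sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))):
        for node in comm:
            modules[node] = k
    net.modules, net.modularity = modules, float(q)
    return modules, float(q)


def topology(net: CoNetwork) -> TopologySummary:
    """Topological summary; path metrics are over unordered reachable pairs
    within components (disconnected graphs report within-component values)."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return TopologySummary(0, 0, 0.0, 0.0, 0.0, 0.0, 0.0,
                               net.modularity, None, 0.0)
    avg_degree = 2.0 * e / n
    density = nx.density(g)
    clustering = nx.average_clustering(g)  # degree<2 nodes contribute 0
    lengths = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        for src, dists in nx.all_pairs_shortest_path_length(sub):
            for dst, l in dists.items():
                if src < dst:
                    lengths.append(l)
    diameter = float(max(lengths)) if lengths else 0.0
    avg_path = float(np.mean(lengths)) if lengths else 0.0
    signs = [attr["sign"] for _, _, attr in g.edges(data=True)]
    pct_pos = 100.0 * sum(s == "positive" for s in signs) / e if e else 0.0
    n_modules = len(set(net.modules.values())) if net.modules else None
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        avg_degree=avg_degree,
        clustering_coefficient=clustering,
        density=density,
        diameter=diameter,
        avg_path_length=avg_path,
        modularity=net.modularity,
        n_modules=n_modules,
        pct_positive_edges=pct_pos,
    )


# ---------------------------------------------------------------------------
# convenience: tables -> network
# ---------------------------------------------------------------------------

def network_from_tables(rel_bacteria: RelAbundanceTable | None,
                        rel_fungi: RelAbundanceTable | None,
                        samples, mode: str, group: str,
                        seed: int = 0, **thresholds) -> CoNetwork:
    """Filter genera, correlate, gate and modularise in one call.

    For single-domain modes pass that domain's table; for
    ``cross_domain`` pass both.
    """
    filter_kw = {k: thresholds[k] for k in
                 ("occurrence_min", "bacterial_mean_ra_min", "fungal_mean_ra_min")
                 if k in thresholds}
    gate_kw = {k: thresholds[k] for k in ("rho_min", "q_max") if k in thresholds}
    parts, domains = [], {}
    for rel in (rel_bacteria, rel_fungi):
        if rel is None:
            continue
        if mode != "cross_domain" and rel.domain != mode:
            continue
        kept = filter_genera(rel, samples, rel.domain, **filter_kw)
        part = rel.values.loc[kept, list(samples)]
        parts.append(part)
        domains.update({t: rel.domain for t in kept})
    if not parts:
        raise ValueError(f"no tables supplied for mode {mode!r}")
    values = pd.concat(parts, axis=0)
    rho, p = spearman_matrix(values)
    net = build_network(rho, p, mode=mode, group=group, domains=domains, **gate_kw)
    detect_modules(net, seed=seed)
    return net


def write_edge_list(net: CoNetwork, path) -> None:
    net.edge_table().to_csv(path, sep="\t", index=False)
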