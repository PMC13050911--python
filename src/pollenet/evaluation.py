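"""Validation experiments that exercise the pipeline against planted ground
truth or closed-form expectations.

These are the package's own end-to-end checks: planted correlation-block
edge recovery, keystone identification against an exhaustive small-graph
oracle, Louvain modularity against closed forms, PERMANOVA type-I error
under an exchangeable null, the discrete support of the 4-species bootstrap
Spearman, and recovery of the planted core-set summed abundance.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

from .core_visitation import bootstrap_species_spearman, core_contribution, identify_core
from .diversity import bray_curtis, permanova
from .io_model import RelAbundanceTable, assign_groups, to_relative_abundance
from .networks import CoNetwork, detect_modules, network_from_tables
from .synthetic import SynthSpec, generate_counts, generate_pollen_counts

__all__ = [
    "planted_edge_recovery",
    "brute_force_core",
    "keystone_oracle_agreement",
    "modularity_closed_forms",
    "permanova_type1_error",
    "bootstrap_lattice_check",
    "core_contribution_recovery",
    "remaining_rate_calibration",
]


# ---------------------------------------------------------------------------
# planted-block edge recovery
# ---------------------------------------------------------------------------

def planted_edge_recovery(n_seeds: int = 10, base_seed: int = 0,
                          domain: str = "bacteria",
                          group: str = "Cross_open") -> dict:
    """Build the per-group network on synthetic data and score it against
    the planted correlation blocks.

    Recovery is the fraction of planted within-block pairs retained as
    edges; the spurious rate is the fraction of cross-block pairs (taxa in
    two *different* planted blocks, latently independent) retained as
    edges.  Both are averaged over ``n_seeds`` independent datasets.
    """
    recov, spurious = [], []
    for k in range(n_seeds):
        spec = SynthSpec(seed=base_seed + k)
        bact, fung, meta = generate_counts(spec)
        groups = assign_groups(meta)
        samples = [s for s in groups.index if groups[s] == group]
        rel_b = to_relative_abundance(bact)
        rel_f = to_relative_abundance(fung)
        net = network_from_tables(rel_b, rel_f, samples, mode=domain, group=group,
                                  seed=base_seed + k)
        edges = {frozenset((a, b)) for a, b in net.graph.edges}
        block_of = {}
        blocks = [b for b in spec.planted_blocks
                  if all(t in spec.taxon_ids(domain) for t in b.taxa)]
        for i, blk in enumerate(blocks):
            for t in blk.taxa:
                block_of[t] = i
        within = [frozenset((a, b))
                  for blk in blocks for a, b in itertools.combinations(blk.taxa, 2)]
        cross = [frozenset((a, b))
                 for a, b in itertools.combinations(block_of, 2)
                 if block_of[a] != block_of[b]]
        recov.append(sum(pair in edges for pair in within) / len(within))
        spurious.append(sum(pair in edges for pair in cross) / len(cross))
    return {
        "recovery": float(np.mean(recov)),
        "spurious": float(np.mean(spurious)),
        "per_seed_recovery": recov,
        "per_seed_spurious": spurious,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# keystone oracle
# ---------------------------------------------------------------------------

def _bfs_shortest_path_counts(g: nx.Graph, src):
    """Distances and shortest-path counts from ``src`` plus the number of
    shortest s->t paths through each node, by explicit BFS DAG accumulation
    (Brandes-free; independent of networkx centrality code)."""
    dist = {src: 0}
    sigma = {src: 1.0}
    order = [src]
    queue = deque([src])
    preds: dict = {src: []}
    while queue:
        v = queue.popleft()
        for w in g.neighbors(v):
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0.0
                preds[w] = []
                order.append(w)
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return dist, sigma, preds, order


def _brute_betweenness(g: nx.Graph) -> dict:
    """Unweighted betweenness by enumerating all shortest paths pair by
    pair (feasible for small graphs only)."""
    nodes = list(g.nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist, sigma, preds, _ = _bfs_shortest_path_counts(g, s)
        if t not in dist or sigma[t] == 0:
            continue
        # enumerate all shortest s-t paths by walking predecessor lists
        stack = [[t]]
        paths = []
        while stack:
            path = stack.pop()
            head = path[-1]
            if head == s:
                paths.append(path)
                continue
            for p in preds[head]:
                stack.append(path + [p])
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0 if n > 2 else 1.0
    return {v: s / norm for v, s in score.items()}


def brute_force_core(g: nx.Graph, top_fraction: float = 0.10) -> list:
    """Reference keystone set: same top-decile union rule, but with degree
    and betweenness computed from scratch."""
    nodes = sorted(g.nodes)
    if not nodes or g.number_of_edges() == 0:
        return []
    k = math.ceil(top_fraction * len(nodes))
    deg = {v: sum(1 for _ in g.neighbors(v)) for v in nodes}
    btw = {v: round(b, 10) for v, b in _brute_betweenness(g).items()}
    by_deg = sorted(nodes, key=lambda v: (-deg[v], -btw[v], v))[:k]
    by_btw = sorted(nodes, key=lambda v: (-btw[v], -deg[v], v))[:k]
    return sorted(set(by_deg) | set(by_btw))


def keystone_oracle_agreement(n_graphs: int = 200, seed: int = 0,
                              n_max: int = 12) -> dict:
    """Compare :func:`identify_core` with the exhaustive oracle on a corpus
    of random graphs with at most ``n_max`` nodes."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_graphs):
        n = int(rng.integers(4, n_max + 1))
        p = float(rng.uniform(0.2, 0.6))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        if g.number_of_edges() == 0:
            g.add_edge("n00", "n01")
        net = CoNetwork(graph=g, group="synthetic", mode="bacteria")
        if identify_core(net) == brute_force_core(g):
            agree += 1
    return {"agreement": agree / n_graphs, "n_graphs": n_graphs}


# ---------------------------------------------------------------------------
# modularity closed forms
# ---------------------------------------------------------------------------

def modularity_closed_forms(seed: int = 0) -> dict:
    """Louvain Q on two graphs with known optima: two disjoint triangles
    (Q = 0.5) and the complete graph K5 (Q = 0)."""
    tri = nx.Graph()
    tri.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    net_tri = CoNetwork(graph=tri, group="toy", mode="bacteria")
    _, q_tri = detect_modules(net_tri, seed=seed)
    k5 = nx.complete_graph(5)
    net_k5 = CoNetwork(graph=k5, group="toy", mode="bacteria")
    _, q_k5 = detect_modules(net_k5, seed=seed)
    return {"two_triangles": q_tri, "k5": q_k5}


# ---------------------------------------------------------------------------
# PERMANOVA type-I calibration
# ---------------------------------------------------------------------------

def permanova_type1_error(n_sims: int = 1000, n_per_group: int = 6,
                          n_groups: int = 2, n_taxa: int = 20,
                          alpha: float = 0.05, n_perm: int = 199,
                          seed: int = 0) -> dict:
    """Rejection rate of PERMANOVA at ``alpha`` when group labels are
    exchangeable (iid lognormal compositions, no group effect)."""
    rng = np.random.default_rng(seed)
    n = n_per_group * n_groups
    labels = np.repeat([f"g{i}" for i in range(n_groups)], n_per_group)
    rejections = 0
    for _ in range(n_sims):
        comp = np.exp(rng.normal(0, 1, size=(n_taxa, n)))
        comp /= comp.sum(axis=0)
        rel = RelAbundanceTable(
            values=pd.DataFrame(comp, index=[f"t{i}" for i in range(n_taxa)],
                                columns=[f"s{i}" for i in range(n)]),
            taxonomy=pd.Series("unclassified", index=[f"t{i}" for i in range(n_taxa)]),
            domain="bacteria",
        )
        d = bray_curtis(rel)
        res = permanova(d, labels, n_permutations=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        if res.p_value <= alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims,
            "alpha": alpha}


# ---------------------------------------------------------------------------
# bootstrap lattice
# ---------------------------------------------------------------------------

def bootstrap_lattice_check(n_iter: int = 5000, seed: int = 0) -> dict:
    """At 4 species without ties, Spearman's rho can only take the 11
    lattice values {0, +/-0.2, ..., +/-1.0}.  Checks the entire bootstrap
    distribution against that support and re-runs for seed determinism."""
    spec = SynthSpec(seed=seed)
    pollen = generate_pollen_counts(spec)
    rng = np.random.default_rng(seed + 1)
    x = {sp: pollen.loc[(pollen.species == sp) & (pollen.treatment == "open"),
                        "grains"].to_numpy()
         for sp in spec.species}
    y = {sp: rng.normal(50 + 10 * i, 5, spec.n_reps)
         for i, sp in enumerate(spec.species)}
    boot = bootstrap_species_spearman(x, y, n_iter=n_iter, seed=seed)
    lattice = np.round(np.arange(-1.0, 1.01, 0.2), 10)
    valid = boot.rhos[~np.isnan(boot.rhos)]
    on_lattice = np.isclose(valid[:, None], lattice[None, :], atol=1e-9).any(axis=1)
    boot2 = bootstrap_species_spearman(x, y, n_iter=n_iter, seed=seed)
    return {
        "fraction_on_lattice": float(on_lattice.mean()),
        "n_valid": int(valid.size),
        "deterministic": bool(
            np.array_equal(boot.rhos, boot2.rhos, equal_nan=True)
            and boot.ci_low == boot2.ci_low and boot.ci_high == boot2.ci_high
        ),
        "median": boot.median,
        "ci": (boot.ci_low, boot.ci_high),
    }


# ---------------------------------------------------------------------------
# planted core recovery / pollen calibration
# ---------------------------------------------------------------------------

def core_contribution_recovery(seed: int = 0, domain: str = "fungi") -> dict:
    """Recover the planted core set's summed relative abundance in the
    cross-pollinated open group."""
    spec = SynthSpec(seed=seed)
    bact, fung, meta = generate_counts(spec)
    table = {"bacteria": bact, "fungi": fung}[domain]
    groups = assign_groups(meta)
    core = next(c for c in spec.core_specs
                if set(c.taxa) <= set(spec.taxon_ids(domain)))
    samples = [s for s in groups.index if groups[s] == core.group]
    rel = to_relative_abundance(table)
    report = core_contribution(core.taxa, rel, samples, group=core.group)
    return {
        "planted_pct": 100.0 * core.target,
        "recovered_mean_pct": report.taxo_contrib_mean,
        "recovered_se_pct": report.taxo_contrib_se,
        "n_samples": len(samples),
    }


def remaining_rate_calibration(n_seeds: int = 200, base_seed: int = 0) -> dict:
    """Mean simulated remaining rate per species over many generator seeds,
    for comparison with the per-species target means."""
    from .core_visitation import remaining_rate_table

    spec0 = SynthSpec()
    sums = {sp: [] for sp in spec0.species}
    for k in range(n_seeds):
        pollen = generate_pollen_counts(SynthSpec(seed=base_seed + k))
        rates = remaining_rate_table(pollen)
        for sp in spec0.species:
            sums[sp].append(rates.loc[rates.species == sp, "remaining_rate"].mean())
    return {sp: {"mean": float(np.mean(v)),
                 "se": float(np.std(v, ddof=1) / np.sqrt(len(v)))}
            for sp, v in sums.items()}
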