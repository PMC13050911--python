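"""Core (keystone) taxa, their community contribution, and the
insect-visitation statistics built on pollen remaining rates.

Core taxa are network nodes ranked in the top 10% for *either* degree or
betweenness centrality (union rule, ceil cutoff).  Their contribution is
the per-sample summed relative abundance (taxonomic, and weighted by
predicted-function tables) reported as mean +/- SE in percent.

The pollen remaining rate of an open-treatment replicate is its grain
count as a percentage of the species' mean bagged-treatment count; the
species-level association between remaining rate and core-taxon function
is estimated with an unpaired bootstrap Spearman correlation, and the
LA-vs-MC contrast with Cohen's d (pooled SD; +/- values read as SEs are
converted via sd = se * sqrt(n)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._letters import compact_letters
from .diversity import AnovaResult
from .io_model import FunctionTable, RelAbundanceTable
from .networks import CoNetwork

__all__ = [
    "CoreReport",
    "BootstrapSpearman",
    "VisitationResult",
    "identify_core",
    "core_contribution",
    "core_count_summary",
    "remaining_rate",
    "remaining_rate_table",
    "tukey_anova",
    "bootstrap_species_spearman",
    "cohens_d",
    "trophic_breakdown",
    "visitation_analysis",
]


@dataclass
class CoreReport:
    """Per-group core genus set and its taxonomic/functional contribution."""

    group: str
    domain: str
    core_genera: list
    taxo_contrib_mean: float  # percent
    taxo_contrib_se: float
    func_contrib_mean: float | None = None
    func_contrib_se: float | None = None

    @property
    def n_core(self) -> int:
        return len(self.core_genera)


@dataclass
class BootstrapSpearman:
    rhos: np.ndarray
    median: float
    mean: float
    ci_low: float
    ci_high: float
    n_iterations: int
    n_missing: int = 0


@dataclass
class VisitationResult:
    rates: pd.DataFrame          # species, replicate, remaining_rate
    species_summary: pd.DataFrame  # mean, se, letter per species
    anova: AnovaResult
    bootstrap: BootstrapSpearman | None = None
    cohens_d: float | None = None


# ---------------------------------------------------------------------------
# core taxa
# ---------------------------------------------------------------------------

def identify_core(net: CoNetwork, top_fraction: float = 0.10) -> list:
    """Nodes in the top ``top_fraction`` (ceil) by degree OR betweenness.

    Betweenness is unweighted shortest-path betweenness, rounded to 10
    decimals so float summation order cannot break mathematical ties.
    Ties at the cutoff rank are broken by the other centrality, then
    lexicographic id.  Edgeless networks yield an empty core with a
    warning.
    """
    g = net.graph
    nodes = sorted(g.nodes)
    if not nodes or g.number_of_edges() == 0:
        warnings.warn(f"{net.group}/{net.mode}: edgeless network, no core taxa")
        return []
    k = math.ceil(top_fraction * len(nodes))
    deg = dict(g.degree())
    btw = {v: round(b, 10)
           for v, b in nx.betweenness_centrality(g, normalized=True).items()}
    by_deg = sorted(nodes, key=lambda v: (-deg[v], -btw[v], v))[:k]
    by_btw = sorted(nodes, key=lambda v: (-btw[v], -deg[v], v))[:k]
    return sorted(set(by_deg) | set(by_btw))


def core_contribution(core, r: RelAbundanceTable, samples,
                      f: FunctionTable | None = None,
                      group: str = "", domain: str | None = None) -> CoreReport:
    """Mean +/- SE (percent) of the per-sample summed relative abundance of
    the core set, taxonomic and (if a function table is given) weighted by
    per-genus predicted-function weights."""
    core = sorted(core)
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample group")
    missing = [t for t in core if t not in r.values.index]
    if missing:
        raise ValueError(f"core genera absent from the table: {missing}")
    sub = r.values.loc[core, samples] if core else pd.DataFrame(
        np.zeros((0, len(samples))), columns=samples)
    taxo = sub.sum(axis=0).to_numpy() * 100.0
    n = len(samples)
    se = float(np.std(taxo, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    func_mean = func_se = None
    if f is not None:
        w = f.genus_weights().reindex(core).fillna(0.0)
        func = (sub.mul(w, axis=0).sum(axis=0)).to_numpy() * 100.0
        func_mean = float(np.mean(func)) if core else 0.0
        func_se = float(np.std(func, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return CoreReport(
        group=group,
        domain=domain or r.domain,
        core_genera=core,
        taxo_contrib_mean=float(np.mean(taxo)) if core else 0.0,
        taxo_contrib_se=se if core else 0.0,
        func_contrib_mean=func_mean,
        func_contrib_se=func_se,
    )


def core_count_summary(counts_by_group: dict) -> dict:
    """Aggregate per-group core genus counts.

    ``counts_by_group`` maps ``(domain, group) -> n_core``.  Returns totals
    per domain, the grand total, and the percentage share of the
    cross-pollinated open group.
    """
    total = sum(counts_by_group.values())
    by_domain: dict = {}
    cross_open = 0
    for (domain, group), n in counts_by_group.items():
        by_domain[domain] = by_domain.get(domain, 0) + n
        if group == "Cross_open":
            cross_open += n
    share = 100.0 * cross_open / total if total else 0.0
    return {
        "total": total,
        "by_domain": by_domain,
        "cross_open": cross_open,
        "cross_open_share_pct": share,
    }


def trophic_breakdown(r: RelAbundanceTable, f: FunctionTable, samples) -> pd.DataFrame:
    """Per-sample summed relative abundance (%) by trophic mode / function
    label, with mean and SE columns.  Descriptive only."""
    samples = list(samples)
    rows = {}
    for mode, sub in f.table.groupby("function_id"):
        w = sub.set_index("taxon_id")["value"]
        taxa = [t for t in w.index if t in r.values.index]
        vals = r.values.loc[taxa, samples].mul(w.reindex(taxa), axis=0).sum(axis=0) * 100
        rows[mode] = vals
    out = pd.DataFrame(rows).T
    out["mean"] = out[samples].mean(axis=1)
    out["se"] = out[samples].std(axis=1, ddof=1) / np.sqrt(len(samples))
    return out


# ---------------------------------------------------------------------------
# pollen remaining rate
# ---------------------------------------------------------------------------

def remaining_rate(pollen: pd.DataFrame, species: str) -> np.ndarray:
    """Per-replicate pollen remaining rates (%) for one species:
    ``100 * open_i / mean(bagging)``.  Rates may exceed 100."""
    sub = pollen[pollen["species"] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} not in the pollen table")
    bag = sub.loc[sub["treatment"] == "bagging", "grains"].to_numpy(dtype=float)
    opn = sub.loc[sub["treatment"] == "open", "grains"].to_numpy(dtype=float)
    if bag.size == 0 or bag.mean() <= 0:
        raise ValueError(f"species {species!r}: bagging mean must be positive")
    return 100.0 * opn / bag.mean()


def remaining_rate_table(pollen: pd.DataFrame) -> pd.DataFrame:
    """Long table of per-replicate remaining rates for every species."""
    rows = []
    for sp in pollen["species"].unique():
        for i, rate in enumerate(remaining_rate(pollen, sp), start=1):
            rows.append({"species": sp, "replicate": i, "remaining_rate": rate})
    return pd.DataFrame(rows)


def tukey_anova(values, labels, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc tests and compact letters.

    Levene's test for homogeneity of variances is reported alongside
    (the design calls for checking it before the ANOVA).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[labels == g] for g in groups]
    for g, v in zip(groups, by_group):
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    lev_stat, lev_p = stats.levene(*by_group)
    if np.allclose(values, values[0]):
        effects = pd.DataFrame({"F": [0.0], "df1": [len(groups) - 1],
                                "df2": [len(values) - len(groups)], "p": [1.0]},
                               index=["species"])
        letters = {g: "a" for g in groups}
        return AnovaResult(effects=effects, posthoc=None, letters=letters,
                           notes=["constant response",
                                  f"levene_stat={lev_stat}", f"levene_p={lev_p}"])
    f_stat, p_val = stats.f_oneway(*by_group)
    effects = pd.DataFrame(
        {"F": [float(f_stat)], "df1": [len(groups) - 1],
         "df2": [len(values) - len(groups)], "p": [float(p_val)]},
        index=["species"],
    )
    hsd = stats.tukey_hsd(*by_group)
    rows, pair_p = [], {}
    for i, a in enumerate(groups):
        for j, b in enumerate(groups):
            if i < j:
                pv = float(hsd.pvalue[i, j])
                rows.append({"A": a, "B": b,
                             "diff": float(np.mean(by_group[i]) - np.mean(by_group[j])),
                             "p": pv})
                pair_p[frozenset((a, b))] = pv
    means = {g: float(np.mean(v)) for g, v in zip(groups, by_group)}
    letters = compact_letters(groups, pair_p, means, alpha=alpha)
    return AnovaResult(effects=effects, posthoc=pd.DataFrame(rows), letters=letters,
                       notes=[f"levene_stat={float(lev_stat)}",
                              f"levene_p={float(lev_p)}"])


# ---------------------------------------------------------------------------
# bootstrap Spearman and Cohen's d
# ---------------------------------------------------------------------------

def bootstrap_species_spearman(x: dict, y: dict, n_iter: int = 5000,
                               seed: int = 0) -> BootstrapSpearman:
    """Species-level Spearman correlation by unpaired bootstrap.

    ``x`` and ``y`` map species -> replicate arrays.  Each iteration
    resamples every species' x-replicates and y-replicates independently
    with replacement (the two measurements come from different samples and
    are not paired), takes species means, and computes the Spearman rho
    across species.  Iterations whose species means have zero rank variance
    are recorded as missing.
    """
    species = sorted(x)
    if sorted(y) != species:
        raise ValueError("x and y must cover the same species")
    if len(species) < 3:
        raise ValueError("need at least 3 species")
    for sp in species:
        if len(x[sp]) < 2 or len(y[sp]) < 2:
            raise ValueError(f"species {sp!r} needs >= 2 replicates per variable")
    rng = np.random.default_rng(seed)
    s = len(species)
    xm = np.empty((n_iter, s))
    ym = np.empty((n_iter, s))
    for k, sp in enumerate(species):
        arr = np.asarray(x[sp], dtype=float)
        idx = rng.integers(0, len(arr), size=(n_iter, len(arr)))
        xm[:, k] = arr[idx].mean(axis=1)
    for k, sp in enumerate(species):
        arr = np.asarray(y[sp], dtype=float)
        idx = rng.integers(0, len(arr), size=(n_iter, len(arr)))
        ym[:, k] = arr[idx].mean(axis=1)
    rx = stats.rankdata(xm, axis=1)
    ry = stats.rankdata(ym, axis=1)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c ** 2).sum(axis=1) * (ry_c ** 2).sum(axis=1))
    valid = denom > 0
    rhos = np.full(n_iter, np.nan)
    rhos[valid] = (rx_c * ry_c).sum(axis=1)[valid] / denom[valid]
    good = rhos[valid]
    if good.size == 0:
        raise ValueError("all bootstrap iterations had undefined rho")
    lo, hi = np.percentile(good, [2.5, 97.5])
    return BootstrapSpearman(
        rhos=rhos,
        median=float(np.median(good)),
        mean=float(np.mean(good)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_iterations=n_iter,
        n_missing=int((~valid).sum()),
    )


def cohens_d(m1: float, disp1: float, n1: int, m2: float, disp2: float, n2: int,
             dispersion: str = "se") -> float:
    """Cohen's d with pooled SD.

    ``dispersion`` is ``"sd"`` or ``"se"``; SEs are converted via
    ``sd = se * sqrt(n)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if disp1 <= 0 or disp2 <= 0:
        raise ValueError("dispersions must be positive")
    if dispersion == "se":
        s1, s2 = disp1 * math.sqrt(n1), disp2 * math.sqrt(n2)
    elif dispersion == "sd":
        s1, s2 = disp1, disp2
    else:
        raise ValueError("dispersion must be 'sd' or 'se'")
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("pooled variance is zero")
    return (m1 - m2) / math.sqrt(sp2)


def visitation_analysis(pollen: pd.DataFrame, core_function_by_species: dict | None
                        = None, n_iter: int = 5000, seed: int = 0,
                        d_pair: tuple = ("LA", "MC")) -> VisitationResult:
    """Full visitation workflow: remaining rates, one-way ANOVA with Tukey
    letters, optional bootstrap Spearman against per-species core-function
    replicates, and the Cohen's d contrast for ``d_pair``."""
    rates = remaining_rate_table(pollen)
    anova = tukey_anova(rates["remaining_rate"], rates["species"])
    summary = (
        rates.groupby("species")["remaining_rate"]
        .agg(mean="mean", se=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    if anova.letters:
        summary["letter"] = summary["species"].map(anova.letters)
    boot = None
    if core_function_by_species is not None:
        x = {sp: rates.loc[rates["species"] == sp, "remaining_rate"].to_numpy()
             for sp in rates["species"].unique()}
        boot = bootstrap_species_spearman(x, core_function_by_species,
                                          n_iter=n_iter, seed=seed)
    d = None
    a, b = d_pair
    if {a, b} <= set(rates["species"]):
        ra = rates.loc[rates["species"] == a, "remaining_rate"].to_numpy()
        rb = rates.loc[rates["species"] == b, "remaining_rate"].to_numpy()
        d = cohens_d(ra.mean(), ra.std(ddof=1), len(ra),
                     rb.mean(), rb.std(ddof=1), len(rb), dispersion="sd")
    return VisitationResult(rates=rates, species_summary=summary, anova=anova,
                            bootstrap=boot, cohens_d=d)
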