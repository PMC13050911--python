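"""Alpha and beta diversity: rarefaction, Chao1, Shannon, Faith's PD,
Venn OTU partitioning, ANOVA comparisons, Bray-Curtis and PERMANOVA.

Conventions (stated because the indices have several dialects):

* Chao1 is the bias-corrected form ``S_obs + F1(F1-1) / (2(F2+1))`` so that
  doubleton-free samples remain defined.
* Shannon entropy uses natural logarithms (nats).
* Faith's PD is rooted: the branch path from every observed tip up to the
  root is included.
* Rarefaction subsamples reads without replacement (multivariate
  hypergeometric), one draw per sample; samples below the depth are
  excluded and listed, not rescued by lowering the depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist

from ._letters import compact_letters
from .io_model import CountTable, PhyloTree, RelAbundanceTable, validate_metadata

__all__ = [
    "DiversityTable",
    "AnovaResult",
    "PermanovaResult",
    "rarefy",
    "chao1",
    "shannon",
    "faith_pd",
    "alpha_diversity",
    "venn_partition",
    "two_way_anova",
    "welch_games_howell",
    "bray_curtis",
    "permanova",
]


@dataclass
class DiversityTable:
    """Per-sample alpha-diversity indices at a fixed rarefaction depth."""

    per_sample: pd.DataFrame  # columns: chao1, shannon, pd (pd optional)
    rarefaction_depth: int
    excluded_samples: list = field(default_factory=list)


@dataclass
class AnovaResult:
    """Factor effects plus optional post-hoc table and significance letters."""

    effects: pd.DataFrame  # index: factor; columns: F, df1, df2 (or df), p
    posthoc: pd.DataFrame | None = None
    letters: dict | None = None
    notes: list = field(default_factory=list)


@dataclass
class PermanovaResult:
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# rarefaction and alpha indices
# ---------------------------------------------------------------------------

def rarefy(t: CountTable, depth: int, seed: int = 0):
    """Subsample every sample to ``depth`` reads without replacement.

    Returns ``(CountTable, excluded)`` where ``excluded`` lists
    ``(sample_id, reason)`` for samples whose library is below the depth.
    Raises if no sample reaches the depth.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    libs = t.library_sizes()
    keep = [s for s in t.sample_ids if libs[s] >= depth]
    excluded = [
        (s, f"library {int(libs[s])} < depth {depth}")
        for s in t.sample_ids
        if libs[s] < depth
    ]
    if not keep:
        raise ValueError(f"rarefaction depth {depth} exceeds every library size")
    rng = np.random.default_rng(seed)
    out = np.empty((len(t.taxon_ids), len(keep)), dtype=np.int64)
    for j, s in enumerate(keep):
        col = t.counts[s].to_numpy()
        if libs[s] == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=t.taxon_ids, columns=keep)
    rarefied = CountTable(
        counts=counts, taxonomy=t.taxonomy.copy(), domain=t.domain, level=t.level
    )
    return rarefied, excluded


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: ``S_obs + F1(F1-1) / (2(F2+1))``."""
    x = np.asarray(counts)
    if not np.issubdtype(x.dtype, np.integer):
        if not np.allclose(x, np.round(x)):
            raise ValueError("chao1 requires integer counts")
        x = np.round(x).astype(np.int64)
    if (x < 0).any():
        raise ValueError("chao1 requires non-negative counts")
    s_obs = int((x > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon entropy in nats over the nonzero proportions."""
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("shannon requires a positive library size")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def faith_pd(counts, taxon_ids, tree: PhyloTree) -> float:
    """Rooted Faith's phylogenetic diversity.

    Sum of branch lengths of the minimal rooted subtree spanning the root
    and every taxon with count > 0.  Errors if an observed taxon is missing
    from the tree.
    """
    x = np.asarray(counts)
    observed = [t for t, c in zip(taxon_ids, x) if c > 0]
    if not observed:
        return 0.0
    tips = {tip.name: tip for tip in tree.tree.tips()}
    seen: set = set()
    total = 0.0
    for name in observed:
        node = tips.get(name)
        if node is None:
            raise ValueError(f"observed taxon {name!r} not found in the tree")
        while node is not None and id(node) not in seen:
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def alpha_diversity(t: CountTable, depth: int, tree: PhyloTree | None = None,
                    seed: int = 0) -> DiversityTable:
    """Rarefy, then compute Chao1, Shannon and (if a tree is given) PD per
    sample."""
    rarefied, excluded = rarefy(t, depth, seed=seed)
    rows = {}
    for s in rarefied.sample_ids:
        col = rarefied.counts[s].to_numpy()
        row = {"chao1": chao1(col), "shannon": shannon(col)}
        if tree is not None:
            row["pd"] = faith_pd(col, rarefied.taxon_ids, tree)
        rows[s] = row
    return DiversityTable(
        per_sample=pd.DataFrame.from_dict(rows, orient="index"),
        rarefaction_depth=depth,
        excluded_samples=excluded,
    )


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

def venn_partition(t: CountTable, meta: pd.DataFrame, species: str) -> dict:
    """Shared / unique OTU counts between the open and bagging treatments of
    one plant species, with percentages of each treatment's OTU pool."""
    meta = validate_metadata(meta)
    sub = meta[meta["species"] == species]
    if sub.empty:
        raise ValueError(f"species {species!r} not present in metadata")
    pools = {}
    for tr in ("open", "bagging"):
        samples = [
            s for s in sub.loc[sub["treatment"] == tr, "sample_id"] if s in t.sample_ids
        ]
        if not samples:
            raise ValueError(f"species {species!r} has no {tr!r} samples in the table")
        present = (t.counts[samples] > 0).any(axis=1)
        pools[tr] = set(t.counts.index[present])
    shared = pools["open"] & pools["bagging"]
    uo = pools["open"] - pools["bagging"]
    ub = pools["bagging"] - pools["open"]

    def pct(part, pool):
        return 100.0 * len(part) / len(pool) if pool else 0.0

    return {
        "n_shared": len(shared),
        "n_unique_open": len(uo),
        "n_unique_bagging": len(ub),
        "pct_unique_open": pct(uo, pools["open"]),
        "pct_unique_bagging": pct(ub, pools["bagging"]),
        "pct_shared_open": pct(shared, pools["open"]),
        "pct_shared_bagging": pct(shared, pools["bagging"]),
    }


# ---------------------------------------------------------------------------
# ANOVA family
# ---------------------------------------------------------------------------

def two_way_anova(values: pd.Series, meta: pd.DataFrame) -> AnovaResult:
    """Two-way ANOVA of a per-sample index on treatment, species and their
    interaction (classical decomposition; type II sums of squares, which
    coincide with the balanced-design partition).

    Cells with fewer than 2 replicates make the interaction term
    unavailable; it is flagged in ``notes`` and an additive model is fit.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    meta = validate_metadata(meta).set_index("sample_id")
    df = pd.DataFrame(
        {
            "value": values,
            "treatment": meta.loc[values.index, "treatment"].to_numpy(),
            "species": meta.loc[values.index, "species"].to_numpy(),
        }
    )
    notes: list = []
    if np.isclose(df["value"].var(ddof=0), 0.0):
        # degenerate: nothing to partition
        effects = pd.DataFrame(
            {"F": 0.0, "df": [1, 1, 1], "p": 1.0},
            index=["treatment", "species", "treatment:species"],
        )
        return AnovaResult(effects=effects, notes=["constant response"])
    cell_n = df.groupby(["treatment", "species"], sort=True).size()
    with_interaction = (cell_n >= 2).all()
    if not with_interaction:
        notes.append("interaction unavailable: a cell has < 2 replicates")
        model = ols("value ~ C(treatment) + C(species)", data=df).fit()
    else:
        model = ols("value ~ C(treatment) * C(species)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    rename = {
        "C(treatment)": "treatment",
        "C(species)": "species",
        "C(treatment):C(species)": "treatment:species",
    }
    effects = pd.DataFrame(
        {
            "F": [tab.loc[k, "F"] for k in tab.index if k in rename],
            "df": [tab.loc[k, "df"] for k in tab.index if k in rename],
            "p": [tab.loc[k, "PR(>F)"] for k in tab.index if k in rename],
        },
        index=[rename[k] for k in tab.index if k in rename],
    )
    return AnovaResult(effects=effects, notes=notes)


def welch_games_howell(values, labels, alpha: float = 0.05) -> AnovaResult:
    """Welch's ANOVA (Satterthwaite df) with Games-Howell pairwise post-hoc
    tests and compact significance letters at ``alpha``."""
    import pingouin as pg

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": np.asarray(labels)})
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, sub in df.groupby("group"):
        if len(sub) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        if np.isclose(sub["value"].var(ddof=1), 0.0):
            raise ValueError(
                f"group {g!r} has zero variance; Welch's ANOVA is undefined "
                "for exact ties — jitter or use an exact test"
            )
    welch = pg.welch_anova(data=df, dv="value", between="group")
    f_val = float(welch.loc[0, "F"])
    p_val = float(welch.loc[0, "p_unc"])
    df1 = float(welch.loc[0, "ddof1"])
    df2 = float(welch.loc[0, "ddof2"])
    effects = pd.DataFrame(
        {"F": [f_val], "df1": [df1], "df2": [df2], "p": [p_val]}, index=["group"]
    )
    gh = pg.pairwise_gameshowell(data=df, dv="value", between="group")
    posthoc = gh.rename(columns={"pval": "p"})[["A", "B", "diff", "se", "df", "p"]]
    pair_p = {frozenset((r["A"], r["B"])): r["p"] for _, r in posthoc.iterrows()}
    means = df.groupby("group")["value"].mean().to_dict()
    letters = compact_letters(groups, pair_p, means, alpha=alpha)
    return AnovaResult(effects=effects, posthoc=posthoc, letters=letters)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(r: RelAbundanceTable) -> pd.DataFrame:
    """Sample x sample Bray-Curtis dissimilarity
    ``BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``.

    Pairs of all-zero samples are undefined (NaN) and flagged with a
    warning.
    """
    vals = r.values.to_numpy().T  # samples x taxa
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero = vals.sum(axis=1) == 0
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(vals, metric="braycurtis"))
    if zero.sum() >= 2:
        warnings.warn("pairs of all-zero samples yield undefined Bray-Curtis entries")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=r.sample_ids, columns=r.sample_ids)


def _permute_pseudo_f(d2: np.ndarray, labels: np.ndarray, n_perm: int,
                      rng: np.random.Generator):
    """Observed pseudo-F plus its permutation distribution (vectorised)."""
    n = len(labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    ss_total = d2.sum() / (2.0 * n)

    def ss_within(assign):
        ssw = 0.0
        for g in range(k):
            idx = np.where(assign == g)[0]
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        return ssw

    ssw_obs = ss_within(inv)
    ssa_obs = ss_total - ssw_obs
    f_obs = (ssa_obs / (k - 1)) / (ssw_obs / (n - k))

    perms = np.array([rng.permutation(inv) for _ in range(n_perm)])
    ssw_perm = np.zeros(n_perm)
    for g in range(k):
        y = (perms == g).astype(float)  # n_perm x n
        n_g = int((inv == g).sum())
        ssw_perm += np.einsum("pi,ij,pj->p", y, d2, y) / (2.0 * n_g)
    ssa_perm = ss_total - ssw_perm
    f_perm = (ssa_perm / (k - 1)) / (ssw_perm / (n - k))
    return f_obs, f_perm, ssa_obs / ss_total


def permanova(d: pd.DataFrame, grouping, n_permutations: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Pseudo-F partitions the squared-dissimilarity sums; the p-value is
    ``(1 + #{permuted F >= observed}) / (1 + n_permutations)`` so its
    resolution is ``1/(n_permutations + 1)`` and it is never 0.
    """
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    labels = np.asarray(pd.Series(grouping).reindex(d.index)
                        if isinstance(grouping, (pd.Series, dict)) else grouping)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 samples")
    d2 = np.asarray(d, dtype=float) ** 2
    rng = np.random.default_rng(seed)
    f_obs, f_perm, r2 = _permute_pseudo_f(d2, labels, n_permutations, rng)
    p = (1.0 + (f_perm >= f_obs).sum()) / (1.0 + n_permutations)
    return PermanovaResult(r2=float(r2), pseudo_f=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations)
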