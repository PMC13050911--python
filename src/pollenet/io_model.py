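"""Data model and I/O for taxa-by-sample count tables, sample metadata,
predicted-function tables and phylogenetic trees.

All downstream stages (diversity, networks, core-taxon statistics) consume
the containers defined here.  Counts are integers; relative abundances are
the only floating-point representation of community composition.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "RANKS",
    "CountTable",
    "RelAbundanceTable",
    "FunctionTable",
    "PhyloTree",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_function_table",
    "write_function_table",
    "read_tree",
    "write_tree",
    "assign_groups",
    "to_relative_abundance",
    "aggregate_level",
    "parse_rank",
]

#: Taxonomic ranks understood by :func:`aggregate_level`, in lineage order.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

DOMAINS = ("bacteria", "fungi")
GROUPS = ("Self_open", "Self_bagging", "Cross_open", "Cross_bagging")
TREATMENTS = ("open", "bagging")
POLLINATIONS = ("self", "cross")

UNCLASSIFIED = "unclassified"


@dataclass
class CountTable:
    """Taxa x samples table of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer matrix, taxa as rows, samples as columns.
    taxonomy : pandas.Series
        Rank-delimited lineage string per taxon (may be ``"unclassified"``).
    domain : str
        Either ``"bacteria"`` or ``"fungi"``.
    level : str
        Taxonomic level of the rows, e.g. ``"OTU"``, ``"genus"``, ``"phylum"``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    domain: str
    level: str = "OTU"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        if self.taxonomy.isna().any():
            missing = self.taxonomy.index[self.taxonomy.isna()][0]
            raise ValueError(f"taxonomy missing for taxon {missing!r}")

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)


@dataclass
class RelAbundanceTable:
    """Per-sample proportions on the same axes as a :class:`CountTable`.

    Columns of samples with any reads sum to 1; all-zero samples stay
    all-zero (flagged with a warning at construction time).
    """

    values: pd.DataFrame
    taxonomy: pd.Series
    domain: str
    level: str = "OTU"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if (arr < -1e-12).any() or (arr > 1 + 1e-9).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = arr.sum(axis=0)
        bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0))
        if bad.any():
            raise ValueError(
                f"sample columns must sum to 1 (or 0): {list(self.values.columns[bad])}"
            )

    @property
    def taxon_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class FunctionTable:
    """Predicted-function weights per genus (PICRUSt2/FUNGuild-style output).

    Long format with columns ``taxon_id``, ``function_id``, ``value`` where
    ``value`` is the weight of that function per unit relative abundance of
    the genus.  For fungal guild tables each genus carries a single trophic
    mode with weight 1, so functional relative abundance equals taxonomic
    relative abundance.
    """

    table: pd.DataFrame
    domain: str

    def __post_init__(self) -> None:
        required = {"taxon_id", "function_id", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"function table needs columns {sorted(required)}")
        if (self.table["value"].to_numpy() < 0).any():
            raise ValueError("function values must be non-negative")

    def genus_weights(self) -> pd.Series:
        """Total function weight per genus (sum over function ids)."""
        return self.table.groupby("taxon_id")["value"].sum()

    def flag_unknown(self, known_taxa) -> list:
        """Genera referenced here but absent from the companion count table."""
        known = set(known_taxa)
        return sorted(set(self.table["taxon_id"]) - known)


@dataclass
class PhyloTree:
    """Rooted phylogenetic tree with non-negative branch lengths."""

    tree: TreeNode

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if len(names) != len(set(names)):
            raise ValueError("tip names must be unique")
        for node in self.tree.traverse():
            if node.length is not None and node.length < 0:
                raise ValueError("branch lengths must be non-negative")

    @property
    def tip_names(self) -> list:
        return [t.name for t in self.tree.tips()]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path, domain: str, level: str = "OTU") -> CountTable:
    """Read a TSV count table (taxa rows, sample columns, optional trailing
    ``taxonomy`` column) into a :class:`CountTable`.

    Raises ``ValueError`` on duplicate ids, ragged rows, negative or
    non-integer counts.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(parts)} fields, expected {n_fields})"
                )
            rows.append(parts)
    has_tax = header[-1].lower() == "taxonomy"
    sample_ids = header[1:-1] if has_tax else header[1:]
    taxon_ids = [r[0] for r in rows]
    seen: set = set()
    for t in taxon_ids:
        if t in seen:
            raise ValueError(f"{path}: duplicate taxon id {t!r}")
        seen.add(t)
    if len(sample_ids) != len(set(sample_ids)):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    data = np.empty((len(rows), len(sample_ids)), dtype=np.int64)
    for i, r in enumerate(rows):
        vals = r[1:-1] if has_tax else r[1:]
        for j, v in enumerate(vals):
            try:
                iv = int(v)
            except ValueError as exc:
                raise ValueError(f"{path}: non-integer count {v!r} for {r[0]!r}") from exc
            if iv < 0:
                raise ValueError(f"{path}: negative count {iv} for {r[0]!r}")
            data[i, j] = iv
    taxonomy = pd.Series(
        [r[-1] if has_tax else UNCLASSIFIED for r in rows], index=taxon_ids
    )
    counts = pd.DataFrame(data, index=taxon_ids, columns=sample_ids)
    return CountTable(counts=counts, taxonomy=taxonomy, domain=domain, level=level)


def write_count_table(t: CountTable, path) -> None:
    out = t.counts.copy()
    out["taxonomy"] = t.taxonomy
    out.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata (sample_id, species, treatment, pollination,
    replicate) from TSV."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "species", "treatment", "pollination", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in metadata: {dup!r}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_function_table(path, domain: str) -> FunctionTable:
    table = pd.read_csv(path, sep="\t")
    return FunctionTable(table=table, domain=domain)


def write_function_table(f: FunctionTable, path) -> None:
    f.table.to_csv(path, sep="\t", index=False)


def read_tree(path) -> PhyloTree:
    return PhyloTree(tree=TreeNode.read(str(path), format="newick"))


def write_tree(t: PhyloTree, path) -> None:
    buf = io.StringIO()
    t.tree.write(buf, format="newick")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def assign_groups(meta: pd.DataFrame) -> pd.Series:
    """Map each sample to its pollination x treatment group.

    ``(self, open) -> Self_open``, ``(cross, bagging) -> Cross_bagging``, etc.
    """
    meta = validate_metadata(meta)
    out = {}
    for _, row in meta.iterrows():
        sid = row["sample_id"]
        pol, tr = row["pollination"], row["treatment"]
        if pd.isna(pol) or pol not in POLLINATIONS:
            raise ValueError(f"sample {sid!r}: unknown pollination {pol!r}")
        if pd.isna(tr) or tr not in TREATMENTS:
            raise ValueError(f"sample {sid!r}: unknown treatment {tr!r}")
        out[sid] = f"{pol.capitalize()}_{tr}"
    return pd.Series(out, name="group")


def to_relative_abundance(t: CountTable) -> RelAbundanceTable:
    """Divide each sample column by its library size.

    All-zero samples are retained as all-zero columns with a warning;
    an entirely empty table is an error.
    """
    libs = t.library_sizes()
    if (libs == 0).all():
        raise ValueError("no sample has any reads")
    zero = libs.index[libs == 0]
    if len(zero):
        warnings.warn(f"samples with zero reads kept as all-zero: {list(zero)}")
    denom = libs.replace(0, 1)
    values = t.counts.div(denom, axis=1)
    return RelAbundanceTable(
        values=values, taxonomy=t.taxonomy.copy(), domain=t.domain, level=t.level
    )


def parse_rank(lineage: str, rank: str) -> str | None:
    """Extract the label at ``rank`` from a semicolon-delimited lineage.

    Greengenes-style prefixes (``k__``, ``p__``, ...) are honoured;
    unprefixed lineages are read positionally.  Returns ``None`` when the
    rank is absent or empty.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
    if not isinstance(lineage, str) or not lineage.strip():
        return None
    fields = [f.strip() for f in lineage.split(";")]
    prefixed = any(len(f) > 2 and f[1:3] == "__" for f in fields)
    if prefixed:
        for f in fields:
            if len(f) >= 3 and f[1:3] == "__" and _PREFIX_TO_RANK.get(f[0]) == rank:
                label = f[3:].strip()
                return label or None
        return None
    idx = RANKS.index(rank)
    if idx < len(fields):
        label = fields[idx]
        return label or None
    return None


def aggregate_level(t: CountTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing the same label at ``rank``.

    Taxa whose lineage cannot be parsed at that rank are pooled under
    ``"unclassified"``.  Per-sample library sizes are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {RANKS}")
    labels = [parse_rank(lin, rank) or UNCLASSIFIED for lin in t.taxonomy]
    grouped = t.counts.groupby(pd.Index(labels, name=rank)).sum()
    # representative lineage per label: first occurrence, truncated at rank
    rep: dict = {}
    depth = RANKS.index(rank) + 1
    for lin, lab in zip(t.taxonomy, labels):
        if lab not in rep:
            if lab == UNCLASSIFIED:
                rep[lab] = UNCLASSIFIED
            else:
                fields = [f.strip() for f in str(lin).split(";")]
                rep[lab] = ";".join(fields[:depth])
    taxonomy = pd.Series({lab: rep[lab] for lab in grouped.index})
    return CountTable(counts=grouped, taxonomy=taxonomy, domain=t.domain, level=rank)
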