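"""End-to-end orchestration: simulate -> diversity -> networks -> core ->
visitation, with a provenance manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_visitation import (
    core_contribution,
    identify_core,
    visitation_analysis,
)
from .diversity import alpha_diversity, bray_curtis, permanova, two_way_anova
from .io_model import (
    assign_groups,
    read_count_table,
    read_function_table,
    read_metadata,
    read_tree,
    to_relative_abundance,
    write_count_table,
    write_function_table,
    write_metadata,
    write_tree,
)
from .networks import network_from_tables, topology, write_edge_list
from .synthetic import (
    SynthSpec,
    generate_counts,
    generate_function_table,
    generate_pollen_counts,
    generate_tree,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_to_dir"]

log = logging.getLogger("pollenet")


@dataclass
class RunConfig:
    """Pipeline thresholds and seeds.  Defaults are the analysis defaults:
    rarefaction to 40,000 (bacteria) / 39,000 (fungi) reads, |rho| >= 0.65,
    q < 0.05, bacterial occurrence >= 5 samples and mean RA >= 0.05%,
    fungal mean RA >= 0.001%, top-10% core rule, 5,000 bootstrap
    iterations."""

    depths: dict = field(default_factory=lambda: {"bacteria": 40000, "fungi": 39000})
    rho_min: float = 0.65
    q_max: float = 0.05
    occurrence_min: int = 5
    bacterial_mean_ra_min: float = 5e-4
    fungal_mean_ra_min: float = 1e-5
    core_top_fraction: float = 0.10
    bootstrap_iters: int = 5000
    n_permutations: int = 999
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.rho_min <= 1:
            raise ValueError("rho_min must lie in (0, 1]")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must lie in (0, 1]")
        if self.occurrence_min < 1:
            raise ValueError("occurrence_min must be >= 1")
        if not 0 < self.core_top_fraction <= 1:
            raise ValueError("core_top_fraction must lie in (0, 1]")
        if min(self.depths.values()) < 1:
            raise ValueError("rarefaction depths must be >= 1")
        if self.bootstrap_iters < 1 or self.n_permutations < 99:
            raise ValueError("bootstrap_iters >= 1 and n_permutations >= 99 required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def simulate_to_dir(spec: SynthSpec, outdir) -> dict:
    """Write a full synthetic dataset (counts, metadata, trees, function
    tables, pollen counts) to ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bact, fung, meta = generate_counts(spec)
    files = {}
    for name, table in (("bacteria", bact), ("fungi", fung)):
        p = outdir / f"counts_{name}.tsv"
        write_count_table(table, p)
        files[f"counts_{name}"] = p
        tree = generate_tree(table.taxon_ids, seed=spec.seed)
        tp = outdir / f"tree_{name}.nwk"
        write_tree(tree, tp)
        files[f"tree_{name}"] = tp
        core = next((c.taxa for c in spec.core_specs
                     if set(c.taxa) <= set(table.taxon_ids)), ())
        func = generate_function_table(core, table.taxon_ids, name, seed=spec.seed)
        fp = outdir / f"functions_{name}.tsv"
        write_function_table(func, fp)
        files[f"functions_{name}"] = fp
    mp = outdir / "metadata.tsv"
    write_metadata(meta, mp)
    files["metadata"] = mp
    pollen = generate_pollen_counts(spec)
    pp = outdir / "pollen.tsv"
    pollen.to_csv(pp, sep="\t", index=False)
    files["pollen"] = pp
    return files


def run_pipeline(config: RunConfig, outdir, spec: SynthSpec | None = None,
                 input_dir=None) -> dict:
    """Run every stage in dependency order and write TSV outputs plus a
    ``manifest.json`` recording version, seeds, thresholds and input
    checksums.  Either a :class:`SynthSpec` (simulate first) or an
    ``input_dir`` of previously written files must be given."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is not None:
        input_dir = outdir / "inputs"
        simulate_to_dir(spec, input_dir)
    elif input_dir is None:
        raise ValueError("either a synthetic spec or an input directory is required")
    input_dir = Path(input_dir)

    tables = {d: read_count_table(input_dir / f"counts_{d}.tsv", domain=d,
                                  level="genus")
              for d in ("bacteria", "fungi")}
    trees = {d: read_tree(input_dir / f"tree_{d}.nwk") for d in ("bacteria", "fungi")}
    funcs = {d: read_function_table(input_dir / f"functions_{d}.tsv", domain=d)
             for d in ("bacteria", "fungi")}
    meta = read_metadata(input_dir / "metadata.tsv")
    pollen = pd.read_csv(input_dir / "pollen.tsv", sep="\t")
    groups = assign_groups(meta)

    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "inputs": {p.name: _sha256(p) for p in sorted(input_dir.glob("*"))},
        "stages": {},
    }

    # -- diversity ---------------------------------------------------------
    log.info("stage: diversity")
    for d, table in tables.items():
        div = alpha_diversity(table, depth=config.depths[d], tree=trees[d],
                              seed=config.seed)
        div.per_sample.to_csv(outdir / f"alpha_{d}.tsv", sep="\t",
                              index_label="sample_id")
        anova_rows = []
        for index in div.per_sample.columns:
            res = two_way_anova(div.per_sample[index],
                                meta[meta.sample_id.isin(div.per_sample.index)])
            eff = res.effects.copy()
            eff.insert(0, "index", index)
            anova_rows.append(eff)
        pd.concat(anova_rows).to_csv(outdir / f"anova_{d}.tsv", sep="\t",
                                     index_label="factor")
        rel = to_relative_abundance(table)
        d_bc = bray_curtis(rel)
        d_bc.to_csv(outdir / f"braycurtis_{d}.tsv", sep="\t")
        perm = permanova(d_bc, groups.reindex(d_bc.index),
                         n_permutations=config.n_permutations, seed=config.seed)
        manifest["stages"][f"permanova_{d}"] = {
            "r2": perm.r2, "pseudo_f": perm.pseudo_f, "p": perm.p_value,
            "excluded_from_alpha": div.excluded_samples,
        }

    # -- networks + core ---------------------------------------------------
    log.info("stage: networks")
    rel = {d: to_relative_abundance(t) for d, t in tables.items()}
    thresholds = dict(
        rho_min=config.rho_min, q_max=config.q_max,
        occurrence_min=config.occurrence_min,
        bacterial_mean_ra_min=config.bacterial_mean_ra_min,
        fungal_mean_ra_min=config.fungal_mean_ra_min,
    )
    core_rows = []
    topo_rows = []
    for group in sorted(groups.unique()):
        samples = [s for s in groups.index if groups[s] == group]
        for mode in ("bacteria", "fungi", "cross_domain"):
            net = network_from_tables(rel["bacteria"], rel["fungi"], samples,
                                      mode=mode, group=group, seed=config.seed,
                                      **thresholds)
            write_edge_list(net, outdir / f"edges_{group}_{mode}.tsv")
            topo = topology(net).as_dict()
            topo.update(group=group, mode=mode)
            topo_rows.append(topo)
            if mode == "cross_domain":
                # core taxa reported from the bacteria-fungi interaction net
                core = identify_core(net, top_fraction=config.core_top_fraction)
                for d in ("bacteria", "fungi"):
                    core_d = [t for t in core
                              if net.graph.nodes[t]["domain"] == d]
                    if not core_d:
                        continue
                    rep = core_contribution(core_d, rel[d], samples, f=funcs[d],
                                            group=group, domain=d)
                    core_rows.append({
                        "group": group, "domain": d, "n_core": rep.n_core,
                        "core_genera": ",".join(rep.core_genera),
                        "taxo_mean_pct": rep.taxo_contrib_mean,
                        "taxo_se_pct": rep.taxo_contrib_se,
                        "func_mean_pct": rep.func_contrib_mean,
                        "func_se_pct": rep.func_contrib_se,
                    })
    pd.DataFrame(topo_rows).to_csv(outdir / "topology.tsv", sep="\t", index=False)
    pd.DataFrame(core_rows).to_csv(outdir / "core_report.tsv", sep="\t", index=False)

    # -- visitation --------------------------------------------------------
    log.info("stage: visitation")
    open_meta = meta[meta.treatment == "open"]
    func_by_species = {}
    bact_core = [r for r in core_rows if r["domain"] == "bacteria"]
    all_bact_core = sorted({t for r in bact_core for t in r["core_genera"].split(",")})
    if all_bact_core:
        w = funcs["bacteria"].genus_weights().reindex(all_bact_core).fillna(0.0)
        for sp in open_meta.species.unique():
            ss = list(open_meta.loc[open_meta.species == sp, "sample_id"])
            vals = (rel["bacteria"].values.loc[all_bact_core, ss]
                    .mul(w, axis=0).sum(axis=0) * 100.0)
            func_by_species[sp] = vals.to_numpy()
    vis = visitation_analysis(
        pollen, core_function_by_species=func_by_species or None,
        n_iter=config.bootstrap_iters, seed=config.seed)
    vis.rates.to_csv(outdir / "remaining_rates.tsv", sep="\t", index=False)
    vis.species_summary.to_csv(outdir / "visitation_summary.tsv", sep="\t",
                               index=False)
    manifest["stages"]["visitation"] = {
        "anova_p": float(vis.anova.effects.loc["species", "p"]),
        "cohens_d": vis.cohens_d,
        "bootstrap": None if vis.bootstrap is None else {
            "median": vis.bootstrap.median, "mean": vis.bootstrap.mean,
            "ci": [vis.bootstrap.ci_low, vis.bootstrap.ci_high],
            "n_iterations": vis.bootstrap.n_iterations,
            "n_missing": vis.bootstrap.n_missing,
        },
    }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
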