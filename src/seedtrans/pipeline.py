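"""Config-driven orchestration of the full analysis with provenance.

A single YAML (or dict) configuration names the inputs, toggles stages,
and sets every analysis threshold (CSS quantile, abundance filter,
prevalence, correlation/FDR cut-offs, h^2 class boundaries, alpha) with
defaults equal to the published cut-offs. ``run`` executes the enabled
stages in dependency order, writes each stage's tables under the output
directory, and emits a manifest (package version, seeds, parameters,
input checksums) sufficient to reproduce every artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (CountTable, DataError, SampleMeta, TaxonomyTable,
                 read_count_table, read_sample_meta, read_taxonomy, write_tsv)
from .normalize import css_normalize, mean_technical_replicates, transform
from .stats import dissimilarity, pcoa, permanova
from .transmission import (classify_succession, convergence_trajectory, core_otus,
                           detect_transmitted, transmission_overlap)
from .niche_neutral import (estimate_niche_responsiveness, filter_low_abundance,
                            fit_neutral_model, partition_neutral)
from .source_tracking import track_by_timepoint
from .networks import (build_network, detect_modules, edge_jaccard, graph_stats,
                       merge_meta, sparcc, sparcc_pvalues)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "normalize", "ordination", "transmission", "succession",
    "niche_neutral", "sources", "networks", "meta_network",
)


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; unknown keys are rejected."""

    # inputs (ignored when the simulate stage is enabled)
    counts_path: str | None = None
    meta_path: str | None = None
    taxonomy_path: str | None = None
    out_dir: str = "results"
    stages: tuple = ALL_STAGES
    seed: int = 0
    # thresholds, defaulting to the published cut-offs
    css_quantile: float = 0.5
    abundance_filter: float = 1e-4
    core_prevalence: float = 0.8
    r_threshold: float = 0.3
    fdr: float = 0.05
    h2_low: float = 0.2
    h2_high: float = 0.4
    alpha: float = 0.05
    n_perm_permanova: int = 999
    n_boot_h2: int = 100
    sparcc_resamples: int = 20
    sparcc_perm: int = 100
    average_technical_replicates: bool = True
    # simulate-stage knobs (desk-scale defaults)
    sim_compartments: tuple = ("BS", "RS", "R", "S1", "L1", "Se")

    def __post_init__(self) -> None:
        checks = [
            (0.0 < self.css_quantile <= 1.0, "css_quantile in (0, 1]"),
            (0.0 <= self.abundance_filter < 1.0, "abundance_filter in [0, 1)"),
            (0.0 < self.core_prevalence <= 1.0, "core_prevalence in (0, 1]"),
            (0.0 <= self.r_threshold < 1.0, "r_threshold in [0, 1)"),
            (0.0 < self.fdr <= 1.0, "fdr in (0, 1]"),
            (0.0 < self.alpha < 1.0, "alpha in (0, 1)"),
            (0.0 < self.h2_low < self.h2_high < 1.0, "0 < h2_low < h2_high < 1"),
            (self.n_perm_permanova >= 1, "n_perm_permanova >= 1"),
            (self.n_boot_h2 >= 1, "n_boot_h2 >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise DataError(f"invalid configuration: expected {msg}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise DataError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise DataError(f"unknown configuration key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "sim_compartments"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    needs_data = [s for s in stages if s != "simulate"]
    if needs_data and "simulate" not in stages and config.counts_path is None:
        raise DataError("stages need input data: set counts_path or enable 'simulate'")
    if any(s in stages for s in ("networks", "meta_network")) and "normalize" not in stages and "simulate" not in stages:
        raise DataError("network stages require the 'normalize' stage")

    manifest: dict = {
        "package": "seedtrans", "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed, "parameters": asdict(config),
        "stages_run": [], "inputs": {}, "artifacts": [],
    }

    def save(df: pd.DataFrame, name: str, index_label=None):
        path = out / name
        write_tsv(df, path, index_label=index_label)
        manifest["artifacts"].append(name)

    truth = None
    if "simulate" in stages:
        from .synthetic import Scenario, StudyDesign, generate_full_study

        design = StudyDesign(compartments=tuple(config.sim_compartments))
        table, meta, tax, truth = generate_full_study(design=design, seed=config.seed)
        save(table.counts, "simulated_counts.tsv", index_label="otu_id")
        save(meta.table, "simulated_meta.tsv")
        save(tax.table, "simulated_taxonomy.tsv", index_label="otu_id")
        with open(out / "simulated_truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, default=str)
        manifest["artifacts"].append("simulated_truth.json")
        manifest["stages_run"].append("simulate")
    else:
        table = read_count_table(config.counts_path)
        meta = read_sample_meta(config.meta_path)
        tax = read_taxonomy(config.taxonomy_path) if config.taxonomy_path else None
        for key, path in (("counts", config.counts_path), ("meta", config.meta_path),
                          ("taxonomy", config.taxonomy_path)):
            if path:
                manifest["inputs"][key] = {"path": str(path), "sha256": _file_checksum(path)}
    meta.check_join(table)
    manifest["inputs"]["counts_sha256"] = table.checksum()

    css = None
    if "normalize" in stages:
        css = css_normalize(table, quantile=config.css_quantile)
        save(css.values.round(6), "css_normalized.tsv", index_label="otu_id")
        manifest["stages_run"].append("normalize")

    if "ordination" in stages:
        t_ord, meta_ord = (
            mean_technical_replicates(table, meta)
            if config.average_technical_replicates else (table, meta)
        )
        css_ord = css_normalize(t_ord, quantile=config.css_quantile)
        d = dissimilarity(css_ord, metric="bray_curtis")
        save(d.matrix.round(6), "bray_curtis.tsv", index_label="sample_id")
        coords = pcoa(d, k=2)
        save(coords.coordinates.round(6), "pcoa_coordinates.tsv", index_label="sample_id")
        grouping = [meta_ord.lookup(s)["compartment"] for s in d.sample_ids]
        perm = permanova(d, grouping, n_perm=config.n_perm_permanova, seed=config.seed)
        save(pd.DataFrame([{"factor": "compartment", "pseudo_F": perm.statistic,
                            "R2": perm.extra["R2"], "p": perm.p_value,
                            "n_perm": perm.n_perm}]), "permanova.tsv")
        manifest["stages_run"].append("ordination")

    harvest_age = int(max(meta.table.loc[meta.table["compartment"] == "Se", "age_days"]))
    progeny_year = int(meta.table["year"].max())
    parent_year = int(meta.table["year"].min())
    gen_groups = {
        "parent_harvest": meta.samples(compartment="Se", year=parent_year, age_days=harvest_age),
        "sowing": meta.samples(compartment="Se", year=progeny_year, age_days=0),
        "progeny_harvest": meta.samples(compartment="Se", year=progeny_year, age_days=harvest_age),
    }
    trans = None
    if "transmission" in stages:
        trans = detect_transmitted(table, meta, gen_groups)
        status = trans.status.to_frame()
        save(status, "transmission_status.tsv", index_label="otu_id")
        save(trans.summary_by_age(table, meta), "transmission_by_age.tsv")
        cores = core_otus(table, meta, prevalence=config.core_prevalence)
        save(transmission_overlap(trans, cores), "venn_regions.tsv")
        traj = convergence_trajectory(table, meta, restrict_to=trans.transmitted or None)
        save(traj.distances, "convergence_distances.tsv")
        manifest["stages_run"].append("transmission")

    if "succession" in stages:
        seed_ids = meta.samples(compartment="Se", year=progeny_year)
        seed_tab = table.subset_samples(seed_ids)
        ra = transform(seed_tab, "relative_abundance")
        meta_seed = SampleMeta(meta.table[meta.table["sample_id"].isin(seed_ids)].copy())
        succ = classify_succession(ra, meta_seed, alpha=config.alpha)
        save(succ.table, "succession_modes.tsv", index_label="otu_id")
        manifest["stages_run"].append("succession")

    if "niche_neutral" in stages:
        seed_ids = meta.samples(compartment="Se", year=progeny_year)
        seed_ids = [s for s in seed_ids if int(meta.lookup(s)["age_days"]) > 0]
        seed_tab = filter_low_abundance(table.subset_samples(seed_ids),
                                        threshold=config.abundance_filter)
        meta_seed = SampleMeta(meta.table[meta.table["sample_id"].isin(seed_ids)].copy())
        fit = fit_neutral_model(seed_tab)
        save(fit.table.round(6), "neutral_fit.tsv", index_label="otu_id")
        save(partition_neutral(fit), "neutral_partition_summary.tsv")
        with open(out / "neutral_fit.json", "w") as fh:
            json.dump({"m": fit.m, "N": fit.N, "R2": fit.R2,
                       "n_communities": fit.n_communities, "at_bound": fit.at_bound}, fh, indent=1)
        manifest["artifacts"].append("neutral_fit.json")
        clr = transform(seed_tab, "CLR")
        focus = trans.transmitted if trans is not None else list(seed_tab.otu_ids)[:30]
        focus = [o for o in focus if o in clr.values.index] or list(seed_tab.otu_ids)[:10]
        # h^2 only for the focal (transmitted) OTUs to keep runs short;
        # the CLR geometry still comes from the full filtered table
        h2 = estimate_niche_responsiveness(
            clr, meta_seed, n_boot=config.n_boot_h2, seed=config.seed, otus=focus,
        )
        save(h2.table.round(6), "niche_responsiveness.tsv", index_label="otu_id")
        manifest["stages_run"].append("niche_neutral")

    if "sources" in stages:
        res = track_by_timepoint(table, meta, seed=config.seed)
        save(res.per_sink.round(6), "source_contributions_per_sink.tsv")
        save(res.by_compartment.round(6), "source_contributions_by_compartment.tsv")
        save(res.by_compartment_age.round(6), "source_contributions_by_compartment_age.tsv")
        manifest["stages_run"].append("sources")

    nets = []
    if "networks" in stages or "meta_network" in stages:
        rng = np.random.default_rng(config.seed)
        for (comp, age), sub in meta.table.groupby(["compartment", "age_days"], sort=True):
            sids = list(sub["sample_id"])
            if len(sids) < 6:
                continue
            sub_tab = table.subset_samples(sids)
            # keep taxa with enough prevalence for a stable basis system
            prev = (sub_tab.counts > 0).mean(axis=1)
            mean_ra = sub_tab.relative_abundance().mean(axis=1)
            keep = mean_ra[prev >= 0.5].sort_values(ascending=False).index[:30]
            if len(keep) < 8:
                continue
            sub_tab = sub_tab.subset_otus(list(keep))
            s = int(rng.integers(2 ** 31 - 1))
            rho = sparcc(sub_tab, n_resample=config.sparcc_resamples, seed=s)
            p, q = sparcc_pvalues(sub_tab, rho, n_perm=config.sparcc_perm, seed=s)
            net = build_network(rho, q, r_threshold=config.r_threshold,
                                fdr=config.fdr, context=(comp, int(age)), tax=tax, p=p)
            if net.n_edges:
                nets.append(net)
        edge_rows = []
        for net in nets:
            tab = net.edge_table()
            tab.insert(0, "compartment", net.context[0])
            tab.insert(1, "age_days", net.context[1])
            edge_rows.append(tab)
        if edge_rows:
            save(pd.concat(edge_rows, ignore_index=True).round(6), "network_edges.tsv")
        stat_rows = []
        for net in nets:
            gs = graph_stats(net)
            stat_rows.append({"compartment": net.context[0], "age_days": net.context[1],
                              "n_nodes": gs.n_nodes, "n_edges": gs.n_edges,
                              "ABC": gs.abc_index, "GA": gs.ga_index, "Bertz": gs.bertz_index,
                              "hubs": ";".join(gs.hubs)})
        if stat_rows:
            save(pd.DataFrame(stat_rows).round(4), "network_stats.tsv")
        manifest["stages_run"].append("networks")

    if "meta_network" in stages and len(nets) >= 2:
        metanet = merge_meta(nets)
        mods = detect_modules(metanet, seed=config.seed)
        save(mods.composition.round(6), "meta_modules.tsv")
        jmat, _ = edge_jaccard(nets)
        save(jmat.round(6), "network_jaccard.tsv", index_label="network")
        with open(out / "meta_network.json", "w") as fh:
            json.dump({"n_nodes": metanet.n_nodes, "n_edges": metanet.n_edges,
                       "modularity": mods.modularity,
                       "n_modules": len(set(mods.membership.values()))}, fh, indent=1)
        manifest["artifacts"].append("meta_network.json")
        manifest["stages_run"].append("meta_network")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
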