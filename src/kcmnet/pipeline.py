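"""End-to-end protocol orchestration.

``run_pipeline`` executes the full construction-and-analysis chain —
per-omics filtering and log transform, NMR bucket selection and
agglomeration, merging, per-group network construction, topology,
k-clique communities and cross-group comparison — and writes every
artifact plus a manifest recording each numeric decision (thresholds,
pseudocounts, cut heights, chosen regularisation).  Identical config and
seed produce identical outputs; one top-level seed fans out to per-stage
seeds by stage-name hashing so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import cliquecomm, compare, netbuild, nmr_reduce, preprocess, synthdata, tables_io, topology
from .errors import ValidationError
from .tables_io import FeatureTable


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs; loadable from YAML."""

    # data source: either a simulation config or per-omics table paths
    simulate: Optional[synthdata.SimConfig] = None
    taxa_path: Optional[str] = None
    voc_path: Optional[str] = None
    nmr_path: Optional[str] = None         # binned buckets, samples x features
    design_path: Optional[str] = None
    # preprocessing
    ra_threshold: float = 0.5
    filter_scope: str = "per_timepoint_union"
    pseudocount: Optional[float] = None    # None = half smallest positive value
    # NMR reduction
    selection_labels: str = "arm"          # design column used as classes
    selection_timepoint: str = "Te"
    agglomeration_timepoint: str = "T0"    # baseline: intrinsic correlation,
                                           # free of intervention effects
    folds: int = 5
    cut: object = "auto"
    cap: float = 0.7
    # networks
    policies: Dict[str, netbuild.ThresholdPolicy] = field(default_factory=dict)
    mode: str = "signed"
    k_list: List[int] = field(default_factory=lambda: [3, 4])
    min_jaccard: float = 0.5
    # bookkeeping
    outdir: str = "kcm_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        pol = raw.pop("policies", {})
        cfg = cls(**raw)
        if sim is not None:
            cons = sim.pop("consortia", None)
            if cons is not None:
                sim["consortia"] = [synthdata.Consortium(**c) for c in cons]
            cfg.simulate = synthdata.SimConfig(**sim)
        cfg.policies = {k: netbuild.ThresholdPolicy(**v) for k, v in pol.items()}
        return cfg

    def validate(self) -> None:
        problems = []
        if self.simulate is None:
            for name in ("taxa_path", "voc_path", "nmr_path", "design_path"):
                p = getattr(self, name)
                if p is None:
                    problems.append(f"{name} is required when not simulating")
                elif not Path(p).exists():
                    problems.append(f"{name} does not exist: {p}")
        if any(k < 2 for k in self.k_list):
            problems.append("community orders k must all be >= 2")
        if self.filter_scope not in preprocess.FILTER_SCOPES:
            problems.append(f"unknown filter scope {self.filter_scope!r}")
        if problems:
            raise ValidationError("invalid pipeline config:\n  - " + "\n  - ".join(problems))


def _split_timepoints(table: FeatureTable, design: pd.DataFrame) -> Tuple[FeatureTable, FeatureTable]:
    tp = design.loc[table.sample_ids, "timepoint"]
    t0 = [s for s in table.sample_ids if tp[s] == "T0"]
    te = [s for s in table.sample_ids if tp[s] == "Te"]
    return table.subset_samples(t0), table.subset_samples(te)


def _concat_samples(a: FeatureTable, b: FeatureTable) -> FeatureTable:
    values = pd.concat([a.values, b.values], axis=0)
    return FeatureTable(values, dict(a.feature_type), dict(a.units))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full protocol and return the output manifest."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "artifacts": {}}

    # ------------------------------------------------------------------ load
    if cfg.simulate is not None:
        sim_cfg = dataclasses.replace(cfg.simulate, seed=stage_seed(cfg.seed, "simulate"))
        t0_all, te_all, design, truth = synthdata.simulate_cohort(sim_cfg)
        manifest["stages"]["simulate"] = {"seed": sim_cfg.seed,
                                          "n_subjects_per_cell": sim_cfg.n_subjects_per_cell}
        full = _concat_samples(t0_all, te_all)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
        manifest["artifacts"]["ground_truth"] = "ground_truth.json"
    else:
        design = tables_io.read_design(cfg.design_path)
        taxa = tables_io.read_feature_table(cfg.taxa_path, "microbiome",
                                            units=tables_io.UNIT_PERCENT_RA)
        voc = tables_io.read_feature_table(cfg.voc_path, "volatilome",
                                           units=tables_io.UNIT_PERCENT_RA)
        nmr = tables_io.read_feature_table(cfg.nmr_path, "metabolome_nmr")
        full = tables_io.merge_tables([taxa, voc, nmr], design)
    tables_io.check_design_covers(full, design)

    # ------------------------------------------------------------ preprocess
    fcfg = preprocess.FilterConfig(ra_threshold=cfg.ra_threshold, scope=cfg.filter_scope)
    blocks: Dict[str, FeatureTable] = {}
    filter_log: Dict[str, dict] = {}
    pseudo_used: Dict[str, float] = {}
    for omics in ("microbiome", "volatilome"):
        block = full.select_type(omics)
        kept, removed = preprocess.filter_by_median_abundance(block, fcfg, design)
        filter_log[omics] = {"removed": sorted(removed), "n_kept": kept.n_features}
        pc = cfg.pseudocount if cfg.pseudocount is not None else preprocess.default_pseudocount(kept)
        pseudo_used[omics] = pc
        blocks[omics] = preprocess.log_transform(kept, pc)
    manifest["stages"]["filter"] = {"ra_threshold": cfg.ra_threshold,
                                    "scope": cfg.filter_scope, **filter_log}
    manifest["stages"]["log_transform"] = {"pseudocount": pseudo_used}

    # ------------------------------------------------------------ nmr reduce
    nmr_block = full.select_type("metabolome_nmr")
    sel_samples = [s for s in nmr_block.sample_ids
                   if design.loc[s, "timepoint"] == cfg.selection_timepoint]
    labels = design.loc[sel_samples, cfg.selection_labels].to_numpy()
    sel_seed = stage_seed(cfg.seed, "nmr_selection")
    selection = nmr_reduce.select_informative_buckets(
        nmr_block.subset_samples(sel_samples), labels,
        folds=cfg.folds, seed=sel_seed,
    )
    if len(selection.kept_feature_ids) < 2:
        raise ValidationError(
            "stage nmr_reduce: fewer than 2 informative buckets selected; "
            "cannot agglomerate"
        )
    selected = nmr_block.subset_features(selection.kept_feature_ids)
    agg_samples = [s for s in selected.sample_ids
                   if design.loc[s, "timepoint"] == cfg.agglomeration_timepoint]
    amap = nmr_reduce.agglomerate_features(selected.subset_samples(agg_samples),
                                           cut=cfg.cut, cap=cfg.cap)
    pooled = nmr_reduce.pool_agglomerates(selected, amap)
    amap.to_json(out / "agglomeration_map.json")
    manifest["artifacts"]["agglomeration_map"] = "agglomeration_map.json"
    manifest["stages"]["nmr_reduce"] = {
        "seed": sel_seed,
        "chosen_C": selection.optimizer_trace["chosen_C"],
        "n_selected_buckets": len(selection.kept_feature_ids),
        "cut_height": amap.cut_height,
        "n_agglomerates": len(amap.pooled_ids),
    }

    # ----------------------------------------------------------------- merge
    merged_parts = [blocks["microbiome"], blocks["volatilome"], pooled]
    merged_full = tables_io.merge_tables(merged_parts, design)
    merged_t0, merged_te = _split_timepoints(merged_full, design)
    for name, tab in (("merged_T0", merged_t0), ("merged_Te", merged_te)):
        p = f"{name}.csv"
        tables_io.write_feature_table(tab, out / p)
        tables_io.write_feature_metadata(tab, out / f"{name}.features.tsv")
        manifest["artifacts"][name] = p
    manifest["stages"]["merge"] = {"n_features": merged_full.n_features}

    # -------------------------------------------------------------- networks
    nets: Dict[str, netbuild.OmicsNetwork] = {}
    for tab in (merged_t0, merged_te):
        nets.update(netbuild.apply_group_policy(tab, design,
                                                policies=cfg.policies, mode=cfg.mode))
    manifest["stages"]["networks"] = {
        name: {"t": net.provenance.t, "n_samples": net.provenance.n_samples,
               "mode": net.provenance.mode, "policy": net.provenance.policy,
               "n_nodes": net.n_nodes, "n_edges": net.n_edges}
        for name, net in sorted(nets.items())
    }
    for name, net in sorted(nets.items()):
        tables_io.export_network(net, out / f"net_{name}.graphml", "graphml")
        tables_io.export_network(net, out / f"net_{name}.edges.tsv", "edgelist")
        manifest["artifacts"][f"network_{name}"] = f"net_{name}.graphml"

    # ---------------------------------------------- topology and communities
    comms: Dict[Tuple[str, int], cliquecomm.CommunitySet] = {}
    for name, net in sorted(nets.items()):
        rep = topology.topology_report(net)
        tables_io.write_json_report(rep, out / f"topology_{name}.json")
        manifest["artifacts"][f"topology_{name}"] = f"topology_{name}.json"
        for k in cfg.k_list:
            cs = cliquecomm.k_clique_communities(net, k)
            comms[(name, k)] = cs
            overlap = cliquecomm.community_overlap(cs, types=dict(net.graph.nodes(data="omics_type")))
            report = {**cs.to_dict(), "bridge_nodes": overlap.to_dict()["bridge_nodes"]}
            p = f"communities_{name}_k{k}.json"
            tables_io.write_json_report(report, out / p)
            manifest["artifacts"][f"communities_{name}_k{k}"] = p
    manifest["stages"]["communities"] = {
        f"{name}_k{k}": cs.n_communities for (name, k), cs in sorted(comms.items())
    }

    # ----------------------------------------------------------- comparisons
    pairs = []
    for sex in ("F", "M"):
        for pair in ((f"Te_{sex}_A", f"Te_{sex}_P"),
                     (f"T0_{sex}", f"Te_{sex}_A"),
                     (f"T0_{sex}", f"Te_{sex}_P")):
            if pair[0] in nets and pair[1] in nets:
                pairs.append(pair)
    comparisons = {}
    for ga, gb in pairs:
        for k in cfg.k_list:
            rep = compare.compare_networks(nets[ga], nets[gb], k=k,
                                           min_jaccard=cfg.min_jaccard)
            p = f"compare_{ga}_vs_{gb}_k{k}.json"
            tables_io.write_json_report(rep, out / p)
            manifest["artifacts"][f"compare_{ga}_vs_{gb}_k{k}"] = p
            comparisons[f"{ga}_vs_{gb}_k{k}"] = {
                "edge_jaccard": rep.edge_jaccard,
                "n_matched": len(rep.community_matching.matches),
                "n_unmatched_a": len(rep.community_matching.unmatched_a),
                "n_unmatched_b": len(rep.community_matching.unmatched_b),
            }
    manifest["stages"]["compare"] = comparisons

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
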