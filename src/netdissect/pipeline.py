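"""End-to-end orchestration: simulate -> build -> topology -> modules ->
enrichment -> expression -> variants, from a single seeded config.

Every stage reads its inputs from disk and writes its outputs (plus a
JSON block) under the output directory, so a run can be resumed: with
``resume=True`` stages whose block file already exists are skipped and
their cached block reused.  A run with a fixed seed is byte-reproducible.
Stages whose inputs are absent are recorded as skipped; any stage error
aborts the run with a failure marker naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import enrichment as enr
from . import expression as expr
from . import mcode, network, synth, topology, variants
from .errors import NetdissectError
from .graph import TypedGraph

INPUT_FILES = {
    "ppi": "inputs/ppi_edges.tsv",
    "genes_diabetes": "inputs/diabetes_genes.txt",
    "genes_dr": "inputs/dr_genes.txt",
    "cerna": "inputs/cerna_edges.tsv",
    "expression": "inputs/expression.tsv",
    "groups": "inputs/sample_groups.tsv",
    "gene_sets": "inputs/gene_sets.gmt",
    "snps": "inputs/snps.tsv",
    "fasta": "inputs/transcripts.fa",
    "seeds": "inputs/mirna_seeds.tsv",
    "motifs": "inputs/tf_motifs.tsv",
    "truth": "inputs/ground_truth.json",
}

STAGES = ("simulate", "build", "topology", "modules", "enrichment",
          "expression", "variants")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    synth: synth.SynthConfig | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    mcode_params: mcode.McodeParams = field(default_factory=mcode.McodeParams)
    hub_k: int = 50
    top_n_modules: int = 5
    de_p_cutoff: float = 0.05
    de_fc_cutoff: float = 1.5
    coexpr_p_cutoff: float = 0.05
    r2_threshold: float = 0.8
    seed_match_mode: str = "7mer-m8"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synth") is not None:
            d["synth"] = synth.SynthConfig(**{
                **d["synth"],
                "clique_size_range": tuple(
                    d["synth"].get("clique_size_range", (8, 12))
                ),
            })
        if "mcode_params" in d:
            d["mcode_params"] = mcode.McodeParams(**d["mcode_params"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            d["synth"]["clique_size_range"] = list(
                self.synth.clique_size_range
            )
        return d

    def input_path(self, key: str) -> str | None:
        if self.synth is not None:
            return os.path.join(self.outdir, INPUT_FILES[key])
        path = self.inputs.get(key)
        return path if path and os.path.exists(path) else None


def _write_json(obj, path: str) -> None:
    os.makedirs(os.path.dirname(path), exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _block_path(cfg: PipelineConfig, stage: str) -> str:
    return os.path.join(cfg.outdir, "stages", f"{stage}.json")


def _out(cfg: PipelineConfig, *parts: str) -> str:
    path = os.path.join(cfg.outdir, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


# -- stages ------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    if cfg.synth is None:
        return {"status": "skipped", "reason": "inputs supplied externally"}
    scfg = dataclasses.replace(cfg.synth, seed=cfg.seed)
    graph, truth = synth.gen_ppi_network(scfg)
    clique_nodes = sorted({n for c in truth.planted_cliques for n in c})
    labels = synth.gen_disease_sets(graph, scfg, prefer=clique_nodes)
    truth.disease_sets = labels
    cerna = synth.gen_cerna_edges(graph, scfg)

    # assemble the integrated network once, to define the measured gene
    # universe and couple SNP planting to real ceRNA edges
    diabetes = {g for g, t in labels.items() if t in ("diabetes", "common")}
    dr = {g for g, t in labels.items() if t in ("DR", "common")}
    clmn, _ = network.build_clmn(graph, diabetes, dr, cerna)

    matrix, etruth = synth.gen_expression(clmn.nodes(), scfg)
    truth.merge(etruth)
    fixture = synth.gen_snp_fixture(clmn, scfg)
    truth.merge(fixture.truth)
    coding = [n for n in clmn.nodes() if clmn.node_type(n) != "lncRNA"]
    gene_sets = synth.gen_gene_sets(coding, scfg)

    graph.to_tsv(_out(cfg, INPUT_FILES["ppi"]))
    with open(_out(cfg, INPUT_FILES["genes_diabetes"]), "w") as fh:
        fh.write("\n".join(sorted(diabetes)) + "\n")
    with open(_out(cfg, INPUT_FILES["genes_dr"]), "w") as fh:
        fh.write("\n".join(sorted(dr)) + "\n")
    network.write_cerna_tsv(cerna, _out(cfg, INPUT_FILES["cerna"]))
    expr.write_expression_tsv(
        matrix, _out(cfg, INPUT_FILES["expression"]),
        _out(cfg, INPUT_FILES["groups"]),
    )
    enr.write_gmt(enr.GeneSetCollection(gene_sets, "synthetic"),
                  _out(cfg, INPUT_FILES["gene_sets"]))
    variants.write_snp_tsv(fixture.snps, _out(cfg, INPUT_FILES["snps"]))
    variants.write_fasta(fixture.sequences, _out(cfg, INPUT_FILES["fasta"]))
    variants.write_element_tsv(fixture.seeds,
                               _out(cfg, INPUT_FILES["seeds"]), "mirna")
    variants.write_element_tsv(fixture.motifs,
                               _out(cfg, INPUT_FILES["motifs"]), "tf")
    truth.write_json(_out(cfg, INPUT_FILES["truth"]))
    return {
        "status": "ok",
        "ppi_nodes": graph.number_of_nodes(),
        "ppi_edges": graph.number_of_edges(),
        "cerna_edges": int(len(cerna)),
        "n_snps": int(len(fixture.snps)),
        "planted_site_events": len(truth.planted_site_events),
        "planted_de_genes": len(truth.planted_de_genes),
    }


def stage_build(cfg: PipelineConfig) -> dict:
    ppi_path = cfg.input_path("ppi")
    if ppi_path is None:
        return {"status": "skipped", "reason": "no PPI edge table"}
    ppi = network.read_ppi_tsv(ppi_path)
    diabetes = network.read_gene_list(cfg.input_path("genes_diabetes"))
    dr = network.read_gene_list(cfg.input_path("genes_dr"))
    cerna_path = cfg.input_path("cerna")
    cerna = network.read_cerna_tsv(cerna_path) if cerna_path else \
        pd.DataFrame(columns=["lncrna", "gene", "shared_mirnas"])
    clmn, report = network.build_clmn(ppi, diabetes, dr, cerna)
    clmn.to_graphml(_out(cfg, "network", "clmn.graphml"))
    clmn.to_tsv(_out(cfg, "network", "clmn_edges.tsv"),
                _out(cfg, "network", "clmn_nodes.tsv"))
    type_counts = pd.Series(list(clmn.node_types().values())).value_counts()
    block = {
        "status": "ok",
        "nodes": clmn.number_of_nodes(),
        "edges": clmn.number_of_edges(),
        "ppi_edges": clmn.number_of_edges("ppi"),
        "cerna_edges": clmn.number_of_edges("cerna"),
        "type_counts": {k: int(v) for k, v in sorted(type_counts.items())},
        "genes_not_in_ppi": len(report.genes_not_in_ppi),
        "cerna_edges_dropped": len(report.cerna_edges_dropped),
    }
    return block


def _load_clmn(cfg: PipelineConfig) -> TypedGraph:
    return TypedGraph.from_graphml(
        os.path.join(cfg.outdir, "network", "clmn.graphml")
    )


def stage_topology(cfg: PipelineConfig) -> dict:
    clmn = _load_clmn(cfg)
    metrics = topology.compute_node_metrics(clmn)
    metrics.to_csv(_out(cfg, "topology", "node_metrics.tsv"), sep="\t")

    fits = {}
    for label in ("lncRNA", "diabetes", "DR", "common"):
        degs = metrics.loc[metrics["type"] == label, "degree"]
        try:
            fit = topology.fit_power_law(degs)
            fits[label] = dataclasses.asdict(fit)
        except NetdissectError as exc:
            fits[label] = {"error": str(exc)}
    comparisons = []
    for metric in ("degree", "bc", "tc"):
        comparisons.extend(topology.compare_metric_by_type(metrics, metric))
    topology.comparisons_frame(comparisons).to_csv(
        _out(cfg, "topology", "comparisons.tsv"), sep="\t", index=False
    )
    hubs = topology.select_hubs(metrics, cfg.hub_k)
    is_lnc = metrics["type"] == "lncRNA"
    hub_lnc = topology.select_hubs(
        metrics, cfg.hub_k, node_filter=lambda n: bool(is_lnc.get(n, False))
    )
    hub_lnc = [h for h in hub_lnc if is_lnc.get(h, False)]
    props = topology.regulating_proportions(clmn, hub_lnc)
    props.to_csv(_out(cfg, "topology", "hub_lncrna_proportions.tsv"),
                 sep="\t")
    _write_json({"hubs": hubs, "hub_lncrnas": hub_lnc},
                _out(cfg, "topology", "hubs.json"))
    return {
        "status": "ok",
        "power_law_fits": fits,
        "n_comparisons": len(comparisons),
        "hubs": hubs[:10],
        "hub_lncrnas": hub_lnc[:10],
        "mean_common_proportion": (
            float(props["p_common"].mean()) if len(props) else None
        ),
    }


def stage_modules(cfg: PipelineConfig) -> dict:
    clmn = _load_clmn(cfg)
    modules = mcode.predict_complexes(clmn, cfg.mcode_params)
    top = mcode.rank_modules(modules, cfg.top_n_modules)
    _write_json(mcode.modules_json(top),
                _out(cfg, "modules", "top_modules.json"))
    for i, mod in enumerate(top, 1):
        clmn.subgraph(mod.members).to_graphml(
            _out(cfg, "modules", f"module_{i:02d}.graphml")
        )
    return {
        "status": "ok",
        "n_detected": len(modules),
        "n_reported": len(top),
        "scores": [round(m.score, 4) for m in top],
        "sizes": [m.size for m in top],
    }


def stage_enrichment(cfg: PipelineConfig) -> dict:
    gmt_path = cfg.input_path("gene_sets")
    if gmt_path is None:
        return {"status": "skipped", "reason": "no gene-set collection"}
    collection = enr.read_gmt(gmt_path)
    clmn = _load_clmn(cfg)
    coding = {n for n in clmn.nodes() if clmn.node_type(n) != "lncRNA"}
    universe = collection.all_genes() & coding
    with open(os.path.join(cfg.outdir, "modules",
                           "top_modules.json")) as fh:
        top = json.load(fh)
    results = {}
    for i, mod in enumerate(top, 1):
        query = set(mod["members"]) & universe
        table = enr.enrich(query, collection, universe)
        table.to_csv(_out(cfg, "enrichment", f"module_{i:02d}.tsv"),
                     sep="\t", index=False)
        sig = table[table["p_bh"] < 0.05]
        results[f"module_{i:02d}"] = {
            "query_size": len(query),
            "n_significant": int(len(sig)),
            "top_set": (None if table.empty
                        else str(table.iloc[0]["set_name"])),
        }
    return {"status": "ok", "universe_size": len(universe),
            "modules": results}


def stage_expression(cfg: PipelineConfig) -> dict:
    matrix_path = cfg.input_path("expression")
    groups_path = cfg.input_path("groups")
    if matrix_path is None or groups_path is None:
        return {"status": "skipped", "reason": "no expression matrix"}
    matrix = expr.read_expression_tsv(matrix_path, groups_path)
    de = expr.differential_expression(
        matrix, p_cutoff=cfg.de_p_cutoff, fc_cutoff=cfg.de_fc_cutoff
    )
    de.to_csv(_out(cfg, "expression", "differential_expression.tsv"),
              sep="\t")
    clmn = _load_clmn(cfg)
    with open(os.path.join(cfg.outdir, "topology", "hubs.json")) as fh:
        hub_lnc = json.load(fh)["hub_lncrnas"]
    pairs = []
    for lnc in hub_lnc:
        for gene in clmn.neighbors(lnc, kind="cerna"):
            if lnc in matrix.values.index and gene in matrix.values.index:
                pairs.append((lnc, gene))
    logm = expr.log2_transform(matrix)
    coex = expr.coexpression(pairs, logm, p_cutoff=cfg.coexpr_p_cutoff)
    coex.to_csv(_out(cfg, "expression", "coexpression.tsv"),
                sep="\t", index=False)
    return {
        "status": "ok",
        "n_genes": int(len(de)),
        "n_significant_de": int(de["significant"].sum()),
        "n_pairs": int(len(coex)),
        "n_significant_pairs": int(coex["significant"].sum()),
    }


def stage_variants(cfg: PipelineConfig) -> dict:
    snp_path = cfg.input_path("snps")
    if snp_path is None:
        return {"status": "skipped", "reason": "no SNP table"}
    snps = variants.read_snp_tsv(snp_path)
    seqs = variants.read_fasta(cfg.input_path("fasta"))
    seeds = variants.read_element_tsv(cfg.input_path("seeds"))
    motifs = variants.read_element_tsv(cfg.input_path("motifs"))
    clmn = _load_clmn(cfg)

    kept = variants.ld_filter(snps, cfg.r2_threshold)
    events = []
    for _, row in kept.iterrows():
        seq = seqs.get(str(row["lncrna_id"]))
        if seq is None:
            continue
        if row["region_class"] == "lncRNA":
            events.extend(variants.mirna_site_call(
                seq, row, seeds, mode=cfg.seed_match_mode
            ))
        elif row["region_class"] == "TFBS":
            events.extend(variants.tfbs_call(seq, row, motifs))
    events = [e for e in events if clmn.has_node(e.lncrna_id)]
    pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(
        _out(cfg, "variants", "site_events.tsv"), sep="\t", index=False
    )
    disruption = variants.cerna_disruption(events, clmn)
    disruption.to_csv(_out(cfg, "variants", "cerna_disruption.tsv"),
                      sep="\t", index=False)
    snp_map = variants.build_snp_map(kept, clmn)
    _write_json(snp_map, _out(cfg, "variants", "snp_map.json"))
    status_counts = disruption["status"].value_counts() if len(disruption) \
        else pd.Series(dtype=int)
    return {
        "status": "ok",
        "n_snps_input": int(len(snps)),
        "n_snps_after_ld": int(len(kept)),
        "n_site_events": len(events),
        "disruption_counts": {k: int(v)
                              for k, v in sorted(status_counts.items())},
        "fraction_lncrnas_with_snp": snp_map["fraction_with_snp"],
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "build": stage_build,
    "topology": stage_topology,
    "modules": stage_modules,
    "enrichment": stage_enrichment,
    "expression": stage_expression,
    "variants": stage_variants,
}


def run_all(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages in order and write ``report.json``."""
    os.makedirs(cfg.outdir, exist_ok=True)
    blocks: dict[str, dict] = {}
    for stage in STAGES:
        bpath = _block_path(cfg, stage)
        if resume and os.path.exists(bpath):
            with open(bpath) as fh:
                blocks[stage] = json.load(fh)
            continue
        try:
            block = _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            _write_json({"failed_stage": stage, "error": str(exc)},
                        os.path.join(cfg.outdir, "FAILED.json"))
            raise NetdissectError(f"stage {stage!r} failed: {exc}") from exc
        blocks[stage] = block
        _write_json(block, bpath)
    report = {
        "seed": cfg.seed,
        "parameters": cfg.to_dict(),
        "stages": blocks,
    }
    _write_json(report, os.path.join(cfg.outdir, "report.json"))
    return report
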