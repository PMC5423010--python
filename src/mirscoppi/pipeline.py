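"""End-to-end orchestration: simulate -> sponge -> motif -> topology ->
cluster -> evaluate -> enrich, with a reproducible run manifest.

Every stage output is a pure function of (inputs, config, seed); re-running
with identical inputs and configuration reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import mcl, motifs, simulate, topology
from .datamodel import (
    EdgeList,
    GeneList,
    PipelineConfig,
    concat_expression,
    read_edge_list,
    read_expression_matrix,
    read_gene_list,
    read_gmt,
    read_sample_labels,
    write_network,
)
from .evaluate import (
    EvaluationError,
    evaluate_module,
    ora_enrichment,
    rank_and_select_signatures,
)
from .motifs import MotifMatch
from .sponge import (
    SharedMiRNAStat,
    SpongeCandidate,
    build_regulation_profiles,
    infer_sponge_network,
)

logger = logging.getLogger("mirscoppi")


# ---------------------------------------------------------------------------
# Stage helpers shared by CLI and tests
# ---------------------------------------------------------------------------

def sponge_step(bundle: simulate.SyntheticBundle, config: PipelineConfig):
    """Run Step 1 on a bundle: profiles + four-condition inference."""
    expr_cerna = concat_expression(bundle.expr_lncrna, bundle.expr_mrna)
    profiles = build_regulation_profiles(bundle.expr_mirna, expr_cerna,
                                         bundle.mirna_targets)
    net, candidates = infer_sponge_network(profiles, expr_cerna,
                                           bundle.disease_genes, config,
                                           lncrna_ids=bundle.lncrna_ids)
    return net, candidates, profiles


def motif_step(sponge_edges: EdgeList, ppi: EdgeList, lnc_target: EdgeList,
               lncrna_ids: GeneList):
    """Run Step 2: integrate layers, enumerate motifs, merge into the network."""
    integrated = motifs.integrate_networks(sponge_edges, ppi, lnc_target,
                                           lncrna_ids)
    matches = motifs.enumerate_motifs(integrated)
    coreg = motifs.build_coreg_network(matches)
    return integrated, matches, coreg


# ---------------------------------------------------------------------------
# Audit / intermediate-file round trips
# ---------------------------------------------------------------------------

_CAND_HEADER = ("ceRNA_i\tceRNA_j\tshared\tM\tN\tK\tp\tcos\tcol\tsim\tcorr\t"
                "corr_p\tdisease\tsharing\tpattern\tpositive_corr\taccepted\t"
                "shared_mirnas\treject_reason\n")


def _fmt(v) -> str:
    return "NA" if v is None else repr(v)


def write_candidates(candidates: list[SpongeCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(_CAND_HEADER)
        for c in sorted(candidates, key=lambda c: c.pair):
            s = c.stat
            fh.write("\t".join([
                c.ceRNA_i, c.ceRNA_j, str(s.x), str(s.M), str(s.N), str(s.K),
                repr(s.p), _fmt(c.cos), _fmt(c.col), _fmt(c.sim), _fmt(c.corr),
                _fmt(c.corr_p), str(int(c.passed_disease)),
                str(int(c.passed_sharing)), str(int(c.passed_pattern)),
                str(int(c.passed_positive_corr)), str(int(c.accepted)),
                ",".join(c.shared_mirnas), c.reject_reason,
            ]) + "\n")


def read_candidates(path) -> list[SpongeCandidate]:
    out: list[SpongeCandidate] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("ceRNA_i\t"):
            raise ValueError(f"{path}: unexpected candidate-file header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            stat = SharedMiRNAStat(int(f[3]), int(f[4]), int(f[5]), int(f[2]),
                                   float(f[6]))

            def opt(v: str) -> float | None:
                return None if v == "NA" else float(v)

            out.append(SpongeCandidate(
                f[0], f[1], f[17].split(",") if f[17] else [], stat,
                cos=opt(f[7]), col=opt(f[8]), sim=opt(f[9]), corr=opt(f[10]),
                corr_p=opt(f[11]), passed_disease=bool(int(f[12])),
                passed_sharing=bool(int(f[13])), passed_pattern=bool(int(f[14])),
                passed_positive_corr=bool(int(f[15])),
                reject_reason=f[18] if len(f) > 18 else "",
            ))
    return out


def write_motifs(matches: list[MotifMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_type\ts1\ts2\tp1\tp2\n")
        for m in matches:
            fh.write("\t".join([m.motif_type, *m.sponge_pair, *m.proteins])
                     + "\n")


def read_motifs(path) -> list[MotifMatch]:
    """Lightweight matches (sponge pair + proteins) for topology statistics."""
    out: list[MotifMatch] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("motif_type\t"):
            raise ValueError(f"{path}: unexpected motif-file header")
        for line in fh:
            t, s1, s2, p1, p2 = line.rstrip("\n").split("\t")[:5]
            out.append(MotifMatch(t, (s1, s2), (p1, p2), edges=(), kinds=()))
    return out


def write_scores(scores, path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tmodule_id\tsize\tauc\tacc\topi\tis_signature\n")
        for rank, s in enumerate(scores, 1):
            fh.write(f"{rank}\t{s.module_id}\t{s.size}\t{s.auc:.4f}\t"
                     f"{s.acc:.4f}\t{s.opi:.4f}\t{int(s.is_signature)}\n")


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(paths: dict) -> simulate.SyntheticBundle:
    return simulate.SyntheticBundle(
        expr_mirna=read_expression_matrix(paths["mirna_expr"]),
        expr_lncrna=read_expression_matrix(paths["lncrna_expr"]),
        expr_mrna=read_expression_matrix(paths["mrna_expr"]),
        mirna_targets=read_edge_list(paths["mirna_targets"], "mirna_target"),
        ppi=read_edge_list(paths["ppi"], "ppi"),
        lnc_target=read_edge_list(paths["lnc_target"], "lnc_target"),
        disease_genes=read_gene_list(paths["disease_genes"], "disease"),
        lncrna_ids=read_gene_list(paths["lncrna_ids"], "lncRNA"),
        labels=read_sample_labels(paths["labels"]),
    )


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute all stages from a YAML config file; returns the run manifest.

    The config holds an ``outdir``, a ``seed``, either a ``simulate`` block
    (generator parameters) or an ``inputs`` block (file paths), and an
    optional ``params`` block overriding :class:`PipelineConfig` defaults.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    outdir = Path(cfg.get("outdir", config_path.parent / "mirscoppi_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    params = PipelineConfig(random_seed=seed, **cfg.get("params", {}))
    manifest = RunManifest(config=cfg, seed=seed)

    if "simulate" in cfg:
        bundle, _ = simulate.generate_dataset(seed=seed,
                                              **(cfg["simulate"] or {}))
        input_paths = bundle.write(outdir / "inputs")
    elif "inputs" in cfg:
        input_paths = {k: Path(v) for k, v in cfg["inputs"].items()
                       if k != "gmt"}
        bundle = _load_inputs(cfg["inputs"])
    else:
        raise ValueError("config needs a 'simulate' or 'inputs' block")
    for name, p in input_paths.items():
        manifest.input_digests[name] = _digest(Path(p))

    # Step 1 — sponge inference
    sponge_net, candidates, _ = sponge_step(bundle, params)
    write_network(sponge_net, outdir / "sponge_edges.tsv")
    write_candidates(candidates, outdir / "candidates.tsv")
    manifest.outputs["sponge_edges"] = str(outdir / "sponge_edges.tsv")
    manifest.outputs["candidates"] = str(outdir / "candidates.tsv")
    manifest.counts["candidates_tested"] = len(candidates)
    manifest.counts["sponge_edges"] = sponge_net.n_edges

    # Step 2 — motifs and merged network
    _, matches, coreg = motif_step(sponge_net.as_edge_list("sponge"),
                                   bundle.ppi, bundle.lnc_target,
                                   bundle.lncrna_ids)
    write_motifs(matches, outdir / "motifs.tsv")
    write_network(coreg, outdir / "coreg.tsv")
    manifest.outputs["motifs"] = str(outdir / "motifs.tsv")
    manifest.outputs["coreg_network"] = str(outdir / "coreg.tsv")
    manifest.counts["motifs_found"] = len(matches)
    for etype, n in coreg.edge_type_counts().items():
        manifest.counts[f"coreg_{etype}_edges"] = n

    # Step 3 — topology, clustering, evaluation
    report: dict[str, object] = {}
    if coreg.n_nodes >= 2:
        dist = topology.degree_distribution(coreg)
        report["characteristic_path_length"] = topology.characteristic_path_length(coreg)
        try:
            report["degree_powerlaw_r2"] = topology.power_law_r2(
                {k: v for k, v in dist.items() if k > 0}).r_squared
        except (topology.InsufficientDataError, ValueError):
            report["degree_powerlaw_r2"] = "NA"
        stats_ = topology.edge_statistics(coreg, matches, candidates)
        report["motif_shared_mirna_corr"] = (stats_.corr if stats_.corr_defined
                                             else "NA")
        hubs = topology.select_hubs(coreg, params.hub_fraction)
        (outdir / "hubs.txt").write_text("\n".join(hubs) + "\n")
        manifest.outputs["hubs"] = str(outdir / "hubs.txt")
        manifest.counts["hubs"] = len(hubs)
        clusters = mcl.mcl_cluster(coreg, inflation=params.mcl_inflation,
                                   expansion=params.mcl_expansion)
        partition = mcl.extract_modules(clusters, params.min_module_size)
    else:
        logger.info("empty co-regulation network; topology/clustering skipped")
        partition = mcl.ModulePartition([], [])
    with open(outdir / "topology.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in report.items():
            fh.write(f"{k}\t{v}\n")
    manifest.outputs["topology"] = str(outdir / "topology.tsv")
    mcl.write_modules(partition, outdir / "modules.tsv")
    manifest.outputs["modules"] = str(outdir / "modules.tsv")
    manifest.counts["modules_kept"] = len(partition)

    expr_cerna = concat_expression(bundle.expr_lncrna, bundle.expr_mrna)
    scores = []
    for mid, members in partition.items():
        try:
            scores.append(evaluate_module(members, expr_cerna, bundle.labels,
                                          folds=params.cv_folds, seed=seed,
                                          module_id=mid,
                                          signature_cutoff=params.signature_cutoff))
        except EvaluationError as exc:
            logger.warning("module %d not evaluable: %s", mid, exc)
    if scores:
        scores = rank_and_select_signatures(scores, params.signature_cutoff)
    write_scores(scores, outdir / "scores.tsv")
    manifest.outputs["scores"] = str(outdir / "scores.tsv")
    manifest.counts["modules_evaluated"] = len(scores)
    manifest.counts["signatures_selected"] = sum(s.is_signature for s in scores)

    gmt_path = cfg.get("inputs", {}).get("gmt") if "inputs" in cfg else None
    if gmt_path:
        gene_sets = read_gmt(gmt_path)
        universe = set(expr_cerna.gene_ids)
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("module_id\tterm_id\toverlap\tterm_size\tmodule_size\t"
                     "universe\tp\tp_adjusted\n")
            n_hits = 0
            for mid, members in partition.items():
                tested = members & universe
                if not tested:
                    continue
                for r in ora_enrichment(tested, gene_sets, universe,
                                        params.enrichment_alpha):
                    fh.write(f"{mid}\t{r.term_id}\t{r.overlap}\t{r.term_size}"
                             f"\t{r.module_size}\t{r.universe}\t{r.p:.6g}\t"
                             f"{r.p_adjusted:.6g}\n")
                    n_hits += 1
        manifest.outputs["enrichment"] = str(outdir / "enrichment.tsv")
        manifest.counts["enriched_terms"] = n_hits

    manifest.write(outdir / "manifest.json")
    return manifest
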