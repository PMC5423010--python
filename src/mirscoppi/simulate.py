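"""Seeded synthetic input bundles with planted ground truth.

The generator emulates the statistical structure the inference assumes:
pairs of ceRNAs jointly and negatively regulated by a dedicated block of
shared miRNAs (which makes the pair positively co-expressed and gives both
members near-identical regulator-correlation vectors), background ceRNAs with
at most two incidental regulators, a protein layer wiring every planted pair
into one type-A and one type-B co-regulation motif, and tumor/normal
mean-shifted differential modules for the classification stage.

Negative regulation (-reg_strength) is used so that miRNA-ceRNA correlations
are strongly non-zero and the two sponges correlate positively with each
other — the canonical ceRNA mechanism. Regulator blocks of distinct planted
pairs are disjoint so the ground truth is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datamodel import (
    EdgeList,
    ExpressionMatrix,
    GeneList,
    SampleLabels,
    TypedNetwork,
    canonical_edge,
    write_edge_list,
    write_gene_list,
    write_sample_labels,
)

logger = logging.getLogger("mirscoppi")


class ParameterError(ValueError):
    """Infeasible generator configuration."""


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, in memory."""

    expr_mirna: ExpressionMatrix
    expr_lncrna: ExpressionMatrix
    expr_mrna: ExpressionMatrix
    mirna_targets: EdgeList
    ppi: EdgeList
    lnc_target: EdgeList
    disease_genes: GeneList
    lncrna_ids: GeneList
    labels: SampleLabels

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna_expr": out / "mirna_expr.tsv",
            "lncrna_expr": out / "lncrna_expr.tsv",
            "mrna_expr": out / "mrna_expr.tsv",
            "mirna_targets": out / "mirna_targets.tsv",
            "ppi": out / "ppi.tsv",
            "lnc_target": out / "lnc_target.tsv",
            "disease_genes": out / "disease_genes.txt",
            "lncrna_ids": out / "lncrna_ids.txt",
            "labels": out / "labels.tsv",
        }
        self.expr_mirna.write(paths["mirna_expr"])
        self.expr_lncrna.write(paths["lncrna_expr"])
        self.expr_mrna.write(paths["mrna_expr"])
        write_edge_list(self.mirna_targets, paths["mirna_targets"])
        write_edge_list(self.ppi, paths["ppi"])
        write_edge_list(self.lnc_target, paths["lnc_target"])
        write_gene_list(self.disease_genes, paths["disease_genes"])
        write_gene_list(self.lncrna_ids, paths["lncrna_ids"])
        write_sample_labels(self.labels, paths["labels"])
        return paths


@dataclass
class GroundTruth:
    planted_sponge_pairs: set[tuple[str, str]]
    planted_regulators: dict[str, set[str]]
    planted_motifs: list[tuple[str, tuple[str, str], tuple[str, str]]]
    differential_modules: list[tuple[frozenset, float]]


def generate_dataset(
    n_mirna: int = 100,
    n_lncrna: int = 30,
    n_mrna: int = 120,
    n_tumor: int = 72,
    n_normal: int = 72,
    n_pairs: int = 20,
    shared_per_pair: int = 4,
    reg_strength: float = 1.0,
    noise_sd: float = 0.3,
    delta: float = 3.0,
    seed: int = 0,
    n_decoy_disease: int = 20,
    max_background_regulators: int = 2,
    n_extra_proteins: int = 30,
    n_background_ppi: int = 40,
    n_diff_modules: int = 2,
    diff_module_size: int = 8,
) -> tuple[SyntheticBundle, GroundTruth]:
    """Generate a complete input bundle plus its ground truth.

    Planted pair kinds cycle lncRNA-lncRNA, lncRNA-mRNA, mRNA-mRNA. Each pair
    (A, B) receives a dedicated, disjoint block of ``shared_per_pair`` miRNAs
    and expression A = -w * sum(block) + eps, likewise B, with
    w = ``reg_strength`` and eps ~ N(0, noise_sd^2). Tumor columns of each
    differential module are shifted by +``delta``. Identical seeds produce
    bit-identical bundles.
    """
    if shared_per_pair < 3:
        raise ParameterError("shared_per_pair must be >= 3")
    if reg_strength <= 0:
        raise ParameterError("reg_strength must be > 0")
    if n_pairs * shared_per_pair > n_mirna:
        raise ParameterError(
            f"{n_pairs} pairs x {shared_per_pair} shared miRNAs need "
            f"{n_pairs * shared_per_pair} disjoint regulators but only "
            f"{n_mirna} miRNAs exist"
        )
    kinds = [("lnc", "lnc"), ("lnc", "mrna"), ("mrna", "mrna")]
    pair_kinds = [kinds[i % 3] for i in range(n_pairs)]
    need_lnc = sum(k.count("lnc") for k in pair_kinds)
    need_mrna = sum(k.count("mrna") for k in pair_kinds)
    if need_lnc > n_lncrna or need_mrna + n_diff_modules * diff_module_size > n_mrna:
        raise ParameterError("not enough lncRNAs/mRNAs for the planted structure")

    rng = np.random.default_rng(seed)
    mirnas = [f"miR{i:03d}" for i in range(n_mirna)]
    lncs = [f"LNC{i:03d}" for i in range(n_lncrna)]
    mrnas = [f"GENE{i:03d}" for i in range(n_mrna)]
    samples = [f"T{i:03d}" for i in range(n_tumor)] + \
              [f"N{i:03d}" for i in range(n_normal)]
    ns = len(samples)
    tumor_cols = np.arange(n_tumor)

    mirna_vals = rng.normal(size=(n_mirna, ns))
    lnc_vals = rng.normal(size=(n_lncrna, ns))
    mrna_vals = rng.normal(size=(n_mrna, ns))

    # --- planted sponge pairs ------------------------------------------------
    lnc_cursor = mrna_cursor = 0
    planted_pairs: set[tuple[str, str]] = set()
    planted_regs: dict[str, set[str]] = {}
    target_edges: set[tuple[str, str]] = set()
    planted_names: list[tuple[str, str]] = []
    for p, (ka, kb) in enumerate(pair_kinds):
        block = list(range(p * shared_per_pair, (p + 1) * shared_per_pair))
        signal = -reg_strength * mirna_vals[block].sum(axis=0)
        members = []
        for kind in (ka, kb):
            if kind == "lnc":
                name, row = lncs[lnc_cursor], lnc_vals[lnc_cursor]
                lnc_cursor += 1
            else:
                name, row = mrnas[mrna_cursor], mrna_vals[mrna_cursor]
                mrna_cursor += 1
            row[:] = signal + rng.normal(0.0, noise_sd, size=ns)
            members.append(name)
            planted_regs[name] = {mirnas[i] for i in block}
            target_edges.update(canonical_edge(mirnas[i], name) for i in block)
        planted_pairs.add(canonical_edge(*members))
        planted_names.append(tuple(members))

    planted_set = set(planted_regs)
    background = [g for g in lncs + mrnas if g not in planted_set]

    # --- background regulators (at most max_background_regulators each) ------
    for gene in background:
        k = int(rng.integers(0, max_background_regulators + 1))
        if k:
            for mir in rng.choice(mirnas, size=k, replace=False):
                target_edges.add(canonical_edge(str(mir), gene))

    # --- disease list: planted sponges plus decoys ---------------------------
    decoys = [str(g) for g in
              rng.choice(background, size=min(n_decoy_disease, len(background)),
                         replace=False)]
    disease = GeneList(planted_set | set(decoys), "disease")

    # --- PPI / lncRNA-target layer wiring each pair into both motif types ----
    ppi_edges: set[tuple[str, str]] = set()
    lnc_target_edges: set[tuple[str, str]] = set()
    planted_motifs: list[tuple[str, tuple[str, str], tuple[str, str]]] = []

    def link(sponge: str, protein: str) -> None:
        if sponge.startswith("LNC"):
            lnc_target_edges.add(canonical_edge(sponge, protein))
        else:
            ppi_edges.add(canonical_edge(sponge, protein))

    proteins: list[str] = []
    for p, (a, b) in enumerate(planted_names):
        pa, pb, pc, pq = (f"PROT{4 * p + i:03d}" for i in range(4))
        proteins += [pa, pb, pc, pq]
        link(a, pa)
        link(b, pb)
        ppi_edges.add(canonical_edge(pa, pb))
        link(a, pc)
        link(b, pc)
        ppi_edges.add(canonical_edge(pc, pq))
        s1, s2 = canonical_edge(a, b)
        p1, p2 = (pa, pb) if s1 == a else (pb, pa)
        planted_motifs.append(("A", (s1, s2), (p1, p2)))
        planted_motifs.append(("B", (s1, s2), (pc, pq)))
    extra = [f"PROT{4 * n_pairs + i:03d}" for i in range(n_extra_proteins)]
    proteins += extra
    pool = extra if len(extra) >= 2 else proteins
    added = 0
    while added < n_background_ppi:
        u, v = rng.choice(pool, size=2, replace=False)
        e = canonical_edge(str(u), str(v))
        if e not in ppi_edges:
            ppi_edges.add(e)
            added += 1

    # --- differential modules (tumor mean shift) -----------------------------
    diff_modules: list[tuple[frozenset, float]] = []
    diff_pool = [g for g in mrnas if g not in planted_set]
    cursor = 0
    for _ in range(n_diff_modules):
        members = diff_pool[cursor:cursor + diff_module_size]
        cursor += diff_module_size
        for g in members:
            mrna_vals[mrnas.index(g)][tumor_cols] += delta
        diff_modules.append((frozenset(members), delta))

    bundle = SyntheticBundle(
        expr_mirna=ExpressionMatrix(mirnas, samples, mirna_vals),
        expr_lncrna=ExpressionMatrix(lncs, samples, lnc_vals),
        expr_mrna=ExpressionMatrix(mrnas, samples, mrna_vals),
        mirna_targets=EdgeList(target_edges, "mirna_target"),
        ppi=EdgeList(ppi_edges, "ppi"),
        lnc_target=EdgeList(lnc_target_edges, "lnc_target"),
        disease_genes=disease,
        lncrna_ids=GeneList(set(lncs), "lncRNA"),
        labels=SampleLabels({s: ("tumor" if s.startswith("T") else "normal")
                             for s in samples}),
    )
    truth = GroundTruth(planted_pairs, planted_regs, planted_motifs,
                        diff_modules)
    logger.info("synthetic bundle: %d planted pairs, %d target edges, "
                "%d PPIs, %d lnc-target edges", n_pairs, len(target_edges),
                len(ppi_edges), len(lnc_target_edges))
    return bundle, truth


def truth_comparison(
    inferred: TypedNetwork | set[tuple[str, str]],
    truth: GroundTruth,
) -> tuple[float | None, float]:
    """Precision and recall of inferred sponge edges against the planted set.

    Precision is None (flagged) when nothing was inferred.
    """
    if isinstance(inferred, TypedNetwork):
        edges = inferred.edges_of_type("sponge")
    else:
        edges = {canonical_edge(a, b) for a, b in inferred}
    planted = truth.planted_sponge_pairs
    hit = len(edges & planted)
    recall = hit / len(planted) if planted else 0.0
    if not edges:
        logger.warning("no inferred sponge edges; precision undefined")
        return None, recall
    return hit / len(edges), recall
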