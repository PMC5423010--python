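"""Module evaluation: SVM classification of tumor vs normal samples
(ACC/AUC/OPI via stratified cross-validation), signature selection, and
over-representation analysis against user-supplied gene sets.

Classifier conventions are pinned so results are reproducible: RBF kernel,
cost 1, kernel width 1/n_features, features standardized to zero mean and
unit variance within each training fold, stratified seeded fold assignment.
ACC is the pooled out-of-fold correct fraction; AUC comes from pooled
out-of-fold decision values via the rank (Mann-Whitney) formulation — the
probability that a random tumor sample scores above a random normal one.
OPI, the overall prognostic index, is (AUC + ACC) / 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .datamodel import TUMOR, ExpressionMatrix, SampleLabels
from .sponge import shared_mirna_pvalue

logger = logging.getLogger("mirscoppi")


class EvaluationError(ValueError):
    pass


@dataclass
class ModuleScore:
    module_id: int
    size: int
    auc: float
    acc: float
    opi: float
    is_signature: bool = False


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    term_size: int
    module_size: int
    universe: int
    p: float
    p_adjusted: float


def overall_prognostic_index(auc: float, acc: float) -> float:
    """OPI = (AUC + ACC) / 2; both arguments must be in [0, 1]."""
    if not (0.0 <= auc <= 1.0 and 0.0 <= acc <= 1.0):
        raise ValueError(f"AUC/ACC out of [0, 1]: {auc}, {acc}")
    return (auc + acc) / 2.0


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank formulation (ties get average rank)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def evaluate_module(
    module_genes: set[str],
    expr: ExpressionMatrix,
    labels: SampleLabels,
    folds: int = 10,
    seed: int = 0,
    module_id: int = 0,
    signature_cutoff: float = 0.9,
) -> ModuleScore:
    """Cross-validated SVM performance of a module's expression features.

    Features are the expression rows of the module's measured genes (genes
    absent from the matrix are dropped with a warning; protein-only nodes have
    no expression and simply never match). Samples are the labeled columns.
    """
    usable = sorted(g for g in module_genes if g in expr)
    missing = len(module_genes) - len(usable)
    if missing:
        logger.warning("module %d: %d gene(s) without expression dropped",
                       module_id, missing)
    if len(usable) < 2:
        raise EvaluationError(
            f"module {module_id}: fewer than 2 genes with expression"
        )
    samples = [s for s in expr.sample_ids if s in labels]
    if len(samples) < len(labels):
        raise EvaluationError("labeled sample(s) missing from the expression matrix")
    y = np.array([1 if labels[s] == TUMOR else 0 for s in samples])
    if min(int(y.sum()), int((1 - y).sum())) < folds:
        raise EvaluationError(
            f"each class needs >= {folds} samples for {folds}-fold CV"
        )
    cols = [expr.sample_ids.index(s) for s in samples]
    X = np.vstack([expr.row(g) for g in usable])[:, cols].T

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    decision = np.empty(len(samples))
    predicted = np.empty(len(samples), dtype=int)
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        clf = SVC(C=1.0, kernel="rbf", gamma=1.0 / X.shape[1])
        clf.fit(scaler.transform(X[train]), y[train])
        Xt = scaler.transform(X[test])
        decision[test] = clf.decision_function(Xt)
        predicted[test] = clf.predict(Xt)
    acc = float(np.mean(predicted == y))
    auc = rank_auc(decision, y)
    opi = overall_prognostic_index(auc, acc)
    return ModuleScore(module_id, len(usable), auc, acc, opi,
                       is_signature=(acc > signature_cutoff
                                     and auc > signature_cutoff))


def rank_and_select_signatures(
    scores: list[ModuleScore], cutoff: float = 0.9
) -> list[ModuleScore]:
    """Sort by OPI descending (ties: size desc, then id) and set signature flags.

    A module is a signature when BOTH its ACC and AUC exceed the cutoff.
    """
    if not scores:
        raise ValueError("no module scores")
    ranked = sorted(scores, key=lambda s: (-s.opi, -s.size, s.module_id))
    for s in ranked:
        s.is_signature = s.acc > cutoff and s.auc > cutoff
    return ranked


def ora_enrichment(
    module_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation with BH adjustment.

    Gene sets are intersected with the universe; the module must be a subset
    of the universe. Returns terms with adjusted p < alpha, sorted by
    adjusted p (ties by raw p, then term id).
    """
    if not universe:
        raise ValueError("empty universe")
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    results: list[EnrichmentResult] = []
    for term in sorted(gene_sets):
        term_genes = gene_sets[term] & universe
        overlap = len(module_genes & term_genes)
        p = shared_mirna_pvalue(len(universe), len(term_genes),
                                len(module_genes), overlap)
        results.append(EnrichmentResult(term, overlap, len(term_genes),
                                        len(module_genes), len(universe),
                                        p, p_adjusted=np.nan))
    if results:
        _, adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    hits = [r for r in results if r.p_adjusted < alpha]
    hits.sort(key=lambda r: (r.p_adjusted, r.p, r.term_id))
    return hits
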