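"""Identification of the disease-related miRNA sponge (ceRNA) interaction network.

Two candidate ceRNAs are accepted as a sponge pair when four conditions hold:

(i)   both are in the disease gene list;
(ii)  they share at least ``min_shared_mirnas`` validated miRNA regulators and
      the sharing is significant under an upper-tail hypergeometric test
      (p < ``hypergeom_alpha``);
(iii) they show a similar miRNA regulation pattern: the mean of a cosine score
      and a collaboration score over the shared miRNAs' regulator-ceRNA
      correlations, Sim >= ``sim_threshold``;
(iv)  their own expression profiles are positively correlated (r > 0,
      p < ``corr_alpha``).

The cosine score is the cosine of the two correlation vectors C_i, C_j over
the shared miRNAs. The collaboration score uses absolute correlations AC and,
deliberately, square roots of *sums* (not sums of squares) in its denominator:

    Col = sum_k AC_ik AC_jk / (sqrt(sum_k AC_ik) * sqrt(sum_k AC_jk))

which makes it an "excessive" estimate bounded by 1 for AC in [0, 1]
(Cauchy-Schwarz with a^2 <= a). Sim = (Cos + Col) / 2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import (
    EdgeList,
    ExpressionMatrix,
    GeneList,
    PipelineConfig,
    TypedNetwork,
    UndefinedScoreError,
    canonical_edge,
)

logger = logging.getLogger("mirscoppi")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def pearson_with_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the exact two-sided t-test p-value.

    p is computed from t = r * sqrt((n-2) / (1 - r^2)) on n-2 degrees of
    freedom; |r| = 1 yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedScoreError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def shared_mirna_pvalue(M: int, N: int, K: int, x: int) -> float:
    """Upper-tail hypergeometric probability of sharing >= x regulators.

    M is the total number of miRNAs in the dataset, N and K the numbers
    regulating each ceRNA, x the observed shared count. Returns
    p = 1 - sum_{i=0}^{x-1} C(N,i) C(M-N,K-i) / C(M,K) = P(X >= x).
    """
    if not (0 <= N <= M and 0 <= K <= M):
        raise ValueError(f"need N, K <= M; got M={M}, N={N}, K={K}")
    if not 0 <= x <= min(N, K):
        raise ValueError(f"need 0 <= x <= min(N, K); got x={x}")
    return float(stats.hypergeom.sf(x - 1, M, N, K))


def cosine_score(c_i: np.ndarray, c_j: np.ndarray) -> float:
    """Cosine of the two shared-miRNA correlation vectors; in [-1, 1]."""
    c_i = np.asarray(c_i, dtype=float)
    c_j = np.asarray(c_j, dtype=float)
    if c_i.shape != c_j.shape or c_i.ndim != 1 or c_i.size < 1:
        raise ValueError("need equal-length 1-d vectors of length >= 1")
    ni = float(np.sqrt(c_i @ c_i))
    nj = float(np.sqrt(c_j @ c_j))
    if ni == 0.0 or nj == 0.0:
        raise UndefinedScoreError("cosine score undefined for an all-zero vector")
    val = float(c_i @ c_j) / (ni * nj)
    return max(-1.0, min(1.0, val))


def collaboration_score(ac_i: np.ndarray, ac_j: np.ndarray) -> float:
    """Collaboration score over absolute correlations; in [0, 1] for AC in [0, 1].

    The denominator uses square roots of sums of the AC values themselves.
    """
    ac_i = np.asarray(ac_i, dtype=float)
    ac_j = np.asarray(ac_j, dtype=float)
    if ac_i.shape != ac_j.shape or ac_i.ndim != 1 or ac_i.size < 1:
        raise ValueError("need equal-length 1-d vectors of length >= 1")
    if np.any(ac_i < 0) or np.any(ac_j < 0):
        raise ValueError("absolute correlations must be non-negative")
    si = float(ac_i.sum())
    sj = float(ac_j.sum())
    if si == 0.0 or sj == 0.0:
        raise UndefinedScoreError("collaboration score undefined for a zero-sum vector")
    return float(ac_i @ ac_j) / (np.sqrt(si) * np.sqrt(sj))


def similarity_score(cos: float, col: float) -> float:
    """Sim = (Cos + Col) / 2."""
    if not -1.0 <= cos <= 1.0:
        raise ValueError(f"cosine score out of [-1, 1]: {cos}")
    if not 0.0 <= col <= 1.0 + 1e-12:
        raise ValueError(f"collaboration score out of [0, 1]: {col}")
    return (cos + col) / 2.0


# ---------------------------------------------------------------------------
# Regulation profiles
# ---------------------------------------------------------------------------

@dataclass
class RegulationProfile:
    """A ceRNA with its measured, validated miRNA regulators.

    ``correlations`` maps each regulator miRNA to the Pearson correlation C
    between the miRNA's and the ceRNA's expression profiles.
    """

    ceRNA: str
    regulators: list[str]
    correlations: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.regulators) != set(self.correlations):
            raise ValueError("regulators and correlations disagree")
        if not all(np.isfinite(list(self.correlations.values()))):
            raise ValueError("non-finite correlation")


@dataclass
class RegulationProfileSet:
    """Profiles keyed by ceRNA plus the size M of the miRNA universe."""

    profiles: dict[str, RegulationProfile]
    n_mirnas: int

    def __contains__(self, cerna: str) -> bool:
        return cerna in self.profiles

    def __getitem__(self, cerna: str) -> RegulationProfile:
        return self.profiles[cerna]

    def __len__(self) -> int:
        return len(self.profiles)


def build_regulation_profiles(
    expr_mirna: ExpressionMatrix,
    expr_cerna: ExpressionMatrix,
    mirna_targets: EdgeList,
) -> RegulationProfileSet:
    """Per-ceRNA regulator sets and miRNA-ceRNA expression correlations.

    Only target edges whose miRNA endpoint is in the miRNA matrix and whose
    ceRNA endpoint is in the ceRNA matrix are kept; ceRNAs with no measured
    validated regulator get no profile. Edges are undirected on disk, so the
    miRNA endpoint is recognized by membership in the miRNA matrix.
    """
    mirna_set = set(expr_mirna.gene_ids)
    regulators: dict[str, set[str]] = {}
    for a, b in mirna_targets.edges:
        if a in mirna_set and b in expr_cerna and b not in mirna_set:
            mir, target = a, b
        elif b in mirna_set and a in expr_cerna and a not in mirna_set:
            mir, target = b, a
        else:
            continue
        regulators.setdefault(target, set()).add(mir)
    profiles: dict[str, RegulationProfile] = {}
    for cerna, mirs in regulators.items():
        target_row = expr_cerna.row(cerna)
        corrs: dict[str, float] = {}
        for mir in sorted(mirs):
            try:
                r, _ = pearson_with_pvalue(expr_mirna.row(mir), target_row)
            except UndefinedScoreError:
                logger.warning("constant expression for %s/%s; regulator skipped",
                               mir, cerna)
                continue
            corrs[mir] = r
        if corrs:
            profiles[cerna] = RegulationProfile(cerna, sorted(corrs), corrs)
    if not profiles:
        logger.warning("no miRNA-target edge matched the expression matrices")
    return RegulationProfileSet(profiles, expr_mirna.n_genes)


# ---------------------------------------------------------------------------
# Sponge-pair inference
# ---------------------------------------------------------------------------

@dataclass
class SharedMiRNAStat:
    M: int
    N: int
    K: int
    x: int
    p: float


@dataclass
class SpongeCandidate:
    """One ceRNA pair with its scores and per-condition audit flags."""

    ceRNA_i: str
    ceRNA_j: str
    shared_mirnas: list[str]
    stat: SharedMiRNAStat
    cos: float | None = None
    col: float | None = None
    sim: float | None = None
    corr: float | None = None
    corr_p: float | None = None
    passed_disease: bool = False
    passed_sharing: bool = False
    passed_pattern: bool = False
    passed_positive_corr: bool = False
    reject_reason: str = ""

    @property
    def accepted(self) -> bool:
        return (self.passed_disease and self.passed_sharing
                and self.passed_pattern and self.passed_positive_corr)

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_edge(self.ceRNA_i, self.ceRNA_j)


def infer_sponge_network(
    profiles: RegulationProfileSet,
    expr_cerna: ExpressionMatrix,
    disease_genes: GeneList,
    config: PipelineConfig,
    lncrna_ids: GeneList | None = None,
) -> tuple[TypedNetwork, list[SpongeCandidate]]:
    """Apply the four sponge conditions to every sufficiently-sharing pair.

    Candidates are all profiled ceRNA pairs sharing at least
    ``config.min_shared_mirnas`` regulators; each candidate records flags for
    all four conditions so rejections are auditable. Accepted pairs become
    ``sponge`` edges of the returned network. Passing the full universe of
    genes as ``disease_genes`` disables condition (i).
    """
    if len(profiles) == 0:
        raise ValueError("no regulation profiles supplied")
    if len(disease_genes) == 0:
        raise ValueError("disease gene list is empty")
    lnc_ids = lncrna_ids.symbols if lncrna_ids is not None else set()
    candidates: list[SpongeCandidate] = []
    net = TypedNetwork()
    M = profiles.n_mirnas
    cernas = sorted(profiles.profiles)
    for gi, gj in itertools.combinations(cernas, 2):
        pi, pj = profiles[gi], profiles[gj]
        shared = sorted(set(pi.regulators) & set(pj.regulators))
        x = len(shared)
        if x < config.min_shared_mirnas:
            continue
        p = shared_mirna_pvalue(M, len(pi.regulators), len(pj.regulators), x)
        cand = SpongeCandidate(
            ceRNA_i=gi, ceRNA_j=gj, shared_mirnas=shared,
            stat=SharedMiRNAStat(M, len(pi.regulators), len(pj.regulators), x, p),
        )
        cand.passed_disease = gi in disease_genes and gj in disease_genes
        cand.passed_sharing = p < config.hypergeom_alpha
        c_i = np.array([pi.correlations[m] for m in shared])
        c_j = np.array([pj.correlations[m] for m in shared])
        try:
            cand.cos = cosine_score(c_i, c_j)
            cand.col = collaboration_score(np.abs(c_i), np.abs(c_j))
            cand.sim = similarity_score(cand.cos, cand.col)
            cand.passed_pattern = cand.sim >= config.sim_threshold
        except UndefinedScoreError as exc:
            cand.reject_reason = f"undefined regulation-pattern score: {exc}"
            logger.warning("pair (%s, %s): %s", gi, gj, cand.reject_reason)
        try:
            cand.corr, cand.corr_p = pearson_with_pvalue(
                expr_cerna.row(gi), expr_cerna.row(gj))
            cand.passed_positive_corr = (cand.corr > 0
                                         and cand.corr_p < config.corr_alpha)
        except UndefinedScoreError as exc:
            cand.reject_reason = (cand.reject_reason + "; " if cand.reject_reason
                                  else "") + f"undefined expression correlation: {exc}"
            logger.warning("pair (%s, %s): %s", gi, gj, cand.reject_reason)
        candidates.append(cand)
        if cand.accepted:
            kind_i = "lncRNA" if gi in lnc_ids else "mRNA_protein"
            kind_j = "lncRNA" if gj in lnc_ids else "mRNA_protein"
            net.add_edge(gi, gj, "sponge", kind_i, kind_j)
    logger.info("sponge inference: %d candidate pair(s), %d accepted",
                len(candidates), len(net.edges))
    return net, candidates
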