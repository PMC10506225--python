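"""Benchmarking statistics for gene-level intolerance scores.

Covers the evaluation toolkit used to compare constraint scores against
curated essential-gene sets: expected-count-matched control sets, ROC/AUC,
the DeLong test for correlated AUCs, TPR at a fixed FPR with bootstrap
uncertainty, score thresholding and Venn-style set partitions, enrichment
log odds ratios with Wald intervals, an interval-overlap permutation test
for deletion depletion, and the prior-influence summary that contrasts
scores from a feature-informed model with a feature-free one as a function
of gene "length" (expected LOF count n).

All operations accept arbitrary score columns: they never assume the scores
came from this package's model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "LabeledScores",
    "ContingencyTable2x2",
    "EnrichmentResult",
    "match_genes",
    "roc_auc",
    "delong_test",
    "tpr_at_fpr",
    "threshold_classify",
    "venn_partition",
    "enrichment_log_or",
    "deletion_overlap_permutation",
    "prior_influence_summary",
]

ESSENTIAL = "essential"
NONESSENTIAL = "nonessential"


@dataclass(frozen=True)
class LabeledScores:
    """Aligned gene identifiers, scores (higher = predicted intolerant) and labels."""

    gene_ids: np.ndarray
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.gene_ids)
        sc = np.asarray(self.scores, dtype=float)
        lb = np.asarray(self.labels)
        if not (ids.size == sc.size == lb.size):
            raise ValueError("gene_ids, scores and labels must be aligned")
        bad = set(np.unique(lb)) - {ESSENTIAL, NONESSENTIAL}
        if bad:
            raise ValueError(f"unknown labels {bad}")
        object.__setattr__(self, "gene_ids", ids)
        object.__setattr__(self, "scores", sc)
        object.__setattr__(self, "labels", lb)

    @property
    def y_true(self) -> np.ndarray:
        return (self.labels == ESSENTIAL).astype(int)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (essential/nonessential) x (predicted intolerant/tolerant)."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency counts must be nonnegative")


@dataclass(frozen=True)
class EnrichmentResult:
    log_or: float
    se: float
    ci_low: float
    ci_high: float


def match_genes(essential: pd.Series, pool: pd.Series) -> list[tuple[str, str]]:
    """1:1 nearest-neighbor matching on expected LOF count, without replacement.

    ``essential`` and ``pool`` map gene id -> expected count n.  Matching is
    greedy in descending order of the essential gene's n (ties broken by gene
    id), each essential gene taking the as-yet-unmatched pool gene with the
    smallest |delta n| (ties broken by pool order).  Deterministic; this is a
    plain nearest-neighbor stand-in for propensity-matching tools and can
    diverge from optimal matching when the pool is tight.
    """
    if len(pool) < len(essential):
        raise ValueError("pool must be at least as large as the essential set")
    pool_ids = np.asarray(pool.index)
    pool_n = pool.to_numpy(dtype=float)
    available = np.ones(pool_ids.size, dtype=bool)
    order = sorted(essential.items(), key=lambda kv: (-kv[1], kv[0]))
    pairs: list[tuple[str, str]] = []
    for gene, n in order:
        idx = np.flatnonzero(available)
        if idx.size == 0:
            raise ValueError("matching pool exhausted")
        j = idx[np.argmin(np.abs(pool_n[idx] - n))]
        available[j] = False
        pairs.append((gene, str(pool_ids[j])))
    return pairs


def roc_auc(data: LabeledScores) -> float:
    """Probability that a random essential gene outscores a random
    nonessential one, ties counting one half."""
    y = data.y_true
    if y.min() == y.max():
        raise ValueError("ROC needs both essential and nonessential genes")
    return float(roc_auc_score(y, data.scores))


def _delong_placements(y: np.ndarray, scores: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # midrank formulation
    v10 = np.empty(pos.size)
    v01 = np.empty(neg.size)
    for i, s in enumerate(pos):
        v10[i] = ((s > neg).sum() + 0.5 * (s == neg).sum()) / neg.size
    for j, s in enumerate(neg):
        v01[j] = ((pos > s).sum() + 0.5 * (pos == s).sum()) / pos.size
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """DeLong test for the difference of two correlated AUCs.

    ``scores_a`` and ``scores_b`` are paired scores on the same genes.
    Returns ``(auc_a, auc_b, two_sided_p)``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (scores_a.size == scores_b.size == labels.size):
        raise ValueError("paired scores and labels must have equal length")
    y = (labels == ESSENTIAL).astype(int) if labels.dtype.kind in "UO" else labels.astype(int)
    if y.min() == y.max():
        raise ValueError("DeLong test needs both classes")
    m = int(y.sum())
    n = int(y.size - m)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((scores_a, scores_b)):
        v10[k], v01[k] = _delong_placements(y, s)
        aucs[k] = v10[k].mean()
    s10 = np.cov(v10)  # 2x2 covariance of placement values among positives
    s01 = np.cov(v01)
    var = (s10 / m + s01 / n)  # covariance matrix of (auc_a, auc_b)
    c = np.array([1.0, -1.0])
    delta = aucs[0] - aucs[1]
    v = float(c @ var @ c)
    if v <= 0:
        p = 1.0 if delta == 0.0 else 0.0
    else:
        z = delta / np.sqrt(v)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), min(max(p, np.finfo(float).tiny), 1.0)


def tpr_at_fpr(
    data: LabeledScores, target_fpr: float, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Highest TPR among thresholds whose empirical FPR <= target, with a
    stratified-bootstrap standard error."""
    if not 0.0 < target_fpr < 1.0:
        raise ValueError("target FPR must lie strictly in (0, 1)")
    if n_boot < 1:
        raise ValueError("need at least one bootstrap resample")

    def _tpr(y: np.ndarray, s: np.ndarray) -> float:
        fpr, tpr, _ = roc_curve(y, s)
        ok = fpr <= target_fpr
        return float(tpr[ok].max()) if ok.any() else 0.0

    y = data.y_true
    point = _tpr(y, data.scores)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size), rng.choice(neg, size=neg.size)]
        )
        boots[b] = _tpr(y[idx], data.scores[idx])
    return point, float(boots.std(ddof=1))


def threshold_classify(scores: pd.Series, cutoff: float, direction: str) -> set[str]:
    """Genes called intolerant by an inclusive score cutoff.

    ``direction`` is ``"high_is_intolerant"`` (call score >= cutoff) or
    ``"low_is_intolerant"`` (call score <= cutoff, e.g. LOEUF-style scores).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if direction == "high_is_intolerant":
        mask = scores >= cutoff
    elif direction == "low_is_intolerant":
        mask = scores <= cutoff
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return {str(g) for g in scores.index[mask]}


def venn_partition(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Per-gene membership table across named gene sets.

    Adds ``n_sets`` and ``unique_to`` columns supporting "predicted by one
    method only" and "predicted by at least one method" queries.
    """
    if not sets:
        raise ValueError("need at least one gene set")
    union = sorted(set().union(*sets.values()))
    table = pd.DataFrame(
        {name: [g in members for g in union] for name, members in sets.items()},
        index=union,
    )
    counts = table.sum(axis=1)
    table["n_sets"] = counts
    only = table[list(sets)].idxmax(axis=1)
    table["unique_to"] = np.where(counts == 1, only, "")
    return table


def enrichment_log_or(table: ContingencyTable2x2) -> EnrichmentResult:
    """Log odds ratio log((n11/n12)/(n21/n22)) with Wald 95% interval.

    The standard error is sqrt(1/n11 + 1/n12 + 1/n21 + 1/n22); no continuity
    correction is applied, so every cell must be positive.
    """
    cells = (table.n11, table.n12, table.n21, table.n22)
    if min(cells) == 0:
        raise ValueError("log odds ratio undefined with a zero cell")
    log_or = float(np.log((table.n11 / table.n12) / (table.n21 / table.n22)))
    se = float(np.sqrt(sum(1.0 / c for c in cells)))
    return EnrichmentResult(
        log_or=log_or, se=se, ci_low=log_or - 1.96 * se, ci_high=log_or + 1.96 * se
    )


def _overlap_matrix(deletions: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Boolean (deletions x genes) half-open interval overlap, per chromosome."""
    d_chrom = deletions["chrom"].to_numpy()
    g_chrom = genes["chrom"].to_numpy()
    out = (d_chrom[:, None] == g_chrom[None, :])
    out &= deletions["start"].to_numpy()[:, None] < genes["end"].to_numpy()[None, :]
    out &= genes["start"].to_numpy()[None, :] < deletions["end"].to_numpy()[:, None]
    return out


def deletion_overlap_permutation(
    deletions: pd.DataFrame,
    target_genes: set[str],
    pool: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    pseudo_count: bool = False,
    exhaustive: bool = False,
):
    """Permutation test for depletion of a gene set in genomic deletions.

    ``deletions`` and ``pool`` are BED-style frames (chrom, start, end, name);
    ``target_genes`` must name genes present in ``pool``.  The statistic is
    the proportion of deletions overlapping at least one target gene
    (0-based half-open intersection on the same chromosome, strand ignored).
    Each permutation draws |target| genes from the pool uniformly without
    replacement; the one-tailed p-value is the fraction of permutations whose
    proportion is <= the observed one.  With ``pseudo_count`` the
    (b+1)/(B+1) estimator is used instead, avoiding exact zeros.  With
    ``exhaustive`` every subset of the pool is enumerated instead of sampling
    (only sensible for small pools); ``B`` and ``seed`` are then ignored.

    Returns ``(observed_prop, null_props, p_value)``.
    """
    if B < 1 and not exhaustive:
        raise ValueError("need at least one permutation")
    pool = pool.reset_index(drop=True)
    names = pool["name"].astype(str)
    target_idx = np.flatnonzero(names.isin(target_genes))
    if target_idx.size != len(target_genes):
        missing = set(target_genes) - set(names)
        raise ValueError(f"target genes absent from pool: {sorted(missing)[:5]}")
    if len(pool) < target_idx.size:
        raise ValueError("pool smaller than the target set")
    overlap = _overlap_matrix(deletions, pool)
    observed = float(overlap[:, target_idx].any(axis=1).mean())
    if exhaustive:
        from itertools import combinations

        null = np.array(
            [
                overlap[:, list(idx)].any(axis=1).mean()
                for idx in combinations(range(len(pool)), target_idx.size)
            ]
        )
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(B)
        for b in range(B):
            idx = rng.choice(len(pool), size=target_idx.size, replace=False)
            null[b] = overlap[:, idx].any(axis=1).mean()
    hits = int((null <= observed).sum())
    total = null.size
    p = (hits + 1) / (total + 1) if pseudo_count else hits / total
    return observed, null, float(p)


def prior_influence_summary(
    scores_with: pd.DataFrame,
    scores_without: pd.DataFrame,
    n_values: pd.Series,
    n_bins: int = 10,
):
    """Absolute score shift from the feature-informed prior, binned by n.

    ``scores_with`` and ``scores_without`` are score tables (gene_id,
    deeplof_score) from a feature model and a feature-free model fitted to the
    same genes; ``n_values`` maps gene_id -> expected LOF count.  Returns
    ``(per_gene, binned, rho)`` where ``binned`` holds the mean |delta score|
    per n-quantile bin and ``rho`` is the Spearman correlation between bin
    median n and bin mean |delta| (NaN when all deltas are identical).
    Because the prior dominates the posterior exactly when n is small, a
    feature-informed prior moves scores most for short genes, so rho is
    expected to be negative.
    """
    a = scores_with.set_index("gene_id")["deeplof_score"]
    b = scores_without.set_index("gene_id")["deeplof_score"]
    if not a.index.equals(b.index):
        if set(a.index) != set(b.index):
            raise ValueError("score tables cover different gene sets")
        b = b.reindex(a.index)
    n = n_values.reindex(a.index)
    if n.isna().any():
        raise ValueError("n_values missing for some scored genes")
    per_gene = pd.DataFrame(
        {"n": n, "abs_delta": (a - b).abs()}, index=a.index
    )
    bins = pd.qcut(per_gene["n"], q=n_bins, duplicates="drop")
    binned = per_gene.groupby(bins, observed=True).agg(
        median_n=("n", "median"), mean_abs_delta=("abs_delta", "mean")
    )
    if binned["mean_abs_delta"].nunique() <= 1:
        rho = float("nan")
    else:
        rho = float(
            stats.spearmanr(binned["median_n"], binned["mean_abs_delta"]).statistic
        )
    return per_gene, binned, rho
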