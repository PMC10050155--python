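"""Single-sample gene-set enrichment (ssGSEA).

Converts a genes-by-samples matrix into a sets-by-samples score matrix.
For each sample, genes are ranked by expression (average ranks for ties)
and, walking down the ranking, the enrichment score of a set is the
summed difference between the cumulative rank-weighted mass of in-set
genes and the cumulative uniform mass of out-of-set genes:

    ES = sum_i [ P_in(i) - P_out(i) ],
    P_in(i)  = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha,
    P_out(i) = #{j<=i, j not in S} / (N - |S|),

with genes ordered by decreasing rank r. Because the statistic is purely
rank-based, scores are invariant to any strictly increasing per-sample
transform of the expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from dualsub.types import ExpressionMatrix, GeneSetCollection

#: below this fraction of a set found in the matrix, scoring warns
COVERAGE_WARN = 0.8
#: below this fraction, scoring refuses
COVERAGE_ERROR = 0.3


@dataclass(frozen=True)
class ScoringParams:
    """ssGSEA parameters.

    alpha
        Rank-weight exponent (>= 0). 0.25 follows the GSVA ssgsea default.
    normalise
        Divide the whole score matrix by its global max - min.
    tie_method
        Tied expression values receive average ranks (fixed).
    min_coverage_warn, min_coverage_error
        Set-coverage thresholds applied after dropping set members absent
        from the matrix.
    """

    alpha: float = 0.25
    normalise: bool = True
    tie_method: str = "average"
    min_coverage_warn: float = COVERAGE_WARN
    min_coverage_error: float = COVERAGE_ERROR

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tie_method != "average":
            raise ValueError("only average-rank tie handling is supported")


def rank_within_sample(column: np.ndarray) -> np.ndarray:
    """Rank one sample's expression values, 1..N with N = highest.

    Ties receive average ranks. An all-constant vector is rejected: it
    carries no ordering information and would make every set score equal.
    """
    x = np.asarray(column, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("rank_within_sample: non-finite values")
    if x.size < 2 or np.all(x == x[0]):
        raise ValueError("rank_within_sample: constant vector has no ranking")
    return scipy.stats.rankdata(x, method="average")


def _filter_sets(
    sets: GeneSetCollection, features: list[str], params: ScoringParams
) -> dict[str, list[str]]:
    """Intersect each set with the matrix features, enforcing coverage."""
    feature_set = set(features)
    out: dict[str, list[str]] = {}
    for name in sets.set_names:
        members = sets.sets[name]
        present = [m for m in members if m in feature_set]
        coverage = len(present) / len(members)
        if not present:
            raise ValueError(
                f"gene set {name!r} has zero overlap with the matrix features"
            )
        if coverage < params.min_coverage_error:
            raise ValueError(
                f"gene set {name!r} coverage {coverage:.0%} is below the "
                f"minimum {params.min_coverage_error:.0%}"
            )
        if coverage < params.min_coverage_warn:
            warnings.warn(
                f"gene set {name!r}: only {len(present)}/{len(members)} members "
                f"({coverage:.0%}) present in the matrix",
                UserWarning,
                stacklevel=3,
            )
        if len(present) == len(features):
            raise ValueError(
                f"gene set {name!r} covers every matrix feature; the "
                "out-of-set mass is undefined"
            )
        out[name] = present
    return out


def ssgsea_score(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    params: ScoringParams | None = None,
) -> ExpressionMatrix:
    """Score every gene set in every sample; returns sets x samples."""
    params = params or ScoringParams()
    filtered = _filter_sets(sets, matrix.feature_ids, params)
    values = matrix.values
    n_genes, n_samples = values.shape
    feature_index = {f: i for i, f in enumerate(matrix.feature_ids)}
    set_names = list(filtered)
    masks = np.zeros((len(set_names), n_genes), dtype=bool)
    for si, name in enumerate(set_names):
        masks[si, [feature_index[g] for g in filtered[name]]] = True

    scores = np.empty((len(set_names), n_samples), dtype=float)
    for j in range(n_samples):
        ranks = rank_within_sample(values[:, j])
        order = np.argsort(-ranks, kind="stable")
        r_ord = ranks[order]
        weights = np.abs(r_ord) ** params.alpha
        for si in range(len(set_names)):
            in_ord = masks[si][order]
            w_in = np.where(in_ord, weights, 0.0)
            p_in = np.cumsum(w_in)
            p_in /= p_in[-1]
            p_out = np.cumsum(~in_ord) / (n_genes - in_ord.sum())
            scores[si, j] = float(np.sum(p_in - p_out))

    if params.normalise:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span
    return ExpressionMatrix(
        pd.DataFrame(scores, index=set_names, columns=matrix.sample_ids)
    )


def mean_scores_by_class(
    scores: ExpressionMatrix, labels: pd.Series | dict
) -> pd.DataFrame:
    """Average each set's scores across samples within each class.

    ``labels`` maps sample id -> class. Every sample in ``scores`` must be
    labelled; classes appear in label order of first occurrence.
    """
    if isinstance(labels, dict):
        labels = pd.Series(labels)
    labels = labels.astype(str)
    missing = [s for s in scores.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"unlabelled sample(s): {missing[:10]}")
    lab = labels.loc[scores.sample_ids]
    classes = list(dict.fromkeys(lab))
    out = pd.DataFrame(index=scores.feature_ids, columns=classes, dtype=float)
    for cls in classes:
        cols = lab.index[lab == cls]
        out[cls] = scores.data[list(cols)].mean(axis=1)
    return out
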