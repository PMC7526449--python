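"""Per-sample regulator activity scores from target-gene expression.

The statistic is a single-sample running-sum enrichment. For one sample,
genes are sorted by expression in decreasing order; two cumulative
distribution functions accumulate the absolute expression weight of target
genes (foreground) and non-target genes (background). The signed value of
foreground minus background at the position of the largest absolute gap is
the preliminary activity score: positive when targets concentrate among the
most highly expressed genes, negative when they concentrate at the bottom.

The preliminary score is then normalized by the mean absolute score of the
same statistic under random re-assignments of the target labels across
genes (default 1000 permutations), giving a sample-specific activity score
comparable across regulators with different target-set sizes.

By convention TF activity tracks target expression positively while miRNA
activity is reported with the opposite sign (miRNAs repress their targets),
so a miRNA whose targets are lowly expressed receives a positive activity.
Repressor TFs and activating miRNAs violate the convention and need
per-regulator interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    SINGLE_CHANNEL,
    ActivityMatrix,
    ExpressionMatrix,
    RegulatorSet,
)

DEFAULT_N_PERM = 1000


class ScoringError(ValueError):
    """Degenerate input to the activity statistic."""


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common distribution of rank-wise means.

    Ties within a column receive the average of the reference values at the
    tied ranks.
    """
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ScoringError("quantile normalization needs >=2 samples")
    reference = np.sort(arr, axis=0).mean(axis=1)
    # rank with average ties, then read the reference at (possibly fractional)
    # rank positions by linear interpolation between adjacent order statistics
    ranks = values.rank(axis=0, method="average").to_numpy() - 1.0
    lo = np.floor(ranks).astype(int)
    hi = np.ceil(ranks).astype(int)
    frac = ranks - lo
    out = reference[lo] * (1.0 - frac) + reference[hi] * frac
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_expression(em: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples; median-center genes for intensity data.

    Two-channel log-ratio data is already relative to a common reference, so
    only the quantile step applies. Single-channel intensities are
    additionally centered by each gene's across-sample median so that scores
    reflect relative expression.
    """
    if em.values.shape[1] < 2:
        raise ScoringError("normalization needs >=2 samples")
    normalized = quantile_normalize(em.values)
    if em.dialect == SINGLE_CHANNEL:
        normalized = normalized.sub(normalized.median(axis=1), axis=0)
    return ExpressionMatrix(values=normalized, dialect=em.dialect)


def _sorted_profile(
    expr: np.ndarray, genes: np.ndarray, weighted: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Sort order for one sample: expression decreasing, ties by gene symbol.

    With ``weighted=False`` every gene gets unit weight (a KS-style running
    sum over ranks instead of expression magnitudes).
    """
    order = np.lexsort((genes, -expr))
    weights = np.abs(expr[order]) if weighted else np.ones(expr.size)
    return order, weights


def _max_gap(weights: np.ndarray, is_target: np.ndarray) -> float:
    """Signed foreground-background gap at the position of maximal |gap|."""
    wt = weights * is_target
    # totals taken from the cumulative sums so the CDFs end exactly at 1
    cwt = np.cumsum(wt)
    cw = np.cumsum(weights)
    st = cwt[-1]
    sb = cw[-1] - st
    if st == 0.0:
        raise ScoringError("total target weight is zero")
    if sb == 0.0:
        raise ScoringError("total non-target weight is zero")
    diff = cwt / st - (cw - cwt) / sb
    j = int(np.argmax(np.abs(diff)))  # argmax returns the earliest maximizer
    return float(diff[j])


def base_preliminary_score(
    expr: np.ndarray,
    is_target: np.ndarray,
    gene_names: np.ndarray | None = None,
    weighted: bool = True,
) -> float:
    """Preliminary activity score in [-1, 1] for one sample.

    Parameters
    ----------
    expr
        Expression values for all genes (normalized scale).
    is_target
        Boolean indicator of the regulator's targets, aligned with ``expr``.
    gene_names
        Symbols used to break expression ties deterministically; defaults to
        positional order.
    weighted
        Weight the running sums by |expression| (default); ``False`` gives
        the unweighted KS-style rank statistic.
    """
    expr = np.asarray(expr, dtype=float)
    is_target = np.asarray(is_target, dtype=bool)
    if expr.shape != is_target.shape:
        raise ScoringError("expression and target vectors differ in length")
    if is_target.all() or not is_target.any():
        raise ScoringError("need at least one target and one non-target gene")
    if gene_names is None:
        gene_names = np.arange(expr.size)
    order, weights = _sorted_profile(expr, np.asarray(gene_names), weighted)
    return _max_gap(weights, is_target[order])


def _permuted_gaps(
    weights: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max-gap scores for ``n_perm`` uniform random k-subsets of positions.

    ``weights`` is the |expression| profile already in sorted order; because
    a uniform random subset of genes is exchangeable, permuting the target
    indicator is equivalent to drawing random positions in the sorted order.
    """
    n = weights.size
    # k smallest of iid uniforms = uniform random k-subset
    pos = np.argpartition(rng.random((n_perm, n)), k - 1, axis=1)[:, :k]
    targ = np.zeros((n_perm, n), dtype=bool)
    targ[np.arange(n_perm)[:, None], pos] = True
    wt = weights * targ
    cwt = np.cumsum(wt, axis=1)
    cw = np.cumsum(weights)
    st = cwt[:, -1:]
    sb = cw[-1] - st
    if np.any(st == 0.0) or np.any(sb == 0.0):
        raise ScoringError("degenerate expression profile under permutation")
    diff = cwt / st - (cw[None, :] - cwt) / sb
    j = np.argmax(np.abs(diff), axis=1)
    return diff[np.arange(n_perm), j]


def permutation_scores(
    expr: np.ndarray,
    n_targets: int,
    n_perm: int,
    rng: np.random.Generator,
    gene_names: np.ndarray | None = None,
    weighted: bool = True,
) -> np.ndarray:
    """Null score vector for one sample: the statistic under random targets."""
    expr = np.asarray(expr, dtype=float)
    if gene_names is None:
        gene_names = np.arange(expr.size)
    _, weights = _sorted_profile(expr, np.asarray(gene_names), weighted)
    return _permuted_gaps(weights, n_targets, n_perm, rng)


@dataclass
class _PreparedSample:
    order: np.ndarray
    weights: np.ndarray


def base_activity(
    em: ExpressionMatrix,
    sets: list[RegulatorSet],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    weighted: bool = True,
) -> ActivityMatrix:
    """Normalized activity scores for every regulator in every sample.

    Each (regulator, sample) cell is the preliminary score divided by the
    mean absolute permuted score from its own RNG substream (keyed by the
    regulator's sorted-name rank and the sample position, so results do not
    depend on evaluation order). miRNA scores are negated after
    normalization. Regulators whose targets do not intersect the matrix are
    skipped with a warning.
    """
    if n_perm < 1:
        raise ScoringError("n_perm must be >= 1")
    genes = em.genes.to_numpy(dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes)}
    expr = em.values.to_numpy(dtype=float)
    n_genes, n_samples = expr.shape

    prepared: list[_PreparedSample] = []
    for s in range(n_samples):
        order, weights = _sorted_profile(expr[:, s], genes, weighted)
        prepared.append(_PreparedSample(order=order, weights=weights))

    name_rank = {
        name: r for r, name in enumerate(sorted({s.name for s in sets}))
    }
    rows: dict[str, np.ndarray] = {}
    for reg in sets:
        idx = [gene_pos[t] for t in reg.targets if t in gene_pos]
        if not idx:
            warnings.warn(
                f"regulator {reg.name!r}: no targets in expression matrix; "
                "skipped",
                stacklevel=2,
            )
            continue
        if len(idx) >= n_genes:
            raise ScoringError(f"regulator {reg.name!r} targets every gene")
        indicator = np.zeros(n_genes, dtype=bool)
        indicator[idx] = True
        k = len(idx)
        scores = np.empty(n_samples)
        for s in range(n_samples):
            prep = prepared[s]
            prelim = _max_gap(prep.weights, indicator[prep.order])
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=seed, spawn_key=(name_rank[reg.name], s)
                )
            )
            null = _permuted_gaps(prep.weights, k, n_perm, rng)
            norm = float(np.mean(np.abs(null)))
            if norm == 0.0:
                raise ScoringError(
                    f"degenerate profile: zero permutation norm for "
                    f"{reg.name!r} in sample {em.samples[s]!r}"
                )
            scores[s] = prelim / norm
        if reg.regulator_class == "miRNA":
            scores = -scores
        rows[reg.name] = scores

    if not rows:
        raise ScoringError("no regulator overlaps the expression matrix")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=em.samples)
    df.index.name = "regulator"
    return ActivityMatrix(
        scores=df, n_permutations=n_perm, seed=seed, dialect=em.dialect
    )
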