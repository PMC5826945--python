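"""Developmental expression-pattern analysis.

Each gene's trajectory is min-max standardized to [0, 1] across all of its
samples, x -> (x - min) / (max - min), then its mean over the early window
(age <= early_stage_max) is compared with its mean over the late window
(age >= late_stage_min); samples between the windows are ignored.  The
gene-set statistic is the number of candidate genes whose early mean
strictly exceeds the late mean, and its significance comes from redrawing
size-matched gene sets from a background universe.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .network import _permutation_pvalue
from .types import ExpressionMatrix, PermutationTestResult

logger = logging.getLogger(__name__)


def minmax_normalize(values) -> np.ndarray:
    """Min-max standardization onto [0, 1].

    A constant vector maps to all zeros (with a warning) rather than raising,
    so flat housekeeping genes do not abort batch runs.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("minmax_normalize needs a 1-d vector of length >= 2")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("constant expression vector; normalized to all zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _early_late_flags(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    early_stage_max: float,
    late_stage_min: float,
) -> dict[str, bool]:
    """Per-gene flag: does the normalized early-window mean strictly exceed
    the late-window mean?  Genes absent from the matrix are dropped with a
    log line."""
    if early_stage_max >= late_stage_min:
        raise ParameterError("early_stage_max must be < late_stage_min")
    ages = expr.meta["age_days"].to_numpy(dtype=float)
    early = ages <= early_stage_max
    late = ages >= late_stage_min
    if not early.any() or not late.any():
        raise ValidationError("empty early or late developmental window")
    present = [g for g in dict.fromkeys(genes) if g in expr.genes]
    missing = [g for g in dict.fromkeys(genes) if g not in expr.genes]
    if missing:
        logger.warning(
            "%d gene(s) absent from expression matrix; dropped: %s",
            len(missing), missing[:5],
        )
    flags: dict[str, bool] = {}
    mat = expr.values.loc[present].to_numpy(dtype=float)
    for g, row in zip(present, mat):
        lo, hi = row.min(), row.max()
        if hi == lo:
            flags[g] = False  # flat gene: strict inequality can never hold
            continue
        norm = (row - lo) / (hi - lo)
        flags[g] = bool(norm[early].mean() > norm[late].mean())
    return flags


def early_late_statistic(
    expr: ExpressionMatrix,
    candidates: Sequence[str],
    early_stage_max: float,
    late_stage_min: float,
) -> int:
    """Number of candidate genes expressed higher early than late.

    Ties (including flat genes) count as not exceeding.
    """
    flags = _early_late_flags(expr, candidates, early_stage_max, late_stage_min)
    return int(sum(flags.values()))


def pattern_permutation_test(
    expr: ExpressionMatrix,
    candidates: Sequence[str],
    background: Sequence[str],
    n_permutations: int,
    seed,
    early_stage_max: float,
    late_stage_min: float,
) -> PermutationTestResult:
    """Is the early-high gene count of the candidate set larger than chance?

    Permuted sets draw as many genes as the candidate set has measurable
    members from the background universe (candidate genes may be redrawn;
    the background is the comparison population, not an exclusion list).
    """
    flags = _early_late_flags(
        expr, list(dict.fromkeys(list(background) + list(candidates))),
        early_stage_max, late_stage_min,
    )
    measurable = [g for g in dict.fromkeys(candidates) if g in flags]
    observed = sum(flags[g] for g in measurable)
    pool = sorted(g for g in dict.fromkeys(background) if g in flags)
    scores = {g: float(flags[g]) for g in pool}
    return _permutation_pvalue(
        observed, scores, pool, len(measurable), n_permutations, seed
    )


def normalized_trajectories(expr: ExpressionMatrix, genes: Sequence[str]):
    """Min-max normalized expression for plotting, genes x samples."""
    present = [g for g in dict.fromkeys(genes) if g in expr.genes]
    out = expr.values.loc[present].copy()
    for g in present:
        out.loc[g] = minmax_normalize(out.loc[g].to_numpy())
    return out
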