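"""Case-control differential expression: per-gene, per-region two-sample t-tests."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats as _stats

from .errors import ValidationError
from .types import DeResult, ExpressionMatrix

logger = logging.getLogger(__name__)


def de_test(case_values, control_values, equal_var: bool = True) -> DeResult:
    """Two-sample t-test of expression between cases and controls.

    Classical pooled-variance Student t by default (``equal_var=False``
    switches to Welch).  Requires >= 2 values per group and non-degenerate
    variance.  Returns a DeResult with empty gene/region labels; callers
    fill those in.
    """
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValidationError("each group needs >= 2 values")
    if np.var(case, ddof=1) == 0 and np.var(ctrl, ddof=1) == 0:
        raise ValidationError("zero variance in both groups; t undefined")
    t, p = _stats.ttest_ind(case, ctrl, equal_var=equal_var)
    mean_case, mean_control = float(case.mean()), float(ctrl.mean())
    return DeResult(
        gene_id="",
        region="",
        mean_case=mean_case,
        mean_control=mean_control,
        t_statistic=float(t),
        p_two_sided=float(p),
        direction="up" if mean_case > mean_control else "down",
        n_case=int(case.size),
        n_control=int(ctrl.size),
    )


def de_scan(
    expr: ExpressionMatrix,
    candidates: Sequence[str],
    regions: Sequence[str] | None = None,
    equal_var: bool = True,
) -> list[DeResult]:
    """Test every candidate gene in every region with enough cases/controls.

    ``regions=None`` scans all regions having >= 2 case and >= 2 control
    samples.  Genes or regions failing the preconditions are skipped with a
    log line; a panel with no case or no control samples at all is an error.
    """
    diag = expr.meta["diagnosis"].astype(str)
    if not (diag == "case").any() or not (diag == "control").any():
        raise ValidationError("expression panel has no case or no control samples")
    if regions is None:
        regions = sorted(
            r for r in expr.meta["region"].unique()
            if ((diag == "case") & (expr.meta["region"] == r)).sum() >= 2
            and ((diag == "control") & (expr.meta["region"] == r)).sum() >= 2
        )
    results: list[DeResult] = []
    for gene in dict.fromkeys(candidates):
        if gene not in expr.genes:
            logger.warning("gene %s absent from expression matrix; skipped", gene)
            continue
        row = expr.values.loc[gene]
        for region in regions:
            in_region = expr.meta["region"] == region
            case = row[in_region & (diag == "case")].to_numpy(dtype=float)
            ctrl = row[in_region & (diag == "control")].to_numpy(dtype=float)
            if case.size < 2 or ctrl.size < 2:
                logger.info(
                    "gene %s region %s: too few case/control samples; skipped",
                    gene, region,
                )
                continue
            try:
                res = de_test(case, ctrl, equal_var=equal_var)
            except ValidationError as exc:
                logger.warning("gene %s region %s skipped: %s", gene, region, exc)
                continue
            res.gene_id = gene
            res.region = region
            results.append(res)
    return results
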