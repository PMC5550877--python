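"""Two-group differential expression and fold-change filtering.

The DE rule combines a fold-change filter (two-fold by default, inclusive)
with a per-gene Welch two-sample t-test on ``log2(value + pseudocount)``;
significance status uses the raw P value, with Benjamini-Hochberg adjusted
values reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .enrich import bh_fdr
from .errors import InputError, StatisticsError
from .expression import ExpressionMatrix

__all__ = ["DEResult", "FoldFilterResult", "compute_de", "filter_by_fold", "de_frame"]

UP = "up"
DOWN = "down"
NOT_SIGNIFICANT = "not_significant"


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    p_value: float
    q_value: float
    status: str


@dataclass(frozen=True)
class FoldFilterResult:
    selected_ids: tuple[str, ...]
    threshold: float
    strict: bool


def compute_de(
    matrix: ExpressionMatrix,
    control_label: str,
    perturbed_label: str,
    pseudocount: float | None = None,
    alpha: float = 0.05,
    fold: float = 2.0,
) -> list[DEResult]:
    """Per-gene fold change and Welch t-test between two conditions.

    Parameters
    ----------
    pseudocount
        Added to linear values before ratios and logs.  Defaults to
        ``1e-6 * global mean`` of the matrix (scale-aware zero protection).
    alpha
        Raw P-value threshold entering the status call.
    fold
        Linear fold-change threshold; status requires ``|log2fc| >= log2(fold)``
        (inclusive).

    Returns
    -------
    list of :class:`DEResult`, one per gene in matrix order.
    """
    if not 0.0 < alpha <= 1.0:
        raise InputError(f"alpha must be in (0, 1], got {alpha}")
    if fold <= 0:
        raise InputError(f"fold must be positive, got {fold}")
    ctrl = matrix.samples_for(control_label)
    pert = matrix.samples_for(perturbed_label)
    if len(ctrl) < 2 or len(pert) < 2:
        raise StatisticsError(
            f"need >=2 samples per group, got {len(ctrl)} control / {len(pert)} perturbed"
        )
    if pseudocount is None:
        global_mean = float(matrix.values.to_numpy().mean())
        pseudocount = 1e-6 * global_mean if global_mean > 0 else 1e-6
    elif pseudocount < 0:
        raise InputError(f"pseudocount must be nonnegative, got {pseudocount}")

    xc = matrix.values[ctrl].to_numpy(dtype=float)
    xp = matrix.values[pert].to_numpy(dtype=float)
    mean_c = xc.mean(axis=1)
    mean_p = xp.mean(axis=1)
    if pseudocount == 0 and (np.any(mean_c == 0) or np.any(mean_p == 0)):
        raise InputError("zero group mean with pseudocount 0; use a positive pseudocount")
    log2fc = np.log2(mean_p + pseudocount) - np.log2(mean_c + pseudocount)

    lc = np.log2(xc + pseudocount)
    lp = np.log2(xp + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        _, p = stats.ttest_ind(lp, lc, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: p undefined under the t model; report 1
    # for identical means (no evidence) and 0 for a deterministic difference.
    bad = np.isnan(p)
    if bad.any():
        diff = lp.mean(axis=1) - lc.mean(axis=1)
        p[bad & np.isclose(diff, 0.0)] = 1.0
        p[bad & ~np.isclose(diff, 0.0)] = 0.0
    q = bh_fdr(p)

    log2_thresh = np.log2(fold)
    results = []
    for gid, lfc, pv, qv in zip(matrix.gene_ids, log2fc, p, q):
        if pv < alpha and lfc >= log2_thresh:
            status = UP
        elif pv < alpha and lfc <= -log2_thresh:
            status = DOWN
        else:
            status = NOT_SIGNIFICANT
        results.append(
            DEResult(
                gene_id=gid,
                log2fc=float(lfc),
                p_value=float(pv),
                q_value=float(qv),
                status=status,
            )
        )
    return results


def de_frame(results: Sequence[DEResult]):
    """Tabulate DE results (gene_id, log2fc, p_value, q_value, status)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "status": [r.status for r in results],
        }
    )


def significant_genes(results: Sequence[DEResult]) -> set[str]:
    """Genes whose status is up or down."""
    return {r.gene_id for r in results if r.status != NOT_SIGNIFICANT}


def filter_by_fold(
    fold_changes: Mapping[str, float], threshold: float, strict: bool = True
) -> FoldFilterResult:
    """Select ids whose fold change exceeds (or reaches) a threshold.

    Order is preserved from the input mapping.  ``strict=True`` means
    ``fold > threshold``; otherwise ``fold >= threshold``.
    """
    if threshold <= 0:
        raise InputError(f"threshold must be positive, got {threshold}")
    bad = {k: v for k, v in fold_changes.items() if not v > 0}
    if bad:
        raise InputError(f"nonpositive fold changes: {bad}")
    if strict:
        selected = tuple(k for k, v in fold_changes.items() if v > threshold)
    else:
        selected = tuple(k for k, v in fold_changes.items() if v >= threshold)
    return FoldFilterResult(selected_ids=selected, threshold=threshold, strict=strict)
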