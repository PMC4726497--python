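"""Perturbation expression analysis: CNOT7-anticorrelated transcript calling.

A transcript is *anticorrelated* with Cnot7 when it goes up on Cnot7
knockdown and down on CNOT7 overexpression — the behaviour expected of a
direct deadenylation target. Both contrasts are tested per gene with a
Welch t-test oriented as (perturbation − control), so inverse-to-Cnot7
means t_kd > 0 and t_oe < 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("control", "knockdown", "overexpression")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 abundance matrix (genes x samples) with a group label per sample."""

    values: pd.DataFrame
    groups: pd.Series  # sample -> {control, knockdown, overexpression}

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)!r}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]


def welch_t(a, b) -> tuple[float, float]:
    """Welch unequal-variance t with Satterthwaite df; sign = mean(a) − mean(b).

    Degenerate input (zero variance in both groups, equal means) is
    defined as t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        # zero noise but distinct means: infinitely strong evidence
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _welch_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t over gene x sample blocks, with the degenerate rule."""
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    flat = (a.var(axis=1, ddof=1) == 0.0) & (b.var(axis=1, ddof=1) == 0.0)
    equal = flat & (a.mean(axis=1) == b.mean(axis=1))
    t[equal] = 0.0
    p[equal] = 1.0
    shifted = flat & ~equal
    t[shifted] = np.copysign(np.inf, a.mean(axis=1) - b.mean(axis=1))[shifted]
    p[shifted] = 0.0
    return t, p


def call_anticorrelated(
    matrix: ExpressionMatrix,
    alpha: float = 0.01,
    dysreg_rule: str = "combined",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene differential results for the Cnot7 perturbation design.

    Columns: t_kd, p_kd (knockdown vs control), t_oe, p_oe
    (overexpression vs control), t_comb, p_comb (knockdown vs
    overexpression — the full dynamic range of the perturbation pair),
    dysregulated, anticorrelated.

    ``dysreg_rule`` picks the dysregulation call: ``'combined'``
    (default) uses the single knockdown-vs-overexpression test, which
    spans twice the planted effect and so has far more power at small n
    than either contrast against control; ``'both'`` requires p < alpha
    in both per-contrast tests; ``'any'`` in at least one. ``fdr=True``
    applies Benjamini-Hochberg to the thresholded p-values first.
    Anticorrelated additionally requires t_kd > 0 and t_oe < 0 (up on
    knockdown, down on overexpression — inverse to Cnot7).
    """
    if dysreg_rule not in ("combined", "both", "any"):
        raise ValueError(
            f"dysreg_rule must be 'combined', 'both' or 'any', got {dysreg_rule!r}"
        )
    cols = {g: matrix.samples_in(g) for g in GROUPS}
    for g, samples in cols.items():
        if len(samples) < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples, has {len(samples)}")
    ctrl = matrix.values[cols["control"]].to_numpy(float)
    kd = matrix.values[cols["knockdown"]].to_numpy(float)
    oe = matrix.values[cols["overexpression"]].to_numpy(float)

    t_kd, p_kd = _welch_matrix(kd, ctrl)
    t_oe, p_oe = _welch_matrix(oe, ctrl)
    t_comb, p_comb = _welch_matrix(kd, oe)

    if fdr:
        q_kd, q_oe = _benjamini_hochberg(p_kd), _benjamini_hochberg(p_oe)
        q_comb = _benjamini_hochberg(p_comb)
    else:
        q_kd, q_oe, q_comb = p_kd, p_oe, p_comb
    if dysreg_rule == "combined":
        dysregulated = q_comb < alpha
    elif dysreg_rule == "both":
        dysregulated = (q_kd < alpha) & (q_oe < alpha)
    else:
        dysregulated = (q_kd < alpha) | (q_oe < alpha)
    anticorrelated = dysregulated & (t_kd > 0) & (t_oe < 0)

    return pd.DataFrame(
        {
            "t_kd": t_kd,
            "p_kd": p_kd,
            "t_oe": t_oe,
            "p_oe": p_oe,
            "t_comb": t_comb,
            "p_comb": p_comb,
            "dysregulated": dysregulated,
            "anticorrelated": anticorrelated,
        },
        index=matrix.values.index,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def anticorrelated_genes(results: pd.DataFrame) -> set[str]:
    return set(results.index[results["anticorrelated"]])


def recover_truth(results: pd.DataFrame, truth: set[str]) -> dict[str, float]:
    """Confusion-matrix fractions of the anticorrelated flag vs planted truth.

    Sensitivity is NaN when the truth set is empty; observed FDR is NaN
    when nothing was called.
    """
    called = anticorrelated_genes(results)
    universe = set(results.index)
    truth = truth & universe
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    tn = len(universe) - tp - fp - fn
    return {
        "sensitivity": tp / (tp + fn) if truth else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "fdr": fp / (tp + fp) if called else float("nan"),
    }
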