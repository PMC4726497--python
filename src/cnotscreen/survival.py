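"""Weighted gene signature construction and survival stratification.

The candidate target genes are turned into a prognostic signature
weighted by each gene's inverse Pearson correlation with the driver
(CNOT7) across the perturbation samples: weight_g = −r_g, so genes
anticorrelated with the driver get positive weights and a high score
means high expression of the CNOT7-anticorrelated program. Patients are
scored by a normalized weighted sum of per-gene z-scores, split at the
median score, and compared by the Mantel-Cox (log-rank) test on distant
metastasis-free survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """Weighted gene list: entries map gene symbol -> real weight."""

    entries: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("signature must be non-empty")
        w = np.asarray(list(self.entries.values()), dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("signature weights must be finite")
        if np.all(w == 0):
            raise ValueError("signature weights must not all be zero")

    @property
    def genes(self) -> list[str]:
        return list(self.entries)


@dataclass(frozen=True)
class SurvivalCohort:
    """Patient follow-up (time, event) plus a patient x gene expression matrix.

    event = 1 marks an observed distant-metastasis event, 0 censoring.
    """

    clinical: pd.DataFrame  # index patient id; columns time, event
    expression: pd.DataFrame  # patients x genes

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.clinical.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if (self.clinical["time"] < 0).any():
            raise ValueError("follow-up times must be non-negative")
        if not self.clinical["event"].isin((0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        if not self.clinical.index.equals(self.expression.index):
            raise ValueError("clinical and expression patient ids differ")


def build_signature(
    genes: set[str], matrix: ExpressionMatrix, driver: str
) -> GeneSignature:
    """Signature weighted by inverse correlation with the driver gene.

    weight_g = −corr(gene g, driver) over all samples. Zero-variance
    genes (or a zero-variance driver) have undefined correlation and are
    excluded with a warning.
    """
    values = matrix.values
    if driver not in values.index:
        raise KeyError(f"driver {driver!r} not in expression matrix")
    missing = genes - set(values.index)
    if missing:
        raise KeyError(f"signature genes absent from matrix: {sorted(missing)[:5]!r}")
    d = values.loc[driver].to_numpy(float)
    if d.std() == 0:
        raise ValueError(f"driver {driver!r} has zero variance")
    entries: dict[str, float] = {}
    skipped = []
    for g in sorted(genes):
        x = values.loc[g].to_numpy(float)
        if x.std() == 0:
            skipped.append(g)
            continue
        entries[g] = float(-np.corrcoef(x, d)[0, 1])
    if skipped:
        log.warning("excluded %d zero-variance genes from signature: %s",
                    len(skipped), skipped[:5])
    return GeneSignature(entries, provenance=f"-pearson_r vs {driver}")


def map_orthologs(
    signature: GeneSignature, ortholog_map: dict[str, str]
) -> tuple[GeneSignature | None, float]:
    """Rename signature genes through a mouse -> human ortholog map.

    Unmapped genes are dropped and counted (coverage = mapped/total),
    never silently. If two mouse genes map to one human symbol the
    larger-|weight| entry wins and the collision is logged.
    """
    mapped: dict[str, float] = {}
    n_unmapped = 0
    for gene, weight in signature.entries.items():
        human = ortholog_map.get(gene)
        if human is None:
            n_unmapped += 1
            continue
        if human in mapped:
            log.warning("ortholog collision on %s; keeping larger-|weight| entry", human)
            if abs(weight) <= abs(mapped[human]):
                continue
        mapped[human] = weight
    coverage = len(signature.entries) - n_unmapped
    frac = coverage / len(signature.entries)
    if not mapped:
        return None, 0.0
    return GeneSignature(mapped, provenance=signature.provenance + " (ortholog-mapped)"), frac


def score_patients(signature: GeneSignature, cohort: SurvivalCohort) -> pd.Series:
    """Per-patient signature score.

    Each available gene is z-standardized across patients; the score is
    sum_g w_g * z_gp / sum_g |w_g| over the genes present in the cohort.
    Missing genes are excluded with renormalization (logged), never
    imputed.
    """
    expr = cohort.expression
    present = [g for g in signature.genes if g in expr.columns]
    if not present:
        raise ValueError("no signature genes present in cohort expression")
    n_missing = len(signature.genes) - len(present)
    if n_missing:
        log.info("scoring with %d/%d signature genes (%d missing in cohort)",
                 len(present), len(signature.genes), n_missing)
    sub = expr[present].to_numpy(float)
    sd = sub.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all available signature genes have zero variance in cohort")
    z = (sub[:, keep] - sub[:, keep].mean(axis=0)) / sd[keep]
    w = np.asarray([signature.entries[g] for g in present])[keep]
    scores = z @ w / np.abs(w).sum()
    return pd.Series(scores, index=expr.index, name="score")


@dataclass(frozen=True)
class StratificationResult:
    scores: pd.Series
    labels: pd.Series  # 'high' / 'low'
    chi_square: float
    p_value: float
    group_stats: pd.DataFrame = field(repr=False)


def _km_median(time: np.ndarray, event: np.ndarray) -> float:
    """Kaplan-Meier median survival time (NaN if the curve stays above 0.5)."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(time, event)
    return float(km.median_survival_time_)


def stratify_logrank(
    scores: pd.Series, cohort: SurvivalCohort, split: str = "median"
) -> StratificationResult:
    """Median-split Kaplan-Meier comparison with the Mantel-Cox test.

    Patients scoring above the median form the 'high' group; ties go to
    the 'low' group (deterministic). The chi-square is the standard
    log-rank observed-minus-expected statistic over the pooled risk
    table.
    """
    if split != "median":
        raise ValueError("only median split is supported")
    clin = cohort.clinical.loc[scores.index]
    cut = scores.median()
    high = scores > cut  # ties to the low group
    if high.sum() < 2 or (~high).sum() < 2:
        raise ValueError("median split needs at least 2 patients per group")
    labels = pd.Series(np.where(high, "high", "low"), index=scores.index, name="group")
    t, e = clin["time"].to_numpy(float), clin["event"].to_numpy(int)
    res = logrank_test(t[high.values], t[~high.values],
                       e[high.values], e[~high.values])
    stats_rows = []
    for name, mask in (("high", high.values), ("low", ~high.values)):
        stats_rows.append({
            "group": name,
            "n": int(mask.sum()),
            "events": int(e[mask].sum()),
            "median_survival": _km_median(t[mask], e[mask]),
        })
    return StratificationResult(
        scores=scores,
        labels=labels,
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        group_stats=pd.DataFrame(stats_rows).set_index("group"),
    )
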