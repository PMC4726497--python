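"""Synthetic data with planted ground truth for every pipeline input.

Emulates, at desk scale, the four data modalities the pipeline
consumes: (a) 3'UTR sequence sets with motif sites planted at known
prevalences on top of a random base composition; (b) a three-group
(control / Cnot7-knockdown / CNOT7-overexpression) log2 expression
design with planted anticorrelated genes; (c) negative-binomial RIP
count libraries with planted FLAG-IP enrichment; (d) survival cohorts
whose hazard depends log-linearly on a signature score. Every generator
is a pure function of its configuration: identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .motifs import IUPAC_RNA, MotifDefinition
from .scan import UtrRecord
from .survival import GeneSignature, SurvivalCohort

BASES = np.array(list("ACGU"))

# Stream tags keeping the four generators' random streams independent
# under one master seed.
_STREAM_UTR, _STREAM_EXPR, _STREAM_RIP, _STREAM_COHORT = 11, 13, 17, 19


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs.

    Expression effects are on the log2 scale (``effect_size_delta`` is
    the planted knockdown shift; overexpression gets the opposite sign).
    RIP counts are negative-binomial with variance mean + dispersion *
    mean^2. Cohort follow-up is in months.
    """

    seed: int = 0
    n_genes: int = 5000
    utr_length_mean: float = 400.0
    utr_length_sd: float = 120.0
    # mildly AU-rich, as mammalian 3'UTRs are
    base_composition: tuple[float, float, float, float] = (0.28, 0.21, 0.21, 0.30)
    motif_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "CPE": 0.25,
            "PUM": 0.15,
            "NRE": 0.20,
            "CPSF": 0.40,
            "ARE_permissive": 0.30,
            "ARE_stringent": 0.10,
        }
    )
    n_planted_anticorr: int = 250
    effect_size_delta: float = 1.5
    noise_sd: float = 0.5
    n_per_group: int = 4
    rip_mean: float = 100.0
    rip_dispersion: float = 0.05
    rip_fold: float = 4.0
    rip_frac_enriched: float = 0.05
    cohort_n: int = 600
    hazard_beta: float = -0.7
    censor_rate: float = 0.2
    follow_up_max: float = 120.0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        for name, frac in {
            "censor_rate": self.censor_rate,
            "rip_frac_enriched": self.rip_frac_enriched,
            **{f"prevalence[{k}]": v for k, v in self.motif_prevalence.items()},
        }.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        for name, count in {
            "n_genes": self.n_genes,
            "n_planted_anticorr": self.n_planted_anticorr,
            "cohort_n": self.cohort_n,
        }.items():
            if count < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rip_dispersion < 0:
            raise ValueError("rip_dispersion must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def _realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete RNA word satisfying a degenerate IUPAC pattern."""
    return "".join(
        rng.choice(sorted(IUPAC_RNA[code])) for code in pattern
    )


def simulate_utrs(
    config: SimulationConfig, motifs: list[MotifDefinition]
) -> tuple[list[UtrRecord], pd.DataFrame]:
    """UTR set with planted motif sites and the planted-truth table.

    Each gene's background sequence is drawn i.i.d. from
    ``base_composition``. For each motif, a ``motif_prevalence``
    fraction of genes receives one planted site: a concrete realization
    of a randomly chosen pattern, overwritten at a start position drawn
    uniformly among positions not overlapping previously planted sites
    in that gene. Chance (unplanted) occurrences remain possible and
    expected — the truth table records only planted sites.
    """
    rng = _rng(config, _STREAM_UTR)
    ids = gene_ids(config.n_genes)
    lengths = np.maximum(
        np.rint(rng.normal(config.utr_length_mean, config.utr_length_sd, config.n_genes)),
        20,
    ).astype(int)
    seqs = [
        rng.choice(BASES, size=L, p=config.base_composition) for L in lengths
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in ids]
    truth_rows = []
    for motif in motifs:
        prevalence = config.motif_prevalence.get(motif.name, 0.0)
        chosen = np.flatnonzero(rng.random(config.n_genes) < prevalence)
        for gi in chosen:
            word = _realize_pattern(
                motif.patterns[int(rng.integers(len(motif.patterns)))], rng
            )
            L, w = lengths[gi], len(word)
            if w > L:
                raise ValueError(
                    f"motif {motif.name!r} ({w} nt) longer than UTR of gene "
                    f"{ids[gi]!r} ({L} nt)"
                )
            if sum(e - s for s, e in occupied[gi]) + w > L:
                raise ValueError(
                    f"cannot pack planted sites into gene {ids[gi]!r} ({L} nt)"
                )
            free = np.ones(L - w + 1, dtype=bool)
            for s, e in occupied[gi]:
                free[max(0, s - w + 1): e] = False
            starts = np.flatnonzero(free)
            if starts.size == 0:
                raise ValueError(
                    f"no non-overlapping position left for {motif.name!r} in "
                    f"gene {ids[gi]!r}"
                )
            start = int(starts[rng.integers(starts.size)])
            seqs[gi][start: start + w] = list(word)
            occupied[gi].append((start, start + w))
            truth_rows.append(
                {
                    "gene_id": ids[gi],
                    "motif_name": motif.name,
                    "start": start,
                    "end": start + w,
                    "planted_seq": word,
                }
            )
    records = [UtrRecord(g, "".join(s)) for g, s in zip(ids, seqs)]
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "motif_name", "start", "end", "planted_seq"]
    )
    return records, truth


def simulate_expression(
    config: SimulationConfig,
) -> tuple["ExpressionMatrix", set[str]]:
    """Three-group log2 expression matrix with planted anticorrelated genes.

    Planted genes are shifted +delta in knockdown and −delta in
    overexpression relative to control; all genes get i.i.d. Gaussian
    noise with sd ``noise_sd``. Per-gene baseline means are drawn
    N(8, 1.5) log2 units, a typical array intensity range. A driver row
    named ``Cnot7`` records the perturbation itself (−2 log2 units in
    knockdown, +2 in overexpression) and is never part of the planted
    truth set.
    """
    from .expression import ExpressionMatrix

    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 for a t-test")
    if config.n_planted_anticorr > config.n_genes:
        raise ValueError("n_planted_anticorr exceeds n_genes")
    rng = _rng(config, _STREAM_EXPR)
    ids = gene_ids(config.n_genes)
    planted_idx = rng.choice(config.n_genes, config.n_planted_anticorr, replace=False)
    planted = set() if config.effect_size_delta == 0 else {ids[i] for i in planted_idx}

    base = rng.normal(8.0, 1.5, config.n_genes)
    driver_base = 8.0
    k = config.n_per_group
    samples, cols, group_of = [], [], {}
    shifts = {"control": 0.0, "knockdown": +config.effect_size_delta,
              "overexpression": -config.effect_size_delta}
    driver_shift = {"control": 0.0, "knockdown": -2.0, "overexpression": +2.0}
    for group, shift in shifts.items():
        mean = base.copy()
        if config.effect_size_delta != 0:
            mean[planted_idx] += shift
        block = mean[:, None] + rng.normal(0.0, config.noise_sd, (config.n_genes, k))
        driver_row = (driver_base + driver_shift[group]
                      + rng.normal(0.0, config.noise_sd, (1, k)))
        block = np.vstack([block, driver_row])
        for j in range(k):
            name = f"{group}_{j + 1}"
            cols.append(name)
            group_of[name] = group
        samples.append(block)
    values = pd.DataFrame(np.hstack(samples), index=ids + ["Cnot7"], columns=cols)
    values.index.name = "gene_id"
    groups = pd.Series(group_of, name="group")
    return ExpressionMatrix(values, groups), planted


def simulate_rip(
    config: SimulationConfig, enriched_genes: set[str] | None = None
) -> tuple[pd.DataFrame, set[str]]:
    """Negative-binomial RIP count table with planted FLAG-IP enrichment.

    Per-gene abundance varies log-normally around ``rip_mean`` and is
    shared across the three libraries; planted genes have their
    ``ip_flag`` mean multiplied by ``rip_fold``. ``rip_dispersion`` = 0
    gives the Poisson limit. By default a ``rip_frac_enriched`` fraction
    of genes is planted at random; passing ``enriched_genes`` plants a
    caller-chosen set instead (e.g. the anticorrelated truth genes, for
    a jointly planted design).
    """
    if config.rip_mean <= 0:
        raise ValueError("rip_mean must be positive")
    rng = _rng(config, _STREAM_RIP)
    ids = gene_ids(config.n_genes)
    # lognormal with unit mean around rip_mean
    sigma = 0.5
    base = config.rip_mean * rng.lognormal(-sigma**2 / 2, sigma, config.n_genes)
    if enriched_genes is None:
        n_enriched = int(round(config.rip_frac_enriched * config.n_genes))
        enriched_idx = rng.choice(config.n_genes, n_enriched, replace=False)
    else:
        unknown = enriched_genes - set(ids)
        if unknown:
            raise ValueError(f"unknown genes to enrich: {sorted(unknown)[:5]!r}")
        pos = {g: i for i, g in enumerate(ids)}
        enriched_idx = np.array(sorted(pos[g] for g in enriched_genes), dtype=int)
    truth = set() if config.rip_fold == 1.0 else {ids[i] for i in enriched_idx}

    flag_mean = base.copy()
    if config.rip_fold != 1.0:
        flag_mean[enriched_idx] *= config.rip_fold

    def draw(mean: np.ndarray) -> np.ndarray:
        if config.rip_dispersion == 0.0:
            return rng.poisson(mean)
        size = 1.0 / config.rip_dispersion
        return rng.negative_binomial(size, size / (size + mean))

    counts = pd.DataFrame(
        {
            "ip_flag": draw(flag_mean),
            "ip_control": draw(base),
            "input": draw(base),
        },
        index=ids,
    )
    counts.index.name = "gene_id"
    return counts, truth


# Baseline exponential hazard: median event time follow_up_max/3 at score 0.
def _baseline_hazard(config: SimulationConfig) -> float:
    horizon = config.follow_up_max if np.isfinite(config.follow_up_max) else 120.0
    return float(np.log(2) / (horizon / 3.0))


def simulate_cohort(
    signature: GeneSignature, config: SimulationConfig
) -> SurvivalCohort:
    """Survival cohort whose hazard depends on the signature score.

    Patient expression of signature genes is standard normal; event
    times are exponential with hazard h0 * exp(hazard_beta * score); a
    ``censor_rate`` fraction of patients is censored at a uniform time
    before their event, and follow-up is administratively truncated at
    ``follow_up_max``.
    """
    if config.cohort_n < 2:
        raise ValueError("cohort_n must be >= 2")
    rng = _rng(config, _STREAM_COHORT)
    n = config.cohort_n
    patients = [f"patient{i:04d}" for i in range(n)]
    genes = signature.genes
    expr = pd.DataFrame(
        rng.standard_normal((n, len(genes))), index=patients, columns=genes
    )
    expr.index.name = "patient_id"
    w = np.asarray([signature.entries[g] for g in genes])
    z = (expr.to_numpy() - expr.to_numpy().mean(0)) / expr.to_numpy().std(0)
    score = z @ w / np.abs(w).sum()
    hazard = _baseline_hazard(config) * np.exp(config.hazard_beta * score)
    t_event = rng.exponential(1.0 / hazard)
    event = np.ones(n, dtype=int)

    censored = rng.random(n) < config.censor_rate
    t_obs = t_event.copy()
    t_obs[censored] = rng.uniform(0.0, t_event[censored])
    event[censored] = 0
    if np.isfinite(config.follow_up_max):
        late = t_obs > config.follow_up_max
        t_obs[late] = config.follow_up_max
        event[late] = 0
    clinical = pd.DataFrame({"time": t_obs, "event": event}, index=patients)
    clinical.index.name = "patient_id"
    return SurvivalCohort(clinical, expr)


def simulate_ortholog_map(
    genes: list[str], coverage: float = 0.74, seed: int = 0
) -> dict[str, str]:
    """Synthetic mouse -> human ortholog map covering a ``coverage``
    fraction of genes (human symbol = upper-cased mouse symbol), mirroring
    the partial ortholog representation of real cross-species cohorts."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    n_mapped = int(round(coverage * len(genes)))
    mapped = rng.choice(len(genes), n_mapped, replace=False)
    return {genes[i]: genes[i].upper() for i in sorted(mapped)}
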