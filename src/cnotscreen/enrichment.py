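"""Motif enrichment by genome resampling.

Tests whether a target gene set carries a motif more often than expected
by drawing random gene sets of the same size from the annotated genome
background, many times, and comparing the observed count of
motif-bearing genes against that resampled null. Two p-values are
reported per motif: the standard empirical permutation p (headline) and
a one-tailed t-style normal approximation formed from the null mean and
standard deviation, kept for comparability with older resampling
pipelines that summarize the null with a t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from zlib import crc32

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    motif_name: str
    n_target: int
    k_obs: int  # target genes with >=1 site
    s_obs: int  # total sites in target
    n_perm: int
    null_k: np.ndarray
    null_s: np.ndarray
    p_empirical: float
    p_t: float
    enriched: bool
    considered: bool = True

    @property
    def null_mean(self) -> float:
        return float(self.null_k.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_k.std(ddof=1)) if self.n_perm > 1 else 0.0


def sample_null(
    background: pd.DataFrame,
    motif_name: str,
    n: int,
    n_perm: int,
    seed: int | np.random.SeedSequence,
    replace: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Resampled null for one motif: draw ``n`` genes from the background
    ``n_perm`` times and record (genes-with-motif, total-sites) per draw.

    Draws are without replacement by default (gene sets are sets).
    """
    if n > len(background):
        raise ValueError(
            f"cannot draw {n} genes from a background of {len(background)}"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = background[motif_name].to_numpy(dtype=np.int64)
    present = counts >= 1
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, len(counts), size=(n_perm, n))
    else:
        # row-wise uniform draws without replacement
        idx = np.argsort(rng.random((n_perm, len(counts))), axis=1, kind="stable")[:, :n]
    null_k = present[idx].sum(axis=1)
    null_s = counts[idx].sum(axis=1)
    return null_k, null_s


def enrichment_test(
    target: set[str],
    background: pd.DataFrame,
    motif_name: str,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
    statistic: str = "genes",
    replace: bool = False,
) -> EnrichmentResult:
    """Permutation enrichment test of one motif in a target set.

    p_empirical uses add-one smoothing: (1 + #{null >= observed}) /
    (n_perm + 1), so it is bounded below by 1/(n_perm+1). p_t is the
    upper-tail probability of t = (obs − null_mean)/null_sd against a
    t distribution with n_perm − 1 df; when the null is degenerate
    (sd = 0) p_t is 1 if the observation equals the null values, else 0.

    ``statistic`` chooses the tested quantity: 'genes' (count of
    motif-bearing genes, default) or 'sites' (total site count).
    """
    missing = target - set(background.index)
    if missing:
        raise ValueError(
            f"target genes absent from background: {sorted(missing)[:5]!r}"
        )
    if statistic not in ("genes", "sites"):
        raise ValueError(f"statistic must be 'genes' or 'sites', got {statistic!r}")
    sub = background.loc[sorted(target), motif_name]
    k_obs = int((sub >= 1).sum())
    s_obs = int(sub.sum())
    null_k, null_s = sample_null(
        background, motif_name, len(target), n_perm, seed, replace=replace
    )
    null = null_k if statistic == "genes" else null_s
    obs = k_obs if statistic == "genes" else s_obs
    p_emp = (1 + int((null >= obs).sum())) / (n_perm + 1)
    mean, sd = float(null.mean()), float(null.std(ddof=1)) if n_perm > 1 else 0.0
    if sd == 0.0:
        p_t = 1.0 if obs == mean else (0.0 if obs > mean else 1.0)
    else:
        p_t = float(stats.t.sf((obs - mean) / sd, df=n_perm - 1))
    return EnrichmentResult(
        motif_name=motif_name,
        n_target=len(target),
        k_obs=k_obs,
        s_obs=s_obs,
        n_perm=n_perm,
        null_k=null_k,
        null_s=null_s,
        p_empirical=p_emp,
        p_t=p_t,
        enriched=p_emp <= alpha,
    )


def _child_seed(master_seed: int, motif_name: str) -> np.random.SeedSequence:
    """Per-motif child seed keyed by motif name, so a panel's results do
    not depend on the order motifs are listed in."""
    return np.random.SeedSequence([int(master_seed), crc32(motif_name.encode())])


def motif_panel(
    target: set[str],
    background: pd.DataFrame,
    motif_names: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "genes",
) -> list[EnrichmentResult]:
    """One enrichment test per motif with independent per-motif seeds."""
    if motif_names is None:
        motif_names = list(background.columns)
    return [
        enrichment_test(
            target,
            background,
            name,
            n_perm=n_perm,
            seed=_child_seed(seed, name),
            alpha=alpha,
            statistic=statistic,
        )
        for name in motif_names
    ]


def apply_min_count_filter(
    results: list[EnrichmentResult], min_genes: int = 10
) -> list[EnrichmentResult]:
    """Mark motifs present in fewer than ``min_genes`` target genes as not
    considered (too few carriers for the test to be meaningful)."""
    out = []
    for r in results:
        if r.k_obs < min_genes:
            out.append(
                EnrichmentResult(
                    **{**r.__dict__, "enriched": False, "considered": False}
                )
            )
        else:
            out.append(r)
    return out


def panel_summary(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat panel table: one row per motif with null summaries and p-values."""
    return pd.DataFrame(
        [
            {
                "motif": r.motif_name,
                "n_target": r.n_target,
                "k_obs": r.k_obs,
                "s_obs": r.s_obs,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "p_empirical": r.p_empirical,
                "p_t": r.p_t,
                "enriched": r.enriched,
                "considered": r.considered,
            }
            for r in results
        ]
    ).set_index("motif")
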