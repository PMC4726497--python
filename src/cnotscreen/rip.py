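"""RIP-seq enrichment calling.

Three count libraries per gene: the FLAG-CNOT7 immunoprecipitate
(``ip_flag``), a control IP from empty-vector cells (``ip_control``) and
input RNA (``input``). A transcript is called CNOT7-bound when its
depth-normalized abundance in the FLAG IP exceeds BOTH the input and the
control IP by a fold threshold. The design has single libraries, so the
rule is a fold-change criterion, not a dispersion-based test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

LIBRARIES = ("ip_flag", "ip_control", "input")


def _check_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in LIBRARIES if c not in counts.columns]
    if missing:
        raise ValueError(f"RIP count table missing libraries: {missing!r}")
    vals = counts[list(LIBRARIES)]
    if (vals < 0).any().any():
        raise ValueError("RIP counts must be non-negative")
    zero = [c for c in LIBRARIES if vals[c].sum() == 0]
    if zero:
        raise ValueError(f"all-zero RIP libraries: {zero!r}")


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million within each library (gene x library)."""
    _check_counts(counts)
    vals = counts[list(LIBRARIES)].astype(float)
    return vals / vals.sum(axis=0) * 1e6


def call_enriched(
    counts: pd.DataFrame, threshold: float = 2.0, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Fold-change enrichment of the FLAG IP over input and control IP.

    Fold-changes are computed on counts rescaled to the mean library
    depth ("counts at average depth"), with ``pseudocount`` added on
    that count scale so ratios stay finite and a 0/0 gene gets fold 1
    exactly. ``enriched`` requires fold >= threshold against BOTH
    comparators.
    """
    if threshold <= 0:
        raise ValueError(f"fold threshold must be positive, got {threshold}")
    _check_counts(counts)
    vals = counts[list(LIBRARIES)].astype(float)
    sizes = vals.sum(axis=0)
    scaled = vals * (sizes.mean() / sizes)  # depth-fair counts
    num = scaled["ip_flag"] + pseudocount
    fc_input = num / (scaled["input"] + pseudocount)
    fc_control = num / (scaled["ip_control"] + pseudocount)
    return pd.DataFrame(
        {
            "fc_input": fc_input,
            "fc_control": fc_control,
            "enriched": (fc_input >= threshold) & (fc_control >= threshold),
        },
        index=counts.index,
    )


def enriched_genes(calls: pd.DataFrame) -> set[str]:
    return set(calls.index[calls["enriched"]])


def intersect_anticorrelated(
    rip_calls: pd.DataFrame, de_results: pd.DataFrame
) -> list[str]:
    """Sorted intersection of RIP-enriched and Cnot7-anticorrelated genes.

    This is the joint set of transcripts physically bound by CNOT7 and
    inversely regulated by it — the pipeline's candidate direct targets.
    """
    anticorr = set(de_results.index[de_results["anticorrelated"]])
    return sorted(enriched_genes(rip_calls) & anticorr)


def recover_joint_truth(called: list[str], truth: set[str]) -> dict[str, float]:
    """Recall/precision of a called gene list against a planted truth set."""
    called_set = set(called)
    tp = len(called_set & truth)
    return {
        "recall": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(called_set) if called_set else float("nan"),
    }
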