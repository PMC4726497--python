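"""Independent oracles used by the tests.

Deliberately naive implementations — brute-force enumeration and the
textbook risk-table recursion — kept separate from the package code so
the checks stay two-route.
"""

from __future__ import annotations

import numpy as np

from cnotscreen.motifs import IUPAC_RNA


def brute_force_sites(seq: str, patterns: list[str]) -> list[tuple[int, int, str]]:
    """Enumerate every start position against the IUPAC table."""
    out = set()
    for pat in patterns:
        m = len(pat)
        for start in range(len(seq) - m + 1):
            window = seq[start : start + m]
            if all(base in IUPAC_RNA[code] for code, base in zip(pat, window)):
                out.add((start, start + m, window))
    return sorted(out)


def hand_logrank_chi2(
    t1: np.ndarray, e1: np.ndarray, t2: np.ndarray, e2: np.ndarray
) -> float:
    """Unweighted log-rank chi-square from the pooled risk-table recursion."""
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        n1 = np.sum(t1 >= t)
        n2 = np.sum(t2 >= t)
        d1 = np.sum((t1 == t) & (e1 == 1))
        d2 = np.sum((t2 == t) & (e2 == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2:
            continue
        e1_t = d * n1 / n
        O_minus_E += d1 - e1_t
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return float(O_minus_E**2 / V)
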