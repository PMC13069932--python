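"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive quantities from first
principles (per-pixel loops, exhaustive pair counting, exhaustive
cutoff search) so the vectorized implementations are checked against
something that cannot share their bugs.
"""

from __future__ import annotations

import numpy as np
import pytest


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive concordant-pair counting (ties count one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_youden(scores, labels) -> tuple[float, float, float]:
    """Best cutoff by exhaustive search over observed scores.

    Positive call = score >= cutoff; ties in J break toward the
    smallest cutoff.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for c in sorted(set(scores.tolist())):
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, c, sens, spec)
    return best[1], best[2], best[3]


def quantify_field_bruteforce(image) -> tuple[float, float, float]:
    """Pure-python per-pixel recomputation of threshold, intensity, area."""
    img = np.asarray(image, float)
    pixels = [img[r, c] for r in range(img.shape[0]) for c in range(img.shape[1])]
    thr = (min(pixels) + max(pixels)) / 2.0
    stained = [v for v in pixels if v < thr]
    mean_int = sum(stained) / len(stained) if stained else float("nan")
    pct = 100.0 * len(stained) / len(pixels)
    return thr, mean_int, pct


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
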