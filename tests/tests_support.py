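"""Brute-force oracles shared across test modules."""

import numpy as np


def brute_force_auc(labels, scores):
    """All-pairs comparison count with ties scored 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_ap(labels, scores):
    """Precision averaged at each positive's rank (untied scores)."""
    order = np.argsort(-scores)
    y = labels[order]
    precisions = []
    tp = 0
    for k, yk in enumerate(y, start=1):
        if yk == 1:
            tp += 1
            precisions.append(tp / k)
    return float(np.mean(precisions))
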