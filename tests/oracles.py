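"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (exhaustive enumeration, textbook
dynamic programming) and shares no code with the package.
"""

import numpy as np


def nw_identity(a: str, b: str) -> float:
    """Needleman–Wunsch identity: match +1, mismatch 0, linear gap -1.

    Among optimal-score alignments the one with the most identical
    aligned pairs is chosen; identity = identities / min(len(a), len(b)).
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    # DP over (score, identities), maximised lexicographically
    score = np.full((n + 1, m + 1), NEG)
    ident = np.zeros((n + 1, m + 1))
    score[0, :] = -np.arange(m + 1)
    score[:, 0] = -np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1]
            cands = [
                (score[i - 1, j - 1] + (1.0 if match else 0.0),
                 ident[i - 1, j - 1] + (1.0 if match else 0.0)),
                (score[i - 1, j] - 1.0, ident[i - 1, j]),
                (score[i, j - 1] - 1.0, ident[i, j - 1]),
            ]
            score[i, j], ident[i, j] = max(cands)
    return ident[n, m] / min(n, m)


def greedy_keep(sequences: dict, identities, cutoff: float) -> list:
    """Hand simulation of greedy redundancy removal.

    ``sequences`` maps key -> sequence; ``identities`` is a callable
    (seq, seq) -> identity.  Keys visited by decreasing length then key.
    """
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    kept = []
    for key in order:
        if all(identities(sequences[key], sequences[k]) <= cutoff for k in kept):
            kept.append(key)
    return kept


def brute_min_distance(coords_a, coords_b) -> float:
    """All-pairs double loop minimum Euclidean distance."""
    best = float("inf")
    for a in coords_a:
        for b in coords_b:
            d = float(np.sqrt(((np.asarray(a) - np.asarray(b)) ** 2).sum()))
            best = min(best, d)
    return best


def pair_count_auc(scores, labels) -> float:
    """Mann–Whitney AUC by exhaustive pair comparison (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pearson(x, y) -> float:
    """Pearson r from first principles (covariance over SD product)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


def brute_best_f(scores, labels, mode: str = "harmonic"):
    """Exhaustive F-measure scan over every distinct cutoff (ties: lowest)."""
    best_f, best_c = -1.0, None
    for c in sorted(set(float(s) for s in scores)):
        tp = sum(1 for s, l in zip(scores, labels) if s > c and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s > c and l == 0)
        fn = sum(1 for s, l in zip(scores, labels) if s <= c and l == 1)
        if tp + fp == 0 or tp + fn == 0:
            continue
        prec = tp / (tp + fp)
        rec = tp / (tp + fn)
        if mode == "harmonic":
            if prec + rec == 0:
                continue
            f = 2 * prec * rec / (prec + rec)
        else:
            f = (prec * rec) ** 0.5
        if f > best_f:
            best_f, best_c = f, c
    return best_c, best_f
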