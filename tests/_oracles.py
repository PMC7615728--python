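"""Independent brute-force oracles used across the test suite.

These deliberately avoid the algorithms they check: depth enumerates
candidate directions, AUC counts pairs, Youden scans thresholds.
"""

import numpy as np


def brute_force_depth(q, cloud) -> int:
    """Tukey depth by enumerating all directions orthogonal to point pairs."""
    cloud = np.asarray(cloud, float)
    q = np.asarray(q, float)
    vecs = [p - q for p in cloud]
    vecs += [cloud[i] - cloud[j] for i in range(len(cloud)) for j in range(i)]
    best = len(cloud)
    for v in vecs:
        if np.allclose(v, 0):
            continue
        for u in (np.array([-v[1], v[0]]), np.array([v[1], -v[0]])):
            cnt = int(np.count_nonzero((cloud - q) @ u >= -1e-12))
            best = min(best, cnt)
    return best


def pair_count_auc(scores, truth) -> float:
    """AUC as the fraction of (error, clean) pairs won, ties counting half."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_youden(scores, truth) -> float:
    """Max over all cutoffs of Se + Sp - 1, flagging scores > cutoff."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, bool)
    best = 0.0
    cutoffs = np.concatenate([[-np.inf], np.unique(scores)])
    for t in cutoffs:
        flag = scores > t
        se = np.count_nonzero(flag & truth) / truth.sum()
        sp = np.count_nonzero(~flag & ~truth) / (~truth).sum()
        best = max(best, se + sp - 1)
    return best
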