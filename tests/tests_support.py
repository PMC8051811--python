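"""Independent oracles shared across test modules.

These implementations deliberately avoid the package's own code paths:
the Otsu oracle scans raw pixel values exhaustively, and the matching
oracle enumerates assignments recursively.
"""

import numpy as np


def brute_force_otsu_split(values: np.ndarray) -> float:
    """Exhaustive intra-class-variance minimizer over all value splits.

    Every distinct pixel value is tried as the class-0 upper bound; the
    weighted within-class variance is computed directly from the raw
    values. Returns the smallest minimizing threshold.
    """
    values = values.astype(np.float64)
    best_t, best_v = None, np.inf
    for t in np.unique(values)[:-1]:
        c0, c1 = values[values <= t], values[values > t]
        v = (len(c0) * c0.var() + len(c1) * c1.var()) / values.size
        if v < best_v - 1e-12:
            best_v, best_t = v, float(t)
    return best_t


def brute_force_max_matching(ioumat, t: float) -> int:
    """Exhaustive optimal one-to-one matching maximizing TP at threshold t."""
    cand = [
        (int(r.gt_id), int(r.pred_id))
        for r in ioumat.pairs.itertuples(index=False)
        if r.iou >= t
    ]
    adj: dict[int, list[int]] = {}
    for g, p in cand:
        adj.setdefault(g, []).append(p)
    gts = sorted(adj)

    def best_from(idx, used):
        if idx == len(gts):
            return 0
        best = best_from(idx + 1, used)  # leave this gt unmatched
        for p in adj[gts[idx]]:
            if p not in used:
                best = max(best, 1 + best_from(idx + 1, used | {p}))
        return best

    return best_from(0, frozenset())


def random_label_maps(rng, shape=(48, 48), n_max=6):
    """A pair of blobby random label maps with <= n_max instances each."""

    def one():
        lab = np.zeros(shape, np.int32)
        n = rng.integers(1, n_max + 1)
        for k in range(1, n + 1):
            r, c = rng.integers(5, shape[0] - 5, size=2)
            rad = rng.integers(3, 8)
            rr, cc = np.ogrid[: shape[0], : shape[1]]
            sel = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
            lab[sel & (lab == 0)] = k
        return lab

    return one(), one()
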