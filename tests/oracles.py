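"""Independent brute-force oracles used only by the tests.

These re-derive the texture statistics with plain double loops over pixel
pairs, deliberately sharing no code with the package implementation.
"""

import numpy as np

OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]


def naive_local_moran(plane, mask, scheme):
    """O(n^2) local Moran's I over a masked window, all four weight schemes."""
    mask = np.asarray(mask, bool)
    pix = [tuple(p) for p in np.argwhere(mask)]
    x = {p: float(plane[p]) for p in pix}
    n = len(pix)
    mean = sum(x.values()) / n
    var = sum((v - mean) ** 2 for v in x.values()) / n
    neigh = {
        p: [q for q in pix
            if q != p and abs(q[0] - p[0]) <= 1 and abs(q[1] - p[1]) <= 1]
        for p in pix
    }
    total_edges = sum(len(v) for v in neigh.values())

    def weight(p, q):
        if scheme == "B":
            return 1.0
        if scheme == "W":
            return 1.0 / len(neigh[p])
        if scheme == "C":
            return n / total_edges
        if scheme == "U":
            return 1.0 / total_edges
        raise ValueError(scheme)

    out = np.full(mask.shape, np.nan)
    for p in pix:
        s = sum(weight(p, q) * (x[q] - mean) for q in neigh[p])
        out[p] = (x[p] - mean) / var * s
    return out


def naive_global_moran_row_standardized(plane, mask):
    """Global Moran's I with row-standardised weights, from its definition:
    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    mask = np.asarray(mask, bool)
    pix = [tuple(p) for p in np.argwhere(mask)]
    vals = np.array([float(plane[p]) for p in pix])
    z = vals - vals.mean()
    n = len(pix)
    s0 = 0.0
    cross = 0.0
    for i, p in enumerate(pix):
        neigh = [j for j, q in enumerate(pix)
                 if q != p and abs(q[0] - p[0]) <= 1 and abs(q[1] - p[1]) <= 1]
        for j in neigh:
            w = 1.0 / len(neigh)
            s0 += w
            cross += w * z[i] * z[j]
    return (n / s0) * cross / (z ** 2).sum()


def naive_lbp(plane, mask, R=1):
    """Pixel-loop LBP with the east-first counter-clockwise bit order."""
    mask = np.asarray(mask, bool)
    h, w = mask.shape
    codes = np.full((h, w), -1, dtype=int)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            code = 0
            ok = True
            for p, (dr, dc) in enumerate(OFFSETS):
                rr, cc = r + dr * R, c + dc * R
                if not (0 <= rr < h and 0 <= cc < w and mask[rr, cc]):
                    ok = False
                    break
                if plane[rr, cc] - plane[r, c] >= 0:
                    code |= 1 << p
            if ok:
                codes[r, c] = code
    return codes
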