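"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the FROC oracle
re-matches candidates from scratch at every threshold with plain loops,
the Otsu oracle scans all histogram splits, and the Adam oracle is a
scalar recurrence transcribed directly from the update equations.
"""

import numpy as np


def brute_force_froc(candidates, truths, operating_points):
    """Exhaustive-threshold FROC.

    candidates: list of (series_id, position_xyz, score);
    truths: list of (series_id, center_xyz, diameter_mm).
    Returns (sensitivities tuple, auc) with auc = mean sensitivity.
    """
    scans = sorted({c[0] for c in candidates} | {t[0] for t in truths})
    n_scans = len(scans)
    n_truths = len(truths)
    thresholds = sorted({c[2] for c in candidates})
    curve = []
    for thr in thresholds:
        kept = [c for c in candidates if c[2] >= thr]
        detected = 0
        for t_sid, t_center, t_d in truths:
            for c_sid, c_pos, _ in kept:
                if c_sid != t_sid:
                    continue
                dist = sum((a - b) ** 2 for a, b in zip(c_pos, t_center)) ** 0.5
                if dist <= t_d / 2.0:
                    detected += 1
                    break
        fps = 0
        for c_sid, c_pos, _ in kept:
            inside_any = False
            for t_sid, t_center, t_d in truths:
                if c_sid != t_sid:
                    continue
                dist = sum((a - b) ** 2 for a, b in zip(c_pos, t_center)) ** 0.5
                if dist <= t_d / 2.0:
                    inside_any = True
                    break
            if not inside_any:
                fps += 1
        curve.append((fps / n_scans, detected / n_truths))
    sens = []
    for f in operating_points:
        ok = [s for r, s in curve if r <= f]
        sens.append(max(ok) if ok else 0.0)
    return tuple(sens), float(np.mean(sens))


def brute_force_otsu(voxels, nbins=256):
    """Exhaustive between-class-variance threshold scan."""
    hist, edges = np.histogram(voxels.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(float)
    best_var, best_thr = -1.0, centers[0]
    total = hist.sum()
    for i in range(1, nbins):
        w0 = hist[:i].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i] * centers[:i]).sum() / w0
        m1 = (hist[i:] * centers[i:]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[i - 1]
    return best_thr


def scalar_adam_oracle(g_sequence, mu=0.9, upsilon=0.9999, eta=0.01, eps=1e-8):
    """Transcribed scalar Adam recurrence; returns the list of deltas."""
    m = 0.0
    n = 0.0
    deltas = []
    for t, g in enumerate(g_sequence, start=1):
        m = mu * m + (1 - mu) * g
        n = upsilon * n + (1 - upsilon) * g * g
        m_hat = m / (1 - mu**t)
        n_hat = n / (1 - upsilon**t)
        deltas.append(-eta * m_hat / (np.sqrt(n_hat) + eps))
    return deltas


def flood_fill_components(mask):
    """BFS 26-connected component count on a small boolean array."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    shape = mask.shape
    count = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.where(mask & ~seen)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < shape[i] for i in range(3)) and mask[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
    return count
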