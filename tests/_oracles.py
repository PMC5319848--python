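"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from first principles with plain loops — no
scipy.signal, no pandas groupby tricks — so that a disagreement points at
the implementation, not at a shared dependency.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(values: np.ndarray, prominence: float,
                      distance_samples: float) -> list[int]:
    """Exhaustive peak scan with the same selection rules as detect_peaks.

    1. every strict local maximum is a candidate;
    2. candidates are visited tallest-first; one is kept only when no
       already-kept peak lies closer than ``distance_samples``;
    3. survivors must have topographic prominence >= ``prominence``, where
       the prominence is the peak height minus the higher of the two base
       levels (the minimum between the peak and the nearest taller sample,
       or the interval edge, on each side).
    """
    v = np.asarray(values, dtype=float)
    candidates = [i for i in range(1, v.size - 1)
                  if v[i] > v[i - 1] and v[i] > v[i + 1]]
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: -v[i]):
        if all(abs(i - j) >= distance_samples for j in kept):
            kept.append(i)
    out = []
    for i in kept:
        # left base
        j = i - 1
        left_min = v[i]
        while j >= 0 and v[j] <= v[i]:
            left_min = min(left_min, v[j])
            j -= 1
        # right base
        j = i + 1
        right_min = v[i]
        while j < v.size and v[j] <= v[i]:
            right_min = min(right_min, v[j])
            j += 1
        if v[i] - max(left_min, right_min) >= prominence:
            out.append(i)
    return sorted(out)


def brute_force_pairing(z_positions, pointed_positions) -> list[tuple[float, float]]:
    """Exhaustive nearest-Z assignment with the half-local-SL guard.

    Returns (tfl, local_sl) pairs. Ties in distance go to the left Z.
    """
    z = sorted(float(p) for p in z_positions)
    out = []
    for p in pointed_positions:
        best = None
        for zi in z:  # left-to-right: ties keep the first (left) Z
            d = abs(p - zi)
            if best is None or d < best[1]:
                best = (zi, d)
        # bracketing sarcomere
        left = [zi for zi in z if zi <= p]
        right = [zi for zi in z if zi > p]
        if len(z) < 2:
            local_sl = float("inf")
        elif left and right:
            local_sl = min(right) - max(left)
        elif left:
            local_sl = z[-1] - z[-2]
        else:
            local_sl = z[1] - z[0]
        if best[1] < 0.5 * local_sl:
            out.append((best[1], local_sl))
    return out


def naive_ddct(table, target: str, reference: str, control_samples) -> dict:
    """Plain-arithmetic 2^-ddCt: replicate means on the Ct scale, per-sample
    dCt, control-mean dCt, fold change."""
    samples = sorted(set(table["sample_id"]))
    mean_ct = {}
    for s in samples:
        for t in (target, reference):
            cts = [row.ct for row in table.itertuples()
                   if row.sample_id == s and row.target == t]
            mean_ct[(s, t)] = sum(cts) / len(cts)
    dct = {s: mean_ct[(s, target)] - mean_ct[(s, reference)] for s in samples}
    ctrl = [dct[s] for s in samples if s in set(control_samples)]
    ctrl_mean = sum(ctrl) / len(ctrl)
    return {s: 2.0 ** (-(dct[s] - ctrl_mean)) for s in samples}


def ols_closed_form(x, y) -> tuple[float, float]:
    """Normal-equation least squares: slope and intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return float(slope), float((sy - slope * sx) / n)


def hill_grid_search(pca, active, pca50_grid, n_grid) -> float:
    """Best RSS over a (pCa50, n_H) grid with the analytically optimal
    f_max for each shape."""
    pca = np.asarray(pca, float)
    active = np.asarray(active, float)
    best = np.inf
    for p50 in pca50_grid:
        for n in n_grid:
            g = 1.0 / (1.0 + 10.0 ** (n * (pca - p50)))
            denom = float(g @ g)
            if denom == 0:
                continue
            fmax = float(g @ active) / denom
            rss = float(np.sum((active - fmax * g) ** 2))
            best = min(best, rss)
    return best
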