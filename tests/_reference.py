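"""Naive, loop-everything reference implementations used as oracles.

These deliberately avoid the package's vectorised/compiled code paths: every
window is walked with explicit Python loops and medians are taken by sorting
Python lists.  They exist only to cross-check the production pipeline.
"""

from __future__ import annotations

import numpy as np


def lower_median(values):
    srt = sorted(values)
    return srt[(len(srt) - 1) // 2]


def mirror_pad_ref(plane, ms):
    """Reflect-without-edge padding via explicit index mapping."""
    n, m = plane.shape

    def reflect(i, size):
        # map any integer into [0, size) by reflecting across the borders
        while i < 0 or i >= size:
            if i < 0:
                i = -i
            if i >= size:
                i = 2 * (size - 1) - i
        return i

    out = np.empty((n + 2 * ms, m + 2 * ms), dtype=plane.dtype)
    for i in range(n + 2 * ms):
        for j in range(m + 2 * ms):
            out[i, j] = plane[reflect(i - ms, n), reflect(j - ms, m)]
    return out


def restore_pixel_ref(padded, maskp, r0, c0, sw1=7, sw2=5, b=((-1, 0), (1, 0), (0, -1), (0, 1))):
    """Literal per-pixel restoration: main window scan, per-neighbour
    secondary-window medians from the original plane, raster dilation with
    max/min alternation until fixpoint, then the lower median of the useful
    neighbourhood.  Returns (value, restored_flag)."""
    h1, h2 = sw1 // 2, sw2 // 2
    window = {}  # (i, j) local -> [value, state]; states: clean/stage1/stage2/noisy
    for i in range(sw1):
        for j in range(sw1):
            rr, cc = r0 + i - h1, c0 + j - h1
            if i == h1 and j == h1:
                window[(i, j)] = [int(padded[rr, cc]), "center"]
            elif not maskp[rr, cc]:
                window[(i, j)] = [int(padded[rr, cc]), "clean"]
            else:
                window[(i, j)] = [int(padded[rr, cc]), "noisy"]

    # nested (secondary window) pass, reading original data only
    for (i, j), cell in window.items():
        if cell[1] != "noisy":
            continue
        rr, cc = r0 + i - h1, c0 + j - h1
        candidates = []
        for di in range(-h2, h2 + 1):
            for dj in range(-h2, h2 + 1):
                if not maskp[rr + di, cc + dj]:
                    candidates.append(int(padded[rr + di, cc + dj]))
        if candidates:
            cell[0] = lower_median(candidates)
            cell[1] = "stage1"

    # dilation: raster passes until fixpoint, alternating max/min from max
    pick_max = True
    changed = True
    while changed:
        changed = False
        for i in range(sw1):
            for j in range(sw1):
                cell = window[(i, j)]
                if cell[1] != "noisy":
                    continue
                candidates = []
                for di, dj in b:
                    nb = window.get((i + di, j + dj))
                    if nb is not None and nb[1] in ("clean", "stage1", "stage2"):
                        candidates.append(nb[0])
                if candidates:
                    cell[0] = max(candidates) if pick_max else min(candidates)
                    cell[1] = "stage2"
                    pick_max = not pick_max
                    changed = True

    useful = [c[0] for pos, c in window.items() if c[1] in ("clean", "stage1", "stage2")]
    if not useful:
        return int(padded[r0, c0]), False
    return lower_median(useful), True


def denoise_ref(data, channel_mask, sw1=7, sw2=5):
    """Whole-image reference restoration (independent output buffer)."""
    ms = sw1 // 2 + sw2 // 2
    out = data.copy()
    for ch in range(3):
        padded = mirror_pad_ref(data[:, :, ch].astype(np.int64), ms)
        maskp = mirror_pad_ref(channel_mask[:, :, ch].astype(np.uint8), ms).astype(bool)
        rs, cs = np.nonzero(channel_mask[:, :, ch])
        for r, c in zip(rs, cs):
            value, _ = restore_pixel_ref(padded, maskp, r + ms, c + ms, sw1, sw2)
            out[r, c, ch] = value
    return out


def response_ref(plane, offsets, weights):
    """Brute-force |kernel * plane| with explicit mirror padding."""
    reach = max(max(abs(r), abs(c)) for r, c in offsets)
    padded = mirror_pad_ref(plane.astype(np.int64), reach)
    n, m = plane.shape
    out = np.zeros((n, m), dtype=np.int64)
    for i in range(n):
        for j in range(m):
            acc = 0
            for (dr, dc), w in zip(offsets, weights):
                acc += w * padded[i + reach + dr, j + reach + dc]
            out[i, j] = abs(acc)
    return out


def detect_ref(data, kernel_set, threshold=0, extremes=(0, 255)):
    """Literal two-round thresholding: per location, min over 24 responses,
    argmin tie-broken by kernel then channel, extreme-value gate."""
    n, m, _ = data.shape
    responses = {}
    for rnd, kernels in (("r1", kernel_set.first_round), ("r2", kernel_set.second_round)):
        for k in kernels:
            for j in range(3):
                responses[(rnd, k.index, j)] = response_ref(
                    data[:, :, j], k.offsets, k.weights
                )
    location = np.zeros((n, m), dtype=bool)
    for x in range(n):
        for y in range(m):
            jind = None
            for rnd, kernels in (("r1", kernel_set.first_round), ("r2", kernel_set.second_round)):
                vals = [
                    (int(responses[(rnd, k.index, j)][x, y]), k.index, j)
                    for k in kernels
                    for j in range(3)
                ]
                best = min(vals)  # lexicographic: value, kernel index, channel
                if best[0] > threshold:
                    jind = best[2]
                    break
            if jind is not None and int(data[x, y, jind]) in extremes:
                location[x, y] = True
    channel = location[:, :, None] & np.isin(data.astype(np.int64), np.asarray(extremes))
    return location, channel
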