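"""Compiled inner loop of the restoration pipeline.

The per-pixel work (build the main window, fill gaps by alternating-max/min
dilation, take the neighbourhood median) is branch-heavy and sequential
within a window, so it is JIT-compiled with numba; the stage-1 secondary
medians are precomputed once per channel (see ``restoration._stage1_maps``)
because they depend only on the original plane, never on the window they are
read from.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# position states inside a workspace
CLEAN = 0
STAGE1 = 1
STAGE2 = 2
UNRESTORED = 3


@njit(cache=False)
def restore_flagged(padded, maskp, s1val, s1ok, rows, cols, half1, b_off, start_max):
    """Restore every flagged pixel of one channel.

    Parameters are padded-plane coordinates: ``padded`` (int64), ``maskp``
    (bool), ``s1val``/``s1ok`` the precomputed secondary-window medians and
    their validity, ``rows``/``cols`` the flagged centres.  Returns the
    replacement values, a restored flag and per-pixel state counts
    (clean, stage1, stage2, degenerate) over the window excluding the centre.
    """
    npix = rows.shape[0]
    sw1 = 2 * half1 + 1
    out = np.empty(npix, dtype=np.int64)
    restored = np.zeros(npix, dtype=np.uint8)
    counts = np.zeros((npix, 4), dtype=np.int64)
    values = np.empty((sw1, sw1), dtype=np.int64)
    states = np.empty((sw1, sw1), dtype=np.uint8)
    buf = np.empty(sw1 * sw1, dtype=np.int64)

    for p in range(npix):
        r0 = rows[p]
        c0 = cols[p]
        # stage 0/1: original clean values, plus secondary-window medians for
        # noisy neighbours (computed from original data only)
        for i in range(sw1):
            for j in range(sw1):
                rr = r0 + i - half1
                cc = c0 + j - half1
                if not maskp[rr, cc]:
                    states[i, j] = CLEAN
                    values[i, j] = padded[rr, cc]
                elif s1ok[rr, cc]:
                    states[i, j] = STAGE1
                    values[i, j] = s1val[rr, cc]
                else:
                    states[i, j] = UNRESTORED
                    values[i, j] = padded[rr, cc]
        # the centre is the pixel under repair: never a candidate, never filled
        states[half1, half1] = UNRESTORED

        # stage 2: raster-scan dilation, alternating max/min, repeated until
        # fixpoint; freshly filled positions join the useful set immediately
        pick_max = start_max
        changed = True
        while changed:
            changed = False
            for i in range(sw1):
                for j in range(sw1):
                    if i == half1 and j == half1:
                        continue
                    if states[i, j] != UNRESTORED:
                        continue
                    has = False
                    best = 0
                    for k in range(b_off.shape[0]):
                        ni = i + b_off[k, 0]
                        nj = j + b_off[k, 1]
                        if ni < 0 or nj < 0 or ni >= sw1 or nj >= sw1:
                            continue
                        if states[ni, nj] == UNRESTORED:
                            continue
                        v = values[ni, nj]
                        if not has:
                            best = v
                            has = True
                        elif pick_max:
                            if v > best:
                                best = v
                        else:
                            if v < best:
                                best = v
                    if has:
                        values[i, j] = best
                        states[i, j] = STAGE2
                        pick_max = not pick_max
                        changed = True

        # final replacement: lower median of the useful neighbourhood
        nval = 0
        for i in range(sw1):
            for j in range(sw1):
                if i == half1 and j == half1:
                    continue
                s = states[i, j]
                if s == UNRESTORED:
                    counts[p, 3] += 1
                else:
                    counts[p, s] += 1
                    buf[nval] = values[i, j]
                    nval += 1
        if nval == 0:
            out[p] = padded[r0, c0]  # degenerate: keep the original value
            restored[p] = 0
        else:
            srt = np.sort(buf[:nval])
            out[p] = srt[(nval - 1) // 2]
            restored[p] = 1
    return out, restored, counts
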