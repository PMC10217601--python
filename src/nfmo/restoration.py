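"""Nested-window restoration of impulsive pixels.

For every flagged pixel the method repairs the *neighbourhood* before the
pixel itself:

1. a main window of side ``sw1`` (default 7) is centred on the pixel;
2. every noisy neighbour in that window is first estimated as the median of
   the non-noisy pixels inside its own secondary window of side ``sw2``
   (default 5), read from the original plane only;
3. neighbours the secondary window could not estimate (no clean pixel in
   reach) are filled by a morphological dilation: scanning the window left to
   right, top to bottom, each gap takes the maximum or minimum — alternating,
   starting with the maximum — of the useful values under a 4-connex
   structuring element, and immediately joins the useful set;  passes repeat
   until nothing changes;
4. the pixel is replaced by the lower median of its 48 reconstructed
   neighbours (the centre's own corrupted value never participates).

Windows never read values restored for *other* centres: replacements go to a
separate output buffer, so the result is independent of processing order and
each pixel can be repaired in parallel.

The pixel-level operations here are the plain, readable implementations; the
image-level :func:`denoise` delegates the per-pixel loop to the compiled
engine in :mod:`nfmo._engine`, which implements the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _engine
from .detection import NoiseMask
from .errors import ValidationError
from .imaging_io import ColorImage, mirror_pad, validate_image

# re-exported state codes
CLEAN = _engine.CLEAN
STAGE1 = _engine.STAGE1
STAGE2 = _engine.STAGE2
UNRESTORED = _engine.UNRESTORED

STATE_NAMES = {CLEAN: "clean", STAGE1: "stage1", STAGE2: "stage2", UNRESTORED: "unrestored"}

#: 4-connex structuring element (edge-adjacent neighbours; origin excluded)
FOUR_CONNEX = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class RestorationConfig:
    """Window sizes, structuring element and degenerate-pixel policy.

    ``sw1``/``sw2`` are the odd sides of the main and secondary windows; the
    mirror-pad size is Ms = floor(sw1/2) + floor(sw2/2), the furthest distance
    at which original data can influence a repair.  ``degenerate_policy``
    currently supports only ``"keep"``: a flagged pixel with no usable
    information anywhere in reach is left unchanged and counted.
    """

    sw1: int = 7
    sw2: int = 5
    structuring_element: tuple[tuple[int, int], ...] = FOUR_CONNEX
    degenerate_policy: str = "keep"

    def __post_init__(self) -> None:
        for name, sw in (("sw1", self.sw1), ("sw2", self.sw2)):
            if sw < 3 or sw % 2 == 0:
                raise ValidationError(f"{name} must be odd and >= 3, got {sw}")
        if (0, 0) in self.structuring_element:
            raise ValidationError("the structuring element must exclude the origin")
        if not self.structuring_element:
            raise ValidationError("the structuring element must be non-empty")
        if self.degenerate_policy != "keep":
            raise ValidationError(f"unknown degenerate policy {self.degenerate_policy!r}")

    @property
    def half1(self) -> int:
        return self.sw1 // 2

    @property
    def half2(self) -> int:
        return self.sw2 // 2

    @property
    def ms(self) -> int:
        """Mirror-pad size: floor(sw1/2) + floor(sw2/2)."""
        return self.sw1 // 2 + self.sw2 // 2


@dataclass
class AlternationState:
    """Max/min alternation of the dilation fill; starts at maximum and
    toggles after every successful replacement."""

    pick_max: bool = True

    def pick(self, candidates: list[int]) -> int:
        value = max(candidates) if self.pick_max else min(candidates)
        self.pick_max = not self.pick_max
        return value


@dataclass
class RestorationWorkspace:
    """The sw1 x sw1 working copy of one channel around a flagged pixel.

    ``center`` is the flagged pixel's position in *padded* plane coordinates.
    ``states`` holds one code per position; the centre starts (and stays)
    ``UNRESTORED`` — it is the pixel under repair, excluded from every count,
    candidate set and median.
    """

    values: np.ndarray
    states: np.ndarray
    center: tuple[int, int]
    config: RestorationConfig

    def state_counts(self) -> dict[str, int]:
        """Counts per state over the window, excluding the centre."""
        h = self.config.half1
        m = np.ones_like(self.states, dtype=bool)
        m[h, h] = False
        return {
            name: int(np.count_nonzero(self.states[m] == code))
            for code, name in STATE_NAMES.items()
        }

    @property
    def degenerate_positions(self) -> int:
        return self.state_counts()["unrestored"]


def _lower_median(values: np.ndarray) -> int:
    """Median with the lower-of-the-two convention for even counts, so the
    result is always an observed value."""
    srt = np.sort(np.asarray(values))
    return int(srt[(len(srt) - 1) // 2])


def build_workspace(
    channel_plane: np.ndarray,
    channel_mask: np.ndarray,
    center: tuple[int, int],
    config: RestorationConfig | None = None,
) -> RestorationWorkspace:
    """Copy the main window around ``center`` out of the padded plane.

    ``channel_plane`` and ``channel_mask`` must be mirror-padded by
    ``config.ms``; ``center`` is given in padded coordinates.
    """
    config = config or RestorationConfig()
    h = config.half1
    r, c = center
    if r - h < 0 or c - h < 0 or r + h >= channel_plane.shape[0] or c + h >= channel_plane.shape[1]:
        raise ValidationError(
            f"window around {center} exceeds the padded plane {channel_plane.shape}; "
            f"pad by at least Ms={config.ms}"
        )
    values = channel_plane[r - h : r + h + 1, c - h : c + h + 1].astype(np.int64)
    states = np.where(
        channel_mask[r - h : r + h + 1, c - h : c + h + 1], UNRESTORED, CLEAN
    ).astype(np.uint8)
    states[h, h] = UNRESTORED  # centre is the pixel under repair
    return RestorationWorkspace(values=values, states=states, center=(r, c), config=config)


def nested_restore(
    workspace: RestorationWorkspace,
    channel_plane: np.ndarray,
    channel_mask: np.ndarray,
    config: RestorationConfig | None = None,
) -> RestorationWorkspace:
    """Stage 1: estimate each noisy neighbour from its own secondary window.

    Candidates are the non-noisy pixels (per ``channel_mask``) inside the
    sw2 x sw2 window centred on the neighbour, read from the *original*
    padded plane; estimates produced for other centres in the same pass are
    never re-used.  Neighbours with an empty candidate set stay unrestored.
    """
    config = config or workspace.config
    h1, h2 = config.half1, config.half2
    r0, c0 = workspace.center
    for i in range(config.sw1):
        for j in range(config.sw1):
            if i == h1 and j == h1:
                continue
            if workspace.states[i, j] != UNRESTORED:
                continue
            rr = r0 + i - h1
            cc = c0 + j - h1
            win = channel_plane[rr - h2 : rr + h2 + 1, cc - h2 : cc + h2 + 1]
            wmask = channel_mask[rr - h2 : rr + h2 + 1, cc - h2 : cc + h2 + 1]
            clean = win[~wmask]
            if clean.size:
                workspace.values[i, j] = _lower_median(clean)
                workspace.states[i, j] = STAGE1
    return workspace


def dilate_fill(
    workspace: RestorationWorkspace, config: RestorationConfig | None = None
) -> RestorationWorkspace:
    """Stage 2: fill the remaining gaps by alternating-max/min dilation.

    Raster passes (left to right, top to bottom) repeat until a fixpoint;
    each filled position immediately joins the useful set.  Positions still
    unrestored afterwards are degenerate (this happens only when the whole
    window held no useful value at all).
    """
    config = config or workspace.config
    sw1, h = config.sw1, config.half1
    alternation = AlternationState()
    changed = True
    while changed:
        changed = False
        for i in range(sw1):
            for j in range(sw1):
                if i == h and j == h:
                    continue
                if workspace.states[i, j] != UNRESTORED:
                    continue
                candidates = []
                for dr, dc in config.structuring_element:
                    ni, nj = i + dr, j + dc
                    if 0 <= ni < sw1 and 0 <= nj < sw1 and workspace.states[ni, nj] != UNRESTORED:
                        candidates.append(int(workspace.values[ni, nj]))
                if candidates:
                    workspace.values[i, j] = alternation.pick(candidates)
                    workspace.states[i, j] = STAGE2
                    changed = True
    return workspace


def replace_center(workspace: RestorationWorkspace) -> int:
    """Final step: the lower median of the useful neighbour values.

    Degenerate positions (and the centre itself) are excluded; if every
    neighbour is degenerate the centre keeps its original value per the
    ``"keep"`` policy.
    """
    h = workspace.config.half1
    keep = np.ones_like(workspace.states, dtype=bool)
    keep[h, h] = False
    useful = keep & (workspace.states != UNRESTORED)
    if not useful.any():
        return int(workspace.values[h, h])
    return _lower_median(workspace.values[useful])


def restore_pixel(
    channel_plane: np.ndarray,
    channel_mask: np.ndarray,
    center: tuple[int, int],
    config: RestorationConfig | None = None,
) -> tuple[int, RestorationWorkspace]:
    """Run the full per-pixel pipeline on padded data; returns the
    replacement value and the finished workspace."""
    config = config or RestorationConfig()
    ws = build_workspace(channel_plane, channel_mask, center, config)
    nested_restore(ws, channel_plane, channel_mask, config)
    dilate_fill(ws, config)
    return replace_center(ws), ws


@dataclass
class RestorationReport:
    """Bookkeeping for one :func:`denoise` call (counts are over channel
    entries; window-position counts exclude centres)."""

    flagged: int = 0
    restored_centers: int = 0
    unrestored_centers: int = 0
    clean_positions: int = 0
    stage1_positions: int = 0
    stage2_positions: int = 0
    degenerate_positions: int = 0

    @property
    def degenerate_pixels(self) -> int:
        """Flagged pixels left unrestored (no information anywhere in reach)."""
        return self.unrestored_centers


def _stage1_maps(
    padded: np.ndarray, maskp: np.ndarray, half2: int
) -> tuple[np.ndarray, np.ndarray]:
    """Secondary-window medians for every position of the padded plane.

    The stage-1 estimate of a noisy position depends only on the original
    plane, so it is shared by every main window that contains the position.
    Returns (values, validity); positions closer than ``half2`` to the padded
    border are marked invalid (no main window ever reads them).
    """
    sw2 = 2 * half2 + 1
    wv = sliding_window_view(padded, (sw2, sw2)).reshape(-1, sw2 * sw2)
    wm = sliding_window_view(maskp, (sw2, sw2)).reshape(-1, sw2 * sw2)
    n_clean = (~wm).sum(axis=1)
    vals = np.where(wm, np.int64(1 << 30), wv)  # sentinel above any intensity
    vals.sort(axis=1)
    idx = np.maximum(n_clean - 1, 0) // 2
    med = vals[np.arange(vals.shape[0]), idx]
    core_shape = (padded.shape[0] - sw2 + 1, padded.shape[1] - sw2 + 1)
    s1val = np.zeros(padded.shape, dtype=np.int64)
    s1ok = np.zeros(padded.shape, dtype=bool)
    sl = (slice(half2, half2 + core_shape[0]), slice(half2, half2 + core_shape[1]))
    s1val[sl] = med.reshape(core_shape)
    s1ok[sl] = (n_clean > 0).reshape(core_shape)
    return s1val, s1ok


def denoise(
    image: ColorImage | np.ndarray,
    mask: NoiseMask,
    config: RestorationConfig | None = None,
) -> tuple[np.ndarray, RestorationReport]:
    """Repair every channel-flagged pixel of ``image``.

    ``mask`` is typically the detector's output, or the injection truth mask
    when the corruption locations are known exactly.  Unflagged entries pass
    through unchanged; replacements are written to a separate output buffer,
    so results do not depend on processing order.
    """
    config = config or RestorationConfig()
    data = image.data if isinstance(image, ColorImage) else image
    data = validate_image(data)
    if mask.channel.shape != data.shape:
        raise ValidationError(
            f"mask shape {mask.channel.shape} does not match image shape {data.shape}"
        )
    ms = config.ms
    b_off = np.asarray(config.structuring_element, dtype=np.int64)
    out = data.copy()
    report = RestorationReport()
    for ch in range(3):
        chmask = mask.channel[:, :, ch]
        rr, cc = np.nonzero(chmask)
        report.flagged += rr.size
        if rr.size == 0:
            continue
        padded = mirror_pad(data[:, :, ch].astype(np.int64), ms)
        maskp = np.pad(chmask, ms, mode="reflect")
        s1val, s1ok = _stage1_maps(padded, maskp, config.half2)
        vals, restored, counts = _engine.restore_flagged(
            padded,
            maskp,
            s1val,
            s1ok,
            (rr + ms).astype(np.int64),
            (cc + ms).astype(np.int64),
            config.half1,
            b_off,
            True,
        )
        out[rr, cc, ch] = vals.astype(np.uint8)
        report.restored_centers += int(restored.sum())
        report.unrestored_centers += int(rr.size - restored.sum())
        totals = counts.sum(axis=0)
        report.clean_positions += int(totals[CLEAN])
        report.stage1_positions += int(totals[STAGE1])
        report.stage2_positions += int(totals[STAGE2])
        report.degenerate_positions += int(totals[UNRESTORED])
    return out, report
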