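"""Seeded medical-like synthetic fixtures.

Real targets of this tool — retina fundus photographs, brain MRI slices,
chest X-rays exported as 8-bit rasters — are piecewise smooth, show repeated
texture, and often sit on a predominantly dark background.  The families here
emulate those traits one at a time so each pipeline stage can be tested with
exact ground truth and no external downloads:

- ``constant``: a flat mid-intensity field (pure detector/restorer algebra);
- ``gradient``: a smooth horizontal ramp (edge-free, extreme-free clean data);
- ``piecewise-constant``: random rectangular plateaus (organ-like regions);
- ``repeated-texture``: a tiled random patch (periodic anatomy, e.g. rib
  shadows or cortical folds);
- ``dark-background-disc``: a bright structured disc on a near-black ground
  (retina/X-ray layout).

Clean fixture intensities stay inside ``intensity_range`` (default 8..247):
well-exposed clean tissue rarely saturates the 8-bit range, and keeping clean
data off {0, 255} makes the injected impulses the only extremes in a fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .imaging_io import ColorImage
from .restoration import RestorationConfig

FAMILIES = (
    "constant",
    "gradient",
    "piecewise-constant",
    "repeated-texture",
    "dark-background-disc",
)


@dataclass
class FixtureSpec:
    """Family, size (rows, cols), seed and clean intensity range."""

    family: str
    size: tuple[int, int] = (256, 256)
    seed: int = 0
    intensity_range: tuple[int, int] = (8, 247)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown fixture family {self.family!r}; choose from {FAMILIES}"
            )
        lo, hi = self.intensity_range
        if not (0 <= lo < hi <= 255):
            raise ValidationError(f"invalid intensity range {self.intensity_range}")


def generate(spec: FixtureSpec) -> ColorImage:
    """Deterministically generate the requested fixture family."""
    n, m = spec.size
    lo, hi = spec.intensity_range
    rng = np.random.default_rng(spec.seed)
    if spec.family == "constant":
        data = np.full((n, m, 3), (lo + hi) // 2, dtype=np.uint8)
    elif spec.family == "gradient":
        row = np.round(np.linspace(lo, hi, m)).astype(np.uint8)
        data = np.repeat(np.tile(row, (n, 1))[:, :, None], 3, axis=2)
    elif spec.family == "piecewise-constant":
        data = np.full((n, m, 3), (lo + hi) // 2, dtype=np.uint8)
        for _ in range(12):
            r0, r1 = np.sort(rng.integers(0, n, size=2))
            c0, c1 = np.sort(rng.integers(0, m, size=2))
            data[r0 : r1 + 1, c0 : c1 + 1] = rng.integers(lo, hi + 1, size=3, dtype=np.uint8)
    elif spec.family == "repeated-texture":
        tile = rng.integers(lo, hi + 1, size=(8, 8, 3), dtype=np.uint8)
        reps = (-(-n // 8), -(-m // 8), 1)
        data = np.tile(tile, reps)[:n, :m, :]
    else:  # dark-background-disc
        background = rng.integers(2, 11, size=(n, m), dtype=np.uint8)
        rows, cols = np.indices((n, m))
        cy, cx = n / 2.0, m / 2.0
        radius = 0.38 * min(n, m)
        dist = np.sqrt((rows - cy) ** 2 + (cols - cx) ** 2)
        inside = dist <= radius
        # radial fall-off from hi at the centre to mid-range at the rim,
        # channel-weighted like a fundus photograph (red brightest)
        profile = hi - (hi - (lo + hi) / 2.0) * (dist / radius)
        data = np.repeat(background[:, :, None], 3, axis=2).astype(np.float64)
        for ch, weight in enumerate((1.0, 0.78, 0.52)):
            plane = data[:, :, ch]
            plane[inside] = profile[inside] * weight
        # a darker vessel-like annulus inside the disc for structure
        ring = inside & (np.abs(dist - 0.55 * radius) < 0.04 * min(n, m))
        data[ring] *= 0.45
        data = np.clip(np.round(data), 0, 255).astype(np.uint8)
    return ColorImage(data)


@dataclass
class WorkedExample:
    """A hand-built high-density neighbourhood for walking through the
    restoration stages.

    ``plane``/``mask`` form a small already-padded channel; the 7x7 main
    window around ``center`` contains exactly 3 clean positions among its 48
    neighbours, clustered in one corner so that nested filtering restores a
    strict subset of the noisy neighbours and the dilation fill completes the
    rest.  ``expected_counts`` is derived from the construction geometry
    (Chebyshev reach of the secondary window), not from running the pipeline.
    """

    plane: np.ndarray
    mask: np.ndarray
    center: tuple[int, int]
    config: RestorationConfig
    expected_counts: dict[str, int]


def make_worked_example() -> WorkedExample:
    """Build the 3-clean-of-48 neighbourhood described above."""
    config = RestorationConfig()
    size = 17
    center = (8, 8)
    clean_positions = {(5, 5): 231, (5, 6): 234, (6, 5): 228}
    plane = np.zeros((size, size), dtype=np.int64)  # impulses carry value 0
    mask = np.ones((size, size), dtype=bool)
    for (r, c), v in clean_positions.items():
        plane[r, c] = v
        mask[r, c] = False

    # expected stage counts from geometry: a noisy neighbour is restored in
    # stage 1 iff some clean pixel lies within its secondary window
    # (Chebyshev distance <= floor(sw2/2)); everything else is completed in
    # stage 2 because the useful set is non-empty and the window 4-connected.
    h1, h2 = config.half1, config.half2
    stage1 = 0
    total = 0
    for i in range(-h1, h1 + 1):
        for j in range(-h1, h1 + 1):
            if i == 0 and j == 0:
                continue
            total += 1
            pos = (center[0] + i, center[1] + j)
            if pos in clean_positions:
                continue
            if any(
                max(abs(pos[0] - cr), abs(pos[1] - cc)) <= h2
                for cr, cc in clean_positions
            ):
                stage1 += 1
    expected = {
        "clean": len(clean_positions),
        "stage1": stage1,
        "stage2": total - len(clean_positions) - stage1,
        "unrestored": 0,
    }
    return WorkedExample(plane, mask, center, config, expected)
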