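"""Directional modified-Laplacian kernels for impulse detection.

The detector measures local intensity variation with 16 zero-sum directional
second-derivative stencils, rotated in steps of pi/8.  The first eight (K1-K8)
probe the immediate neighbourhood; the second eight (K9-K16) ignore the eight
pixels adjacent to the centre, so that a pair of connected impulses with equal
extreme values cannot hide from the detector in round one and escape round two
as well.

The default coefficients are a documented stand-in with the required
properties (zero response on constant input, strictly positive centre weight,
negative weights elsewhere, ring-1 exclusion in the second round); a published
coefficient set can be substituted through :func:`load_kernel_file`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError, ValidationError

Offset = tuple[int, int]


@dataclass(frozen=True)
class Kernel:
    """One directional second-derivative stencil.

    ``offsets[k]`` is the (row, col) displacement carrying integer weight
    ``weights[k]``.  ``angle`` is the nominal probing direction in radians
    (a multiple of pi/8).
    """

    index: int
    angle: float
    offsets: tuple[Offset, ...]
    weights: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.weights):
            raise ValidationError("offsets and weights must have equal length")
        if sum(self.weights) != 0:
            raise ValidationError(
                f"kernel K{self.index}: coefficients must sum to zero "
                f"(got {sum(self.weights)})"
            )
        try:
            centre = self.offsets.index((0, 0))
        except ValueError:
            raise ValidationError(f"kernel K{self.index}: centre offset (0,0) missing") from None
        if self.weights[centre] <= 0:
            raise ValidationError(f"kernel K{self.index}: centre weight must be positive")
        for off, w in zip(self.offsets, self.weights):
            if off != (0, 0) and w >= 0:
                raise ValidationError(
                    f"kernel K{self.index}: non-centre weight at {off} must be negative"
                )

    @property
    def reach(self) -> int:
        """Chebyshev radius of the support."""
        return max(max(abs(r), abs(c)) for r, c in self.offsets)

    def touches_ring1(self) -> bool:
        """True if any support offset lies in the 8-connected ring around the centre."""
        return any(max(abs(r), abs(c)) == 1 for r, c in self.offsets)


@dataclass(frozen=True)
class KernelSet:
    """The two detection rounds: K1-K8 (ring 1) and K9-K16 (ring 2 only)."""

    first_round: tuple[Kernel, ...]
    second_round: tuple[Kernel, ...]

    def __post_init__(self) -> None:
        if len(self.first_round) != 8 or len(self.second_round) != 8:
            raise ValidationError("each detection round requires exactly 8 kernels")
        for k in self.second_round:
            if k.touches_ring1():
                raise ValidationError(
                    f"kernel K{k.index}: second-round kernels must not touch the "
                    "8-connected ring adjacent to the centre"
                )

    @property
    def all_kernels(self) -> tuple[Kernel, ...]:
        return self.first_round + self.second_round

    @property
    def reach(self) -> int:
        return max(k.reach for k in self.all_kernels)


def _stencil(index: int, angle: float, v: Offset) -> Kernel:
    """Three-point second derivative along lattice direction ``v``:
    +2 at the centre, -1 at +v and -v."""
    vr, vc = v
    return Kernel(
        index=index,
        angle=angle,
        offsets=((0, 0), (vr, vc), (-vr, -vc)),
        weights=(2, -1, -1),
    )


# probing directions; angles are the nominal multiples of pi/8 per round
_RING1_AXIS = [(0, 1), (1, 1), (1, 0), (1, -1)]       # 0, pi/4, pi/2, 3pi/4
_KNIGHT = [(1, 2), (2, 1), (2, -1), (1, -2)]          # pi/8 family (ring-2 offsets)
_RING2_AXIS = [(0, 2), (2, 2), (2, 0), (2, -2)]       # doubled axis/diagonal


def build_default_kernels() -> KernelSet:
    """Construct the default 16-kernel set.

    First round: K1-K4 along the axis/diagonal directions at angles
    0, pi/4, pi/2, 3pi/4 and K5-K8 along the knight directions for the
    pi/8 family.  Second round: K9-K12 use the doubled axis/diagonal offsets
    and K13-K16 reuse the knight offsets at their native ring-2 positions, so
    no second-round kernel touches the 8-connected ring.
    """
    first = [
        _stencil(i + 1, i * math.pi / 4, v) for i, v in enumerate(_RING1_AXIS)
    ] + [
        _stencil(i + 5, (2 * i + 1) * math.pi / 8, v) for i, v in enumerate(_KNIGHT)
    ]
    second = [
        _stencil(i + 9, i * math.pi / 4, v) for i, v in enumerate(_RING2_AXIS)
    ] + [
        _stencil(i + 13, (2 * i + 1) * math.pi / 8, v) for i, v in enumerate(_KNIGHT)
    ]
    return KernelSet(tuple(first), tuple(second))


def load_kernel_file(path: str | Path) -> KernelSet:
    """Parse a plain-text kernel override file into a :class:`KernelSet`.

    Format: 16 blank-line-separated blocks, one kernel per block, each line an
    ``offset_row offset_col weight`` triplet.  The first eight blocks form the
    first detection round.  Structural violations (non-zero sum, missing
    centre, ring-1 support in the second round) raise
    :class:`~nfmo.errors.ConfigurationError`.
    """
    text = Path(path).read_text()
    blocks: list[list[str]] = [[]]
    for line in text.splitlines():
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            if blocks[-1]:
                blocks.append([])
            continue
        blocks[-1].append(stripped)
    if blocks and not blocks[-1]:
        blocks.pop()
    if len(blocks) != 16:
        raise ConfigurationError(
            f"{path}: expected 16 kernel blocks, found {len(blocks)}"
        )
    kernels: list[Kernel] = []
    for idx, block in enumerate(blocks, start=1):
        offsets: list[Offset] = []
        weights: list[int] = []
        for line in block:
            parts = line.split()
            if len(parts) != 3:
                raise ConfigurationError(
                    f"{path}: kernel K{idx}: expected 'row col weight', got {line!r}"
                )
            try:
                r, c, w = (int(p) for p in parts)
            except ValueError as exc:
                raise ConfigurationError(
                    f"{path}: kernel K{idx}: non-integer entry in {line!r}"
                ) from exc
            offsets.append((r, c))
            weights.append(w)
        angle = ((idx - 1) % 8) * math.pi / 8
        try:
            kernels.append(Kernel(idx, angle, tuple(offsets), tuple(weights)))
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc
    try:
        return KernelSet(tuple(kernels[:8]), tuple(kernels[8:]))
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
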