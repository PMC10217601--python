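"""Seeded salt-and-pepper corruption with ground-truth masks.

The default corruption model is channel-independent: every (location, channel)
entry is hit with probability ``density``, and a hit is driven to 255 (salt)
with probability ``salt_fraction``, else to 0 (pepper).  A coupled mode
(``per_channel=False``) corrupts all three channels of a chosen location
together — the polarity of each channel remains independent — which models
transmission errors that destroy whole pixels rather than single planes.

Randomness comes from :class:`numpy.random.Generator` seeded with
``NoiseSpec.seed`` (PCG64, ``rng_algorithm`` records this), so a spec
regenerates bit-identical output across runs and releases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import NoiseMask
from .errors import ValidationError
from .imaging_io import ColorImage, validate_image

#: RNG family used by :func:`inject`; recorded so results stay reproducible
#: across releases.
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass
class NoiseSpec:
    """Corruption parameters: density d in [0, 1], salt fraction, seed, mode."""

    density: float
    salt_fraction: float = 0.5
    seed: int = 0
    per_channel: bool = True
    rng_algorithm: str = RNG_ALGORITHM

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValidationError(f"density must lie in [0, 1], got {self.density}")
        if not 0.0 <= self.salt_fraction <= 1.0:
            raise ValidationError(
                f"salt fraction must lie in [0, 1], got {self.salt_fraction}"
            )


def inject(image: ColorImage | np.ndarray, spec: NoiseSpec) -> tuple[np.ndarray, NoiseMask]:
    """Corrupt ``image`` per ``spec``; return the noisy copy and the truth mask.

    The truth mask records exactly the corrupted entries, including impulses
    whose extreme value happens to coincide with the original pixel value.
    """
    data = image.data if isinstance(image, ColorImage) else image
    data = validate_image(data)
    n, m, _ = data.shape
    rng = np.random.default_rng(spec.seed)
    if spec.per_channel:
        hit = rng.random((n, m, 3)) < spec.density
    else:
        hit = np.repeat((rng.random((n, m)) < spec.density)[:, :, None], 3, axis=2)
    salt = rng.random((n, m, 3)) < spec.salt_fraction
    noisy = data.copy()
    noisy[hit & salt] = 255
    noisy[hit & ~salt] = 0
    location = hit.any(axis=2)
    return noisy, NoiseMask(location=location, channel=hit)
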