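"""In-memory container for one fluorescence channel."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError

CHANNEL_ROLES = ("surface", "internal", "nuclear")


@dataclass
class FluorescenceImage:
    """One 2-D grid of non-negative intensities with a channel role.

    ``channel_role`` declares what the channel stains: the cell-surface
    DN stain, the internalized DN stain, or the nuclear counterstain.
    Operations that are only meaningful for one role refuse other roles,
    so surface and internalized intensities (different fluorophores) are
    never mixed in a single sum. ``pixel_size_nm`` is optional metadata.
    """

    pixels: np.ndarray
    channel_role: str
    pixel_size_nm: float | None = None

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.ndim != 2 or pixels.size == 0:
            raise InvalidInputError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(pixels)):
            raise InvalidInputError("pixel intensities must be finite")
        if pixels.min() < 0:
            raise InvalidInputError("pixel intensities must be >= 0")
        if self.channel_role not in CHANNEL_ROLES:
            raise InvalidParameterError(
                f"channel_role must be one of {CHANNEL_ROLES}"
            )
        if self.pixel_size_nm is not None and not self.pixel_size_nm > 0:
            raise InvalidParameterError("pixel_size_nm must be > 0")
        self.pixels = pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "FluorescenceImage":
        """Copy of this image with new pixel data, same role and metadata."""
        return FluorescenceImage(pixels, self.channel_role, self.pixel_size_nm)


def require_role(image: FluorescenceImage, role: str) -> None:
    """Raise unless ``image`` carries the expected channel role."""
    if image.channel_role != role:
        raise InvalidParameterError(
            f"expected a {role!r} channel, got {image.channel_role!r}"
        )
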