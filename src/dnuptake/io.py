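"""Config and image IO: YAML/JSON configs, single/multi-page TIFF channels."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .exceptions import InvalidInputError
from .image import FluorescenceImage

__all__ = ["load_config", "read_channel", "write_channel"]


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file by extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_channel(
    path,
    channel_role: str,
    channel_index: int | None = None,
    pixel_size_nm: float | None = None,
) -> FluorescenceImage:
    """Read one channel from a TIFF file.

    2-D files are used directly; for multi-page/multi-channel stacks
    ``channel_index`` selects the page along the first axis.
    """
    data = np.asarray(tifffile.imread(str(path)))
    if data.ndim == 3:
        if channel_index is None:
            raise InvalidInputError(
                f"{path}: multi-channel TIFF requires channel_index"
            )
        data = data[channel_index]
    elif data.ndim != 2:
        raise InvalidInputError(f"{path}: expected a 2-D or 3-D TIFF")
    return FluorescenceImage(data.astype(float), channel_role, pixel_size_nm)


def write_channel(path, pixels: np.ndarray) -> None:
    """Write one 2-D intensity grid as a float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(pixels, dtype=np.float32))
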