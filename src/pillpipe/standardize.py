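"""Standardize a detected pill into the classifier's square input.

The detection's rectangular box is cropped as-is — the predicted mask is
*not* used to cut out the contour, so the background texture and its lighting
context stay in the crop.  The shorter side is padded symmetrically to a
square (extra pixel on the bottom/right for odd remainders) and the result is
resized to 224x224 with bilinear interpolation, preserving the pill's aspect
ratio exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .errors import InvalidArgument


@dataclass
class StandardizedCrop:
    image: np.ndarray                       # (out, out, 3) uint8
    source_box: tuple[int, int, int, int]   # clamped half-open box
    scale: float                            # padded-square -> output factor
    pad: tuple[int, int, int, int]          # (top, bottom, left, right), px


def crop_pad_resize(image: np.ndarray, box, out_size: int = 224,
                    pad_mode: str = "edge", fill=(0, 0, 0)) -> StandardizedCrop:
    """Crop ``box`` from ``image``, pad to square, resize to ``out_size``.

    ``pad_mode`` is ``'edge'`` (replicate border pixels; default) or
    ``'constant'`` with ``fill``.  Boxes partially outside the image are
    clamped first; a zero-area box after clamping is an error.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InvalidArgument("image must be H x W x 3")
    r0, c0, r1, c1 = (int(v) for v in box)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, image.shape[0]), min(c1, image.shape[1])
    if r1 <= r0 or c1 <= c0:
        raise InvalidArgument(f"degenerate box after clamping: {box}")
    crop = image[r0:r1, c0:c1]
    h, w = crop.shape[:2]
    side = max(h, w)
    pad_v, pad_h = side - h, side - w
    top, left = pad_v // 2, pad_h // 2
    pads = (top, pad_v - top, left, pad_h - left)
    if pad_v or pad_h:
        spec = ((pads[0], pads[1]), (pads[2], pads[3]), (0, 0))
        if pad_mode == "edge":
            crop = np.pad(crop, spec, mode="edge")
        else:
            crop = np.stack([np.pad(crop[:, :, ch], spec[:2], mode="constant",
                                    constant_values=fill[ch]) for ch in range(3)],
                            axis=2)
    out = np.asarray(Image.fromarray(crop.astype(np.uint8))
                     .resize((out_size, out_size), Image.BILINEAR))
    return StandardizedCrop(image=out, source_box=(r0, c0, r1, c1),
                            scale=out_size / side, pad=pads)
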