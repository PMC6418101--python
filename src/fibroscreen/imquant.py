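"""Well-image quantification: the D×A/nuclei ASMA score.

A well's myofibroblast readout is summarised as staining density D (mean
ASMA intensity over the suprathreshold stain area), stained area A
(suprathreshold pixel count) and nucleus count N from the DAPI channel;
the score is S = D*A/N, i.e. integrated suprathreshold ASMA intensity per
nucleus.  Quantification is per-field; no per-cell assignment is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from skimage import measure
from skimage.filters import threshold_otsu


class ImageError(ValueError):
    """Raised for malformed image inputs."""


@dataclass(frozen=True)
class QuantParams:
    """Thresholding and filtering parameters for well quantification.

    ``*_threshold_method`` is "otsu" (data-driven, default) or "fixed" (uses
    the corresponding fixed threshold in AU).  Components smaller than
    ``min_nucleus_area`` pixels are discarded as debris.
    """

    dapi_threshold_method: str = "otsu"
    asma_threshold_method: str = "otsu"
    dapi_threshold: float = 0.0
    asma_threshold: float = 0.0
    min_nucleus_area: int = 9
    bit_depth: int = 16

    def validate(self) -> None:
        for m in (self.dapi_threshold_method, self.asma_threshold_method):
            if m not in ("otsu", "fixed"):
                raise ImageError(f"unknown threshold method {m!r}")
        if self.min_nucleus_area < 1:
            raise ImageError("min_nucleus_area must be >= 1")
        vmax = 2 ** self.bit_depth - 1
        for t in (self.dapi_threshold, self.asma_threshold):
            if not 0 <= t <= vmax:
                raise ImageError(f"fixed threshold {t} outside bit depth range")


@dataclass(frozen=True)
class WellQuant:
    """One well's quantified readout.

    score is D*A/N and is undefined (None) when no nuclei are detected;
    such wells are excluded from downstream statistics.
    """

    density: float
    area: int
    nuclei: int
    score: float | None

    @property
    def defined(self) -> bool:
        return self.score is not None


def _threshold(channel: np.ndarray, method: str, fixed: float) -> float | None:
    """Resolve a channel threshold; None means nothing can exceed it."""
    if method == "fixed":
        return fixed
    flat = channel.ravel()
    if flat.min() == flat.max():
        # constant image: no foreground distinguishable (documented degenerate
        # case, returns an unsatisfiable threshold rather than erroring)
        return None
    return float(threshold_otsu(channel))


def segment_nuclei(
    dapi: np.ndarray, params: QuantParams = QuantParams()
) -> tuple[int, np.ndarray]:
    """Count DAPI-positive nuclei by threshold + connected components.

    Thresholds the channel (Otsu by default), labels 8-connected components,
    and discards components below ``params.min_nucleus_area``.  Touching
    nuclei merge into one component; under-segmentation is accepted
    behaviour.  Returns ``(count, label_mask)``.
    """
    params.validate()
    dapi = np.asarray(dapi, dtype=float)
    if dapi.size == 0:
        raise ImageError("empty DAPI channel")
    if dapi.ndim != 2:
        raise ImageError(f"expected a 2-D channel, got shape {dapi.shape}")
    if not np.all(np.isfinite(dapi)):
        raise ImageError("non-finite pixel values in DAPI channel")

    thr = _threshold(dapi, params.dapi_threshold_method, params.dapi_threshold)
    if thr is None:
        return 0, np.zeros(dapi.shape, dtype=np.int32)
    fg = dapi > thr
    labels = measure.label(fg, connectivity=2)
    if params.min_nucleus_area > 1 and labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < params.min_nucleus_area)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
    labels, count = measure.label(labels > 0, connectivity=2, return_num=True)
    return count, labels.astype(np.int32)


def quantify_asma(
    image_pair: np.ndarray, params: QuantParams = QuantParams()
) -> WellQuant:
    """Quantify a registered (DAPI, ASMA) stack into a WellQuant.

    A = ASMA pixels above threshold; D = mean ASMA intensity over those
    pixels (0 if A = 0); N = nucleus count from :func:`segment_nuclei`;
    S = D*A/N when N > 0, else undefined.
    """
    image_pair = np.asarray(image_pair, dtype=float)
    if image_pair.ndim != 3 or image_pair.shape[0] != 2:
        raise ImageError(
            f"expected a (2, H, W) stack (DAPI, ASMA), got shape {image_pair.shape}"
        )
    dapi, asma = image_pair
    if dapi.shape != asma.shape:
        raise ImageError("channel shape mismatch")

    n, _ = segment_nuclei(dapi, params)

    thr = _threshold(asma, params.asma_threshold_method, params.asma_threshold)
    if thr is None:
        area, density = 0, 0.0
    else:
        mask = asma > thr
        area = int(mask.sum())
        density = float(asma[mask].mean()) if area > 0 else 0.0

    score = density * area / n if n > 0 else None
    if n > 0 and area == 0:
        score = 0.0
    return WellQuant(density=density, area=area, nuclei=n, score=score)


def read_image(path) -> np.ndarray:
    """Read a two-channel TIFF stack (channel order DAPI, ASMA)."""
    arr = tifffile.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ImageError(f"{path}: expected a 2-page stack, got shape {arr.shape}")
    return arr


def write_image(path, stack: np.ndarray) -> None:
    """Write a (2, H, W) stack as a 16-bit multi-page TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ImageError(f"expected a (2, H, W) stack, got shape {stack.shape}")
    tifffile.imwrite(path, stack.astype(np.uint16))
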