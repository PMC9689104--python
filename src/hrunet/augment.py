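"""Training-time augmentation: the general six-transform set (GIA) and
cropped-blood-vessel augmentation (CBVIA).

GIA maps each image/label pair to six geometric variants — identity,
horizontal flip, vertical flip, 180-degree rotation, and +/-30-degree
rotations — with the label undergoing the identical transform.  CBVIA
multiplies the image by its binary vessel mask (the "cropped blood
vessel", CBV) and adds the CBV image plus its vertical flip, encoding
the anatomical prior that plaque only occurs inside the artery.  Per
original sample the training pool therefore grows eightfold (6 + 2).

These transforms are train-only; evaluation always sees original,
un-augmented images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentedPair", "general_augment", "crop_blood_vessel",
           "cbv_augment", "build_training_set", "GIA_TAGS", "CBV_TAGS"]

GIA_TAGS = ("identity", "H", "V", "R180", "R+30", "R-30")
CBV_TAGS = ("CV", "V∘CV")


@dataclass(frozen=True)
class AugmentedPair:
    image: np.ndarray      # float grid, same shape as label
    label: np.ndarray      # binary {0,1}
    provenance: str        # one of GIA_TAGS + CBV_TAGS

    def __post_init__(self):
        if self.image.shape != self.label.shape:
            raise ValueError("image and label dimensions must match")


def _check_aligned(image: np.ndarray, label: np.ndarray) -> None:
    if image.shape != label.shape:
        raise ValueError(f"image/label shape mismatch: {image.shape} vs {label.shape}")


def _check_binary(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1, found values {vals[:8]}")
    return mask


def _rotate(image: np.ndarray, angle: float, is_label: bool) -> np.ndarray:
    """Rotate about the image center, canvas kept, corners filled with 0.

    Bilinear for intensity images; nearest for labels, re-binarized at
    0.5 so rotated labels stay strictly {0,1}.
    """
    order = 0 if is_label else 1
    out = ndimage.rotate(image.astype(np.float32), angle, reshape=False,
                         order=order, mode="constant", cval=0.0)
    if is_label:
        return (out >= 0.5).astype(image.dtype)
    return out.astype(np.float32)


def _transform(arr: np.ndarray, tag: str, is_label: bool) -> np.ndarray:
    if tag == "identity":
        return arr.copy()
    if tag == "H":
        return arr[:, ::-1].copy()
    if tag == "V":
        return arr[::-1, :].copy()
    if tag == "R180":
        return arr[::-1, ::-1].copy()
    if tag == "R+30":
        return _rotate(arr, +30.0, is_label)
    if tag == "R-30":
        return _rotate(arr, -30.0, is_label)
    raise ValueError(f"unknown transform tag {tag!r}")


def general_augment(image: np.ndarray, label: np.ndarray) -> list[AugmentedPair]:
    """The six-variant general augmentation of one image/label pair."""
    _check_aligned(image, label)
    _check_binary(label, "label")
    return [AugmentedPair(_transform(image, t, is_label=False),
                          _transform(label, t, is_label=True), t)
            for t in GIA_TAGS]


def crop_blood_vessel(image: np.ndarray, vessel_mask: np.ndarray) -> np.ndarray:
    """Elementwise product of image and binary vessel mask (the CBV image)."""
    _check_aligned(image, vessel_mask)
    vessel_mask = _check_binary(vessel_mask, "vessel_mask")
    return (image * vessel_mask).astype(np.float32)


def cbv_augment(image: np.ndarray, label: np.ndarray,
                vessel_mask: np.ndarray) -> list[AugmentedPair]:
    """CBV image with the original label, plus their vertical flips.

    The plaque label must lie inside the vessel mask; masking the image
    then cannot orphan any label pixel, so the label is reused unchanged
    rather than clipped.
    """
    _check_aligned(image, label)
    label = _check_binary(label, "label")
    vessel_mask = _check_binary(vessel_mask, "vessel_mask")
    if np.any(label.astype(bool) & ~vessel_mask.astype(bool)):
        raise ValueError("plaque label has pixels outside the vessel mask")
    cv = crop_blood_vessel(image, vessel_mask)
    return [
        AugmentedPair(cv, label.copy(), "CV"),
        AugmentedPair(cv[::-1, :].copy(), label[::-1, :].copy(), "V∘CV"),
    ]


def build_training_set(samples) -> list[AugmentedPair]:
    """Full training pool: 6 GIA + 2 CBVIA pairs per original sample.

    ``samples`` is an iterable of objects with ``image``, ``plaque_mask``
    and ``vessel_mask`` attributes (e.g. PhantomSample), or
    (image, plaque_mask, vessel_mask) triplets.
    """
    out: list[AugmentedPair] = []
    for s in samples:
        if hasattr(s, "image"):
            img, lab, ves = s.image, s.plaque_mask, s.vessel_mask
        else:
            img, lab, ves = s
        out.extend(general_augment(img, lab))
        out.extend(cbv_augment(img, lab, ves))
    return out
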