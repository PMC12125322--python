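"""Marker quantification of stained TMA spot images.

Deterministic classical operators (Beer-Lambert stain separation,
threshold + morphology segmentation) with the same output contract the
classifier consumes: a continuous staining intensity on the 0-3 scale,
its rounded integer score, and the percentage of the relevant cellular
compartment that stains positive.  Marker conventions:

=========  ====================  =========================
marker     compartment           scores reported
=========  ====================  =========================
CDX2       nuclear, epithelium   intensity + percent
FRMD6      cytoplasm, epithelium intensity + percent
HTR2B      cytoplasm, epithelium intensity only
ZEB1       nuclear, epithelium   percent only (presence)
KER        cytoplasm             intensity + percent
BCAT       nuclear               intensity + percent
=========  ====================  =========================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import DAB_OD_PER_UNIT, STAIN_DAB, STAIN_HEMATOXYLIN

__all__ = [
    "QuantResult",
    "EmptyMaskError",
    "separate_stains",
    "segment_epithelium",
    "score_intensity",
    "round_intensity",
    "percent_positive",
    "quantify_spot",
    "POSITIVITY_OD",
]

#: Markers whose percentage / intensity is reported (see module table).
MARKER_CONVENTIONS = {
    "CDX2": {"intensity": True, "percent": True},
    "FRMD6": {"intensity": True, "percent": True},
    "HTR2B": {"intensity": True, "percent": False},
    "ZEB1": {"intensity": False, "percent": True},
    "KER": {"intensity": True, "percent": True},
    "BCAT": {"intensity": True, "percent": True},
}

#: DAB optical density above which a pixel counts as positively stained.
POSITIVITY_OD = 0.12

#: Hematoxylin OD threshold separating epithelium from other tissue.
_EPITHELIUM_OD = 0.45


class EmptyMaskError(ValueError):
    """No-tissue signal: a score was requested over an empty compartment."""


@dataclass(frozen=True)
class QuantResult:
    """Scores for one spot/marker image.

    Fields irrelevant for the marker's convention are ``None``.
    """

    marker: str
    continuous_intensity: float | None
    rounded_intensity: int | None
    percent_positive: float | None
    area_analyzed: int

    def __post_init__(self):
        if self.continuous_intensity is not None:
            expect = round_intensity(self.continuous_intensity)
            if self.rounded_intensity != expect:
                raise ValueError("rounded_intensity inconsistent with continuous value")
        if self.percent_positive is not None and not (
            0.0 <= self.percent_positive <= 100.0
        ):
            raise ValueError("percent_positive outside [0,100]")


def separate_stains(image, stain_vectors=None):
    """Decompose an 8-bit RGB image into hematoxylin and DAB density maps.

    Inverts the two-stain Beer-Lambert model: per-pixel optical density
    ``OD = -log10(I/255)`` is solved in least squares against the two
    stain OD vectors; densities are clipped at zero.
    """
    if stain_vectors is None:
        stain_vectors = (STAIN_HEMATOXYLIN, STAIN_DAB)
    h_vec, d_vec = (np.asarray(v, float) for v in stain_vectors)
    if np.linalg.norm(np.cross(h_vec, d_vec)) < 1e-8:
        raise ValueError("stain vectors are collinear")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.size == 0:
        raise ValueError("expected a nonempty HxWx3 image")
    od = -np.log10(np.maximum(image.astype(float), 1.0) / 255.0)
    basis = np.stack([h_vec, d_vec], axis=1)  # 3x2
    sol, *_ = np.linalg.lstsq(basis, od.reshape(-1, 3).T, rcond=None)
    dens = np.clip(sol.T.reshape(image.shape[0], image.shape[1], 2), 0.0, None)
    return dens[..., 0], dens[..., 1]


def segment_epithelium(image, stain_vectors=None):
    """Binary epithelium mask from stain densities (threshold + morphology).

    Epithelial regions carry dense hematoxylin; DAB-positive epithelium
    may mask the hematoxylin signal, so pixels above the DAB positivity
    threshold are also included.  Deterministic; may return an empty
    mask on background-only images.
    """
    h_map, d_map = separate_stains(image, stain_vectors)
    raw = (h_map > _EPITHELIUM_OD) | (d_map > POSITIVITY_OD)
    footprint = ndimage.generate_binary_structure(2, 2)
    mask = ndimage.binary_closing(raw, footprint, iterations=2)
    mask = ndimage.binary_opening(mask, footprint, iterations=2)
    # drop specks (noise-induced components)
    labels, nlab = ndimage.label(mask)
    if nlab:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, nlab + 1))
        keep = np.flatnonzero(sizes >= 32) + 1
        mask = np.isin(labels, keep)
    return mask


def score_intensity(dab_map, mask, calibration=DAB_OD_PER_UNIT,
                    positivity_od=POSITIVITY_OD):
    """Mean DAB optical density over positive masked pixels, on the 0-3 scale.

    The mean is taken over positive pixels only (density above the
    positivity threshold), so intensity and percent positive stay
    independent; the monotone calibration divides by the density of one
    intensity unit and clips to [0, 3].  Returns 0.0 when no pixel in
    the compartment is positive.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("empty compartment mask")
    vals = np.asarray(dab_map, float)[mask]
    pos = vals[vals > positivity_od]
    if pos.size == 0:
        return 0.0
    return float(np.clip(pos.mean() / calibration, 0.0, 3.0))


def round_intensity(x):
    """Round a continuous 0-3 intensity to the integer score.

    Intervals: [0, 0.5) -> 0, [0.5, 1.5) -> 1, [1.5, 2.5) -> 2,
    [2.5, 3] -> 3.  Values outside [0, 3] are a domain error.
    """
    x = float(x)
    if not 0.0 <= x <= 3.0:
        raise ValueError(f"intensity {x!r} outside [0, 3]")
    return int(min(np.floor(x + 0.5), 3))


def percent_positive(dab_map, compartment_mask, positivity_od=POSITIVITY_OD):
    """Percentage of the compartment whose DAB density exceeds the threshold."""
    mask = np.asarray(compartment_mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("empty compartment mask")
    vals = np.asarray(dab_map, float)[mask]
    return float(100.0 * np.count_nonzero(vals > positivity_od) / vals.size)


def quantify_spot(image, marker, stain_vectors=None, mask=None):
    """Full quantification of one spot image for one marker.

    Segments the epithelial compartment (unless ``mask`` is supplied),
    separates stains, and reports the scores the marker's convention
    calls for as a :class:`QuantResult`.
    """
    marker = str(marker).upper()
    if marker not in MARKER_CONVENTIONS:
        raise ValueError(f"unknown marker {marker!r}")
    _, d_map = separate_stains(image, stain_vectors)
    if mask is None:
        mask = segment_epithelium(image, stain_vectors)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise EmptyMaskError("no tissue found in spot")
    conv = MARKER_CONVENTIONS[marker]
    cont = rounded = pct = None
    if conv["intensity"]:
        cont = score_intensity(d_map, mask)
        rounded = round_intensity(cont)
    if conv["percent"]:
        pct = percent_positive(d_map, mask)
    return QuantResult(
        marker=marker,
        continuous_intensity=cont,
        rounded_intensity=rounded,
        percent_positive=pct,
        area_analyzed=int(mask.sum()),
    )
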