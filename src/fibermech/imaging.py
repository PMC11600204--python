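"""Synthetic microscope frames of the sensing-probe tip and Harris-corner
deflection tracking.

The real readout films the probe from above and localises the tip corner
with Harris corner detection; the deflection enters the force calculation
as an integral number of pixels.  This module renders a minimal stand-in
frame — a dark probe silhouette on a bright background with a distinct
tip corner — and recovers the integer-pixel horizontal displacement of
that corner against a zero-deflection reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import corner_harris, corner_peaks, corner_subpix

__all__ = ["FrameSpec", "render_probe_frame", "detect_tip", "DetectionFailure"]


class DetectionFailure(RuntimeError):
    """No corner above the response threshold near the reference row."""


@dataclass(frozen=True)
class FrameSpec:
    """Synthetic frame geometry and rendering parameters.

    The probe runs vertically from the top edge down to ``tip_row``; its
    left edge sits at ``reference_col`` plus the deflection.  Intensities
    are 8-bit grey levels.
    """

    height: int = 96
    width: int = 128
    tip_row: int = 60
    reference_col: int = 48
    probe_width_px: int = 10
    probe_intensity: float = 40.0
    background_intensity: float = 200.0
    pixel_size: float = 1.1028e-6  # m/px, matches the short probe preset
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.tip_row < self.height - 2):
            raise ValueError("tip must be inside the frame")
        if not (2 < self.reference_col < self.width - self.probe_width_px - 2):
            raise ValueError("probe must be inside the frame")


def render_probe_frame(spec: FrameSpec, true_deflection: float) -> np.ndarray:
    """Render a grayscale frame with the tip displaced by ``true_deflection``.

    ``true_deflection`` is in metres; sub-pixel positions are drawn with
    linear edge anti-aliasing (area coverage).  Additive Gaussian noise of
    ``spec.noise_sigma`` grey levels is applied when requested; seeded.
    """
    shift_px = true_deflection / spec.pixel_size
    left = spec.reference_col + shift_px
    right = left + spec.probe_width_px
    if left < 1 or right > spec.width - 2:
        raise ValueError("deflection places the probe outside the frame")

    img = np.full((spec.height, spec.width), spec.background_intensity)
    cols = np.arange(spec.width)
    # fractional column coverage of the probe silhouette
    coverage = np.clip(np.minimum(cols + 1.0, right) - np.maximum(cols, left),
                       0.0, 1.0)
    dark = spec.background_intensity - coverage * (
        spec.background_intensity - spec.probe_intensity
    )
    img[: spec.tip_row, :] = dark[None, :]
    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def detect_tip(
    image: np.ndarray,
    reference: tuple[int, int] | None = None,
    *,
    row_tolerance: int = 4,
    min_relative_response: float = 0.05,
) -> int:
    """Integer-pixel horizontal displacement of the probe tip corner.

    Runs Harris corner detection, keeps the peaks within ``row_tolerance``
    rows of the reference tip row, localises the left (tracked) tip corner
    with sub-pixel refinement and returns its column displacement rounded
    to whole pixels — the readout convention that makes the force an
    integral multiple of the per-pixel resolution.  ``reference`` is the
    (row, col) of the left tip corner in a zero-deflection frame; without
    it the strongest corner's own column is returned.
    """
    img = np.asarray(image, dtype=float)
    response = corner_harris(img, k=0.05, sigma=1.5)
    peaks = corner_peaks(
        response,
        min_distance=3,
        threshold_rel=0.1,
        num_peaks=8,
    )
    if peaks.size == 0 or response.max() <= min_relative_response:
        raise DetectionFailure("no corner above the response threshold")
    if reference is None:
        best = peaks[np.argmax(response[peaks[:, 0], peaks[:, 1]])]
        return int(best[1])
    ref_row, ref_col = reference
    near = peaks[np.abs(peaks[:, 0] - ref_row) <= row_tolerance]
    if near.size == 0:
        raise DetectionFailure("no corner near the reference row")
    # the silhouette has two tip corners (left and right edge); the left
    # one is the tracked feature
    strengths = response[near[:, 0], near[:, 1]]
    candidates = near[strengths >= 0.5 * strengths.max()]
    best = candidates[np.argmin(candidates[:, 1])]
    refined = corner_subpix(img, best[None, :].astype(float), window_size=7)
    col = refined[0, 1] if np.isfinite(refined[0, 1]) else float(best[1])
    return int(round(col - ref_col))
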