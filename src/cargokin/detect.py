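"""Per-frame spot detection for point-like cargoes.

The detector mirrors the classic band-pass particle localization recipe:
a difference-of-Gaussians response at the particle scale, candidate local
maxima above an intensity-percentile threshold, sub-pixel refinement by an
intensity-weighted centroid, and a normalized non-particle discrimination
score with a cutoff. The score is the band-pass response normalized to the
frame's response range — a monotone proxy for the discrimination score of
interactive tracking plugins, not numerically identical to any of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

__all__ = ["DetectionParams", "Spot", "detect_spots"]


@dataclass
class DetectionParams:
    """Detection configuration.

    kernel_radius : float
        Particle scale in µm (typical 0.1–1 µm). Sets the band-pass scale
        and the sub-pixel refinement window.
    intensity_percentile : float
        Fraction of brightest response pixels retained as candidates
        (typical 0.1–0.5 *percent* in plugin conventions is expressed here
        as a fraction, e.g. 0.005); candidates must exceed the
        (1 − percentile) quantile of the response.
    cutoff_score : float
        Spots whose normalized response score falls below this are
        discarded (default 0.01).
    """

    kernel_radius: float = 0.3
    intensity_percentile: float = 0.005
    cutoff_score: float = 0.01

    def __post_init__(self) -> None:
        if self.kernel_radius <= 0:
            raise ValueError("kernel_radius must be positive")
        if not 0 < self.intensity_percentile < 1:
            raise ValueError("intensity_percentile must be in (0, 1)")
        if self.cutoff_score < 0:
            raise ValueError("cutoff_score must be >= 0")


@dataclass
class Spot:
    """One detected particle in one frame (position in µm)."""

    frame: int
    x: float
    y: float
    intensity: float
    score: float


def detect_spots(
    frame_image: np.ndarray,
    dp: DetectionParams,
    pixel_size: float,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect point-like particles in a single 2-D frame.

    The band-pass response is a Gaussian blur at ``kernel_radius`` minus a
    blur at 3× that radius (suppressing both pixel noise and slowly varying
    background). Local maxima above the response quantile are refined to
    sub-pixel positions by the intensity-weighted centroid of the response
    within ``kernel_radius``. A constant frame yields no spots.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame_image must be 2-D")
    sig_px = dp.kernel_radius / pixel_size
    resp = ndimage.gaussian_filter(img, sig_px) - ndimage.gaussian_filter(
        img, 3 * sig_px
    )
    rmin, rmax = resp.min(), resp.max()
    if rmax - rmin <= 0:
        return []
    thr = np.quantile(resp, 1.0 - dp.intensity_percentile)
    peaks = peak_local_max(
        resp,
        min_distance=max(1, int(round(sig_px))),
        threshold_abs=thr,
        exclude_border=False,
    )
    h, w = img.shape
    rad = max(1, int(round(sig_px)))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disk = (xx**2 + yy**2) <= rad**2
    spots = []
    for r, c in peaks:
        score = (resp[r, c] - rmin) / (rmax - rmin)
        if score < dp.cutoff_score:
            continue
        y0, y1 = max(0, r - rad), min(h, r + rad + 1)
        x0, x1 = max(0, c - rad), min(w, c + rad + 1)
        win = resp[y0:y1, x0:x1]
        dmask = disk[rad - (r - y0) : rad + (y1 - r), rad - (c - x0) : rad + (x1 - c)]
        wgt = np.clip(win, 0, None) * dmask
        tot = wgt.sum()
        if tot <= 0:
            cy, cx = float(r), float(c)
        else:
            gy, gx = np.mgrid[y0:y1, x0:x1]
            cy = float((wgt * gy).sum() / tot)
            cx = float((wgt * gx).sum() / tot)
        spots.append(
            Spot(
                frame=frame_index,
                x=cx * pixel_size,
                y=cy * pixel_size,
                intensity=float(img[r, c]),
                score=float(score),
            )
        )
    spots.sort(key=lambda s: (s.y, s.x))
    return spots
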