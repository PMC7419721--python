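"""Random-dot stereogram rendering with log-Gabor micropatterns.

Each stimulus is a pair of images (left eye, right eye) of a 10-degree disc
of bandpass dots on a mid-gray background.  Dots inside the "pie" region —
the disc minus a missing 90-degree sector at one of four positions — are
displaced horizontally by half the disparity in opposite directions in the
two eyes (positive disparity = crossed, pie in front: the left-eye copy
shifts rightward), with sub-pixel accuracy.  Dots in the missing sector and
the identity of the dot field itself are shared between the eyes, so a
zero-disparity render is bit-identical across eyes.

Each dot is an isotropic log-Gabor patch: its amplitude spectrum is a
log-Gaussian bump (1-octave full bandwidth at half height by default) around
the peak frequency set by the element size, which makes the element zero-mean
— the rendered field's mean luminance stays at the background level.
Overlapping dots sum; the summed field is clipped to a symmetric range and
scaled so the rendered Michelson contrast equals the requested per-eye value.
Luminance is normalized to [0, 1]; mapping to physical cd/m² is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["RDSSpec", "render_rds", "interocular_correlation", "save_rds_png"]

#: sector_position -> center angle (degrees, counterclockwise from +x) of the
#: missing 90-degree wedge: 1 = up, 2 = down, 3 = left, 4 = right.
SECTOR_ANGLES = {1: 90.0, 2: 270.0, 3: 180.0, 4: 0.0}
MIN_PPD = 20


@dataclass(frozen=True)
class RDSSpec:
    """Geometry and contrast of one random-dot stereogram pair.

    Angles in degrees, element size in arcmin, disparity in arcsec, contrasts
    in percent Michelson.  ``dot_count`` defaults to a density of 25
    elements/deg² over the disc.
    """

    disparity: float
    sector_position: int = 1
    disc_diameter: float = 10.0
    element_size: float = 10.0
    sector_angle: float = 90.0
    contrast_left: float = 80.0
    contrast_right: float = 80.0
    pixels_per_degree: int = 32
    dot_count: int | None = None
    bandwidth_octaves: float = 1.0
    dot_density: float = 25.0  # elements per deg^2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.disparity <= 4096.0:
            raise ValueError(f"disparity must lie in [0, 4096] arcsec, got {self.disparity}")
        if self.sector_position not in SECTOR_ANGLES:
            raise ValueError(f"sector_position must be in {sorted(SECTOR_ANGLES)}")
        for c in (self.contrast_left, self.contrast_right):
            if not 1.0 <= c <= 100.0:
                raise ValueError(f"contrast must lie in [1, 100] percent, got {c}")
        if self.pixels_per_degree < MIN_PPD:
            raise ValueError(
                f"pixels_per_degree = {self.pixels_per_degree} cannot represent arcsec-scale "
                f"disparities; use at least {MIN_PPD} px/deg"
            )
        if not 0.0 < self.sector_angle < 360.0:
            raise ValueError("sector_angle must lie in (0, 360) degrees")

    @property
    def n_dots(self) -> int:
        if self.dot_count is not None:
            return int(self.dot_count)
        r = self.disc_diameter / 2.0
        return int(round(self.dot_density * math.pi * r * r))

    @property
    def support_radius(self) -> float:
        """Truncation radius of one element, in degrees."""
        return self.element_size / 60.0


@lru_cache(maxsize=8)
def _radial_kernel(element_size: float, bandwidth_octaves: float) -> tuple[np.ndarray, np.ndarray]:
    """Radial spatial profile k(r) of the isotropic log-Gabor element.

    Obtained by inverse FFT of the isotropic log-Gaussian amplitude spectrum
    on a fine grid, tapered to zero at the support radius, with the residual
    DC removed so the truncated element integrates to zero.  Returns
    (radii in degrees, normalized profile with unit peak).
    """
    f0 = 60.0 / element_size  # peak frequency, c/deg
    n, ppd = 1024, max(128.0, 16.0 * f0)
    fx = np.fft.fftfreq(n, d=1.0 / ppd)
    fr = np.hypot(*np.meshgrid(fx, fx))
    sig2 = bandwidth_octaves / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # log2-sigma
    with np.errstate(divide="ignore"):
        spectrum = np.exp(-np.log2(np.where(fr > 0, fr, 1.0) / f0) ** 2 / (2.0 * sig2**2))
    spectrum[fr == 0] = 0.0
    kernel = np.fft.fftshift(np.fft.ifft2(spectrum).real)
    c = n // 2
    prof = kernel[c, c:]
    r = np.arange(n - c) / ppd
    rmax = element_size / 60.0
    taper = np.where(r < rmax, np.cos(np.pi * r / (2.0 * rmax)) ** 2, 0.0)
    # zero 2D integral over the support: subtract c0 * taper^2
    c0 = np.trapezoid(r * taper * prof, r) / np.trapezoid(r * taper * taper, r)
    prof = taper * prof - c0 * taper * taper
    return r, prof / np.abs(prof).max()


def _stamp(field: np.ndarray, half: int, ppd: int, x: float, y: float, amp: float,
           r_prof: np.ndarray, k_prof: np.ndarray, pr: int) -> None:
    n = field.shape[0]
    cx, cy = int(round(x * ppd)) + half, int(round(y * ppd)) + half
    x0, x1 = max(0, cx - pr), min(n, cx + pr + 1)
    y0, y1 = max(0, cy - pr), min(n, cy + pr + 1)
    if x0 >= x1 or y0 >= y1:
        return
    gx = (np.arange(x0, x1) - half) / ppd - x
    gy = (np.arange(y0, y1) - half) / ppd - y
    rr = np.hypot(gx[None, :], gy[:, None])
    field[y0:y1, x0:x1] += amp * np.interp(rr, r_prof, k_prof, right=0.0)


def render_rds(spec: RDSSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the (left, right) image pair, normalized luminance in [0, 1].

    Dot positions, polarities and the dot field are identical in the two
    eyes; only dots whose centers fall inside the pie region are displaced by
    ±disparity/2 (sub-pixel, via the element's continuous radial profile).
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.disc_diameter / 2.0
    half_shift = spec.disparity / 3600.0 / 2.0  # deg
    margin = spec.support_radius + half_shift + 2.0 / spec.pixels_per_degree
    half = int(math.ceil((R + margin) * spec.pixels_per_degree))
    n = 2 * half + 1

    u = rng.uniform(0.0, 1.0, spec.n_dots)
    theta = rng.uniform(0.0, 2.0 * math.pi, spec.n_dots)
    xs = np.sqrt(u) * R * np.cos(theta)
    ys = np.sqrt(u) * R * np.sin(theta)
    pol = rng.choice([-1.0, 1.0], spec.n_dots)

    center = math.radians(SECTOR_ANGLES[spec.sector_position])
    ang = np.arctan2(ys, xs)
    delta = np.angle(np.exp(1j * (ang - center)))
    in_pie = np.abs(delta) > math.radians(spec.sector_angle) / 2.0

    r_prof, k_prof = _radial_kernel(spec.element_size, spec.bandwidth_octaves)
    pr = int(math.ceil(spec.support_radius * spec.pixels_per_degree)) + 1
    left = np.zeros((n, n))
    right = np.zeros((n, n))
    for x, y, a, pie in zip(xs, ys, pol, in_pie):
        if pie and half_shift > 0:
            # crossed disparity: left-eye copy shifts rightward
            _stamp(left, half, spec.pixels_per_degree, x + half_shift, y, a, r_prof, k_prof, pr)
            _stamp(right, half, spec.pixels_per_degree, x - half_shift, y, a, r_prof, k_prof, pr)
        else:
            _stamp(left, half, spec.pixels_per_degree, x, y, a, r_prof, k_prof, pr)
            _stamp(right, half, spec.pixels_per_degree, x, y, a, r_prof, k_prof, pr)

    # symmetric clip + scale: Michelson contrast equals the request exactly,
    # mean luminance stays at the 0.5 background (elements are zero-mean)
    amp = min(left.max(), right.max(), -left.min(), -right.min())
    if amp <= 0:  # pragma: no cover - would need an empty dot field
        amp = 1.0
    left = np.clip(left, -amp, amp)
    right = np.clip(right, -amp, amp)
    img_l = 0.5 + 0.5 * (spec.contrast_left / 100.0) * left / amp
    img_r = 0.5 + 0.5 * (spec.contrast_right / 100.0) * right / amp
    return img_l, img_r


def interocular_correlation(left: np.ndarray, right: np.ndarray, window=None) -> float:
    """Pearson correlation of pixel luminances inside a window.

    ``window`` is a boolean mask or an (y0, y1, x0, x1) slice tuple; default
    is the full image.  Returns NaN when either windowed image is constant
    (the correlation is undefined there).
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("images must have equal shape")
    if window is None:
        a, b = left.ravel(), right.ravel()
    elif isinstance(window, np.ndarray) and window.dtype == bool:
        a, b = left[window], right[window]
    else:
        y0, y1, x0, x1 = window
        a, b = left[y0:y1, x0:x1].ravel(), right[y0:y1, x0:x1].ravel()
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def save_rds_png(spec: RDSSpec, path_left: str, path_right: str, path_sheet: str | None = None) -> None:
    """Render and save the pair as 8-bit grayscale PNGs, plus an optional
    side-by-side proof sheet."""
    from PIL import Image

    left, right = render_rds(spec)
    to8 = lambda im: Image.fromarray(np.round(im * 255.0).astype(np.uint8), mode="L")
    to8(left).save(path_left)
    to8(right).save(path_right)
    if path_sheet:
        gap = np.full((left.shape[0], 16), 0.5)
        to8(np.hstack([left, gap, right])).save(path_sheet)
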