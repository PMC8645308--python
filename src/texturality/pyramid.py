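"""Complex steerable pyramid built with polar-separable frequency-domain filters.

The decomposition splits an image into a real highpass residual, ``n_scales``
levels of ``n_orientations`` complex ("analytic") oriented bands, and a real
lowpass residual.  Radial filters are raised cosines one octave wide in
``log2`` frequency; angular filters follow ``cos^(K-1)`` with K orientation
bands, so that the squared filters tile the frequency plane exactly (a tight
frame).  All filtering is circular and implemented with the FFT, downsampling
is alias-free frequency-domain cropping, and the real parts of the bands
reconstruct the input to machine precision.

Scale 1 is the finest level (center frequency ``image_size / 4`` cycles per
image for the default geometry); each coarser level halves the resolution.
Internally bands are stored 0-indexed: ``bands[s][o]`` is scale ``s + 1``,
orientation ``o + 1`` of the 1-indexed convention used in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ShapeError, SizeError, ValidationError

__all__ = [
    "PyramidConfig",
    "SteerablePyramid",
    "build_pyramid",
    "reconstruct",
    "partial_lowpass_images",
]


@dataclass(frozen=True)
class PyramidConfig:
    """Geometry of the decomposition and of the statistics computed on it.

    Parameters
    ----------
    n_scales : int
        Number of dyadic scales (default 4).
    n_orientations : int
        Number of orientation bands per scale (default 4).
    neighborhood : int
        Odd width, in samples, of the central autocorrelation window used by
        the statistics layer (default 7).
    image_size : int
        Side length of the (square) input image in pixels.
    synthesis_iterations : int
        Recorded for provenance only; the decomposition never iterates.
    """

    n_scales: int = 4
    n_orientations: int = 4
    neighborhood: int = 7
    image_size: int = 256
    synthesis_iterations: int = 20

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValidationError(f"n_scales must be >= 1, got {self.n_scales}")
        if self.n_orientations < 2:
            raise ValidationError(
                f"n_orientations must be >= 2, got {self.n_orientations}"
            )
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValidationError(
                f"neighborhood must be odd and >= 3, got {self.neighborhood}"
            )
        divisor = 2 ** (self.n_scales + 1)
        if self.image_size <= 0 or self.image_size % divisor != 0:
            raise SizeError(
                f"image_size must be divisible by 2^(n_scales+1) = {divisor}, "
                f"got {self.image_size}"
            )
        coarsest = self.image_size // 2**self.n_scales
        if coarsest < self.neighborhood:
            raise SizeError(
                f"coarsest level side {coarsest} cannot support a "
                f"{self.neighborhood}x{self.neighborhood} window"
            )

    def band_size(self, scale: int) -> int:
        """Side length of the grid at 1-indexed ``scale``."""
        return self.image_size // 2 ** (scale - 1)


@dataclass
class SteerablePyramid:
    """Decomposition of one image.

    ``bands[s][o]`` holds the complex coefficients of scale ``s + 1``
    (0 = finest), orientation ``o + 1``.  ``dc_mean`` is the mean removed
    from the input before filtering.
    """

    highpass: np.ndarray
    bands: list = field(default_factory=list)
    lowpass: np.ndarray = None
    dc_mean: float = 0.0

    @property
    def n_scales(self) -> int:
        return len(self.bands)

    @property
    def n_orientations(self) -> int:
        return len(self.bands[0]) if self.bands else 0


# --- frequency-domain filters ------------------------------------------------


@lru_cache(maxsize=64)
def _polar_grids(size: int):
    """log2 radial frequency (0 at Nyquist) and angle on the fftshifted grid."""
    f = (np.arange(size) - size // 2) / (size / 2.0)
    fx, fy = np.meshgrid(f, f)
    rad = np.hypot(fx, fy)
    rad[size // 2, size // 2] = 2.0**-60  # keep log finite; masked by the clip
    log_rad = np.log2(rad)
    angle = np.arctan2(fy, fx)
    log_rad.flags.writeable = False
    angle.flags.writeable = False
    return log_rad, angle


def _highpass_mask(log_rad: np.ndarray, shift: float) -> np.ndarray:
    # raised-cosine amplitude: 0 below one octave under the cutoff, 1 above it
    x = np.clip(log_rad + shift, -1.0, 0.0)
    return np.cos(0.5 * np.pi * x)


def _lowpass_mask(log_rad: np.ndarray, shift: float) -> np.ndarray:
    h = _highpass_mask(log_rad, shift)
    return np.sqrt(np.clip(1.0 - h * h, 0.0, None))


def _angular_order_and_norm(n_orientations: int):
    n = n_orientations - 1
    const = (
        2.0 ** (2 * n)
        * math.factorial(n) ** 2
        / (n_orientations * math.factorial(2 * n))
    )
    return n, math.sqrt(const)


@lru_cache(maxsize=64)
def _level_filters(size: int, n_orientations: int):
    """Masks used at one pyramid level of side ``size``.

    Returns (hmask, lomask, analytic_masks, steer_masks) where the analytic
    masks are single-lobed and doubled (build side) and the steer masks are
    the signed full-plane cos^(K-1) lobes (reconstruction side).
    """
    log_rad, angle = _polar_grids(size)
    hmask = _highpass_mask(log_rad, 1.0)
    lomask = _lowpass_mask(log_rad, 1.0)
    order, norm = _angular_order_and_norm(n_orientations)
    analytic, steer = [], []
    for o in range(n_orientations):
        theta = np.mod(angle - np.pi * o / n_orientations + np.pi, 2 * np.pi) - np.pi
        lobe = np.cos(theta) ** order
        analytic.append(2.0 * norm * lobe * (np.abs(theta) < np.pi / 2))
        steer.append(norm * lobe)
    for m in (hmask, lomask, *analytic, *steer):
        m.flags.writeable = False
    return hmask, lomask, tuple(analytic), tuple(steer)


@lru_cache(maxsize=64)
def _front_filters(size: int):
    log_rad, _ = _polar_grids(size)
    hi0 = _highpass_mask(log_rad, 0.0)
    lo0 = _lowpass_mask(log_rad, 0.0)
    hi0.flags.writeable = False
    lo0.flags.writeable = False
    return hi0, lo0


def _fft(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(x))


def _ifft(X: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.ifftshift(X))


# --- analysis ----------------------------------------------------------------


def build_pyramid(image: np.ndarray, config: PyramidConfig) -> SteerablePyramid:
    """Decompose ``image`` into the complex steerable pyramid.

    The input mean is removed first and stored in ``dc_mean``.  Deterministic;
    raises :class:`SizeError` on a wrongly sized input and
    :class:`ValidationError` on non-finite pixels.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise SizeError(f"image must be square 2-D, got shape {image.shape}")
    if image.shape[0] != config.image_size:
        raise SizeError(
            f"image side {image.shape[0]} does not match configured "
            f"image_size {config.image_size} (must be divisible by "
            f"2^(n_scales+1) = {2 ** (config.n_scales + 1)})"
        )
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite pixels")

    dc_mean = float(image.mean())
    dft = _fft(image - dc_mean)
    hi0, lo0 = _front_filters(config.image_size)
    highpass = _ifft(dft * hi0).real
    lodft = dft * lo0

    order, _ = _angular_order_and_norm(config.n_orientations)
    phase_factor = (-1j) ** order

    bands: list[list[np.ndarray]] = []
    for _ in range(config.n_scales):
        m = lodft.shape[0]
        hmask, lomask, analytic, _steer = _level_filters(m, config.n_orientations)
        level = [
            _ifft(phase_factor * lodft * hmask * amask) for amask in analytic
        ]
        bands.append(level)
        q = m // 4
        # amplitude-preserving downsample: crop the masked spectrum, rescale
        lodft = (lodft * lomask)[q : q + m // 2, q : q + m // 2] / 4.0

    lowpass = _ifft(lodft).real
    return SteerablePyramid(
        highpass=highpass, bands=bands, lowpass=lowpass, dc_mean=dc_mean
    )


def _check_pyramid(pyr: SteerablePyramid, config: PyramidConfig) -> None:
    if pyr.n_scales != config.n_scales or pyr.n_orientations != config.n_orientations:
        raise ShapeError(
            f"pyramid has {pyr.n_scales} scales x {pyr.n_orientations} "
            f"orientations, config expects {config.n_scales} x "
            f"{config.n_orientations}"
        )
    if pyr.highpass.shape != (config.image_size, config.image_size):
        raise ShapeError(
            f"highpass shape {pyr.highpass.shape} does not match "
            f"image_size {config.image_size}"
        )
    for s in range(config.n_scales):
        expected = config.band_size(s + 1)
        for o, band in enumerate(pyr.bands[s]):
            if band.shape != (expected, expected):
                raise ShapeError(
                    f"band[{s + 1}][{o + 1}] has shape {band.shape}, "
                    f"expected ({expected}, {expected})"
                )
    low = config.image_size // 2**config.n_scales
    if pyr.lowpass.shape != (low, low):
        raise ShapeError(
            f"lowpass shape {pyr.lowpass.shape}, expected ({low}, {low})"
        )


def _merge_level(
    ldft: np.ndarray,
    level_bands,
    n_orientations: int,
    unwind: complex,
) -> np.ndarray:
    """One inverse-cascade step: upsample the running lowpass spectrum and
    fold in the real parts of this level's oriented bands."""
    m = 2 * ldft.shape[0]
    hmask, lomask, _analytic, steer = _level_filters(m, n_orientations)
    dft = np.zeros((m, m), dtype=complex)
    q = m // 4
    dft[q : q + m // 2, q : q + m // 2] = 4.0 * ldft
    dft *= lomask
    for o in range(n_orientations):
        bdft = _fft(np.asarray(level_bands[o]).real)
        dft += unwind * bdft * steer[o] * hmask
    return dft


def reconstruct(pyr: SteerablePyramid, config: PyramidConfig) -> np.ndarray:
    """Invert the decomposition from the real parts of the subbands.

    The filters form a tight frame, so this reproduces the input of
    :func:`build_pyramid` up to floating-point error.
    """
    _check_pyramid(pyr, config)
    order, _ = _angular_order_and_norm(config.n_orientations)
    unwind = (1j) ** order
    ldft = _fft(np.asarray(pyr.lowpass, dtype=float))
    for s in range(config.n_scales - 1, -1, -1):
        ldft = _merge_level(ldft, pyr.bands[s], config.n_orientations, unwind)
    hi0, lo0 = _front_filters(config.image_size)
    outdft = ldft * lo0 + _fft(np.asarray(pyr.highpass, dtype=float)) * hi0
    return _ifft(outdft).real + pyr.dc_mean


def partial_lowpass_images(
    pyr: SteerablePyramid, config: PyramidConfig
) -> list[np.ndarray]:
    """Coarse-to-fine partial reconstructions.

    Element ``s`` (0-indexed ``s - 1``) is the image rebuilt from the lowpass
    residual plus every band at scale >= ``s``, expressed at the resolution of
    scale ``s``; the final element is the lowpass residual itself.  Length is
    ``n_scales + 1``.
    """
    _check_pyramid(pyr, config)
    order, _ = _angular_order_and_norm(config.n_orientations)
    unwind = (1j) ** order
    partials = [np.asarray(pyr.lowpass, dtype=float)]
    ldft = _fft(partials[0])
    for s in range(config.n_scales - 1, -1, -1):
        ldft = _merge_level(ldft, pyr.bands[s], config.n_orientations, unwind)
        partials.append(_ifft(ldft).real)
    partials.reverse()
    return partials


def dump_subbands(pyr: SteerablePyramid, directory) -> list:
    """Debug dump: write each band's real and imaginary planes as 32-bit
    float TIFFs named ``band_s{scale}_o{orientation}_{re|im}.tif``."""
    import tifffile
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for s, level in enumerate(pyr.bands, start=1):
        for o, band in enumerate(level, start=1):
            for plane, tag in ((band.real, "re"), (band.imag, "im")):
                path = directory / f"band_s{s}_o{o}_{tag}.tif"
                tifffile.imwrite(path, plane.astype(np.float32))
                written.append(path)
    return written
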