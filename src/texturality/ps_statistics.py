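"""Full Portilla-Simoncelli-style statistic set of one image.

From the complex steerable pyramid this module computes marginal pixel
moments, per-scale skew/kurtosis and central autocorrelations of the partial
lowpass reconstructions, magnitude means and autocorrelations of every
oriented band, and the within-scale / cross-scale correlation matrices of
the linear (real-part) and energy (magnitude) subbands.

Conventions
-----------
* Moments are population moments (divide by N); kurtosis is non-excess, so a
  Gaussian map reads 3.
* Zero-variance (degenerate) maps report skewness 0, kurtosis 3, a
  delta-at-center autocorrelation, and zero correlations (unit self
  correlation).
* Autocorrelations are circular, normalized to 1 at the center lag.
* Magnitude maps are implicitly mean-subtracted by the Pearson/autocorrelation
  normalizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .pyramid import PyramidConfig, build_pyramid, partial_lowpass_images

__all__ = [
    "PixelStats",
    "PSStatistics",
    "compute_ps_statistics",
    "marginal_moments",
    "central_autocorrelation",
    "cross_band_correlation",
    "phase_double_upsample",
    "flatten_statistics",
]

#: relative variance floor below which a map is treated as constant
_DEGENERATE_REL_VAR = 1e-20


def _is_degenerate(var: float, mean: float) -> bool:
    return var <= _DEGENERATE_REL_VAR * (1.0 + mean * mean)


def marginal_moments(map_: np.ndarray):
    """Population (mean, variance, skewness, kurtosis) of a real map.

    Kurtosis is non-excess (Gaussian -> 3).  A constant map returns
    ``(c, 0.0, 0.0, 3.0)`` by convention.
    """
    m = np.asarray(map_, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValidationError("map contains non-finite values")
    mean = float(m.mean())
    d = m - mean
    var = float(np.mean(d * d))
    if _is_degenerate(var, mean):
        return mean, 0.0, 0.0, 3.0
    skew = float(np.mean(d**3)) / var**1.5
    kurt = float(np.mean(d**4)) / var**2
    return mean, var, skew, kurt


def central_autocorrelation(map_: np.ndarray, neighborhood: int) -> np.ndarray:
    """Central window of the circular, variance-normalized autocorrelation.

    Entry ``(i, j)`` is the correlation at lag ``(i - c, j - c)`` with
    ``c = neighborhood // 2``; the center entry is exactly 1.  A constant map
    returns the delta-at-center matrix by convention.
    """
    if neighborhood % 2 == 0 or neighborhood < 1:
        raise ValidationError(f"neighborhood must be odd, got {neighborhood}")
    m = np.asarray(map_, dtype=float)
    if neighborhood > min(m.shape):
        raise ValidationError(
            f"neighborhood {neighborhood} exceeds map side {min(m.shape)}"
        )
    c = neighborhood // 2
    mean = float(m.mean())
    d = m - mean
    var = float(np.mean(d * d))
    if _is_degenerate(var, mean):
        out = np.zeros((neighborhood, neighborhood))
        out[c, c] = 1.0
        return out
    F = np.fft.fft2(d)
    full = np.fft.ifft2(F * np.conj(F)).real / (m.size * var)
    idx_r = (np.arange(neighborhood) - c) % m.shape[0]
    idx_c = (np.arange(neighborhood) - c) % m.shape[1]
    out = full[np.ix_(idx_r, idx_c)]
    out[c, c] = 1.0
    return out


def cross_band_correlation(
    maps_a: Sequence[np.ndarray], maps_b: Sequence[np.ndarray]
) -> np.ndarray:
    """Pearson correlation matrix between two lists of equally shaped maps.

    ``out[i, j] = corr(maps_a[i], maps_b[j])``.  When the two lists are the
    same the result is symmetric with unit diagonal.  A zero-variance map
    contributes 0 off-diagonal and 1 on the self-diagonal by convention.
    """
    if len(maps_a) == 0 or len(maps_b) == 0:
        raise ValidationError("map lists must be non-empty")
    shape = np.shape(maps_a[0])
    for m in list(maps_a) + list(maps_b):
        if np.shape(m) != shape:
            raise ValidationError("all maps must share one shape")
    same = maps_a is maps_b or (
        len(maps_a) == len(maps_b)
        and all(a is b for a, b in zip(maps_a, maps_b))
    )
    A = np.stack([np.ravel(np.asarray(m, dtype=float)) for m in maps_a])
    B = A if same else np.stack(
        [np.ravel(np.asarray(m, dtype=float)) for m in maps_b]
    )
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = Ac if same else B - B.mean(axis=1, keepdims=True)
    va = np.mean(Ac * Ac, axis=1)
    vb = va if same else np.mean(Bc * Bc, axis=1)
    dga = np.array([_is_degenerate(v, mu) for v, mu in zip(va, A.mean(axis=1))])
    dgb = dga if same else np.array(
        [_is_degenerate(v, mu) for v, mu in zip(vb, B.mean(axis=1))]
    )
    sa = np.where(dga, 1.0, np.sqrt(np.where(dga, 1.0, va)))
    sb = sa if same else np.where(dgb, 1.0, np.sqrt(np.where(dgb, 1.0, vb)))
    out = (Ac @ Bc.T) / (n * np.outer(sa, sb))
    out[dga, :] = 0.0
    out[:, dgb] = 0.0
    if same:
        out = 0.5 * (out + out.T)
        np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


# --- cross-scale plumbing ----------------------------------------------------


def _fourier_upsample2(z: np.ndarray) -> np.ndarray:
    """2x upsampling by spectral zero padding with Nyquist-bin splitting.

    Sample-exact: ``out[::2, ::2] == z`` to floating-point precision.
    """
    m = z.shape[0]
    Z = np.fft.fftshift(np.fft.fft2(z))
    big = np.zeros((2 * m, 2 * m), dtype=complex)
    q = m // 2
    big[q : q + m, q : q + m] = Z
    big[q + m, :] = big[q, :] * 0.5
    big[q, :] *= 0.5
    big[:, q + m] = big[:, q] * 0.5
    big[:, q] *= 0.5
    return np.fft.ifft2(np.fft.ifftshift(big)) * 4.0


def phase_double_upsample(coarse_band: np.ndarray, target_shape) -> np.ndarray:
    """Upsample a complex band 2x while doubling its phase.

    Magnitude and phase are interpolated separately, so the output magnitude
    equals the (sinc-)upsampled input magnitude everywhere and the output
    phase at original sample positions is exactly twice the input phase.
    """
    coarse = np.asarray(coarse_band, dtype=complex)
    if coarse.ndim != 2 or coarse.shape[0] != coarse.shape[1]:
        raise ValidationError(f"coarse band must be square, got {coarse.shape}")
    target_shape = tuple(target_shape)
    if target_shape != (2 * coarse.shape[0], 2 * coarse.shape[1]):
        raise ValidationError(
            f"target shape {target_shape} is not 2x the coarse shape "
            f"{coarse.shape}"
        )
    if coarse.shape[0] % 2 != 0:
        raise ValidationError("coarse band side must be even")
    mag = np.abs(coarse)
    safe = np.where(mag > 0.0, mag, 1.0)
    doubled = np.where(mag > 0.0, coarse * coarse / safe, 0.0)
    mag_up = np.clip(_fourier_upsample2(mag).real, 0.0, None)
    w = _fourier_upsample2(doubled)
    wabs = np.abs(w)
    phasor = np.where(wabs > 1e-300, w / np.where(wabs > 0.0, wabs, 1.0), 1.0)
    return mag_up * phasor


# --- the full statistic set --------------------------------------------------


@dataclass
class PixelStats:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    minimum: float
    maximum: float


@dataclass
class PSStatistics:
    """Structured statistic set of one image; scales are 0-indexed here
    (scale ``s`` of the 1-indexed reporting convention is index ``s - 1``)."""

    config: PyramidConfig
    pixel_stats: PixelStats
    highpass_variance: float
    lowpass_skew: np.ndarray  # (n_scales + 1,), coarsest (lowpass residual) last
    lowpass_kurt: np.ndarray  # (n_scales + 1,)
    raw_autocorr: list  # n_scales + 1 matrices, neighborhood x neighborhood
    band_variance: np.ndarray  # (n_scales, n_ori) variance of band real parts
    mag_means: np.ndarray  # (n_scales, n_ori)
    mag_autocorr: list  # [scale][ori] neighborhood x neighborhood
    cross_ori_mag: list  # n_scales matrices (n_ori x n_ori)
    cross_ori_real: list  # n_scales matrices (n_ori x n_ori)
    cross_scale_mag: list  # n_scales - 1 matrices (n_ori x n_ori)
    cross_scale_real: list  # n_scales - 1 matrices (n_ori x 2 n_ori)


def compute_ps_statistics(
    image: np.ndarray, config: PyramidConfig
) -> PSStatistics:
    """Compute the full statistic set of ``image`` under ``config``."""
    pyr = build_pyramid(image, config)
    image = np.asarray(image, dtype=float)
    nb = config.neighborhood
    n_sc, n_or = config.n_scales, config.n_orientations

    mean, var, skew, kurt = marginal_moments(image)
    pixel_stats = PixelStats(
        mean=mean,
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        minimum=float(image.min()),
        maximum=float(image.max()),
    )
    highpass_variance = marginal_moments(pyr.highpass)[1]

    partials = partial_lowpass_images(pyr, config)
    lowpass_skew = np.empty(n_sc + 1)
    lowpass_kurt = np.empty(n_sc + 1)
    raw_autocorr = []
    for i, p in enumerate(partials):
        _, _, sk, ku = marginal_moments(p)
        lowpass_skew[i] = sk
        lowpass_kurt[i] = ku
        raw_autocorr.append(central_autocorrelation(p, nb))

    reals = [[b.real for b in level] for level in pyr.bands]
    mags = [[np.abs(b) for b in level] for level in pyr.bands]

    band_variance = np.array(
        [[marginal_moments(r)[1] for r in level] for level in reals]
    )
    mag_means = np.array([[float(m.mean()) for m in level] for level in mags])
    mag_autocorr = [
        [central_autocorrelation(m, nb) for m in level] for level in mags
    ]
    cross_ori_mag = [cross_band_correlation(level, level) for level in mags]
    cross_ori_real = [cross_band_correlation(level, level) for level in reals]

    cross_scale_mag = []
    cross_scale_real = []
    for s in range(n_sc - 1):
        target = pyr.bands[s][0].shape
        up = [
            phase_double_upsample(pyr.bands[s + 1][o], target)
            for o in range(n_or)
        ]
        cross_scale_mag.append(
            cross_band_correlation(mags[s], [np.abs(u) for u in up])
        )
        parent_parts = [u.real for u in up] + [u.imag for u in up]
        cross_scale_real.append(
            cross_band_correlation(reals[s], parent_parts)
        )

    return PSStatistics(
        config=config,
        pixel_stats=pixel_stats,
        highpass_variance=highpass_variance,
        lowpass_skew=lowpass_skew,
        lowpass_kurt=lowpass_kurt,
        raw_autocorr=raw_autocorr,
        band_variance=band_variance,
        mag_means=mag_means,
        mag_autocorr=mag_autocorr,
        cross_ori_mag=cross_ori_mag,
        cross_ori_real=cross_ori_real,
        cross_scale_mag=cross_scale_mag,
        cross_scale_real=cross_scale_real,
    )


def flatten_statistics(ps: PSStatistics) -> dict:
    """Serialize a :class:`PSStatistics` to a flat ordered mapping of named
    scalars.

    Naming scheme (scales and orientations 1-indexed):

    * ``pix.{mean,var,skew,kurt,min,max}``, ``hp.var``
    * ``loSkew.s{i}`` / ``loKurt.s{i}`` for the partial lowpass images,
      ``i = 1 .. n_scales + 1`` (coarsest last)
    * ``rawAC.s{i}.dy{dy}.dx{dx}`` for every lag in the central window
    * ``bandVar.s{i}.o{j}``, ``magMean.s{i}.o{j}``
    * ``magAC.s{i}.o{j}.dy{dy}.dx{dx}``
    * ``xOriMag.s{i}.o{a}.o{b}`` / ``xOriReal.s{i}.o{a}.o{b}`` (full matrices)
    * ``xSclMag.s{i}.o{a}.o{b}``: scale ``i`` orientation ``a`` vs
      phase-doubled scale ``i + 1`` orientation ``b``
    * ``xSclReal.s{i}.o{a}.o{b}{re|im}``
    """
    nb = ps.config.neighborhood
    c = nb // 2
    n_or = ps.config.n_orientations
    out: dict[str, float] = {}
    px = ps.pixel_stats
    out["pix.mean"] = px.mean
    out["pix.var"] = px.variance
    out["pix.skew"] = px.skewness
    out["pix.kurt"] = px.kurtosis
    out["pix.min"] = px.minimum
    out["pix.max"] = px.maximum
    out["hp.var"] = ps.highpass_variance
    for i, (sk, ku) in enumerate(zip(ps.lowpass_skew, ps.lowpass_kurt), 1):
        out[f"loSkew.s{i}"] = float(sk)
        out[f"loKurt.s{i}"] = float(ku)
    for i, ac in enumerate(ps.raw_autocorr, 1):
        for dy in range(-c, c + 1):
            for dx in range(-c, c + 1):
                out[f"rawAC.s{i}.dy{dy}.dx{dx}"] = float(ac[dy + c, dx + c])
    for s in range(len(ps.mag_means)):
        for o in range(n_or):
            out[f"bandVar.s{s + 1}.o{o + 1}"] = float(ps.band_variance[s, o])
            out[f"magMean.s{s + 1}.o{o + 1}"] = float(ps.mag_means[s, o])
    for s, level in enumerate(ps.mag_autocorr, 1):
        for o, ac in enumerate(level, 1):
            for dy in range(-c, c + 1):
                for dx in range(-c, c + 1):
                    out[f"magAC.s{s}.o{o}.dy{dy}.dx{dx}"] = float(
                        ac[dy + c, dx + c]
                    )
    for tag, mats in (("xOriMag", ps.cross_ori_mag), ("xOriReal", ps.cross_ori_real)):
        for s, mat in enumerate(mats, 1):
            for a in range(n_or):
                for b in range(n_or):
                    out[f"{tag}.s{s}.o{a + 1}.o{b + 1}"] = float(mat[a, b])
    for s, mat in enumerate(ps.cross_scale_mag, 1):
        for a in range(n_or):
            for b in range(n_or):
                out[f"xSclMag.s{s}.o{a + 1}.o{b + 1}"] = float(mat[a, b])
    for s, mat in enumerate(ps.cross_scale_real, 1):
        for a in range(n_or):
            for b in range(n_or):
                out[f"xSclReal.s{s}.o{a + 1}.o{b + 1}re"] = float(mat[a, b])
                out[f"xSclReal.s{s}.o{a + 1}.o{b + 1}im"] = float(
                    mat[a, b + n_or]
                )
    return out
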