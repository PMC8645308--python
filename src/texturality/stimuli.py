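"""Synthetic labeled stimuli and a simulated observer.

Texture generators are stationary random processes (filtered noise, dense
gabor fields, binarized noise, Poisson dot fields); non-texture generators
impose global, position-dependent structure (one large blob, a horizon
scene, a big outlined polygon, a mirror-symmetric layout).  Every generator
is a pure function of its seed, emits pixels in [0, 1], and produces images
that pass :class:`~texturality.pyramid.PyramidConfig` validation.

The simulated observer turns summary features into per-image "texture"
response proportions through a logistic model plus binomial trial noise,
matching the structure the screening analysis assumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "StimulusSpec",
    "DatasetManifest",
    "TEXTURE_KINDS",
    "NONTEXTURE_KINDS",
    "GENERATOR_VERSION",
    "make_texture",
    "make_nontexture",
    "render",
    "dataset_records",
    "render_record",
    "make_dataset",
    "simulate_observer",
]

GENERATOR_VERSION = "1.0"

TEXTURE_KINDS = ("filtered_noise", "gabor_field", "binarized_noise", "dot_field")
NONTEXTURE_KINDS = ("single_blob", "horizon_scene", "big_polygon", "symmetric_layout")


@dataclass(frozen=True)
class StimulusSpec:
    kind: str
    size: int = 256
    params: Mapping = field(default_factory=dict)
    seed: int = 0


def _normalize(raw: np.ndarray, mean: float = 0.5, sd: float = 0.15) -> np.ndarray:
    z = (raw - raw.mean()) / (raw.std() + 1e-12)
    return np.clip(mean + sd * z, 0.0, 1.0)


def _fft_convolve(impulses: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    # circular convolution keeps the process stationary on the torus
    return np.fft.ifft2(np.fft.fft2(impulses) * np.fft.fft2(kernel)).real


def _radial_freq(size: int) -> np.ndarray:
    f = np.fft.fftfreq(size) * size  # cycles per image
    fx, fy = np.meshgrid(f, f)
    return np.hypot(fx, fy)


def _gabor_kernel(size: int, freq_cpi: float, theta: float, sigma: float) -> np.ndarray:
    x = np.arange(size) - size // 2
    xx, yy = np.meshgrid(x, x)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    env = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    k = env * np.cos(2.0 * np.pi * freq_cpi * u / size)
    return np.fft.ifftshift(k)


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size) - size // 2
    xx, yy = np.meshgrid(x, x)
    return np.fft.ifftshift(np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2)))


# --- texture generators ------------------------------------------------------


def _filtered_noise(rng, size, alpha=1.0):
    if not 0.0 <= alpha <= 3.0:
        raise ValidationError(f"alpha out of range: {alpha}")
    white = rng.standard_normal((size, size))
    fr = _radial_freq(size)
    fr[0, 0] = 1.0
    spec = np.fft.fft2(white) / fr**alpha
    spec[0, 0] = 0.0
    return _normalize(np.fft.ifft2(spec).real)


def _gabor_field(rng, size, carrier_cpi=32.0, orientation=None, density=0.02):
    """Dense field of random-position gabor micropatterns.

    ``orientation`` in degrees fixes a single carrier orientation; ``None``
    mixes four orientations.
    """
    n = max(1, int(density * size * size))
    sigma = 0.75 * size / carrier_cpi
    thetas = (
        [np.deg2rad(orientation)]
        if orientation is not None
        else [np.pi * k / 4 for k in range(4)]
    )
    canvas = np.zeros((size, size))
    for theta in thetas:
        impulses = np.zeros((size, size))
        m = max(1, n // len(thetas))
        ys = rng.integers(0, size, m)
        xs = rng.integers(0, size, m)
        amps = rng.choice([-1.0, 1.0], m)
        np.add.at(impulses, (ys, xs), amps)
        canvas += _fft_convolve(impulses, _gabor_kernel(size, carrier_cpi, theta, sigma))
    return _normalize(canvas)


def _binarized_noise(rng, size, alpha=1.0, low=0.15, high=0.85):
    noise = _filtered_noise(rng, size, alpha=alpha)
    return np.where(noise > np.median(noise), high, low)


def _dot_field(rng, size, density=0.004, radius=2.5, polarity=1):
    if polarity not in (-1, 1):
        raise ValidationError("polarity must be +1 (bright) or -1 (dark)")
    n = max(3, int(rng.poisson(density * size * size)))
    impulses = np.zeros((size, size))
    ys = rng.integers(0, size, n)
    xs = rng.integers(0, size, n)
    np.add.at(impulses, (ys, xs), 1.0)
    blobs = _fft_convolve(impulses, _gaussian_kernel(size, radius))
    base = 0.35 if polarity > 0 else 0.65
    img = base + polarity * 0.6 * blobs / max(blobs.max(), 1e-12)
    return np.clip(img, 0.0, 1.0)


# --- non-texture generators --------------------------------------------------


def _coords(size):
    x = (np.arange(size) + 0.5) / size
    return np.meshgrid(x, x)  # xx, yy in (0, 1)


def _single_blob(rng, size, amplitude=0.45):
    xx, yy = _coords(size)
    cx = 0.5 + rng.choice([-1.0, 1.0]) * rng.uniform(0.08, 0.18)
    cy = 0.5 + rng.uniform(-0.1, 0.1)
    r0 = rng.uniform(0.18, 0.26)
    stretch = rng.uniform(0.8, 1.25)
    phi = rng.uniform(0, np.pi)
    dx = (xx - cx) * np.cos(phi) + (yy - cy) * np.sin(phi)
    dy = -(xx - cx) * np.sin(phi) + (yy - cy) * np.cos(phi)
    r = np.hypot(dx * stretch, dy / stretch)
    edge = 0.03
    blob = 1.0 / (1.0 + np.exp((r - r0) / edge))
    img = 0.3 + amplitude * blob + 0.005 * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 1.0)


def _horizon_scene(rng, size, n_shapes=4):
    xx, yy = _coords(size)
    base = 0.45 + rng.uniform(-0.08, 0.08)
    # undulating horizon line puts energy into the low-frequency bands
    phase = rng.uniform(0, 2 * np.pi, 2)
    horizon = (
        base
        + 0.04 * np.sin(2 * np.pi * 2 * xx[0] + phase[0])
        + 0.02 * np.sin(2 * np.pi * 5 * xx[0] + phase[1])
    )[None, :]
    sky = 0.78 + 0.14 * (horizon - yy) / base
    ground = 0.3 - 0.12 * (yy - horizon) / (1 - base)
    blend = 1.0 / (1.0 + np.exp((yy - horizon) / 0.006))
    img = blend * sky + (1 - blend) * ground
    for _ in range(int(n_shapes)):
        cx = rng.uniform(0.1, 0.9)
        cy = rng.uniform(base + 0.06, 0.92)
        rx = rng.uniform(0.06, 0.18)
        ry = rng.uniform(0.05, 0.14)
        r = np.hypot((xx - cx) / rx, (yy - cy) / ry)
        shape = 1.0 / (1.0 + np.exp((r - 1.0) / 0.03))
        img += rng.choice([-1.0, 1.0]) * rng.uniform(0.18, 0.3) * shape
    img += 0.005 * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 1.0)


def _big_polygon(rng, size, n_vertices=6, outline_width=2.5):
    from scipy.spatial import ConvexHull

    xx, yy = _coords(size)
    center = 0.5 + rng.choice([-1.0, 1.0], 2) * rng.uniform(0.06, 0.14, 2)
    pts = center + rng.uniform(-0.32, 0.32, size=(max(int(n_vertices), 4) + 4, 2))
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]  # counterclockwise
    p = np.stack([xx.ravel(), yy.ravel()], axis=1)
    inside = np.ones(p.shape[0], dtype=bool)
    min_dist = np.full(p.shape[0], np.inf)
    for i in range(len(verts)):
        a, b = verts[i], verts[(i + 1) % len(verts)]
        e = b - a
        cross = e[0] * (p[:, 1] - a[1]) - e[1] * (p[:, 0] - a[0])
        inside &= cross >= 0
        t = np.clip(((p - a) @ e) / (e @ e), 0.0, 1.0)
        proj = a + t[:, None] * e
        min_dist = np.minimum(min_dist, np.hypot(*(p - proj).T))
    inside = inside.reshape(size, size)
    outline = (min_dist.reshape(size, size) < outline_width / size)
    img = np.full((size, size), 0.58)
    img[inside] = 0.44
    img[outline] = 0.12
    img += 0.005 * rng.standard_normal((size, size))
    return np.clip(img, 0.0, 1.0)


def _symmetric_layout(rng, size, n_elements=3):
    half = size // 2
    xx, yy = _coords(size)
    left = np.full((size, size), 0.42)
    for _ in range(int(n_elements)):
        cx = rng.uniform(0.08, 0.42)
        cy = rng.uniform(0.12, 0.88)
        sig = rng.uniform(0.04, 0.09)
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.25, 0.4)
        left += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))
    left += 0.004 * rng.standard_normal((size, size))
    img = left.copy()
    img[:, size - half :] = left[:, half - 1 :: -1]  # mirror the left half
    return np.clip(img, 0.0, 1.0)


_TEXTURE_GENERATORS = {
    "filtered_noise": _filtered_noise,
    "gabor_field": _gabor_field,
    "binarized_noise": _binarized_noise,
    "dot_field": _dot_field,
}
_NONTEXTURE_GENERATORS = {
    "single_blob": _single_blob,
    "horizon_scene": _horizon_scene,
    "big_polygon": _big_polygon,
    "symmetric_layout": _symmetric_layout,
}


def _render(spec: StimulusSpec, table) -> np.ndarray:
    if spec.kind not in table:
        raise ValidationError(
            f"unknown stimulus kind {spec.kind!r}; expected one of "
            f"{sorted(table)}"
        )
    if spec.size < 8 or spec.size % 2:
        raise ValidationError(f"invalid stimulus size {spec.size}")
    rng = np.random.default_rng(spec.seed)
    try:
        img = table[spec.kind](rng, spec.size, **dict(spec.params))
    except TypeError as exc:
        raise ValidationError(
            f"invalid params for {spec.kind!r}: {exc}"
        ) from exc
    assert img.shape == (spec.size, spec.size)
    return img


def make_texture(spec: StimulusSpec) -> np.ndarray:
    """Render a stationary texture-class stimulus."""
    return _render(spec, _TEXTURE_GENERATORS)


def make_nontexture(spec: StimulusSpec) -> np.ndarray:
    """Render a globally structured non-texture stimulus."""
    return _render(spec, _NONTEXTURE_GENERATORS)


def render(spec: StimulusSpec) -> np.ndarray:
    """Render a stimulus of either class."""
    if spec.kind in _TEXTURE_GENERATORS:
        return make_texture(spec)
    return make_nontexture(spec)


# --- datasets ----------------------------------------------------------------


@dataclass
class DatasetManifest:
    records: list  # dicts: id, file, kind, seed, label
    master_seed: int
    n_per_class: int
    generator_version: str = GENERATOR_VERSION
    size: int = 256

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _derive_seed(master_seed: int, label: int, index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(label, index))
    return int(ss.generate_state(1)[0])


def dataset_records(n_per_class: int, master_seed: int, size: int = 256) -> list:
    """Deterministic per-image specs: kinds cycled within class, per-image
    seeds derived from the master seed by a counter scheme."""
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    records = []
    for label, kinds, prefix in (
        (1, TEXTURE_KINDS, "tex"),
        (0, NONTEXTURE_KINDS, "non"),
    ):
        for i in range(n_per_class):
            kind = kinds[i % len(kinds)]
            records.append(
                {
                    "id": f"{prefix}{i:04d}",
                    "file": f"{prefix}{i:04d}.png",
                    "kind": kind,
                    "seed": _derive_seed(master_seed, label, i),
                    "label": label,
                }
            )
    return records


def render_record(record: Mapping, size: int = 256) -> np.ndarray:
    return render(StimulusSpec(kind=record["kind"], size=size, seed=record["seed"]))


def make_dataset(
    n_per_class: int,
    master_seed: int,
    out_dir=None,
    size: int = 256,
) -> DatasetManifest:
    """Generate the balanced two-class dataset.

    When ``out_dir`` is given, images are written as 16-bit grayscale PNGs
    next to ``manifest.csv`` and a ``dataset.json`` config snapshot.
    """
    records = dataset_records(n_per_class, master_seed, size=size)
    manifest = DatasetManifest(
        records=records, master_seed=master_seed, n_per_class=n_per_class, size=size
    )
    if out_dir is not None:
        from .io import write_image

        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise IOError(f"cannot create output directory {out}: {exc}") from exc
        for rec in records:
            write_image(out / rec["file"], render_record(rec, size=size))
        manifest.to_frame().to_csv(out / "manifest.csv", index=False)
        (out / "dataset.json").write_text(
            json.dumps(
                {
                    "generator_version": GENERATOR_VERSION,
                    "master_seed": master_seed,
                    "n_per_class": n_per_class,
                    "size": size,
                    "texture_kinds": list(TEXTURE_KINDS),
                    "nontexture_kinds": list(NONTEXTURE_KINDS),
                },
                indent=1,
            )
        )
    return manifest


# --- simulated observer ------------------------------------------------------


def simulate_observer(
    feature_matrix: np.ndarray,
    feature_labels: Sequence[str],
    weights: Mapping[str, float],
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    n_trials: int = 32,
    seed: int = 0,
) -> np.ndarray:
    """Per-image 'texture' response proportions from a logistic observer.

    ``p_true = logistic(intercept + weights . z(features) + N(0, noise_sd))``
    per image; the returned proportion is the mean of ``n_trials`` Bernoulli
    draws.  Features are z-scored across the image set.
    """
    X = np.asarray(feature_matrix, dtype=float)
    labels = list(feature_labels)
    if X.ndim != 2 or X.shape[1] != len(labels):
        raise ValidationError("feature matrix and labels must align")
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    unknown = [lab for lab in weights if lab not in labels]
    if unknown:
        raise ValidationError(f"unknown feature labels in weights: {unknown}")
    rng = np.random.default_rng(seed)
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    eta = np.full(X.shape[0], float(intercept))
    for lab, w in weights.items():
        eta += float(w) * Z[:, labels.index(lab)]
    if noise_sd > 0:
        eta += rng.normal(0.0, noise_sd, size=eta.shape)
    p_true = 1.0 / (1.0 + np.exp(-eta))
    return rng.binomial(int(n_trials), p_true) / float(n_trials)
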