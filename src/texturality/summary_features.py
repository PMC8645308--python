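"""Class-by-frequency summary variables and behavioral screening.

The full statistic set is collapsed into 34 labeled variables: seven classes
per frequency band (power, skew, kurt, cpL, cpE, coL, coE at 64/32/16/8
cycles per image for the default geometry) plus two cross-scale classes (cfE,
cfL) for each of the three adjacent-scale pairs, labeled by the coarser
band's frequency.

Canonical label order is class-major: every per-band class over the bands
finest-to-coarsest, then ``cfE`` and ``cfL`` over the scale pairs.  Labels
read ``class@frequency``, e.g. ``cpE@16``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .errors import ConvergenceError, UnsupportedConfigError, ValidationError
from .ps_statistics import PSStatistics

__all__ = [
    "FrequencyMap",
    "SummaryFeatureVector",
    "PER_BAND_CLASSES",
    "CROSS_SCALE_CLASSES",
    "MOMENT_CLASSES",
    "canonical_labels",
    "summarize",
    "moment_subset",
    "logistic_correlation",
    "select_top_k",
]

PER_BAND_CLASSES = ("power", "skew", "kurt", "cpL", "cpE", "coL", "coE")
CROSS_SCALE_CLASSES = ("cfE", "cfL")
MOMENT_CLASSES = ("power", "skew", "kurt")


@dataclass(frozen=True)
class FrequencyMap:
    """Maps pyramid scales to spatial-frequency band labels.

    ``band_freq[s - 1] = image_size / 2^(s + 1)`` cycles per image for scale
    ``s`` (finest first): (64, 32, 16, 8) for a 256-pixel image with 4 scales.
    """

    image_size: int = 256
    deg_per_image: float = 4.1
    n_scales: int = 4

    @property
    def band_freq(self) -> tuple:
        freqs = []
        for s in range(1, self.n_scales + 1):
            f = self.image_size / 2 ** (s + 1)
            freqs.append(int(f) if float(f).is_integer() else f)
        return tuple(freqs)


@dataclass(frozen=True)
class SummaryFeatureVector:
    """Ordered, labeled summary variables of one image."""

    values: tuple
    labels: tuple

    def __post_init__(self):
        if len(self.values) != len(self.labels):
            raise ValidationError("values and labels must align")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.values))

    @property
    def classes(self) -> tuple:
        return tuple(lab.split("@")[0] for lab in self.labels)


def canonical_labels(fmap: FrequencyMap) -> tuple:
    """The fixed 34-label order for the default 4-scale geometry."""
    freqs = fmap.band_freq
    labels = [f"{cls}@{f}" for cls in PER_BAND_CLASSES for f in freqs]
    labels += [f"{cls}@{f}" for cls in CROSS_SCALE_CLASSES for f in freqs[1:]]
    return tuple(labels)


def _offcenter_mean(ac: np.ndarray) -> float:
    k = ac.shape[0]
    c = k // 2
    total = float(ac.sum()) - float(ac[c, c])
    return total / (ac.size - 1)


def _offdiag_mean(mat: np.ndarray) -> float:
    k = mat.shape[0]
    return (float(mat.sum()) - float(np.trace(mat))) / (k * k - k)


def summarize(ps: PSStatistics, fmap: FrequencyMap) -> SummaryFeatureVector:
    """Collapse a full statistic set into the 34 summary variables.

    Per band ``s`` (frequency ``f_s``):

    * ``power``: mean over orientations of the band real-part variance
    * ``skew`` / ``kurt``: skew/kurtosis of partial lowpass ``s``
    * ``cpL``: mean off-center entry of the partial-lowpass autocorrelation
    * ``cpE``: mean off-center entry of the magnitude autocorrelations,
      averaged over orientations
    * ``coL`` / ``coE``: mean off-diagonal of the within-scale real/magnitude
      correlation matrices

    Per adjacent scale pair, labeled by the coarser frequency:

    * ``cfE``: mean of the cross-scale magnitude correlation matrix
    * ``cfL``: mean absolute entry of the cross-scale real/imag matrix

    Only the default 4-scale, 4-orientation layout is supported.
    """
    cfg = ps.config
    if cfg.n_scales != 4 or cfg.n_orientations != 4:
        raise UnsupportedConfigError(
            "the 34-variable summary is defined for 4 scales x 4 "
            f"orientations, got {cfg.n_scales} x {cfg.n_orientations}"
        )
    if fmap.n_scales != cfg.n_scales or fmap.image_size != cfg.image_size:
        raise UnsupportedConfigError(
            "frequency map does not match the statistics' configuration"
        )
    by_class: dict[str, list[float]] = {
        "power": [float(v) for v in ps.band_variance.mean(axis=1)],
        "skew": [float(v) for v in ps.lowpass_skew[: cfg.n_scales]],
        "kurt": [float(v) for v in ps.lowpass_kurt[: cfg.n_scales]],
        "cpL": [_offcenter_mean(ps.raw_autocorr[s]) for s in range(cfg.n_scales)],
        "cpE": [
            float(np.mean([_offcenter_mean(ac) for ac in ps.mag_autocorr[s]]))
            for s in range(cfg.n_scales)
        ],
        "coL": [_offdiag_mean(m) for m in ps.cross_ori_real],
        "coE": [_offdiag_mean(m) for m in ps.cross_ori_mag],
        "cfE": [float(m.mean()) for m in ps.cross_scale_mag],
        "cfL": [float(np.abs(m).mean()) for m in ps.cross_scale_real],
    }
    labels = canonical_labels(fmap)
    values = []
    for lab in labels:
        cls, freq = lab.split("@")
        freqs = fmap.band_freq if cls in PER_BAND_CLASSES else fmap.band_freq[1:]
        idx = [str(f) for f in freqs].index(freq)
        values.append(by_class[cls][idx])
    return SummaryFeatureVector(values=tuple(values), labels=labels)


def moment_subset(v: SummaryFeatureVector) -> SummaryFeatureVector:
    """Restrict a summary vector to the power/skew/kurt classes (12 values)."""
    fmap = FrequencyMap()
    if tuple(v.labels) != canonical_labels(fmap):
        # accept any image size with the canonical class layout
        classes = [lab.split("@")[0] for lab in v.labels]
        expected = [c for c in PER_BAND_CLASSES for _ in range(4)] + [
            c for c in CROSS_SCALE_CLASSES for _ in range(3)
        ]
        if classes != expected:
            raise UnsupportedConfigError(
                "moment_subset requires the default 34-variable layout"
            )
    keep = [
        i for i, lab in enumerate(v.labels) if lab.split("@")[0] in MOMENT_CLASSES
    ]
    return SummaryFeatureVector(
        values=tuple(v.values[i] for i in keep),
        labels=tuple(v.labels[i] for i in keep),
    )


def logistic_correlation(
    x: Sequence[float],
    p: Sequence[float],
    n_trials,
    name: str | None = None,
) -> float:
    """Signed logistic correlation between one feature and response proportions.

    Standardizes ``x``, fits ``p_hat = 1 / (1 + exp(-(a + b z)))`` by maximum
    likelihood (each ``p_i`` treated as the mean of ``n_trials`` Bernoulli
    responses), and returns ``sign(b)`` times the Pearson correlation between
    the fitted and observed proportions.  A zero-variance feature returns 0
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    if x.shape != p.shape or x.ndim != 1:
        raise ValidationError("x and p must be 1-D and aligned")
    if x.size < 10:
        raise ValidationError(f"need at least 10 images, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("feature values must be finite")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("proportions must lie in [0, 1]")
    n = np.broadcast_to(np.asarray(n_trials, dtype=float), p.shape)
    if np.any(n < 1):
        raise ValidationError("n_trials must be >= 1")

    sd = x.std()
    if sd <= 0:
        warnings.warn(
            f"feature {name or '<unnamed>'} has zero variance; "
            "logistic correlation set to 0",
            stacklevel=2,
        )
        return 0.0
    z = (x - x.mean()) / sd

    def nll_grad(theta):
        a, b = theta
        t = a + b * z
        # -log L up to a constant, numerically stable
        nll = float(np.sum(n * (p * np.logaddexp(0.0, -t) + (1 - p) * np.logaddexp(0.0, t))))
        q = 1.0 / (1.0 + np.exp(-t))
        resid = n * (q - p)
        return nll, np.array([resid.sum(), float(resid @ z)])

    res = optimize.minimize(
        nll_grad,
        x0=np.zeros(2),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-50.0, 50.0), (-50.0, 50.0)],
    )
    if not res.success:
        raise ConvergenceError(
            f"logistic fit did not converge for feature {name or '<unnamed>'}: "
            f"{res.message}"
        )
    a, b = res.x
    if abs(b) < 1e-12:
        return 0.0
    p_hat = 1.0 / (1.0 + np.exp(-(a + b * z)))
    if p_hat.std() <= 0 or p.std() <= 0:
        return 0.0
    r = float(np.corrcoef(p_hat, p)[0, 1])
    return float(np.sign(b)) * r


def select_top_k(
    correlations: Sequence[float] | Mapping[str, float],
    labels: Sequence[str] | None = None,
    k: int = 6,
) -> list:
    """The ``k`` feature labels with the largest absolute correlation.

    Sorted by ``|correlation|`` descending; ties keep the canonical label
    order.  Accepts either a mapping label -> value or parallel sequences.
    """
    if isinstance(correlations, Mapping):
        labels = list(correlations.keys())
        values = np.asarray(list(correlations.values()), dtype=float)
    else:
        if labels is None:
            raise ValidationError("labels required when correlations is a sequence")
        labels = list(labels)
        values = np.asarray(correlations, dtype=float)
    if len(labels) != values.size:
        raise ValidationError("labels and correlations must align")
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if k > values.size:
        raise ValidationError(f"k={k} exceeds the number of features {values.size}")
    order = np.argsort(-np.abs(values), kind="stable")
    return [labels[i] for i in order[:k]]
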