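"""Per-modality feature extraction and multi-modal fusion.

Three fixed-length feature vectors are built per aligned time window:

* EEG, EMD path — 11 statistics per grouped mode signal I1..I4 → 44 dims;
* EEG, filter baseline — the same 11 statistics per brain-wave band → 99;
* image sequence — 7 bounding-box displacement features plus 5 statistics
  of the difference of the two patches' 2-D DCT coefficient matrices → 12;
* motion — per-axis mean and variance of the 3-axis signal → 6.

Fusing EEG(EMD) + image + motion by concatenation gives the 62-dim vector
fed to the classifier (99 + 12 + 6 = 117 on the baseline path).

Statistic conventions (pinned for reproducibility): Shannon entropy in
nats over 64 equal-width amplitude bins; population variance; MAD is the
mean absolute deviation from the mean; skewness m3/m2^1.5 and non-excess
kurtosis m4/m2^2, both 0 for zero-variance input; IQR with linear
interpolation; unnormalised L1/L2/Linf norms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dctn
from sklearn.base import BaseEstimator, TransformerMixin

from . import bands as _bands
from . import emd as _emd
from .signal import TimeSeries

__all__ = [
    "FeatureVector",
    "BoundingBox",
    "FramePair",
    "MotionWindow",
    "STAT_NAMES",
    "SPATIAL_NAMES",
    "DCT_DIFF_NAMES",
    "MOTION_NAMES",
    "stat_features",
    "eeg_features_emd",
    "eeg_features_band",
    "spatial_image_features",
    "dct2",
    "zero_fill_align",
    "dct_diff_features",
    "image_features",
    "motion_features",
    "fuse",
    "EMDFeatureExtractor",
    "BandFeatureExtractor",
    "ImageFeatureExtractor",
    "MotionFeatureExtractor",
]

STAT_NAMES: tuple[str, ...] = (
    "entropy",
    "mean",
    "iqr",
    "mad",
    "range",
    "variance",
    "skewness",
    "kurtosis",
    "l2",
    "l1",
    "linf",
)

SPATIAL_NAMES: tuple[str, ...] = (
    "dx_min",
    "dx_max",
    "dy_min",
    "dy_max",
    "dabs_x_mean",
    "dabs_y_mean",
    "center_shift",
)

DCT_DIFF_NAMES: tuple[str, ...] = (
    "dct_mean",
    "dct_median",
    "dct_variance",
    "dct_skewness",
    "dct_kurtosis",
)

MOTION_NAMES: tuple[str, ...] = (
    "mean_x",
    "mean_y",
    "mean_z",
    "var_x",
    "var_y",
    "var_z",
)

_MODALITY_DIMS: dict[str, tuple[int, ...]] = {
    "eeg_emd": (44,),
    "eeg_band": (99,),
    "image": (12,),
    "motion": (6,),
    "fused": (62, 117),
}

ENTROPY_BINS = 64


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-order named real vector from one modality (or their fusion)."""

    values: np.ndarray
    names: tuple[str, ...]
    modality: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if values.ndim != 1 or values.size != len(self.names):
            raise ValueError("values and names must be 1-D and equal-length")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        allowed = _MODALITY_DIMS.get(self.modality)
        if allowed is None:
            raise ValueError(f"unknown modality {self.modality!r}")
        if values.size not in allowed:
            raise ValueError(
                f"modality {self.modality!r} expects {allowed} features, "
                f"got {values.size}"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned object box in pixel coordinates (inclusive edges)."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if self.xmin > self.xmax or self.ymin > self.ymax:
            raise ValueError(f"degenerate box {self}")

    @property
    def x_mean(self) -> float:
        return (self.xmax + self.xmin) / 2

    @property
    def y_mean(self) -> float:
        return (self.ymax + self.ymin) / 2


@dataclass(frozen=True)
class FramePair:
    """Two consecutive frames' object annotation: boxes plus pixel patches."""

    box_a: BoundingBox
    box_b: BoundingBox
    patch_a: np.ndarray
    patch_b: np.ndarray

    def __post_init__(self) -> None:
        for name in ("patch_a", "patch_b"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.ndim != 2 or p.size == 0:
                raise ValueError(f"{name} must be a nonempty 2-D matrix")
            object.__setattr__(self, name, p)


@dataclass(frozen=True)
class MotionWindow:
    """One window of the 3-axis motion signal."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate_hz: float = 31.0

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("x", "y", "z"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
        n = {a.size for a in arrays.values()}
        if len(n) != 1 or n.pop() < 2:
            raise ValueError("x, y, z must have equal length >= 2")
        for name, a in arrays.items():
            object.__setattr__(self, name, a)


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, population variance, skewness, non-excess kurtosis)."""
    mean = float(np.mean(x))
    centered = x - mean
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        return mean, 0.0, 0.0, 0.0
    m3 = float(np.mean(centered**3))
    m4 = float(np.mean(centered**4))
    return mean, m2, m3 / m2**1.5, m4 / m2**2


def _entropy(x: np.ndarray, n_bins: int = ENTROPY_BINS) -> float:
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def stat_features(s: TimeSeries | np.ndarray) -> np.ndarray:
    """The 11 signal statistics, in the fixed order of ``STAT_NAMES``.

    [entropy, mean, IQR, MAD, range, variance, skewness, kurtosis,
    L2, L1, Linf].
    """
    x = s.samples if isinstance(s, TimeSeries) else np.asarray(s, dtype=float)
    if x.size == 0:
        raise ValueError("cannot compute statistics of an empty sequence")
    mean, var, skew, kurt = _moments(x)
    q1, q3 = np.percentile(x, [25, 75])
    return np.array(
        [
            _entropy(x),
            mean,
            float(q3 - q1),
            float(np.mean(np.abs(x - mean))),
            float(np.max(x) - np.min(x)),
            var,
            skew,
            kurt,
            float(np.sqrt(np.sum(x * x))),
            float(np.sum(np.abs(x))),
            float(np.max(np.abs(x))),
        ]
    )


def eeg_features_emd(
    x: TimeSeries,
    sd_threshold: float = _emd.DEFAULT_SD_THRESHOLD,
    max_iter: int = _emd.DEFAULT_MAX_SIFT_ITER,
    max_imfs: int = _emd.DEFAULT_MAX_IMFS,
) -> FeatureVector:
    """44-dim EEG feature vector via EMD: 11 statistics per group I1..I4."""
    dec = _emd.decompose(x, sd_threshold, max_iter, max_imfs)
    grouped = _emd.group_imfs(dec)
    blocks = [stat_features(g) for g in grouped.groups]
    names = tuple(
        f"I{gi}.{stat}" for gi in range(1, 5) for stat in STAT_NAMES
    )
    return FeatureVector(np.concatenate(blocks), names, "eeg_emd")


def eeg_features_band(x: TimeSeries) -> FeatureVector:
    """99-dim baseline EEG feature vector: 11 statistics per band × 9 bands."""
    bandset = _bands.extract_bands(x)
    blocks = [stat_features(ts) for _, ts in bandset]
    names = tuple(
        f"{band}.{stat}" for band in _bands.BAND_NAMES for stat in STAT_NAMES
    )
    return FeatureVector(np.concatenate(blocks), names, "eeg_band")


def spatial_image_features(
    p: FramePair, sqrt_distance: bool = True
) -> np.ndarray:
    """The 7 bounding-box displacement features between consecutive frames.

    In order: the changes of the four box edges, the changes of the
    absolute values of the two box-centre coordinates, and their combined
    magnitude.  With ``sqrt_distance`` (default) the 7th feature is the
    Euclidean norm of the two centre changes; with ``False`` the raw sum
    of squares is returned instead.
    """
    a, b = p.box_a, p.box_b
    d_abs_x = abs(b.x_mean) - abs(a.x_mean)
    d_abs_y = abs(b.y_mean) - abs(a.y_mean)
    shift = d_abs_x**2 + d_abs_y**2
    if sqrt_distance:
        shift = float(np.sqrt(shift))
    return np.array(
        [
            b.xmin - a.xmin,
            b.xmax - a.xmax,
            b.ymin - a.ymin,
            b.ymax - a.ymax,
            d_abs_x,
            d_abs_y,
            shift,
        ]
    )


def dct2(patch: np.ndarray) -> np.ndarray:
    """2-D type-II DCT with orthonormal scaling."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or patch.size == 0:
        raise ValueError("patch must be a nonempty 2-D matrix")
    return dctn(patch, type=2, norm="ortho")


def zero_fill_align(d_small: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad a DCT coefficient matrix up to ``target_shape``.

    The original coefficients stay in the low-frequency (top-left) corner;
    zeros fill the added high-frequency rows and columns.  This is how two
    differently sized object patches are compared coefficient-by-
    coefficient: padding the smaller matrix is equivalent to resizing the
    smaller patch up without adding high-frequency content.
    """
    d_small = np.asarray(d_small, dtype=float)
    rows, cols = target_shape
    if rows < d_small.shape[0] or cols < d_small.shape[1]:
        raise ValueError(
            f"target shape {target_shape} smaller than input {d_small.shape}"
        )
    out = np.zeros((rows, cols), dtype=float)
    out[: d_small.shape[0], : d_small.shape[1]] = d_small
    return out


def dct_diff_features(p: FramePair) -> np.ndarray:
    """Statistics of the difference of the two patches' DCT matrices.

    Both coefficient matrices are zero-filled to the common (elementwise
    maximum) shape; the returned vector is [mean, median, variance,
    skewness, kurtosis] of the flattened difference, with the same
    conventions as :func:`stat_features`.
    """
    da = dct2(p.patch_a)
    db = dct2(p.patch_b)
    shape = (max(da.shape[0], db.shape[0]), max(da.shape[1], db.shape[1]))
    diff = (zero_fill_align(db, shape) - zero_fill_align(da, shape)).ravel()
    mean, var, skew, kurt = _moments(diff)
    return np.array([mean, float(np.median(diff)), var, skew, kurt])


def image_features(p: FramePair, sqrt_distance: bool = True) -> FeatureVector:
    """12-dim image feature vector: 7 spatial + 5 DCT-difference features."""
    values = np.concatenate(
        [spatial_image_features(p, sqrt_distance), dct_diff_features(p)]
    )
    return FeatureVector(values, SPATIAL_NAMES + DCT_DIFF_NAMES, "image")


def motion_features(w: MotionWindow) -> FeatureVector:
    """6-dim motion feature vector: per-axis mean then population variance."""
    values = np.array(
        [
            np.mean(w.x),
            np.mean(w.y),
            np.mean(w.z),
            np.var(w.x),
            np.var(w.y),
            np.var(w.z),
        ]
    )
    return FeatureVector(values, MOTION_NAMES, "motion")


def fuse(
    eeg: FeatureVector, img: FeatureVector, mot: FeatureVector
) -> FeatureVector:
    """Concatenate EEG, image and motion features into one fused vector.

    44 + 12 + 6 = 62 dims on the EMD path; 99 + 12 + 6 = 117 on the filter
    baseline path.
    """
    if eeg.modality not in ("eeg_emd", "eeg_band"):
        raise ValueError(f"first argument must be an EEG vector, got {eeg.modality!r}")
    if img.modality != "image" or mot.modality != "motion":
        raise ValueError(
            f"expected (eeg, image, motion), got "
            f"({eeg.modality!r}, {img.modality!r}, {mot.modality!r})"
        )
    names = (
        tuple(f"eeg.{n}" for n in eeg.names)
        + tuple(f"img.{n}" for n in img.names)
        + tuple(f"mot.{n}" for n in mot.names)
    )
    return FeatureVector(
        np.concatenate([eeg.values, img.values, mot.values]), names, "fused"
    )


# ---------------------------------------------------------------------------
# scikit-learn transformer facade
# ---------------------------------------------------------------------------


class _StatelessTransformer(TransformerMixin, BaseEstimator):
    """Base for the stateless per-window featurizers.

    ``fit`` only records the input count; ``transform`` maps a sequence of
    windows to a fixed-width feature matrix, so these compose with sklearn
    pipelines and feature unions.
    """

    def fit(self, X, y=None):  # noqa: D102 - sklearn contract
        self.n_features_in_ = None  # variable-length windows, not a matrix
        return self

    def _feature_vector(self, window) -> FeatureVector:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        rows = [self._feature_vector(w) for w in X]
        if not rows:
            return np.empty((0, len(self.get_feature_names_out())))
        return np.vstack([r.values for r in rows])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        raise NotImplementedError


class EMDFeatureExtractor(_StatelessTransformer):
    """EEG epochs → 44-dim EMD feature matrix.

    Accepts an iterable of :class:`TimeSeries` or raw 1-D arrays (then
    interpreted at ``rate_hz``).
    """

    def __init__(
        self,
        rate_hz: float = 512.0,
        sd_threshold: float = _emd.DEFAULT_SD_THRESHOLD,
        max_iter: int = _emd.DEFAULT_MAX_SIFT_ITER,
        max_imfs: int = _emd.DEFAULT_MAX_IMFS,
    ):
        self.rate_hz = rate_hz
        self.sd_threshold = sd_threshold
        self.max_iter = max_iter
        self.max_imfs = max_imfs

    def _feature_vector(self, window) -> FeatureVector:
        ts = window if isinstance(window, TimeSeries) else TimeSeries(window, self.rate_hz)
        return eeg_features_emd(ts, self.sd_threshold, self.max_iter, self.max_imfs)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([f"I{g}.{s}" for g in range(1, 5) for s in STAT_NAMES])


class BandFeatureExtractor(_StatelessTransformer):
    """EEG epochs → 99-dim filter-baseline feature matrix."""

    def __init__(self, rate_hz: float = 512.0):
        self.rate_hz = rate_hz

    def _feature_vector(self, window) -> FeatureVector:
        ts = window if isinstance(window, TimeSeries) else TimeSeries(window, self.rate_hz)
        return eeg_features_band(ts)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(
            [f"{b}.{s}" for b in _bands.BAND_NAMES for s in STAT_NAMES]
        )


class ImageFeatureExtractor(_StatelessTransformer):
    """Frame pairs → 12-dim image feature matrix."""

    def __init__(self, sqrt_distance: bool = True):
        self.sqrt_distance = sqrt_distance

    def _feature_vector(self, window) -> FeatureVector:
        return image_features(window, self.sqrt_distance)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(SPATIAL_NAMES + DCT_DIFF_NAMES)


class MotionFeatureExtractor(_StatelessTransformer):
    """Motion windows → 6-dim motion feature matrix.

    Accepts :class:`MotionWindow` objects or (T, 3) arrays.
    """

    def __init__(self, rate_hz: float = 31.0):
        self.rate_hz = rate_hz

    def _feature_vector(self, window) -> FeatureVector:
        if not isinstance(window, MotionWindow):
            arr = np.asarray(window, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("motion window must be a MotionWindow or (T, 3) array")
            window = MotionWindow(arr[:, 0], arr[:, 1], arr[:, 2], self.rate_hz)
        return motion_features(window)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(MOTION_NAMES)
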