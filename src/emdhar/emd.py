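"""Empirical mode decomposition (EMD) with envelope-energy stopping.

EMD represents a signal x(t) as a finite sum of intrinsic mode functions
(IMFs) plus a residue,

    x(t) = sum_i c_i(t) + r_K(t),

where each IMF c_i is produced by *sifting*: repeatedly subtracting the
mean of the cubic-spline upper and lower envelopes until the envelope-mean
energy is small relative to the signal energy,

    SD = sum |m(t)|^2 / sum |d_{j-1}(t)|^2 <= sd_threshold   (default 0.3).

Lower-index IMFs occupy higher frequency bands, so EMD acts as an
adaptive, fully data-driven filter bank: unlike IIR band filters it
introduces no nonlinear phase distortion.

For EEG epochs the decomposition typically yields 4-8 IMFs; to obtain a
fixed-length representation the IMFs are merged into exactly four grouped
signals I1..I4 (high to low frequency) by :func:`group_imfs`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .signal import TimeSeries

__all__ = [
    "NotSiftableError",
    "IMFDecomposition",
    "GroupedIMFs",
    "find_extrema",
    "envelopes",
    "sd_criterion",
    "sift",
    "decompose",
    "group_imfs",
    "is_imf",
]

DEFAULT_SD_THRESHOLD = 0.3
DEFAULT_MAX_SIFT_ITER = 100
DEFAULT_MAX_IMFS = 12


class NotSiftableError(ValueError):
    """Signal has too few extrema to build both envelopes."""


class SiftConvergenceWarning(UserWarning):
    """Sifting stopped at the iteration cap before meeting the SD criterion."""


@dataclass(frozen=True)
class IMFDecomposition:
    """Ordered IMFs c_1..c_K plus the final residue r_K.

    Invariant: ``sum(imfs) + residue`` reconstructs the source signal to
    floating-point accuracy, because every stage is an exact subtraction.
    """

    imfs: tuple[TimeSeries, ...]
    residue: TimeSeries
    sd_threshold: float = DEFAULT_SD_THRESHOLD

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        total = self.residue.samples.copy()
        for imf in self.imfs:
            total += imf.samples
        return total


@dataclass(frozen=True)
class GroupedIMFs:
    """Exactly four grouped mode signals I1..I4 (high to low frequency).

    ``members[k]`` holds the 1-based IMF indices summed into group k; the
    four tuples partition {1..K}.  Groups left empty (when fewer than four
    IMFs exist) carry an all-zero signal.
    """

    groups: tuple[TimeSeries, TimeSeries, TimeSeries, TimeSeries]
    members: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 4 or len(self.members) != 4:
            raise ValueError("GroupedIMFs requires exactly four groups")


def find_extrema(
    s: TimeSeries | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Strict interior local maxima and minima of a signal.

    Returns ``(max_idx, max_val, min_idx, min_val)``.  A plateau that is a
    local extremum is represented by its first index.

    Raises
    ------
    ValueError
        If the signal has fewer than 3 samples.
    """
    x = s.samples if isinstance(s, TimeSeries) else np.asarray(s, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to locate interior extrema")

    # Compress equal-valued runs so plateaus reduce to their first index.
    run_start = np.flatnonzero(np.concatenate(([True], np.diff(x) != 0)))
    rv = x[run_start]
    if rv.size < 3:
        empty_i = np.array([], dtype=int)
        empty_v = np.array([], dtype=float)
        return empty_i, empty_v, empty_i.copy(), empty_v.copy()

    step = np.sign(np.diff(rv))
    max_runs = np.flatnonzero((step[:-1] > 0) & (step[1:] < 0)) + 1
    min_runs = np.flatnonzero((step[:-1] < 0) & (step[1:] > 0)) + 1
    max_idx = run_start[max_runs]
    min_idx = run_start[min_runs]
    return max_idx, x[max_idx], min_idx, x[min_idx]


def _mirror_knots(
    idx: np.ndarray, val: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect the two extrema nearest each signal end across the boundary.

    Standard mitigation of spline end swings: extrema at indices t near the
    left edge gain mirror images at -t, and near the right edge at
    2(n-1) - t, before the spline is fitted; the envelope is then evaluated
    only on [0, n-1].
    """
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    ext_i = np.concatenate([left_i, idx, right_i]).astype(float)
    ext_v = np.concatenate([left_v, val, right_v])
    # Mirroring an extremum sitting exactly on the boundary duplicates its
    # abscissa; keep one copy so knots stay strictly increasing.
    keep = np.concatenate(([True], np.diff(ext_i) > 0))
    return ext_i[keep], ext_v[keep]


def envelopes(s: TimeSeries | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower cubic-spline envelopes evaluated at every sample.

    Natural cubic splines (zero second derivative at the end knots) are fit
    through the maxima and the minima respectively, after mirror-extending
    the two extrema nearest each end.

    Raises
    ------
    NotSiftableError
        If fewer than 2 maxima or 2 minima exist.
    """
    x = s.samples if isinstance(s, TimeSeries) else np.asarray(s, dtype=float)
    max_idx, max_val, min_idx, min_val = find_extrema(x)
    if max_idx.size < 2 or min_idx.size < 2:
        raise NotSiftableError(
            f"need >= 2 maxima and >= 2 minima, found {max_idx.size} / {min_idx.size}"
        )
    t = np.arange(x.size)
    ui, uv = _mirror_knots(max_idx, max_val, x.size)
    li, lv = _mirror_knots(min_idx, min_val, x.size)
    upper = CubicSpline(ui, uv, bc_type="natural")(t)
    lower = CubicSpline(li, lv, bc_type="natural")(t)
    return upper, lower


def sd_criterion(m: np.ndarray, d_prev: np.ndarray) -> float:
    """Envelope-mean energy relative to the sifted signal energy.

    ``SD = sum |m(t)|^2 / sum |d_{j-1}(t)|^2``; sifting stops once SD drops
    to the threshold or below.
    """
    m = np.asarray(m, dtype=float)
    d_prev = np.asarray(d_prev, dtype=float)
    if m.shape != d_prev.shape:
        raise ValueError("m and d_prev must have equal length")
    denom = float(np.sum(d_prev * d_prev))
    if denom == 0.0:
        raise ZeroDivisionError("sifted signal has zero energy; SD undefined")
    return float(np.sum(m * m)) / denom


def _zero_crossings(x: np.ndarray) -> int:
    signs = np.sign(x)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def is_imf(
    s: TimeSeries | np.ndarray, sd_threshold: float = DEFAULT_SD_THRESHOLD
) -> bool:
    """Whether a signal already satisfies the IMF properties.

    Standard definition: the extrema and zero-crossing counts differ by at
    most one, and the envelope-mean energy ratio is within the sifting
    threshold.  Non-siftable or zero-energy signals are not IMFs.
    """
    x = s.samples if isinstance(s, TimeSeries) else np.asarray(s, dtype=float)
    if x.size < 3:
        return False
    try:
        upper, lower = envelopes(x)
    except NotSiftableError:
        return False
    max_idx, _, min_idx, _ = find_extrema(x)
    n_extrema = max_idx.size + min_idx.size
    if abs(n_extrema - _zero_crossings(x)) > 1:
        return False
    m = 0.5 * (upper + lower)
    try:
        return sd_criterion(m, x) <= sd_threshold
    except ZeroDivisionError:
        return False


def _is_monotonic(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def sift(
    d0: TimeSeries,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_iter: int = DEFAULT_MAX_SIFT_ITER,
) -> TimeSeries:
    """Extract a single IMF from ``d0`` by iterative envelope-mean removal.

    Each iteration subtracts the mean of the upper and lower envelopes; the
    iterate d_j is returned as the IMF as soon as the SD criterion computed
    from (m, d_{j-1}) is not greater than ``sd_threshold``.

    Raises
    ------
    NotSiftableError
        If ``d0`` itself lacks the extrema needed for envelopes (distinct
        from hitting the iteration cap, which only warns).
    """
    d = d0.samples.copy()
    if max_iter == 0:
        warnings.warn(
            "max_iter=0: returning the input unsifted", SiftConvergenceWarning
        )
        return d0.with_samples(d)
    for j in range(max_iter):
        try:
            upper, lower = envelopes(d)
        except NotSiftableError:
            if j == 0:
                raise
            # The iterate degenerated mid-sift; accept it as the IMF.
            break
        m = 0.5 * (upper + lower)
        sd = sd_criterion(m, d)
        d = d - m
        if sd <= sd_threshold:
            return d0.with_samples(d)
    else:
        warnings.warn(
            f"sifting did not meet SD <= {sd_threshold} in {max_iter} iterations",
            SiftConvergenceWarning,
        )
    return d0.with_samples(d)


def decompose(
    x: TimeSeries,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_iter: int = DEFAULT_MAX_SIFT_ITER,
    max_imfs: int = DEFAULT_MAX_IMFS,
) -> IMFDecomposition:
    """Full EMD of a signal into IMFs plus a residue.

    IMFs are extracted in order of decreasing frequency by repeated sifting
    of the running residue r_i = r_{i-1} - c_i.  Decomposition stops when
    the residue is monotonic, is no longer siftable, or ``max_imfs`` have
    been extracted; a residue that itself satisfies the IMF properties is
    taken as the final IMF (leaving a zero residue) and completes the
    decomposition.

    The operation is deterministic: identical inputs give bit-identical
    outputs.
    """
    if len(x) < 3:
        raise ValueError("need at least 3 samples to decompose")
    residue = x.samples.copy()
    imfs: list[TimeSeries] = []
    while len(imfs) < max_imfs:
        if _is_monotonic(residue):
            break
        if imfs and is_imf(residue, sd_threshold):
            imfs.append(x.with_samples(residue.copy(), id=f"imf{len(imfs) + 1}"))
            residue = np.zeros_like(residue)
            break
        try:
            c = sift(x.with_samples(residue), sd_threshold, max_iter)
        except NotSiftableError:
            break
        imfs.append(x.with_samples(c.samples, id=f"imf{len(imfs) + 1}"))
        residue = residue - c.samples
    return IMFDecomposition(
        imfs=tuple(imfs),
        residue=x.with_samples(residue, id="residue"),
        sd_threshold=sd_threshold,
    )


#: 1-based IMF membership of the four groups, for 4..8 extracted IMFs.
_GROUPING_TABLE: dict[int, tuple[tuple[int, ...], ...]] = {
    4: ((1,), (2,), (3,), (4,)),
    5: ((1,), (2,), (3, 4), (5,)),
    6: ((1,), (2, 3), (4, 5), (6,)),
    7: ((1, 2), (3, 4), (5, 6), (7,)),
    8: ((1, 2), (3, 4), (5, 6), (7, 8)),
}


def grouping_members(n_imfs: int) -> tuple[tuple[int, ...], ...]:
    """1-based IMF indices assigned to groups I1..I4 for a given IMF count.

    Counts of 4-8 follow the fixed table; below 4 the IMFs fill the leading
    groups (the rest stay empty); above 8 every IMF from index 7 on is
    merged into I4.
    """
    if n_imfs < 1:
        raise ValueError("no IMFs to group")
    if n_imfs in _GROUPING_TABLE:
        return _GROUPING_TABLE[n_imfs]
    if n_imfs < 4:
        return tuple(
            (i + 1,) if i < n_imfs else () for i in range(4)
        )
    return ((1, 2), (3, 4), (5, 6), tuple(range(7, n_imfs + 1)))


def group_imfs(dec: IMFDecomposition) -> GroupedIMFs:
    """Merge the IMFs of a decomposition into the four grouped signals.

    Each group signal is the elementwise sum of its member IMFs; every IMF
    belongs to exactly one group.  With fewer than four IMFs the trailing
    groups are all-zero signals (a warning is emitted so downstream feature
    rows can be recognised as degenerate).
    """
    k = dec.n_imfs
    if k == 0:
        raise ValueError("no IMFs to group")
    members = grouping_members(k)
    if k < 4:
        warnings.warn(
            f"only {k} IMFs extracted; groups {k + 1}..4 are zero signals",
            UserWarning,
        )
    template = dec.imfs[0]
    groups = []
    for gi, member in enumerate(members, start=1):
        if member:
            total = np.sum([dec.imfs[i - 1].samples for i in member], axis=0)
        else:
            total = np.zeros(len(template))
        groups.append(template.with_samples(total, id=f"I{gi}"))
    return GroupedIMFs(groups=tuple(groups), members=members)
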