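"""Reading, filtering and reshaping of parcellated BOLD time series.

The source-space object is a plain ``T x N`` real matrix (rows = time frames,
columns = regions) with a repetition time (TR) attached.  Temporal
preprocessing follows the standard resting-state recipe: a second-order
Butterworth band-pass (0.008-0.08 Hz) applied forward-backward so that no
group delay distorts the lag structure, followed by discarding the first and
last 5% of frames to avoid filter border effects.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal


class TimeSeriesParseError(ValueError):
    """Raised when a time-series file cannot be parsed into a numeric matrix."""


class ShapeError(ValueError):
    """Raised when an array has an invalid or inconsistent shape."""


class FilterConfigError(ValueError):
    """Raised when a filter band is infeasible for the sampling rate."""


@dataclass
class BoldTimeSeries:
    """A ``T x N`` regional signal matrix with sampling information.

    Parameters
    ----------
    data : ndarray, shape (T, N)
        Regional signals, rows are time frames.
    tr_seconds : float
        Repetition time (sampling period) in seconds.
    region_labels : list of str, optional
        One label per region; generated as ``r000..`` if omitted.
    subject_id : str
    condition : str
        Condition label, e.g. ``REST``, ``WM``, ``MOT``.
    """

    data: np.ndarray
    tr_seconds: float
    region_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError(f"data must be 2-D, got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise ShapeError(f"need at least 2 time frames, got {self.data.shape[0]}")
        if self.data.shape[1] < 2:
            raise ShapeError(f"need at least 2 regions, got {self.data.shape[1]}")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise TimeSeriesParseError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not self.region_labels:
            self.region_labels = [f"r{i:03d}" for i in range(self.data.shape[1])]
        if len(self.region_labels) != self.data.shape[1]:
            raise ShapeError(
                f"{len(self.region_labels)} labels for {self.data.shape[1]} regions"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "BoldTimeSeries":
        """Copy of this object with ``data`` replaced."""
        return dataclasses.replace(self, data=data)


@dataclass
class FilterSpec:
    """Butterworth band-pass specification (defaults: order 2, 0.008-0.08 Hz)."""

    order: int = 2
    low_hz: float = 0.008
    high_hz: float = 0.08

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise FilterConfigError(
                f"band [{self.low_hz}, {self.high_hz}] Hz infeasible for "
                f"TR={tr_seconds}s (Nyquist {nyquist:.4g} Hz)"
            )
        if self.order < 1:
            raise FilterConfigError(f"order must be >= 1, got {self.order}")

    def sos(self, tr_seconds: float) -> np.ndarray:
        """Second-order-section coefficients for the sampling rate 1/TR."""
        self.validate(tr_seconds)
        fs = 1.0 / tr_seconds
        return signal.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass",
            fs=fs, output="sos",
        )


@dataclass
class PatternSet:
    """Time-by-time spatial patterns pooled across subjects/conditions.

    ``patterns`` is ``K x N`` (one row per time frame); ``train_mask`` marks
    the training rows.  When z-scoring is on, the per-region mean/SD are
    computed on the training rows only and stored so the transform is
    invertible.
    """

    patterns: np.ndarray
    train_mask: np.ndarray
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    frame_subjects: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return self.patterns.shape[1]

    @property
    def train(self) -> np.ndarray:
        return self.patterns[self.train_mask]

    @property
    def test(self) -> np.ndarray:
        return self.patterns[~self.train_mask]

    def unnormalize(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return np.asarray(x)
        return np.asarray(x) * self.sd + self.mean


def load_timeseries(
    path: str | Path,
    tr_seconds: float,
    subject_id: str = "",
    condition: str = "",
    allow_transpose: bool = False,
) -> BoldTimeSeries:
    """Load a delimited numeric matrix (rows = time frames) as a BoldTimeSeries.

    The delimiter is sniffed (comma/tab/whitespace); an optional single header
    row of region labels is detected.  If ``allow_transpose`` and the file has
    more columns than rows, the matrix is transposed with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", header=None)
    except Exception as exc:  # pragma: no cover - delegated parse failures
        raise TimeSeriesParseError(f"cannot parse {path}: {exc}") from exc

    labels: list[str] = []
    first = df.iloc[0]
    if first.apply(lambda v: isinstance(v, str)).any():
        labels = [str(v) for v in first]
        df = df.iloc[1:].reset_index(drop=True)

    try:
        data = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise TimeSeriesParseError(f"non-numeric cell in {path}: {exc}") from exc
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        r, c = bad[0]
        raise TimeSeriesParseError(
            f"non-finite value in {path} at row {r}, column {c}"
        )
    if data.shape[0] < 2:
        raise ShapeError(f"{path}: fewer than 2 time frames")
    if allow_transpose and data.shape[1] > data.shape[0]:
        warnings.warn(
            f"{path}: more columns than rows; transposing to rows=time",
            stacklevel=2,
        )
        data = data.T
        labels = []
    return BoldTimeSeries(
        data=data, tr_seconds=tr_seconds,
        region_labels=labels, subject_id=subject_id, condition=condition,
    )


def save_timeseries(ts: BoldTimeSeries, path: str | Path, header: bool = True) -> None:
    """Write a BoldTimeSeries as delimited text (region-label header optional).

    The delimiter follows the file extension: tab for ``.tsv``, comma
    otherwise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.DataFrame(ts.data, columns=ts.region_labels)
    df.to_csv(path, index=False, header=header, sep=sep, float_format="%.17g")


def bandpass_filter(ts: BoldTimeSeries, spec: FilterSpec | None = None) -> BoldTimeSeries:
    """Zero-phase Butterworth band-pass, each region filtered independently.

    Forward-backward (``sosfiltfilt``) application cancels the group delay,
    preserving the lag structure that the forward-shifted correlations rely
    on; the effective magnitude response is the squared one-pass response.
    """
    spec = spec or FilterSpec()
    sos = spec.sos(ts.tr_seconds)
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return ts.with_data(filtered)


def trim_edges(ts: BoldTimeSeries, fraction: float = 0.05) -> BoldTimeSeries:
    """Discard ``floor(fraction * T)`` frames from each end of the series."""
    if not 0.0 <= fraction < 0.5:
        raise ValueError(f"fraction must be in [0, 0.5), got {fraction}")
    n = int(np.floor(fraction * ts.n_frames))
    if n == 0:
        return ts.with_data(ts.data.copy())
    if ts.n_frames - 2 * n < 2:
        raise ShapeError(
            f"trimming {n} frames per end leaves fewer than 2 of {ts.n_frames}"
        )
    return ts.with_data(ts.data[n:-n].copy())


def preprocess(
    ts: BoldTimeSeries,
    spec: FilterSpec | None = None,
    trim_fraction: float = 0.05,
) -> BoldTimeSeries:
    """Band-pass then edge-trim: the standard temporal preprocessing chain."""
    return trim_edges(bandpass_filter(ts, spec), trim_fraction)


def build_pattern_set(
    series: list[BoldTimeSeries],
    train_frac: float = 0.9,
    normalize: bool = True,
    seed: int = 0,
) -> PatternSet:
    """Pool frames across recordings and split train/test at the subject level.

    All frames of a held-out subject go to the test side: the split shuffles
    the subject order (seeded) and assigns whole subjects to the training side
    until the requested frame fraction is reached.  Z-scoring, when on, uses
    per-region statistics of the training frames only.
    """
    if not series:
        raise ValueError("no series given")
    n = series[0].n_regions
    for ts in series:
        if ts.n_regions != n:
            raise ShapeError(
                f"inconsistent region counts: {ts.n_regions} vs {n}"
            )
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")

    patterns = np.vstack([ts.data for ts in series])
    subj = np.concatenate([
        np.full(ts.n_frames, ts.subject_id or f"s{i}", dtype=object)
        for i, ts in enumerate(series)
    ])
    total = patterns.shape[0]

    rng = np.random.default_rng(seed)
    subjects = list(dict.fromkeys(subj))  # stable unique order
    rng.shuffle(subjects)
    frames_per = {s: int((subj == s).sum()) for s in subjects}

    target = train_frac * total
    train_subjects: set[str] = set()
    acc = 0
    for s in subjects:
        if acc >= target:
            break
        train_subjects.add(s)
        acc += frames_per[s]
    if len(train_subjects) == len(subjects):  # keep at least one test subject
        train_subjects.discard(subjects[-1])

    train_mask = np.array([s in train_subjects for s in subj])

    mean = sd = None
    if normalize:
        train = patterns[train_mask]
        mean = train.mean(axis=0)
        sd = train.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        patterns = (patterns - mean) / sd

    return PatternSet(
        patterns=patterns, train_mask=train_mask,
        mean=mean, sd=sd, frame_subjects=subj,
    )
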