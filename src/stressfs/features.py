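"""Multi-domain EEG feature extraction and fusion.

Per channel: Hjorth activity/mobility/complexity, peak-to-peak amplitude,
line length, kurtosis, skewness (time domain); relative and absolute power
in theta / alpha / sigma / low-beta / high-beta plus broadband total power
(frequency domain); Welch spectral entropy and Katz fractal dimension
(time-frequency domain).  Across channel pairs: phase-locking value (PLV)
connectivity.  Everything is fused into one row per epoch and z-scored
column-wise.

Two per-channel rosters are provided:

``"full"`` (default)
    20 descriptors per channel.  This is the 14-descriptor literal roster
    augmented with the five absolute band powers and broadband total power,
    so that the fused dimensionality is ``20*C + C*(C-1)/2`` — 161 features
    for 7 channels, 188 for 8, 86 for 4.
``"literal"``
    The 14 descriptors listed above without the absolute-power block.

All moments use the population convention (divide by N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.signal import hilbert

from .errors import (
    ConstantColumnError,
    ConstantSignalError,
    ExtractionError,
    InsufficientChannelsError,
    InvalidBandError,
    TooShortSignalError,
)
from .preprocessing import EpochSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "FeatureTable",
    "Standardizer",
    "hjorth_parameters",
    "peak_to_peak",
    "line_length",
    "skewness_kurtosis",
    "relative_band_powers",
    "absolute_band_powers",
    "spectral_entropy",
    "katz_fd",
    "phase_locking_value",
    "extract_features",
    "zscore_normalize",
    "fused_dimension",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise InvalidBandError(f"band {self.name}: need lo < hi, got [{self.lo}, {self.hi})")


#: The five analysis bands; their union (4-30 Hz) is the relative-power denominator.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 15.0),
    BandDefinition("low_beta", 15.0, 20.0),
    BandDefinition("high_beta", 20.0, 30.0),
)


@dataclass
class FeatureTable:
    """Fused feature matrix: one row per epoch, provenance-bearing column names.

    Column names are ``<channel>|<domain>|<feature>`` for per-channel
    descriptors and ``<chA>-<chB>|connectivity|plv`` for pairs.
    """

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (epochs x features)")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("y length must equal number of rows")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        y = None if self.y is None else self.y[idx]
        return FeatureTable(self.X[idx], list(self.feature_names), y)

    def to_csv(self, path) -> None:
        """Write as CSV: header = feature names, final column ``label``."""
        df = pd.DataFrame(self.X, columns=self.feature_names)
        if self.y is not None:
            df["label"] = self.y
        df.to_csv(path, index=False, float_format="%.17g")  # lossless round-trip

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        y = None
        if "label" in df.columns:
            y = df.pop("label").to_numpy(dtype=int)
        return cls(df.to_numpy(dtype=float), list(df.columns), y)


# ---------------------------------------------------------------------------
# Per-channel descriptors
# ---------------------------------------------------------------------------

def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity, mobility and complexity of a single-channel signal.

    Activity is the population variance; mobility the SD ratio of the first
    difference to the signal; complexity the mobility of the first difference
    over the mobility of the signal (≈1 for a pure sinusoid).

    Raises
    ------
    ConstantSignalError
        If the signal (or its first difference) has zero variance, where
        mobility/complexity involve a division by zero.  Activity would be 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise TooShortSignalError("Hjorth parameters need >= 3 samples")
    activity = float(x.var())
    if activity == 0.0:
        raise ConstantSignalError("mobility undefined for a constant signal (activity = 0)")
    d1 = np.diff(x)
    var1 = float(d1.var())
    if var1 == 0.0:
        raise ConstantSignalError("complexity undefined: first difference is constant")
    mobility = float(np.sqrt(var1 / activity))
    d2 = np.diff(d1)
    mobility_d1 = float(np.sqrt(d2.var() / var1))
    return activity, mobility, mobility_d1 / mobility


def peak_to_peak(x: np.ndarray) -> float:
    """max(x) - min(x); shift-invariant and non-negative."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise TooShortSignalError("peak_to_peak of an empty signal")
    return float(x.max() - x.min())


def line_length(x: np.ndarray) -> float:
    """Total vertical excursion: sum of absolute first differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise TooShortSignalError("line_length needs >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def skewness_kurtosis(x: np.ndarray) -> tuple[float, float]:
    """Population skewness and (non-excess) kurtosis.

    Kurtosis is the fourth central moment over sigma**4, so it is >= 1 for
    any sample and -> 3 for a Gaussian.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise TooShortSignalError("moments need >= 3 samples")
    mu = x.mean()
    d = x - mu
    var = float((d**2).mean())
    if var == 0.0:
        raise ConstantSignalError("skewness/kurtosis undefined for zero variance")
    sd = np.sqrt(var)
    skew = float((d**3).mean() / sd**3)
    kurt = float((d**4).mean() / var**2)
    return skew, kurt


def _welch(x: np.ndarray, fs: float, seg_s: float = 4.0):
    nperseg = min(int(round(seg_s * fs)), x.size)
    return sps.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2
    )


def _band_mask(f: np.ndarray, band: BandDefinition) -> np.ndarray:
    return (f >= band.lo) & (f < band.hi)


def absolute_band_powers(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    seg_s: float = 4.0,
) -> np.ndarray:
    """Welch power in each band (PSD integrated over the half-open band)."""
    for b in bands:
        if b.hi > fs / 2.0:
            raise InvalidBandError(f"band {b.name} [{b.lo}, {b.hi}) exceeds Nyquist {fs / 2}")
    f, pxx = _welch(np.asarray(x, dtype=float), fs, seg_s)
    df = f[1] - f[0]
    return np.array([pxx[_band_mask(f, b)].sum() * df for b in bands])


def relative_band_powers(
    x: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    seg_s: float = 4.0,
) -> np.ndarray:
    """Percent power per band, relative to the union of all ``bands``.

    With the default contiguous bands the denominator is 4-30 Hz, so the
    five values sum to exactly 100.
    """
    powers = absolute_band_powers(x, fs, bands, seg_s)
    total = powers.sum()
    if total <= 0.0:
        raise ConstantSignalError("zero in-band power; relative powers undefined")
    return 100.0 * powers / total


def spectral_entropy(
    x: np.ndarray,
    fs: float,
    fmin: float = 4.0,
    fmax: float = 35.0,
    seg_s: float = 4.0,
) -> float:
    """Shannon entropy (natural log) of the normalized Welch PSD.

    Computed over ``[fmin, min(fmax, 45, Nyquist)]``; the PSD is normalized
    to sum to 1 over that range, so the result lies in ``[0, log K]`` for K
    analysis bins.  Amplitude-scaling invariant.
    """
    x = np.asarray(x, dtype=float)
    hi = min(fmax, 45.0, fs / 2.0)
    if hi <= fmin:
        raise InvalidBandError(f"empty analysis range [{fmin}, {hi}] Hz")
    f, pxx = _welch(x, fs, seg_s)
    sel = (f >= fmin) & (f <= hi)
    p = pxx[sel]
    total = p.sum()
    if total <= 0.0:
        raise ConstantSignalError("zero power in the analysis range")
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of the waveform.

    The signal is treated as a planar curve of points ``(i, x_i)`` with unit
    time step: ``L`` is the curve length (sum of successive point distances),
    ``d`` the maximum distance from the first point, ``n`` the number of
    steps, and ``D = log10(n) / (log10(d/L) + log10(n))``.  A straight line
    (e.g. a ramp) gives exactly 1; any other curve gives > 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise TooShortSignalError("Katz dimension needs >= 2 samples")
    dx = np.diff(x)
    L = float(np.sqrt(1.0 + dx**2).sum())
    i = np.arange(x.size, dtype=float)
    d = float(np.sqrt(i**2 + (x - x[0]) ** 2).max())
    n = x.size - 1
    if d == 0.0 or L == 0.0:
        raise ConstantSignalError("degenerate curve: zero extent")
    return float(np.log10(n) / (np.log10(d / L) + np.log10(n)))


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def phase_locking_value(
    epoch: np.ndarray,
    fs: float | None = None,
    band: BandDefinition | None = None,
) -> np.ndarray:
    """Pairwise phase-locking value matrix for one epoch.

    Instantaneous phases come from the analytic (Hilbert) signal of each
    channel; ``PLV_ab = |mean exp(i (phi_a - phi_b))|``.  Entries lie in
    [0, 1], the matrix is symmetric with unit diagonal; identical channels
    or a constant phase lag give 1, independent phases give ~sqrt(pi)/(2 sqrt(N)).

    ``band`` optionally narrows the signal with a zero-phase FIR band-pass
    before phase estimation (requires ``fs``); the default is broadband.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise InsufficientChannelsError("PLV needs a (channels x samples) array with >= 2 channels")
    data = epoch
    if band is not None:
        if fs is None:
            raise ValueError("band-limited PLV requires fs")
        taps = sps.firwin(
            min(129, 2 * (epoch.shape[1] // 6) + 1),
            [band.lo, band.hi],
            pass_zero=False,
            window="hamming",
            fs=fs,
        )
        data = sps.filtfilt(taps, [1.0], epoch, axis=1)
    phases = np.angle(hilbert(data, axis=1))
    z = np.exp(1j * phases)
    # PLV_ab = |mean_t z_a conj(z_b)|, computed as a Gram matrix.
    plv = np.abs(z @ z.conj().T) / epoch.shape[1]
    np.fill_diagonal(plv, 1.0)
    return np.clip(plv, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

_TIME_FEATURES = (
    "activity", "mobility", "complexity", "ptp", "line_length", "kurtosis", "skewness",
)


def fused_dimension(n_channels: int, roster: str = "full") -> int:
    """Number of fused features for ``n_channels`` under a roster mode."""
    per_channel = 20 if roster == "full" else 14
    return per_channel * n_channels + n_channels * (n_channels - 1) // 2


def _channel_features(
    x: np.ndarray, fs: float, bands, roster: str, seg_s: float
) -> list[float]:
    activity, mobility, complexity = hjorth_parameters(x)
    skew, kurt = skewness_kurtosis(x)
    vals = [
        activity, mobility, complexity,
        peak_to_peak(x), line_length(x), kurt, skew,
    ]
    rel = relative_band_powers(x, fs, bands, seg_s)
    vals.extend(rel)
    if roster == "full":
        absolute = absolute_band_powers(x, fs, bands, seg_s)
        vals.extend(absolute)
        vals.append(float(absolute.sum()))
    vals.append(spectral_entropy(x, fs, seg_s=seg_s))
    vals.append(katz_fd(x))
    return vals


def _channel_feature_names(name: str, bands, roster: str) -> list[str]:
    cols = [f"{name}|time|{feat}" for feat in _TIME_FEATURES]
    cols += [f"{name}|frequency|relpow_{b.name}" for b in bands]
    if roster == "full":
        cols += [f"{name}|frequency|abspow_{b.name}" for b in bands]
        cols.append(f"{name}|frequency|total_power")
    cols.append(f"{name}|time_frequency|spectral_entropy")
    cols.append(f"{name}|time_frequency|katz_fd")
    return cols


def extract_features(
    epochs: EpochSet,
    roster: str = "full",
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    plv_band: BandDefinition | None = None,
    seg_s: float = 4.0,
) -> FeatureTable:
    """Compute the full multi-domain feature vector for every epoch.

    Columns are ordered deterministically: per-channel blocks in channel
    order, then PLV pairs in lexicographic (i, j) order.  Epochs on which
    any descriptor fails (e.g. a flat channel) are dropped with a warning;
    if every epoch fails an :class:`ExtractionError` is raised.
    """
    if roster not in ("full", "literal", "plv"):
        raise ValueError(f"unknown roster mode {roster!r}")
    names = list(epochs.channel_names)
    cols: list[str] = []
    if roster != "plv":
        for name in names:
            cols.extend(_channel_feature_names(name, bands, roster))
    n_ch = epochs.n_channels
    pairs = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
    cols.extend(f"{names[i]}-{names[j]}|connectivity|plv" for i, j in pairs)

    rows, kept, failed = [], [], []
    for e in range(epochs.n_epochs):
        epoch = epochs.epochs[e]
        try:
            vals: list[float] = []
            if roster != "plv":
                for c in range(n_ch):
                    vals.extend(_channel_features(epoch[c], epochs.fs, bands, roster, seg_s))
            plv = phase_locking_value(epoch, epochs.fs, band=plv_band)
            vals.extend(plv[i, j] for i, j in pairs)
        except (ConstantSignalError, TooShortSignalError) as exc:
            failed.append((e, str(exc)))
            continue
        rows.append(vals)
        kept.append(e)
    if failed:
        warnings.warn(
            f"dropped {len(failed)} epoch(s) with failed features: "
            + "; ".join(f"epoch {e}: {msg}" for e, msg in failed[:5]),
            stacklevel=2,
        )
    if not rows:
        raise ExtractionError("feature extraction failed on every epoch")
    X = np.asarray(rows, dtype=float)
    y = None if epochs.labels is None else epochs.labels[np.asarray(kept)]
    return FeatureTable(X, cols, y)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Column-wise z-score parameters learned on training rows.

    Population standard deviation (divide by N); parameters are applied
    unchanged to held-out rows.
    """

    mean_: np.ndarray = field(default=None)  # type: ignore[assignment]
    sd_: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_names: list[str] = field(default_factory=list)

    def fit(self, table: FeatureTable) -> "Standardizer":
        mean = table.X.mean(axis=0)
        sd = table.X.std(axis=0)
        flat = np.flatnonzero(sd == 0.0)
        if flat.size:
            raise ConstantColumnError(
                "zero-spread column(s): "
                + ", ".join(table.feature_names[i] for i in flat[:5])
            )
        self.mean_, self.sd_ = mean, sd
        self.feature_names = list(table.feature_names)
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        if table.feature_names != self.feature_names:
            raise ValueError("feature names differ from the fitting table")
        return FeatureTable(
            (table.X - self.mean_) / self.sd_, list(table.feature_names), table.y
        )


def zscore_normalize(table: FeatureTable) -> tuple[FeatureTable, Standardizer]:
    """Z-score every column on the given rows; returns the fitted parameters
    so held-out rows can be transformed with training statistics only."""
    std = Standardizer().fit(table)
    return std.transform(table), std
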