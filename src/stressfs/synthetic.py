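"""Seed-reproducible synthetic inputs with the structure the method assumes.

Two generators:

:func:`generate_eeg`
    Two-class multichannel oscillatory EEG.  Each epoch is a sum of
    band-limited Gaussian oscillations (one per analysis band, synthesized
    by zero-phase filtering of white noise so PSD-based features have
    realistic spread) plus broadband sensor noise.  The stress class can
    differ in per-band power (``band_effects``, power ratios class 1 vs
    class 0) and in pairwise phase coupling (``coupling_pairs`` share a
    common oscillatory process in class 1).

:func:`generate_table`
    Abstract feature tables with planted structure: informative columns
    (class-shifted Gaussians at a stated standardized effect size),
    redundant columns (correlated copies of informative parents), and pure
    noise columns.  Ground-truth index sets are returned for recovery
    scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigError
from .features import DEFAULT_BANDS, FeatureTable
from .preprocessing import EpochSet

__all__ = [
    "SyntheticSpec",
    "PlantedTableSpec",
    "PlantedTruth",
    "generate_eeg",
    "generate_table",
    "signal_recovery",
]

#: Rough 1/f-like base amplitudes (uV RMS) per default band, rest condition.
_BASE_AMPLITUDES = {
    "theta": 1.0,
    "alpha": 1.5,
    "sigma": 0.8,
    "low_beta": 0.7,
    "high_beta": 0.6,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the signal-level generator.

    ``band_effects`` maps band name to the class-1/class-0 power ratio; the
    default emulates the classic stress signature of frontal alpha
    suppression with a beta increase.  ``coupling_pairs`` lists channel
    pairs whose phase locking is elevated under stress.
    """

    n_channels: int = 7
    fs: float = 256.0
    window_s: float = 20.0
    n_epochs_per_class: int = 20
    band_effects: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.6, "high_beta": 1.4}
    )
    coupling_pairs: tuple[tuple[int, int], ...] = ((0, 1),)
    coupling_strength: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 60:
            raise ConfigError(f"fs must exceed 60 Hz, got {self.fs}")
        if self.window_s < 0.5:  # < 2 cycles of the lowest (4 Hz) band
            raise ConfigError(
                f"window_s = {self.window_s} too short for 2 cycles of 4 Hz"
            )
        if self.n_channels < 2:
            raise ConfigError("need >= 2 channels")
        if self.n_epochs_per_class < 1:
            raise ConfigError("need >= 1 epoch per class")
        if any(r <= 0 for r in self.band_effects.values()):
            raise ConfigError("band power ratios must be positive")
        known = {b.name for b in DEFAULT_BANDS}
        unknown = set(self.band_effects) - known
        if unknown:
            raise ConfigError(f"unknown band(s) in band_effects: {sorted(unknown)}")
        for a, b in self.coupling_pairs:
            if not (0 <= a < self.n_channels and 0 <= b < self.n_channels and a != b):
                raise ConfigError(f"invalid coupling pair ({a}, {b})")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ConfigError("coupling_strength must lie in [0, 1]")


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise via zero-phase FIR filtering."""
    pad = 256
    white = rng.standard_normal(n + 2 * pad)
    taps = sps.firwin(129, [lo, hi], pass_zero=False, window="hamming", fs=fs)
    shaped = sps.filtfilt(taps, [1.0], white)[pad:-pad]
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def generate_eeg(spec: SyntheticSpec) -> EpochSet:
    """Generate a balanced, labeled :class:`EpochSet` under ``spec``.

    Class-1 epochs scale each band's amplitude by ``sqrt(ratio)`` (so power
    scales by the ratio) and, for every coupled channel pair, mix a shared
    oscillatory process into both channels with weight
    ``coupling_strength`` (variance-preserving), which elevates their
    broadband phase-locking value.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samp = int(round(spec.window_s * spec.fs))
    coupled = {ch for pair in spec.coupling_pairs for ch in pair}
    epochs, labels = [], []
    for label in (0, 1):
        for _ in range(spec.n_epochs_per_class):
            epoch = np.zeros((spec.n_channels, n_samp))
            # One shared process per band for the coupled channels (class 1).
            shared = {
                b.name: _band_noise(rng, n_samp, spec.fs, b.lo, b.hi)
                for b in DEFAULT_BANDS
            }
            for ch in range(spec.n_channels):
                for b in DEFAULT_BANDS:
                    amp = _BASE_AMPLITUDES[b.name]
                    if label == 1:
                        amp *= np.sqrt(spec.band_effects.get(b.name, 1.0))
                    own = _band_noise(rng, n_samp, spec.fs, b.lo, b.hi)
                    if label == 1 and ch in coupled:
                        c = spec.coupling_strength
                        own = np.sqrt(1.0 - c**2) * own + c * shared[b.name]
                    epoch[ch] += amp * own
                epoch[ch] += spec.noise_sd * rng.standard_normal(n_samp)
            epochs.append(epoch)
            labels.append(label)
    return EpochSet(
        epochs=np.stack(epochs),
        fs=spec.fs,
        window_s=spec.window_s,
        labels=np.asarray(labels),
    )


# ---------------------------------------------------------------------------
# Planted feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedTableSpec:
    """Planted-structure table: informative, redundant-copy, and noise columns."""

    n_rows: int = 400
    n_informative: int = 5
    n_redundant: int = 20
    n_noise: int = 75
    effect_size: float = 1.0  # standardized class-mean separation
    redundancy_rho: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_rows, 0) < 0 or self.n_rows < 4:
            raise ConfigError("need >= 4 rows")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ConfigError("feature counts must be >= 0")
        if self.n_informative + self.n_redundant + self.n_noise == 0:
            raise ConfigError("zero total features")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ConfigError("redundant copies need at least one informative parent")
        if not 0.0 <= self.redundancy_rho <= 1.0:
            raise ConfigError("redundancy_rho must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth column indices after shuffling."""

    informative: np.ndarray
    redundant: np.ndarray
    noise: np.ndarray
    parent: dict[int, int]  # redundant column -> its informative parent

    def groups(self) -> list[set[int]]:
        """One planted signal group per informative column: the column plus
        all of its correlated copies."""
        out = []
        for inf in self.informative:
            members = {int(inf)}
            members.update(r for r, p in self.parent.items() if p == int(inf))
            out.append(members)
        return out


def generate_table(spec: PlantedTableSpec) -> tuple[FeatureTable, PlantedTruth]:
    """Draw a planted-structure table with balanced binary labels.

    Informative column j: ``N((y - 1/2) * effect_size, 1)`` so the
    standardized class separation equals ``effect_size``.  Redundant copy:
    ``rho * parent + sqrt(1 - rho^2) * N(0, 1)`` (population correlation
    rho to its parent, round-robin over parents).  Noise columns are
    independent standard normals.  Column order is shuffled; the returned
    :class:`PlantedTruth` records where everything landed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1  # balanced (class 0 gets the extra row if n is odd)

    m = spec.n_informative + spec.n_redundant + spec.n_noise
    X = np.empty((n, m))
    for j in range(spec.n_informative):
        X[:, j] = rng.standard_normal(n) + (y - 0.5) * spec.effect_size
    for k in range(spec.n_redundant):
        parent = k % spec.n_informative
        X[:, spec.n_informative + k] = spec.redundancy_rho * X[:, parent] + np.sqrt(
            1.0 - spec.redundancy_rho**2
        ) * rng.standard_normal(n)
    for k in range(spec.n_noise):
        X[:, spec.n_informative + spec.n_redundant + k] = rng.standard_normal(n)

    perm = rng.permutation(m)  # shuffled column i holds original column perm[i]
    X = X[:, perm]
    pos = np.argsort(perm)  # original column j now sits at position pos[j]
    informative = np.sort(pos[: spec.n_informative])
    redundant = np.sort(pos[spec.n_informative : spec.n_informative + spec.n_redundant])
    noise = np.sort(pos[spec.n_informative + spec.n_redundant :])
    parent = {
        int(pos[spec.n_informative + k]): int(pos[k % spec.n_informative])
        for k in range(spec.n_redundant)
    }
    names = [f"f{j:03d}" for j in range(m)]
    truth = PlantedTruth(informative, redundant, noise, parent)
    return FeatureTable(X, names, y), truth


def signal_recovery(mask: np.ndarray, truth: PlantedTruth) -> tuple[int, int]:
    """Score a selection mask against the planted ground truth.

    Returns ``(n_informative_selected, n_groups_recovered)`` where a signal
    group (an informative column together with its correlated copies)
    counts as recovered if the mask keeps any member.  With high-rho copies
    the group-level count is the scientifically meaningful one: parent and
    copy are near-exchangeable carriers of the same planted signal.
    """
    mask = np.asarray(mask, dtype=bool)
    n_inf = int(mask[truth.informative].sum()) if truth.informative.size else 0
    n_groups = sum(any(mask[i] for i in grp) for grp in truth.groups())
    return n_inf, n_groups
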