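"""EEG feature extraction: band decomposition, DE/PSD, asymmetry features.

Raw multichannel recordings are band-pass filtered into the five canonical
EEG rhythms — delta (1-3 Hz), theta (4-7 Hz), alpha (8-13 Hz), beta
(14-30 Hz) and gamma (>31 Hz, capped below Nyquist) — segmented into
fixed-length windows, and summarized per window, channel and band.

Differential entropy (DE) is computed under the Gaussian assumption as
``0.5 * ln(2 * pi * e * var)`` of the band-filtered window; power spectral
density (PSD) is the log of the mean periodogram power inside the band.
Asymmetry features (DASM, RASM, ASM) are derived from DE values at symmetric
left/right electrode pairs.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

GAMMA_CAP_FRACTION = 0.45  # open-ended gamma band is capped at 0.45 * rate
VARIANCE_FLOOR = 1e-12

FEATURE_KINDS = ("DE", "PSD", "DASM", "RASM", "ASM")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandSpec:
    """A frequency band; ``high=None`` means open-ended (gamma)."""

    name: str
    low: float
    high: float | None

    def __post_init__(self):
        if self.low <= 0:
            raise ConfigurationError(f"band {self.name}: low edge must be > 0")
        if self.high is not None and not self.low < self.high:
            raise ConfigurationError(
                f"band {self.name}: low ({self.low}) must be < high ({self.high})"
            )

    def effective_high(self, rate: float) -> float:
        return GAMMA_CAP_FRACTION * rate if self.high is None else self.high


def default_bands() -> list[BandSpec]:
    return [
        BandSpec("delta", 1.0, 3.0),
        BandSpec("theta", 4.0, 7.0),
        BandSpec("alpha", 8.0, 13.0),
        BandSpec("beta", 14.0, 30.0),
        BandSpec("gamma", 31.0, None),
    ]


@dataclass
class RawRecording:
    """One trial: channels x samples EEG (microvolts) with identifiers."""

    data: np.ndarray
    rate: float
    channel_labels: list[str]
    subject_id: str
    trial_id: str
    label: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError(
                f"recording {self.subject_id}/{self.trial_id}: data must be "
                f"channels x samples, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError(
                f"recording {self.subject_id}/{self.trial_id}: non-finite samples"
            )
        if self.rate <= 0:
            raise ConfigurationError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise DataError(
                f"recording {self.subject_id}/{self.trial_id}: "
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataError("duplicate channel labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ElectrodeMontage:
    """Channel labels, projected 2-D scalp positions, and mirror pairs."""

    labels: list[str]
    coords2d: np.ndarray
    symmetric_pairs: list[tuple[int, int]]

    def __post_init__(self):
        self.coords2d = np.asarray(self.coords2d, dtype=float)
        n = len(self.labels)
        if self.coords2d.shape != (n, 2):
            raise ConfigurationError(
                f"coords2d must be {n} x 2, got {self.coords2d.shape}"
            )
        if not np.all(np.isfinite(self.coords2d)):
            raise ConfigurationError("non-finite montage coordinates")
        for left, right in self.symmetric_pairs:
            if not (0 <= left < n and 0 <= right < n) or left == right:
                raise ConfigurationError(f"invalid symmetric pair ({left}, {right})")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class FeatureTensor:
    """Per-trial windows(T) x channels(N) x bands(F) feature values."""

    values: np.ndarray
    band_names: list[str]
    window_seconds: float
    subject_id: str
    trial_id: str
    label: int
    feature_kind: str = "DE"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataError(f"feature tensor must be T x N x F, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise DataError(
                f"feature tensor {self.subject_id}/{self.trial_id}: non-finite values"
            )


@dataclass
class FeatureConfig:
    feature_kind: str = "DE"
    bands: list[BandSpec] = field(default_factory=default_bands)
    window_seconds: float = 1.0
    stride_seconds: float | None = None  # default: non-overlapping
    smoothing: int | None = None  # moving-average length along T, off by default
    log_psd: bool = True

    def __post_init__(self):
        if self.feature_kind not in FEATURE_KINDS:
            raise ConfigurationError(
                f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        if self.window_seconds <= 0:
            raise ConfigurationError("window_seconds must be > 0")
        if self.stride_seconds is None:
            self.stride_seconds = self.window_seconds
        if self.stride_seconds <= 0:
            raise ConfigurationError("stride_seconds must be > 0")
        if not self.bands:
            raise ConfigurationError("band list must be non-empty")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def bandpass_decompose(rec: RawRecording, bands: list[BandSpec] | None = None) -> np.ndarray:
    """Zero-phase band-pass filter ``rec`` into each band.

    Returns an array of shape ``(n_bands, channels, samples)``.  Uses an
    order-4 Butterworth filter applied forward-backward (``sosfiltfilt``) so
    band energy is not time-shifted.
    """
    bands = default_bands() if bands is None else bands
    nyquist = rec.rate / 2.0
    out = np.empty((len(bands), rec.n_channels, rec.n_samples))
    for i, band in enumerate(bands):
        high = band.effective_high(rec.rate)
        if high >= nyquist or band.low >= nyquist:
            raise ConfigurationError(
                f"band {band.name} ({band.low}-{high} Hz) exceeds Nyquist "
                f"({nyquist} Hz) at rate {rec.rate} Hz"
            )
        sos = sps.butter(4, [band.low, high], btype="bandpass", fs=rec.rate, output="sos")
        out[i] = sps.sosfiltfilt(sos, rec.data, axis=-1)
    return out


def segment_windows(sig: np.ndarray, rate: float, window_seconds: float,
                    stride_seconds: float) -> list[np.ndarray]:
    """Cut ``channels x samples`` into fixed windows; drop trailing partials."""
    sig = np.asarray(sig)
    win = int(round(window_seconds * rate))
    stride = int(round(stride_seconds * rate))
    if win < 2:
        raise ConfigurationError(f"window of {win} samples is too short (min 2)")
    if stride < 1:
        raise ConfigurationError("stride must be at least one sample")
    n = sig.shape[-1]
    if win > n:
        logger.warning("window (%d samples) longer than signal (%d); no windows", win, n)
        return []
    count = (n - win) // stride + 1
    return [sig[..., i * stride : i * stride + win] for i in range(count)]


def differential_entropy(window: np.ndarray, eps: float = VARIANCE_FLOOR) -> float:
    """Gaussian differential entropy ``0.5 * ln(2 pi e var)`` in nats.

    The variance is floored at ``eps`` so constant windows stay finite.
    """
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise DataError("differential entropy needs at least 2 samples")
    var = float(np.var(window))
    if var < eps:
        logger.warning("degenerate (near-constant) window; variance floored at %g", eps)
        var = eps
    return 0.5 * math.log(2.0 * math.pi * math.e * var)


def power_spectral_density(window: np.ndarray, rate: float, band: BandSpec,
                           log: bool = True, eps: float = VARIANCE_FLOOR) -> float:
    """Mean periodogram power over frequency bins inside ``[low, high)``."""
    window = np.asarray(window, dtype=float)
    if window.size < 8:
        raise DataError("PSD needs at least 8 samples")
    freqs, power = sps.periodogram(window, fs=rate)
    high = band.effective_high(rate)
    sel = (freqs >= band.low) & (freqs < high)
    if not np.any(sel):
        raise ConfigurationError(
            f"band {band.name} ({band.low}-{high} Hz) contains no frequency bin "
            f"for a {window.size}-sample window at {rate} Hz"
        )
    mean_power = float(power[sel].mean())
    return math.log(mean_power + eps) if log else mean_power


def asymmetry_features(de: np.ndarray, montage: ElectrodeMontage, kind: str) -> np.ndarray:
    """DASM/RASM/ASM tensors from a DE tensor of shape ``T x N x F``.

    DASM = DE_left - DE_right; RASM = DE_left / DE_right (denominator
    epsilon-guarded); ASM = [DASM || RASM] concatenated along the pair axis.
    """
    if kind not in ("DASM", "RASM", "ASM"):
        raise ConfigurationError(f"unknown asymmetry kind {kind!r}")
    if not montage.symmetric_pairs:
        raise ConfigurationError("montage has no symmetric pairs")
    de = np.asarray(de, dtype=float)
    left_idx = [l for l, _ in montage.symmetric_pairs]
    right_idx = [r for _, r in montage.symmetric_pairs]
    left, right = de[:, left_idx, :], de[:, right_idx, :]
    if kind == "DASM":
        return left - right
    denom = np.where(np.abs(right) < VARIANCE_FLOOR,
                     np.where(right < 0, -VARIANCE_FLOOR, VARIANCE_FLOOR), right)
    rasm = left / denom
    if kind == "RASM":
        return rasm
    return np.concatenate([left - right, rasm], axis=1)


def extract_features(rec: RawRecording, cfg: FeatureConfig,
                     montage: ElectrodeMontage | None = None) -> FeatureTensor:
    """Full pipeline: band decomposition -> windowing -> per-window features.

    Deterministic given its inputs.  Asymmetry kinds require a montage with
    symmetric pairs.
    """
    try:
        stacks = bandpass_decompose(rec, cfg.bands)
        windows_per_band = [
            segment_windows(stack, rec.rate, cfg.window_seconds, cfg.stride_seconds)
            for stack in stacks
        ]
        n_windows = len(windows_per_band[0])
        n_ch = rec.n_channels
        de_needed = cfg.feature_kind != "PSD"
        values = np.empty((n_windows, n_ch, len(cfg.bands)))
        for f, band_windows in enumerate(windows_per_band):
            band = cfg.bands[f]
            for t, win in enumerate(band_windows):
                for c in range(n_ch):
                    if de_needed:
                        values[t, c, f] = differential_entropy(win[c])
                    else:
                        values[t, c, f] = power_spectral_density(
                            win[c], rec.rate, band, log=cfg.log_psd
                        )
        if cfg.feature_kind in ("DASM", "RASM", "ASM"):
            if montage is None:
                raise ConfigurationError(
                    f"{cfg.feature_kind} features need an electrode montage"
                )
            values = asymmetry_features(values, montage, cfg.feature_kind)
        if cfg.smoothing:
            values = uniform_filter1d(values, size=int(cfg.smoothing), axis=0,
                                      mode="nearest")
    except (ConfigurationError, DataError) as exc:
        raise type(exc)(
            f"feature extraction failed for {rec.subject_id}/{rec.trial_id}: {exc}"
        ) from exc
    return FeatureTensor(
        values=values,
        band_names=[b.name for b in cfg.bands],
        window_seconds=cfg.window_seconds,
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        label=rec.label,
        feature_kind=cfg.feature_kind,
    )


# ---------------------------------------------------------------------------
# montages
# ---------------------------------------------------------------------------

_TRAILING_INT = re.compile(r"^(.*?)(\d+)$")


def mirror_pairs(labels: list[str]) -> list[tuple[int, int]]:
    """Derive (left, right) index pairs by odd/even label-suffix mirroring.

    Follows the 10-20 convention: an odd-numbered label (left hemisphere)
    pairs with the next even number of the same prefix (e.g. F3-F4, CB1-CB2).
    Midline labels (no digit suffix, or no partner) are skipped.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    pairs = []
    for lab in labels:
        m = _TRAILING_INT.match(lab)
        if not m:
            continue
        prefix, num = m.group(1), int(m.group(2))
        if num % 2 == 1:
            partner = f"{prefix}{num + 1}"
            if partner in index:
                pairs.append((index[lab], index[partner]))
    return pairs


_SEED62_ROWS = [
    (0.90, ["FP1", "FPZ", "FP2"]),
    (0.75, ["AF3", "AF4"]),
    (0.60, ["F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8"]),
    (0.30, ["FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8"]),
    (0.00, ["T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8"]),
    (-0.30, ["TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8"]),
    (-0.60, ["P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8"]),
    (-0.75, ["PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8"]),
    (-0.90, ["CB1", "O1", "OZ", "O2", "CB2"]),
]


def seed62_montage() -> ElectrodeMontage:
    """62-channel extended 10-20 montage (approximate 2-D scalp layout).

    Positions are generated from a row/arc scheme on the unit disc; they are
    adequate for kNN graph construction and topographic plotting.  27
    symmetric pairs follow from odd/even label mirroring.
    """
    labels: list[str] = []
    coords: list[tuple[float, float]] = []
    for y, row in _SEED62_ROWS:
        half_width = 0.95 * math.sqrt(max(1.0 - y * y, 0.05))
        n = len(row)
        if n == 1:
            xs = [0.0]
        elif n == 2:
            xs = [-0.4 * half_width, 0.4 * half_width]
        else:
            xs = list(np.linspace(-half_width, half_width, n))
        labels.extend(row)
        coords.extend((x, y) for x in xs)
    return ElectrodeMontage(labels, np.array(coords), mirror_pairs(labels))


def read_edf_recording(path: str, subject_id: str, trial_id: str, label: int,
                       channels: list[str] | None = None) -> RawRecording:
    """Thin EDF reader adapter (optional; requires the ``mne`` package)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "EDF input requires the optional 'mne' dependency (pip install stgate[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise DataError(f"EDF file {path} is missing channels {missing}")
        raw.pick(channels)
    return RawRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        rate=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id,
        trial_id=trial_id,
        label=label,
    )
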