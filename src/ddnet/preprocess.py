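"""Filtering, epoching, artifact/SNR trial rejection, and epoch balancing.

The processing chain mirrors a standard event-related EEG pipeline for
sensor-space connectivity:

1. broadband conditioning (1–70 Hz band-pass plus 50 Hz line notch),
2. decomposition into seven canonical narrow bands (δ…γ2) with a 4th-order
   Butterworth applied forward and backward (zero phase),
3. rejection of trials with |amplitude| > 200 µV on any channel, trials
   failing a per-sensor signal-to-noise criterion, and trials answered
   incorrectly,
4. random subsampling so every subject/condition cell contributes the same
   number of clean epochs to the group comparison.

Filtering operates on reflection-padded copies of each epoch (half an
epoch on each side) and re-crops afterwards, suppressing edge transients
on the short 800 ms windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "EpochSet",
    "RejectionReport",
    "filter_bands",
    "segment_epochs",
    "reject_trials",
    "balance_epoch_counts",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges for {self.name}: "
                             f"{self.low_hz}-{self.high_hz} Hz")


#: Canonical seven-band decomposition (δ…γ2).  γ2 sits above the 50 Hz line
#: notch, hence the 48/52 Hz guard gap around it.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta1", 13.0, 20.0),
    BandDefinition("beta2", 20.0, 30.0),
    BandDefinition("gamma1", 30.0, 48.0),
    BandDefinition("gamma2", 52.0, 70.0),
)


@dataclass
class EpochSet:
    """Trials × channels × samples array with acquisition metadata.

    ``data`` is in microvolts; ``channels`` fixes channel order and must
    match the montage used downstream.  ``trial_info`` carries one row per
    trial (at least ``condition``; optionally ``correct``, ``rt_ms``).
    """

    data: np.ndarray
    fs: float = 250.0
    channels: tuple[str, ...] = ()
    subject: str = ""
    group: str = ""
    condition: str = ""
    window_ms: float = 800.0
    trial_info: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.channels and len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels do not match data")
        if self.trial_info is not None and len(self.trial_info) != self.n_trials:
            raise ValueError("trial_info rows must match n_trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, idx) -> "EpochSet":
        """Return a copy restricted to trials ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        info = None
        if self.trial_info is not None:
            info = self.trial_info.iloc[idx].reset_index(drop=True)
        return replace(self, data=self.data[idx], trial_info=info)


@dataclass
class RejectionReport:
    """Per-trial rejection flags plus per-sensor SNR values.

    Exactly one of the flags is set per rejected trial; kept trials carry
    none.  ``flags`` values: ``kept``, ``amplitude_rejected``,
    ``snr_rejected``, ``incorrect_response``.
    """

    flags: list[str]
    snr: np.ndarray  # (n_trials, n_channels); NaN where not evaluated

    def __post_init__(self):
        allowed = {"kept", "amplitude_rejected", "snr_rejected",
                   "incorrect_response"}
        bad = set(self.flags) - allowed
        if bad:
            raise ValueError(f"unknown rejection flags: {bad}")

    @property
    def n_kept(self) -> int:
        return self.flags.count("kept")

    def counts(self) -> dict[str, int]:
        return {k: self.flags.count(k)
                for k in ("kept", "amplitude_rejected", "snr_rejected",
                          "incorrect_response")}

    def to_frame(self, channels=None) -> pd.DataFrame:
        df = pd.DataFrame({"trial": np.arange(len(self.flags)),
                           "flag": self.flags})
        snr = pd.DataFrame(
            self.snr,
            columns=[f"snr_{c}" for c in (channels or
                                          range(self.snr.shape[1]))])
        return pd.concat([df, snr], axis=1)


def _broadband_sos(fs: float, low: float = 1.0, high: float = 70.0):
    """Chebyshev-II broadband band-pass (40 dB stop-band attenuation)."""
    return signal.cheby2(6, 40, [low, high], btype="bandpass", fs=fs,
                         output="sos")


def _apply_zero_phase(x: np.ndarray, sos: np.ndarray, pad: int) -> np.ndarray:
    """Forward-backward SOS filter on reflection-padded last axis."""
    if pad > 0:
        x = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    if pad > 0:
        y = y[..., pad:-pad]
    return y


def filter_bands(
    epochs: EpochSet,
    bands=CANONICAL_BANDS,
    notch_hz: float | None = 50.0,
    notch_q: float = 30.0,
    broadband: tuple[float, float] | None = (1.0, 70.0),
    order: int = 4,
) -> dict[str, EpochSet]:
    """Decompose epochs into zero-phase band-limited copies.

    The broadband stage (Chebyshev-II 1–70 Hz band-pass and an IIR line
    notch) runs first; each narrow band is then isolated with a 4th-order
    Butterworth applied forward and backward (``sosfiltfilt``), so no band
    introduces a phase shift.  Epochs are reflection-padded by half their
    length on each side before every filter and re-cropped afterwards.

    Returns a mapping from band name to a new :class:`EpochSet`.
    """
    if not bands:
        raise ValueError("band list is empty")
    nyq = epochs.fs / 2.0
    for b in bands:
        if b.high_hz >= nyq:
            raise ValueError(
                f"band {b.name} ({b.low_hz}-{b.high_hz} Hz) exceeds the "
                f"Nyquist frequency {nyq} Hz")
    if epochs.n_samples < 3 * order:
        raise ValueError("epochs too short for the filter order")

    pad = epochs.n_samples // 2
    x = epochs.data
    if broadband is not None:
        x = _apply_zero_phase(x, _broadband_sos(epochs.fs, *broadband), pad)
    if notch_hz is not None and notch_hz < nyq:
        b_n, a_n = signal.iirnotch(notch_hz, notch_q, fs=epochs.fs)
        sos_n = signal.tf2sos(b_n, a_n)
        x = _apply_zero_phase(x, sos_n, pad)

    out: dict[str, EpochSet] = {}
    for b in bands:
        sos = signal.butter(order, [b.low_hz, b.high_hz], btype="bandpass",
                            fs=epochs.fs, output="sos")
        y = _apply_zero_phase(x, sos, pad)
        out[b.name] = replace(epochs, data=y)
    return out


def segment_epochs(
    continuous: np.ndarray,
    onsets,
    window_ms: float = 800.0,
    fs: float = 250.0,
    **meta,
) -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous recording.

    ``continuous`` is channels × samples; each epoch is the half-open
    window ``[onset, onset + round(window_ms * fs / 1000))``.  Onsets whose
    window overruns the recording are skipped with a warning.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_win = int(round(window_ms * fs / 1000.0))
    n_total = continuous.shape[1]
    kept, skipped = [], []
    for onset in onsets:
        onset = int(onset)
        if onset < 0 or onset + n_win > n_total:
            skipped.append(onset)
            continue
        kept.append(continuous[:, onset:onset + n_win])
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} onset(s) overrunning the recording: "
            f"{skipped}", stacklevel=2)
    data = (np.stack(kept, axis=0) if kept
            else np.empty((0, continuous.shape[0], n_win)))
    return EpochSet(data=data, fs=fs, window_ms=window_ms, **meta)


def sensor_snr(data: np.ndarray) -> np.ndarray:
    """Per-trial, per-sensor SNR of event-locked epochs.

    The evoked signal is the across-trial mean; the noise of each trial and
    sensor is the standard deviation of its residual after subtracting that
    mean.  SNR = peak-to-peak(mean signal) / (2 · sd(residual)).  Returns
    an (n_trials, n_channels) array; zero residual gives +inf.
    """
    mean = data.mean(axis=0)                      # (channels, samples)
    p2p = mean.max(axis=-1) - mean.min(axis=-1)   # (channels,)
    resid_sd = (data - mean).std(axis=-1)         # (trials, channels)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = p2p / (2.0 * resid_sd)
    snr[np.isnan(snr)] = np.inf  # 0/0: flat signal, zero noise
    return snr


def reject_trials(
    epochs: EpochSet,
    amp_limit_uv: float = 200.0,
    snr_min: float = 1.0,
    correct_flags=None,
) -> tuple[EpochSet, RejectionReport]:
    """Drop artifactual, low-SNR, and incorrectly answered trials.

    Stages run in order amplitude → SNR → correctness, so the cross-trial
    mean entering the SNR computation is taken over amplitude-clean trials
    only.  A trial fails the amplitude stage if any sample on any channel
    exceeds ±``amp_limit_uv``; it fails the SNR stage if any sensor's SNR
    on that trial is below ``snr_min``.  ``correct_flags`` may be omitted
    (all trials treated as correct) or taken from ``epochs.trial_info``.
    """
    n = epochs.n_trials
    if n < 2:
        raise ValueError("need at least 2 trials to estimate SNR")
    if correct_flags is None and epochs.trial_info is not None \
            and "correct" in epochs.trial_info:
        correct_flags = epochs.trial_info["correct"].to_numpy()
    flags = ["kept"] * n
    snr_full = np.full((n, epochs.n_channels), np.nan)

    amp_bad = np.abs(epochs.data).max(axis=(1, 2)) > amp_limit_uv
    for i in np.flatnonzero(amp_bad):
        flags[i] = "amplitude_rejected"

    clean = np.flatnonzero(~amp_bad)
    if clean.size >= 2:
        snr = sensor_snr(epochs.data[clean])
        snr_full[clean] = snr
        snr_bad = (snr < snr_min).any(axis=1)
        for i in clean[snr_bad]:
            flags[i] = "snr_rejected"

    if correct_flags is not None:
        correct_flags = np.asarray(correct_flags, dtype=bool)
        for i in range(n):
            if flags[i] == "kept" and not correct_flags[i]:
                flags[i] = "incorrect_response"

    keep_idx = [i for i, f in enumerate(flags) if f == "kept"]
    if not keep_idx:
        raise ValueError("all trials rejected")
    return epochs.select(keep_idx), RejectionReport(flags, snr_full)


def balance_epoch_counts(
    groups: dict[str, list[EpochSet]],
    seed: int | None = None,
) -> dict[str, list[EpochSet]]:
    """Equalise clean-epoch counts across groups by random subsampling.

    Every subject/condition cell is subsampled without replacement to the
    minimum trial count found across all cells of all groups, keeping
    trial order.  Cells already at the minimum pass through unchanged.
    """
    counts = [es.n_trials for sets in groups.values() for es in sets]
    if not counts or min(counts) < 1:
        raise ValueError("every subject needs at least one kept epoch")
    target = min(counts)
    rng = np.random.default_rng(seed)
    out: dict[str, list[EpochSet]] = {}
    for name, sets in groups.items():
        balanced = []
        for es in sets:
            if es.n_trials == target:
                balanced.append(es)
            else:
                idx = np.sort(rng.choice(es.n_trials, size=target,
                                         replace=False))
                balanced.append(es.select(idx))
        out[name] = balanced
    return out
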