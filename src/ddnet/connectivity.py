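"""Weighted Phase Lag Index (wPLI) adjacency estimation.

The wPLI quantifies consistent, *lagged* phase synchronization between two
sensors.  With cross-spectral samples ``S_k = X_a,k · conj(X_b,k)`` it is

    wPLI(a, b) = |E[Im S]| / E[|Im S|]  ∈ [0, 1],

the ratio of the signed to the unsigned mean imaginary cross-spectrum.
Zero-lag (and antiphase) coupling contributes nothing to the imaginary
part, which makes the estimator insensitive to instantaneous volume
conduction / leakage — the property that motivates its use on sensor-space
EEG.  When the denominator is zero (no imaginary energy at all, e.g.
identical signals) the value is defined as 0: there is no consistent lag.

For single-trial estimation the expectation runs over within-trial time
samples of the analytic signal, after excluding the first and last 10 % of
samples where the Hilbert transform of a short epoch is unreliable.  An
across-trial estimation mode (expectation over trials per time sample,
then averaged over time) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochSet

__all__ = ["ConnectivityMatrix", "analytic_signal", "wpli_matrix",
           "wpli_epochs", "EDGE_FRACTION"]

#: Fraction of samples dropped at each epoch edge before phase statistics.
EDGE_FRACTION = 0.10


@dataclass
class ConnectivityMatrix:
    """Symmetric wPLI adjacency for one trial (or trial average).

    ``values`` is channels × channels, entries in [0, 1], zero diagonal.
    """

    values: np.ndarray
    band: str = ""
    subject: str = ""
    group: str = ""
    condition: str = ""
    trial: int | None = None
    channels: tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.allclose(v, v.T):
            raise ValueError("values must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-9).any():
            raise ValueError("wPLI entries must lie in [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def analytic_signal(epochs: EpochSet) -> np.ndarray:
    """Analytic (complex) representation of band-limited epochs.

    Returns a complex array of the same shape as ``epochs.data``; the
    instantaneous phase is its argument.  Raises on constant channels,
    whose phase is undefined.
    """
    x = epochs.data
    if np.any(x.std(axis=-1) == 0):
        raise ValueError("constant channel: instantaneous phase undefined")
    return hilbert(x, axis=-1)


def _edge_slice(n_samples: int, edge_fraction: float) -> slice:
    k = int(np.floor(edge_fraction * n_samples))
    return slice(k, n_samples - k)


def wpli_matrix(
    analytic: np.ndarray,
    edge_fraction: float = EDGE_FRACTION,
    debias: bool = False,
    min_samples: int = 20,
    **meta,
) -> ConnectivityMatrix:
    """Single-trial wPLI adjacency from a channels × samples analytic array.

    Parameters
    ----------
    analytic : complex ndarray, shape (channels, samples)
        Analytic signal of one band-limited trial.
    edge_fraction : float
        Fraction of samples excluded at each end before the expectation.
    debias : bool
        If True, use the debiased squared estimator
        ``(E[Im S]² − E[(Im S)²]/n·n) …`` correction; the plain estimator is
        the default (positively biased at small n but matches the standard
        definition).
    min_samples : int
        Minimum usable samples after edge exclusion.
    """
    z = np.asarray(analytic)
    if z.ndim != 2:
        raise ValueError("expected one trial: (channels, samples)")
    sl = _edge_slice(z.shape[1], edge_fraction)
    z = z[:, sl]
    if z.shape[1] < min_samples:
        raise ValueError(
            f"only {z.shape[1]} usable samples after edge exclusion; "
            f"need ≥ {min_samples}")
    # Im S_ab,k = Im(z_a conj(z_b)) for all pairs at once.
    imag = np.einsum("as,bs->abs", z, np.conj(z)).imag
    if debias:
        # Debiased squared estimator: cross-products of distinct samples,
        # (ΣIm)²−ΣIm² over (Σ|Im|)²−ΣIm², square-rooted and floored at 0.
        ssum = imag.sum(axis=-1)
        sqsum = (imag ** 2).sum(axis=-1)
        num = np.maximum(ssum ** 2 - sqsum, 0.0)
        den = (np.abs(imag).sum(axis=-1)) ** 2 - sqsum
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0),
                                 0.0))
    else:
        num = np.abs(imag.mean(axis=-1))
        den = np.abs(imag).mean(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    w = 0.5 * (w + w.T)  # enforce exact symmetry against fp noise
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(values=w, **meta)


def wpli_epochs(
    epochs: EpochSet,
    band: str = "",
    mode: str = "time",
    edge_fraction: float = EDGE_FRACTION,
    debias: bool = False,
) -> list[ConnectivityMatrix]:
    """wPLI matrices for every trial of a band-limited epoch set.

    ``mode='time'`` (default) estimates each trial's matrix over its own
    time samples, returning one matrix per trial.  ``mode='trials'``
    estimates a single matrix with the expectation over trials at each
    time sample (averaged over time afterwards), returning a one-element
    list.
    """
    z = analytic_signal(epochs)
    meta = dict(band=band, subject=epochs.subject, group=epochs.group,
                condition=epochs.condition, channels=epochs.channels)
    if mode == "time":
        return [
            wpli_matrix(z[t], edge_fraction=edge_fraction, debias=debias,
                        trial=t, **meta)
            for t in range(epochs.n_trials)
        ]
    if mode == "trials":
        sl = _edge_slice(epochs.n_samples, edge_fraction)
        zt = z[:, :, sl]
        # pool cross-spectral samples over trials × time: across-trial
        # phase consistency, many more effective observations per pair
        imag = np.einsum("tas,tbs->abts", zt, np.conj(zt)).imag
        imag = imag.reshape(imag.shape[0], imag.shape[1], -1)
        if debias:
            ssum = imag.sum(axis=-1)
            sqsum = (imag ** 2).sum(axis=-1)
            num = np.maximum(ssum ** 2 - sqsum, 0.0)
            den = (np.abs(imag).sum(axis=-1)) ** 2 - sqsum
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.sqrt(np.where(den > 0,
                                     num / np.where(den > 0, den, 1.0), 0.0))
        else:
            num = np.abs(imag.mean(axis=-1))
            den = np.abs(imag).mean(axis=-1)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        return [ConnectivityMatrix(values=w, trial=None, **meta)]
    raise ValueError(f"unknown mode {mode!r}")


def average_matrices(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of single-trial matrices (subject-level adjacency)."""
    if not mats:
        raise ValueError("no matrices to average")
    stack = np.stack([m.values for m in mats])
    first = mats[0]
    return ConnectivityMatrix(
        values=stack.mean(axis=0), band=first.band, subject=first.subject,
        group=first.group, condition=first.condition, trial=None,
        channels=first.channels)
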