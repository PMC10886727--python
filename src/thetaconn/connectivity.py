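"""Windowed phase-locking value (PLV) and weighted phase lag index (wPLI).

Both metrics are computed per trial on three 1 s windows with 50 % overlap
after cue onset (w1: 0-1 s, w2: 0.5-1.5 s, w3: 1-2 s).  The instantaneous
phase comes from the analytic signal of the full 2.5 s epoch, which is then
sliced to the window; computing the Hilbert transform window-by-window would
put a transform edge at every window boundary.

For two channels x, y with analytic signals z_x, z_y:

    PLV  = | mean_t exp(i * (phi_x(t) - phi_y(t))) |
    wPLI = | mean_t Im(P_xy(t)) | / mean_t |Im(P_xy(t))|,   P_xy = z_x conj(z_y)

PLV is 1 iff the phase difference is constant over the window.  wPLI weights
phase leads/lags by the imaginary cross-spectrum, so purely instantaneous
(zero-lag, volume-conducted) coupling contributes nothing; when every
imaginary sample is zero the estimator is 0/0 and we return 0 with a
degeneracy flag instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .preprocess import EpochedRecording
from .signals import analytic_signal

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisWindow",
    "DEFAULT_WINDOWS",
    "ConnectivityTensor",
    "instantaneous_phase",
    "plv",
    "wpli",
    "windowed_connectivity",
]

METRICS = ("plv", "wpli")
#: minimum cycles of the band-centre frequency a window must contain
MIN_CYCLES = 3.0


@dataclass(frozen=True)
class AnalysisWindow:
    """One sliding analysis window, in seconds relative to cue onset."""

    label: str
    start: float
    stop: float

    def n_samples(self, fs: float) -> int:
        return int(round(self.stop * fs)) - int(round(self.start * fs))

    def slice(self, fs: float, time0: float) -> slice:
        s0 = int(round((time0 + self.start) * fs))
        s1 = int(round((time0 + self.stop) * fs))
        return slice(s0, s1)


DEFAULT_WINDOWS: tuple[AnalysisWindow, ...] = (
    AnalysisWindow("w1", 0.0, 1.0),
    AnalysisWindow("w2", 0.5, 1.5),
    AnalysisWindow("w3", 1.0, 2.0),
)


@dataclass
class ConnectivityTensor:
    """Connectivity values for one metric on one recording cell.

    ``values`` has shape (n_pairs, n_windows, n_trials) with every entry in
    [0, 1].  ``pairs`` lists unordered channel-label pairs in upper-triangle
    order; the tensor is symmetric in pair order by construction.
    ``degenerate`` flags wPLI cells whose imaginary cross-spectrum was
    identically zero (value reported as 0).
    """

    metric: str
    values: np.ndarray
    pairs: tuple[tuple[str, str], ...]
    windows: tuple[AnalysisWindow, ...]
    degenerate: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.pairs):
            raise ValueError("values must be (pairs, windows, trials)")
        if self.values.size and (
            np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12
        ):
            raise ValueError("connectivity values must lie in [0, 1]")

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    def pair_index(self, a: str, b: str) -> int:
        try:
            return self.pairs.index((a, b))
        except ValueError:
            return self.pairs.index((b, a))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per pair x window x trial)."""
        n_pairs, n_win, n_trials = self.values.shape
        pi, wi, ti = np.meshgrid(
            np.arange(n_pairs), np.arange(n_win), np.arange(n_trials), indexing="ij"
        )
        deg = (
            self.degenerate[pi.ravel(), wi.ravel(), ti.ravel()]
            if self.degenerate is not None
            else np.zeros(self.values.size, dtype=bool)
        )
        return pd.DataFrame(
            {
                "subject": self.metadata.get("subject_id", 0),
                "session": self.metadata.get("session", ""),
                "condition": self.metadata.get("condition", ""),
                "metric": self.metric,
                "window": [self.windows[w].label for w in wi.ravel()],
                "chan_i": [self.pairs[p][0] for p in pi.ravel()],
                "chan_j": [self.pairs[p][1] for p in pi.ravel()],
                "trial": ti.ravel(),
                "value": self.values[pi.ravel(), wi.ravel(), ti.ravel()],
                "degenerate": deg,
            }
        )


def instantaneous_phase(
    trial: np.ndarray, fs: float, window: AnalysisWindow | None = None, time0: float = 0.5
) -> np.ndarray:
    """Instantaneous phase (radians, wrapped to (-pi, pi]) per channel sample.

    The analytic signal is taken over the full epoch; when a window is given
    the phase series is sliced to it afterwards.
    """
    trial = np.asarray(trial, dtype=float)
    if not trial.any():
        raise ValueError("all-zero input has undefined phase")
    phi = np.angle(analytic_signal(trial))
    if window is not None:
        phi = phi[..., window.slice(fs, time0)]
    return phi


def plv(theta_diff: np.ndarray) -> float:
    """Modulus of the mean unit phasor of a phase-difference series."""
    theta_diff = np.asarray(theta_diff, dtype=float)
    if theta_diff.size == 0:
        raise ValueError("empty phase-difference series")
    return float(np.abs(np.mean(np.exp(1j * theta_diff))))


def wpli(cross: np.ndarray) -> tuple[float, bool]:
    """Weighted phase lag index from complex (or imaginary) cross-spectral samples.

    Returns ``(value, degenerate)``; degenerate means every imaginary sample
    was zero (pure zero-lag coupling), reported as value 0.
    """
    cross = np.asarray(cross)
    if cross.size == 0:
        raise ValueError("empty cross-spectrum")
    im = np.imag(cross) if np.iscomplexobj(cross) else cross.astype(float)
    denom = np.mean(np.abs(im))
    if denom == 0:
        return 0.0, True
    return float(np.abs(np.mean(im)) / denom), False


def _pair_list(labels: Iterable[str]) -> tuple[tuple[str, str], ...]:
    labels = list(labels)
    iu, ju = np.triu_indices(len(labels), 1)
    return tuple((labels[i], labels[j]) for i, j in zip(iu, ju))


def _windowed_metrics(
    data: np.ndarray,
    fs: float,
    time0: float,
    windows: tuple[AnalysisWindow, ...],
    metric: str,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised core: data (n_epochs, n_channels, n_samples) ->
    (values, degenerate) of shape (n_epochs, n_pairs, n_windows)."""
    n_ep, n_ch, _ = data.shape
    iu, ju = np.triu_indices(n_ch, 1)
    out = np.empty((n_ep, len(iu), len(windows)))
    deg = np.zeros_like(out, dtype=bool)
    for c0 in range(0, n_ep, chunk):
        sl = slice(c0, min(c0 + chunk, n_ep))
        z = analytic_signal(data[sl])
        if metric == "plv":
            u = z / np.abs(z)
            for w, win in enumerate(windows):
                uw = u[:, :, win.slice(fs, time0)]
                g = uw @ uw.conj().swapaxes(-1, -2) / uw.shape[-1]
                out[sl, :, w] = np.abs(g)[:, iu, ju]
        else:  # wpli
            for w, win in enumerate(windows):
                zw = z[:, :, win.slice(fs, time0)]
                im = zw[:, iu].real * zw[:, ju].imag - zw[:, iu].imag * zw[:, ju].real
                num = np.abs(im.mean(axis=-1))
                den = np.abs(im).mean(axis=-1)
                ok = den > 0
                out[sl, :, w] = np.divide(num, den, out=np.zeros_like(num), where=ok)
                deg[sl, :, w] = ~ok
    return np.clip(out, 0.0, 1.0), deg


def windowed_connectivity(
    rec: EpochedRecording,
    metric: str = "plv",
    windows: tuple[AnalysisWindow, ...] = DEFAULT_WINDOWS,
    band: tuple[float, float] | None = None,
) -> ConnectivityTensor:
    """Per-trial, per-pair, per-window connectivity for one recording cell.

    The recording is expected to be theta-filtered (and normalised); the
    band recorded by :func:`thetaconn.preprocess.bandpass_theta` is used to
    validate that each window holds at least 3 cycles of the band centre.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if rec.n_channels < 13:
        warnings.warn(
            f"only {rec.n_channels} channels configured; proceeding on available pairs",
            stacklevel=2,
        )
    band = band or rec.metadata.get("band")
    if band is not None:
        centre = 0.5 * (band[0] + band[1])
        for win in windows:
            if (win.stop - win.start) * centre < MIN_CYCLES:
                raise ValueError(
                    f"window {win.label} holds fewer than {MIN_CYCLES} cycles at {centre} Hz"
                )
    # core operates on (epochs, channels, samples)
    values, degenerate = _windowed_metrics(
        rec.data.transpose(1, 0, 2), rec.fs, rec.time0, windows, metric
    )
    return ConnectivityTensor(
        metric=metric,
        values=values.transpose(1, 2, 0),
        pairs=_pair_list(rec.channel_labels),
        windows=windows,
        degenerate=degenerate.transpose(1, 2, 0) if metric == "wpli" else None,
        metadata={
            "subject_id": rec.subject_id,
            "session": rec.session,
            "condition": rec.condition,
            "fs": rec.fs,
        },
    )
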