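"""Epoching, theta band-pass filtering, and two-condition amplitude normalisation.

Epochs span -0.5 s to +2 s around cue onset (2.5 s at the configured sampling
rate).  The band-pass is a zero-phase spectral-gain filter (see
:mod:`thetaconn.signals`): unity gain on the passband, raised-cosine
transitions 2 Hz wide, and exactly zero gain beyond them, i.e. more than
40 dB attenuation at 1 Hz and 12 Hz for the default 3-8 Hz theta band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .signals import apply_gain, band_gain

logger = logging.getLogger(__name__)

__all__ = ["EpochedRecording", "epoch", "bandpass_theta", "normalise_trials"]

#: seconds of pre-onset padding inside every epoch
PRE_ONSET_S = 0.5
#: seconds of post-onset signal inside every epoch
POST_ONSET_S = 2.0
#: epoch edges whose filtered samples are flagged as edge-affected
EDGE_FLAG_S = 0.25

SESSIONS = ("Pre", "Sleep", "Post")
CONDITIONS = ("L", "R")


@dataclass
class EpochedRecording:
    """Multichannel epoched EEG for one (subject, session, condition) cell.

    Attributes
    ----------
    data : array, shape (n_channels, n_trials, n_samples)
    fs : sampling rate in Hz
    time0 : cue-onset time in seconds from the start of the epoch (0.5 s)
    channel_labels : ordered channel names (10-20 system)
    session : one of ``Pre``, ``Sleep``, ``Post``
    condition : cued hand, ``L`` or ``R``
    subject_id : integer subject index
    metadata : free-form provenance (filter band, normalisation factors, ...)
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    session: str = "Pre"
    condition: str = "L"
    subject_id: int = 0
    time0: float = PRE_ONSET_S
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, trials, samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} channel rows but {len(self.channel_labels)} labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if np.isnan(self.data).any():
            raise ValueError("epoched data contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to cue onset."""
        return np.arange(self.n_samples) / self.fs - self.time0

    def copy_with(self, **kwargs: Any) -> "EpochedRecording":
        return replace(self, **kwargs)


def epoch(
    continuous: np.ndarray,
    onsets: np.ndarray,
    fs: float,
    channel_labels: tuple[str, ...] | None = None,
    **rec_kwargs: Any,
) -> EpochedRecording:
    """Cut trials of [-0.5, 2) s around each onset sample from continuous data.

    Uses 0-based, half-open windows ``[onset - 0.5*fs, onset + 2*fs)``.
    Onsets too close to either end of the record are dropped with a logged
    count rather than raising.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size == 0:
        raise ValueError("empty onset list")
    if fs <= 0:
        raise ValueError("fs must be positive")
    pre = int(round(PRE_ONSET_S * fs))
    post = int(round(POST_ONSET_S * fs))
    n = continuous.shape[-1]
    valid = (onsets - pre >= 0) & (onsets + post <= n)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("epoch: dropped %d/%d out-of-range onsets", n_dropped, onsets.size)
    kept = onsets[valid]
    if kept.size == 0:
        raise ValueError("no onset leaves a complete [-0.5, 2) s window")
    trials = np.stack([continuous[:, o - pre : o + post] for o in kept], axis=1)
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(continuous.shape[0]))
    rec = EpochedRecording(trials, fs, tuple(channel_labels), **rec_kwargs)
    rec.metadata["n_onsets_dropped"] = n_dropped
    return rec


def bandpass_theta(
    rec: EpochedRecording,
    band: tuple[float, float] = (3.0, 8.0),
    transition: float = 2.0,
) -> EpochedRecording:
    """Zero-phase band-pass of every channel and trial.

    The gain is exactly 1 inside ``band`` and exactly 0 beyond the 2 Hz
    transition edges, so re-applying the filter leaves passband content
    unchanged.  The first and last 0.25 s of each epoch are flagged as
    edge-affected in the metadata.
    """
    lo, hi = band
    if rec.fs <= 2 * hi:
        raise ValueError(f"fs={rec.fs} must exceed twice the upper band edge {hi}")
    gain = band_gain(rec.n_samples, rec.fs, lo, hi, transition)
    out = rec.copy_with(data=apply_gain(rec.data, gain))
    out.metadata = dict(rec.metadata)
    out.metadata.update(band=(lo, hi), transition=transition, edge_flag_s=EDGE_FLAG_S)
    return out


def normalise_trials(
    rec_a: EpochedRecording,
    rec_b: EpochedRecording,
) -> tuple[EpochedRecording, EpochedRecording]:
    """Per-channel amplitude normalisation pooled over two conditions.

    Every trial of every channel is divided by that channel's grand-mean RMS
    amplitude computed over all trials of *both* conditions (left- and
    right-hand cues of the same subject and session).  Phase-based metrics are
    amplitude-blind, so this only pins the physical scale; the applied factors
    are recorded in the metadata.
    """
    if rec_a.channel_labels != rec_b.channel_labels:
        raise ValueError("conditions have different channel labels")
    if rec_a.fs != rec_b.fs:
        raise ValueError("conditions have different sampling rates")
    rms_a = np.sqrt(np.mean(rec_a.data**2, axis=-1))  # (channels, trials)
    rms_b = np.sqrt(np.mean(rec_b.data**2, axis=-1))
    factor = np.concatenate([rms_a, rms_b], axis=1).mean(axis=1)  # per channel
    zero = np.flatnonzero(factor == 0)
    if zero.size:
        names = [rec_a.channel_labels[i] for i in zero]
        raise ValueError(f"zero grand-mean RMS on channel(s): {', '.join(names)}")
    outs = []
    for rec in (rec_a, rec_b):
        out = rec.copy_with(data=rec.data / factor[:, None, None])
        out.metadata = dict(rec.metadata)
        out.metadata["normalisation_factors"] = {
            lab: float(f) for lab, f in zip(rec.channel_labels, factor)
        }
        outs.append(out)
    return outs[0], outs[1]
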