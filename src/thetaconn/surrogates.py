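"""Surrogate-data significance testing for connectivity values.

Two randomisation schemes build an empirical null, per channel and epoch:

* ``phase`` - the rFFT phases of the positive-frequency bins are randomly
  permuted (independently per channel), negative bins follow by Hermitian
  symmetry, and DC/Nyquist stay real.  The amplitude spectrum is preserved
  exactly while cross-channel phase relations are destroyed.
* ``time`` - each channel's samples are randomly permuted (the sample
  multiset is preserved).  Scrambling whitens the spectrum, so before
  computing connectivity the surrogate is re-band-passed with the same
  filter as the real data; without this the null would not be comparable.

Each real connectivity value is compared against the null distribution of
its own (pair, window, trial) cell: values not exceeding the null's rank-based
95th centile are set to zero and flagged for exclusion from later statistics.
With n surrogates the keep decision is equivalent to an empirical p-value
(1 + #{null >= real}) / (n + 1) <= alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .connectivity import (
    DEFAULT_WINDOWS,
    AnalysisWindow,
    ConnectivityTensor,
    _windowed_metrics,
)
from .preprocess import EpochedRecording
from .signals import apply_gain, band_gain

logger = logging.getLogger(__name__)

__all__ = [
    "SurrogateEnsemble",
    "SignificanceMask",
    "phase_shuffle",
    "time_shuffle",
    "build_null",
    "significance_prune",
]


@dataclass
class SurrogateEnsemble:
    """Null connectivity values: (n_surrogates, n_pairs, n_windows, n_trials)."""

    metric: str
    method: str
    null_values: np.ndarray
    rng_seed: Any = None
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def n_surrogates(self) -> int:
        return self.null_values.shape[0]


@dataclass
class SignificanceMask:
    """Keep decisions per (pair, window, trial) with audit quantities."""

    keep: np.ndarray
    centile: np.ndarray
    p_values: np.ndarray
    alpha: float


def phase_shuffle(trial: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomised surrogate of real-valued data along the last axis.

    Positive-frequency phases are permuted per channel; amplitudes, DC and
    Nyquist are untouched, so |FFT(out)| equals |FFT(in)| bin-wise.
    """
    trial = np.asarray(trial, dtype=float)
    n = trial.shape[-1]
    spec = np.fft.rfft(trial, axis=-1)
    amp = np.abs(spec)
    phase = np.angle(spec)
    hi = spec.shape[-1] - 1 if n % 2 == 0 else spec.shape[-1]
    phase[..., 1:hi] = rng.permuted(phase[..., 1:hi], axis=-1)
    out = amp * np.exp(1j * phase)
    out[..., 0] = spec[..., 0]
    if n % 2 == 0:
        out[..., -1] = spec[..., -1]
    return np.fft.irfft(out, n=n, axis=-1)


def time_shuffle(trial: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each channel's samples (multiset preserved)."""
    trial = np.asarray(trial, dtype=float)
    order = np.argsort(rng.random(trial.shape), axis=-1)
    return np.take_along_axis(trial, order, axis=-1)


def build_null(
    rec: EpochedRecording,
    metric: str = "plv",
    n: int = 100,
    method: str = "phase",
    rng: np.random.Generator | int | None = None,
    windows: tuple[AnalysisWindow, ...] = DEFAULT_WINDOWS,
    batch: int = 2048,
) -> SurrogateEnsemble:
    """Full windowed-connectivity computation on ``n`` surrogates of ``rec``.

    The recording must already be preprocessed exactly as for the real
    computation.  Returns the per-cell empirical null distribution.
    """
    if method not in ("phase", "time"):
        raise ValueError("method must be 'phase' or 'time'")
    if n < 20:
        warnings.warn(f"n={n} surrogates: the 95th centile is unstable", stacklevel=2)
    rng = np.random.default_rng(rng)
    n_trials = rec.n_trials
    data = rec.data.transpose(1, 0, 2)  # (trials, channels, samples)
    band = rec.metadata.get("band")
    gain = None
    if method == "time":
        if band is None:
            warnings.warn(
                "time-shuffled surrogates of unfiltered data: null may be miscalibrated",
                stacklevel=2,
            )
        else:
            tw = rec.metadata.get("transition", 2.0)
            gain = band_gain(rec.n_samples, rec.fs, band[0], band[1], tw)

    chunks = []
    # surrogate index is the leading axis; generate in batches of whole replicates
    reps_per_batch = max(1, batch // max(n_trials, 1))
    done = 0
    while done < n:
        n_rep = min(reps_per_batch, n - done)
        block = np.broadcast_to(data, (n_rep,) + data.shape).reshape(
            n_rep * n_trials, rec.n_channels, rec.n_samples
        )
        if method == "phase":
            sur = phase_shuffle(block, rng)
        else:
            sur = time_shuffle(block, rng)
            if gain is not None:
                sur = apply_gain(sur, gain)
        vals, _ = _windowed_metrics(sur, rec.fs, rec.time0, windows, metric)
        chunks.append(
            vals.reshape(n_rep, n_trials, vals.shape[1], vals.shape[2]).transpose(0, 2, 3, 1)
        )
        done += n_rep
    null_values = np.concatenate(chunks, axis=0)
    return SurrogateEnsemble(
        metric=metric,
        method=method,
        null_values=null_values,
        metadata={"subject_id": rec.subject_id, "session": rec.session,
                  "condition": rec.condition, "n_trials": n_trials},
    )


def significance_prune(
    real: ConnectivityTensor,
    null: SurrogateEnsemble,
    alpha: float = 0.05,
) -> tuple[ConnectivityTensor, SignificanceMask]:
    """Zero out connectivity cells not exceeding the null 95th centile.

    The centile is the rank-based upper order statistic (``method='higher'``),
    so the keep rule matches the empirical p-value with the +1 correction:
    keep iff (1 + #{null >= real}) / (n + 1) <= alpha ... up to ties.
    Degenerate wPLI cells are never kept and get p = 1.
    """
    if real.metric != null.metric:
        raise ValueError("metric mismatch between real tensor and null ensemble")
    expected = (null.n_surrogates,) + real.values.shape
    if null.null_values.shape != expected:
        raise ValueError(
            f"null shape {null.null_values.shape} does not match real {expected}"
        )
    nv = null.null_values
    centile = np.quantile(nv, 1 - alpha, axis=0, method="higher")
    keep = real.values > centile
    p = (1 + (nv >= real.values[None]).sum(axis=0)) / (null.n_surrogates + 1)
    if real.degenerate is not None:
        keep &= ~real.degenerate
        p = np.where(real.degenerate, 1.0, p)
    pruned = ConnectivityTensor(
        metric=real.metric,
        values=np.where(keep, real.values, 0.0),
        pairs=real.pairs,
        windows=real.windows,
        degenerate=real.degenerate,
        metadata=dict(real.metadata),
    )
    n_links = keep.size
    logger.info(
        "significance_prune: kept %d/%d cells (%.1f%%)",
        int(keep.sum()), n_links, 100 * keep.mean() if n_links else 0.0,
    )
    return pruned, SignificanceMask(keep=keep, centile=centile, p_values=p, alpha=alpha)
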