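"""Synthetic EEG studies with planted, labelled phase-coupling structure.

The generator emulates the statistical structure of a targeted-memory-
reactivation (TMR) sleep study: 13 scalp channels of the 10-20 system,
2.5 s epochs around auditory cue onsets, three sessions (pre-sleep wake,
slow-wave sleep, post-sleep wake), two cue conditions (left- / right-hand),
plus per-block reaction-time tables with sequence learning, overnight
improvement and a left-hand-only TMR benefit.

Signal model
------------
Every channel carries a *carrier* oscillation plus 1/f background noise.
The carrier is a Gaussian process whose spectrum is flat across the theta
analysis band and its filter transition skirts; because it is exactly
Gaussian, phase-randomised surrogates of the generated data are
distributionally exchangeable with it, which is what makes the downstream
surrogate test calibrate at its nominal level on uncoupled channels.

A planted coupling between channels (p, q) with strength ``kappa`` and phase
lag ``lag`` replaces q's oscillation by

    q_osc = w0 * own + kappa * rotate(base_p, lag),      w0 = max(0, 1 - sum kappa)

where ``base_p`` is p's base oscillator ("the shared oscillator") and
``rotate`` shifts the instantaneous phase by ``lag`` radians.  kappa = 1 with
no noise gives a perfectly phase-locked pair (PLV = 1); kappa = 0 leaves the
channels independent.  A channel targeted by several couplings accumulates
their contributions (its own-oscillator weight shrinks accordingly); the
*source* side of a coupling always refers to the base oscillator, so hub
channels can drive several targets without being diluted themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .preprocess import CONDITIONS, SESSIONS, EpochedRecording
from .signals import analytic_signal, band_gain, pink_gain, shaped_gaussian

__all__ = [
    "CHANNELS_1020",
    "SimulationConfig",
    "PlantedCoupling",
    "BehaviouralEffects",
    "SyntheticStudy",
    "generate_epochs",
    "generate_behavioural",
    "generate_study",
    "default_couplings",
    "leakage_matrix",
]

#: the 13 scalp channels recorded in the emulated montage
CHANNELS_1020 = ("Fz", "Cz", "Pz", "F3", "F4", "C5", "CP3", "C6", "CP4", "P7", "P8", "O1", "O2")

SESSION_INDEX = {s: i for i, s in enumerate(SESSIONS)}
CONDITION_INDEX = {c: i for i, c in enumerate(CONDITIONS)}

#: carrier spectrum extends this many Hz beyond the analysis band so that it
#: is flat across the analysis filter's transition skirts
CARRIER_MARGIN_HZ = 2.0
#: rolloff width of the carrier spectrum outside the widened band
CARRIER_EDGE_HZ = 0.5
#: ramp length (s) at the edges of a time-localised coupling support
SUPPORT_RAMP_S = 0.05


@dataclass
class SimulationConfig:
    """Study-level generator settings.

    The defaults are the package's reference study conditions: 16 subjects,
    60 trials per (session, condition) cell, 100 Hz sampling, 2.5 s epochs
    from -0.5 s to 2 s around cue onset, theta carrier (3-8 Hz), pink (1/f)
    background at an oscillation-to-noise amplitude ratio of 2.
    """

    n_subjects: int = 16
    n_trials_per_cell: int = 60
    fs: float = 100.0
    epoch_span: tuple[float, float] = (-0.5, 2.0)
    channel_labels: tuple[str, ...] = CHANNELS_1020
    carrier_band: tuple[float, float] = (3.0, 8.0)
    noise_exponent: float = 1.0
    snr: float = 2.0
    mixing_matrix: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_trials_per_cell < 1:
            raise ValueError("n_trials_per_cell must be >= 1")
        if self.fs <= 2 * self.carrier_band[1]:
            raise ValueError("fs must exceed twice the carrier band upper edge")
        if self.epoch_span[0] > 0 or self.epoch_span[1] < 2.0:
            raise ValueError("epoch_span must cover at least [0, 2] s around onset")
        if self.snr <= 0:
            raise ValueError("snr must be positive (use np.inf for noise-free)")
        if self.mixing_matrix is not None:
            m = np.asarray(self.mixing_matrix, dtype=float)
            n = len(self.channel_labels)
            if m.shape != (n, n):
                raise ValueError(f"mixing_matrix must be {n}x{n}")
            off = m.sum(axis=1) - np.diag(m)
            if np.any(np.diag(m) <= off):
                raise ValueError("mixing_matrix rows must be diagonally dominant")
            self.mixing_matrix = m / m.sum(axis=1, keepdims=True)

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_span[1] - self.epoch_span[0]) * self.fs))

    @property
    def time0(self) -> float:
        return -self.epoch_span[0]

    def cell_rng(self, subject: int, session: str, condition: str) -> np.random.Generator:
        """Deterministic RNG for one (subject, session, condition) cell.

        Derivation: ``SeedSequence(seed, spawn_key=(session_idx, condition_idx,
        subject))`` so any cell can be regenerated in isolation.
        """
        key = (SESSION_INDEX[session], CONDITION_INDEX[condition], subject)
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


@dataclass(frozen=True)
class PlantedCoupling:
    """A set of phase-coupled channel pairs sharing strength and lag.

    In every ``(source, target)`` pair the *first* label's base oscillator is
    the shared carrier injected (lagged, scaled by ``kappa``) into the second
    channel.  ``sessions`` / ``conditions`` restrict where the coupling is
    active; ``support`` optionally restricts it to a time interval (seconds
    relative to cue onset).
    """

    pairs: tuple[tuple[str, str], ...]
    kappa: float
    lag: float = np.pi / 4
    sessions: frozenset[str] = frozenset(SESSIONS)
    conditions: frozenset[str] = frozenset(CONDITIONS)
    support: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if not -np.pi < self.lag <= np.pi:
            raise ValueError("lag must lie in (-pi, pi]")
        object.__setattr__(self, "sessions", frozenset(self.sessions))
        object.__setattr__(self, "conditions", frozenset(self.conditions))
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))

    def applies_to(self, session: str, condition: str) -> bool:
        return session in self.sessions and condition in self.conditions

    def to_dict(self) -> dict[str, Any]:
        return {
            "pairs": [list(p) for p in self.pairs],
            "kappa": self.kappa,
            "lag": self.lag,
            "sessions": sorted(self.sessions),
            "conditions": sorted(self.conditions),
            "support": list(self.support) if self.support else None,
        }


@dataclass
class BehaviouralEffects:
    """Effect sizes of the behavioural generator (milliseconds unless noted).

    ``learning_rate`` is the per-block exponential approach rate towards the
    asymptotic sequence skill ``learn_max``; ``rt_noise_sd`` is the standard
    deviation of the lognormal multiplicative noise on block medians.
    """

    learning_rate: float = 1.0 / 12.0
    overnight_gain: float = 20.0
    tmr_gain_left: float = 40.0
    base_rt: float = 480.0
    learn_max: float = 80.0
    rt_noise_sd: float = 0.06
    n_sequence_blocks: int = 48
    n_random_blocks: int = 4

    def __post_init__(self) -> None:
        for name in ("learning_rate", "overnight_gain", "tmr_gain_left",
                     "base_rt", "learn_max", "rt_noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.base_rt <= 0:
            raise ValueError("base_rt (RT scale) must be positive")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be non-negative")


@dataclass
class SyntheticStudy:
    """All artefacts of one simulated study, with the planted ground truth."""

    config: SimulationConfig
    recordings: dict[tuple[int, str, str], EpochedRecording]
    truth: list[PlantedCoupling]
    behavioural: pd.DataFrame
    seed_used: int
    subject_factors: np.ndarray | None = None

    def cell(self, subject: int, session: str, condition: str) -> EpochedRecording:
        return self.recordings[(subject, session, condition)]


def _support_mask(config: SimulationConfig, support: tuple[float, float] | None) -> np.ndarray:
    if support is None:
        return np.ones(config.n_samples)
    t = np.arange(config.n_samples) / config.fs - config.time0
    ramp = SUPPORT_RAMP_S
    lo, hi = support
    up = np.clip((t - (lo - ramp)) / ramp, 0, 1)
    down = np.clip(((hi + ramp) - t) / ramp, 0, 1)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def generate_epochs(
    config: SimulationConfig,
    couplings: Iterable[PlantedCoupling],
    session: str,
    condition: str,
    subject: int = 0,
) -> EpochedRecording:
    """Generate one (subject, session, condition) cell of epoched data."""
    if session not in SESSIONS:
        raise ValueError(f"session must be one of {SESSIONS}")
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    labels = config.channel_labels
    active = [c for c in couplings if c.applies_to(session, condition)]
    for c in active:
        for p, q in c.pairs:
            for lab in (p, q):
                if lab not in labels:
                    raise ValueError(f"coupling references unknown channel {lab!r}")
    rng = config.cell_rng(subject, session, condition)
    n_ch = len(labels)
    n_tr = config.n_trials_per_cell
    n_sp = config.n_samples
    lo, hi = config.carrier_band
    carrier = band_gain(
        n_sp, config.fs,
        max(lo - CARRIER_MARGIN_HZ, CARRIER_EDGE_HZ + 0.1), hi + CARRIER_MARGIN_HZ,
        CARRIER_EDGE_HZ,
    )
    base = shaped_gaussian(rng, (n_ch, n_tr, n_sp), carrier)
    idx = {lab: i for i, lab in enumerate(labels)}

    # accumulate lagged source contributions per target channel
    contrib = np.zeros_like(base)
    total_kappa = np.zeros(n_ch)
    analytic_cache: dict[str, np.ndarray] = {}
    for c in active:
        mask = _support_mask(config, c.support)
        rot = np.exp(-1j * c.lag)
        for p, q in c.pairs:
            if p not in analytic_cache:
                analytic_cache[p] = analytic_signal(base[idx[p]])
            lagged = np.real(analytic_cache[p] * rot)
            contrib[idx[q]] += c.kappa * lagged * mask
            total_kappa[idx[q]] += c.kappa
    w0 = np.maximum(0.0, 1.0 - total_kappa)
    osc = w0[:, None, None] * base + contrib

    data = osc
    if np.isfinite(config.snr):
        noise = shaped_gaussian(
            rng, (n_ch, n_tr, n_sp), pink_gain(n_sp, config.fs, config.noise_exponent)
        )
        data = osc + noise / config.snr
    if config.mixing_matrix is not None:
        data = np.einsum("cd,dts->cts", config.mixing_matrix, data)

    return EpochedRecording(
        data=data,
        fs=config.fs,
        channel_labels=labels,
        session=session,
        condition=condition,
        subject_id=subject,
        time0=config.time0,
        metadata={"seed": config.seed, "planted": [c.to_dict() for c in active]},
    )


def generate_behavioural(
    config: SimulationConfig,
    effects: BehaviouralEffects | None = None,
    subject_factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-block reaction-time table for every subject.

    Rows: (subject, session in {pre, post}, sequence in {Re, NRe}, hand in
    {L, R}, block_index, block_type in {sequence, random}, rt_ms).  Block
    medians follow an exponential learning curve shared by the two sequences,
    drop by ``overnight_gain`` after sleep, and drop additionally by
    ``tmr_gain_left`` for the reactivated (Re) sequence on left-hand trials
    only.  Random blocks carry no sequence-specific gain.  Noise is lognormal
    multiplicative on the block median, so ``rt_noise_sd = 0`` recovers the
    model medians exactly.
    """
    effects = effects or BehaviouralEffects()
    if subject_factors is None:
        subject_factors = np.ones(config.n_subjects)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))
    nb, nr = effects.n_sequence_blocks, effects.n_random_blocks
    rows = []
    for subj in range(config.n_subjects):
        u = float(subject_factors[subj])
        for session, sess_i in (("pre", 0), ("post", 1)):
            for sequence in ("Re", "NRe"):
                for hand in ("L", "R"):
                    b_idx = np.arange(nb + nr)
                    is_random = b_idx >= nb
                    b_global = b_idx + sess_i * nb
                    learned = effects.learn_max * (1 - np.exp(-effects.learning_rate * b_global))
                    med = np.full(nb + nr, effects.base_rt, dtype=float)
                    med[~is_random] -= learned[~is_random]
                    if session == "post":
                        med[~is_random] -= effects.overnight_gain
                        if sequence == "Re" and hand == "L":
                            med[~is_random] -= effects.tmr_gain_left * u
                    noise = (
                        np.exp(effects.rt_noise_sd * rng.standard_normal(nb + nr))
                        if effects.rt_noise_sd > 0
                        else 1.0
                    )
                    rt = med * noise
                    rows.append(
                        pd.DataFrame(
                            {
                                "subject": subj,
                                "session": session,
                                "sequence": sequence,
                                "hand": hand,
                                "block_index": b_idx,
                                "block_type": np.where(is_random, "random", "sequence"),
                                "rt_ms": rt,
                            }
                        )
                    )
    table = pd.concat(rows, ignore_index=True)
    if (table["rt_ms"] <= 0).any():
        raise ValueError("effect sizes produce non-positive reaction times")
    return table


# ---------------------------------------------------------------------------
# reference planted-effect structure

#: session-level coupling strength of the frontal and inter-hemispheric links:
#: elevated in slow-wave sleep, intermediate before sleep, lowest after sleep
K_SESSION = {"Pre": 0.78, "Sleep": 0.92, "Post": 0.68}
#: baseline within-hemisphere coupling, present in every session and condition
K_WITHIN = 0.75
#: extra within-hemisphere coupling of the hemisphere contralateral to the
#: cued hand, present during sleep and after sleep but not before
K_HAND = 0.15

_LAGS = {"frontal_L": np.pi / 4, "frontal_R": np.pi / 3, "between": np.pi / 2.2,
         "within_L": 2 * np.pi / 5, "within_R": -2 * np.pi / 5}


def default_couplings(hand_factor: float = 1.0) -> list[PlantedCoupling]:
    """The reference planted-effect structure.

    Left and right central channels (C5, C6) act as hub oscillators.  Each
    hub drives its hemisphere's remaining motor channels (within-hemisphere
    links) and the ipsilateral frontal channel (hemisphere-frontal links);
    C6 additionally carries C5's oscillator (inter-hemispheric link).
    Frontal and inter-hemispheric strengths follow ``K_SESSION``
    (Sleep > Pre > Post); the hemisphere contralateral to the cued hand gains
    ``K_HAND * hand_factor`` extra within-hemisphere coupling in the Sleep
    and Post sessions, which is the planted hand-discrimination effect.
    """
    coup: list[PlantedCoupling] = []
    for sess, k in K_SESSION.items():
        coup.append(PlantedCoupling((("C5", "F3"),), k, _LAGS["frontal_L"], sessions={sess}))
        coup.append(PlantedCoupling((("C6", "F4"),), k, _LAGS["frontal_R"], sessions={sess}))
        coup.append(PlantedCoupling((("C5", "C6"),), k, _LAGS["between"], sessions={sess}))
        for cond in CONDITIONS:
            contralateral_boost = sess in ("Sleep", "Post")
            k_l = K_WITHIN + (K_HAND * hand_factor if cond == "R" and contralateral_boost else 0)
            k_r = K_WITHIN + (K_HAND * hand_factor if cond == "L" and contralateral_boost else 0)
            coup.append(PlantedCoupling((("C5", "CP3"), ("C5", "P7")), min(k_l, 1.0),
                                        _LAGS["within_L"], sessions={sess}, conditions={cond}))
            coup.append(PlantedCoupling((("C6", "CP4"), ("C6", "P8")), min(k_r, 1.0),
                                        _LAGS["within_R"], sessions={sess}, conditions={cond}))
    return coup


def leakage_matrix(n_channels: int, strength: float = 0.4) -> np.ndarray:
    """Instantaneous volume-conduction-like mixing: each channel leaks into
    its two ring neighbours with the given relative weight (rows are
    normalised by :class:`SimulationConfig` on construction)."""
    m = np.eye(n_channels)
    for i in range(n_channels):
        m[i, (i + 1) % n_channels] = strength
        m[i, (i - 1) % n_channels] = strength
    return m


def generate_study(
    config: SimulationConfig,
    couplings: list[PlantedCoupling] | None = None,
    effects: BehaviouralEffects | None = None,
    behaviour_link_sd: float = 0.0,
    sessions: tuple[str, ...] = SESSIONS,
    conditions: tuple[str, ...] = CONDITIONS,
) -> SyntheticStudy:
    """Generate the full study: recordings for every cell plus behaviour.

    ``behaviour_link_sd`` > 0 draws a per-subject factor u ~ N(1, sd)
    (clipped to [0.2, 1.8]) that scales *both* the hand-specific coupling
    increment and the TMR reaction-time benefit, planting a cross-subject
    correlation between sleep connectivity and overnight improvement.
    """
    effects = effects or BehaviouralEffects()
    factor_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(7,)))
    if behaviour_link_sd > 0:
        factors = np.clip(
            1 + behaviour_link_sd * factor_rng.standard_normal(config.n_subjects), 0.2, 1.8
        )
    else:
        factors = np.ones(config.n_subjects)

    recordings: dict[tuple[int, str, str], EpochedRecording] = {}
    truth_union: list[PlantedCoupling] = []
    for subj in range(config.n_subjects):
        subj_coup = couplings if couplings is not None else default_couplings(factors[subj])
        if subj == 0:
            truth_union = list(subj_coup)
        for session in sessions:
            for condition in conditions:
                recordings[(subj, session, condition)] = generate_epochs(
                    config, subj_coup, session, condition, subject=subj
                )
    behaviour = generate_behavioural(config, effects, subject_factors=factors)
    return SyntheticStudy(
        config=config,
        recordings=recordings,
        truth=truth_union,
        behavioural=behaviour,
        seed_used=config.seed,
        subject_factors=factors,
    )
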