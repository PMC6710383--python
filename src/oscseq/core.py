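"""Phase-oscillator ensemble dynamics for rhythm-based sequence learning.

An ensemble of ``N`` phase oscillators is driven by a symbolic input
stream (one symbol, or no input, per discrete time step).  Each input
symbol is associated with a target phase.  Oscillators whose phase is
close to a target phase at input time are *attuned* to that input's
rhythm: their phase is reset and their frequency is retuned so that,
cycle by cycle, they come to hit the target phase exactly when the
input recurs.  The amount of re-tuning an already attuned ensemble
needs when an item appears at the wrong position yields an error
signal that classifies test items as congruent or incongruent
continuations of a learned sequence.

The model is a discrete map (no continuous-time integration).  All
phases live on the circle ``[0, 2*pi)``; frequencies are in cycles per
time step.

Every operation in this module is vectorized: an "ensemble" may carry
arbitrary leading axes (e.g. ``(n_channels, N)`` or
``(n_seeds, n_channels, N)``), which is how multi-pixel and multi-seed
simulations are run efficiently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from math import pi

import numpy as np

TWO_PI = 2.0 * pi

__all__ = [
    "TWO_PI",
    "OscState",
    "ModelParams",
    "TargetMap",
    "EnsembleState",
    "StepResult",
    "ErrorTrace",
    "wrap_phase",
    "signed_phase_diff",
    "circular_distance",
    "init_ensemble",
    "advance_phases",
    "classify_state",
    "match_update",
    "mismatch_update",
    "step",
    "decide_congruence",
]


def wrap_phase(phi):
    """Wrap phase(s) into ``[0, 2*pi)``."""
    return np.mod(phi, TWO_PI)


def signed_phase_diff(a, b):
    """Minimal signed circular difference ``a - b`` in ``(-pi, pi]``.

    This is the quantity used wherever the update rules need a phase
    error: a naive ``a - b`` breaks at the 0/2*pi seam.
    """
    d = np.mod(np.asarray(a, dtype=float) - b, TWO_PI)
    return np.where(d > pi, d - TWO_PI, d)


def circular_distance(a, b):
    """Unsigned circular distance between phases, in ``[0, pi]``."""
    return np.abs(signed_phase_diff(a, b))


class OscState(enum.IntEnum):
    """Phase state of an oscillator relative to its nearest target phase.

    ``LOCKED``
        within ``theta_locked`` of the target: dynamically stable, no
        learning update while the input matches.
    ``LOCKING``
        within ``theta_locking`` but not locked: eligible for a phase
        reset and frequency retune at input time.
    ``IN_TRANSIT``
        anywhere else: untouched by learning, a pool of free
        oscillators.
    """

    IN_TRANSIT = 0
    LOCKING = 1
    LOCKED = 2


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one oscillator ensemble.

    Parameters
    ----------
    n_oscillators:
        Ensemble size ``N``.
    theta_locked, theta_locking:
        Phase-distance thresholds (radians) separating the locked /
        locking / in-transit states.
    noise_std:
        Standard deviation (radians) of the zero-mean Gaussian phase
        jitter added on every step.  The default is numerically
        negligible but kept configurable.
    freq_init_low, freq_init_high:
        Bounds of the uniform distribution initial frequencies are
        drawn from (cycles per time step).  Defaults are the visual
        band; the auditory band is ``[5, 6]``.
    seed:
        Seed for the ensemble's random number generator.
    mismatch_variant:
        Which reading of the mismatch frequency rule to use
        (see :func:`mismatch_update`); ``"intent"`` (default), ``"a"``
        or ``"b"``.
    mismatch_gain:
        Period-scaling coefficient of the ``"intent"`` mismatch rule
        (dimensionless, default 0.9; see :func:`mismatch_update`).
    freq_floor:
        Lower clamp applied to frequencies after every learning update;
        the alternative retuning rules can drive a frequency negative,
        which has no physical reading in the phase-advance map.
    """

    n_oscillators: int = 100
    theta_locked: float = pi / 60
    theta_locking: float = pi / 6
    noise_std: float = 1e-10
    freq_init_low: float = 0.01
    freq_init_high: float = 1.0
    seed: int = 0
    mismatch_variant: str = "intent"
    mismatch_gain: float = 0.9
    freq_floor: float = 1e-6

    def __post_init__(self):
        if not (0 < self.theta_locked < self.theta_locking < pi):
            raise ValueError(
                "need 0 < theta_locked < theta_locking < pi, got "
                f"{self.theta_locked}, {self.theta_locking}"
            )
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if not (0 < self.freq_init_low < self.freq_init_high):
            raise ValueError("need 0 < freq_init_low < freq_init_high")
        if self.n_oscillators < 1:
            raise ValueError("n_oscillators must be positive")
        if self.mismatch_variant not in ("intent", "a", "b"):
            raise ValueError("mismatch_variant must be 'intent', 'a' or 'b'")
        if not (0 < self.mismatch_gain <= 1):
            raise ValueError("mismatch_gain must be in (0, 1]")

    @classmethod
    def visual(cls, **kw) -> "ModelParams":
        """Visual-module parameters (initial frequency band [0.01, 1])."""
        return cls(**kw)

    @classmethod
    def auditory(cls, **kw) -> "ModelParams":
        """Auditory-module parameters (initial frequency band [5, 6])."""
        kw.setdefault("freq_init_low", 5.0)
        kw.setdefault("freq_init_high", 6.0)
        return cls(**kw)


@dataclass(frozen=True)
class TargetMap:
    """Association of input symbols with target phases.

    Symbols are positive integers; ``0`` is reserved for "no input"
    and may never appear as an entry.  Target phases lie in
    ``[0, 2*pi)``.
    """

    symbols: tuple
    target_phases: tuple

    def __post_init__(self):
        if len(self.symbols) == 0:
            raise ValueError("TargetMap must have at least one entry")
        if len(self.symbols) != len(self.target_phases):
            raise ValueError("symbols and target_phases differ in length")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("symbols must be unique")
        if 0 in self.symbols:
            raise ValueError("symbol 0 is reserved for 'no input'")
        if any(s < 0 for s in self.symbols):
            raise ValueError("symbols must be positive integers")
        for p in self.target_phases:
            if not (0 <= p < TWO_PI):
                raise ValueError("target phases must lie in [0, 2*pi)")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def symbol_array(self) -> np.ndarray:
        return np.asarray(self.symbols, dtype=np.int64)

    @property
    def phase_array(self) -> np.ndarray:
        return np.asarray(self.target_phases, dtype=float)

    def phase_of(self, symbol: int) -> float:
        """Target phase associated with ``symbol``."""
        try:
            return self.target_phases[self.symbols.index(symbol)]
        except ValueError:
            raise KeyError(f"symbol {symbol} not in target map") from None

    # --- canonical maps used throughout the experiments -----------------
    @classmethod
    def unimodal(cls) -> "TargetMap":
        """Black -> pi/2, white -> 3*pi/2 (pixel gray-level inputs)."""
        from . import stimuli

        return cls(
            symbols=(stimuli.BLACK, stimuli.WHITE),
            target_phases=(pi / 2, 3 * pi / 2),
        )

    @classmethod
    def crossmodal_visual(cls) -> "TargetMap":
        """Single 'bright' symbol at 3*pi/2 (disc stimuli drive one level)."""
        from . import stimuli

        return cls(symbols=(stimuli.BRIGHT,), target_phases=(3 * pi / 2,))

    @classmethod
    def auditory(cls) -> "TargetMap":
        """Low pitch -> pi/2, high pitch -> 3*pi/2."""
        from . import stimuli

        return cls(
            symbols=(stimuli.PITCH_LOW, stimuli.PITCH_HIGH),
            target_phases=(pi / 2, 3 * pi / 2),
        )


@dataclass
class EnsembleState:
    """Mutable state of one (or a stack of) oscillator ensemble(s).

    ``phases``, ``freqs`` and ``last_reset`` share a common shape whose
    last axis is the oscillator axis; leading axes, if any, index
    independent ensembles (channels, seeds, ...).  ``last_reset`` holds
    the time step of each oscillator's most recent phase reset (0 if it
    was never reset), so ``t - last_reset`` is the reset age used to
    weight the error signal.
    """

    phases: np.ndarray
    freqs: np.ndarray
    last_reset: np.ndarray
    t: int = 0

    def copy(self) -> "EnsembleState":
        return EnsembleState(
            phases=self.phases.copy(),
            freqs=self.freqs.copy(),
            last_reset=self.last_reset.copy(),
            t=self.t,
        )

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[-1]


@dataclass
class StepResult:
    """Outcome of one simulation step.

    ``resets`` flags the oscillators that received a match or mismatch
    update this step; ``error`` is the reset-age-weighted reset count
    ``e(t) = sum_i resets_i * dt_i`` (per leading-axis ensemble, summed
    over the oscillator axis only); ``states`` holds the post-advance,
    pre-update :class:`OscState` labels.
    """

    resets: np.ndarray
    error: np.ndarray | float
    states: np.ndarray


@dataclass
class ErrorTrace:
    """History of per-step error values (and optional decisions)."""

    errors: list = field(default_factory=list)
    decisions: list = field(default_factory=list)

    def append(self, error, decision=None) -> None:
        self.errors.append(error)
        if decision is not None:
            self.decisions.append(decision)

    def running_max(self) -> float:
        return max(self.errors) if self.errors else 0.0

    def as_array(self) -> np.ndarray:
        return np.asarray(self.errors, dtype=float)


def init_ensemble(params: ModelParams, rng=None, shape=()) -> EnsembleState:
    """Draw a fresh ensemble: uniform phases and frequencies.

    Phases are uniform on ``[0, 2*pi)``, frequencies uniform on the
    configured init band, all oscillators start un-reset at ``t = 0``.
    Fully determined by ``params.seed`` (or by ``rng`` if given).
    ``shape`` prepends leading ensemble axes.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    full = tuple(shape) + (params.n_oscillators,)
    return EnsembleState(
        phases=rng.uniform(0.0, TWO_PI, size=full),
        freqs=rng.uniform(params.freq_init_low, params.freq_init_high, size=full),
        last_reset=np.zeros(full, dtype=np.int64),
        t=0,
    )


def advance_phases(state: EnsembleState, params: ModelParams, rng) -> EnsembleState:
    """Free-run every oscillator one step: ``phi += 2*pi*f + eta``.

    ``eta`` is zero-mean Gaussian jitter with ``params.noise_std``.
    Phases are wrapped back into ``[0, 2*pi)``; frequencies are
    untouched; the clock advances.  Mutates ``state`` in place and
    returns it.
    """
    incr = TWO_PI * state.freqs
    if params.noise_std > 0:
        incr = incr + rng.normal(0.0, params.noise_std, size=state.phases.shape)
    state.phases = wrap_phase(state.phases + incr)
    state.t += 1
    return state


def classify_state(phase, targets: TargetMap, params: ModelParams):
    """Classify phase(s) against the *nearest* target phase.

    Returns ``(states, nearest_index)`` where ``states`` holds
    :class:`OscState` codes and ``nearest_index`` indexes into the
    target map.  The nearest target (unsigned circular distance)
    determines which symbol an oscillator is locked/locking to; ties
    break toward the lower-indexed map entry.
    """
    phase = np.asarray(phase, dtype=float)
    # distances to every target: (..., n_targets)
    d = circular_distance(phase[..., None], targets.phase_array)
    nearest = np.argmin(d, axis=-1)
    dmin = np.take_along_axis(d, nearest[..., None], axis=-1)[..., 0]
    states = np.full(phase.shape, OscState.IN_TRANSIT, dtype=np.int8)
    states[dmin < params.theta_locking] = OscState.LOCKING
    states[dmin < params.theta_locked] = OscState.LOCKED
    return states, nearest


def match_update(phase, freq, target_phase, delta_t):
    """Phase reset and frequency retune for a matching input.

    The phase is set exactly to the target phase; the frequency is
    corrected by the signed circular phase error spread over the
    ``delta_t`` steps since the oscillator's last reset::

        f' = f - wrap(phi - phi_hat) / (2*pi*delta_t)

    For an input recurring every ``delta_t`` steps this makes the next
    arrival at the target exact: the fixed point is ``f* = k/delta_t``.
    """
    delta_t = np.maximum(np.asarray(delta_t, dtype=float), 1.0)
    err = signed_phase_diff(phase, target_phase)
    new_phase = np.broadcast_to(
        np.asarray(target_phase, dtype=float), np.shape(phase)
    ).copy() if np.shape(phase) else float(target_phase)
    new_freq = np.asarray(freq, dtype=float) - err / (TWO_PI * delta_t)
    return new_phase, new_freq


def _mismatch_phase_term(phase, target_phase):
    """Circular representative of ``phi + (2*pi - phi_hat)`` in ``(pi, 3*pi]``.

    The mismatch rule's phase term is the raw sum of the current phase
    and the inverted target; taking its minimal circular representative
    (offset by one full turn so it stays positive) keeps the rule
    continuous across the 0/2*pi seam.
    """
    return TWO_PI + signed_phase_diff(phase, target_phase)


def mismatch_update(phase, freq, target_phase, delta_t, variant="intent",
                    gain=0.9):
    """Phase inversion and period change for a conflicting input.

    The phase is inverted through the target: ``phi' = 2*pi - phi_hat``.
    The frequency rule retunes the period so the oscillator, free
    running, arrives at the target phase about one input interval later
    (when its phase was lagging the target) or earlier (when leading)
    than it would have at its current period.

    ``variant="intent"`` (default) realizes this as a period change of
    ``gain`` parts in ``delta_t``::

        f' = f * (1 + s*gain/delta_t),   s = +1 leading, -1 lagging

    with leading/lagging read off the sign of the minimal circular
    phase error (an exact tie counts as lagging; in ensemble runs the
    per-step phase jitter dithers this tie).  An oscillator near the
    reset cadence (``f ~ 1/delta_t``) thereby slips its target arrival
    by roughly one stimulus slot per cycle.  ``gain`` must stay
    strictly below 1: at exactly one part in ``delta_t`` the updated
    frequencies remain on a dyadic-rational lattice whose phase orbits
    keep re-hitting the target phases exactly, and the ensemble
    degenerates into a self-trapping reset cascade.

    Two further readings of the rule are kept selectable, differing in
    how the reciprocal reset age distributes over the terms; with
    ``E = 2*pi + wrap(phi - phi_hat)``:

    * ``"a"``: ``f' = f + (1/delta_t) * (f - E/(2*pi*delta_t))``
    * ``"b"``: ``f' = f + f/delta_t - E/(2*pi*delta_t)``
    """
    delta_t = np.maximum(np.asarray(delta_t, dtype=float), 1.0)
    freq = np.asarray(freq, dtype=float)
    if variant == "intent":
        leading = np.asarray(signed_phase_diff(phase, target_phase)) > 0
        new_freq = freq * np.where(leading, 1.0 + gain / delta_t,
                                   1.0 - gain / delta_t)
    elif variant == "a":
        e_term = _mismatch_phase_term(phase, target_phase)
        new_freq = freq + (freq - e_term / (TWO_PI * delta_t)) / delta_t
    elif variant == "b":
        e_term = _mismatch_phase_term(phase, target_phase)
        new_freq = freq + freq / delta_t - e_term / (TWO_PI * delta_t)
    else:
        raise ValueError(f"unknown mismatch variant {variant!r}")
    new_phase = wrap_phase(TWO_PI - np.asarray(target_phase, dtype=float))
    new_phase = (
        np.broadcast_to(new_phase, np.shape(phase)).copy()
        if np.shape(phase)
        else float(new_phase)
    )
    return new_phase, new_freq


def step(state: EnsembleState, input_symbol, targets: TargetMap,
         params: ModelParams, rng) -> tuple[EnsembleState, StepResult]:
    """Advance one time step and apply the learning rules.

    Order within a step: (1) every oscillator free-runs
    (:func:`advance_phases`); (2) if an input is present, each
    oscillator is classified against its nearest target; *locking*
    oscillators receive a match update when the input symbol equals the
    nearest target's symbol and a mismatch update otherwise; *locked*
    oscillators receive a mismatch update when the symbol conflicts
    (this is what lets a fully attuned ensemble flag a violation) and
    are otherwise left alone; in-transit oscillators are never touched;
    (3) each updated oscillator counts as a reset and its reset clock
    restarts; (4) the error is the sum of reset ages over resetting
    oscillators, computed with ages valid *before* the reset; (5) a
    blank slot (symbol 0) performs only the free-run: no resets, zero
    error.

    ``input_symbol`` may be a scalar or an array matching the state's
    leading (ensemble) axes, so stacks of ensembles with different
    per-channel inputs advance in one call.
    """
    advance_phases(state, params, rng)
    phases = state.phases
    lead_shape = phases.shape[:-1]

    sym = np.asarray(input_symbol)
    known = np.isin(sym, targets.symbol_array) | (sym == 0)
    if not np.all(known):
        bad = np.unique(np.atleast_1d(sym)[~np.atleast_1d(known)])
        raise ValueError(f"unknown input symbol(s): {bad.tolist()}")

    states, nearest = classify_state(phases, targets, params)
    resets = np.zeros(phases.shape, dtype=bool)
    error = np.zeros(lead_shape, dtype=float)

    active = np.broadcast_to((sym != 0)[..., None] if sym.shape else sym != 0,
                             phases.shape)
    if np.any(active):
        near_sym = targets.symbol_array[nearest]
        near_phase = targets.phase_array[nearest]
        sym_b = np.broadcast_to(sym[..., None] if sym.shape else sym,
                                phases.shape)
        same = near_sym == sym_b
        match = active & (states == OscState.LOCKING) & same
        mismatch = active & ~same & (
            (states == OscState.LOCKING) | (states == OscState.LOCKED)
        )
        resets = match | mismatch
        if np.any(resets):
            dt = np.maximum(state.t - state.last_reset, 1).astype(float)
            new_phases = phases.copy()
            new_freqs = state.freqs.copy()
            if np.any(match):
                p, f = match_update(
                    phases[match], state.freqs[match],
                    near_phase[match], dt[match],
                )
                new_phases[match] = p
                new_freqs[match] = f
            if np.any(mismatch):
                p, f = mismatch_update(
                    phases[mismatch], state.freqs[mismatch],
                    near_phase[mismatch], dt[mismatch],
                    variant=params.mismatch_variant, gain=params.mismatch_gain,
                )
                new_phases[mismatch] = p
                new_freqs[mismatch] = f
            error = np.sum(resets * dt, axis=-1)
            state.phases = new_phases
            state.freqs = np.maximum(new_freqs, params.freq_floor)
            state.last_reset = np.where(resets, state.t, state.last_reset)

    if not lead_shape:
        error = float(error)
    return state, StepResult(resets=resets, error=error, states=states)


def decide_congruence(trace: ErrorTrace, current_error) -> bool:
    """Classify the current step as incongruent.

    Returns ``True`` (incongruent) iff the current error strictly
    exceeds the maximum of all previous per-step errors of the trial.
    With no history the answer is ``False``: a violation cannot be
    asserted before anything was learned, and the model is only queried
    after at least one full presentation.
    """
    if not trace.errors:
        return False
    return bool(np.asarray(current_error) > trace.running_max())
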