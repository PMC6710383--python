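"""Trial orchestration: attunement runs, congruence trials, accuracy sweeps.

A *trial* presents a repeated stimulus sequence to a bank of oscillator
ensembles (one per input channel), pools the per-step error signal by
summation across ensembles, and asks at the test step whether the test
item is an incongruent continuation.  Channels whose input streams are
identical are statistically exchangeable, so the bank is simulated as
one state block per distinct stream pattern with a ``(n_seeds,
n_channels_in_group, n_oscillators)`` layout; this batches Monte-Carlo
runs over seeds without changing any single-ensemble trajectory.

Seed convention: run ``r`` of a sweep uses seed ``base_seed + r``, and
paired congruent/incongruent trials share the seed list, so accuracy
curves are paired across congruency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stimuli
from .core import (
    EnsembleState,
    ErrorTrace,
    ModelParams,
    OscState,
    TargetMap,
    decide_congruence,
    init_ensemble,
    step,
)

__all__ = [
    "TrialSpec",
    "TrialResult",
    "SimResult",
    "ChannelGroup",
    "simulate_streams",
    "attune",
    "run_trial",
    "run_trials",
    "run_multimodal",
    "accuracy_curve",
    "per_sequence_accuracy",
]


class _SeedStack:
    """Adapter presenting one generator per seed as a single stacked RNG.

    Draws with a leading axis equal to the number of seeds, taking each
    slice from that seed's own generator, so every Monte-Carlo run has
    an independent, reproducible random stream regardless of how many
    runs are batched together.
    """

    def __init__(self, seed_keys):
        self.rngs = [np.random.default_rng(k) for k in seed_keys]

    def _stack(self, fn, size):
        if size is None or np.ndim(size) == 0 or len(size) == 0:
            raise ValueError("stacked draws need an explicit shape")
        if size[0] != len(self.rngs):
            raise ValueError("leading axis must equal the number of seeds")
        return np.stack([fn(r, tuple(size[1:])) for r in self.rngs])

    def uniform(self, low=0.0, high=1.0, size=None):
        return self._stack(lambda r, s: r.uniform(low, high, s), size)

    def normal(self, loc=0.0, scale=1.0, size=None):
        return self._stack(lambda r, s: r.normal(loc, scale, s), size)


@dataclass
class ChannelGroup:
    """Channels sharing one input stream pattern (hence one state block)."""

    pattern: np.ndarray            # (n_steps,) symbols, test step excluded
    channels: np.ndarray           # channel indices in the StreamBundle
    modality: str                  # "V" or "A"
    full_stream: np.ndarray        # (n_steps_total,) including test step

    @property
    def is_background(self) -> bool:
        return not self.full_stream.any()


@dataclass
class SimResult:
    """Outcome of driving a channel bank through a stream bundle."""

    errors: np.ndarray             # (n_seeds, n_steps) pooled error
    groups: list                   # ChannelGroup per state block
    states: list                   # final EnsembleState per group,
                                   # phases shaped (n_seeds, n_channels, N)
    locked_fraction: np.ndarray | None = None   # (n_seeds, n_steps)
    reset_counts: np.ndarray | None = None      # (n_seeds, n_steps)

    def decisions(self) -> np.ndarray:
        """Per-seed congruence call at the final step (True=incongruent)."""
        return self.errors[:, -1] > self.errors[:, :-1].max(axis=1)

    def channel_states(self, modality=None):
        """Yield ``(channel_index, phases, freqs)`` per channel."""
        for g, st in zip(self.groups, self.states):
            if modality is not None and g.modality != modality:
                continue
            for j, ch in enumerate(g.channels):
                yield ch, st.phases[:, j, :], st.freqs[:, j, :]


def _group_streams(bundle: stimuli.StreamBundle, learn_steps: int):
    """Partition channels by their stream pattern over the learning steps.

    Grouping on the learning part (test step excluded) keeps the
    partition identical between the congruent and incongruent arm of a
    paired trial; for the rendered stimuli the test-step symbol is
    constant within each group anyway.
    """
    groups = []
    seen = {}
    for i in range(bundle.n_channels):
        key = (bundle.modality[i], bundle.symbols[i, :learn_steps].tobytes())
        if key not in seen:
            seen[key] = len(groups)
            groups.append([i])
        else:
            groups[seen[key]].append(i)
    out = []
    for idx in groups:
        idx = np.asarray(idx)
        out.append(ChannelGroup(
            pattern=bundle.symbols[idx[0], :learn_steps].copy(),
            channels=idx,
            modality=bundle.modality[idx[0]],
            full_stream=bundle.symbols[idx[0]].copy(),
        ))
    return out


def simulate_streams(
    bundle: stimuli.StreamBundle,
    seeds,
    visual_params: ModelParams | None = None,
    auditory_params: ModelParams | None = None,
    visual_targets: TargetMap | None = None,
    auditory_targets: TargetMap | None = None,
    *,
    crossmodal: bool | None = None,
    record: bool = False,
    skip_background: bool = True,
) -> SimResult:
    """Drive one ensemble per channel through the bundle's streams.

    Channels are simulated in pattern groups; the pooled error is the
    exact sum of per-ensemble errors.  Background channels (all-zero
    stream) receive no learning updates and contribute zero error; they
    are skipped unless their final state is needed (``skip_background=
    False``, e.g. for cluster maps).
    """
    seeds = list(seeds)
    if crossmodal is None:
        crossmodal = "A" in bundle.modality
    if visual_params is None:
        visual_params = ModelParams.visual()
    if visual_targets is None:
        visual_targets = (TargetMap.crossmodal_visual() if crossmodal
                          else TargetMap.unimodal())
    if crossmodal and auditory_params is None:
        auditory_params = ModelParams.auditory()
    if crossmodal and auditory_targets is None:
        auditory_targets = TargetMap.auditory()

    n_steps = bundle.n_steps
    groups = _group_streams(bundle, n_steps)
    kept, states, rngs, confs = [], [], [], []
    for gi, g in enumerate(groups):
        if skip_background and g.is_background:
            continue
        params, targets = (
            (auditory_params, auditory_targets) if g.modality == "A"
            else (visual_params, visual_targets)
        )
        rng = _SeedStack([[int(s), gi] for s in seeds])
        st = init_ensemble(params, rng=rng,
                           shape=(len(seeds), len(g.channels)))
        kept.append(g)
        states.append(st)
        rngs.append(rng)
        confs.append((params, targets))

    S = len(seeds)
    errors = np.zeros((S, n_steps))
    locked = np.zeros((S, n_steps)) if record else None
    resets = np.zeros((S, n_steps)) if record else None
    n_osc_total = sum(
        st.phases.shape[1] * st.phases.shape[2] for st in states) or 1

    for t in range(n_steps):
        for g, st, rng, (params, targets) in zip(kept, states, rngs, confs):
            sym = int(g.full_stream[t])
            _, res = step(st, sym, targets, params, rng)
            errors[:, t] += res.error.sum(axis=-1)
            if record:
                locked[:, t] += (
                    (res.states == OscState.LOCKED).sum(axis=(1, 2)))
                resets[:, t] += res.resets.sum(axis=(1, 2))
    if record:
        locked /= n_osc_total
    return SimResult(errors=errors, groups=kept, states=states,
                     locked_fraction=locked, reset_counts=resets)


def attune(sequence, repetitions: int, seeds, *, grid_size: int = 20,
           geometry: str = "disjoint", record: bool = False,
           skip_background: bool = True, **params_kw) -> SimResult:
    """Present ``repetitions`` full cycles of a sequence (no test item)."""
    bundle = stimuli.build_streams(sequence, repetitions,
                                   grid_size=grid_size, geometry=geometry)
    return simulate_streams(bundle, seeds, record=record,
                            skip_background=skip_background, **params_kw)


@dataclass(frozen=True)
class TrialSpec:
    """One congruence trial: which item is probed, and how.

    ``tested_item`` is the 1-based position on the presented-items axis
    (it must exceed the sequence length: the model is only probed after
    at least one full presentation).  Items ``1 .. tested_item-1`` of
    the cyclic continuation are presented, then the test item replaces
    the one due at ``tested_item``.
    """

    sequence: object
    tested_item: int
    congruent: bool
    seed: int = 0
    visual_params: ModelParams = field(default_factory=ModelParams.visual)
    auditory_params: ModelParams = field(default_factory=ModelParams.auditory)
    grid_size: int = 20
    geometry: str = "disjoint"

    def __post_init__(self):
        if self.tested_item < len(self.sequence) + 1:
            raise ValueError(
                "tested_item must lie beyond the first full presentation")


@dataclass
class TrialResult:
    decision_incongruent: bool
    correct: bool
    trace: ErrorTrace
    sim: SimResult


def run_trials(sequence, tested_item: int, congruent: bool, seeds, *,
               visual_params=None, auditory_params=None,
               grid_size: int = 20, geometry: str = "disjoint",
               record: bool = False) -> SimResult:
    """Batched congruence trials (one per seed); see :class:`TrialSpec`."""
    if tested_item < len(sequence) + 1:
        raise ValueError("tested_item must lie beyond the first full presentation")
    test = stimuli.make_test_item(sequence, tested_item, congruent)
    bundle = stimuli.build_streams(
        sequence, 1, test_item=test, n_items=tested_item - 1,
        grid_size=grid_size, geometry=geometry)
    return simulate_streams(bundle, seeds, visual_params=visual_params,
                            auditory_params=auditory_params, record=record)


def run_trial(spec: TrialSpec) -> TrialResult:
    """Run a single trial and classify the test item.

    ``correct`` means the congruence call matches the ground truth of
    the test item.
    """
    sim = run_trials(
        spec.sequence, spec.tested_item, spec.congruent, [spec.seed],
        visual_params=spec.visual_params, auditory_params=spec.auditory_params,
        grid_size=spec.grid_size, geometry=spec.geometry)
    errs = sim.errors[0]
    trace = ErrorTrace(errors=list(errs[:-1]))
    decision = decide_congruence(trace, errs[-1])
    trace.append(errs[-1], decision)
    return TrialResult(
        decision_incongruent=decision,
        correct=(decision == (not spec.congruent)),
        trace=trace,
        sim=sim,
    )


def run_multimodal(sequence: stimuli.CrossmodalSequence, tested_item: int,
                   congruent: bool, seeds, **kw) -> SimResult:
    """Crossmodal trial: pixel ensembles plus one auditory ensemble.

    Identical trial logic to :func:`run_trials`; the auditory channel
    uses the five-fold higher initial frequency band.  An explicitly
    constructed all-visual sequence simply runs without auditory input.
    """
    return run_trials(sequence, tested_item, congruent, seeds, **kw)


def channel_trajectory(bundle: stimuli.StreamBundle, channel: int, seed: int,
                       params: ModelParams | None = None,
                       targets: TargetMap | None = None) -> pd.DataFrame:
    """Full per-oscillator trajectory of one channel's ensemble.

    Intended for diagnostics and plotting on single channels (the
    per-step, per-oscillator table grows quickly); columns are
    ``t, oscillator_id, phase, freq, state, reset``.
    """
    crossmodal = "A" in bundle.modality
    modality = bundle.modality[channel]
    if params is None:
        params = (ModelParams.auditory() if modality == "A"
                  else ModelParams.visual())
    if targets is None:
        targets = (TargetMap.auditory() if modality == "A" else
                   TargetMap.crossmodal_visual() if crossmodal else
                   TargetMap.unimodal())
    rng = np.random.default_rng([int(seed), int(channel)])
    st = init_ensemble(params, rng=rng)
    rows = []
    for t in range(bundle.n_steps):
        st, res = step(st, int(bundle.symbols[channel, t]), targets,
                       params, rng)
        for i in range(params.n_oscillators):
            rows.append((st.t, i, st.phases[i], st.freqs[i],
                         OscState(int(res.states[i])).name.lower(),
                         int(res.resets[i])))
    return pd.DataFrame(
        rows, columns=["t", "oscillator_id", "phase", "freq",
                       "state", "reset"])


def accuracy_curve(sequences, item_range, n_runs: int, base_seed: int = 0,
                   **trial_kw) -> pd.DataFrame:
    """Mean correctness per tested item over sequences x seeds.

    Congruent and incongruent trials are paired on the same seed list;
    the combined accuracy weights the two arms equally (the test-item
    congruence ratio of the task is 0.5).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = [base_seed + r for r in range(n_runs)]
    rows = []
    for item in item_range:
        acc = {}
        for congruent in (True, False):
            correct = []
            for seq in sequences:
                sim = run_trials(seq, item, congruent, seeds, **trial_kw)
                dec = sim.decisions()
                correct.append(dec == (not congruent))
            acc[congruent] = float(np.mean(correct))
        rows.append({
            "tested_item": item,
            "accuracy_congruent": acc[True],
            "accuracy_incongruent": acc[False],
            "accuracy_combined": 0.5 * (acc[True] + acc[False]),
            "n_runs": n_runs,
        })
    return pd.DataFrame(rows)


def per_sequence_accuracy(n_runs: int, item_range=None, base_seed: int = 0,
                          **trial_kw) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combined accuracy per five-item sequence, plus entropy grouping.

    Returns ``(per_sequence, by_entropy)`` tables; the per-sequence
    accuracy is averaged over the full tested-item range supplied
    (default items 6..25).
    """
    if item_range is None:
        item_range = range(6, 26)
    seeds = [base_seed + r for r in range(n_runs)]
    rows = []
    for seq in stimuli.enumerate_unimodal():
        per_item = []
        for item in item_range:
            accs = []
            for congruent in (True, False):
                sim = run_trials(seq, item, congruent, seeds, **trial_kw)
                accs.append(np.mean(sim.decisions() == (not congruent)))
            per_item.append(0.5 * (accs[0] + accs[1]))
        rows.append({
            "code": seq.code,
            "sequence": str(seq),
            "entropy": stimuli.sequence_entropy(seq),
            "accuracy": float(np.mean(per_item)),
        })
    table = pd.DataFrame(rows).sort_values("code").reset_index(drop=True)
    grouped = (table.groupby(table["entropy"].round(6))["accuracy"]
               .agg(["mean", "count"]).reset_index()
               .rename(columns={"entropy": "entropy_bits",
                                "mean": "accuracy", "count": "n_sequences"}))
    return table, grouped
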