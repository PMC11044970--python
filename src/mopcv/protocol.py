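"""Iterative CV refinement from trajectory-space sampling.

The loop alternates between three stages. Unbiased runs in the declared
initial and final basins seed a 2-state discriminant CV (stage 1). That CV
defines a trajectory-space end-to-end coordinate used to bias a path-polymer
run (stage 2). The sampled polymers are then classified by |S|: crumpled
(trapped) polymers reveal metastable basins — including ones absent from the
training data, found by density-based clustering — while elongated (reactive)
polymers supply transition-state configurations; both feed the training set
of a refined multi-state CV (stage 3). The loop terminates once a reactive
polymer connects the declared initial and final basins.

Target layout for retraining follows a fixed pattern: metastable states get
narrow latent targets (width 0.3), discovered intermediates medium ones
(1.0), transition-state data broad ones (4.0), all spaced Δ = 15 apart and
anchored so the final state sits at +15. Intermediates are ordered along the
path by Euclidean distance from the initial basin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import OPTICS

from .bias import BiasConfig
from .deeptda import (StateDataset, TDAModel, TDATargets, TrainingConfig,
                      train_cv)
from .dynamics import BrownianParams, run_simulation
from .mop import PathPolymer, PathSample, end_to_end_cv, relax_polymer, run_mop
from .potentials import PotentialSurface, ThermoParams


@dataclass
class ProtocolConfig:
    """Thresholds and knobs of the iterative refinement loop."""

    trapped_threshold: float = 0.3     # |S| at or below → trapped
    reactive_threshold: float = 1.0    # |S| at or above → reactive
    ts_multiplier: float = 3.0         # the m in [μ_lo + mσ_lo, μ_hi - mσ_hi]
    per_state_cap: int = 6000          # training samples per state
    min_cluster_samples: int = 50
    new_state_separation: float = 0.5  # length units, centroid-to-known distance
    basin_radius: float = 0.3          # endpoint membership radius
    early_fraction: float = 0.1        # leading fraction of a run to discard
    max_iterations: int = 5
    width_meta: float = 0.3
    width_intermediate: float = 1.0
    width_transition: float = 4.0
    center_spacing: float = 15.0

    def __post_init__(self) -> None:
        if not self.trapped_threshold < self.reactive_threshold:
            raise ValueError("trapped threshold must lie below reactive threshold")
        if self.ts_multiplier <= 0:
            raise ValueError("transition-window multiplier must be positive")


@dataclass
class ProtocolSystem:
    """Everything the loop needs to know about the physical system."""

    potential: PotentialSurface
    thermo: ThermoParams = field(default_factory=ThermoParams)
    physical: BrownianParams = field(default_factory=BrownianParams)
    initial_point: np.ndarray = None   # a configuration inside the initial basin
    final_point: np.ndarray = None
    # short chains explore and discover states quickly; the refined pass
    # uses longer chains so complete two-saddle trajectories fit into the
    # path duration N*dt
    n_beads: int = 96
    n_beads_refined: int = 288
    unbiased_steps: int = 30_000
    unbiased_stride: int = 5
    relax_steps: int = 10_000
    mop_steps: int = 400_000
    mop_steps_refined: int = 1_500_000
    mop_stride: int = 500
    dt_poly: float = 0.01
    damping_poly: float = 100.0
    # exploration bias for the first pass: the cap admits single-saddle
    # stretches but keeps the direct high-ridge crossing closed
    mop_bias: BiasConfig = field(default_factory=lambda: BiasConfig(
        barrier=17.0, pace=25, sigma=0.02, height=0.2, bias_factor=1e6))
    # refined-CV pass: higher ceiling so complete two-saddle spans can form
    mop_bias_refined: BiasConfig = field(default_factory=lambda: BiasConfig(
        barrier=19.5, pace=25, sigma=0.02, height=0.2, bias_factor=1e6))
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.initial_point = np.asarray(self.initial_point, dtype=float)
        self.final_point = np.asarray(self.final_point, dtype=float)


@dataclass
class KnownState:
    """A labelled training state with its data and its role along the path."""

    data: np.ndarray                 # (n, d) configurations
    kind: str                        # "meta" | "intermediate" | "transition"
    name: str


@dataclass
class IterationState:
    """Mutable state of the refinement loop."""

    cv: TDAModel
    states: list[KnownState]         # ordered along the path, initial → final
    iteration: int = 0
    terminated: bool = False
    history: list[dict] = field(default_factory=list)
    samples: list[PathSample] = field(default_factory=list)


def classify_paths(samples: Sequence[PathSample], config: ProtocolConfig,
                   total_steps: Optional[int] = None
                   ) -> tuple[list[PathSample], list[PathSample], list[PathSample]]:
    """Split samples into (trapped, reactive, discarded) by |S|.

    Samples captured during the leading ``early_fraction`` of the run — where
    bias deposition is most aggressive — are discarded regardless of S.
    """
    if total_steps is None:
        total_steps = max((s.step for s in samples), default=0)
    cutoff = config.early_fraction * total_steps
    trapped, reactive, discarded = [], [], []
    for s in samples:
        if s.step <= cutoff:
            discarded.append(s)
        elif abs(s.S) <= config.trapped_threshold:
            trapped.append(s)
        elif abs(s.S) >= config.reactive_threshold:
            reactive.append(s)
        else:
            discarded.append(s)
    return trapped, reactive, discarded


def discover_states(trapped: Sequence[PathSample],
                    known_states: Sequence[np.ndarray],
                    config: ProtocolConfig,
                    rng: Optional[np.random.Generator] = None,
                    max_pool: int = 20_000) -> list[np.ndarray]:
    """Find metastable states not represented in the known-state data.

    All beads of the trapped polymers are pooled and clustered with OPTICS;
    clusters whose centroid lies farther than ``new_state_separation`` from
    every known state's configurations are returned as new-state datasets.
    """
    if not trapped:
        raise ValueError("trapped set is empty")
    rng = np.random.default_rng(0) if rng is None else rng
    pool = np.concatenate([s.beads for s in trapped])
    if len(pool) > max_pool:
        pool = pool[rng.choice(len(pool), max_pool, replace=False)]
    min_samples = min(config.min_cluster_samples, max(5, len(pool) // 10))
    labels = OPTICS(min_samples=min_samples, xi=0.05).fit(pool).labels_
    new_states = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        members = pool[labels == lab]
        centroid = members.mean(axis=0)
        dists = [np.min(np.linalg.norm(ks - centroid, axis=1)) for ks in known_states]
        if all(d > config.new_state_separation for d in dists):
            new_states.append(members)
    if not new_states and labels.max(initial=-1) < 0:
        import warnings
        warnings.warn("no clusters found in trapped data", stacklevel=2)
    return new_states


class EmptyWindowError(ValueError):
    """The transition-state CV window is empty (bounds inverted)."""


def harvest_transition_data(reactive: Sequence[PathSample], cv_model: TDAModel,
                            state_moments: tuple[tuple[float, float],
                                                 tuple[float, float]],
                            config: ProtocolConfig) -> np.ndarray:
    """Beads of reactive paths whose CV lies between two flanking states.

    ``state_moments`` holds (mean, std) of the CV in the lower and upper
    flanking states; the closed selection window is
    [μ_lo + m σ_lo, μ_hi - m σ_hi] with m = ``ts_multiplier``.
    """
    (mu_lo, sig_lo), (mu_hi, sig_hi) = state_moments
    lo = mu_lo + config.ts_multiplier * sig_lo
    hi = mu_hi - config.ts_multiplier * sig_hi
    if lo > hi:
        raise EmptyWindowError(
            f"transition window [{lo:.3f}, {hi:.3f}] is empty; "
            "use a smaller ts_multiplier")
    if not reactive:
        return np.empty((0, cv_model.n_in))
    beads = np.concatenate([s.beads for s in reactive])
    s_vals = cv_model.evaluate(beads)
    return beads[(s_vals >= lo) & (s_vals <= hi)]


def _cap(data: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    if len(data) <= cap:
        return data
    return data[rng.choice(len(data), cap, replace=False)]


def build_targets(states: Sequence[KnownState], config: ProtocolConfig) -> TDATargets:
    """Latent target layout for an ordered state list.

    Two pure metastable states use the compact (-7, 7)/(0.2, 0.2) layout;
    larger layouts space centers by Δ anchored at +Δ for the final state,
    with widths set by each state's kind.
    """
    n = len(states)
    if n == 2 and all(s.kind == "meta" for s in states):
        return TDATargets.two_state()
    width_of = {"meta": config.width_meta,
                "intermediate": config.width_intermediate,
                "transition": config.width_transition}
    d = config.center_spacing
    centers = tuple(d * (i - (n - 2)) for i in range(n))
    widths = tuple(width_of[s.kind] for s in states)
    return TDATargets(centers, widths)


def _train_on_states(states: Sequence[KnownState], system: ProtocolSystem,
                     config: ProtocolConfig,
                     rng: np.random.Generator) -> TDAModel:
    caps = [_cap(s.data, config.per_state_cap, rng) for s in states]
    X = np.concatenate(caps)
    y = np.concatenate([np.full(len(c), k) for k, c in enumerate(caps)])
    targets = build_targets(states, config)
    tcfg = replace(system.training, seed=int(rng.integers(2**31)))
    return train_cv(StateDataset(X, y), targets, tcfg)


def _endpoint_in(point: np.ndarray, reps: np.ndarray, radius: float) -> bool:
    return bool(np.min(np.linalg.norm(reps - point, axis=1)) <= radius)


def _connects(sample: PathSample, initial_reps: np.ndarray, final_reps: np.ndarray,
              radius: float) -> bool:
    first, last = sample.beads[0], sample.beads[-1]
    fwd = (_endpoint_in(first, initial_reps, radius)
           and _endpoint_in(last, final_reps, radius))
    bwd = (_endpoint_in(last, initial_reps, radius)
           and _endpoint_in(first, final_reps, radius))
    return fwd or bwd


def _sample_basin(system: ProtocolSystem, point: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    traj = run_simulation(system.potential, point, system.physical,
                          system.thermo, system.unbiased_steps,
                          stride=system.unbiased_stride, rng=rng)
    return traj.positions[1:]    # drop the deterministic start


def initialize_protocol(system: ProtocolSystem,
                        config: ProtocolConfig = ProtocolConfig()
                        ) -> IterationState:
    """Stage 1: unbiased runs in the two declared basins + 2-state CV."""
    rng = np.random.default_rng(system.seed)
    data_a = _sample_basin(system, system.initial_point, rng)
    data_b = _sample_basin(system, system.final_point, rng)
    states = [KnownState(data_a, "meta", "initial"),
              KnownState(data_b, "meta", "final")]
    cv = _train_on_states(states, system, config, rng)
    return IterationState(cv=cv, states=states)


def iterate(state: IterationState, system: ProtocolSystem,
            config: ProtocolConfig = ProtocolConfig()) -> IterationState:
    """One refinement iteration: MoP run, classify, discover, retrain.

    Sets ``terminated`` when a reactive polymer connects the declared initial
    and final basins; trapped-only evidence never terminates the loop.
    """
    rng = np.random.default_rng((system.seed, state.iteration + 1))
    first = state.iteration == 0
    bias_cfg = system.mop_bias if first else system.mop_bias_refined
    n_beads = system.n_beads if first else system.n_beads_refined
    n_steps = system.mop_steps if first else system.mop_steps_refined
    samples = []
    # one polymer leg from each declared basin: a suboptimal CV often
    # resolves the escape direction from only one of them
    for start in (system.initial_point, system.final_point):
        beads0 = np.tile(start, (n_beads, 1))
        polymer = relax_polymer(beads0, system.potential,
                                n_steps=system.relax_steps,
                                physical=system.physical,
                                thermo=system.thermo,
                                dt_poly=system.dt_poly,
                                damping_poly=system.damping_poly, rng=rng)
        leg, _ = run_mop(polymer, system.potential, state.cv, bias_cfg,
                         n_steps=n_steps, stride=system.mop_stride,
                         rng=rng)
        samples.extend(leg)
    trapped, reactive, discarded = classify_paths(samples, config,
                                                  total_steps=n_steps)
    if not trapped and not reactive:
        raise RuntimeError("no trapped and no reactive paths sampled; "
                           "run MoP longer or raise the bias barrier")
    initial_reps = state.states[0].data
    final_reps = state.states[-1].data
    connecting = [s for s in reactive
                  if _connects(s, initial_reps, final_reps, config.basin_radius)]
    record = {"iteration": state.iteration + 1, "n_samples": len(samples),
              "n_trapped": len(trapped), "n_reactive": len(reactive),
              "n_connecting": len(connecting)}
    if connecting:
        state.history.append({**record, "event": "terminated"})
        return IterationState(cv=state.cv, states=state.states,
                              iteration=state.iteration + 1, terminated=True,
                              history=state.history, samples=samples)

    known_data = [s.data for s in state.states]
    new_state_data = discover_states(trapped, known_data, config, rng) if trapped else []
    record["n_new_states"] = len(new_state_data)

    meta_states = [s for s in state.states if s.kind != "transition"]
    initial_state, final_state = meta_states[0], meta_states[-1]
    intermediates = list(meta_states[1:-1])
    origin = initial_state.data.mean(axis=0)
    for i, data in enumerate(new_state_data):
        intermediates.append(KnownState(data, "intermediate",
                                        f"discovered_{state.iteration + 1}_{i}"))
    intermediates.sort(key=lambda s: np.linalg.norm(s.data.mean(axis=0) - origin))
    ordered = [initial_state, *intermediates, final_state]

    # intermediate retraining on metastable states only, to re-score S and
    # place the transition-state window confidently
    cv_meta = _train_on_states(ordered, system, config, rng)

    def rescore(s: PathSample) -> PathSample:
        poly = PathPolymer(s.beads, physical=system.physical, thermo=system.thermo)
        S, _, _ = end_to_end_cv(poly, cv_meta)
        return PathSample(beads=s.beads, v_eff=s.v_eff, S=S, step=s.step)

    rescored = [rescore(s) for s in samples]
    _, reactive2, _ = classify_paths(rescored, config,
                                     total_steps=n_steps)
    states_final = ordered
    if reactive2:
        # transition window between the initial state and its neighbour
        mom_lo = cv_meta.state_moments[0]
        mom_hi = cv_meta.state_moments[1]
        ts_data = harvest_transition_data(reactive2, cv_meta, (mom_lo, mom_hi),
                                          config)
        record["n_transition"] = len(ts_data)
        if len(ts_data) >= 4:
            ts_state = KnownState(ts_data, "transition",
                                  f"ts_{state.iteration + 1}")
            states_final = [ordered[0], ts_state, *ordered[1:]]
    cv_new = (_train_on_states(states_final, system, config, rng)
              if states_final is not ordered else cv_meta)
    state.history.append({**record, "event": "retrained",
                          "n_states": len(states_final)})
    return IterationState(cv=cv_new, states=states_final,
                          iteration=state.iteration + 1, terminated=False,
                          history=state.history, samples=samples)


def run_protocol(system: ProtocolSystem,
                 config: ProtocolConfig = ProtocolConfig()) -> IterationState:
    """Run the full loop until termination or ``max_iterations``."""
    state = initialize_protocol(system, config)
    for _ in range(config.max_iterations):
        state = iterate(state, system, config)
        if state.terminated:
            break
    return state
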