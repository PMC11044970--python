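"""Path classification, state discovery, harvesting, and the loop itself."""

import numpy as np
import pytest

from mopcv.bias import BiasConfig
from mopcv.deeptda import TDATargets
from mopcv.mop import PathSample
from mopcv.potentials import DoubleWellIn2D
from mopcv.protocol import (EmptyWindowError, KnownState, ProtocolConfig,
                            ProtocolSystem, build_targets, classify_paths,
                            discover_states, harvest_transition_data,
                            run_protocol)


def _sample(S, step=100_000, beads=None):
    b = np.zeros((4, 2)) if beads is None else beads
    return PathSample(beads=b, v_eff=0.0, S=S, step=step)


class TestClassification:
    def test_small_end_to_end_values_are_trapped(self):
        samples = [_sample(s) for s in (0.1, 0.05, -0.2)]
        trapped, reactive, discarded = classify_paths(samples, ProtocolConfig())
        assert len(trapped) == 3 and not reactive and not discarded

    def test_reactive_is_sign_independent(self):
        samples = [_sample(1.5), _sample(-1.3)]
        trapped, reactive, _ = classify_paths(samples, ProtocolConfig())
        assert len(reactive) == 2 and not trapped

    def test_gap_between_thresholds_is_discarded(self):
        _, _, discarded = classify_paths([_sample(0.65)], ProtocolConfig())
        assert len(discarded) == 1

    def test_early_fraction_discarded_regardless_of_s(self):
        early = _sample(1.8, step=5_000)
        _, reactive, discarded = classify_paths([early], ProtocolConfig(),
                                                total_steps=100_000)
        assert not reactive and len(discarded) == 1

    def test_trapped_only_evidence_cannot_terminate(self):
        # a polymer whose endpoints happen to sit in both declared basins but
        # whose end-to-end CV is small is classified trapped, and the loop's
        # termination draws exclusively from the reactive set
        beads = np.array([[-0.52, 1.47], [0.0, 1.0], [0.99, 1.18]])
        trapped, reactive, _ = classify_paths([_sample(0.05, beads=beads)],
                                              ProtocolConfig())
        assert trapped and not reactive

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ProtocolConfig(trapped_threshold=1.2, reactive_threshold=1.0)


class TestDiscovery:
    def test_planted_blob_recovered(self, rng):
        known = rng.normal([0.0, 0.0], 0.05, (400, 2))
        planted_center = np.array([1.2, 0.8])
        planted = rng.normal(planted_center, 0.05, (400, 2))
        beads = np.concatenate([known, planted])
        rng2 = np.random.default_rng(0)
        samples = [PathSample(beads=beads[i::4], v_eff=0.0, S=0.0,
                              step=100_000) for i in range(4)]
        new = discover_states(samples, [known], ProtocolConfig(), rng2)
        assert len(new) == 1
        assert np.linalg.norm(new[0].mean(axis=0) - planted_center) < 0.05

    def test_known_basins_yield_no_new_states(self, rng):
        known = rng.normal([0.0, 0.0], 0.05, (600, 2))
        samples = [PathSample(beads=known[i::3], v_eff=0.0, S=0.0,
                              step=100_000) for i in range(3)]
        new = discover_states(samples, [known], ProtocolConfig(),
                              np.random.default_rng(0))
        assert new == []

    def test_empty_trapped_set_rejected(self):
        with pytest.raises(ValueError):
            discover_states([], [], ProtocolConfig())


class TestHarvest:
    def _reactive(self, svals, cv):
        # beads placed so the cv maps them onto prescribed values
        beads = np.stack([svals, np.zeros_like(svals)], axis=-1)
        return [PathSample(beads=beads, v_eff=0.0, S=2.0, step=100_000)]

    def test_window_arithmetic(self):
        class LineCV:
            n_in = 2

            def evaluate(self, X):
                return np.atleast_2d(X)[:, 0]

        svals = np.linspace(-8.0, 1.0, 19)   # spaced 0.5 apart
        samples = self._reactive(svals, None)
        # moments (-7, 0.2) and (0, 1.0) with m = 3: window [-6.4, -3.0]
        out = harvest_transition_data(samples, LineCV(),
                                      ((-7.0, 0.2), (0.0, 1.0)),
                                      ProtocolConfig())
        got = np.sort(out[:, 0])
        expected = svals[(svals >= -6.4) & (svals <= -3.0)]
        assert np.allclose(got, expected)

    def test_inverted_window_raises(self):
        class LineCV:
            n_in = 2

            def evaluate(self, X):
                return np.atleast_2d(X)[:, 0]

        with pytest.raises(EmptyWindowError):
            harvest_transition_data(self._reactive(np.zeros(3), None),
                                    LineCV(), ((-1.0, 2.0), (1.0, 2.0)),
                                    ProtocolConfig())


class TestTargetLayout:
    def _state(self, kind):
        return KnownState(data=np.zeros((10, 2)), kind=kind, name=kind)

    def test_two_metastable_states_use_compact_layout(self):
        t = build_targets([self._state("meta"), self._state("meta")],
                          ProtocolConfig())
        assert t == TDATargets.two_state()

    def test_three_state_layout(self):
        t = build_targets([self._state("meta"), self._state("intermediate"),
                           self._state("meta")], ProtocolConfig())
        assert t.centers == (-15.0, 0.0, 15.0)
        assert t.widths == (0.3, 1.0, 0.3)

    def test_four_state_layout_inserts_transition(self):
        states = [self._state("meta"), self._state("transition"),
                  self._state("intermediate"), self._state("meta")]
        t = build_targets(states, ProtocolConfig())
        assert t.centers == (-30.0, -15.0, 0.0, 15.0)
        assert t.widths == (0.3, 4.0, 1.0, 0.3)

    def test_extension_preserves_relative_order(self):
        # adding states keeps earlier states' centers strictly increasing
        base = [self._state("meta"), self._state("meta")]
        ext = [self._state("meta"), self._state("intermediate"),
               self._state("meta")]
        tb = build_targets(base, ProtocolConfig())
        te = build_targets(ext, ProtocolConfig())
        assert tb.centers[0] < tb.centers[-1]
        assert te.centers[0] < te.centers[1] < te.centers[-1]


def test_two_state_system_terminates_in_one_iteration():
    """A double well has no hidden intermediate: the first trajectory-space
    run already samples complete reactive paths between the two basins."""
    pot = DoubleWellIn2D(barrier=1.0, half_width=0.7, k_transverse=4.0)
    bias = BiasConfig(barrier=9.0, pace=25, sigma=0.02, height=0.2,
                      bias_factor=1e6)
    system = ProtocolSystem(
        potential=pot,
        initial_point=np.array([-0.7, 0.0]),
        final_point=np.array([0.7, 0.0]),
        n_beads=96, n_beads_refined=96,
        unbiased_steps=15_000, relax_steps=5_000,
        mop_steps=150_000, mop_steps_refined=150_000, mop_stride=250,
        mop_bias=bias, mop_bias_refined=bias,
        seed=3,
    )
    state = run_protocol(system, ProtocolConfig())
    assert state.terminated
    assert state.iteration == 1
    assert state.history[-1]["n_connecting"] > 0
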