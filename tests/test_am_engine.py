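"""AM engine: config contracts, loop identities, determinism, ascent."""

import numpy as np
import pytest

from hallucinet.am_engine import (
    AMConfig,
    NetworkBundle,
    classical_am,
    config_from_preset,
    generative_am,
    invert_latent,
    run_simulation,
)
from hallucinet.metrics import input_dependence
from hallucinet.presets import make_preset


class TestAMConfig:
    def test_snapshot_beyond_iterations_rejected(self):
        with pytest.raises(ValueError, match="exceeds iterations"):
            AMConfig(iterations=100, snapshot_iters=(10, 2000))

    def test_fixed_requires_target(self):
        with pytest.raises(ValueError, match="target_index"):
            AMConfig(error_function="fixed", target_index=None)

    @pytest.mark.parametrize("kwargs", [
        {"am_type": "hybrid"}, {"error_function": "maximal"},
        {"step_size": -1.0}, {"iterations": -5}, {"inversion_steps": -1},
    ])
    def test_invalid_fields(self, kwargs):
        with pytest.raises(ValueError):
            AMConfig(**kwargs)

    def test_default_schedule_matches_run_length(self):
        cfg = AMConfig()
        assert cfg.iterations == 1000
        assert cfg.snapshot_iters == (10, 50, 100, 1000)

    def test_step_defaults_per_am_type(self):
        assert AMConfig(am_type="classical", error_function="deep_dream"
                        ).resolved_step != 0
        assert AMConfig(am_type="generative").resolved_step != 0


class TestClassicalAM:
    def test_zero_iterations_is_identity(self, classifier, input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="classical", error_function="deep_dream",
                       iterations=0, snapshot_iters=())
        traj = classical_am(classifier, images[0], cfg)
        assert len(traj.snapshots) == 1
        assert traj.snapshots[0][0] == 0
        assert np.array_equal(traj.final_image, images[0])

    def test_objective_ascends(self, classifier, input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="classical", error_function="deep_dream",
                       terminal_layer="fc_top", iterations=300,
                       snapshot_iters=(), step_size=0.02)
        traj = classical_am(classifier, images[0], cfg)
        assert len(traj.objective_series) == 300
        assert traj.objective_series[-1] > traj.objective_series[0]

    def test_converts_class_to_fixed_target(self, classifier, input_pool):
        images, labels = input_pool
        target = int((labels[0] + 3) % 8)
        cfg = AMConfig(am_type="classical", error_function="fixed",
                       target_index=target, iterations=500, snapshot_iters=())
        traj = classical_am(classifier, images[0], cfg)
        assert int(classifier.predict(traj.final_image[None])[0]) == target

    def test_bitwise_deterministic(self, classifier, input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="classical", error_function="deep_dream",
                       iterations=50, snapshot_iters=(10, 50), seed=3)
        a = classical_am(classifier, images[1], cfg)
        b = classical_am(classifier, images[1], cfg)
        assert np.array_equal(a.final_image, b.final_image)
        assert np.array_equal(a.objective_series, b.objective_series)
        for (ia, sa), (ib, sb) in zip(a.snapshots, b.snapshots):
            assert ia == ib and np.array_equal(sa, sb)

    def test_snapshot_schedule_recorded(self, classifier, input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="classical", error_function="deep_dream",
                       iterations=100, snapshot_iters=(10, 50, 100))
        traj = classical_am(classifier, images[0], cfg)
        assert [it for it, _ in traj.snapshots] == [0, 10, 50, 100]

    def test_outputs_stay_in_canonical_range(self, classifier, input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="classical", error_function="fixed",
                       target_index=2, iterations=100, snapshot_iters=())
        final = classical_am(classifier, images[0], cfg).final_image
        assert final.min() >= 0.0 and final.max() <= 1.0


class TestInvertLatent:
    def test_fixed_point_of_decoded_code(self, generator):
        rng = np.random.default_rng(1)
        z0 = generator.clamp(rng.uniform(-0.2, 0.2, generator.latent_dim))
        target = generator.decode(z0)
        z = invert_latent(generator, target, inversion_steps=0)
        # warm start comes from the paired encoder; refining must not leave
        # the already-minimal reconstruction
        loss0 = float(np.mean((generator.decode(z) - target) ** 2))
        z_ref = invert_latent(generator, target, inversion_steps=50)
        loss1 = float(np.mean((generator.decode(z_ref) - target) ** 2))
        assert loss1 <= loss0 + 1e-6

    def test_descent_never_worse_than_warm_start(self, generator, input_pool):
        images, _ = input_pool
        z_warm = invert_latent(generator, images[0], inversion_steps=0)
        z_opt = invert_latent(generator, images[0], inversion_steps=100)
        loss_warm = float(np.mean((generator.decode(z_warm) - images[0]) ** 2))
        loss_opt = float(np.mean((generator.decode(z_opt) - images[0]) ** 2))
        assert loss_opt <= loss_warm

    def test_inversion_beats_random_codes(self, generator, input_pool):
        images, _ = input_pool
        rng = np.random.default_rng(0)
        z = invert_latent(generator, images[2], inversion_steps=50)
        rms_inv = float(np.sqrt(np.mean((generator.decode(z) - images[2]) ** 2)))
        rand_rms = []
        for _ in range(10):
            zr = rng.uniform(generator.latent_lower, generator.latent_upper)
            rand_rms.append(float(np.sqrt(np.mean(
                (generator.decode(zr) - images[2]) ** 2))))
        assert rms_inv < np.mean(rand_rms)


class TestGenerativeAM:
    def test_zero_iterations_returns_reconstruction(self, classifier, generator,
                                                    input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="generative", error_function="winner_take_all",
                       iterations=0, snapshot_iters=())
        traj = generative_am(classifier, generator, images[0], cfg)
        z = invert_latent(generator, images[0], inversion_steps=0)
        expected = generator.decode(generator.clamp(z))
        assert np.allclose(traj.final_image, expected)

    def test_converts_class_to_fixed_target(self, classifier, generator,
                                            input_pool):
        images, labels = input_pool
        target = int((labels[3] + 3) % 8)
        cfg = AMConfig(am_type="generative", error_function="fixed",
                       target_index=target, iterations=500, snapshot_iters=())
        traj = generative_am(classifier, generator, images[3], cfg)
        assert int(classifier.predict(traj.final_image[None])[0]) == target

    def test_benchmark_preserves_confident_class(self, classifier, generator,
                                                 input_pool):
        images, _ = input_pool
        pred_in = int(classifier.predict(images[4][None])[0])
        cfg = AMConfig(am_type="generative", error_function="winner_take_all",
                       iterations=500, snapshot_iters=())
        traj = generative_am(classifier, generator, images[4], cfg)
        assert int(classifier.predict(traj.final_image[None])[0]) == pred_in

    def test_final_latent_recorded_and_clamped(self, classifier, generator,
                                               input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="generative", error_function="winner_take_all",
                       iterations=50, snapshot_iters=())
        traj = generative_am(classifier, generator, images[0], cfg)
        assert traj.final_latent is not None
        assert (traj.final_latent >= generator.latent_lower - 1e-6).all()
        assert (traj.final_latent <= generator.latent_upper + 1e-6).all()

    def test_bitwise_deterministic(self, classifier, generator, input_pool):
        images, _ = input_pool
        cfg = AMConfig(am_type="generative", error_function="winner_take_all",
                       iterations=50, snapshot_iters=(50,))
        a = generative_am(classifier, generator, images[5], cfg)
        b = generative_am(classifier, generator, images[5], cfg)
        assert np.array_equal(a.final_image, b.final_image)
        assert np.array_equal(a.final_latent, b.final_latent)


class TestSpontaneityAndSaturation:
    def test_deep_dream_keeps_more_input_structure(self, classifier, input_pool):
        """Input-seeded (deep-dream) runs must correlate with the input more
        than spontaneous (fixed-target) runs at equal iterations and layer."""
        images, labels = input_pool
        n = 8
        corr_dd, corr_fx = [], []
        for i in range(n):
            dd = classical_am(classifier, images[i], AMConfig(
                am_type="classical", error_function="deep_dream",
                iterations=300, snapshot_iters=())).final_image
            fx = classical_am(classifier, images[i], AMConfig(
                am_type="classical", error_function="fixed",
                target_index=int((labels[i] + 3) % 8),
                iterations=300, snapshot_iters=())).final_image
            corr_dd.append(input_dependence(images[i], dd))
            corr_fx.append(input_dependence(images[i], fx))
        assert np.mean(corr_dd) > np.mean(corr_fx)

    def test_generative_updates_saturate(self, classifier, generator, input_pool):
        images, labels = input_pool
        cfg = AMConfig(am_type="generative", error_function="fixed",
                       target_index=int((labels[0] + 3) % 8),
                       iterations=1000, snapshot_iters=(200, 800, 1000))
        traj = generative_am(classifier, generator, images[0], cfg)
        early = np.abs(traj.snapshot_at(200) - traj.snapshots[0][1]).mean()
        late = np.abs(traj.snapshot_at(1000) - traj.snapshot_at(800)).mean()
        assert late < early


class TestRunSimulation:
    def test_benchmark_dispatches_generative_wta(self, classifier, generator,
                                                 input_pool):
        images, _ = input_pool
        traj = run_simulation("benchmark", images[0],
                              NetworkBundle(classifier, generator),
                              seed=1, iterations=20, snapshot_iters=(10,))
        assert traj.config.am_type == "generative"
        assert traj.config.error_function == "winner_take_all"
        assert traj.config.terminal_layer == "fc_top"

    def test_psychedelic_complex_dispatches_classical_deep_dream(
            self, classifier, generator, input_pool):
        images, _ = input_pool
        traj = run_simulation("psychedelic_complex", images[0],
                              NetworkBundle(classifier, generator),
                              seed=1, iterations=20, snapshot_iters=())
        assert traj.config.am_type == "classical"
        assert traj.config.error_function == "deep_dream"
        assert traj.config.terminal_layer == "fc_top"

    def test_cbs_simple_applies_blur_and_lower_layer(self, classifier, generator,
                                                     input_pool):
        images, _ = input_pool
        traj = run_simulation("cbs_simple", images[0],
                              NetworkBundle(classifier, generator),
                              seed=1, iterations=20, snapshot_iters=())
        assert traj.config.am_type == "generative"
        assert traj.config.error_function == "fixed"
        assert traj.config.terminal_layer == "conv2"
        degraded = traj.snapshots[0][1]
        assert not np.array_equal(degraded, images[0])        # centre blurred
        assert np.array_equal(degraded[0, 0], images[0][0, 0])  # corner intact

    def test_fixed_target_drawn_from_preset_list(self):
        preset = make_preset("neurodegenerative_complex")
        cfg = config_from_preset(preset, seed=5, iterations=10,
                                 snapshot_iters=())
        assert cfg.target_index in preset.fixed_targets

    def test_unknown_preset(self, classifier, generator, input_pool):
        images, _ = input_pool
        with pytest.raises(ValueError, match="unknown preset"):
            run_simulation("nonexistent", images[0],
                           NetworkBundle(classifier, generator))

    def test_generative_without_generator_rejected(self, classifier, input_pool):
        images, _ = input_pool
        with pytest.raises(ValueError, match="generator"):
            run_simulation("benchmark", images[0], NetworkBundle(classifier, None))
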