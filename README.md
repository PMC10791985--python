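# hallucinet

Synthetic visual hallucinations from coupled classifier/generator networks
via activation maximisation.

Visual hallucinations differ systematically between aetiologies:
hallucinations in neurodegenerative conditions (Parkinson's disease, Lewy
body dementia) are typically realistic, spontaneous and complex; those in
Charles Bonnet syndrome (visual loss) are realistic and spontaneous but
often simple; psychedelic visuals are typically dream-like distortions
seeded by the visual scene, simple or complex. `hallucinet` models these
three phenomenological dimensions — **veridicality**, **spontaneity**,
**complexity** — as three orthogonal manipulations of an
activation-maximisation (AM) loop over a trained image classifier:

| dimension    | manipulation                                                     |
|--------------|------------------------------------------------------------------|
| veridicality | optimise pixels directly (ClassicalAM) vs. a generator's latent code (GenerativeAM) |
| spontaneity  | error function: Fixed (input-independent) / Deep-Dream (input-seeded) / Winner-Take-All (benchmark) |
| complexity   | terminal layer: top categorical layer vs. lower convolutional layer |

One AM iteration forwards the image to the terminal layer, converts the
activations `a` into an error signal `e` (one-hot for Fixed/WTA, `e = a`
for Deep-Dream, i.e. objectives `a_j` and `½‖a‖²`), backpropagates, and
ascends with a normalised step `v ← v + η·g/mean|g|`. Six presets
(benchmark, neurodegenerative_complex, cbs_complex, cbs_simple,
psychedelic_complex, psychedelic_simple) bind the axes to aetiologies; the
CBS presets additionally degrade the input with a central blur. Realism is
quantified with the Inception Score,
`IS = exp(mean_n KL(p(y|x_n) ‖ p̄(y)))`, computed from an independently
trained classifier.

Everything runs at desk scale on a self-contained fixture subsystem: a
procedural 8-category shape dataset, a small CNN classifier and a trained
latent-code image generator, all deterministic from integer seeds. An
adapter contract (any object with the `ClassifierNetwork` /
`GeneratorNetwork` methods) accepts externally supplied full-scale
networks. See `docs/methods.md` for the model, parameters and limitations.

## Worked example

```python
import numpy as np
from hallucinet import (FixtureSpec, generate_dataset, run_simulation,
                        NetworkBundle, score_image_set,
                        train_fixture_classifier, train_fixture_generator)

data = generate_dataset(FixtureSpec(samples_per_class=200, seed=42))
clf = train_fixture_classifier(data, seed=42)     # ~1 min, held-out acc ≈ 0.97
gen = train_fixture_generator(data, seed=42)      # ~2 min, recon RMS ≈ 0.063
nets = NetworkBundle(clf, gen)

bird_like = generate_dataset(FixtureSpec(samples_per_class=1, seed=7)).images[1]
traj = run_simulation("neurodegenerative_complex", bird_like, nets, seed=1)

print("input class:", clf.predict(bird_like[None])[0])
print("output class:", clf.predict(traj.final_image[None])[0])
print("objective first->last: %.3f -> %.3f"
      % (traj.objective_series[0], traj.objective_series[-1]))
```

prints

```
input class: 1
output class: 7
objective first->last: -3.653 -> 106.943
```

The input was confidently seen as category 1 (square); the Fixed error
function's pre-chosen target (category 7, ring, drawn from the preset's
target list by the seed) took over the percept regardless —
the defining signature of a spontaneous hallucination — while the
generator kept the output on its learned image manifold. The trajectory
holds snapshots after iterations 0, 10, 50, 100 and 1 000 plus the
per-iteration objective.

The same machinery is scriptable from the shell:

```bash
hallucinet demo --seed 1 --out demo_out/        # all six presets + scores
hallucinet simulate --preset cbs_simple --input eye.png --out run/
hallucinet score --images run/ --weights fixture:default
```

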