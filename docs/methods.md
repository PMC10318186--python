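# Methods

`gaitbalance` assesses walking-balance impairment from 3D skeleton
sequences.  It has four scientific components: a synthetic gait simulator
that emulates a three-level balance-impairment study, an input-normalization
pipeline, a residual 1D convolutional classifier evaluated with
leave-one-subject-out cross-validation, and a layer-wise relevance
propagation (LRP) explainer.  This note records the models, the parameters
that matter, and the design decisions taken where the design was open.

## Skeleton model

Frames hold 3D positions (meters) of the 32-joint Kinect body-tracking
hierarchy (pelvis = 0 through ear = 31).  Analyses run on a simplified
21-joint skeleton that drops the hands, hand tips, thumbs and face joints,
whose positions track their parent joints and carry little balance
information.  Axis convention everywhere: x = walking direction,
y = left-right, z = up-down.

Thirteen named joint groups (`A0` … `G2`) define the inputs of the ablation
study; each is derived from the 21-joint control set `A0` by removing the
joints its description names, and the derived lists are asserted at import
time against the published index tables.

## Synthetic gait simulator

The study the package emulates is not deposited, so the simulator is a
first-class component, not a fixture.  It generates 10 subjects x 10 trials
x 3 levels = 300 walks over a 4 m walkway, sampled at an effective 8 Hz.
The balance levels correspond to: free walking (level 0), limb weights plus
restricted knee/elbow flexibility (level 1), and additionally hunched
posture and restricted vision (level 2).

Each walk is a deterministic forward-kinematic model: the pelvis advances at
walking speed v with lateral sway (frequency f) and vertical bounce (2f);
rigid thigh/shank segments follow phase-locked sinusoidal hip-swing and
knee-flexion angles with a π left-right offset; the trunk chain is pitched
forward by the trunk-flexion angle; arms swing anti-phase to the ipsilateral
leg; hands and face joints ride rigidly on their parents.  Independent
zero-mean Gaussian noise (default sd 8 mm, the order of Kinect's joint
position error) is added to every coordinate.  The frame count is
`round(walkway / v * rate)` clipped to the observed 22–38 envelope, so frame
count itself is (realistically) informative about speed.

Per-level parameter means (trial-level sd in parentheses):

| parameter | level 0 | level 1 | level 2 | sd |
|---|---|---|---|---|
| speed (m/s) | 1.30 | 1.05 | 0.85 | 0.05 |
| leg-swing frequency (Hz) | 1.8 | 1.6 | 1.4 | 0.06 |
| foot clearance (m) | 0.050 | 0.030 | 0.020 | 0.004 |
| trunk flexion (deg) | 5 | 8 | 25 | 2 |
| lateral sway (m) | 0.020 | 0.030 | 0.040 | 0.005 |
| arm swing (m) | 0.12 | 0.10 | 0.08 | 0.01 |

Speeds and cadences were chosen so that transit times at 8 Hz map onto the
observed 22–38-frame range; trunk flexion jumps at level 2 (the hunchback
condition) while levels 0/1 overlap; clearance and sway shift moderately.
Each subject additionally carries idiosyncratic offsets drawn once (speed sd
0.06 m/s, cadence sd 0.06 Hz, arm swing sd 0.04 m) plus anthropometric
variation.  Arm-swing identity variance is deliberately set at twice its
per-level step so that arm joints act mainly as subject-specific
distractors — the mechanism behind the finding that removing arm joints
helps a subject-generalizing classifier.  Random streams are split per
(subject, level, trial) from one root seed, so generation is
order-independent and fully reproducible.

What the simulator does **not** model: ground-reaction dynamics, foot-ground
contact constraints, tracking dropouts/occlusions, asymmetric pathologies,
or any validated biomechanics.  Passing tests therefore demonstrate that the
pipeline recovers the statistical structure this generator encodes — speed,
cadence, clearance, posture — not clinical validity on real patients.

## Preprocessing

In order: (1) simplify to 21 joints; (2) keep the **last** 20 frames
(subjects may stand still just after the start command, so the tail of the
recording is reliably walking); (3) subtract the pelvis position of the
first retained frame from every coordinate, anchoring the analyzed window at
the origin and making the pipeline exactly translation invariant; (4) select
the joint group.  Centering precedes selection, so groups without the pelvis
(legs-only `G2`) are still pelvis-anchored.  "First frame" means the first
*retained* frame: the stated purpose of centering is to remove the spatial
offset of the analyzed window, and discarded leading frames may be pre-walk
standing (the alternative — first recorded frame — only shifts every tensor
by a constant).  The default `A0` input is 20 x 21 x 3 = 1,260 scalars.

## Classifier

Input is arranged as a 20-step time series with 3·J channels (joint-major,
axis-minor).  The network is `n_blocks` residual blocks → dropout → global
average pooling over time → dense layer → 3 class scores.  Each block:
conv(k1) → BN → ReLU → conv(k2) → BN → ReLU → conv(k3) → BN → ReLU, with the
block input added to the branch output; a bias-free 1-wide convolution
projects the skip path when channel counts differ.  Defaults: kernels
(5, 3, 1), 64 channels, 3 blocks, cross-entropy loss, Adam at lr 1e-4,
early stopping on validation loss with best-epoch restoration.

Decisions the published setup leaves open, fixed here: merge by addition
(the standard residual reading) after the third ReLU, no extra activation
after the merge; dropout rate 0.5; average pooling; batch size 16; early
stopping patience 20 epochs with max 300.  Ties in the argmax go to the
smaller class index.  All initialization and shuffling derive from the model
seed, and the stack is plain NumPy with explicit forward/backward passes, so
two runs with the same seed produce bit-identical parameters.  The engine is
implemented in-package (conv/BN/ReLU/dropout/pooling/dense plus
SGD/RMSprop/Adam) because the explainer needs exact access to every affine
operation — batch-norm folding and the residual merge are handled
analytically rather than through a framework's autograd graph.

## Evaluation protocol

Leave-one-subject-out: one fold per subject; the held-out subject is tested
by a model that never saw them; the validation subject (early stopping) is
the cyclic successor of the test subject ("another one subject" is all the
protocol fixes; a random-per-fold policy is available).  With 10 subjects
the folds are 240/30/30 train/validation/test samples.  Test predictions
from all folds are **pooled** into one complete set before metrics are
computed — every sample is tested exactly once and per-fold metrics are not
averaged.  Metrics: pooled accuracy; one-vs-rest per-class precision,
recall, F1; macro (unweighted) averages across the three levels.  A class
never predicted contributes precision 0 with a warning.

The ablation runs the full LOSO protocol per joint group with identical
seeds and reports accuracy improvement over `A0`.  Hyperparameter sweeps
(kernel triples {1,3,5,7}³, channels {4,8,16,32,64}, 1–4 blocks,
SGD/RMSprop/Adam) train on a single fixed fold by default so the 64-point
kernel grid stays tractable; full LOSO per grid point is a flag.

## Layer-wise relevance propagation

The predicted (or a chosen) class's pre-softmax score is redistributed
backwards: neuron j passes relevance to input i in proportion to its forward
contribution z_ij = a_i·w_ij, with denominator z_j = Σ_i z_ij.  The bias is
not part of the denominator, which makes the redistribution *exactly*
conserving at every layer regardless of biases.  Batch norm is folded into
the adjacent convolution (exact at inference), ReLU and dropout pass
relevance through, global average pooling is an affine layer with equal
weights, and the residual merge splits relevance between branch and skip in
proportion to their contribution to the sum.

Stabilization was the one genuinely open numerical design point, and
measurement drove the choice.  An absolute stabilizer
(z_j + ε·sign(z_j), any ε > 0) destroys conservation in this architecture:
the merge split can hand the branch and skip paths relevance totals orders
of magnitude above the explained score with opposite signs, and because the
two paths traverse different numbers of redistribution steps, the per-step
ε-shrinkage no longer cancels between them (observed gaps of 5–75x the
score).  The default is therefore **ε = 0 with an exact-zero-denominator
guard**: float64 handles small denominators, and the observed conservation
gap on trained default models is ~1e-7 (documented tolerance 1e-2).  A
positive ε applies a relative stabilizer (denominator z_j·(1+ε)) for
experimentation.  The full-network pass also rescales relevance after each
step to the total the rule prescribes in exact arithmetic — a
floating-point drift correction that is the identity map in exact
arithmetic; the standalone rule functions are uncompensated and are what
the oracle tests (exact conservation on toys; gradient x input equality on
bias-free affine networks) exercise.

Contribution matrices aggregate mean absolute relevance per (axis, joint,
frame) over a set of samples, arranged as X/Y/Z axis blocks x joints x 20
frames; a signed-mean export exists as well.  Relevance magnitudes of
individual cells can be large where denominators are small; the aggregated
matrices are interpreted relatively (which cells dominate), not absolutely.

## Problem sizes used by the test suite

The suite reproduces the structural facts on the full default layout
(300 sequences) and runs complete LOSO evaluations at the default
configuration both for the learning property (majority over 3 seeds,
stopping early once the majority is decided) and for the three-way
ablation-direction check (A0 vs G1 vs G2 with a shared seed).  Reduced
cohorts (4–5 subjects, narrow networks) are used only where the property
under test is structural rather than statistical: with 150 pooled
predictions the ablation ordering is decided by two or three samples, so
direction checks need the full-size experiment.  The generator's level
parameters are never varied between tests.

## Known limitations

* The simulator targets statistical structure, not biofidelity; absolute
  accuracies on synthetic data say nothing about accuracy on real cohorts.
* LRP attributions are exactly conserving but can concentrate large
  opposite-signed relevance in cells where forward contributions nearly
  cancel; interpret aggregated matrices relatively.
* The NumPy training engine is single-threaded and CPU-bound; it is sized
  for 20-frame, tens-of-channels inputs, not for large-scale deep learning.
* Early stopping restores the best-validation-loss epoch; with very small
  validation sets (one subject, 30 samples) the stopping point is noisy,
  which is inherent to the protocol, not the implementation.
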