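# Methods

## Membrane model

A capsule of unstressed radius `a0`, osmotically pre-inflated by
`α = a/a0 − 1`, flows along a tube of radius `R` at confinement
`β = a/R`. Its infinitely thin membrane follows one of three classical 2D
constitutive laws, written in the shifted surface strain invariants
`I1 = λ1² + λ2² − 2`, `I2 = (λ1 λ2)² − 1` (rest state at the origin):

* neo-Hookean: `W = (Gs/2) (I1 − 1 + 1/(I2 + 1))`, strain-softening,
  `Ks = 3 Gs`;
* Skalak: `W = (Gs/4)(I1² + 2I1 − 2I2) + (C Gs/4) I2²`, strain-hardening,
  `Ks = (1 + 2C) Gs`;
* 2D Hooke: `W = (Gs/4)(2I1 − 2I2 + I1²/(1 − νs))`, linear,
  `Ks = (1 + νs)/(1 − νs) Gs`.

Under this convention all three energies vanish at rest. The NH
incompressibility term is sometimes printed with denominator `I2 − 1`,
which is singular at the rest state in the shifted convention; `capmech`
uses `I2 + 1` (the standard 2D NH form) and exposes the literal variant
behind `strain_energy(..., as_printed=True)` for comparison. Moduli are
stored as `Gs` plus the law parameter; `Ks` is always derived through
`area_dilatation_modulus`, never stored, so the two can never disagree.
`equivalent_parameters(Ks/Gs)` inverts the SK and Hooke relations at equal
modulus ratio (`C = (r−1)/2`, `νs = (r−1)/(r+1)`), which is how a capsule
classified as "SK or Hooke" maps between the two parameterisations.

The flow enters only through the capillary numbers `Ca^Gs = μU/Gs`,
`Ca^Ks = μU/Ks` (viscous stress over membrane elastic stress); predictions
are made in capillary-number space and converted to N/m with the measured
`μU`.

## Synthetic forward model

A fluid–structure simulation of a capsule in tube flow is out of scope;
`steady_profile` instead draws the steady footprint from a fixed
phenomenological shape family — a polar mode expansion of the axisymmetric
generatrix `r(θ)/r0 = 1 + E cos 2θ + A cos θ − D b(θ) [+ N cos 3θ]` with
`r0 = (1+α)β` and the rear bump `b(θ) = ((1−cos θ)/2)⁴`:

| mode | gain | driver | role |
|------|------|--------|------|
| `E`  | `0.18 · Ca^Gs/0.21`      | shear Ca | axial elongation |
| `A`  | `0.06 · Ca^Ks/0.055`     | dilatation Ca | front/rear asymmetry |
| `D`  | `0.22 · (Ca^Ks/0.055)²`  | dilatation Ca | rear flattening → parachute dimple |
| `N`  | `0.05 · (d1+d2)/2`, NH only | both | NH-identifying perturbation |

The gains are fixed, documented constants of the package — a shape
phenomenology, not a fit to any published simulation. The family is built
to reproduce the structure an inverse method relies on:

* `Ca → 0` degenerates to a circle of radius `r0` (max deviation < 1e-6);
* the enclosed volume of the solid of revolution is renormalised to the
  inflated sphere volume `(4/3)π r0³` analytically (Simpson quadrature on a
  4096-point generatrix), so shape changes are volume-preserving;
* tip-to-tail length is monotone in `Ca^Gs` at fixed `Ca^Ks`;
* SK and Hooke produce *identical* footprints at matched
  `(Ca^Ks, Ca^Gs)` — the strongest form of the observed SK/Hooke
  degeneracy at moderate deformation — while the `N` mode keeps NH
  identifiable.

Profiles are resampled to `n_nodes` equal arc-length nodes (spacing CV
well below 1%), centred on the polygon centroid, counter-clockwise, in
tube-radius units. Optional zero-mean Gaussian radial node noise (units of
`r0`, seeded, default 0) is applied before a final polyline volume
renormalisation.

Default study conditions are `β = 0.77`, `α = 3%`,
`Ca^Ks ∈ [0.02, 0.055]`, `Ca^Gs ∈ [0.03, 0.21]`, laws mixed 1/3 each
(largest-remainder rounding), uniform Ca draws per law with each law's
`Ks/Gs` consistency enforced: NH samples sit on the line
`Ca^Gs = 3 Ca^Ks`; SK/Hooke draws are rejected until `Ca^Gs > Ca^Ks`
(positive `C`, `νs`). The sampling design (independent uniforms with
rejection) and the equal law mixture are package choices.

What the generator does **not** emulate: wall lubrication films, membrane
wrinkling or bending, viscosity contrast, unsteady shapes, asymmetric or
off-axis capsules, and real camera artefacts beyond additive Gaussian pixel
noise. Tests passing on this surrogate therefore demonstrate that the
*pipeline* (extraction, learning, inversion) works on data with the right
statistical structure, not that any specific physical capsule will be
recovered at the quoted accuracy.

## Image processing

`rasterize` renders a profile into a square camera frame covering the tube
bore, dark capsule on light background, pixel-centre point-in-polygon fill
with no anti-aliasing; resolution is specified as pixels per *undeformed*
capsule diameter. The extraction chain then:

1. subtracts the background frame (absolute difference), thresholds (Otsu
   by default, fixed threshold configurable), keeps the largest 8-connected
   component and centres it in a square region of interest one tube
   diameter wide;
2. follows the outer border with Moore-neighbour tracing (Jacob stopping
   criterion), counter-clockwise in mathematical orientation — one-pixel-
   thin protrusions are traversed on both sides and de-duplicated;
3. smooths the staircase border with overlapping local least-squares
   quadratics (window 9 px by default) fitted in a chord-aligned rotated
   frame, then pushes the curve outward by 0.5 px along its normal: border
   following returns outermost foreground pixel *centres*, which sit about
   half a pixel inside the true outline, and without this correction every
   extracted profile is systematically shrunk;
4. resamples `n_nodes` equal arc-length nodes and rescales to tube-radius
   units (RoI side = one tube diameter).

`to_feature_vector` canonicalises a profile into the network input: the
start node is pinned to the leading tip — the maximum-x crossing of the
symmetry axis, located by interpolation, with the node sequence re-sampled
at equal arc increments from that point. Re-phasing (rather than rolling to
the nearest node) matters: a half-node-spacing phase offset after pixel
re-extraction is an order of magnitude larger than the extraction noise
itself and dominates the error budget if left in. The vector is the
interleaved `(x1, y1, x2, y2, …)` sequence, centroid-centred.

## Network and training

Input `2N` → three hidden layers of 128 (Dense → batch-norm → ReLU →
dropout 0.3) → a 3-way softmax classification head and a 2-output linear
regression head on standardised `(Ca^Ks, Ca^Gs)`. Loss: cross-entropy plus
`λ = 1` times the squared loss summed over the two standardised targets,
both averaged over the batch. Optimiser: Adam, initial learning rate
0.001, mini-batches of 128, He initialisation, all seeded; batch-norm uses
running statistics (momentum 0.9) at inference, so prediction is a pure
feed-forward function. Target standardisation (train-split mean/sd)
travels with the serialised parameters.

10% of the samples are held out for validation. The learning rate is
reduced ×0.1 whenever the validation loss has not improved for 100 epochs,
training stops after 300 stagnant epochs (or 5000 total), and the
parameters of the best validation epoch are returned. The long patience is
deliberate: the SK/Hooke degeneracy puts an irreducible ~`ln 2 · 2/3`
floor under the classification entropy, and short-patience schedules stop
long before the regression head has converged beneath that noise.

A `shared_trunk=False` flag trains two independent networks instead (one
per task); each then monitors its own validation loss, which is the natural
reading when the two tasks are separated. The default remains the single
shared-trunk network.

## Inverse baseline

`mean_hausdorff(R, T)` is the directed mean of nearest-neighbour distances
from `R` to `T` after moving both point sets to their centres of mass
(k-d tree accelerated; a symmetric max-of-both-directions variant is
available behind a flag). `inverse_predict` linearly scans a labelled
library — by default the 400-profile training set — and returns the labels
of the minimum-distance entry, ties broken by the lowest index. Distances
are computed on the resampled membrane nodes, not raw pixels.

## Evaluation

Accuracy is reported as the mean absolute percentage error
`MAPE = (100/M) Σ |y_true − y_pred| / |y_true|` of the predicted capillary
numbers on held-out samples, plus a per-law confusion table.
`run_recovery_study` sweeps membrane-node counts and camera resolutions
over seeds (each cell: fresh 400-sample training set, fresh 100-sample
test set, fresh network; per-seed raw values are kept alongside
aggregates). Numeric resolutions push the test inputs through the full
raster + extraction chain; `None` feeds clean vectors.

Two regimes behave differently, and deliberately so. With clean vectors,
10-node and 60-node inputs give statistically indistinguishable accuracy —
an equal-arc 10-node sampling of this smooth low-dimensional shape family
is still fully informative — so the benefit of more nodes appears in the
imaging regime, where extraction noise is averaged over more nodes.
Prediction error falls with camera resolution in both the extraction
metric (mean node error in tube radii) and the end-to-end MAPE.

Problem sizes used throughout (400 training / 100 test samples, 3 seeds,
100-test-sample study cells) are the package's study conditions; prediction
latency is logged by the CLI for information but never asserted in tests,
being hardware-dependent.

## Known limitations

* The surrogate's absolute MAPE values quantify the pipeline on surrogate
  data only; real capsules introduce model error the generator cannot see.
* The SK/Hooke classification is irreducibly ambiguous at matched moduli —
  by construction here, and physically at moderate deformation; only the
  elastic parameters are trustworthy for those two laws.
* Only steady, axisymmetric, single-capsule footprints are handled; no
  video tracking, mid-plane reconstruction or multi-particle scenes.
* The three classical laws are a closed hypothesis set; the method cannot
  discover a new constitutive law.
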