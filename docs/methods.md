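# Methods

## Model and procedure

rbfseg classifies pixels of a 2-D grayscale image with a three-layer RBF
network. The procedure, end to end:

1. **Features.** For each pixel, the vector (x, y, f, |∇f|): column and row
   position normalized by (dim − 1), intensity min–max scaled over the
   image, and the magnitude of the central-difference gradient normalized
   by the image-wide maximum (0 when the image is flat). Coordinates are
   0-based (row, col); x maps to column and y to row. The gradient operator
   uses edge replication at borders, so a border pixel sees half the
   one-sided difference. Scaling constants are stored with the model and
   re-applied verbatim at inference; features of the training image are
   reproduced bit-exactly.
2. **Training pixels.** Seeded sampling without replacement, a fixed count
   per class, optionally disjoint from an exclusion set (so test pixels
   never overlap training pixels). Targets are one-hot over the sorted
   distinct label values. Labels never enter the feature columns — cluster
   and classification distances use only the four continuous components,
   because at inference labels do not exist.
3. **Centers.** Plain k-means (Lloyd's algorithm) on the training features:
   initial centers are k distinct training samples drawn from a seeded
   stream; assignment is nearest-center by Euclidean distance with ties to
   the lowest index; updates are member means. Convergence is declared when
   the largest center displacement is ≤ `tol` (default 1e-9) — a floating
   point relaxation of exact center equality — with a `max_iter` guard
   (default 300). An empty cluster is re-seeded to the sample farthest from
   its nearest surviving center; this rule is plumbing, chosen to be
   deterministic and to preserve k. An optional `n_init` runs seeded
   restarts and keeps the lowest within-cluster SSE.
4. **Width.** One shared σ = c_max/√(2g), with c_max the maximum pairwise
   center distance. The formula makes σ a global function of the center
   set, so a per-node width would be g copies of the same number; it is
   stored once. Fewer than two centers, or coincident centers, make σ
   undefined and raise a degeneracy error rather than guessing.
5. **Weights.** The hidden-to-output matrix is the least-squares minimizer
   of U = Σ‖Y − D‖²/(2E), solved by orthogonal decomposition on the
   ridge-augmented system (default ridge 1e-8; ridge 0 demands full column
   rank and raises otherwise). Least squares cannot impose Σ_j y_j = 1, so
   raw scores drive the argmax classification and a clipped-renormalized
   copy is provided where a probability-like vector is wanted (uniform when
   every raw score is ≤ 0; where defined, the renormalization preserves the
   argmax).
6. **Iterative mode.** Gradient descent on U from ω = 0 with centers and σ
   frozen, logging U every `log_every` epochs and stopping at
   `target_error` or `epochs`. The default step is 1/L with
   L = λ_max(AᵀA)/E, the objective's Lipschitz constant, which guarantees a
   monotone curve. This mode exists to expose the error trajectory — a
   rapid early drop, then a plateau at the closed-form floor; closed form
   is the reference solution and the default.

All randomness descends from one integer seed through named substreams
(center initialization, pixel sampling, phantom noise, phantom geometry),
so every stage is reproducible independently.

## Parameters that matter

| parameter | default | units/range | why |
|---|---|---|---|
| `per_class` | 200 (CLI) | pixels | enough for stable class statistics at 128×128 without touching most of the image |
| `g` | ⌈√E⌉, clamped to [2, E] | hidden nodes | standard bias/variance compromise when nothing is known about the class geometry; g = E gives exact interpolation |
| `ridge` | 1e-8 | — | negligible bias, but keeps near-duplicate centers from blowing up the solve |
| `tol` (k-means) | 1e-9 | feature units | displacement threshold replacing exact center equality |
| `lr` | 1/L (computed) | — | largest step with guaranteed descent |
| `noise_sd` | 0.08 | intensity | benchmark noise level; see below |

## The phantom generator

Phantoms are piecewise-constant class maps plus i.i.d. additive Gaussian
noise clipped to [0, 1]; the noiseless map is the ground-truth label image.
Geometries: `nested_ellipses` (background / large ellipse / nested inner
ellipse, √-spaced so regions have comparable areas — loosely a head slice
with a lesion), `bands` (equal-height horizontal layers), `blobs` (three
seeded disks per foreground class). The benchmark spec is 128×128
nested ellipses, three classes at means 0.15/0.50/0.85, noise sd 0.08.

`bayes_accuracy` computes the accuracy ceiling of the optimal
intensity-only (MAP) classifier under that mixture — priors from the
noiseless class areas, equal-variance Gaussians, evaluated by trapezoidal
quadrature of max_k π_k φ(t; μ_k, σ) on a ±10σ grid; clipping at [0, 1] is
ignored, which overstates the overlap negligibly at these parameters. For
the benchmark the ceiling is ≈ 0.981 (the middle class loses mass on both
sides: 2Φ(2.1875) − 1 ≈ 0.971 before weighting). Measured held-out
accuracy ≈ 0.977 sits just below it.

What the phantoms do **not** emulate: spatially correlated noise, Rician
magnitude statistics, bias fields, partial-volume edges, anatomy-specific
shape. Passing the phantom suites therefore shows the pipeline is correct
and near-optimal under its stated noise model — not that it meets any
accuracy figure on clinical MRI.

## Numerical choices and degenerate inputs

- Activation-at-center identity asserted to 1e-12 absolute.
- Argmax ties (classification and cluster assignment) go to the lowest
  index — deterministic and order-stable.
- A flat image yields zero gradient features and a zero span for intensity;
  both normalize to 0 rather than dividing by zero.
- Percentages are exact `Decimal` arithmetic rounded half-even to two
  places, so report-table values reproduce without float artifacts.
- Model JSON serializes floats via `repr`, making save/load round trips
  bit-exact.
- 16-bit PNG quantizes intensities to 1/65535; a second save/load cycle is
  exact.

## Design choices where the design was open

- **Closed-form vs iterative training.** Both are kept because they answer
  different questions: the solve is the estimator, the descent shows the
  training dynamics. Their agreement (closed-form error ≤ iterative, curve
  plateau at the floor) is itself a test.
- **CLI + library.** The library is the interface; the `rbfseg` command is
  a thin wrapper (simulate / train / segment / evaluate / archive) for
  shell pipelines, with exit codes 0 / 2 (input) / 3 (degeneracy).
- **Archive.** A JSON manifest with SHA-256 content hashes stands in for a
  picture-archive flavor of storage: append-only ids, hash verification on
  read. No networking, DICOM, or worklist integration.
- **Problem sizes.** Tests and the acceptance script run the benchmark at
  128×128 with 600 training pixels and 10 phantom seeds — large enough that
  the accuracy estimate's seed-to-seed spread is a fraction of a percent,
  small enough to iterate on quickly.

## Known limitations

- Features are four global-coordinate scalars; no texture, multi-scale or
  neighborhood features, so thin structures and low-contrast boundaries
  are hard for it by construction.
- One shared width: strongly anisotropic or multi-scale class geometry is
  a poor fit for the σ formula.
- Centers are never refined supervisedly; k-means is label-blind.
- 2-D only; NIfTI volumes must be sliced by the caller (the reader refuses
  to pick a slice silently).
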