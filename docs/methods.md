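# Methods

## The problem

Double electron–electron resonance (DEER/PELDOR) measures distances between
spin labels on a biomolecule through the magnetic dipolar coupling of the two
unpaired electrons. The orientation-averaged signal of an isolated pair at
distance r (nm) is the dipolar kernel

    gamma(r, t) = ∫₀¹ cos((3z² − 1) D t) dz,     D = mu0 * gamma_e² * hbar / (4 pi r³),

evaluated in closed form through Fresnel integrals (scipy's pi/2-argument
convention; `D(1 nm) ≈ 327 rad/us`, i.e. the textbook 52 MHz). For an ensemble
with distance density p(r) the observed form factor is the Fredholm integral
of the first kind, `Gamma(t) = ∫ p(r) gamma(r, t) dr`, whose inversion is
ill-posed. Small fully connected networks solve this inversion surprisingly
well; this package implements the machinery to find out *how*: descrambling
their internal signal bases by optimization over the special orthogonal group.

## Descrambling

Backprop training fixes the network function `y = F_n W_n ... F_1 W_1 x` but
not the basis of any hidden signal space — each hidden layer is "scrambled" by
an arbitrary invertible change of basis absorbed into the adjacent weight
matrices. We look for the rotation P ∈ SO(d) of a tapped layer's signal space
that extremizes an interpretability functional of the tapped signals. The
default functional is Tikhonov smoothness,

    eta_T(Q) = || D P(Q) M ||_F²,

where M is the tapped signal array over the whole input library X, D is the
periodic Fourier spectral second-derivative matrix on d points of a unit
interval, and P(Q) = (1 − Q)(1 + Q)⁻¹ is the Cayley transform of an
antisymmetric generator Q. The Cayley chart keeps P exactly in SO(d) for every
real antisymmetric Q (the eigenvalues of Q are imaginary, so 1 + Q is never
singular) and misses only the measure-zero subset of SO(d) with eigenvalue −1;
starting the optimizer at Q = 0 with a line-search method, that subset is
never hit in practice and is deliberately not handled specially.

The gradient is derived analytically through the chart: from
dP = −(1 + P) dQ (1 + Q)⁻¹, any functional with Euclidean gradient G_P at P
has

    d eta / d Q  =  −(1 + P)ᵀ G_P (1 + Q)⁻ᵀ,

antisymmetrized onto the free (strictly triangular) parameters of Q. For the
smoothness functional G_P = 2 DᵀD P C with C = M Mᵀ the signal Gram matrix, so
the cost per iteration is O(d³) after one pass over X; columns of X may be
accumulated in batches of any size without changing the result. The test
suite verifies the analytic gradient against central finite differences to
better than 1e−6 relative (measured ~1e−10).

Optimization is L-BFGS (scipy, memory 10) from Q = 0, stopping at gradient
∞-norm ≤ 1e−8 or 500 iterations. Because the objective is a fourth-power
quantity of typical magnitude 1e6–1e9, the absolute gradient tolerance is
often unreachable in float64 and runs commonly stop at the iteration cap with
the objective long since flat; `converged=False` then records that honestly
rather than signalling a failure.

Functional menu: `tikhonov` (smoothness of tapped signals), the
diagonal-dominance functionals `max_diag_sum` = Tr(PW) and
`max_diag_normsq` = ||diag(PW)||₂² (maximized via negation), and
`tikhonov_plus_link`, the weighted sum of signal smoothness and the
smoothness of the downstream weight matrix along its link dimension —
`||D P W_{k+1}ᵀ||_F²`, since differentiating W_{k+1}Pᵀ along its columns
equals differentiating P W_{k+1}ᵀ along its rows. The combination weight
defaults to 1: the two terms have the same units (both are second-derivative
norms on the same d-point unit-interval grid) and no other weighting is
privileged a priori.

### Wiretap bookkeeping

Inserting the unit operator P⁻¹P leaves the network function untouched; how
the two factors are stored depends on the tap:

* **before the activation** — P is absorbed into W_k and its bias (the bias is
  a constant input column, so it rotates with the layer); the inverse Pᵀ
  cannot pass through the elementwise nonlinearity and is recorded as an
  explicit per-layer pre-activation undo that `forward` applies.
* **after the activation** — P is recorded as a post-activation transform and
  Pᵀ is absorbed into W_{k+1} exactly; if the tapped layer is the last one,
  the undo is recorded on the output side instead.

Either way the end-to-end outputs are preserved to machine precision, which
the suite asserts at 1e−8 relative over random networks, taps and rotations.

## Link-rank truncation

A layer whose weight matrix has only r significant singular values can be
split through its SVD into a rank-r linear compression `sqrt(S_r) V_rᵀ`
(identity activation) followed by an expansion `U_r sqrt(S_r)` carrying the
original bias and activation. The split is exact at full rank, exact for an
exactly rank-r matrix, and otherwise perturbs outputs by at most the sum of
discarded singular values times the downstream Lipschitz constants. The
balanced `sqrt(S)` split keeps the two factors at comparable scale; any other
split of S between the factors is mathematically equivalent. At the full
256-wide solver layout the default truncation rank is 80. Descrambling then
operates on the r-dimensional link between the factors.

## The synthetic data generator

No experimental data is consumed; the generator emulates the features of
realistic DEER records with known ground truth:

* **distributions** — mixtures of 1–3 Gaussians truncated to the distance
  grid and renormalized. This is the simplest family that produces the
  multi-peak densities typical of spin-labelled proteins. Component positions
  stay 0.7 nm (bottom) and 1.2 nm (top) inside the grid so truncation is
  negligible; widths 0.15–0.4 nm.
* **composition** — V(t) = B(t)·(1 − λ(1 − Γ(t))) + ε with the canonical
  three-dimensional homogeneous spin-bath background B(t) = exp(−k t),
  modulation depth λ ~ U(0.15, 0.5), decay rate k ~ U(0.02, 0.25) us⁻¹ and
  white noise σ ~ U(0.005, 0.03) — the range of a competently measured
  modern DEER trace (noise a fraction of a percent to a few percent of the
  normalized echo).
* **grids** — full scale: 256 time points on [0, 3.2] us and 256 distances on
  [1.5, 8] nm (the standard working range of the experiment). Reduced scale,
  used throughout the tests and the end-to-end study: 64 points on
  [0, 2.56] us and [2.5, 6.5] nm, chosen so that the fastest dipolar
  component at r_min stays below the Nyquist frequency of the coarser grid.
* **seeding** — every record derives its own integer seed from the master
  seed via `numpy` SeedSequence; datasets are pure functions of
  (n_records, config, seed).

What the generator does **not** emulate: orientation selection, multi-spin
effects, exchange coupling, excitation-bandwidth distortions, phase noise and
drift of real spectrometers, or the heavier-tailed nuisance statistics of
real sample libraries. Passing tests therefore demonstrate the machinery —
kernel physics, training, descrambling, replication — under controlled
conditions, not performance parity on experimental data.

## Solver networks

Layout: input > fully connected > tanh > fully connected > logistic output
("sigmoidal" hidden unit read as tanh; "logsig" as the logistic function —
the positive range of the output unit is what matters, since the output is a
probability density). Training is plain backprop with Adam (lr 3e−3 at study
scale, β = 0.9/0.999), mean squared error, Glorot-uniform initialization from
the run seed, and a held-out validation split. Targets are scaled to per-bin
probability mass (density × grid step) so the logistic output range covers
them. Training is bit-reproducible from the seed; ensembles derive member
seeds from the base seed.

## Numerical choices

* Spectral second derivative: even d only, built by DFT diagonalization with
  integer frequencies on a unit interval, symmetrized against roundoff. The
  unit-interval convention makes smoothness penalties scale-consistent
  across layer widths.
* Kernel evaluation switches to the analytic limit gamma = 1 below
  D·t < 1e−6 (error O((Dt)²) ≈ 1e−12), avoiding the 0/0 of the closed form.
* Quadrature for the Fredholm forward map: trapezoidal on the uniform grid.
* Unitary DFT normalization everywhere in the interpretation views, so
  frequency-domain conjugation preserves Frobenius norms; "symmetrized" 2-D
  spectra are zero-frequency-centered magnitude maps.
* SVD sign convention: largest-magnitude entry of each left singular vector
  positive.
* Cayley transforms and the regularized transform are computed by linear
  solves, never explicit inverses.

## The rational replica

The interpreted network is rebuilt from standard DSP parts, mirroring what
descrambling reveals: a zero-frequency notch removes the background, a
low-pass filter removes noise, and a single linear map converts the filtered
trace to a distance distribution.

* **Filters** — linear-phase FIR, equiripple (Parks–McClellan) with a
  least-squares fallback; passband weighted 3:1 over the stopband so the
  passband deviation stays under 1 dB even for tight transition bands. The
  notch gets an exact zero at DC by subtracting the tap mean. Full-scale
  specs: order-256 high-pass with stopband edge 0.001 and passband edge
  0.008, and order-32 low-pass with passband edge 0.01 and stopband edge 0.3
  (normalized to Nyquist = 1). At the 64-point reduced scale the same roles
  are filled by an order-32 notch (0.01/0.1) and an order-16 low-pass
  (0.35/0.75), rescaled because the coarser grid moves the same physical
  frequencies up the normalized axis. Band edges are configuration, not
  automation: occasional adjustment per dataset is expected.
* **Zero-phase application** — forward–backward filtering, so the dipolar
  oscillation phase that carries the distance information is untouched; the
  effective response is the squared magnitude.
* **Time–distance transform** — T = ((F Fᵀ + λ1)⁻¹ F Pᵀ)ᵀ fitted on 2,000
  synthetic (filtered trace, distribution) pairs; the frequency-axis
  rearrangement the network performs is linear and folds into the same
  matrix. T is trained on *filtered* traces, consistent with its position
  after the filters in the pipeline. λ from the L-curve corner (maximum
  curvature of the log residual vs log solution-norm curve) over a 40-point
  grid, 1e−6…1e2.
* **Pipeline** — low-pass → notch → T → clip negatives → renormalize; an
  all-zero estimate skips renormalization and is flagged.

The replica's fidelity claim is quantified *up to the noise* (filtering
cannot un-draw a noise realization): the filtered noiseless composition is
compared against the depth-scaled, background-attenuated clean form factor
passed through the same filters, and matches to a few percent relative L2;
peak positions of noiseless single-Gaussian records are recovered within one
grid step in well over 90% of cases.

## Study scale and reproducibility

The end-to-end study trains 64 → 32 → 64 solvers on 5,000 synthetic records
(800 epochs, ~15 s per member on one CPU) from three independent seeds,
descrambles each first layer, and compares the descrambled frequency-domain
maps |F₊ W₁ F₋|. The maps agree pairwise with correlation above 0.7 after
aligning over circular shifts and reflection of the link dimension — the
residual gauge freedom of the descrambled basis (circular shifts of the link
only re-phase the frequency map, so the remaining variation is genuine
training-to-training difference). Descrambling reduces the smoothness
objective by four orders of magnitude relative to the scrambled basis, and
validation NRMSE lands around 0.4; the pilot-calibrated acceptance threshold
is 0.5. These problem sizes keep the whole study comfortably within a
single-CPU coffee break while preserving every qualitative feature of the
full 256-wide layout.

## Known limitations

* Only square-signal fully connected layers are descrambled; convolutional
  layers and non-orthogonal (general linear) descrambler subgroups are out
  of scope.
* Only even layer widths can use the spectral smoothness functional (the odd
  periodic stencil differs and is never needed here).
* The Chebyshev character of the output signal library is reported as a
  descriptive cosine-similarity diagnostic, not asserted: the observed
  polynomials are distorted and the distortion is training-dependent.
* The reduced-scale replica inherits the band-edge compromises of short
  traces: very long distances (slow oscillations) overlap the notch band and
  very short distances approach Nyquist, which is why the reduced-scale
  distance grid is narrower than the full one.
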