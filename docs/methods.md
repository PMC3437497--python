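# Methods

## Model and sign convention

Each node is a Wilson–Cowan pair

    du/dt = -u + f(c1*u - c2*v + P + eps * sum_j w_ij u_j) + sigma * xi(t)
    dv/dt = -v + f(c3*u - c4*v + Q),          f(x) = 1/(1 + exp(-x)),

with c1 = c2 = c3 = 10 and c4 = -2. The inhibitory terms carry explicit
minus signs (the Hoppensteadt–Izhikevich convention), so the effective
within-node weights are (+10, -10) onto u and (+10, +2) onto v. This is the
unique sign placement (among the four candidates for the two v-terms) for
which the canonical exploration window P ∈ (-6, 6), Q ∈ (-12, 0) contains a
limit-cycle region covering all three reference points (-2.5, -8.5),
(-1.5, -6) and (2.5, -3.5); `node_model.self_check()` asserts a non-empty
Hopf locus in that window and fails loudly if the convention is ever broken.
A useful structural fact: the substitution (u, v, P, Q) → (1-u, 1-v, -P,
-Q-12) is an exact symmetry of the node, which maps (-2.5, -8.5) onto
(2.5, -3.5) — these two points therefore share the period and H'(0) exactly.

Coupling enters the u-equation only, inside the firing-rate argument, with
row-normalized weights w_ij = b_ij / Σ_k b_ik (b_ij = 1 ⇔ link from node j
to node i). Nodes without afferents receive no coupling input.

## Fixed points and bifurcation loci

Rest states are found by a 1-D reduction: for each u the v-nullcline
v = f(c3 u - c4 v + Q) is solved by fixed-point iteration (a contraction,
Lipschitz constant |c4| · max f′ = 0.5), then sign changes of the remaining
u-residual are bracketed on 2001 samples over the invariant box
[-0.25, 1.25]² and polished by bisection to 1e-12; roots closer than 1e-8
are merged. Stability comes from the analytic 2×2 Jacobian (entries use
f′ = f(1-f)) via the trace/determinant classification.

The bifurcation scan walks a rectangular grid, tracks fixed points across
grid edges by nearest-u matching, and bisects: Hopf points where the trace
of a tracked non-saddle fixed point crosses zero with positive determinant,
saddle-node points where the number of rest states changes. Loci are
returned as unordered point sets (curve ordering is a plotting concern).
Codimension-two structure and global bifurcations are out of scope.

## Stochastic integration

Euler–Maruyama with dt = 0.1: deterministic drift step plus
noise_sigma·√dt·ξ Gaussian increments applied to u only, independently per
node and step. The printed protocol is runs of T = 10 000 time units with
the first 1000 time units discarded as transient and initial conditions
uniform on (0, 1); the test-scale experiments use T = 3000 / transient 300,
which the modular-network contrast already resolves cleanly. noise_sigma
(default 0.01) is interpreted as the diffusion amplitude multiplying √dt·ξ;
at this magnitude the alternative reading (variance rather than SD) is
dynamically indistinguishable. Optional quenched per-node P-jitter
(canonical interval (0, 0.01)) is drawn once per run from the run's seed.

Discretization: at dt = 0.1 the bulk limit-cycle periods (~4–6 time units,
i.e. ~50 steps per cycle) carry an O(10%) Euler period bias; deterministic
period cross-checks against the phase-reduction period are therefore run at
dt = 0.01, where the bias is ~1%. The stochastic FC experiments use the
protocol dt = 0.1, matching the study conditions; all sign- and
ranking-level conclusions are insensitive to the bias.

## Functional connectivity

Pearson correlation is the standard product–moment coefficient of the
u-series. Mean phase coherence is |⟨exp(i(φ_i - φ_j))⟩_t| with phases read
off the analytic signal (Hilbert transform) of each mean-centred series
(the phase of a nonzero-mean analytic signal is ill-defined; the paper-level
definition does not state the centring, which is numerically necessary).
The first and last 5% of phase samples are excluded from the average to
suppress Gibbs ringing at the record boundaries (configurable). FC is
computed from u-series only. Constant series yield flagged zero entries
(correlation) or are rejected (phase).

## Graph metrics and SC–FC agreement

FC matrices are binarized by keeping the K strongest off-diagonal links,
K = round(density × n(n-1)/2) with the density of the OR-symmetrized SC
(link if either direction exists); ties break in (i, j) lexicographic order
so the result is deterministic. L averages BFS distances over *connected*
ordered pairs only, with the disconnected-pair fraction reported alongside
(binarized FC can fragment; an infinite-L convention would make the
parameter-plane maps incomparable). C is the mean local clustering with
degree-<2 nodes contributing zero. References L_rand, C_rand are means over
a seeded ensemble (default 100 draws) of G(n, m) graphs — sampled rather
than closed-form because the networks are small — giving λ = L/L_rand,
γ = C/C_rand and the small-world index γ/λ. SC–FC agreement is the Jaccard
coefficient of the off-diagonal link sets; its chance level is estimated by
re-placing the FC's edges uniformly at random (default 100 seeded draws),
reported as mean ± SD.

## Phase reduction

The linear change of variables x = c1 u - c2 v + P + coupling,
y = c3 u - c4 v + Q makes the coupling additive:

    dx/dt = -x + P + c1 f(x) - c2 f(y) + eps Σ_j w_ij f(x_j)
    dy/dt = -y + Q + c3 f(x) - c4 f(y).

Pipeline, all on the transformed uncoupled node:

1. **Limit cycle** — long integration (RK45, rtol 1e-10 at headline
   precision, 1e-7 for maps) past a 500-unit transient; period from a
   Poincaré section (upward crossing of x through its orbit mean) with
   solver event root-finding, a rough crossing-based estimate first sizing
   the event window; the orbit is resampled to M uniform points (1024
   headline, 256 for maps). Amplitude below 1e-4 ⇒ explicit no-limit-cycle
   outcome.
2. **Adjoint** — dZ/dt = -J(t)ᵀZ integrated backwards (the periodic adjoint
   is attracting in reverse time) over ≥ 20 periods until the per-period
   direction change is < 1e-8, then scaled so Z·F = 1/T; the identity is
   re-verified pointwise. Phase convention: θ ∈ [0, 1), drift 1/T. The
   impulse-response property (a perturbation δ on x at phase θ shifts the
   asymptotic phase by δ·Z_x(θT)) is verified against direct simulation in
   the test suite.
3. **Interaction function** — H(θ) = (1/T)∫ Z_x(s) f(x(s+θT)) ds by
   uniform-grid quadrature (circular correlation via FFT); the headline
   H'(0) by the direct quadrature ∫ Z_x f′(x) x′ ds, never by
   differentiating sampled H; spectral differentiation of H serves as an
   independent cross-check (agreement to ~1e-4 relative).

Synchrony stability: the phase-locking Jacobian at the synchronous state is
ε·H'(0)·(w_ij − δ_ij Σ_k w_ik). Rows sum to zero, forcing one zero
eigenvalue; the state is stable iff the remaining eigenvalues have negative
real part. For uniform global coupling w_ij = c the nonzero eigenvalues are
degenerate; with c = 1/N they equal −1 (in units of ε·H'(0)) with
multiplicity N−1, and with row normalization c = 1/(N−1) they equal
−N/(N−1) — both negative, so the stability verdict is identical; the
scale-free "units of ε·H'(0)" form is exposed as an option.

## Coupling strength for the network experiments

The API default is eps = 1 (the printed convenience value). For the
parameter-plane experiments the package uses eps = 0.5
(`sweep.SWEEP_EPSILON`), calibrated once by the theory's own validity
diagnostic: the largest coupling at which a reciprocally coupled pair under
study noise realizes the phase-reduction verdict at all three reference
points (in-phase lock where H'(0) > 0, no in-phase lock where H'(0) < 0).
The diagnostic holds for eps ∈ [0.2, 0.5]; at eps = 1 strong coupling
stabilizes the in-phase state even where H'(0) < 0 (confirmed at dt = 0.005,
so not a discretization artifact), i.e. the dynamics leaves the
weak-coupling regime the whole analysis presupposes, while at eps ≤ 0.1 the
noise overwhelms the coupling within feasible run lengths — the exact
tradeoff that motivates an intermediate choice. The calibration uses only
the two-node phase-locking verdict, not the SC–FC agreement quantities the
experiments measure.

## Synthetic data

The synthetic cortex fixture is a seeded directed stochastic-block-model
graph (5 balanced communities, within/between link probabilities 0.65/0.06)
emulating only the size (47 nodes), density (0.1–0.3) and modular tendency
of tract-tracing connectomes; it is labelled synthetic throughout and
carries none of the spatial, hierarchical or weighted structure of real
anatomical data. Consequently, passing tests demonstrate the mechanism —
parameter-dependent decoupling of FC from SC — not a quantitative fit to
any empirical connectome. Purely modular matrices are the analytically
transparent case (the synchrony prediction is exact per module);
Maslov–Sneppen rewiring (pair swaps rejected on self-loops/duplicates,
budget 10 attempted swaps per edge) provides the degree-matched null.

## Problem sizes

Test-scale experiments use a 13×13 grid over the canonical window
(increment 1.0), T = 3000, transient 300, and the 12-node modular network
(3 modules of 4), with one noise realization per grid point and per-point
seeds derived from (base seed, grid index); the full 49×49 / T = 10 000 /
N = 47 protocol is available as `SweepConfig.paper_scale`. H'(0) maps reuse
one grid computation across structural matrices.

## Known limitations

- Bulk limit-cycle periods in this parameterization are ~3–14 time units;
  periods of ~50 time units occur only in the narrow band adjacent to the
  saddle-node boundary where the cycle dies with diverging period (the
  survey utility refines toward that boundary to expose the long-period
  tail). Descriptions quoting a "typical" period an order of magnitude
  above the bulk value are consistent with counting dt = 0.1 steps rather
  than time units.
- No axonal transmission delays (a delay would enter H as a phase shift and
  can flip synchrony stability); no heterogeneity study beyond the optional
  P-jitter; no forward models of EEG/fMRI observables.
- The Erdős–Rényi reference and the connected-pairs L convention make λ and
  γ well-defined on fragmented graphs but not comparable to penalty-based
  conventions in other software.
- `binarize_to_density` is deterministic under ties, which matters for the
  all-equal degenerate case but makes tie resolution basis-dependent
  (lexicographic in node order).
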