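# Methods

## Model

`trifactor` fits non-negative matrix tri-factorization (NMTF): given a
non-negative data matrix X (n × m), find non-negative latent matrices
U (n × k1), S (k1 × k2), V (m × k2) minimizing the squared Frobenius
reconstruction error

    D_Fro(X ‖ U S Vᵀ) = ‖X − U S Vᵀ‖²_F .

U spans the row space with k1 latent vectors, V the column space with k2,
and S encodes the interaction between the two latent spaces. The objective
carries no regularization or orthogonality terms; non-negativity is the
only constraint. The problem is non-convex jointly but convex in each
factor with the others fixed, which is the structure all four solvers
exploit. All reported objective values are normalized:

    D = ‖X − U S Vᵀ‖²_F / ‖X‖²_F ,

so D = 1 for the zero model and D = 0 for an exact factorization. The
unnormalized loss is recoverable by multiplying by ‖X‖²_F (cached once per
data matrix; the all-zero matrix is rejected at load time because D is
undefined for it).

For sparse X the objective is evaluated through the trace expansion

    ‖X‖² − 2·tr(Sᵀ Uᵀ X V) + tr((Uᵀ U S)(Vᵀ V Sᵀ)ᵀ) ,

which touches only k-sized intermediates and never materializes the dense
n × m reconstruction. Sparse matrices are treated as matrices whose
unstored cells are exact zeros contributing to the loss — not as missing
data — so dense and sparse storage paths compute the same quantity (tested
to 1e-10 relative).

## Solvers

One iteration updates U, then V, then S, each sub-update seeing the
already-updated earlier factors. The objective is evaluated once per full
iteration, after all three sub-updates — per-sub-update evaluation would
triple the cost and change what a trace point means.

**Multiplicative update rules (MUR).** Gradient-ratio updates, e.g.
U ← U ⊙ (X V Sᵀ) ⊘ (U S Vᵀ V Sᵀ), and analogously for V and S.
Non-negativity is preserved by construction and zero entries are absorbing
(the multiplicative lock). Denominators are floored at δ = 1e-12 before
the Hadamard division; flooring keeps the lock intact (a locked entry has
a zero numerator as well) while ruling out NaN/Inf. The objective is
non-increasing under MUR; the suite asserts this to 1e-12 absolute slack.

**Alternating least squares (ALS).** Each factor is set to the exact
unconstrained least-squares minimizer of its subproblem, e.g.
U ← [(X V Sᵀ)(S Vᵀ V Sᵀ)⁻¹]₊, then negative entries are zeroed. The
inverse is implemented as a k × k linear solve; on singular normal
matrices (rank-deficient factors, common once projection has zeroed
columns) it falls back to the pseudo-inverse with a logged warning rather
than crashing. The zeroing heuristic means ALS is *not* monotone and can
be unstable, particularly on dense data; the suite deliberately asserts
nothing about its objective direction. The fixed-point property at an
exact factorization holds only for k1 = k2 with full-rank S — with
rectangular S the normal matrices are singular and the pseudo-inverse
returns the minimum-norm solution rather than the incumbent factor.

**Projected gradients (PG).** Additive updates factor ← [factor − η P]₊
where P is the gradient rescaled by the current factor (e.g.
P_u = U − U ⊘ (U S Vᵀ V Sᵀ) ⊙ (X V Sᵀ)) and the step size η is chosen in
closed form as the ratio of Σ(P ⊙ (denominator-term − numerator-term)) to
a positive quadratic trace form in P. With η pinned to 1 the update is
algebraically identical to MUR — the suite checks this entrywise to 1e-10,
and end-to-end as identical traces under shared seeds. When the trace
denominator vanishes (P = 0 at a fixed point) the factor update is
skipped, preserving the fixed point.

**Cyclic coordinate descent (COD, HALS-style).** Sweeps columns of U in
ascending order, then columns of V, then entries of S row-major, each
coordinate update using all previously updated coordinates. The column
update

    u_i ← [u_i + ((X V Sᵀ)_i − (U S Vᵀ V Sᵀ)_i) / (S Vᵀ V Sᵀ)_ii]₊

projects the *full* updated value, not the increment alone: the
restricted objective is an isotropic quadratic in the column, so this is
its exact non-negative minimizer (the problem separates per entry;
projecting only the increment could never decrease a coordinate and is
not a descent rule). The per-column curvature (S Vᵀ V Sᵀ)_ii pairs column
i of U with row i of S, the only shape-consistent reading. Coordinates
with zero curvature are skipped. The S sweep maintains a running
G[i,:] @ S cache updated after each entry, so a full sweep costs
O(nk1² + mk2² + k1k2(k1 + k2)) instead of O(k1²k2²). COD is monotone;
each coordinate update matches a brute-force 1-D quadratic minimizer
(tested to 1e-10 against three-point quadratic fits of the dense
objective).

## Driver

Factors are initialized with independent uniform(0, 1) draws (U, then V,
then S) from a seeded generator. Each run terminates with one of three
statuses:

- **converged** — the relative change |D_{i} − D_{i−1}| / D_{i−1} fell
  below ε (default 1e-6) at iteration i ≥ n_start (default 100; MUR can
  plateau early and trigger the rule spuriously without the floor). The
  absolute value is taken exactly as stated, so an *increase* smaller
  than ε also stops the run; sustained increases are the divergence
  detector's job. A previous objective at or below 1e-15 counts as
  converged outright: an exactly recovered factorization decays into
  denormal territory where relative changes are meaningless noise and the
  ε rule would otherwise never fire.
- **max_iter_reached** — the n_stop cap (default 50,000) was hit.
  Such runs are excluded from iteration/runtime means everywhere.
- **diverged** — the divergence detector fired, or D became NaN/Inf.

**Divergence detection** operates on the trailing 20-iteration window of a
single trace: it fires on any non-finite value, when more than half of
the window's steps are rises, or when the latest value exceeds the
window's minimum by more than 10×. The window length and level factor
make a qualitative "oscillates or blows up" judgement operational. Two
guards keep the rule honest: it waits for a full window (early transients
are not oscillation), and a step counts as a rise only when the increase
exceeds both ε relative to the previous value and 1e-12 absolutely —
without the guards, runs that had already converged in substance (ALS
jittering at ~1e-8 relative on a plateau, or exact recoveries jittering
at 1e-16) get mislabelled as diverged before n_start lets the stopping
rule fire.

**Restarts** run with seeds seed, seed+1, …, giving reproducible
independent initializations; summaries expose the best run (lowest final
objective), the min–max span of final objectives, and mean iterations
over converged runs only.

## Synthetic data

`make_synthetic` draws uniform(0, 1) truth factors and forms
X = U S Vᵀ + noise_level · E with E also uniform(0, 1) — additive uniform
noise keeps X non-negative without a clipping step that would distort the
noise model. With density < 1 a uniformly random mask retains exactly
⌈density · n · m⌉ cells (the rest become true zeros) and X is returned in
sparse storage.

The named presets mirror two data regimes at desk scale (n·m ≤ 250,000,
so every solver finishes in seconds): `dense-small` (150 × 100, density
1.0, like flattened image collections), `sparse-1pct` (400 × 300, density
1.3%, like ratings matrices), and `sparse-sub1pct` (500 × 500, density
0.1%, like document-term matrices). True ranks are 4 and noise 0.01
(noise-free for the sub-percent preset, whose retained-cell count is near
the information floor already).

**What masking does and does not emulate.** Masking reproduces the
*storage and cost profile* of real sparse data, but a masked product is
not itself low-rank: the best rank-4 fit of a 1%-masked product plateaus
near D ≈ 0.9, and no optimizer can do better at that rank. Masked presets
are therefore benchmarking fixtures, not recovery targets.
`make_sparse_lowrank` fills that role: it draws sparse factors (entries
non-zero with probability p) and a positive diagonal S, so X = U S Vᵀ
holds exactly, X is sparse (density ≈ k·p²), and a zero-error rank-k
factorization exists. Parameter-recovery and method-ordering experiments
on the sparse regime use this construction. Neither generator emulates
the semantic content of real images, ratings or text — passing recovery
tests show the optimizers find planted structure under the stated noise
and sparsity, not that they will match any particular real dataset's
convergence profile.

## Benchmarking harness

`compare_methods` runs every solver on every preset with shared restart
seeds (identical initializations across methods, so iteration counts are
directly comparable), aggregates mean iterations and runtime over
converged runs only, flags cells where nothing converged, and attaches
iteration speed-up ratios relative to MUR. `rank_sweep` varies
k1 = k2 = k and reports the same aggregates per rank; it rejects ranks
above min(n, m). Plot hooks emit tidy per-iteration frames rather than
figures.

At desk scale the qualitative ordering of the methods reproduces the
expected pattern: COD needs severalfold fewer iterations than MUR on
dense data (majority of shared-seed restarts, and on means), and ALS
converges fastest on sparse exactly-factorizable data while being the
unstable method elsewhere. Wall-clock numbers are hardware-bound and not
comparable across machines; the harness reports them for relative
comparison only.

## Numerical choices (summary)

- Hadamard-division floor δ = 1e-12 (MUR/PG); preserves the zero lock.
- ALS k × k normal systems solved with `numpy.linalg.solve`, pseudo-inverse
  fallback on singularity.
- PG degenerate step size (0/0 at a fixed point) skips that factor's
  update.
- COD zero-curvature coordinates are skipped and logged.
- Exact-zero objective threshold 1e-15 (relative scale); divergence rise
  guard ε-relative with 1e-12 absolute floor.
- Problem sizes in tests and the acceptance script (matrices up to
  150 × 100, ranks ≤ 6, ten restarts) are chosen so the full study runs
  in minutes on a single core; iteration-count *orderings* at this scale
  match the large-scale picture, absolute counts and runtimes do not
  transfer.

## Known limitations

- ALS fixed-point and normal-equation checks require full-rank,
  equal-rank factors; rank-deficient instances exercise the pseudo-inverse
  fallback, whose minimum-norm solutions are valid but not unique.
- The divergence detector is a single-trace operational surrogate for a
  judgement that is genuinely cross-method ("substantially higher at
  convergence than other methods"); cross-method comparison lives in the
  bench reports.
- No mini-batch/stochastic variants, no alternative divergences (KL,
  alpha, beta), no orthogonality or sparsity regularizers, no multiple
  inner updates per factor per iteration.
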