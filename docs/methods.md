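# Methods

`gpsmcap` benchmarks the *generative capacity* of probabilistic sequence
models: how faithfully an MSA generated by a fitted model reproduces the
statistics of an MSA drawn from the distribution the model was trained to
represent.  This note records the models, the metrics, the synthetic study
conditions, and the numerical choices behind them.

## Models

**Pairwise Potts Hamiltonian.**  The maximum-entropy distribution
constrained by all bivariate marginals,

    p(S) = exp(-E(S)) / Z,    E(S) = Σ_i h^i_{s_i} + Σ_{i<j} J^ij_{s_i s_j},

with `L(L-1)/2·(q-1)² + L(q-1)` free parameters after gauge reduction
(10,723,040 at L=232, q=21).  Energies are reported up to the dropped
constant `log Z`; every correlation-based comparison is invariant to that
shift.  A `TripletTerm` (a q×q×q tensor on three chosen sites) can augment
the energy for mis-specification experiments; it is never part of a fit.

*Inference* is marginal matching: iterate between estimating the model's
bivariate marginals and moving parameters toward the pseudocount-smoothed
data marginals.  Two estimators share one update rule (`potts.fit_potts`):

- **exact** — full enumeration of the `q^L` table; used whenever
  `q^L ≤ 2·10⁶`.  This is also the brute-force oracle the tests compare the
  Gibbs sampler against.
- **mcmc** — persistent Gibbs chains (no re-burn-in between parameter
  updates), marginals estimated from a few recorded sweeps per iteration.

The default parameter update is the damped log-ratio rule
`Δθ = -γ (log f_data - log f_model)` with `γ = 0.5`, halved whenever the
marginal discrepancy oscillates upward.  We chose the log-ratio
(iterative-proportional) form over a plain marginal-difference gradient
because its effective step is conditioned by the marginals themselves: the
difference rule needs `γ` of order `1/f(1-f)` to make progress and converges
an order of magnitude slower on the enumerable systems the test-suite fits.
The linear rule remains available (`update_rule="linear"`).

Smoothing follows the convex-mix convention
`f̂ = (1-w)·f + w/q` with `w = 1/N` by default, which keeps frequencies
normalized while matching the customary "pseudocount of 1/N" magnitude.
Couplings are shrunk after every step by a proximal SCAD adjustment
(`λ = 0.001` by default, second shape parameter `a = 3.7`, the conventional
value): the penalty derivative is `λ` below `λ`, decays linearly to zero at
`aλ`, and vanishes beyond — sparsifying weak couplings without biasing
strong ones.  The default stopping tolerance is twice the binomial standard
error of the data marginals (`1/√N`); MCMC-estimator fits that stay above
the tolerance (their marginal estimates are themselves noisy at
`~0.5/√(chains·sweeps)`) return the best model found with
`fit_report.converged = False` rather than failing.

**Site-independent model.**  Closed form: `h^i_a = -log f̂^i_a`,
`p(S) = Π_i f̂^i_{s_i}`, `L(q-1)` parameters (4,640 at L=232, q=21).
Energies are exact (no normalizer ambiguity).

**Standard VAE.**  A symmetric encoder/decoder MLP over one-hot sequences:
three hidden ReLU layers of 250 units, a 7-dimensional diagonal-Gaussian
latent bottleneck with unit-Normal prior, mini-batches of 200 — 2,697,636
parameters at L=232, q=21.  The decoder's output layer is normalized per
site to a categorical over the q residues and generation draws one residue
per site; independent Bernoulli draws over a one-hot layout need not produce
valid sequences, whereas the per-site categorical guarantees them and
matches the one-hot semantics of the data.  Training maximizes the ELBO with
Adam (1e-3) for a fixed epoch count; the per-epoch loss trace is kept on the
model.  The network is implemented directly on numpy arrays with
hand-written backpropagation, which keeps it dependency-free and exactly
reproducible from one integer seed.

Sequence energies for the VAE are estimated by importance sampling from the
encoder posterior (default 1000 draws, log-domain accumulation); the ELBO is
exposed as a second, cheaper estimator, and on well-trained models the two
correlate above 0.99.  A per-dimension KL activity diagnostic
(`latent_activity`) flags posterior collapse (dimensions with mean KL below
0.01 nats).

## Metrics

All metrics compare an *evaluation* MSA (generated by a model) to a *target*
MSA (drawn from the reference distribution), as pure functions of the MSAs
plus declared seeds.

1. **Covariance correlation** — Pearson ρ over all
   `C^ij_αβ = f^ij_αβ - f^i_α f^j_β` entries (unsmoothed; smoothing is an
   inference device, not part of the observable).  All entries enter,
   including near-zero ones.  The regression slope is reported alongside ρ
   because magnitude shrinkage — characteristic of VAE samples — is
   invisible to a scale-blind correlation.
2. **r20** — for each word length n, random position sets are drawn (3000
   by default, shared across model comparisons via one seed); at each set
   the 20 most frequent words *of the target MSA* are selected (ties broken
   lexicographically for determinism) and the Pearson r between their target
   and evaluation frequencies is averaged over sets.  Sets whose top-k
   frequencies have fewer than three observed words, or zero variance, are
   skipped and counted.  **cc-r20** runs the same pipeline on the connected
   correlations of the same words.
3. **Hamming distribution** — normalized histogram of pairwise distances
   (all pairs up to 2·10⁷, an unbiased random subsample beyond), compared by
   total variation distance `TVD = ½ Σ|f - g|`; a mode-centered, max-
   normalized log-log rescaling exposes the tails.  Mode ties resolve to the
   smallest distance.
4. **Energy correlation** — Pearson ρ between per-sequence `E(S) = -log p(S)`
   of the evaluated model and of the true target on a 1K test MSA.

Connected correlations use the standard partition-cumulant (Möbius) formula
`Σ_P (-1)^{|P|-1}(|P|-1)! Π_B f(B)` over set partitions of the positions; at
order 2 it reduces exactly to `C^ij_αβ`, and it vanishes identically under
site independence — the package's fastest analytic self-check.

**Estimation bounds.**  Finite MSAs bound every score away from its ideal:
the ceiling is measured by drawing two *independent* MSAs from the same
distribution and scoring one against the other.  The API requires two
distinct seeds so a self-comparison can never silently reuse one stream.
Pearson on a zero-variance vector is undefined; such comparisons return 0
with a `degenerate` flag, consistent with reporting zero correlation for a
covariance-free model.

## Synthetic targets and study conditions

The benchmark materializes a known target distribution, draws disjoint
training/target/test MSAs from it on independently seeded streams, fits each
requested model family, and scores the generated evaluation MSAs.

- **Random Potts target** — Gaussian fields (σ = 0.3) everywhere and
  Gaussian q×q coupling blocks (σ = 0.6) on a random 30% of position pairs.
  These scales give clearly detectable pair covariances without frustrated,
  slow-mixing landscapes; the desk-scale default is L=20, q=6 with 100K
  training/target/evaluation sequences.  The intent is a stand-in with the
  statistical character of a family-trained Potts model at a size where the
  whole train → generate → evaluate loop runs in minutes on one CPU; the
  full natural-data scale (L≈232, q=21, millions of sequences) remains
  expressible through the same configuration.
- **Parity (XOR) target** — i.i.d. bits at n_bits sites, the last site their
  parity.  With uniform bits (the default) all pairwise covariances vanish
  exactly while the full (n_bits+1)-point structure is deterministic: the
  canonical distribution no pairwise model can represent.  Uniform parity,
  however, is *invisible to correlation-based scores*: every admissible word
  has the same frequency and the same connected correlation, so both the
  model score and the estimation bound degenerate to comparisons of pure
  sampling noise.  The generator therefore accepts a bit `bias`; at
  bias = 0.35 word frequencies carry real variance, a pairwise fit still
  reproduces every pair statistic (r20 at the bound for n = 2), and the XOR
  structure stays inaccessible (r20 measurably below the bound at n = 3).
  The mis-specification experiments in the acceptance suite use that biased
  variant; the uniform default keeps the analytic worked examples
  (covariances exactly 0, three-point connected correlation 0.125 at
  n_bits = 2).
- **Triplet-injected target** — a random pairwise Potts model plus one
  parity-patterned three-site interaction (strength −1.5).  A fresh pairwise
  fit to its samples scores at the bound for n = 2 and detectably below at
  n = 3, despite only one of the C(5,3) position sets containing the
  triplet.  A *single-cell* triplet on near-uniform binary sites is a much
  weaker probe than one might expect — its third cumulant is small because
  the perturbation is largely absorbed into one- and two-point statistics —
  which is why the parity-patterned tensor is used.

Seeds for every stage derive from one master seed combined with a CRC tag of
the stage name, so enabling or removing a model never perturbs another
stage's stream; reports serialize to sorted-key JSON with no timestamps and
rerun byte-identically.

## What the synthetic conditions do and do not show

The generators produce equilibrium i.i.d. samples of known distributions
with pairwise (optionally three-body) structure over small alphabets.  They
contain no phylogenetic correlation between sequences, no alignment gaps
with insert-state structure, no position-specific conservation profile taken
from a real family, and far smaller state spaces than natural proteins.
Passing tests therefore demonstrate the correctness and sensitivity of the
machinery — samplers against enumeration oracles, inference fixed points,
metric orderings, mis-specification detection — not any claim about a
particular protein family.  Natural aligned FASTA MSAs can be run through
the same pipeline unchanged (a greedy 50%-identity phylogenetic filter is
included; identity counts the gap as an ordinary 21st character, and
positions are 0-based internally, 1-based in user-facing messages).

## Numerical choices and limitations

- Enumeration is capped at `q^L ≤ 10⁷` states; word tables at `q^n ≤ 2²⁴`
  entries (dense bincount).  Beyond either cap the operation raises a size
  error rather than degrading silently.
- Gibbs sweeps update sites in a fresh random order each sweep; chains are
  independent; generation discards a configurable burn-in and thins between
  records.  Equilibration is the user's responsibility for glassy models —
  the report records the sampler settings but the package does not test
  convergence of arbitrary targets.
- The desk-scale Potts MCMC fit typically ends above its stopping tolerance
  (the marginal estimator's own noise floor); the fit report says so
  honestly, and the resulting models reproduce target statistics to the
  precision the benchmark measures.
- The importance-sampling energy estimator is consistent but noisy for
  poorly trained encoders (heavy-tailed weights); the ELBO estimator is the
  robust alternative and their agreement is itself a useful diagnostic.
- Hamming subsampling draws pairs with replacement (unbiased; simpler than
  without-replacement bookkeeping at 10⁷+ pairs).
- The identity filter treats a gap-gap column as a match ("gap is a
  character").  Auditing the opposite convention is a one-line change in
  `identity_violations`; the choice has no effect on synthetic targets,
  which are gap-free.
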