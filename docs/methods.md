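# Methods

## Overview

plfkit re-implements, in portable software, the computational core of a
hardware-accelerated Bayesian phylogenetic analysis: the phylogenetic
likelihood function (PLF) with per-node scaling and root log-likelihood
assembly, two approximate natural-log backends designed for deeply
pipelined datapaths, the double-buffered node store a host would use to
manage a co-processor's memory, an MCMC tree search over clock-constrained
trees that drives the kernel incrementally, and an analytic cost model for
fixed-latency likelihood pipelines. Everything runs offline: a synthetic
data module generates the clock trees and GTR alignments used throughout
the tests.

## Substitution model

Nucleotide states are ordered A, C, G, T everywhere. The GTR rate matrix is
built from six exchangeabilities (AC, AG, AT, CG, CT, GT) and a stationary
distribution pi, with off-diagonals Q_ij = r_ij pi_j, zero row sums, and a
global rescaling so that -sum_i pi_i Q_ii = 1: branch lengths are expected
substitutions per site. Transition matrices P(t) = exp(Qt) are computed by
eigendecomposition of the pi-symmetrized matrix D^{1/2} Q D^{-1/2}, which
reversibility makes symmetric; the decomposition is cached per model so
P(t) is two small matrix products per call. Entries are clipped to [0, 1]
to remove ~1e-17 rounding negatives at tiny t; row sums remain within
1e-12 of 1 without renormalization. Rate heterogeneity, invariant sites
and non-nucleotide alphabets are out of scope.

## Likelihood kernel

Alignment columns are collapsed to distinct site patterns with a
multiplicity vector (`num_sites`); all kernel tables have one row per
pattern. Leaves map IUPAC codes to state-compatibility rows (one-hot for
A/C/G/T, multi-hot for ambiguity codes, all-ones for gaps and N). The
pruning update for parent k with children i, j is

    clP_k[c, N] = (sum_M P_i[N, M] clP_i[c, M]) * (sum_M P_j[N, M] clP_j[c, M])

implemented as two (p x 4)(4 x 4) matrix products and an elementwise
multiply. Every internal node is then scaled: the per-pattern maximum scP
becomes the normalizer (row maxima exactly 1 afterwards) and ln(scP) is
added to a cumulative per-pattern lnScaler vector; a node inherits the
elementwise sum of its children's lnScaler vectors, and leaves start at
zero. Scaling at *every* node (rather than on demand) mirrors a pipeline
that always normalizes; the choice of the row maximum as the scaler is the
one that makes "normalize" produce unit row maxima with an additive log
compensation. The root assembles

    lnL = sum_c num_sites[c] (ln(sum_N pi_N clP_root[c, N]) + lnScaler_root[c]),

with the site sum executed through the pipelined-accumulator emulation
(below). Scaling is exactly compensated: with the exact log backend,
enabling or disabling it changes lnL by < 1e-12 on the test trees.

Two precision modes exist. `double` (default) keeps all arithmetic in IEEE
doubles. `faithful` rounds the conditional, scaler and lnScaler vectors to
the nearest single-precision value after each operation while keeping the
logs and the root accumulation in double — the mixed precision a
single-precision streaming datapath with a double-precision likelihood
stage would exhibit.

### Pipelined accumulator

A deeply pipelined floating-point adder used as an accumulator holds one
partial sum per pipeline stage (depth 14 by default). The emulation
distributes inputs round-robin over `depth` partial sums and then reduces
the partials pairwise in a fixed order. The result is a deterministic
reassociation of the sequential sum; on 1e4 random doubles it agrees with
left-to-right summation to better than 1e-9 relative. Cycle counts of the
hardware coalescing logic are not modeled.

## Natural-log backends

`exact` is numpy's double-precision log.

`chebyshev` splits [1e-32, 1] into 16 segments of two decades each
(consecutive boundaries ratio 100; 1.0 is included in the last segment,
x = 1e-3 falls in segment 15). The lower limit reflects the observation
that scaled likelihood values in practice stay above 1e-32; inputs below
it raise an out-of-range error by default, because silently extrapolating
is exactly the failure mode that derails searches. Per segment, the
truncated Chebyshev series of ln(x) of length 5 is generated at 60
significant digits (64-node Chebyshev quadrature for the inner products)
and expanded to monomial coefficients c0..c4 in raw x, stored as doubles
— the small-x segments need coefficient magnitudes around 1e121, far
beyond single precision, which is why the table is double-only. Evaluation
computes x^2, x^3 = x^2 x, x^4 = x^2 x^2 and the dot product with the
segment's coefficients; segment selection is a 4-level binary comparison
over the boundaries (vectorized evaluation uses a sorted search that the
tests pin to the scalar comparison network).

Two measured facts about this construction matter downstream:

* **Self-similarity.** ln(100 a u) = ln(100 a) + ln(u), so every segment
  poses the same fitting problem up to its constant term. The measured max
  error is 0.51451 nats in every segment, and the error curves coincide
  after log-x alignment.
* **Accuracy is intrinsically limited.** For ln over [a, 100a] mapped to
  [-1, 1], the Chebyshev coefficients decay only like (99/121)^k, so a
  5-coefficient truncation leaves ~0.51 nats of error and even a minimax
  fit of the same degree would leave ~0.15. The fit is also not monotone
  over roughly the last 7% of each segment, where the truncation wiggle
  exceeds the flattening slope of ln; boundary discontinuities stay within
  twice the per-segment max error. Consequences for search quality are
  discussed under Limitations.

`desoras` is the classic bit-manipulation fast log: extract the IEEE 754
single-precision biased exponent E and mantissa m in [1, 2), approximate
log2 x by (E - 128) + (-m/3 + 2)m - 2/3, and multiply by the stored
decimal constant 0.69314718. The quadratic is exact at m = 1, so powers of
two incur only the ~6e-10 error of the ln 2 constant. Measured max error
over [1e-9, 1] is 6.73e-3 nats. Inputs below a hard clamp threshold
(1e-10 by default) return exactly 0. Matching how this approximation is
deployed in practice, the backend serves only the scaler log; the root
log-likelihood keeps the exact log. The chebyshev backend is used for both
logs, as a hardware pipeline would be.

## Node store

Per-(chain, node) records (conditional table, scaler vector, transition
matrix) live in a store with two slots per node, "pending" and
"committed". Proposal evaluation writes pending slots only; acceptance
swaps the slot handles for the touched nodes in O(1) with no data copy
(instrumented: the copy counter must stay zero), and rejection simply
clears the pending flags. The committed view is therefore never mutated
in place, which is what makes rejection exact. Memory-bank layout, DMA
timing and address arithmetic of a real co-processor are not modeled;
addresses are opaque handles.

## MCMC search

The state is a rooted binary clock-constrained tree (all root-to-leaf
paths equal; branch lengths derived from node ages) plus a fixed GTR
model. Three moves:

* clock-preserving NNI (swap a child of p with p's sibling, valid when
  p is older than the sibling), drawn uniformly from the currently valid
  moves; Hastings ratio = (valid moves before)/(valid moves after);
* node-age slide, uniform between the oldest child and the parent
  (symmetric, Hastings 0);
* root-age multiplier exp(tuning (u - 1/2)) with Hastings ln m.

Default mixture 0.4/0.4/0.2; the root-scale tuning constant is 0.5.
Priors: uniform over topologies; non-root internal ages i.i.d. uniform on
[0, root age] restricted to valid orderings with a common normalizer (so
topology moves carry no age-prior ratio); exponential root age with
configurable mean (default 0.5, the synthetic generator's default tree
height) to keep the joint density proper. The Metropolis-Hastings rule is
min(1, exp(lnL ratio + prior ratio + Hastings ratio)); a two-state toy
chain driven by the same rule reproduces its stationary distribution to
within Monte Carlo error in the tests.

Only dirty nodes — those whose conditional tables a move invalidates,
closed upward to the root — are recomputed, into pending store slots; the
cold-chain lnL is cached so rejection costs nothing further. An audit mode
recomputes the likelihood from scratch every k generations and asserts
agreement to 1e-8, which pins the incremental path to the full evaluation
for every backend and precision mode. Metropolis coupling runs chain i at
heat 1/(1 + 0.1 i), exponentiating the posterior term; adjacent chains
propose heat swaps every 10 generations with the standard coupled ratio.
With one chain the coupled driver consumes the identical random stream as
the single-chain driver, so the two are bitwise equal.

Substitution-model parameters are held fixed during a run
(fixed-at-truth validation mode); sampling exchangeabilities is out of
scope.

## Tree statistics

Splits are taxon bipartitions induced by internal edges of the unrooted
interpretation, canonicalized as the side not containing the
lexicographically first taxon; trivial splits are dropped. Majority-rule
consensus keeps splits above 0.5 frequency (they necessarily nest) and
annotates each consensus node with its frequency. ASDSF follows the usual
convention: for every split reaching 0.1 frequency in at least one run,
take the sample standard deviation (ddof 1) of its frequency across runs
and average; < 0.1 is the convergence cutoff used throughout.
Robinson-Foulds distance is the size of the symmetric difference of the
split sets; the native implementation is cross-checked against dendropy's
bipartition machinery in the tests.

## Synthetic data

Topologies come from a forward Yule process (uniformly chosen lineage
splits at exponential waiting times), which is ultrametric by
construction; ages are rescaled so the root age equals the requested tree
height and leaf labels are attached in rng-permuted order so that labels
carry no shape information. Alignments evolve site-independently from
root states drawn from pi through the model's transition matrices;
sequences are gapless by default, with an optional i.i.d. N-injection
rate. Fixing the seed reproduces trees and alignments bitwise.

Default study conditions, chosen once: 8 taxa, tree height 0.5
(substitutions per site root-to-tip — enough divergence to be informative
without saturation), 2000 sites for the search-quality studies, Jukes-
Cantor unless a test needs unequal rates. What the generator does *not*
emulate: indels and alignment error, rate variation across sites and
lineages, model misspecification, and base-composition heterogeneity —
so passing searches here demonstrate kernel and sampler correctness, not
robustness to real-data pathologies.

The `transversion_trap_dataset` is a deliberately adversarial fixture for
the fast-log clamp: transversion exchangeabilities are set to 1e-7, a
near-identical transition-only background (height 0.005) pulls posterior
branch lengths toward ~1/length, and the topological signal is carried by
clade-marker transversion sites (C inside a true clade, A outside).
Merging a marker across its clade boundary gives a per-pattern scaler of
roughly (1e-7 x branch length) < 1e-10, so a clamped log erases precisely
the penalties that anchor the topology.

## Cost model

The accelerator-time model treats the likelihood datapath as a
fixed-latency pipeline emitting one character result per cycle:
t = (L_nr lambda + lambda c)(1 - r) + (L_r lambda + lambda c) r, with clock period lambda,
sequence length c, root-evaluation fraction r, and per-device non-root /
root latencies (built-ins: 119/251 cycles at 165 MHz, 109/261 at
310 MHz). The (1 - r) weighting is applied for both device profiles (one
published variant of the formula omits it; the weighted form is the one
that reproduces the published 310 MHz column). Outputs are rounded
half-up to 0.1 µs. For the built-in benchmark rows the model reproduces
the published per-node times except one dataset (m346), whose published
cell is inconsistent with its own (c, r) inputs by about 1 µs — that cell
is excluded from automated checks. Host-transfer setup time and software
baselines are not modeled.

## Numerical choices and degenerate inputs

* A conditional-likelihood row of exact zeros raises an underflow error
  naming the pattern; so does a non-positive root site likelihood.
* Branch length 0 yields the identity transition matrix; negative lengths
  are rejected.
* `pipelined_accumulate([])` is 0; single-element input returns it.
* x = 1.0 is assigned to the last Chebyshev segment (the domain is
  (0, 1]); inputs below 1e-32 raise rather than clamp by default.
* Ties in the scaler maximum are harmless: any attained maximum gives the
  same scP.
* Root-age proposals that would drop the root below its children are
  rejected outright (out of prior support).

## Problem sizes used in the checks

The enumeration-oracle comparisons use up to 5 taxa and 8 patterns
(4^4 = 256 internal assignments per pattern). The search-quality study
uses five 8-taxon 2000-site datasets with 50k-generation runs (two exact
chain seeds plus one chebyshev run each); the fast-log divergence study
uses the 10-taxon trap dataset with two 15k-generation runs per backend.
These sizes were chosen so the full study remains a desk-scale
computation while leaving the posterior well resolved.

## Known limitations

* **The piecewise-Chebyshev backend visibly perturbs inference on
  strongly resolved data.** With ~0.5-nat log errors entering both the
  scaler and root logs, relative log likelihoods between topologies shift
  by several nats. On the 8-taxon study datasets — where independent
  exact-backend runs agree perfectly (seed-pair RF 0) — the chebyshev
  consensus differs from the exact consensus by RF 0-10 depending on the
  dataset. The corresponding acceptance check is intentionally left
  failing rather than weakened: a 5-coefficient polynomial per two-decade
  segment cannot be made accurate enough for the bound as stated, and on
  sharply peaked posteriors "no worse than between-run noise" collapses
  to demanding exactness. On weakly resolved posteriors (many taxa, few
  informative sites) the same backend's distortion is comparable to
  run-to-run variability, which is the regime where such approximations
  earn their keep.
* The sampler's move set is minimal (NNI + age slide + root scale);
  mixing on large or multimodal posteriors would benefit from subtree
  moves and tuned proposals.
* The faithful precision mode rounds stored vectors per operation but
  does not emulate fused-multiply-add or accumulation-order differences
  of any specific hardware.
* Pattern compression treats ambiguity codes as distinct characters; two
  columns equal up to ambiguity semantics are not merged.
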