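# plfkit

A software re-implementation of a hardware-style phylogenetic likelihood
pipeline: the Felsenstein-pruning kernel with per-node scaling and root
log-likelihood assembly, pluggable natural-log backends (exact, a
16-segment piecewise-Chebyshev approximation, and the de Soras fast log
with its hard 1e-10 clamp), a double-buffered pending/committed node
store, a Bayesian MCMC search over clock-constrained trees that drives the
kernel incrementally, split-based diagnostics (majority-rule consensus,
ASDSF, Robinson-Foulds), and an analytic cost model that predicts per-node
accelerator time for fixed-latency pipelines.

It is aimed at people studying how arithmetic approximations and
pipeline-oriented restructurings of the phylogenetic likelihood function
(PLF) affect Bayesian tree inference — without needing the hardware: every
stage is testable offline against exact oracles and synthetic data.

## The core computation

For a rooted binary tree, model transition matrices P(t) = exp(Qt) under
GTR (branch lengths in expected substitutions/site), and compressed site
patterns c with multiplicities numSites[c], the kernel computes, per
internal node k with children i and j,

    clP_k[c, N] = (Σ_M P_i[N,M] clP_i[c,M]) · (Σ_M P_j[N,M] clP_j[c,M]),

normalizes each pattern row by its maximum scP[c] (accumulating ln scP
into a running lnScaler vector), and assembles at the root

    lnL = Σ_c numSites[c] · ( ln Σ_N π_N clP_root[c,N] + lnScaler_root[c] ),

with the site sum run through a deterministic emulation of a 14-stage
pipelined accumulator. The MCMC driver proposes clock-preserving moves,
recomputes only the invalidated nodes into pending store slots, and
commits or rejects by handle swap — the accept/reject rule is standard
Metropolis–Hastings, min(1, exp(ΔlnL + Δln prior + ln Hastings)).

The cost model predicts the average accelerator time per tree node as
(L_nonroot·λ + λc)(1−r) + (L_root·λ + λc)·r for clock period λ, sequence
length c and root-evaluation fraction r.

## Worked example

```python
import plfkit as pk

spec = pk.SimSpec(n_taxa=8, tree_height=0.5, alignment_length=1000, seed=42)
tree, seqs = pk.simulate_dataset(spec)          # clock tree + GTR alignment
data = pk.compress_alignment(seqs)              # site patterns + numSites

for backend in ("exact", "chebyshev", "desoras"):
    print(backend, pk.tree_log_likelihood(tree, pk.GTRParams.jc(), data, backend))
```

prints

```
exact -6340.298584622701
chebyshev -6542.316546992716
desoras -6337.954861880169
```

The exact value is the reference log likelihood of the true tree. The
chebyshev backend (max error ≈ 0.51 nats per log call, the intrinsic
limit of a 5-coefficient polynomial per two-decade segment) shifts lnL by
a few hundred nats at this size; the de Soras backend, whose smooth-region
error is below 7×10⁻³ nats and which only serves the scaler log, stays
within a few nats. Absolute shifts are harmless in themselves — MCMC only
consumes likelihood *ratios* — and `examples/fast_log_failure.py` shows
the case that is not harmless: the de Soras 1e-10 clamp erases
branch-length penalties and makes independent runs stop converging
(ASDSF 0.139 vs 0.000 for the exact log on the same data).

The same functionality is exposed as a CLI:

```bash
plfkit simulate --taxa 8 --sites 1000 --height 0.5 --seed 42 --out demo
plfkit lnl --tree demo.nwk --align demo.fasta --backend chebyshev
plfkit mcmc --align demo.fasta --ngen 20000 --nruns 2 --seed 1 --out runs/
plfkit consensus runs/run1.nwk runs/run2.nwk --out cons.nwk
plfkit rf cons.nwk demo.nwk
plfkit costmodel --device v2p --chars 963 --rootratio 0.038   # -> 6.6
```

Each script in `examples/` is a short narrative demo of one capability
(kernel backends, log-approximation profiling, MCMC search, cost model,
fast-log failure reproduction).

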