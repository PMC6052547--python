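# Methods

## The problem and the model

A sequence profile (PSSM) records, for every site of a protein sequence, a
20-dimensional probability column over amino-acid types — the per-site
evolutionary preferences that similarity searches, alignment tools and many
downstream predictors consume. Profiles are classically built by iterative
database search, whose cost scales with the database; a *de novo* generator
instead predicts the profile from the single input sequence, in time linear
in its length.

profgen's generator is a causal recurrent network. Residue t (a symbol from
the 20-letter alphabet) is embedded as a dense d-dimensional vector
u_t = E[x_t]; a single LSTM layer with input, forget and output gates around
a constant-error memory cell consumes u_1..u_t and produces v_t; a fully
connected layer maps v_t to 20 logits whose softmax is the predicted column
for site t:

    i_t = σ(u_t W_i + h_{t-1} R_i + b_i)
    f_t = σ(u_t W_f + h_{t-1} R_f + b_f)
    z_t = τ(u_t W_z + h_{t-1} R_z + b_z)
    o_t = σ(u_t W_o + h_{t-1} R_o + b_o)
    c_t = f_t ∘ c_{t-1} + i_t ∘ z_t
    v_t = h_t = o_t ∘ τ(c_t)
    y_t = softmax(v_t W_fc + b_fc)

The recurrent state (h, c) starts as the null vector at the N-terminus, so
y_t is a function of residues 1..t only. Both recurrent quantities are
treated as "the memory": the memory-reset mode (below) clears both.

The forward pass, backpropagation through time and Adam are implemented
directly in NumPy. The analytic gradients are verified against central
finite differences in the test suite (1e-5 relative tolerance on a tiny
model at 64-bit precision).

### Parameters that matter

| parameter | meaning | reference value | scaled-down experiments |
|---|---|---|---|
| d | embedding dimension | 400 | 16 |
| H | LSTM gate unit size | 3200 | 64 |
| batch size | sequences per update | 200 | 100 |
| epoch subsample | sequences per epoch | 40 000 | full training pool |
| epochs | updates budget | 5000 | 30–130 |
| dropout | on embedding output, train only | 0.5 | 0.5 (0 for the long-range probe) |
| cost | RMSE between softmax output and target | — | — |
| optimizer | Adam | lr 1e-3 | lr 3e-3 |

The reference values define the full-scale configuration; every experiment
in this package runs the identical code at the scaled-down sizes, which keep
each training run in the one-to-two-minute range on a single CPU.

Initialisation: Glorot-uniform input weights, orthogonal recurrent blocks
per gate, forget-gate bias +1 (the standard recipe that biases early
training toward retaining memory), embedding rows uniform(−0.1, 0.1). The
padding symbol's embedding row is pinned to zero and excluded from
gradients; padded positions are masked out of the cost.

### Numerical choices

- 64-bit arithmetic by default; the training backend can run in 32-bit
  (`TrainingConfig.dtype="float32"`), roughly halving time and memory.
  Row-normalisation invariants hold to 1e-9 at 64-bit and 1e-5 at 32-bit.
- Softmax and sigmoid use the standard max-shift / two-sided stable forms.
- The RMSE cost is undefined-gradient at exactly zero loss; the backward
  pass returns zero gradients there (the optimum has been reached).
- Training batches are bucketed by length (sort, then chunk) to limit
  padding waste; this reorders sequences within an epoch but is fully
  deterministic under the config seed.
- Divergence (non-finite loss) aborts training with a diagnostic rather
  than continuing.

## Truncated memory ("memory reset")

A predictor with memory reset length L generates the column at site t from
the previous L sites including the current one: the window
max(1, t−L+1)..t is re-run from the null state and the final output row is
kept. L ≥ N reproduces the full forward pass bit for bit. This is a
per-site sliding window, not a block reset, matching the definition of
"profiles based on information from the previous five sites, including the
current site". The truncated mode is an analysis tool applied to a model
trained at full context; it quantifies how much of the model's performance
depends on memory longer than L.

## The synthetic teacher

Full-scale training imitates profiles produced by iterative HMM searches
over millions of sequences — out of reach at desk scale. The synthetic
teacher replaces that target distribution with a generative rule whose
context dependence is exactly known:

- Each site carries a hidden environment state e_t ∈ {1..n_states}; each
  state owns a fixed probability column drawn once from a symmetric
  Dirichlet(α). The target row at t is the column of e_t, and the residue
  at t is sampled from it.
- e_t is a *deterministic hash* of the previous context_k residues,
  optionally persisted from the previous site with hash-derived
  pseudo-probability ρ (run-length control), and in long-range mode
  determined by the residue at t−Δ (sites before Δ share one state).
  Determinism makes the teacher rule itself the Bayes-optimal predictor, so
  cosine-similarity ceilings are known (1.0), and causality matches the
  generator's: the target at t never depends on residues after t.

Defaults: n_states = 4, context_k = 2, ρ = 0, α = 0.5, lengths uniform in
[50, 100]. ρ defaults to zero so the dependency range is exactly context_k
(or Δ), keeping the memory-length experiments sharp; nonzero ρ is available
for more realistic environment run lengths.

What the teacher does *not* emulate: real profiles have position-correlated
column shapes driven by structure and evolution, gapped alignments,
length-dependent alignment depth, and 20-way preferences that are not
exchangeable across the alphabet. Passing the recovery experiments shows
the architecture and training loop can extract context-dependent rules of
the stated range from sequence alone — not that the scaled-down model would
produce search-grade profiles for real proteins.

## Experiments

**Recovery** (`experiments.recovery_experiment`): teacher with context_k=2;
2000 training pairs, 200 held-out; d=16, H=64; 70 epochs, batch 100, Adam
lr 3e-3, dropout 0.5, random-start cropping, 32-bit backend (~1.5 min on
one CPU). Reported: mean positional cosine on held-out pairs, the
context-free baseline (the single fixed column maximising mean cosine —
proportional to the mean of norm-normalised target rows, computed on the
training targets), and the mean-by-position cosine curve.

The curve's first context_k positions score below the plateau: training
crops start at random sites, so the residues determining a crop's first
sites lie before the window and the model can only learn an averaged
prediction for the first steps after a null state. This is the synthetic
analogue of the early-sequence accuracy deficit of a null-initialised
recurrent generator.

**Memory power** (`experiments.longrange_experiment`): teacher whose column
at t is dictated by the residue at t−Δ with Δ=20 (a β-strand-like pairing);
n_states=4, α=0.2; 1000 training pairs, 100 held-out; d=16, H=64, 60
epochs, no dropout, no cropping (~1–2 min per run). Three deliberate
design choices serve the probe: sharper columns (α=0.2) keep the hidden
states well separated so the gain ceiling (1 − baseline ≈ 0.3) has dynamic
range; dropout is off because a single distant residue carries the whole
signal, and dropping it converts training examples into noise; cropping is
off because a crop's first Δ sites would have their determining residue
hidden. The same trained model is evaluated at full context and with
memory reset L=5: full context recovers the long-range rule (gain ≳ 0.15
over the fixed-column baseline, averaged over 3 seeds), while the L=5
window — which can never see site t−20 — stays within noise of the
baseline.

**Linear work**: the forward pass performs exactly one LSTM step per
residue; the log-log slope of step count versus length is exactly 1. This
is the algorithmic counterpart of linear profile-generation time; wall-clock
timing on any particular machine is outside the test surface.

## Evaluation metrics

- **Positional cosine**: cos(y_t, target_t) per site; dataset aggregation
  averages per position over the pairs that reach that position.
- **TP/FP/unknown labeling**: same superfamily → TP; different fold or
  class → FP; same fold but different superfamily → unknown; self-hits →
  unknown. (The cited benchmark ruleset reduced to the standard SCOP
  convention.)
- **Weighted ROC**: hits sorted by e-value ascending (stable ties); each
  counted hit adds 1/|query superfamily| to its axis. One FP per query
  therefore totals the number of distinct superfamilies.
- **pAUC**: trapezoidal area for weighted FP ∈ [0, fp_limit], interpolated
  at the cutoff (the step curve makes trapezoid = rectangle sum, so an
  independent rectangle oracle agrees to 1e-12), extended horizontally if
  the curve ends before the budget, normalized by fp_limit × tp_max so the
  statistic lies in [0, 1]. The default budget is the superfamily count
  (one weighted FP per query on average).

## File formats

- **HHM dialect**: match-state emission scores are integers −1000·log2(p),
  `*` = probability zero; rows renormalised after decoding (decode error ≤
  1e-3 from quantization). The producing tool family's published layout.
- **PSSM dialect**: per 1-based position, consensus residue (argmax),
  half-bit log-odds round(2·log2(p/q)) with p clamped at 1e-4, frequency
  percentages, then a full-precision frequency block that makes the round
  trip lossless (≤ 1e-9). Background q is a required input with a uniform
  0.05 default; no empirical background is hard-coded because none is
  canonical for this conversion.
- Columns everywhere follow the alphabetical one-letter order
  `ACDEFGHIKLMNPQRSTVWY`; positions are 1-based in files, 0-based in
  arrays.

## Known limitations

- The delivered experiments are scaled down by design; headline benchmark
  numbers from full-scale searches (SCOP-wide pAUCs, wall-clock timings)
  require external search tools, benchmark databases and weeks of GPU
  training, and are not reproduced here.
- Single-direction prediction only: columns early in the sequence are
  predicted from little context (the deficit quantified above); combining
  N- and C-terminal passes is out of scope.
- The NumPy training loop is single-process; the reference configuration
  (d=400, H=3200, 40k-sequence epochs) is expressible but not practical on
  one CPU.
- The synthetic teacher's caveats above bound what desk-scale results say
  about real sequence data.
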