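# Methods

## Model

The package treats annotation completion as unsupervised density modelling
of a binary protein × GO-term matrix. A restricted Boltzmann machine (RBM)
assigns each joint configuration of visible units `v` (terms) and hidden
units `h` (latent functional features) the energy
`E(v,h) = −a·v − b·h − vᵀWh`; the bipartite structure makes the
conditionals logistic and block Gibbs sampling cheap. The maximum-likelihood
gradient for a weight is the difference of data and model expectations of
`vᵢhⱼ`; contrastive divergence (CD-1) approximates the model expectation
with a one-step Gibbs reconstruction of the minibatch.

The deep model stacks RBMs greedily: layer 1 trains on the annotation
matrix, each further layer on the hidden activation *probabilities* of the
layer beneath (probabilities rather than samples: the standard
lower-variance choice). There is no global fine-tuning pass after stacking.
At inference the stack is unfolded into a deterministic mean-field pass —
probabilities up through every layer, then down through the transposed
(tied) weights — and the downward visible probabilities are the association
scores. A score's only use is to rank candidate pairs, so any per-column
monotone distortion (e.g. dropout scaling) leaves the ranking metrics
unchanged.

### Assumptions

- Annotations are true-path closed before modelling; every matrix entering
  the model is closed under the ontology's `is_a`/`part_of` parent
  relations (part_of propagation can be switched off).
- Prediction is transductive: the model scores the same protein rows it was
  trained on. A temporal split evaluates those scores against annotations
  added in a newer snapshot, restricted to the training universe, because
  the model cannot score proteins or terms it never saw.
- Scores are compared only against the zero-entries of the training matrix;
  known annotations are never candidates.

## Training hyperparameters

| parameter | default | notes |
|---|---|---|
| learning rate ε | 0.01 | per CD update, applied to the batch-mean gradient |
| epochs | 25 | full passes over shuffled rows |
| CD steps k | 1 | one Gibbs reconstruction |
| batch size | 100 | conventional minibatch size |
| weight decay λ | 1e-4 | L2 on W only, not biases (standard practice) |
| dropout | 0.5 | hidden layer only |
| init | uniform01 | W ~ U(0,1); `gaussian` (σ = 0.01) also first-class |
| hidden widths | halving | `max(1, floor(c/2))` per layer, 5 hidden layers |

Dropout uses one shared Bernoulli mask per minibatch applied to the hidden
units of both the data and reconstruction phases; because both gradient
terms see the same mask, no rescaling is needed during training, and at
inference hidden activations are scaled by the keep-probability. The
reconstruction is sampled binary from the visible conditional, while both
correlation terms use hidden probabilities (low-variance estimator).
Uniform(0,1) initialisation is the package default; all-positive initial
weights start the hidden units deep in saturation on dense matrices, so the
small-instance tests and synthetic-recovery runs use the gaussian
initialiser. "Iterations" are read as epochs (configurable via `epochs`).

## Numerical choices

- Sigmoid inputs are clipped to ±500 (inert at double precision — expit
  saturates far earlier) and outputs are kept strictly inside (0,1), so
  cross-entropies never produce log(0).
- Exact enumeration (partition function, likelihood, gradient) refuses
  instances with more than 20 total units and uses log-sum-exp throughout.
- Fmax sweeps the threshold grid 0.00…1.00 in steps of 0.01 and returns the
  smallest arg-max threshold on ties; the tests bound the discretisation
  error against an exact sweep over the distinct score values.
- AUC and ranking loss follow the Mann–Whitney convention: tied pairs count
  one half. Terms (or proteins) with a single class present are excluded
  from the per-term (per-protein) averages rather than scored 0, with
  counts logged.
- MacroAvgF1 binarises at 0.5 by default (exposed as a flag; reports record
  the threshold used) and averages over terms with at least one true
  positive.
- The halving layer planner clamps widths at 1 so tiny ontologies remain
  trainable end to end.

## Preprocessing rules

Obsolete terms are dropped before any edge construction and annotations to
them are discarded with a warning. Both `is_a` and `relationship: part_of`
become propagating parent edges; cross-namespace parent edges are dropped
with a warning. IEA-evidence annotations (electronic, hence potentially
circular for this task) and NOT-qualified records are excluded by default.
After true-path closure, the three namespace roots (GO:0008150, GO:0005575,
GO:0003674 — annotated to nearly everything, hence uninformative) and terms
with no annotated protein are removed; proteins left without annotations
are dropped. Matrices are built per subontology (BP, CC or MF); namespaces
are never mixed. Protein identity is GAF column 2 (DB object ID) with no
cross-database mapping; duplicate records collapse to a single 1.

## Synthetic benchmark

The generator emulates the statistical regime of real annotation data
without imitating any particular species:

- **DAG**: single root; each non-root term draws `max(1, Poisson(1.5))`
  parents uniformly from earlier terms. Mean parent count 1.5 mirrors the
  sparse multi-parent character of GO; uniform attachment gives a mix of
  deep and shallow terms.
- **Annotations**: latent modules (a stochastic block model over leaf
  terms) give masked entries genuine, recoverable signal — each module owns
  a random set of leaf-ward terms, each protein joins each module
  independently, and a protein's specific annotations are the union of its
  modules' terms plus rare spurious leaves (noise rate 0.01/leaf). Rows are
  the true-path closure of the specific annotations.
- **Masking**: each most-specific annotated term is hidden with probability
  ρ (default 0.2) and ancestors supported only by masked terms are pruned,
  so the training matrix stays closed — mimicking incompleteness, which in
  real data removes specific leaves, not arbitrary entries. Proteins that
  would lose everything are resampled (bounded retries).

What this does *not* emulate: real GO degree distributions, per-species
term counts, evidence-code heterogeneity, or annotation biases that
correlate with protein families. Passing recovery tests on this benchmark
shows the pipeline learns planted co-annotation structure; it does not
certify accuracy on any particular organism's annotation corpus.

Default problem size for the recovery benchmark and the acceptance script:
500 proteins × 200 terms, 10 modules of 5 terms, join probability 0.2,
depth-2 stack — small enough to run in seconds on one CPU while leaving
thousands of masked pairs to recover.

## Known limitations

- CD-1 with a small learning rate and few epochs underfits: at the
  benchmark's default budget (ε = 0.01, 25 epochs, batches of 100 over 500
  proteins — 125 updates) the per-term recovery AUC is barely above chance
  (~0.52–0.54), although it strictly beats the prevalence baseline. The
  same code reaches ~0.73–0.81 with longer schedules (see the worked
  example and the masking-sanity tests, which size their training budgets
  accordingly). The acceptance script deliberately reports the default
  budget unchanged.
- The per-term average AUC on this benchmark also has a structural ceiling
  near ~0.8: terms whose masked positives arise from the spurious-leaf
  noise process are unpredictable by construction and contribute ~0.5 each
  to the average (a converged truncated-SVD reference lands at ~0.78 on the
  same split).
- No persistent CD, momentum, supervised fine-tuning or GPU path; models
  are stored as plain JSON, which is comfortable up to a few thousand terms
  but not beyond.
- The evaluation protocol scores all zero-entries of the training universe;
  an alternative (restricting to terms present in both snapshots) would
  change the negative set and is not implemented.
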