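# Methods

## Model

The WRKY drought pathway is a discrete Bayesian network over eight binary
nodes (1 = activation, 0 = inhibition). The structure is fixed from the
biology — no structure learning is attempted, both because public
expression data for WRKY under abiotic stress are scarce and because four
of the nodes are protein complexes with no expression signal at all. The
joint distribution factorizes into one Bernoulli conditional per node given
its parents:

| node | parents | biology |
|------|---------|---------|
| A | — | WRKY18, ABA-induced TF, promotes drought response |
| B | — | WRKY40, ABA-induced TF, antagonist |
| C | A, B | WRKY18-40 heterocomplex |
| D | A | WRKY18-18 homocomplex (activator of H) |
| E | B | WRKY40-40 homocomplex (repressor of H) |
| F | C | WRKY60, induced via the heterocomplex |
| G | F | WRKY60-60 homocomplex (activator of H) |
| H | D, E, G | downstream drought-response gene |

Node identity is the single letter; the biological labels are display
metadata, overridable from config, because the complex identities are
inferred from pathway context rather than stated outright.

Inference is exact full enumeration of the 2⁸ = 256 joint states. The
moralized graph is loopy and not singly connected, so message passing is
not applicable; at this size enumeration is both simpler and exact.
Probabilities are handled in linear space (underflow is impossible at 8
factors) and all iteration is in sorted node-id order, so every result is
bit-stable across runs.

## Data and the synthetic generator

Real expression data exist only for the gene nodes A, B, F, H. The
preprocessing stage normalizes each dataset separately (default per-gene
z-score; `minmax` and `none` are config options — the normalization used
for the original composite is not documented, so the choice is exposed and
logged rather than claimed), binarizes each gene at its own mean or median
(strictly greater than the threshold maps to 1; ties map to 0,
deterministically), and concatenates the datasets row-wise into one
composite. The study-scale composite has 116 observations; the simulation
fixtures default to the same size. The per-dataset sample counts composing
the original 116 are not published; the test fixtures use 40 + 40 + 36.

The protein-complex columns C, D, E, G are then synthesized from their
observed network neighbours. Each complex node has a rule table over the
configurations of its conditioning nodes (parents and children among the
observed columns):

* configurations fully consistent with the complex being active (or
  inactive) are set deterministically — e.g. D (activated by A, activating
  H) is 1 whenever A=1 and H=1, and 0 whenever A=0 and H=0;
* mixed configurations are assigned the biologically favoured value `v`
  with probability `p`, else `1−v`, where `p` is drawn uniformly from the
  discrete set {0.6, 0.7, 0.8, 0.9, 1.0} (mean 0.8).

Two readings of the probability draw are possible; the generator draws a
fresh `p` per observation (one draw per assignment event), with a single
per-column draw available behind `per_column=True`. Assignment of 0-valued
targets uses the same probability set symmetrically. Each complex node
consumes its own seeded random stream keyed by (run seed, node), so the
order in which columns are synthesized cannot change any value.

What the generator does and does not emulate: it reproduces the dependency
structure linking complexes to their observed neighbours and the
calibrated assignment noise, but the simulated gene columns are i.i.d.
draws from the network itself — real microarray composites carry batch
effects, platform differences and normalization artifacts that the
generator does not model. Passing tests therefore validate the procedure
and its calibration, not the biology of any particular GEO series.

`generate_composite` returns both the fully sampled ground truth and the
pipeline-style dataset (real-tagged gene columns + re-synthesized complex
columns), which is what makes parameter-recovery and procedure-consistency
tests possible.

## Parameter estimation

Counts (n, k) per node and parent configuration are the sufficient
statistics. The Bayesian branch uses the conjugate Beta-Binomial update:
prior Beta(α, β) (default the flat Beta(1,1); per-entry informative priors
are accepted), posterior Beta(α+k, β+n−k), point estimate the posterior
mean. With the flat prior this is (k+1)/(n+2): strictly interior to (0,1)
for any finite data, so downstream enumeration never divides by a
structural zero. The MLE branch reports k/n and flags unobserved
configurations (n=0) as undefined rather than silently substituting 0 or
0.5; the pipeline's downstream default replaces an undefined MLE entry
with the corresponding Bayesian estimate and logs the substitution. The
point estimate is the posterior mean, not the mode — exposed but fixed by
default.

The sink H deserves a note: the published local-probability table omits
H's conditionals, and because the utility scope is H's parent set (see
below) every expected utility marginalizes H out — the intervention
ranking is invariant to H's CPT. Injected published-style parameter tables
therefore fill H with a neutral 0.5 CPT; the simulation ground truth
(`wrky_reference_parameters`) instead uses a biologically shaped H CPT
(high activation probability when D and G are on and E is off, mirrored
at the other extreme) so that forward-sampled data exercise all of H's
configurations.

## Decision inference

An intervention do(X=x) mutilates the network: X's incoming edges are
severed and its conditional becomes a point mass. For root nodes this
coincides with conditioning; for interior nodes the do-semantics reading
matches the modelling intent that an acted-on node "becomes deterministic".
The expected utility of an action is the utility-weighted sum of the
outcome distribution over the scope (G, D, E) — the drought gene's
regulators, computed exactly in the mutilated network. The utility table
scores activator-on/repressor-off configurations highest (100) down to the
mirror image (0); utilities are dimensionless relative scores and no
normalization is applied. EU is exactly equivariant under adding a
constant to all utilities, and monotone in each single utility entry.

All 14 actions (7 candidate nodes × activate/inhibit) are evaluated and
sorted by EU, descending, with deterministic (node, action) tie-breaks.
The per-node maximum over the two actions is also reported, matching the
usual "maximum expected utility per node" bar-chart presentation.

## Numerical choices and test scales

* Joint-table normalization is asserted to 1e-12; engine-vs-oracle
  equivalence to 1e-10 (pure-Python enumeration oracle in the test suite).
* Stochastic checks use 3-binomial-standard-error bands: parameter
  recovery runs at 20,000 forward-sampled observations (every one of the
  22 entries recovered by both estimators; the two estimators agree to
  <0.01), synthesis fidelity at 10,000 rows (zero deterministic-rule
  violations; Assign-row frequencies within the band around 0.8).
  These sizes give tight bands while keeping the default suite fast.
* Degenerate inputs: zero-variance genes are centred (not scaled) with a
  warning; binarization ties map to 0; evidence of probability zero raises
  a dedicated error rather than returning 0/0; MLE n=0 entries are flagged,
  never imputed.
* Reproducibility: a single run seed drives named sub-streams (sampling vs
  per-node synthesis), so reruns with the same config and seed are
  byte-identical and column/synthesis order never matters.

## Limitations

* The composite of real GEO series is out of scope (no downloading or
  platform annotation handling); the preprocessing stage is validated on
  synthetic expression matrices only.
* Single-node interventions only; multi-node action spaces and utility
  elicitation are not modelled.
* Only point estimates feed the decision stage; posterior uncertainty is
  not propagated into the EU ranking.
* The published numeric EU values exist only as chart bars, so the package
  pins the printed worked-example EUs exactly and asserts the full-network
  result at the level of the reported ordering.
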