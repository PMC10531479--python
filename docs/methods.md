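# Methods

`fdtox` models the propensity of fullerene derivatives (FDs) — C60-type
carbon cages decorated with small functional groups — to bind proteins
implicated in aquatic toxicity. The observable is a set of 12 docking-style
binding scores per compound (an average over a large human-protein panel, a
best-complex binding affinity, and scores for ten PDB proteins with close
orthologues in fish and amphibians), consumed as data: the package never
computes docking scores. Around those responses it implements four modeling
layers — structure-derived descriptors, a Monte-Carlo SMILES optimal
descriptor, counter-propagation neural networks, ordinary least squares —
plus a leverage applicability domain and a structural-alert screen, and a
synthetic-table generator that makes the whole pipeline testable without the
original compound table.

## Synthetic compound tables

The generator emulates the study design: `n_compounds` (default 169) cages
decorated with motifs drawn from a grammar of the functional groups the
compound class actually carries (primary/tertiary amines, ammonium, nitro,
phosphonate ester, fluoride, nitrile, carboxylic acid, secondary amide,
alcohol), a recorded train/test split (default 127/42), and a handful of
pristine (undecorated) cages, which real data show to be the least active.

Two cores are available. The default is corannulene, the C20H10 buckybowl:
a genuine curved fullerene fragment that parses and draws quickly and
offers ten rim CH attachment sites; downstream code must not depend on core
size, so a small core is the safer default. A literal Kekulé C60 SMILES is
also provided (derived from the truncated-icosahedron graph with all 30
double bonds on hexagon–hexagon edges); substitution there uses the
1,2-addition motif — demote a C=C to a single bond, saturate one carbon,
substitute the other.

Responses are **simulated, never docked**. Each response r_k is

    y_k = mu_k + a_k·F1 + b_k·F2 + eps_k,   eps_k ~ N(0, s_k²) i.i.d.

where F1 is the standardized topological diameter of the generated
structure (the size factor) and F2 is the standardized polarizability proxy
orthogonalized against F1. Because (F1, F2) are exactly orthonormal
in-sample, the implied correlation matrix is analytic,

    corr(j, k) = (a_j a_k + b_j b_k) / (sigma_j sigma_k),
    sigma_k = sqrt(a_k² + b_k² + s_k²),

and `implied_response_correlation` exposes it, so the generator can be
checked against its own closed form (the suite verifies agreement within
±0.05 at n = 2000). Default means, loadings and noise were chosen once to
put scores on the ≈4000–7800 scale of the study with pairwise correlations
spread over roughly 0.55–0.97; the two endocrine-receptor scores sit below
the panel average, and the copper amine oxidase response (1D6U) is
deliberately noisy — it is the weak response in the real data. When a real
compound table is supplied (CSV with id, SMILES, split, responses),
generation is skipped and the recorded split is honored verbatim.

What the generator does **not** emulate: real docking-score distributions
(only their scale and correlation structure), 3-D geometry and pose
effects, and any descriptor–response relationship beyond the two latent
factors. Tests passing on synthetic data therefore demonstrate mechanical
and statistical correctness of the pipeline, not chemical validity of the
fitted models on real FDs.

## Descriptors

Twenty-seven structure-derived predictors: topological diameter TD (longest
shortest path, in bonds, on the hydrogen-depleted graph of the largest
fragment), polarizability volume QPpolrz, and 25 drug-like descriptors.
All structure handling is RDKit; the per-slot conventions are tabulated in
the `fdtox.descriptors` module docstring. Two deliberate approximations:

* **QPpolrz** is a quantum-chemistry-package quantity; when the input table
  ships it, the supplied column is used and flagged `supplied`. Otherwise an
  additive atomic-increment proxy (increments adapted from Miller's atomic
  hybrid components, hybridization-aware for C and N) is computed and
  flagged `computed`. The two are never mixed silently.
* The drug-like set originates from a desktop package that publishes no
  formulas; slots like drug-likeness (QED here), cLogS (Delaney ESOL) and
  "symmetric atoms" (atoms in a graph-automorphism equivalence class of
  size ≥ 2 — the documented reading of an ambiguous name, overridable by
  supplying the column) are reproducible conventions, not bit-exact clones.

## SMILES optimal descriptor (DCW)

DCW(m) = Σ_k count_k(m)·CW(A_k) over local SMILES attributes: single tokens
of the RDKit-canonical SMILES (bracket atoms, Cl/Br, ring-closure digits
are one token) and, at order 2, adjacent token pairs written in
lexicographic order. Correlation weights start at 1.0 and are tuned by
greedy hill-climbing Monte Carlo: each move perturbs one randomly chosen
active weight by ±step and is kept iff |Pearson r(DCW, endpoint)| on the
training set does not decrease — so the training-|r| trajectory is
non-decreasing by construction. Attributes occurring in fewer than
`threshold` training compounds (default 3) are frozen at weight 0;
attributes never seen in training contribute 0 and are counted. A final
OLS line calibrates raw DCW onto endpoint units, fitted on training only.
Defaults (order 2, threshold 3, 30 epochs, step 0.1) follow common practice
for this descriptor family; the original software's exact settings are not
published, and all are exposed.

## Counter-propagation network (CPANN)

A square Kohonen lattice with a congruent output layer: training presents
objects in seeded shuffled order, finds the best-matching unit (BMU) by
Euclidean distance on the input weights, and moves both the input and
output weights of every neuron within the current radius toward the
object's descriptor/target vectors, scaled by a triangular kernel and the
current learning rate. Prediction is a pure lookup of the BMU's output
weights. Since the reference toolbox publishes no formulas, standard
Kohonen choices are used and exposed: planar rectangular lattice, radius
linear from grid_n/2 to 0, learning rate linear from 0.5 to 0.01, BMU ties
to the lowest row-major index, per-column min-max normalization from
training data with clipped (and warned) out-of-range queries. Every update
is a convex combination, so weights remain in [0, 1]; quantization error is
recorded per epoch. The study architectures are the defaults in the model
registry: 20×20/600 epochs for the exploratory all-descriptor net, 14×14
with 400/300 epochs for the two predictive nets. Leave-one-out CV retrains
the net n times, omitting one object each time.

## Regression, metrics, registry

OLS with intercept via least squares; R²/Q² are squared Pearson
correlations of observed vs fitted/predicted. That convention cannot see a
constant shift or a sign flip, so the PRESS-style variant
1 − Σ(y−ŷ)²/Σ(y−ȳ_train)² is always reported alongside and anti-correlated
predictions trigger a warning. The registry fits six entries per response:
all-descriptor regression and CPANN (28 predictors including DCW), and the
four predictive models on (QPpolrz, TD) or DCW alone. The shared DCW column
is the one optimized against the average binding score; the DCW-based
predictive entries refit DCW per response, mirroring per-endpoint practice
for this descriptor. For the all-descriptor regression, columns that are
constant or linearly dependent on the training split are dropped by pivoted
QR before fitting — single-core synthetic sets make several cage-derived
counts degenerate; `fit_ols` itself remains strict and raises on rank
deficiency.

## Applicability domain

Leverage h = x'(X'X)⁻¹x against the training design (intercept included);
training leverages sum to p+1. Warning threshold h* = 3(p+1)/n — the
conventional Williams-plot choice, overridable. Standardized residuals
divide by the training residual SD with p+1 degrees of freedom; |std
residual| > 3 flags response outliers, h > h* flags structural outliers.
Flagged compounds are retained and annotated, never dropped.

## Structural alerts

Fourteen aquatic-toxicity alerts (TA identifiers from the ToxAlerts
catalogue: amines, ammonium, conjugated nitro/nitrile/acid Michael
acceptors, nitrobenzene, phosphoric esters, amides, acids, alcohols,
benzylic and fluorine halides) ship as local SMARTS. The authoritative
web-service patterns are not public; each SMARTS here is written from the
alert's chemical name, and its contract is the shipped positive/negative
control pair (28 structures, enforced by the suite), not parity with the
service. Match counts are symmetry-deduplicated and non-overlapping.
Compounds predicted above a concern threshold (default 5000, anchored to
the score below which undecorated cages cluster) with no alert are flagged
for manual review rather than cleared.

## Problem sizes and determinism

The analysis drivers and acceptance script run at the study size
(169 compounds, 127/42, full architectures; LOO-CV retrains 127 nets).
The test suite uses scaled-down nets and tables (60-compound fixtures,
5–8-neuron grids, tens of epochs) — the properties under test (weight
bounds, monotone quantization error, null behavior under y-scrambling,
oracle agreement) are size-independent. Every stochastic component (table
generation, weight initialization, presentation order, Monte-Carlo moves,
shuffles) draws from an explicit seed; equal config + seed reproduces
byte-equal artifacts.

## Known limitations

* Real binding scores, and hence the study's printed statistics, require
  the original compound table; without it the two real-data reproduction
  checks in the acceptance suite fail by design rather than silently pass.
* Squared-correlation Q² is generous to shifted or rescaled predictions;
  rely on the PRESS variant when comparing models on different scales.
* The drug-like descriptor conventions approximate, not clone, the desktop
  package that produced the study's tables; models fitted on supplied
  descriptor columns and on computed ones are not interchangeable.
* Alert SMARTS encode the printed alert names; borderline chemotypes
  (e.g. whether an activated alkyne requires a specific activating group)
  follow the controls, which are intentionally conservative.
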