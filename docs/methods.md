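# Methods

This note documents the models and procedures implemented in `cytoqsar`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Problem setting

The package predicts the cytotoxic potency of a small molecule against a
human cell line, expressed on the p-scale: pIC50 (or pGI50) is the negative
base-10 logarithm of the molar concentration at which viability (or growth)
is reduced by half. On this scale 10 µM corresponds to 5.0 — the
conventional boundary between active and inactive compounds — and each unit
is a tenfold change in potency. Models are trained per cell line and per
endpoint from curated activity tables, and a panel of such models turns one
query structure into a cytotoxicity profile with a therapeutic-index
estimate.

## Data curation

**Structure filters.** Records are removed, not repaired, in a fixed order:

1. *mixture* — more than one connected component (no salt stripping;
   a multi-fragment record is ambiguous about which species was assayed);
2. *charged* — net formal charge ≠ 0 (zwitterions with net zero are kept;
   net charge is the testable reading of "charged structure");
3. *inorganic* — no carbon atom, or carbon without any C–C or C–H bond
   (this rejects CO2-like species while keeping all ordinary organics);
4. *overweight* — molecular mass strictly greater than 1250 Da
   (exactly 1250 Da is kept).

Duplicate structures are detected through a canonical-SMILES identity
(RDKit canonicalisation), which is stable across atom order, SMILES
spelling, and runs.

**Activity handling.** Concentrations are converted to the p-scale as
−log10 of the value in mol/L; supported units are nM, µM, mM and M. Only
exact values train models — rows with `>`, `<` or `~` qualifiers are
excluded. Replicates of one (compound, cell line, endpoint) triple are
consolidated by the median after conversion (an even count takes the
midpoint of the two central values). A cell line yields a training set only
with strictly more than `min_compounds = 100` unique curated compounds.

## Descriptors

Three families, all pure functions of the heavy-atom graph:

**Multilevel atom neighborhoods (MNA).** The level-0 string of an atom is
its type (element, aromatic flag, attached-H count, formal charge); the
level-k string wraps the type around the lexicographically sorted
level-(k−1) strings of its bonded neighbors. A molecule's descriptor set is
the multiset of strings over levels 0..L (L ∈ {1,2,3}; default 2). For
regression, columns are occurrence counts of the k most frequent strings in
the training set (default k = 512, ties broken lexicographically); the
vocabulary is frozen into the model bundle so query-time featurisation of a
training compound reproduces its training row exactly.

**Quantitative atom neighborhoods (QNA).** With tabulated first ionization
potentials IP and electron affinities EA (experimental values in eV for H,
B, C, N, O, F, Si, P, S, Cl, Br, I; other elements raise an explicit
error), each atom carries A = (IP+EA)/2 (Mulliken-style electronegativity)
and B = (IP−EA)^(−1/2) (a softness-like quantity). These are propagated
over the bond graph through M = exp(−C/2), C the heavy-atom adjacency
matrix, giving per-atom pairs

    P_i = B_i Σ_k M_ik B_k ,   Q_i = B_i Σ_k M_ik B_k A_k .

The exponential is evaluated as its power series truncated after the 24th
adjacency power: for molecules up to ~30 heavy atoms the spectral radius of
C/2 stays near 1.5, and 24 terms keep the truncation error below 1e−6
against a dense matrix exponential (verified by an oracle test; a very
short series — a handful of terms — deviates at the 1e−3 level and was
therefore not used). Molecule-level features are means of Gaussian bumps on
a g×g grid spanning the training set's (P, Q) range (g ∈ {4,6,8}; bump
width = grid spacing; grid frozen into the bundle).

**Whole-molecule descriptors**, in fixed order: topological length (graph
diameter in bonds), topological volume (sum of covalent radii over heavy
atoms), lipophilicity (Crippen atom-additive logP — an approximation to
any particular logP implementation), positive/negative formal-charge
counts, H-bond acceptor and donor counts, aromatic-atom count, molecular
weight, halogen count ({F, Cl, Br, I}).

All columns are standardized to zero mean/unit variance with scalers stored
in the bundle; constant columns are dropped with a log entry.

## Single model: selection + RBF network

The regression stack is deliberately deterministic:

1. **Selection.** Ridge regression with a penalised intercept (a constant
   column inside the design matrix, under the same penalty λ). Backward
   elimination repeatedly drops the column with the smallest |weight|
   relative to its sandwich standard error; each visited subset is scored
   by leave-one-out Q² computed with the exact hat-matrix identity
   e_loo,i = e_i/(1 − H_ii), and the subset maximising the LOO score along
   the path (down to `min_features = 5`) is retained. The penalised
   intercept is what makes the LOO identity exact under row deletion; the
   bias it introduces is O(ȳ·λ/n), negligible at the λ values used.
2. **RBF stage.** A Gaussian kernel network with every training row as a
   center, kernel width = median pairwise Euclidean distance in the reduced
   space (fallback 1.0 when the geometry is degenerate), and output weights
   from kernel ridge regression on the mean-centered target. The output
   penalty λ_out is chosen from {0.01, 0.1, 1.0} by the internal
   leave-many-out score (5 seeded splits holding out 20%). Q²_LOO of the
   fitted model uses the kernel-ridge LOO identity, which is exact for a
   fixed width and target offset (oracle-tested against explicit refits to
   < 1e−8).

Degenerate inputs: a constant target defines R² = Q² = 0 (zero-variance
guard) and yields constant predictions; fewer than 10 training rows refuse
to train.

## Consensus ensemble and applicability domain

For each training set, `n_variants` (default 320) single models are trained
under configurations drawn deterministically from a grid crossing
descriptor-family subsets, MNA level (1, 2) and vocabulary size (128, 256),
QNA grid resolution (4, 6), and selection penalty (0.1, 1.0). Each variant
trains on a 90% subsample drawn without replacement with a per-variant seed
(sampling with replacement would duplicate kernel centers and make the RBF
system singular; subsampling provides the same ensemble diversity).
Variants whose training R², leave-one-out Q², and internal leave-many-out
R² are all strictly above 0.5 enter the consensus; the consensus prediction
is their unweighted mean, with per-model values retained for audit. An
empty selection is reported as "no acceptable model", never silently.

Applicability domain, three methods, OR-combined (one "out" ⇒ out of
domain):

* **similarity** — Tanimoto between binary presence-sets of level-2
  neighborhood strings; out below 0.70 against every training compound;
* **leverage** — hat value of the query in any accepted model's reduced
  linear space above the conventional cutoff 3(p+1)/n;
* **accuracy** — |consensus prediction − mean experimental value of the 3
  most similar training compounds| above the consensus 5-fold RMSE (ties in
  similarity broken by compound key). Until a 5-fold RMSE has been
  attached, this method reports "unavailable" and does not veto.

## Validation protocols

R² and RMSE follow the standard definitions (R² may be negative and is
reported as-is). 5-fold cross-validation partitions compounds at random
(seeded, recorded), refits the **entire** pipeline per fold — vocabulary,
grid, scalers, ensemble, selection — on the 80% and predicts the held-out
20%; the pooled out-of-fold predictions give R²_5-fold and RMSE_5-fold
(pooling, rather than averaging per-fold scores, weights every compound
equally and is the documented convention here). A fold with no acceptable
model marks the whole report "not available". Final acceptance requires
R²_5-fold > 0.5 and RMSE_5-fold < 1, both strict; the threshold is
configurable.

## Panel profiles and therapeutic index

A panel report applies every supplied consensus model to one curated query
and groups rows into non-tumor and tumor. Group means pool pIC50 and pGI50
rows and count each (cell line, endpoint) row once — a cell line modelled
at both endpoints contributes two rows. The therapeutic index is
TI = 10^Δ with Δ = mean_tumor − mean_non-tumor, printed to one decimal;
advisory labels: ≥ 10 preferable, > 5 candidate, < 2 narrow. Out-of-domain
rows are included in group means by default; `--ad-strict` excludes them
(both modes exist because excluding unreliable predictions is advisable but
changes the means in ways a user should opt into).

## Synthetic benchmark

The generator assembles compounds from a frozen alphabet of 8 disubstituted
scaffolds × 12 substituents; true activity = 5.0 + additive contributions
drawn once from Uniform(−1.5, 1.5) at a fixed alphabet seed and centered to
zero mean per fragment group (so the expected dataset mean equals the
offset). Observations add homoscedastic Gaussian noise (default σ = 0.2,
the conventional magnitude of assay noise on the p-scale); deliberate
duplicates receive independent noise to exercise median consolidation, and
invalid records (mixtures, charged, overweight) exercise the curation
filters. Every scaffold is slot-asymmetric (no automorphism exchanges the
two substitution positions), which makes all 1152 combinations distinct
molecules; with symmetric scaffolds, position-swapped equal-activity twins
both shrink the space and measurably degrade out-of-sample accuracy.

What passing on this benchmark shows: the pipeline recovers a known
additive structure–activity relationship from noisy, duplicated, partially
invalid records at realistic dataset sizes (5-fold R² ≈ 0.96 at n = 500,
σ = 0.2, 16 variants; per-fragment contribution MAE ≈ 0.02 log units).
What it does not show: performance on real medicinal-chemistry series,
which exhibit non-additive activity cliffs, scaffold hopping, correlated
assay artifacts, and far sparser coverage of chemical space. Real
per-cell-line accuracies depend on the underlying bioactivity database and
are expected to be substantially lower (cross-validated R² in the 0.5–0.9
range, as in the bundled reference tables).

## Problem sizes and defaults

| parameter | default | notes |
| --- | --- | --- |
| max mass | 1250 Da | strict `>` rejects |
| min unique compounds | 100 | strict `>` accepts |
| MNA level / vocabulary | 2 / 512 | ensemble varies 1–2 / 128–256 |
| QNA grid | 6×6 | ensemble varies 4–6 |
| selection ridge λ | 0.1 | ensemble varies 0.1–1.0 |
| RBF λ_out grid | 0.01, 0.1, 1.0 | chosen by internal LMO |
| n_variants | 320 | tests and examples use 16 for speed |
| selection thresholds | 0.5 / 0.5 / 0.5 | strict `>` on R², Q², LMO R² |
| final acceptance | R² > 0.5, RMSE < 1 | 5-fold, pooled |
| AD similarity | 0.70 | Tanimoto on level-2 string sets |
| AD leverage | 3(p+1)/n | conventional hat-value cutoff |
| synthetic benchmark | n = 500, σ = 0.2 | 16 variants, seeded |

## Known limitations

* The neighborhood-descriptor scheme is this package's own normative
  definition; numerical agreement with any proprietary descriptor
  implementation is not a goal.
* Tautomers and stereoisomers are not canonicalised apart; 3-D and
  quantum-chemical descriptors are out of scope.
* The leave-many-out score refits only the RBF output layer per split
  (selection is held fixed), so it is mildly optimistic relative to a full
  refit; the 5-fold protocol, which does refit everything, is the
  authoritative external estimate.
* Consensus weighting is uniform; no attempt is made to weight models by
  their internal statistics.
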