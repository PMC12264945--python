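# Methods

## Contact-map construction

Tertiary contact maps are built from residue coordinates: entry (i, j)
is 1 when the inter-residue distance is at most the cutoff (default
9.5 Å, a value that balances sensitivity and specificity for
residue-level structure).  Two distance definitions are provided
because conventions differ between studies: `min_heavy_atom` (minimum
over all heavy-atom pairs of the two residues; the default, and the
most inclusive reading) and `representative_atom` (C3′ for RNA, CB with
CA fallback for proteins).  Secondary-structure maps come from
dot-bracket strings; each bracket tier — `()`, `[]`, `{}`, `<>`, then
`Aa`–`Zz` — is matched with its own stack, so pseudoknots are parsed
exactly.

All maps then pass through the near-diagonal exclusion band: entries
with |i−j| ≤ w are zeroed, with w = 4 for nucleotides and w = 6 for
amino acids by default.  The band removes the trivial chain-adjacency
signal a sequence model already has, leaving secondary/tertiary
structure as the target.  Band application is idempotent and the band
half-width travels with the map so every downstream stage (masking,
featurization, evaluation) uses the same eligible-pair set.

Indices are 0-based and intervals half-open internally; CT output uses
the format's 1-based convention.  PDB/mmCIF reading takes the first
model, one chain (explicitly selected when the file has several),
drops hydrogens and heteroatoms, and rejects chains containing
modified/unknown residues.  Residues with no heavy atoms are rejected;
a full per-residue-type atom-completeness check (which needs reference
atom inventories with terminal-residue special cases) is not
implemented — callers working with partially modelled crystal
structures should pre-filter.

## Attention processing and the agreement statistic

Raw attention stacks are L×H×N×N non-negative arrays, one N×N map per
(layer, head), rows summing to 1 when the provider row-normalizes.
Before classification the maps are *symmetrized* — fixed as the
arithmetic mean (A + Aᵀ)/2, which preserves total mass up to transpose
averaging — and then refined with the *Average Product Correction*,
APC(a)_ij = a_ij − rowsum_i·colsum_j/total, which removes per-position
background attention (the same correction applied to coevolutionary
coupling matrices).  The order is fixed: symmetrize, then APC.  APC on
an all-zero map is a structured degenerate-input error naming the
offending heads.

The per-head agreement statistic is a weighted mean of the contact
indicator over token pairs, pooled over molecules:

    p(f) = Σ_x Σ_{i,j} f(i,j)·ℓ(a_ij) / Σ_x Σ_{i,j} ℓ(a_ij)

with ℓ(a) = a·1[a > θ] in the thresholded form (θ = 0.3 by convention)
and ℓ(a) = a in the threshold-free form; the two coincide at θ = 0 for
strictly positive attention.  Thresholding at 0.3 discards most of the
mass of heads with diffuse attention, which makes the statistic
unstable for nucleic-acid-scale models, hence the threshold-free
variant is the default here (`theta=None`).

Two eligibility policies are provided because the summation range is a
genuine design choice: `all` sums over every entry of the map, while
`band_excluded` (default) removes pairs with |i−j| ≤ w from numerator
and denominator.  The default matches the contact maps' exclusion band,
preventing purely local heads from scoring well on near-diagonal
contacts that are excluded from the target anyway.  Scores are computed
on raw attention by default, since the statistic is defined on
attention weights as the model emits them; a flag scores processed maps
instead.  Heads with zero eligible mass score 0 and are flagged, rather
than propagating NaN.

## Featurization, balancing, splits

Each eligible pair (i < j, j − i > w) of each molecule is one sample
with L·H features (processed attention at (i, j), layer-major order
`layer{l}_head{h}`) and the contact-map entry as label.  Only
upper-triangle pairs are emitted because processed maps are symmetric.
Contact density off the band is a few percent, so training tables are
balanced by randomly undersampling the majority class to the minority
count (without replacement, seeded); minority samples are never
discarded, and balancing is global across the pooled molecules.

Train/test splitting is at the molecule level: the test set receives
⌊fraction·n⌋ molecules (at least 1), e.g. 425 molecules at 0.15 give
362/63.  Training batches are nested subsets drawn without replacement;
the default schedule interpolates geometrically from 20 molecules to
the full training set in 5 steps, supporting learning-curve studies of
how few molecules a probe actually needs.

## Classifiers

Five tabular classifiers (logistic regression, decision tree, random
forest, MLP, XGBoost) train on balanced pair tables with library
default hyperparameters — recorded verbatim into each model's
provenance together with a SHA-256 of the training table — plus
explicit seeds and single-threaded tree learners for determinism.
Predicted contact maps place the per-pair probability at (i, j) and
(j, i), define the band and diagonal as 0, and threshold at 0.5 (no
calibration is attempted).

The convolutional predictor is a deliberately small NumPy network: two
3×3 'same' convolutions (L·H channels → 8 hidden, ReLU → 1), logits
symmetrized as (Z + Zᵀ)/2 before the sigmoid so predictions are
symmetric by construction, binary cross-entropy restricted to eligible
unpadded pixels, Adam (lr 0.02, 30 epochs) over per-molecule steps.
On planted corpora the contact signal is essentially linear in the
aware channels, so this capacity is sufficient; the architecture is a
design choice of this package, not a reproduction of any published
topology.

## Evaluation

Predictions are scored per molecule over the flattened eligible
upper-triangle pairs: macro-F1 is the unweighted mean of contact-class
and non-contact-class F1 (an absent class scores 0), and MCC is defined
as 0 when its denominator vanishes.  Dataset scores are unweighted
arithmetic means over molecules; molecules with no eligible pairs are
skipped and listed.  Evaluation is restricted to eligible pairs so the
score space matches the sample space the classifiers saw.  External
predictions (PDB structures or dot-bracket strings) are benchmarked by
converting them with the same cutoff/window as the truths; the report
records those parameters and notes that 3D-superposition metrics
(RMSD/TM-score) are out of scope.

## Synthetic study conditions

The generator's defaults define the study conditions and are not tuned
per experiment: 50 molecules of length 40–80 nt, a 6-layer × 12-head
grid (small-RNA-language-model sized), 3 aware heads at (1,3), (3,7),
(5,1), signal fraction α = 0.8, pseudoknot probability 0.1, 2 tertiary
extras per molecule, window 4.

Secondary structures are built by recursive stem-loop placement (stem
length 3–6 bp, hairpin loops ≥ 3 nt, occasional multi-loop splits),
with an optional crossing stem on the `[` tier; tertiary maps add
sparse long-range extras (each residue in at most 2).  Sequences are
random ACGU with Watson–Crick-complementary letters under stems.  Toy
coordinates place residues on a 20 Å line and translate each matched
partner to 3 Å from its mate, so the 9.5 Å contact map provably equals
the band-filtered matching — a self-checking harness for the distance
code.

Attention: aware-head rows are α·C(i,·)/deg(i) + (1−α)·noise, where the
noise is row-wise Dirichlet (normalized unit-rate gamma) — the simplest
model meeting the non-negativity and row-sum contracts; a contact-free
row parks its signal mass on the diagonal, which the band-excluded
scoring ignores, so a pure-signal head scores exactly 1.  Unaware heads
follow a locality kernel exp(−|i−j|/2) mixed 60/40 with the same noise.
All randomness flows from the single corpus seed.

What the generator does *not* emulate: thermodynamically realistic
folding, realistic transformer attention statistics (multi-scale heads,
positional artifacts, special-token effects), sequence-dependent
attention, or length distributions of curated structure sets.  Passing
tests therefore demonstrate that the pipeline is correct and sensitive
to planted structure at controlled signal levels — not that any
particular pretrained model encodes structure.

## The few-shot contrast experiment

`fewshot_experiment` trains a probe on the first 20 corpus molecules
(generation order is already randomized) and evaluates on the rest.
Held-out macro-F1/MCC are computed on the *balanced* held-out pair
table — the same sample space the probe was trained on, where a
signal-free probe sits at macro-F1 ≈ 0.5.  On the full, heavily
imbalanced pair set a chance-level probe scores macro-F1 ≈ 0.35 simply
because of the class skew, which conflates imbalance with
informativeness; the molecule-level map evaluation (full eligible set)
is returned alongside, and its mean MCC is the imbalance-robust
summary.  At α = 1 the probe is near-perfect by either measure; at
α = 0 it is at chance by either measure.

## Numerical and problem-size choices

Float64 throughout; row normalization checked to 1e-6; the θ=0 versus
threshold-free equivalence holds to 1e-12; head ranking breaks ties by
(layer, head) ascending for reproducibility.  Validation corpora use
35–50 molecules of 40–80 nt (the few-shot and head-recovery studies)
and 14 molecules of 30–50 nt (CNN checks); these sizes give stable
statistics for the planted-signal conditions while keeping the full
suite fast on a single CPU.

## Known limitations

- No language-model adapters ship with the package; the provider
  contract plus the file-backed `.npz` provider are the integration
  surface.
- Residue-level atom-completeness filtering is coarse (see above).
- Tabular hyperparameters are library defaults; no search or
  calibration is performed.
- The CNN is a compact stand-in sized for planted-signal corpora, not a
  tuned architecture for real attention stacks.
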