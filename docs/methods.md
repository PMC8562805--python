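# Methods

## Model and rationale

A limited-flexibility ΔΔG predictor evaluated on one coordinate set is
treated as a random draw: prediction = μ + ε, where μ is the value the
energy function converges to for this complex and ε reflects coordinate-
set idiosyncrasies (crystallization conditions, fitting choices, minor
composition differences).  Averaging over n independent near-redundant
structures keeps μ and shrinks the spread of the estimate from σ to σ/√n.
The part of the error that is shared across all structures of a mutant —
force-field bias, error in the experimental reference value — does not
average away.  The package separates the two components with the model

    RMSE(n)² = σ²_single / n + σ²_systematic

fitted by ordinary least squares of RMSE² against 1/n (the model is
linear in 1/n; negative component estimates are clipped to zero before
taking square roots).  Note the standard error of an n-structure mean is
σ/√n by the central limit theorem, and that is what `EnsembleReport`
reports; simulation tests confirm the √n scaling directly.

## The homolog filter

A usable homolog must contain the right chains, with nearly the right
sequences, in the right quaternary arrangement.  The three gates:

* **Chain completeness.** A one-to-one assignment of every user chain to
  a distinct subject chain, chosen to maximise summed sequence identity
  over the bipartite identity matrix.  For homo-oligomers, ties on total
  identity are broken by the smaller pooled superposition RMSD, then by
  lexicographic subject chain ID (with ≤ 5 user chains and ≤ 8 subject
  chains all injective assignments are enumerated so tie-breaking is
  exact; larger problems use the Hungarian algorithm).
* **Identity ≥ 0.90** per chain, with identity defined as identical
  aligned positions divided by min(query length, subject length), so a
  complete fragment scores 1.0.  The gate is inclusive (≥, configurable).
* **RMSD ≤ 6.0 Å** from a *single* global Kabsch superposition of the
  whole subject onto the query, fitted on the Cα atoms of aligned residue
  pairs pooled across all corresponding chains.  Fitting chains jointly
  rather than per chain is deliberate: it preserves quaternary geometry,
  so a candidate whose subunits are individually correct but mutually
  rearranged fails the gate (a 20 Å displaced subunit leaves a best-fit
  pooled RMSD of roughly half the displacement).  Extraneous subject
  chains are moved by the same transform.  Gapped positions contribute no
  fit points; residues without a Cα are skipped.

Alignments are global with free end gaps, BLOSUM62, gap open 11 / extend
1 (Biopython `PairwiseAligner`), deterministic by taking the aligner's
first co-optimal alignment.  Significance gating uses the Karlin–Altschul
form E = K·m·n·exp(−λS) with the tabulated gapped-BLOSUM62 constants
λ = 0.267, K = 0.041, m = query residues, n = total residues in the
searched collection.  These locally computed E-values reproduce gating
behaviour (self-matches and near-identical chains pass 10⁻¹¹ easily;
unrelated chains fail by many orders of magnitude); they are not
numerically comparable with any particular search server's output.

Sequences are taken from resolved (coordinate) residues rather than
SEQRES so that every aligned position can supply superposition atoms and
a mutation site.  Alternate locations collapse to the highest-occupancy
conformer (ties prefer altloc 'A'); model 1 only; waters excluded; common
modified residues (MSE, SEP, ...) map to parent one-letter codes, other
HET residues to 'X'.

## Mutation translation

Author numbering differs between entries of the same complex, so the
user's sites (chain, number, insertion code, in query numbering) are
mapped through the chain-correspondence alignment onto each homolog's own
numbering.  Two strict checks: a site aligned to a gap (unresolved in the
homolog) makes the homolog *unmappable* for this mutation, and a homolog
whose residue at the mapped site differs from the stated wild type is
excluded rather than mutated from a different background — both are
recorded as per-structure statuses, not errors, and do not abort the
ensemble.

## ΔΔG backends

The energy function is a pluggable contract (deterministic
structure + subunits + mutation → kcal/mol).  The built-in `surrogate` is
a contact-hydropathy score, Σ w·C·(h(wt) − h(mut)) with C the number of
heavy atoms of the opposite subunit within 6.0 Å of the mutated residue,
h the Kyte–Doolittle hydropathy, and w = 0.05 kcal/mol per contact per
hydropathy unit.  It is rigid-motion invariant and zero for
non-interface sites, which is exactly what the pipeline tests need; it is
documented as not a physical potential.  `table:<csv>` serves
precomputed values (duplicate conflicting keys are a load-time error;
floats parse in round-trip mode so exports reload exactly).
`external:<binary>` shells out to a user-supplied program and passes its
run parameters through verbatim.  Kd = exp(ΔG/RT) conversion uses
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and defaults to 298 K.

Evaluations and filter decisions are cached in JSON key-value stores
keyed by (structure, subunit partition, canonicalised mutation token
order, backend name) and (query, subunits, candidate, cutoffs)
respectively, so each computation happens once ever per cache directory.

## Evaluation statistics

Gold-standard positive: experimental ΔΔG strictly < 0 (zeros are
negatives).  Test positive: predicted ΔΔG strictly below the threshold.
ROC thresholds are placed at midpoints between consecutive unique
predictions plus ±∞ sentinels, swept loosest to strictest; the curve is
reported as TPR versus TNR (its area equals the conventional AUC).  PPV
is undefined — absent, never 0 — at thresholds with no test positives,
and the TP+FP denominator is reported alongside because PPV grows
erratic as it shrinks.  The paired single-vs-multi comparison is a
two-sided Wilcoxon signed-rank test on squared errors: zero differences
dropped, mid-ranks for ties, exact tail probabilities by dynamic
programming over the (doubled) rank-sum distribution for n ≤ 25, normal
approximation with continuity correction and tie-corrected variance
above.  The single-structure baseline picks one structure per mutant
uniformly at random and averages RMSE and correlation over five
randomizations (seeded).  Pearson p-values use the t-transform.

## Synthetic fixtures

The generator emulates what near-redundant database entries actually do:
rigid placement differences, Å-scale coordinate noise, a few per-cent of
mutated positions, renumbering offsets, insertion codes, extra/missing
chains, displaced subunits, and unresolved residues.  Toy complexes are
idealized extended backbones (N, CA, C, O, CB per residue; 3.8 Å residue
spacing with a small deterministic zigzag to avoid collinear Cα traces),
two 50-residue chains by default with the subunits 4.6 Å apart — far more
than the 20 interface atom pairs within 6 Å that contact-based logic
needs.  Sequences are seeded-random over a 19-letter alphabet (no
glycine, since every residue carries a CB).  Every derived variant gets a
JSON sidecar predicting the filter stage it must reach; generation is
byte-identical under a fixed seed.  The default chain length of 50
residues keeps even a 30 %-mutated chain far inside the E-value gate, so
designed identity failures fail at the identity check and not earlier.

What the fixtures do *not* emulate: real secondary/tertiary structure,
side-chain packing, crystal contacts, or a physical energy landscape —
so passing tests demonstrate the correctness of the search, filter,
mapping, caching and averaging machinery, not the accuracy of any energy
function on real proteins.

The ΔΔG observation simulator draws, per mutant, a shared systematic
offset ~ N(0, σ_systematic) plus independent per-structure noise
~ N(0, σ_single) around a true value (default N(0, 1.5 kcal/mol), a
typical spread of measured interface-mutation effects); the experimental
value equals the truth.  Closed forms under this model (ensemble RMSE =
√(σ²_single/n + σ²_systematic)) anchor the simulation tests.

## Numerical choices and edge cases

* Kabsch via SVD with a determinant sign correction, so the rotation is
  always proper even for planar point sets; < 3 points or collinear sets
  are errors.  The test oracle is the independent quaternion-eigenvalue
  (Horn) method; agreement is required to 1e-6 Å.
* Simulation sizes (10,000 mutants; 100 oracle instances; 20 replicates)
  were chosen so sampling error sits well inside each asserted tolerance
  while the whole suite runs in seconds.
* Problem sizes, tolerances and seeds are fixed in the tests; assertions
  on stochastic quantities use tolerances derived from the sampling error
  at those sizes (e.g. σ/√n within 5 % at 10,000 replicates).

## Known limitations

* The local directory provider re-reads and re-aligns every structure
  per job; fine at desk scale (tens to hundreds of files), not tuned for
  a full-database sweep.  A remote search provider is an interface to
  implement, not a shipped client.
* No flexible alignment: a genuinely hinge-bent homolog of the same
  complex fails the RMSD gate by design.
* Insertions/deletions and non-canonical target residues are out of
  scope for mutation specifications.
* The surrogate backend ranks mutations only by contact count and
  hydropathy change; any scientific use requires a real energy function
  through the table or external backend.
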