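# Methods

## Mass arithmetic

All masses are monoisotopic; a ~2 ppm precursor accuracy claim is only
meaningful against the monoisotopic peak. Neutral peptide mass is
`Σ residue masses + H₂O (18.010565 Da) + Σ modification deltas`; an
`[M+zH]z+` ion is `(M + z·1.007276)/z`. Residue masses are the standard
elemental-composition values to five decimals. Fragment ladders cover
the b series (N-terminal prefix + charging protons) and y series
(C-terminal suffix + water + protons), excluding the full-length ion.

The default modification registry models an in-gel tryptic digest
searched with: static propionamide on Cys (+71.03711, the acrylamide
adduct), and variable Met oxidation (+15.99491), Lys acetylation
(+42.01057), Ser/Thr/Tyr phosphorylation (+79.96633) and the Lys GG
ubiquitination remnant (+114.04293). Deltas are standard
elemental-composition sums. Static modifications apply to every target
residue; variable ones only at positions declared on the peptide
(1-based). Terminal modifications are not modelled. m/z values are
reported to 4 decimals and compared with an absolute tolerance of 5e-4
in tests.

## Target-decoy FDR

Decoy databases append one reversed-sequence record per target under
the `REV_` accession prefix (composite size = 2× targets). The FDR
estimator for a concatenated search is `2D/(T+D)`, capped at 1: decoy
hits (D) estimate half of the incorrect matches, which split roughly
evenly between target and decoy sequences. The simpler `D/T` ratio is
available as an option. Thresholding picks the *lowest* score whose
estimated FDR meets the bound (ties retained via ≥ comparison), which
maximises retained identifications and is monotone in the FDR budget.

Filtering cascades three levels: PSMs; unique peptides keyed by
(sequence, modification set) — charge-agnostic — represented by their
best-scoring PSM; and single-accession protein groups represented by
their best peptide, with a minimum of two distinct peptides per
protein enforced before the protein-level threshold. Shared peptides
count toward every mapped protein (no razor assignment). Decoy entries
drive the estimates and are then removed from the report; an
unsatisfiable policy returns an empty result with diagnostics rather
than raising. The pipeline consumes one composite database per run;
merging searches across multiple sequence databases is out of scope.

## Spectral counting

Each retained PSM contributes one count to every protein it maps to,
partitioned by population and experiment; shared-peptide multi-counting
is an acknowledged upward bias. Raw summed counts are reported (no
length or NSAF normalisation; a normalisation hook exists but is off by
default). "Experiments observed" counts the experiments with at least
one PSM, per population and in total.

## Exclusive/enriched classification

Proteins with counts in exactly one population are exclusive
(`HC_ONLY`/`NSC_ONLY`). Each shared protein with counts (a, b) is
tested against margins (T_H, T_N) — by default the total retained
spectral counts per population over the whole protein set, the standard
spectral-count contingency design; margins are a parameter — in the
table `[a, b; T_H−a, T_N−b]`. The two-sided p-value is computed by the
minimum-likelihood method: the hypergeometric point probabilities of
all tables with the observed margins that are no more probable than the
observed table (relative tie tolerance 1e-7) are summed. The
double-one-tail alternative is available but not the default; the two
differ for asymmetric margins. p < alpha (default 0.05, raw — no
multiple-testing correction, though a Benjamini–Hochberg column is
emitted for information) reassigns the protein toward the population
with the larger count share; share ties stay `SHARED_UNRESOLVED`.
p-values print in 2-significant-digit scientific notation; values below
1e-300 print as `0`.

Published tables round p to ~2 significant digits, so when filtering
*printed* p-value columns a value printed exactly at alpha is treated as
passing (the underlying value was below it); recomputed full-precision
p-values use the strict inequality.

## Category profiling

Annotations are a user-supplied accession → (localization, function)
table; category proportions depend on the annotation snapshot used, so
no live ontology lookup is performed and a protein with multiple
annotations keeps the first listed one. Unmapped accessions fall into
"not annotated". Proportions are reported protein-weighted ("before
quantification") and spectral-count-weighted ("after quantification");
both sum to 1, and they coincide exactly when all proteins have equal
counts. Profile comparisons report signed differences in percentage
points.

## Synthetic data generator

The generator defines the study conditions the statistical guarantees
are validated under: 2 populations × 3 runs × 8 gel fractions; 300
proteins of random sequence (length uniform on 100–600), of which 20
each are HC-specific, NSC-specific, HC-enriched and NSC-enriched
(fold 8); 5,000 PSMs per run; contamination ε = 0.05 (fraction of
NSC-run spectra drawn from the HC abundance profile, mimicking damaged
unlabeled hair cells sorted into the dye-low gate); 10% incorrect
matches, half landing on decoy sequences; Gaussian scores N(3.5, 0.8)
for correct and N(1.5, 0.5) for incorrect matches, a stand-in for a
database-search score that is adequate for FDR-calibration work.

Abundances are a single symmetric Dirichlet draw over the balanced
proteins, shared by both populations; designated proteins receive the
deterministic mean weight 1/n before their class bump (zeroed in the
other population for specific classes, ×fold for enriched ones).
Keeping the designated classes' total mass deterministic makes a
symmetric design give balanced proteins *exactly* equal sampling rates
in both populations, so the false-reassignment rate of the exact test
can be assessed against its nominal level; with fully random class
masses, every balanced protein would inherit the same random
between-population bias and the comparison would be confounded.

Peptides are drawn uniformly from the chosen protein's tryptic digest
(cleave after K/R, not before P, ≤2 missed cleavages, length 6–40;
proteins with no eligible peptide are resampled away). Gel fraction is
the protein's length octile for correct matches and uniform for
incorrect ones. Charge is 2 (70%) or 3 (30%); the observed m/z adds
~1 ppm Gaussian instrument error to the theoretical value. One RNG
stream per run, seeded `seed + run_index`, keeps runs independently
reproducible. Peptides are emitted unmodified; modification arithmetic
is exercised directly by the mass module.

What the generator does **not** emulate: realistic protein abundance
dynamic range (Dirichlet tails are mild), peptide detectability and
ionisation efficiency, score dependence on peptide properties,
chromatographic structure, or shared peptides between proteins (random
sequences virtually never collide). Passing recovery tests therefore
demonstrate the statistical machinery under the declared design, not
performance on real spectra.

## Validation design and problem sizes

- Fisher implementation vs an exact-rational brute-force enumeration for
  *all* 2×2 tables with both margins ≤ 12, plus spot-checks against
  `scipy.stats.fisher_exact`.
- FDR-estimator calibration: 100 replicates at 5,000-PSM depth; the
  mean estimate − realized false-discovery-proportion difference must
  sit within 3 Monte-Carlo standard errors of zero.
- Enrichment recovery: 25 replicates of the full design (ε = 0.05,
  fold 8) through the complete filter → count → classify pipeline;
  ≥80% of designated enriched proteins recovered with the correct
  direction, ≤5% of balanced proteins falsely reassigned at α = 0.05.
- Contamination masking: mean exclusive calls among truly HC-specific
  proteins strictly decrease over ε ∈ {0, 0.1, 0.2}. This check runs at
  a depth of 1,000 PSMs/run: at full depth even small ε floods every
  specific protein with wrong-population counts and the exclusive count
  saturates at ~0 for all ε > 0, hiding the gradient the property is
  about.

## Numerical and degenerate-input choices

- Fisher p snaps to exactly 1.0 when the summed support reaches
  1 − 1e-9 (the symmetric-table case); p ∈ (0, 1].
- `estimate_fdr` returns 0 when nothing passes the threshold; all-decoy
  prefixes cap at 1.
- Score ties at a threshold are retained; deterministic ordering is
  (score desc, spectrum_id asc).
- Empty PSM tables flow through the pipeline as empty reports with
  warnings, never exceptions.
- A fixture row that prints no spectral count is loaded as missing,
  flagged, imputed to 1 for membership classification, and excluded
  from sum checks.

## Known limitations

- The packaged reference tables were transcribed from an extracted text
  of the source tables; the two exclusive-protein tables each carry one
  row fewer than the totals stated in the accompanying text (63 vs 64
  and 102 vs 103), and the missing rows are not recoverable from the
  available text. Classification of the fixtures reproduces the table
  contents, not the stated totals. (The source itself also disagrees
  internally: one figure caption prints 104 where the text arithmetic
  gives 103.)
- Dataset-level figures of the emulated study (total PSMs, achieved
  FDRs, category percentages) depend on unreleased raw spectra and a
  historical annotation snapshot; they are context, not reproduction
  targets.
- Spectral counting without normalisation biases toward long, abundant
  proteins; the Fisher margins design makes calls compositional (a very
  abundant protein in one population depresses every other protein's
  share there).
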