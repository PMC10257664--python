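# Methods

This note records the models, conventions and design choices behind
`neoact`, and what the synthetic data does and does not establish.

## Variant → peptide enumeration

Variants are expressed on the transcript coding sequence (CDS), 1-based
and inclusive; VCF input is converted on read (the shared indel anchor
base is trimmed). The edited CDS is translated with the standard codon
table, truncating at the first stop codon and ignoring a trailing
partial codon. Candidate windows are every k-mer (k ∈ {8..11} by
default, configurable — the MHC class I ligand length range; the length
set is a convention, not a measured property of any assay) of the mutant
protein that covers at least one variant-derived residue, clipped at the
protein ends.

Changed residues are located by variant class:

* substitutions — the affected codon span, restricted to residues that
  actually differ (a synonymous edit yields nothing);
* in-frame insertions/deletions — the block between the longest common
  prefix and suffix of the two proteins; a clean deletion marks the
  junction residue, so junction-spanning k-mers are still enumerated;
* frameshifts — everything from the first diverging residue to the
  (truncated) end of the mutant protein. A stop-gain therefore yields no
  windows at all.

Wild-type partner windows are attached only for length-preserving
substitutions, where the two proteins share coordinates. Indel- and
frameshift-derived windows have no aligned wild-type counterpart, so the
mutant-vs-wild-type affinity filter is skipped for them downstream.

Two upstream filters use strict inequalities exactly as written in their
rules: VAF must be **>** 0.01, and a mutant peptide found verbatim in
the reference proteome (exact k-mer membership over the supplied
proteome FASTA) is removed. Both filters are order-preserving and
idempotent. Duplicate mutant peptides arising from distinct variants are
kept as separate records for provenance; de-duplication happens only at
ranking, keeping the lowest-IC50 record.

Tumor mutation burden is reported as nonsynonymous mutations per
megabase; the exome denominator is a caller-supplied parameter, since it
depends on the capture kit.

## Affinity ensemble and consensus

The ensemble interface takes any five callables mapping
`(peptide, allele) → IC50 nM`, or a pre-computed exchange TSV with
exactly five distinct predictor labels per peptide. The consensus rule:
count the values below 500 nM; if at least three, the consensus is the
minimum of the five, otherwise the sentinel 50 000 nM. All threshold
comparisons in the package are strict (`< 500`, `> 500`, `> 0.01`,
`< 1`, `IC50_mut > IC50_wt`): equality passes. A failed or missing
predictor contributes the sentinel — it cannot vote "binder" and cannot
become the minimum unless all five fail — preserving the five-slot
arity conservatively.

The built-in predictor is a log2-odds PSSM: smoothed column frequencies
over background, scored additively, min–max normalized to [0, 1] using
the matrix's own attainable score range, and mapped to nanomolar as
`IC50 = 50000^(1−score)` so that the transform's range matches the
sentinel scale. Five parameterizations (different pseudocounts) provide
a fully self-contained, deliberately correlated ensemble for testing;
it is a simple motif model, not a replacement for modern pan-allele
predictors, and its absolute IC50s should not be interpreted
biochemically.

Ranking is by ascending mutant consensus IC50; ties break by descending
VAF (more clonal mutations first), then lexicographic peptide, making
output byte-deterministic. `top_n` reflects the practice of taking a
5–20-peptide shortlist per patient.

## Immunoassay scoring

* ELISPOT: positive iff spots > 10 and spots ≥ 2× the negative control.
  Replicate wells are combined by the mean spot count rounded half-up —
  one deterministic call per peptide. The combination rule is a package
  choice; the positivity thresholds are the standard published rule.
* LDH cytotoxicity: the corrected-lysis formula of the CytoTox 96
  assay manual, `100·(E − Es − Ts)/(Tmax − Ts)` on 490 nm absorbances.
  Values outside [0, 100] are reported unclipped with an `out_of_range`
  flag, preserving raw evidence from noisy plates.
* Tetramer fractions: point estimate with a 95% Wilson score interval
  (closed form; the interval is clamped to contain the point estimate
  at the k = 0 and k = n boundaries where floating point would
  otherwise violate it).

## Clonotype dynamics

Clonotype identity is the exact triple (CDR3 amino-acid sequence,
V call, J call), matching single-cell VDJ conventions; a CDR3-only
comparison is available by constructing clones with empty gene calls.
The pathogen-TCR screen is modeled as an exact-CDR3 blocklist file; the
database producing such lists is consumed, not reimplemented.

Fold-change uses a pseudocount of 0.5 added to read counts (not
frequencies) in both numerator and denominator, so clones unseen at
baseline get a finite, depth-bounded estimate; with pseudocount 0 and
nonzero counts it reduces to the exact frequency ratio. The earliest
timepoint of a series is the baseline (pre-infusion samples carry
negative month values); `max_fold_change` is the largest fold over
post-baseline timepoints and `persists_at_last` is detection at the
final sample. No significance test is attached to an expansion: at the
read depths involved, a binomial test would declare tiny folds
significant, and the scientifically interesting quantity is the
magnitude.

## Clinical outcomes

RECIST 1.1 is implemented for target lesions only — sums of longest
diameters — because that is what lesion-diameter time series support;
nodal short-axis rules and non-target lesions are out of scope. Response
percent change is computed from baseline, progression from the nadir
(the smallest sum at any assessment strictly before the current one,
baseline included). Progression takes precedence over response at the
same timepoint; a new lesion is progression regardless of target
shrinkage. Best overall response is the best pre-progression category
without requiring a confirmation scan.

ORR counts CR+PR, DCR counts CR+PR+SD, both as percentages of evaluable
patients rounded half-up to one decimal. Survival uses the Kaplan–Meier
product-limit estimator (lifelines); the median is the smallest event
time where the curve reaches 0.5 or below (with a 1e-12 tolerance for
float accumulation), and its 95% CI comes from the exponential-Greenwood
log-log curve bands. Adverse events count each patient once per term per
arm at their worst CTCAE grade.

## Synthetic data: what it emulates, and what it does not

Generators draw from independent seeded streams (master seed + fixed
label), so outputs are byte-reproducible and adding a generator never
perturbs the others.

* Proteome/CDS: random proteins (80–200 aa) with consistent CDS and no
  internal stops. No homology structure, codon bias or isoforms.
* Variants: missense / in-frame deletion / 1-bp frameshift mix (80/10/10
  by default); VAFs from Beta(0.3, 3) — right-skewed with mass near the
  0.01 cutoff — with a configurable 10% forced below threshold to
  exercise the strict-inequality edge.
* Binder sets: anchor positions (2 and 9 by default, as in common
  A*11:01-like 9-mer motifs) drawn from small residue sets, uniform
  elsewhere. Real binding chemistry is not simulated; tests of the PSSM
  therefore show motif recovery and rank separation, not predictive
  accuracy on real ligands.
* Clonotype series: baseline frequencies from a flat Dirichlet over 200
  clones; designated clones start at frequency 2×10⁻⁴ and are multiplied
  by programmed folds (default 2/10/100, the dynamic range reported for
  responding patients) at the first two post-infusion timepoints, then
  contract to 20% of peak; counts are multinomial at 10⁵ reads. Spike
  recovery within ±25% at this depth shows estimator correctness under
  multinomial sampling noise, not under PCR/primer bias, which is not
  modeled.
* Trial fixture: the published per-patient outcomes (response category
  and duration, infusion counts 2,3,2,8,15,8,3,6,6,6,2, lymphodepletion
  arm) and group-level adverse-event counts are literal data files;
  per-patient AE rows are reconstructed deterministically from the group
  counts (grade ≥3 patients first, the remainder at grade 2), which
  round-trips the published percentages exactly. Lesion trajectories are
  synthetic curves built to land in each patient's recorded category —
  they reproduce categories, not real tumor kinetics.

Problem sizes in the test suite (500 enumeration instances, 10⁴
consensus tuples, all ≤6-subject survival patterns, 200 repertoire
simulations per fold) were chosen as the smallest sizes at which the
oracle comparisons are exhaustive or statistically stable.

## Known limitations

* Cohort-scale quantities that depend on restricted-access patient data
  (per-patient mutation burdens, neoantigen counts, survival medians,
  tetramer ranges) are not recomputable here; the corresponding methods
  are validated by oracle and property tests on synthetic data instead.
* No proteasomal-cleavage, TAP-transport or immunogenicity modeling;
  binding affinity is the only selection axis, and HLA alleles are
  inputs (no typing).
* No splice-, fusion- or intron-retention-derived peptides; one CDS per
  transcript.
* The product-limit median CI uses the log-log band inversion; with very
  few subjects the bounds are often open, which is reported as `None`
  rather than guessed.
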