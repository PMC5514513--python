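# Methods

`protevar` implements a desk-scale onco-proteogenomic variant-peptide
detection pipeline: variant peptide database construction, split
target-decoy FDR estimation, a three-stage post-search filter cascade,
cross-engine confidence tiers, and a resampling enrichment test. This note
documents the models and procedures, the parameters that matter, the
synthetic-data generator that stands in for real inputs, and the design
choices made where the design was genuinely open.

## In-silico tryptic digestion

Digestion follows the conventional trypsin rule: cleave C-terminal to K or
R unless the next residue is P, with up to `max_missed` internal missed
cleavage sites (default 2) and a peptide length window of 6–35 residues
inclusive (the range routinely detected by shotgun MS). The proline
suppression rule matches the default behavior of the common search
engines; it is configurable through `CleavageSpec` for workflows that use
the unsuppressed rule. Coordinates are 1-based inclusive throughout.

Non-standard residues (X, U, B, Z) are tolerated in input sequences but
are never cleavage sites, and peptides containing X are excluded from
membership indexes and variant enumeration — an unknown residue cannot be
confidently matched against anything.

Isobaric leucine and isoleucine are indistinguishable by standard MS, so
every comparison against a reference proteome is performed after mapping
I→L (`il_collapse`).

## Variant application and peptide enumeration

Variants arrive pre-translated to protein level (the output of a
consequence predictor such as VEP); nucleotide-level consequence calling
is out of scope except for fusions, which are naturally defined in
nucleotide space. The affected-span conventions are:

* **substitution** — the replaced residue;
* **insertion** — the inserted run plus one flanking residue on each
  side: a peptide covering only the insertion junction still differs from
  the reference, so it must count as variant-overlapping;
* **deletion** — the junction residue pair left behind;
* **frameshift / stop loss** — everything from the variant position to
  the new C-terminus. These records must carry the complete novel
  C-terminal sequence; translating downstream genomic sequence is the
  caller's job.

Variant peptides are all tryptic peptides of the mutated protein that
overlap the affected span, carry at most two missed cleavages in total,
and are absent from the canonical reference proteome under I/L collapse.
The "at most two missed cleavages in total" reading is the simplest one
consistent with the analytic bound that an internal, cleavage-neutral
substitution is detectable in exactly six tryptic peptides (1 + 2 + 3 for
0/1/2 missed cleavages). Build-time filtering uses the canonical proteome
only; the stricter three-proteome filter is re-applied post-search, where
a peptide matching *any* commonly used reference must be discarded.

Fusions are handled by concatenating the 5' and 3' coding fragments and
translating either all three frames (curated fusions whose reading frame
is unknown) or frame 0 only (in-frame fusions from RNA-seq). Translation
stops at the first stop codon per frame, and only peptides whose residue
span crosses the junction-encoding codon boundary are kept — peptides
wholly on one side are ordinary reference or out-of-frame sequence and
carry no fusion evidence.

Duplicate peptides are collapsed by exact sequence with provenance and
variant identifiers merged, and the output ordering is lexicographic
everywhere, so database builds are byte-reproducible.

## Split target-decoy database and FDR

Every target entry (reference protein or variant peptide) gains exactly
one decoy: the full reversal of its sequence, with a `rev_` header prefix,
in a decoy class matching its partition. Reversal preserves amino-acid
composition and length, and applying it twice reconstructs the target
database exactly.

The variant partition is small and — because most implanted variants are
not expressed — enriched for incorrect matches. A pooled target-decoy
estimate lets abundant, high-scoring reference PSMs subsidize spurious
variant acceptances; FDR is therefore estimated separately per partition,
each against its own decoys, and further stratified by precursor charge
state (the conventional reading of treating different mass-to-charge
populations separately; strata below a configurable size can be merged to
avoid unstable estimates). Engines are filtered independently and merged
only at tiering.

Within a stratum, PSMs are sorted by score (e-values are mapped to
−log10), and at every cutoff the estimate is

    FDR(c) = (D(c) + 1) / T(c)

with D and T the decoy and target counts at or above the cutoff; q-values
are the running minimum from the permissive end, and targets with
q ≤ 0.01 are accepted. The add-one correction is the default because the
uncorrected D/T estimator is measurably anticonservative in finite
samples: picking the largest acceptance set with estimated FDR below the
threshold systematically favors cutoffs where the decoy count fluctuates
low, and on simulated data (200 independent draws, exchangeable decoy and
incorrect-target scores) uncorrected acceptance at a nominal 1% produced a
realized false-discovery proportion of ~1.35% at per-stratum accepted sets
of ~1000 and >2% at smaller ones, while the corrected estimator sits
within Monte-Carlo error of 1%. The uncorrected variant remains available
(`conservative=False`, CLI `--uncorrected`). At tied scores decoys are
counted before targets, the conservative convention.

A consequence of the correction: a stratum can only accept PSMs at 1% FDR
once it contains at least 100 targets above the top decoy. This is the
intended behavior — spectral FDR estimates over a handful of PSMs carry no
statistical meaning.

## Post-search filter cascade

Three filters run in fixed order; each only removes PSMs, and every
removal is attributed to exactly one filter with its evidence, so
survivors plus the removal log always reconstruct the input.

1. **Reference filtration.** Any accepted variant peptide whose
   I/L-collapsed sequence occurs in any of the reference proteomes
   (Ensembl-, RefSeq-, and UniProt-style references indexed together) is
   removed, logged with the matching source(s).
2. **Chemical-modification conflict.** Dependent-peptide records
   (spectra re-explained as mass-shifted modifications of already
   identified peptides) with positional probability above 0.8 are matched
   to variant PSMs by (raw file, scan id). A record proposing a different
   base peptide or site is a discordant explanation and removes the PSM
   — preference is deliberately given to the dependent-peptide
   assignment. A record at the same site whose delta mass equals the
   ref→alt residue mass difference within tolerance describes the same
   mutation in different nomenclature, and the PSM is retained. PSMs
   without single-residue site information (fusion and indel peptides)
   are removed on any confident dependent record, since concordance
   cannot be established. The scan-matching key assumes engines report
   un-merged scans; merged-scan headers would need upstream
   normalization.
3. **Protein abundance.** A variant PSM survives only if at least one
   canonical-sequence PSM of the same parent protein was identified in
   the same sample. Matching is at the accession level by default;
   passing gene identifiers on both sides gives a gene-level mode.

The delta-mass tolerance defaults to 0.01 Da: high-resolution MS1
accuracy separates almost all single-residue substitution deltas at this
scale (the closest standard pair beyond exact I/L equality, K vs Q,
differs by 0.036 Da). Near-isobaric deamidation-like deltas (N→D,
+0.984 Da) are treated like any other candidate, with no special-casing.

## Dependent-peptide substitution calling

Independently of filtering, dependent-peptide records are mined for
substitutions: for records with positional probability ≥ 0.95, the delta
mass is compared against the mass difference from the base residue to
every other standard residue (monoisotopic masses from pyteomics). A
unique match within 0.01 Da is an unambiguous substitution call; multiple
matches (always including the I/L pair when either is a candidate) are
emitted flagged ambiguous. Records whose delta is within tolerance of
zero are skipped — a mass-invisible change (identity, or I↔L) cannot be
distinguished from the unmodified peptide.

## Tiers and summaries

Filtered PSMs from the three engines are grouped by exact peptide
sequence (engines report concrete sequences; an I/L-collapsed grouping
mode is available) with spectral count defined as distinct (raw file,
scan id) pairs pooled across engines and samples:

* tier 1 — every peptide surviving filtration;
* tier 2 — identified by at least two engines;
* tier 3 — identified by all three engines;
* tier 4 — identified by all three engines with ≥ 2 spectra.

The tiers are nested by construction. Spectral counts are global across
samples by default; a per-sample accounting can be had by partitioning
the input PSMs before tiering. Mutation summaries count distinct
(gene, variant) pairs per gene and report the median mutations per gene.

## Enrichment resampling

The enrichment test asks whether the genes behind the detected variant
peptides are over-represented in annotation categories (e.g. druggable
gene classes) relative to equally sized random peptide sets from a
standard reference search. The resampling unit is the peptide: the
observed category counts are compared against `n_resamples` (default
100,000) uniform subsamples without replacement from the background, and
the empirical p-value uses the add-one estimator
(1 + #{null ≥ observed}) / (n_resamples + 1), which never returns zero
and makes null p-values super-uniform. With a fixed seed the output is
bit-reproducible. On a small worked case the empirical p-value converges
to the exact hypergeometric tail, which the tests verify.

## Synthetic data generator

The generator (`protevar.simulate`) emulates the *shape* of a real
experiment, not its physics:

* **Proteome** — random sequences with near-vertebrate residue
  frequencies; the combined K+R frequency (default 0.11) sets the median
  tryptic peptide length to the 8–20 residue range of real proteomes.
* **Variants** — substitutions, indels, frameshifts and stop losses
  implanted at interior positions with recorded ground truth (expected
  peptide sets). Implanted substitutions are cleavage-neutral (ref and
  alt outside K/R/P) so each one's analytic six-peptide expectation
  holds; cleavage-site-changing substitutions are exercised separately in
  unit tests. Fusions reverse-translate fragments of two proteome
  proteins, so fusion partners have canonical peptides and can pass the
  abundance filter, as real fusion partners do.
* **PSMs** — correct spectra are shared across engines (each engine
  reports one with its detection probability and an independent score
  draw); incorrect spectra are engine-specific and split evenly in
  expectation between target and decoy matches. Scores are Gaussian:
  correct at mean 10, sd 2 (on the −log10 e-value scale) and incorrect
  and decoy matches share mean 5, sd 2 — the target-decoy assumption
  holds by construction, which is what makes the calibration measurement
  meaningful. Two canonical peptides of every variant-hosting protein are
  forced into the expressed set, reflecting that a protein carrying an
  expressed variant also produces reference peptides.
* **Dependent records** — a configurable fraction of true variant
  spectra receive a conflicting (different-site PTM) or concordant
  (same-site, substitution-delta) dependent record; standalone records
  with exact substitution deltas exercise the variant caller.
  Mass-invisible substitutions are never implanted, since no
  dependent-peptide search could report them.
* Truth labels live in sidecar tables only; nothing the pipeline parses
  leaks them.

Default sizes (40 substitutions plus indels/frameshifts over 25 proteins,
85% of variant peptides expressed, 5 spectra per expressed peptide, 1200
noise spectra per engine in the variant partition) put per-stratum
accepted counts in the hundreds — the deep-proteome regime in which
spectral FDR estimation is statistically meaningful. Calibration and
recovery results on this generator show that the estimators and filters
behave as designed under their own assumptions; they do not show
robustness to the things the generator does not model: correlated engine
scores, spectrum quality variation, chimeric spectra, retention-time
structure, PTM-rich samples, or shared peptides between paralogs.

## Numerical and degenerate-input conventions

* E-values equal to zero would map to an infinite score and are rejected
  at parse time (scores must be finite).
* A stratum with decoys but no targets is skipped with a warning; no
  decoys means q = 0 everywhere under the uncorrected estimator and
  1/T under the corrected one.
* Best-PSM-per-spectrum ties break lexicographically by peptide, then
  prefer the reference partition — an ambiguous spectrum should never
  create a variant identification.
* Empty digestion products, fully filtered variants, and empty category
  tables all return empty results rather than raising.
* Seeds: every stochastic component takes either a `SimulationConfig`
  seed or an explicit `numpy` generator; fixed seeds give byte-identical
  fixture files and bit-identical enrichment results.

## Known limitations

* The reference filter and index operate on tryptic peptides of the
  provided references; semi-tryptic or non-specific matches are out of
  scope.
* The conflict filter keys on (raw file, scan id) and cannot resolve
  merged-scan identifiers.
* Fusion support covers junction-spanning peptides of simple 5'/3'
  fusions; inversions and more complex rearrangements are not modeled.
* The enrichment test treats peptides as exchangeable; it does not model
  peptide-level detectability covariates (length, hydrophobicity,
  abundance), which a more refined null would.
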