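# protevar

Onco-proteogenomic variant peptide detection: build variant/fusion peptide
search databases from protein-level variant records, construct split
target-decoy databases, estimate partition-specific spectral FDR from
multi-engine PSM tables, apply a post-search filter cascade, assign
cross-engine confidence tiers, and test detected variants for gene-category
enrichment.

## The problem

Standard shotgun-proteomics searches assign MS2 spectra to peptides from a
*reference* protein database, so peptides carrying somatic or germline
variants — the proteoforms that matter most in cancer — are invisible to
them. Proteogenomics augments the search database with variant sequences
from population catalogs (dbSNP, COSMIC, UniProt annotations) and from
sample-specific exome/RNA-seq calls. That gain in scope brings two
statistical hazards:

* the variant partition of the database is small and mostly unexpressed,
  so pooled false-discovery-rate estimates driven by abundant reference
  identifications dramatically understate the error rate among variant
  peptide-spectrum matches (PSMs);
* a "variant" PSM can be an isobaric match to a reference peptide
  (Leu/Ile), a mis-assigned chemical or post-translational modification
  whose mass shift mimics a substitution, or a match to a protein with no
  other evidence of expression in that sample.

`protevar` implements the corresponding counter-measures as a reusable
toolkit: a **split target-decoy** FDR (each database partition competes
against its own reversed-sequence decoys, stratified by precursor charge,
with the add-one-corrected estimator (D+1)/T and 1% spectral FDR
threshold), followed by **reference filtration** under I/L equivalence,
a **dependent-peptide conflict filter** (positional probability > 0.8),
and a **protein-abundance filter** requiring same-sample canonical
evidence. Surviving peptides are ranked into four nested confidence tiers
by engine agreement (X!Tandem-, Comet-, MS-GF+-style standardized tables)
and spectral count, and a peptide-level resampling test scores gene
categories for enrichment with the estimator
p = (1 + #{null ≥ observed}) / (n + 1).

A key analytic fact shapes the whole problem: an internal amino-acid
substitution that leaves the cleavage pattern unchanged can be observed in
**exactly six** tryptic peptides at up to two missed cleavages — variant
detection operates at the edge of detectability by construction.

Everything is testable without downloads: `protevar.simulate` generates
seed-reproducible toy proteomes, implanted variants and fusions,
multi-engine PSM tables with controlled target/decoy score structure, and
dependent-peptide tables, with ground-truth labels in sidecar files.

## Worked example

Apply the AKT1 E17K hotspot substitution to its reference protein,
enumerate the variant tryptic peptides, and build the four-class split
target-decoy database:

```python
from protevar import (
    CleavageSpec, PeptideIndex, ProteinRecord, VariantRecord,
    apply_variant, build_search_database, enumerate_variant_peptides,
)

ref = ProteinRecord("P31749", "AKT1", "MSDVAIVKEGWLHKRGEYIKTWRPRYFLLK",
                    "uniprot_canonical")
spec = CleavageSpec(min_len=6, max_len=35, max_missed=2)
index = PeptideIndex.build([[ref]], spec)

variant = VariantRecord("rs121434592", "AKT1", "P31749", "sav",
                        position=17, ref_seq="E", alt_seq="K",
                        provenance=frozenset({"cosmic"}))
mutated, span = apply_variant(ref, variant)
peptides = enumerate_variant_peptides(mutated, span, spec, index,
                                      variant.variant_id, variant.provenance)
for p in peptides:
    print(f"{p.sequence:30s} missed={p.missed_cleavages} span={p.mutated_span}")

db = build_search_database([ref], peptides, {variant.variant_id: variant})
print(db.class_counts())
```

prints

```
EGWLHKRGK                      missed=2 span=(9, 9)
RGKYIK                         missed=2 span=(3, 3)
GKYIKTWRPR                     missed=2 span=(2, 2)
{'reference_target': 1, 'variant_target': 3, 'reference_decoy': 1, 'variant_decoy': 3}
```

E17K *creates* a tryptic cleavage site, so instead of the canonical six
peptides only three length-eligible peptides overlap the mutated position
— each tagged with the 1-based span of variant-derived residues, each
absent from the reference under I/L collapse, and each paired with a
reversed decoy in the variant-decoy class. Variant database entries carry
a structured header
(`var|rs121434592|AKT1|sav|cosmic|9-9|p1`) that downstream FDR and
filtering stages parse to classify PSMs.

The same stages are available from the shell:

```bash
protevar simulate --seed 3 --outdir fixtures/
protevar build-db --ref fixtures/reference.fasta \
    --variants fixtures/variants.tsv --fusions fixtures/fusions.tsv --out db.fa
protevar fdr --psms fixtures/psms_tandem.tsv --engine tandem \
    --threshold 0.01 --out accepted_tandem.tsv
protevar filter --accepted accepted_tandem.tsv --engines tandem \
    --ref-fasta fixtures/reference.fasta --dependents fixtures/dependents.tsv \
    --variants fixtures/variants.tsv --out filtered.tsv --log removals.tsv
protevar tier --filtered filtered.tsv --engines tandem --out tiers.tsv
```

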