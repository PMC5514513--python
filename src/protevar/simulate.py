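"""Seed-reproducible synthetic fixtures for every pipeline stage.

The generator emulates the shape of a real onco-proteogenomic experiment
without any raw MS data: a toy proteome stands in for the reference
database, implanted protein-level variants and fusions for the consequence
predictor output, and per-engine PSM tables for the standardized
tab-delimited search outputs. Scores are drawn from two Gaussians — one for
correct assignments, one shared by decoy matches and incorrect target
matches — so the central target-decoy assumption (incorrect matches and
decoy matches follow the same law) holds by construction and FDR
calibration can be measured against known truth labels.

Truth labels are written to a sidecar table, never into the headers the
pipeline reads.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fdr import ENGINES, PSM, write_psm_table
from .filters import MONOISOTOPIC_MASS, DependentPeptideRecord, write_dependent_table
from .proteome import CleavageSpec, PeptideIndex, ProteinRecord, digest
from .variants import (
    FusionEvent,
    SearchDatabase,
    VariantPeptide,
    VariantRecord,
    apply_variant,
    build_search_database,
    collapse_duplicates,
    enumerate_variant_peptides,
    fusion_peptides,
    write_database_fasta,
    write_fusion_table,
    write_variant_table,
)

__all__ = [
    "SimulationConfig",
    "SimulationScaffold",
    "SimulatedDataset",
    "generate_proteome",
    "implant_variants",
    "generate_fusions",
    "prepare_scaffold",
    "simulate_psm_tables",
    "write_fixture_dir",
    "write_proteome_fasta",
]

#: Approximate vertebrate amino-acid background frequencies for the 18
#: residues other than K/R; K/R frequency is a tunable knob because it sets
#: the tryptic peptide length distribution.
_NON_KR = "ACDEFGHILMNPQSTVWY"
_NON_KR_WEIGHTS = np.array(
    [8.3, 1.4, 5.4, 6.8, 3.9, 7.1, 2.3, 6.0, 9.7, 2.4, 4.1, 6.3, 4.0, 6.6, 5.5, 6.9, 1.1, 2.9]
)
_NON_KR_WEIGHTS = _NON_KR_WEIGHTS / _NON_KR_WEIGHTS.sum()

#: One codon per residue (stop-free), for reverse-translating fusion fragments.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCG", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; the defaults are the study
    conditions used throughout the test-suite.

    Score distributions are Gaussian: correct PSMs at ``true_score_mean``
    (on the -log10 e-value scale), incorrect target and decoy PSMs share
    ``null_score_mean``. ``kr_frequency`` is the combined K+R residue
    frequency (0.11 puts the median tryptic peptide length in the 8-20
    range typical of real proteomes). ``present_fraction`` is the fraction
    of database variant peptides actually "expressed"; the rest serve as
    the pool for incorrect target matches.
    """

    seed: int = 0
    n_proteins: int = 25
    protein_length_range: tuple[int, int] = (150, 400)
    kr_frequency: float = 0.11
    n_sav: int = 40
    n_insertion: int = 5
    n_deletion: int = 5
    n_frameshift: int = 3
    n_stop_loss: int = 2
    n_fusions: int = 2
    cleavage: CleavageSpec = field(default_factory=CleavageSpec)
    true_score_mean: float = 10.0
    true_score_sd: float = 2.0
    null_score_mean: float = 5.0
    null_score_sd: float = 2.0
    engine_detection_probabilities: dict[str, float] = field(
        default_factory=lambda: {"tandem": 0.90, "comet": 0.85, "msgf": 0.95}
    )
    present_fraction: float = 0.85
    spectra_per_true_peptide: int = 5
    n_true_reference_peptides: int = 150
    n_noise_spectra_reference: int = 600
    n_noise_spectra_variant: int = 1200
    charges: tuple[int, ...] = (2, 3)
    charge_probabilities: tuple[float, ...] = (0.6, 0.4)
    fraction_ptm_confusable: float = 0.1
    fraction_ptm_matching: float = 0.1
    n_dependent_savs: int = 20
    raw_file: str = "sample01.raw"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_proteome(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[ProteinRecord]:
    """Random proteins over the 20 residues, K/R frequency set by config."""
    rng = config.rng() if rng is None else rng
    p_kr = config.kr_frequency
    residues = np.array(list(_NON_KR) + ["K", "R"])
    weights = np.concatenate([_NON_KR_WEIGHTS * (1 - p_kr), [p_kr / 2, p_kr / 2]])
    lo, hi = config.protein_length_range
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(residues, size=length, p=weights))
        records.append(
            ProteinRecord(
                accession=f"PROT{i:04d}",
                description=f"synthetic protein {i}",
                sequence=seq,
                source="uniprot_canonical",
            )
        )
    return records


def _draw_sav(seq: str, rng: np.random.Generator) -> tuple[int, str, str]:
    """An internal, cleavage-neutral substitution (ref/alt outside K/R/P,
    so the tryptic cleavage pattern is unchanged)."""
    margin = 20
    candidates = [
        i for i in range(margin, len(seq) - margin) if seq[i] not in "KRP"
    ]
    pos = int(rng.choice(candidates)) + 1
    ref = seq[pos - 1]
    alts = [a for a in _NON_KR if a not in (ref, "P")]
    alt = str(rng.choice(alts))
    return pos, ref, alt


def implant_variants(
    proteome: Sequence[ProteinRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Place variants at valid positions and record the ground truth.

    Returns the variant records and a table with one row per expected
    variant peptide (variant_id, gene, protein_accession, class, peptide,
    mutated span within the peptide), computed with
    :func:`enumerate_variant_peptides` against the proteome's own
    I/L-collapsed index. A variant whose peptides are all filtered away
    appears with an empty peptide field.
    """
    rng = config.rng() if rng is None else rng
    index = PeptideIndex.build([list(proteome)], config.cleavage)
    margin = 20
    eligible = [p for p in proteome if len(p) >= 2 * margin + 10]
    if not eligible:
        raise ValueError("proteome has no protein long enough to host variants")
    tags = np.array(sorted({"dbsnp", "cosmic", "uniprot", "exome", "rnaseq"}))

    variants: list[VariantRecord] = []
    counter = 0

    def _provenance() -> frozenset[str]:
        k = int(rng.integers(1, 3))
        return frozenset(rng.choice(tags, size=k, replace=False).tolist())

    for _ in range(config.n_sav):
        protein = eligible[int(rng.integers(len(eligible)))]
        pos, ref, alt = _draw_sav(protein.sequence, rng)
        counter += 1
        variants.append(
            VariantRecord(
                variant_id=f"v{counter:04d}",
                gene=f"GENE{protein.accession[-4:]}",
                protein_accession=protein.accession,
                variant_class="sav",
                position=pos,
                ref_seq=ref,
                alt_seq=alt,
                provenance=_provenance(),
            )
        )
    for _ in range(config.n_insertion):
        protein = eligible[int(rng.integers(len(eligible)))]
        pos = int(rng.integers(margin, len(protein) - margin)) + 1
        alt = "".join(rng.choice(list(_NON_KR), size=int(rng.integers(1, 4))))
        counter += 1
        variants.append(
            VariantRecord(
                variant_id=f"v{counter:04d}",
                gene=f"GENE{protein.accession[-4:]}",
                protein_accession=protein.accession,
                variant_class="insertion",
                position=pos,
                ref_seq="",
                alt_seq=alt,
                provenance=_provenance(),
            )
        )
    for _ in range(config.n_deletion):
        protein = eligible[int(rng.integers(len(eligible)))]
        pos = int(rng.integers(margin, len(protein) - margin)) + 1
        length = int(rng.integers(1, 4))
        counter += 1
        variants.append(
            VariantRecord(
                variant_id=f"v{counter:04d}",
                gene=f"GENE{protein.accession[-4:]}",
                protein_accession=protein.accession,
                variant_class="deletion",
                position=pos,
                ref_seq=protein.sequence[pos - 1 : pos - 1 + length],
                alt_seq="",
                provenance=_provenance(),
            )
        )
    for cls_, count in (("frameshift", config.n_frameshift), ("stop_loss", config.n_stop_loss)):
        for _ in range(count):
            protein = eligible[int(rng.integers(len(eligible)))]
            pos = len(protein) + 1 if cls_ == "stop_loss" else int(rng.integers(margin, len(protein) - margin)) + 1
            tail = "".join(rng.choice(list(_NON_KR + "KR"), size=int(rng.integers(10, 31))))
            counter += 1
            variants.append(
                VariantRecord(
                    variant_id=f"v{counter:04d}",
                    gene=f"GENE{protein.accession[-4:]}",
                    protein_accession=protein.accession,
                    variant_class=cls_,
                    position=pos,
                    ref_seq="",
                    alt_seq=tail,
                    provenance=_provenance(),
                )
            )

    by_accession = {p.accession: p for p in proteome}
    rows = []
    for variant in variants:
        mutated, span = apply_variant(by_accession[variant.protein_accession], variant)
        peptides = enumerate_variant_peptides(
            mutated, span, config.cleavage, index, variant.variant_id, variant.provenance
        )
        if not peptides:
            rows.append(
                {
                    "variant_id": variant.variant_id,
                    "gene": variant.gene,
                    "protein_accession": variant.protein_accession,
                    "class": variant.variant_class,
                    "peptide": "",
                    "mutated_start": 0,
                    "mutated_end": 0,
                }
            )
        for pep in peptides:
            rows.append(
                {
                    "variant_id": variant.variant_id,
                    "gene": variant.gene,
                    "protein_accession": variant.protein_accession,
                    "class": variant.variant_class,
                    "peptide": pep.sequence,
                    "mutated_start": pep.mutated_span[0],
                    "mutated_end": pep.mutated_span[1],
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=["variant_id", "gene", "protein_accession", "class", "peptide", "mutated_start", "mutated_end"],
    )
    return variants, truth


def generate_fusions(
    proteome: Sequence[ProteinRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[FusionEvent]:
    """Fusions built by reverse-translating an N-terminal fragment of one
    protein and an internal fragment of another; alternating in-frame and
    three-frame events."""
    rng = config.rng() if rng is None else rng
    fusions: list[FusionEvent] = []
    for i in range(config.n_fusions):
        a, b = rng.choice(len(proteome), size=2, replace=False)
        pa, pb = proteome[int(a)], proteome[int(b)]
        a_len = int(rng.integers(20, min(40, len(pa) - 1)))
        b_start = int(rng.integers(10, max(11, len(pb) - 40)))
        five = "".join(_CODON[aa] for aa in pa.sequence[:a_len] if aa in _CODON)
        three = "".join(_CODON[aa] for aa in pb.sequence[b_start : b_start + 40] if aa in _CODON)
        fusions.append(
            FusionEvent(
                fusion_id=f"fus{i:03d}:{pa.accession}:{pb.accession}",
                five_prime_nt=five,
                three_prime_nt=three,
                frame_mode="in_frame" if i % 2 == 0 else "three_frame",
                provenance="rnaseq" if i % 2 == 0 else "cosmic",
            )
        )
    return fusions


@dataclass
class SimulationScaffold:
    """The structural part of a simulated experiment (proteome, database,
    ground-truth peptide sets), reusable across independent score draws."""

    proteome: list[ProteinRecord]
    variants: list[VariantRecord]
    fusions: list[FusionEvent]
    canonical_index: PeptideIndex
    variant_peptides: list[VariantPeptide]
    database: SearchDatabase
    variant_truth: pd.DataFrame
    reference_peptides: pd.DataFrame  # peptide -> accessions (semicolon-joined)
    parent_accessions: dict[str, set[str]]
    variant_site_info: dict[str, tuple[int, str, str]]
    variant_headers: dict[str, str]


def prepare_scaffold(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulationScaffold:
    """Generate proteome, variants, fusions and the search database once."""
    rng = config.rng() if rng is None else rng
    proteome = generate_proteome(config, rng)
    variants, variant_truth = implant_variants(proteome, config, rng)
    fusions = generate_fusions(proteome, config, rng)

    index = PeptideIndex.build([proteome], config.cleavage)
    by_accession = {p.accession: p for p in proteome}
    all_peptides: list[VariantPeptide] = []
    parent: dict[str, set[str]] = {}
    site_info: dict[str, tuple[int, str, str]] = {}
    for variant in variants:
        mutated, span = apply_variant(by_accession[variant.protein_accession], variant)
        peps = enumerate_variant_peptides(
            mutated, span, config.cleavage, index, variant.variant_id, variant.provenance
        )
        for pep in peps:
            parent.setdefault(pep.sequence, set()).add(variant.protein_accession)
            if variant.variant_class == "sav":
                site_info[pep.sequence] = (pep.mutated_span[0], variant.ref_seq, variant.alt_seq)
        all_peptides.extend(peps)
    for fusion in fusions:
        peps = fusion_peptides(fusion, config.cleavage, index)
        partners = fusion.fusion_id.split(":")[1:]
        for pep in peps:
            parent.setdefault(pep.sequence, set()).update(partners)
        all_peptides.extend(peps)

    collapsed = collapse_duplicates(all_peptides)
    lookup = {v.variant_id: v for v in variants}
    database = build_search_database(proteome, collapsed, lookup)
    headers = {e.sequence: e.header for e in database.by_class("variant_target")}

    ref_rows: dict[str, set[str]] = {}
    variant_seqs = {p.sequence for p in collapsed}
    for protein in proteome:
        for occ in digest(protein, config.cleavage):
            if occ.sequence not in variant_seqs:
                ref_rows.setdefault(occ.sequence, set()).add(protein.accession)
    reference_peptides = pd.DataFrame(
        [{"peptide": s, "accessions": ";".join(sorted(a))} for s, a in sorted(ref_rows.items())]
    )
    return SimulationScaffold(
        proteome=proteome,
        variants=variants,
        fusions=fusions,
        canonical_index=index,
        variant_peptides=collapsed,
        database=database,
        variant_truth=variant_truth,
        reference_peptides=reference_peptides,
        parent_accessions=parent,
        variant_site_info=site_info,
        variant_headers=headers,
    )


@dataclass
class SimulatedDataset:
    """One simulated experiment: per-engine PSMs, dependent-peptide records,
    and sidecar truth tables."""

    scaffold: SimulationScaffold
    psms: dict[str, list[PSM]]
    dependents: list[DependentPeptideRecord]
    truth: pd.DataFrame  # engine, raw_file, scan_id, peptide, partition, label
    dependent_truth: pd.DataFrame


def _sample_charge(config: SimulationConfig, rng: np.random.Generator) -> int:
    return int(rng.choice(config.charges, p=config.charge_probabilities))


def simulate_psm_tables(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    scaffold: SimulationScaffold | None = None,
) -> SimulatedDataset:
    """Draw one experiment's PSM tables, dependent records, and truth labels.

    Correct spectra are shared across engines (each engine reports one with
    its detection probability and an independent score draw from the true
    distribution); incorrect spectra are engine-specific, split evenly in
    expectation between target and decoy matches with scores from the
    shared null distribution. For every protein hosting a variant or a
    fusion partner, two canonical peptides are forced into the "present"
    reference set, so expressed variants always have same-sample abundance
    evidence.
    """
    rng = config.rng() if rng is None else rng
    if scaffold is None:
        scaffold = prepare_scaffold(config, rng)
    raw = config.raw_file
    engines = list(ENGINES)
    det = config.engine_detection_probabilities

    var_seqs = [p.sequence for p in scaffold.variant_peptides]
    n_present = max(1, int(round(config.present_fraction * len(var_seqs)))) if var_seqs else 0
    present_var = (
        sorted(rng.choice(var_seqs, size=n_present, replace=False).tolist()) if n_present else []
    )
    noise_var_pool = sorted(set(var_seqs) - set(present_var))

    ref_df = scaffold.reference_peptides
    ref_seqs = ref_df["peptide"].tolist()
    ref_accs = dict(zip(ref_df["peptide"], ref_df["accessions"]))
    host_accessions = {a for parents in scaffold.parent_accessions.values() for a in parents}
    forced: list[str] = []
    by_host: dict[str, list[str]] = {}
    for seq, accs in ref_accs.items():
        for acc in accs.split(";"):
            by_host.setdefault(acc, []).append(seq)
    for acc in sorted(host_accessions):
        forced.extend(by_host.get(acc, [])[:2])
    n_ref = min(config.n_true_reference_peptides, len(ref_seqs))
    present_ref = sorted(
        set(rng.choice(ref_seqs, size=n_ref, replace=False).tolist()) | set(forced)
    )
    noise_ref_pool = sorted(set(ref_seqs) - set(present_ref))

    scan = 0
    psms: dict[str, list[PSM]] = {e: [] for e in engines}
    truth_rows: list[dict] = []
    dependents: list[DependentPeptideRecord] = []
    dep_truth_rows: list[dict] = []

    def _true_spectra(peptide: str, partition: str) -> None:
        nonlocal scan
        if partition == "variant":
            accessions = frozenset({scaffold.variant_headers[peptide]})
            db_class = "variant_target"
        else:
            accessions = frozenset(ref_accs[peptide].split(";"))
            db_class = "reference_target"
        for _ in range(config.spectra_per_true_peptide):
            scan += 1
            charge = _sample_charge(config, rng)
            reported = False
            for engine in engines:
                if rng.random() >= det[engine]:
                    continue
                reported = True
                score = float(rng.normal(config.true_score_mean, config.true_score_sd))
                psms[engine].append(
                    PSM(raw, scan, peptide, charge, engine, score, db_class, accessions)
                )
                truth_rows.append(
                    {
                        "engine": engine,
                        "raw_file": raw,
                        "scan_id": scan,
                        "peptide": peptide,
                        "partition": partition,
                        "label": "true",
                    }
                )
            if reported and partition == "variant":
                _maybe_dependent(peptide, scan)

    def _maybe_dependent(peptide: str, scan_id: int) -> None:
        info = scaffold.variant_site_info.get(peptide)
        if info is None:
            return
        site, ref, alt = info
        parents = sorted(scaffold.parent_accessions.get(peptide, {"unknown"}))
        base = peptide[: site - 1] + ref + peptide[site:]
        u = rng.random()
        if u < config.fraction_ptm_confusable:
            # conflicting explanation: confidently localized PTM at another site
            other = site + 1 if site < len(peptide) else site - 1
            dependents.append(
                DependentPeptideRecord(raw, scan_id, base, parents[0], 15.9949, other, 0.9)
            )
            dep_truth_rows.append({"raw_file": raw, "scan_id": scan_id, "kind": "conflicting"})
        elif u < config.fraction_ptm_confusable + config.fraction_ptm_matching:
            # concordant explanation: same site, delta equal to the substitution
            delta = MONOISOTOPIC_MASS[alt] - MONOISOTOPIC_MASS[ref]
            dependents.append(
                DependentPeptideRecord(raw, scan_id, base, parents[0], delta, site, 0.9)
            )
            dep_truth_rows.append({"raw_file": raw, "scan_id": scan_id, "kind": "matching"})

    for peptide in present_var:
        _true_spectra(peptide, "variant")
    for peptide in present_ref:
        _true_spectra(peptide, "reference")

    decoy_var_pool = var_seqs
    decoy_ref_pool = ref_seqs

    def _noise_spectra(n: int, partition: str, engine: str) -> None:
        nonlocal scan
        target_pool = noise_var_pool if partition == "variant" else noise_ref_pool
        decoy_pool = decoy_var_pool if partition == "variant" else decoy_ref_pool
        for _ in range(n):
            scan += 1
            charge = _sample_charge(config, rng)
            score = float(rng.normal(config.null_score_mean, config.null_score_sd))
            as_decoy = bool(rng.random() < 0.5) if target_pool else True
            if as_decoy:
                seq = decoy_pool[int(rng.integers(len(decoy_pool)))]
                peptide = seq[::-1]
                if partition == "variant":
                    accessions = frozenset({"rev_" + scaffold.variant_headers[seq]})
                else:
                    accessions = frozenset("rev_" + a for a in ref_accs[seq].split(";"))
                db_class = f"{partition}_decoy"
                label = "decoy"
            else:
                peptide = target_pool[int(rng.integers(len(target_pool)))]
                if partition == "variant":
                    accessions = frozenset({scaffold.variant_headers[peptide]})
                else:
                    accessions = frozenset(ref_accs[peptide].split(";"))
                db_class = f"{partition}_target"
                label = "incorrect"
            psms[engine].append(PSM(raw, scan, peptide, charge, engine, score, db_class, accessions))
            truth_rows.append(
                {
                    "engine": engine,
                    "raw_file": raw,
                    "scan_id": scan,
                    "peptide": peptide,
                    "partition": partition,
                    "label": label,
                }
            )

    for engine in engines:
        _noise_spectra(config.n_noise_spectra_variant, "variant", engine)
        _noise_spectra(config.n_noise_spectra_reference, "reference", engine)

    # standalone dependent-peptide substitutions (for variant calling)
    if config.n_dependent_savs and ref_seqs:
        long_refs = [s for s in ref_seqs if len(s) >= 8]
        for _ in range(config.n_dependent_savs):
            base = long_refs[int(rng.integers(len(long_refs)))]
            site = int(rng.integers(1, len(base) + 1))
            ref = base[site - 1]
            # a substitution with no mass shift (I<->L) is invisible to a
            # dependent-peptide search, so never implant one
            alt = str(
                rng.choice(
                    [
                        a
                        for a in MONOISOTOPIC_MASS
                        if abs(MONOISOTOPIC_MASS[a] - MONOISOTOPIC_MASS[ref]) > 0.01
                    ]
                )
            )
            delta = MONOISOTOPIC_MASS[alt] - MONOISOTOPIC_MASS[ref]
            prob = float(rng.uniform(0.95, 1.0))
            scan += 1
            dependents.append(
                DependentPeptideRecord(raw, scan, base, ref_accs[base].split(";")[0], delta, site, prob)
            )
            dep_truth_rows.append(
                {
                    "raw_file": raw,
                    "scan_id": scan,
                    "kind": "sav",
                    "base_peptide": base,
                    "site": site,
                    "ref": ref,
                    "alt": alt,
                }
            )

    truth = pd.DataFrame(
        truth_rows, columns=["engine", "raw_file", "scan_id", "peptide", "partition", "label"]
    )
    dependent_truth = pd.DataFrame(
        dep_truth_rows, columns=["raw_file", "scan_id", "kind", "base_peptide", "site", "ref", "alt"]
    )
    return SimulatedDataset(
        scaffold=scaffold,
        psms=psms,
        dependents=dependents,
        truth=truth,
        dependent_truth=dependent_truth,
    )


def write_proteome_fasta(proteome: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in proteome:
            fh.write(f">{rec.accession} {rec.description}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fixture_dir(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the full fixture set: reference FASTA, variant/fusion tables,
    the split target-decoy database, per-engine PSM tables, dependent
    peptides, and the sidecar truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scaffold = dataset.scaffold
    write_proteome_fasta(scaffold.proteome, outdir / "reference.fasta")
    write_variant_table(scaffold.variants, outdir / "variants.tsv")
    write_fusion_table(scaffold.fusions, outdir / "fusions.tsv")
    write_database_fasta(scaffold.database, outdir / "database.fasta")
    for engine, psms in dataset.psms.items():
        write_psm_table(psms, outdir / f"psms_{engine}.tsv")
    write_dependent_table(dataset.dependents, outdir / "dependents.tsv")
    dataset.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    dataset.dependent_truth.to_csv(outdir / "dependent_truth.tsv", sep="\t", index=False)
    scaffold.variant_truth.to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)
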