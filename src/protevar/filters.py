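"""Post-search filter cascade and dependent-peptide substitution calling.

A spectral-FDR cutoff alone does not make a variant PSM trustworthy: the
peptide may be indistinguishable from a reference peptide (I/L isobars), the
mass shift may actually be a chemical/post-translational modification on a
reference peptide, or the parent protein may show no other evidence of
expression in the sample. Three filters address these failure modes in
order:

1. reference-proteome filtration with I/L equivalence (against Ensembl-,
   RefSeq-, and UniProt-style references together);
2. a chemical-modification conflict filter driven by dependent-peptide
   records (mass-shifted re-assignments of already-identified peptides),
   applied conservatively: a discordant dependent explanation removes the
   PSM, a concordant one (same site, delta mass equal to the ref->alt
   residue mass difference) retains it;
3. a protein-abundance filter requiring at least one canonical-sequence
   PSM of the same parent protein in the same sample.

Dependent-peptide records are additionally mined directly for single
amino-acid variants: a confidently localized mass shift that matches the
mass difference from the base residue to exactly one other standard residue
is itself a substitution call.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pyteomics import mass as _pmass

from .fdr import PSM
from .proteome import PeptideIndex
from .variants import DECOY_PREFIX

__all__ = [
    "MONOISOTOPIC_MASS",
    "DependentPeptideRecord",
    "SavCall",
    "Removal",
    "read_dependent_table",
    "write_dependent_table",
    "reference_filter",
    "ptm_conflict_filter",
    "dependent_variant_calls",
    "abundance_filter",
    "apply_filter_cascade",
    "removal_log_frame",
]

#: Monoisotopic residue masses (Daltons) for the 20 standard amino acids.
MONOISOTOPIC_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

DEPENDENT_TSV_COLUMNS = [
    "raw_file",
    "scan_id",
    "base_peptide",
    "base_protein",
    "delta_mass",
    "site_position",
    "positional_probability",
]


@dataclass(frozen=True)
class DependentPeptideRecord:
    """A spectrum explained as a mass-shifted modification of an already
    identified (base) peptide, with the localization confidence of the
    proposed site."""

    raw_file: str
    scan_id: int
    base_peptide: str
    base_protein: str
    delta_mass: float
    site_position: int
    positional_probability: float

    def __post_init__(self) -> None:
        if not (1 <= self.site_position <= len(self.base_peptide)):
            raise ValueError(
                f"{self.raw_file}:{self.scan_id}: site {self.site_position} outside base peptide"
            )
        if not (0.0 <= self.positional_probability <= 1.0):
            raise ValueError(f"{self.raw_file}:{self.scan_id}: positional probability outside [0,1]")


@dataclass(frozen=True)
class SavCall:
    """A single amino-acid variant inferred from a dependent peptide."""

    raw_file: str
    scan_id: int
    base_protein: str
    base_peptide: str
    site_position: int
    ref: str
    candidates: tuple[str, ...]
    ambiguous: bool

    @property
    def alt(self) -> str | None:
        """The called substitution when unambiguous, else None."""
        return self.candidates[0] if not self.ambiguous else None


@dataclass(frozen=True)
class Removal:
    """One PSM removed by one filter, with the evidence that removed it."""

    filter_name: str
    psm: PSM
    reason: str
    evidence: str


def read_dependent_table(path: str | Path) -> list[DependentPeptideRecord]:
    """Read dependent-peptide records from the documented tab-delimited
    dialect (a MaxQuant dependent-peptide export subset)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DEPENDENT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        DependentPeptideRecord(
            raw_file=row.raw_file,
            scan_id=int(row.scan_id),
            base_peptide=row.base_peptide,
            base_protein=row.base_protein,
            delta_mass=float(row.delta_mass),
            site_position=int(row.site_position),
            positional_probability=float(row.positional_probability),
        )
        for row in df.itertuples(index=False)
    ]


def write_dependent_table(records: Sequence[DependentPeptideRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "raw_file": r.raw_file,
                "scan_id": r.scan_id,
                "base_peptide": r.base_peptide,
                "base_protein": r.base_protein,
                "delta_mass": r.delta_mass,
                "site_position": r.site_position,
                "positional_probability": r.positional_probability,
            }
            for r in records
        ],
        columns=DEPENDENT_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def reference_filter(
    psms: Sequence[PSM],
    index: PeptideIndex,
) -> tuple[list[PSM], list[Removal]]:
    """Remove variant PSMs whose I/L-collapsed peptide occurs in any
    reference proteome; each removal records the matching source(s)."""
    survivors: list[PSM] = []
    removals: list[Removal] = []
    for psm in psms:
        sources = index.sources(psm.peptide)
        if sources:
            removals.append(
                Removal(
                    filter_name="reference",
                    psm=psm,
                    reason="peptide matches reference proteome under I/L collapse",
                    evidence=",".join(sorted(sources)),
                )
            )
        else:
            survivors.append(psm)
    return survivors, removals


def ptm_conflict_filter(
    psms: Sequence[PSM],
    dependents: Sequence[DependentPeptideRecord],
    variant_site_info: Mapping[str, tuple[int, str, str]] | None = None,
    prob_floor: float = 0.8,
    mass_tol: float = 0.01,
) -> tuple[list[PSM], list[Removal]]:
    """Remove variant PSMs whose spectrum has a discordant dependent-peptide
    explanation.

    Dependent records below ``prob_floor`` positional probability are
    ignored. For a confidently localized record on the same (raw_file,
    scan_id) spectrum: if its site matches the PSM's mutated position and
    its delta mass equals the ref->alt residue mass difference within
    ``mass_tol``, the two explanations describe the same mutation and the
    PSM is retained; any other confidently localized explanation is a
    conflict and the PSM is removed (preference is given to the
    dependent-peptide assignment — the conservative choice).

    ``variant_site_info`` maps peptide sequence to (site within peptide,
    ref residue, alt residue); PSMs whose peptide has no entry (fusions,
    indels) are removed on any confident dependent record, since
    concordance cannot be established.
    """
    by_scan: dict[tuple[str, int], list[DependentPeptideRecord]] = {}
    for rec in dependents:
        if rec.positional_probability > prob_floor:
            by_scan.setdefault((rec.raw_file, rec.scan_id), []).append(rec)

    survivors: list[PSM] = []
    removals: list[Removal] = []
    for psm in psms:
        conflicting = None
        for rec in by_scan.get((psm.raw_file, psm.scan_id), ()):
            info = (variant_site_info or {}).get(psm.peptide)
            if info is None:
                conflicting = (rec, "no site information to establish concordance")
                break
            site, ref, alt = info
            if rec.site_position != site:
                conflicting = (rec, f"dependent site {rec.site_position} != mutated site {site}")
                break
            expected = MONOISOTOPIC_MASS[alt] - MONOISOTOPIC_MASS[ref]
            if abs(rec.delta_mass - expected) > mass_tol:
                conflicting = (
                    rec,
                    f"delta {rec.delta_mass:+.4f} Da inconsistent with {ref}->{alt} ({expected:+.4f} Da)",
                )
                break
        if conflicting is None:
            survivors.append(psm)
        else:
            rec, why = conflicting
            removals.append(
                Removal(
                    filter_name="ptm_conflict",
                    psm=psm,
                    reason=why,
                    evidence=f"{rec.base_peptide}@{rec.site_position} p={rec.positional_probability:.2f}",
                )
            )
    return survivors, removals


def dependent_variant_calls(
    dependents: Sequence[DependentPeptideRecord],
    prob_floor: float = 0.95,
    mass_tol: float = 0.01,
) -> list[SavCall]:
    """Call single amino-acid variants from dependent-peptide records.

    For each record with positional probability >= ``prob_floor``, the
    delta mass is compared with the mass difference from the base residue
    to every other standard residue. Exactly one match within ``mass_tol``
    yields an unambiguous substitution call; multiple matches are emitted
    flagged ambiguous (I/L, near-isobaric pairs at loose tolerances).
    Records whose delta mass is within ``mass_tol`` of zero are skipped:
    they are indistinguishable from the unmodified peptide.
    """
    calls: list[SavCall] = []
    for rec in dependents:
        if rec.positional_probability < prob_floor:
            continue
        if abs(rec.delta_mass) <= mass_tol:
            continue
        ref = rec.base_peptide[rec.site_position - 1]
        if ref not in MONOISOTOPIC_MASS:
            continue
        candidates = tuple(
            sorted(
                alt
                for alt, m in MONOISOTOPIC_MASS.items()
                if alt != ref and abs(rec.delta_mass - (m - MONOISOTOPIC_MASS[ref])) <= mass_tol
            )
        )
        if not candidates:
            continue
        calls.append(
            SavCall(
                raw_file=rec.raw_file,
                scan_id=rec.scan_id,
                base_protein=rec.base_protein,
                base_peptide=rec.base_peptide,
                site_position=rec.site_position,
                ref=ref,
                candidates=candidates,
                ambiguous=len(candidates) > 1,
            )
        )
    return calls


def abundance_filter(
    variant_psms: Sequence[PSM],
    canonical_psms: Sequence[PSM],
    parent_accessions: Mapping[str, Iterable[str]],
    sample_key: Callable[[PSM], str] | None = None,
) -> tuple[list[PSM], list[Removal]]:
    """Remove variant PSMs with no same-sample canonical evidence for the
    parent protein.

    ``parent_accessions`` maps a variant peptide sequence to the parent
    protein accession(s) of the variant(s) it carries; ``sample_key``
    extracts the sample identity from a PSM (default: the raw file).
    Matching is at the accession level; passing gene identifiers in both
    the map and the canonical PSM accessions gives a gene-level mode.
    """
    if sample_key is None:
        sample_key = lambda p: p.raw_file  # noqa: E731
    evidence: set[tuple[str, str]] = set()
    for psm in canonical_psms:
        if psm.is_decoy:
            continue
        sample = sample_key(psm)
        for acc in psm.protein_accessions:
            evidence.add((sample, acc.removeprefix(DECOY_PREFIX)))

    survivors: list[PSM] = []
    removals: list[Removal] = []
    for psm in variant_psms:
        sample = sample_key(psm)
        parents = set(parent_accessions.get(psm.peptide, ()))
        supported = sorted(p for p in parents if (sample, p) in evidence)
        if supported:
            survivors.append(psm)
        else:
            removals.append(
                Removal(
                    filter_name="abundance",
                    psm=psm,
                    reason="no canonical PSM for parent protein in the same sample",
                    evidence=",".join(sorted(parents)) or "no parent accession",
                )
            )
    return survivors, removals


def apply_filter_cascade(
    variant_psms: Sequence[PSM],
    index: PeptideIndex,
    dependents: Sequence[DependentPeptideRecord],
    canonical_psms: Sequence[PSM],
    parent_accessions: Mapping[str, Iterable[str]],
    variant_site_info: Mapping[str, tuple[int, str, str]] | None = None,
    prob_floor: float = 0.8,
    mass_tol: float = 0.01,
    sample_key: Callable[[PSM], str] | None = None,
) -> tuple[list[PSM], list[Removal]]:
    """Run the three filters in order (reference -> chemical-modification
    conflict -> protein abundance); each filter only removes, and every
    removal is attributed to exactly one filter."""
    survivors, removals = reference_filter(variant_psms, index)
    survivors, r2 = ptm_conflict_filter(
        survivors, dependents, variant_site_info, prob_floor=prob_floor, mass_tol=mass_tol
    )
    survivors, r3 = abundance_filter(survivors, canonical_psms, parent_accessions, sample_key=sample_key)
    return survivors, removals + r2 + r3


def removal_log_frame(removals: Sequence[Removal]) -> pd.DataFrame:
    """Tabulate removals (filter name, spectrum, peptide, reason, evidence)."""
    return pd.DataFrame(
        [
            {
                "filter": r.filter_name,
                "raw_file": r.psm.raw_file,
                "scan_id": r.psm.scan_id,
                "engine": r.psm.engine,
                "peptide": r.psm.peptide,
                "reason": r.reason,
                "evidence": r.evidence,
            }
            for r in removals
        ],
        columns=["filter", "raw_file", "scan_id", "engine", "peptide", "reason", "evidence"],
    )
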