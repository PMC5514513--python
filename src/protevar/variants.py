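"""Variant application, variant/fusion peptide enumeration, and split
target-decoy search database construction.

Protein-level variant records (single amino-acid variants, insertions,
deletions, frameshifts, stop losses) are applied to reference sequences; the
tryptic peptides overlapping the mutated span, absent from the canonical
reference under I/L equivalence, become the variant partition of the search
database. Fusions are handled in nucleotide space: the 5'/3' fragments are
concatenated and translated (three-frame or in-frame), and only peptides whose
residue span crosses the junction are kept. Every target entry gets a
full-sequence-reversal decoy in its own decoy class, so FDR can later be
estimated separately for the reference and variant partitions.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .proteome import (
    CleavageSpec,
    PeptideIndex,
    ProteinRecord,
    digest,
)

__all__ = [
    "VariantRecord",
    "FusionEvent",
    "VariantPeptide",
    "SearchDatabase",
    "VariantApplicationError",
    "VARIANT_CLASSES",
    "PROVENANCE_TAGS",
    "DECOY_PREFIX",
    "VARIANT_MARKER",
    "apply_variant",
    "enumerate_variant_peptides",
    "fusion_peptides",
    "collapse_duplicates",
    "build_search_database",
    "variant_header",
    "parse_variant_header",
    "write_database_fasta",
    "read_variant_table",
    "write_variant_table",
    "read_fusion_table",
    "write_fusion_table",
]

VARIANT_CLASSES = frozenset({"sav", "insertion", "deletion", "frameshift", "stop_loss"})
PROVENANCE_TAGS = frozenset({"dbsnp", "cosmic", "uniprot", "exome", "rnaseq"})

#: Decoy entries are marked by this header prefix.
DECOY_PREFIX = "rev_"
#: Variant-partition entries are marked by this header prefix.
VARIANT_MARKER = "var|"

_NT_ALPHABET = frozenset("ACGTN")


class VariantApplicationError(ValueError):
    """A variant is inconsistent with its reference protein."""


@dataclass(frozen=True)
class VariantRecord:
    """A protein-level variant, as emitted by a consequence predictor.

    ``position`` is the 1-based protein coordinate where the affected span
    starts. ``ref_seq`` is the residue run consumed (empty for insertions);
    ``alt_seq`` the run introduced. For frameshift/stop_loss, ``alt_seq``
    must carry the complete novel C-terminal sequence from ``position``
    onward — nucleotide-level consequence calling happens upstream.
    """

    variant_id: str
    gene: str
    protein_accession: str
    variant_class: str
    position: int
    ref_seq: str
    alt_seq: str
    provenance: frozenset[str]

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"{self.variant_id}: unknown variant class {self.variant_class!r}")
        if self.position < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")
        if self.variant_class == "sav" and (len(self.ref_seq) != 1 or len(self.alt_seq) != 1):
            raise ValueError(f"{self.variant_id}: sav requires single ref and alt residues")
        if not self.provenance:
            raise ValueError(f"{self.variant_id}: provenance must be non-empty")
        unknown = set(self.provenance) - PROVENANCE_TAGS
        if unknown:
            raise ValueError(f"{self.variant_id}: unknown provenance tags {sorted(unknown)}")
        object.__setattr__(self, "provenance", frozenset(self.provenance))


@dataclass(frozen=True)
class FusionEvent:
    """A gene fusion given as 5' and 3' coding-nucleotide fragments meeting
    at the junction."""

    fusion_id: str
    five_prime_nt: str
    three_prime_nt: str
    frame_mode: str  # "three_frame" or "in_frame"
    provenance: str

    def __post_init__(self) -> None:
        if self.frame_mode not in ("three_frame", "in_frame"):
            raise ValueError(f"{self.fusion_id}: frame_mode must be three_frame or in_frame")
        if not self.five_prime_nt or not self.three_prime_nt:
            raise ValueError(f"{self.fusion_id}: both nucleotide fragments must be non-empty")
        for name, nt in (("five_prime_nt", self.five_prime_nt), ("three_prime_nt", self.three_prime_nt)):
            bad = set(nt.upper()) - _NT_ALPHABET
            if bad:
                raise ValueError(f"{self.fusion_id}: invalid nucleotides {sorted(bad)} in {name}")
        if self.frame_mode == "in_frame" and len(self.five_prime_nt) % 3 != 0:
            raise ValueError(f"{self.fusion_id}: in_frame requires 5' length divisible by 3")


@dataclass(frozen=True)
class VariantPeptide:
    """A tryptic peptide carrying variant-derived residues.

    ``mutated_span`` is the 1-based start/end, within the peptide, of the
    residues attributable to the variant. ``variant_ids`` and
    ``database_tags`` accumulate contributors when duplicates are collapsed.
    """

    sequence: str
    variant_ids: frozenset[str]
    mutated_span: tuple[int, int]
    missed_cleavages: int
    database_tags: frozenset[str]

    def __post_init__(self) -> None:
        s, e = self.mutated_span
        if not (1 <= s <= e <= len(self.sequence)):
            raise ValueError(f"mutated_span {self.mutated_span} outside peptide {self.sequence!r}")
        object.__setattr__(self, "variant_ids", frozenset(self.variant_ids))
        object.__setattr__(self, "database_tags", frozenset(self.database_tags))


def apply_variant(protein: ProteinRecord, variant: VariantRecord) -> tuple[ProteinRecord, tuple[int, int]]:
    """Apply ``variant`` to ``protein``; return the mutated record and the
    affected span (1-based inclusive, on the mutated sequence).

    Span conventions: a SAV's span is the substituted residue; an
    insertion's span is the inserted run plus one flanking residue on each
    side (a peptide covering only the junction still differs from
    reference); a deletion's span is the junction residue pair;
    frameshift/stop_loss spans run from ``position`` to the new C-terminus.
    """
    seq = protein.sequence
    pos = variant.position
    cls_ = variant.variant_class
    vid = variant.variant_id

    def _check_ref() -> None:
        found = seq[pos - 1 : pos - 1 + len(variant.ref_seq)]
        if found != variant.ref_seq:
            raise VariantApplicationError(
                f"{vid}: reference mismatch at {protein.accession}:{pos} "
                f"(expected {variant.ref_seq!r}, found {found!r})"
            )

    if cls_ == "sav":
        if pos > len(seq):
            raise VariantApplicationError(f"{vid}: position {pos} beyond sequence length {len(seq)}")
        _check_ref()
        mutated = seq[: pos - 1] + variant.alt_seq + seq[pos:]
        span = (pos, pos)
    elif cls_ == "insertion":
        if pos > len(seq) + 1:
            raise VariantApplicationError(f"{vid}: insertion position {pos} beyond length+1")
        mutated = seq[: pos - 1] + variant.alt_seq + seq[pos - 1 :]
        span = (max(1, pos - 1), min(len(mutated), pos + len(variant.alt_seq)))
    elif cls_ == "deletion":
        if pos - 1 + len(variant.ref_seq) > len(seq):
            raise VariantApplicationError(f"{vid}: deleted span exceeds sequence length")
        _check_ref()
        mutated = seq[: pos - 1] + seq[pos - 1 + len(variant.ref_seq) :]
        if not mutated:
            raise VariantApplicationError(f"{vid}: deletion consumes the whole protein")
        span = (max(1, pos - 1), min(len(mutated), pos))
    elif cls_ in ("frameshift", "stop_loss"):
        if pos > len(seq) + 1:
            raise VariantApplicationError(f"{vid}: position {pos} beyond length+1")
        if not variant.alt_seq:
            raise VariantApplicationError(f"{vid}: {cls_} requires the novel C-terminal sequence in alt")
        mutated = seq[: pos - 1] + variant.alt_seq
        span = (pos, len(mutated))
    else:  # pragma: no cover - guarded by VariantRecord validation
        raise AssertionError(cls_)

    record = replace(protein, accession=f"{protein.accession}:{vid}", sequence=mutated)
    return record, span


def _peptides_overlapping_span(
    mutated: ProteinRecord,
    span: tuple[int, int],
    spec: CleavageSpec,
    reference_index: PeptideIndex | None,
    variant_id: str,
    database_tags: Iterable[str],
) -> list[VariantPeptide]:
    s, e = span
    tags = frozenset(database_tags)
    out: list[VariantPeptide] = []
    for occ in digest(mutated, spec):
        if occ.end < s or occ.start > e:
            continue
        if "X" in occ.sequence:
            continue
        if reference_index is not None and occ.sequence in reference_index:
            continue
        rel = (max(1, s - occ.start + 1), min(len(occ.sequence), e - occ.start + 1))
        out.append(
            VariantPeptide(
                sequence=occ.sequence,
                variant_ids=frozenset({variant_id}),
                mutated_span=rel,
                missed_cleavages=occ.missed_cleavages,
                database_tags=tags,
            )
        )
    return out


def enumerate_variant_peptides(
    mutated: ProteinRecord,
    span: tuple[int, int],
    spec: CleavageSpec,
    reference_index: PeptideIndex | None,
    variant_id: str = "",
    database_tags: Iterable[str] = (),
) -> list[VariantPeptide]:
    """Tryptic peptides of the mutated protein that overlap the affected span
    and are absent from the canonical reference under I/L collapse.

    For an internal SAV that neither creates nor destroys a cleavage site
    (and with length filters disabled) this yields exactly six peptides:
    one with zero missed cleavages, two with one, three with two.
    """
    s, e = span
    if not (1 <= s <= e <= len(mutated.sequence)):
        raise ValueError(f"span {span} outside mutated sequence of length {len(mutated.sequence)}")
    return _peptides_overlapping_span(mutated, span, spec, reference_index, variant_id, database_tags)


def _translate_prefix(nt: str) -> str:
    """Translate ``nt`` (frame 0), stopping at the first stop codon."""
    usable = nt[: len(nt) // 3 * 3]
    if not usable:
        return ""
    aa = str(Seq(usable).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


def fusion_peptides(
    event: FusionEvent,
    spec: CleavageSpec,
    reference_index: PeptideIndex | None,
) -> list[VariantPeptide]:
    """Tryptic peptides spanning the fusion junction.

    The concatenated coding sequence is translated in all three frames
    (``three_frame``) or in frame 0 only (``in_frame``); translation stops
    at the first stop codon per frame. A peptide is returned only if its
    residue span crosses the codon boundary encoding the junction; the
    reference-index filter applies as for any variant peptide.
    """
    nt = (event.five_prime_nt + event.three_prime_nt).upper()
    junction = len(event.five_prime_nt)  # boundary between nt[junction-1] and nt[junction]
    frames = (0,) if event.frame_mode == "in_frame" else (0, 1, 2)
    out: list[VariantPeptide] = []
    for frame in frames:
        aa = _translate_prefix(nt[frame:])
        if not aa:
            continue
        protein = ProteinRecord(
            accession=f"{event.fusion_id}:f{frame}",
            description="",
            sequence=aa,
            source="fusion",
        )
        # residue r (1-based) covers nucleotides frame+3(r-1)+1 .. frame+3r
        for occ in digest(protein, spec):
            nt_start = frame + 3 * (occ.start - 1) + 1
            nt_end = frame + 3 * occ.end
            if not (nt_start <= junction and nt_end >= junction + 1):
                continue
            if "X" in occ.sequence:
                continue
            if reference_index is not None and occ.sequence in reference_index:
                continue
            # residues whose codons touch the junction boundary
            r_lo = -(-(junction - frame) // 3)  # ceil
            r_hi = -(-(junction + 1 - frame) // 3)
            rel = (max(1, r_lo - occ.start + 1), min(len(occ.sequence), r_hi - occ.start + 1))
            out.append(
                VariantPeptide(
                    sequence=occ.sequence,
                    variant_ids=frozenset({event.fusion_id}),
                    mutated_span=rel,
                    missed_cleavages=occ.missed_cleavages,
                    database_tags=frozenset({event.provenance}),
                )
            )
    return out


def collapse_duplicates(peptides: Sequence[VariantPeptide]) -> list[VariantPeptide]:
    """Collapse peptides identical by exact sequence, merging their variant
    identifiers and database tags; output is sorted lexicographically by
    sequence. The representative span/missed-cleavage values come from the
    first contributor in input order."""
    by_seq: dict[str, VariantPeptide] = {}
    for pep in peptides:
        prev = by_seq.get(pep.sequence)
        if prev is None:
            by_seq[pep.sequence] = pep
        else:
            by_seq[pep.sequence] = replace(
                prev,
                variant_ids=prev.variant_ids | pep.variant_ids,
                database_tags=prev.database_tags | pep.database_tags,
                missed_cleavages=min(prev.missed_cleavages, pep.missed_cleavages),
            )
    return [by_seq[s] for s in sorted(by_seq)]


def variant_header(
    peptide: VariantPeptide,
    variants: Mapping[str, VariantRecord] | None = None,
    ordinal: int | None = None,
) -> str:
    """Header for a variant-partition FASTA entry.

    Grammar: ``var|<id[,id...]>|<gene[,gene...]>|<class[,class...]>|<tags>|<start-end>[|p<ordinal>]``.
    Gene and class are resolved through ``variants`` when given, else ``NA``.
    The ordinal disambiguates distinct peptides of one variant that would
    otherwise share every header field.
    """
    ids = sorted(peptide.variant_ids)
    bad = [i for i in ids if "|" in i or "," in i]
    if bad:
        raise ValueError(f"variant ids may not contain '|' or ',': {bad}")
    genes: list[str] = []
    classes: list[str] = []
    if variants:
        genes = sorted({variants[v].gene for v in ids if v in variants})
        classes = sorted({variants[v].variant_class for v in ids if v in variants})
    s, e = peptide.mutated_span
    parts = [
        ",".join(ids),
        ",".join(genes) or "NA",
        ",".join(classes) or "NA",
        ",".join(sorted(peptide.database_tags)) or "NA",
        f"{s}-{e}",
    ]
    if ordinal is not None:
        parts.append(f"p{ordinal}")
    return VARIANT_MARKER + "|".join(parts)


def parse_variant_header(header: str) -> dict[str, object]:
    """Invert :func:`variant_header`."""
    if not header.startswith(VARIANT_MARKER):
        raise ValueError(f"not a variant header: {header!r}")
    parts = header[len(VARIANT_MARKER) :].split("|")
    if len(parts) not in (5, 6):
        raise ValueError(f"malformed variant header: {header!r}")
    ids, genes, classes, tags, span = parts[:5]
    s, e = span.split("-")
    return {
        "variant_ids": frozenset(ids.split(",")),
        "genes": frozenset(g for g in genes.split(",") if g != "NA"),
        "classes": frozenset(c for c in classes.split(",") if c != "NA"),
        "database_tags": frozenset(t for t in tags.split(",") if t != "NA"),
        "mutated_span": (int(s), int(e)),
    }


DATABASE_CLASSES = ("reference_target", "variant_target", "reference_decoy", "variant_decoy")


@dataclass(frozen=True)
class DatabaseEntry:
    header: str
    sequence: str
    db_class: str


@dataclass
class SearchDatabase:
    """Split target-decoy search database: reference and variant targets,
    each paired with full-sequence-reversal decoys in its own decoy class."""

    entries: list[DatabaseEntry] = field(default_factory=list)

    def by_class(self, db_class: str) -> list[DatabaseEntry]:
        return [e for e in self.entries if e.db_class == db_class]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in DATABASE_CLASSES}
        for e in self.entries:
            counts[e.db_class] += 1
        return counts


def build_search_database(
    reference: Sequence[ProteinRecord],
    variant_peptides: Sequence[VariantPeptide],
    variants: Mapping[str, VariantRecord] | None = None,
    decoy_prefix: str = DECOY_PREFIX,
) -> SearchDatabase:
    """Assemble the four-class split target-decoy database.

    Reference proteins become ``reference_target`` entries, collapsed variant
    peptides ``variant_target`` entries; every target gains exactly one decoy
    whose sequence is the exact reversal, in the matching decoy class, header
    prefixed with ``decoy_prefix``.
    """
    entries: list[DatabaseEntry] = []
    seen: set[str] = set()

    def _add(header: str, sequence: str, db_class: str) -> None:
        if header in seen:
            raise ValueError(f"duplicate database header: {header!r}")
        seen.add(header)
        entries.append(DatabaseEntry(header, sequence, db_class))

    for rec in reference:
        _add(rec.accession, rec.sequence, "reference_target")
    for i, pep in enumerate(collapse_duplicates(variant_peptides), start=1):
        _add(variant_header(pep, variants, ordinal=i), pep.sequence, "variant_target")
    for entry in list(entries):
        _add(
            decoy_prefix + entry.header,
            entry.sequence[::-1],
            entry.db_class.replace("_target", "_decoy"),
        )
    return SearchDatabase(entries)


def write_database_fasta(db: SearchDatabase, path: str | Path, width: int = 60) -> None:
    """Write the database as FASTA, one entry per target/decoy sequence."""
    with open(path, "w") as fh:
        for entry in db.entries:
            fh.write(f">{entry.header}\n")
            for i in range(0, len(entry.sequence), width):
                fh.write(entry.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tab-delimited variant / fusion dialects
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = ["variant_id", "gene", "protein_accession", "class", "position", "ref", "alt", "provenance"]
FUSION_TSV_COLUMNS = ["fusion_id", "five_prime_nt", "three_prime_nt", "frame_mode", "provenance"]


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read protein-level variants from the documented tab-delimited dialect.

    Columns: variant_id, gene, protein_accession, class, position (1-based),
    ref, alt, provenance (comma-separated tags). Header row required; empty
    ref/alt cells mean the empty string.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        VariantRecord(
            variant_id=row["variant_id"],
            gene=row["gene"],
            protein_accession=row["protein_accession"],
            variant_class=row["class"],
            position=int(row["position"]),
            ref_seq=row["ref"],
            alt_seq=row["alt"],
            provenance=frozenset(t for t in row["provenance"].split(",") if t),
        )
        for _, row in df.iterrows()
    ]


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": v.variant_id,
                "gene": v.gene,
                "protein_accession": v.protein_accession,
                "class": v.variant_class,
                "position": v.position,
                "ref": v.ref_seq,
                "alt": v.alt_seq,
                "provenance": ",".join(sorted(v.provenance)),
            }
            for v in variants
        ],
        columns=VARIANT_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_fusion_table(path: str | Path) -> list[FusionEvent]:
    """Read fusion events (fusion_id, five_prime_nt, three_prime_nt,
    frame_mode, provenance) from a tab-delimited file."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in FUSION_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        FusionEvent(
            fusion_id=row.fusion_id,
            five_prime_nt=row.five_prime_nt,
            three_prime_nt=row.three_prime_nt,
            frame_mode=row.frame_mode,
            provenance=row.provenance,
        )
        for row in df.itertuples(index=False)
    ]


def write_fusion_table(fusions: Sequence[FusionEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "fusion_id": f.fusion_id,
                "five_prime_nt": f.five_prime_nt,
                "three_prime_nt": f.three_prime_nt,
                "frame_mode": f.frame_mode,
                "provenance": f.provenance,
            }
            for f in fusions
        ],
        columns=FUSION_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
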