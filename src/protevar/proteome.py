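"""Reference proteomes, in-silico tryptic digestion, and the I/L-collapsed
peptide membership index.

Tryptic peptide space is the substrate for everything downstream: variant
peptides are enumerated by digesting mutated proteins, and detected peptides
are filtered against the digested reference proteomes. Digestion follows the
conventional trypsin rule (cleave C-terminal to K/R, suppressed when the next
residue is P) with a configurable number of missed cleavages and a length
window; isobaric leucine/isoleucine are treated as identical wherever peptides
are compared against a reference.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "CleavageSpec",
    "PeptideOccurrence",
    "PeptideIndex",
    "FastaParseError",
    "read_fasta",
    "digest",
    "cleavage_boundaries",
    "il_collapse",
    "STANDARD_RESIDUES",
]

#: The 20 standard amino acids.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residues tolerated in input sequences beyond the standard 20
#: (unknown, selenocysteine, ambiguity codes). They are never cleavage
#: sites, and peptides containing X are excluded from membership indexes
#: because they cannot be confidently matched.
TOLERATED_RESIDUES = frozenset("XUBZ")

_IL_TABLE = str.maketrans("I", "L")


class FastaParseError(ValueError):
    """A FASTA entry is malformed (missing header or empty sequence)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An accessioned amino-acid sequence with a source-proteome tag."""

    accession: str
    description: str
    sequence: str
    source: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.accession!r}: empty sequence")
        if not self.sequence.isupper():
            raise ValueError(f"protein {self.accession!r}: sequence must be uppercase")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageSpec:
    """Parameters of the in-silico digestion.

    Defaults describe tryptic digestion as used by the common search
    engines: cleave after K/R except before P, up to two missed cleavage
    sites, peptide length 6-35 (inclusive on both ends).
    """

    cleave_after: frozenset[str] = frozenset("KR")
    suppress_before: frozenset[str] = frozenset("P")
    max_missed: int = 2
    min_len: int = 6
    max_len: int = 35

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        # frozensets may arrive as plain strings/sets from callers
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))
        object.__setattr__(self, "suppress_before", frozenset(self.suppress_before))


@dataclass(frozen=True)
class PeptideOccurrence:
    """One digestion product located on its parent protein (1-based, inclusive)."""

    sequence: str
    protein_accession: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")


def il_collapse(sequence: str) -> str:
    """Replace every isoleucine by leucine (the two are isobaric and
    indistinguishable by standard MS)."""
    return sequence.translate(_IL_TABLE)


def read_fasta(path: str | Path, source: str) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and trailing stop symbols (``*``) stripped.
    The accession is the first whitespace-delimited token of the header.
    An entry with an empty header or an empty sequence raises
    :class:`FastaParseError` naming the offending entry.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper().rstrip("*")
        if not rec.id:
            raise FastaParseError(f"{path}: entry #{i + 1} has no header")
        if not seq:
            raise FastaParseError(f"{path}: entry {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate accession {rec.id!r}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                accession=rec.id,
                description=rec.description,
                sequence=seq,
                source=source,
            )
        )
    return records


def cleavage_boundaries(sequence: str, spec: CleavageSpec) -> list[int]:
    """0-based cut positions delimiting the fully-digested segments.

    Returns ``[0, ..., len(sequence)]``; a cut at position ``i`` means the
    bond between residues ``i-1`` and ``i`` is cleaved. Cleavage occurs
    after residues in ``cleave_after`` unless the following residue is in
    ``suppress_before``.
    """
    bounds = [0]
    n = len(sequence)
    for i in range(1, n):
        if sequence[i - 1] in spec.cleave_after and sequence[i] not in spec.suppress_before:
            bounds.append(i)
    if n > 0:
        bounds.append(n)
    return bounds


def digest(protein: ProteinRecord, spec: CleavageSpec = CleavageSpec()) -> list[PeptideOccurrence]:
    """Enumerate tryptic peptides of ``protein`` under ``spec``.

    Every peptide delimited by two cleavage points with at most
    ``spec.max_missed`` internal missed cleavage sites and length within
    ``[min_len, max_len]`` is returned, in order of start position then
    length. An empty protein yields an empty list.
    """
    seq = protein.sequence
    bounds = cleavage_boundaries(seq, spec)
    out: list[PeptideOccurrence] = []
    for j in range(len(bounds) - 1):
        for k in range(j + 1, min(j + spec.max_missed + 2, len(bounds))):
            start, end = bounds[j], bounds[k]
            length = end - start
            if length < spec.min_len or length > spec.max_len:
                continue
            out.append(
                PeptideOccurrence(
                    sequence=seq[start:end],
                    protein_accession=protein.accession,
                    start=start + 1,
                    end=end,
                    missed_cleavages=k - j - 1,
                )
            )
    return out


class PeptideIndex:
    """I/L-collapsed membership index over digested reference proteomes.

    Answers "is this peptide present in any reference?" and, per peptide,
    which source proteomes contain it. Membership is invariant under I<->L
    substitution in the query. Peptides containing X are excluded (they
    cannot be confidently matched).
    """

    def __init__(self) -> None:
        self._members: dict[str, set[str]] = {}

    @classmethod
    def build(
        cls,
        proteomes: Iterable[Sequence[ProteinRecord]],
        spec: CleavageSpec = CleavageSpec(),
    ) -> "PeptideIndex":
        """Digest each proteome and index the resulting peptides by source."""
        proteomes = list(proteomes)
        if not proteomes:
            raise ValueError("at least one proteome is required")
        index = cls()
        for proteome in proteomes:
            for protein in proteome:
                for occ in digest(protein, spec):
                    index.add(occ.sequence, protein.source)
        return index

    def add(self, peptide: str, source: str) -> None:
        if "X" in peptide:
            return
        self._members.setdefault(il_collapse(peptide), set()).add(source)

    def __contains__(self, peptide: str) -> bool:
        return il_collapse(peptide) in self._members

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[str]:
        return iter(self._members)

    def sources(self, peptide: str) -> frozenset[str]:
        """Source proteomes containing ``peptide`` (empty if absent)."""
        return frozenset(self._members.get(il_collapse(peptide), ()))

    def partition_counts(self) -> dict[frozenset[str], int]:
        """Count peptides by the exact set of sources sharing them.

        The partition over source combinations underlies summaries of how
        much tryptic space the reference proteomes share.
        """
        counts: dict[frozenset[str], int] = {}
        for members in self._members.values():
            key = frozenset(members)
            counts[key] = counts.get(key, 0) + 1
        return counts
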