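"""Per-engine PSM parsing and split target-decoy spectral FDR.

The variant partition of a proteogenomic search database is small and
enriched for incorrect matches relative to the reference partition, so a
pooled target-decoy estimate understates the error rate among variant PSMs.
FDR is therefore computed separately for the variant and reference
partitions, each against decoys generated from its own database partition,
and further stratified by precursor charge state. PSMs with q-value at or
below the threshold (default 1% spectral FDR) are retained.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .variants import DECOY_PREFIX, VARIANT_MARKER

__all__ = [
    "ENGINES",
    "PSM",
    "QValuedPSM",
    "PsmSchemaError",
    "classify_database_class",
    "parse_psm_table",
    "write_psm_table",
    "select_best_psm_per_spectrum",
    "assign_q_values",
    "split_fdr",
    "pooled_fdr",
]

#: The three search engines whose standardized outputs the pipeline merges.
ENGINES = ("tandem", "comet", "msgf")

#: Documented columns of the standardized per-engine PSM dialect.
PSM_TSV_COLUMNS = ["raw_file", "scan_id", "peptide", "charge", "e_value", "protein_accessions"]


class PsmSchemaError(ValueError):
    """A PSM table does not conform to the documented schema."""


@dataclass(frozen=True)
class PSM:
    """One engine's spectrum-to-peptide assignment.

    ``score`` is oriented so larger is better (e-values are negated-log10
    transformed at parse time). ``database_class`` reflects the partition
    and target/decoy status of the matched database entries.
    """

    raw_file: str
    scan_id: int
    peptide: str
    charge: int
    engine: str
    score: float
    database_class: str
    protein_accessions: frozenset[str]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"{self.raw_file}:{self.scan_id}: charge must be >= 1")
        if not math.isfinite(self.score):
            raise ValueError(f"{self.raw_file}:{self.scan_id}: score must be finite")
        object.__setattr__(self, "protein_accessions", frozenset(self.protein_accessions))

    @property
    def is_decoy(self) -> bool:
        return self.database_class.endswith("_decoy")

    @property
    def partition(self) -> str:
        """``variant`` or ``reference``."""
        return "variant" if self.database_class.startswith("variant") else "reference"


@dataclass(frozen=True)
class QValuedPSM:
    """A target PSM with its stratum and monotonized q-value."""

    psm: PSM
    stratum: tuple[str, int]
    q_value: float


def classify_database_class(
    accessions: Iterable[str],
    decoy_prefix: str = DECOY_PREFIX,
    variant_marker: str = VARIANT_MARKER,
) -> str:
    """Derive the database class from matched protein accessions.

    A PSM is a decoy only if every matched accession carries the decoy
    prefix. If the accessions straddle partitions, the variant marker wins
    (the rarer class), keeping the variant-partition error estimate
    conservative.
    """
    accs = list(accessions)
    if not accs:
        raise ValueError("PSM with no protein accessions")
    is_decoy = all(a.startswith(decoy_prefix) for a in accs)
    stripped = [a[len(decoy_prefix) :] if a.startswith(decoy_prefix) else a for a in accs]
    is_variant = any(s.startswith(variant_marker) for s in stripped)
    partition = "variant" if is_variant else "reference"
    return f"{partition}_{'decoy' if is_decoy else 'target'}"


def parse_psm_table(path: str | Path, engine: str) -> list[PSM]:
    """Parse one engine's standardized tab-delimited PSM table.

    Columns: raw_file, scan_id, peptide, charge, e_value,
    protein_accessions (semicolon-separated). E-values are mapped to
    "larger is better" scores via ``-log10``; a ``score`` column already on
    that orientation may be supplied instead of ``e_value``. Modifications
    are expected to be pre-stripped from the peptide strings.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    has_evalue = "e_value" in df.columns
    required = [c for c in PSM_TSV_COLUMNS if c != "e_value"] + (["e_value"] if has_evalue else ["score"])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PsmSchemaError(f"{path}: missing column(s) {missing}")
    psms: list[PSM] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        raw_score = row.e_value if has_evalue else row.score
        try:
            value = float(raw_score)
            score = -math.log10(value) if has_evalue else value
            charge = int(row.charge)
        except ValueError as exc:
            raise PsmSchemaError(f"{path}, line {i}: non-numeric field ({exc})") from None
        accessions = frozenset(a for a in row.protein_accessions.split(";") if a)
        try:
            psms.append(
                PSM(
                    raw_file=row.raw_file,
                    scan_id=int(row.scan_id),
                    peptide=row.peptide,
                    charge=charge,
                    engine=engine,
                    score=score,
                    database_class=classify_database_class(accessions),
                    protein_accessions=accessions,
                )
            )
        except ValueError as exc:
            raise PsmSchemaError(f"{path}, line {i}: {exc}") from None
    return psms


def write_psm_table(psms: Sequence[PSM], path: str | Path) -> None:
    """Write PSMs in the standardized dialect (scores as e-values)."""
    pd.DataFrame(
        [
            {
                "raw_file": p.raw_file,
                "scan_id": p.scan_id,
                "peptide": p.peptide,
                "charge": p.charge,
                "e_value": 10.0 ** (-p.score),
                "protein_accessions": ";".join(sorted(p.protein_accessions)),
            }
            for p in psms
        ],
        columns=PSM_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def select_best_psm_per_spectrum(psms: Sequence[PSM]) -> list[PSM]:
    """Keep, per (raw_file, scan_id, engine), the highest-scoring PSM.

    Ties are broken lexicographically by peptide, then by database class
    preferring reference over variant (conservative: an ambiguous spectrum
    should not create a variant identification).
    """
    best: dict[tuple[str, int, str], PSM] = {}
    for psm in psms:
        key = (psm.raw_file, psm.scan_id, psm.engine)
        cur = best.get(key)
        if cur is None or _best_key(psm) < _best_key(cur):
            best[key] = psm
    return [best[k] for k in sorted(best)]


def _best_key(psm: PSM) -> tuple[float, str, int]:
    # smaller is "more preferred": high score, then lexicographic peptide,
    # then reference before variant
    return (-psm.score, psm.peptide, 0 if psm.partition == "reference" else 1)


def _stratum_qvalues(stratum_psms: list[PSM], conservative: bool) -> list[tuple[PSM, float]]:
    """q-values for the target PSMs of one stratum.

    At each score cutoff FDR = (#decoys >= cutoff) / (#targets >= cutoff);
    q-values are the running minimum from the permissive end (monotonized).
    At tied scores decoys are counted before targets (conservative tie
    handling). ``conservative`` (the default) uses the add-one (D+1)/T
    estimator, which is required for finite-sample FDR control; disabling
    it gives the uncorrected D/T estimate, which is measurably
    anticonservative when accepted sets are small.
    """
    order = sorted(stratum_psms, key=lambda p: (-p.score, not p.is_decoy))
    n_decoys = 0
    n_targets = 0
    raw: list[tuple[PSM, float]] = []
    for psm in order:
        if psm.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
            num = n_decoys + 1 if conservative else n_decoys
            raw.append((psm, num / n_targets))
    out: list[tuple[PSM, float]] = []
    running = math.inf
    for psm, fdr in reversed(raw):
        running = min(running, fdr)
        out.append((psm, min(running, 1.0)))
    out.reverse()
    return out


def _strata(
    psms: Sequence[PSM],
    split: bool,
    stratify_charge: bool,
    merge_below: int,
) -> dict[tuple[str, int], list[PSM]]:
    strata: dict[tuple[str, int], list[PSM]] = {}
    for psm in psms:
        partition = psm.partition if split else "pooled"
        charge = psm.charge if stratify_charge else 0
        strata.setdefault((partition, charge), []).append(psm)
    if merge_below > 0:
        merged: dict[tuple[str, int], list[PSM]] = {}
        for (partition, charge), members in strata.items():
            key = (partition, charge) if len(members) >= merge_below else (partition, 0)
            merged.setdefault(key, []).extend(members)
        strata = merged
    return strata


def assign_q_values(
    psms: Sequence[PSM],
    split: bool = True,
    stratify_charge: bool = True,
    conservative: bool = True,
    merge_below: int = 0,
) -> list[QValuedPSM]:
    """Compute per-stratum q-values for every target PSM.

    Strata are (partition, charge) pairs; ``split=False`` pools the
    reference and variant partitions (for comparison only — the split
    estimate is the recommended one). ``merge_below`` merges charge strata
    smaller than the given size into a partition-wide stratum to avoid
    unstable estimates.
    """
    out: list[QValuedPSM] = []
    for stratum, members in sorted(_strata(psms, split, stratify_charge, merge_below).items()):
        if not any(not p.is_decoy for p in members):
            warnings.warn(f"stratum {stratum}: no target PSMs, skipped", stacklevel=2)
            continue
        for psm, q in _stratum_qvalues(members, conservative):
            out.append(QValuedPSM(psm=psm, stratum=stratum, q_value=q))
    return out


def split_fdr(
    psms: Sequence[PSM],
    threshold: float = 0.01,
    stratify_charge: bool = True,
    conservative: bool = True,
    merge_below: int = 0,
) -> list[QValuedPSM]:
    """Accepted target PSMs under the split target-decoy estimate.

    FDR is computed separately for the variant and reference partitions,
    each stratified by charge; target PSMs with q-value <= ``threshold``
    are returned.
    """
    return [
        q
        for q in assign_q_values(
            psms, split=True, stratify_charge=stratify_charge, conservative=conservative, merge_below=merge_below
        )
        if q.q_value <= threshold
    ]


def pooled_fdr(
    psms: Sequence[PSM],
    threshold: float = 0.01,
    stratify_charge: bool = True,
    conservative: bool = True,
    merge_below: int = 0,
) -> list[QValuedPSM]:
    """Accepted target PSMs with both partitions pooled into one estimate.

    Provided for comparison: when the variant partition is enriched for
    incorrect matches, pooling lets high-scoring reference PSMs subsidize
    the acceptance of spurious variant PSMs.
    """
    return [
        q
        for q in assign_q_values(
            psms, split=False, stratify_charge=stratify_charge, conservative=conservative, merge_below=merge_below
        )
        if q.q_value <= threshold
    ]
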