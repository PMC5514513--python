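"""Cross-engine consensus tiers, per-gene mutation summaries, and the
resampling enrichment test for druggable gene categories.

Filtered PSMs from the three engines are grouped by peptide sequence into
four nested confidence tiers:

* tier 1 — all peptides surviving filtration;
* tier 2 — peptides identified by at least two engines;
* tier 3 — peptides identified by all three engines;
* tier 4 — peptides identified by all three engines with two or more
  spectra.

Category enrichment asks whether the genes behind the detected variant
peptides are over-represented in annotation categories (e.g. druggable
genes) relative to equally sized random subsamples of peptides from a
standard reference search. The null distribution is built by uniform
subsampling without replacement; the empirical p-value uses the
add-one-corrected estimator, which never returns zero.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fdr import ENGINES, PSM
from .proteome import il_collapse
from .variants import VariantRecord

__all__ = [
    "TieredPeptide",
    "EnrichmentResult",
    "assign_tiers",
    "tier_of",
    "summarize_mutations",
    "category_enrichment",
    "write_tier_table",
    "read_category_table",
]


@dataclass(frozen=True)
class TieredPeptide:
    """A variant peptide with its cross-engine consensus evidence."""

    sequence: str
    variant_ids: frozenset[str]
    engines: frozenset[str]
    spectral_count: int
    samples: frozenset[str]
    tier: int

    def __post_init__(self) -> None:
        if self.spectral_count < 1:
            raise ValueError("spectral_count must be >= 1")
        if self.tier != tier_of(len(self.engines), self.spectral_count):
            raise ValueError("tier inconsistent with engine set and spectral count")


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs null category count with its empirical p-value."""

    category: str
    observed: int
    null_mean: float
    null_sd: float
    empirical_p: float
    enriched: bool


def tier_of(n_engines: int, spectral_count: int) -> int:
    """Confidence tier implied by engine agreement and spectral support."""
    if n_engines >= 3 and spectral_count >= 2:
        return 4
    if n_engines >= 3:
        return 3
    if n_engines >= 2:
        return 2
    return 1


def assign_tiers(
    psms: Sequence[PSM],
    variant_ids: Mapping[str, frozenset[str]] | None = None,
    sample_key: Callable[[PSM], str] | None = None,
    collapse_il: bool = False,
) -> list[TieredPeptide]:
    """Group filtered PSMs (all engines together) into tiered peptides.

    Peptides are grouped by exact sequence (engines report concrete
    sequences); ``collapse_il=True`` groups under I/L equivalence instead.
    Spectral count is the number of distinct (raw_file, scan_id) pairs,
    pooled across engines and samples. Output is sorted by descending tier
    then sequence.
    """
    if sample_key is None:
        sample_key = lambda p: p.raw_file  # noqa: E731
    groups: dict[str, list[PSM]] = {}
    for psm in psms:
        key = il_collapse(psm.peptide) if collapse_il else psm.peptide
        groups.setdefault(key, []).append(psm)
    out: list[TieredPeptide] = []
    for seq, members in groups.items():
        engines = frozenset(p.engine for p in members)
        spectra = {(p.raw_file, p.scan_id) for p in members}
        out.append(
            TieredPeptide(
                sequence=seq,
                variant_ids=frozenset((variant_ids or {}).get(seq, frozenset())),
                engines=engines,
                spectral_count=len(spectra),
                samples=frozenset(sample_key(p) for p in members),
                tier=tier_of(len(engines), len(spectra)),
            )
        )
    out.sort(key=lambda t: (-t.tier, t.sequence))
    return out


def summarize_mutations(
    tiered: Sequence[TieredPeptide],
    variants: Mapping[str, VariantRecord],
    min_tier: int = 1,
) -> tuple[pd.Series, float]:
    """Count distinct mutations per gene among peptides at or above
    ``min_tier``; returns (per-gene counts, median mutations per gene).

    Variant identifiers that do not resolve in ``variants`` are excluded
    with a warning-free count (they are typically fusions carried through
    a SAV-oriented summary).
    """
    pairs: set[tuple[str, str]] = set()
    for pep in tiered:
        if pep.tier < min_tier:
            continue
        for vid in pep.variant_ids:
            rec = variants.get(vid)
            if rec is not None:
                pairs.add((rec.gene, vid))
    counts = pd.Series(
        pd.DataFrame(sorted(pairs), columns=["gene", "variant_id"]).groupby("gene").size()
        if pairs
        else [],
        dtype=int,
        name="n_mutations",
    )
    median = float(counts.median()) if len(counts) else float("nan")
    return counts, median


def category_enrichment(
    observed_peptides: Sequence[str],
    background_peptides: Sequence[str],
    categories: Mapping[str, Sequence[str]],
    n_resamples: int = 100_000,
    alpha: float = 0.01,
    seed: int | None = None,
    chunk: int = 4096,
) -> list[EnrichmentResult]:
    """Resampling test for category over-representation.

    ``categories`` maps a peptide to the annotation categories of its
    gene(s). ``n_resamples`` subsamples of size ``len(observed_peptides)``
    are drawn uniformly without replacement from the background; for each
    category, the empirical p-value is (1 + #{null >= observed}) /
    (n_resamples + 1). Results are sorted by category name; fixed seed
    gives bit-reproducible output.
    """
    n_obs = len(observed_peptides)
    n_bg = len(background_peptides)
    if n_bg < n_obs:
        raise ValueError(f"background ({n_bg}) smaller than observed ({n_obs})")
    cat_names = sorted({c for pep_cats in categories.values() for c in pep_cats})
    if not cat_names:
        return []
    cat_idx = {c: i for i, c in enumerate(cat_names)}

    indicator = np.zeros((n_bg, len(cat_names)), dtype=np.int32)
    for i, pep in enumerate(background_peptides):
        for c in categories.get(pep, ()):
            indicator[i, cat_idx[c]] = 1

    observed = np.zeros(len(cat_names), dtype=np.int64)
    for pep in observed_peptides:
        for c in categories.get(pep, ()):
            observed[cat_idx[c]] += 1

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(cat_names), dtype=np.int64)
    total = np.zeros(len(cat_names), dtype=np.float64)
    total_sq = np.zeros(len(cat_names), dtype=np.float64)
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        keys = rng.random((m, n_bg))
        idx = np.argpartition(keys, n_obs - 1, axis=1)[:, :n_obs] if n_obs < n_bg else np.tile(
            np.arange(n_bg), (m, 1)
        )
        counts = indicator[idx].sum(axis=1)  # (m, n_cat)
        exceed += (counts >= observed).sum(axis=0)
        total += counts.sum(axis=0)
        total_sq += (counts.astype(np.float64) ** 2).sum(axis=0)
        done += m

    mean = total / n_resamples
    var = np.maximum(total_sq / n_resamples - mean**2, 0.0)
    p = (1 + exceed) / (n_resamples + 1)
    return [
        EnrichmentResult(
            category=c,
            observed=int(observed[i]),
            null_mean=float(mean[i]),
            null_sd=float(np.sqrt(var[i])),
            empirical_p=float(p[i]),
            enriched=bool(p[i] < alpha),
        )
        for c, i in ((c, cat_idx[c]) for c in cat_names)
    ]


def write_tier_table(tiered: Sequence[TieredPeptide], path: str | Path) -> None:
    """Write tiered peptides as TSV (tier, sequence, engines, counts)."""
    pd.DataFrame(
        [
            {
                "tier": t.tier,
                "sequence": t.sequence,
                "variant_ids": ",".join(sorted(t.variant_ids)),
                "engines": ",".join(e for e in ENGINES if e in t.engines),
                "spectral_count": t.spectral_count,
                "samples": ",".join(sorted(t.samples)),
            }
            for t in tiered
        ],
        columns=["tier", "sequence", "variant_ids", "engines", "spectral_count", "samples"],
    ).to_csv(path, sep="\t", index=False)


def read_category_table(path: str | Path) -> dict[str, list[str]]:
    """Read a peptide->category table (TSV columns: peptide, category; one
    row per pair)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("peptide", "category"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.peptide, []).append(row.category)
    return out
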