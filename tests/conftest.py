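"""Shared fixtures and independent oracles for the test-suite."""

from __future__ import annotations

import numpy as np
import pytest

from protevar.proteome import CleavageSpec, ProteinRecord
from protevar.simulate import SimulationConfig, prepare_scaffold


def brute_force_digest(seq: str, spec: CleavageSpec) -> set[tuple[str, int, int, int]]:
    """Exhaustive digestion oracle: enumerate every substring and keep those
    whose boundaries are valid cleavage points and whose internal
    missed-cleavage count is within the spec. Returns (sequence, start, end,
    missed) tuples with 1-based inclusive coordinates."""

    def is_boundary(i: int) -> bool:
        if i == 0 or i == len(seq):
            return True
        return seq[i - 1] in spec.cleave_after and seq[i] not in spec.suppress_before

    out: set[tuple[str, int, int, int]] = set()
    for s in range(len(seq)):
        for e in range(s + 1, len(seq) + 1):
            if not (is_boundary(s) and is_boundary(e)):
                continue
            mc = sum(
                1
                for i in range(s + 1, e)
                if seq[i - 1] in spec.cleave_after and seq[i] not in spec.suppress_before
            )
            if mc > spec.max_missed:
                continue
            if not (spec.min_len <= e - s <= spec.max_len):
                continue
            out.add((seq[s:e], s + 1, e, mc))
    return out


@pytest.fixture
def unfiltered_spec() -> CleavageSpec:
    """Tryptic rules with the length filter disabled."""
    return CleavageSpec(min_len=1, max_len=10**6, max_missed=2)


@pytest.fixture
def toy_protein() -> ProteinRecord:
    return ProteinRecord("P1", "toy", "MKTAYRGWDDKLPVNTRAAGW", "uniprot_canonical")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced synthetic experiment for fast structural tests."""
    return SimulationConfig(
        seed=3,
        n_proteins=8,
        n_sav=6,
        n_insertion=2,
        n_deletion=2,
        n_frameshift=1,
        n_stop_loss=1,
        n_fusions=2,
        present_fraction=1.0,
        spectra_per_true_peptide=2,
        n_true_reference_peptides=60,
        n_noise_spectra_reference=100,
        n_noise_spectra_variant=100,
        n_dependent_savs=10,
    )


@pytest.fixture(scope="session")
def small_scaffold(small_config):
    return prepare_scaffold(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
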