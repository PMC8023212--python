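"""Shared fixtures: small seeded synthetic genomes and gene models."""

from __future__ import annotations

import numpy as np
import pytest

from bsamap import CrossDesign, generate_reference, induce_mutations


@pytest.fixture(scope="session")
def toy_reference():
    """Small two-chromosome genome with a sparse toy annotation."""
    genome, models = generate_reference(
        n_chrom=2,
        lengths=(60_000, 60_000),
        seed=11,
        genes_per_chrom=2,
        cds_codon_range=(60, 120),
    )
    return genome, models


@pytest.fixture(scope="session")
def toy_mutations(toy_reference):
    genome, models = toy_reference
    return induce_mutations(genome, models, n_mutations=40, seed=12)


@pytest.fixture
def error_free_design():
    """Design with perfect phenotyping and error-free reads."""
    return CrossDesign(misclassification=0.0, seq_error=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
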