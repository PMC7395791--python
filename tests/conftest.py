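"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pgsra.genodata import GenotypePanel


def make_panel(
    genotypes,
    bp=None,
    chromosome="1",
    label="pop",
    variant_ids=None,
    counted=None,
    other=None,
) -> GenotypePanel:
    """Build a small panel from a plain genotype matrix (samples x variants)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if bp is None:
        bp = 1000 * (1 + np.arange(m))
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": chromosome,
            "bp": np.asarray(bp, dtype=np.int64),
            "counted_allele": counted if counted is not None else ["A"] * m,
            "other_allele": other if other is not None else ["G"] * m,
        }
    )
    return GenotypePanel(
        population_label=label,
        sample_ids=[f"s{i}" for i in range(n)],
        variants=variants,
        genotypes=g,
    )


def random_panel(
    rng: np.random.Generator,
    n_samples: int,
    n_variants: int,
    label: str = "pop",
    bp=None,
    maf_range=(0.1, 0.5),
) -> GenotypePanel:
    """Panel of independent binomial genotypes (no LD)."""
    p = rng.uniform(*maf_range, size=n_variants)
    g = rng.binomial(2, p, size=(n_samples, n_variants))
    return make_panel(g, bp=bp, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
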