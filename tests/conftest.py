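"""Shared fixtures: synthetic datasets and crafted matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from yphylo.core import CallState, GenotypeMatrix, Variant
from yphylo.report import PipelineConfig, run_pipeline
from yphylo.simulate import SimConfig, simulate_dataset, write_fixture_set

A = CallState.ANCESTRAL
D = CallState.DERIVED
M = CallState.MISSING
U = CallState.AMBIGUOUS


def noiseless_config(seed: int = 1, **kwargs) -> SimConfig:
    """The exact-recovery regime: no error, no missingness, deep coverage."""
    base = dict(
        n_case_samples=30,
        n_control_samples=20,
        n_clades=8,
        variants_per_branch=3,
        singleton_count=5,
        recurrent_count=2,
        per_read_error=0.0,
        missing_rate=0.0,
        mean_coverage=50.0,
        seed=seed,
    )
    base.update(kwargs)
    return SimConfig(**base)


def pipeline_on_fixture(config: SimConfig, tmp_path: Path, **overrides):
    """Write a fixture set and run the whole pipeline on it."""
    fixture_dir = tmp_path / f"fixture_{config.seed}"
    write_fixture_set(config, fixture_dir)
    pc = PipelineConfig(
        vcf=str(fixture_dir / "calls.vcf"),
        anchor=config.anchor_name,
        samples=str(fixture_dir / "samples.tsv"),
        known_variants=str(fixture_dir / "known_variants.tsv"),
        scaffold=str(fixture_dir / "scaffold.tsv"),
        **overrides,
    )
    return run_pipeline(pc, tmp_path / f"out_{config.seed}")


def make_matrix(samples, variant_specs, rows) -> GenotypeMatrix:
    """Build a matrix from compact specs.

    ``variant_specs``: list of (position, name) or positions; ``rows``: one
    list of CallState per sample.
    """
    variants = []
    for spec in variant_specs:
        if isinstance(spec, tuple):
            pos, name = spec
        else:
            pos, name = spec, None
        variants.append(
            Variant(
                contig="chrY",
                position=pos,
                ancestral_allele="A",
                derived_allele="G",
                name=name,
            )
        )
    calls = np.array(rows, dtype=np.int8)
    return GenotypeMatrix(samples, variants, calls)


@pytest.fixture(scope="session")
def noiseless_data():
    """One noiseless dataset shared by read-only tests."""
    config = noiseless_config(seed=1)
    matrix, truth = simulate_dataset(config)
    return config, matrix, truth
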