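"""Shared fixtures: small in-memory genomes and session-scoped synthetic
studies reused across integration-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from succer.core import FragmentIndex, GeneModel, GenomeAssets, Region
from succer.ders import DERConfig, annotate_ders, call_ders, quantify_regions
from succer.integration import assign_nearest_gene, attach_expression
from succer.pipeline import run_demo
from succer.simulate import SimulationConfig, simulate_study


@pytest.fixture
def toy_assets() -> GenomeAssets:
    return GenomeAssets(
        {"chr1": 40, "chr2": 20},
        {"chr1": "ACGT" * 10, "chr2": "AACCGGTTAACCGGTTAACC"},
    )


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("gA", "chr1", "+", 100, 500, [(100, 200), (300, 500)]),
        GeneModel("gB", "chr1", "-", 1000, 1400, [(1000, 1400)]),
    ]


def fragment_indices(result) -> dict[str, FragmentIndex]:
    return {
        s: FragmentIndex.from_arrays(
            df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
        )
        for s, df in result.fragments.items()
    }


def call_on_simulation(result, config=None):
    matrix = quantify_regions(
        result.regions, fragment_indices(result), result.config.groups
    )
    return matrix, call_ders(matrix, config or DERConfig())


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Full demonstration pipeline at the default study conditions, seed 1."""
    outdir = tmp_path_factory.mktemp("demo")
    manifest = run_demo(str(outdir), seed=1)
    return manifest, outdir


@pytest.fixture(scope="session")
def recovery_study():
    """Recovery-scale study: 1 Mb genome, 2000 regions, 10% GAIN / 10% LOSS
    at |beta| >= log2(3), depth 200, phi=10, 2+2 replicates, seed 1."""
    cfg = SimulationConfig(
        seed=1, n_chroms=2, chrom_length=500_000, n_regions=2000,
        n_genes=500, gene_length_range=(800, 1500),
    )
    result = simulate_study(cfg)
    matrix, ders = call_on_simulation(result)
    return result, matrix, ders


@pytest.fixture(scope="session")
def correlation_study():
    """Correlation-recovery study: 600 planted region-gene links at
    rho_target = 0.7, seed 1, with the pipeline's assignments attached."""
    cfg = SimulationConfig(
        seed=1, n_chroms=3, chrom_length=1_000_000, n_regions=3000, n_genes=700
    )
    result = simulate_study(cfg)
    _, ders = call_on_simulation(result)
    annotate_ders(ders, result.genes)
    assignments, _ = assign_nearest_gene(ders, result.genes)
    assignments, _ = attach_expression(assignments, result.expression)
    return result, ders, assignments
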