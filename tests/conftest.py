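"""Shared fixtures: small random matrices and session-scoped simulations.

The end-to-end fixtures (ten neutral and twenty sweep replicates, each a
full simulate -> scan run) are expensive, so they are computed once per
session and shared between the calibration, recovery and sanity tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcmscan import (
    HaplotypeMatrix,
    PipelineConfig,
    SimulationConfig,
    run_scan,
    simulate_population,
    write_phased_vcf,
)


def random_matrix(rng: np.random.Generator, n_hap: int, n_sites: int,
                  spacing: int = 1_000, chrom: str = "1") -> HaplotypeMatrix:
    """Random phased matrix with evenly spaced sites (no monomorphic columns)."""
    alleles = rng.integers(0, 2, size=(n_hap, n_sites)).astype(np.uint8)
    # re-draw monomorphic columns so every site is a usable SNP
    for j in range(n_sites):
        while alleles[:, j].sum() in (0, n_hap):
            alleles[:, j] = rng.integers(0, 2, size=n_hap)
    positions = np.arange(1, n_sites + 1, dtype=np.int64) * spacing
    return HaplotypeMatrix(chrom=chrom, positions=positions, alleles=alleles,
                           sample_ids=[f"S{i}" for i in range(n_hap // 2)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260201)


@pytest.fixture(scope="session")
def neutral_scans(tmp_path_factory) -> list[dict]:
    """Ten full neutral (s = 0) single-chromosome replicates, scanned."""
    root = tmp_path_factory.mktemp("neutral")
    out = []
    for rep in range(10):
        matrix, truth = simulate_population(SimulationConfig(seed=1000 + rep))
        vcf = root / f"sim_{rep}.vcf"
        write_phased_vcf(matrix, str(vcf))
        res = run_scan(PipelineConfig(vcf_path=str(vcf),
                                      out_dir=str(root / f"out_{rep}")))
        res["truth"] = truth
        res["matrix"] = matrix
        out.append(res)
    return out


@pytest.fixture(scope="session")
def sweep_scans(tmp_path_factory) -> list[dict]:
    """Twenty sweep replicates (s = 0.05 driven to freq >= 0.8).

    Each replicate embeds the sweep chromosome among two neutral
    chromosomes, mirroring a genome where selected regions are a small
    fraction of the scanned SNPs (the rank transform and robust
    calibration are genome-wide).
    """
    root = tmp_path_factory.mktemp("sweep")
    out = []
    for rep in range(20):
        mats = {}
        truth = None
        sweep_matrix = None
        for c in range(3):
            chrom = str(c + 1)
            s = 0.05 if c == 2 else 0.0
            cfg = SimulationConfig(seed=2000 + 10 * rep + c, s=s, chrom=chrom)
            matrix, tr = simulate_population(cfg)
            mats[chrom] = matrix
            if s > 0:
                truth, sweep_matrix = tr, matrix
        vcf = root / f"sim_{rep}.vcf"
        write_phased_vcf(mats, str(vcf))
        res = run_scan(PipelineConfig(vcf_path=str(vcf),
                                      out_dir=str(root / f"out_{rep}")))
        res["truth"] = truth
        res["sweep_chrom"] = "3"
        res["sweep_matrix"] = sweep_matrix
        out.append(res)
    return out
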