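"""Shared fixtures: small simulated panel contexts reused across tests."""

from dataclasses import dataclass

import pytest

from mixdeconv import (
    build_panel,
    calibrate,
    call_alleles,
    generate_reads,
    sample_population,
)
from mixdeconv.reads import ReadGenerationParams
from mixdeconv.util import derive_seed


@dataclass
class SimContext:
    panel: object
    freqs: object
    population: list
    calib: object
    depth: int

    def readset(self, profile, seed):
        return generate_reads(
            profile,
            self.panel,
            ReadGenerationParams(total_reads=self.depth, seed=seed),
        )


def _build_context(kind, n_loci, alleles, depth, seed, n_calib=15):
    panel = build_panel(kind, n_loci, seed=seed)
    freqs, population = sample_population(panel, alleles, 120, seed=seed + 1)
    samples = []
    for prof in population[20 : 20 + n_calib]:
        params = ReadGenerationParams(
            total_reads=depth, seed=derive_seed(seed, "calib", prof.sample_id)
        )
        counts = call_alleles(generate_reads(prof, panel, params), panel)
        samples.append((prof, counts))
    calib = calibrate(samples, panel)
    return SimContext(
        panel=panel, freqs=freqs, population=population, calib=calib, depth=depth
    )


@pytest.fixture(scope="session")
def mh_ctx():
    """Small MH context: 10 loci, per-locus depth near the full assay's."""
    return _build_context("MH", 10, alleles=5, depth=50_000, seed=7)


@pytest.fixture(scope="session")
def str_ctx():
    """Small STR context: 10 loci with stutter and length attenuation."""
    return _build_context("STR", 10, alleles=8, depth=85_000, seed=3)
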