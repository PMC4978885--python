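"""Shared fixtures: the study-like simulation scenario and one full run."""

from __future__ import annotations

import numpy as np
import pytest

from ltrtracer.abundance import sublineage_profile
from ltrtracer.clustering import cluster_sequences, repetitive_fraction
from ltrtracer.synthetic import (
    STUDY_BACKGROUND_LENGTH,
    STUDY_MIN_SPACING,
    ReadSimConfig,
    read_origins,
    simulate_reads,
    simulate_reference_panel,
    simulate_species_genome,
    study_like_specs,
)
from ltrtracer.tracers import kmerize_panel


@pytest.fixture(scope="session")
def study_scenario():
    """Panel, genome and tracers for the study-like conditions."""
    specs = study_like_specs()
    panel = simulate_reference_panel(specs, seed=11)
    genome = simulate_species_genome(
        panel, specs, STUDY_BACKGROUND_LENGTH, seed=12,
        min_spacing=STUDY_MIN_SPACING,
    )
    tracers, _ = kmerize_panel(panel)
    return {"specs": specs, "panel": panel, "genome": genome, "tracers": tracers}


@pytest.fixture(scope="session")
def study_run(study_scenario):
    """One 50 k-read clustering run of the study-like genome."""
    genome = study_scenario["genome"]
    tracers = study_scenario["tracers"]
    n = 50_000
    reads, starts = simulate_reads(
        genome, ReadSimConfig(n_reads=n, error_rate=0.005, seed=13),
        return_starts=True,
    )
    origins = read_origins(genome, starts)
    clusters = cluster_sequences(reads, tracers, method="components")
    estimate = repetitive_fraction(clusters, n)
    sub_sf = {t.sublineage: t.superfamily for t in tracers}
    profile = sublineage_profile(clusters, n, sub_sf, species="sim")
    return {
        "n": n,
        "reads": reads,
        "starts": np.asarray(starts),
        "origins": origins,
        "clusters": clusters,
        "estimate": estimate,
        "profile": profile,
    }
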