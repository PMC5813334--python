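"""Shared simulated cohorts (session-scoped: simulation is deterministic)."""

import numpy as np
import pandas as pd
import pytest

from episig import synthetic_data as synth


@pytest.fixture(scope="session")
def signature_cohort():
    """Training-style cohort: 198 fully separating probes, low noise.

    7 patients / 6 carriers / 56 controls with planted effects of |delta
    beta| in [0.20, 0.35] (143 hypo, 55 hyper) and noise calibrated so every
    signature probe separates patients from controls completely.
    """
    effects = synth.signature_probe_effects(
        n_hypo=143, n_hyper=55, n_background_probes=2000,
        magnitude_range=(0.20, 0.35), seed=3,
    )
    cfg = synth.SimulationConfig(
        n_background_probes=2000, planted_probe_effects=effects,
        noise_sd=0.15, seed=3,
    )
    manifest = synth.generate_manifest(cfg)
    beta, sheet, truth = synth.simulate_cohort(cfg, manifest)
    return cfg, manifest, beta, sheet, truth


@pytest.fixture(scope="session")
def plain_cohort():
    """Null cohort at default noise: no planted effects anywhere."""
    cfg = synth.SimulationConfig(n_background_probes=1500, seed=5)
    manifest = synth.generate_manifest(cfg)
    beta, sheet, truth = synth.simulate_cohort(cfg, manifest)
    return cfg, manifest, beta, sheet, truth


@pytest.fixture()
def tiny_manifest():
    """Hand-built sorted manifest of six autosomal probes in two clusters."""
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(6)],
            "chrom": ["chr1"] * 6,
            "pos": [100, 300, 650, 2000, 2400, 2900],
            "island_relation": ["island"] * 3 + ["open_sea"] * 3,
            "flag_xy": False,
            "flag_snp": False,
            "flag_crossreactive": False,
        }
    )
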