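"""Shared fixtures: a small and a full-size synthetic dataset.

The small dataset keeps per-test runtime low; the full-size one (113
family members + 500 background genes, the default study conditions) is
built once per session and shared by the acceptance checks.
"""

from __future__ import annotations

import pytest

from hsp_atlas.synthetic_data import (
    SyntheticConfig,
    simulate_all,
    simulate_genome,
)


def small_config(seed: int = 3) -> SyntheticConfig:
    cfg = SyntheticConfig(
        seed=seed,
        family_sizes={"HSP100": 6, "HSP90": 5, "HSP70": 7, "HSP60": 6, "sHSP": 8},
        n_background_genes=80,
        chromosome_length_bp=160_000,
        planted_motifs=(("ABRE3HVA22", "HSP100_05"), ("HY5AT", "sHSP_07")),
        isoform_two=("HSP60_05",),
        isoform_three=("HSP70_06",),
    )
    # counts fit inside the 16 non-duplicate family genes of this config
    cfg.orthologs.genomes = {
        "sorghum_like": {"ks": 0.234, "omega": 0.19, "count": 15},
        "rice_like": {"ks": 0.481, "omega": 0.09, "count": 10},
    }
    cfg.orthologs.union_size = 16
    return cfg


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synthetic_small")
    return simulate_all(small_config(), outdir)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default study conditions: 113 planted members, 500 background."""
    outdir = tmp_path_factory.mktemp("synthetic_default")
    return simulate_genome(SyntheticConfig(seed=11), outdir)
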