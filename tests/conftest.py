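"""Shared fixtures: tiny hand-built panels and a reusable mid-size
synthetic pipeline run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import exogene as xg
from exogene.vcfio import PanelData


def make_panel(
    n_variants: int = 4,
    samples: list[str] | None = None,
    **overrides,
) -> PanelData:
    """Small all-passing panel; column overrides patch the variant table."""
    samples = samples or [f"P{i}" for i in range(1, 6)]
    vids = [f"1:{1000 * (i + 1)}:A:G" for i in range(n_variants)]
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [1000 * (i + 1) for i in range(n_variants)],
            "ref": "A",
            "alt": "G",
            "gene": ["GBA1"] * n_variants,
            "group": 1,
            "region": "exonic",
            "canonical": True,
            "cadd": 15.0,
            "qual": 1000.0,
            "filter": "PASS",
            "low_complexity": False,
            "phase_warning": False,
            "lowqual_warning": False,
        },
        index=pd.Index(vids, name="variant_id"),
    )
    for col, values in overrides.items():
        variants[col] = values
    rng = np.random.default_rng(1)
    genotypes = pd.DataFrame(
        rng.integers(0, 2, size=(n_variants, len(samples))),
        index=variants.index,
        columns=samples,
    )
    depth = pd.DataFrame(
        30, index=variants.index, columns=samples, dtype=int
    )
    return PanelData(variants, genotypes, depth)


@pytest.fixture
def tiny_panel() -> PanelData:
    return make_panel()


@pytest.fixture(scope="session")
def recovery_config() -> xg.SimulationConfig:
    """Mid-size cohort with strongly biased planted variants."""
    return xg.SimulationConfig(
        n_subjects=350,
        n_background_variants=80,
        n_planted_variants=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def pipeline_result(recovery_config) -> xg.PipelineResult:
    return xg.run_all(recovery_config)
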