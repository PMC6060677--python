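"""Shared fixtures: small synthetic cohorts built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from nmrmetab import CohortDesign, RegionSet, exclude_regions, pqn_normalize, simulate_cohort


def small_design(**kw) -> CohortDesign:
    """A fast cohort: coarse grid, light crowding; override freely."""
    base = dict(
        n_per_class={"case": 8, "village_control": 8},
        n_points=1500,
        n_background=40,
        n_envelope=4,
        noise_sd=0.001,
        seed=5,
    )
    base.update(kw)
    return CohortDesign(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """8 vs 8 null cohort (no class effects)."""
    return simulate_cohort(small_design())


@pytest.fixture(scope="session")
def effect_cohort():
    """12 vs 12 cohort with three strong designated effect metabolites."""
    design = small_design(
        n_per_class={"case": 12, "village_control": 12},
        effect_map={"case": {"hippurate": 1.8, "p-cresol sulphate": 1.8, "formate": 1.8}},
        n_points=4500,  # resolve the 0.003 ppm linewidth
        jitter_sd_ppm=0.0005,  # sub-grid: apex columns stay informative unaligned
        seed=21,
    )
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def preprocessed_effect(effect_cohort):
    """Effect cohort after water exclusion and PQN, with the 0/1 class vector."""
    matrix, table, truth = effect_cohort
    m = exclude_regions(matrix, RegionSet([(4.7, 4.9)]))
    m, _ = pqn_normalize(m)
    labels = table.labels_for(m.sample_ids)
    y = (np.asarray(labels) == "case").astype(float)
    return m, y, truth
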