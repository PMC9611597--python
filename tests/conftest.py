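import numpy as np
import pytest

import empowermap as em


@pytest.fixture(scope="session")
def lattice_3x4():
    return em.build_region_lattice(3, 4)


@pytest.fixture(scope="session")
def lattice_4x4():
    return em.build_region_lattice(4, 4)


@pytest.fixture(scope="session")
def templates():
    return em.final_modes()


@pytest.fixture(scope="session")
def small_survey(lattice_4x4):
    """A modest simulated survey with nonzero fixed and spatial effects."""
    truth = em.GroundTruth(
        beta=np.vstack([
            [0.3, 0.4, 0.3, 0.6, 0.0, 0.1, 0.2, 0.4],
            [-0.3, -0.4, -0.3, -0.6, 0.0, -0.1, -0.2, -0.4],
        ]),
        psu_sd=0.3,
        region_sd=0.8,
        epsilon=0.05,
    )
    df, gt = em.simulate_survey(
        lattice_4x4, truth, psus_per_region=4,
        respondents_per_psu_range=(15, 30), seed=101, lattice_shape=(4, 4),
    )
    return df, gt


@pytest.fixture(scope="session")
def small_fit(small_survey, lattice_4x4):
    """One quick spatial fit shared by the tests that only inspect chains."""
    df, gt = small_survey
    assignment = em.fit_kmodes(df)
    design = em.build_design(df, assignment.labels)
    fit = em.mcmc_fit(
        design, graph=lattice_4x4,
        settings=em.McmcSettings(800, 200, 4), spatial=True, seed=303,
    )
    return df, gt, design, fit
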