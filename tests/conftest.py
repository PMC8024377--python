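"""Shared fixtures: the packaged synthetic cohort G1 and derived objects.

Expensive artefacts (the G1 tables, the fitted three-subtype model) are
session-scoped so the recovery tests share one computation.
"""

import numpy as np
import pandas as pd
import pytest

import mssustain as ms


@pytest.fixture(scope="session")
def g1():
    """(config, controls, patients) — the packaged default fixture."""
    return ms.default_fixture()


@pytest.fixture(scope="session")
def g1_normative(g1):
    _, controls, _ = g1
    return ms.fit_normative(controls)


@pytest.fixture(scope="session")
def g1_selection(g1, g1_normative):
    _, controls, patients = g1
    return ms.select_features(controls, patients, 0.5, model=g1_normative)


@pytest.fixture(scope="session")
def g1_baseline(g1):
    _, _, patients = g1
    return patients.loc[patients.groupby("subject_id")["visit_time"].idxmin()]


@pytest.fixture(scope="session")
def g1_zscores(g1_baseline, g1_normative, g1_selection):
    return ms.compute_zscores(g1_baseline, g1_normative,
                              features=list(g1_selection.retained))


@pytest.fixture(scope="session")
def g1_grid(g1_selection):
    return ms.build_event_grid(g1_selection.retained)


@pytest.fixture(scope="session")
def fit_opts(g1):
    """Scaled-down fitting profile used throughout the suite; the emission
    scale matches the generator's known measurement dispersion."""
    config, _, _ = g1
    return ms.SustainOptions(starts=5, split_starts=2, em_max_iter=15,
                             em_tol=0.01, sigma=config.noise_scale, seed=11)


@pytest.fixture(scope="session")
def g1_cv(g1_zscores, g1_grid, fit_opts):
    """Leave-one-dataset-out subtype-count selection on the fixture."""
    return ms.cv_select_subtypes(g1_zscores, g1_grid,
                                 candidates=(1, 2, 3, 4), opts=fit_opts)


@pytest.fixture(scope="session")
def g1_fit3(g1_cv, g1_zscores, g1_grid, fit_opts):
    """Three-subtype model fitted to the G1 baseline z-scores (the CV's
    final all-data refit when it selected three subtypes)."""
    if g1_cv.final_model.n_subtypes == 3:
        return g1_cv.final_model
    return ms.fit_sustain(g1_zscores, g1_grid, 3, fit_opts)


@pytest.fixture(scope="session")
def g1_long_cohort(g1):
    """G1-parameter cohort with five annual visits (longer follow-up for
    survival/treatment-response recovery)."""
    config, _, _ = g1
    return ms.generate_patients(config, 2000, n_datasets=3, n_visits=5)


def align_subtypes(pred, truth, n_subtypes):
    """Best label permutation (applied to pred) and its accuracy."""
    from itertools import permutations

    best_acc, best_perm = -1.0, None
    for p in permutations(range(n_subtypes)):
        acc = (np.asarray(p)[np.asarray(pred, dtype=int)] == truth).mean()
        if acc > best_acc:
            best_acc, best_perm = acc, p
    return best_perm, best_acc
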