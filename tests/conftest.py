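import logging

import numpy as np
import pytest

from cpcmorph import (
    AtrophyPhantomSpec,
    CpcConfig,
    compute_cpc_volume,
    make_cohort,
)
from cpcmorph.cli import phantom_region_labels
from cpcmorph.voi import VoiFeatureTable, subject_features

# ratio features legitimately produce empty-region warnings on tiny phantoms
logging.getLogger("cpcmorph.voi").setLevel(logging.ERROR)
logging.getLogger("cpcmorph.stats").setLevel(logging.ERROR)


@pytest.fixture
def small_spec():
    """12^3 phantom that fits comfortably in unit-test time."""
    return AtrophyPhantomSpec(
        grid_shape=(12, 12, 12),
        structure_radii=(2.0, 3.5, 5.0),
        blur_sigma=1.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def default_config():
    return CpcConfig()


def build_cohort_features(
    n_per_group=20, rates=None, noise_sd=0.01, seed=7, config=None
):
    """Full pipeline on a synthetic cohort; returns (features, labels, base_spec)."""
    rates = rates if rates is not None else {"NL": 0.0, "AD": 0.6}
    base = AtrophyPhantomSpec(
        grid_shape=(12, 12, 12),
        structure_radii=(2.0, 3.5, 5.0),
        blur_sigma=1.0,
        noise_sd=noise_sd,
    )
    cohort = make_cohort(n_per_group, rates, base, seed)
    labels = phantom_region_labels(base)
    config = config or CpcConfig()
    tables = [
        subject_features(
            compute_cpc_volume(s.maps_t, s.maps_tt, config),
            s.maps_t,
            s.maps_tt,
            labels,
            s.subject_id,
            s.group,
        )
        for s in cohort
    ]
    return VoiFeatureTable.concat(tables), labels, base


@pytest.fixture(scope="session")
def cohort_features():
    """Shared 20+20 NL/AD cohort at low noise; reused by slow pipeline tests."""
    features, _, _ = build_cohort_features()
    return features


def nnls_active_set_oracle(design, response):
    """Brute-force NNLS for 4 unknowns: enumerate all 2^4 active sets,
    solve each reduced unconstrained LS, keep the feasible minimum."""
    design = np.asarray(design, dtype=float)
    response = np.asarray(response, dtype=float)
    best_x, best_obj = np.zeros(4), float(np.sum(response**2))
    for mask in range(1, 16):
        cols = [i for i in range(4) if mask >> i & 1]
        sub = design[:, cols]
        sol, *_ = np.linalg.lstsq(sub, response, rcond=None)
        if np.any(sol < -1e-12):
            continue
        x = np.zeros(4)
        x[cols] = np.clip(sol, 0.0, None)
        obj = float(np.sum((design @ x - response) ** 2))
        if obj < best_obj - 1e-15:
            best_x, best_obj = x, obj
    return best_x, best_obj


def auc_pair_counting_oracle(neg, pos):
    """AUC by exhaustive pair comparison; ties count one half."""
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
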