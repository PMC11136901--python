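"""Shared fixtures: one small synthetic landscape, prepared once per
session, plus a quick reduced-MCMC fit reused by several test modules."""

from types import SimpleNamespace

import numpy as np
import pytest

import plateausdm as ps


@pytest.fixture(scope="session")
def land():
    """Small coastal landscape with known truth and sampled presences."""
    cfg = ps.LandscapeConfig(n_rows=40, n_cols=50, lat_range=(25.0, 45.0),
                             lon_range=(116.0, 136.0), seed=11)
    env = ps.make_landscape(cfg)
    truth = ps.default_true_response()
    suit = ps.true_suitability(env, truth)
    occ = ps.sample_occurrences(suit, env, 120, seed=4)
    return SimpleNamespace(cfg=cfg, env=env, truth=truth, suit=suit, occ=occ)


@pytest.fixture(scope="session")
def prepped(land):
    """Cleaned/thinned occurrences, calibration areas, shared transform and
    one presence/pseudo-absence design matrix."""
    cleaned = ps.clean_records(land.occ, land.env)
    thinned = ps.thin_records(cleaned, 20.0, n_rep=5, seed=2)
    domain = ps.eez_mask(land.env)
    areas = {r: ps.buffer_area(thinned, r, domain, env=land.env)
             for r in (1000.0, 1500.0, 2000.0)}
    env_norm, transform = ps.normalize_predictors(land.env, areas[2000.0])
    pa = ps.draw_pseudo_absences(areas[1000.0], len(thinned), 7, thinned,
                                 env=land.env)
    data = thinned.concat(pa)
    names = env_norm.layer_names
    X = env_norm.values_at(data.table["row"].to_numpy(),
                           data.table["col"].to_numpy(), names)
    y = (data.table["label"] == "presence").to_numpy(dtype=float)
    return SimpleNamespace(thinned=thinned, domain=domain, areas=areas,
                           env_norm=env_norm, transform=transform, pa=pa,
                           data=data, names=names, X=X, y=y)


@pytest.fixture(scope="session")
def quick_fit(prepped):
    """A reduced-MCMC naive fit shared by prediction/evaluation tests."""
    prior = ps.build_prior("naive", predictors=prepped.names)
    model = ps.PlateauModel(prepped.y, prepped.X, prepped.names, prior)
    return model.fit(ps.MCMCConfig(n_iter=300, n_warmup=200, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
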