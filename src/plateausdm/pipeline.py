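"""End-to-end experiment orchestration.

Runs the full comparison design on a synthetic landscape: simulate ->
prepare occurrences -> fit naive and physiologically informed plateau
models across calibration-buffer extents and pseudo-absence replicates ->
project present and warmed future suitability onto the largest buffer ->
evaluate (spatially blocked Boyce index, permutation importance, response
curves) -> compare (cross-buffer Jaccard stability, range expansion and
contraction, southern limits, paired Wilcoxon contrasts).

Every stage writes plain-text artifacts (ASCII rasters, CSV, JSON) under
an output directory and is independently re-runnable; ``run_experiment``
chains all stages and writes a manifest listing every artifact with its
seed and a configuration hash.  Re-running with the same configuration
reproduces byte-identical CSV/JSON outputs.

Seed policy: one master seed; per-stage streams are derived by hashing
(stage, buffer, model type, replicate), so replicates are independent but
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape as ls
from .compare import (BinaryMap, binarize, jaccard, pairwise_jaccard,
                      paired_wilcoxon, project_map, range_change,
                      southern_limit)
from .evaluation import (cross_validate, permutation_importance,
                         response_curve, spatial_block_folds)
from .grids import EnvStack, read_ascii_grid, write_ascii_grid
from .model import (MCMCConfig, PlateauModel, PlateauResults, build_prior,
                    default_constraints)
from .occurrences import (CalibrationArea, NormalizationTransform,
                          OccurrenceSet, buffer_area, clean_records,
                          draw_pseudo_absences, normalize_predictors,
                          thin_records, vif_check)

log = logging.getLogger("plateausdm")

CONSTRAINED = ["temp_mean", "depth"]


def derive_seed(master, *tokens):
    """Deterministic sub-seed (< 2^31) from the master seed and stage tokens."""
    key = "|".join([str(int(master))] + [str(t) for t in tokens])
    return int(hashlib.sha256(key.encode()).hexdigest()[:8], 16) % (2**31)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full experiment configuration with study defaults (three buffers of
    1000/1500/2000 km, 25 pseudo-absence replicates, 2x5000 MCMC with 4000
    warm-up, 20-km thinning, 10 % omission threshold, VIF < 10)."""

    landscape: dict = field(default_factory=dict)
    truth_beta0: float = 2.5
    n_presences: int = 150
    bias_strength: float = 0.0
    sampling_lat_min: float | None = None
    sampling_lat_max: float | None = None
    buffers_km: list = field(default_factory=lambda: [1000.0, 1500.0, 2000.0])
    replicates: int = 25
    model_types: list = field(default_factory=lambda: ["naive", "informed"])
    thin_km: float = 20.0
    thin_reps: int = 10
    omission: float = 0.10
    vif_threshold: float = 10.0
    eez_km: float = 370.0
    mcmc: dict = field(default_factory=dict)
    future: dict = field(default_factory=lambda: {
        "delta_temp": 2.0, "delta_range": 0.0, "warming_sd": 0.3})
    cv: dict = field(default_factory=lambda: {
        "enabled": True, "k": 5, "block_rows": 10, "block_cols": 10})
    importance: dict = field(default_factory=lambda: {
        "enabled": True, "n_perm": 5})
    predict_thin_to: int = 400
    seed: int = 1

    def mcmc_config(self, seed):
        return MCMCConfig(**{**self.mcmc, "seed": seed})

    def landscape_config(self):
        return ls.LandscapeConfig(**{
            **self.landscape,
            "seed": self.landscape.get("seed",
                                       derive_seed(self.seed, "landscape"))})

    def to_dict(self):
        return asdict(self)

    def config_hash(self):
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def validate_config(raw: dict):
    """Validate a raw config mapping; returns (RunConfig, errors).

    All violations are collected and reported at once.
    """
    errors = []
    known = set(RunConfig.__dataclass_fields__)
    raw = dict(raw or {})
    for key in raw:
        if key not in known:
            errors.append(f"unknown configuration key: {key!r}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    cfg = RunConfig(**cfg_kwargs)
    radii = list(cfg.buffers_km)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        errors.append(f"buffer radii must be strictly increasing: {radii}")
    if cfg.replicates < 1:
        errors.append("replicates must be >= 1")
    m = {**MCMCConfig().to_dict(), **cfg.mcmc}
    if m["n_warmup"] >= m["n_iter"]:
        errors.append(f"MCMC warm-up ({m['n_warmup']}) must be smaller than "
                      f"the iteration count ({m['n_iter']})")
    for t in cfg.model_types:
        if t not in ("naive", "informed"):
            errors.append(f"unknown model type {t!r}")
    if not 0 <= cfg.omission < 1:
        errors.append("omission must be in [0, 1)")
    return cfg, errors


def load_config(path=None):
    """Load a YAML run configuration; an empty/missing file yields the full
    default configuration.  Raises ValueError listing every violation."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    cfg, errors = validate_config(raw)
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _timer(stage):
    t0 = time.perf_counter()
    return lambda **kw: log.info(
        "stage=%s seconds=%.2f %s", stage, time.perf_counter() - t0,
        " ".join(f"{k}={v}" for k, v in kw.items()))


def simulate(cfg: RunConfig, outdir):
    """Generate the landscape, ground truth, occurrences and future stack."""
    done = _timer("simulate")
    out = Path(outdir) / "landscape"
    lcfg = cfg.landscape_config()
    env = ls.make_landscape(lcfg)
    truth = ls.default_true_response(cfg.truth_beta0)
    suit = ls.true_suitability(env, truth)
    region = None
    if cfg.sampling_lat_min is not None or cfg.sampling_lat_max is not None:
        lat2d, _ = env.grid.mesh()
        region = np.ones(env.grid.shape, dtype=bool)
        if cfg.sampling_lat_min is not None:
            region &= lat2d >= cfg.sampling_lat_min
        if cfg.sampling_lat_max is not None:
            region &= lat2d <= cfg.sampling_lat_max
    occ = ls.sample_occurrences(suit, env, cfg.n_presences,
                                cfg.bias_strength,
                                seed=derive_seed(cfg.seed, "sample"),
                                region_mask=region)
    fut = ls.make_future(env, seed=derive_seed(cfg.seed, "future"),
                         **cfg.future)
    env.write_dir(out / "present")
    fut.write_dir(out / "future")
    write_ascii_grid(out / "true_suitability.asc", env.grid, suit)
    truth.to_json(out / "truth.json")
    occ.to_csv(out / "occurrences_raw.csv")
    done(presences=len(occ), sea_cells=int(env.sea.sum()))
    return env, fut, truth, occ


def prep(cfg: RunConfig, outdir):
    """Clean + thin occurrences, build calibration areas, normalize."""
    done = _timer("prep")
    out = Path(outdir) / "prep"
    out.mkdir(parents=True, exist_ok=True)
    land_dir = Path(outdir) / "landscape"
    env = EnvStack.read_dir(land_dir / "present")
    occ = OccurrenceSet.from_csv(land_dir / "occurrences_raw.csv")
    cleaned = clean_records(occ, env)
    thinned = thin_records(cleaned, cfg.thin_km, cfg.thin_reps,
                           seed=derive_seed(cfg.seed, "thin"))
    domain = ls.eez_mask(env, cfg.eez_km)
    areas = {}
    for r in cfg.buffers_km:
        areas[r] = buffer_area(thinned, r, domain, env=env)
        write_ascii_grid(out / f"area_{int(r)}km.asc", env.grid,
                         areas[r].mask.astype(float))
    largest = areas[max(cfg.buffers_km)]
    env_norm, transform = normalize_predictors(env, largest)
    vif, vif_ok = vif_check(env, largest, cfg.vif_threshold)
    thinned.to_csv(out / "occurrences_thinned.csv")
    transform.to_json(out / "transform.json")
    vif.to_csv(out / "vif.csv", float_format="%.6g")
    (out / "prep_log.json").write_text(json.dumps(
        {"cleaning": thinned.meta.get("cleaning_log"),
         "thinning": thinned.meta.get("thinning"),
         "vif_pass": vif_ok,
         "area_cells": {str(int(r)): a.n_cells for r, a in areas.items()}},
        indent=1, sort_keys=True))
    done(retained=len(thinned), largest_area=largest.n_cells)
    return env, thinned, areas, env_norm, transform


def _load_prep(cfg, outdir):
    out = Path(outdir)
    env = EnvStack.read_dir(out / "landscape" / "present")
    thinned = OccurrenceSet.from_csv(out / "prep" / "occurrences_thinned.csv")
    transform = NormalizationTransform.from_json(out / "prep" / "transform.json")
    areas = {}
    for r in cfg.buffers_km:
        _, arr = read_ascii_grid(out / "prep" / f"area_{int(r)}km.asc")
        areas[r] = CalibrationArea(arr > 0.5, float(r), len(thinned))
    return env, thinned, areas, transform


def _fit_one(cfg, env_norm, thinned, area, transform, model_type, buffer_km,
             rep, pa_set):
    names = list(env_norm.layer_names)
    data = thinned.concat(pa_set)
    X = env_norm.values_at(data.table["row"].to_numpy(),
                           data.table["col"].to_numpy(), names)
    y = (data.table["label"] == "presence").to_numpy(dtype=float)
    prior = build_prior(model_type,
                        default_constraints() if model_type == "informed" else None,
                        transform, predictors=names)
    mseed = derive_seed(cfg.seed, "mcmc", int(buffer_km), model_type, rep)
    res = PlateauModel(y, X, names, prior).fit(cfg.mcmc_config(mseed))
    res.meta = {"buffer_km": buffer_km, "model_type": model_type,
                "replicate": rep, "pa_seed": pa_set.meta.get("seed"),
                "mcmc_seed": mseed}
    return res, data


def fit(cfg: RunConfig, outdir):
    """Fit every (buffer x model type x replicate) model; pseudo-absence
    sets are drawn per (buffer, replicate) and shared across model types so
    naive/informed contrasts are paired."""
    done = _timer("fit")
    out = Path(outdir) / "fits"
    env, thinned, areas, transform = _load_prep(cfg, outdir)
    env_norm = transform.apply(env)
    records = []
    for r in cfg.buffers_km:
        for rep in range(cfg.replicates):
            pa_seed = derive_seed(cfg.seed, "pa", int(r), rep)
            pa = draw_pseudo_absences(areas[r], len(thinned), pa_seed,
                                      thinned, env=env)
            for mt in cfg.model_types:
                res, data = _fit_one(cfg, env_norm, thinned, areas[r],
                                     transform, mt, r, rep, pa)
                path = out / f"buffer{int(r)}" / mt / f"rep{rep:02d}.csv"
                res.save(path)
                records.append({"buffer_km": r, "model_type": mt,
                                "replicate": rep, "pa_seed": pa_seed,
                                "mcmc_seed": res.meta["mcmc_seed"],
                                "posterior": str(path.relative_to(outdir))})
                log.info("stage=fit buffer=%s type=%s replicate=%d "
                         "accept=%.2f", int(r), mt, rep,
                         res.accept_rates.mean())
    (out / "fit_index.json").write_text(
        json.dumps(records, indent=1, sort_keys=True))
    done(n_models=len(records))
    return records


def _iter_fits(cfg, outdir):
    out = Path(outdir)
    records = json.loads((out / "fits" / "fit_index.json").read_text())
    for rec in records:
        yield rec, PlateauResults.load(out / rec["posterior"])


def project(cfg: RunConfig, outdir):
    """Project each fitted model onto the largest buffer, present and
    future, and binarize with the 10 %-omission threshold of its own
    training presences."""
    done = _timer("project")
    out = Path(outdir)
    env, thinned, areas, transform = _load_prep(cfg, outdir)
    fut = EnvStack.read_dir(out / "landscape" / "future")
    env_norm = transform.apply(env)
    fut_norm = transform.apply(fut)
    domain = areas[max(cfg.buffers_km)].mask
    names = list(env_norm.layer_names)
    prows = thinned.table["row"].to_numpy()
    pcols = thinned.table["col"].to_numpy()
    index = []
    for rec, res in _iter_fits(cfg, outdir):
        base = out / "maps" / f"buffer{int(rec['buffer_km'])}" / rec["model_type"]
        base.mkdir(parents=True, exist_ok=True)
        rep = rec["replicate"]
        suit_now = project_map(res, env_norm, domain, names,
                               thin_to=cfg.predict_thin_to)
        suit_fut = project_map(res, fut_norm, domain, names,
                               thin_to=cfg.predict_thin_to)
        pres_suit = res.predict_mean(
            env_norm.values_at(prows, pcols, names),
            thin_to=cfg.predict_thin_to)
        b_now = binarize(suit_now, pres_suit, cfg.omission, env.grid)
        b_fut = BinaryMap(np.isfinite(suit_fut) & (suit_fut >= b_now.threshold),
                          b_now.threshold, env.grid)
        for tag, arr in (("suit_present", suit_now), ("suit_future", suit_fut)):
            write_ascii_grid(base / f"rep{rep:02d}_{tag}.asc", env.grid, arr)
        for tag, bm in (("bin_present", b_now), ("bin_future", b_fut)):
            write_ascii_grid(base / f"rep{rep:02d}_{tag}.asc", env.grid,
                             bm.cells.astype(float))
        index.append({**{k: rec[k] for k in
                         ("buffer_km", "model_type", "replicate")},
                      "threshold": round(float(b_now.threshold), 10),
                      "dir": str(base.relative_to(out))})
    (out / "maps" / "map_index.json").write_text(
        json.dumps(index, indent=1, sort_keys=True))
    done(n_maps=len(index))
    return index


def evaluate(cfg: RunConfig, outdir):
    """Cross-validated Boyce index and permutation importance per model,
    plus marginal response curves of the constrained predictors."""
    done = _timer("evaluate")
    out = Path(outdir)
    env, thinned, areas, transform = _load_prep(cfg, outdir)
    env_norm = transform.apply(env)
    names = list(env_norm.layer_names)
    boyce_rows, imp_rows = [], []
    curves_written = set()
    for rec, res in _iter_fits(cfg, outdir):
        r, mt, rep = rec["buffer_km"], rec["model_type"], rec["replicate"]
        pa = draw_pseudo_absences(areas[r], len(thinned), rec["pa_seed"],
                                  thinned, env=env)
        data = thinned.concat(pa)
        X = env_norm.values_at(data.table["row"].to_numpy(),
                               data.table["col"].to_numpy(), names)
        if cfg.cv.get("enabled", True):
            folds = spatial_block_folds(
                data.table["lon"], data.table["lat"], data.table["label"],
                cfg.cv.get("block_rows", 10), cfg.cv.get("block_cols", 10),
                cfg.cv.get("k", 5),
                seed=derive_seed(cfg.seed, "folds", int(r), rep))
            prior = build_prior(mt, default_constraints() if mt == "informed"
                                else None, transform, predictors=names)
            mseed = derive_seed(cfg.seed, "cv", int(r), mt, rep)
            scores = cross_validate(data, env_norm, areas[r], prior,
                                    cfg.mcmc_config(mseed), folds, names,
                                    thin_to=cfg.predict_thin_to)
            for f, s in enumerate(scores, start=1):
                boyce_rows.append({"buffer_km": r, "model_type": mt,
                                   "replicate": rep, "fold": f, "boyce": s})
        if cfg.importance.get("enabled", True):
            imp = permutation_importance(
                res, X, cfg.importance.get("n_perm", 5),
                seed=derive_seed(cfg.seed, "perm", int(r), mt, rep))
            imp_rows.append({"buffer_km": r, "model_type": mt,
                             "replicate": rep, **imp.to_dict()})
        if (r, mt) not in curves_written and rep == 0:
            Xbg, _ = env_norm.sea_values(names, mask=areas[r].mask)
            Xbg = Xbg[np.isfinite(Xbg).all(axis=1)]
            for pred in CONSTRAINED:
                lim = {c.predictor: c.hard_limit
                       for c in default_constraints()}[pred]
                curve = response_curve(
                    res, pred, Xbg, transform=transform,
                    extend_to=float(transform.normalize_value(pred, lim)),
                    thin_to=cfg.predict_thin_to)
                cdir = out / "eval" / "curves"
                cdir.mkdir(parents=True, exist_ok=True)
                curve.to_csv(cdir / f"{pred}_buffer{int(r)}_{mt}.csv",
                             index=False, float_format="%.8g")
            curves_written.add((r, mt))
    out_eval = out / "eval"
    out_eval.mkdir(parents=True, exist_ok=True)
    report = {"boyce_summary": {}}
    if boyce_rows:
        bt = pd.DataFrame(boyce_rows)
        bt.to_csv(out_eval / "boyce.csv", index=False, float_format="%.8g")
        for (r, mt), sub in bt.groupby(["buffer_km", "model_type"]):
            report["boyce_summary"][f"{int(r)}:{mt}"] = {
                "mean": round(float(sub["boyce"].mean()), 6),
                "sd": round(float(sub["boyce"].std(ddof=1)), 6)
                if len(sub) > 1 else 0.0}
    if imp_rows:
        it = pd.DataFrame(imp_rows)
        it.to_csv(out_eval / "importance.csv", index=False,
                  float_format="%.8g")
        report["importance_mean"] = {
            f"{int(r)}:{mt}": {k: round(float(v), 6) for k, v in
                               sub[names].mean().items()}
            for (r, mt), sub in it.groupby(["buffer_km", "model_type"])}
    (out_eval / "eval_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    done(n_boyce=len(boyce_rows))
    return report


def _load_binary_maps(cfg, outdir, tag):
    """{(buffer, type): [BinaryMap per replicate]} from saved rasters."""
    out = Path(outdir)
    index = json.loads((out / "maps" / "map_index.json").read_text())
    maps = {}
    for rec in index:
        _, arr = read_ascii_grid(out / rec["dir"]
                                 / f"rep{rec['replicate']:02d}_{tag}.asc")
        key = (rec["buffer_km"], rec["model_type"])
        maps.setdefault(key, []).append(
            BinaryMap(np.nan_to_num(arr) > 0.5, rec["threshold"],
                      meta=dict(rec)))
    return maps


def compare(cfg: RunConfig, outdir):
    """Cross-buffer Jaccard stability, range changes under the warmed
    stack, southern limits, and paired Wilcoxon contrasts."""
    done = _timer("compare")
    out = Path(outdir)
    env = EnvStack.read_dir(out / "landscape" / "present")
    now = _load_binary_maps(cfg, outdir, "bin_present")
    fut = _load_binary_maps(cfg, outdir, "bin_future")
    report = {"jaccard": {}, "range_change": {}, "southern_limit": {},
              "wilcoxon": {}}
    jacc_values = {}
    for mt in cfg.model_types:
        for i, r1 in enumerate(cfg.buffers_km):
            for r2 in cfg.buffers_km[i + 1:]:
                mat, summary = pairwise_jaccard(now[(r1, mt)], now[(r2, mt)])
                key = f"{int(r1)}x{int(r2)}:{mt}"
                report["jaccard"][key] = {k: round(v, 6) if isinstance(v, float)
                                          else v for k, v in summary.items()}
                jacc_values[key] = mat.ravel()
    if len(cfg.model_types) == 2 and len(cfg.buffers_km) >= 2:
        a, b = cfg.model_types
        for i, r1 in enumerate(cfg.buffers_km):
            for r2 in cfg.buffers_km[i + 1:]:
                va = jacc_values[f"{int(r1)}x{int(r2)}:{a}"]
                vb = jacc_values[f"{int(r1)}x{int(r2)}:{b}"]
                try:
                    v, p = paired_wilcoxon(vb, va, alternative="greater")
                    report["wilcoxon"][f"jaccard_{int(r1)}x{int(r2)}_"
                                       f"{b}_gt_{a}"] = {
                        "V": v, "p": float(f"{p:.6g}")}
                except ValueError:
                    pass
    rc_rows = []
    for (r, mt), maps_now in now.items():
        exp_list, con_list, south = [], [], []
        for rep, (m_now, m_fut) in enumerate(zip(maps_now, fut[(r, mt)])):
            e, c = range_change(m_now, m_fut)
            rc_rows.append({"buffer_km": r, "model_type": mt,
                            "replicate": rep, "expansion_pct": e,
                            "contraction_pct": c})
            exp_list.append(e)
            con_list.append(c)
            south.append(southern_limit(m_now, env.grid.lats))
        report["range_change"][f"{int(r)}:{mt}"] = {
            "expansion_mean": round(float(np.mean(exp_list)), 4),
            "expansion_se": round(float(np.std(exp_list, ddof=1)
                                        / np.sqrt(len(exp_list))), 4)
            if len(exp_list) > 1 else 0.0,
            "contraction_mean": round(float(np.mean(con_list)), 4),
            "contraction_se": round(float(np.std(con_list, ddof=1)
                                          / np.sqrt(len(con_list))), 4)
            if len(con_list) > 1 else 0.0}
        report["southern_limit"][f"{int(r)}:{mt}"] = round(
            float(np.mean(south)), 4)
    if len(cfg.model_types) == 2 and cfg.replicates >= 3:
        a, b = cfg.model_types
        rc = pd.DataFrame(rc_rows)
        for r in cfg.buffers_km:
            for metric in ("expansion_pct", "contraction_pct"):
                xa = rc[(rc.buffer_km == r) & (rc.model_type == a)] \
                    .sort_values("replicate")[metric].to_numpy()
                xb = rc[(rc.buffer_km == r) & (rc.model_type == b)] \
                    .sort_values("replicate")[metric].to_numpy()
                try:
                    v, p = paired_wilcoxon(xa, xb)
                    report["wilcoxon"][f"{metric}_{int(r)}_{a}_vs_{b}"] = {
                        "V": v, "p": float(f"{p:.6g}")}
                except ValueError:
                    pass
    cdir = out / "comparison"
    cdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rc_rows).to_csv(cdir / "range_change.csv", index=False,
                                 float_format="%.8g")
    (cdir / "comparison_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    done(n_jaccard_blocks=len(report["jaccard"]))
    return report


def run_experiment(cfg: RunConfig, outdir):
    """Run every stage and write a reproducible manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    simulate(cfg, outdir)
    prep(cfg, outdir)
    fit_records = fit(cfg, outdir)
    project(cfg, outdir)
    eval_report = evaluate(cfg, outdir)
    comp_report = compare(cfg, outdir)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "models": fit_records,
        "n_models": len(fit_records),
        "eval_report": "eval/eval_report.json" if eval_report else None,
        "comparison_report": "comparison/comparison_report.json",
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
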