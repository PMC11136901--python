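"""Bayesian plateau (trapezoidal envelope) species distribution model.

The per-predictor response is a trapezoid on the 0-1 normalized predictor
scale: flat (optimal) between edges ``c1 <= c2`` and declining linearly
outside with non-negative slopes ``b1`` (ascending side) and ``b2``
(descending side).  A single global intercept ``beta0`` plays the apex
role; occurrence labels are Bernoulli with

    p = logistic(beta0 + sum_j f_j(x_j)),
    f_j(x) = -b1_j * max(0, c1_j - x) - b2_j * max(0, x - c2_j).

Two prior regimes are supported.  *Naive*: vague priors on everything
(beta0 ~ N(0, 5); slopes half-normal(10); edges the order statistics of two
independent U(0,1)).  *Physiologically informed*: for selected predictors
the plateau edges are restricted to the normalized image of a laboratory
optimal range, and the descending slope is deterministically linked to a
hard tolerance limit so that suitability at the limit equals a configured
"effectively absent" floor:  b2 = (beta0 - L) / (x_limit - c2) with
L = logit(floor).

Inference is by component-wise adaptive random-walk Metropolis (adaptation
during warm-up only), with the study-default configuration of 2 chains x
5000 iterations (4000 warm-up), both chains started from the same initial
values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "PlateauParams", "PhysioConstraint", "PriorSpec", "PredictorPrior",
    "MCMCConfig", "PlateauModel", "PlateauResults", "plateau_response",
    "presence_probability", "log_likelihood", "build_prior",
    "default_constraints", "convergence_diagnostics",
]

_LP_CLIP = 27.631021  # logit(1 - 1e-12): probability floor inside the likelihood


# --------------------------------------------------------------------------
# response / likelihood primitives
# --------------------------------------------------------------------------

def plateau_response(x, c1, c2, b1, b2):
    """Trapezoid log-odds penalty; 0 on the plateau, <= 0 elsewhere."""
    x = np.asarray(x, dtype=float)
    return -b1 * np.maximum(0.0, c1 - x) - b2 * np.maximum(0.0, x - c2)


def _linear_predictor(X, params):
    """X: (n, J) normalized predictors; params: PlateauParams."""
    X = np.asarray(X, dtype=float)
    pen = plateau_response(X, params.c1[None, :], params.c2[None, :],
                           params.b1[None, :], params.b2[None, :])
    return params.beta0 + pen.sum(axis=1)


def presence_probability(X, params):
    """Per-row presence probability for normalized predictor rows ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != params.c1.size:
        raise ValueError(f"predictor vector has {X.shape[1]} columns, "
                         f"model has {params.c1.size}")
    if np.isnan(X).any():
        raise ValueError("missing predictor value in input")
    return expit(_linear_predictor(X, params))


def log_likelihood(y, X, params):
    """Bernoulli log likelihood; probabilities clamped to [1e-12, 1-1e-12]."""
    y = np.asarray(y, dtype=float)
    lp = np.clip(_linear_predictor(X, params), -_LP_CLIP, _LP_CLIP)
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


@dataclass
class PlateauParams:
    """One full parameter point: arrays over predictors plus the intercept."""

    beta0: float
    c1: np.ndarray
    c2: np.ndarray
    b1: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        self.c1, self.c2, self.b1, self.b2 = (
            np.asarray(a, dtype=float) for a in (self.c1, self.c2, self.b1, self.b2))
        if np.any(self.c1 > self.c2 + 1e-12):
            raise ValueError("plateau edges must satisfy c1 <= c2")
        if np.any(self.b1 < 0) or np.any(self.b2 < 0):
            raise ValueError("plateau slopes must be non-negative")


# --------------------------------------------------------------------------
# priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysioConstraint:
    """Laboratory/field tolerance information for one predictor.

    ``optimal_range`` and ``hard_limit`` are in physical units (degC, m...);
    they are mapped through the predictor normalization when the prior is
    built.  ``limit_side`` says which tail the hard limit bounds.
    """

    predictor: str
    optimal_range: tuple
    hard_limit: float
    limit_side: str = "upper"

    def __post_init__(self):
        lo, hi = self.optimal_range
        if lo > hi:
            raise ValueError("optimal_range must be (low, high)")
        if self.limit_side not in ("upper", "lower", "both", "none"):
            raise ValueError("limit_side must be upper/lower/both/none")
        if self.limit_side == "upper" and self.hard_limit < hi:
            raise ValueError("optimal range must lie inside the hard limit")
        if self.limit_side == "lower" and self.hard_limit > lo:
            raise ValueError("optimal range must lie inside the hard limit")


def default_constraints():
    """Tolerance table for the Japanese sea cucumber: optimal growth
    temperature 15-18 degC with a 26 degC upper thermal limit; optimal depth
    0-40 m with a 200 m maximum depth limit."""
    return [
        PhysioConstraint("temp_mean", (15.0, 18.0), 26.0, "upper"),
        PhysioConstraint("depth", (0.0, 40.0), 200.0, "upper"),
    ]


@dataclass
class PredictorPrior:
    """Prior entry for one predictor's trapezoid parameters.

    mode:
      free       -- edges uniform order statistics on [0, 1], slopes
                    half-normal(slope_sd)
      informed   -- edges confined to (or fixed at) the normalized optimal
                    range; b2 deterministically linked to the hard limit
      linear_only-- single linear coefficient ~ N(0, 5) (no trapezoid)
      excluded   -- predictor dropped from the linear predictor
    """

    name: str
    mode: str = "free"
    c1_bounds: tuple = (0.0, 1.0)
    c2_bounds: tuple = (0.0, 1.0)
    c1_fixed: float | None = None
    c2_fixed: float | None = None
    slope_sd: float = 10.0
    b2_link_limit: float | None = None  # normalized hard-limit location

    def __post_init__(self):
        if self.mode not in ("free", "informed", "linear_only", "excluded"):
            raise ValueError(f"unknown prior mode {self.mode!r}")


@dataclass
class PriorSpec:
    """Complete prior over PlateauParams; one entry per predictor."""

    predictors: list
    beta0_mean: float = 0.0
    beta0_sd: float = 5.0
    absent_floor: float = 0.01  # presence probability at a hard limit

    def __post_init__(self):
        names = [p.name for p in self.predictors]
        if len(names) != len(set(names)):
            raise ValueError("duplicate predictor prior entry")

    @property
    def floor_logit(self):
        return float(logit(self.absent_floor))

    @property
    def names(self):
        return [p.name for p in self.predictors]

    def entry(self, name):
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def has_linked_slope(self):
        return any(p.b2_link_limit is not None for p in self.predictors)

    def to_dict(self):
        return {"predictors": [asdict(p) for p in self.predictors],
                "beta0_mean": self.beta0_mean, "beta0_sd": self.beta0_sd,
                "absent_floor": self.absent_floor}

    @classmethod
    def from_dict(cls, d):
        preds = [PredictorPrior(**{**p, "c1_bounds": tuple(p["c1_bounds"]),
                                   "c2_bounds": tuple(p["c2_bounds"])})
                 for p in d["predictors"]]
        return cls(preds, d["beta0_mean"], d["beta0_sd"], d["absent_floor"])


def build_prior(mode, constraints=None, transform=None, predictors=None,
                slope_sd=10.0, absent_floor=0.01):
    """Build the prior for a naive or physiologically informed model.

    Parameters
    ----------
    mode : {"naive", "informed"}
    constraints : list of PhysioConstraint, used only in informed mode.
    transform : NormalizationTransform mapping physical units to the shared
        0-1 scale (required in informed mode).
    predictors : ordered predictor names; defaults to the transform's.
    """
    if mode not in ("naive", "informed"):
        raise ValueError("mode must be 'naive' or 'informed'")
    if predictors is None:
        if transform is None:
            raise ValueError("need predictor names or a transform")
        predictors = list(transform.layers)
    entries = {name: PredictorPrior(name, "free", slope_sd=slope_sd)
               for name in predictors}
    if mode == "informed":
        if transform is None:
            raise ValueError("informed priors need a normalization transform")
        for con in constraints or []:
            if con.predictor not in entries:
                raise ValueError(f"constraint references unknown predictor "
                                 f"{con.predictor!r}")
            if con.limit_side != "upper":
                raise NotImplementedError(
                    "only upper hard limits are implemented")
            lo = transform.normalize_value(con.predictor, con.optimal_range[0])
            hi = transform.normalize_value(con.predictor, con.optimal_range[1])
            lim = transform.normalize_value(con.predictor, con.hard_limit)
            # an optimum reaching below the observed minimum simply pins the
            # lower edge at the observed floor; the upper end must lie
            # inside the observed range for the plateau to be locatable
            if not (0.0 <= hi <= 1.0 + 1e-9) or lo > hi:
                raise ValueError(
                    f"optimal range of {con.predictor!r} maps to [{lo:.3f}, "
                    f"{hi:.3f}], outside the normalized observed range")
            lo, hi = min(max(lo, 0.0), hi), min(hi, 1.0)
            e = entries[con.predictor]
            e.mode = "informed"
            if hi - lo < 1e-9:
                e.c1_fixed, e.c2_fixed = lo, hi
            elif con.optimal_range[0] <= transform.offsets[con.predictor]:
                # optimum starts at the observed minimum: pin both edges
                e.c1_fixed, e.c2_fixed = lo, hi
            else:
                e.c1_bounds = (lo, hi)
                e.c2_bounds = (lo, hi)
            e.b2_link_limit = float(lim)
    return PriorSpec(list(entries.values()), absent_floor=absent_floor)


# --------------------------------------------------------------------------
# MCMC
# --------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Sampler configuration (study default: 2 chains, 5000 iterations of
    which 4000 warm-up, identical initial values across chains)."""

    n_chains: int = 2
    n_iter: int = 5000
    n_warmup: int = 4000
    seed: int = 0
    jitter_inits: bool = False
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if not (0 < self.n_warmup < self.n_iter):
            raise ValueError("need 0 < n_warmup < n_iter")

    def to_dict(self):
        return asdict(self)


class _FreeParam:
    __slots__ = ("name", "kind", "j", "lo", "hi", "step")

    def __init__(self, name, kind, j, lo, hi, step):
        self.name, self.kind, self.j = name, kind, j
        self.lo, self.hi, self.step = lo, hi, step


class PlateauModel:
    """Plateau SDM bound to presence/pseudo-absence data.

    Parameters
    ----------
    endog : (n,) 0/1 labels (1 = presence).
    exog : (n, J) predictor matrix on the shared 0-1 normalized scale.
    names : predictor names (columns of ``exog``).
    prior : PriorSpec (see :func:`build_prior`).
    link : only "logit" is supported.
    """

    def __init__(self, endog, exog, names, prior: PriorSpec, link="logit"):
        if link != "logit":
            raise NotImplementedError("only the logistic link is implemented")
        self.y = np.asarray(endog, dtype=float).ravel()
        self.X = np.asarray(exog, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("endog/exog shapes are inconsistent")
        if np.isnan(self.X).any():
            raise ValueError("exog contains missing values")
        self.names = list(names)
        if len(self.names) != self.X.shape[1]:
            raise ValueError("names do not match exog columns")
        if set(prior.names) != set(self.names):
            raise ValueError("prior entries do not match predictors")
        # reorder prior entries to column order
        self.prior = PriorSpec([prior.entry(n) for n in self.names],
                               prior.beta0_mean, prior.beta0_sd,
                               prior.absent_floor)
        if self.y.min() == self.y.max():
            raise ValueError("data must contain both presences and absences")

    @classmethod
    def from_dataframe(cls, frame, prior, label_col="label", names=None):
        """Build from a tidy table with one predictor column per name and a
        presence/pseudo_absence label column."""
        names = names or [c for c in frame.columns if c != label_col]
        y = (frame[label_col].astype(str) == "presence").astype(float).to_numpy()
        X = frame[names].to_numpy(dtype=float)
        return cls(y, X, names, prior)

    # -------------------------------------------------------------- fitting
    def _initial_params(self, rng=None):
        J = len(self.names)
        c1 = np.empty(J)
        c2 = np.empty(J)
        b1 = np.empty(J)
        b2 = np.empty(J)
        beta0 = max(1.0, self.prior.floor_logit + 1.0)
        for j, e in enumerate(self.prior.predictors):
            lo1, hi1 = e.c1_bounds
            lo2, hi2 = e.c2_bounds
            c1[j] = e.c1_fixed if e.c1_fixed is not None else lo1 + 0.25 * (hi1 - lo1)
            c2[j] = e.c2_fixed if e.c2_fixed is not None else lo2 + 0.75 * (hi2 - lo2)
            b1[j] = 1.0
            b2[j] = 1.0
        p = PlateauParams(beta0, c1, c2, b1, b2)
        self._apply_links(p)
        if rng is not None:  # optional jitter
            p.c1 += rng.uniform(-0.02, 0.0, J)
            p.c2 += rng.uniform(0.0, 0.02, J)
            p.beta0 += rng.normal(0.0, 0.1)
            self._apply_links(p)
        return p

    def _apply_links(self, p: PlateauParams):
        L = self.prior.floor_logit
        for j, e in enumerate(self.prior.predictors):
            if e.b2_link_limit is not None:
                p.b2[j] = (p.beta0 - L) / (e.b2_link_limit - p.c2[j])

    def _free_params(self):
        out = [_FreeParam("beta0", "beta0", None, -np.inf, np.inf, 0.5)]
        for j, e in enumerate(self.prior.predictors):
            if e.mode == "excluded":
                continue
            if e.c1_fixed is None:
                out.append(_FreeParam(f"c1[{e.name}]", "c1", j,
                                      e.c1_bounds[0], e.c1_bounds[1], 0.1))
            if e.c2_fixed is None:
                out.append(_FreeParam(f"c2[{e.name}]", "c2", j,
                                      e.c2_bounds[0], e.c2_bounds[1], 0.1))
            out.append(_FreeParam(f"b1[{e.name}]", "b1", j, 0.0, np.inf, 1.0))
            if e.b2_link_limit is None:
                out.append(_FreeParam(f"b2[{e.name}]", "b2", j, 0.0, np.inf, 1.0))
        return out

    def _log_prior(self, p: PlateauParams):
        pr = self.prior
        lpri = -0.5 * ((p.beta0 - pr.beta0_mean) / pr.beta0_sd) ** 2
        if pr.has_linked_slope() and p.beta0 < pr.floor_logit:
            return -np.inf  # linked slope would be negative
        for j, e in enumerate(pr.predictors):
            if e.mode == "excluded":
                continue
            if not (e.c1_bounds[0] - 1e-12 <= p.c1[j] <= e.c1_bounds[1] + 1e-12) \
                    and e.c1_fixed is None:
                return -np.inf
            if not (e.c2_bounds[0] - 1e-12 <= p.c2[j] <= e.c2_bounds[1] + 1e-12) \
                    and e.c2_fixed is None:
                return -np.inf
            if p.c1[j] > p.c2[j] or p.b1[j] < 0:
                return -np.inf
            lpri += -0.5 * (p.b1[j] / e.slope_sd) ** 2
            if e.b2_link_limit is None:
                if p.b2[j] < 0:
                    return -np.inf
                lpri += -0.5 * (p.b2[j] / e.slope_sd) ** 2
        return lpri

    def loglike(self, params: PlateauParams):
        return log_likelihood(self.y, self.X, params)

    def fit(self, config: MCMCConfig | None = None):
        """Run the sampler and return a :class:`PlateauResults`."""
        cfg = config or MCMCConfig()
        free = self._free_params()
        n_keep = cfg.n_iter - cfg.n_warmup
        names_out = (["beta0"]
                     + [f"{k}[{n}]" for n in self.names for k in ("c1", "c2", "b1", "b2")])
        draws = {nm: np.empty((cfg.n_chains, n_keep)) for nm in names_out}
        accept = np.zeros(cfg.n_chains)
        for chain in range(cfg.n_chains):
            rng = np.random.default_rng([int(cfg.seed) % (2**31), chain])
            p = self._initial_params(rng if cfg.jitter_inits else None)
            lpost = self.loglike(p) + self._log_prior(p)
            if not np.isfinite(lpost):
                raise RuntimeError(
                    "non-finite posterior at initialization; parameters: "
                    f"{p}")
            steps = np.array([fp.step for fp in free])
            acc_win = np.zeros(len(free))
            n_acc = 0
            for it in range(cfg.n_iter):
                for i, fp in enumerate(free):
                    p_new, ok = self._propose(p, fp, steps[i], rng)
                    if ok:
                        lpri = self._log_prior(p_new)
                        if np.isfinite(lpri):
                            lpost_new = self.loglike(p_new) + lpri
                            if np.log(rng.uniform()) < lpost_new - lpost:
                                p, lpost = p_new, lpost_new
                                acc_win[i] += 1
                                n_acc += 1
                if it < cfg.n_warmup and (it + 1) % cfg.adapt_interval == 0:
                    rate = acc_win / cfg.adapt_interval
                    steps *= np.exp(np.clip(rate - cfg.target_accept, -0.5, 0.5))
                    steps = np.clip(steps, 1e-4, 50.0)
                    acc_win[:] = 0
                if it >= cfg.n_warmup:
                    k = it - cfg.n_warmup
                    draws["beta0"][chain, k] = p.beta0
                    for j, nm in enumerate(self.names):
                        draws[f"c1[{nm}]"][chain, k] = p.c1[j]
                        draws[f"c2[{nm}]"][chain, k] = p.c2[j]
                        draws[f"b1[{nm}]"][chain, k] = p.b1[j]
                        draws[f"b2[{nm}]"][chain, k] = p.b2[j]
            accept[chain] = n_acc / (cfg.n_iter * len(free))
        return PlateauResults(self, cfg, draws, accept)

    def _propose(self, p: PlateauParams, fp: _FreeParam, step, rng):
        eps = rng.normal(0.0, step)
        q = PlateauParams(p.beta0, p.c1.copy(), p.c2.copy(),
                          p.b1.copy(), p.b2.copy())
        if fp.kind == "beta0":
            q.beta0 = p.beta0 + eps
        else:
            arr = getattr(q, fp.kind)
            arr[fp.j] += eps
            v = arr[fp.j]
            if not (fp.lo <= v <= fp.hi):
                return p, False
            if fp.kind == "c1" and v > q.c2[fp.j]:
                return p, False
            if fp.kind == "c2" and v < q.c1[fp.j]:
                return p, False
        self._apply_links(q)
        if np.any(q.b2 < 0):
            return p, False
        return q, True


# --------------------------------------------------------------------------
# results
# --------------------------------------------------------------------------

class PlateauResults:
    """Posterior draws plus diagnostics for a fitted plateau SDM.

    ``draws`` maps parameter name -> array of shape (n_chains, n_draws);
    deterministic (linked or fixed) parameters are stored alongside the
    sampled ones so every draw is a complete PlateauParams point.
    """

    def __init__(self, model, config, draws, accept_rates, meta=None):
        self.model = model
        self.config = config
        self.draws = draws
        self.accept_rates = np.asarray(accept_rates, dtype=float)
        self.names = list(model.names) if model is not None else meta["names"]
        self.prior = model.prior if model is not None else meta["prior"]
        self.meta = meta or {}

    # ----------------------------------------------------------- accessors
    @property
    def n_draws(self):
        """Retained draws per chain."""
        return next(iter(self.draws.values())).shape[1]

    @property
    def n_chains(self):
        return next(iter(self.draws.values())).shape[0]

    def flat(self, name):
        return self.draws[name].reshape(-1)

    def param_points(self, thin_to=None):
        """Iterate over retained draws as PlateauParams (optionally an even
        deterministic subsample of at most ``thin_to`` draws)."""
        total = self.n_chains * self.n_draws
        idx = np.arange(total)
        if thin_to is not None and thin_to < total:
            idx = np.linspace(0, total - 1, thin_to).round().astype(int)
        beta0 = self.flat("beta0")
        c1 = np.column_stack([self.flat(f"c1[{n}]") for n in self.names])
        c2 = np.column_stack([self.flat(f"c2[{n}]") for n in self.names])
        b1 = np.column_stack([self.flat(f"b1[{n}]") for n in self.names])
        b2 = np.column_stack([self.flat(f"b2[{n}]") for n in self.names])
        for i in idx:
            yield PlateauParams(beta0[i], c1[i], c2[i], b1[i], b2[i])

    # ---------------------------------------------------------- prediction
    def predict(self, X, ci=0.95, thin_to=None):
        """Posterior mean presence probability and central interval.

        Returns (mean, lower, upper) arrays over rows of ``X``.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.names):
            raise ValueError("predictor matrix does not match the fitted model")
        probs = np.stack([presence_probability(X, p)
                          for p in self.param_points(thin_to)], axis=0)
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.quantile(probs, [alpha, 1.0 - alpha], axis=0)
        return probs.mean(axis=0), lo, hi

    def predict_mean(self, X, thin_to=None):
        return self.predict(X, thin_to=thin_to)[0]

    # --------------------------------------------------------- diagnostics
    def diagnostics(self):
        return convergence_diagnostics(self)

    def summary(self, ci=0.95):
        """Posterior summary table (mean, sd, interval, R-hat, ESS)."""
        diag = self.diagnostics()
        rows = []
        alpha = (1.0 - ci) / 2.0
        for name, arr in self.draws.items():
            flat = arr.reshape(-1)
            lo, hi = np.quantile(flat, [alpha, 1.0 - alpha])
            rows.append({"parameter": name, "mean": flat.mean(),
                         "sd": flat.std(ddof=1), f"{100*alpha:g}%": lo,
                         f"{100*(1-alpha):g}%": hi,
                         "r_hat": diag.loc[name, "r_hat"],
                         "ess": diag.loc[name, "ess"]})
        return pd.DataFrame(rows).set_index("parameter")

    def credible_interval(self, name, ci=0.95):
        alpha = (1.0 - ci) / 2.0
        return tuple(np.quantile(self.flat(name), [alpha, 1.0 - alpha]))

    # ----------------------------------------------------------------- IO
    def save(self, path):
        """Write draws as CSV (one row per draw) plus a JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = {"chain": np.repeat(np.arange(self.n_chains), self.n_draws),
                "draw": np.tile(np.arange(self.n_draws), self.n_chains)}
        for name, arr in self.draws.items():
            cols[name] = arr.reshape(-1)
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
        sidecar = {"names": self.names, "config": self.config.to_dict(),
                   "prior": self.prior.to_dict(),
                   "accept_rates": [round(float(a), 6) for a in self.accept_rates],
                   "meta": self.meta}
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path):
        path = Path(path)
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        table = pd.read_csv(path)
        n_chains = int(table["chain"].max()) + 1
        n_draws = len(table) // n_chains
        draws = {}
        for col in table.columns:
            if col in ("chain", "draw"):
                continue
            draws[col] = table[col].to_numpy().reshape(n_chains, n_draws)
        cfg = MCMCConfig(**sidecar["config"])
        meta = dict(sidecar.get("meta") or {})
        meta["names"] = sidecar["names"]
        meta["prior"] = PriorSpec.from_dict(sidecar["prior"])
        return cls(None, cfg, draws, sidecar["accept_rates"], meta=meta)

    # ------------------------------------------------------------ plotting
    def plot_response(self, curve_table, ax=None, hard_limit=None):
        """Plot a marginal response curve table (see evaluation.response_curve)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        x = curve_table["value"]
        ax.fill_between(x, curve_table["lower"], curve_table["upper"],
                        alpha=0.3, color="tab:blue")
        ax.plot(x, curve_table["mean"], color="tab:blue")
        if hard_limit is not None:
            ax.axvline(hard_limit, color="k", ls="--", lw=1)
        ax.set_ylim(0, 1)
        ax.set_ylabel("presence probability")
        return ax


def convergence_diagnostics(results, rhat_warn=1.1):
    """Split-R-hat and bulk effective sample size per parameter (via arviz).

    Emits a warning (never an error) for any parameter with R-hat above
    ``rhat_warn``.  Requires at least two chains.
    """
    import arviz as az
    draws = results.draws if hasattr(results, "draws") else results
    first = next(iter(draws.values()))
    if first.ndim != 2 or first.shape[0] < 2:
        raise ValueError("convergence diagnostics need >= 2 chains")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz complains about tiny chains
        for name, arr in draws.items():
            if np.allclose(arr, arr.reshape(-1)[0]):
                rhat, ess = 1.0, float(arr.size)  # degenerate (fixed) parameter
            else:
                rhat = float(az.rhat(az.convert_to_dataset(arr[None] if arr.ndim == 1
                                                           else arr))["x"].values)
                ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
            rows.append({"parameter": name, "r_hat": rhat, "ess": ess})
    out = pd.DataFrame(rows).set_index("parameter")
    bad = out[out["r_hat"] > rhat_warn]
    if len(bad):
        warnings.warn(
            "R-hat above %.2f for: %s" % (rhat_warn, ", ".join(bad.index)),
            UserWarning)
    return out
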