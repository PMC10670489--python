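"""Tree-structured Parzen Estimator (TPE) hyper-parameter optimization.

Sequential model-based search: after a few random start-up trials the
observed objective values are split at the gamma-quantile into "good" and
"bad" trials; per-parameter density estimates l(x) (good) and g(x) (bad)
are formed (Gaussian KDE for continuous parameters, add-one counts for
categorical ones); candidates are sampled from l and the one maximizing
log l(x) - log g(x) is evaluated next.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

from .network import NetConfig

__all__ = ["SearchSpace", "default_search_space", "tpe_maximize", "hpo_tpe"]

#: parameter spec: ("uniform", lo, hi) | ("loguniform", lo, hi) |
#: ("choice", (options, ...))
SearchSpace = dict


def default_search_space() -> SearchSpace:
    """The tuned surface of the CNN-LSTM: layer count, learning rate,
    dropout, reject threshold and augmentation mode."""
    return {
        "n_layers": ("choice", (25, 56)),
        "learning_rate": ("loguniform", 1e-4, 0.05),
        "dropout": ("uniform", 0.1, 0.25),
        "reject_threshold": ("choice", (0.2, 0.8)),
        "augmentation": ("choice", ("none", "frequency", "value", "both")),
    }


def _sample_prior(spec, rng):
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "loguniform":
        return float(np.exp(rng.uniform(math.log(spec[1]), math.log(spec[2]))))
    if kind == "choice":
        return spec[1][int(rng.integers(len(spec[1])))]
    raise ValueError(f"unknown parameter kind {kind!r}")


def _kde(values: np.ndarray, lo: float, hi: float):
    """Gaussian KDE with a widened fallback for degenerate samples."""
    if np.unique(values).size < 2:
        center = values[0] if values.size else 0.5 * (lo + hi)
        sd = (hi - lo) / 10.0 or 1.0
        return stats.norm(loc=center, scale=sd)
    try:
        return stats.gaussian_kde(values)
    except np.linalg.LinAlgError:
        return stats.norm(loc=values.mean(), scale=values.std() + 1e-9)


def _logpdf(model, x):
    if isinstance(model, stats.gaussian_kde):
        return float(model.logpdf([x])[0])
    return float(model.logpdf(x))


def _rvs(model, n, rng):
    if isinstance(model, stats.gaussian_kde):
        return model.resample(n, seed=rng).ravel()
    return model.rvs(size=n, random_state=rng)


def _propose(space, trials, rng, gamma, n_candidates):
    values = np.array([v for _, v in trials])
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    order = np.argsort(-values)  # maximize
    good_idx = set(order[:n_good].tolist())

    models = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "choice":
            options = spec[1]
            cg = np.ones(len(options))
            cb = np.ones(len(options))
            for i, (params, _) in enumerate(trials):
                j = options.index(params[name])
                (cg if i in good_idx else cb)[j] += 1
            models[name] = ("choice", options, cg / cg.sum(), cb / cb.sum())
        else:
            lo, hi = spec[1], spec[2]
            tf = math.log if kind == "loguniform" else (lambda v: v)
            goods = np.array([tf(p[name]) for i, (p, _) in enumerate(trials)
                              if i in good_idx])
            bads = np.array([tf(p[name]) for i, (p, _) in enumerate(trials)
                             if i not in good_idx])
            l_lo, l_hi = tf(lo), tf(hi)
            models[name] = ("cont", kind, lo, hi,
                            _kde(goods, l_lo, l_hi), _kde(bads, l_lo, l_hi))

    best_score, best_params = -np.inf, None
    for _ in range(n_candidates):
        params, score = {}, 0.0
        for name, model in models.items():
            if model[0] == "choice":
                _, options, pg, pb = model
                j = int(rng.choice(len(options), p=pg))
                params[name] = options[j]
                score += math.log(pg[j]) - math.log(pb[j])
            else:
                _, kind, lo, hi, lmod, gmod = model
                tf = math.log if kind == "loguniform" else (lambda v: v)
                itf = math.exp if kind == "loguniform" else (lambda v: v)
                draw = float(np.clip(_rvs(lmod, 1, rng)[0], tf(lo), tf(hi)))
                params[name] = float(min(max(itf(draw), lo), hi))
                score += _logpdf(lmod, draw) - _logpdf(gmod, draw)
        if score > best_score:
            best_score, best_params = score, params
    return best_params


def tpe_maximize(objective, space: SearchSpace, budget: int, seed: int = 0,
                 gamma: float = 0.25, n_startup: int = 8,
                 n_candidates: int = 24):
    """Maximize ``objective(params)`` over ``space`` with ``budget`` trials.

    Returns (best_params, history) where history is the list of
    (params, value) in evaluation order; the running best is therefore
    non-decreasing when the budget grows under the same seed.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[tuple[dict, float]] = []
    for t in range(budget):
        if t < n_startup or len(trials) < 2:
            params = {k: _sample_prior(spec, rng) for k, spec in space.items()}
        else:
            params = _propose(space, trials, rng, gamma, n_candidates)
        trials.append((params, float(objective(params))))
    best_params, _ = max(trials, key=lambda pv: pv[1])
    return best_params, trials


def hpo_tpe(objective=None, space: SearchSpace | None = None,
            budget: int = 20, seed: int = 0,
            X=None, y=None, base_cfg: NetConfig | None = None,
            k: int = 5) -> tuple[NetConfig, list]:
    """Tune the CNN-LSTM by TPE; the objective defaults to the mean CV F1
    of a model trained on (X, y) with the sampled hyper-parameters."""
    space = space or default_search_space()
    base = base_cfg or NetConfig()
    if objective is None:
        if X is None or y is None:
            raise ValueError("provide an objective or (X, y)")
        from .training import train_cv

        def objective(params):
            cfg = dataclasses.replace(base, **params)
            return train_cv(cfg, X, y, k=k).mean_f1

    best_params, history = tpe_maximize(objective, space, budget, seed=seed)
    valid = {f.name for f in dataclasses.fields(NetConfig)}
    overrides = {k_: v for k_, v in best_params.items() if k_ in valid}
    return dataclasses.replace(base, **overrides), history
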