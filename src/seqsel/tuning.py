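"""Tuning-model family, BIC model selection and unit classification.

The pre-saccadic response of a unit (mean rate 50 ms before to 20 ms after
saccade onset on no-choice trials) is fit with every linear combination of
three terms plus a constant baseline b0:

* value sigmoid      f(V) = b1 / (1 + exp(-s (V - t))),   s in (0,1], t in (0,1)
* circular Gaussian  g(D) = b2 * exp(w (cos(D - p) - 1)), w in (0,4pi], p in [0,2pi)
* interaction        h(V,D) = b3 * sigmoid(V) * exp(w (cos(D - p) - 1))

giving 8 models: {}, {f}, {g}, {h}, {f,g}, {f,h}, {g,h}, {f,g,h}.  Models
sharing f and h use one (s,t); models sharing g and h use one (w,p).
Selection is by BIC with k counted as the number of included terms (a
deliberately loose complexity count so marginal units are retained).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datatypes import NeuronData, TESTED_DIRECTIONS, TrialRecord, snap_direction
from .rates import window_mean_rates

MODEL_IDS = ("const", "f", "g", "h", "fg", "fh", "gh", "fgh")

#: response epoch for model fitting, ms re saccade onset
RESPONSE_WINDOW = (-50.0, 20.0)


def _param_names(model_id: str) -> list[str]:
    names = ["b0"]
    if "f" in model_id:
        names.append("b1")
    if "g" in model_id:
        names.append("b2")
    if "h" in model_id:
        names.append("b3")
    if "f" in model_id or "h" in model_id:
        names += ["s", "t"]
    if "g" in model_id or "h" in model_id:
        names += ["w", "p"]
    return names


def eval_model(
    V: np.ndarray, D: np.ndarray, params: dict[str, float], model_id: str
) -> np.ndarray:
    """Predicted rate for value V (in [0,1]) and direction D (radians)."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model {model_id!r}")
    for name in _param_names(model_id):
        if name not in params:
            raise ValueError(f"model {model_id!r} missing parameter {name!r}")
    V = np.asarray(V, dtype=float)
    D = np.asarray(D, dtype=float)
    if "s" in params and not (0 < params["s"] <= 1 and 0 < params["t"] < 1):
        raise ValueError("sigmoid parameters out of range")
    if "w" in params and not (0 < params["w"] <= 4 * np.pi):
        raise ValueError("tuning width out of range")

    rate = np.full(np.broadcast(V, D).shape, params["b0"], dtype=float)
    if "f" in model_id or "h" in model_id:
        sig = 1.0 / (1.0 + np.exp(-params["s"] * (V - params["t"])))
    if "g" in model_id or "h" in model_id:
        circ = np.exp(params["w"] * (np.cos(D - params["p"]) - 1.0))
    if "f" in model_id:
        rate = rate + params["b1"] * sig
    if "g" in model_id:
        rate = rate + params["b2"] * circ
    if "h" in model_id:
        rate = rate + params["b3"] * sig * circ
    return rate


def bic(rss: float, n: int, k: int) -> float:
    """n * ln(RSS/n) + k * ln(n); k is the number of included terms."""
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + k * np.log(n)


@dataclass
class ModelFit:
    model_id: str
    params: dict[str, float]
    rss: float
    n: int
    k: int
    bic: float
    converged: bool

    def predict(self, V: np.ndarray, D: np.ndarray) -> np.ndarray:
        return eval_model(V, D, self.params, self.model_id)


_ST_GRID = [(0.3, 0.3), (0.8, 0.5), (0.95, 0.7)]
_W_GRID = [1.0, 3.0, 8.0]


def _starts(model_id: str, resp: np.ndarray) -> list[dict[str, float]]:
    """Multi-start initializations: p at each tested direction crossed with a
    coarse (s,t,w) grid, deduplicated over the parameters the model uses."""
    b0 = float(np.mean(resp))
    amp = float(np.std(resp)) or 1.0
    starts, seen = [], set()
    for pdir in TESTED_DIRECTIONS:
        for (s0, t0), w0 in zip(_ST_GRID, _W_GRID):
            start = {"b0": b0, "b1": amp, "b2": amp, "b3": amp,
                     "s": s0, "t": t0, "w": w0, "p": np.radians(pdir)}
            key = tuple(round(start[n], 6) for n in _param_names(model_id))
            if key in seen:
                continue
            seen.add(key)
            starts.append(start)
    return starts


_BOUNDS = {
    "b0": (-np.inf, np.inf),
    "b1": (-np.inf, np.inf),
    "b2": (-np.inf, np.inf),
    "b3": (-np.inf, np.inf),
    "s": (1e-3, 1.0),
    "t": (1e-3, 1.0 - 1e-3),
    "w": (1e-3, 4 * np.pi),
    # allow p to move through the wrap; reported mod 2pi
    "p": (-np.pi, 3 * np.pi),
}


def fit_single_model(
    V: np.ndarray, D: np.ndarray, resp: np.ndarray, model_id: str
) -> ModelFit:
    """Nonlinear least squares for one family member, multi-start."""
    V = np.asarray(V, float)
    D = np.asarray(D, float)
    resp = np.asarray(resp, float)
    n = resp.size
    k = sum(term in model_id for term in "fgh") if model_id != "const" else 0

    if model_id == "const":
        b0 = float(resp.mean())
        rss = float(np.sum((resp - b0) ** 2))
        return ModelFit("const", {"b0": b0}, rss, n, 0, bic(rss, n, 0), True)

    names = _param_names(model_id)
    lo = np.array([_BOUNDS[nm][0] for nm in names])
    hi = np.array([_BOUNDS[nm][1] for nm in names])

    def resid(x: np.ndarray) -> np.ndarray:
        params = dict(zip(names, x))
        params["p"] = params.get("p", 0.0)
        return _eval_unchecked(V, D, params, model_id) - resp

    best_x, best_cost, ok = None, np.inf, False
    for start in _starts(model_id, resp):
        x0 = np.clip([start[nm] for nm in names], lo, hi)
        try:
            res = optimize.least_squares(
                resid, x0, bounds=(lo, hi), xtol=1e-8, ftol=1e-8, max_nfev=150
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best_x, best_cost, ok = res.x, res.cost, True
    if not ok:
        return ModelFit(model_id, {}, np.inf, n, k, np.inf, False)

    params = dict(zip(names, best_x))
    if "p" in params:
        params["p"] = float(params["p"]) % (2 * np.pi)
    rss = float(2 * best_cost)
    return ModelFit(model_id, params, rss, n, k, bic(rss, n, k), True)


def _eval_unchecked(V, D, params, model_id):
    # optimizer-internal evaluation without range checks (bounds enforce them)
    rate = np.full(np.broadcast(np.asarray(V), np.asarray(D)).shape,
                   params["b0"], dtype=float)
    if "f" in model_id or "h" in model_id:
        sig = 1.0 / (1.0 + np.exp(-params["s"] * (np.asarray(V) - params["t"])))
    if "g" in model_id or "h" in model_id:
        circ = np.exp(params["w"] * (np.cos(np.asarray(D) - params["p"]) - 1.0))
    if "f" in model_id:
        rate = rate + params["b1"] * sig
    if "g" in model_id:
        rate = rate + params["b2"] * circ
    if "h" in model_id:
        rate = rate + params["b3"] * sig * circ
    return rate


def fit_model_family(
    V: np.ndarray, D: np.ndarray, resp: np.ndarray
) -> tuple[dict[str, ModelFit], str]:
    """Fit all 8 models; returns (fits, best model id by minimum BIC)."""
    V = np.asarray(V, float)
    if np.unique(np.round(V, 9)).size < 2 or np.unique(np.round(D, 9)).size < 2:
        raise ValueError("need >= 2 value levels and >= 2 directions")
    fits = {mid: fit_single_model(V, D, resp, mid) for mid in MODEL_IDS}
    valid = {m: f for m, f in fits.items() if f.converged}
    best = min(valid, key=lambda m: valid[m].bic)
    return fits, best


def family_inputs_from_session(
    neuron: NeuronData, trials: list[TrialRecord], psi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(V, D, response) triplets from no-choice trials: target value,
    target direction (radians), mean rate in the pre-saccadic epoch."""
    nc = [t for t in trials if t.trial_type == "no_choice"]
    V = np.array([psi[t.targets[0].gamble_id - 1] for t in nc])
    D = np.radians([t.targets[0].direction for t in nc])
    resp = window_mean_rates(neuron, nc, "saccade_on", RESPONSE_WINDOW)
    return V, D, resp


@dataclass
class UnitClassification:
    task_related_screen: bool
    task_related_bic: bool
    directional: bool
    preferred_direction_fitted: float | None  # radians
    preferred_direction_snapped: float | None  # degrees, one of the tested four
    best_model: str
    screen_p_values: dict[str, float] | None = None


def screen_task_related(
    neuron: NeuronData,
    trials: list[TrialRecord],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = 0,
    alpha: float = 0.05,
) -> tuple[bool, dict[str, float]]:
    """Permutation screen: any 50 ms task interval vs pre-target baseline.

    Baseline is 200-150 ms before target onset.  Task intervals are the
    three 50 ms bins 50-200 ms after target onset and the three bins
    150-0 ms before saccade onset (either epoch suffices).  For each
    interval, trial rates from baseline and interval are pooled and epoch
    labels permuted; two-sided p on the mean difference.
    """
    if len(trials) < 20:
        raise ValueError(f"need >= 20 trials, got {len(trials)}")
    rng = np.random.default_rng(rng)
    base = window_mean_rates(neuron, trials, "target_on", (-200.0, -150.0))

    intervals: dict[str, tuple[str, tuple[float, float]]] = {}
    for lo in (50.0, 100.0, 150.0):
        intervals[f"target+[{int(lo)},{int(lo + 50)})"] = (
            "target_on", (lo, lo + 50.0))
    for lo in (-150.0, -100.0, -50.0):
        intervals[f"saccade[{int(lo)},{int(lo + 50)})"] = (
            "saccade_on", (lo, lo + 50.0))

    pvals = {}
    nt = len(trials)
    for name, (event, win) in intervals.items():
        rate = window_mean_rates(neuron, trials, event, win)
        obs = abs(rate.mean() - base.mean())
        pooled = np.concatenate([base, rate])
        perms = rng.permuted(
            np.broadcast_to(pooled, (n_perm, 2 * nt)).copy(), axis=1
        )
        diffs = np.abs(perms[:, nt:].mean(axis=1) - perms[:, :nt].mean(axis=1))
        pvals[name] = (int(np.sum(diffs >= obs - 1e-12)) + 1) / (n_perm + 1)
    return any(p <= alpha for p in pvals.values()), pvals


def fitted_preferred_direction(fit: ModelFit, v_ref: float = 0.5) -> float:
    """Direction (radians) where the fitted model is maximally active.

    Evaluated on a fine grid at a reference value: for a negative
    direction amplitude the raw p parameter marks the *least* active
    direction (a sign-flipped circular Gaussian), so the maximum of the
    fitted profile is the physiologically meaningful PD.
    """
    grid = np.linspace(0.0, 2 * np.pi, 721, endpoint=False)
    rate = eval_model(np.full_like(grid, v_ref), grid, fit.params, fit.model_id)
    return float(grid[int(np.argmax(rate))])


def classify_unit(
    fits: dict[str, ModelFit],
    best: str,
    task_related_screen: bool = True,
    screen_p_values: dict[str, float] | None = None,
) -> UnitClassification:
    """Directional iff the winning model contains a circular-Gaussian term;
    the preferred direction is where that term makes the model maximally
    active, snapped to the nearest tested direction (ties toward the
    smaller angle)."""
    task_related_bic = best != "const"
    directional = task_related_bic and ("g" in best or "h" in best)
    p_fit = fitted_preferred_direction(fits[best]) if directional else None
    snapped = snap_direction(np.degrees(p_fit)) if directional else None
    return UnitClassification(
        task_related_screen=task_related_screen,
        task_related_bic=task_related_bic,
        directional=directional,
        preferred_direction_fitted=p_fit,
        preferred_direction_snapped=snapped,
        best_model=best,
        screen_p_values=screen_p_values,
    )
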