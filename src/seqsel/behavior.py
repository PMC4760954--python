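"""Subjective value estimation (maximum likelihood difference scaling)
and the behavioral reaction-time regressions.

The observer model is Thurstonian: on a trial offering options i and j,
the probability of choosing i is Phi((psi_i - psi_j) / sigma_d), where
sigma_d is the internal noise of the value comparison.  psi is anchored so
the least preferred option maps to 0 and the most preferred to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .datatypes import TrialRecord

_P_FLOOR = 1e-12
_SIGMA_UNBOUNDED = 1e3


@dataclass
class MLDSFit:
    psi: np.ndarray  # per-option subjective value, anchored to [0, 1]
    sigma_d: float
    loglik: float
    converged: bool
    n_trials: int
    sigma_unbounded: bool = False  # degenerate data: noise not identifiable


def choices_from_trials(trials: list[TrialRecord]) -> np.ndarray:
    """Extract (i, j, r) comparison rows from choice trials.

    Options are 0-based gamble indices (gamble_id - 1); r = 1 means option
    i was chosen over j.  We code i as the first listed target, so r
    records which listed target won.
    """
    rows = []
    for tr in trials:
        if tr.trial_type != "choice":
            continue
        i = tr.targets[0].gamble_id - 1
        j = tr.targets[1].gamble_id - 1
        rows.append((i, j, 1 if tr.chosen_index == 0 else 0))
    return np.asarray(rows, dtype=int)


def mlds_loglik(
    psi: np.ndarray,
    sigma_d: float,
    choices: np.ndarray,
    p_floor: float = _P_FLOOR,
) -> float:
    """Log likelihood of the choice set under (psi, sigma_d).

    ``choices`` rows are (i, j, r) with r = 1 if option i was chosen.
    Choice probabilities below ``p_floor`` are floored to avoid -inf.
    """
    psi = np.asarray(psi, dtype=float)
    choices = np.asarray(choices, dtype=int)
    d = psi[choices[:, 0]] - psi[choices[:, 1]]
    # sign the difference toward the chosen-coded option
    signed = np.where(choices[:, 2] == 1, d, -d)
    p = stats.norm.cdf(signed / sigma_d)
    return float(np.sum(np.log(np.clip(p, p_floor, 1.0))))


def _check_connected(choices: np.ndarray, n_options: int) -> None:
    parent = list(range(n_options))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, _ in choices:
        parent[find(i)] = find(j)
    seen = {find(k) for k in set(choices[:, 0]) | set(choices[:, 1])}
    comps = {}
    for k in range(n_options):
        comps.setdefault(find(k), []).append(k)
    if len(seen) > 1 or any(
        k not in set(choices[:, 0]) | set(choices[:, 1]) for k in range(n_options)
    ):
        raise ValueError(
            "comparison graph is not connected; components: "
            + "; ".join(str(v) for v in comps.values())
        )


def mlds_fit(
    choices: np.ndarray,
    n_options: int,
    n_starts: int = 8,
    rng: np.random.Generator | int | None = 0,
) -> MLDSFit:
    """Fit subjective values and internal noise by maximum likelihood.

    Internally the likelihood is maximized in the unanchored difference
    parametrization (u_1 = 0, unit comparison noise), where it is the
    log-concave probit likelihood; jittered multi-starts guard the
    optimizer anyway.  The anchored scale is recovered afterwards:
    psi = (u - min u)/(max u - min u), sigma_d = 1/(max u - min u).
    """
    choices = np.asarray(choices, dtype=int)
    if choices.size == 0:
        raise ValueError("no choices")
    _check_connected(choices, n_options)
    rng = np.random.default_rng(rng)

    i_idx, j_idx, r = choices[:, 0], choices[:, 1], choices[:, 2]
    sign = np.where(r == 1, 1.0, -1.0)

    def negll(u_free: np.ndarray) -> float:
        u = np.concatenate(([0.0], u_free))
        d = sign * (u[i_idx] - u[j_idx])
        logp = stats.norm.logcdf(d)
        return -float(np.sum(logp))

    best = None
    for k in range(n_starts):
        x0 = rng.normal(0.0, 1.0, size=n_options - 1) if k else np.zeros(n_options - 1)
        res = optimize.minimize(negll, x0, method="BFGS", options={"gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    u = np.concatenate(([0.0], best.x))

    span = u.max() - u.min()
    unbounded = span < 1.0 / _SIGMA_UNBOUNDED
    if unbounded:
        psi = np.zeros(n_options)
        psi[np.argmax(u)] = 1.0
        sigma_d = float("inf")
    else:
        psi = (u - u.min()) / span
        sigma_d = 1.0 / span
    ll = mlds_loglik(psi, sigma_d if np.isfinite(sigma_d) else _SIGMA_UNBOUNDED, choices)
    return MLDSFit(
        psi=psi,
        sigma_d=sigma_d,
        loglik=ll,
        converged=bool(best.success or np.isfinite(best.fun)),
        n_trials=len(choices),
        sigma_unbounded=unbounded,
    )


@dataclass
class RTRegression:
    slope: float  # ms per unit value (or value difference)
    intercept: float
    t_stat: float
    p_value: float
    n_levels: int
    level_values: np.ndarray
    level_mean_rts: np.ndarray


def _level_regression(x: np.ndarray, rts: np.ndarray) -> RTRegression:
    levels = np.unique(x)
    if levels.size < 3:
        raise ValueError(f"need >= 3 value levels, got {levels.size}")
    means = np.array([rts[x == v].mean() for v in levels])
    if np.allclose(means, means[0]):
        return RTRegression(0.0, float(means[0]), 0.0, 1.0, levels.size, levels, means)
    res = stats.linregress(levels, means)
    return RTRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        t_stat=float(res.slope / res.stderr) if res.stderr > 0 else 0.0,
        p_value=float(res.pvalue),
        n_levels=int(levels.size),
        level_values=levels,
        level_mean_rts=means,
    )


def rt_regressions(
    trials: list[TrialRecord],
    psi: np.ndarray,
    exclude_dpsi_below: float = -0.5,
) -> dict[str, RTRegression]:
    """Reaction-time regressions on condition means.

    ``no_choice``: mean RT per target value level against psi.
    ``choice``: mean RT per signed value-difference level (chosen minus
    non-chosen psi); trials with a value difference below
    ``exclude_dpsi_below`` (anomalously fast choices of dominated options)
    are excluded from this regression only.
    """
    psi = np.asarray(psi, dtype=float)
    nc_x, nc_rt, ch_x, ch_rt = [], [], [], []
    for tr in trials:
        if tr.trial_type == "no_choice":
            nc_x.append(psi[tr.targets[0].gamble_id - 1])
            nc_rt.append(tr.rt)
        else:
            d = (
                psi[tr.chosen_target.gamble_id - 1]
                - psi[tr.nonchosen_target.gamble_id - 1]
            )
            if d < exclude_dpsi_below:
                continue
            ch_x.append(round(d, 9))  # stabilize float level identity
            ch_rt.append(tr.rt)
    return {
        "no_choice": _level_regression(np.asarray(nc_x), np.asarray(nc_rt)),
        "choice": _level_regression(np.asarray(ch_x), np.asarray(ch_rt)),
    }
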