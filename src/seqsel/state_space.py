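"""Targeted dimensionality reduction of population activity.

Per unit and 10 ms time bin, z-scored responses are regressed on the task
variables (chosen direction left/right and up/down coded +/-1, chosen
value in [0,1], their non-chosen counterparts, and an intercept).  For
each named variable the across-unit coefficient vector at the time of its
maximal norm defines a state-space axis; the three axes (direction-LR,
direction-UD, chosen value, in that order) are orthogonalized by QR.
Condition-averaged population activity projected on these axes gives
trajectories whose separation carries the value and direction signals; no
PCA denoising step is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import first_run_start
from .datatypes import NeuronData, TrialRecord, snap_direction
from .rates import window_mean_rates

VARIABLE_NAMES = (
    "chosen_dir_lr",
    "chosen_dir_ud",
    "chosen_value",
    "nonchosen_dir_lr",
    "nonchosen_dir_ud",
    "nonchosen_value",
    "intercept",
)
#: the axes that are orthogonalized and projected, in QR order
AXIS_VARIABLES = ("chosen_dir_lr", "chosen_dir_ud", "chosen_value")

STATE_WINDOW = (-200.0, 10.0)  # ms re saccade onset
BIN_MS = 10.0
#: chosen/non-chosen value bands on the psi scale
VALUE_BANDS = ((0.0, 0.3), (0.3, 0.7), (0.7, 1.0 + 1e-9))


def response_tensor(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    window: tuple[float, float] = STATE_WINDOW,
    bin_ms: float = BIN_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """(units, trials, bins) mean rates in 10 ms bins; returns (tensor, bin centers)."""
    lo, hi = window
    starts = np.arange(lo, hi, bin_ms)
    tensor = np.stack(
        [
            np.stack(
                [
                    window_mean_rates(n, trials, "saccade_on", (s, s + bin_ms))
                    for s in starts
                ],
                axis=1,
            )
            for n in neurons
        ]
    )
    return tensor, starts + bin_ms / 2.0


def zscore_unit_responses(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each unit over all trials and time bins (pooled).

    Returns (z, keep_mask); zero-variance units are excluded from the
    mask and filled with zeros.
    """
    tensor = np.asarray(tensor, dtype=float)
    mu = tensor.mean(axis=(1, 2), keepdims=True)
    sd = tensor.std(axis=(1, 2), keepdims=True)
    keep = sd[:, 0, 0] > 0
    z = np.where(sd > 0, (tensor - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, keep


def _dir_codes(direction_deg: float) -> tuple[float, float]:
    d = snap_direction(direction_deg)
    lr = 1.0 if d in (45.0, 315.0) else -1.0  # +1 = right
    ud = 1.0 if d in (45.0, 135.0) else -1.0  # +1 = up
    return lr, ud


def build_design(trials: list[TrialRecord], psi: np.ndarray) -> np.ndarray:
    """Design matrix F (7 coefficients x n_trials) for choice trials."""
    psi = np.asarray(psi, dtype=float)
    cols = []
    for tr in trials:
        if tr.trial_type != "choice":
            raise ValueError("state-space design uses choice trials only")
        clr, cud = _dir_codes(tr.chosen_target.direction)
        nlr, nud = _dir_codes(tr.nonchosen_target.direction)
        cols.append(
            [
                clr,
                cud,
                psi[tr.chosen_target.gamble_id - 1],
                nlr,
                nud,
                psi[tr.nonchosen_target.gamble_id - 1],
                1.0,
            ]
        )
    return np.asarray(cols).T


@dataclass
class AxisSet:
    times: np.ndarray
    beta: np.ndarray  # (n_coefs, n_units, n_bins)
    t_var_max: dict[str, float]  # time of max coefficient-vector norm
    axes_max: np.ndarray  # (n_units, 3): raw axes at their max times
    axes_orth: np.ndarray  # (n_units, 3): QR-orthogonalized axes
    variables: tuple[str, ...] = AXIS_VARIABLES


def fit_task_axes(
    z: np.ndarray,
    F: np.ndarray,
    times: np.ndarray,
    cond_threshold: float = 1e8,
) -> AxisSet:
    """Estimate per-time regression coefficients and the orthogonalized axes.

    ``z`` is (units, trials, bins), ``F`` (7, trials).  beta_{i,t} solves
    the normal equations (F F^T)^-1 F r_{i,t}; per variable the axis is the
    across-unit coefficient vector at its maximal-norm time; axes are
    orthogonalized by QR in the fixed order (dir-LR, dir-UD, value).
    """
    z = np.asarray(z, dtype=float)
    F = np.asarray(F, dtype=float)
    U, T, B = z.shape
    G = F @ F.T
    sv = np.linalg.svd(G, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > cond_threshold:
        corr = np.corrcoef(F)
        bad = [
            (VARIABLE_NAMES[i], VARIABLE_NAMES[j])
            for i in range(len(VARIABLE_NAMES))
            for j in range(i + 1, len(VARIABLE_NAMES))
            if abs(corr[i, j]) > 0.99
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    rflat = z.transpose(1, 0, 2).reshape(T, U * B)
    beta = np.linalg.solve(G, F @ rflat).reshape(len(VARIABLE_NAMES), U, B)

    t_var_max: dict[str, float] = {}
    axes = []
    for var in AXIS_VARIABLES:
        vi = VARIABLE_NAMES.index(var)
        norms = np.linalg.norm(beta[vi], axis=0)
        tm = int(np.argmax(norms))
        t_var_max[var] = float(times[tm])
        axes.append(beta[vi, :, tm])
    M = np.stack(axes, axis=1)  # (units, 3)
    Q, R = np.linalg.qr(M)
    # fix signs so each orthogonal axis correlates positively with its source
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs[None, :]
    return AxisSet(
        times=np.asarray(times, dtype=float),
        beta=beta,
        t_var_max=t_var_max,
        axes_max=M,
        axes_orth=Q,
    )


def condition_average(
    z: np.ndarray,
    trials: list[TrialRecord],
    psi: np.ndarray,
    min_trials: int = 5,
    by: str = "direction_x_value_band",
) -> tuple[np.ndarray, list[dict]]:
    """Average (units, trials, bins) activity into task conditions.

    ``by='direction_x_value_band'`` cells are chosen direction x chosen
    value band; ``by='direction_x_value_level'`` uses the exact chosen
    value level; ``by='full'`` additionally splits by non-chosen value
    band.  Cells with fewer than ``min_trials`` trials are dropped.
    Returns (X_c: (units, conditions, bins), condition info dicts).
    """
    psi = np.asarray(psi, dtype=float)

    def band_of(v: float) -> int:
        for b, (lo, hi) in enumerate(VALUE_BANDS):
            if lo <= v < hi:
                return b
        return len(VALUE_BANDS) - 1

    keys = []
    for tr in trials:
        d = snap_direction(tr.chosen_target.direction)
        cv = psi[tr.chosen_target.gamble_id - 1]
        nv = psi[tr.nonchosen_target.gamble_id - 1]
        if by == "direction_x_value_band":
            keys.append((d, band_of(cv)))
        elif by == "direction_x_value_level":
            keys.append((d, round(cv, 9)))
        elif by == "full":
            keys.append((d, band_of(cv), band_of(nv)))
        else:
            raise ValueError(f"unknown grouping {by!r}")

    uniq = sorted(set(keys))
    Xc, info = [], []
    for key in uniq:
        m = np.array([k == key for k in keys])
        if m.sum() < min_trials:
            continue
        Xc.append(z[:, m, :].mean(axis=1))
        d = key[0]
        entry = {"direction": d, "n_trials": int(m.sum())}
        if by == "direction_x_value_level":
            entry["chosen_value"] = float(key[1])
        else:
            entry["chosen_band"] = key[1]
            entry["chosen_value"] = None
        if by == "full":
            entry["nonchosen_band"] = key[2]
        info.append(entry)
    if not Xc:
        raise ValueError("no condition has enough trials")
    return np.stack(Xc, axis=1), info


def project_trajectories(Xc: np.ndarray, axes: AxisSet) -> np.ndarray:
    """Project condition-averaged activity on the orthogonalized axes.

    ``Xc`` is (units, conditions, bins); returns (3, conditions, bins).
    """
    Xc = np.asarray(Xc, dtype=float)
    if Xc.shape[0] != axes.axes_orth.shape[0]:
        raise ValueError("unit basis mismatch between tensor and axes")
    return np.einsum("ua,ucb->acb", axes.axes_orth, Xc)


@dataclass
class DistanceRegression:
    slope: float
    t_stat: float
    p_value: float
    n_pairs: int
    dvalues: np.ndarray
    distances: np.ndarray


def endpoint_distance_regression(
    endpoints: np.ndarray,
    values: np.ndarray,
    groups: list,
    reference: str = "pairs",
) -> DistanceRegression:
    """Regress 3-D endpoint distances on value differences within groups.

    ``endpoints`` is (3, n_conditions); ``values`` the per-condition value
    of interest; ``groups`` holds the variables kept fixed.  With
    ``reference='pairs'`` all within-group pairs contribute
    (|v_i - v_j|, ||e_i - e_j||); with ``reference='max'`` distances are
    taken from the group's largest-value condition.
    """
    endpoints = np.asarray(endpoints, dtype=float)
    values = np.asarray(values, dtype=float)
    dv, dist = [], []
    for g in sorted(set(groups), key=repr):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        if len(idx) < 2:
            continue
        if reference == "max":
            ref = idx[int(np.argmax(values[idx]))]
            for i in idx:
                if i == ref:
                    continue
                dv.append(values[ref] - values[i])
                dist.append(np.linalg.norm(endpoints[:, ref] - endpoints[:, i]))
        else:
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = idx[a], idx[b]
                    dv.append(abs(values[i] - values[j]))
                    dist.append(np.linalg.norm(endpoints[:, i] - endpoints[:, j]))
    dv = np.asarray(dv)
    dist = np.asarray(dist)
    if dv.size < 3:
        raise ValueError("need >= 3 condition pairs")
    if np.allclose(dist, dist[0]) or np.allclose(dv, dv[0]):
        return DistanceRegression(0.0, 0.0, 1.0, dv.size, dv, dist)
    res = stats.linregress(dv, dist)
    return DistanceRegression(
        slope=float(res.slope),
        t_stat=float(res.slope / res.stderr) if res.stderr > 0 else 0.0,
        p_value=float(res.pvalue),
        n_pairs=int(dv.size),
        dvalues=dv,
        distances=dist,
    )


@dataclass
class VarianceExplained:
    times: np.ndarray
    fractions: np.ndarray  # (3, bins)
    null_thresholds: np.ndarray  # (3, bins), 95th pct of permutation null
    onsets: dict[str, float | None]


def variance_explained_timecourse(
    z: np.ndarray,
    trials: list[TrialRecord],
    psi: np.ndarray,
    axes: AxisSet,
    n_perm: int = 200,
    rng: np.random.Generator | int | None = 0,
    min_run: int = 3,
) -> VarianceExplained:
    """Fraction of condition variance captured by each orthogonal axis.

    Per time bin: conditions are chosen direction x value band; the
    fraction for an axis is sum_c <q, x_c - xbar>^2 over sum_c
    ||x_c - xbar||^2.  The permutation null shuffles trial condition
    labels; an axis's onset is the first run of >= ``min_run`` bins above
    its per-bin 95th-percentile null.
    """
    rng = np.random.default_rng(rng)
    z = np.asarray(z, dtype=float)

    def fractions_for(trial_perm: np.ndarray | None) -> np.ndarray:
        if trial_perm is None:
            tr = trials
            zz = z
        else:
            tr = trials
            zz = z[:, trial_perm, :]
        Xc, _ = condition_average(zz, tr, psi)
        Xc = Xc - Xc.mean(axis=1, keepdims=True)
        tot = np.einsum("ucb,ucb->b", Xc, Xc)
        proj = np.einsum("ua,ucb->acb", axes.axes_orth, Xc)
        per_axis = np.einsum("acb,acb->ab", proj, proj)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, per_axis / tot, 0.0)

    obs = fractions_for(None)
    T = z.shape[1]
    null = np.empty((n_perm,) + obs.shape)
    for i in range(n_perm):
        null[i] = fractions_for(rng.permutation(T))
    thresh = np.quantile(null, 0.95, axis=0)

    onsets: dict[str, float | None] = {}
    for a, var in enumerate(AXIS_VARIABLES):
        idx = first_run_start(obs[a] > thresh[a], min_run)
        onsets[var] = float(axes.times[idx]) if idx is not None else None
    return VarianceExplained(
        times=axes.times, fractions=obs, null_thresholds=thresh, onsets=onsets
    )
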