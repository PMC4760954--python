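"""Chosen/non-chosen influence decomposition and PD/NPD value regressions.

The decomposition models each unit's choice-trial firing rate at time t as
a weighted sum of its own *no-choice* mean rates ("templates") for the
chosen and non-chosen target's direction (or value):

    S_choice(t) = b1 * S_nochoice(attr_chosen, t) + b2 * S_nochoice(attr_nonchosen, t)

with no intercept, on a sliding 20 ms window stepped by 10 ms.  The onset
at which the chosen target dominates is the first run of >= 3 consecutive
steps where a paired t-test of b1 vs b2 across units gives p < 0.05.

The value-effect regression quantifies how normalized pre-saccadic
activity depends on the value of the target in a unit's preferred (PD) or
non-preferred (NPD) direction, with the other slot held at medium value —
opposing slopes with roughly 2:1 magnitude are the relative-action-value
signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import first_run_start
from .datatypes import NeuronData, TESTED_DIRECTIONS, TrialRecord, snap_direction
from .rates import window_mean_rates

#: sliding-window grid, ms re saccade onset
STEP_MS = 10.0
WIDTH_MS = 20.0
GRID_START = -200.0
GRID_STOP = 20.0  # last window is [0, 20)

#: pre-saccadic epoch for the value-effect regression
VALUE_EFFECT_WINDOW = (-50.0, 20.0)

#: value ranks (1-based) forming the low/medium/high bands
LOW_BAND = (1, 2)
MEDIUM_BAND = (3, 4, 5)
HIGH_BAND = (6, 7)


def grid_windows() -> tuple[np.ndarray, np.ndarray]:
    """(window starts, window centers) of the sliding grid."""
    starts = np.arange(GRID_START, GRID_STOP - WIDTH_MS + STEP_MS / 2, STEP_MS)
    return starts, starts + WIDTH_MS / 2.0


@dataclass
class TemplateBank:
    times: np.ndarray  # window centers, ms re saccade
    dir_templates: np.ndarray  # (4 directions, n_steps); nan where masked
    val_templates: np.ndarray  # (7 value ranks, n_steps); nan where masked
    dir_order: tuple[float, ...] = TESTED_DIRECTIONS


def build_templates(
    neuron: NeuronData, trials: list[TrialRecord], psi: np.ndarray
) -> TemplateBank:
    """Per-direction and per-value-rank mean no-choice rates on the grid.

    Cells with fewer than 3 contributing trials are masked (nan).  All
    four directions must be present in the no-choice trials.
    """
    nc = [t for t in trials if t.trial_type == "no_choice"]
    dirs = np.array([t.targets[0].direction for t in nc])
    gids = np.array([t.targets[0].gamble_id for t in nc])
    present = {snap_direction(d) for d in dirs}
    missing = [d for d in TESTED_DIRECTIONS if d not in present]
    if missing:
        raise ValueError(f"no no-choice trials at direction(s) {missing}")

    starts, centers = grid_windows()
    rates = np.stack(
        [
            window_mean_rates(neuron, nc, "saccade_on", (lo, lo + WIDTH_MS))
            for lo in starts
        ],
        axis=1,
    )  # (n_nc_trials, n_steps)

    dir_t = np.full((4, starts.size), np.nan)
    for i, d in enumerate(TESTED_DIRECTIONS):
        m = dirs == d
        if m.sum() >= 3:
            dir_t[i] = rates[m].mean(axis=0)
    val_t = np.full((7, starts.size), np.nan)
    for rank in range(1, 8):
        m = gids == rank
        if m.sum() >= 3:
            val_t[rank - 1] = rates[m].mean(axis=0)
    return TemplateBank(times=centers, dir_templates=dir_t, val_templates=val_t)


@dataclass
class DecompCoefs:
    times: np.ndarray
    b1: np.ndarray  # chosen-template weight per step (nan where masked)
    b2: np.ndarray  # non-chosen-template weight
    masked: np.ndarray


def fit_decomposition(
    choice_rates: np.ndarray,
    chosen_idx: np.ndarray,
    nonchosen_idx: np.ndarray,
    templates: np.ndarray,
    times: np.ndarray,
    cond_threshold: float = 1e8,
) -> DecompCoefs:
    """No-intercept least squares of choice rates on two template columns.

    ``choice_rates`` is (n_choice_trials, n_steps); ``chosen_idx`` /
    ``nonchosen_idx`` index rows of ``templates`` ((n_conditions, n_steps))
    per trial.  Steps with a masked template or a near-collinear design
    (condition number above ``cond_threshold``) are masked.
    """
    choice_rates = np.asarray(choice_rates, dtype=float)
    nT, nS = choice_rates.shape
    if nT < 10:
        raise ValueError("need >= 10 choice trials")
    b1 = np.full(nS, np.nan)
    b2 = np.full(nS, np.nan)
    masked = np.zeros(nS, dtype=bool)
    for s in range(nS):
        x1 = templates[chosen_idx, s]
        x2 = templates[nonchosen_idx, s]
        if np.any(np.isnan(x1)) or np.any(np.isnan(x2)):
            masked[s] = True
            continue
        X = np.column_stack([x1, x2])
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[-1] <= 0 or sv[0] / sv[-1] > cond_threshold:
            masked[s] = True
            continue
        coef, *_ = np.linalg.lstsq(X, choice_rates[:, s], rcond=None)
        b1[s], b2[s] = coef
    return DecompCoefs(times=np.asarray(times), b1=b1, b2=b2, masked=masked)


def decompose_unit(
    neuron: NeuronData,
    trials: list[TrialRecord],
    psi: np.ndarray,
    sort: str,
    bank: TemplateBank | None = None,
) -> DecompCoefs:
    """Decompose one unit's choice-trial activity by direction or value sort."""
    if sort not in ("direction", "value"):
        raise ValueError("sort must be 'direction' or 'value'")
    bank = bank or build_templates(neuron, trials, psi)
    ch = [t for t in trials if t.trial_type == "choice"]
    starts, centers = grid_windows()
    rates = np.stack(
        [
            window_mean_rates(neuron, ch, "saccade_on", (lo, lo + WIDTH_MS))
            for lo in starts
        ],
        axis=1,
    )
    if sort == "direction":
        lut = {d: i for i, d in enumerate(TESTED_DIRECTIONS)}
        ci = np.array([lut[snap_direction(t.chosen_target.direction)] for t in ch])
        ni = np.array([lut[snap_direction(t.nonchosen_target.direction)] for t in ch])
        templates = bank.dir_templates
    else:
        ci = np.array([t.chosen_target.gamble_id - 1 for t in ch])
        ni = np.array([t.nonchosen_target.gamble_id - 1 for t in ch])
        templates = bank.val_templates
    return fit_decomposition(rates, ci, ni, templates, centers)


def decomposition_onset(
    coefs: list[DecompCoefs], min_run: int = 3, alpha: float = 0.05
) -> float | None:
    """First window (center time) of >= 3 consecutive steps with the chosen
    coefficient significantly above the non-chosen one (paired t across units)."""
    b1 = np.stack([c.b1 for c in coefs])
    b2 = np.stack([c.b2 for c in coefs])
    times = coefs[0].times
    nS = b1.shape[1]
    pv = np.ones(nS)
    pos = np.zeros(nS, dtype=bool)
    for s in range(nS):
        ok = ~(np.isnan(b1[:, s]) | np.isnan(b2[:, s]))
        if ok.sum() < 3:
            continue
        d = b1[ok, s] - b2[ok, s]
        if np.allclose(d, 0):
            continue
        tt = stats.ttest_rel(b1[ok, s], b2[ok, s])
        pv[s] = tt.pvalue
        pos[s] = d.mean() > 0
    idx = first_run_start((pv < alpha) & pos, min_run)
    return float(times[idx]) if idx is not None else None


# --------------------------------------------------------------------------
# PD / NPD value-effect regression
# --------------------------------------------------------------------------

VALUE_EFFECT_MODES = (
    "no_choice_PD",
    "no_choice_NPD",
    "choice_vary_PD_fix_NPD",
    "choice_vary_NPD_fix_PD",
)


@dataclass
class ValueEffectFit:
    mode: str
    slope: float  # normalized activity per unit of subjective value
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    n_levels: int
    level_psi: np.ndarray
    level_means: np.ndarray


def value_effect_regression(
    norm_rates: np.ndarray,
    unit_pds: np.ndarray,
    trials: list[TrialRecord],
    psi: np.ndarray,
    mode: str,
) -> ValueEffectFit:
    """Regress population normalized pre-saccadic activity on target value.

    ``norm_rates`` is (n_units, n_trials): per-trial normalized activity
    in the pre-saccadic window.  ``unit_pds`` are snapped preferred
    directions in degrees.  Modes vary the value of the PD or NPD target;
    choice modes hold the other slot's value in the medium band (ranks
    3-5).  Per unit, activity is averaged per varied-value level; level
    means are then averaged across units and regressed on subjective value.
    """
    if mode not in VALUE_EFFECT_MODES:
        raise ValueError(f"mode must be one of {VALUE_EFFECT_MODES}")
    psi = np.asarray(psi, dtype=float)
    norm_rates = np.asarray(norm_rates, dtype=float)
    n_units = norm_rates.shape[0]

    per_unit_level = np.full((n_units, 7), np.nan)
    for u in range(n_units):
        pd = float(unit_pds[u])
        npd = (pd + 180.0) % 360.0
        sums = np.zeros(7)
        counts = np.zeros(7)
        for k, tr in enumerate(trials):
            by_dir = {snap_direction(t.direction): t for t in tr.targets}
            if mode == "no_choice_PD":
                if tr.trial_type != "no_choice" or pd not in by_dir:
                    continue
                varied = by_dir[pd]
            elif mode == "no_choice_NPD":
                if tr.trial_type != "no_choice" or npd not in by_dir:
                    continue
                varied = by_dir[npd]
            else:
                if tr.trial_type != "choice" or pd not in by_dir or npd not in by_dir:
                    continue
                if mode == "choice_vary_PD_fix_NPD":
                    varied, fixed = by_dir[pd], by_dir[npd]
                else:
                    varied, fixed = by_dir[npd], by_dir[pd]
                if fixed.gamble_id not in MEDIUM_BAND:
                    continue
            lvl = varied.gamble_id - 1
            sums[lvl] += norm_rates[u, k]
            counts[lvl] += 1
        with np.errstate(invalid="ignore"):
            per_unit_level[u] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    level_means = np.nanmean(per_unit_level, axis=0)
    have = ~np.isnan(level_means)
    if have.sum() < 3:
        raise ValueError(f"only {int(have.sum())} value levels available in {mode}")
    x = psi[have]
    y = level_means[have]
    res = stats.linregress(x, y)
    df = have.sum() - 2
    tcrit = stats.t.ppf(0.975, df) if df > 0 else np.nan
    return ValueEffectFit(
        mode=mode,
        slope=float(res.slope),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        t_stat=float(res.slope / res.stderr) if res.stderr > 0 else 0.0,
        p_value=float(res.pvalue),
        n_levels=int(have.sum()),
        level_psi=x,
        level_means=y,
    )


def presaccadic_normalized_activity(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    window: tuple[float, float] = VALUE_EFFECT_WINDOW,
) -> np.ndarray:
    """(n_units, n_trials) pre-saccadic rates, min-max normalized per unit.

    Normalization bounds are each unit's minimum and maximum *condition
    mean* across chosen-direction x trial-type conditions (noise-robust),
    matching the convention of scaling population activity to [0, 1]
    before averaging across units.
    """
    raw = np.stack(
        [window_mean_rates(n, trials, "saccade_on", window) for n in neurons]
    )
    conds = np.array(
        [
            (t.trial_type == "choice", snap_direction(t.chosen_target.direction))
            for t in trials
        ],
        dtype=object,
    )
    keys = np.array([f"{c[0]}|{c[1]}" for c in conds])
    out = np.empty_like(raw)
    for u in range(raw.shape[0]):
        means = np.array([raw[u, keys == k].mean() for k in np.unique(keys)])
        lo, hi = means.min(), means.max()
        if hi <= lo:
            raise ValueError(f"unit index {u}: constant across conditions")
        out[u] = (raw[u] - lo) / (hi - lo)
    return out
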