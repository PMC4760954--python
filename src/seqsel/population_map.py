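"""Relative action value maps: normalized direction x time population activity.

Each directional unit contributes its trial-averaged spike density at a row
given by its preferred direction *relative to the chosen target*; rows are
circularly interpolated to a 7.2 degree grid.  Normalization is per unit:
the mean activity 50-0 ms before target onset across all 16 trial
conditions (12 choice = 4 chosen directions x 3 relative placements of the
other target; 4 no-choice directions) maps to 0 and the maximum across
conditions to 1.  Onset statistics compare the chosen-target band (units
with PD within +/-30 deg of the target) against the pre-target background
(-20 to 0 ms) and against the non-chosen band, with a sign-flip
max-statistic permutation correction over time bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._stats import signflip_maxstat_onset
from .datatypes import (
    NeuronData,
    TESTED_DIRECTIONS,
    TrialRecord,
    circular_diff_deg,
    snap_direction,
)
from .rates import sdf_tensor, window_mean_rates

ROW_STEP_DEG = 7.2
BAND_HALFWIDTH_DEG = 30.0
#: non-chosen reference band for no-choice trials (relative angle, degrees)
NOCHOICE_REFERENCE_BAND = (240.0, 300.0)
BACKGROUND_WINDOW = (-20.0, 0.0)  # ms re target onset
MAP_BASELINE_WINDOW = (-50.0, 0.0)  # ms re target onset


def condition_index(trial: TrialRecord) -> int:
    """0..15 condition id: 4 no-choice directions then 12 choice
    (chosen direction x relative placement of the non-chosen target)."""
    d_chosen = snap_direction(trial.chosen_target.direction)
    k = TESTED_DIRECTIONS.index(d_chosen)
    if trial.trial_type == "no_choice":
        return k
    rel = (snap_direction(trial.nonchosen_target.direction) - d_chosen) % 360.0
    j = {90.0: 0, 180.0: 1, 270.0: 2}[rel]
    return 4 + 3 * k + j


def map_normalization_factors(
    neurons: list[NeuronData], trials: list[TrialRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """(baseline, max) per unit for the map convention.

    Baseline: mean rate 50-0 ms before target onset averaged over the 16
    condition means.  Max: the largest condition-mean spike-density value
    across all 16 conditions, target onset to 20 ms after saccade.
    """
    cond = np.array([condition_index(t) for t in trials])
    base_rates = np.stack(
        [window_mean_rates(n, trials, "target_on", MAP_BASELINE_WINDOW) for n in neurons]
    )
    # condition-mean traces around the saccade (where activity peaks)
    tens = sdf_tensor(neurons, trials, "saccade_on", (-250.0, 20.0))
    baselines = np.empty(len(neurons))
    maxes = np.empty(len(neurons))
    for u in range(len(neurons)):
        cmeans_base = [base_rates[u, cond == c].mean() for c in range(16) if np.any(cond == c)]
        baselines[u] = float(np.mean(cmeans_base))
        peak = -np.inf
        for c in range(16):
            m = cond == c
            if np.any(m):
                peak = max(peak, tens.values[u, m].mean(axis=0).max())
        maxes[u] = peak
    bad = np.nonzero(maxes <= baselines)[0]
    if bad.size:
        raise ValueError(f"unit index {bad.tolist()}: max <= baseline, exclude")
    return baselines, maxes


def map_normalize(traces: np.ndarray, baseline: float, peak: float) -> np.ndarray:
    """Affine map sending the unit's baseline to 0 and its maximum to 1."""
    if peak <= baseline:
        raise ValueError("max <= baseline")
    return (np.asarray(traces, dtype=float) - baseline) / (peak - baseline)


@dataclass
class ActionValueMap:
    row_angles: np.ndarray  # 7.2 deg grid of PD angle relative to chosen target
    times: np.ndarray
    values: np.ndarray  # (n_rows, n_times), normalized rate
    condition_label: str
    sample_angles: np.ndarray  # relative angles actually observed
    sample_values: np.ndarray  # (n_samples, n_times) before interpolation


def _circular_interp(angles: np.ndarray, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation on the circle (rows are relative angles)."""
    order = np.argsort(angles)
    a = angles[order]
    v = values[order]
    a_ext = np.concatenate([a, a[:1] + 360.0])
    v_ext = np.concatenate([v, v[:1][None, :].reshape(1, -1)], axis=0)
    out = np.empty((grid.size, values.shape[1]))
    for j in range(values.shape[1]):
        g = np.where(grid < a[0], grid + 360.0, grid)
        out[:, j] = np.interp(g, a_ext, v_ext[:, j])
    return out


def build_map(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    unit_pds_deg: np.ndarray,
    align: str,
    window: tuple[float, float],
    baselines: np.ndarray,
    maxes: np.ndarray,
    condition_label: str = "",
) -> ActionValueMap:
    """Assemble the relative action value map from a trial subset.

    Each (unit, chosen-direction) cell contributes its normalized mean
    trace at relative angle (PD - chosen direction) mod 360; identical
    angles are averaged; rows are then circularly interpolated to the
    7.2 deg grid.  Needs >= 8 directional units.
    """
    if len(neurons) < 8:
        raise ValueError("need >= 8 directional units")
    event = {"target": "target_on", "saccade": "saccade_on"}[align]
    tens = sdf_tensor(neurons, trials, event, window)
    chosen_dirs = np.array([snap_direction(t.chosen_target.direction) for t in trials])

    angles, rows = [], []
    for u, n in enumerate(neurons):
        for d in TESTED_DIRECTIONS:
            m = chosen_dirs == d
            if not np.any(m):
                continue
            trace = map_normalize(tens.values[u, m].mean(axis=0), baselines[u], maxes[u])
            angles.append((float(unit_pds_deg[u]) - d) % 360.0)
            rows.append(trace)
    angles = np.asarray(angles)
    rows = np.stack(rows)

    uniq = np.unique(np.round(angles, 6))
    if uniq.size < 2:
        raise ValueError("all units at one relative angle; cannot interpolate")
    samp_vals = np.stack([rows[np.round(angles, 6) == a].mean(axis=0) for a in uniq])
    grid = np.arange(0.0, 360.0, ROW_STEP_DEG)
    values = _circular_interp(uniq, samp_vals, grid)
    return ActionValueMap(
        row_angles=grid,
        times=tens.bin_centers,
        values=values,
        condition_label=condition_label,
        sample_angles=uniq,
        sample_values=samp_vals,
    )


@dataclass
class OnsetReport:
    align: str
    condition_label: str
    activity_vs_background_ms: float | None
    chosen_vs_nonchosen_ms: float | None
    times: np.ndarray


def onset_stats(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    unit_pds_deg: np.ndarray,
    align: str,
    window: tuple[float, float],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = 0,
    condition_label: str = "",
) -> OnsetReport:
    """Map onset statistics for one trial subset and alignment.

    Per unit, the chosen-band trace averages trials whose chosen target
    lies within +/-30 deg of the unit's PD; the reference trace uses
    trials whose *non-chosen* target does (choice trials) or whose target
    sits 240-300 deg away from the PD (no-choice trials).  Onsets use the
    across-unit sign-flip max-statistic test (multiple-comparison
    corrected over time bins).
    """
    rng = np.random.default_rng(rng)
    event = {"target": "target_on", "saccade": "saccade_on"}[align]
    tens = sdf_tensor(neurons, trials, event, window)
    bg = np.stack(
        [window_mean_rates(n, trials, "target_on", BACKGROUND_WINDOW) for n in neurons]
    )
    is_choice = trials[0].trial_type == "choice"

    act_diffs, cvn_diffs = [], []
    for u, n in enumerate(neurons):
        pd = float(unit_pds_deg[u])
        in_band = np.array(
            [
                abs(circular_diff_deg(pd, t.chosen_target.direction))
                <= BAND_HALFWIDTH_DEG
                for t in trials
            ]
        )
        if is_choice:
            ref_band = np.array(
                [
                    abs(circular_diff_deg(pd, t.nonchosen_target.direction))
                    <= BAND_HALFWIDTH_DEG
                    for t in trials
                ]
            )
        else:
            lo, hi = NOCHOICE_REFERENCE_BAND
            ref_band = np.array(
                [
                    lo <= (pd - t.chosen_target.direction) % 360.0 <= hi
                    for t in trials
                ]
            )
        if in_band.sum() >= 3:
            act_diffs.append(tens.values[u, in_band].mean(axis=0) - bg[u, in_band].mean())
            if ref_band.sum() >= 3:
                cvn_diffs.append(
                    tens.values[u, in_band].mean(axis=0)
                    - tens.values[u, ref_band].mean(axis=0)
                )
    if len(act_diffs) < 3:
        raise ValueError("insufficient units with targets in their PD band")

    idx_a, _, _ = signflip_maxstat_onset(
        np.stack(act_diffs), n_perm, rng.integers(2**31)
    )
    idx_c, _, _ = signflip_maxstat_onset(
        np.stack(cvn_diffs), n_perm, rng.integers(2**31)
    )
    times = tens.bin_centers
    return OnsetReport(
        align=align,
        condition_label=condition_label,
        activity_vs_background_ms=float(times[idx_a]) if idx_a is not None else None,
        chosen_vs_nonchosen_ms=float(times[idx_c]) if idx_c is not None else None,
        times=times,
    )


def split_by_value_difference(
    trials: list[TrialRecord],
    psi: np.ndarray,
    threshold: float = 0.4,
    tol: float = 0.02,
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Split choice trials into small (< threshold) and large (>= threshold)
    absolute value-difference sets, greedily subsampled so their mean
    chosen values agree within ``tol``.

    Returns (small, large).  Raises if either side is empty or the means
    cannot be matched (the achieved gap is reported).
    """
    psi = np.asarray(psi, dtype=float)
    small, large = [], []
    for tr in trials:
        if tr.trial_type != "choice":
            continue
        dv = abs(
            psi[tr.chosen_target.gamble_id - 1]
            - psi[tr.nonchosen_target.gamble_id - 1]
        )
        (large if dv >= threshold else small).append(tr)
    if not small or not large:
        raise ValueError("one value-difference side is empty")

    def chosen_psi(ts):
        return np.array([psi[t.chosen_target.gamble_id - 1] for t in ts])

    small = sorted(small, key=lambda t: psi[t.chosen_target.gamble_id - 1])
    large = sorted(large, key=lambda t: psi[t.chosen_target.gamble_id - 1])
    while True:
        ms, ml = chosen_psi(small).mean(), chosen_psi(large).mean()
        gap = ms - ml
        if abs(gap) <= tol:
            return small, large
        if len(small) <= 3 or len(large) <= 3:
            raise ValueError(f"cannot match chosen-value means; residual gap {gap:.4f}")
        # drop the extreme trial that best shrinks the gap
        cands = []
        if gap > 0:
            cands = [("small", -1), ("large", 0)]  # small too high / large too low
        else:
            cands = [("small", 0), ("large", -1)]
        best = None
        for side, pos in cands:
            pool = small if side == "small" else large
            trial = pool[pos]
            new = [t for t in pool if t is not trial]
            nms = chosen_psi(new).mean() if side == "small" else ms
            nml = chosen_psi(new).mean() if side == "large" else ml
            if side == "small":
                g2 = nms - ml
            else:
                g2 = ms - nml
            if best is None or abs(g2) < abs(best[2]):
                best = (side, pos, g2)
        side, pos, _ = best
        if side == "small":
            small.pop(pos if pos >= 0 else len(small) - 1)
        else:
            large.pop(pos if pos >= 0 else len(large) - 1)
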