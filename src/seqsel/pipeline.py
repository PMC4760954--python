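"""End-to-end orchestration: run every time-resolved analysis on a session
and collect the value-vs-direction onset latencies.

The scientific question each stage answers is the same: when, relative to
saccade onset, does the population first carry information about the
chosen *option* (the economic good) and when about the chosen *direction*
(the action)?  A sequential goods-then-action decision shows up as a
positive gap (direction onset minus value onset).
"""

from __future__ import annotations

import numpy as np

from . import decoding as dec
from . import information as info
from . import regression_decomp as rd
from . import state_space as ss
from .datatypes import NeuronData, TrialRecord
from .rates import sdf_tensor

ANALYSIS_WINDOW = (-200.0, 20.0)  # ms re saccade onset


def _median_or_none(xs: list[float]) -> float | None:
    xs = [x for x in xs if x is not None]
    return float(np.median(xs)) if xs else None


def decoding_onsets(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    psi: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> dict:
    """Per-unit decoding of chosen option and chosen direction.

    Returns median per-unit onsets, per-unit results and population
    summaries for both variables.
    """
    rng = np.random.default_rng(rng)
    choice = [t for t in trials if t.trial_type == "choice"]
    tens = sdf_tensor(neurons, choice, "saccade_on", ANALYSIS_WINDOW)
    labels_val, _ = dec.binarize_chosen_value(choice, psi)
    labels_dir = dec.binarize_chosen_direction(choice)
    config = dec.configuration_groups(choice)

    out = {"option": [], "direction": []}
    for u in range(len(neurons)):
        out["option"].append(
            dec.decode_timecourse(
                tens.values[u],
                labels_val,
                tens.bin_centers,
                n_perm=n_perm,
                rng=rng.integers(2**31),
                unit_id=neurons[u].neuron_id,
                variable="chosen_option",
            )
        )
        out["direction"].append(
            dec.decode_timecourse(
                tens.values[u],
                labels_dir,
                tens.bin_centers,
                n_perm=n_perm,
                rng=rng.integers(2**31),
                unit_id=neurons[u].neuron_id,
                variable="chosen_direction",
                groups=config,
            )
        )
    return {
        "results": out,
        "option_onset_ms": _median_or_none([r.onset for r in out["option"]]),
        "direction_onset_ms": _median_or_none([r.onset for r in out["direction"]]),
        "option_summary": dec.population_accuracy_summary(out["option"]),
        "direction_summary": dec.population_accuracy_summary(out["direction"]),
    }


def mi_onsets(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    psi: np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> dict:
    """Population MI onsets: chosen vs non-chosen option value and direction."""
    rng = np.random.default_rng(rng)
    choice = [t for t in trials if t.trial_type == "choice"]
    nochoice = [t for t in trials if t.trial_type == "no_choice"]
    tens = sdf_tensor(neurons, choice, "saccade_on", ANALYSIS_WINDOW)
    tens_nc = sdf_tensor(neurons, nochoice, "saccade_on", ANALYSIS_WINDOW)

    vg = info.value_rank_bins(psi)
    x_cv = np.array([vg[t.chosen_target.gamble_id - 1] for t in choice])
    x_nv = np.array([vg[t.nonchosen_target.gamble_id - 1] for t in choice])
    x_cd = info.direction_bins(
        [t.chosen_target.direction for t in choice]
    )
    x_nd = info.direction_bins(
        [t.nonchosen_target.direction for t in choice]
    )

    mi = {k: [] for k in ("chosen_value", "nonchosen_value",
                          "chosen_direction", "nonchosen_direction")}
    xs = {
        "chosen_value": x_cv,
        "nonchosen_value": x_nv,
        "chosen_direction": x_cd,
        "nonchosen_direction": x_nd,
    }
    for u in range(len(neurons)):
        for var, x in xs.items():
            res = info.mi_timecourse(
                tens.values[u],
                tens_nc.values[u],
                x,
                tens.bin_centers,
                n_boot=n_boot,
                rng=rng.integers(2**31),
                unit_id=neurons[u].neuron_id,
                variable=var,
            )
            mi[var].append(res.mi)
    stacks = {k: np.stack(v) for k, v in mi.items()}
    times = tens.bin_centers
    return {
        "mi": stacks,
        "times": times,
        "value_onset_ms": info.info_onset(
            stacks["chosen_value"], stacks["nonchosen_value"], times
        ),
        "direction_onset_ms": info.info_onset(
            stacks["chosen_direction"], stacks["nonchosen_direction"], times
        ),
    }


def decomposition_onsets(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    psi: np.ndarray,
) -> dict:
    """Template-regression onsets for the value and direction sorts."""
    val_coefs, dir_coefs = [], []
    for n in neurons:
        bank = rd.build_templates(n, trials, psi)
        val_coefs.append(rd.decompose_unit(n, trials, psi, "value", bank))
        dir_coefs.append(rd.decompose_unit(n, trials, psi, "direction", bank))
    return {
        "value_coefs": val_coefs,
        "direction_coefs": dir_coefs,
        "value_onset_ms": rd.decomposition_onset(val_coefs),
        "direction_onset_ms": rd.decomposition_onset(dir_coefs),
    }


def state_space_onsets(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    psi: np.ndarray,
    n_perm: int = 200,
    rng: np.random.Generator | int | None = 0,
) -> dict:
    """Variance-explained onsets of the value and direction axes.

    Axes are estimated from all choice trials; the variance-explained
    condition averages use only diagonal (180 deg apart) target
    configurations, where the visual response to the target layout is
    balanced across chosen-direction conditions and cannot masquerade as
    an early action signal.
    """
    choice = [t for t in trials if t.trial_type == "choice"]
    tensor, times = ss.response_tensor(neurons, choice)
    z, keep = ss.zscore_unit_responses(tensor)
    z = z[keep]
    F = ss.build_design(choice, psi)
    axes = ss.fit_task_axes(z, F, times)
    diag = np.array(
        [
            abs(((t.targets[0].direction - t.targets[1].direction) % 360.0)) == 180.0
            for t in choice
        ]
    )
    ve = ss.variance_explained_timecourse(
        z[:, diag], [t for t, d in zip(choice, diag) if d], psi, axes,
        n_perm=n_perm, rng=rng,
    )
    dir_onsets = [
        ve.onsets[v] for v in ("chosen_dir_lr", "chosen_dir_ud")
        if ve.onsets[v] is not None
    ]
    return {
        "axes": axes,
        "variance_explained": ve,
        "value_onset_ms": ve.onsets["chosen_value"],
        "direction_onset_ms": min(dir_onsets) if dir_onsets else None,
    }


def sequential_latency_report(
    session: dict,
    n_perm_decode: int = 1000,
    n_boot_mi: int = 100,
    seed: int = 0,
) -> dict:
    """Run all four latency analyses on a generated session.

    Returns per-analysis value/direction onsets (ms re saccade onset) and
    the onset gaps (direction minus value; positive = value first).
    """
    rng = np.random.default_rng(seed)
    trials, neurons, psi = session["trials"], session["neurons"], session["bp"].psi

    d = decoding_onsets(neurons, trials, psi, n_perm_decode, rng.integers(2**31))
    m = mi_onsets(neurons, trials, psi, n_boot_mi, rng.integers(2**31))
    c = decomposition_onsets(neurons, trials, psi)
    s = state_space_onsets(neurons, trials, psi, rng=rng.integers(2**31))

    def gap(val, dr):
        return None if (val is None or dr is None) else float(dr - val)

    report = {
        "decoding": {
            "value_onset_ms": d["option_onset_ms"],
            "direction_onset_ms": d["direction_onset_ms"],
        },
        "mutual_information": {
            "value_onset_ms": m["value_onset_ms"],
            "direction_onset_ms": m["direction_onset_ms"],
        },
        "decomposition": {
            "value_onset_ms": c["value_onset_ms"],
            "direction_onset_ms": c["direction_onset_ms"],
        },
        "state_space": {
            "value_onset_ms": s["value_onset_ms"],
            "direction_onset_ms": s["direction_onset_ms"],
        },
        "details": {"decoding": d, "mi": m, "decomposition": c, "state_space": s},
    }
    gaps = {
        name: gap(v["value_onset_ms"], v["direction_onset_ms"])
        for name, v in report.items()
        if name != "details"
    }
    report["onset_gaps_ms"] = gaps
    present = [g for g in gaps.values() if g is not None]
    report["median_gap_ms"] = float(np.median(present)) if present else None
    return report
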