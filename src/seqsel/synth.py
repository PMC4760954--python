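"""Ground-truth session generator.

Emulates the 7-gamble oculomotor task: blocks of 28 trials (21 choice
trials covering every unordered gamble pair, 7 no-choice trials covering
every gamble), Thurstonian value-driven choices with value-dependent
reaction times, and inhomogeneous-Poisson spike trains whose rates follow
the sigmoid-by-circular-Gaussian tuning family and carry a planted
*sequential* selection signature: chosen-option (value) modulation begins
``L_value`` ms before saccade onset, chosen-direction modulation and
non-preferred-direction value suppression only ``L_dir`` ms before
(``L_value > L_dir``).

Every downstream analysis stage in the package has a recovery target in
the quantities planted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .datatypes import (
    GambleOption,
    NeuronData,
    Target,
    TESTED_DIRECTIONS,
    TrialRecord,
    circular_diff_deg,
    snap_direction,
)

_COLOR_BY_AMOUNT = {1: "cyan", 3: "red", 5: "blue", 9: "green"}

# (max_reward, p_max) cells of the task matrix; the two corner cells with
# unmatched expected value (1.4 and 7.4 units) are not part of the set, so
# expected value is matched along the three diagonals (1.8 / 2.6 / 4.2).
_GAMBLE_CELLS = [
    (3, 0.4),
    (3, 0.8),
    (5, 0.2),
    (5, 0.4),
    (5, 0.8),
    (9, 0.2),
    (9, 0.4),
]


def make_gamble_set() -> list[GambleOption]:
    """The canonical 7 gamble options, ids 1..7 in increasing preference order.

    Minimum reward is always 1 unit (30 ul).  Ids are ordered by expected
    value with ties broken toward the larger maximum reward (the risk
    attitude the default subjective values assume).
    """
    cells = sorted(
        _GAMBLE_CELLS,
        # round EV so the equal-EV diagonals tie exactly; ties broken by max reward
        key=lambda c: (round(c[1] * c[0] + (1 - c[1]) * 1.0, 9), c[0]),
    )
    return [
        GambleOption(
            id=i + 1,
            max_reward=float(mx),
            min_reward=1.0,
            p_max=p,
            colors=(_COLOR_BY_AMOUNT[mx], "cyan"),
        )
        for i, (mx, p) in enumerate(cells)
    ]


def default_subjective_values(gambles: list[GambleOption] | None = None) -> np.ndarray:
    """Default ground-truth subjective values, one per gamble id (ascending).

    A mildly risk-seeking transform of expected value: EV plus a bonus of
    0.1 units per unit of maximum reward, min-max normalized to [0, 1].
    Monotone in EV; the bonus breaks the equal-EV diagonal ties so the
    task has 7 distinct value levels.
    """
    gambles = gambles or make_gamble_set()
    util = np.array([g.expected_value + 0.1 * g.max_reward for g in gambles])
    return (util - util.min()) / (util.max() - util.min())


@dataclass
class BehaviorParams:
    """Generative behavior model.

    ``psi[i]`` is the subjective value of gamble id ``i+1``; ``sigma_d`` is
    the SD of the per-option Gaussian noise in the value comparison.
    Reaction times: ``rt_base - rt_slope * (value drive) + noise``, where
    the drive is the signed value advantage of the chosen target on choice
    trials and the target's value on no-choice trials.
    """

    psi: np.ndarray = field(default_factory=default_subjective_values)
    sigma_d: float = 0.15
    rt_base: float = 280.0  # ms
    rt_slope: float = 40.0  # ms per unit value
    rt_noise_sd: float = 25.0  # ms
    rt_floor: float = 120.0  # ms, physiological minimum

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if self.sigma_d <= 0:
            raise ValueError("sigma_d must be > 0")

    def psi_of(self, gamble_id: int) -> float:
        return float(self.psi[gamble_id - 1])


@dataclass
class LatencyPlan:
    """Planted latencies (ms before saccade onset) of the two selection steps."""

    L_value: float = 110.0
    L_dir: float = 60.0
    rise_tau: float = 20.0  # linear ramp duration, ms
    vis_latency: float = 50.0  # visual response latency after target onset, ms

    def __post_init__(self) -> None:
        if not self.L_value > self.L_dir > 0:
            raise ValueError("need L_value > L_dir > 0 (value before action)")


@dataclass
class GroundTruthNeuron:
    """Parameters of one simulated unit.

    ``b0..b3, s, t, w, p`` are the tuning-family parameters (baseline,
    value / direction / interaction weights in sp/s, sigmoid steepness and
    threshold, tuning width, preferred direction in radians).
    ``beta_pd / beta_npd`` are the relative-action-value weights (sp/s per
    unit of subjective value) applied to the targets in the preferred and
    opposite direction; ``vis_amp`` scales the undifferentiated visual
    response to each target.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    s: float
    t: float
    w: float
    p: float
    beta_pd: float
    beta_npd: float
    vis_amp: float
    model_class: str = "fg"

    def __post_init__(self) -> None:
        if not (0 < self.s <= 1 and 0 < self.t < 1 and 0 < self.w <= 4 * np.pi):
            raise ValueError("tuning parameters out of range")
        if self.model_class in ("fgh", "fg") and not self.beta_pd > 0 >= self.beta_npd:
            raise ValueError("relative action value units need beta_pd > 0 >= beta_npd")

    @property
    def pd_deg(self) -> float:
        return np.degrees(self.p) % 360.0

    @property
    def snapped_pd_deg(self) -> float:
        return snap_direction(self.pd_deg)

    def gdir(self, direction_deg: float | np.ndarray) -> np.ndarray:
        """Unit-peak circular Gaussian around the preferred direction."""
        d = np.radians(direction_deg)
        return np.exp(self.w * (np.cos(d - self.p) - 1.0))

    def fval(self, psi: float | np.ndarray) -> np.ndarray:
        """Unit-range value sigmoid, zero at psi = 0."""
        f0 = 1.0 / (1.0 + np.exp(self.s * self.t))
        return 1.0 / (1.0 + np.exp(-self.s * (np.asarray(psi) - self.t))) - f0


def sample_population(
    n_units: int = 60, rng: np.random.Generator | int | None = 0
) -> list[GroundTruthNeuron]:
    """Default ground-truth population: direction-tuned relative-action-value
    units with preferred directions balanced over the four tested directions
    (plus +/-15 deg jitter) and a planted 2 : -1 PD/NPD value-weight ratio."""
    rng = np.random.default_rng(rng)
    units = []
    for i in range(n_units):
        pd = TESTED_DIRECTIONS[i % 4] + rng.uniform(-15.0, 15.0)
        units.append(
            GroundTruthNeuron(
                b0=rng.uniform(5.0, 15.0),
                b1=rng.uniform(60.0, 90.0),
                b2=rng.uniform(26.0, 34.0),
                b3=0.0,
                s=rng.uniform(0.6, 1.0),
                t=rng.uniform(0.35, 0.65),
                w=rng.uniform(1.5, 3.0),
                p=np.radians(pd % 360.0),
                beta_pd=20.0,
                beta_npd=-10.0,
                vis_amp=rng.uniform(4.0, 10.0),
                model_class="fg",
            )
        )
    return units


# --------------------------------------------------------------------------
# task schedule and behavior
# --------------------------------------------------------------------------

_PLACEHOLDER_RT = 1.0


def make_block_schedule(
    rng: np.random.Generator | int | None,
    block_id: int = 1,
    trial_id_start: int = 1,
    t_start: float = 0.0,
) -> list[TrialRecord]:
    """One block of 28 trials: all 21 unordered gamble pairs as choice trials
    and all 7 gambles as no-choice trials, in randomized order with
    randomized target directions.  Choices and kinematics are placeholders
    until :func:`simulate_choices_rts` fills them in."""
    rng = np.random.default_rng(rng)
    specs: list[tuple[str, tuple[int, ...]]] = []
    for a in range(1, 8):
        for b in range(a + 1, 8):
            specs.append(("choice", (a, b)))
    for g in range(1, 8):
        specs.append(("no_choice", (g,)))
    order = rng.permutation(len(specs))

    trials = []
    t = t_start
    for k, idx in enumerate(order):
        ttype, gids = specs[idx]
        if ttype == "choice":
            d1, d2 = rng.choice(TESTED_DIRECTIONS, size=2, replace=False)
            targets = (Target(d1, gids[0]), Target(d2, gids[1]))
        else:
            targets = (Target(float(rng.choice(TESTED_DIRECTIONS)), gids[0]),)
        t_fix = t
        t_target = t_fix + rng.uniform(500.0, 1000.0)
        t_sacc = t_target + _PLACEHOLDER_RT
        trials.append(
            TrialRecord(
                trial_id=trial_id_start + k,
                block_id=block_id,
                trial_type=ttype,
                targets=targets,
                chosen_index=0,
                t_fix_on=t_fix,
                t_target_on=t_target,
                t_saccade_on=t_sacc,
                t_outcome=t_sacc + 550.0,
                t_reward=t_sacc + 850.0,
                reward_delivered=0.0,
            )
        )
        t = trials[-1].t_reward + 700.0
    return trials


def simulate_choices_rts(
    schedule: list[TrialRecord],
    gambles: list[GambleOption],
    bp: BehaviorParams,
    rng: np.random.Generator | int | None,
) -> list[TrialRecord]:
    """Fill in choices, reaction times, event times and gamble outcomes.

    Choice rule (Thurstonian): each option's subjective value is corrupted
    by independent Gaussian noise of SD ``sigma_d`` and the noisy maximum
    is chosen, so P(choose i over j) = Phi((psi_i - psi_j)/(sigma_d*sqrt2)).
    """
    rng = np.random.default_rng(rng)
    by_id = {g.id: g for g in gambles}
    out = []
    t_shift = 0.0
    for tr in schedule:
        psis = np.array([bp.psi_of(tg.gamble_id) for tg in tr.targets])
        noisy = psis + rng.normal(0.0, bp.sigma_d, size=psis.size)
        chosen = int(np.argmax(noisy))
        if tr.trial_type == "choice":
            drive = psis[chosen] - psis[1 - chosen]
        else:
            drive = psis[0]
        rt = bp.rt_base - bp.rt_slope * drive + rng.normal(0.0, bp.rt_noise_sd)
        rt = max(rt, bp.rt_floor)

        g = by_id[tr.targets[chosen].gamble_id]
        reward = g.max_reward if rng.random() < g.p_max else g.min_reward

        t_fix = tr.t_fix_on + t_shift
        t_target = tr.t_target_on + t_shift
        t_sacc = t_target + rt
        t_outcome = t_sacc + 550.0
        t_reward = t_outcome + 300.0
        out.append(
            TrialRecord(
                trial_id=tr.trial_id,
                block_id=tr.block_id,
                trial_type=tr.trial_type,
                targets=tr.targets,
                chosen_index=chosen,
                t_fix_on=t_fix,
                t_target_on=t_target,
                t_saccade_on=t_sacc,
                t_outcome=t_outcome,
                t_reward=t_reward,
                reward_delivered=reward,
            )
        )
        # keep inter-trial spacing when the realized RT differs from the
        # placeholder used by the scheduler
        t_shift += rt - (tr.t_saccade_on - tr.t_target_on)
    return out


# --------------------------------------------------------------------------
# spiking
# --------------------------------------------------------------------------

SIM_PRE_TARGET = 350.0  # simulate from this long before target onset, ms
SIM_POST_SACCADE = 100.0  # ... to this long after saccade onset


def _ramp(t: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Linear 0 -> 1 ramp starting at ``onset`` over ``tau`` ms."""
    return np.clip((t - onset) / max(tau, 1e-9), 0.0, 1.0)


def rate_timecourse(
    unit: GroundTruthNeuron,
    trial: TrialRecord,
    bp: BehaviorParams,
    lp: LatencyPlan,
    return_raw: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free firing rate of ``unit`` on ``trial`` at 1 ms resolution.

    Returns (bin start times on the session clock, rate in sp/s).  This is
    the generator-side oracle used both for spike thinning and for
    rate-trace comparisons in tests.

    Composition per 1 ms bin:

    * baseline ``b0`` throughout;
    * an undifferentiated visual response to every target from
      ``vis_latency`` after target onset (both targets weighted equally);
    * the chosen-option value term ``b1 * f(psi_chosen)`` (direction-blind)
      ramping in from ``L_value`` before saccade onset;
    * from ``L_dir`` before saccade onset, the direction term
      ``b2 * g(D_chosen)`` (plus the ``b3`` interaction when present), the
      preferred-direction action value ``beta_pd * psi_PDtarget`` and, on
      choice trials, the opposite-direction suppression
      ``beta_npd * psi_NPDtarget``.

    Negative composed rates are clipped at zero.
    """
    t0 = trial.t_target_on - SIM_PRE_TARGET
    t1 = trial.t_saccade_on + SIM_POST_SACCADE
    t = np.arange(np.floor(t0), np.ceil(t1), 1.0)

    vis = _ramp(t, trial.t_target_on + lp.vis_latency, lp.rise_tau)
    rv = _ramp(t, trial.t_saccade_on - lp.L_value, lp.rise_tau)
    rd = _ramp(t, trial.t_saccade_on - lp.L_dir, lp.rise_tau)

    rate = np.full(t.shape, unit.b0)
    drive_vis = sum(unit.gdir(tg.direction) for tg in trial.targets)
    rate += unit.vis_amp * vis * drive_vis

    psi_chosen = bp.psi_of(trial.chosen_target.gamble_id)
    if "f" in unit.model_class or "h" in unit.model_class:
        # the chosen-option value signal is expressed only when the unit is
        # engaged by the display: if the sole target sits in the
        # anti-preferred direction the unit is not driven and shows no value
        # modulation (the flat NPD no-choice signature).  In choice trials
        # some target always engages the unit, so within a fixed target
        # configuration the term carries no direction information before
        # L_dir.
        gate = max(
            1.0
            if abs(circular_diff_deg(tg.direction, unit.snapped_pd_deg)) < 135.0
            else float(unit.gdir(tg.direction))
            for tg in trial.targets
        )
        rate += rv * unit.b1 * unit.fval(psi_chosen) * gate

    late = 0.0
    d_chosen = trial.chosen_target.direction
    if "g" in unit.model_class or "h" in unit.model_class:
        late = late + unit.b2 * unit.gdir(d_chosen)
    if "h" in unit.model_class:
        late = late + unit.b3 * unit.fval(psi_chosen) * unit.gdir(d_chosen)

    pd = unit.snapped_pd_deg
    npd = (pd + 180.0) % 360.0
    for tg in trial.targets:
        if snap_direction(tg.direction) == pd:
            late = late + unit.beta_pd * bp.psi_of(tg.gamble_id)
        elif snap_direction(tg.direction) == npd and trial.trial_type == "choice":
            late = late + unit.beta_npd * bp.psi_of(tg.gamble_id)
    rate = rate + rd * late
    if return_raw:
        return t, rate
    return t, np.maximum(rate, 0.0)


def simulate_spikes(
    trials: list[TrialRecord],
    units: list[GroundTruthNeuron],
    bp: BehaviorParams,
    lp: LatencyPlan,
    rng: np.random.Generator | int | None,
) -> list[NeuronData]:
    """Inhomogeneous-Poisson spike trains for every unit on every trial.

    Spikes are drawn per 1 ms bin with Poisson counts at the bin's constant
    rate (exact thinning for a piecewise-constant intensity) and jittered
    uniformly inside the bin so trains are strictly increasing.
    """
    rng = np.random.default_rng(rng)
    neurons = []
    for uidx, unit in enumerate(units):
        spikes: dict[int, np.ndarray] = {}
        n_clipped = 0
        for tr in trials:
            t, rate = rate_timecourse(unit, tr, bp, lp, return_raw=True)
            n_clipped += int(np.sum(rate < 0.0))
            rate = np.maximum(rate, 0.0)
            counts = rng.poisson(rate * 1e-3)
            idx = np.nonzero(counts)[0]
            if idx.size == 0:
                spikes[tr.trial_id] = np.empty(0)
                continue
            reps = counts[idx]
            starts = np.repeat(t[idx], reps)
            st = np.sort(starts + rng.uniform(0.0, 1.0, size=starts.size))
            spikes[tr.trial_id] = st
        neurons.append(NeuronData(
            neuron_id=uidx + 1,
            spike_times=spikes,
            metadata={"n_clipped_rate_bins": n_clipped},
        ))
    return neurons


# --------------------------------------------------------------------------
# one-call session builder
# --------------------------------------------------------------------------


def make_session(
    n_blocks: int = 30,
    n_units: int = 60,
    seed: int = 0,
    bp: BehaviorParams | None = None,
    lp: LatencyPlan | None = None,
    units: list[GroundTruthNeuron] | None = None,
) -> dict:
    """Generate a complete ground-truth session.

    Returns a dict with keys ``trials``, ``neurons``, ``units`` (ground
    truth), ``gambles``, ``bp``, ``lp``.  Identical seeds give identical
    sessions.
    """
    rng = np.random.default_rng(seed)
    gambles = make_gamble_set()
    bp = bp or BehaviorParams()
    lp = lp or LatencyPlan()
    units = units or sample_population(n_units, rng.integers(2**31))

    schedule = []
    for b in range(n_blocks):
        t0 = schedule[-1].t_reward + 700.0 if schedule else 0.0
        schedule.extend(
            make_block_schedule(
                rng.integers(2**31),
                block_id=b + 1,
                trial_id_start=28 * b + 1,
                t_start=t0,
            )
        )
    trials = simulate_choices_rts(schedule, gambles, bp, rng.integers(2**31))
    neurons = simulate_spikes(trials, units, bp, lp, rng.integers(2**31))
    return {
        "trials": trials,
        "neurons": neurons,
        "units": units,
        "gambles": gambles,
        "bp": bp,
        "lp": lp,
    }


def ground_truth_dict(session: dict) -> dict:
    """JSON-serializable record of the planted ground truth."""
    return {
        "units": [asdict(u) for u in session["units"]],
        "latency_plan": asdict(session["lp"]),
        "behavior": {
            "psi": session["bp"].psi.tolist(),
            "sigma_d": session["bp"].sigma_d,
            "rt_base": session["bp"].rt_base,
            "rt_slope": session["bp"].rt_slope,
            "rt_noise_sd": session["bp"].rt_noise_sd,
        },
    }
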