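"""Time-resolved mutual information between unit activity and task variables.

MI is estimated on a 4 x 4 contingency table per 1 ms time bin: neural
activity is discretized into quartile bins whose boundaries come from
*no-choice* trials at the same time bin (so binning is identical across
trial conditions), and the 7 value levels are packed into 4 ordered groups
(sizes 2,2,2,1 from low to high); the 4 saccade directions map one-to-one.
The plug-in estimate is corrected by the first-order (Panzeri-Treves) bias
term, then residually debiased by the mean of 100 permutation estimates;
significance compares the estimate with the sixth highest permutation
value (empirical p <= 0.05), and non-significant or negative estimates are
set to zero.  With 4 x 4 bins the ceiling is log2(4) = 2 bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._stats import first_run_start

N_F = 4  # activity bins
N_X = 4  # variable bins
LN2 = np.log(2.0)

#: ascending value ranks (0..6) -> 4 ordered groups of sizes (2, 2, 2, 1)
VALUE_GROUP_OF_RANK = np.array([0, 0, 1, 1, 2, 2, 3])


@dataclass
class MIBins:
    rate_boundaries: np.ndarray  # (n_time_bins, 3): Q1, Q2, Q3 per bin
    degenerate: np.ndarray  # bool per time bin: boundaries collapsed
    value_groups: np.ndarray = None  # rank -> group

    def __post_init__(self):
        if self.value_groups is None:
            self.value_groups = VALUE_GROUP_OF_RANK.copy()


def quartile_boundaries(x: np.ndarray) -> np.ndarray:
    """Q1, Q2, Q3 as midpoints between the order statistics flanking each
    quartile cut, so each bin holds an equal number of reference trials."""
    xs = np.sort(np.asarray(x, dtype=float))
    M = xs.size
    out = np.empty(3)
    for qi, q in enumerate((0.25, 0.5, 0.75)):
        k = int(round(M * q))
        k = min(max(k, 1), M - 1)
        out[qi] = 0.5 * (xs[k - 1] + xs[k])
    return out


def build_bins(nochoice_sdf: np.ndarray) -> MIBins:
    """Per-time-bin activity boundaries from no-choice trials.

    ``nochoice_sdf`` is (n_no_choice_trials, n_time_bins); needs >= 8
    trials.  Time bins where the boundaries collapse (near-constant rates)
    are flagged degenerate; callers exclude the unit there.
    """
    nochoice_sdf = np.asarray(nochoice_sdf, dtype=float)
    if nochoice_sdf.shape[0] < 8:
        raise ValueError("need >= 8 no-choice trials to build activity bins")
    xs = np.sort(nochoice_sdf, axis=0)
    M = xs.shape[0]
    ks = [min(max(int(round(M * q)), 1), M - 1) for q in (0.25, 0.5, 0.75)]
    bounds = np.stack([0.5 * (xs[k - 1] + xs[k]) for k in ks], axis=1)
    degenerate = (bounds[:, 2] - bounds[:, 0]) <= 1e-12
    return MIBins(rate_boundaries=bounds, degenerate=degenerate)


def bin_activity(sdf: np.ndarray, bins: MIBins) -> np.ndarray:
    """Discretize (trials, time) activity into 0..3 with the stored boundaries."""
    sdf = np.asarray(sdf, dtype=float)
    b = bins.rate_boundaries
    return (
        (sdf > b[None, :, 0]).astype(np.int64)
        + (sdf > b[None, :, 1])
        + (sdf > b[None, :, 2])
    )


def _plugin_and_bias(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plug-in MI (bits) and first-order bias from (..., N_F, N_X) count tables."""
    counts = np.asarray(counts, dtype=float)
    M = counts.sum(axis=(-2, -1), keepdims=True)
    pij = counts / M
    pi = pij.sum(axis=-1, keepdims=True)
    pj = pij.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pij * np.log2(pij / (pi * pj))
    mi = np.where(pij > 0, terms, 0.0).sum(axis=(-2, -1))
    u_fx = (counts > 0).sum(axis=(-2, -1))
    u_f = (counts.sum(axis=-1) > 0).sum(axis=-1)
    u_x = (counts.sum(axis=-2) > 0).sum(axis=-1)
    bias = (u_fx - u_f - u_x + 1) / (2.0 * M[..., 0, 0] * LN2)
    return mi, bias


def mutual_information(F: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Plug-in MI (bits) and the first-order bias term for one table.

    ``F`` and ``X`` are equal-length integer arrays in 0..3.  The
    bias-corrected estimate is ``mi_raw - bias1``.
    """
    F = np.asarray(F, dtype=int)
    X = np.asarray(X, dtype=int)
    if F.size == 0:
        raise ValueError("empty input")
    if F.size != X.size:
        raise ValueError("F and X must have equal length")
    counts = np.zeros((N_F, N_X))
    np.add.at(counts, (F, X), 1.0)
    mi, bias = _plugin_and_bias(counts)
    return float(mi), float(bias)


@dataclass
class MIResult:
    unit_id: int
    variable: str
    times: np.ndarray
    mi: np.ndarray  # final debiased MI, zeroed where negative/non-significant
    mi_corrected: np.ndarray  # plug-in minus first-order bias (pre-bootstrap)
    bias1: np.ndarray
    boot_bias: np.ndarray
    significant: np.ndarray
    degenerate: np.ndarray


def mi_timecourse(
    sdf: np.ndarray,
    nochoice_sdf: np.ndarray,
    x: np.ndarray,
    times: np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = 0,
    unit_id: int = 0,
    variable: str = "",
) -> MIResult:
    """Debias-and-test MI per time bin for one unit and one variable.

    ``sdf`` (trials, bins) is the activity the MI is computed on, ``x``
    the variable already discretized to 0..3, and ``nochoice_sdf``
    provides the activity-binning reference.  The same ``n_boot``
    permutations of ``x`` are applied at every time bin.
    """
    rng = np.random.default_rng(rng)
    sdf = np.asarray(sdf, dtype=float)
    x = np.asarray(x, dtype=np.int64)
    T, B = sdf.shape
    if T < 16:
        raise ValueError("need >= 16 trials")

    bins = build_bins(nochoice_sdf)
    F = bin_activity(sdf, bins)  # (T, B)

    # observed + permuted one-hot X, (T, (n_boot + 1) * N_X)
    xs = np.empty((n_boot + 1, T), dtype=np.int64)
    xs[0] = x
    for i in range(n_boot):
        xs[i + 1] = rng.permutation(x)
    xoh = np.zeros((T, (n_boot + 1) * N_X))
    cols = np.arange(n_boot + 1)[:, None] * N_X + xs
    xoh[np.arange(T)[None, :].repeat(n_boot + 1, 0).ravel(), cols.ravel()] = 1.0

    counts = np.empty((B, n_boot + 1, N_F, N_X))
    for i in range(N_F):
        ci = (F == i).astype(float).T @ xoh  # (B, (n_boot+1)*N_X)
        counts[:, :, i, :] = ci.reshape(B, n_boot + 1, N_X)

    mi, bias = _plugin_and_bias(counts)  # (B, n_boot+1)
    corr = mi - bias
    obs = corr[:, 0]
    perms = corr[:, 1:]
    boot_bias = perms.mean(axis=1)
    # sixth highest of the permutation values: empirical p <= 0.05 at n_boot=100
    kth = np.sort(perms, axis=1)[:, -max(int(np.ceil(0.05 * n_boot)) + 1, 1)]
    significant = obs > kth
    final = np.where(significant, obs - boot_bias, 0.0)
    final = np.where((final > 0) & ~bins.degenerate, final, 0.0)
    # the information ceiling log2(4) is a hard bound on the true MI
    final = np.minimum(final, np.log2(min(N_F, N_X)))
    return MIResult(
        unit_id=unit_id,
        variable=variable,
        times=np.asarray(times, dtype=float),
        mi=final,
        mi_corrected=obs,
        bias1=bias[:, 0],
        boot_bias=boot_bias,
        significant=significant,
        degenerate=bins.degenerate,
    )


def debias_and_test(
    F: np.ndarray,
    X: np.ndarray,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> tuple[float, bool]:
    """Single-table version of the bootstrap debias-and-test procedure.

    Returns (final MI, significant).  Negative or non-significant
    estimates are zero.
    """
    rng = np.random.default_rng(rng)
    F = np.asarray(F, dtype=np.int64)
    X = np.asarray(X, dtype=np.int64)
    mi_raw, bias = mutual_information(F, X)
    obs = mi_raw - bias
    perm_vals = np.empty(n_boot)
    for i in range(n_boot):
        pm_raw, pm_bias = mutual_information(F, rng.permutation(X))
        perm_vals[i] = pm_raw - pm_bias
    kth = np.sort(perm_vals)[-max(int(np.ceil(0.05 * n_boot)) + 1, 1)]
    significant = bool(obs > kth)
    final = obs - perm_vals.mean()
    if not significant or final < 0:
        return 0.0, significant
    return float(min(final, np.log2(min(N_F, N_X)))), significant


def info_onset(
    chosen_mi: np.ndarray,
    nonchosen_mi: np.ndarray,
    times: np.ndarray,
    min_run: int = 10,
    alpha: float = 0.05,
) -> float | None:
    """Onset of significantly more chosen than non-chosen information.

    Per time bin, a paired t-test across units; the onset is the first bin
    beginning a run of >= ``min_run`` consecutive bins with p < alpha and
    a positive mean difference.
    """
    chosen_mi = np.asarray(chosen_mi, dtype=float)
    nonchosen_mi = np.asarray(nonchosen_mi, dtype=float)
    if chosen_mi.shape[0] < 10:
        raise ValueError("need >= 10 units")
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_rel(chosen_mi, nonchosen_mi, axis=0)
    diff = chosen_mi.mean(axis=0) - nonchosen_mi.mean(axis=0)
    pv = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)
    mask = (pv < alpha) & (diff > 0)
    idx = first_run_start(mask, min_run)
    return float(np.asarray(times)[idx]) if idx is not None else None


def value_rank_bins(psi: np.ndarray) -> np.ndarray:
    """Map each gamble's subjective value to its 4-group bin (by rank)."""
    psi = np.asarray(psi, dtype=float)
    ranks = np.argsort(np.argsort(psi))
    return VALUE_GROUP_OF_RANK[ranks]


def direction_bins(directions_deg: np.ndarray) -> np.ndarray:
    """Map the four tested directions to 0..3."""
    lut = {45.0: 0, 135.0: 1, 225.0: 2, 315.0: 3}
    return np.array([lut[float(d)] for d in np.asarray(directions_deg)], dtype=np.int64)
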