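"""Trial-wise binary linear classification from single-unit spike density.

Per 1 ms time bin, a one-dimensional Fisher discriminant (equal priors,
pooled variance -- i.e. nearest class mean) is trained and evaluated under
leave-one-out cross-validation; significance per bin comes from a label
permutation test (default 1000 shuffles, p <= 0.05), and a unit's onset is
the first bin of a run of >= 10 consecutive significant bins.

The permutation inner loop is numba-compiled; ``loo_accuracy_reference``
is the plain-numpy oracle the compiled kernel is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._stats import first_run_start
from .datatypes import TrialRecord

DECODING_WINDOW = (-200.0, 20.0)  # ms re saccade onset
MIN_TRIALS_PER_CLASS = 10
ONSET_MIN_RUN = 10  # consecutive 1 ms bins


@njit(cache=True)
def _acc_kernel(
    Xb: np.ndarray, L: np.ndarray, loo: bool
) -> np.ndarray:  # pragma: no cover
    """Nearest-class-mean accuracy; Xb is (bins, trials), L is (P, trials).

    ``loo=True`` excludes the scored trial from its own class mean.
    """
    B, T = Xb.shape
    P = L.shape[0]
    acc = np.zeros((P, B))
    for p in range(P):
        n1 = 0
        for j in range(T):
            n1 += L[p, j]
        n0 = T - n1
        for b in range(B):
            s1 = 0.0
            s0 = 0.0
            for j in range(T):
                if L[p, j] == 1:
                    s1 += Xb[b, j]
                else:
                    s0 += Xb[b, j]
            correct = 0.0
            for j in range(T):
                x = Xb[b, j]
                if L[p, j] == 1:
                    mu_own = (s1 - x) / (n1 - 1) if loo else s1 / n1
                    mu_oth = s0 / n0
                else:
                    mu_own = (s0 - x) / (n0 - 1) if loo else s0 / n0
                    mu_oth = s1 / n1
                d_own = abs(x - mu_own)
                d_oth = abs(x - mu_oth)
                if d_own < d_oth:
                    correct += 1.0
                elif d_own == d_oth:
                    correct += 0.5
            acc[p, b] = correct / T
    return acc


def loo_accuracy_reference(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pure-numpy LOO accuracy per bin (oracle for the compiled kernel)."""
    X = np.asarray(X, dtype=float)  # (trials, bins)
    labels = np.asarray(labels).astype(int)
    T = labels.size
    correct = np.zeros(X.shape[1])
    for j in range(T):
        keep = np.arange(T) != j
        mu1 = X[keep & (labels == 1)].mean(axis=0)
        mu0 = X[keep & (labels == 0)].mean(axis=0)
        d1 = np.abs(X[j] - mu1)
        d0 = np.abs(X[j] - mu0)
        pred_score = np.where(d1 < d0, 1.0, np.where(d1 > d0, 0.0, 0.5))
        correct += np.where(
            pred_score == 0.5, 0.5, (pred_score == labels[j]).astype(float)
        )
    return correct / T


@dataclass
class DecodingResult:
    unit_id: int
    variable: str
    times: np.ndarray  # bin centers, ms re alignment event
    accuracy: np.ndarray  # in [0, 1] per bin
    p_perm: np.ndarray
    sig_mask: np.ndarray
    onset: float | None  # ms, first bin of a >= 10-bin significant run


def decode_timecourse(
    sdf: np.ndarray,
    labels: np.ndarray,
    times: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = 0,
    alpha: float = 0.05,
    min_run: int = ONSET_MIN_RUN,
    unit_id: int = 0,
    variable: str = "",
    groups: np.ndarray | None = None,
    loo: bool = True,
) -> DecodingResult:
    """Decode a binary variable from one unit's per-trial spike density.

    ``sdf`` is (trials, bins); ``labels`` binary with >= 10 trials per
    class.  Accuracy per bin is leave-one-out by default (``loo=False``
    scores in-sample prediction with the full-data class means, which is
    optimistically biased but matches a plain train-and-predict reading);
    the permutation p-value is the fraction of label shuffles with
    accuracy at least the observed.

    ``groups`` optionally stratifies the analysis: the classifier is
    trained and evaluated separately within each group (e.g. each pair of
    target locations, so that stimulus-configuration differences cannot
    masquerade as choice information), accuracies are trial-weighted
    averages over groups, and label shuffles stay within groups.
    """
    sdf = np.asarray(sdf, dtype=float)
    labels = np.asarray(labels).astype(np.int64)
    classes = np.unique(labels)
    if classes.size != 2 or not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain exactly the two classes {0, 1}")
    counts = np.bincount(labels)
    if counts.min() < MIN_TRIALS_PER_CLASS:
        raise ValueError(
            f"need >= {MIN_TRIALS_PER_CLASS} trials per class, got {counts.tolist()}"
        )
    rng = np.random.default_rng(rng)

    if groups is None:
        group_masks = [np.ones(labels.size, dtype=bool)]
    else:
        groups = np.asarray(groups)
        group_masks = [groups == g for g in np.unique(groups)]
        group_masks = [m for m in group_masks if np.bincount(labels[m], minlength=2).min() >= 2]
        if not group_masks:
            raise ValueError("no group has both classes")

    T = labels.size
    n_used = sum(int(m.sum()) for m in group_masks)
    obs = np.zeros(sdf.shape[1])
    perm_acc = np.zeros((n_perm, sdf.shape[1]))
    for m in group_masks:
        Xg = np.ascontiguousarray(sdf[m].T)
        lg = labels[m]
        w = m.sum() / n_used
        obs += w * _acc_kernel(Xg, lg[None, :], loo)[0]
        perm_labels = np.empty((n_perm, lg.size), dtype=np.int64)
        for i in range(n_perm):
            perm_labels[i] = rng.permutation(lg)
        perm_acc += w * _acc_kernel(Xg, perm_labels, loo)

    p = (1 + np.sum(perm_acc >= obs[None, :] - 1e-12, axis=0)) / (n_perm + 1)
    sig = p <= alpha
    onset_idx = first_run_start(sig, min_run)
    times = np.asarray(times, dtype=float)
    return DecodingResult(
        unit_id=unit_id,
        variable=variable,
        times=times,
        accuracy=obs,
        p_perm=p,
        sig_mask=sig,
        onset=float(times[onset_idx]) if onset_idx is not None else None,
    )


@dataclass
class PopulationSummary:
    times: np.ndarray
    mean_sig_accuracy: np.ndarray  # nan where no unit is significant
    n_sig_units: np.ndarray


def population_accuracy_summary(results: list[DecodingResult]) -> PopulationSummary:
    """Per bin: mean accuracy over units significant there, and their count.

    Non-significant accuracies are excluded (bins where no unit is
    significant report nan).
    """
    if not results:
        raise ValueError("no decoding results")
    times = results[0].times
    acc = np.stack([r.accuracy for r in results])
    sig = np.stack([r.sig_mask for r in results])
    n_sig = sig.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_acc = np.where(
            n_sig > 0, (acc * sig).sum(axis=0) / np.maximum(n_sig, 1), np.nan
        )
    return PopulationSummary(times=times, mean_sig_accuracy=mean_acc, n_sig_units=n_sig)


def binarize_chosen_value(
    trials: list[TrialRecord], psi: np.ndarray
) -> tuple[np.ndarray, str]:
    """Median split of chosen subjective value into low (0) / high (1).

    Trials exactly at the median are assigned so as to balance the two
    classes (alternating in trial order); the applied rule is returned as
    a log string.
    """
    psi = np.asarray(psi, dtype=float)
    v = np.array([psi[t.chosen_target.gamble_id - 1] for t in trials])
    if np.unique(v).size < 2:
        raise ValueError("all chosen values identical; cannot binarize")
    med = np.median(v)
    labels = np.full(v.size, -1, dtype=np.int64)
    labels[v > med] = 1
    labels[v < med] = 0
    at_med = np.nonzero(labels == -1)[0]
    n_low = int(np.sum(labels == 0))
    n_high = int(np.sum(labels == 1))
    assigned = []
    for idx in at_med:
        lab = 0 if n_low <= n_high else 1
        labels[idx] = lab
        assigned.append(lab)
        n_low += lab == 0
        n_high += lab == 1
    rule = (
        f"median={med:.6g}; {at_med.size} trial(s) at the median assigned "
        f"{assigned} to balance classes"
    )
    return labels, rule


def configuration_groups(trials: list[TrialRecord]) -> np.ndarray:
    """Group id per trial by the unordered pair of target directions.

    Decoding chosen direction within these groups compares trials that saw
    the *same* two target locations, so visual-configuration differences
    cannot contribute to choice-decoding accuracy.
    """
    keys = [frozenset(t.direction for t in tr.targets) for tr in trials]
    uniq = {k: i for i, k in enumerate(sorted(keys, key=sorted))}
    return np.array([uniq[k] for k in keys], dtype=np.int64)


def binarize_chosen_direction(
    trials: list[TrialRecord], axis: str = "left_right"
) -> np.ndarray:
    """Binary chosen-direction labels: 1 = right (45/315 deg) or up (45/135)."""
    pos = {"left_right": (45.0, 315.0), "up_down": (45.0, 135.0)}[axis]
    return np.array(
        [1 if t.chosen_target.direction in pos else 0 for t in trials],
        dtype=np.int64,
    )
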