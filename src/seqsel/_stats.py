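"""Small shared statistical helpers (run detection, sign-flip max-stat test)."""

from __future__ import annotations

import numpy as np


def first_run_start(mask: np.ndarray, min_run: int) -> int | None:
    """Index of the first element beginning >= min_run consecutive True."""
    mask = np.asarray(mask, dtype=bool)
    run = 0
    for i, m in enumerate(mask):
        run = run + 1 if m else 0
        if run >= min_run:
            return i - min_run + 1
    return None


def signflip_maxstat_onset(
    diffs: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = 0,
    alpha: float = 0.05,
) -> tuple[int | None, np.ndarray, float]:
    """Max-statistic sign-flip permutation test across time for paired data.

    ``diffs`` is (n_units, n_bins): per-unit paired differences per time
    bin.  The statistic per bin is the across-unit mean; the null flips
    each unit's sign (all its bins together).  The familywise threshold is
    the (1-alpha) quantile of the permutation distribution of the maximum
    statistic over bins; the onset is the first bin whose observed mean
    exceeds it (one-sided, positive direction).

    The statistic is studentized (a paired t per bin), so bins with large
    sustained effects cannot inflate the familywise threshold for the
    small early effects whose onset is sought.

    Returns (onset index or None, observed per-bin t values, threshold).
    """
    rng = np.random.default_rng(rng)
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    q = np.mean(diffs**2, axis=0)  # flip-invariant second moment

    def t_of(means: np.ndarray) -> np.ndarray:
        var = np.maximum(q - means**2, 0.0) * n / (n - 1)
        return means / np.sqrt(np.maximum(var / n, 1e-300))

    obs = t_of(diffs.mean(axis=0))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_max = t_of(signs @ diffs / n).max(axis=1)
    thresh = float(np.quantile(null_max, 1.0 - alpha))
    sig = obs > thresh
    idx = np.nonzero(sig)[0]
    return (int(idx[0]) if idx.size else None), obs, thresh
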