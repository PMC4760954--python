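"""Spike alignment and firing-rate estimation.

Rates are estimated as spike density functions: spikes binned at 1 ms and
convolved with a unit-integral Gaussian kernel (default sigma = 10 ms,
truncated at +/-4 sigma).  All windows are half-open ``[lo, hi)`` ms
relative to the alignment event.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datatypes import NeuronData, RateTensor, TrialRecord

DEFAULT_KERNEL_SIGMA = 10.0  # ms


def align_spikes(
    neuron: NeuronData,
    trials: list[TrialRecord],
    event: str,
    window: tuple[float, float],
) -> dict[int, np.ndarray]:
    """Spike offsets (ms, negative = before event) per trial within ``window``.

    Raises ``KeyError`` for an unknown event name; a trial missing from the
    neuron's spike table contributes an empty array.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window lo={lo} must be < hi={hi}")
    out: dict[int, np.ndarray] = {}
    for tr in trials:
        t0 = tr.event_time(event)
        st = np.asarray(neuron.spike_times.get(tr.trial_id, ()), dtype=float)
        offs = st - t0
        out[tr.trial_id] = offs[(offs >= lo) & (offs < hi)]
    return out


def gaussian_kernel(
    sigma: float, resolution: float = 1.0, causal: bool = True
) -> np.ndarray:
    """Unit-integral Gaussian kernel sampled at ``resolution`` ms, +/-4 sigma.

    ``causal=True`` (default) keeps only the trailing half (a spike
    contributes to the density at and after its own time, never before).
    Latency and onset estimates are only meaningful with a causal kernel:
    a symmetric kernel smears signals backward in time and biases onsets
    early by up to its half-width.
    """
    half = int(np.ceil(4.0 * sigma / resolution))
    x = np.arange(-half, half + 1) * resolution
    k = np.exp(-0.5 * (x / sigma) ** 2)
    if causal:
        k[x < 0] = 0.0
    return k / (k.sum() * resolution)


def spike_density(
    aligned: dict[int, np.ndarray] | np.ndarray,
    window: tuple[float, float],
    resolution: float = 1.0,
    kernel: np.ndarray | None = None,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike density function(s) in spikes/s.

    Parameters
    ----------
    aligned
        Either a single offset array or a dict of per-trial offset arrays
        (as returned by :func:`align_spikes`).
    kernel
        Optional explicit kernel sampled at ``resolution`` ms; must have
        unit integral.  Default: Gaussian of ``kernel_sigma`` ms.

    Returns
    -------
    (bin_centers, rates) where rates is (n_trials, n_bins) for dict input
    or (n_bins,) for a single train.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if kernel is None:
        kernel = gaussian_kernel(kernel_sigma, resolution)
    else:
        kernel = np.asarray(kernel, dtype=float)
        if not np.isclose(kernel.sum() * resolution, 1.0, atol=1e-6):
            raise ValueError("kernel must have unit integral")

    lo, hi = window
    pad = (kernel.size // 2) * resolution
    edges = np.arange(lo - pad, hi + pad + resolution / 2, resolution)
    centers_all = 0.5 * (edges[:-1] + edges[1:])
    keep = (centers_all >= lo) & (centers_all < hi)

    single = not isinstance(aligned, dict)
    trains = [np.asarray(aligned)] if single else [aligned[k] for k in aligned]
    rates = np.empty((len(trains), keep.sum()))
    for i, st in enumerate(trains):
        counts, _ = np.histogram(st, bins=edges)
        dens = np.convolve(counts, kernel, mode="same") * 1000.0  # spikes/s
        rates[i] = dens[keep]
    centers = centers_all[keep]
    return centers, (rates[0] if single else rates)


def sdf_tensor(
    neurons: list[NeuronData],
    trials: list[TrialRecord],
    event: str,
    window: tuple[float, float],
    resolution: float = 1.0,
    kernel_sigma: float = DEFAULT_KERNEL_SIGMA,
) -> RateTensor:
    """Per-trial spike density for every unit: values[unit, trial, time bin]."""
    lo, hi = window
    values = None
    for i, n in enumerate(neurons):
        # align over a widened window so kernel mass near the edges is correct
        margin = 4.0 * kernel_sigma
        aligned = align_spikes(n, trials, event, (lo - margin, hi + margin))
        centers, rates = spike_density(
            aligned, window, resolution, kernel_sigma=kernel_sigma
        )
        if values is None:
            values = np.empty((len(neurons), len(trials), centers.size))
        values[i] = rates
    edges = np.arange(lo, hi + resolution / 2, resolution)
    return RateTensor(
        values=values,
        align_event=event,
        bin_edges=edges,
        unit_ids=tuple(n.neuron_id for n in neurons),
        trial_ids=tuple(t.trial_id for t in trials),
    )


def window_mean_rates(
    neuron: NeuronData,
    trials: list[TrialRecord],
    event: str,
    window: tuple[float, float],
) -> np.ndarray:
    """Mean firing rate (spikes/s) per trial in a half-open window."""
    lo, hi = window
    aligned = align_spikes(neuron, trials, event, window)
    dur_s = (hi - lo) / 1000.0
    return np.array([aligned[t.trial_id].size / dur_s for t in trials])


def unit_minmax_normalize(rates: np.ndarray) -> np.ndarray:
    """Scale each unit's rates so its minimum is 0 and maximum is 1.

    ``rates`` has units on the first axis; min/max are taken over all
    remaining axes (the declared condition set).  A constant unit raises
    ``ValueError`` -- the caller decides whether to drop it.
    """
    rates = np.asarray(rates, dtype=float)
    flat = rates.reshape(rates.shape[0], -1)
    lo = flat.min(axis=1)
    hi = flat.max(axis=1)
    bad = np.nonzero(hi <= lo)[0]
    if bad.size:
        raise ValueError(f"constant unit(s) at index {bad.tolist()}: max == min")
    shape = (rates.shape[0],) + (1,) * (rates.ndim - 1)
    return (rates - lo.reshape(shape)) / (hi - lo).reshape(shape)
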