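"""Collective-dynamics features: participation and phase synchrony.

Two summary statistics characterise a network simulation:

* **Participation** P_bar: the mean number of feature-variable peaks per
  node over the post-transient window (V for FHN, cytosolic Ca2+ for
  SRK).  Quiescent networks give 0; it is proportional to the fraction
  of oscillating nodes when active nodes share a common rhythm.
* **Coordination** R_bar: the time average of the Kuramoto order
  parameter magnitude R(t) = |mean_j exp(i theta_j(t))| over the
  oscillating nodes, where each node's phase theta_j advances linearly
  by 2*pi between consecutive peaks of its trace.  R_bar = 1 means
  perfect phase locking, ~0 incoherence.

Nodes with fewer than two peaks carry no phase and are excluded from
R_bar; if fewer than 10% of nodes oscillate, R_bar is reported as 0
with ``synchrony_defined=False`` (a near-silent network has no
meaningful collective phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .netsim import SimResult
from .sortedness import Partition

__all__ = [
    "FeatureSummary",
    "count_peaks",
    "peak_times",
    "summarise_participation",
    "phase_from_peaks",
    "kuramoto_R",
    "summarise",
    "interburst_intervals",
]

#: Peak prominence threshold as a fraction of the signal range used for
#: normalisation (the population-wide post-transient range).
PROMINENCE_FRACTION = 0.2
#: Minimum inter-peak separation in output-grid samples.
MIN_SEPARATION = 5
#: Minimum fraction of oscillating nodes for R_bar to be meaningful.
MIN_OSCILLATING_FRACTION = 0.1


@dataclass
class FeatureSummary:
    """Participation and synchrony summaries of one simulation."""

    P_bar: float
    P_bar_k: dict[int, float]
    R_bar: float
    R_bar_k: dict[int, float]
    n_oscillating: int
    feature_variable: str
    synchrony_defined: bool = True

    def as_dict(self) -> dict:
        out = {"P_bar": self.P_bar, "R_bar": self.R_bar, "n_osc": self.n_oscillating}
        for k, v in self.P_bar_k.items():
            out[f"P_bar_{k}"] = v
        for k, v in self.R_bar_k.items():
            out[f"R_bar_{k}"] = v
        return out


def peak_times(
    t: np.ndarray,
    trace: np.ndarray,
    scale: Optional[float] = None,
    prominence_fraction: float = PROMINENCE_FRACTION,
    min_separation: int = MIN_SEPARATION,
) -> np.ndarray:
    """Times of local maxima exceeding a range-relative prominence.

    ``scale`` is the reference signal range (population-wide for network
    runs, so a flat node is not promoted to oscillating by its own
    noise floor); defaults to the trace's own range.  Peak counting is
    invariant to affine rescaling of the trace when ``scale`` rescales
    with it.
    """
    trace = np.asarray(trace, dtype=float)
    if scale is None:
        scale = float(np.ptp(trace))
    if scale <= 0:
        return np.array([])
    idx, _ = find_peaks(
        trace, prominence=prominence_fraction * scale, distance=min_separation
    )
    return t[idx]


def count_peaks(
    t: np.ndarray,
    trace: np.ndarray,
    scale: Optional[float] = None,
    **kwargs,
) -> int:
    """Number of prominent local maxima in a (post-transient) trace."""
    return len(peak_times(t, trace, scale=scale, **kwargs))


def summarise_participation(
    sim: SimResult, partition: Partition
) -> tuple[float, dict[int, float], np.ndarray]:
    """Per-node peak counts averaged globally and per population.

    Returns (P_bar, {k: P_bar_k}, per-node counts).  Counts are taken on
    the feature variable over the post-transient window, with the peak
    prominence referenced to the population-wide signal range.
    """
    mask = sim.post_transient
    t = sim.t[mask]
    X = sim.feature_variable[:, mask]
    scale = float(np.ptp(X))
    counts = np.array([count_peaks(t, X[i], scale=scale) for i in range(sim.N)])
    P_bar = float(counts.mean())
    P_bar_k = {
        k: float(counts[partition.labels == k].mean())
        for k in range(1, partition.K + 1)
    }
    return P_bar, P_bar_k, counts


def phase_from_peaks(t: np.ndarray, pk_times: np.ndarray) -> np.ndarray:
    """Linearly interpolated peak phase on the output grid.

    The phase gains 2*pi between consecutive peaks and is held constant
    before the first and after the last peak.  Requires >= 2 peaks.
    """
    if len(pk_times) < 2:
        raise ValueError("phase requires at least two peaks")
    marks = 2.0 * np.pi * np.arange(len(pk_times))
    return np.interp(t, pk_times, marks)


def kuramoto_R(phases: np.ndarray) -> tuple[float, np.ndarray]:
    """Time-averaged and instantaneous Kuramoto order parameter.

    ``phases`` has shape (n_nodes, T); returns (R_bar, R(t)) with
    R(t) = |mean_j exp(i theta_j(t))|.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if phases.shape[0] < 2:
        raise ValueError("Kuramoto order parameter requires >= 2 nodes")
    z = np.exp(1j * phases).mean(axis=0)
    R_t = np.abs(z)
    return float(R_t.mean()), R_t


def summarise(sim: SimResult, partition: Partition) -> FeatureSummary:
    """Full feature summary (P_bar, R_bar, per-population splits)."""
    mask = sim.post_transient
    t = sim.t[mask]
    X = sim.feature_variable[:, mask]
    scale = float(np.ptp(X))

    counts = np.zeros(sim.N, dtype=int)
    all_pk: list[np.ndarray] = []
    for i in range(sim.N):
        pk = peak_times(t, X[i], scale=scale)
        counts[i] = len(pk)
        all_pk.append(pk)

    P_bar = float(counts.mean())
    P_bar_k = {
        k: float(counts[partition.labels == k].mean())
        for k in range(1, partition.K + 1)
    }

    osc = counts >= 2
    n_osc = int(osc.sum())

    def r_over(node_idx: np.ndarray) -> tuple[float, bool]:
        sel = node_idx[osc[node_idx]]
        if len(sel) < 2 or len(sel) < MIN_OSCILLATING_FRACTION * len(node_idx):
            return 0.0, False
        phases = np.array([phase_from_peaks(t, all_pk[i]) for i in sel])
        r_bar, _ = kuramoto_R(phases)
        return r_bar, True

    all_idx = np.arange(sim.N)
    R_bar, defined = r_over(all_idx)
    R_bar_k = {}
    for k in range(1, partition.K + 1):
        R_bar_k[k], _ = r_over(np.flatnonzero(partition.labels == k))

    var = "V" if sim.kind == "fhn" else "c"
    return FeatureSummary(
        P_bar=P_bar,
        P_bar_k=P_bar_k,
        R_bar=R_bar,
        R_bar_k=R_bar_k,
        n_oscillating=n_osc,
        feature_variable=var,
        synchrony_defined=defined,
    )


def interburst_intervals(
    t: np.ndarray,
    V: np.ndarray,
    spike_threshold: Optional[float] = None,
) -> np.ndarray:
    """Silent gaps between successive bursts of a voltage trace.

    Active episodes are contiguous stretches above ``spike_threshold``
    (default: the midpoint of the voltage range); the gaps between the
    end of one episode and the start of the next are the candidate
    silent phases.  Only gaps exceeding half the longest gap are kept,
    which discards the short intra-burst inter-spike gaps when bursts
    contain several spikes and keeps every gap when each active episode
    is a single event.
    """
    V = np.asarray(V, dtype=float)
    if spike_threshold is None:
        spike_threshold = 0.5 * (V.min() + V.max())
    above = V >= spike_threshold
    ups = np.flatnonzero(~above[:-1] & above[1:])
    downs = np.flatnonzero(above[:-1] & ~above[1:])
    if len(ups) < 2 or len(downs) == 0:
        return np.array([])
    gaps = []
    for d in t[downs]:
        nxt = t[ups][t[ups] > d]
        if len(nxt):
            gaps.append(nxt[0] - d)
    gaps = np.asarray(gaps)
    if len(gaps) == 0:
        return np.array([])
    return gaps[gaps > 0.5 * gaps.max()]
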