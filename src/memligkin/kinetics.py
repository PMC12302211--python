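"""Binding/unbinding events and maximum-likelihood rate constants.

The complex count n_RL(t) of the reversible reaction R + L <=> RL is
treated as a continuously observed birth-death process.  For observed
bind/unbind event counts N_b, N_u the maximum-likelihood estimators are

    k_on  = N_b / Integral[ n_R(t) n_L(t) / V dt ]
    k_off = N_u / Integral[ n_RL(t) dt ]
    K     = k_on / k_off

with Poisson (Fisher-information) standard errors sqrt(N)/Integral and a
delta-method error on K.  Event traces from exact stochastic simulation
carry the exact piecewise-constant integrals; traces sampled at frames use
trapezoidal accumulation.

Binding events are detected with two-threshold hysteresis: a site pair
becomes bound when its distance first drops below ``r_on`` and unbound when
it first exceeds ``r_off`` (r_on < r_off), which suppresses rapid
recrossing noise at the well edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ParticleSystem, Topology


class UndefinedEstimateError(RuntimeError):
    """Raised when an exposure integral is zero and the MLE is undefined."""


@dataclass
class EventTrace:
    """Time series of the complex count and per-pair bound states.

    ``kind = "events"``: exact event trace, ``n_rl[k]`` holds on
    [times[k], times[k+1]).  ``kind = "frames"``: sampled trajectory,
    integrals use the trapezoidal rule.
    """

    times: np.ndarray
    n_rl: np.ndarray
    n_receptors: int
    n_ligands: int
    volume: float
    n_bind_events: int
    n_unbind_events: int
    kind: str = "events"
    pair_bound: np.ndarray | None = None  # (M, nR, nL) bool, frames only

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.n_rl = np.asarray(self.n_rl, dtype=np.float64)
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.kind not in ("events", "frames"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")

    @property
    def n_r_free(self) -> np.ndarray:
        return self.n_receptors - self.n_rl

    @property
    def n_l_free(self) -> np.ndarray:
        return self.n_ligands - self.n_rl

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def _integrate(self, values: np.ndarray) -> float:
        if self.kind == "events":
            dt = np.diff(self.times)
            return float(np.sum(values[:-1] * dt))
        return float(np.trapezoid(values, self.times))

    @property
    def exposure_integral(self) -> float:
        """Integral of n_R_free * n_L_free / V dt (units tau0/sigma0^3)."""
        return self._integrate(self.n_r_free * self.n_l_free) / self.volume

    @property
    def complex_time_integral(self) -> float:
        """Integral of n_RL dt (units tau0)."""
        return self._integrate(self.n_rl)

    def restricted(self, t0: float, t1: float) -> "EventTrace":
        """Sub-trace on [t0, t1] (frames kind only; events not recounted)."""
        m = (self.times >= t0) & (self.times <= t1)
        return EventTrace(self.times[m], self.n_rl[m], self.n_receptors,
                          self.n_ligands, self.volume,
                          self.n_bind_events, self.n_unbind_events,
                          self.kind,
                          None if self.pair_bound is None else self.pair_bound[m])


@dataclass
class RateEstimate:
    """ML rate constants with Poisson standard errors.

    ``kon`` in sigma0^3/tau0, ``koff`` in 1/tau0, ``K = kon/koff`` in
    sigma0^3.  ``koff_defined`` is False when no unbinding event was seen;
    K is then not reported (nan).
    """

    kon: float
    koff: float
    K: float
    se_kon: float
    se_koff: float
    se_K: float
    n_bind_events: int
    n_unbind_events: int
    integral_rl_exposure: float
    integral_complex_time: float
    kon_defined: bool = True
    koff_defined: bool = True


def site_distances(system_or_positions, topology: Topology, box=None) -> np.ndarray:
    """(nR, nL) matrix of minimum-image site-site distances for one frame."""
    if isinstance(system_or_positions, ParticleSystem):
        pos = system_or_positions.positions
        box = system_or_positions.box
    else:
        pos = np.asarray(system_or_positions)
    sr = pos[topology.site_r_indices]
    sl = pos[topology.site_l_indices]
    dv = sl[None, :, :] - sr[:, None, :]
    dv = box.min_image(dv)
    return np.linalg.norm(dv, axis=-1)


def detect_events(times: np.ndarray, distances: np.ndarray,
                  r_on: float, r_off: float, volume: float) -> EventTrace:
    """Two-threshold event detection on per-pair distance series.

    Parameters
    ----------
    times : (M,) frame times
    distances : (M, nR, nL) site-site distances per frame
    r_on, r_off : hysteresis thresholds, r_on < r_off
    volume : box volume used for the volumetric concentration convention
    """
    if r_on >= r_off:
        raise ValueError(f"need r_on < r_off, got {r_on} >= {r_off}")
    times = np.asarray(times, dtype=np.float64)
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim == 1:  # single-pair convenience
        d = d.reshape(-1, 1, 1)
    elif d.ndim == 2:  # (M, nR) with one ligand
        d = d.reshape(d.shape[0], d.shape[1], 1)
    m, n_r, n_l = d.shape
    bound = d[0] < r_on  # initial state from the first frame
    pair_bound = np.empty((m, n_r, n_l), dtype=bool)
    pair_bound[0] = bound
    n_bind = 0
    n_unbind = 0
    for k in range(1, m):
        dk = d[k]
        newly_bound = (~bound) & (dk < r_on)
        newly_unbound = bound & (dk > r_off)
        n_bind += int(np.sum(newly_bound))
        n_unbind += int(np.sum(newly_unbound))
        bound = (bound | newly_bound) & ~newly_unbound
        pair_bound[k] = bound
    n_rl = pair_bound.sum(axis=(1, 2)).astype(np.float64)
    return EventTrace(times, n_rl, n_r, n_l, volume,
                      n_bind, n_unbind, kind="frames",
                      pair_bound=pair_bound)


def detect_events_frames(frame_times, frame_positions, topology: Topology,
                         box, r_on: float = 1.2, r_off: float = 2.0
                         ) -> EventTrace:
    """Event detection straight from trajectory coordinate frames."""
    dists = np.stack([
        site_distances(p, topology, box) for p in frame_positions])
    return detect_events(np.asarray(frame_times), dists, r_on, r_off,
                         box.volume)


def estimate_rates(trace: EventTrace) -> RateEstimate:
    """Maximum-likelihood rate constants from an event trace."""
    expo = trace.exposure_integral
    ctime = trace.complex_time_integral
    n_b = trace.n_bind_events
    n_u = trace.n_unbind_events
    if expo <= 0 and ctime <= 0:
        raise UndefinedEstimateError("zero exposure and zero complex time")
    kon_defined = expo > 0
    koff_defined = ctime > 0 and n_u > 0
    kon = n_b / expo if kon_defined else float("nan")
    se_kon = np.sqrt(max(n_b, 1)) / expo if kon_defined else float("nan")
    koff = n_u / ctime if koff_defined else float("nan")
    se_koff = np.sqrt(max(n_u, 1)) / ctime if koff_defined else float("nan")
    if kon_defined and koff_defined and n_b > 0:
        K = kon / koff
        se_K = K * np.sqrt(1.0 / n_b + 1.0 / n_u)
    else:
        K = float("nan")
        se_K = float("nan")
    return RateEstimate(kon, koff, K, se_kon, se_koff, se_K,
                        n_b, n_u, expo, ctime,
                        kon_defined=kon_defined, koff_defined=koff_defined)


@dataclass
class RateRatios:
    """Membrane constants rescaled by the soluble-reference constants."""

    K_ratio: float
    kon_ratio: float
    koff_ratio: float
    se_K_ratio: float
    se_kon_ratio: float
    se_koff_ratio: float


def rescale_against_reference(membrane: RateEstimate,
                              soluble: RateEstimate) -> RateRatios:
    """Elementwise (K, kon, koff) ratios with delta-method uncertainties."""
    for est, label in ((membrane, "membrane"), (soluble, "soluble")):
        if not (est.kon_defined and est.koff_defined):
            raise UndefinedEstimateError(
                f"{label} estimate has undefined components")
    def ratio(a, sa, b, sb):
        r = a / b
        return r, abs(r) * np.sqrt((sa / a) ** 2 + (sb / b) ** 2)
    k, se_k = ratio(membrane.K, membrane.se_K, soluble.K, soluble.se_K)
    kon, se_kon = ratio(membrane.kon, membrane.se_kon,
                        soluble.kon, soluble.se_kon)
    koff, se_koff = ratio(membrane.koff, membrane.se_koff,
                          soluble.koff, soluble.se_koff)
    return RateRatios(k, kon, koff, se_k, se_kon, se_koff)


def concentrations(trace: EventTrace) -> tuple[float, float, float]:
    """Time-averaged volumetric concentrations ([RL], [R], [L]) in sigma0^-3.

    The full box volume is used in membrane systems too, so K carries
    volume units in both system types and membrane/soluble ratios are
    dimensionless.
    """
    T = trace.duration
    if T <= 0:
        n = trace.n_rl[0] if len(trace.n_rl) else 0.0
        return (n / trace.volume,
                (trace.n_receptors - n) / trace.volume,
                (trace.n_ligands - n) / trace.volume)
    mean_rl = trace._integrate(trace.n_rl) / T
    return (mean_rl / trace.volume,
            (trace.n_receptors - mean_rl) / trace.volume,
            (trace.n_ligands - mean_rl) / trace.volume)


def occupancy_equilibrium_constant(trace: EventTrace) -> float:
    """K from time-averaged concentrations, [RL]/([R][L]); the
    detailed-balance cross-check of the kinetic kon/koff estimate."""
    c_rl, c_r, c_l = concentrations(trace)
    if c_r <= 0 or c_l <= 0:
        raise UndefinedEstimateError("no free receptors or ligands on average")
    return c_rl / (c_r * c_l)


def bootstrap_rates(trace: EventTrace, n_blocks: int = 20,
                    n_boot: int = 200, seed: int = 0) -> dict[str, float]:
    """Stationary block bootstrap SEs for correlated frame traces.

    Splits the trace into ``n_blocks`` contiguous time blocks, resamples
    blocks with replacement and re-estimates the rates; returns the spread
    of the bootstrap distribution for kon, koff and K.
    """
    if trace.kind != "frames" or trace.pair_bound is None:
        raise ValueError("block bootstrap needs a frame trace with pair states")
    m = len(trace.times)
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    rng = np.random.default_rng(seed)
    samples = {"kon": [], "koff": [], "K": []}
    dt = np.median(np.diff(trace.times))
    for _ in range(n_boot):
        picks = rng.integers(0, n_blocks, size=n_blocks)
        nb = nu = 0
        expo = ctime = 0.0
        for p in picks:
            sl = slice(edges[p], edges[p + 1])
            pb = trace.pair_bound[sl]
            if len(pb) < 2:
                continue
            trans = pb[1:].astype(int) - pb[:-1].astype(int)
            nb += int(np.sum(trans == 1))
            nu += int(np.sum(trans == -1))
            n_rl = pb.sum(axis=(1, 2))
            nfree = (trace.n_receptors - n_rl) * (trace.n_ligands - n_rl)
            expo += float(np.sum(nfree)) * dt / trace.volume
            ctime += float(np.sum(n_rl)) * dt
        if nb > 0 and expo > 0:
            samples["kon"].append(nb / expo)
        if nu > 0 and ctime > 0:
            samples["koff"].append(nu / ctime)
        if nb > 0 and nu > 0 and expo > 0 and ctime > 0:
            samples["K"].append((nb / expo) / (nu / ctime))
    return {k: float(np.std(v)) if v else float("nan")
            for k, v in samples.items()}
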