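"""Structural observables: in-plane pair correlation of receptor sites,
ectodomain end-to-end distance before/after binding, binding-geometry
histograms, and the undulation-spectrum bending rigidity.

The bending rigidity kappa of a tensionless quasi-planar membrane follows
from the thermal height-fluctuation spectrum <|h_q|^2> = kBT/(A kappa q^4),
with h_q the discrete Fourier amplitude (FFT/N convention) of the gridded
midplane height field and A the projected membrane area.  The fit window
is restricted to q <= 2*pi/5 sigma0^-1, below the scale where lipid
protrusion modes dominate over bending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import HEAD, Topology


class EmptyResultError(RuntimeError):
    """No samples available for the requested observable."""


@dataclass
class HistogramResult:
    """Normalized density histogram with per-bin standard errors."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int
    se: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


def make_histogram(samples: np.ndarray, bins=50, range=None) -> HistogramResult:
    """Density-normalized histogram; SE per bin from multinomial counting."""
    samples = np.asarray(samples, dtype=float)
    n = len(samples)
    if n == 0:
        raise EmptyResultError("no samples to histogram")
    counts, edges = np.histogram(samples, bins=bins, range=range)
    widths = np.diff(edges)
    n_in = counts.sum()
    density = counts / (n_in * widths)
    p = counts / n_in
    se = np.sqrt(np.maximum(p * (1 - p), 0.0) / n_in) / widths
    return HistogramResult(edges, density, n, se)


# ---------------------------------------------------------------------------
# pair correlation
# ---------------------------------------------------------------------------

@dataclass
class PairCorrelationResult:
    r: np.ndarray
    g: np.ndarray
    se: np.ndarray
    n_frames: int


def pair_correlation_2d(frames_positions, site_indices, box,
                        bins: int = 40, r_max: float | None = None
                        ) -> PairCorrelationResult:
    """In-plane (x-y projected) pair correlation g(r) of tagged sites.

    Normalized per frame by the ideal-gas pair count n(n-1)/2 * 2*pi*r*dr/A;
    averaged over frames with the frame-to-frame scatter as the error bar.
    """
    site_indices = np.asarray(site_indices, dtype=np.int64)
    n = len(site_indices)
    if n < 2:
        raise ValueError("need at least 2 tagged sites for g(r)")
    Lx, Ly = box.lengths[0], box.lengths[1]
    if r_max is None:
        r_max = 0.5 * min(Lx, Ly)
    edges = np.linspace(0.0, r_max, bins + 1)
    area = Lx * Ly
    shell = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    n_pairs = n * (n - 1) / 2.0
    ideal = n_pairs * shell / area
    per_frame = []
    for pos in frames_positions:
        p = np.asarray(pos)[site_indices, :2]
        dv = p[None, :, :] - p[:, None, :]
        dv[..., 0] -= Lx * np.round(dv[..., 0] / Lx)
        dv[..., 1] -= Ly * np.round(dv[..., 1] / Ly)
        rr = np.sqrt(np.sum(dv * dv, axis=-1))
        iu = np.triu_indices(n, k=1)
        counts, _ = np.histogram(rr[iu], bins=edges)
        per_frame.append(counts / ideal)
    per_frame = np.array(per_frame)
    g = per_frame.mean(axis=0)
    m = len(per_frame)
    if m > 1:
        se = per_frame.std(axis=0, ddof=1) / math.sqrt(m)
    else:  # single frame: Poisson counting error
        se = np.sqrt(np.maximum(per_frame[0] * ideal, 1.0)) / ideal / math.sqrt(1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PairCorrelationResult(centers, g, se, m)


# ---------------------------------------------------------------------------
# end-to-end distance and binding geometry
# ---------------------------------------------------------------------------

def gr_crossover(result: PairCorrelationResult, threshold: float = 0.95,
                 smooth: int = 3, r_min: float = 1.0) -> float:
    """Depletion-zone crossover: smallest r beyond ``r_min`` where the
    running-mean-smoothed g(r) first recovers to ``threshold``.

    Smoothing over a few bins keeps single noisy bins from faking an
    early crossover."""
    g = np.convolve(result.g, np.ones(smooth) / smooth, mode="same")
    for rr, gg in zip(result.r, g):
        if rr > r_min and gg >= threshold:
            return float(rr)
    return float("nan")


def end_to_end_samples(frames_positions, topology: Topology, box,
                       bound_per_receptor: np.ndarray | None = None,
                       which: str = "all") -> np.ndarray:
    """R_e samples (first ectodomain bead to site bead) over frames.

    ``bound_per_receptor``: (n_frames, n_receptors) bool from the event
    detector's hysteresis states; ``which`` in {"all", "before_binding",
    "after_binding"} selects unbound/bound receptor-frames.
    """
    if which not in ("all", "before_binding", "after_binding"):
        raise ValueError(f"unknown selection {which!r}")
    first = np.array([r.ecd[0] for r in topology.receptors], dtype=np.int64)
    sites = topology.site_r_indices
    out = []
    for fi, pos in enumerate(frames_positions):
        p = np.asarray(pos)
        dv = box.min_image(p[sites] - p[first])
        re = np.linalg.norm(dv, axis=1)
        if which == "all" or bound_per_receptor is None:
            out.append(re)
        elif which == "after_binding":
            out.append(re[bound_per_receptor[fi]])
        else:
            out.append(re[~bound_per_receptor[fi]])
    return np.concatenate(out) if out else np.zeros(0)


def end_to_end(frames_positions, topology: Topology, box,
               bound_per_receptor: np.ndarray | None = None,
               which: str = "all", bins: int = 40,
               range=None) -> HistogramResult:
    """Histogram of the receptor ectodomain end-to-end distance R_e."""
    samples = end_to_end_samples(frames_positions, topology, box,
                                 bound_per_receptor, which)
    return make_histogram(samples, bins=bins, range=range)


def binding_geometry_samples(frames_positions, topology: Topology, box,
                             pair_bound: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(theta1, theta2, r) samples over bound receptor-ligand pairs.

    Angle conventions match the binding potential: theta1 between the
    receptor's terminal-bond axis and the inter-site vector (own site ->
    partner site); theta2 likewise for the ligand.
    """
    sr = topology.site_r_indices
    sl = topology.site_l_indices
    ar = topology.axis_r_indices
    al = topology.axis_l_indices
    th1, th2, rr = [], [], []
    for fi, pos in enumerate(frames_positions):
        p = np.asarray(pos)
        bound = np.argwhere(pair_bound[fi])
        for i, j in bound:
            a = box.min_image(p[sr[i]] - p[ar[i]])
            b = box.min_image(p[sl[j]] - p[al[j]])
            d = box.min_image(p[sl[j]] - p[sr[i]])
            r = np.linalg.norm(d)
            if r <= 0:
                continue
            c1 = np.dot(a, d) / (np.linalg.norm(a) * r)
            c2 = -np.dot(b, d) / (np.linalg.norm(b) * r)
            th1.append(math.acos(max(-1.0, min(1.0, c1))))
            th2.append(math.acos(max(-1.0, min(1.0, c2))))
            rr.append(r)
    return np.array(th1), np.array(th2), np.array(rr)


def binding_geometry(frames_positions, topology: Topology, box,
                     pair_bound: np.ndarray, bins: int = 30
                     ) -> tuple[HistogramResult, HistogramResult, HistogramResult]:
    """Histograms of (theta1, theta2, r) restricted to bound intervals."""
    th1, th2, rr = binding_geometry_samples(
        frames_positions, topology, box, pair_bound)
    if len(rr) == 0:
        raise EmptyResultError("no bound frames")
    h1 = make_histogram(th1, bins=bins, range=(0.0, math.pi / 2))
    h2 = make_histogram(th2, bins=bins, range=(0.0, math.pi / 2))
    hr = make_histogram(rr, bins=bins)
    return h1, h2, hr


# ---------------------------------------------------------------------------
# undulation spectrum
# ---------------------------------------------------------------------------

Q_PROTRUSION_CROSSOVER = 2.0 * math.pi / 5.0  # sigma0^-1


@dataclass
class SpectrumResult:
    q: np.ndarray             # mode magnitudes used in the fit, sigma0^-1
    s_q: np.ndarray           # <|h_q|^2> per mode, sigma0^2
    kappa: float              # bending rigidity in kBT units
    kappa_se: float
    fit_q_max: float
    n_frames: int
    sigma_tension: float = 0.0  # fitted residual tension, kBT/sigma0^2
    rigid_limit: bool = False


def _gridded_mean_z(p: np.ndarray, box, grid: int) -> np.ndarray:
    """Mean z per x-y cell; empty cells filled with the global mean."""
    Lx, Ly = box.lengths[0], box.lengths[1]
    ix = np.clip((p[:, 0] % Lx) / Lx * grid, 0, grid - 1e-9).astype(int)
    iy = np.clip((p[:, 1] % Ly) / Ly * grid, 0, grid - 1e-9).astype(int)
    total = np.zeros((grid, grid))
    count = np.zeros((grid, grid))
    np.add.at(total, (ix, iy), p[:, 2])
    np.add.at(count, (ix, iy), 1.0)
    mean_z = p[:, 2].mean()
    return np.where(count > 0, total / np.maximum(count, 1), mean_z)


def _leaflet_heads(pos: np.ndarray, topology: Topology, box
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Head-bead indices of the upper and lower leaflet (a lipid belongs
    to the upper leaflet when its head sits above its second tail bead)."""
    heads = topology.lipids[:, 0]
    tails2 = topology.lipids[:, 2]
    dz = pos[heads, 2] - pos[tails2, 2]
    Lz = box.lengths[2]
    if box.periodic[2]:
        dz = dz - Lz * np.round(dz / Lz)
    upper = dz > 0
    return heads[upper], heads[~upper]


def _split_fields(pos: np.ndarray, groups: list[np.ndarray], box, grid: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Two independent height fields from alternating half-samples of each
    bead group; their cross-spectrum is free of bead-sampling noise."""
    halves = ([], [])
    for g in groups:
        halves[0].append(g[0::2])
        halves[1].append(g[1::2])
    fields = []
    for half in halves:
        per_group = [_gridded_mean_z(pos[h], box, grid)
                     if len(h) else np.zeros((grid, grid))
                     for h in half]
        f = np.mean(per_group, axis=0)
        fields.append(f - f.mean())
    return fields[0], fields[1]


def _direct_cross_spectrum(frames, box, topology: Topology,
                           fit_q_max: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Cross-spectrum of the midplane height from direct Fourier sums
    (1/N)*sum_i (z_i - z_leaflet_mean) exp(-i q.r_i) over two alternating
    half-samples of the head beads, at the box-commensurate wavevectors
    with |q| <= fit_q_max.  The two halves carry independent bead-sampling
    noise, so the cross-spectrum estimates the underlying height spectrum
    without the white noise floor."""
    Lx, Ly = box.lengths[0], box.lengths[1]
    pairs = []
    nmax_x = int(fit_q_max * Lx / (2.0 * math.pi)) + 1
    nmax_y = int(fit_q_max * Ly / (2.0 * math.pi)) + 1
    seen = set()
    for nx in range(-nmax_x, nmax_x + 1):
        for ny in range(-nmax_y, nmax_y + 1):
            if (nx, ny) == (0, 0) or (-nx, -ny) in seen:
                continue
            q = math.hypot(2.0 * math.pi * nx / Lx, 2.0 * math.pi * ny / Ly)
            if q <= fit_q_max:
                seen.add((nx, ny))
                pairs.append((2.0 * math.pi * nx / Lx,
                              2.0 * math.pi * ny / Ly))
    if not pairs:
        raise ValueError("no Fourier modes inside the fit window; "
                         "use a larger membrane")
    qv = np.array(pairs)
    qmag = np.linalg.norm(qv, axis=1)
    acc = np.zeros(len(qv))
    n_frames = 0
    for pos in frames:
        pos = np.asarray(pos)
        up, dn = _leaflet_heads(pos, topology, box)
        halves = []
        for half in (0, 1):
            val = np.zeros(len(qv), dtype=complex)
            for leaflet in (up, dn):
                g = leaflet[half::2]
                z = pos[g, 2] - pos[g, 2].mean()
                phase = np.exp(-1j * (qv[:, :1] @ pos[None, g, 0]
                                      + qv[:, 1:] @ pos[None, g, 1]))
                val += (phase * z[None, :]).mean(axis=1)
            halves.append(val / 2.0)
        acc += np.real(halves[0] * np.conj(halves[1]))
        n_frames += 1
    return qmag, acc / n_frames


def height_field(positions: np.ndarray, box, grid: int,
                 head_indices: np.ndarray | None = None,
                 topology: Topology | None = None) -> np.ndarray:
    """Gridded midplane height field, global mean subtracted.

    With a membrane topology, the two leaflets are gridded separately
    (mixing leaflets in one cell would alias the +-half-thickness head
    offsets into spurious height noise) and averaged.  With plain
    ``head_indices`` (e.g. synthetic surfaces) a single field is used.
    """
    pos = np.asarray(positions)
    if topology is not None and len(topology.lipids):
        up, dn = _leaflet_heads(pos, topology, box)
        h = 0.5 * (_gridded_mean_z(pos[up], box, grid)
                   + _gridded_mean_z(pos[dn], box, grid))
    else:
        if head_indices is None:
            raise ValueError("need head_indices or a membrane topology")
        h = _gridded_mean_z(pos[head_indices], box, grid)
    return h - h.mean()


def undulation_spectrum(frames_positions, box, grid: int = 16,
                        topology: Topology | None = None,
                        head_indices: np.ndarray | None = None,
                        fit_q_max: float = Q_PROTRUSION_CROSSOVER
                        ) -> SpectrumResult:
    """Bending rigidity from the q^-4 height-fluctuation spectrum.

    In kBT units the tensionless spectrum is <|h_q|^2> = 1/(A kappa q^4);
    with a residual frame tension sigma the inverse spectrum is
    1/(A <|h_q|^2>) = sigma q^2 + kappa q^4, so a straight-line fit of
    1/(A q^2 S) against q^2 yields (sigma, kappa) jointly and the rigidity
    is unbiased by imperfect tension relaxation.  The spectrum itself is
    the CROSS-spectrum of two height fields built from alternating
    half-samples of the head beads: the finite-bead-sampling noise of the
    gridded field is independent between the halves and cancels, which
    matters because that white noise floor would otherwise swamp the
    q^-4 signal in the upper fit window.  A cell-average (pixel) window
    deconvolution makes the result independent of grid resolution.
    """
    if topology is not None and topology.shape not in ("quasi_planar", ""):
        raise ValueError(
            "undulation spectrum requires a quasi-planar membrane, "
            f"got {topology.shape!r}")
    if topology is None and head_indices is None:
        raise ValueError("need a topology or explicit head_indices")
    frames = list(frames_positions)
    if len(frames) == 0:
        raise EmptyResultError("no frames")
    Lx, Ly = box.lengths[0], box.lengths[1]
    area = Lx * Ly
    if topology is not None and len(topology.lipids):
        # direct (grid-free) nonuniform Fourier sums over head beads; a
        # gridded field at the bead densities reachable here leaves many
        # cells empty per half-sample and biases the spectrum downward
        q_used, s_used = _direct_cross_spectrum(frames, box, topology,
                                                fit_q_max)
    else:
        acc = np.zeros((grid, grid))
        for pos in frames:
            pos = np.asarray(pos)
            h1, h2 = _split_fields(pos, [np.asarray(head_indices)], box,
                                   grid)
            f1 = np.fft.fft2(h1) / (grid * grid)
            f2 = np.fft.fft2(h2) / (grid * grid)
            acc += np.real(f1 * np.conj(f2))
        s_q = acc / len(frames)
        qx = 2.0 * math.pi * np.fft.fftfreq(grid, d=Lx / grid)
        qy = 2.0 * math.pi * np.fft.fftfreq(grid, d=Ly / grid)
        qmag = np.sqrt(qx[:, None] ** 2 + qy[None, :] ** 2)
        # deconvolve the cell-average (pixelization) window so the fit is
        # independent of grid resolution
        window = (np.sinc(qx[:, None] * (Lx / grid) / (2.0 * math.pi)) ** 2
                  * np.sinc(qy[None, :] * (Ly / grid) / (2.0 * math.pi)) ** 2)
        mask = (qmag > 1e-12) & (qmag <= fit_q_max) & (window > 0.5)
        if not np.any(mask):
            raise ValueError("no Fourier modes inside the fit window; "
                             "increase the grid or the box")
        q_used = qmag[mask]
        s_used = s_q[mask] / window[mask]
    pos_ok = s_used > 0
    if pos_ok.sum() < 3:
        return SpectrumResult(q_used, s_used, math.inf, math.inf,
                              fit_q_max, len(frames), rigid_limit=True)
    # weighted straight-line fit: y = sigma + kappa*q^2,
    # y = 1/(A q^2 S); two passes to set the weights self-consistently
    x = q_used[pos_ok] ** 2
    y = 1.0 / (area * x * s_used[pos_ok])
    w = np.ones_like(y)
    for _ in range(2):
        W = np.sum(w)
        xb = np.sum(w * x) / W
        yb = np.sum(w * y) / W
        kappa = float(np.sum(w * (x - xb) * (y - yb))
                      / np.sum(w * (x - xb) ** 2))
        sigma = float(yb - kappa * xb)
        w = 1.0 / np.maximum(sigma + kappa * x, 1e-12) ** 2
    resid = y - (sigma + kappa * x)
    dof = max(len(x) - 2, 1)
    kappa_se = float(np.sqrt(np.sum(w * resid ** 2) / dof
                             / np.sum(w * (x - np.sum(w * x) / np.sum(w))
                                      ** 2)))
    if kappa <= 0 or not np.isfinite(kappa):
        return SpectrumResult(q_used, s_used, math.inf, math.inf,
                              fit_q_max, len(frames), rigid_limit=True)
    return SpectrumResult(q_used, s_used, kappa, kappa_se,
                          fit_q_max, len(frames), sigma_tension=sigma)


def synthetic_undulation_frames(n_frames: int, grid: int, box_length: float,
                                kappa: float,
                                seed: int = 0) -> list[np.ndarray]:
    """Gaussian surfaces drawn from the q^-4 spectrum (spectral oracle).

    ``kappa`` is the rigidity in kBT units.  Returns frames of (grid^2, 3)
    node positions on a regular x-y lattice whose z heights have exactly
    <|h_q|^2> = 1/(A kappa q^4) in the same FFT/N amplitude convention as
    :func:`undulation_spectrum`.  Generate at several times the analysis
    grid so that cell averaging in the estimator mimics a continuum
    membrane (the estimator deconvolves the pixel window).
    """
    rng = np.random.default_rng(seed)
    L = box_length
    area = L * L
    qx = 2.0 * math.pi * np.fft.fftfreq(grid, d=L / grid)
    qmag = np.sqrt(qx[:, None] ** 2 + qx[None, :] ** 2)
    with np.errstate(divide="ignore"):
        var = np.where(qmag > 1e-12, 1.0 / (area * kappa * qmag ** 4), 0.0)
    xs = (np.arange(grid) + 0.5) * L / grid
    xy = np.stack(np.meshgrid(xs, xs, indexing="ij"), axis=-1).reshape(-1, 2)
    frames = []
    n = grid * grid
    for _ in range(n_frames):
        w = rng.standard_normal((grid, grid))
        W = np.fft.fft2(w)          # <|W|^2> = n for white noise
        hq = W * np.sqrt(var / n)   # <|hq|^2> = var, hermitian by construction
        h = np.real(np.fft.ifft2(hq * n))
        frames.append(np.column_stack([xy, h.reshape(-1)]))
    return frames
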