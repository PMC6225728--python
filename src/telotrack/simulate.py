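"""Synthetic trajectory, movie and 3D-foci generators with known ground truth.

Every generator returns a :class:`~telotrack.models.GroundTruth` whose 2D
ensemble MSD obeys a closed form:

* ``simulate_brownian``:  MSD(t) = 4 D t
* ``simulate_fbm``:       MSD(t) = 4 D_alpha t^alpha  (exact fractional
  Brownian motion per axis, Hurst H = alpha / 2, generated by circulant
  embedding with a Cholesky fallback — not an Euler scheme)
* ``simulate_confined``:  MSD(t) = A (1 - e^(-t/tau)) + 4 D_macro t
  (stationary-start Ornstein-Uhlenbeck per axis plus an independent
  Brownian component, exact discrete-time updates)

Coordinates are in nm, time in s (see ``telotrack.models``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import erf

from .models import NM_PER_UM, AcquisitionConfig, GroundTruth, MotionModel

__all__ = [
    "simulate_brownian",
    "simulate_fbm",
    "simulate_confined",
    "add_drift",
    "render_movie",
    "make_nucleus_foci",
    "NucleusFociSample",
]


def _start_positions(n_traj: int, config: AcquisitionConfig, rng: np.random.Generator,
                     margin_px: float = 16.0) -> np.ndarray:
    """Uniform starts inside the field of view, away from the border (nm)."""
    h_nm, w_nm = config.field_nm
    m = margin_px * config.pixel_size
    x = rng.uniform(m, w_nm - m, size=n_traj)
    y = rng.uniform(m, h_nm - m, size=n_traj)
    return np.column_stack([x, y])


def _check_counts(n_traj: int) -> None:
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")


def simulate_brownian(n_traj: int, config: AcquisitionConfig, D: float,
                      seed: Optional[int] = None) -> GroundTruth:
    """Brownian trajectories with per-axis increment variance 2 D dt.

    D is in um^2/s; the 2D ensemble MSD is 4 D t.
    """
    _check_counts(n_traj)
    if D < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    starts = _start_positions(n_traj, config, rng)
    step_sd_nm = np.sqrt(2.0 * D * config.dt) * NM_PER_UM
    steps = rng.normal(0.0, step_sd_nm, size=(n_traj, config.n_frames - 1, 2))
    pos = np.concatenate(
        [starts[:, None, :], starts[:, None, :] + np.cumsum(steps, axis=1)], axis=1
    )
    motion = [MotionModel("brownian", D=D)] * n_traj
    return GroundTruth(pos, np.zeros((config.n_frames, 2)), motion, config.dt)


def _fgn_covariance(n_lags: int, hurst: float, dt: float, d_alpha: float) -> np.ndarray:
    """Autocovariance gamma(0..n_lags) of per-axis fGn increments, nm^2.

    Per-axis fBm variance at time t is 2 * d_alpha * t^(2H) um^2, so the
    increment covariance is d_alpha * dt^(2H) * (|k+1|^2H - 2|k|^2H + |k-1|^2H).
    """
    k = np.arange(n_lags + 1, dtype=float)
    two_h = 2.0 * hurst
    g = d_alpha * dt ** two_h * (
        np.abs(k + 1) ** two_h - 2.0 * np.abs(k) ** two_h + np.abs(k - 1) ** two_h
    )
    return g * NM_PER_UM ** 2


def _sample_fgn(n_series: int, n_inc: int, gamma: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Exact stationary Gaussian series with autocovariance ``gamma``.

    Davies-Harte circulant embedding; falls back to a Cholesky factorization
    of the full covariance matrix when the circulant spectrum is not
    nonnegative (possible for short series at extreme Hurst values).
    """
    m = 2 * n_inc
    circ = np.concatenate([gamma[: n_inc + 1], gamma[n_inc - 1:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() >= -1e-9 * max(lam.max(), 1.0):
        lam = np.clip(lam, 0.0, None)
        v = rng.standard_normal((n_series, m))
        w = rng.standard_normal((n_series, m))
        a = np.zeros((n_series, m), dtype=complex)
        a[:, 0] = np.sqrt(lam[0]) * v[:, 0]
        a[:, n_inc] = np.sqrt(lam[n_inc]) * v[:, n_inc]
        half = np.sqrt(lam[1:n_inc] / 2.0)
        a[:, 1:n_inc] = half * (v[:, 1:n_inc] + 1j * w[:, 1:n_inc])
        a[:, n_inc + 1:] = np.conj(a[:, n_inc - 1:0:-1])
        out = np.fft.fft(a, axis=1)[:, :n_inc].real / np.sqrt(m)
        return out
    # Cholesky fallback: O(n^2) memory, exact.
    idx = np.abs(np.subtract.outer(np.arange(n_inc), np.arange(n_inc)))
    cov = gamma[idx]
    chol = np.linalg.cholesky(cov + 1e-12 * gamma[0] * np.eye(n_inc))
    z = rng.standard_normal((n_series, n_inc))
    return z @ chol.T


def simulate_fbm(n_traj: int, config: AcquisitionConfig, D_alpha: float, alpha: float,
                 seed: Optional[int] = None) -> GroundTruth:
    """Exact fractional-Brownian trajectories with 2D ensemble MSD 4 D_alpha t^alpha.

    Each axis is an independent fBm with Hurst H = alpha/2 and variance
    2 D_alpha t^alpha; alpha = 1 reduces to Brownian motion with D = D_alpha.
    """
    _check_counts(n_traj)
    if not (0 < alpha <= 2):
        raise ValueError("alpha must lie in (0, 2]")
    if D_alpha < 0:
        raise ValueError("D_alpha must be >= 0")
    rng = np.random.default_rng(seed)
    starts = _start_positions(n_traj, config, rng)
    n_inc = config.n_frames - 1
    gamma = _fgn_covariance(n_inc, alpha / 2.0, config.dt, D_alpha)
    inc = _sample_fgn(2 * n_traj, n_inc, gamma, rng)
    inc = inc.reshape(n_traj, 2, n_inc).transpose(0, 2, 1)
    pos = np.concatenate(
        [starts[:, None, :], starts[:, None, :] + np.cumsum(inc, axis=1)], axis=1
    )
    motion = [MotionModel("fbm", D=D_alpha, alpha=alpha)] * n_traj
    return GroundTruth(pos, np.zeros((config.n_frames, 2)), motion, config.dt)


def simulate_confined(n_traj: int, config: AcquisitionConfig, A: float, tau: float,
                      D_macro: float, seed: Optional[int] = None) -> GroundTruth:
    """Confined + macroscopic diffusion: MSD(t) = A (1 - e^(-t/tau)) + 4 D_macro t.

    Per axis: a stationary Ornstein-Uhlenbeck process with stationary
    variance A/4 and relaxation time tau (exact discrete update, initialized
    from the stationary law so the MSD closed form holds from t = 0), plus an
    independent Brownian motion with coefficient D_macro.
    """
    _check_counts(n_traj)
    if A < 0:
        raise ValueError("A must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if D_macro < 0:
        raise ValueError("D_macro must be >= 0")
    rng = np.random.default_rng(seed)
    starts = _start_positions(n_traj, config, rng)
    n = config.n_frames
    sd_ou_nm = np.sqrt(A / 4.0) * NM_PER_UM
    rho = np.exp(-config.dt / tau)
    innov_sd = sd_ou_nm * np.sqrt(1.0 - rho ** 2)
    ou = np.zeros((n_traj, n, 2))
    if sd_ou_nm > 0:
        ou[:, 0, :] = rng.normal(0.0, sd_ou_nm, size=(n_traj, 2))
        innov = rng.normal(0.0, innov_sd, size=(n_traj, n - 1, 2))
        for k in range(1, n):
            ou[:, k, :] = rho * ou[:, k - 1, :] + innov[:, k - 1, :]
    bm_sd_nm = np.sqrt(2.0 * D_macro * config.dt) * NM_PER_UM
    bm = np.zeros((n_traj, n, 2))
    if bm_sd_nm > 0:
        bm[:, 1:, :] = np.cumsum(
            rng.normal(0.0, bm_sd_nm, size=(n_traj, n - 1, 2)), axis=1
        )
    pos = starts[:, None, :] + ou + bm
    motion = [MotionModel("confined", A=A, tau=tau, D_macro=D_macro)] * n_traj
    return GroundTruth(pos, np.zeros((n, 2)), motion, config.dt)


def add_drift(truth: GroundTruth, mode: str = "linear",
              velocity: Sequence[float] = (0.0, 0.0),
              amplitude: Sequence[float] = (0.0, 0.0),
              period: float = 60.0) -> GroundTruth:
    """Return a copy of ``truth`` with a deterministic whole-field drift added.

    mode "linear": offset(frame) = velocity * frame (velocity in nm/frame).
    mode "sine": offset(frame) = amplitude * sin(2 pi * frame * dt / period).
    The same offset is applied to every particle, matching what cell-center
    subtraction can remove.
    """
    frames = np.arange(truth.n_frames, dtype=float)
    if mode == "linear":
        drift = frames[:, None] * np.asarray(velocity, dtype=float)[None, :]
    elif mode == "sine":
        phase = 2.0 * np.pi * frames * truth.dt / period
        drift = np.sin(phase)[:, None] * np.asarray(amplitude, dtype=float)[None, :]
    else:
        raise ValueError("mode must be 'linear' or 'sine'")
    if drift.shape[1] != truth.ndim:
        raise ValueError("drift dimensionality must match trajectories")
    return GroundTruth(
        truth.positions + drift[None, :, :],
        truth.drift + drift,
        list(truth.motion),
        truth.dt,
    )


def _render_frame(positions_px: np.ndarray, amplitudes: np.ndarray,
                  shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Expected photon image: integrated-Gaussian spots on a zero background.

    Pixel (0, 0) is centred at coordinate (0.0, 0.0); each spot deposits
    ``amplitude`` photons in total.
    """
    img = np.zeros(shape, dtype=float)
    h, w = shape
    r = int(np.ceil(4.0 * sigma)) + 1
    s2 = sigma * np.sqrt(2.0)
    for (px, py), amp in zip(positions_px, amplitudes):
        x0, x1 = int(np.floor(px)) - r, int(np.floor(px)) + r + 1
        y0, y1 = int(np.floor(py)) - r, int(np.floor(py)) + r + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c, dtype=float)
        ys = np.arange(y0c, y1c, dtype=float)
        fx = 0.5 * (erf((xs + 0.5 - px) / s2) - erf((xs - 0.5 - px) / s2))
        fy = 0.5 * (erf((ys + 0.5 - py) / s2) - erf((ys - 0.5 - py) / s2))
        img[y0c:y1c, x0c:x1c] += amp * np.outer(fy, fx)
    return img


def render_movie(truth: GroundTruth, config: AcquisitionConfig,
                 seed: Optional[int] = None) -> np.ndarray:
    """Render ground-truth 2D paths into a (n_frames, H, W) float movie.

    Each frame is background + integrated-Gaussian spots (sigma =
    ``config.psf_sigma`` px, ``config.photon_scale`` photons per spot), with
    Poisson photon noise applied when ``photon_scale > 0`` and additive
    Gaussian read noise when ``read_noise > 0``.  Out-of-field particles are
    clipped into the field or dropped for that frame per
    ``config.edge_handling`` (with a warning either way).
    """
    if truth.ndim != 2:
        raise ValueError("render_movie expects 2D trajectories")
    if truth.n_frames != config.n_frames:
        raise ValueError("truth and config disagree on n_frames")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.image_shape
    amp = config.photon_scale if config.photon_scale > 0 else 1.0
    pos_px = truth.positions / config.pixel_size
    out_of_field = (
        (pos_px[..., 0] < 0) | (pos_px[..., 0] > w - 1)
        | (pos_px[..., 1] < 0) | (pos_px[..., 1] > h - 1)
    )
    if out_of_field.any():
        warnings.warn(
            f"{int(out_of_field.sum())} particle-frames leave the field of view "
            f"({config.edge_handling}ped)", stacklevel=2,
        )
    movie = np.empty((config.n_frames, h, w), dtype=float)
    for f in range(config.n_frames):
        p = pos_px[:, f, :].copy()
        if config.edge_handling == "drop":
            p = p[~out_of_field[:, f]]
        else:
            p[:, 0] = np.clip(p[:, 0], 0, w - 1)
            p[:, 1] = np.clip(p[:, 1], 0, h - 1)
        expected = config.background + _render_frame(
            p, np.full(len(p), amp), (h, w), config.psf_sigma
        )
        frame = expected
        if config.photon_scale > 0:
            frame = rng.poisson(expected).astype(float)
        if config.read_noise > 0:
            frame = frame + rng.normal(0.0, config.read_noise, size=frame.shape)
        movie[f] = frame
    return movie


def _uniform_in_sphere(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got) + 8, 3))
        keep = cand[np.einsum("ij,ij->i", cand, cand) <= radius ** 2]
        take = min(len(keep), n - got)
        pts[got:got + take] = keep[:take]
        got += take
    return pts


def _separated_points(n: int, radius: float, min_sep: float,
                      rng: np.random.Generator, max_tries: int = 20000) -> np.ndarray:
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "could not place foci with the requested separation; "
                "increase nucleus_radius or reduce n_foci"
            )
        cand = _uniform_in_sphere(1, radius, rng)[0]
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    return np.array(pts) if pts else np.empty((0, 3))


def _random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@dataclass
class NucleusFociSample:
    """Two-channel 3D foci fixture with planted truth labels.

    foci_a, foci_b : (n, 3) positions in nm.
    cluster_labels : per channel-A focus, planted cluster index (-1 = singleton).
    coloc_truth : per channel-A focus, True if a channel-B partner was planted.
    """

    foci_a: np.ndarray
    foci_b: np.ndarray
    cluster_labels: np.ndarray
    coloc_truth: np.ndarray
    nucleus_radius: float


def make_nucleus_foci(n_foci: int, nucleus_radius: float,
                      aggregate_spec: Optional[dict] = None,
                      coloc_spec: Optional[dict] = None,
                      seed: Optional[int] = None) -> NucleusFociSample:
    """Place ``n_foci`` channel-A foci in a sphere with planted structure.

    aggregate_spec : {"sizes": [2, 2, 3, ...], "distance_nm": d} — plants
        clusters whose consecutive members are exactly ``d`` apart; the
        remaining foci are isolated singletons (pairwise separation at least
        3x the cluster distance so planted counts are unambiguous).
    coloc_spec : {"fraction": f, "offset_nm": o[, "clearance_nm": c]} — a
        channel B of equal size is created; round(f * n) of its foci sit at
        distance ``o`` from distinct A foci, the rest are placed at least
        ``c`` (default 4*o, min 500 nm) from every A focus.
    """
    if n_foci < 0:
        raise ValueError("n_foci must be >= 0")
    rng = np.random.default_rng(seed)
    sizes = list((aggregate_spec or {}).get("sizes", []))
    distance = float((aggregate_spec or {}).get("distance_nm", 0.0))
    if any(s < 2 for s in sizes):
        raise ValueError("cluster sizes must be >= 2")
    n_clustered = sum(sizes)
    if n_clustered > n_foci:
        raise ValueError("aggregate_spec requests more clustered foci than n_foci")
    n_singleton = n_foci - n_clustered
    n_anchors = len(sizes) + n_singleton
    min_sep = max(3.0 * distance, 500.0)
    anchors = _separated_points(n_anchors, nucleus_radius, min_sep, rng)

    foci: list[np.ndarray] = []
    labels: list[int] = []
    for ci, size in enumerate(sizes):
        anchor = anchors[ci]
        foci.append(anchor)
        labels.append(ci)
        prev = anchor
        for _ in range(size - 1):
            prev = prev + distance * _random_unit_vectors(1, rng)[0]
            foci.append(prev)
            labels.append(ci)
    for si in range(n_singleton):
        foci.append(anchors[len(sizes) + si])
        labels.append(-1)
    foci_a = np.array(foci) if foci else np.empty((0, 3))
    cluster_labels = np.asarray(labels, dtype=int)

    coloc_truth = np.zeros(n_foci, dtype=bool)
    foci_b = np.empty((0, 3))
    if coloc_spec is not None and n_foci > 0:
        frac = float(coloc_spec["fraction"])
        offset = float(coloc_spec["offset_nm"])
        clearance = float(coloc_spec.get("clearance_nm", max(4.0 * offset, 500.0)))
        if not (0.0 <= frac <= 1.0):
            raise ValueError("coloc fraction must lie in [0, 1]")
        n_match = int(round(frac * n_foci))
        matched = rng.choice(n_foci, size=n_match, replace=False)
        coloc_truth[matched] = True
        b = [foci_a[i] + offset * _random_unit_vectors(1, rng)[0] for i in matched]
        tries = 0
        while len(b) < n_foci:
            tries += 1
            if tries > 20000:
                raise ValueError("could not place background channel-B foci")
            cand = _uniform_in_sphere(1, nucleus_radius, rng)[0]
            if n_foci == 0 or np.min(np.linalg.norm(foci_a - cand, axis=1)) >= clearance:
                b.append(cand)
        foci_b = np.array(b)
    return NucleusFociSample(foci_a, foci_b, cluster_labels, coloc_truth,
                             nucleus_radius)
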