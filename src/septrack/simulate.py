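"""Synthetic data with known ground truth for every downstream stage.

Emulates the data produced by live-cell single-particle tracking of septal
proteins in rod-shaped bacteria: spherocylindrical cells, 1-3 population
Brownian mixtures with reflecting cell walls, bleaching-limited track
lengths, Gaussian localization error, septal/polar placement bias, rendered
SMLM image stacks, and multi-channel fluorescence line profiles (membrane
pole/septum peaks, nucleoid blobs).

Defaults follow the imaging conditions of the emulated experiments: frame
interval 13 ms, camera pixel 0.0968 µm, profile pixel pitch 0.0645 µm, and
diffusion coefficients (0.017, 0.0509, 0.394) µm²/s for the confined, slow
and fast populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .profiling import CellProfile
from .tracking import CellOutline

__all__ = [
    "SimCellConfig",
    "SimMixtureConfig",
    "GroundTruth",
    "simulate_cell_population",
    "simulate_tracks",
    "simulate_profiles",
    "simulate_image_stack",
    "DEFAULT_D",
    "DEFAULT_DT",
]

#: apparent diffusion coefficients (µm²/s) of the confined, slow-mobile and
#: fast-mobile populations of a septal DNA translocase, and the ~13 ms
#: effective frame interval they were fitted at.
DEFAULT_D = (0.017, 0.0509, 0.394)
DEFAULT_DT = 0.013


@dataclass
class SimCellConfig:
    """Geometry and composition of a simulated cell population."""

    n_cells: int = 100
    length_mean: float = 2.5  # µm
    length_sd: float = 0.4  # µm
    width: float = 1.0  # µm
    septum_prob: float = 0.5
    seed: int | None = None

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.length_mean <= self.width:
            raise ValueError("length_mean must exceed width")
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")
        if not 0.0 <= self.septum_prob <= 1.0:
            raise ValueError("septum_prob must be in [0, 1]")


@dataclass
class SimMixtureConfig:
    """Diffusion-mixture and photophysics parameters for track simulation."""

    k: int = 3
    D: tuple[float, ...] = DEFAULT_D  # µm²/s
    f: tuple[float, ...] = (0.4, 0.4, 0.2)
    dt: float = DEFAULT_DT  # s
    loc_sd: float = 0.02  # µm localization error SD per axis
    p_survive: float = 0.875  # per-frame survival probability
    n_tracks: int = 1000
    septal_bias: float = 0.0  # P(confined molecule starts at septum/pole)
    frame_span: int = 1000  # start frames drawn uniformly from this range
    seed: int | None = None

    def validate(self) -> None:
        if not 1 <= self.k <= 3:
            raise ValueError("k must be 1, 2 or 3")
        if len(self.D) != self.k or len(self.f) != self.k:
            raise ValueError("D and f must have length k")
        if any(d < 0 for d in self.D):
            raise ValueError("all D must be >= 0")
        if abs(sum(self.f) - 1.0) > 1e-9:
            raise ValueError("fractions f must sum to 1")
        if not 0.0 < self.p_survive < 1.0:
            raise ValueError("p_survive must be in (0, 1)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.loc_sd < 0:
            raise ValueError("loc_sd must be >= 0")
        if not 0.0 <= self.septal_bias <= 1.0:
            raise ValueError("septal_bias must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic dataset."""

    labels: np.ndarray | None = None  # per-track population label
    D: tuple[float, ...] | None = None
    f: tuple[float, ...] | None = None
    track_cell: np.ndarray | None = None  # per-track cell_id
    cell_septum: dict[str, bool] = field(default_factory=dict)
    cell_septum_x: dict[str, float | None] = field(default_factory=dict)
    true_length: float | None = None  # µm (profiles)
    n_septa: int | None = None
    n_nucleoids: int | None = None
    true_positions: pd.DataFrame | None = None  # noise-free track positions


# ---------------------------------------------------------------------------
# cell geometry
# ---------------------------------------------------------------------------

def _spherocylinder_vertices(length: float, width: float, n_cap: int = 33) -> np.ndarray:
    """Closed spherocylinder outline: rectangle of length L - w capped by two
    half-circles of diameter w; long axis on x, centred at the origin."""
    a = (length - width) / 2.0
    r = width / 2.0
    th_right = np.linspace(-np.pi / 2, np.pi / 2, n_cap)
    th_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_cap)
    right = np.column_stack([a + r * np.cos(th_right), r * np.sin(th_right)])
    left = np.column_stack([-a + r * np.cos(th_left), r * np.sin(th_left)])
    return np.vstack([right, left])


def _inside_spherocylinder(x: float, y: float, a: float, r: float) -> bool:
    if -a <= x <= a:
        return abs(y) <= r
    c = a if x > a else -a
    return (x - c) ** 2 + y**2 <= r**2


def _reflect_into_cell(x: float, y: float, a: float, r: float) -> tuple[float, float]:
    """Specular reflection across the violated wall; at most 10 reflections,
    then clamp to the nearest interior point."""
    for _ in range(10):
        if -a <= x <= a:
            if abs(y) <= r:
                return x, y
            y = math.copysign(2.0 * r, y) - y  # reflect across y = ±r
            continue
        c = a if x > a else -a
        dx, dy = x - c, y
        rho = math.hypot(dx, dy)
        if rho <= r:
            return x, y
        scale = (2.0 * r - rho) / rho  # radial reflection off the cap
        x, y = c + dx * scale, dy * scale
    # clamp
    if -a <= x <= a:
        return x, math.copysign(min(abs(y), r * (1 - 1e-9)), y)
    c = a if x > a else -a
    dx, dy = x - c, y
    rho = math.hypot(dx, dy)
    if rho > r:
        s = r * (1 - 1e-9) / rho
        x, y = c + dx * s, dy * s
    return x, y


def simulate_cell_population(
    config: SimCellConfig, layout: str = "column", gap: float = 0.8
) -> list[CellOutline]:
    """Draw a population of spherocylindrical cells.

    Lengths are Normal(length_mean, length_sd) truncated below at ``width``;
    each cell carries a Bernoulli(septum_prob) septum flag with the septum
    plane at midcell.  ``layout="column"`` (default) stacks cells in a
    non-overlapping vertical column in the first quadrant so that image
    rendering and track-to-cell assignment are well defined;
    ``layout="origin"`` centres every cell at the origin.
    """
    config.validate()
    if layout not in ("column", "origin"):
        raise ValueError("layout must be 'column' or 'origin'")
    rng = np.random.default_rng(config.seed)
    cells = []
    margin = 1.0
    max_len = config.length_mean + 4 * config.length_sd
    for i in range(config.n_cells):
        length = rng.normal(config.length_mean, config.length_sd)
        attempts = 0
        while length < config.width:
            length = rng.normal(config.length_mean, config.length_sd)
            attempts += 1
            if attempts > 1000:
                length = config.width
                break
        septum = bool(rng.random() < config.septum_prob)
        if layout == "column":
            center = np.array(
                [margin + max_len / 2.0, margin + config.width / 2.0 + i * (config.width + gap)]
            )
        else:
            center = np.zeros(2)
        verts = _spherocylinder_vertices(length, config.width) + center
        poles = np.array(
            [center + [-length / 2.0, 0.0], center + [length / 2.0, 0.0]]
        )
        cells.append(
            CellOutline(
                cell_id=f"cell_{i:04d}",
                vertices=verts,
                poles=poles,
                length=float(length),
                septum=septum,
                septum_x=float(center[0]) if septum else None,
                width=config.width,
                center=center,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# track simulation
# ---------------------------------------------------------------------------

def _uniform_point_in_cell(rng, a: float, r: float) -> tuple[float, float]:
    while True:
        x = rng.uniform(-a - r, a + r)
        y = rng.uniform(-r, r)
        if _inside_spherocylinder(x, y, a, r):
            return x, y


def simulate_tracks(
    cells: list[CellOutline] | None,
    mix: SimMixtureConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate Brownian-mixture tracks inside cells with reflecting walls.

    Each molecule is assigned a population by the fractions ``f``; true
    positions evolve by per-axis Gaussian steps of variance ``2 D_i dt``,
    specularly reflected at the cell boundary.  With probability
    ``septal_bias`` a *confined* (component 0) molecule starts at the septum
    plane of a septum-bearing cell, or at a random pole cap of a septum-less
    cell.  Observed positions add Gaussian(0, loc_sd) per axis.  Track length
    is ``1 + Geometric(1 - p_survive)`` frames (always >= 2).

    ``cells=None`` simulates unbounded diffusion from the origin (useful for
    closed-form checks).

    Returns ``(tracks, GroundTruth)`` where ``tracks`` has columns
    ``track_id, frame, x_um, y_um, cell_id, true_population``.
    """
    mix.validate()
    if cells is not None and len(cells) == 0:
        raise ValueError("cells must be non-empty (or None for free diffusion)")
    rng = np.random.default_rng(mix.seed)
    D = np.asarray(mix.D, dtype=float)
    f = np.asarray(mix.f, dtype=float)
    labels = rng.choice(mix.k, size=mix.n_tracks, p=f)
    n_frames = 1 + rng.geometric(1.0 - mix.p_survive, size=mix.n_tracks)
    cell_idx = (
        rng.integers(0, len(cells), size=mix.n_tracks) if cells is not None else None
    )

    rows = []
    true_rows = []
    track_cell = []
    for t_id in range(mix.n_tracks):
        pop = int(labels[t_id])
        nf = int(n_frames[t_id])
        step_sd = math.sqrt(2.0 * D[pop] * mix.dt)
        if cells is None:
            cell = None
            cx = cy = 0.0
            a = r = np.inf
            x, y = 0.0, 0.0
            cid = None
        else:
            cell = cells[int(cell_idx[t_id])]
            cid = cell.cell_id
            cx, cy = cell.center if cell.center is not None else cell.poles.mean(axis=0)
            r = (cell.width if cell.width is not None else 1.0) / 2.0
            a = (cell.length - 2.0 * r) / 2.0
            if pop == 0 and rng.random() < mix.septal_bias:
                if cell.septum:
                    x = 0.0  # septum plane at midcell (local frame)
                    y = rng.uniform(-r, r) * 0.9
                else:
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    x = side * (a + r / 2.0)
                    y = rng.uniform(-r / 2.0, r / 2.0)
                x, y = _reflect_into_cell(x, y, a, r)
            else:
                x, y = _uniform_point_in_cell(rng, a, r)

        steps = rng.normal(0.0, step_sd, size=(nf - 1, 2)) if nf > 1 else np.empty((0, 2))
        noise = rng.normal(0.0, mix.loc_sd, size=(nf, 2)) if mix.loc_sd > 0 else np.zeros((nf, 2))
        start_frame = int(rng.integers(0, mix.frame_span))

        xs = np.empty(nf)
        ys = np.empty(nf)
        xs[0], ys[0] = x, y
        for s in range(1, nf):
            x, y = x + steps[s - 1, 0], y + steps[s - 1, 1]
            if cells is not None:
                x, y = _reflect_into_cell(x, y, a, r)
            xs[s], ys[s] = x, y

        abs_x = xs + cx
        abs_y = ys + cy
        obs_x = abs_x + noise[:, 0]
        obs_y = abs_y + noise[:, 1]
        frames = start_frame + np.arange(nf)
        for s in range(nf):
            rows.append((t_id, int(frames[s]), obs_x[s], obs_y[s], cid, pop))
            true_rows.append((t_id, int(frames[s]), abs_x[s], abs_y[s]))
        track_cell.append(cid)

    tracks = pd.DataFrame(
        rows, columns=["track_id", "frame", "x_um", "y_um", "cell_id", "true_population"]
    )
    tracks = tracks[tracks.groupby("track_id")["frame"].transform("size") >= 2]
    truth = GroundTruth(
        labels=labels,
        D=tuple(mix.D),
        f=tuple(mix.f),
        track_cell=np.array(track_cell, dtype=object),
        cell_septum={c.cell_id: c.septum for c in cells} if cells else {},
        cell_septum_x={c.cell_id: c.septum_x for c in cells} if cells else {},
        true_positions=pd.DataFrame(
            true_rows, columns=["track_id", "frame", "x_um", "y_um"]
        ),
    )
    return tracks, truth


# ---------------------------------------------------------------------------
# fluorescence line profiles
# ---------------------------------------------------------------------------

_POLE_AMP = 100.0
_POLE_SIGMA = 0.08  # µm
_SEPTUM_AMP_FACTOR = 1.0  # septum peak amplitude relative to pole peaks
_NUCLEOID_AMP = 80.0
_NUCLEOID_SIGMA = 0.10  # µm
_PHASE_AMP = 50.0


def simulate_profiles(
    true_length: float,
    n_septa: int = 0,
    n_nucleoids: int = 1,
    noise_sd: float = 0.0,
    pixel_pitch: float = 0.0645,
    seed: int | None = None,
) -> tuple[CellProfile, GroundTruth]:
    """Synthesize a three-channel cell line profile.

    Membrane channel: Gaussian pole peaks at ±length/2 plus one interior
    Gaussian peak per septum (evenly spaced); DNA channel: one Gaussian blob
    per nucleoid placed between septa; phase channel: a smooth plateau.
    Additive Gaussian noise of SD ``noise_sd`` on all channels (peak SNR =
    100 / noise_sd with the default amplitudes).  The default pixel pitch,
    0.0645 µm, matches a 5-pixel / 322.5-nm profile line width.
    """
    if true_length <= 0:
        raise ValueError("true_length must be positive")
    if n_septa < 0 or n_nucleoids < 0:
        raise ValueError("counts must be >= 0")
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    L = float(true_length)
    if n_septa > 0 and L / (n_septa + 1) < 6 * _POLE_SIGMA:
        raise ValueError(f"{n_septa} septa do not fit in a {L} µm cell")

    # distribute nucleoids over the inter-septal compartments (round-robin)
    bounds = np.concatenate(
        [[-L / 2], -L / 2 + L * np.arange(1, n_septa + 1) / (n_septa + 1), [L / 2]]
    )
    comp_counts = np.zeros(n_septa + 1, dtype=int)
    for j in range(n_nucleoids):
        comp_counts[j % (n_septa + 1)] += 1
    nucleoid_centers = []
    for c, m in enumerate(comp_counts):
        lo, hi = bounds[c], bounds[c + 1]
        if m == 0:
            continue
        # blobs must be optically resolvable: >= 5 sigma centre spacing
        if (hi - lo) / (m + 1) < 5 * _NUCLEOID_SIGMA:
            raise ValueError(
                f"{n_nucleoids} nucleoids do not fit between septa of a {L} µm cell"
            )
        for i in range(m):
            nucleoid_centers.append(lo + (hi - lo) * (i + 1) / (m + 1))

    # grid aligned so that -L/2 falls exactly on a sample
    margin = 0.5
    m = int(np.ceil(margin / pixel_pitch))
    n_samples = int(np.ceil((L + margin) / pixel_pitch)) + m + 1
    pos = -L / 2 + (np.arange(n_samples) - m) * pixel_pitch

    def gauss(mu, sigma, amp):
        return amp * np.exp(-0.5 * ((pos - mu) / sigma) ** 2)

    membrane = gauss(-L / 2, _POLE_SIGMA, _POLE_AMP) + gauss(L / 2, _POLE_SIGMA, _POLE_AMP)
    for s in bounds[1:-1]:
        membrane = membrane + gauss(s, _POLE_SIGMA, _SEPTUM_AMP_FACTOR * _POLE_AMP)
    dna = np.zeros_like(pos)
    for c in nucleoid_centers:
        dna = dna + gauss(c, _NUCLEOID_SIGMA, _NUCLEOID_AMP)
    edge = 0.05
    phase = _PHASE_AMP / (1 + np.exp(-(pos + L / 2) / edge)) / (
        1 + np.exp((pos - L / 2) / edge)
    )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        membrane = membrane + rng.normal(0, noise_sd, pos.shape)
        dna = dna + rng.normal(0, noise_sd, pos.shape)
        phase = phase + rng.normal(0, noise_sd, pos.shape)

    profile = CellProfile(position=pos, phase=phase, membrane=membrane, dna=dna)
    truth = GroundTruth(true_length=L, n_septa=n_septa, n_nucleoids=n_nucleoids)
    return profile, truth


# ---------------------------------------------------------------------------
# image stack rendering
# ---------------------------------------------------------------------------

def simulate_image_stack(
    tracks: pd.DataFrame,
    psf_sigma: float = 0.13,
    background: float = 10.0,
    peak_photons: float = 300.0,
    pixel_size: float = 0.0968,
    seed: int | None = None,
    shape: tuple[int, int] | None = None,
    n_frames: int | None = None,
    apply_noise: bool = True,
) -> np.ndarray:
    """Render localizations as integrated 2D Gaussians with Poisson noise.

    ``peak_photons`` is the expected count in the brightest pixel of a
    pixel-centred emitter; ``background`` is the per-pixel background level.
    The stack has ``max(frame) + 1`` frames unless ``n_frames`` is given, and
    its extent covers all localizations plus a margin unless ``shape`` (H, W)
    is given.  ``apply_noise=False`` returns the noiseless expectation.
    """
    if psf_sigma <= 0 or pixel_size <= 0:
        raise ValueError("psf_sigma and pixel_size must be positive")
    if background < 0 or peak_photons < 0:
        raise ValueError("background and peak_photons must be >= 0")
    rng = np.random.default_rng(seed)

    if tracks is None or len(tracks) == 0:
        nf = n_frames if n_frames is not None else 1
        hw = shape if shape is not None else (32, 32)
        expect = np.full((nf, *hw), float(background))
        return rng.poisson(expect).astype(np.uint16) if apply_noise else expect

    x = tracks["x_um"].to_numpy(dtype=float)
    y = tracks["y_um"].to_numpy(dtype=float)
    frames = tracks["frame"].to_numpy(dtype=int)
    if frames.min() < 0:
        raise ValueError("frames must be >= 0")
    nf = n_frames if n_frames is not None else int(frames.max()) + 1
    if shape is None:
        margin = 1.0  # µm
        if x.min() - margin < 0 or y.min() - margin < 0:
            raise ValueError(
                "localizations (minus margin) must have non-negative coordinates; "
                "pass an explicit shape or shift the data"
            )
        H = int(np.ceil((y.max() + margin) / pixel_size))
        W = int(np.ceil((x.max() + margin) / pixel_size))
    else:
        H, W = shape

    # total photons so that the central pixel of a centred emitter gets
    # peak_photons in expectation
    s = psf_sigma / pixel_size  # PSF sigma in pixels
    frac_1d = erf(0.5 / (s * np.sqrt(2.0)))
    total_photons = peak_photons / (frac_1d**2)

    expect = np.full((nf, H, W), float(background))
    half = int(np.ceil(4 * s)) + 1
    for xi, yi, fi in zip(x, y, frames):
        if fi >= nf:
            continue
        cx = xi / pixel_size - 0.5  # emitter centre in pixel-index units
        cy = yi / pixel_size - 0.5
        c0 = max(0, int(round(cx)) - half)
        c1 = min(W, int(round(cx)) + half + 1)
        r0 = max(0, int(round(cy)) - half)
        r1 = min(H, int(round(cy)) + half + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        cols = np.arange(c0, c1)
        rows_ = np.arange(r0, r1)
        ex = 0.5 * (
            erf((cols + 0.5 - cx) / (s * np.sqrt(2)))
            - erf((cols - 0.5 - cx) / (s * np.sqrt(2)))
        )
        ey = 0.5 * (
            erf((rows_ + 0.5 - cy) / (s * np.sqrt(2)))
            - erf((rows_ - 0.5 - cy) / (s * np.sqrt(2)))
        )
        expect[fi, r0:r1, c0:c1] += total_photons * np.outer(ey, ex)

    if not apply_noise:
        return expect
    return rng.poisson(expect).astype(np.uint16)
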