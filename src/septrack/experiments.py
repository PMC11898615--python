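"""Reproducible benchmark experiments exercising the whole pipeline on
synthetic data with known ground truth.

Each function simulates its inputs from a seed, runs the relevant pipeline
stage(s), and returns a dict of measured quantities.  They are used both by
the test suite and by ``scripts/acceptance.py``.  Problem sizes are chosen
to be comfortably above the statistical requirements of each check while
staying desk-scale (a few minutes on one CPU in total).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .diffusion import (
    JumpData,
    compute_jump_distances,
    compute_msd,
    fit_dwell_times,
    fit_sqd_mixture,
)
from .profiling import (
    TimeLapseTrace,
    count_nucleoids,
    count_septa,
    measure_cell_length,
    septal_localization_fraction,
)
from .simulate import (
    DEFAULT_D,
    DEFAULT_DT,
    SimCellConfig,
    SimMixtureConfig,
    simulate_cell_population,
    simulate_image_stack,
    simulate_profiles,
    simulate_tracks,
)
from .spatial import (
    build_heatmap,
    compute_localization_stats,
    diff_heatmap,
    loess_trend,
    normalize_to_standard_cell,
)
from .stats import dunn_test, kruskal_wallis, shapiro_wilk, wilcoxon_rank_sum
from .tracking import (
    assign_tracks_to_cells,
    detect_spots,
    frame_pair_assignment,
    link_tracks,
)

__all__ = [
    "mixture_recovery",
    "single_population_oracle",
    "linking_oracle",
    "detection_benchmark",
    "dwell_recovery",
    "spatial_uniform_check",
    "loess_enrichment_check",
    "profiling_benchmark",
    "septal_fraction_check",
    "stats_brute_force_check",
    "stats_null_calibration",
    "end_to_end",
]


def _subseeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit seeds from one base seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def mixture_recovery(
    seed: int,
    n_tracks: int = 3000,
    D: tuple[float, ...] = DEFAULT_D,
    f: tuple[float, ...] = (0.33, 0.33, 0.34),
    dt: float = DEFAULT_DT,
) -> dict:
    """Recovery of a three-population diffusion mixture from simulated
    tracks in cells (noiseless localization, reflecting walls)."""
    s1, s2 = _subseeds(seed, 2)
    cells = simulate_cell_population(
        SimCellConfig(n_cells=60, length_mean=2.5, length_sd=0.4, width=1.0,
                      septum_prob=0.5, seed=s1)
    )
    mix = SimMixtureConfig(
        k=3, D=D, f=f, dt=dt, loc_sd=0.0, p_survive=0.875,
        n_tracks=n_tracks, septal_bias=0.0, seed=s2,
    )
    tracks, truth = simulate_tracks(cells, mix)
    jumps = compute_jump_distances(tracks, dt=dt)
    fit = fit_sqd_mixture(jumps, k=3)
    return {
        "D_true": np.asarray(D), "f_true": np.asarray(f),
        "D_hat": fit.D, "f_hat": fit.f,
        "D_rel_err": np.abs(fit.D - np.asarray(D)) / np.asarray(D),
        "f_abs_err": np.abs(fit.f - np.asarray(f)),
        "n_jumps": fit.n_jumps,
    }


def single_population_oracle(
    seed: int, D: float = 0.1, n_tracks: int = 1500, dt: float = DEFAULT_DT
) -> dict:
    """k=1 CDF fit vs the closed-form moment estimator mean(r²)/(4 dt), and
    the MSD linear fit, on clean unbounded single-population tracks."""
    mix = SimMixtureConfig(
        k=1, D=(D,), f=(1.0,), dt=dt, loc_sd=0.0, p_survive=0.875,
        n_tracks=n_tracks, seed=seed,
    )
    tracks, _ = simulate_tracks(None, mix)
    jumps = compute_jump_distances(tracks, dt=dt)
    fit = fit_sqd_mixture(jumps, k=1)
    d_moment = float(np.mean(jumps.r2) / (4.0 * dt))
    msd = compute_msd(tracks, max_lag=4, dt=dt)
    return {
        "D_true": D,
        "D_fit": float(fit.D[0]),
        "D_moment": d_moment,
        "fit_vs_moment_rel_err": abs(fit.D[0] - d_moment) / d_moment,
        "D_msd": msd.D,
        "msd_rel_err": abs(msd.D - D) / D,
        "n_jumps": fit.n_jumps,
    }


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _brute_force_link_cost(prev: np.ndarray, nxt: np.ndarray, max_link: float) -> float:
    """Exhaustive minimum of sum(d²) + max_link² per unlinked spot over all
    one-to-one partial matchings with links <= max_link."""
    b = max_link**2
    n, m = len(prev), len(nxt)
    if n == 0 or m == 0:
        return b * (n + m)
    d2 = (
        (prev[:, None, 0] - nxt[None, :, 0]) ** 2
        + (prev[:, None, 1] - nxt[None, :, 1]) ** 2
    )
    best = [b * (n + m)]

    def recurse(i: int, used: frozenset, cost: float, links: int):
        if i == n:
            total = cost + b * ((n - links) + (m - links))
            best[0] = min(best[0], total)
            return
        recurse(i + 1, used, cost, links)  # leave i unlinked
        for j in range(m):
            if j in used or d2[i, j] > b:
                continue
            recurse(i + 1, used | {j}, cost + d2[i, j], links + 1)

    recurse(0, frozenset(), 0.0, 0)
    return best[0]


def linking_oracle(seed: int, n_instances: int = 100, max_link: float = 0.3) -> dict:
    """Compare the LAP frame-pair assignment cost against exhaustive
    enumeration on random instances with up to 4 spots per frame."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n, m = rng.integers(0, 5, size=2)
        prev = rng.uniform(0, 1.0, size=(n, 2))
        nxt = rng.uniform(0, 1.0, size=(m, 2))
        _, cost = frame_pair_assignment(prev, nxt, max_link)
        oracle = _brute_force_link_cost(prev, nxt, max_link)
        if abs(cost - oracle) < 1e-9:
            agree += 1
    return {"n_agree": agree, "n_instances": n_instances}


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detection_benchmark(
    seed: int,
    n_frames: int = 120,
    emitters_per_frame: int = 8,
    field_px: int = 128,
    background: float = 100.0,
    peak_photons: float = 100.0,
    pixel_size: float = 0.0968,
    match_radius_px: float = 2.0,
) -> dict:
    """Detection recall and localization RMSE on sparse synthetic frames at
    peak SNR = peak_photons / sqrt(background) (default 10)."""
    rng = np.random.default_rng(seed)
    border = 8
    rows = []
    truth = []
    for t in range(n_frames):
        pts = []
        while len(pts) < emitters_per_frame:
            cand = rng.uniform(border, field_px - border, size=2)
            if all(np.hypot(*(cand - p)) > 10 for p in pts):
                pts.append(cand)
        for p in pts:
            x_um = (p[0] + 0.5) * pixel_size
            y_um = (p[1] + 0.5) * pixel_size
            rows.append({"frame": t, "x_um": x_um, "y_um": y_um})
            truth.append((t, p[0], p[1]))
    locs = pd.DataFrame(rows)
    stack = simulate_image_stack(
        locs, psf_sigma=0.13, background=background, peak_photons=peak_photons,
        pixel_size=pixel_size, seed=int(rng.integers(2**31 - 1)),
        shape=(field_px, field_px), n_frames=n_frames,
    )
    det = detect_spots(stack, pixel_size=pixel_size)
    det_px = det.assign(
        col=det["x_um"] / pixel_size - 0.5, row=det["y_um"] / pixel_size - 0.5
    )
    matched = 0
    sq_err = []
    by_frame = dict(tuple(det_px.groupby("frame")))
    for t, cx, cy in truth:
        d = by_frame.get(t)
        if d is None or len(d) == 0:
            continue
        dist = np.hypot(d["col"] - cx, d["row"] - cy)
        i = dist.idxmin()
        if dist[i] <= match_radius_px:
            matched += 1
            sq_err.append(dist[i] ** 2)
    recall = matched / len(truth)
    rmse_px = float(np.sqrt(np.mean(sq_err))) if sq_err else np.inf
    return {"recall": recall, "rmse_px": rmse_px, "n_true": len(truth),
            "n_detected": len(det)}


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def dwell_recovery(
    seed: int,
    n: int = 5000,
    tau: tuple[float, float] = (0.14, 0.33),
    fractions: tuple[float, float] = (0.5, 0.5),
    t_min: float = 0.052,
) -> dict:
    """Two-exponential MLE recovery on simulated truncated dwell times, plus
    the order-1 closed-form check."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(2, size=n, p=fractions)
    durations = t_min + rng.exponential(np.asarray(tau)[labels])
    fit2 = fit_dwell_times(durations, order=2, t_min=t_min)
    fit1 = fit_dwell_times(durations, order=1, t_min=t_min)
    analytic_tau1 = float(np.mean(durations) - t_min)
    return {
        "tau_true": np.asarray(tau),
        "tau_hat": np.asarray(fit2.tau),
        "pct_true": 100 * np.asarray(fractions),
        "pct_hat": np.asarray(fit2.percentages),
        "tau_rel_err": np.abs(np.asarray(fit2.tau) - np.asarray(tau)) / np.asarray(tau),
        "pct_abs_err": np.abs(np.asarray(fit2.percentages) - 100 * np.asarray(fractions)),
        "order1_tau": fit1.tau[0],
        "order1_analytic": analytic_tau1,
        "order1_discrepancy": abs(fit1.tau[0] - analytic_tau1),
        "n": n,
    }


# ---------------------------------------------------------------------------
# spatial
# ---------------------------------------------------------------------------

def _sample_points_in_cell(rng, cell, n, septal_frac=0.0, septal_sd=0.1):
    """Sample localizations uniform along the cell axis (y uniform within the
    local half-width); a fraction may be placed at the septum plane."""
    cx, cy = cell.center
    a = (cell.length - cell.width) / 2.0
    r = cell.width / 2.0
    xs = rng.uniform(-cell.length / 2, cell.length / 2, size=n)
    n_sep = int(round(septal_frac * n))
    if n_sep:
        xs[:n_sep] = np.clip(
            rng.normal(0.0, septal_sd, size=n_sep), -cell.length / 2, cell.length / 2
        )
    half = np.where(
        np.abs(xs) <= a, r, np.sqrt(np.maximum(r**2 - (np.abs(xs) - a) ** 2, 1e-12))
    )
    ys = rng.uniform(-half, half)
    return pd.DataFrame({"x_um": xs + cx, "y_um": ys + cy})


def spatial_uniform_check(seed: int, n_points: int = 10000) -> dict:
    """Uniform axial localizations in one cell: midcell proportion -> 0.2,
    polar proportion -> 0.4; heatmap normalization and self-difference."""
    rng = np.random.default_rng(seed)
    cells = simulate_cell_population(
        SimCellConfig(n_cells=1, length_mean=4.0, length_sd=0.0, width=1.0,
                      septum_prob=0.0, seed=seed)
    )
    cell = cells[0]
    locs = _sample_points_in_cell(rng, cell, n_points)
    pts = normalize_to_standard_cell(locs, cell)
    stats = compute_localization_stats(pts, cell)
    grid = build_heatmap(pts)
    dgrid = diff_heatmap(grid, grid)
    return {
        "midcell_prop": stats.midcell_prop,
        "polar_prop": stats.polar_prop,
        "heatmap_sum": float(grid.sum()),
        "diff_max_abs": float(np.max(np.abs(dgrid))),
        "n": n_points,
        "se_midcell": float(np.sqrt(0.2 * 0.8 / n_points)),
        "se_polar": float(np.sqrt(0.4 * 0.6 / n_points)),
    }


def loess_enrichment_check(
    seed: int, n_seeds: int = 20, n_cells: int = 150, points_per_cell: int = 60
) -> dict:
    """Septal enrichment planted only in septum-bearing, short cells: the
    LOESS trend of midcell proportion vs length must be elevated at short
    lengths (early cell cycle) relative to long lengths."""
    correct = 0
    for s in _subseeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        cells = simulate_cell_population(
            SimCellConfig(n_cells=n_cells, length_mean=2.5, length_sd=0.5,
                          width=1.0, septum_prob=0.0, seed=s)
        )
        med = np.median([c.length for c in cells])
        lengths, props = [], []
        for cell in cells:
            short = cell.length < med
            cell.septum = bool(short and rng.random() < 0.8)
            frac = 0.5 if cell.septum else 0.0
            locs = _sample_points_in_cell(rng, cell, points_per_cell, septal_frac=frac)
            pts = normalize_to_standard_cell(locs, cell)
            st = compute_localization_stats(pts, cell)
            lengths.append(st.length)
            props.append(st.midcell_prop)
        lengths = np.asarray(lengths)
        props = np.asarray(props)
        q25, q75 = np.quantile(lengths, [0.25, 0.75])
        _, fitted, _ = loess_trend(lengths, props, span=0.75, grid=np.array([q25, q75]))
        if fitted[0] > fitted[1]:
            correct += 1
    return {"n_sign_correct": correct, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# profiling
# ---------------------------------------------------------------------------

def profiling_benchmark(
    seed: int, n_cells: int = 500, snr: float = 10.0, pixel_pitch: float = 0.0645
) -> dict:
    """Length / septa / nucleoid accuracy on noisy synthetic profiles.

    Peak SNR is amplitude / noise SD (profile amplitudes are 100 au)."""
    rng = np.random.default_rng(seed)
    noise_sd = 100.0 / snr
    len_ok = septa_ok = nucleoid_ok = 0
    tol = 2 * pixel_pitch
    for i in range(n_cells):
        L = float(rng.uniform(2.0, 3.6))
        n_septa = int(rng.integers(0, 3))
        while n_septa > 0 and L / (n_septa + 1) < 1.0:
            n_septa -= 1  # keep compartments wide enough for >= 1 nucleoid
        n_nuc = int(rng.integers(1, 5))

        def fits(n: int) -> bool:
            comp = L / (n_septa + 1)
            per_comp = int(np.ceil(n / (n_septa + 1)))
            return comp / (per_comp + 1) >= 0.5  # generator blob spacing rule

        while n_nuc > 1 and not fits(n_nuc):
            n_nuc -= 1
        profile, truth = simulate_profiles(
            true_length=L, n_septa=n_septa, n_nucleoids=n_nuc,
            noise_sd=noise_sd, pixel_pitch=pixel_pitch,
            seed=int(rng.integers(2**31 - 1)),
        )
        try:
            length = measure_cell_length(profile)
            if abs(length - L) <= tol:
                len_ok += 1
            if count_septa(profile) == n_septa:
                septa_ok += 1
        except Exception:
            pass
        if count_nucleoids(profile) == n_nuc:
            nucleoid_ok += 1
    return {
        "length_within_2px_rate": len_ok / n_cells,
        "septa_exact_rate": septa_ok / n_cells,
        "nucleoid_exact_rate": nucleoid_ok / n_cells,
        "n_cells": n_cells,
    }


def septal_fraction_check(seed: int, n_traces: int = 45) -> dict:
    """Septal localization fractions on constructed monotone traces must be
    exact to frame resolution."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_traces):
        n = int(rng.integers(10, 40))
        cross = int(rng.integers(1, n))
        intensity = np.where(np.arange(n) >= cross, 2500.0, 500.0)
        trace = TimeLapseTrace(
            time_min=5.0 * np.arange(n), septal_intensity=intensity,
            cycle_start=0, cycle_end=n,
        )
        frac = septal_localization_fraction(trace, threshold=1800.0)
        max_err = max(max_err, abs(frac - (n - cross) / n))
    return {"max_fraction_error": max_err, "n_traces": n_traces}


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def _brute_vargha_delaney(x, y) -> float:
    wins = ties = 0
    for xi in x:
        for yi in y:
            if xi > yi:
                wins += 1
            elif xi == yi:
                ties += 1
    return (wins + 0.5 * ties) / (len(x) * len(y))


def _brute_midranks(values: np.ndarray) -> np.ndarray:
    ranks = np.empty(len(values))
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def _brute_dunn_z(groups: list[np.ndarray], i: int, j: int) -> float:
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = _brute_midranks(pooled)
    sizes = [len(g) for g in groups]
    offs = np.cumsum([0] + sizes)
    rbar = [np.mean(ranks[offs[k] : offs[k + 1]]) for k in range(len(groups))]
    ties = 0.0
    for v in set(pooled.tolist()):
        t = np.sum(pooled == v)
        ties += t**3 - t
    var = N * (N + 1) / 12.0 - ties / (12.0 * (N - 1))
    return (rbar[i] - rbar[j]) / np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))


def stats_brute_force_check(seed: int, n_instances: int = 25) -> dict:
    """Vargha-Delaney A and Dunn z against brute-force pairwise/rank
    computation on small random (tie-rich) inputs."""
    from .stats import vargha_delaney_a

    rng = np.random.default_rng(seed)
    max_a = max_z = 0.0
    for _ in range(n_instances):
        x = rng.integers(0, 6, size=rng.integers(2, 10)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(2, 10)).astype(float)
        g3 = rng.integers(0, 6, size=rng.integers(2, 10)).astype(float)
        max_a = max(max_a, abs(vargha_delaney_a(x, y) - _brute_vargha_delaney(x, y)))
        try:
            res = dunn_test([x, y, g3], adjust="none")
        except ValueError:
            continue  # zero rank variance instance
        for r, (i, j) in zip(res, itertools.combinations(range(3), 2)):
            max_z = max(max_z, abs(r.statistic - _brute_dunn_z([x, y, g3], i, j)))
    return {"max_a_discrepancy": max_a, "max_dunn_z_discrepancy": max_z,
            "n_instances": n_instances}


def stats_null_calibration(
    seed: int, n_rep: int = 2000, n_per_group: int = 40, alpha: float = 0.05
) -> dict:
    """Type-I error of every test under the null (identical normal
    distributions), per-comparison for Dunn (no multiplicity adjustment)."""
    rng = np.random.default_rng(seed)
    rej = {"kruskal_wallis": 0, "wilcoxon": 0, "dunn": 0, "shapiro": 0}
    for _ in range(n_rep):
        g = [rng.normal(size=n_per_group) for _ in range(3)]
        if kruskal_wallis(g).p_value < alpha:
            rej["kruskal_wallis"] += 1
        if wilcoxon_rank_sum(g[0], g[1]).p_value < alpha:
            rej["wilcoxon"] += 1
        if dunn_test(g, adjust="none")[0].p_value < alpha:
            rej["dunn"] += 1
        if shapiro_wilk(g[2]).p_value < alpha:
            rej["shapiro"] += 1
    return {k: v / n_rep for k, v in rej.items()} | {"n_rep": n_rep}


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

#: planted two-condition contrast: condition B emulates earlier septal
#: recruitment — confined molecules are placed at the septum already in
#: short (early-cycle) cells, and the confined fraction is higher; the
#: fraction magnitudes are taken from the fitted population range of septal
#: DNA-translocase data (confined fraction roughly 0.33 vs 0.48).
E2E_CONDITIONS = {
    "A": {"f": (0.33, 0.47, 0.20), "bias_early": 0.15, "bias_late": 0.85},
    "B": {"f": (0.48, 0.37, 0.15), "bias_early": 0.85, "bias_late": 0.85},
}


def _run_condition(seed: int, f, bias_early, bias_late, n_cells=40, n_tracks=1000):
    s1, s2, s3, s4 = _subseeds(seed, 4)
    cells = simulate_cell_population(
        SimCellConfig(n_cells=n_cells, length_mean=2.5, length_sd=0.35,
                      width=1.0, septum_prob=0.7, seed=s1)
    )
    med = np.median([c.length for c in cells])
    short = [c for c in cells if c.length < med]
    long_ = [c for c in cells if c.length >= med]
    frame_span = 350
    parts = []
    offset = 0
    for subset, bias, sub_seed in ((short, bias_early, s2), (long_, bias_late, s4)):
        n_sub = int(round(n_tracks * len(subset) / len(cells)))
        mix = SimMixtureConfig(
            k=3, D=DEFAULT_D, f=f, dt=DEFAULT_DT, loc_sd=0.0, p_survive=0.875,
            n_tracks=n_sub, septal_bias=bias, frame_span=frame_span, seed=sub_seed,
        )
        sub_tracks, _ = simulate_tracks(subset, mix)
        sub_tracks["track_id"] = sub_tracks["track_id"] + offset
        offset += n_sub
        parts.append(sub_tracks)
    true_tracks = pd.concat(parts, ignore_index=True)
    stack = simulate_image_stack(
        true_tracks, psf_sigma=0.13, background=10.0, peak_photons=400.0,
        seed=s3,
    )
    locs = detect_spots(stack)
    linked = link_tracks(locs)
    jumps = compute_jump_distances(linked, dt=DEFAULT_DT)
    assigned = assign_tracks_to_cells(linked, cells)
    lengths, props, septa = [], [], []
    for cell in cells:
        sub = assigned[assigned["cell_id"] == cell.cell_id]
        if len(sub) < 10:
            continue
        pts = normalize_to_standard_cell(sub, cell)
        st = compute_localization_stats(pts, cell)
        lengths.append(st.length)
        props.append(st.midcell_prop)
        septa.append(st.septum)
    return jumps, np.asarray(lengths), np.asarray(props), np.asarray(septa, dtype=bool)


def end_to_end(seed: int, n_seeds: int = 20) -> dict:
    """Full pipeline (simulate -> detect -> link -> diffuse -> spatial ->
    stats) on a two-condition experiment with earlier septal recruitment
    planted in condition B.

    Per seed, checks that (i) the fitted confined fraction is higher in B
    and (ii) among septum-bearing short (early-cycle) cells the midcell
    proportion is higher in B with Wilcoxon p < 0.01 (stratifying on the
    septum flag mirrors the convention of analyzing dividing cells
    separately).

    Fractions are compared with the diffusion coefficients held shared
    between the two conditions (fitted once on the pooled jumps, then fixed
    per condition): with free D the confined/slow trade-off dominates the
    per-condition fraction variance at this data size.
    """
    confined_correct = 0
    wilcoxon_reject = 0
    confined = {"A": [], "B": []}
    pvals = []
    for s in _subseeds(seed, n_seeds):
        sA, sB = _subseeds(s, 2)
        jumps = {}
        lengths = {}
        props = {}
        septa = {}
        for name, cseed in (("A", sA), ("B", sB)):
            cfg = E2E_CONDITIONS[name]
            jd, ln, pr, sp = _run_condition(
                cseed, cfg["f"], cfg["bias_early"], cfg["bias_late"]
            )
            jumps[name] = jd
            lengths[name] = ln
            props[name] = pr
            septa[name] = sp
        pooled = JumpData(
            np.concatenate([jumps["A"].r2, jumps["B"].r2]), DEFAULT_DT
        )
        shared_D = fit_sqd_mixture(pooled, k=3).D
        fits = {
            name: fit_sqd_mixture(jumps[name], k=3, fix_D=shared_D)
            for name in ("A", "B")
        }
        for name in ("A", "B"):
            confined[name].append(float(fits[name].f[0]))
        if fits["B"].f[0] > fits["A"].f[0]:
            confined_correct += 1
        med = np.median(np.concatenate([lengths["A"], lengths["B"]]))
        early_a = props["A"][(lengths["A"] < med) & septa["A"]]
        early_b = props["B"][(lengths["B"] < med) & septa["B"]]
        if len(early_a) >= 3 and len(early_b) >= 3:
            res = wilcoxon_rank_sum(early_b, early_a)
            pvals.append(res.p_value)
            if res.p_value < 0.01 and np.median(early_b) > np.median(early_a):
                wilcoxon_reject += 1
    return {
        "n_seeds": n_seeds,
        "confined_direction_correct": confined_correct,
        "wilcoxon_reject": wilcoxon_reject,
        "mean_confined_A": float(np.mean(confined["A"])),
        "mean_confined_B": float(np.mean(confined["B"])),
        "median_wilcoxon_p": float(np.median(pvals)) if pvals else np.nan,
    }
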