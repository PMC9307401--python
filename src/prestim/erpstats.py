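"""Task statistics: reward parameter, prestimulus time, feedback negativity.

The two quantities specific to this analysis are

* **PT (prestimulus time)** -- the time before the decision marker at which
  the large-bet and small-bet condition averages *last* intersect and stay
  separated through the decision itself.  It is read off the difference
  waveform d(t) = a(t) - b(t) at a frontal midline channel: the latest
  sign change of d before t=0 (linearly interpolated between samples), with
  the persistence requirement that d keeps one sign from that crossing up
  to t=0.

* **Δ (delta amplitude)** -- the absolute loss/gain difference of the
  feedback-locked averages at the medial-frontal negativity latency, i.e.
  at the time of maximal |loss - gain| inside the search window
  (default 150-350 ms after feedback).

Group inference uses permutation tests (label shuffling between groups,
sign flipping within subjects), since only significance thresholds -- not a
parametric test family -- are prescribed for this design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .containers import EvokedWaveform
from .montage import HEAD_RADIUS, is_eog

__all__ = [
    "NoSeparationError",
    "PTResult",
    "MFNLatency",
    "MFNResult",
    "TopoMap",
    "GroupSummary",
    "reward_parameter",
    "compute_pt",
    "mfn_latency",
    "delta_amplitude",
    "mfn_result",
    "shape_scored_amplitude",
    "gls_scored_amplitude",
    "pattern_scored_amplitude",
    "fit_gaussian_peak",
    "gaussian_template",
    "max_separation_time",
    "topomap",
    "permutation_test",
    "group_stats",
]


class NoSeparationError(ValueError):
    """The two condition averages never separate, so no PT exists."""


def reward_parameter(left_value: float, right_value: float) -> float:
    """Reward parameter E: value of the left square over the right square.

    E indexes the risk level of a block (5, 7 and 10 in the three-block
    design this package models).
    """
    if right_value <= 0:
        raise ValueError("right_value must be positive")
    return left_value / right_value


def delta_amplitude(loss_amp: float, gain_amp: float) -> float:
    """Absolute gain-minus-loss amplitude difference in microvolts."""
    return abs(gain_amp - loss_amp)


# ---------------------------------------------------------------------------
# prestimulus time


@dataclass(frozen=True)
class PTResult:
    """Prestimulus time of one waveform pair at one channel."""

    pt: float  # ms before the decision marker (>= 0)
    crossing_time: float  # ms (negative; pt == -crossing_time)
    channel: str
    persistence_ok: bool  # separation held from the crossing through t=0


def _difference(
    evoked_a: EvokedWaveform, evoked_b: EvokedWaveform, channel: str
) -> tuple[np.ndarray, np.ndarray]:
    if evoked_a.times.size != evoked_b.times.size or not np.allclose(
        evoked_a.times, evoked_b.times
    ):
        raise ValueError("waveforms must share one time axis")
    return evoked_a.times, evoked_a.channel(channel) - evoked_b.channel(channel)


def compute_pt(
    evoked_a: EvokedWaveform,
    evoked_b: EvokedWaveform,
    channel: str = "Fz",
    search_window: tuple[float, float] = (-500.0, 0.0),
    tol: float = 0.0,
) -> PTResult:
    """Prestimulus time: last intersection of two averages before the decision.

    Within ``search_window`` (which must end at the decision marker, t=0),
    the crossing is the latest sign change of d(t) = a(t) - b(t); its time
    is linearly interpolated between the two bracketing samples.  Samples
    with |d| <= ``tol`` count as "not separated".

    With the default ``tol=0`` (and no exactly-zero samples) this is simply
    the latest adjacent-sample sign change of d, after which the sign is
    constant by construction.  A positive ``tol`` treats samples with
    |d| <= tol as "not yet separated", so the crossing becomes the moment
    the difference last left the tolerance band for good -- the natural
    reading of "completely separated" on noisy averages.

    Degenerate cases follow the definition of the statistic:

    * d keeps the final sign (above tolerance) over the whole window ->
      the curves were already apart at the window start; ``pt`` is the full
      window length and ``persistence_ok`` is False (no crossing seen);
    * d is inside the tolerance band at t=0 -> separation did not persist;
      the latest sign change is reported with ``persistence_ok=False``;
    * max|d| <= tol -> :class:`NoSeparationError`.
    """
    lo, hi = float(search_window[0]), float(search_window[1])
    if abs(hi) > 1e-9:
        raise ValueError("PT search window must end at the decision marker (0 ms)")
    times, d = _difference(evoked_a, evoked_b, channel)
    mask = (times >= lo - 1e-9) & (times <= 1e-9)
    if not mask.any():
        raise ValueError("search window does not intersect the time axis")
    t = times[mask]
    d = d[mask]
    if np.max(np.abs(d)) <= tol:
        raise NoSeparationError(
            f"waveforms are identical within tolerance {tol} at {channel}; "
            "no separation to time"
        )
    s = np.sign(d)
    s[np.abs(d) <= tol] = 0.0
    window_length = float(t[-1] - t[0])

    if s[-1] != 0:
        # separated at the decision: the crossing opens the final maximal
        # run of constant-sign separated samples
        mismatches = np.flatnonzero(s != s[-1])
        if mismatches.size == 0:
            return PTResult(
                pt=window_length,
                crossing_time=-window_length,
                channel=channel,
                persistence_ok=False,
            )
        k = int(mismatches[-1])
        if s[k] == -s[-1]:
            # opposite separated signs on adjacent samples: interpolate the
            # zero crossing of d between them
            t_cross = t[k] + (t[k + 1] - t[k]) * d[k] / (d[k] - d[k + 1])
        else:
            # separation was lost here; the curves part company at the last
            # unseparated sample
            t_cross = t[k]
        return PTResult(
            pt=float(-t_cross),
            crossing_time=float(t_cross),
            channel=channel,
            persistence_ok=True,
        )

    # not separated at the decision itself: report the latest transition
    # between opposite separated signs, if any
    nz = np.flatnonzero(s != 0)
    flips = (
        np.flatnonzero(s[nz[:-1]] != s[nz[1:]]) if nz.size > 1 else np.array([], int)
    )
    if flips.size == 0:
        return PTResult(
            pt=window_length,
            crossing_time=-window_length,
            channel=channel,
            persistence_ok=False,
        )
    i, j = int(nz[flips[-1]]), int(nz[flips[-1] + 1])
    if j == i + 1:
        t_cross = t[i] + (t[j] - t[i]) * d[i] / (d[i] - d[j])
    else:
        t_cross = t[j - 1]
    return PTResult(
        pt=float(-t_cross),
        crossing_time=float(t_cross),
        channel=channel,
        persistence_ok=False,
    )


def max_separation_time(
    evoked_a: EvokedWaveform,
    evoked_b: EvokedWaveform,
    channel: str = "Fz",
    window: tuple[float, float] = (-500.0, 0.0),
) -> float:
    """Time (ms before the marker) at which |a - b| is largest.

    Ties break toward the earliest sample.  This is the latency at which
    whole-scalp maps of the pre-decision effect are most informative
    (about 50 ms before the decision in the task this package models).
    """
    times, d = _difference(evoked_a, evoked_b, channel)
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError("window does not intersect the time axis")
    t = times[mask]
    k = int(np.argmax(np.abs(d[mask])))  # np.argmax returns the first maximum
    return float(-t[k])


# ---------------------------------------------------------------------------
# feedback negativity


@dataclass(frozen=True)
class MFNLatency:
    latency: float  # ms after the feedback marker
    at_boundary: bool  # argmax landed on a window edge (peak likely outside)


@dataclass(frozen=True)
class MFNResult:
    """Loss/gain amplitudes and their Δ at the feedback-negativity latency."""

    latency: float  # ms after feedback
    loss_amplitude: float  # uV at the latency
    gain_amplitude: float  # uV
    delta: float  # |gain - loss|, uV
    channel: str
    at_boundary: bool = False


def mfn_latency(
    evoked_loss: EvokedWaveform,
    evoked_gain: EvokedWaveform,
    channel: str = "Fz",
    window: tuple[float, float] = (150.0, 350.0),
) -> MFNLatency:
    """Latency of maximal |loss - gain| inside the search window.

    Sample resolution; ties break toward the earliest sample.  If the
    maximum sits on a window edge the true peak probably lies outside, and
    ``at_boundary`` is set.
    """
    times, d = _difference(evoked_loss, evoked_gain, channel)
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} ms contains no samples")
    t = times[mask]
    k = int(np.argmax(np.abs(d[mask])))
    return MFNLatency(latency=float(t[k]), at_boundary=k in (0, t.size - 1))


def mfn_result(
    evoked_loss: EvokedWaveform,
    evoked_gain: EvokedWaveform,
    channel: str = "Fz",
    window: tuple[float, float] = (150.0, 350.0),
    latency: float | None = None,
) -> MFNResult:
    """Loss/gain amplitudes and Δ, read at a detected or imposed latency.

    Passing ``latency`` (e.g. one determined on a grand average) reads both
    condition amplitudes at that fixed time; otherwise the latency is
    detected with :func:`mfn_latency`.
    """
    if latency is None:
        lat = mfn_latency(evoked_loss, evoked_gain, channel, window)
        latency_ms, boundary = lat.latency, lat.at_boundary
    else:
        latency_ms, boundary = float(latency), False
    times = evoked_loss.times
    k = int(np.argmin(np.abs(times - latency_ms)))
    if abs(times[k] - latency_ms) > 1000.0:  # clearly off-axis
        raise ValueError(f"latency {latency_ms} ms is outside the time axis")
    loss_amp = float(evoked_loss.channel(channel)[k])
    gain_amp = float(evoked_gain.channel(channel)[k])
    return MFNResult(
        latency=float(times[k]),
        loss_amplitude=loss_amp,
        gain_amplitude=gain_amp,
        delta=delta_amplitude(loss_amp, gain_amp),
        channel=channel,
        at_boundary=boundary,
    )


def shape_scored_amplitude(
    evoked: EvokedWaveform,
    template: np.ndarray,
    channel: str = "Fz",
    window: tuple[float, float] = (150.0, 350.0),
) -> float:
    """Component amplitude by projection onto a unit-peak template shape.

    Least-squares coefficient of the waveform (at ``channel``, inside
    ``window``) regressed on ``template``, an array over the same time axis
    normalised to 1 at the component peak, with a constant and a linear
    trend as nuisance regressors.  When the waveform is
    ``amplitude x template + drift + noise`` this estimates the peak
    amplitude without the single-sample read-out noise of a pointwise
    measurement (a matched-filter score with detrending; the nuisance terms
    matter because low-frequency background noise behaves like a slow drift
    inside the scoring window and would otherwise leak into the score).
    """
    template = np.asarray(template, dtype=float)
    if template.shape != evoked.times.shape:
        raise ValueError("template must live on the waveform's time axis")
    mask = (evoked.times >= window[0] - 1e-9) & (evoked.times <= window[1] + 1e-9)
    g = template[mask]
    if not np.any(g):
        raise ValueError("template is zero inside the window")
    t = evoked.times[mask]
    t = (t - t.mean()) / max(np.ptp(t), 1.0)
    design = np.column_stack([g, np.ones_like(g), t])
    x = evoked.channel(channel)[mask]
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(coef[0])


def fit_gaussian_peak(
    times: np.ndarray,
    waveform: np.ndarray,
    window: tuple[float, float] = (150.0, 350.0),
    width_ms: float | None = None,
) -> tuple[float, float, float]:
    """Fit a Gaussian peak (plus a linear trend) to a waveform segment.

    Models the segment as ``a * exp(-(t - t0)^2 / (2 w^2)) + c0 + c1 t`` --
    the standard unimodal morphology of an averaged ERP component riding on
    slow background activity -- and returns ``(a, t0, w)`` in (µV, ms, ms).
    Passing ``width_ms`` freezes the width (useful when it was already
    estimated on higher-SNR pooled data).  Initialised at the extremum of
    the segment; raises ``RuntimeError`` if the fit does not converge.
    """
    from scipy.optimize import curve_fit

    times = np.asarray(times, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    mask = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    if mask.sum() < 5:
        raise ValueError("window too small for a peak fit")
    t = times[mask]
    x = waveform[mask]
    k0 = int(np.argmax(np.abs(x - x.mean())))
    a0 = x[k0] - x.mean()
    span = float(t[-1] - t[0])

    if width_ms is None:
        def model(t, a, t0, w, c0, c1):
            return a * np.exp(-((t - t0) ** 2) / (2.0 * w**2)) + c0 + c1 * t

        p0 = [a0, t[k0], span / 8.0, float(x.mean()), 0.0]
        bounds = (
            [-np.inf, t[0], span / 50.0, -np.inf, -np.inf],
            [np.inf, t[-1], span, np.inf, np.inf],
        )
    else:
        def model(t, a, t0, c0, c1):
            return a * np.exp(-((t - t0) ** 2) / (2.0 * width_ms**2)) + c0 + c1 * t

        p0 = [a0, t[k0], float(x.mean()), 0.0]
        bounds = ([-np.inf, t[0], -np.inf, -np.inf], [np.inf, t[-1], np.inf, np.inf])

    popt, _ = curve_fit(model, t, x, p0=p0, bounds=bounds, maxfev=20_000)
    if width_ms is None:
        a, t0, w = float(popt[0]), float(popt[1]), float(abs(popt[2]))
    else:
        a, t0, w = float(popt[0]), float(popt[1]), float(width_ms)
    return a, t0, w


def gaussian_template(
    times: np.ndarray, center_ms: float, width_ms: float
) -> np.ndarray:
    """Unit-peak Gaussian over a time axis (a noise-free scoring template)."""
    times = np.asarray(times, dtype=float)
    return np.exp(-((times - center_ms) ** 2) / (2.0 * float(width_ms) ** 2))


def gls_scored_amplitude(
    evoked: EvokedWaveform,
    template: np.ndarray,
    noise_cov: np.ndarray,
    channel: str = "Fz",
    window: tuple[float, float] = (150.0, 350.0),
) -> float:
    """Component amplitude by generalised-least-squares template scoring.

    Like :func:`shape_scored_amplitude` (template coefficient with constant
    and linear-trend nuisances) but weighted by the inverse of
    ``noise_cov``, the covariance of the waveform's noise over the full
    time axis -- typically estimated from single-trial variability of the
    epochs behind the average.  With temporally correlated background
    activity (EEG noise is far from white) this is substantially more
    efficient than the unweighted fit and remains unbiased for any
    covariance.
    """
    template = np.asarray(template, dtype=float)
    noise_cov = np.asarray(noise_cov, dtype=float)
    n_t = evoked.times.size
    if template.shape != (n_t,) or noise_cov.shape != (n_t, n_t):
        raise ValueError("template/covariance must live on the waveform time axis")
    mask = (evoked.times >= window[0] - 1e-9) & (evoked.times <= window[1] + 1e-9)
    idx = np.flatnonzero(mask)
    g = template[idx]
    if not np.any(g):
        raise ValueError("template is zero inside the window")
    t = evoked.times[idx]
    t = (t - t.mean()) / max(np.ptp(t), 1.0)
    design = np.column_stack([g, np.ones_like(g), t])
    C = noise_cov[np.ix_(idx, idx)]
    x = evoked.channel(channel)[idx]
    ciD = np.linalg.solve(C, design)
    beta = np.linalg.solve(design.T @ ciD, ciD.T @ x)
    return float(beta[0])


def pattern_scored_amplitude(
    evoked: EvokedWaveform,
    template: np.ndarray,
    window: tuple[float, float] = (150.0, 350.0),
) -> float:
    """Component amplitude by projection onto a spatio-temporal pattern.

    Like :func:`shape_scored_amplitude`, but the template is a full
    (channels x time) pattern -- typically the grand-average condition
    difference normalised to unit gain at the analysis channel and peak
    latency -- and the least-squares fit runs jointly over all EEG channels
    inside ``window``, with per-channel constant and linear-trend nuisance
    regressors.  Averaging the fit over the whole montage suppresses
    channel noise that is independent across sensors.
    """
    template = np.asarray(template, dtype=float)
    if template.shape != evoked.data.shape:
        raise ValueError("template must match the waveform's (channels x time) shape")
    mask = (evoked.times >= window[0] - 1e-9) & (evoked.times <= window[1] + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} ms contains no samples")
    eeg = evoked.eeg_indices()
    t = evoked.times[mask]
    t = (t - t.mean()) / max(np.ptp(t), 1.0)
    # project per-channel constant + linear trend out of data and template
    basis = np.column_stack([np.ones_like(t), t])
    q, _ = np.linalg.qr(basis)
    proj = np.eye(t.size) - q @ q.T
    G = template[np.ix_(eeg, np.flatnonzero(mask))] @ proj
    X = evoked.data[np.ix_(eeg, np.flatnonzero(mask))] @ proj
    denom = float(np.sum(G * G))
    if denom <= 0:
        raise ValueError("template is zero inside the window")
    return float(np.sum(X * G) / denom)


# ---------------------------------------------------------------------------
# scalp maps


@dataclass
class TopoMap:
    """Whole-scalp interpolation of channel values at one latency."""

    latency: float  # ms relative to the lock marker
    channel_values: np.ndarray  # per EEG channel, uV
    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)
    grid: np.ndarray  # (res, res), NaN outside the head circle
    grid_x: np.ndarray
    grid_y: np.ndarray
    lock: str = "decision"


def topomap(
    evoked: EvokedWaveform,
    latency: float,
    positions: np.ndarray,
    grid_resolution: int = 67,
    idw_power: float = 2.0,
) -> TopoMap:
    """Interpolate channel values at ``latency`` onto a head-circle raster.

    Inverse-distance weighting inside the electrode convex hull,
    nearest-channel extrapolation between the hull and the head outline,
    NaN outside.  The map is linear in the channel values, so the map of a
    difference waveform equals the difference of the maps.
    """
    times = evoked.times
    k = int(np.argmin(np.abs(times - latency)))
    step = np.median(np.diff(times)) if times.size > 1 else 0.0
    if abs(times[k] - latency) > step / 2 + 1e-9:
        raise ValueError(f"latency {latency} ms is not on the time axis")
    eeg_idx = evoked.eeg_indices()
    values = evoked.data[eeg_idx, k]
    names = tuple(evoked.channel_names[i] for i in eeg_idx)
    pos = np.asarray(positions, dtype=float)
    if pos.shape[0] == len(evoked.channel_names):
        pos = pos[eeg_idx]
    if pos.shape != (eeg_idx.size, 2):
        raise ValueError("positions must cover every channel")

    lin = np.linspace(-HEAD_RADIUS, HEAD_RADIUS, grid_resolution)
    gx, gy = np.meshgrid(lin, lin)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside_head = np.hypot(pts[:, 0], pts[:, 1]) <= HEAD_RADIUS + 1e-12

    grid = np.full(pts.shape[0], np.nan)
    hull = Delaunay(pos)
    in_hull = hull.find_simplex(pts) >= 0
    tree = cKDTree(pos)

    # inverse-distance weights inside the hull (exact at electrode sites)
    idw_pts = np.flatnonzero(inside_head & in_hull)
    if idw_pts.size:
        d = np.linalg.norm(pts[idw_pts, None, :] - pos[None, :, :], axis=2)
        at_site = d < 1e-9
        w = 1.0 / np.maximum(d, 1e-9) ** idw_power
        est = (w @ values) / w.sum(axis=1)
        hit = at_site.any(axis=1)
        if hit.any():
            est[hit] = values[np.argmax(at_site[hit], axis=1)]
        grid[idw_pts] = est

    near_pts = np.flatnonzero(inside_head & ~in_hull)
    if near_pts.size:
        _, nearest = tree.query(pts[near_pts])
        grid[near_pts] = values[nearest]

    return TopoMap(
        latency=float(times[k]),
        channel_values=values,
        channel_names=names,
        positions=pos,
        grid=grid.reshape(grid_resolution, grid_resolution),
        grid_x=gx,
        grid_y=gy,
        lock=evoked.lock,
    )


def plot_topomap(topo: TopoMap, path=None, ax=None, title: str | None = None):
    """Render a scalp map (filled contours, electrode dots, head outline)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    vmax = np.nanmax(np.abs(topo.grid)) or 1.0
    im = ax.imshow(
        topo.grid,
        origin="lower",
        extent=[-HEAD_RADIUS, HEAD_RADIUS, -HEAD_RADIUS, HEAD_RADIUS],
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
    )
    circle = plt.Circle((0, 0), HEAD_RADIUS, fill=False, color="k", lw=1.5)
    ax.add_patch(circle)
    ax.scatter(topo.positions[:, 0], topo.positions[:, 1], s=6, c="k", zorder=3)
    ax.set_xlim(-HEAD_RADIUS * 1.05, HEAD_RADIUS * 1.05)
    ax.set_ylim(-HEAD_RADIUS * 1.05, HEAD_RADIUS * 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title or f"{topo.lock} {topo.latency:+.0f} ms")
    fig.colorbar(im, ax=ax, shrink=0.75, label="µV")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax


# ---------------------------------------------------------------------------
# group-level inference


@dataclass
class GroupSummary:
    """Mean ± SD per group plus permutation p-values for group differences."""

    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)


def _summarise(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def permutation_test(
    a,
    b,
    paired: bool = False,
    n_permutations: int = 10_000,
    seed: int = 0,
    statistic: str = "mean",
) -> float:
    """Two-sided permutation p-value for a difference between two samples.

    Unpaired: group labels are shuffled between the pooled samples.
    Paired: the per-subject differences have their signs flipped.
    ``statistic="mean"`` compares group means; ``statistic="rank"``
    rank-transforms the pooled values first (a permutation Mann-Whitney
    test), which is robust when single-subject estimates have heavy tails.
    The p-value uses the add-one convention p = (1 + #extreme) / (1 + N),
    so the smallest attainable value is 1/(N+1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("permutation test needs at least 2 values per group")
    if statistic not in ("mean", "rank"):
        raise ValueError("statistic must be 'mean' or 'rank'")
    if statistic == "rank" and not paired:
        from scipy.stats import rankdata

        pooled_ranks = rankdata(np.concatenate([a, b]))
        a = pooled_ranks[: a.size]
        b = pooled_ranks[a.size :]
    rng = np.random.default_rng(seed)
    if paired:
        if statistic == "rank":
            from scipy.stats import rankdata

            d0 = a - b
            # signed-rank transform of the per-subject differences
            signed = np.sign(d0) * rankdata(np.abs(d0))
            a, b = signed, np.zeros_like(signed)
        if a.size != b.size:
            raise ValueError("paired test needs equal-length samples")
        d = a - b
        obs = abs(d.mean())
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, d.size))
        stats = np.abs((signs * d[None, :]).mean(axis=1))
    else:
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        n_a = a.size
        stats = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(pooled)
            stats[i] = abs(perm[:n_a].mean() - perm[n_a:].mean())
    extreme = int(np.sum(stats >= obs - 1e-12))
    return float((1 + extreme) / (1 + n_permutations))


def group_stats(
    groups: dict[str, np.ndarray],
    paired: bool = False,
    n_permutations: int = 10_000,
    seed: int = 0,
    statistic: str = "mean",
) -> GroupSummary:
    """Mean ± SD per group and pairwise permutation p-values.

    ``paired=True`` runs sign-flip tests (all groups must then contain the
    same subjects in the same order), otherwise label-shuffling tests.
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    ns: dict[str, int] = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {name!r} needs at least 2 subjects")
        means[name], sds[name] = _summarise(vals)
        ns[name] = int(vals.size)
    summary = GroupSummary(means=means, sds=sds, ns=ns)
    keys = list(groups)
    for i, ka in enumerate(keys):
        for kb in keys[i + 1 :]:
            summary.pairwise_p[(ka, kb)] = permutation_test(
                groups[ka],
                groups[kb],
                paired=paired,
                n_permutations=n_permutations,
                seed=seed,
                statistic=statistic,
            )
    return summary
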