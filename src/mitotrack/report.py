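"""Reporting: z projections, kymographs, speed-distribution fits,
intersection-based threshold estimation and grouped summaries."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ImageSequence4D, Trajectory
from .motion import STATE_LABELS, StateSeries

__all__ = [
    "Kymograph2D",
    "SpeedDistribution",
    "max_project_z",
    "kymograph",
    "kymograph_from_trajectories",
    "fit_speed_distribution",
    "find_intersection_threshold",
    "summarize_groups",
    "export_kymograph_figure",
    "export_parameter_space_figure",
]


@dataclass
class Kymograph2D:
    """Time x distance-along-axis intensity image."""

    image: np.ndarray  # (n_frames, n_axis_bins)
    seconds_per_row: float
    um_per_column: float

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ValueError("kymograph image must be 2-D")


@dataclass
class SpeedDistribution:
    """Normalized speed histogram plus a fitted smooth density."""

    bin_edges: np.ndarray
    densities: np.ndarray
    params: dict
    pdf: Callable[[np.ndarray], np.ndarray]
    ks_statistic: float
    component: str

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        total = float((self.densities * widths).sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"histogram density integrates to {total}, not 1")


def max_project_z(seq: ImageSequence4D) -> np.ndarray:
    """Maximum-intensity projection along z: out[t, y, x] = max_z in[t, z, y, x]."""
    return seq.intensities.max(axis=1)


def kymograph(
    seq: ImageSequence4D,
    axis: np.ndarray | None = None,
    bin_um: float | None = None,
    band: tuple[int, int] | None = None,
) -> Kymograph2D:
    """Image-mode kymograph: per frame, max-project z then collapse the
    direction orthogonal to the (axis-aligned) transport axis within a band.

    Only the axis-aligned (+x) direction is rasterized exactly; other unit
    axes are rejected.  ``band`` is a half-open row range limiting which y
    rows contribute (e.g. one groove).
    """
    md = seq.metadata
    ax = np.asarray(axis if axis is not None else md.anterograde_axis, dtype=float)
    if abs(np.linalg.norm(ax) - 1.0) > 1e-6:
        raise ValueError("axis must be a unit vector")
    if not np.allclose(np.abs(ax), [1.0, 0.0]):
        raise NotImplementedError("image-mode kymograph supports the x axis only")
    if bin_um is None:
        bin_um = md.pixel_size_xy
    if bin_um <= 0:
        raise ValueError("bin_um must be > 0")
    proj = max_project_z(seq)  # (t, y, x)
    if band is not None:
        y0, y1 = band
        if not (0 <= y0 < y1 <= md.height):
            raise ValueError("band outside field")
        proj = proj[:, y0:y1, :]
    profile = proj.max(axis=1)  # (t, x)
    if ax[0] < 0:
        profile = profile[:, ::-1]
    # rebin columns to bin_um
    n_bins = max(1, int(np.ceil(md.width * md.pixel_size_xy / bin_um)))
    x_um = np.arange(md.width) * md.pixel_size_xy
    idx = np.minimum((x_um / bin_um).astype(int), n_bins - 1)
    img = np.zeros((md.n_frames, n_bins))
    for b in range(n_bins):
        cols = idx == b
        if cols.any():
            img[:, b] = profile[:, cols].max(axis=1)
    return Kymograph2D(img, md.frame_interval, bin_um)


def kymograph_from_trajectories(
    trajectories: Sequence[Trajectory],
    n_frames: int,
    axis: np.ndarray | None = None,
    bin_um: float = 0.2,
    extent_um: float | None = None,
) -> Kymograph2D:
    """Trajectory-mode kymograph: rasterize each track's along-axis position."""
    if bin_um <= 0:
        raise ValueError("bin_um must be > 0")
    ax = np.array([1.0, 0.0, 0.0]) if axis is None else np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    if extent_um is None:
        extent_um = max(
            (float((t.positions @ ax).max()) for t in trajectories), default=1.0
        )
    n_bins = max(1, int(np.ceil(extent_um / bin_um)) + 1)
    img = np.zeros((n_frames, n_bins))
    for traj in trajectories:
        s = traj.positions @ ax
        cols = np.clip((s / bin_um).astype(int), 0, n_bins - 1)
        for f, c, inten in zip(traj.frames, cols, traj.intensities):
            if 0 <= f < n_frames:
                img[int(f), c] += inten if inten > 0 else 1.0
    return Kymograph2D(img, 1.0, bin_um)


def fit_speed_distribution(
    values: np.ndarray, component: str = "transient", *, method: str = "lognormal"
) -> SpeedDistribution:
    """Histogram (Freedman-Diaconis bins, density-normalized) plus a fitted curve.

    ``method`` is ``"lognormal"`` (maximum likelihood on the positive speeds,
    the default for right-skewed positive data) or ``"kde"`` (Gaussian kernel
    density, Scott's-rule bandwidth).  The Kolmogorov-Smirnov statistic against
    the fitted curve is reported as a goodness-of-fit measure.
    """
    if component not in ("sustained", "transient"):
        raise ValueError("component must be 'sustained' or 'transient'")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 50:
        raise ValueError(f"need >= 50 values, got {len(v)}")
    pos = v[v > 0]
    if len(pos) < 50 or np.ptp(pos) < 1e-12:
        raise ValueError("degenerate speed values (all zero or constant)")
    edges = np.histogram_bin_edges(pos, bins="fd")
    dens, edges = np.histogram(pos, bins=edges, density=True)

    if method == "lognormal":
        logs = np.log(pos)
        mu, sigma = float(logs.mean()), float(logs.std(ddof=0))
        if sigma < 1e-12:
            raise ValueError("degenerate speed values (zero spread)")
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        pdf = dist.pdf
        ks = float(stats.kstest(pos, dist.cdf).statistic)
        params = {"method": "lognormal", "mu": mu, "sigma": sigma}
    elif method == "kde":
        kde = stats.gaussian_kde(pos)
        pdf = lambda x: kde(np.atleast_1d(x))
        ks = float(
            stats.kstest(
                pos, lambda x: np.array([kde.integrate_box_1d(0, xi) for xi in x])
            ).statistic
        )
        params = {"method": "kde", "bandwidth": float(kde.factor)}
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpeedDistribution(edges, dens, params, pdf, ks, component)


def find_intersection_threshold(
    dist_a: SpeedDistribution,
    dist_b: SpeedDistribution,
    *more: SpeedDistribution,
    xtol: float = 1e-4,
) -> float:
    """Smallest positive crossing of two fitted speed-density curves.

    The crossing is located as a sign change of the density difference on a
    fine grid over the overlapping support, then refined by bisection to
    ``xtol`` um/s.  With more than two distributions, the median of all
    pairwise crossings is returned.
    """
    dists = (dist_a, dist_b, *more)
    if len(dists) > 2:
        xs = [
            find_intersection_threshold(p, q, xtol=xtol)
            for p, q in combinations(dists, 2)
        ]
        return float(np.median(xs))

    # the fitted curves extend beyond each histogram's bins, so the crossing
    # is searched over the union of the two observed speed ranges
    lo = max(min(dist_a.bin_edges[0], dist_b.bin_edges[0]), xtol)
    hi = max(dist_a.bin_edges[-1], dist_b.bin_edges[-1])
    if hi <= lo:
        raise ValueError("no intersection: supports do not overlap")
    grid = np.linspace(lo, hi, 2048)
    diff = np.asarray(dist_a.pdf(grid)) - np.asarray(dist_b.pdf(grid))
    sign = np.sign(diff)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if len(changes) == 0:
        raise ValueError("no intersection: density difference never changes sign")
    k = changes[0]
    f = lambda x: float(dist_a.pdf(np.array([x]))[0] - dist_b.pdf(np.array([x]))[0])
    return float(optimize.brentq(f, grid[k], grid[k + 1], xtol=xtol))


def export_kymograph_figure(ky: Kymograph2D, path) -> None:
    """Save a kymograph as a PNG/SVG image (time down, distance across)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_t, n_x = ky.image.shape
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(
        ky.image,
        aspect="auto",
        cmap="gray",
        extent=(0, n_x * ky.um_per_column, n_t * ky.seconds_per_row, 0),
    )
    ax.set_xlabel("distance along axis (µm)")
    ax.set_ylabel("time (s)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def export_parameter_space_figure(
    series: Sequence[StateSeries], path, threshold: float = 0.05
) -> None:
    """Scatter every valid point in the (signed sustained, transient) plane,
    colored by state, with the threshold box marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"ST": "0.4", "DP": "tab:orange", "AR": "tab:red", "RR": "tab:blue"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for lab in STATE_LABELS:
        xs, ys = [], []
        for s in series:
            sel = s.valid & (s.states == lab)
            xs.extend(s.sustained_signed_speed[sel])
            ys.extend(s.transient_speed[sel])
        ax.scatter(xs, ys, s=4, alpha=0.5, color=colors[lab], label=lab)
    ax.axvline(+threshold, color="k", lw=0.5, ls="--")
    ax.axvline(-threshold, color="k", lw=0.5, ls="--")
    ax.axhline(threshold, color="k", lw=0.5, ls="--")
    ax.set_xlabel("sustained signed speed (µm/s)")
    ax.set_ylabel("transient speed (µm/s)")
    ax.legend(markerscale=3, frameon=False)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def summarize_groups(
    groups: dict[str, Sequence[Sequence[StateSeries]]],
) -> pd.DataFrame:
    """Per-group state proportions (mean +/- sd across image sequences) and
    mean running sustained speed.

    Each group maps to a list of image sequences; each sequence is a list of
    :class:`StateSeries`.  Sequence-level means are the unit of replication.
    """
    if not groups:
        raise ValueError("need at least one group")
    rows = []
    for name, sequences in groups.items():
        if not sequences:
            raise ValueError(f"group {name!r} is empty")
        seq_props = []
        seq_speeds = []
        for seq in sequences:
            counts = dict.fromkeys(STATE_LABELS, 0)
            speeds = []
            for s in seq:
                for k in range(len(s.frames)):
                    if not s.valid[k]:
                        continue
                    counts[s.states[k]] += 1
                    if s.states[k] in ("AR", "RR"):
                        speeds.append(s.sustained_speed[k])
            n = sum(counts.values())
            if n == 0:
                continue
            seq_props.append([counts[lab] / n for lab in STATE_LABELS])
            seq_speeds.append(float(np.mean(speeds)) if speeds else np.nan)
        if not seq_props:
            raise ValueError(f"group {name!r} has no valid frames")
        P = np.asarray(seq_props)
        row = {"group": name, "n_sequences": len(seq_props)}
        for j, lab in enumerate(STATE_LABELS):
            row[f"p_{lab}_mean"] = float(P[:, j].mean())
            row[f"p_{lab}_sd"] = float(P[:, j].std(ddof=0))
        finite = [s for s in seq_speeds if np.isfinite(s)]
        row["run_speed_mean"] = float(np.mean(finite)) if finite else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
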