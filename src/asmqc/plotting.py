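"""Thin matplotlib layer over the tabular outputs (optional eye candy)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_dotplot(points, ax=None, point_size: float = 1.0):
    """Scatter a k-mer sharing plot: forward matches black, reverse red."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    fwd = points.forward
    ax.scatter(points.x[fwd], points.y[fwd], s=point_size, c="k", marker=".")
    ax.scatter(points.x[~fwd], points.y[~fwd], s=point_size, c="r", marker=".")
    ax.set_xlabel("position in A (bp)")
    ax.set_ylabel("position in B (bp)")
    ax.set_title(f"shared {points.k}-mers")
    return ax


def plot_track(track, ax=None, ymax: float = 3.0):
    """Normalized-multiplicity track: informative blue, noninformative gray."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    info = track.informative
    N = track.N.clip(max=ymax)
    ax.scatter(track.positions[~info], N[~info], s=1, c="0.7", marker=".")
    ax.scatter(track.positions[info], N[info], s=1, c="tab:blue", marker=".")
    ax.axhline(1.0, color="k", lw=0.5)
    for level in (0.5, 2.0):
        ax.axhline(level, color="k", lw=0.5, ls=":")
    ax.set_ylim(0, ymax)
    ax.set_xlabel(f"position on {track.scaffold} (bp)")
    ax.set_ylabel("normalized multiplicity N")
    return ax


def plot_histogram(hist, ax=None, xmax: int | None = None):
    """k-mer multiplicity histogram with detected peaks marked."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    xs = sorted(hist.bins)
    ax.plot(xs, [hist.bins[x] for x in xs], lw=1)
    for mult, _h in hist.peaks:
        ax.axvline(mult, color="r", lw=0.5, ls="--")
    if hist.D is not None:
        ax.axvline(hist.D, color="g", lw=1.0, label=f"D = {hist.D}")
        ax.legend()
    if xmax:
        ax.set_xlim(0, xmax)
    ax.set_xlabel("multiplicity")
    ax.set_ylabel("distinct k-mers")
    return ax
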