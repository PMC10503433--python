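"""Map rendering: streamline summary maps, per-segment activity histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["render_maps"]


def _draw_flow(ax, summary, segment=None):
    grid = summary.grid
    if segment is None:
        u, v = summary.mean_u, summary.mean_v
    else:
        sm = summary.segment_maps[segment]
        u, v = sm.mean_u, sm.mean_v
    R, C = u.shape
    y, x = np.mgrid[0:R, 0:C]
    ax.streamplot(
        x[0], y[:, 0], u, v, density=1.2, color="0.45", linewidth=0.8, arrowsize=0.8
    )
    ax.set_xlim(-0.5, C - 0.5)
    ax.set_ylim(R - 0.5, -0.5)
    ppe = grid.pixels_per_span
    ax.set_xticks(np.arange(0, C, ppe))
    ax.set_xticklabels([str(i + 1) for i in range(C // ppe + 1)])
    ax.set_yticks(np.arange(0, R, ppe))
    ax.set_yticklabels([chr(ord("A") + i) for i in range(R // ppe)])
    ax.set_xlabel("electrode")
    ax.set_ylabel("spline")


def _draw_sources(ax, summary):
    for s in summary.sources:
        r, c = s.pixel
        size = 40 + 4 * s.summary_sac  # dot scaled by SAC
        color = "red" if s.type == "active_divergent" else "royalblue"
        ax.scatter([c], [r], s=size, c=color, zorder=5, edgecolors="k")
        ax.annotate(
            f"{s.label} ({s.summary_sac:.0f}%)",
            (c, r),
            textcoords="offset points",
            xytext=(6, 6),
            fontsize=8,
        )


def _hatch_low_contact(ax, summary):
    contact = summary.contact
    if contact is None or not contact.low_contact_flags:
        return
    from .geometry import label_to_grid

    ppe = summary.grid.pixels_per_span
    for lab in contact.low_contact_flags:
        loc = label_to_grid(lab)
        ax.add_patch(
            plt.Rectangle(
                (loc.col * ppe - ppe / 2, loc.row * ppe - ppe / 2),
                ppe,
                ppe,
                fill=False,
                hatch="///",
                edgecolor="orange",
                linewidth=0.8,
                zorder=4,
            )
        )


def render_maps(summary, out_dir: str | Path, segments: bool = False) -> list[Path]:
    """Write the summary map (flow + sources + activity histogram) and,
    optionally, one map per 2-s segment.  Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    fig, (ax_map, ax_hist) = plt.subplots(
        1, 2, figsize=(11, 5), gridspec_kw=dict(width_ratios=[1.3, 1])
    )
    _draw_flow(ax_map, summary)
    _draw_sources(ax_map, summary)
    _hatch_low_contact(ax_map, summary)
    ax_map.set_title(f"EGF summary map — origin of flow {summary.flow_origin}")

    n_seg = len(summary.segment_maps)
    if summary.sources:
        top = summary.sources[0]
        ax_hist.bar(np.arange(n_seg) + 1, top.per_segment_activity, color="goldenrod")
        ax_hist.set_title(f"source activity at {top.label} per 2-s segment")
    else:
        ax_hist.bar(np.arange(n_seg) + 1, np.zeros(n_seg))
        ax_hist.set_title("no active sources")
    ax_hist.set_xlabel("segment")
    ax_hist.set_ylabel("activity (%)")
    ax_hist.set_ylim(0, 100)
    fig.tight_layout()
    p = out / "summary_map.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    if segments:
        for sm in summary.segment_maps:
            fig, ax = plt.subplots(figsize=(5.5, 5))
            _draw_flow(ax, summary, segment=sm.segment_index)
            ax.set_title(
                f"segment {sm.segment_index + 1} — coherence {sm.coherence:.2f}"
            )
            fig.tight_layout()
            p = out / f"segment_{sm.segment_index + 1:02d}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written.append(p)
    return written
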