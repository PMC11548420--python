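"""Campaign plots: per-date descriptor violins and zone-occupancy stacks."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phenology import OccupancySeries
from .zoning import N_ZONES

__all__ = ["plot_campaign"]


def plot_campaign(series: OccupancySeries, out_dir) -> list[Path]:
    """Write an occupancy stack and a descriptor box summary per campaign."""
    out_dir = Path(out_dir)
    written = []

    doys = sorted({e.doy for e in series.entries})
    # mean occupancy across regions per date
    occ = np.zeros((len(doys), N_ZONES))
    for i, doy in enumerate(doys):
        rows = [e.occupancy for e in series.entries if e.doy == doy]
        occ[i] = np.mean(rows, axis=0)

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.stackplot(doys, occ.T, labels=[f"Z{k + 1}" for k in range(N_ZONES)])
    ax.set_xlabel("day of year")
    ax.set_ylabel("zone occupancy fraction")
    ax.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=8)
    fig.tight_layout()
    path = out_dir / "occupancy_stack.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, axes = plt.subplots(3, 1, figsize=(8, 8), sharex=True)
    for ax, name, label in zip(
        axes, ("m_c", "theta_c", "H_c"),
        ("co-polar purity m_c", "pseudo-scattering type θ_c (deg)", "pseudo-entropy H_c"),
    ):
        med = [
            np.mean([e.stats.stats[name]["median"] for e in series.entries if e.doy == doy])
            for doy in doys
        ]
        q1 = [
            np.mean([e.stats.stats[name]["q1"] for e in series.entries if e.doy == doy])
            for doy in doys
        ]
        q3 = [
            np.mean([e.stats.stats[name]["q3"] for e in series.entries if e.doy == doy])
            for doy in doys
        ]
        ax.fill_between(doys, q1, q3, alpha=0.3)
        ax.plot(doys, med, marker="o")
        ax.set_ylabel(label, fontsize=9)
    axes[-1].set_xlabel("day of year")
    fig.tight_layout()
    path = out_dir / "descriptor_series.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
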