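"""Optional rendering of migration radars (matplotlib, lazily imported).

The analysis core is headless: pipelines emit radar *data* (JSON); this
module only turns such data into a figure when matplotlib is available.
"""

from __future__ import annotations

import numpy as np

from .kinematics import RadarCounts


def plot_radar(radar: RadarCounts, ax=None, color="0.3"):
    """Polar bar chart of a 4-dial migration radar (0° = toward the OB).

    Returns the matplotlib axes.  Raises ImportError when matplotlib is
    not installed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = len(radar.counts)
    width = 2 * np.pi / n
    centers = np.arange(n) * width
    ax.bar(centers, radar.percentages, width=width * 0.95, color=color,
           edgecolor="black", alpha=0.8)
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(1)  # counter-clockwise positive
    ax.set_xticks(centers)
    ax.set_xticklabels(radar.labels)
    ax.set_title(f"migration radar (n={radar.n})")
    return ax
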