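"""PNG rendering of time-frequency maps and classifier images."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .tfr import ClassifierImage, TimeFrequencyMap  # noqa: E402


def save_map_png(
    tf_map: TimeFrequencyMap, path: str | Path, cmap: str = "viridis"
) -> Path:
    """Render a power map with labelled time/frequency axes."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    mesh = ax.pcolormesh(
        tf_map.times, tf_map.freqs, tf_map.power, cmap=cmap, shading="auto"
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"channel {tf_map.channel}")
    fig.colorbar(mesh, ax=ax, label="power")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def save_image_png(
    image: ClassifierImage, path: str | Path, cmap: str = "gray"
) -> Path:
    """Render a 64 x 64 classifier image (origin at low frequency, early time)."""
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.imshow(image.pixels, cmap=cmap, vmin=0, vmax=1, origin="lower")
    ax.set_title(image.kind)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
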