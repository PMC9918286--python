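"""Per-nucleotide transcription profiles over satellite windows.

The ordinate at every nucleotide position of a satellite +- flank window
is the number of retained read hits covering that position, pooled over
all samples of a tissue — one track per tissue, drawn in the conventional
colors (grey muscle, blue neurons, red intestine, green hypodermis).
A zero ordinate means no transcription at that position.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .records import ReadHit, ReferenceWindow, SampleMeta

TISSUE_COLORS = {
    "muscle": "grey",
    "neurons": "blue",
    "intestine": "red",
    "hypodermis": "green",
}
_FALLBACK_COLORS = ["tab:purple", "tab:orange", "tab:brown", "tab:olive", "tab:cyan"]


@dataclass
class CoverageProfile:
    satellite_id: str
    window: ReferenceWindow
    depth: dict[str, np.ndarray]  # tissue -> per-position hit depth

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: position (1-based genomic), tissue, depth."""
        rows = []
        for tissue in sorted(self.depth):
            d = self.depth[tissue]
            rows.append(
                pd.DataFrame(
                    {
                        "position": np.arange(self.window.start + 1, self.window.end + 1),
                        "tissue": tissue,
                        "depth": d,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def coverage_profile(
    window: ReferenceWindow,
    hits: list[ReadHit],
    samples: list[SampleMeta],
) -> CoverageProfile:
    """Stack retained hits into per-tissue depth tracks.

    ``hits`` must already be restricted to this window and max-identity
    filtered; each hit's sample_id maps it to a tissue.
    """
    tissue_of = {s.sample_id: s.tissue for s in samples}
    length = window.length
    depth = {t: np.zeros(length, dtype=int) for t in sorted(set(tissue_of.values()))}
    for h in hits:
        if h.satellite_id != window.satellite_id:
            continue
        tissue = tissue_of[h.sample_id]
        # accumulate via diff array; target_end is inclusive
        depth[tissue][h.target_start : h.target_end + 1] += 1
    return CoverageProfile(window.satellite_id, window, depth)


def render_profile(
    profile: CoverageProfile,
    out_path: str,
    shared_scale: bool = False,
) -> str:
    """Write the profile as one stacked panel per tissue.

    x is genomic position across flank-satellite-flank with the satellite
    boundaries marked; y is hit depth (auto-scaled per panel unless
    ``shared_scale``).
    """
    tissues = sorted(profile.depth)
    w = profile.window
    x = np.arange(w.start + 1, w.end + 1)
    fig, axes = plt.subplots(
        len(tissues), 1, figsize=(9, 1.8 * len(tissues)), sharex=True, squeeze=False
    )
    ymax = max((int(d.max()) for d in profile.depth.values()), default=0)
    fallback = iter(_FALLBACK_COLORS * 10)
    for ax, tissue in zip(axes.ravel(), tissues):
        color = TISSUE_COLORS.get(tissue, next(fallback))
        d = profile.depth[tissue]
        ax.fill_between(x, d, step="mid", color=color, alpha=0.8)
        ax.axvline(w.sat_start + 1, color="black", lw=0.8, ls="--")
        ax.axvline(w.sat_end, color="black", lw=0.8, ls="--")
        ax.set_ylabel(f"{tissue}\nhits", fontsize=8)
        ax.set_ylim(0, (ymax if shared_scale else max(1, int(d.max()))) * 1.1 + 0.1)
    axes.ravel()[-1].set_xlabel(f"{w.chrom} position (satellite {profile.satellite_id})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
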