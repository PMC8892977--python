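"""Synthetic stand-in editing-efficiency panels for three well-studied
guide RNAs.

Full per-site amplicon-sequencing panels are not bundled with this
package; what is public are their summary figures: the on-target editing
efficiency, the number of detected sites, and the summed editing activity
across the panel.  ``synthetic_panel`` reconstructs a panel consistent
with those three numbers by giving the on-target site its published
efficiency and distributing the remaining activity over the off-target
sites as a geometric-decay tail bounded below by the reporting cutoff
(0.05%).  The Poisson-binomial mean cuts/cell depends only on the summed
activity, so it is exact for these stand-ins; the pmf shape is synthetic.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .cutsim import DEFAULT_CUTOFF_PERCENT, EditingPanel

__all__ = ["synthetic_panel", "REFERENCE_PANELS", "reference_panel"]

#: Published summary figures (on-target %, number of sites, summed
#: editing activity %) for three single-on-target guides.
REFERENCE_PANELS: Dict[str, dict] = {
    "RAG1": dict(on_target_percent=93.0, n_sites=84, total_percent=134.7),
    "RAG2": dict(on_target_percent=94.8, n_sites=50, total_percent=149.6),
    "VEGFA": dict(on_target_percent=41.3, n_sites=105, total_percent=183.9),
}


def synthetic_panel(
    name: str,
    on_target_percent: float,
    n_sites: int,
    total_percent: float,
    cutoff_percent: float = DEFAULT_CUTOFF_PERCENT,
    decay: float = 0.9,
) -> EditingPanel:
    """Deterministic synthetic panel matching published summary figures.

    Off-target site i (of n_sites - 1) gets efficiency
    ``cutoff + surplus * decay**i / sum_j decay**j`` so every site clears
    the cutoff and the panel sums exactly to ``total_percent``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    n_off = n_sites - 1
    surplus = total_percent - on_target_percent - n_off * cutoff_percent
    if surplus < 0:
        raise ValueError(
            "summary figures inconsistent: total activity below "
            "on-target + cutoff floor"
        )
    sites = [("on_target", on_target_percent / 100.0)]
    if n_off:
        w = decay ** np.arange(n_off)
        offs = cutoff_percent + surplus * w / w.sum()
        sites += [
            (f"off_target_{i + 1:03d}", float(e) / 100.0)
            for i, e in enumerate(offs)
        ]
    return EditingPanel(name, tuple(sites))


def reference_panel(name: str) -> EditingPanel:
    """Synthetic stand-in panel for one of the guides in
    :data:`REFERENCE_PANELS`."""
    return synthetic_panel(name, **REFERENCE_PANELS[name])
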