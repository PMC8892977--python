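"""Expected CRISPR break sites per cell from editing-efficiency panels.

A guide RNA edits its on-target site and a panel of off-target sites, each
with some efficiency measured by amplicon sequencing.  Treating each site
as an independent Bernoulli event per cell, the number of cut sites per
cell follows a Poisson-binomial distribution whose mean is the sum of the
per-site efficiencies.  Both the exact distribution (dynamic programming
over sites) and a per-cell Monte-Carlo simulation are provided;
independence across sites and cells is an assumption, not a measured fact.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EditingPanel",
    "CutDistribution",
    "load_panel",
    "exact_distribution",
    "simulate_cells",
    "summarize",
]

#: Default panel cutoff: sites below 0.05% editing efficiency are dropped.
DEFAULT_CUTOFF_PERCENT = 0.05


@dataclasses.dataclass(frozen=True)
class EditingPanel:
    """Per-site editing probabilities for one guide RNA."""

    gRNA_name: str
    sites: Tuple[Tuple[str, float], ...]

    def __post_init__(self):
        if not self.sites:
            raise ValueError("panel must contain at least one site")
        for site_id, p in self.sites:
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"site {site_id!r}: efficiency {p} outside [0, 1]"
                )

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, p in self.sites], dtype=np.float64)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclasses.dataclass(frozen=True)
class CutDistribution:
    """Distribution of cut sites per cell.

    ``pmf[k]`` is P(k cuts) for k = 0..n_sites; ``n_cells_simulated`` is 0
    for the exact distribution.
    """

    pmf: np.ndarray
    mean: float
    n_cells_simulated: int = 0

    def __post_init__(self):
        s = float(np.sum(self.pmf))
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"pmf sums to {s}, not 1")


def load_panel(
    path,
    gRNA_name: Optional[str] = None,
    cutoff_percent: float = DEFAULT_CUTOFF_PERCENT,
) -> EditingPanel:
    """Read a CSV panel with columns ``site_id, efficiency_percent``.

    Efficiencies are converted to fractions; rows strictly below
    ``cutoff_percent`` are dropped.  Values outside [0, 100] raise with the
    offending row named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"site_id", "efficiency_percent"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"panel CSV must have columns {sorted(required)}; "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"panel {path} contains no sites")
    sites: List[Tuple[str, float]] = []
    for _, row in df.iterrows():
        eff = float(row["efficiency_percent"])
        if not 0.0 <= eff <= 100.0:
            raise ValueError(
                f"site {row['site_id']!r}: efficiency {eff}% outside [0, 100]"
            )
        if eff < cutoff_percent:
            continue
        sites.append((str(row["site_id"]), eff / 100.0))
    if not sites:
        raise ValueError(
            f"panel {path}: no sites at or above the {cutoff_percent}% cutoff"
        )
    return EditingPanel(gRNA_name or path.stem, tuple(sites))


def exact_distribution(panel: EditingPanel) -> CutDistribution:
    """Exact Poisson-binomial pmf by dynamic programming over sites.

    O(n_sites^2) time: the pmf is convolved with [1-p, p] one site at a
    time.  The mean equals the sum of the efficiencies.
    """
    ps = panel.probabilities
    pmf = np.zeros(ps.size + 1, dtype=np.float64)
    pmf[0] = 1.0
    for p in ps:
        # new[k] = old[k]*(1-p) + old[k-1]*p; RHS evaluated before assignment
        pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
        pmf[0] *= 1.0 - p
    return CutDistribution(pmf=pmf, mean=float(ps.sum()), n_cells_simulated=0)


def simulate_cells(
    panel: EditingPanel, n_cells: int, rng_seed: int = 0
) -> CutDistribution:
    """Monte-Carlo twin of :func:`exact_distribution`.

    Each simulated cell draws an independent Bernoulli(p_i) per site; the
    empirical pmf and mean are returned.  Reproducible from ``rng_seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ps = panel.probabilities
    counts = np.zeros(ps.size + 1, dtype=np.int64)
    # draw in chunks to bound memory at ~10M Bernoulli variables
    chunk = max(1, int(10_000_000 // max(ps.size, 1)))
    done = 0
    while done < n_cells:
        m = min(chunk, n_cells - done)
        cuts = (rng.random((m, ps.size)) < ps).sum(axis=1)
        counts += np.bincount(cuts, minlength=ps.size + 1)
        done += m
    pmf = counts / float(n_cells)
    mean = float(np.arange(pmf.size) @ pmf)
    return CutDistribution(pmf=pmf, mean=mean, n_cells_simulated=int(n_cells))


def summarize(dist: CutDistribution) -> pd.DataFrame:
    """One-row summary: mean, variance, P(0), P(>=1), P(>=2)."""
    k = np.arange(dist.pmf.size, dtype=np.float64)
    mean = float(k @ dist.pmf)
    var = float((k - mean) ** 2 @ dist.pmf)
    return pd.DataFrame(
        [
            {
                "mean_cuts": dist.mean,
                "variance": var,
                "p_zero_cuts": float(dist.pmf[0]),
                "p_ge_1_cut": float(dist.pmf[1:].sum()),
                "p_ge_2_cuts": float(dist.pmf[2:].sum()),
                "n_cells_simulated": dist.n_cells_simulated,
            }
        ]
    )
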