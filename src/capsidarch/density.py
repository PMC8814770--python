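"""Multimodal genome-length density estimation and architecture tallies.

Phage genome-length distributions are strongly multimodal, with narrow modes
at small genomes and broad, sparse modes among jumbo phages.  A single
global kernel bandwidth either over-smooths the narrow modes or fragments
the broad ones, so the density is estimated piecewise: the data range is
partitioned into genome-length regions, a Gaussian-kernel bandwidth is
selected per region by cross-validated likelihood, and the per-region
densities are combined weighted by each region's share of the sample, then
renormalized to unit mass on a common grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KernelDensity

from .g2t import ELONGATED, ArchitectureAssignment, GenomeToTResults
from .lattice import LatticeArchitecture

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_REGIONS",
    "DensityEstimate",
    "PeakSet",
    "select_bandwidth",
    "multiregion_density",
    "find_density_peaks",
    "tally_architectures",
]

#: genome-length regions (kbp) used for piecewise bandwidth selection;
#: configurable because the partition is a judgement call on the data.
DEFAULT_REGIONS: tuple[tuple[float, float], ...] = (
    (17.0, 130.0),
    (130.0, 210.0),
    (210.0, 270.0),
    (270.0, 498.0),
)

#: candidate Gaussian bandwidths (kbp), log-spaced; finer than the narrowest
#: mode and wider than the jumbo-region spread.
DEFAULT_BANDWIDTHS: np.ndarray = np.logspace(np.log10(0.1), np.log10(30.0), 30)

GRID_SIZE = 2048


@dataclass
class DensityEstimate:
    """A combined, normalized genome-length density on a common grid."""

    grid: np.ndarray
    density: np.ndarray
    regions: list[dict]  # {lo, hi, bandwidth, n}
    normalization: float

    def mass(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class PeakSet:
    """Strict local maxima of a density estimate, optionally annotated with
    the architecture assignment of each peak's genome length."""

    peaks: list[dict] = field(default_factory=list)  # {genome_kbp, density, assignment}

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p["genome_kbp"] for p in self.peaks])


def select_bandwidth(
    values: Sequence[float],
    candidate_bandwidths: Sequence[float] | None = None,
    folds: int = 5,
    seed: int | None = 0,
) -> float:
    """Pick the Gaussian-KDE bandwidth maximizing mean held-out
    log-likelihood under k-fold cross-validation with seeded shuffling."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.size == 0:
        raise ValueError("empty region: no values to select a bandwidth for")
    if candidate_bandwidths is None:
        candidate_bandwidths = DEFAULT_BANDWIDTHS
    candidates = np.asarray(candidate_bandwidths, dtype=float)
    if np.any(candidates <= 0):
        raise ValueError("candidate bandwidths must be positive")
    if x.size < folds:
        # too few points to cross-validate: fall back to the smallest candidate
        logger.warning(
            "region has %d < %d values; using smallest candidate bandwidth", x.size, folds
        )
        return float(candidates.min())
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        KernelDensity(kernel="gaussian"), {"bandwidth": candidates}, cv=cv
    )
    search.fit(x)
    return float(search.best_params_["bandwidth"])


def multiregion_density(
    values: Sequence[float],
    regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS,
    candidate_bandwidths: Sequence[float] | None = None,
    folds: int = 5,
    seed: int | None = 0,
    grid_size: int = GRID_SIZE,
) -> DensityEstimate:
    """Piecewise Gaussian KDE with per-region cross-validated bandwidths.

    Each region's KDE is weighted by its sample fraction, summed on a common
    grid, and renormalized to unit trapezoid mass.  Regions must be ordered,
    disjoint, and cover every value (region membership is ``lo <= g <= hi``;
    at shared edges the left region wins).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("no values")
    regions = [(float(lo), float(hi)) for lo, hi in regions]
    for (lo, hi), (lo2, _) in zip(regions, regions[1:]):
        if hi > lo2:
            raise ValueError("regions must be ordered and disjoint")
    membership = np.full(x.size, -1)
    for i, (lo, hi) in enumerate(regions):
        sel = (membership < 0) & (x >= lo) & (x <= hi)
        membership[sel] = i
    if np.any(membership < 0):
        bad = x[membership < 0]
        raise ValueError(
            f"{bad.size} value(s) outside all regions (e.g. {bad[0]:.3g} kbp)"
        )

    region_info = []
    kdes = []
    for i, (lo, hi) in enumerate(regions):
        vals = x[membership == i]
        if vals.size == 0:
            logger.info("region [%g, %g] kbp is empty; skipped", lo, hi)
            continue
        bw = select_bandwidth(vals, candidate_bandwidths, folds=folds, seed=seed)
        kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(vals.reshape(-1, 1))
        region_info.append({"lo": lo, "hi": hi, "bandwidth": bw, "n": int(vals.size)})
        kdes.append((kde, vals.size / x.size))

    max_bw = max(r["bandwidth"] for r in region_info)
    grid = np.linspace(x.min() - 3 * max_bw, x.max() + 3 * max_bw, grid_size)
    density = np.zeros_like(grid)
    for kde, weight in kdes:
        density += weight * np.exp(kde.score_samples(grid.reshape(-1, 1)))
    norm = float(np.trapezoid(density, grid))
    density /= norm
    return DensityEstimate(
        grid=grid, density=density, regions=region_info, normalization=norm
    )


def find_density_peaks(
    estimate: DensityEstimate,
    fit: GenomeToTResults | None = None,
    mre: float | None = None,
    architectures: Sequence[LatticeArchitecture] | None = None,
    min_prominence_frac: float = 0.01,
) -> PeakSet:
    """Strict local maxima of the density with prominence above a fraction
    of the global maximum (suppresses float-noise maxima).  When a fitted
    genome-to-T model is supplied, each peak's genome length is annotated
    with its architecture assignment."""
    if estimate.grid.size < 3:
        raise ValueError("grid too short to define interior maxima")
    prominence = min_prominence_frac * float(estimate.density.max())
    idx, _ = find_peaks(estimate.density, prominence=prominence)
    peaks = []
    for i in idx:
        g = float(estimate.grid[i])
        entry: dict = {"genome_kbp": g, "density": float(estimate.density[i])}
        if fit is not None and mre is not None and g > 0:
            entry["assignment"] = fit.assign(g, mre, architectures)
        else:
            entry["assignment"] = None
        peaks.append(entry)
    return PeakSet(peaks=peaks)


def tally_architectures(
    assignments: Sequence[ArchitectureAssignment],
) -> pd.DataFrame:
    """Per-architecture counts and percentages over a set of assignments.

    One row per selected architecture label plus summary rows for the
    icosahedral and elongated totals; percentages sum to 100 up to rounding.
    """
    if not assignments:
        raise ValueError("no assignments to tally")
    labels = [a.label for a in assignments]
    counts = pd.Series(labels).value_counts()
    total = int(counts.sum())
    rows = [
        {
            "label": label,
            "count": int(cnt),
            "percent": 100.0 * cnt / total,
            "kind": ELONGATED if label == ELONGATED else "icosahedral",
        }
        for label, cnt in counts.items()
    ]
    df = pd.DataFrame(rows)

    def _t_sort(label: str) -> float:
        return float("inf") if label == ELONGATED else float(label.removeprefix("T="))

    df = df.sort_values("label", key=lambda s: s.map(_t_sort)).reset_index(drop=True)
    n_elong = int(df.loc[df["kind"] == ELONGATED, "count"].sum())
    df.attrs["n_total"] = total
    df.attrs["n_elongated"] = n_elong
    df.attrs["n_icosahedral"] = total - n_elong
    df.attrs["percent_elongated"] = 100.0 * n_elong / total
    return df
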