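"""Ensemble statistics used by the validation battery.

The histogram and L² conventions are fixed package-wide: density
histograms use 20 bins over a stated range with frequencies divided by the
bin width (so they integrate to one exactly), and two binned densities are
compared as  sqrt(Σ_k (Δp_k)²·w_k)  with w_k the bin widths, also reported
as a percentage of the reference curve's maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np


def density_histogram(samples, value_range: Tuple[float, float],
                      bins: int = 20) -> Tuple[np.ndarray, np.ndarray]:
    """Normalized binned density estimate.

    Returns (density values, bin edges); Σ value_k·width_k = 1 exactly.
    Samples above the range are counted in the last bin (and the clipped
    count is reported via a warning-free return contract: callers choose
    ranges covering their samples).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample set")
    lo, hi = map(float, value_range)
    if hi <= lo:
        raise ValueError("invalid range")
    clipped = np.clip(samples, lo, np.nextafter(hi, lo))
    edges = np.linspace(lo, hi, bins + 1)
    counts, _ = np.histogram(clipped, bins=edges)
    width = edges[1] - edges[0]
    density = counts / (counts.sum() * width)
    return density, edges


def rebin_density(density: np.ndarray, edges: np.ndarray,
                  new_edges: np.ndarray) -> np.ndarray:
    """Integral-preserving rebin of a piecewise-constant density.

    The returned values are averages of the input density over the new
    bins (mass overlapping each new bin divided by its width); mass
    outside the new range is dropped.
    """
    density = np.asarray(density, float)
    edges = np.asarray(edges, float)
    cum = np.concatenate([[0.0], np.cumsum(density * np.diff(edges))])
    cdf = lambda x: np.interp(x, edges, cum)  # noqa: E731
    new_edges = np.asarray(new_edges, float)
    mass = np.diff(cdf(new_edges))
    return mass / np.diff(new_edges)


def l2_difference(pdf_a: np.ndarray, pdf_b: np.ndarray,
                  widths) -> Tuple[float, float]:
    """(absolute L² value, % of the reference maximum).

    ``pdf_a`` is the reference when expressing the percentage. Both inputs
    must share one binning; ``widths`` may be a scalar bin width or a
    per-bin array.
    """
    pdf_a = np.asarray(pdf_a, float)
    pdf_b = np.asarray(pdf_b, float)
    if pdf_a.shape != pdf_b.shape:
        raise ValueError("histograms must share one binning")
    w = np.broadcast_to(np.asarray(widths, float), pdf_a.shape)
    l2 = math.sqrt(float(((pdf_a - pdf_b) ** 2 * w).sum()))
    ref_max = float(np.max(np.abs(pdf_a)))
    pct = 100.0 * l2 / ref_max if ref_max > 0 else 0.0
    return l2, pct


def solution_error(ensemble_mean: np.ndarray,
                   exact: np.ndarray) -> float:
    """ε = max over sampled times of |exact − ensemble mean|."""
    ensemble_mean = np.asarray(ensemble_mean, float)
    exact = np.asarray(exact, float)
    if ensemble_mean.shape != exact.shape:
        raise ValueError("curves must share one time grid")
    return float(np.max(np.abs(exact - ensemble_mean)))


def loglog_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of log y against log x (both must be > 0)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log slope needs positive data")
    return float(np.polyfit(np.log(x), np.log(y), 1)[0])


# ---------------------------------------------------------------------------
# stochastically gated binding: relaxation function and its asymptote
# ---------------------------------------------------------------------------

@dataclass
class RelaxationRecord:
    """Complex-count trajectory of the gated-binding model plus the
    parameters entering the closed-form long-time asymptote."""

    times: np.ndarray
    complexes: np.ndarray          # ensemble-mean C(t)
    kappa_f: float                 # μm³/s
    kappa_r: float                 # s⁻¹
    a: float                       # activation rate, s⁻¹
    b: float                       # inactivation rate, s⁻¹
    L0: float                      # ligand number density, μm⁻³
    D: float                       # μm²/s
    C_eq: Optional[float] = None   # default: C at the latest recorded time

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.complexes = np.asarray(self.complexes, float)
        if self.C_eq is None:
            self.C_eq = float(self.complexes[-1])


def relaxation_asymptote(rec: RelaxationRecord, t) -> np.ndarray:
    """Diffusion-controlled power-law tail of the relaxation function:

        κ_f (1 + a/b) (4πDt)^(−3/2) / [κ_r (1 + a/b + L0·κ_f/κ_r)²].
    """
    t = np.asarray(t, float)
    ab = rec.a / rec.b
    denom = rec.kappa_r * (1.0 + ab + rec.L0 * rec.kappa_f / rec.kappa_r) ** 2
    return rec.kappa_f * (1.0 + ab) * (4.0 * math.pi * rec.D * t) ** (-1.5) \
        / denom


def relaxation_analysis(rec: RelaxationRecord,
                        slope_window: Optional[Tuple[float, float]] = None
                        ) -> dict:
    """Relaxation curve 1 − C(t)/C_eq, its closed-form asymptote, and a
    log-log tail-slope estimate over ``slope_window`` (s)."""
    relax = (rec.C_eq - rec.complexes) / rec.C_eq if rec.C_eq != 0 \
        else np.ones_like(rec.complexes)
    pos = rec.times > 0
    asym = np.full_like(relax, np.nan)
    asym[pos] = relaxation_asymptote(rec, rec.times[pos])
    slope = np.nan
    if slope_window is not None:
        lo, hi = slope_window
        sel = (rec.times >= lo) & (rec.times <= hi) & (relax > 0)
        if sel.sum() >= 3:
            slope = loglog_slope(rec.times[sel], relax[sel])
    return {"times": rec.times, "relaxation": relax, "asymptote": asym,
            "tail_slope": slope, "C_eq": rec.C_eq}


# ---------------------------------------------------------------------------
# cluster counting for polarization diagnostics
# ---------------------------------------------------------------------------

def count_clusters(points: np.ndarray, radius: float,
                   min_samples: int = 2) -> int:
    """Number of density-based clusters of membrane points.

    DBSCAN on Cartesian (chordal) distances; a diagnostic for coarsening
    of active-receptor clusters, not an acceptance metric.  Isolated
    points count as their own clusters.
    """
    from sklearn.cluster import DBSCAN
    points = np.asarray(points, float)
    if len(points) == 0:
        return 0
    labels = DBSCAN(eps=radius, min_samples=min_samples).fit(points).labels_
    return int(len(set(labels[labels >= 0])) + (labels < 0).sum())
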