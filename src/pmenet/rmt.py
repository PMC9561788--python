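"""Random-matrix-theory threshold selection.

The similarity threshold for network construction is chosen by a spectral
criterion: as the correlation matrix is thresholded at increasing cutoffs,
its eigenvalue nearest-neighbor spacing distribution (NNSD) transitions
from Gaussian-orthogonal-ensemble statistics (Wigner surmise, level
repulsion — the signature of a densely coupled random background) to
Poisson statistics (independent levels — the signature of decoupled,
system-specific modules).  The selected threshold is the smallest cutoff
at which the NNSD is consistent with Poisson and remains so at the next
testable cutoff.

Spacing statistics only make sense on an *unfolded* spectrum: eigenvalues
are mapped through a smooth estimate of the cumulative spectral density so
that the mean level spacing is one everywhere, making NNSDs comparable
across spectra of different densities.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .correlation import CorrelationMatrix, threshold_matrix

logger = logging.getLogger(__name__)

#: Minimum spectrum size for a meaningful NNSD.
MIN_EIGENVALUES = 20


@dataclass
class SpacingSample:
    """Nearest-neighbor spacings of an unfolded spectrum (mean ~ 1)."""

    spacings: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.spacings, dtype=float)
        if np.any(s < -1e-9):
            raise ValueError("unfolded spacings must be non-negative")
        self.spacings = np.clip(s, 0.0, None)

    def __len__(self) -> int:
        return len(self.spacings)

    @property
    def mean(self) -> float:
        return float(np.mean(self.spacings))


def unfold_spectrum(eigenvalues: np.ndarray, n_knots: int | None = None,
                    edge_trim: float = 0.025) -> SpacingSample:
    """Unfold a spectrum and return its nearest-neighbor spacings.

    The empirical cumulative spectral distribution (a staircase at midrank
    heights i + 1/2) is smoothed by a monotone cubic (PCHIP) interpolant
    through quantile-spaced knots; eigenvalues mapped through this smooth
    cumulative count have unit mean spacing.  `n_knots` controls the
    smoothing (fewer knots = smoother density estimate); the default is
    max(5, round(sqrt(m))) for m eigenvalues.

    A fraction `edge_trim` of levels is discarded at each end of the
    spectrum before unfolding: the smooth density estimate is unreliable
    at the spectral edges, and detached extreme levels (e.g. the Perron
    eigenvalues contributed by dense modules) are not part of the bulk
    ensemble the spacing statistics describe.

    Degenerate eigenvalues are allowed and produce zero spacings.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if not (0 <= edge_trim < 0.5):
        raise ValueError("edge_trim must lie in [0, 0.5)")
    k = int(lam.size * edge_trim)
    if k:
        lam = lam[k:-k]
    m = lam.size
    if m < MIN_EIGENVALUES:
        raise ValueError(
            f"spectrum too small for NNSD ({m} < {MIN_EIGENVALUES} eigenvalues)"
        )
    if n_knots is None:
        n_knots = max(5, round(math.sqrt(m)))
    n_knots = int(min(max(n_knots, 3), m))
    midrank = np.arange(m) + 0.5
    idx = np.unique(np.round(np.linspace(0, m - 1, n_knots)).astype(int))
    x, y = lam[idx], midrank[idx]
    # collapse duplicate abscissae (degenerate levels) to their mean height
    ux, inv = np.unique(x, return_inverse=True)
    if ux.size < 2:
        raise ValueError("spectrum is fully degenerate; cannot unfold")
    uy = np.zeros_like(ux)
    np.add.at(uy, inv, y)
    uy /= np.bincount(inv)
    f = PchipInterpolator(ux, uy, extrapolate=True)
    unfolded = f(lam)
    spacings = np.diff(unfolded)
    return SpacingSample(spacings=np.clip(spacings, 0.0, None))


@dataclass
class GofResult:
    """Chi-square goodness-of-fit of a spacing histogram to a reference NNSD."""

    chi2: float
    dof: int
    p_value: float


def _equal_probability_edges(ppf, n_bins: int) -> np.ndarray:
    q = np.arange(1, n_bins) / n_bins
    inner = ppf(q)
    return np.concatenate(([0.0], inner, [np.inf]))


def _poisson_ppf(q: np.ndarray) -> np.ndarray:
    # inverse CDF of P(s) = exp(-s)
    return -np.log1p(-q)


def _wigner_ppf(q: np.ndarray) -> np.ndarray:
    # inverse CDF of the Wigner surmise P(s) = (pi s / 2) exp(-pi s^2 / 4)
    return np.sqrt(-4.0 * np.log1p(-q) / np.pi)


def spacing_gof(spacings: SpacingSample | np.ndarray, dist: str = "poisson",
                n_bins: int | None = None) -> GofResult:
    """Chi-square test of unfolded spacings against a reference distribution.

    Bins are equal-probability under the reference (`poisson` for
    P(s)=e^-s, `wigner` for the GOE surmise), so expected counts are m/n_bins
    in every bin; dof = n_bins - 1.  Default n_bins = max(5, ceil(1 + log2 m)).
    Adjacent bins are merged if the expected count drops below one (only
    possible for pathological n_bins).
    """
    s = spacings.spacings if isinstance(spacings, SpacingSample) else np.asarray(spacings, float)
    m = s.size
    if m < MIN_EIGENVALUES:
        raise ValueError(f"need at least {MIN_EIGENVALUES} spacings, got {m}")
    if n_bins is None:
        n_bins = max(5, math.ceil(1 + math.log2(m)))
    if m / n_bins < 1:
        merged = max(2, m // 2)
        logger.warning("spacing_gof: expected count < 1; merging %d bins into %d",
                       n_bins, merged)
        n_bins = merged
    ppf = {"poisson": _poisson_ppf, "wigner": _wigner_ppf}[dist]
    edges = _equal_probability_edges(ppf, n_bins)
    observed, _ = np.histogram(s, bins=edges)
    expected = np.full(n_bins, m / n_bins)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    dof = n_bins - 1
    p = float(stats.chi2.sf(chi2, dof))
    return GofResult(chi2=chi2, dof=dof, p_value=p)


def nnsd_poisson_test(spacings: SpacingSample | np.ndarray,
                      n_bins: int | None = None) -> GofResult:
    """Goodness-of-fit of the NNSD against the Poisson form P(s) = e^(-s)."""
    return spacing_gof(spacings, dist="poisson", n_bins=n_bins)


# ---------------------------------------------------------------------------
# Threshold scan and selection
# ---------------------------------------------------------------------------

SCAN_COLUMNS = ["threshold", "n_nodes", "n_eigenvalues", "chi2", "dof",
                "p_value", "poisson_ok", "testable"]


@dataclass
class ThresholdScan:
    """Per-threshold spectral statistics driving the RMT threshold choice.

    One row per scanned cutoff: size of the non-isolated submatrix, its
    eigenvalue count, the Poisson NNSD chi-square test, and whether the
    Poisson hypothesis is accepted at the scan's alpha.  Cutoffs whose
    submatrix falls below the minimum spectrum size are flagged untestable.
    """

    table: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        t = self.table["threshold"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError("scan thresholds must be strictly increasing")
        n = self.table["n_nodes"].to_numpy()
        if np.any(np.diff(n) > 0):
            raise ValueError("retained-node count must be non-increasing")
        p = self.table["p_value"].dropna()
        if len(p) and (p.min() < 0 or p.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"alpha": self.alpha,
             "rows": self.table.where(self.table.notna(), None).to_dict("records")},
            indent=2, default=float,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def scan_thresholds(corr: CorrelationMatrix, t_min: float = 0.01,
                    t_max: float = 0.95, step: float = 0.01,
                    alpha: float = 0.05,
                    n_knots: int | None = None) -> ThresholdScan:
    """Scan cutoffs over [t_min, t_max] and test the NNSD at each.

    For each cutoff the non-isolated thresholded submatrix is built, its
    eigenvalues computed, unfolded, and tested against the Poisson NNSD;
    `poisson_ok` records p >= alpha.  Submatrices smaller than the minimum
    spectrum size are carried as untestable rows rather than errors.
    """
    if not (0 < t_min < t_max < 1) or step <= 0:
        raise ValueError("invalid scan grid")
    n_steps = int(round((t_max - t_min) / step))
    grid = np.round(t_min + step * np.arange(n_steps + 1), 10)
    grid = grid[grid <= t_max + 1e-12]
    rows = []
    for t in grid:
        sub = threshold_matrix(corr, float(t))
        n_nodes = sub.size
        row = {"threshold": float(t), "n_nodes": n_nodes,
               "n_eigenvalues": n_nodes, "chi2": np.nan, "dof": np.nan,
               "p_value": np.nan, "poisson_ok": False, "testable": False}
        if n_nodes >= MIN_EIGENVALUES:
            eig = np.linalg.eigvalsh(sub.values)
            try:
                spacings = unfold_spectrum(eig, n_knots=n_knots)
                gof = nnsd_poisson_test(spacings)
            except ValueError:
                rows.append(row)
                continue
            row.update(chi2=gof.chi2, dof=gof.dof, p_value=gof.p_value,
                       poisson_ok=bool(gof.p_value >= alpha), testable=True)
        rows.append(row)
    table = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    return ThresholdScan(table=table, alpha=alpha)


def select_threshold(scan: ThresholdScan, mode: str = "auto",
                     fixed_t: float | None = None) -> float:
    """Pick the similarity threshold from a scan.

    auto:
        the smallest cutoff at which the Poisson hypothesis is accepted
        and remains accepted at the next testable cutoff (requiring two
        consecutive acceptances suppresses single-threshold flickers).
    fixed:
        return `fixed_t` verbatim; used to hold the threshold constant
        across networks that are to be compared (e.g. 0.83).
    """
    if mode == "fixed":
        if fixed_t is None:
            raise ValueError("fixed mode requires fixed_t")
        return float(fixed_t)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    rows = scan.table[scan.table["testable"]].reset_index(drop=True)
    if rows.empty:
        raise ValueError("no testable threshold in scan; cannot auto-select")
    ok = rows["poisson_ok"].to_numpy()
    for i in range(len(rows) - 1):
        if ok[i] and ok[i + 1]:
            return float(rows.loc[i, "threshold"])
    raise ValueError(
        "no threshold with two consecutive Poisson acceptances; scan table:\n"
        + rows.to_string(index=False)
    )
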