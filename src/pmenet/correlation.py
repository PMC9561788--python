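"""Spearman rank correlation matrices over ASV abundance profiles.

Co-occurrence is measured by Spearman's rho, i.e. the Pearson correlation
of midranks.  Because ranks are invariant under strictly monotone
transforms, any log or power transform of the counts leaves the matrix
unchanged; the pipeline therefore correlates rarefied counts directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .abundance import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric Spearman rho matrix with unit diagonal.

    Attributes
    ----------
    values:
        (p, p) array, values[i, j] = rho between ASV i and ASV j.
    asv_ids:
        node labels, aligned with the matrix axes.
    n_obs:
        number of samples each pairwise rho was computed from.
    """

    values: np.ndarray
    asv_ids: list
    n_obs: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if v.shape[0] != len(self.asv_ids):
            raise ValueError("asv_ids length does not match matrix size")
        if not np.allclose(v, v.T, atol=0, rtol=0, equal_nan=True):
            raise ValueError("correlation matrix must be exactly symmetric")
        if v.size and np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")
        self.values = v

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries as a flat vector."""
        iu = np.triu_indices(self.size, k=1)
        return self.values[iu]


def spearman_matrix(table: AbundanceTable) -> CorrelationMatrix:
    """All-pairs Spearman rho over the rows (ASVs) of an abundance table.

    Zeros take part in ranking as ties.  An ASV with zero variance across
    samples has undefined correlations; these are set to 0 with a warning
    (such a node cannot co-vary and will drop out as isolated downstream).
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    X = table.counts.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    ranks = stats.rankdata(X, axis=1)  # midranks: zeros tie like any value
    with warnings.catch_warnings(), np.errstate(invalid="ignore",
                                                divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(ranks)
    if constant.any():
        logger.warning(
            "spearman_matrix: %d zero-variance ASV(s); correlations set to 0: %s",
            constant.sum(),
            [a for a, c in zip(table.asv_ids, constant) if c][:10],
        )
    rho = np.nan_to_num(rho, nan=0.0)
    rho = (rho + rho.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(rho, 1.0)
    np.clip(rho, -1.0, 1.0, out=rho)
    return CorrelationMatrix(values=rho, asv_ids=table.asv_ids,
                             n_obs=table.n_samples)


def threshold_matrix(corr: CorrelationMatrix, t: float) -> CorrelationMatrix:
    """Zero out entries with |rho| < t and drop isolated rows/columns.

    The unit diagonal is retained.  A row whose off-diagonal entries all
    fall below the threshold corresponds to an ASV with no surviving link;
    it is removed so the returned matrix is the non-isolated submatrix.
    """
    if not (0 < t < 1):
        raise ValueError("threshold must lie in (0, 1)")
    v = corr.values.copy()
    mask = np.abs(v) < t
    np.fill_diagonal(mask, False)
    v[mask] = 0.0
    off = v.copy()
    np.fill_diagonal(off, 0.0)
    keep = np.where(np.any(off != 0.0, axis=1))[0]
    v = v[np.ix_(keep, keep)]
    ids = [corr.asv_ids[i] for i in keep]
    return CorrelationMatrix(values=v, asv_ids=ids, n_obs=corr.n_obs)
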