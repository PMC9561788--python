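"""Reading, validation, filtering and rarefaction of ASV count tables.

The pipeline's raw input is an ASV-by-sample table of non-negative integer
read counts, a taxonomy table mapping each ASV to a (up to) seven-rank
lineage, and per-sample metadata describing the incubation design
(treatment group, sediment layer, sampling week, replicate).  All
downstream network inference operates on tables that have been rarefied to
a common sequencing depth and filtered by relative abundance and
prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical lineage ranks, most to least inclusive (Silva-style).
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Metadata columns every sample record must carry.
METADATA_COLUMNS = ("group", "layer", "week", "replicate")


class AbundanceTableError(ValueError):
    """Raised when an abundance table violates its invariants."""


@dataclass
class AbundanceTable:
    """ASV x sample integer counts plus taxonomy and sample metadata.

    Parameters
    ----------
    counts:
        DataFrame indexed by ASV id with one column per sample; values are
        non-negative integer read counts.
    taxonomy:
        Series mapping ASV id -> semicolon-separated lineage string
        (``domain;phylum;...``).  Keys must cover every ASV in `counts`;
        trailing ranks may be missing or empty (unassigned).
    metadata:
        DataFrame indexed by sample id with columns
        ``group, layer, week, replicate``; must contain exactly one record
        per sample in `counts`.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise AbundanceTableError(f"duplicate ASV identifiers: {dupes}")
        if counts.columns.has_duplicates:
            dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise AbundanceTableError(f"duplicate sample identifiers: {dupes}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise AbundanceTableError("counts must be integers")
            self.counts = counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            bad = counts.index[(arr < 0).any(axis=1)].tolist()
            raise AbundanceTableError(f"negative count in ASVs {bad}")
        missing_tax = counts.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise AbundanceTableError(
                f"ASVs without taxonomy: {missing_tax.tolist()}"
            )
        missing_meta = counts.columns.difference(self.metadata.index)
        if len(missing_meta):
            raise AbundanceTableError(
                f"samples missing from metadata: {missing_meta.tolist()}"
            )
        absent = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if absent:
            raise AbundanceTableError(f"metadata lacks columns {absent}")

    # -- convenience ------------------------------------------------------
    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def lineage(self, asv: str) -> dict[str, str]:
        """Return the rank -> name mapping for one ASV (missing ranks empty)."""
        parts = [p.strip() for p in str(self.taxonomy.loc[asv]).split(";")]
        parts += [""] * (len(RANKS) - len(parts))
        return dict(zip(RANKS, parts))


@dataclass
class GroupSelector:
    """Conjunction of equality tests over metadata columns.

    ``GroupSelector({"group": "aeration", "layer": "top"}, label="aer-top")``
    selects the aerated top-layer samples.  Selections smaller than
    `min_samples` trigger a warning; selections with fewer than two samples
    are an error (a correlation needs at least two observations).
    """

    where: dict = field(default_factory=dict)
    label: str = "all"
    min_samples: int = 9

    def mask(self, metadata: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=metadata.index)
        for col, val in self.where.items():
            if col not in metadata.columns:
                raise KeyError(f"selector references unknown metadata column {col!r}")
            m &= metadata[col] == val
        return m


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    """Read a TSV, tolerating a leading '# Constructed from biom file' line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("# Constructed from biom file") else 0
    return pd.read_csv(path, sep="\t", skiprows=skip, **kw)


def read_abundance(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
) -> AbundanceTable:
    """Read the three input TSVs and return a validated table.

    The counts file has ASVs as rows (first column = ASV id) and samples as
    columns; the taxonomy file has columns ``asv_id`` and ``lineage``
    (semicolon-separated ranks); the metadata file has columns
    ``sample, group, layer, week, replicate``.  Row and column order is
    preserved from the files.
    """
    counts = _read_tsv(counts_path, index_col=0)
    try:
        counts = counts.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise AbundanceTableError(f"counts do not parse as numbers: {exc}") from exc
    tax_df = _read_tsv(taxonomy_path)
    if tax_df.shape[1] < 2:
        raise AbundanceTableError("taxonomy file needs id and lineage columns")
    taxonomy = pd.Series(
        tax_df.iloc[:, 1].astype(str).values, index=tax_df.iloc[:, 0].astype(str)
    )
    if taxonomy.index.has_duplicates:
        dupes = taxonomy.index[taxonomy.index.duplicated()].unique().tolist()
        raise AbundanceTableError(f"duplicate taxonomy entries: {dupes}")
    meta = _read_tsv(metadata_path, index_col=0)
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise AbundanceTableError(f"duplicate metadata samples: {dupes}")
    counts.index = counts.index.astype(str)
    return AbundanceTable(counts=counts, taxonomy=taxonomy, metadata=meta)


def write_abundance(table: AbundanceTable, outdir: str | Path,
                    prefix: str = "") -> dict[str, Path]:
    """Write counts/taxonomy/metadata TSVs in the dialect `read_abundance` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}counts.tsv",
        "taxonomy": outdir / f"{prefix}taxonomy.tsv",
        "metadata": outdir / f"{prefix}metadata.tsv",
    }
    table.counts.rename_axis("asv_id").to_csv(paths["counts"], sep="\t")
    tax = table.taxonomy.rename("lineage").rename_axis("asv_id")
    tax.to_frame().to_csv(paths["taxonomy"], sep="\t")
    table.metadata.rename_axis("sample").to_csv(paths["metadata"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample every sample to exactly `depth` reads without replacement.

    Samples whose total is below `depth` are dropped with a warning.
    Subsampling is multivariate hypergeometric (QIIME-style rarefaction),
    so each rarefied count never exceeds the original and the expectation
    of a count c in a sample of total N is c * depth / N.  Deterministic
    for a given seed and input.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, list(dropped),
        )
    cols = {}
    for s in table.counts.columns:
        if s not in keep:
            continue
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(cols, index=table.counts.index)
    return AbundanceTable(counts=counts, taxonomy=table.taxonomy,
                          metadata=table.metadata.loc[counts.columns])


def filter_relative_abundance(table: AbundanceTable,
                              min_frac: float = 1e-5) -> AbundanceTable:
    """Drop ASVs whose pooled relative abundance is below `min_frac`.

    Relative abundance of an ASV is its total count over the grand total of
    the table (pooled across samples).  ASVs exactly at the threshold are
    retained (only those strictly below are removed); the default 1e-5
    corresponds to the conventional 0.001% cut.
    """
    if not (0 <= min_frac < 1):
        raise ValueError("min_frac must be in [0, 1)")
    grand = table.counts.to_numpy().sum()
    if grand == 0:
        raise AbundanceTableError("empty table (grand total is zero)")
    frac = table.counts.sum(axis=1) / grand
    keep = frac[frac >= min_frac].index
    counts = table.counts.loc[keep]
    return AbundanceTable(counts=counts, taxonomy=table.taxonomy,
                          metadata=table.metadata)


def filter_prevalence(table: AbundanceTable,
                      min_prevalence: float = 0.5) -> AbundanceTable:
    """Keep ASVs present (count > 0) in strictly more than `min_prevalence`
    of the samples.

    The default 0.5 implements the "present in more than half of the
    samples" rule used before network construction; the strict inequality
    means an ASV present in exactly half the samples is removed.
    """
    n = table.n_samples
    prev = (table.counts > 0).sum(axis=1) / n
    keep = prev[prev > min_prevalence].index
    counts = table.counts.loc[keep]
    return AbundanceTable(counts=counts, taxonomy=table.taxonomy,
                          metadata=table.metadata)


def select_group(table: AbundanceTable, selector: GroupSelector) -> AbundanceTable:
    """Return the sample subset matched by `selector` (ASV set unchanged).

    Prevalence filtering is meant to happen *after* group selection, so
    the full ASV set is carried through here.
    """
    mask = selector.mask(table.metadata)
    samples = table.metadata.index[mask]
    samples = [s for s in table.counts.columns if s in set(samples)]
    if len(samples) == 0:
        raise AbundanceTableError(f"selector {selector.label!r} matched no samples")
    if len(samples) < 2:
        raise AbundanceTableError(
            f"selector {selector.label!r} matched {len(samples)} sample(s); "
            "need at least 2"
        )
    if len(samples) < selector.min_samples:
        logger.warning(
            "selector %r matched only %d samples (< %d)",
            selector.label, len(samples), selector.min_samples,
        )
    counts = table.counts[samples]
    return AbundanceTable(counts=counts, taxonomy=table.taxonomy,
                          metadata=table.metadata.loc[samples])
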