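"""Count-table IO and the data-cleaning stage.

Handles the HUMAnN2 gene-families TSV dialect (annotation ID in the first
column, one numeric column per sample, values on a counts-per-megabase
scale), the accompanying sample-metadata table, sequencing-depth
classification, contaminant-row removal against mock/soil control samples,
per-sample rescaling, and imputation of a third replicate for two-sample
groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phyllodiff")

#: Accepted first-column headers for count TSVs.
COUNT_HEADER_ALIASES = ("# Gene Family", "annotation_id")

#: Sequencing-depth class breakpoints, in reads.  The published class
#: definitions leave a gap between 1.6m and 1.7m; reads in (1.6m, 1.7m)
#: are assigned to "large" here since "deep" starts above 1.7m.
DEPTH_BREAKS = (233_000, 500_000, 1_700_000)
DEPTH_LABELS = ("small", "moderate", "large", "deep")

VALID_TREATMENTS = frozenset({"watered", "drought", "none"})
VALID_CLASSES = frozenset({"experimental", "mock", "soil"})
CONTROL_CLASSES = frozenset({"mock", "soil"})

#: Floor applied to method-of-moments dispersion when imputing a replicate.
IMPUTE_DISPERSION_FLOOR = 0.01


class CountTableError(ValueError):
    """Raised when a count table or its metadata violates the contract."""


@dataclass
class CountTable:
    """An annotation x sample matrix of non-negative counts with sample metadata.

    Parameters
    ----------
    counts
        DataFrame with annotation IDs as the index and sample IDs as
        columns; values are non-negative finite reals (raw or
        counts-per-megabase scale).
    samples
        DataFrame indexed by sample ID with columns ``site``,
        ``treatment`` (watered / drought / none) and ``class``
        (experimental / mock / soil).  An optional boolean ``imputed``
        column marks pseudo-replicates.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate annotation IDs: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.counts.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise CountTableError("counts must be finite and non-negative")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise CountTableError(f"samples missing from metadata: {missing}")
        for col in ("site", "treatment", "class"):
            if col not in self.samples.columns:
                raise CountTableError(f"metadata lacks required column {col!r}")
        bad_t = set(self.samples["treatment"]) - VALID_TREATMENTS
        if bad_t:
            raise CountTableError(f"unknown treatment values: {sorted(bad_t)}")
        bad_c = set(self.samples["class"]) - VALID_CLASSES
        if bad_c:
            raise CountTableError(f"unknown sample class values: {sorted(bad_c)}")

    # -- conveniences -----------------------------------------------------
    @property
    def annotation_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_annotations(self) -> int:
        return self.counts.shape[0]

    def meta(self, sample_id: str) -> pd.Series:
        return self.samples.loc[sample_id]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def experimental_samples(self) -> list[str]:
        cls = self.samples.loc[self.counts.columns, "class"]
        return [s for s in self.counts.columns if cls[s] == "experimental"]

    def control_samples(self) -> list[str]:
        cls = self.samples.loc[self.counts.columns, "class"]
        return [s for s in self.counts.columns if cls[s] in CONTROL_CLASSES]

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        return CountTable(self.counts[list(sample_ids)].copy(),
                          self.samples.loc[list(sample_ids)].copy())

    def drop_annotations(self, annotation_ids) -> "CountTable":
        keep = self.counts.index.difference(pd.Index(annotation_ids), sort=False)
        return CountTable(self.counts.loc[keep].copy(), self.samples.copy())

    def write(self, counts_path, metadata_path=None, header: str = "# Gene Family") -> None:
        """Write the counts as a gene-families TSV (and optionally the metadata CSV)."""
        out = self.counts.copy()
        out.index.name = header
        out.to_csv(counts_path, sep="\t")
        if metadata_path is not None:
            meta = self.samples.copy()
            meta.index.name = "sample_id"
            meta.to_csv(metadata_path)


@dataclass(frozen=True)
class DepthClass:
    """A sequencing-depth class with its half-open bounds in reads."""

    label: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.label not in DEPTH_LABELS:
            raise ValueError(f"unknown depth label {self.label!r}")


_DEPTH_CLASSES = (
    DepthClass("small", 0, DEPTH_BREAKS[0]),
    DepthClass("moderate", DEPTH_BREAKS[0], DEPTH_BREAKS[1]),
    DepthClass("large", DEPTH_BREAKS[1], DEPTH_BREAKS[2]),
    DepthClass("deep", DEPTH_BREAKS[2], float("inf")),
)


def classify_depth(total_reads: float) -> DepthClass:
    """Classify a sample's read depth into small / moderate / large / deep.

    Breakpoints are 233k, 500k and 1.7m reads; intervals are half-open on
    the right, so 233,000 reads is "moderate" and reads between 1.6m and
    1.7m fall in "large" (the published definitions leave that range
    unassigned; "deep" is reserved for > 1.7m).
    """
    if total_reads < 0:
        raise ValueError(f"total_reads must be >= 0, got {total_reads}")
    for cls in _DEPTH_CLASSES:
        if cls.lower <= total_reads < cls.upper:
            return cls
    raise AssertionError("unreachable: depth classes partition [0, inf)")


def read_count_table(path, metadata_path) -> CountTable:
    """Read a gene-families TSV plus its sample-metadata CSV.

    Both the ``# Gene Family`` (HUMAnN2) and ``annotation_id`` first-column
    headers are accepted.  Rows whose counts are all zero are retained;
    filtering is an explicit downstream step.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.name not in COUNT_HEADER_ALIASES:
        raise CountTableError(
            f"unrecognised count-table header {counts.index.name!r}; "
            f"expected one of {COUNT_HEADER_ALIASES}"
        )
    counts.index.name = None
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    if counts.index.has_duplicates:
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise CountTableError(f"duplicate annotation IDs in {path}: {dups[:5]}")

    meta = pd.read_csv(metadata_path, dtype=str)
    if "sample_id" not in meta.columns:
        raise CountTableError(f"metadata {metadata_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    if "imputed" in meta.columns:
        meta["imputed"] = meta["imputed"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes"))

    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise CountTableError(f"samples missing from metadata: {missing}")
    return CountTable(counts.astype(float), meta)


def filter_contaminants(
    table: CountTable, threshold: float = 0.0
) -> tuple[CountTable, list[str]]:
    """Remove annotations observed in mock/soil control samples.

    Every annotation whose count exceeds ``threshold`` (default 0, i.e.
    any presence) in at least one mock or soil sample is removed from all
    samples; the control columns themselves are dropped from the returned
    table.  If the table has no control samples the operation is the
    identity, with a warning.
    """
    controls = table.control_samples()
    if not controls:
        warnings.warn("no mock/soil samples present; contaminant filter is a no-op",
                      stacklevel=2)
        return table, []
    present = (table.counts[controls] > threshold).any(axis=1)
    removed = table.counts.index[present].tolist()
    keep_samples = [s for s in table.counts.columns if s not in controls]
    cleaned = CountTable(
        table.counts.loc[~present, keep_samples].copy(),
        table.samples.loc[keep_samples].copy(),
    )
    logger.info("contaminant filter removed %d of %d annotations and %d control columns",
                len(removed), table.n_annotations, len(controls))
    return cleaned, removed


def normalize_cpm(table: CountTable, per_megabase_denominators) -> CountTable:
    """Scale each sample's counts by its per-megabase denominator.

    ``per_megabase_denominators`` maps sample ID -> positive denominator
    (sequencing output in megabases); a scalar applies to every sample.
    """
    denom = per_megabase_denominators
    if np.isscalar(denom):
        denom = {s: float(denom) for s in table.sample_ids}
    denom = pd.Series(denom, dtype=float)
    missing = [s for s in table.sample_ids if s not in denom.index]
    if missing:
        raise ValueError(f"no denominator for samples: {missing}")
    bad = denom[denom <= 0]
    if len(bad):
        raise ValueError(f"non-positive denominators for: {list(bad.index)}")
    scaled = table.counts.div(denom[table.sample_ids], axis=1)
    return CountTable(scaled, table.samples.copy())


def impute_replicate(group: CountTable, seed: int, suffix: str = "_imp") -> CountTable:
    """Append one pseudo-replicate to a two-sample group.

    The downstream two-stage test needs three replicates per group; groups
    observed with only two get a third column drawn per annotation from a
    negative binomial whose moments come from the two observed values
    (dispersion floored at 0.01), at a depth matching the geometric mean
    of the two observed column totals.  The new column is flagged
    ``imputed=True`` in the metadata and the observed columns are
    untouched.
    """
    if len(group.sample_ids) != 2:
        raise ValueError(
            f"imputation needs exactly 2 samples, got {len(group.sample_ids)} "
            "(3+ needs no imputation; 1 is unanalyzable)"
        )
    rng = np.random.default_rng(seed)
    y = group.counts.to_numpy(dtype=float)
    totals = y.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cannot impute from an all-zero sample")
    target_depth = float(np.sqrt(totals[0] * totals[1]))
    # per-annotation mean on the common-depth scale
    scaled = y / totals[None, :] * target_depth
    mean = scaled.mean(axis=1)
    var = 0.5 * (scaled[:, 0] - scaled[:, 1]) ** 2  # df=1 estimate
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, (var - mean) / np.maximum(mean, 1e-300) ** 2, 0.0)
    phi = np.maximum(phi, IMPUTE_DISPERSION_FLOOR)
    r = 1.0 / phi
    p = r / (r + np.maximum(mean, 0.0))
    draws = np.where(mean > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)

    first = group.sample_ids[0]
    new_id = f"{first}{suffix}"
    counts = group.counts.copy()
    counts[new_id] = draws.astype(float)
    meta = group.samples.copy()
    if "imputed" not in meta.columns:
        meta["imputed"] = False
    row = meta.loc[first].copy()
    row["imputed"] = True
    meta.loc[new_id] = row
    return CountTable(counts, meta)


def drop_zero_rows(table: CountTable) -> tuple[CountTable, list[str]]:
    """Drop annotations with zero total count, logging how many."""
    zero = table.counts.sum(axis=1) == 0
    removed = table.counts.index[zero].tolist()
    if removed:
        logger.info("dropping %d all-zero annotation rows", len(removed))
    return CountTable(table.counts.loc[~zero].copy(), table.samples.copy()), removed
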