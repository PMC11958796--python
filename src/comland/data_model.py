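"""Domain containers and table plumbing for ASV count data.

The raw currency of every stage is a samples x ASVs table of integer read
counts.  This module provides validated containers (:class:`CountTable`,
:class:`RelAbundTable`, :class:`SampleMetadata`), TSV readers/writers, the
two quality filters applied to the sequenced tables (drop ASVs with fewer
than 100 reads across samples; drop samples with fewer than 10,000 reads),
rarefaction to a common depth (used for visual summaries only, never by the
statistical stages) and conversion to relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

START = "start"
FINAL = "final"

#: accepted orientations for on-disk tables
SAMPLES_AS_ROWS = "samples_as_rows"
ASVS_AS_ROWS = "asvs_as_rows"


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dupes = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass(frozen=True)
class CountTable:
    """Integer read counts, samples as rows, ASVs as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("CountTable.data must be a pandas DataFrame")
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "ASV")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(values < 0):
                raise ValueError("counts must be non-negative")
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("counts must be integral")
        if values.dtype != np.int64:
            object.__setattr__(self, "data", df.astype(np.int64))

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def select_samples(self, ids: Iterable) -> "CountTable":
        return CountTable(self.data.loc[list(ids)])

    def select_asvs(self, ids: Iterable) -> "CountTable":
        return CountTable(self.data.loc[:, list(ids)])


@dataclass(frozen=True)
class RelAbundTable:
    """Relative abundances: each row is a composition summing to one."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "ASV")
        values = df.to_numpy(dtype=float)
        if values.size:
            if np.any(values < 0) or np.any(values > 1):
                raise ValueError("relative abundances must lie in [0, 1]")
            sums = values.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                raise ValueError(
                    f"rows must sum to 1 (offenders: {list(df.index[bad[:5]])})"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list:
        return list(self.data.columns)

    @property
    def abund(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def select_samples(self, ids: Iterable) -> "RelAbundTable":
        return RelAbundTable(self.data.loc[list(ids)])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample experiment annotations.

    One row per sample: ``time_point`` ("start" or "final"), ``parent_id``
    (the starting community a final sample was revived from; equal to the
    sample's own id for start samples) and ``replicate`` (1..n for final
    samples).  ``site`` and ``date`` are free-text and optional.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"time_point", "parent_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        _check_unique(df.index, "sample")
        bad_tp = set(df["time_point"]) - {START, FINAL}
        if bad_tp:
            raise ValueError(f"unknown time_point values: {sorted(bad_tp)}")
        finals = df[df["time_point"] == FINAL]
        if len(finals):
            if "replicate" not in df.columns:
                raise ValueError("final samples require a replicate column")
            pairs = finals[["parent_id", "replicate"]]
            if pairs.duplicated().any():
                raise ValueError("duplicate (parent_id, replicate) among finals")
            known_starts = set(df.index[df["time_point"] == START])
            orphans = sorted(set(finals["parent_id"]) - known_starts)
            if orphans:
                logger.warning(
                    "%d final samples reference unknown parents (e.g. %s)",
                    len(orphans), orphans[:3],
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def start_ids(self) -> list:
        return list(self.data.index[self.data["time_point"] == START])

    @property
    def final_ids(self) -> list:
        return list(self.data.index[self.data["time_point"] == FINAL])

    def parents(self) -> pd.Series:
        """parent_id per final sample."""
        finals = self.data[self.data["time_point"] == FINAL]
        return finals["parent_id"]

    def replicate_map(self) -> pd.DataFrame:
        """Wide view of final samples: parents as rows, replicates as columns."""
        finals = self.data[self.data["time_point"] == FINAL].reset_index()
        finals = finals.rename(columns={finals.columns[0]: "sample_id"})
        return finals.pivot(index="parent_id", columns="replicate",
                            values="sample_id")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_count_table(path, orientation: str = SAMPLES_AS_ROWS) -> CountTable:
    """Read a tab-separated ASV table ('#' comment lines ignored)."""
    if orientation not in (SAMPLES_AS_ROWS, ASVS_AS_ROWS):
        raise ValueError(f"unknown orientation: {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"parse error in {path}: {exc}") from exc
    if df.index.isna().any() or df.columns.isna().any():
        raise ValueError(f"malformed header or ids in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == ASVS_AS_ROWS:
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path,
                      orientation: str = SAMPLES_AS_ROWS) -> None:
    df = table.data if orientation == SAMPLES_AS_ROWS else table.data.T
    df.to_csv(path, sep="\t")


_META_COLUMNS = ["time_point", "parent_id", "replicate", "site", "date"]


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     dtype={"parent_id": str})
    df.index = df.index.astype(str)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype("Int64")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    cols = [c for c in _META_COLUMNS if c in meta.data.columns]
    meta.data[cols].to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Quality filters
# ---------------------------------------------------------------------------

def filter_asvs_min_reads(table: CountTable, min_total: int = 100) -> CountTable:
    """Drop ASVs with fewer than ``min_total`` reads summed across samples.

    The bound is inclusive: an ASV with exactly ``min_total`` reads survives
    ("fewer than" means strictly below).
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.data.sum(axis=0) >= min_total
    if not keep.any():
        logger.warning("ASV filter removed every ASV (min_total=%d)", min_total)
    return CountTable(table.data.loc[:, keep])


def filter_samples_min_reads(table: CountTable,
                             min_total: int = 10000) -> CountTable:
    """Drop samples with fewer than ``min_total`` total reads (inclusive bound)."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.data.sum(axis=1) >= min_total
    if not keep.any():
        logger.warning("sample filter removed every sample (min_total=%d)",
                       min_total)
    return CountTable(table.data.loc[keep])


def rarefy(table: CountTable, depth: int = 10000, seed: int = 0) -> CountTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Every output row sums to exactly ``depth``; reproducible given ``seed``.
    Raises if any sample is shallower than ``depth``.
    """
    totals = table.data.sum(axis=1)
    shallow = list(totals.index[totals < depth])
    if shallow:
        raise ValueError(f"samples shallower than depth {depth}: {shallow[:10]}")
    rng = np.random.default_rng(seed)
    counts = table.counts
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return CountTable(pd.DataFrame(out, index=table.data.index,
                                   columns=table.data.columns))


def to_relative(table: CountTable) -> RelAbundTable:
    """Divide each row by its total; rows of all zeros are rejected."""
    totals = table.data.sum(axis=1).to_numpy(dtype=float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero-sum samples cannot be normalised: "
            f"{list(table.data.index[zero[:10]])}"
        )
    rel = table.data.to_numpy(dtype=float) / totals[:, None]
    return RelAbundTable(pd.DataFrame(rel, index=table.data.index,
                                      columns=table.data.columns))
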