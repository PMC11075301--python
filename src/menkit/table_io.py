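"""Feature-table I/O, filtering, rarefaction and log transformation.

A feature table is an ASV x sample matrix of non-negative integer counts
plus per-sample metadata (group label, month, subject). Tables are stored
on disk as TSV with a ``#OTU ID`` leading column, the metadata as a TSV
with columns ``sample_id``, ``group``, ``month``, ``subject``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError

logger = logging.getLogger(__name__)

TABLE_INDEX = "#OTU ID"
METADATA_COLUMNS = ("sample_id", "group", "month", "subject")


@dataclass
class FeatureTable:
    """Count matrix (ASV x sample) with aligned sample metadata.

    Attributes
    ----------
    counts : numpy.ndarray
        Integer matrix of shape ``(n_asv, n_sample)``; never negative.
    asv_ids, sample_ids : list of str
        Unique row / column identifiers.
    metadata : pandas.DataFrame
        Indexed by sample id, with ``group`` (str), ``month`` (int) and
        ``subject`` (str) columns, one row per sample, same order as
        ``sample_ids``.
    """

    counts: np.ndarray
    asv_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        n_asv, n_samp = self.counts.shape
        if len(self.asv_ids) != n_asv:
            raise FormatError(
                f"{len(self.asv_ids)} ASV ids for {n_asv} count rows"
            )
        if len(self.sample_ids) != n_samp:
            raise FormatError(
                f"{len(self.sample_ids)} sample ids for {n_samp} count columns"
            )
        if len(set(self.asv_ids)) != n_asv:
            dup = _first_duplicate(self.asv_ids)
            raise FormatError(f"duplicate ASV id: {dup!r}")
        if len(set(self.sample_ids)) != n_samp:
            dup = _first_duplicate(self.sample_ids)
            raise FormatError(f"duplicate sample id: {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            # tolerate float storage only when every value is integral
            if not np.all(np.isfinite(self.counts)) or np.any(
                self.counts != np.floor(self.counts)
            ):
                bad = np.argwhere(self.counts != np.floor(self.counts))
                row = self.asv_ids[bad[0][0]] if bad.size else "?"
                raise FormatError(f"non-integer count in row {row!r}")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            row = self.asv_ids[int(np.argwhere(self.counts < 0)[0][0])]
            raise FormatError(f"negative count in row {row!r}")
        if self.metadata is not None:
            missing = [s for s in self.sample_ids if s not in self.metadata.index]
            if missing:
                raise FormatError(f"metadata missing for sample {missing[0]!r}")
            # keep metadata aligned to column order
            self.metadata = self.metadata.loc[self.sample_ids]

    # -- convenience ---------------------------------------------------
    @property
    def n_asv(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.asv_ids, columns=self.sample_ids
        )

    def select_samples(self, sample_ids: list[str]) -> "FeatureTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        meta = self.metadata.loc[sample_ids] if self.metadata is not None else None
        return FeatureTable(
            self.counts[:, idx], list(self.asv_ids), list(sample_ids), meta
        )

    def select_asvs(self, keep: np.ndarray) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return FeatureTable(
            self.counts[keep],
            [self.asv_ids[i] for i in keep],
            list(self.sample_ids),
            self.metadata,
        )

    def subset(self, group: str | None = None, month: int | None = None) -> "FeatureTable":
        """Samples matching a (group, month) stratum, metadata order."""
        if self.metadata is None:
            raise AnalysisError("subset requires metadata")
        mask = pd.Series(True, index=self.metadata.index)
        if group is not None:
            mask &= self.metadata["group"] == group
        if month is not None:
            mask &= self.metadata["month"] == month
        return self.select_samples(list(self.metadata.index[mask]))


def _first_duplicate(items: list[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


# ---------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------

def read_feature_table(table_path, metadata_path) -> FeatureTable:
    """Read a count TSV plus metadata TSV into a validated table.

    Sample order follows the metadata file. Raises :class:`FormatError`
    naming the offending row on malformed input.
    """
    raw = pd.read_csv(table_path, sep="\t", index_col=0, dtype=str)
    meta = read_metadata(metadata_path)
    asv_ids = [str(i) for i in raw.index]
    counts = np.empty(raw.shape, dtype=np.int64)
    for i, (asv, row) in enumerate(raw.iterrows()):
        try:
            vals = row.astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-integer count in row {asv!r}") from exc
        counts[i] = vals.to_numpy()
    table_samples = [str(c) for c in raw.columns]
    missing = [s for s in table_samples if s not in meta.index]
    if missing:
        raise FormatError(f"metadata missing for sample {missing[0]!r}")
    order = [s for s in meta.index if s in set(table_samples)]
    frame = pd.DataFrame(counts, index=asv_ids, columns=table_samples)[order]
    return FeatureTable(frame.to_numpy(), asv_ids, order, meta.loc[order])


def read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"metadata lacks column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id in metadata: {dup!r}")
    meta = meta.set_index("sample_id")
    try:
        meta["month"] = meta["month"].astype(int)
    except ValueError as exc:
        raise FormatError("metadata month column is not integer") from exc
    return meta


def write_feature_table(table: FeatureTable, table_path, metadata_path=None) -> None:
    frame = table.to_frame()
    frame.index.name = TABLE_INDEX
    frame.to_csv(table_path, sep="\t")
    if metadata_path is not None and table.metadata is not None:
        out = table.metadata.reset_index()
        out = out.rename(columns={out.columns[0]: "sample_id"})
        out.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------
# filtering / transformation
# ---------------------------------------------------------------------

def filter_low_abundance(
    table: FeatureTable, min_total: int = 10, min_samples: int = 3
) -> FeatureTable:
    """Drop rare ASVs, judged separately within each month stratum.

    Within a stratum an ASV fails when its summed count is below
    ``min_total`` or it occurs (count > 0) in fewer than ``min_samples``
    samples. An ASV is removed only when it fails in every stratum, so a
    taxon abundant at any time point survives. Tables without metadata
    are treated as a single stratum.
    """
    if table.metadata is not None and "month" in table.metadata.columns:
        months = table.metadata["month"].to_numpy()
        strata = [months == m for m in np.unique(months)]
    else:
        strata = [np.ones(table.n_samples, dtype=bool)]
    passes = np.zeros(table.n_asv, dtype=bool)
    for mask in strata:
        sub = table.counts[:, mask]
        ok = (sub.sum(axis=1) >= min_total) & ((sub > 0).sum(axis=1) >= min_samples)
        passes |= ok
    if not passes.any():
        logger.warning("low-abundance filter removed every ASV")
    return table.select_asvs(passes)


def prevalence_filter(table: FeatureTable, min_fraction: float = 0.5) -> FeatureTable:
    """Keep ASVs present in at least ``ceil(min_fraction * n_samples)`` samples."""
    if not 0 < min_fraction <= 1:
        raise AnalysisError("min_fraction must lie in (0, 1]")
    need = math.ceil(min_fraction * table.n_samples)
    keep = (table.counts > 0).sum(axis=1) >= need
    return table.select_asvs(keep)


def rarefy(table: FeatureTable, depth: int = 37_800, seed: int | None = None) -> FeatureTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` reads are dropped (logged). Raises
    :class:`AnalysisError` when no sample is deep enough.
    """
    if depth <= 0:
        raise AnalysisError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    kept_cols: list[int] = []
    new_cols: list[np.ndarray] = []
    for j in range(table.n_samples):
        if totals[j] < depth:
            logger.info(
                "dropping sample %s (%d < %d reads)",
                table.sample_ids[j], totals[j], depth,
            )
            continue
        new_cols.append(
            rng.multivariate_hypergeometric(table.counts[:, j], depth)
        )
        kept_cols.append(j)
    if not kept_cols:
        raise AnalysisError(f"no sample reaches rarefaction depth {depth}")
    sample_ids = [table.sample_ids[j] for j in kept_cols]
    meta = table.metadata.loc[sample_ids] if table.metadata is not None else None
    return FeatureTable(
        np.column_stack(new_cols).astype(np.int64), list(table.asv_ids), sample_ids, meta
    )


def log_transform(
    table: FeatureTable, base: float = 10.0, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Elementwise ``log_base(count + pseudocount)`` as an ASV x sample frame."""
    if pseudocount <= 0:
        raise AnalysisError("pseudocount must be positive")
    values = np.log(table.counts + pseudocount) / np.log(base)
    return pd.DataFrame(values, index=table.asv_ids, columns=table.sample_ids)
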