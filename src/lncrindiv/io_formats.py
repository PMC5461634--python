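"""Tabular I/O, probe aggregation and expression filtering.

All files are plain tab-separated text with a header row. Expression tables
have lncRNA identifiers in the first column and one column per sample; the
phenotype table maps each sample to its group (``normal`` / ``cancer``) and
optionally carries survival columns. The rank machinery downstream is
scale-free, so any monotone preprocessed scale (log2 by convention) is
acceptable; missing values are rejected because rank comparisons have no NA
semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMAL = "normal"
CANCER = "cancer"
_VALID_GROUPS = {NORMAL, CANCER}


class FormatError(ValueError):
    """Raised when an input table violates the documented format."""


@dataclass
class ExpressionMatrix:
    """A lncRNA-by-sample expression matrix with per-sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by lncRNA id with one column per sample. Finite,
        no missing values, no duplicated row or column labels.
    group
        Series mapping every sample (column of ``values``) to ``"normal"``
        or ``"cancer"``.
    """

    values: pd.DataFrame
    group: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicated lncRNA ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicated sample ids: {dups}")
        if v.isna().any().any():
            bad = v.index[v.isna().any(axis=1)].tolist()
            raise FormatError(f"missing values are not supported; rows with NA: {bad}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise FormatError("expression values must be finite")
        missing = [s for s in v.columns if s not in self.group.index]
        if missing:
            raise FormatError(f"samples absent from phenotype table: {missing}")
        self.group = self.group.reindex(v.columns)
        bad_groups = set(self.group.unique()) - _VALID_GROUPS
        if bad_groups:
            raise FormatError(
                f"group labels must be one of {sorted(_VALID_GROUPS)}, got {sorted(bad_groups)}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def lnc_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> pd.Index:
        return self.group.index[self.group == group]

    def subset_group(self, group: str) -> "ExpressionMatrix":
        cols = self.samples_in_group(group)
        return ExpressionMatrix(self.values[cols], self.group.loc[cols])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.group.loc[list(sample_ids)])

    @property
    def normal(self) -> pd.DataFrame:
        return self.values[self.samples_in_group(NORMAL)]

    @property
    def cancer(self) -> pd.DataFrame:
        return self.values[self.samples_in_group(CANCER)]


def read_phenotype(path) -> pd.DataFrame:
    """Read the sample phenotype table (sample_id, group, optional survival).

    The table must contain columns ``sample_id`` and ``group``; optional
    columns ``time`` and ``event`` plus any clinical covariates are preserved.
    """
    pheno = pd.read_csv(path, sep="\t", dtype={0: str})
    if "sample_id" not in pheno.columns or "group" not in pheno.columns:
        raise FormatError("phenotype table needs 'sample_id' and 'group' columns")
    if pheno["sample_id"].duplicated().any():
        dups = pheno.loc[pheno["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicated sample ids in phenotype table: {dups}")
    pheno = pheno.set_index("sample_id")
    if "time" in pheno.columns:
        if (pheno["time"].dropna() < 0).any():
            raise FormatError("survival times must be non-negative")
        has_time = pheno["time"].notna()
        if "event" not in pheno.columns or pheno.loc[has_time, "event"].isna().any():
            raise FormatError("'event' must be defined wherever 'time' is")
    return pheno


def read_expression(path, phenotype_path) -> ExpressionMatrix:
    """Read an expression TSV plus its phenotype table into an ExpressionMatrix.

    Row and column order is preserved from the file. Duplicated lncRNA or
    sample ids, NA values, and samples missing from the phenotype table all
    raise :class:`FormatError` naming the offender.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    pheno = read_phenotype(phenotype_path)
    return ExpressionMatrix(values, pheno["group"])


def write_expression(matrix: ExpressionMatrix, path, phenotype_path=None) -> None:
    """Write an expression matrix (and optionally its phenotype) as TSV.

    Values are written at full float precision so that a
    read_expression/write_expression round trip is value-exact.
    """
    out = matrix.values.copy()
    out.index.name = out.index.name or "lnc_id"
    out.to_csv(path, sep="\t")
    if phenotype_path is not None:
        pheno = pd.DataFrame({"sample_id": matrix.sample_ids, "group": matrix.group.values})
        pheno.to_csv(phenotype_path, sep="\t", index=False)


def read_probe_map(path) -> pd.Series:
    """Read a two-column probe_id -> lnc_id map.

    A probe may map to only one lncRNA; several probes may share a lncRNA.
    """
    m = pd.read_csv(path, sep="\t", dtype=str)
    if m.shape[1] < 2:
        raise FormatError("probe map needs two columns: probe_id, lnc_id")
    probe_col, lnc_col = m.columns[:2]
    if m[probe_col].duplicated().any():
        dups = m.loc[m[probe_col].duplicated(), probe_col].tolist()
        raise FormatError(f"probes mapping to more than one lncRNA: {dups}")
    return pd.Series(m[lnc_col].values, index=m[probe_col].values, name="lnc_id")


def aggregate_probes(probe_matrix: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to lncRNA level by the per-sample mean.

    Probes absent from the map are dropped (a count is logged). The output has
    one row per lncRNA, sorted by id so the result does not depend on probe
    row order; each value is the arithmetic mean of the lncRNA's probes on the
    provided scale.
    """
    if probe_map.index.duplicated().any():
        raise FormatError("probe map assigns some probe to more than one lncRNA")
    mapped = probe_matrix.index.intersection(probe_map.index)
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if len(mapped) == 0:
        raise FormatError("no probe in the matrix is present in the probe map")
    if n_dropped:
        logger.info("aggregate_probes: dropped %d unmapped probes", n_dropped)
    sub = probe_matrix.loc[mapped]
    out = sub.groupby(probe_map.loc[mapped].values).mean()
    out.index.name = "lnc_id"
    return out.sort_index()


def filter_expressed(matrix: ExpressionMatrix, min_nonzero_frac: float = 0.9) -> ExpressionMatrix:
    """Keep lncRNAs with non-zero expression in at least ``min_nonzero_frac``
    of samples (inclusive threshold); row order is preserved.
    """
    if not 0 < min_nonzero_frac <= 1:
        raise ValueError("min_nonzero_frac must be in (0, 1]")
    frac = (matrix.values != 0).mean(axis=1)
    keep = frac >= min_nonzero_frac
    if not keep.any():
        raise FormatError("expression filter removed every lncRNA")
    return ExpressionMatrix(matrix.values.loc[keep], matrix.group)
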