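"""Count-table and sample-metadata I/O for paired-compartment amplicon studies.

The pipeline starts from a classified taxa-by-sample read-count table (one
row per taxon, one column per sample) and a sample metadata table giving,
for every sample, the reactor it came from, the compartment it represents
(``granular`` biomass withdrawn from the reactor, or ``effluent`` suspended
solids) and the day since reactor seeding.  This module reads, validates and
writes those tables and derives the paired (reactor, day) structure that the
retention-ratio statistic needs.

Nothing is ever silently dropped: validation failures raise, and samples
that cannot be paired are reported in :class:`PairedIndex.unpaired`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "PairedIndex",
    "SamplePair",
    "ValidationError",
    "GRANULAR",
    "EFFLUENT",
    "COMPARTMENTS",
    "DEFAULT_COMPARTMENT_ALIASES",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "build_paired_index",
]

GRANULAR = "granular"
EFFLUENT = "effluent"
COMPARTMENTS = (GRANULAR, EFFLUENT)

#: Accepted spellings for the two compartments.  The study labels reactor-content
#: samples "R" (e.g. R1R) and effluent samples "E" (e.g. R1E).
DEFAULT_COMPARTMENT_ALIASES: Mapping[str, str] = {
    "granular": GRANULAR,
    "granule": GRANULAR,
    "granules": GRANULAR,
    "reactor": GRANULAR,
    "r": GRANULAR,
    "effluent": EFFLUENT,
    "eff": EFFLUENT,
    "suspended": EFFLUENT,
    "e": EFFLUENT,
}

METADATA_COLUMNS = ("sample_id", "reactor", "compartment", "day")


class ValidationError(ValueError):
    """Raised when a table or metadata frame violates its invariants."""


@dataclass(frozen=True)
class CountTable:
    """Taxa × samples matrix of non-negative integer read counts.

    Parameters
    ----------
    data
        DataFrame with taxon labels as the index and sample ids as columns;
        entries are non-negative integers.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy()
        if values.size and (values < 0).any():
            bad = df.columns[(values < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative counts in samples: {bad}")
        if not np.issubdtype(values.dtype, np.integer):
            raise ValidationError("counts must be integers (use from_frame to coerce)")
        if values.size:
            zero = df.columns[values.sum(axis=0) == 0].tolist()
            if zero:
                raise ValidationError(f"samples with zero total reads: {zero}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, strict: bool = True) -> "CountTable":
        """Build a table from a numeric frame, coercing to integers.

        With ``strict`` (default) non-integral values abort; otherwise they
        are rounded half-to-even with a warning.
        """
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("counts contain NaN or infinite entries")
        rounded = np.rint(values)
        if not np.array_equal(values, rounded):
            if strict:
                rows, cols = np.nonzero(values != rounded)
                taxon, sample = df.index[rows[0]], df.columns[cols[0]]
                raise ValidationError(
                    f"non-integral count {values[rows[0], cols[0]]!r} for "
                    f"taxon {taxon!r} in sample {sample!r}"
                )
            import warnings

            warnings.warn("non-integral counts rounded to nearest integer")
        out = pd.DataFrame(
            rounded.astype(np.int64), index=df.index.astype(str), columns=df.columns.astype(str)
        )
        return cls(out)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CountTable(self.data.loc[:, list(sample_ids)])


class SamplePair(NamedTuple):
    reactor: str
    day: int
    granular: str
    effluent: str


@dataclass(frozen=True)
class PairedIndex:
    """Contemporaneous (reactor, day) granular/effluent sample pairs."""

    pairs: tuple[SamplePair, ...]
    unpaired: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.pairs)

    def for_reactor(self, reactor: str) -> list[SamplePair]:
        return [p for p in self.pairs if p.reactor == reactor]

    @property
    def reactors(self) -> list[str]:
        return sorted({p.reactor for p in self.pairs})


def read_count_table(path: str | Path, format: str = "tsv", *, strict: bool = True) -> CountTable:
    """Read a taxa × samples count table.

    ``tsv``: tab-separated, first column holds taxon labels, header row holds
    sample ids.  ``biom_dense``: BIOM format v1.0 JSON with a dense matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValidationError(f"malformed count table {path}: {exc}") from exc
        non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if non_numeric:
            raise ValidationError(f"non-numeric sample columns in {path}: {non_numeric}")
        df.index = df.index.astype(str)
        return CountTable.from_frame(df, strict=strict)
    if format == "biom_dense":
        return _read_biom_dense(path, strict=strict)
    raise ValueError(f"unknown count-table format: {format!r}")


def _read_biom_dense(path: Path, *, strict: bool) -> CountTable:
    """Minimal reader for BIOM v1.0 JSON tables with dense matrix data."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise ValidationError(f"{path}: only dense BIOM v1.0 matrices are supported")
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    data = np.asarray(doc["data"], dtype=float)
    if data.shape != (len(taxa), len(samples)):
        raise ValidationError(
            f"{path}: data shape {data.shape} does not match "
            f"{len(taxa)} rows x {len(samples)} columns"
        )
    return CountTable.from_frame(pd.DataFrame(data, index=taxa, columns=samples), strict=strict)


def write_count_table(ct: CountTable, path: str | Path) -> None:
    """Write a count table as UTF-8 TSV with a ``taxon`` index header."""
    df = ct.data.copy()
    df.index.name = "taxon"
    df.to_csv(path, sep="\t")


def read_metadata(
    path: str | Path,
    *,
    aliases: Mapping[str, str] = DEFAULT_COMPARTMENT_ALIASES,
) -> pd.DataFrame:
    """Read sample metadata (CSV or TSV, sniffed from the header line).

    Required columns: ``sample_id, reactor, compartment, day``.  Compartment
    labels are normalized to {granular, effluent} through ``aliases``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "reactor": str})
    return validate_metadata(df, aliases=aliases)


def validate_metadata(
    df: pd.DataFrame,
    *,
    aliases: Mapping[str, str] = DEFAULT_COMPARTMENT_ALIASES,
) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    out = df.loc[:, list(METADATA_COLUMNS)].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["reactor"] = out["reactor"].astype(str)
    comp = out["compartment"].astype(str).str.strip().str.lower()
    unknown = sorted(set(comp) - set(aliases))
    if unknown:
        raise ValidationError(f"unknown compartment labels: {unknown}")
    out["compartment"] = comp.map(aliases)
    try:
        out["day"] = out["day"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"day column is not integer: {exc}") from exc
    if (out["day"] < 0).any():
        raise ValidationError("negative day values in metadata")
    if out["sample_id"].duplicated().any():
        dupes = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dupes}")
    key = out[["reactor", "compartment", "day"]]
    if key.duplicated().any():
        dupes = key[key.duplicated()].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (reactor, compartment, day): {dupes}")
    return out.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.loc[:, list(METADATA_COLUMNS)].to_csv(path, index=False)


def build_paired_index(meta: pd.DataFrame) -> PairedIndex:
    """Pair contemporaneous granular and effluent samples per reactor.

    Every (reactor, day) with both compartments present yields a pair;
    samples without a contemporaneous mate are listed in ``unpaired``.
    """
    if len(meta) == 0:
        return PairedIndex(pairs=())
    pairs: list[SamplePair] = []
    unpaired: list[str] = []
    for (reactor, day), grp in meta.groupby(["reactor", "day"], sort=True):
        by_comp = {row.compartment: row.sample_id for row in grp.itertuples()}
        if GRANULAR in by_comp and EFFLUENT in by_comp:
            pairs.append(SamplePair(str(reactor), int(day), by_comp[GRANULAR], by_comp[EFFLUENT]))
        else:
            unpaired.extend(grp["sample_id"].tolist())
    return PairedIndex(pairs=tuple(pairs), unpaired=tuple(unpaired))
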