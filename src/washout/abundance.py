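"""Relative-abundance transforms, genus collapsing and dominant-genus selection.

Relative read abundance — each sample's counts divided by that sample's
library size — is the unit of the whole downstream analysis.  Genus-level
collapsing sums counts over taxa that share a genus assignment (Greengenes
style rank prefixes, ``g__Zoogloea``); reads without a genus assignment keep
their OTU label.  Dominant-genus selection reproduces the "most abundant
genera common to all sample categories" logic, where a category is one
reactor × compartment combination (six categories for three reactors).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import CountTable, ValidationError

__all__ = [
    "RelAbundTable",
    "to_relative",
    "parse_rank",
    "collapse_to_genus",
    "category_means",
    "select_common_top",
    "cumulative_share",
]

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}

_COLSUM_TOL = 1e-9


@dataclass(frozen=True)
class RelAbundTable:
    """Taxa × samples matrix of per-sample relative abundances.

    Every sample column sums to 1 (within 1e-9); entries lie in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.size == 0:
            return
        if (values < 0).any() or (values > 1 + _COLSUM_TOL).any():
            raise ValidationError("relative abundances outside [0, 1]")
        sums = values.sum(axis=0)
        bad = self.data.columns[np.abs(sums - 1.0) > _COLSUM_TOL].tolist()
        if bad:
            raise ValidationError(f"sample columns not summing to 1: {bad}")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def to_relative(ct: CountTable | RelAbundTable) -> RelAbundTable:
    """Total-sum scale each sample column to relative abundances.

    Accepts a count table or (idempotently) an abundance table; any positive
    rescaling of the columns yields the same result.
    """
    df = ct.data.astype(float)
    sums = df.sum(axis=0)
    zero = df.columns[sums <= 0].tolist()
    if zero:
        raise ValidationError(f"cannot normalize zero-sum samples: {zero}")
    return RelAbundTable(df.div(sums, axis=1))


def parse_rank(label: str, rank: str = "genus") -> str | None:
    """Extract a rank assignment from a Greengenes-style taxonomy label.

    Returns e.g. ``"g__Zoogloea"`` from ``"k__Bacteria;...;g__Zoogloea"`` or
    from a bare ``"g__Zoogloea"``; ``None`` when the rank is missing or empty.
    """
    prefix = RANK_PREFIXES.get(rank)
    if prefix is None:
        raise ValueError(f"unknown taxonomy rank: {rank!r}")
    for part in re.split(r"[;|]", label):
        part = part.strip()
        if part.startswith(prefix):
            name = part[len(prefix):].strip()
            return f"{prefix}{name}" if name else None
    return None


def collapse_to_genus(ct: CountTable, rank: str = "genus") -> CountTable:
    """Sum counts over taxa sharing a genus label.

    Taxa without a genus assignment are retained under their own label
    (so unclassified reads surface as ``OTU_*`` rows rather than vanishing
    into an artificial bin).  Total counts per sample are conserved.
    """
    groups = []
    n_with_rank = 0
    for label in ct.taxa:
        parsed = parse_rank(label, rank)
        if parsed is not None:
            n_with_rank += 1
            groups.append(parsed)
        else:
            groups.append(label)
    if n_with_rank == 0:
        raise ValidationError(f"no taxon label carries a {rank!r} assignment")
    collapsed = ct.data.groupby(pd.Index(groups, name=ct.data.index.name), sort=False).sum()
    return CountTable(collapsed)


def _category_labels(meta: pd.DataFrame) -> pd.Series:
    return meta["reactor"].astype(str) + "/" + meta["compartment"].astype(str)


def category_means(ra: RelAbundTable, meta: pd.DataFrame) -> pd.DataFrame:
    """Mean relative abundance per taxon for each reactor × compartment category.

    Returns a taxon × category frame; the per-category sample count is
    available in the ``attrs["n_samples"]`` mapping.  Each category column
    sums to 1 because the mean is linear.
    """
    meta = meta.set_index("sample_id")
    samples = [s for s in ra.samples if s in meta.index]
    if not samples:
        raise ValidationError("no overlap between abundance table samples and metadata")
    cats = _category_labels(meta.loc[samples])
    out = ra.data.loc[:, samples].T.groupby(cats.values).mean().T
    out.attrs["n_samples"] = cats.value_counts().to_dict()
    return out


def select_common_top(
    ra: RelAbundTable,
    meta: pd.DataFrame,
    n: int,
    *,
    min_mean: float = 0.0,
    rank_by: str = "grand_mean",
) -> list[str]:
    """Select the ``n`` most abundant taxa present in every sample category.

    "Present" means mean relative abundance strictly above ``min_mean``
    (default 0) in each reactor × compartment category; ranking uses the
    grand mean over all samples (``rank_by="grand_mean"``) or the minimum
    category mean (``rank_by="category_min"``), ties broken by label.
    """
    means = category_means(ra, meta)
    common = means.index[(means > min_mean).all(axis=1)]
    if len(common) == 0:
        return []
    if rank_by == "grand_mean":
        score = ra.data.loc[common].mean(axis=1)
    elif rank_by == "category_min":
        score = means.loc[common].min(axis=1)
    else:
        raise ValueError(f"unknown rank_by: {rank_by!r}")
    ranked = score.sort_index().sort_values(ascending=False, kind="stable")
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} taxa are common to all categories (requested {n})"
        )
    return ranked.index[:n].tolist()


def cumulative_share(ra: RelAbundTable, taxa: list[str]) -> tuple[float, float]:
    """Mean ± sd (over samples) of the summed relative abundance of ``taxa``.

    This is the "these genera add up to X ± Y % of the total population"
    summary; values are returned as percentages.
    """
    totals = ra.data.loc[taxa].sum(axis=0) * 100.0
    sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
    return float(totals.mean()), sd
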