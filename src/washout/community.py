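"""Community-level comparisons: Bray-Curtis, NMDS ordination, diversity.

Bray-Curtis dissimilarity BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i) is
computed on per-sample relative abundances (library sizes differ between the
granular and effluent compartments, so raw-count Bray-Curtis would conflate
depth with composition).  Similarity is reported as (1 - BC) x 100 %.

NMDS here is Kruskal-style non-metric multidimensional scaling: find a
k-dimensional configuration whose Euclidean distances preserve the rank
order of the input dissimilarities, minimizing Kruskal stress-1

    stress = sqrt( sum (d_ij - dhat_ij)^2 / sum d_ij^2 ),

where dhat is the isotonic (pool-adjacent-violators) regression of the
configuration distances onto the dissimilarity rank order.  The optimizer
alternates an isotonic fit with a Guttman (SMACOF) update, accepts an update
only if stress decreases (so the stress trace is monotone), and keeps the
best of one classical-scaling start plus random restarts.

Diversity indices are the classical ones for amplicon surveys: Margalef
richness (S - 1)/ln N, Shannon entropy H' = -sum p_i ln p_i, and Pielou
evenness J = H'/ln S (undefined for single-taxon samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .abundance import RelAbundTable, to_relative
from .tables_io import CountTable, PairedIndex, ValidationError

__all__ = [
    "bray_curtis",
    "dissimilarity_matrix",
    "paired_similarity_summary",
    "between_group_similarity",
    "OrdinationResult",
    "nmds",
    "classical_scaling",
    "isotonic_fit",
    "margalef",
    "shannon",
    "pielou",
    "diversity_table",
]


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity between two non-negative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundance vectors must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(x, y))


def dissimilarity_matrix(table: CountTable | RelAbundTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis matrix over samples, on relative abundances."""
    ra = to_relative(table)
    data = ra.data.to_numpy(dtype=float).T  # samples x taxa
    return DistanceMatrix(squareform(pdist(data, metric="braycurtis")), ids=ra.samples)


def paired_similarity_summary(dm: DistanceMatrix, pairs: PairedIndex) -> pd.DataFrame:
    """Mean ± sd Bray-Curtis similarity (%) of contemporaneous pairs per reactor.

    Similarity = (1 - BC) x 100 for each granular/effluent pair; the summary
    is the per-reactor mean and sample standard deviation over days.
    """
    ids = set(dm.ids)
    rows = []
    for p in pairs.pairs:
        for s in (p.granular, p.effluent):
            if s not in ids:
                raise KeyError(f"paired sample {s!r} missing from dissimilarity matrix")
        rows.append({"reactor": p.reactor, "day": p.day, "similarity": (1.0 - dm[p.granular, p.effluent]) * 100.0})
    per_pair = pd.DataFrame(rows)
    out = (
        per_pair.groupby("reactor")["similarity"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    out.attrs["per_pair"] = per_pair
    return out


def between_group_similarity(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    *,
    window: tuple[int, int] | None = None,
    compartment: str | None = None,
) -> pd.DataFrame:
    """Mean cross-reactor Bray-Curtis similarity (%) within a day window.

    Averages (1 - BC) x 100 over all sample pairs drawn from two different
    reactors, optionally restricted to one compartment and to days in
    ``window = (first, last)`` inclusive.
    """
    sel = meta
    if window is not None:
        sel = sel[(sel["day"] >= window[0]) & (sel["day"] <= window[1])]
    if compartment is not None:
        sel = sel[sel["compartment"] == compartment]
    sel = sel[sel["sample_id"].isin(dm.ids)]
    groups = {r: g["sample_id"].tolist() for r, g in sel.groupby("reactor")}
    reactors = sorted(groups)
    if any(len(groups[r]) == 0 for r in reactors):
        raise ValidationError("empty reactor group in the selected window")
    rows = []
    for i, ra in enumerate(reactors):
        for rb in reactors[i + 1 :]:
            sims = [
                (1.0 - dm[a, b]) * 100.0
                for a in groups[ra]
                for b in groups[rb]
            ]
            rows.append({"reactor_a": ra, "reactor_b": rb, "mean_similarity": float(np.mean(sims)), "n_pairs": len(sims)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrdinationResult:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # |samples| x k, column-centered
    stress: float
    n_restarts: int
    best_restart: int  # 0 = classical-scaling start
    converged: bool
    degenerate: bool
    stress_trace: tuple[float, ...]  # per-iteration stress of the best run

    def frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.ids), columns=cols)


def isotonic_fit(values: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit of ``values`` taken in ``order``.

    Pool-adjacent-violators: walk the sequence, merging adjacent blocks whose
    means violate monotonicity; every element of a merged block receives the
    block mean.  Returns the fit in the original element positions.
    """
    y = values[order]
    n = y.size
    # blocks as (sum, count) stacks
    sums = np.empty(n)
    counts = np.empty(n, dtype=np.int64)
    top = -1
    for v in y:
        top += 1
        sums[top] = v
        counts[top] = 1
        while top > 0 and sums[top - 1] / counts[top - 1] > sums[top] / counts[top]:
            sums[top - 1] += sums[top]
            counts[top - 1] += counts[top]
            top -= 1
    fit_sorted = np.repeat(sums[: top + 1] / counts[: top + 1], counts[: top + 1])
    fit = np.empty_like(fit_sorted)
    fit[order] = fit_sorted
    return fit


def classical_scaling(delta: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) metric scaling of a squared-distance matrix."""
    n = delta.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (delta**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    idx = np.argsort(eigvals)[::-1][:k]
    vals = np.clip(eigvals[idx], 0.0, None)
    return eigvecs[:, idx] * np.sqrt(vals)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float((d**2).sum())
    if denom <= 1e-300:
        # fully collapsed configuration: 0/0, not a valid solution
        return math.inf
    return math.sqrt(float(((d - dhat) ** 2).sum()) / denom)


def _nmds_single(
    delta: np.ndarray,
    x0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, list[float], bool]:
    n = delta.shape[0]
    delta_norm = math.sqrt(float((delta**2).sum()))

    def _canonical(x: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # stress-1 is scale-invariant; pin the configuration size to the
        # dissimilarities so the scale cannot drift over iterations
        size = math.sqrt(float((d**2).sum()))
        if size > 0 and delta_norm > 0:
            c = delta_norm / size
            return x * c, d * c
        return x, d

    # primary (weak) tie treatment: within tied dissimilarities, order by the
    # current configuration distance so ties do not constrain the fit
    x = x0 - x0.mean(axis=0)
    x, d = _canonical(x, pdist(x))
    order = np.lexsort((d, delta))
    dhat = isotonic_fit(d, order)
    stress = _stress1(d, dhat)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        # Guttman transform toward the disparities, rescaled to the size of
        # the current distances so the step does not shrink the configuration
        target = dhat * math.sqrt(float((d**2).sum()) / max(float((dhat**2).sum()), 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, target / d, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x_new = (b @ x) / n
        x_new -= x_new.mean(axis=0)
        x_new, d_new = _canonical(x_new, pdist(x_new))
        order = np.lexsort((d_new, delta))
        dhat_new = isotonic_fit(d_new, order)
        stress_new = _stress1(d_new, dhat_new)
        if stress_new >= stress:
            converged = True
            break
        improved = stress - stress_new
        x, d, dhat, stress = x_new, d_new, dhat_new, stress_new
        trace.append(stress)
        if stress == 0.0 or improved < tol * max(stress, 1e-300):
            converged = True
            break
    return x, stress, trace, converged


def nmds(
    dm: DistanceMatrix | np.ndarray,
    k: int = 2,
    *,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix, best of several starts.

    Restart 0 initializes from classical scaling; the remaining restarts use
    seeded Gaussian configurations.  Within each run stress is strictly
    non-increasing.  A matrix whose off-diagonal dissimilarities are all
    equal carries no rank information; it is flagged ``degenerate`` and the
    coordinates are still returned.
    """
    if isinstance(dm, DistanceMatrix):
        ids = tuple(dm.ids)
        full = dm.data.astype(float)
    else:
        full = np.asarray(dm, dtype=float)
        ids = tuple(str(i) for i in range(full.shape[0]))
    n = full.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    delta = squareform(full, checks=False)
    degenerate = bool(delta.size) and np.allclose(delta, delta[0])

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float], bool] | None = None
    best_restart = 0
    for restart in range(n_restarts):
        if restart == 0:
            x0 = classical_scaling(full, k)
            if not np.any(x0):  # degenerate classical solution
                x0 = rng.standard_normal((n, k))
        else:
            x0 = rng.standard_normal((n, k))
        result = _nmds_single(delta, x0, max_iter, tol)
        if best is None or result[1] < best[1]:
            best = result
            best_restart = restart
    x, stress, trace, converged = best
    return OrdinationResult(
        ids=ids,
        coordinates=x,
        stress=stress,
        n_restarts=n_restarts,
        best_restart=best_restart,
        converged=converged,
        degenerate=degenerate,
        stress_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------


def margalef(S: int, N: int) -> float:
    """Margalef richness (S - 1)/ln N: taxon count corrected for depth."""
    if S < 1:
        raise ValueError(f"need at least one taxon, got S={S}")
    if N < 2:
        raise ValueError(f"need at least two reads, got N={N}")
    return (S - 1) / math.log(N)


def shannon(p: Sequence[float]) -> float:
    """Shannon entropy H' = -sum p_i ln p_i over the nonzero entries."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def pielou(p: Sequence[float]) -> float:
    """Pielou evenness J = H'/ln S; NaN for single-taxon communities."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"relative abundances sum to {p.sum()}, not 1")
    s = int((p > 0).sum())
    if s <= 1:
        return math.nan
    return shannon(p) / math.log(s)


def diversity_table(ct: CountTable) -> pd.DataFrame:
    """Per-sample richness, reads, Margalef, Shannon and Pielou indices."""
    rows = []
    for sample in ct.samples:
        counts = ct.data[sample].to_numpy()
        n = int(counts.sum())
        s = int((counts > 0).sum())
        p = counts[counts > 0] / n
        rows.append(
            {
                "sample_id": sample,
                "richness_S": s,
                "reads_N": n,
                "margalef": margalef(s, n) if n >= 2 else math.nan,
                "shannon": shannon(p),
                "pielou": pielou(np.sort(p)[::-1]) if s > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows)
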