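"""End-to-end orchestration: counts + metadata in, report directory out.

A run loads (or simulates) a count table and sample metadata, collapses to
genus level where taxonomy prefixes are present, computes relative
abundances, selects the dominant genera common to every reactor ×
compartment category, and writes the full set of numeric outputs: category
means, retention-ratio series, trend correlations, steady-state tests
against 1, the Bray-Curtis dissimilarity matrix, paired and cross-reactor
similarity summaries, NMDS coordinates, diversity indices, and a manifest
recording the seed and configuration hash so reruns are reproducible.

Also hosts the small reactor-arithmetic helpers (hydraulic residence time,
influent COD:N ratio) used to sanity-check operating parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import (
    RelAbundTable,
    category_means,
    collapse_to_genus,
    cumulative_share,
    select_common_top,
    to_relative,
)
from .community import (
    between_group_similarity,
    dissimilarity_matrix,
    diversity_table,
    nmds,
    paired_similarity_summary,
)
from .retention import (
    DEFAULT_STARTUP_END_DAY,
    STEADY,
    pearson_trend,
    phase_test_table,
    retention_series,
    trend_table,
    wilcoxon_vs_one,
)
from .tables_io import (
    CountTable,
    build_paired_index,
    read_count_table,
    read_metadata,
    validate_metadata,
    write_count_table,
    write_metadata,
)
from .washout_sim import scenario_paper_like, simulate_scenario

logger = logging.getLogger("washout")

__all__ = ["RunConfig", "ReactorSpec", "hydraulic_residence_time", "cod_n_ratio", "run_pipeline"]


@dataclass(frozen=True)
class ReactorSpec:
    """Operating parameters of one sequencing batch reactor."""

    cycle_length_h: float
    exchange_ratio: float
    influent_cod: float  # mg/L
    influent_nh4n: float  # mg/L

    def __post_init__(self) -> None:
        if self.cycle_length_h <= 0 or self.influent_cod <= 0 or self.influent_nh4n <= 0:
            raise ValueError("reactor parameters must be positive")
        if not (0.0 < self.exchange_ratio <= 1.0):
            raise ValueError(f"exchange ratio must be in (0, 1]: {self.exchange_ratio}")


def hydraulic_residence_time(cycle_length_h: float, exchange_ratio: float) -> float:
    """HRT in hours: cycle length divided by the volume exchange ratio.

    A 4 h cycle with 43% volume exchange gives 9.3 h (reported to 1 decimal).
    """
    if cycle_length_h <= 0:
        raise ValueError(f"cycle length must be positive: {cycle_length_h}")
    if not (0.0 < exchange_ratio <= 1.0):
        raise ValueError(f"exchange ratio must be in (0, 1]: {exchange_ratio}")
    return round(cycle_length_h / exchange_ratio, 1)


def cod_n_ratio(influent_cod: float, influent_nh4n: float) -> str:
    """Influent COD:N ratio normalized to 100 parts COD, e.g. ``"100:6"``."""
    if influent_cod <= 0:
        raise ValueError(f"influent COD must be positive: {influent_cod}")
    if influent_nh4n <= 0:
        raise ValueError(f"influent NH4-N must be positive: {influent_nh4n}")
    return f"100:{round(100.0 * influent_nh4n / influent_cod)}"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end analysis run."""

    counts_path: str | None = None
    metadata_path: str | None = None
    scenario: str | None = None  # "paper_like" to simulate instead of loading
    out_dir: str = "washout_report"
    seed: int = 0
    top_n: int = 19
    startup_end_day: int = DEFAULT_STARTUP_END_DAY
    zero_policy: str = "exclude"  # exclude | pseudocount
    pseudocount: float = 0.5
    collapse_rank: str | None = "genus"
    nmds_k: int = 2
    nmds_restarts: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(dataclasses.asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[CountTable, pd.DataFrame]:
    if config.scenario is not None:
        if config.scenario != "paper_like":
            raise ValueError(f"unknown scenario: {config.scenario!r}")
        out = simulate_scenario(scenario_paper_like(config.seed))
        return out.counts, out.metadata
    if config.counts_path is None or config.metadata_path is None:
        raise ValueError("either a scenario or counts/metadata paths are required")
    fmt = "biom_dense" if str(config.counts_path).endswith((".biom", ".json")) else "tsv"
    counts = read_count_table(config.counts_path, format=fmt)
    meta = read_metadata(config.metadata_path)
    return counts, meta


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write the report directory; returns its path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        counts, meta = _load_inputs(config)
        meta = validate_metadata(meta)
        write_count_table(counts, out_dir / "counts.tsv")
        write_metadata(meta, out_dir / "metadata.csv")

        stage = "abundance"
        if config.collapse_rank is not None:
            try:
                counts = collapse_to_genus(counts, config.collapse_rank)
            except Exception:
                logger.info("no %s-level labels found; keeping taxa as-is", config.collapse_rank)
        if config.zero_policy == "pseudocount":
            padded = counts.data.astype(float) + config.pseudocount
            ra = to_relative(_FloatTable(padded))
        elif config.zero_policy == "exclude":
            ra = to_relative(counts)
        else:
            raise ValueError(f"unknown zero policy: {config.zero_policy!r}")
        ra.data.to_csv(out_dir / "relative_abundance.tsv", sep="\t")
        cat_means = category_means(ra, meta)
        cat_means.to_csv(out_dir / "category_means.tsv", sep="\t")
        top = select_common_top(ra, meta, config.top_n)
        share_mean, share_sd = cumulative_share(ra, top)
        (out_dir / "top_genera.txt").write_text("\n".join(top) + "\n")
        logger.info(
            "%d common dominant genera cover %.1f ± %.1f%% of reads", len(top), share_mean, share_sd
        )

        stage = "retention"
        pairs = build_paired_index(meta)
        logger.info("%d contemporaneous pairs, %d unpaired samples", len(pairs), len(pairs.unpaired))
        series = retention_series(ra, pairs, top, startup_end_day=config.startup_end_day)
        n_undef = sum(s.n_undefined for s in series)
        logger.info("%d undefined retention points across %d series", n_undef, len(series))
        pts = pd.concat(
            [s.points.assign(taxon=s.taxon, reactor=s.reactor) for s in series], ignore_index=True
        )
        pts.to_csv(out_dir / "retention_series.tsv", sep="\t", index=False)
        trends = trend_table([pearson_trend(s) for s in series])
        trends.to_csv(out_dir / "trend_correlations.tsv", sep="\t", index=False)
        phase_tests = phase_test_table([wilcoxon_vs_one(s, STEADY) for s in series])
        phase_tests.to_csv(out_dir / "steady_state_tests.tsv", sep="\t", index=False)
        n_nc = int((trends["not_computable"] != "").sum()) + int(
            (phase_tests["not_computable"] != "").sum()
        )
        logger.info("%d not-computable tests", n_nc)

        stage = "community"
        dm = dissimilarity_matrix(ra)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out_dir / "bray_curtis.tsv", sep="\t"
        )
        paired_sim = paired_similarity_summary(dm, pairs)
        paired_sim.to_csv(out_dir / "paired_similarity.tsv", sep="\t", index=False)
        last_day = int(meta["day"].max())
        between = between_group_similarity(dm, meta, window=(max(0, last_day - 14), last_day))
        between.to_csv(out_dir / "between_reactor_similarity.tsv", sep="\t", index=False)
        ord_res = nmds(dm, k=config.nmds_k, n_restarts=config.nmds_restarts, seed=config.seed)
        coords = ord_res.frame()
        with open(out_dir / "nmds_coordinates.tsv", "w") as fh:
            fh.write(f"# stress={ord_res.stress:.6f} converged={ord_res.converged}\n")
            coords.rename_axis("sample_id").to_csv(fh, sep="\t")
        diversity = diversity_table(counts)
        diversity.to_csv(out_dir / "diversity.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "package": "washout",
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "config_hash": config.digest(),
            "n_samples": len(meta),
            "n_pairs": len(pairs),
            "n_unpaired": len(pairs.unpaired),
            "n_undefined_ratios": int(n_undef),
            "n_not_computable_tests": n_nc,
            "top_genera": top,
            "top_genera_share_pct": {"mean": share_mean, "sd": share_sd},
            "nmds_stress": ord_res.stress,
            "outputs": sorted(
                {p.name for p in out_dir.iterdir() if p.is_file()} | {"manifest.json"}
            ),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out_dir


@dataclass(frozen=True)
class _FloatTable:
    """Pseudocounted counts: float-valued but column-normalizable like counts."""

    data: pd.DataFrame
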