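"""End-to-end orchestration: classify -> summarize -> groups -> stats.

Given the three input tables, the pipeline writes six artifacts to the
output directory:

* ``classifications.csv`` — per-key five-way classification with its
  regression evidence;
* ``park_summary.csv`` — per-park community-change metrics;
* ``systemwide_summary.csv`` — cross-park aggregates per season x RCP;
* ``trend_groups.csv`` (+ ``typology_thresholds.json``) — the five-group
  park typology for the configured stratum;
* ``stats_report.json`` — the comparative-statistics results;
* ``manifest.json`` — input hashes, settings, seed and software version,
  plus output hashes, so reruns are verifiably identical.

CSV artifacts are serialized canonically (fixed column order, ``.``
decimal, LF line endings, 6 significant digits for derived reals) so the
determinism check is byte-level.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community_change import summarize_parks, systemwide_summary
from .comparative_stats import compare_seasons, latitude_regression, regional_anova, region_vs_overall
from .data_model import (
    RCPS,
    REGIONS,
    SEASONS,
    ValidationError,
    missing_thresholds,
    normalize_rcp,
    normalize_season,
    read_parks,
    read_suitability_table,
    read_thresholds,
)
from .park_typology import classify_parks
from .trend_classifier import ClassifierSettings, classify_all, year_round_table

logger = logging.getLogger("avichange")

FLOAT_FORMAT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML-loadable, CLI-overridable)."""

    suitability: str
    thresholds: str
    parks: str
    out_dir: str = "avichange_out"
    seasons: tuple[str, ...] = SEASONS
    rcps: tuple[str, ...] = RCPS
    alpha: float = 0.05
    permissive: bool = False
    colonization_requires_significance: bool = False
    typology_season: str = "summer"
    typology_rcp: str = "RCP8.5"
    typology_geometry: str = "rectangle"
    seed: int = 0
    metrics: tuple[str, ...] = ("bray_curtis", "prop_colonization", "prop_extirpation")

    def __post_init__(self) -> None:
        self.seasons = tuple(normalize_season(s) for s in self.seasons)
        self.rcps = tuple(normalize_rcp(r) for r in self.rcps)
        self.typology_season = normalize_season(self.typology_season)
        self.typology_rcp = normalize_rcp(self.typology_rcp)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def classifier_settings(self) -> ClassifierSettings:
        return ClassifierSettings(
            alpha=self.alpha,
            colonization_requires_significance=self.colonization_requires_significance,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_canonical_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format=FLOAT_FORMAT)


def validate_inputs(config: RunConfig) -> dict:
    """Cross-check key consistency across the three tables (report-only).

    Reports species missing thresholds, parks present in the suitability
    table but absent from metadata (and vice versa), and per-key
    completeness percentages. Never raises for orphans.
    """
    suit = read_suitability_table(config.suitability)
    thr = read_thresholds(config.thresholds)
    parks = read_parks(config.parks)
    from .data_model import audit_completeness

    orphan_thresholds = missing_thresholds(suit, thr)
    suit_parks = set(suit["park_id"])
    meta_parks = set(parks["park_id"])
    audit = audit_completeness(suit)
    report = {
        "n_suitability_rows": int(len(suit)),
        "n_species": int(suit["species_id"].nunique()),
        "n_parks_in_suitability": len(suit_parks),
        "n_parks_in_metadata": len(meta_parks),
        "species_season_missing_threshold": [
            tuple(r) for r in orphan_thresholds.itertuples(index=False)
        ],
        "parks_missing_metadata": sorted(suit_parks - meta_parks),
        "parks_without_suitability": sorted(meta_parks - suit_parks),
        "n_keys": int(len(audit)),
        "pct_keys_complete": float(100.0 * audit["complete"].mean()) if len(audit) else 100.0,
    }
    return report


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis chain; returns the artifact paths.

    Any stage failure raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            logger.info("stage %s: start", name)
            return fn()
        except Exception as exc:
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    def _read():
        suit = read_suitability_table(config.suitability)
        thr = read_thresholds(config.thresholds)
        parks = read_parks(config.parks)
        suit = suit[suit["season"].isin(config.seasons) & suit["rcp"].isin(config.rcps)]
        if suit.empty:
            raise ValidationError("no suitability rows left after season/RCP selection")
        return suit, thr, parks

    suit, thr, parks = stage("read_inputs", _read)

    def _classify():
        settings = config.classifier_settings()
        full = classify_all(
            suit, thr, settings, permissive=config.permissive, drop_excluded=False
        )
        yr = year_round_table(full)
        return full[full["included"]].reset_index(drop=True), yr

    classifications, year_round = stage("classify", _classify)

    def _summarize():
        summaries = summarize_parks(classifications, year_round=year_round)
        system = systemwide_summary(summaries)
        return summaries, system

    park_summary, system = stage("summarize", _summarize)

    groups = thresholds_sidecar = None
    if config.typology_season in config.seasons and config.typology_rcp in config.rcps:
        def _groups():
            return classify_parks(
                park_summary,
                season=config.typology_season,
                rcp=config.typology_rcp,
                geometry=config.typology_geometry,
            )
        groups, thresholds_sidecar = stage("groups", _groups)
    else:
        logger.warning(
            "typology stratum (%s, %s) not in the selected seasons/RCPs; skipping groups",
            config.typology_season, config.typology_rcp,
        )

    def _stats():
        report: dict = {"settings": {"alpha": config.alpha, "seed": config.seed}}
        for rcp in config.rcps:
            rs = park_summary[park_summary["rcp"] == rcp]
            block: dict = {}
            if set(config.seasons) >= {"summer", "winter"}:
                for metric in config.metrics:
                    s = rs.loc[rs["season"] == "summer", metric]
                    w = rs.loc[rs["season"] == "winter", metric]
                    if len(s) >= 3 and len(w) >= 3:
                        block[f"seasonal_{metric}"] = compare_seasons(
                            s, w, alpha=config.alpha
                        ).to_dict()
            for season in config.seasons:
                ss = rs[rs["season"] == season]
                if ss.empty:
                    continue
                for metric in config.metrics:
                    try:
                        block[f"latitude_{metric}_{season}"] = latitude_regression(
                            ss, parks, metric
                        ).to_dict()
                    except ValidationError as exc:
                        logger.warning("latitude regression skipped (%s, %s): %s", season, metric, exc)
                    try:
                        block[f"regional_anova_{metric}_{season}"] = regional_anova(
                            ss, parks, metric
                        ).to_dict()
                    except ValidationError as exc:
                        logger.warning("regional ANOVA skipped (%s, %s): %s", season, metric, exc)
                for region in REGIONS:
                    n_region = parks.loc[parks["region"] == region, "park_id"].isin(
                        ss["park_id"]
                    ).sum()
                    if n_region >= 3:
                        block[f"region_vs_overall_bray_curtis_{season}_{region}"] = (
                            region_vs_overall(
                                ss, parks, "bray_curtis", region, alpha=config.alpha
                            ).to_dict()
                        )
            report[rcp] = block
        return report

    stats_report = stage("stats", _stats)

    def _write():
        write_canonical_csv(classifications, out_dir / "classifications.csv")
        artifacts["classifications"] = out_dir / "classifications.csv"
        write_canonical_csv(park_summary, out_dir / "park_summary.csv")
        artifacts["park_summary"] = out_dir / "park_summary.csv"
        write_canonical_csv(system, out_dir / "systemwide_summary.csv")
        artifacts["systemwide_summary"] = out_dir / "systemwide_summary.csv"
        if groups is not None:
            write_canonical_csv(groups, out_dir / "trend_groups.csv")
            artifacts["trend_groups"] = out_dir / "trend_groups.csv"
            with open(out_dir / "typology_thresholds.json", "w") as fh:
                json.dump(thresholds_sidecar.to_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            artifacts["typology_thresholds"] = out_dir / "typology_thresholds.json"
        with open(out_dir / "stats_report.json", "w") as fh:
            json.dump(stats_report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts["stats_report"] = out_dir / "stats_report.json"

    stage("write_outputs", _write)

    def _manifest():
        manifest = {
            "version": __version__,
            "config": _config_dict(config),
            "inputs": {
                name: _sha256(Path(getattr(config, name)))
                for name in ("suitability", "thresholds", "parks")
            },
            "outputs": {name: _sha256(path) for name, path in sorted(artifacts.items())},
        }
        path = out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        artifacts["manifest"] = path

    stage("manifest", _manifest)
    return artifacts


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
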