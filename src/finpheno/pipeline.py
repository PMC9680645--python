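"""End-to-end workflow: simulate/ingest -> label -> features -> statistics.

One YAML config drives the whole run; every stage writes its output under
the run directory and the run closes with a manifest recording the config
hash, seeds, input digests and output list, so a run can be verified and
reproduced bit-for-bit (timestamps excluded).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .anomaly import detect_anomalies, write_anomaly_csv
from .errors import ConfigError, PipelineStageError
from .features import Grain, credit_ratio_monthly, resample, write_features_csv
from .group_inference import games_howell, phase_groups, welch_anova, write_inference_csv
from .ledger_ingest import (
    StatementDialect,
    assemble_ledger,
    parse_statement_file,
    read_statement_csv,
    write_ledger_csv,
)
from .lifechart import LifeChart, read_lifechart_csv, write_lifechart_csv
from .preprocess import preprocess_ledger, write_labeled_csv
from .synthetic_data import (
    SyntheticConfig,
    generate_ledger,
    generate_lifechart,
    statement_dialect,
    write_ground_truth_json,
    write_statement_files,
)
from .temporal_stats import Scheme, burstiness_by_phase, write_burstiness_csv

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_all"]


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration (one YAML file, per-stage sections)."""

    mode: str = "simulate"  # 'simulate' | 'ingest'
    statements_dir: str | None = None
    dialect: StatementDialect | None = None
    chart_path: str | None = None
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    grain: str = "daily"
    anomaly_grain: str = "weekly"
    contamination: float = 0.05
    n_trees: int = 100
    alpha: float = 0.05
    merge_phases: bool = False
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(raw=raw)
        cfg.mode = raw.get("mode", "simulate")
        if cfg.mode not in ("simulate", "ingest"):
            raise ConfigError(f"mode must be 'simulate' or 'ingest', got {cfg.mode!r}")
        cfg.seed = int(raw.get("seed", 0)) if seed is None else seed
        if cfg.mode == "ingest":
            for key in ("statements_dir", "chart"):
                if key not in raw:
                    raise ConfigError(f"ingest mode requires config field {key!r}")
            cfg.statements_dir = raw["statements_dir"]
            cfg.chart_path = raw["chart"]
            cfg.dialect = (
                StatementDialect(**raw["dialect"]) if "dialect" in raw else statement_dialect()
            )
        else:
            sim = dict(raw.get("simulate", {}))
            sim["seed"] = cfg.seed
            if "start" in sim and isinstance(sim["start"], str):
                from datetime import date as _date

                sim["start"] = _date.fromisoformat(sim["start"])
            cfg.simulate = SyntheticConfig(**sim)
        stats = raw.get("stats", {})
        cfg.alpha = float(stats.get("alpha", 0.05))
        cfg.merge_phases = bool(stats.get("merge_phases", False))
        an = raw.get("anomaly", {})
        cfg.contamination = float(an.get("contamination", 0.05))
        cfg.n_trees = int(an.get("n_trees", 100))
        return cfg


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    inputs: dict[str, str]
    outputs: list[str]
    started: str
    finished: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(path: Path, writer) -> Path:
    """Write via a .partial file, renaming only on success."""
    partial = path.with_suffix(path.suffix + ".partial")
    writer(partial)
    partial.rename(path)
    return path


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute every stage in sequence and write the run manifest.

    A stage failure raises :class:`PipelineStageError` naming the stage;
    outputs of completed stages remain, the failing stage's partial output
    keeps its ``.partial`` suffix.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()
    inputs: dict[str, str] = {}
    outputs: list[Path] = []

    def stage(name: str, fn):
        log.info("stage %s: start", name)
        try:
            result = fn()
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 — re-raised with stage context
            raise PipelineStageError(name, str(exc)) from exc
        log.info("stage %s: done", name)
        return result

    def _acquire():
        if config.mode == "simulate":
            chart = generate_lifechart(config.simulate)
            ledger, truth = generate_ledger(chart, config.simulate)
            stmt_dir = out / "statements"
            write_statement_files(ledger, stmt_dir, quirk_profile="camelot")
            outputs.append(_write(out / "chart.csv", lambda p: write_lifechart_csv(chart, p)))
            outputs.append(
                _write(out / "ground_truth.json", lambda p: write_ground_truth_json(truth, p))
            )
            dialect = statement_dialect()
        else:
            stmt_dir = Path(config.statements_dir)
            chart = read_lifechart_csv(config.chart_path)
            inputs[str(config.chart_path)] = _digest(Path(config.chart_path))
            dialect = config.dialect
        files = sorted(stmt_dir.glob("*.csv"))
        if not files:
            raise ConfigError(f"no statement files found in {stmt_dir}")
        for f in files:
            inputs[str(f)] = _digest(f)
        per_file = []
        n_errors = 0
        for f in files:
            res = parse_statement_file(read_statement_csv(f), dialect)
            per_file.append(res.transactions)
            n_errors += len(res.errors)
        if n_errors:
            log.warning("ingest: %d row-level errors collected and skipped", n_errors)
        ledger = assemble_ledger(per_file)
        outputs.append(_write(out / "ledger.csv", lambda p: write_ledger_csv(ledger, p)))
        return ledger, chart

    ledger, chart = stage("ingest", _acquire)

    labeled = stage("preprocess", lambda: preprocess_ledger(ledger, chart))
    outputs.append(_write(out / "labeled.csv", lambda p: write_labeled_csv(labeled, p)))

    def _features():
        span = (chart.span[0], _chart_end(chart))
        per_grain = {
            g: resample(labeled, g, chart=chart, span=span) for g in Grain
        }
        for g, series in per_grain.items():
            outputs.append(
                _write(out / f"features_{g.value}.csv", lambda p, s=series: write_features_csv(s, p))
            )
        ratio = credit_ratio_monthly(labeled)
        def _w(p):
            import csv as _csv
            with open(p, "w", newline="") as fh:
                w = _csv.writer(fh)
                w.writerow(["month", "credit_pct"])
                for pt in ratio:
                    w.writerow([f"{pt.month:%Y-%m}", repr(pt.credit_pct)])
        outputs.append(_write(out / "credit_ratio_monthly.csv", _w))
        return per_grain

    per_grain = stage("features", _features)
    daily = per_grain[Grain.DAILY]

    def _burstiness():
        results = []
        for scheme in (Scheme.D, Scheme.C):
            results.extend(
                burstiness_by_phase(labeled, daily, scheme, merge=config.merge_phases)
            )
        outputs.append(_write(out / "burstiness.csv", lambda p: write_burstiness_csv(results, p)))
        return results

    stage("burstiness", _burstiness)

    def _inference():
        path = out / "inference.csv"
        partial = path.with_suffix(".csv.partial")
        if partial.exists():
            partial.unlink()
        for endpoint in ("frequency", "volume"):
            groups = phase_groups(daily, endpoint, merge=config.merge_phases)
            welch = welch_anova(groups)
            pairs = games_howell(groups, alpha=config.alpha)
            grouping = "merged" if config.merge_phases else "by_severity"
            write_inference_csv(endpoint, grouping, welch, pairs, partial, append=True)
        partial.rename(path)
        outputs.append(path)

    stage("inference", _inference)

    def _anomaly():
        weekly = per_grain[Grain.WEEKLY]
        report = detect_anomalies(
            weekly,
            contamination=config.contamination,
            n_trees=config.n_trees,
            seed=config.seed,
        )
        outputs.append(
            _write(out / "anomaly.csv", lambda p: write_anomaly_csv(weekly, report, p))
        )
        return report

    stage("anomaly", _anomaly)

    finished = datetime.now(timezone.utc).isoformat()
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        seed=config.seed,
        version=__version__,
        inputs=inputs,
        outputs=sorted(str(p.relative_to(out)) for p in outputs),
        started=started,
        finished=finished,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _chart_end(chart: LifeChart):
    from datetime import timedelta

    from .lifechart import next_month

    return next_month(chart.span[1]) - timedelta(days=1)
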