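"""End-to-end orchestration: config-driven runs with a manifest.

Stages: curate -> build_psn -> louvain (optional bigclam) -> enrich (all
five feature classes) -> symptom_resolution -> module profiles for the
largest modules, plus a cohort summary table. Every artifact is a plain
text file; the manifest records the config snapshot, seeds, SHA-256
digests, and stage timings so identical runs are digest-verifiable.
"""

from __future__ import annotations

import datetime as _dt
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from ._utils import dump_json, round_half_up, sha256_file
from .communities import (
    Partition,
    bigclam,
    louvain,
    module_size_table,
)
from .curation import FeatureClass, PatientRecord, curate
from .efficacy import module_profile, symptom_resolution, write_resolution_csv
from .enrichment import enrich, write_enrichment_csv
from .errors import ConfigError, InputError, StageError
from .io import (
    read_records,
    read_term_dictionary,
    write_curation_report,
    write_labels_tsv,
    write_records_csv,
    write_term_dictionary,
)
from .psn import build_psn, write_edgelist, write_graphml
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["CohortSummary", "RunManifest", "summarize_cohort", "run_pipeline",
           "load_config", "DEFAULT_CONFIG"]

AGE_BANDS = [("<20", 0, 19), ("20-39", 20, 39), ("40-59", 40, 59),
             ("60-79", 60, 79), (">=80", 80, None)]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "output_dir": "psnstrat-run",
    "input": {},  # records/dictionary paths, or a "simulate" section
    "curation": {"policy": "drop_unknown"},
    "psn": {"main_threshold": 0.8},
    "communities": {
        "resolution": 1.0,
        "tolerance": 1e-7,
        "bigclam": {"enabled": False, "n_communities": 5},
    },
    "enrichment": {"alpha": 0.05, "bh_correction": False},
    "efficacy": {"min_support": 5},
    "profiles": {"top_modules": 3, "top_k": 10},
}


@dataclass
class CohortSummary:
    """Demographic margins of a curated cohort."""

    n: int
    sex_counts: dict[str, int]
    age_mean: float | None
    age_sd: float | None
    age_band_counts: dict[str, int]
    outcome_counts: dict[str, int]

    def to_dict(self) -> dict:
        sex = {
            key: {
                "count": count,
                "percent": round_half_up(100.0 * count / self.n, 2),
            }
            for key, count in sorted(self.sex_counts.items())
        }
        return {
            "n": self.n,
            "sex": sex,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_bands": self.age_band_counts,
            "outcomes": dict(sorted(self.outcome_counts.items())),
        }

    def sex_percent(self, sex: str) -> float:
        return round_half_up(100.0 * self.sex_counts.get(sex, 0) / self.n, 2)


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Counts, percentages (two decimals) and half-open age bands."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    sex_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    band_counts = {name: 0 for name, _, _ in AGE_BANDS}
    ages = []
    for record in records:
        if record.sex:
            sex_counts[record.sex] = sex_counts.get(record.sex, 0) + 1
        if record.outcome:
            outcome_counts[record.outcome] = outcome_counts.get(record.outcome, 0) + 1
        if record.age is not None:
            ages.append(record.age)
            for name, lo, hi in AGE_BANDS:
                if record.age >= lo and (hi is None or record.age < hi + 1):
                    band_counts[name] += 1
                    break
    age_mean = round_half_up(float(np.mean(ages)), 2) if ages else None
    age_sd = round_half_up(float(np.std(ages, ddof=1)), 2) if len(ages) > 1 else None
    return CohortSummary(
        n=len(records),
        sex_counts=sex_counts,
        age_mean=age_mean,
        age_sd=age_sd,
        age_band_counts=band_counts,
        outcome_counts=outcome_counts,
    )


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    started: str = ""
    stages: list[dict] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "started": self.started,
            "config": self.config,
            "stages": self.stages,
            "artifacts": self.artifacts,
        }


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid with a YAML file, overlaid with *overrides*."""
    config = _deep_merge({}, DEFAULT_CONFIG)
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config must be a YAML mapping")
        config = _deep_merge(config, loaded)
    if overrides:
        config = _deep_merge(config, overrides)
    return config


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


class _Runner:
    def __init__(self, config: dict, out_dir: Path, manifest: RunManifest):
        self.config = config
        self.out_dir = out_dir
        self.manifest = manifest

    def run_stage(self, name: str, fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except StageError:
            raise
        except (InputError, ConfigError) as exc:
            raise StageError(name, type(exc).__name__.lower(), str(exc)) from exc
        except Exception as exc:  # noqa: BLE001 - annotate with the stage
            raise StageError(name, "internal", str(exc)) from exc
        self.manifest.stages.append(
            {
                "stage": name,
                "status": "succeeded",
                "seconds": round(time.perf_counter() - start, 4),
            }
        )
        return result

    def register(self, path: Path) -> None:
        rel = str(path.relative_to(self.out_dir))
        self.manifest.artifacts[rel] = sha256_file(path)


def _stage_seeds(root_seed: int, names: Sequence[str]) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0]) % (2**31)
        for name, child in zip(names, children)
    }


def run_pipeline(
    config: dict | str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute every stage and write artifacts plus ``manifest.json``.

    On a stage failure the partially written outputs are moved under a
    ``failed/`` prefix and the :class:`StageError` is re-raised.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config = _deep_merge(config, {"seed": int(seed)})
    root_seed = int(config.get("seed", 0))

    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config,
        seed=root_seed,
        started=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
    )
    runner = _Runner(config, out_dir, manifest)
    seeds = _stage_seeds(root_seed, ["simulate", "detect", "bigclam"])

    try:
        _run_stages(runner, seeds)
    except StageError:
        failed = out_dir / "failed"
        failed.mkdir(exist_ok=True)
        for item in sorted(out_dir.iterdir()):
            if item.is_file():
                item.rename(failed / item.name)
        raise
    manifest_path = out_dir / "manifest.json"
    dump_json(manifest.to_dict(), manifest_path)
    return manifest


def _resolve_inputs(runner: _Runner, seeds: dict[str, int]):
    config = runner.config
    section = config.get("input") or {}
    if "simulate" in section and section["simulate"]:
        sim_kwargs = dict(section["simulate"])
        sim_kwargs.setdefault("seed", seeds["simulate"])
        gen_config = GeneratorConfig(**sim_kwargs)
        records, truth, dictionary = generate_cohort(gen_config)
        records_path = runner.out_dir / "simulated_records.csv"
        write_records_csv(records, records_path)
        dict_path = runner.out_dir / "simulated_dictionary.tsv"
        write_term_dictionary(dictionary, dict_path)
        truth_path = runner.out_dir / "simulated_truth.tsv"
        write_labels_tsv(truth.labels, truth_path)
        for p in (records_path, dict_path, truth_path):
            runner.register(p)
        return records, dictionary
    if "records" not in section or "dictionary" not in section:
        raise ConfigError(
            "config.input must provide 'records' and 'dictionary' paths "
            "or a 'simulate' section"
        )
    records = read_records(section["records"])
    dictionary = read_term_dictionary(section["dictionary"])
    return records, dictionary


def _run_stages(runner: _Runner, seeds: dict[str, int]) -> None:
    config = runner.config
    out = runner.out_dir

    policy = config["curation"].get("policy", "drop_unknown")

    def _curate_stage():
        records, dictionary = _resolve_inputs(runner, seeds)
        return curate(records, dictionary, policy)

    curated, report = runner.run_stage("curate", _curate_stage)
    write_curation_report(report, out / "curation_report.json")
    summary = summarize_cohort(curated)
    dump_json(summary.to_dict(), out / "cohort_summary.json")
    runner.register(out / "curation_report.json")
    runner.register(out / "cohort_summary.json")

    threshold = float(config["psn"].get("main_threshold", 0.8))
    psn = runner.run_stage("build_psn", build_psn, curated, threshold)
    write_edgelist(psn, out / "psn_edgelist.txt")
    write_graphml(psn, out / "psn.graphml")
    runner.register(out / "psn_edgelist.txt")

    comm_cfg = config["communities"]
    partition: Partition = runner.run_stage(
        "detect",
        louvain,
        psn,
        seeds["detect"],
        float(comm_cfg.get("tolerance", 1e-7)),
        float(comm_cfg.get("resolution", 1.0)),
    )
    write_labels_tsv(partition.assignment, out / "partition.tsv")
    dump_json(
        {
            **partition.metadata(),
            "seed": seeds["detect"],
            "resolution": comm_cfg.get("resolution", 1.0),
            "module_sizes": [
                {"module": m, "size": s, "share_percent": p}
                for m, s, p in module_size_table(partition)
            ],
        },
        out / "partition_meta.json",
    )
    runner.register(out / "partition.tsv")
    runner.register(out / "partition_meta.json")

    bc_cfg = comm_cfg.get("bigclam") or {}
    if bc_cfg.get("enabled"):
        cover = runner.run_stage(
            "bigclam",
            bigclam,
            psn,
            int(bc_cfg.get("n_communities", 5)),
            seeds["bigclam"],
        )
        dump_json(cover.to_dict(), out / "bigclam_cover.json")
        runner.register(out / "bigclam_cover.json")

    networked = [r for r in curated if r.patient_id in partition.assignment]
    alpha = float(config["enrichment"].get("alpha", 0.05))
    bh = bool(config["enrichment"].get("bh_correction", False))
    for cls in FeatureClass:
        results = runner.run_stage(
            f"enrich_{cls.value}", enrich, networked, partition, cls, alpha, bh
        )
        path = out / f"enrichment_{cls.value}.csv"
        write_enrichment_csv(results, path)
        runner.register(path)

    min_support = int(config["efficacy"].get("min_support", 5))
    resolution = runner.run_stage(
        "efficacy", symptom_resolution, networked, partition, min_support
    )
    write_resolution_csv(resolution, out / "symptom_resolution.csv")
    runner.register(out / "symptom_resolution.csv")

    top_modules = int(config["profiles"].get("top_modules", 3))
    top_k = int(config["profiles"].get("top_k", 10))
    for module_id, _, _ in module_size_table(partition)[:top_modules]:
        profile = runner.run_stage(
            f"profile_m{module_id}",
            module_profile,
            networked,
            partition,
            module_id,
            alpha,
            top_k,
            min_support,
        )
        path = out / f"profile_m{module_id}.json"
        dump_json(profile, path)
        runner.register(path)
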