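"""End-to-end pipeline runner driven by a YAML run configuration.

Stages: synth (optional) -> preprocess -> connectome -> graph sweep and/or
ROI statistics. Every output file lands under the run's output directory
and is checksummed into a JSON manifest; identical configuration and seed
produce identical checksums. All randomness descends from the single root
seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from . import preprocess as pp
from .connectome import correlate, graph_from_matrix
from .roistats import normalize_volumes, region_table
from .sweep import metric_sweep, node_metrics_at
from .synth import AtlasSpec, SynthConfig, gen_atlas, gen_cohort, gen_measure_table
from .types import ValidationError

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("mouseconn")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated run configuration (see ``load`` for the YAML schema)."""

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ("synth", "preprocess", "connectome",
                               "graph", "roistats")
    synth: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    connectome: dict = field(default_factory=dict)
    graphm: dict = field(default_factory=dict)
    roistats: dict = field(default_factory=dict)
    input_dir: Path | None = None
    verbosity: str = "INFO"

    @classmethod
    def load(cls, path: str | Path, **overrides) -> "RunConfig":
        data = mio.load_yaml(path)
        version = data.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported config schema version {version}")
        data.update(overrides)
        if "out_dir" not in data:
            raise ValidationError("config must set out_dir")
        data["out_dir"] = Path(data["out_dir"])
        if data.get("input_dir") is not None:
            data["input_dir"] = Path(data["input_dir"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        known = {"synth", "preprocess", "connectome", "graph", "roistats"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if "synth" not in self.stages:
            if self.input_dir is None or not Path(self.input_dir).exists():
                raise ValidationError(
                    "input_dir must exist when the synth stage is disabled")


def _stage_timer(name: str):
    start = time.perf_counter()

    def done(**params):
        log.info("stage %s finished in %.2fs (%s)", name,
                 time.perf_counter() - start, params)
    return done


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    logging.basicConfig(level=config.verbosity)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    complete = True
    try:
        cohort = None
        if "synth" in config.stages:
            done = _stage_timer("synth")
            synth_cfg = SynthConfig(seed=config.seed, **config.synth)
            cohort = gen_cohort(synth_cfg)
            ts_dir = out_dir / "timeseries"
            ts_dir.mkdir(exist_ok=True)
            for series in cohort:
                p = mio.write_timeseries(
                    series, ts_dir / mio.timeseries_filename(series))
                outputs.extend([p, p.with_suffix(p.suffix + ".json")])
            # a small atlas and the measure tables for the roistats stage
            n_labels = min(synth_cfg.n_nodes, 139)
            spec = AtlasSpec(
                grid_shape=(32, 32, 16), voxel_dims=(0.2, 0.2, 0.5),
                label_voxel_counts={k: 60 for k in range(1, n_labels + 1)},
                label_names={k: synth_cfg.node_names()[k - 1]
                             for k in range(1, n_labels + 1)})
            image, names = gen_atlas(spec, seed=config.seed)
            outputs.append(mio.write_atlas_nifti(
                image, spec.voxel_dims, out_dir / "atlas.nii",
                name_table=names))
            outputs.append((out_dir / "atlas.labels.tsv"))
            for measure in ("volume_mm3", "FA"):
                table = gen_measure_table(synth_cfg, seed=config.seed,
                                          measure=measure)
                if measure == "volume_mm3":
                    table = normalize_volumes(table)
                outputs.append(mio.write_measure_table(
                    table, out_dir / f"measures_{measure}.csv"))
            done(n_series=len(cohort))
        elif config.input_dir is not None:
            cohort = [mio.read_timeseries(p)
                      for p in sorted(Path(config.input_dir).glob("*.tsv"))
                      if not p.name.endswith(".labels.tsv")]

        matrices = {}
        if "preprocess" in config.stages or "connectome" in config.stages:
            if not cohort:
                raise ValidationError("no time series available")
        if "preprocess" in config.stages:
            done = _stage_timer("preprocess")
            cohort = [pp.run_chain(s, **config.preprocess) for s in cohort]
            done(n_series=len(cohort))
        if "connectome" in config.stages:
            done = _stage_timer("connectome")
            mat_dir = out_dir / "matrices"
            mat_dir.mkdir(exist_ok=True)
            for series in cohort:
                cm = correlate(series)
                matrices[(series.subject_id, series.session,
                          series.group)] = cm
                outputs.append(mio.write_matrix(
                    cm.z, cm.node_names,
                    mat_dir / f"{series.subject_id}_{series.session}.z.csv"))
            done(n_matrices=len(matrices))
        if "graph" in config.stages:
            done = _stage_timer("graph")
            rows, auc_rows = [], []
            rng = np.random.default_rng(config.seed)
            gcfg = dict(config.graphm)
            node_density = gcfg.pop("node_density", 0.16)
            for (subj, sess, group), cm in matrices.items():
                sw = metric_sweep(cm, seed=int(rng.integers(2**31)), **gcfg)
                rec = sw.records.assign(subject_id=subj, session=sess,
                                        group=group)
                rows.append(rec)
                for metric, value in sw.auc.items():
                    auc_rows.append({"subject_id": subj, "session": sess,
                                     "group": group, "metric": metric,
                                     "auc": value})
                nm = node_metrics_at(cm, density=node_density)
                node_path = out_dir / f"nodes_{subj}_{sess}.csv"
                nm.table.to_csv(node_path)
                outputs.append(node_path)
            if rows:
                sweep_path = out_dir / "sweep.csv"
                pd.concat(rows, ignore_index=True).to_csv(
                    sweep_path, index=False)
                outputs.append(sweep_path)
                auc_path = out_dir / "auc.csv"
                pd.DataFrame(auc_rows).to_csv(auc_path, index=False)
                outputs.append(auc_path)
                g_example = graph_from_matrix(next(iter(matrices.values())))
                outputs.extend(mio.write_brainnet(
                    g_example, out_dir / "connectome"))
            done(n_graphs=len(matrices))
        if "roistats" in config.stages:
            done = _stage_timer("roistats")
            measures_path = out_dir / "measures_FA.csv"
            if measures_path.exists():
                table = mio.read_measure_table(measures_path)
                for sess in sorted(table["session"].unique()):
                    stats_tab = region_table(table, measure="FA",
                                             session=sess,
                                             **config.roistats)
                    p = out_dir / f"region_stats_FA_{sess}.csv"
                    stats_tab.to_csv(p, index=False)
                    outputs.append(p)
            done()
    except Exception:
        complete = False
        raise
    finally:
        manifest_path = out_dir / "manifest.json"
        existing = [p for p in outputs if Path(p).exists()]
        mio.write_manifest(existing, manifest_path, seed=config.seed,
                           complete=complete,
                           extra={"stages": list(config.stages)})
    import json
    return json.loads(manifest_path.read_text())
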