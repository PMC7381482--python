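"""Experiment orchestration: configuration, seeds, manifests, end-to-end runs.

Both case studies can be run at two scales: ``full`` mirrors the published
replicate counts (20 hub networks with 10 lesions per severity level; 12
action networks with 500 episodes per cell), while ``desk`` reduces
replicate counts only -- never the severity grids -- to sizes that finish
on a single CPU in minutes (5 hub networks x 5 lesions per level; 3 action
networks x 100 episodes per cell).

Every stage's randomness is derived from the master seed via
:func:`lesionlab.seeds.derive_seed`; a :class:`RunManifest` records the
configuration, derived seeds and output checksums so deterministic stages
reproduce bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beverage as bev
from . import semantic as sem
from .hub import HubNet, init_network, train, max_unit_error, naming_accuracy
from .patterns import build_profile, generate_patterns, write_patterns
from .seeds import derive_seed
from .srn import SRNConfig, train_cohort
from . import action_analysis as aa

__version__ = "0.1.0"

SCALE_PRESETS = {
    "full": {"hub_networks": 20, "lesions_per_level": 10,
             "srn_networks": 12, "episodes_per_cell": 500},
    "desk": {"hub_networks": 5, "lesions_per_level": 5,
             "srn_networks": 3, "episodes_per_cell": 100},
}


@dataclass
class ExperimentConfig:
    case_study: str = "semantic"  # "semantic" | "action"
    profiles: tuple = ("P1-like", "P2-like")
    scale: str = "desk"
    master_seed: int = 0
    output_dir: str = "runs/latest"
    # explicit overrides (None -> scale preset)
    hub_networks: int | None = None
    lesions_per_level: int | None = None
    srn_networks: int | None = None
    episodes_per_cell: int | None = None
    hub_epochs: int | None = None  # None -> HubConfig default

    def __post_init__(self):
        if self.case_study not in ("semantic", "action"):
            raise ValueError(f"unknown case study {self.case_study!r}")
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale preset {self.scale!r}")
        preset = SCALE_PRESETS[self.scale]
        for k, v in preset.items():
            if getattr(self, k) is None:
                setattr(self, k, v)

    @staticmethod
    def from_file(path: str | Path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yml", ".yaml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        bad = sorted(set(data) - known)
        if bad:
            raise ValueError(f"unknown config keys: {bad}")
        if "profiles" in data:
            data["profiles"] = tuple(data["profiles"])
        return ExperimentConfig(**data)


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    started: str = ""
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def record(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                   default=str))


def _outdir(config: ExperimentConfig) -> Path:
    out = Path(config.output_dir)
    for sub in ("patterns", "checkpoints", "results"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    return out


def run_semantic(config: ExperimentConfig) -> RunManifest:
    """Case study 1 end-to-end: generate, train, lesion, analyse."""
    out = _outdir(config)
    manifest = RunManifest(dataclasses.asdict(config),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    ms = config.master_seed
    areas_summary = {}
    attractor_summaries = {}
    for profile_id in config.profiles:
        profile = build_profile(profile_id)
        nets, sets = [], []
        for i in range(config.hub_networks):
            s_var = derive_seed(ms, f"{profile_id}-variant", i)
            s_init = derive_seed(ms, f"{profile_id}-netinit", i)
            s_train = derive_seed(ms, f"{profile_id}-train", i)
            manifest.seeds[f"{profile_id}-{i}"] = {
                "variant": s_var, "init": s_init, "train": s_train}
            ps = generate_patterns(profile, s_var)
            write_patterns(out / "patterns" / f"{profile_id}-{i}.csv", ps)
            net = init_network(seed=s_init)
            train(net, ps, epochs=config.hub_epochs, seed=s_train)
            net.save(out / "checkpoints" / f"{profile_id}-{i}.npz")
            nets.append(net)
            sets.append(ps)
        curves = []
        for grid in sem.default_grids(config.lesions_per_level):
            curve = sem.run_damage_grid(nets, grid, sets, master_seed=ms)
            curve.insert(0, "profile", profile_id)
            curves.append(curve)
            res = sem.area_between_curves(curve)
            areas_summary[f"{profile_id}:{grid.kind}"] = {
                "mean": res.mean, "sd": res.sd, "ci95": list(res.ci95)}
        all_curves = pd.concat(curves, ignore_index=True)
        curve_path = out / "results" / f"curves-{profile_id}.csv"
        all_curves.to_csv(curve_path, index=False)
        manifest.record(curve_path)
        attractor_summaries[profile_id] = [
            sem.attractor_summary(net, ps) for net, ps in zip(nets, sets)]
        wpath = out / "results" / f"weights-{profile_id}.csv"
        sem.weight_summary(nets).to_csv(wpath, index=False)
        manifest.record(wpath)
    if len(config.profiles) >= 2:
        anova = sem.attractor_anova(attractor_summaries)
        apath = out / "results" / "attractor-anova.csv"
        anova.to_csv(apath)
        manifest.record(apath)
    areas_path = out / "results" / "areas.json"
    areas_path.write_text(json.dumps(areas_summary, indent=1))
    manifest.record(areas_path)
    manifest.write(out / "manifest.json")
    return manifest


def run_action(config: ExperimentConfig) -> RunManifest:
    """Case study 2 end-to-end: train cohort, sweep damage, analyse."""
    out = _outdir(config)
    manifest = RunManifest(dataclasses.asdict(config),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    ms = config.master_seed
    corpus, grammar = bev.build_corpus()
    corpus.export_json(out / "patterns" / "corpus.json")
    (out / "patterns" / "grammar.json").write_text(grammar.to_json())
    nets = train_cohort(config.srn_networks, SRNConfig(), corpus, ms)
    for i, net in enumerate(nets):
        net.save(out / "checkpoints" / f"srn-{i}.npz")
        manifest.seeds[f"srn-{i}"] = derive_seed(ms, "srn-init", i)
    report = aa.damage_sweep(nets, corpus,
                             episodes_per_cell=config.episodes_per_cell,
                             master_seed=ms)
    rpath = out / "results" / "error-report.csv"
    report.to_csv(rpath, index=False)
    manifest.record(rpath)
    crux = aa.crux_analysis(report)
    cpath = out / "results" / "crux.csv"
    crux.to_csv(cpath, index=False)
    manifest.record(cpath)
    # survival under the published mild activation noise
    rows = []
    for task in ("coffee", "tea"):
        episodes = []
        for i, net in enumerate(nets):
            episodes += aa.run_damaged_episodes(
                net, corpus, "activation_noise", 0.10, task,
                config.episodes_per_cell, derive_seed(ms, f"survival{i}", 0))
        curve = aa.survival_analysis(episodes, corpus, task)
        for s, p in zip(curve.steps, curve.proportion):
            rows.append((task, int(s), float(p)))
    spath = out / "results" / "survival.csv"
    pd.DataFrame(rows, columns=["task", "step", "proportion"]).to_csv(
        spath, index=False)
    manifest.record(spath)
    thresholds = {task: aa.scaling_threshold_search(nets, corpus, task)
                  for task in ("coffee", "tea")}
    tpath = out / "results" / "scaling-thresholds.json"
    tpath.write_text(json.dumps(thresholds))
    manifest.record(tpath)
    manifest.write(out / "manifest.json")
    return manifest
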