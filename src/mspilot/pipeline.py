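"""End-to-end orchestration: simulate -> preprocess -> fit -> group ->
backfit -> parameters -> dynamics -> spectral -> statistics.

Every random draw descends from the master seed through
``numpy.random.SeedSequence`` spawning, so two runs with the same
configuration produce identical outputs (and identical manifest hashes).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .backfit import backfit, microstate_parameters
from .config import PipelineConfig
from .dynamics import mean_hurst
from .groupmaps import align_full_permutation, label_canonical
from .io import file_sha256, write_maps
from .microstates import compute_gfp, find_gfp_peaks, modified_kmeans
from .preprocess import preprocess_recording
from .spectral import group_by_area, theta_power, welch_psd
from .stats import posthoc_paired_bonferroni, rm_anova
from .synth import (
    ProtocolSpec,
    TaskItem,
    generate_template_maps,
    simulate_protocol,
    uniform_sequence_model,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "canonical_templates"]


@dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    record_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def register(self, path: Path) -> None:
        self.outputs[str(path)] = file_sha256(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))


def canonical_templates(n_channels: int = 64, n_classes: int = 7):
    """The shipped canonical A–G label templates.

    These are synthetic stand-in topographies (generated by
    ``generate_template_maps`` with a fixed seed and stored as package
    data), not topographies taken from any published atlas; supply your
    own template maps for labelling real data.
    """
    from importlib import resources

    if n_channels == 64 and n_classes == 7:
        path = resources.files("mspilot.data") / "canonical_templates_synthetic.csv"
        df = pd.read_csv(str(path), index_col=0)
        return df.to_numpy(dtype=float), list(df.index), list(df.columns)
    maps = generate_template_maps(n_classes, n_channels, seed=1905)
    return maps.maps, list(maps.class_labels), maps.channel_names


def _fit_task(item: TaskItem, cfg: PipelineConfig, seed: int):
    gfp = compute_gfp(item.recording)
    peaks = find_gfp_peaks(gfp, min_distance_ms=cfg.min_peak_distance_ms)
    X = item.recording.data[:, peaks].T
    return modified_kmeans(
        X,
        n_classes=cfg.n_classes,
        n_init=cfg.n_init,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        seed=seed,
    )


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=cfg.seed, config=cfg.to_dict())
    cfg.to_yaml(out / "resolved_config.yaml")

    master = np.random.SeedSequence(cfg.seed)
    templates = generate_template_maps(
        cfg.n_classes,
        cfg.n_channels,
        max_similarity=cfg.max_similarity,
        seed=int(master.generate_state(1)[0] % 2**31),
    )
    spec = ProtocolSpec(
        stages=tuple(cfg.stages),
        baseline_duration=cfg.baseline_duration,
        trial_duration=cfg.trial_duration,
        sampling_rate=cfg.sampling_rate,
    )
    base_model = uniform_sequence_model(cfg.n_classes, cfg.mean_dwell_baseline)
    trial_model = uniform_sequence_model(cfg.n_classes, cfg.mean_dwell_trial)

    member_maps = []
    all_items: list[tuple[int, TaskItem]] = []
    for p in range(cfg.n_participants):
        p_seed = int(master.spawn(1)[0].generate_state(1)[0] % 2**31)
        items = simulate_protocol(
            spec,
            templates,
            base_model,
            trial_model,
            seed=p_seed,
            snr_db=cfg.snr_db,
            gfp_uv=cfg.gfp_uv,
            envelope_freq=cfg.envelope_freq,
        )
        for item in items:
            if cfg.do_preprocess:
                rec, report = preprocess_recording(
                    item.recording,
                    low=cfg.band_low,
                    high=cfg.band_high,
                    epoch_seconds=cfg.epoch_seconds,
                    target_fs=cfg.target_fs,
                )
                item.recording = rec
                manifest.warnings += [
                    f"p{p} {item.labels.task_id}: {w}" for w in report.warnings
                ]
            sol = _fit_task(item, cfg, seed=p_seed)
            member_maps.append(sol.maps)
            all_items.append((p, item))
    manifest.record_counts["task_items"] = len(all_items)
    manifest.record_counts["member_map_sets"] = len(member_maps)

    if len(member_maps) >= 2:
        global_maps, alignment = align_full_permutation(member_maps)
        manifest.record_counts["alignment_iterations"] = alignment.n_iter
    else:
        global_maps = member_maps[0]
    tpl_maps, tpl_labels, _ = canonical_templates(cfg.n_channels, cfg.n_classes)
    global_maps, class_labels, scores = label_canonical(global_maps, tpl_maps, tuple(tpl_labels))
    maps_path = write_maps(
        global_maps,
        list(templates.channel_names),
        out / "global_maps.csv",
        class_labels,
    )
    manifest.register(maps_path)

    param_rows, dyn_rows, spec_rows = [], [], []
    for p, item in all_items:
        seq = backfit(item.recording, global_maps)
        seq.stage, seq.task_type, seq.task_id = item.stage, item.labels.task_type, item.labels.task_id
        pars = microstate_parameters(seq)
        for k, cls in enumerate(class_labels):
            param_rows.append(
                {
                    "participant": p,
                    "stage": item.stage,
                    "task_type": item.task_type,
                    "session": item.session,
                    "class": cls,
                    "coverage": pars.coverage[k],
                    "occurrence": pars.occurrence[k],
                    "duration": pars.duration[k],
                }
            )
        if cfg.do_dynamics:
            dres = mean_hurst(seq, k_max=cfg.k_max)
            dyn_rows.append(
                {
                    "participant": p,
                    "stage": item.stage,
                    "task_type": item.task_type,
                    "session": item.session,
                    "entropy_rate": dres.entropy_rate,
                    "hurst_mean": dres.hurst_mean,
                }
            )
        if cfg.do_spectral:
            psd = welch_psd(
                item.recording,
                window_seconds=cfg.welch_window_seconds,
                overlap=cfg.welch_overlap,
            )
            powers = theta_power(psd, band=tuple(cfg.theta_band))
            try:
                areas = group_by_area(powers, item.recording.channel_names)
            except ValueError:
                areas = {}
                manifest.warnings.append(
                    f"p{p} {item.labels.task_id}: channels not mappable to areas"
                )
            for area, val in areas.items():
                spec_rows.append(
                    {
                        "participant": p,
                        "stage": item.stage,
                        "task_type": item.task_type,
                        "session": item.session,
                        "area": area,
                        "theta_power": val,
                    }
                )

    params = pd.DataFrame(param_rows)
    params.to_csv(out / "microstate_parameters.csv", index=False)
    manifest.register(out / "microstate_parameters.csv")
    manifest.record_counts["parameter_rows"] = len(params)
    if dyn_rows:
        dyn = pd.DataFrame(dyn_rows)
        dyn.to_csv(out / "dynamics.csv", index=False)
        manifest.register(out / "dynamics.csv")
    if spec_rows:
        spc = pd.DataFrame(spec_rows)
        spc.to_csv(out / "theta_power.csv", index=False)
        manifest.register(out / "theta_power.csv")

    if cfg.do_stats and cfg.n_participants >= 2:
        _run_stats(out, manifest, params, dyn_rows, spec_rows)

    manifest.write(out / "manifest.json")
    return manifest


def _run_stats(out: Path, manifest: RunManifest, params, dyn_rows, spec_rows) -> None:
    """TASK x STAGE (x CLASS / x AREA) repeated-measures tables."""
    agg = (
        params.groupby(["participant", "task_type", "stage", "class"], observed=True)
        .mean(numeric_only=True)
        .reset_index()
    )
    n_subj = params["participant"].nunique()
    for dv in ("coverage", "occurrence", "duration"):
        table = rm_anova(agg, dv=dv, within=["task_type", "stage", "class"])
        table.to_csv(out / f"anova_{dv}.csv", index=False)
        manifest.register(out / f"anova_{dv}.csv")
        if n_subj >= 3:
            ph = posthoc_paired_bonferroni(agg, dv=dv, family="task_type", per_level_of="class")
            ph.to_csv(out / f"posthoc_{dv}_task.csv", index=False)
            manifest.register(out / f"posthoc_{dv}_task.csv")
    if dyn_rows:
        dyn = pd.DataFrame(dyn_rows)
        dagg = (
            dyn.groupby(["participant", "task_type", "stage"], observed=True)
            .mean(numeric_only=True)
            .reset_index()
        )
        for dv in ("entropy_rate", "hurst_mean"):
            table = rm_anova(dagg, dv=dv, within=["task_type", "stage"])
            table.to_csv(out / f"anova_{dv}.csv", index=False)
            manifest.register(out / f"anova_{dv}.csv")
    if spec_rows:
        spc = pd.DataFrame(spec_rows)
        sagg = (
            spc.groupby(["participant", "task_type", "stage", "area"], observed=True)
            .mean(numeric_only=True)
            .reset_index()
        )
        table = rm_anova(sagg, dv="theta_power", within=["task_type", "stage", "area"])
        table.to_csv(out / "anova_theta.csv", index=False)
        manifest.register(out / "anova_theta.csv")
        if n_subj >= 3:
            ph = posthoc_paired_bonferroni(sagg, dv="theta_power", family="task_type", per_level_of="area")
            ph.to_csv(out / "posthoc_theta_task.csv", index=False)
            manifest.register(out / "posthoc_theta_task.csv")
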