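"""End-to-end orchestration: simulate/load -> preprocess -> MI -> networks ->
group statistics, driven by a single YAML config with a reproducibility
manifest.

Config schema (YAML)::

    seed: 1
    output_dir: out
    input:
      kind: simulation            # or: edf_dir | text_dir
      directory: recs/            # for edf_dir/text_dir: files <group>_<subject>.<ext>
    simulation:
      duration_s: 60.0
      sampling_rate: 250.0
      n_subjects: 3
      groups:                     # per-group generative coupling strengths
        HC:   {interhemispheric: 0.8, fronto_parietal: 0.6}
        PSND: {interhemispheric: 0.6, fronto_parietal: 0.5}
        PSMD: {interhemispheric: 0.4, fronto_parietal: 0.4}
        PSD:  {interhemispheric: 0.2, fronto_parietal: 0.3}
      noise_sd: 1.0
    preprocessing:
      low_hz: 0.1
      high_hz: 100.0
      reference: average          # none | average | linked_pair
      reference_pair: [T3, T4]    # only for linked_pair
      epoch_seconds: 5.0
      amplitude_threshold: null   # microvolts; null disables epoch rejection
    analysis:
      n_bins: 11
      threshold_grid: {start: 0.10, stop: 0.30, step: 0.01}
      alpha: 0.05
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .graph import DEFAULT_THRESHOLD_GRID, HemisphereMap, threshold_sweep
from .io import read_recording, write_mi_matrix
from .mi import HistogramSpec, MIMatrix, mi_matrix
from .preprocess import preprocess
from .recording import EEGRecording, MONTAGE_16
from .simulate import CohortScenario, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    output_dir: Path = Path("mibrain_out")
    input_kind: str = "simulation"
    input_directory: Optional[Path] = None
    duration_s: float = 60.0
    sampling_rate: float = 250.0
    n_subjects: int = 3
    group_strengths: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "HC": {"interhemispheric": 0.8, "fronto_parietal": 0.7, "intrahemispheric": 0.2},
            "PSND": {"interhemispheric": 0.6, "fronto_parietal": 0.55, "intrahemispheric": 0.45},
            "PSMD": {"interhemispheric": 0.4, "fronto_parietal": 0.4, "intrahemispheric": 0.6},
            "PSD": {"interhemispheric": 0.2, "fronto_parietal": 0.25, "intrahemispheric": 0.75},
        }
    )
    noise_sd: float = 1.0
    low_hz: float = 0.1
    high_hz: float = 100.0
    reference: str = "average"
    reference_pair: Optional[Tuple[str, str]] = None
    epoch_seconds: float = 5.0
    amplitude_threshold: Optional[float] = None
    n_bins: int = 11
    threshold_grid: Tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    alpha: float = 0.05

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if self.input_kind not in ("simulation", "edf_dir", "text_dir"):
            raise ValueError(f"unknown input kind {self.input_kind!r}")
        if self.input_kind != "simulation":
            if self.input_directory is None:
                raise ValueError(f"input kind {self.input_kind!r} requires a directory")
            self.input_directory = Path(self.input_directory)
            if not self.input_directory.is_dir():
                raise ValueError(f"input directory {self.input_directory} does not exist")
        for f in self.threshold_grid:
            if not 0 < f <= 1:
                raise ValueError(f"threshold fraction {f} outside (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sim = raw.get("simulation", {})
        pre = raw.get("preprocessing", {})
        ana = raw.get("analysis", {})
        inp = raw.get("input", {})
        grid = ana.get("threshold_grid", None)
        if isinstance(grid, dict):
            grid = tuple(
                np.round(
                    np.arange(grid["start"], grid["stop"] + grid["step"] / 2, grid["step"]), 6
                )
            )
        elif grid is not None:
            grid = tuple(float(g) for g in grid)
        else:
            grid = DEFAULT_THRESHOLD_GRID
        kwargs = dict(
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir", "mibrain_out"),
            input_kind=inp.get("kind", "simulation"),
            input_directory=inp.get("directory"),
            duration_s=float(sim.get("duration_s", 60.0)),
            sampling_rate=float(sim.get("sampling_rate", 250.0)),
            n_subjects=int(sim.get("n_subjects", 3)),
            noise_sd=float(sim.get("noise_sd", 1.0)),
            low_hz=float(pre.get("low_hz", 0.1)),
            high_hz=float(pre.get("high_hz", 100.0)),
            reference=pre.get("reference", "average"),
            epoch_seconds=float(pre.get("epoch_seconds", 5.0)),
            n_bins=int(ana.get("n_bins", 11)),
            threshold_grid=grid,
            alpha=float(ana.get("alpha", 0.05)),
        )
        if pre.get("reference_pair"):
            kwargs["reference_pair"] = tuple(pre["reference_pair"])
        if pre.get("amplitude_threshold") is not None:
            kwargs["amplitude_threshold"] = float(pre["amplitude_threshold"])
        if "groups" in sim:
            kwargs["group_strengths"] = {
                g: {k: float(v) for k, v in d.items()} for g, d in sim["groups"].items()
            }
        return cls(**kwargs)

    def scenarios(self) -> List[CohortScenario]:
        out = []
        for i, (group, strengths) in enumerate(self.group_strengths.items()):
            out.append(
                CohortScenario(
                    group_label=group,
                    n_subjects=self.n_subjects,
                    interhemispheric_strength=strengths.get("interhemispheric", 0.0),
                    fronto_parietal_strength=strengths.get("fronto_parietal", 0.0),
                    intrahemispheric_strength=strengths.get("intrahemispheric", 0.3),
                    noise_sd=self.noise_sd,
                    seed=self.seed * 4 + i,
                )
            )
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["output_dir"] = str(d["output_dir"])
    if d["input_directory"] is not None:
        d["input_directory"] = str(d["input_directory"])
    d["threshold_grid"] = [float(f) for f in d["threshold_grid"]]
    return d


def load_input_recordings(
    config: RunConfig, failure_log: Optional[list] = None
) -> List[Tuple[str, str, EEGRecording]]:
    """Return (group, subject_id, recording) triples from simulation or disk.

    For directory input, files are named ``<group>_<subject>.<ext>`` and are
    reordered to the canonical 16-channel montage when all its labels are
    present. Unreadable files are logged and skipped; pass ``failure_log`` (a
    list) to collect ``(path, error)`` entries for them.
    """
    triples = []
    if config.input_kind == "simulation":
        counter: Dict[str, int] = {}
        for group, rec in simulate_cohort(
            config.scenarios(),
            duration_s=config.duration_s,
            sampling_rate=config.sampling_rate,
        ):
            counter[group] = counter.get(group, 0) + 1
            triples.append((group, f"{group}_{counter[group]:02d}", rec))
        return triples

    suffix = ".edf" if config.input_kind == "edf_dir" else None
    paths = sorted(
        p for p in config.input_directory.iterdir()
        if p.is_file() and (suffix is None or p.suffix.lower() == suffix)
        and p.suffix.lower() in (".edf", ".txt", ".tsv", ".csv")
    )
    if not paths:
        raise ValueError(f"no recordings found in {config.input_directory}")
    failures = []
    for path in paths:
        group = path.stem.split("_")[0]
        try:
            rec = read_recording(path)
        except Exception as exc:  # per-file failure: log, skip, report
            logger.error("skipping %s: %s", path, exc)
            failures.append((str(path), str(exc)))
            continue
        if set(MONTAGE_16) <= set(rec.channel_labels):
            order = [rec.channel_labels.index(l) for l in MONTAGE_16]
            rec = EEGRecording(
                data=rec.data[order],
                sampling_rate=rec.sampling_rate,
                channel_labels=MONTAGE_16,
                reference=rec.reference,
            )
        triples.append((group, path.stem, rec))
    if failure_log is not None:
        failure_log.extend(failures)
    return triples


def analyse_recordings(
    triples: List[Tuple[str, str, EEGRecording]], config: RunConfig
) -> Tuple[Dict[str, MIMatrix], pd.DataFrame, Dict[str, int]]:
    """Preprocess, estimate MI, and sweep thresholds for every subject.

    Returns the per-subject MI matrices, the tidy long-format metric table
    (subject, group, threshold, metric, value), and per-subject retained epoch
    counts.
    """
    spec = HistogramSpec(n_bins=config.n_bins)
    hemi = HemisphereMap()
    mi_by_subject: Dict[str, MIMatrix] = {}
    epoch_counts: Dict[str, int] = {}
    rows = []
    for group, subject, rec in triples:
        epoched = preprocess(
            rec,
            low_hz=config.low_hz,
            high_hz=config.high_hz,
            reference_scheme=config.reference,
            reference_pair=config.reference_pair,
            epoch_duration_s=config.epoch_seconds,
            amplitude_threshold=config.amplitude_threshold,
        )
        mi = mi_matrix(epoched, spec)
        mi_by_subject[subject] = mi
        epoch_counts[subject] = epoched.n_epochs
        for record in threshold_sweep(mi, config.threshold_grid, hemi):
            for metric, value in (
                ("interhemispheric_edges", record["interhemispheric_edges"]),
                ("mean_clustering", record["mean_clustering"]),
            ):
                rows.append(
                    {
                        "subject": subject,
                        "group": group,
                        "threshold": record["fraction"],
                        "metric": metric,
                        "value": float(value),
                    }
                )
    return mi_by_subject, pd.DataFrame(rows), epoch_counts


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all outputs under
    ``config.output_dir``; returns that directory.

    Outputs: per-subject MI matrices (TSV + JSON sidecar), the tidy metric
    table, one comparison table per metric (TSV + JSON), and ``manifest.json``
    with the config echo, version, epoch counts and output checksums.
    """
    from .stats import compare_across_thresholds

    started = time.time()
    failures: List[Tuple[str, str]] = []
    triples = load_input_recordings(config, failure_log=failures)
    if not triples:
        raise ValueError("empty cohort")
    out = config.output_dir
    (out / "mi").mkdir(parents=True, exist_ok=True)

    mi_by_subject, metric_table, epoch_counts = analyse_recordings(triples, config)
    groups_present = sorted({g for g, _, _ in triples})

    written: List[Path] = []
    group_of = {s: g for g, s, _ in triples}
    for subject, mi in mi_by_subject.items():
        p = write_mi_matrix(
            mi,
            out / "mi" / f"{subject}.tsv",
            sidecar={
                "subject": subject,
                "group": group_of[subject],
                "n_bins": config.n_bins,
                "reference": config.reference,
            },
        )
        written += [p, p.with_suffix(p.suffix + ".json")]

    metric_path = out / "metrics.tsv"
    metric_table.to_csv(metric_path, sep="\t", index=False, float_format="%.10g")
    written.append(metric_path)

    for metric in ("interhemispheric_edges", "mean_clustering"):
        try:
            comparison = compare_across_thresholds(
                metric_table, metric, alpha=config.alpha, group_order=tuple(groups_present)
            )
        except ValueError as exc:
            logger.warning("skipping comparison for %s: %s", metric, exc)
            continue
        cpath = out / f"comparison_{metric}.tsv"
        comparison.table.to_csv(cpath, sep="\t", index=False, float_format="%.10g")
        jpath = out / f"comparison_{metric}.json"
        jpath.write_text(comparison.table.to_json(orient="records", indent=2))
        written += [cpath, jpath]

    manifest = {
        "version": __version__,
        "config": _config_dict(config),
        "epoch_counts": epoch_counts,
        "groups": groups_present,
        "n_subjects": len(triples),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
        "skipped_inputs": [{"path": p, "error": e} for p, e in failures],
        "elapsed_s": round(time.time() - started, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d subjects, outputs in %s", len(triples), out)
    return out
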