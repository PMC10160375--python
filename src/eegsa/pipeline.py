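"""End-to-end orchestration: synth -> spectral -> corr -> rf_select ->
pca_comb -> cnn -> eval, from a single seeded config.

Every stage seed derives deterministically from the master seed, each
intermediate artifact is written to the output directory as plain text
(CSV/JSON), and a manifest records the config echo and seed chain so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corr, pca_comb, rf_select, spectral, synth
from .cnn import CNNConfig, PCAFusedCNN
from .evaluation import evaluate_predictions
from .recording import RawRecording, read_csv


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``synth_spec`` / ``data_paths`` provides the input
    recordings.  ``data_paths`` maps group label -> list of recording CSV
    paths for real (or externally generated) data.
    """

    synth_spec: synth.SynthSpec | None = None
    data_paths: dict[str, list[str]] | None = None
    n_high: int = 13
    n_low: int = 12
    window_s: float = 5.0
    overlap: float = 0.5
    threshold_uv: float = 200.0
    notch_hz: float = 50.0
    n_perm: int = 10_000
    alpha_lenient: float = 0.1
    regions_for_selection: tuple[str, ...] = ("F", "C")
    rf_grid: tuple[tuple[int, ...], tuple[int, ...]] | None = (
        (5, 10, 15, 20, 30, 50),
        (2, 4, 6, 8, 10, 15, 20),
    )
    forest_spec: rf_select.ForestSpec = field(
        default_factory=lambda: rf_select.ForestSpec(11, 10)
    )
    pca_threshold: float = 0.877
    pca_k: int | None = None
    cnn: CNNConfig = field(default_factory=CNNConfig)
    stack: int = 20
    stack_stride: int | None = 5
    split: str = "epoch"
    seed: int = 0
    outdir: str | Path = "eegsa_run"

    def validate(self) -> None:
        if (self.synth_spec is None) == (self.data_paths is None):
            raise ValueError("set exactly one of synth_spec / data_paths")
        if self.split not in ("epoch", "subject"):
            raise ValueError("split must be 'epoch' or 'subject'")


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: pd.DataFrame
    comparisons: pd.DataFrame
    selected: list[str]
    trace: rf_select.EliminationTrace
    basis: pca_comb.PCABasis
    k: int
    weights: np.ndarray
    report: "object"
    manifest: dict


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and persist all artifacts.

    Aborts with the failing stage's name; artifacts written before the
    failure remain on disk.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "synth"
    try:
        seed = _stage_seed(config.seed, stage)
        manifest["stages"][stage] = {"seed": seed}
        if config.synth_spec is not None:
            recs = synth.generate_cohort(
                config.synth_spec, config.n_high, config.n_low, seed=seed
            )
        else:
            recs = _load_recordings(config.data_paths)

        stage = "features"
        regions = tuple(r for r in ("F", "C", "P", "O") if recs[0].region_channels(r))
        tables = []
        for rec in recs:
            clean = spectral.remove_line_noise(rec, f0=config.notch_hz)
            mask = spectral.flag_artifacts(
                clean, threshold=config.threshold_uv, epoch_s=config.window_s
            )
            tables.append(
                spectral.extract_features(
                    clean,
                    window_s=config.window_s,
                    overlap=config.overlap,
                    metrics=spectral.METRICS,
                    regions=regions,
                    mask=mask,
                )
            )
        features = pd.concat(tables, ignore_index=True)
        features.to_csv(out / "features.csv", index=False)
        manifest["stages"][stage] = {"n_rows": len(features), "regions": list(regions)}

        stage = "correlate"
        seed = _stage_seed(config.seed, stage)
        subj = corr.subject_means(features)
        comparisons = corr.evaluate_correlations(
            subj, regions=regions, n_perm=config.n_perm, seed=seed
        )
        comparisons.to_csv(out / "correlations.csv", index=False)
        manifest["stages"][stage] = {"seed": seed, "n_perm": config.n_perm}

        stage = "select"
        selected = corr.select_features(
            comparisons,
            alpha_lenient=config.alpha_lenient,
            regions_for_selection=config.regions_for_selection,
        )
        (out / "selected_features.json").write_text(json.dumps(selected, indent=2))
        manifest["stages"][stage] = {"n_selected": len(selected)}
        if len(selected) < 2:
            raise ValueError("correlation screening selected fewer than 2 features")
        missing = [c for c in selected if c not in features.columns]
        if missing:
            raise ValueError(f"selected features missing from table: {missing}")
        X = features[selected]
        y = (features["group"].to_numpy() == "low").astype(int)

        stage = "rf"
        seed = _stage_seed(config.seed, stage)
        if config.rf_grid is not None:
            spec, surface = rf_select.rf_grid_search(
                X, y, n_estimators_grid=config.rf_grid[0],
                max_depth_grid=config.rf_grid[1], seed=seed,
            )
            surface.to_csv(out / "rf_grid.csv", index=False)
        else:
            spec = rf_select.ForestSpec(
                config.forest_spec.n_estimators, config.forest_spec.max_depth, seed
            )
        trace = rf_select.backward_eliminate(X, y, spec, seed=seed)
        trace.importance_initial.rename("score").to_csv(out / "importance.csv")
        trace.trace.to_csv(out / "elimination_trace.csv", index=False)
        manifest["stages"][stage] = {
            "seed": seed,
            "n_estimators": spec.n_estimators,
            "max_depth": spec.max_depth,
            "retained": trace.best_features,
        }

        stage = "pca"
        basis = pca_comb.fit_pca(features[trace.best_features])
        k = config.pca_k or pca_comb.select_k(basis, threshold=config.pca_threshold)
        weights = pca_comb.composite_weights(basis, k)
        pd.DataFrame(
            {
                "component": [f"F{i + 1}" for i in range(basis.z)],
                "eigenvalue": basis.eigenvalues,
                "contribution_pct": basis.contributions,
                "cumulative_pct": basis.cumulative,
            }
        ).to_csv(out / "pca_components.csv", index=False)
        (out / "composite_weights.json").write_text(
            json.dumps({"k": k, "weights": weights.tolist()}, indent=2)
        )
        manifest["stages"][stage] = {"k": k}

        stage = "cnn"
        seed = _stage_seed(config.seed, stage)
        scores = basis.transform(features[trace.best_features], k=k)
        maps, labels, subj_map = pca_comb.build_cnn_inputs(
            scores,
            features["subject_id"].to_numpy(),
            features["group"].to_numpy(),
            shape=config.cnn.input_shape,
            stack=config.stack,
            stride=config.stack_stride,
        )
        cfg = CNNConfig(**{**config.cnn.__dict__, "seed": seed})
        rng = np.random.default_rng(seed + 13)
        from .evaluation import _epoch_split, _subject_split

        if config.split == "subject":
            test_mask = _subject_split(subj_map, labels, 0.25, rng)
        else:
            test_mask = _epoch_split(labels, 0.25, rng)
        result = PCAFusedCNN(cfg).train(maps, labels, test_mask=test_mask)
        result.history.to_csv(out / "training_curves.csv", index=False)
        manifest["stages"][stage] = {
            "seed": seed,
            "n_samples": len(labels),
            "n_test": int(test_mask.sum()),
        }

        stage = "eval"
        pred, score = result.model.predict(maps[test_mask])
        report = evaluate_predictions(labels[test_mask], pred, score)
        (out / "report.json").write_text(
            json.dumps({"counts": report.counts, **report.as_row()}, indent=2)
        )
        pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr}).to_csv(
            out / "roc.csv", index=False
        )
        manifest["stages"][stage] = {"auc": report.auc}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(_config_echo(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest["config"] = _config_echo(config)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(
        config=config,
        features=features,
        comparisons=comparisons,
        selected=selected,
        trace=trace,
        basis=basis,
        k=k,
        weights=weights,
        report=report,
        manifest=manifest,
    )


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    echo["outdir"] = str(echo["outdir"])
    return echo


def _load_recordings(data_paths: dict[str, list[str]]) -> list[RawRecording]:
    recs = []
    for group, paths in data_paths.items():
        for p in paths:
            recs.append(read_csv(p, group=group))
    if not recs:
        raise ValueError("data_paths contain no recordings")
    return recs


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file.

    Recognized top-level keys mirror the dataclass fields; ``synth``
    accepts either ``default: true`` (with optional overrides) or a full
    generator spec mapping; ``cnn`` and ``forest`` accept their dataclass
    fields.
    """
    payload = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "synth" in payload:
        s = payload.pop("synth")
        if s.get("default", False):
            over = {k: v for k, v in s.items() if k != "default"}
            kwargs["synth_spec"] = synth.default_spec(**over)
        else:
            kwargs["synth_spec"] = synth.SynthSpec(**s)
    if "data_paths" in payload:
        kwargs["data_paths"] = payload.pop("data_paths")
    if "forest" in payload:
        kwargs["forest_spec"] = rf_select.ForestSpec(**payload.pop("forest"))
    if "cnn" in payload:
        c = payload.pop("cnn")
        if "input_shape" in c:
            c["input_shape"] = tuple(c["input_shape"])
        if "n_filters" in c:
            c["n_filters"] = tuple(c["n_filters"])
        kwargs["cnn"] = CNNConfig(**c)
    if "rf_grid" in payload:
        g = payload.pop("rf_grid")
        kwargs["rf_grid"] = None if g is None else (tuple(g[0]), tuple(g[1]))
    if "regions_for_selection" in payload:
        payload["regions_for_selection"] = tuple(payload["regions_for_selection"])
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}", stacklevel=2)
    kwargs.update({k: v for k, v in payload.items() if k in known})
    return PipelineConfig(**kwargs)
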