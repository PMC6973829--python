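"""Named end-to-end experiments over the synthetic study.

Each experiment is a pure function of (generator config, experiment
config, seeds): it streams blocks from the generator, epochs them,
computes features, and evaluates classifiers, returning tidy pandas
frames.  Passing an output directory additionally writes the frames as
CSV plus a JSON manifest sufficient to re-run the experiment
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import epochs as ep
from . import features as ft
from .evaluate import (ClassifierSpec, band_ttests, cross_condition,
                       crossvalidate, empirical_chance, fuse_scores,
                       subsample_balance)
from .reduce_select import CV_GRID, K_GRID, FRatioSelector, PCAByInnerCV
from .synth import (CONDITIONS, STIMULI, GenConfig, condition_stimulus,
                    generate_dataset, generate_layout, region_group)

__all__ = ["ExperimentConfig", "collect_features", "run_single_trial",
           "run_duration_sweep", "run_segment_sweep", "run_fusion",
           "run_temporal_evolution", "run_source_selection",
           "run_band_ttests", "run_cross_conditional", "run_all"]

DURATION_GRID = (600, 900, 1200, 1500, 1800)        # ms
SEGMENT_GRID = (100, 200, 300, 400, 500, 600)       # ms, at T = 1200


@dataclass
class ExperimentConfig:
    """Shared knobs for all experiment runners."""
    gen: GenConfig = field(default_factory=GenConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    T_ms: float = 1200.0
    L: int = 4
    seed: int = 0
    cv_folds: int = 10
    pca_grid: tuple = CV_GRID
    k_grid: tuple = K_GRID
    n_subsample_repeats: int = 5
    out_dir: str | None = None

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=lambda o: list(o) if hasattr(o, "__iter__") else str(o)))


def _write(cfg: ExperimentConfig, name: str, frames: dict[str, pd.DataFrame]) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, df in frames.items():
        df.to_csv(out / f"{name}_{key}.csv", index=False)
    (out / f"{name}_manifest.json").write_text(
        json.dumps({"experiment": name, "config": cfg.manifest()}, indent=2))


def collect_features(cfg: ExperimentConfig, scope: str = "local-10",
                     T_ms: float | None = None, L: int | None = None,
                     offsets=(0.0,), rejection_horizon_ms: float | None = None,
                     space: str = "sensor", bands=None, kind: str = "wavelet"):
    """Stream the dataset once and return stacked features.

    Blocks are generated, epoched and converted to features one at a
    time so that a full-size dataset never resides in memory.  Returns
    ``(X, y, index, meta)`` where meta rows are (condition, subject,
    label, offset_ms).
    """
    T = cfg.T_ms if T_ms is None else T_ms
    L = cfg.L if L is None else L
    if bands is None:
        bands = ft.ALL_BANDS if space == "source" else ft.SENSOR_BANDS
    layout = None
    clusters = None
    if space == "sensor":
        layout = generate_layout(cfg.gen.n_sensors, cfg.gen.n_motor_excluded,
                                 seed=cfg.gen.seed)
        layout = layout.with_clusters(ft.ward_cluster_sensors(layout, 10))
    spec = ft.WaveletSpec(fs=cfg.gen.fs)
    scope_eff = "source-89" if space == "source" else scope
    X_rows, y_rows, meta = [], [], []
    index = None
    for block in generate_dataset(cfg.gen, space=space, layout=layout):
        for off in offsets:
            eset = ep.extract_epochs(block, T, maintenance_offset_ms=off,
                                     rejection_horizon_ms=rejection_horizon_ms)
            # at nonzero offsets only the shifted maintenance epochs are new
            use = [e for e in eset
                   if off == offsets[0] or e.label == ep.MAINTENANCE]
            for e in use:
                if kind == "psd":
                    fv = ft.psd_features(e, layout, bands=bands)
                else:
                    region_labels = getattr(block, "region_labels", None)
                    fv = ft.extract_features(e, layout, scope_eff, bands, L,
                                             spec, region_labels=region_labels)
                X_rows.append(fv.values)
                y_rows.append(1 if e.label == ep.TRANSITION else 0)
                meta.append((e.condition, e.subject_id, e.label, e.offset))
                index = fv.index
    X = np.asarray(X_rows) if X_rows else np.empty((0, 0))
    return X, np.asarray(y_rows, dtype=int), index, meta


def _result_row(condition: str, res, extra: dict | None = None) -> dict:
    row = {"condition": condition, "n": res.n, "accuracy": res.accuracy,
           "accuracy_sd": res.accuracy_sd, "sensitivity": res.sensitivity,
           "specificity": res.specificity, "chance": res.chance,
           "above_chance": res.above_chance}
    if extra:
        row.update(extra)
    return row


def run_single_trial(cfg: ExperimentConfig, scopes=("global", "left-hemi",
                                                    "right-hemi", "local-10"),
                     include_psd: bool = True,
                     conditions=("ACT",) + CONDITIONS) -> pd.DataFrame:
    """Per-condition and pooled (ACT) cross-validated decoding.

    Local features go through PCA with inner-CV cumulative variance;
    the smaller global/hemispheric vectors are used as-is.  Optionally
    adds the Welch-PSD baseline at the local scope.
    """
    rows = []
    jobs = [(s, "wavelet") for s in scopes]
    if include_psd:
        jobs.append(("local-10", "psd"))
    for scope, kind in jobs:
        X, y, index, meta = collect_features(cfg, scope=scope, kind=kind)
        conds = np.array([m[0] for m in meta])
        for cond in conditions:
            sel = slice(None) if cond == "ACT" else conds == cond
            Xs, ys = X[sel], y[sel]
            if len(np.unique(ys)) < 2 or np.bincount(ys).min() < 2:
                continue
            reducer = (PCAByInnerCV(cfg.pca_grid, cfg.classifier, seed=cfg.seed)
                       if scope == "local-10" and kind == "wavelet" else None)
            res = crossvalidate(Xs, ys, cfg.classifier, k=cfg.cv_folds,
                                seed=cfg.seed, reducer=reducer)
            rows.append(_result_row(cond, res,
                                    {"scope": scope, "feature": kind,
                                     "dim": X.shape[1]}))
    df = pd.DataFrame(rows)
    _write(cfg, "single_trial", {"metrics": df})
    return df


def run_duration_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Decoding vs transition-state duration T in 600..1800 ms steps of 300.

    Global 4-band features with fixed 300 ms segments; the feature
    dimension per row is 4 * (T / 300).
    """
    seg_ms = 300
    rows = []
    for T in DURATION_GRID:
        if T % seg_ms:
            raise ValueError(f"T = {T} ms not divisible by {seg_ms} ms segments")
        L = T // seg_ms
        X, y, index, meta = collect_features(cfg, scope="global", T_ms=float(T), L=L)
        res = crossvalidate(X, y, cfg.classifier, k=cfg.cv_folds, seed=cfg.seed)
        rows.append(_result_row("ACT", res, {"T_ms": T, "L": L, "dim": X.shape[1]}))
    df = pd.DataFrame(rows)
    _write(cfg, "duration_sweep", {"metrics": df})
    return df


def run_segment_sweep(cfg: ExperimentConfig, T_ms: float = 1200.0) -> pd.DataFrame:
    """Decoding vs segment length l in 100..600 ms at fixed T = 1200 ms."""
    import logging
    log = logging.getLogger(__name__)
    rows = []
    for l in SEGMENT_GRID:
        if T_ms % l:
            log.warning("segment length %d ms does not divide T = %.0f ms; skipped",
                        l, T_ms)
            continue
        L = int(T_ms // l)
        X, y, index, meta = collect_features(cfg, scope="global", T_ms=T_ms, L=L)
        res = crossvalidate(X, y, cfg.classifier, k=cfg.cv_folds, seed=cfg.seed)
        rows.append(_result_row("ACT", res, {"l_ms": l, "L": L, "dim": X.shape[1]}))
    df = pd.DataFrame(rows)
    _write(cfg, "segment_sweep", {"metrics": df})
    return df


def run_fusion(cfg: ExperimentConfig) -> pd.DataFrame:
    """Accuracy-vs-p profile for fused left/right hemispheric scores.

    Left and right hemispheric models are cross-validated on identical
    folds; their out-of-fold continuous scores are combined as
    S_f = p S_l + (1-p) S_r over p = 0..1 (step 0.1).
    """
    Xl, y, _, _ = collect_features(cfg, scope="left-hemi")
    Xr, y2, _, _ = collect_features(cfg, scope="right-hemi")
    assert np.array_equal(y, y2)
    res_l = crossvalidate(Xl, y, cfg.classifier, k=cfg.cv_folds, seed=cfg.seed)
    res_r = crossvalidate(Xr, y, cfg.classifier, k=cfg.cv_folds, seed=cfg.seed)
    profile = fuse_scores(res_l.scores, res_r.scores, y)
    profile["left_accuracy"] = res_l.accuracy
    profile["right_accuracy"] = res_r.accuracy
    _write(cfg, "fusion", {"profile": profile})
    return profile


def run_temporal_evolution(cfg: ExperimentConfig, step_ms: float = 100.0,
                           horizon_ms: float = 1800.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maintenance subwindows shifted toward the next switch.

    A 1200 ms maintenance window slides from the press out to 1800 ms in
    100 ms steps (seven offsets), so maintenance rows outnumber
    transition rows sevenfold; random majority subsampling rebalances
    before classification.  Returns (pooled metrics, per-offset
    detection profile).
    """
    offsets = ep.maintenance_subwindows(cfg.T_ms, step_ms, horizon_ms)
    X, y, index, meta = collect_features(cfg, scope="local-10", offsets=offsets,
                                         rejection_horizon_ms=horizon_ms)
    groups = np.array([m[3] if m[2] == ep.MAINTENANCE else -1.0 for m in meta])
    reducer = PCAByInnerCV(cfg.pca_grid, cfg.classifier, seed=cfg.seed)
    res, profile = subsample_balance(X, y, cfg.classifier,
                                     n_repeats=cfg.n_subsample_repeats,
                                     seed=cfg.seed, k=cfg.cv_folds,
                                     reducer=reducer, groups=groups)
    metrics = pd.DataFrame([_result_row("ACT", res, {"n_offsets": len(offsets)})])
    profile = profile.rename(columns={"group": "offset_ms"})
    _write(cfg, "temporal_evolution", {"metrics": metrics, "profile": profile})
    return metrics, profile


def run_source_selection(cfg: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Source-space decoding with F-ratio selection and selection reports.

    Features: 89 regions x 6 bands x L segments.  Per outer fold the
    selector picks k by inner CV and records which bands/regions the
    selected features came from; distributions are averaged over folds.
    Returns (metrics, tidy selection distribution).
    """
    X, y, index, meta = collect_features(cfg, space="source")
    reducer = FRatioSelector(k_grid=cfg.k_grid, classifier=cfg.classifier,
                             seed=cfg.seed, index=index)
    res = crossvalidate(X, y, cfg.classifier, k=cfg.cv_folds, seed=cfg.seed,
                        reducer=reducer)
    band_rows: dict[str, list] = {}
    region_rows: dict[str, list] = {}
    for d in res.reducer_detail:
        for b, v in d["band_distribution"].items():
            band_rows.setdefault(b, []).append(v)
        for r, v in d["region_distribution"].items():
            region_rows.setdefault(r, []).append(v)
    dist = pd.concat([
        pd.DataFrame({"kind": "band", "name": list(band_rows),
                      "share": [np.mean(v) for v in band_rows.values()]}),
        pd.DataFrame({"kind": "region", "name": list(region_rows),
                      "share": [np.mean(v) for v in region_rows.values()],
                      "group": [region_group(r) for r in region_rows]}),
    ], ignore_index=True)
    metrics = pd.DataFrame([_result_row("ACT", res, {"dim": X.shape[1]})])
    _write(cfg, "source_selection", {"metrics": metrics, "selection": dist})
    return metrics, dist


def run_band_ttests(cfg: ExperimentConfig, T_ms: float | None = None) -> pd.DataFrame:
    """Paired transition-vs-maintenance t-tests of whole-epoch band power."""
    T = cfg.T_ms if T_ms is None else T_ms
    X, y, index, meta = collect_features(cfg, scope="global",
                                         bands=ft.ALL_BANDS, L=1, T_ms=T)
    trans = X[y == 1]
    maint = X[y == 0]
    df = band_ttests(trans, maint, ft.ALL_BANDS)
    _write(cfg, "band_ttests", {"ttests": df})
    return df


def run_cross_conditional(cfg: ExperimentConfig, scope: str = "local-10") -> pd.DataFrame:
    """Train on one stimulus factor, test on the others (3 x 3 design)."""
    X, y, index, meta = collect_features(cfg, scope=scope)
    stim = np.array([condition_stimulus(m[0]) for m in meta])
    by_stim = {s: (X[stim == s], y[stim == s]) for s in STIMULI}
    reducer = (PCAByInnerCV(cfg.pca_grid, cfg.classifier, seed=cfg.seed)
               if scope == "local-10" else None)
    df = cross_condition(by_stim, cfg.classifier, reducer=reducer, seed=cfg.seed)
    _write(cfg, "cross_conditional", {"matrix": df})
    return df


def run_all(cfg: ExperimentConfig) -> dict[str, object]:
    """Run every experiment on one synthetic dataset; write a report.

    Any sub-failure aborts with the failing stage named.
    """
    results: dict[str, object] = {}
    stages = [
        ("band_ttests", lambda: run_band_ttests(cfg)),
        ("single_trial", lambda: run_single_trial(cfg)),
        ("duration_sweep", lambda: run_duration_sweep(cfg)),
        ("segment_sweep", lambda: run_segment_sweep(cfg)),
        ("fusion", lambda: run_fusion(cfg)),
        ("temporal_evolution", lambda: run_temporal_evolution(cfg)),
        ("source_selection", lambda: run_source_selection(cfg)),
        ("cross_conditional", lambda: run_cross_conditional(cfg)),
    ]
    for name, fn in stages:
        try:
            results[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"experiment stage {name!r} failed: {exc}") from exc
    if cfg.out_dir is not None:
        lines = ["# Synthetic decoding report", ""]
        for name, res in results.items():
            lines.append(f"## {name}")
            frames = res if isinstance(res, tuple) else (res,)
            for fr in frames:
                lines.append(fr.to_markdown(index=False) if hasattr(fr, "to_markdown")
                             else str(fr))
                lines.append("")
        Path(cfg.out_dir, "report.md").write_text("\n".join(lines))
    return results
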