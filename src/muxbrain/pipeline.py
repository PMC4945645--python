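"""Configuration-driven orchestration of the full analysis.

Stages, in order: synthetic cohort (or cohort manifest) -> per-band layers
via surrogate-thresholded coherence -> multiplex assembly -> per-layer
structural descriptors -> layer reducibility and group SNR -> multiplex
PageRank centrality profiles -> random-forest discrimination with hub
identification.  Every stage writes its artifacts to the output directory
and the run ends with a machine-readable summary (versions, seeds, timings).
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .centrality import DEFAULT_D, multiplex_pagerank
from .classify import (
    RF_DEFAULTS,
    identify_hubs,
    jaccard_index,
    loo_feature_ranking,
    profiles_to_matrix,
    scan_hyperparameters,
    topk_classification,
)
from .connectivity import build_layers, make_band_scheme
from .descriptors import describe_layer
from .io import (
    descriptor_table,
    profile_table,
    write_layers,
    write_reducibility,
    write_report,
)
from .multiplex import assemble_multiplex
from .reducibility import group_snr, reduce_layers
from .synth import SyntheticConfig, generate_cohort, read_cohort, write_cohort

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "connect",
    "descriptors",
    "reduce",
    "centrality",
    "classify",
    "summary",
)

_KNOWN_KEYS = {
    "input_manifest",
    "synthetic",
    "band_scheme",
    "n_surrogates",
    "z_threshold",
    "D",
    "D_grid",
    "k_grid",
    "rf_params",
    "top_k",
    "hub_fraction",
    "output_dir",
    "seed",
    "log_level",
    "n_repeats",
}


@dataclass
class PipelineConfig:
    """Validated run configuration; unknown keys are rejected at load time."""

    output_dir: str
    input_manifest: str | None = None
    synthetic: dict | None = None
    band_scheme: tuple[float, float, float] = (0.01, 0.25, 0.02)
    n_surrogates: int = 100
    z_threshold: float = 3.0
    D: float = DEFAULT_D
    D_grid: list[float] | None = None
    k_grid: list[int] | None = None
    rf_params: dict = field(default_factory=lambda: dict(RF_DEFAULTS))
    top_k: int = 10
    hub_fraction: float = 0.05
    seed: int = 0
    n_repeats: int = 1
    log_level: str = "INFO"


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and fully validate a YAML config, collecting all errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    errors = []
    for key in raw:
        if key not in _KNOWN_KEYS:
            errors.append(f"unknown key: {key!r}")
    if "output_dir" not in raw:
        errors.append("missing required key: 'output_dir'")
    if raw.get("D") is not None and raw["D"] < 0:
        errors.append("field 'D': inter-layer weight must be non-negative")
    if raw.get("z_threshold") is not None and raw["z_threshold"] <= 0:
        errors.append("field 'z_threshold': must be positive")
    if raw.get("n_surrogates") is not None and raw["n_surrogates"] < 20:
        errors.append("field 'n_surrogates': need at least 20")
    if raw.get("hub_fraction") is not None and not 0 < raw["hub_fraction"] < 1:
        errors.append("field 'hub_fraction': must be in (0, 1)")
    band = raw.get("band_scheme")
    if band is not None:
        try:
            make_band_scheme(*band)
        except (TypeError, ValueError) as exc:
            errors.append(f"field 'band_scheme': {exc}")
    if raw.get("input_manifest") is None and raw.get("synthetic") is None:
        errors.append("either 'input_manifest' or 'synthetic' must be given")
    synth = raw.get("synthetic")
    if synth is not None:
        try:
            _synthetic_config(synth, raw.get("seed", 0))
        except (TypeError, ValueError) as exc:
            errors.append(f"field 'synthetic': {exc}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    known = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    if "band_scheme" in known:
        known["band_scheme"] = tuple(known["band_scheme"])
    return PipelineConfig(**known)


def _synthetic_config(synth: dict, seed: int) -> SyntheticConfig:
    synth = dict(synth)
    effects = {
        int(g): [(int(b), set(nodes), float(s)) for b, nodes, s in eff]
        for g, eff in synth.pop("group_effects", {}).items()
    }
    hubs = {int(g): set(h) for g, h in synth.pop("hub_nodes_per_group", {}).items()}
    synth.setdefault("seed", seed)
    return SyntheticConfig(group_effects=effects, hub_nodes_per_group=hubs, **synth)


def run_pipeline(cfg: PipelineConfig, last_stage: str = "classify") -> dict:
    """Execute the stages up to ``last_stage`` (inclusive), write artifacts
    under ``cfg.output_dir``, return the run summary (also written as
    ``summary.json``)."""
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}")
    stop_after = STAGES.index(last_stage)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    summary: dict = {
        "muxbrain_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stages": {},
    }

    def _stage(name):
        t0 = time.perf_counter()
        summary["stages"][name] = {"status": "running"}
        return t0

    def _done(name, t0, **info):
        summary["stages"][name] = {
            "status": "completed",
            "seconds": round(time.perf_counter() - t0, 3),
            **info,
        }

    def _finalize() -> dict:
        summary["config"] = asdict(cfg)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        return summary

    # --- simulate / load -------------------------------------------------
    t0 = _stage("simulate")
    try:
        if cfg.input_manifest:
            cohort = read_cohort(Path(cfg.input_manifest).parent)
        else:
            cohort = generate_cohort(_synthetic_config(cfg.synthetic, cfg.seed))
            write_cohort(cohort, out / "cohort")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    _done("simulate", t0, n_subjects=len(cohort.subjects))
    if stop_after <= STAGES.index("simulate"):
        return _finalize()

    scheme = make_band_scheme(*cfg.band_scheme)

    # --- connect ----------------------------------------------------------
    t0 = _stage("connect")
    subject_layers = []
    edge_counts = []
    for s, ts in enumerate(cohort.subjects):
        try:
            layers, _ = build_layers(
                ts, scheme, n_surrogates=cfg.n_surrogates,
                z_threshold=cfg.z_threshold, seed=int(rng.integers(2**31)),
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'connect' failed for subject {s}: {exc}") from exc
        subject_layers.append(layers)
        edge_counts.append([l.n_edges for l in layers])
        write_layers(layers, out / "layers" / f"subject_{s:03d}")
    _done("connect", t0, edge_counts=edge_counts)
    if stop_after <= STAGES.index("connect"):
        return _finalize()

    # --- descriptors ------------------------------------------------------
    t0 = _stage("descriptors")
    rows = []
    for s, layers in enumerate(subject_layers):
        for k, layer in enumerate(layers):
            if layer.n_edges == 0:
                continue
            rows.append((f"subject_{s:03d}", k,
                         describe_layer(layer, seed=int(rng.integers(2**31)))))
    descriptor_table(rows).to_csv(out / "descriptors.csv", index=False)
    _done("descriptors", t0, n_rows=len(rows))
    if stop_after <= STAGES.index("descriptors"):
        return _finalize()

    # --- reduce -----------------------------------------------------------
    t0 = _stage("reduce")
    distances = []
    dist_labels = []
    optimal_steps = []
    skipped = []
    for s, layers in enumerate(subject_layers):
        if any(l.n_edges == 0 for l in layers):
            skipped.append(s)  # empty layer: Laplacian rescaling undefined
            continue
        try:
            res = reduce_layers(layers)
        except Exception as exc:
            raise RuntimeError(f"stage 'reduce' failed for subject {s}: {exc}") from exc
        distances.append(res.distance_matrix)
        dist_labels.append(cohort.labels[s])
        optimal_steps.append(res.optimal_step)
        write_reducibility(res, out / "reducibility" / f"subject_{s:03d}")
    snr_available = len(set(dist_labels)) == 2 and all(
        dist_labels.count(g) >= 2 for g in set(dist_labels))
    if snr_available:
        snr = group_snr(distances, dist_labels)
        np.savetxt(out / "snr_relative_difference.csv", snr.relative_difference,
                   delimiter=",")
    _done("reduce", t0, optimal_steps=optimal_steps, skipped_subjects=skipped,
          snr_computed=snr_available)
    if stop_after <= STAGES.index("reduce"):
        return _finalize()

    # --- centrality -------------------------------------------------------
    t0 = _stage("centrality")
    profiles = [
        multiplex_pagerank(assemble_multiplex(layers, cfg.D))
        for layers in subject_layers
    ]
    profile_table(profiles).to_csv(out / "centrality_profiles.csv", index=False)
    _done("centrality", t0, D=cfg.D)
    if stop_after <= STAGES.index("centrality"):
        return _finalize()

    # --- classify ---------------------------------------------------------
    t0 = _stage("classify")
    x = profiles_to_matrix(profiles)
    labels = np.asarray(cohort.labels)
    ranking = loo_feature_ranking(x, labels, rf_params=cfg.rf_params, seed=cfg.seed)
    if cfg.D_grid and cfg.k_grid:
        best, report, _ = scan_hyperparameters(
            subject_layers, labels, cfg.D_grid, cfg.k_grid,
            rf_params=cfg.rf_params, seed=cfg.seed, n_repeats=cfg.n_repeats,
        )
        best_D, best_k = best
    else:
        best_D, best_k = cfg.D, min(cfg.top_k, x.shape[1])
        report = topk_classification(
            x, labels, ranking, top_k=best_k, rf_params=cfg.rf_params,
            seed=cfg.seed, n_repeats=max(cfg.n_repeats, 1), D=cfg.D,
        )
    write_report(report, out / "classification_report.json")
    group_hubs = {}
    for g in sorted(set(cohort.labels)):
        gp = [p for p, l in zip(profiles, cohort.labels) if l == g]
        group_hubs[int(g)] = identify_hubs(gp, fraction=cfg.hub_fraction).nodes
    top_features = [int(i) for i in ranking.top_features(best_k)]
    overlaps = {
        str(g): jaccard_index(hubs, top_features) for g, hubs in group_hubs.items()
    }
    (out / "hubs.json").write_text(json.dumps({
        "group_hubs": group_hubs,
        "top_features": top_features,
        "jaccard_hub_feature_overlap": overlaps,
    }, indent=2))
    _done("classify", t0, accuracy=report.accuracy, D=best_D, top_k=best_k)

    # --- summary ----------------------------------------------------------
    t0 = _stage("summary")
    _done("summary", t0)
    return _finalize()
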