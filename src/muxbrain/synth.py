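"""Synthetic cohorts with planted band-specific group structure.

Emulates resting-state ROI time series at fMRI-like scale: N regions
(default 40, scalable to 264), T samples (default 180) at TR = 2 s (Nyquist
0.25 Hz), white Gaussian background noise, and band-limited latent signals
shared by configured node sets.  A latent is white noise whose Fourier
coefficients outside the target band are zeroed (exact band confinement, no
filter ringing), normalized to unit variance, and added to every member node
scaled by the coupling strength.  Group membership selects which effects are
applied, so the two groups differ only in the configured bands.

Planted multiplex fixtures (random layers with designated high-degree hubs)
bypass signal generation for fast reducibility/centrality tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .connectivity import (
    FrequencyBandScheme,
    LayerNetwork,
    RoiTimeSeriesSet,
    make_band_scheme,
)

__all__ = [
    "SyntheticConfig",
    "LabeledCohort",
    "GroundTruthMultiplex",
    "generate_subject_timeseries",
    "generate_cohort",
    "generate_planted_multiplex",
    "write_cohort",
    "read_cohort",
]

GROUP_LABELS = (0, 1)  # 0 = control-like, 1 = patient-like


@dataclass
class SyntheticConfig:
    """Study-condition parameters for a synthetic two-group cohort.

    A modular background keeps every band's network non-empty and modular,
    as in real band-specific functional connectivity: the ROIs are split into
    ``background_modules`` contiguous modules and, in every band, each module
    shares its own band-limited latent scaled by ``background_strength``
    (set it to 0 for a pure-noise baseline).

    ``group_effects`` maps each group label to a list of
    ``(band_index, coupled_node_ids, coupling_strength)`` effects realized as
    shared band-limited latents.  ``hub_nodes_per_group`` plants broadband
    high-centrality nodes: each hub shares a broadband latent with a
    quarter of the ROIs (partners drawn once from the config seed).
    """

    n_subjects_per_group: int = 10
    n_rois: int = 40
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    band_scheme_params: tuple[float, float, float] = (0.01, 0.25, 0.02)
    group_effects: dict = field(default_factory=dict)
    hub_nodes_per_group: dict = field(default_factory=dict)
    hub_strength: float = 0.8
    background_modules: int = 4
    background_strength: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.n_timepoints < 64:
            raise ValueError("need >= 64 time points for spectral estimation")
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.background_strength <= 1:
            raise ValueError("background_strength must be in [0, 1]")
        if not 1 <= self.background_modules <= self.n_rois:
            raise ValueError("background_modules must be in [1, n_rois]")
        scheme = self.band_scheme()
        for group, effects in self.group_effects.items():
            if group not in GROUP_LABELS:
                raise ValueError(f"unknown group label {group!r}")
            for band, nodes, strength in effects:
                if not 0 <= band < scheme.n_bands:
                    raise ValueError(f"band index {band} outside the band scheme")
                if len(nodes) == 0:
                    raise ValueError("coupled node set must not be empty")
                if any(not 0 <= v < self.n_rois for v in nodes):
                    raise ValueError("coupled node id out of range")
                if not 0 <= strength <= 1:
                    raise ValueError("coupling strength must be in [0, 1]")
        for group, hubs in self.hub_nodes_per_group.items():
            if group not in GROUP_LABELS:
                raise ValueError(f"unknown group label {group!r}")
            if any(not 0 <= h < self.n_rois for h in hubs):
                raise ValueError("hub node id out of range")

    def band_scheme(self) -> FrequencyBandScheme:
        return make_band_scheme(*self.band_scheme_params)

    def module_partition(self) -> np.ndarray:
        """Background module label per ROI (contiguous, near-equal blocks)."""
        return (np.arange(self.n_rois) * self.background_modules) // self.n_rois


@dataclass
class LabeledCohort:
    subjects: list[RoiTimeSeriesSet]
    labels: list[int]
    ground_truth: SyntheticConfig
    subject_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.labels):
            raise ValueError("labels must match subjects")
        if len(set(self.labels)) != 2:
            raise ValueError("cohort must contain exactly two label values")


@dataclass
class GroundTruthMultiplex:
    layers: list[LayerNetwork]
    planted_hubs: set[int]
    planted_partition_per_layer: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = self.layers[0].n_nodes
        if any(not 0 <= h < n for h in self.planted_hubs):
            raise ValueError("planted hub outside the node set")


def _band_limited_noise(
    rng: np.random.Generator, n: int, tr: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Unit-variance noise with Fourier support confined to [f_lo, f_hi)."""
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(rng.standard_normal(n))
    mask = (freqs >= f_lo - 1e-12) & (freqs < f_hi - 1e-12)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}) holds no Fourier bins at n={n}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate band-limited latent")
    return x / sd


def _hub_partners(cfg: SyntheticConfig, group: int, hub: int) -> np.ndarray:
    """Partner ROIs of a planted hub, fixed by the config seed (ground truth)."""
    rng = np.random.default_rng((cfg.seed, group, hub, 7919))
    others = np.array([i for i in range(cfg.n_rois) if i != hub])
    k = max(1, cfg.n_rois // 4)
    return rng.choice(others, size=min(k, others.size), replace=False)


def generate_subject_timeseries(
    cfg: SyntheticConfig, group: int, seed: int
) -> RoiTimeSeriesSet:
    """One subject's ROI x time matrix under the group's planted effects.

    Each configured (band, node set, strength) effect adds a shared
    band-limited latent to its member rows; planted hubs add a broadband
    latent shared between the hub and its partner nodes.  Independent
    Gaussian noise of sd ``noise_sd`` is added everywhere.  Deterministic
    given (cfg, group, seed).
    """
    if group not in GROUP_LABELS:
        raise ValueError(f"unknown group label {group!r}")
    rng = np.random.default_rng(seed)
    n, t, tr = cfg.n_rois, cfg.n_timepoints, cfg.tr_seconds
    scheme = cfg.band_scheme()
    x = cfg.noise_sd * rng.standard_normal((n, t))
    effects = cfg.group_effects.get(group, [])
    # nodes covered by an effect take their band content from the effect
    # latent alone: the module background yields in that band so planted
    # couplings stay identifiable instead of being diluted by the module's
    # own in-band latent
    covered = {b: set() for b in range(scheme.n_bands)}
    for band, nodes, _ in effects:
        covered[band] |= set(nodes)
    if cfg.background_strength > 0:
        modules = cfg.module_partition()
        for b, (lo, hi) in enumerate(scheme.band_edges):
            keep = np.array([i not in covered[b] for i in range(n)])
            for m in range(cfg.background_modules):
                latent = _band_limited_noise(rng, t, tr, lo, hi)
                x[(modules == m) & keep] += cfg.background_strength * latent
    for band, nodes, strength in effects:
        lo, hi = scheme.band_edges[band]
        latent = _band_limited_noise(rng, t, tr, lo, hi)
        for node in nodes:
            x[node] += strength * latent
    for hub in cfg.hub_nodes_per_group.get(group, []):
        latent = _band_limited_noise(rng, t, tr, scheme.f_low, scheme.f_high)
        x[hub] += cfg.hub_strength * latent
        for p in _hub_partners(cfg, group, hub):
            x[p] += 0.5 * cfg.hub_strength * latent
    return RoiTimeSeriesSet(values=x, tr_seconds=tr)


def generate_cohort(cfg: SyntheticConfig) -> LabeledCohort:
    """Two groups of ``n_subjects_per_group`` subjects with derived seeds.

    Subject ``i`` of the cohort uses seed ``cfg.seed + i``, so subjects are
    independent but the whole cohort is reproducible from one seed.
    """
    subjects, labels, seeds = [], [], []
    idx = 0
    for group in GROUP_LABELS:
        for _ in range(cfg.n_subjects_per_group):
            seed = cfg.seed + idx
            subjects.append(generate_subject_timeseries(cfg, group, seed))
            labels.append(group)
            seeds.append(seed)
            idx += 1
    return LabeledCohort(subjects=subjects, labels=labels, ground_truth=cfg,
                         subject_seeds=seeds)


def generate_planted_multiplex(
    n_nodes: int,
    n_layers: int,
    hub_spec: tuple[set[int], int] | None,
    base_edge_prob: float,
    seed: int = 0,
) -> GroundTruthMultiplex:
    """Random unit-weight layers with designated high-degree hub nodes.

    Each layer is an independent Erdos-Renyi graph at ``base_edge_prob``;
    every planted hub additionally connects to ``extra_degree`` uniformly
    chosen non-neighbors in every layer.  Inter-layer weight is left to be
    assigned at multiplex assembly.
    """
    if not 0 < base_edge_prob < 1:
        raise ValueError("base_edge_prob must be in (0, 1)")
    hubs: set[int] = set()
    extra_degree = 0
    if hub_spec is not None:
        hubs, extra_degree = set(hub_spec[0]), int(hub_spec[1])
        if any(not 0 <= h < n_nodes for h in hubs):
            raise ValueError("hub node id out of range")
        if extra_degree >= n_nodes:
            raise ValueError("hub extra-degree must be below n_nodes")
    rng = np.random.default_rng(seed)
    layers = []
    for layer_idx in range(n_layers):
        upper = rng.random((n_nodes, n_nodes)) < base_edge_prob
        a = np.triu(upper, k=1).astype(float)
        a = a + a.T
        for hub in hubs:
            non_neighbors = np.flatnonzero((a[hub] == 0) & (np.arange(n_nodes) != hub))
            k = min(extra_degree, non_neighbors.size)
            chosen = rng.choice(non_neighbors, size=k, replace=False)
            a[hub, chosen] = 1.0
            a[chosen, hub] = 1.0
        layers.append(LayerNetwork(z=a, band=(float(layer_idx), float(layer_idx + 1))))
    return GroundTruthMultiplex(layers=layers, planted_hubs=hubs)


# ---------------------------------------------------------------------------
# cohort serialization: one CSV per subject + a JSON manifest


def write_cohort(cohort: LabeledCohort, directory: str | Path) -> Path:
    """Write one CSV per subject (rows = ROIs, columns = time) + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = cohort.ground_truth
    manifest = {
        "labels": list(cohort.labels),
        "subject_seeds": list(cohort.subject_seeds),
        "tr_seconds": cfg.tr_seconds,
        "files": [],
        "config": _config_to_jsonable(cfg),
    }
    for i, ts in enumerate(cohort.subjects):
        fname = f"subject_{i:03d}.csv"
        np.savetxt(directory / fname, ts.values, delimiter=",", fmt="%.17e")
        manifest["files"].append(fname)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory / "manifest.json"


def read_cohort(directory: str | Path) -> LabeledCohort:
    """Round-trip reader for :func:`write_cohort` output."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg = _config_from_jsonable(manifest["config"])
    subjects = [
        RoiTimeSeriesSet(
            values=np.loadtxt(directory / f, delimiter=",", ndmin=2),
            tr_seconds=manifest["tr_seconds"],
        )
        for f in manifest["files"]
    ]
    return LabeledCohort(
        subjects=subjects,
        labels=list(manifest["labels"]),
        ground_truth=cfg,
        subject_seeds=list(manifest["subject_seeds"]),
    )


def _config_to_jsonable(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["group_effects"] = {
        str(g): [[b, sorted(int(v) for v in nodes), s] for b, nodes, s in effects]
        for g, effects in cfg.group_effects.items()
    }
    d["hub_nodes_per_group"] = {
        str(g): sorted(int(h) for h in hubs)
        for g, hubs in cfg.hub_nodes_per_group.items()
    }
    return d


def _config_from_jsonable(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["band_scheme_params"] = tuple(d["band_scheme_params"])
    d["group_effects"] = {
        int(g): [(b, set(nodes), s) for b, nodes, s in effects]
        for g, effects in d["group_effects"].items()
    }
    d["hub_nodes_per_group"] = {
        int(g): set(hubs) for g, hubs in d["hub_nodes_per_group"].items()
    }
    return SyntheticConfig(**d)
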