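"""Seeded synthetic two-group resting-state cohorts with planted truth.

Generates multi-subject 4D BOLD-like volumes in which every voxel signal is
a mixture of three spatial network templates (central executive network,
CEN; default mode network, DMN; salience network, SN) driven by node time
courses drawn from a known linear-Gaussian structural equation model, plus
a linear drift and additive white scanner noise.  The directed model, the
spatial templates, and all per-subject seeds are returned as a ground-truth
bundle, so every downstream stage (ICA, voxelwise statistics, Bayesian
network structure learning, permutation testing) can be scored by recovery
of the planted truth.

The spatial templates are sparse, hard-edged spheres (optionally
Gaussian-feathered).  Sparse blobs are super-Gaussian over voxels, which is
what makes the subsequent *spatial* ICA identifiable; no extra source
transformation is applied by default.  Node dynamics are temporally white
by default (the downstream network model treats time points as exchangeable
samples); an AR(1) knob is available but off by default.
"""
from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "NETWORK_NAMES",
    "GROUP_LABELS",
    "OverlapError",
    "NetworkSpec",
    "DirectedModelSpec",
    "CohortConfig",
    "SubjectBold",
    "GroundTruth",
    "ras_affine",
    "make_network_templates",
    "simulate_node_timecourses",
    "simulate_subject_bold",
    "simulate_cohort",
    "save_bold",
    "load_bold",
    "default_network_specs",
    "default_hub_model",
    "default_cohort_config",
]

NETWORK_NAMES = ("CEN", "DMN", "SN")
GROUP_LABELS = ("HR", "LR")

#: isotropic voxel size of the synthetic grid, millimetres
VOXEL_SIZE_MM = 4.0


class OverlapError(ValueError):
    """Raised when planted network templates overlap more than allowed."""


def ras_affine(volume_shape: Sequence[int], voxel_size_mm: float = VOXEL_SIZE_MM) -> np.ndarray:
    """RAS-oriented affine with isotropic voxels and origin at volume center."""
    shape = np.asarray(volume_shape, dtype=float)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (shape - 1) / 2.0
    return affine


@dataclass(frozen=True)
class NetworkSpec:
    """One planted network: a named set of spherical blobs with group loadings.

    ``blobs`` is a sequence of ``(center, radius, amplitude)`` where ``center``
    is a voxel index triple, ``radius`` is in voxels (>= 1) and ``amplitude``
    scales the blob.  ``loading_scale_per_group`` multiplies the whole
    network's contribution per group, which is how between-group
    within-network connectivity differences are planted.
    """

    name: str
    blobs: tuple = ()
    loading_scale_per_group: Mapping[str, float] = field(
        default_factory=lambda: {g: 1.0 for g in GROUP_LABELS}
    )

    def __post_init__(self):
        for _, radius, _ in self.blobs:
            if radius < 1:
                raise ValueError(f"blob radius must be >= 1 voxel, got {radius}")
        for group, scale in self.loading_scale_per_group.items():
            if scale <= 0:
                raise ValueError(f"loading scale for group {group!r} must be > 0")

    def validate_grid(self, volume_shape: Sequence[int]) -> None:
        shape = np.asarray(volume_shape)
        for center, radius, _ in self.blobs:
            c = np.asarray(center)
            if np.any(c < 0) or np.any(c >= shape):
                raise IndexError(
                    f"blob center {tuple(center)} of network {self.name!r} "
                    f"outside grid {tuple(volume_shape)}"
                )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "blobs": [
                {"center": list(map(int, c)), "radius": float(r), "amplitude": float(a)}
                for c, r, a in self.blobs
            ],
            "loading_scale_per_group": dict(self.loading_scale_per_group),
        }


@dataclass(frozen=True)
class DirectedModelSpec:
    """Linear-Gaussian directed model over named network nodes.

    Each node at each time point is the weighted sum of its parents at the
    same time point plus independent Gaussian noise:
    ``x_j(t) = sum_p w_{p->j} x_p(t) + eps_j(t)``, ``eps_j ~ N(0, sd_j^2)``.
    ``group_overrides`` maps a group label to ``{(parent, child): weight}``
    replacements, which is how between-group effective-connectivity
    differences are planted.
    """

    nodes: tuple = NETWORK_NAMES
    edges: tuple = ()  # ((parent, child, weight), ...)
    noise_sd: Mapping[str, float] | float = 1.0
    group_overrides: Mapping[str, Mapping[tuple, float]] = field(default_factory=dict)

    def __post_init__(self):
        declared = set(self.nodes)
        for parent, child, _ in self.edges:
            if parent not in declared or child not in declared:
                raise ValueError(f"edge ({parent}, {child}) uses undeclared node")
        for sd in self._noise_sd_map().values():
            if sd <= 0:
                raise ValueError("noise_sd must be > 0")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((p, c) for p, c, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed model contains a cycle")

    def _noise_sd_map(self) -> dict:
        if isinstance(self.noise_sd, Mapping):
            return dict(self.noise_sd)
        return {node: float(self.noise_sd) for node in self.nodes}

    def weight_matrix(self, group: str | None = None) -> np.ndarray:
        """Parent-by-child weight matrix, with group overrides applied."""
        idx = {node: i for i, node in enumerate(self.nodes)}
        w = np.zeros((len(self.nodes), len(self.nodes)))
        for parent, child, weight in self.edges:
            w[idx[parent], idx[child]] = weight
        if group is not None and group in self.group_overrides:
            for (parent, child), weight in self.group_overrides[group].items():
                w[idx[parent], idx[child]] = weight
        return w

    def analytic_covariance(self, group: str | None = None) -> np.ndarray:
        """Closed-form node covariance (I - W')^-1 D (I - W')^-T of the system."""
        w = self.weight_matrix(group)
        n = len(self.nodes)
        sd = self._noise_sd_map()
        d = np.diag([sd[node] ** 2 for node in self.nodes])
        inv = np.linalg.inv(np.eye(n) - w.T)
        return inv @ d @ inv.T

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "edges": [[p, c, float(w)] for p, c, w in self.edges],
            "noise_sd": self._noise_sd_map(),
            "group_overrides": {
                g: {f"{p}->{c}": float(w) for (p, c), w in ov.items()}
                for g, ov in self.group_overrides.items()
            },
        }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    Defaults emulate the study design being modelled: 17 high-risk vs 12
    low-risk subjects, a TR of 2.5 s, and a 24x24x18 grid at 4 mm isotropic
    that is large enough to hold three disjoint networks yet small enough
    for second-scale end-to-end runs.
    """

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"HR": 17, "LR": 12}
    )
    volume_shape: tuple = (24, 24, 18)
    n_timepoints: int = 120
    tr_seconds: float = 2.5
    drift_slope: float = 0.02
    noise_sd: float = 0.5
    seed: int = 0
    ar_coeff: float = 0.0

    def __post_init__(self):
        if any(n < 1 for n in self.n_subjects_per_group.values()):
            raise ValueError("each group needs at least one subject")
        if self.n_timepoints <= 15:
            raise ValueError("n_timepoints must exceed the discardable prefix + 10")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    def to_dict(self) -> dict:
        return {
            "n_subjects_per_group": dict(self.n_subjects_per_group),
            "volume_shape": list(self.volume_shape),
            "n_timepoints": self.n_timepoints,
            "tr_seconds": self.tr_seconds,
            "drift_slope": self.drift_slope,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "ar_coeff": self.ar_coeff,
        }


@dataclass
class SubjectBold:
    """One subject's 4D volume plus mask, affine, repetition time and labels."""

    data: np.ndarray  # (x, y, z, t)
    mask: np.ndarray  # (x, y, z) boolean
    tr_seconds: float
    subject_id: str
    group: str
    affine: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape of data")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if np.isnan(self.data).any():
            raise ValueError("data contains missing values")
        if self.affine is None:
            self.affine = ras_affine(self.data.shape[:3])

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    def timeseries(self) -> np.ndarray:
        """In-mask voxel time series as a (time, voxels) matrix."""
        return self.data[self.mask].T


@dataclass
class GroundTruth:
    """Everything the generator knows: planted maps, masks, dynamics, seeds."""

    templates: dict  # label -> 3D map
    masks: dict  # label -> 3D boolean mask
    node_series: dict  # subject_id -> DataFrame (time x nodes)
    specs: tuple
    model: DirectedModelSpec
    config: CohortConfig
    subject_seeds: dict  # subject_id -> {"series": int, "noise": int}

    def to_json_dict(self) -> dict:
        return {
            "network_specs": [s.to_dict() for s in self.specs],
            "model": self.model.to_dict(),
            "config": self.config.to_dict(),
            "subject_seeds": self.subject_seeds,
        }


# ---------------------------------------------------------------------------
# template construction


def make_network_templates(
    specs: Sequence[NetworkSpec],
    volume_shape: Sequence[int],
    max_overlap: float = 0.0,
    feather_sigma_vox: float = 0.0,
):
    """Build nonnegative 3D spatial maps and binary truth masks from specs.

    Returns ``(maps, masks)`` dicts keyed by network name.  The pairwise
    overlap fraction ``|A & B| / min(|A|, |B|)`` of the truth masks must not
    exceed ``max_overlap``.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("network names must be pairwise distinct")
    grids = np.indices(volume_shape)
    maps, masks = {}, {}
    for spec in specs:
        spec.validate_grid(volume_shape)
        vol = np.zeros(volume_shape)
        for center, radius, amplitude in spec.blobs:
            dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
            vol[dist2 <= radius**2] += amplitude
        masks[spec.name] = vol > 0
        if feather_sigma_vox > 0:
            from scipy.ndimage import gaussian_filter

            vol = gaussian_filter(vol, feather_sigma_vox)
        maps[spec.name] = vol
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = np.logical_and(masks[a], masks[b]).sum()
            denom = min(masks[a].sum(), masks[b].sum())
            if denom and inter / denom > max_overlap:
                raise OverlapError(
                    f"templates {a!r} and {b!r} overlap by {inter / denom:.3f} "
                    f"(> {max_overlap})"
                )
    return maps, masks


# ---------------------------------------------------------------------------
# node dynamics


def simulate_node_timecourses(
    model: DirectedModelSpec,
    n_timepoints: int,
    seed,
    group: str | None = None,
    ar_coeff: float = 0.0,
) -> pd.DataFrame:
    """Draw node time courses from the linear-Gaussian directed model.

    Time points are i.i.d. draws from the structural equation system unless
    ``ar_coeff`` adds AR(1) temporal smoothing to the node noises.  The
    implied population covariance is ``model.analytic_covariance(group)``
    (AR smoothing leaves the marginal covariance unchanged because the
    innovations are rescaled by sqrt(1 - phi^2)).
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(model.nodes)
    sd = model._noise_sd_map()
    w = model.weight_matrix(group)
    noise = rng.standard_normal((n_timepoints, len(nodes)))
    noise *= np.array([sd[n] for n in nodes])
    if ar_coeff:
        if not -1 < ar_coeff < 1:
            raise ValueError("ar_coeff must lie in (-1, 1)")
        smoothed = np.empty_like(noise)
        smoothed[0] = noise[0]
        scale = np.sqrt(1.0 - ar_coeff**2)
        for t in range(1, n_timepoints):
            smoothed[t] = ar_coeff * smoothed[t - 1] + scale * noise[t]
        noise = smoothed
    g = nx.DiGraph()
    g.add_nodes_from(range(len(nodes)))
    g.add_edges_from(zip(*np.nonzero(w)))
    x = np.zeros_like(noise)
    for j in nx.topological_sort(g):
        x[:, j] = x @ w[:, j] + noise[:, j]
    return pd.DataFrame(x, columns=nodes)


# ---------------------------------------------------------------------------
# subject volumes


def simulate_subject_bold(
    templates: Mapping[str, np.ndarray],
    node_series: pd.DataFrame,
    cohort: CohortConfig,
    group: str,
    subject_seed,
    loadings: Mapping[str, float] | None = None,
    subject_id: str = "sub",
) -> SubjectBold:
    """Mix templates with node series into one subject's 4D volume.

    Voxel signal = sum over networks of
    ``loading(group) * template(voxel) * node_series(t)``, plus a linear
    drift ``drift_slope * t`` and white Gaussian noise of sd
    ``cohort.noise_sd``.
    """
    if set(templates) != set(node_series.columns):
        raise ValueError(
            f"template labels {sorted(templates)} do not match node labels "
            f"{sorted(node_series.columns)}"
        )
    n_t = len(node_series)
    if n_t != cohort.n_timepoints:
        raise ValueError("node series length must equal cohort n_timepoints")
    loadings = loadings or {}
    shape = tuple(cohort.volume_shape)
    data = np.zeros(shape + (n_t,))
    for label, template in templates.items():
        scale = float(loadings.get(label, 1.0))
        data += scale * template[..., None] * node_series[label].to_numpy()
    data += cohort.drift_slope * np.arange(n_t)
    rng = np.random.default_rng(subject_seed)
    if cohort.noise_sd > 0:
        data += rng.normal(0.0, cohort.noise_sd, size=data.shape)
    return SubjectBold(
        data=data,
        mask=np.ones(shape, dtype=bool),
        tr_seconds=cohort.tr_seconds,
        subject_id=subject_id,
        group=group,
        affine=ras_affine(shape),
    )


# ---------------------------------------------------------------------------
# whole cohorts


def _subject_seeds(config_seed: int, index: int) -> tuple:
    ss = np.random.SeedSequence(entropy=config_seed, spawn_key=(index,))
    series_seed, noise_seed = (int(s) for s in ss.generate_state(2))
    return series_seed % 2**31, noise_seed % 2**31


def simulate_cohort(
    config: CohortConfig,
    network_specs: Sequence[NetworkSpec],
    model: DirectedModelSpec,
    out_dir: str | Path | None = None,
):
    """Generate the full two-group cohort; optionally write it to disk.

    Returns ``(subjects, truth)`` where ``subjects`` is a list of
    :class:`SubjectBold` and ``truth`` a :class:`GroundTruth`.  When
    ``out_dir`` is given, one gzipped NIfTI-1 per subject
    (``sub-<id>_bold.nii.gz``), a ``participants.tsv`` group table and a
    ``ground_truth.json`` sidecar are written; the gzip stream carries no
    timestamp so identical seeds yield byte-identical files.
    """
    maps, masks = make_network_templates(network_specs, config.volume_shape)
    loadings_by_group = {
        g: {s.name: s.loading_scale_per_group.get(g, 1.0) for s in network_specs}
        for g in config.n_subjects_per_group
    }
    subjects, node_series, seeds = [], {}, {}
    index = 0
    for group, count in config.n_subjects_per_group.items():
        for k in range(count):
            subject_id = f"{group}{k + 1:02d}"
            series_seed, noise_seed = _subject_seeds(config.seed, index)
            series = simulate_node_timecourses(
                model, config.n_timepoints, series_seed, group=group,
                ar_coeff=config.ar_coeff,
            )
            bold = simulate_subject_bold(
                maps, series, config, group, noise_seed,
                loadings=loadings_by_group[group], subject_id=subject_id,
            )
            subjects.append(bold)
            node_series[subject_id] = series
            seeds[subject_id] = {"series": series_seed, "noise": noise_seed}
            index += 1
    truth = GroundTruth(
        templates=maps, masks=masks, node_series=node_series,
        specs=tuple(network_specs), model=model, config=config,
        subject_seeds=seeds,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for bold in subjects:
            save_bold(bold, out_dir / f"sub-{bold.subject_id}_bold.nii.gz")
        table = pd.DataFrame(
            {"subject_id": [b.subject_id for b in subjects],
             "group": [b.group for b in subjects]}
        )
        table.to_csv(out_dir / "participants.tsv", sep="\t", index=False)
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
    return subjects, truth


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a (gzipped, timestamp-free, hence reproducible) NIfTI-1 file."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    path = Path(path)
    payload = img.to_bytes()
    if path.suffix == ".gz":
        with open(path, "wb") as fh:
            with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(payload)
    else:
        path.write_bytes(payload)


def save_bold(bold: SubjectBold, path: str | Path) -> None:
    save_nifti(bold.data, bold.affine, path)


def load_bold(path: str | Path, subject_id: str, group: str,
              tr_seconds: float = 2.5) -> SubjectBold:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    return SubjectBold(
        data=data,
        mask=np.ones(data.shape[:3], dtype=bool),
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        group=group,
        affine=np.asarray(img.affine),
    )


# ---------------------------------------------------------------------------
# study-condition defaults


def default_network_specs(dmn_hr_loading: float = 1.5):
    """Three disjoint spherical networks; the DMN carries an HR>LR loading.

    Blob radius is 4 voxels (16 mm at the 4 mm grid) so that the planted
    features are comfortably larger than the default 8 mm FWHM smoothing
    kernel — a resolvability requirement for any recovery phantom.
    """
    return (
        NetworkSpec("CEN", (((6, 6, 9), 4.0, 1.0),)),
        NetworkSpec("DMN", (((17, 6, 9), 4.0, 1.0),),
                    {"HR": dmn_hr_loading, "LR": 1.0}),
        NetworkSpec("SN", (((11, 17, 9), 4.0, 1.0),)),
    )


def default_hub_model(
    sn_cen: float = 0.6,
    sn_dmn: float = 0.5,
    group_overrides: Mapping | None = None,
) -> DirectedModelSpec:
    """Salience-network hub: SN sends to CEN and DMN, receives nothing."""
    return DirectedModelSpec(
        nodes=NETWORK_NAMES,
        edges=(("SN", "CEN", sn_cen), ("SN", "DMN", sn_dmn)),
        noise_sd=1.0,
        group_overrides=group_overrides or {},
    )


def default_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    return CohortConfig(seed=seed, **overrides)
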