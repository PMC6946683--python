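"""Core data containers.

Coordinates are in nanometres throughout, right-handed, with z = 0 at the
nominal microvillar tip plane and z increasing luminally.  Bounding boxes
are half-open: a point p is inside extent e iff e[d, 0] <= p[d] < e[d, 1]
for every dimension d.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Optional, Sequence

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "as_extent",
    "TerminiPattern",
    "Filament",
    "GlycocalyxNetwork",
    "CoatedCrossSection",
    "LabeledVolume",
    "NNResult",
    "RDFResult",
    "OrderMetrics",
    "AutocorrResult",
    "MorphometryResult",
    "ProbeSpec",
    "PermeationResult",
]


def as_extent(extent: Any, dim: Optional[int] = None) -> np.ndarray:
    """Coerce ``extent`` to a (d, 2) float array and validate lo < hi."""
    e = np.asarray(extent, dtype=float)
    if e.ndim != 2 or e.shape[1] != 2:
        raise ParameterError(f"extent must have shape (d, 2), got {e.shape}")
    if dim is not None and e.shape[0] != dim:
        raise ParameterError(f"extent must be {dim}-dimensional, got {e.shape[0]}")
    if np.any(e[:, 1] <= e[:, 0]):
        raise ParameterError("extent sides must have positive length")
    return e


def _tolist(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _tolist(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_tolist(v) for v in x]
    return x


@dataclass
class TerminiPattern:
    """A planar (2D) or volumetric (3D) set of filament-termini coordinates.

    Parameters
    ----------
    points:
        (n, d) array of coordinates in nm, d in {2, 3}.
    extent:
        (d, 2) half-open bounding box in nm.
    regime_label:
        Optional packing-regime tag ('hexagonal', 'liquid_crystal',
        'liquid', 'csr') recorded by the generator.
    seed:
        Seed used to generate the pattern, if synthetic.
    tip_ids:
        Optional (n,) integer array tagging each point with the microvillar
        tip its filament is anchored to (cross-sections only).
    meta:
        Construction-rule ground truth (lattice constant, jitter sd,
        hard-core diameter, target mean NN spacing, ...).
    """

    points: np.ndarray
    extent: np.ndarray
    regime_label: Optional[str] = None
    seed: Optional[int] = None
    tip_ids: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, max(2, self.points.shape[-1] or 2))
        d = self.points.shape[1]
        if d not in (2, 3):
            raise ParameterError(f"points must be 2D or 3D, got dimension {d}")
        self.extent = as_extent(self.extent, d)
        if self.tip_ids is not None:
            self.tip_ids = np.asarray(self.tip_ids, dtype=int)
            if self.tip_ids.shape[0] != self.points.shape[0]:
                raise ParameterError("tip_ids length must match number of points")
        if len(self.points):
            lo, hi = self.extent[:, 0], self.extent[:, 1]
            eps = 1e-9 * np.maximum(1.0, np.abs(hi))
            if np.any(self.points < lo - eps) or np.any(self.points >= hi + eps):
                raise ParameterError("points must lie inside the extent (half-open box)")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dimensionality(self) -> int:
        return self.points.shape[1]

    def project(self) -> "TerminiPattern":
        """Project a 3D pattern along the terminal-plane normal (z) to 2D."""
        if self.dimensionality == 2:
            return self
        return TerminiPattern(
            points=self.points[:, :2].copy(),
            extent=self.extent[:2].copy(),
            regime_label=self.regime_label,
            seed=self.seed,
            tip_ids=None if self.tip_ids is None else self.tip_ids.copy(),
            meta=dict(self.meta, projected_from=3),
        )

    def to_dataframe(self):
        import pandas as pd

        cols = {"x_nm": self.points[:, 0], "y_nm": self.points[:, 1]}
        if self.dimensionality == 3:
            cols["z_nm"] = self.points[:, 2]
        if self.tip_ids is not None:
            cols["tip_id"] = self.tip_ids
        return pd.DataFrame(cols)


@dataclass
class Filament:
    """One glycocalyx filament: an ordered polyline from a tip anchor to a
    terminus, tagged with its core diameter (uncoated)."""

    nodes: np.ndarray  # (m, 3) nm
    tip_index: int
    terminus_index: int
    core_diameter: float  # nm
    merged_with: Optional[int] = None  # host filament index if merged near the top

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3 or self.nodes.shape[0] < 2:
            raise ParameterError("filament nodes must be an (m>=2, 3) array")
        if self.core_diameter <= 0:
            raise ParameterError("core diameter must be positive")

    @property
    def length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.nodes, axis=0), axis=1)))


@dataclass
class GlycocalyxNetwork:
    """Generative ground truth: anchors, filament polylines, lateral
    contacts, and the terminal-plane termini."""

    anchors: np.ndarray  # (t, 3) nm, microvillar tip positions
    per_tip_counts: np.ndarray  # (t,) filaments generated per tip
    filaments: list  # list[Filament]
    contacts: list  # list[(fil_i, fil_j, node_i, node_j)]
    termini_points: np.ndarray  # (m, 3) nm
    termini_diameters: np.ndarray  # (m,) nm globular tip diameters
    extent: np.ndarray  # (3, 2) nm
    params: Any = None  # GeneratorParams echo
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.anchors = np.asarray(self.anchors, dtype=float)
        self.per_tip_counts = np.asarray(self.per_tip_counts, dtype=int)
        self.termini_points = np.asarray(self.termini_points, dtype=float)
        self.termini_diameters = np.asarray(self.termini_diameters, dtype=float)
        self.extent = as_extent(self.extent, 3)

    @property
    def n_tips(self) -> int:
        return self.anchors.shape[0]

    @property
    def n_filaments(self) -> int:
        return len(self.filaments)

    @property
    def terminal_plane_z(self) -> float:
        return float(np.median(self.termini_points[:, 2]))

    @property
    def core_diameters(self) -> np.ndarray:
        return np.array([f.core_diameter for f in self.filaments])

    def total_filament_length(self) -> float:
        """Total polyline length in nm."""
        return float(sum(f.length for f in self.filaments))

    def validate(self, plane_tolerance: float = 10.0, contact_tolerance: float = 1.0):
        """Check construction invariants; raise ParameterError on violation."""
        for i, f in enumerate(self.filaments):
            if not np.allclose(f.nodes[0], self.anchors[f.tip_index]):
                raise ParameterError(f"filament {i} does not start at its tip anchor")
            if not np.allclose(f.nodes[-1], self.termini_points[f.terminus_index]):
                raise ParameterError(f"filament {i} does not end at its terminus")
        z = self.termini_points[:, 2]
        if len(z) and (z.max() - z.min()) > 2 * plane_tolerance + 6 * (
            self.params.terminal_plane_sd if self.params is not None else 2.0
        ):
            raise ParameterError("termini do not lie within the terminal-plane band")
        for fi, fj, ni, nj in self.contacts:
            sep = np.linalg.norm(self.filaments[fi].nodes[ni] - self.filaments[fj].nodes[nj])
            max_sep = (
                0.5 * (self.filaments[fi].core_diameter + self.filaments[fj].core_diameter)
                + contact_tolerance
            )
            if sep > max_sep:
                raise ParameterError("contact pair separated beyond contact tolerance")
        return True

    def to_dict(self) -> dict:
        from dataclasses import asdict as _asdict

        params = None
        if self.params is not None:
            params = _tolist(_asdict(self.params))
        return {
            "schema": "glycomesh.network/1",
            "seed": self.seed,
            "extent": self.extent.tolist(),
            "anchors": self.anchors.tolist(),
            "per_tip_counts": self.per_tip_counts.tolist(),
            "filaments": [
                {
                    "nodes": f.nodes.tolist(),
                    "tip_index": int(f.tip_index),
                    "terminus_index": int(f.terminus_index),
                    "core_diameter": float(f.core_diameter),
                    "merged_with": f.merged_with,
                }
                for f in self.filaments
            ],
            "contacts": [[int(a), int(b), int(c), int(d)] for a, b, c, d in self.contacts],
            "termini_points": self.termini_points.tolist(),
            "termini_diameters": self.termini_diameters.tolist(),
            "params": params,
            "meta": _tolist(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GlycocalyxNetwork":
        from .generate import GeneratorParams

        params = None
        if d.get("params"):
            p = dict(d["params"])
            p["extent"] = tuple(tuple(row) for row in p["extent"])
            params = GeneratorParams(**p)
        return cls(
            anchors=np.array(d["anchors"], dtype=float).reshape(-1, 3),
            per_tip_counts=np.array(d["per_tip_counts"], dtype=int),
            filaments=[
                Filament(
                    nodes=np.array(f["nodes"], dtype=float),
                    tip_index=f["tip_index"],
                    terminus_index=f["terminus_index"],
                    core_diameter=f["core_diameter"],
                    merged_with=f.get("merged_with"),
                )
                for f in d["filaments"]
            ],
            contacts=[tuple(c) for c in d["contacts"]],
            termini_points=np.array(d["termini_points"], dtype=float).reshape(-1, 3),
            termini_diameters=np.array(d["termini_diameters"], dtype=float),
            extent=np.array(d["extent"], dtype=float),
            params=params,
            seed=d.get("seed"),
            meta=d.get("meta", {}),
        )


@dataclass
class CoatedCrossSection:
    """A filament cross-section as seen in a replica cast: the platinum
    coating encases the core, so the measured width is core + 2 * coating."""

    core_diameter: float  # nm (ground truth; nan if unknown)
    coating_thickness: float  # nm
    measured_outer_diameter: float  # nm

    def __post_init__(self):
        if self.coating_thickness < 0:
            raise ParameterError("coating thickness must be >= 0")
        if self.measured_outer_diameter <= 0:
            raise ParameterError("measured outer diameter must be positive")


@dataclass
class LabeledVolume:
    """Rasterized network volume with labels {0 background, 1 coating, 2 core}."""

    data: np.ndarray  # (nz, ny, nx) uint8
    voxel_size: float  # nm, isotropic
    origin: np.ndarray  # (3,) nm, position of voxel (0,0,0) center, (x,y,z)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)


# ---------------------------------------------------------------------------
# Result documents
# ---------------------------------------------------------------------------


@dataclass
class NNResult:
    nn_distances: np.ndarray  # nm, one per non-excluded point
    mean: float
    sd: float
    n: int
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    gaussian_mu: float
    gaussian_sigma: float
    edge_buffer: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return _tolist(asdict(self))


@dataclass
class RDFResult:
    r: np.ndarray  # bin centers, nm
    g: np.ndarray  # dimensionless
    first_peak_r: float  # nm
    bin_width: float
    edge_correction: str = "border"
    n_reference: int = 0
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return _tolist(asdict(self))


@dataclass
class OrderMetrics:
    psi6: float
    fft_sixfold_ratio: float
    regime_call: str
    thresholds: tuple = (0.35, 0.7)
    n_interior: int = 0

    def to_dict(self) -> dict:
        return _tolist(asdict(self))


@dataclass
class AutocorrResult:
    r: np.ndarray  # nm
    profile: np.ndarray  # radially averaged autocorrelation
    first_offpeak_r: float  # nm; nan if degenerate
    render_px: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return _tolist(asdict(self))


@dataclass
class MorphometryResult:
    measurement_kind: str  # pore_size | filament_diameter | layer_thickness
    #                        | filaments_per_tip | tip_diameter
    samples: np.ndarray  # nm or counts
    n: int
    mean: float
    sd: float
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @classmethod
    def from_samples(cls, kind: str, samples: Sequence[float], params=None, warnings=None):
        from .exceptions import EmptyResultError

        s = np.asarray(samples, dtype=float)
        if s.size == 0:
            raise EmptyResultError(f"{kind}: no samples")
        return cls(
            measurement_kind=kind,
            samples=s,
            n=int(s.size),
            mean=float(s.mean()),
            sd=float(s.std(ddof=1)) if s.size > 1 else 0.0,
            params=dict(params or {}),
            warnings=list(warnings or []),
        )

    def to_dict(self) -> dict:
        return _tolist(asdict(self))


@dataclass
class ProbeSpec:
    """A rigid-sphere diffusion probe (dextran analog)."""

    label: str
    stokes_radius: float  # nm
    n_probes: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.stokes_radius <= 0:
            raise ParameterError("stokes_radius must be positive")
        if self.n_probes < 1:
            raise ParameterError("n_probes must be >= 1")


@dataclass
class PermeationResult:
    probe: ProbeSpec
    fraction_reaching_base: float
    depth_z: np.ndarray  # nm, bin depths from the luminal face downward
    depth_fraction: np.ndarray  # fraction of probes reaching at least that depth
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        return _tolist(d)
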