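"""Synthetic glycocalyx generator.

The enteric glycocalyx is modeled, following freeze-etch observations, as a
columnar brush: rod-like mucin filaments emerge from microvillar tips
(~7 per tip), rise ~1 µm through the layer while making zigzagged lateral
contacts (~30 nm mesh), and end in a single flat terminal plane of ~10 nm
globular tips spaced ~32 nm apart, packed anywhere between hexagonal
crystal and liquid.

Generative choices (no generative equations exist for real tissue; these
are this package's definitions, documented in docs/methods.md):

* terminal-plane packing regimes:
  - ``hexagonal``      triangular lattice + small isotropic Gaussian jitter
    (jitter sd <= 0.1 * spacing by convention),
  - ``liquid_crystal`` triangular lattice + larger Gaussian jitter
    (quasi-order retained),
  - ``liquid``         Matern type-II hard-core process;
* filament paths: discretized walk along the anchor->terminus chord with an
  early lateral splay (filaments interlace almost immediately above the
  tips) and rough per-node zigzag excursions; endpoints are exact;
* lateral contacts: node pairs within a capture radius snapped to their
  midpoint, subsampled to the requested contacts-per-µm rate;
* per-tip filament counts: rounded Gaussian, clipped at >= 1;
* coating: uniform-thickness platinum shell.

A calibration contract maps a *requested ground-truth mean nearest-neighbor
spacing* to the regime's length parameter (lattice constant or hard-core
diameter) through a dimensionless factor estimated once per regime/jitter
ratio from a large unit-spacing simulation with a fixed internal seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._rng import child_rng
from .datatypes import (
    Filament,
    GlycocalyxNetwork,
    LabeledVolume,
    TerminiPattern,
    as_extent,
)
from .exceptions import (
    DegenerateExtentError,
    ParameterError,
    ResolutionError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorParams",
    "REGIMES",
    "generate_termini_pattern",
    "generate_csr_pattern",
    "generate_network",
    "rasterize_network",
    "cross_section",
    "spacing_factor",
    "calibrate_mesh",
]

REGIMES = ("hexagonal", "liquid_crystal", "liquid")

# Matern-II proposal density: lambda_p * d_hc^2 (dimensionless). Fixed so the
# retained process is close to jamming (liquid-like, Fig 3g appearance).
_MATERN_C = 2.0

# Internal seed for the spacing-calibration simulations (part of the
# calibration contract, not of any user-visible randomness).
_CALIBRATION_SEED = 20240131

_spacing_factor_cache: dict = {}


@dataclass
class GeneratorParams:
    """Ground-truth parameters of the synthetic glycocalyx.

    All lengths in nm.  Defaults are the measured statistics of the adult
    mouse enteric glycocalyx: 1.0 ± 0.1 µm layer, 7 ± 1.5 filaments per
    microvillar tip, 5.3 ± 1.3 nm filament cores, 10.2 ± 1.2 nm globular
    tips spaced ~32 nm in a liquid-crystalline terminal plane, ~30 nm mesh.
    The platinum coating thickness (2.0 nm) is a package convention for the
    replica-cast emulation, not a measured value.
    """

    microvillus_spacing: float = 100.0  # center-to-center of tip anchors
    filaments_per_tip_mean: float = 7.0
    filaments_per_tip_sd: float = 1.5
    layer_thickness: float = 1000.0
    layer_thickness_sd: float = 100.0  # base-topography variation
    termini_regime: str = "liquid_crystal"
    termini_mean_spacing: float = 32.0  # target ground-truth mean NN spacing
    termini_jitter_sd: float = 4.0  # quasi-ordered (liquid-crystalline) plane
    tip_diameter_mean: float = 10.2
    tip_diameter_sd: float = 1.2
    filament_core_diameter_mean: float = 5.3
    filament_core_diameter_sd: float = 1.3
    coating_thickness: float = 2.0
    contact_rate: float = 12.0  # lateral contacts per µm of filament
    merge_fraction: float = 0.0  # fraction of filaments merging near the top
    step_nm: float = 15.0  # path discretization step in z
    zigzag_amplitude: float = 12.0  # per-node lateral excursion sd
    contact_capture_radius: float = 20.0
    terminal_plane_sd: float = 2.0  # flatness of the terminal plane
    anchor_xy_jitter_frac: float = 0.1
    min_core_diameter: float = 2.0
    extent: tuple = ((0.0, 1000.0), (0.0, 1000.0), (-500.0, 1100.0))
    seed: int = 0

    def __post_init__(self):
        positive = [
            "microvillus_spacing",
            "layer_thickness",
            "termini_mean_spacing",
            "tip_diameter_mean",
            "filament_core_diameter_mean",
            "step_nm",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in [
            "filaments_per_tip_sd",
            "layer_thickness_sd",
            "termini_jitter_sd",
            "tip_diameter_sd",
            "filament_core_diameter_sd",
            "coating_thickness",
            "contact_rate",
            "zigzag_amplitude",
            "terminal_plane_sd",
        ]:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.filaments_per_tip_mean < 1:
            raise ParameterError("filaments_per_tip_mean must be >= 1")
        if not 0 <= self.merge_fraction < 1:
            raise ParameterError("merge_fraction must be in [0, 1)")
        if self.termini_regime not in REGIMES:
            raise ParameterError(f"unknown termini regime '{self.termini_regime}'")
        if self.termini_jitter_sd >= self.termini_mean_spacing:
            raise ParameterError("termini_jitter_sd must be < termini_mean_spacing")
        if (
            self.termini_regime == "hexagonal"
            and self.termini_jitter_sd > 0.1 * self.termini_mean_spacing
        ):
            raise ParameterError(
                "hexagonal regime requires jitter sd <= 0.1 * mean spacing"
            )
        if self.layer_thickness <= self.tip_diameter_mean:
            raise ParameterError("infeasible geometry: layer thinner than a tip")
        e = as_extent(self.extent, 3)
        if self.layer_thickness >= e[2, 1]:
            raise ParameterError("extent must contain the terminal plane in z")
        self.extent = tuple(tuple(row) for row in e)

    @property
    def extent_array(self) -> np.ndarray:
        return np.asarray(self.extent, dtype=float)


# ---------------------------------------------------------------------------
# Termini patterns
# ---------------------------------------------------------------------------


def _triangular_lattice(a: float, extent: np.ndarray) -> np.ndarray:
    """Axis-aligned triangular lattice with constant ``a`` filling ``extent``."""
    (x0, x1), (y0, y1) = extent
    dy = a * np.sqrt(3.0) / 2.0
    rows = np.arange(y0, y1, dy)
    pts = []
    for i, y in enumerate(rows):
        xoff = 0.0 if i % 2 == 0 else a / 2.0
        xs = np.arange(x0 + xoff, x1, a)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.concatenate(pts) if pts else np.empty((0, 2))


def _matern_ii(
    d_hc: float, intensity: float, extent: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Matern type-II hard-core thinning of a Poisson proposal process.

    A proposal point survives iff no other proposal within the hard-core
    distance carries a smaller uniform mark.  Simulated on the extent
    expanded by one hard-core distance to avoid edge bias, then clipped.
    """
    lo = extent[:, 0] - d_hc
    hi = extent[:, 1] + d_hc
    area = np.prod(hi - lo)
    n = rng.poisson(intensity * area)
    pts = rng.uniform(lo, hi, size=(n, 2))
    marks = rng.uniform(size=n)
    tree = cKDTree(pts)
    keep = np.ones(n, dtype=bool)
    for i, j in tree.query_pairs(d_hc):
        if marks[i] < marks[j]:
            keep[j] = False
        else:
            keep[i] = False
    pts = pts[keep]
    inside = np.all((pts >= extent[:, 0]) & (pts < extent[:, 1]), axis=1)
    return pts[inside]


def _brute_mean_nn(points: np.ndarray) -> float:
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(d[:, 1].mean())


def spacing_factor(regime: str, jitter_ratio: float = 0.0) -> float:
    """Dimensionless ratio (mean NN spacing) / (length parameter).

    For the lattice-based regimes the length parameter is the lattice
    constant; for ``liquid`` it is the hard-core diameter.  Estimated once
    per (regime, jitter ratio) from a large unit-parameter simulation with
    a fixed internal seed, then cached.  Zero-jitter lattices are exact.
    """
    if regime not in REGIMES:
        raise ParameterError(f"unknown regime '{regime}'")
    if regime != "liquid" and jitter_ratio == 0.0:
        return 1.0
    key = (regime, round(float(jitter_ratio), 5))
    if key in _spacing_factor_cache:
        return _spacing_factor_cache[key]
    rng = np.random.default_rng(_CALIBRATION_SEED)
    ext = np.array([[0.0, 70.0], [0.0, 70.0]])
    if regime == "liquid":
        pts = _matern_ii(1.0, _MATERN_C, ext, rng)
    else:
        pts = _triangular_lattice(1.0, ext)
        pts = pts + rng.normal(0.0, jitter_ratio, size=pts.shape)
    factor = _brute_mean_nn(pts)
    _spacing_factor_cache[key] = factor
    return factor


def generate_termini_pattern(
    regime: str,
    mean_spacing: float,
    jitter_sd: float,
    extent,
    seed: int,
    min_points: int = 25,
) -> TerminiPattern:
    """Generate a 2D termini pattern with a requested mean NN spacing.

    Parameters
    ----------
    regime:
        'hexagonal', 'liquid_crystal' or 'liquid'.
    mean_spacing:
        Target ground-truth mean nearest-neighbor spacing in nm.
    jitter_sd:
        Isotropic Gaussian displacement sd in nm (lattice regimes).  Applied
        self-similarly: the jitter actually used is
        ``(jitter_sd / mean_spacing) * lattice_constant`` so that the
        calibration factor is exact under rescaling.  Ignored for the
        hard-core 'liquid' regime (recorded in ``meta``).
    extent:
        2D half-open box, each side >= 10 * mean_spacing.
    seed:
        Pattern seed (jitter / thinning draws).
    """
    if mean_spacing <= 0:
        raise ParameterError("mean_spacing must be > 0")
    if jitter_sd < 0 or jitter_sd >= mean_spacing:
        raise ParameterError("jitter_sd must be in [0, mean_spacing)")
    ext = as_extent(extent, 2)
    sides = ext[:, 1] - ext[:, 0]
    if np.any(sides < 10 * mean_spacing):
        raise DegenerateExtentError(
            "extent must span at least 10 * mean_spacing per side"
        )
    capacity = np.prod(sides) / (mean_spacing**2 * np.sqrt(3) / 2)
    if capacity < min_points:
        raise DegenerateExtentError(
            f"extent holds ~{capacity:.0f} points; need >= {min_points}"
        )
    if regime == "hexagonal" and jitter_sd > 0.1 * mean_spacing:
        raise ParameterError("hexagonal regime requires jitter sd <= 0.1 * spacing")

    rng = child_rng(seed, f"termini/{regime}")
    meta = {"target_mean_nn": float(mean_spacing), "regime": regime}
    if regime == "liquid":
        factor = spacing_factor("liquid")
        d_hc = mean_spacing / factor
        pts = _matern_ii(d_hc, _MATERN_C / d_hc**2, ext, rng)
        meta.update(hard_core_diameter=d_hc, jitter_sd=0.0, spacing_factor=factor)
    else:
        ratio = jitter_sd / mean_spacing
        factor = spacing_factor(regime, ratio)
        a = mean_spacing / factor
        jitter_used = ratio * a
        pts = _triangular_lattice(a, ext)
        if jitter_used > 0:
            pts = pts + rng.normal(0.0, jitter_used, size=pts.shape)
        inside = np.all((pts >= ext[:, 0]) & (pts < ext[:, 1]), axis=1)
        pts = pts[inside]
        meta.update(
            lattice_constant=a, jitter_sd=jitter_used, spacing_factor=factor
        )
    if len(pts) < min_points:
        raise DegenerateExtentError(
            f"pattern holds {len(pts)} points; need >= {min_points}"
        )
    return TerminiPattern(
        points=pts, extent=ext, regime_label=regime, seed=seed, meta=meta
    )


def generate_csr_pattern(intensity: float, extent, seed: int) -> TerminiPattern:
    """Homogeneous Poisson (CSR) pattern: the null model for spacing stats."""
    if intensity <= 0:
        raise ParameterError("intensity must be > 0")
    ext = as_extent(extent, 2)
    rng = child_rng(seed, "termini/csr")
    n = rng.poisson(intensity * np.prod(ext[:, 1] - ext[:, 0]))
    pts = rng.uniform(ext[:, 0], ext[:, 1], size=(n, 2))
    return TerminiPattern(
        points=pts,
        extent=ext,
        regime_label="csr",
        seed=seed,
        meta={"intensity": float(intensity)},
    )


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------


def _anchor_lattice(params: GeneratorParams, rng, n_tips: Optional[int]) -> np.ndarray:
    ext = params.extent_array
    xy = _triangular_lattice(params.microvillus_spacing, ext[:2])
    if n_tips is not None:
        if len(xy) < n_tips:
            raise ParameterError(
                f"extent holds only {len(xy)} tips; {n_tips} requested"
            )
        center = ext[:2].mean(axis=1)
        order = np.argsort(np.linalg.norm(xy - center, axis=1), kind="stable")
        xy = xy[order[:n_tips]]
    if params.anchor_xy_jitter_frac > 0:
        xy = xy + rng.normal(
            0.0,
            params.anchor_xy_jitter_frac * params.microvillus_spacing,
            size=xy.shape,
        )
        xy = np.clip(xy, ext[:2, 0], np.nextafter(ext[:2, 1], -np.inf))
    z = rng.normal(0.0, params.layer_thickness_sd, size=len(xy))
    z = np.clip(z, ext[2, 0], params.layer_thickness / 2)
    return np.column_stack([xy, z])


def _assign_termini(
    anchors_xy: np.ndarray,
    fil_tip: np.ndarray,
    termini_xy: np.ndarray,
    merge_fraction: float,
    rng,
) -> Tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-available assignment of filaments to termini.

    Returns (terminus index per filament, merge-host filament per filament
    or -1).  A ``merge_fraction`` share of filaments does not claim its own
    terminus but merges with the nearest already-assigned filament's.
    Filaments that find no free terminus within a local search radius also
    merge — multiple filaments converging on one globular tip, which is why
    replica filament counts underestimate the filament number.
    """
    n_fil = len(fil_tip)
    n_merge = int(round(merge_fraction * n_fil))
    order = rng.permutation(n_fil)
    primary, merged = order[: n_fil - n_merge], order[n_fil - n_merge :]
    tree = cKDTree(termini_xy)
    assigned = np.full(n_fil, -1, dtype=int)
    host = np.full(n_fil, -1, dtype=int)
    taken_by = np.full(len(termini_xy), -1, dtype=int)
    k_cap = min(64, len(termini_xy))  # local search only; beyond it, merge
    natural_merges = []
    for fi in primary:
        a = anchors_xy[fil_tip[fi]]
        k = 1
        placed = False
        while k < k_cap:
            k = min(2 * k, k_cap)
            _, idx = tree.query(a, k=k)
            idx = np.atleast_1d(idx)
            free = idx[taken_by[idx] < 0]
            if len(free):
                assigned[fi] = free[0]
                taken_by[free[0]] = fi
                placed = True
                break
        if not placed:
            natural_merges.append(fi)
    for fi in natural_merges:
        a = anchors_xy[fil_tip[fi]]
        _, idx = tree.query(a, k=min(8, len(termini_xy)))
        idx = np.atleast_1d(idx)
        taken = idx[taken_by[idx] >= 0]
        if len(taken) == 0:
            _, j = tree.query(a, k=1)
            taken = np.atleast_1d(j)
        hf = int(taken_by[taken[0]]) if taken_by[taken[0]] >= 0 else -1
        if hf < 0:
            assigned[fi] = int(taken[0])
            taken_by[taken[0]] = fi
            continue
        assigned[fi] = assigned[hf]
        host[fi] = hf
    primary_placed = np.array([fi for fi in primary if host[fi] < 0], dtype=int)
    host_tree = cKDTree(anchors_xy[fil_tip[primary_placed]])
    for fi in merged:
        _, j = host_tree.query(anchors_xy[fil_tip[fi]], k=1)
        hf = int(primary_placed[int(j)])
        assigned[fi] = assigned[hf]
        host[fi] = hf
    return assigned, host


def _bridge_path(
    a: np.ndarray,
    t: np.ndarray,
    step_nm: float,
    amplitude: float,
    rng,
    splay_fraction: float = 0.35,
) -> np.ndarray:
    """Zigzag polyline from anchor ``a`` to terminus ``t``.

    The lateral coordinates reach the terminus position within the lower
    ``splay_fraction`` of the rise (filaments interlace with neighbors
    almost immediately after emerging) and carry independent per-node
    excursions of sd ``amplitude``; both endpoints are honored exactly.
    """
    dz = t[2] - a[2]
    n = max(3, int(round(abs(dz) / step_nm)) + 1)
    s = np.linspace(0.0, 1.0, n)
    lat = np.clip(s / max(splay_fraction, 1e-6), 0.0, 1.0)
    base = np.empty((n, 3))
    base[:, 0] = a[0] + lat * (t[0] - a[0])
    base[:, 1] = a[1] + lat * (t[1] - a[1])
    base[:, 2] = a[2] + s * dz
    if amplitude > 0 and n > 2:
        # independent per-node lateral excursions of sd ~amplitude: a rough
        # zigzag (not a smooth wander) whose segments repeatedly approach
        # the neighboring filaments, as the replica side views show
        jitter = rng.normal(0.0, amplitude, size=(n, 2))
        jitter[0] = 0.0
        jitter[-1] = 0.0
        base[:, :2] += jitter
    return base


def generate_network(
    params: GeneratorParams,
    seed: Optional[int] = None,
    n_tips: Optional[int] = None,
) -> GlycocalyxNetwork:
    """Generate a ground-truth glycocalyx network.

    Stages (each on its own named child stream of ``seed``): tip anchors on
    a jittered triangular lattice with Gaussian base topography; per-tip
    filament counts; a terminal-plane termini pattern; greedy
    filament-to-terminus assignment (with optional merging); Brownian-bridge
    filament paths; lateral-contact snapping at ~``contact_rate`` contacts
    per µm; core and tip diameter draws.
    """
    seed = params.seed if seed is None else seed
    ext = params.extent_array

    rng_anchor = child_rng(seed, "network/anchors")
    anchors = _anchor_lattice(params, rng_anchor, n_tips)
    if len(anchors) == 0:
        raise ParameterError("extent holds no microvillar tips")

    rng_counts = child_rng(seed, "network/counts")
    counts = np.clip(
        np.rint(
            rng_counts.normal(
                params.filaments_per_tip_mean,
                params.filaments_per_tip_sd,
                size=len(anchors),
            )
        ),
        1,
        None,
    ).astype(int)
    fil_tip = np.repeat(np.arange(len(anchors)), counts)
    n_fil = len(fil_tip)

    termini_pattern = generate_termini_pattern(
        params.termini_regime,
        params.termini_mean_spacing,
        params.termini_jitter_sd,
        ext[:2],
        seed=int(child_rng(seed, "network/termini").integers(2**31)),
    )
    rng_assign = child_rng(seed, "network/assign")
    assigned, host = _assign_termini(
        anchors[:, :2], fil_tip, termini_pattern.points, params.merge_fraction, rng_assign
    )

    # keep only claimed termini; remap indices
    used = np.unique(assigned)
    remap = -np.ones(termini_pattern.n, dtype=int)
    remap[used] = np.arange(len(used))
    assigned = remap[assigned]
    rng_plane = child_rng(seed, "network/terminal_plane")
    termini_z = params.layer_thickness + rng_plane.normal(
        0.0, params.terminal_plane_sd, size=len(used)
    )
    termini_points = np.column_stack([termini_pattern.points[used], termini_z])

    rng_path = child_rng(seed, "network/paths")
    rng_diam = child_rng(seed, "network/diameters")
    core_d = np.clip(
        rng_diam.normal(
            params.filament_core_diameter_mean,
            params.filament_core_diameter_sd,
            size=n_fil,
        ),
        params.min_core_diameter,
        None,
    )
    filaments = []
    merge_floor = 0.7 * params.layer_thickness  # merges happen near the top
    for fi in range(n_fil):
        a = anchors[fil_tip[fi]]
        t = termini_points[assigned[fi]]
        path = _bridge_path(a, t, params.step_nm, params.zigzag_amplitude, rng_path)
        filaments.append(
            Filament(
                nodes=path,
                tip_index=int(fil_tip[fi]),
                terminus_index=int(assigned[fi]),
                core_diameter=float(core_d[fi]),
                merged_with=None,
            )
        )
    # contacts are made before merge-copying so a merged filament shares its
    # host's exact (post-snap) upper path
    merged_set = set(int(i) for i in np.nonzero(host >= 0)[0])
    contacts = _make_contacts(
        filaments, params, child_rng(seed, "network/contacts"), skip=merged_set
    )
    for fi in sorted(merged_set):
        hf = int(host[fi])
        f, h = filaments[fi], filaments[hf]
        zm = child_rng(seed, f"network/merge/{fi}").uniform(
            merge_floor, params.layer_thickness - 2 * params.step_nm
        )
        above_f = f.nodes[:, 2] >= zm
        above_h = h.nodes[:, 2] >= zm
        if above_f.any() and above_h.any():
            shared = h.nodes[above_h].copy()
            below = f.nodes[~above_f]
            join = np.vstack([below, shared]) if len(below) else shared
            join[0] = f.nodes[0]
            filaments[fi] = Filament(
                nodes=join,
                tip_index=f.tip_index,
                terminus_index=h.terminus_index,
                core_diameter=f.core_diameter,
                merged_with=hf,
            )

    rng_tip = child_rng(seed, "network/tip_diameters")
    tip_diam = np.clip(
        rng_tip.normal(
            params.tip_diameter_mean, params.tip_diameter_sd, size=len(used)
        ),
        2.0,
        None,
    )
    net = GlycocalyxNetwork(
        anchors=anchors,
        per_tip_counts=counts,
        filaments=filaments,
        contacts=contacts,
        termini_points=termini_points,
        termini_diameters=tip_diam,
        extent=ext,
        params=params,
        seed=seed,
        meta={
            "termini_pattern_meta": termini_pattern.meta,
            "n_merged": int((host >= 0).sum()),
        },
    )
    logger.info(
        "generated network: %d tips, %d filaments, %d contacts, seed=%d",
        net.n_tips,
        net.n_filaments,
        len(contacts),
        seed,
    )
    return net


def _make_contacts(filaments, params: GeneratorParams, rng, skip=frozenset()):
    """Snap node pairs of different filaments within the capture radius to
    their midpoints; subsample to ~contact_rate contacts per µm.

    Filaments listed in ``skip`` (those about to merge with a host) take no
    part in contact formation.
    """
    if params.contact_rate == 0:
        return []
    nodes = []
    owner = []
    node_idx = []
    for fi, f in enumerate(filaments):
        m = len(f.nodes)
        if m <= 2 or fi in skip:
            continue
        nodes.append(f.nodes[1 : m - 1])
        owner.append(np.full(m - 2, fi))
        node_idx.append(np.arange(1, m - 1))
    if not nodes:
        return []
    nodes = np.concatenate(nodes)
    owner = np.concatenate(owner)
    node_idx = np.concatenate(node_idx)
    tree = cKDTree(nodes)
    pairs = np.array(sorted(tree.query_pairs(params.contact_capture_radius)))
    if len(pairs) == 0:
        return []
    diff = owner[pairs[:, 0]] != owner[pairs[:, 1]]
    pairs = pairs[diff]
    total_len_um = sum(f.length for f in filaments) / 1000.0
    target = int(round(params.contact_rate * total_len_um))
    order = rng.permutation(len(pairs))
    contacts = []
    used = set()  # each node snaps at most once, so contacts stay coincident
    for k in order:
        if len(contacts) >= target:
            break
        i, j = pairs[k]
        if i in used or j in used:
            continue
        used.add(int(i))
        used.add(int(j))
        fi, fj = int(owner[i]), int(owner[j])
        ni, nj = int(node_idx[i]), int(node_idx[j])
        mid = 0.5 * (filaments[fi].nodes[ni] + filaments[fj].nodes[nj])
        filaments[fi].nodes[ni] = mid
        filaments[fj].nodes[nj] = mid
        contacts.append((fi, fj, ni, nj))
    return sorted(contacts)


# ---------------------------------------------------------------------------
# Rasterization and cross-sections
# ---------------------------------------------------------------------------


def _sample_polylines(filaments, step: float):
    """Densely resample filament polylines; returns points and per-point core radii."""
    pts, radii = [], []
    for f in filaments:
        seg = np.diff(f.nodes, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        for k in range(len(seg)):
            n = max(2, int(np.ceil(seg_len[k] / step)) + 1)
            t = np.linspace(0.0, 1.0, n, endpoint=False)
            pts.append(f.nodes[k] + t[:, None] * seg[k])
            radii.append(np.full(n, f.core_diameter / 2.0))
        pts.append(f.nodes[-1:])
        radii.append([f.core_diameter / 2.0])
    return np.concatenate(pts), np.concatenate(radii)


def rasterize_network(
    network: GlycocalyxNetwork,
    voxel_size: float,
    coating_thickness: Optional[float] = None,
    bbox=None,
    max_voxels: int = 60_000_000,
) -> LabeledVolume:
    """Rasterize filaments into a labeled volume {0 bg, 1 coating, 2 core}.

    Emulates the platinum/carbon replica cast: voxels within the core
    radius of a filament axis are core; within core radius +
    ``coating_thickness`` are coating.  ``bbox`` restricts the output to a
    sub-box (3x2, nm), which is how per-filament cross-section stacks are
    produced without rasterizing a full micrometre-scale volume.
    """
    if coating_thickness is None:
        coating_thickness = (
            network.params.coating_thickness if network.params is not None else 0.0
        )
    min_core = min(f.core_diameter for f in network.filaments)
    if voxel_size > min_core / 2.0:
        raise ResolutionError(
            f"voxel_size {voxel_size} nm too coarse for min core diameter {min_core} nm"
        )
    box = as_extent(bbox, 3) if bbox is not None else network.extent
    shape = np.ceil((box[:, 1] - box[:, 0]) / voxel_size).astype(int)
    if int(np.prod(shape)) > max_voxels:
        raise ResolutionError(
            f"requested volume of {np.prod(shape):,} voxels exceeds max_voxels; "
            "pass a smaller bbox or coarser voxel_size"
        )
    pts, radii = _sample_polylines(network.filaments, voxel_size / 2.0)
    margin = radii.max() + coating_thickness + voxel_size
    inside = np.all(
        (pts >= box[:, 0] - margin) & (pts <= box[:, 1] + margin), axis=1
    )
    pts, radii = pts[inside], radii[inside]
    data = np.zeros(shape[::-1], dtype=np.uint8)  # (nz, ny, nx)
    origin = box[:, 0] + voxel_size / 2.0
    if len(pts):
        tree = cKDTree(pts)
        xs = origin[0] + voxel_size * np.arange(shape[0])
        ys = origin[1] + voxel_size * np.arange(shape[1])
        gx, gy = np.meshgrid(xs, ys, indexing="xy")
        for iz in range(shape[2]):
            z = origin[2] + voxel_size * iz
            centers = np.column_stack(
                [gx.ravel(), gy.ravel(), np.full(gx.size, z)]
            )
            dist, idx = tree.query(centers, k=1, distance_upper_bound=margin)
            r = np.where(np.isfinite(dist), radii[np.minimum(idx, len(radii) - 1)], 0)
            lab = np.zeros(gx.size, dtype=np.uint8)
            lab[dist <= r + coating_thickness] = 1
            lab[dist <= r] = 2
            data[iz] = lab.reshape(shape[1], shape[0])
    return LabeledVolume(
        data=data,
        voxel_size=voxel_size,
        origin=origin,
        meta={
            "coating_thickness": float(coating_thickness),
            "core_diameters": [float(f.core_diameter) for f in network.filaments],
            "labels": {"0": "background", "1": "coating", "2": "core"},
        },
    )


def cross_section(network: GlycocalyxNetwork, z: float) -> TerminiPattern:
    """Intersect filaments with the plane at height ``z``.

    Returns a 2D pattern with one point per filament crossing, tagged with
    the anchor-tip identity, emulating a freeze-etch cross-fracture run
    just above the microvilli.  A plane outside the layer yields an empty
    pattern with a warning.
    """
    pts, tips = [], []
    for f in network.filaments:
        zs = f.nodes[:, 2]
        if not (zs.min() <= z <= zs.max()):
            continue
        # contact snapping can leave z mildly non-monotone; scan segments for
        # the first sign change and interpolate there
        d0, d1 = zs[:-1] - z, zs[1:] - z
        crossing = np.nonzero((d0 <= 0) & (d1 >= 0) | (d0 >= 0) & (d1 <= 0))[0]
        if len(crossing) == 0:
            continue
        k = int(crossing[0])
        z0, z1 = zs[k], zs[k + 1]
        w = 0.0 if z1 == z0 else (z - z0) / (z1 - z0)
        p = f.nodes[k] + w * (f.nodes[k + 1] - f.nodes[k])
        pts.append(p[:2])
        tips.append(f.tip_index)
    ext = network.extent[:2]
    if not pts:
        logger.warning("cross_section: plane z=%.1f nm outside the layer", z)
        return TerminiPattern(
            points=np.empty((0, 2)),
            extent=ext,
            regime_label="cross_section",
            seed=network.seed,
            meta={"z": float(z), "empty": True},
        )
    pts = np.clip(np.array(pts), ext[:, 0], np.nextafter(ext[:, 1], -np.inf))
    return TerminiPattern(
        points=pts,
        extent=ext,
        regime_label="cross_section",
        seed=network.seed,
        tip_ids=np.array(tips, dtype=int),
        meta={"z": float(z)},
    )


# ---------------------------------------------------------------------------
# Mesh calibration
# ---------------------------------------------------------------------------


def calibrate_mesh(
    target_mean_pore: float,
    params: Optional[GeneratorParams] = None,
    max_iter: int = 2,
    rel_tol: float = 0.03,
) -> Tuple[GeneratorParams, float]:
    """Scale the generator's lateral lengths so the mean side-view pore size
    equals ``target_mean_pore`` (nm).

    The zigzag network has no closed-form pore size, so calibration is by
    self-similar scaling: all lateral length parameters are multiplied by a
    common factor found by secant iteration on the measured mean opening of
    large calibration networks (internal fixed seeds).  Returns the scaled
    params and the recorded ground-truth mean pore size (the mean over all
    openings of two further calibration networks).
    """
    from .morphometry import pore_sizes  # local import to avoid a cycle

    if params is None:
        params = GeneratorParams(
            extent=((0.0, 2000.0), (0.0, 2000.0), (-500.0, 1100.0))
        )

    def scaled(p: GeneratorParams, k: float) -> GeneratorParams:
        return replace(
            p,
            microvillus_spacing=p.microvillus_spacing * k,
            termini_mean_spacing=p.termini_mean_spacing * k,
            termini_jitter_sd=p.termini_jitter_sd * k,
            zigzag_amplitude=p.zigzag_amplitude * k,
            contact_capture_radius=p.contact_capture_radius * k,
        )

    def measure(p: GeneratorParams, cal_seed: int) -> float:
        net = generate_network(p, seed=cal_seed)
        res = pore_sizes(net, n_openings=None, seed=cal_seed)
        return res.mean

    k = 1.0
    p = params
    for it in range(max_iter):
        m = measure(scaled(params, k), _CALIBRATION_SEED + it)
        if abs(m - target_mean_pore) / target_mean_pore <= rel_tol:
            break
        k *= target_mean_pore / m
    p = scaled(params, k)
    truths = [
        measure(p, _CALIBRATION_SEED + 100 + j) for j in range(2)
    ]
    ground_truth = float(np.mean(truths))
    logger.info(
        "mesh calibration: scale=%.3f, ground-truth mean pore=%.2f nm", k, ground_truth
    )
    return p, ground_truth
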