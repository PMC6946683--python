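"""Network-level morphometry: pore size, coating-corrected filament
diameters, layer thickness, filaments-per-tip counts, globular-tip
diameters.

Pore ("mesh") size follows the freeze-etch side-view protocol: the network
is projected through a thin lateral slab onto a 2D rendering, enclosed open
spaces are the connected background components, and the per-opening
statistic is the maximal distance between the filament surfaces outlining
the opening (max caliper of the void region).  Openings are sampled
uniformly at random with a seed.

Filament diameters are measured on replica-cast emulations (labeled
volumes or CoatedCrossSection records) and corrected by subtracting twice
the platinum coating thickness.
"""

from __future__ import annotations

from typing import Iterable, Optional, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from ._rng import child_rng
from .datatypes import (
    CoatedCrossSection,
    GlycocalyxNetwork,
    LabeledVolume,
    MorphometryResult,
    TerminiPattern,
)
from .exceptions import (
    CoatingModelError,
    EmptyResultError,
    GroupingError,
    ParameterError,
    TopologyError,
)

__all__ = [
    "render_side_view",
    "pore_sizes",
    "opening_diameters",
    "filament_diameters",
    "layer_thickness",
    "filaments_per_tip",
    "tip_diameters",
]


# ---------------------------------------------------------------------------
# Pore size
# ---------------------------------------------------------------------------


def render_side_view(
    network: GlycocalyxNetwork,
    pixel_size: float = 1.0,
    slab_axis: int = 1,
    slab_center: Optional[float] = None,
    slab_thickness: float = 40.0,
    z_range: Optional[tuple] = None,
) -> np.ndarray:
    """Project filaments within a thin lateral slab onto a 2D side view.

    Returns a boolean image (True = filament) in (z, lateral) orientation,
    the in-silico analog of a side-view montage of the replica.  Segments
    are drawn at their core diameter.
    """
    if slab_axis not in (0, 1):
        raise ParameterError("slab_axis must be 0 (x) or 1 (y)")
    lat_axis = 1 - slab_axis
    ext = network.extent
    if slab_center is None:
        slab_center = float(ext[slab_axis].mean())
    lo_s, hi_s = slab_center - slab_thickness / 2, slab_center + slab_thickness / 2
    if z_range is None:
        z0 = float(np.median(network.anchors[:, 2]))
        z1 = network.terminal_plane_z
    else:
        z0, z1 = z_range
    lat0, lat1 = ext[lat_axis]
    nx = int(np.ceil((lat1 - lat0) / pixel_size))
    nz = int(np.ceil((z1 - z0) / pixel_size))
    img = np.zeros((nz, nx), dtype=bool)

    def to_px(lat, z):
        return (z - z0) / pixel_size, (lat - lat0) / pixel_size  # (row, col)

    for f in network.filaments:
        nodes = f.nodes
        in_slab = (nodes[:, slab_axis] >= lo_s) & (nodes[:, slab_axis] < hi_s)
        if not in_slab.any():
            continue
        r_px = max(0.5, f.core_diameter / 2.0 / pixel_size)
        for k in range(len(nodes) - 1):
            if not (in_slab[k] or in_slab[k + 1]):
                continue
            r0, c0 = to_px(nodes[k, lat_axis], nodes[k, 2])
            r1, c1 = to_px(nodes[k + 1, lat_axis], nodes[k + 1, 2])
            d = np.hypot(r1 - r0, c1 - c0)
            if d == 0:
                rr, cc = draw_disk((r0, c0), r_px, shape=img.shape)
                img[rr, cc] = True
                continue
            # thick segment = rectangle + end caps
            nr, nc = -(c1 - c0) / d, (r1 - r0) / d
            rect_r = [r0 + nr * r_px, r1 + nr * r_px, r1 - nr * r_px, r0 - nr * r_px]
            rect_c = [c0 + nc * r_px, c1 + nc * r_px, c1 - nc * r_px, c0 - nc * r_px]
            rr, cc = draw_polygon(rect_r, rect_c, shape=img.shape)
            img[rr, cc] = True
            for r, c in ((r0, c0), (r1, c1)):
                rr, cc = draw_disk((r, c), r_px, shape=img.shape)
                img[rr, cc] = True
    return img


def _component_caliper(coords: np.ndarray) -> float:
    """Maximal pairwise distance among component pixel centers (px units)."""
    if len(coords) <= 2:
        return float(
            np.max(np.linalg.norm(coords - coords[0], axis=1)) if len(coords) else 0.0
        )
    try:
        hull = ConvexHull(coords)
        v = coords[hull.vertices]
    except QhullError:
        v = coords
    d2 = np.sum((v[:, None, :] - v[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def opening_diameters(
    filament_image: np.ndarray,
    pixel_size: float = 1.0,
    min_area_px: int = 9,
    neck_depth_px: float = 2.0,
) -> np.ndarray:
    """Max-caliper diameters (nm) of the enclosed openings in a 2D rendering.

    An *opening* is a watershed basin of the void's distance transform: a
    pocket of open space bounded by filaments, separated from its neighbors
    at constrictions deeper than ``neck_depth_px`` — the way locally
    identifiable open spaces are picked out by eye.  Compact voids (e.g.
    grid cells) are single basins, so the designed-grid diagonal identity
    is untouched, while a long irregular corridor decomposes into its
    pockets.  Basins touching the image border are unbounded and skipped.
    One pixel is added to each caliper: void-pixel centers sit half a pixel
    from the bounding filament surface on either side.
    """
    from skimage.morphology import h_maxima
    from skimage.segmentation import watershed

    void = ~np.asarray(filament_image, dtype=bool)
    if not void.any():
        return np.array([])
    edt = ndimage.distance_transform_edt(void)
    markers, n = ndimage.label(h_maxima(edt, neck_depth_px))
    if n == 0:
        return np.array([])
    labels = watershed(-edt, markers, mask=void)
    border = set(
        np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        ).tolist()
    ) - {0}
    out = []
    objs = ndimage.find_objects(labels)
    for lab in range(1, int(labels.max()) + 1):
        sl = objs[lab - 1]
        if sl is None or lab in border:
            continue
        ys, xs = np.nonzero(labels[sl] == lab)
        if len(ys) < min_area_px:
            continue
        coords = np.column_stack([ys + sl[0].start, xs + sl[1].start]).astype(float)
        out.append((_component_caliper(coords) + 1.0) * pixel_size)
    return np.asarray(out)


def pore_sizes(
    source: Union[GlycocalyxNetwork, np.ndarray],
    n_openings: Optional[int] = 101,
    seed: int = 0,
    pixel_size: float = 1.0,
    slab_thickness: float = 60.0,
    min_area_px: int = 9,
) -> MorphometryResult:
    """Mesh/pore size: maximal surface-to-surface distance across randomly
    selected enclosed openings of the network rendering.

    ``source`` may be a network (rendered via :func:`render_side_view` on
    two perpendicular mid-layer slabs — the interlaced network proper,
    excluding the inter-microvillar splay region near the base) or a
    pre-rendered 2D boolean filament image.  ``n_openings=None`` measures
    every enclosed opening.
    """
    warnings = []
    if isinstance(source, GlycocalyxNetwork):
        z_top = source.terminal_plane_z
        z_range = (0.3 * z_top, z_top - 50.0)
        imgs = [
            render_side_view(
                source,
                pixel_size=pixel_size,
                slab_axis=ax,
                slab_thickness=slab_thickness,
                z_range=z_range,
            )
            for ax in (0, 1)
        ]
        mode = "projection(network)"
    else:
        imgs = [np.asarray(source, dtype=bool)]
        mode = "projection(image)"
    diam = np.concatenate(
        [opening_diameters(img, pixel_size, min_area_px) for img in imgs]
    )
    if len(diam) == 0:
        raise TopologyError("no enclosed openings found in the rendering")
    if n_openings is not None:
        rng = child_rng(seed, "morphometry/pore_openings")
        if n_openings > len(diam):
            warnings.append(
                f"only {len(diam)} openings available; sampling with replacement"
            )
            idx = rng.choice(len(diam), size=n_openings, replace=True)
        else:
            idx = rng.choice(len(diam), size=n_openings, replace=False)
        diam = diam[idx]
    return MorphometryResult.from_samples(
        "pore_size",
        diam,
        params={
            "mode": mode,
            "pixel_size": pixel_size,
            "slab_thickness": slab_thickness,
            "n_openings": n_openings,
            "seed": seed,
        },
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Filament diameter with coating correction
# ---------------------------------------------------------------------------


def _outer_diameter_from_volume(vol: LabeledVolume) -> float:
    """Outer (coated) diameter at the central cross-section of a labeled
    volume: area-equivalent circle diameter of the filled region, which is
    unbiased at finite voxel size for the near-circular sections produced
    by the replica emulation (a max-inscribed-circle reading carries a
    systematic negative bias of over a voxel from center sampling)."""
    mid = vol.data.shape[0] // 2
    plane = vol.data[mid] > 0
    if not plane.any():
        raise EmptyResultError("empty cross-section slice")
    area = float(plane.sum()) * vol.voxel_size**2
    return float(2.0 * np.sqrt(area / np.pi))


def filament_diameters(
    sections: Union[Iterable[LabeledVolume], Iterable[CoatedCrossSection]],
    coating_thickness: float,
) -> MorphometryResult:
    """Core filament diameters after subtracting twice the coating thickness.

    For labeled volumes the outer diameter is measured at the central slice
    (max inscribed circle); for :class:`CoatedCrossSection` records the
    stored measured value is used.  Non-physical (<= 0) corrected values are
    excluded with a warning; more than 10% of them indicates a wrong
    coating model and raises :class:`CoatingModelError`.
    """
    if coating_thickness < 0:
        raise ParameterError("coating_thickness must be >= 0")
    outers = []
    for s in sections:
        if isinstance(s, LabeledVolume):
            outers.append(_outer_diameter_from_volume(s))
        elif isinstance(s, CoatedCrossSection):
            outers.append(float(s.measured_outer_diameter))
        else:
            raise ParameterError(f"unsupported section type {type(s)!r}")
    outers = np.asarray(outers)
    if outers.size == 0:
        raise EmptyResultError("no cross-sections provided")
    core = outers - 2.0 * coating_thickness
    bad = core <= 0
    warnings = []
    if bad.any():
        if bad.mean() > 0.10:
            raise CoatingModelError(
                f"{bad.sum()}/{len(core)} sections have outer <= 2*coating; "
                "coating model inconsistent with the data"
            )
        warnings.append(f"excluded {int(bad.sum())} non-physical corrected diameters")
    return MorphometryResult.from_samples(
        "filament_diameter",
        core[~bad],
        params={"coating_thickness": coating_thickness, "n_input": int(len(core))},
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Layer geometry and counts
# ---------------------------------------------------------------------------


def layer_thickness(
    network: GlycocalyxNetwork, n_profiles: int = 53, seed: int = 0
) -> MorphometryResult:
    """Layer thickness at random lateral positions: terminal-plane height
    minus the local microvillar tip-anchor height."""
    if network.n_tips == 0:
        raise EmptyResultError("network has no tips")
    if n_profiles < 1:
        raise EmptyResultError("n_profiles must be >= 1")
    rng = child_rng(seed, "morphometry/thickness_profiles")
    z_term = network.terminal_plane_z
    replace = n_profiles > network.n_tips
    idx = rng.choice(network.n_tips, size=n_profiles, replace=replace)
    thickness = z_term - network.anchors[idx, 2]
    return MorphometryResult.from_samples(
        "layer_thickness",
        thickness,
        params={"n_profiles": n_profiles, "seed": seed},
        warnings=(["sampled tips with replacement"] if replace else []),
    )


def filaments_per_tip(
    section: TerminiPattern, dedup_tolerance: float = 0.0
) -> MorphometryResult:
    """Filament count per microvillar tip from a cross-section pattern.

    With ``dedup_tolerance > 0``, points closer than the tolerance (nm)
    within the same tip group are counted once — the resolution-limited
    counting that makes replica counts an underestimate when filaments have
    merged.  The default (0) counts every crossing.
    """
    if section.tip_ids is None:
        raise GroupingError("cross-section pattern has no tip identities")
    if section.n == 0:
        raise EmptyResultError("empty cross-section")
    counts = []
    for tip in np.unique(section.tip_ids):
        pts = section.points[section.tip_ids == tip]
        if dedup_tolerance <= 0 or len(pts) == 1:
            counts.append(len(pts))
            continue
        # cluster points within the tolerance (union-find over close pairs)
        tree = cKDTree(pts)
        parent = np.arange(len(pts))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in tree.query_pairs(dedup_tolerance):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        counts.append(len({find(i) for i in range(len(pts))}))
    return MorphometryResult.from_samples(
        "filaments_per_tip",
        counts,
        params={"dedup_tolerance": dedup_tolerance, "z": section.meta.get("z")},
    )


def tip_diameters(
    network: GlycocalyxNetwork, n: int = 82, seed: int = 0
) -> MorphometryResult:
    """Globular-terminus diameters sampled from the terminal plane."""
    if n <= 0:
        raise EmptyResultError("n must be >= 1")
    m = len(network.termini_diameters)
    if m == 0:
        raise EmptyResultError("network has no termini")
    rng = child_rng(seed, "morphometry/tip_diameters")
    idx = rng.choice(m, size=n, replace=n > m)
    return MorphometryResult.from_samples(
        "tip_diameter",
        network.termini_diameters[idx],
        params={"n": n, "seed": seed},
        warnings=(["sampled termini with replacement"] if n > m else []),
    )
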