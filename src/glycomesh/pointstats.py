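"""Spacing and order statistics on termini point patterns.

Implements the four estimators used to quantify terminal-plane packing:

* nearest-neighbor distances with a Gaussian fit to the histogram,
* radial distribution function g(r) with border edge-correction and
  first-peak spacing,
* image-autocorrelation spacing (FFT of a rendered point image, radially
  averaged),
* sixfold bond-orientational order (psi6 over Delaunay neighborhoods) with
  an FFT sixfold-spot ratio and a packing-regime call.

Nearest-neighbor spacing measures the *minimum* inter-point distance per
point and is systematically smaller than the *average*-spacing measures
(RDF first peak, autocorrelation first off-peak) on disordered patterns —
the reason the three estimators legitimately disagree on the same pattern.

Edge handling: NN reference points within ``edge_buffer`` of the boundary
are excluded (their neighbors may lie in the buffer); RDF reference points
must be at least ``r_max`` from the boundary while all points count as
neighbors.  Buffers apply per dimension only where the extent side is
longer than four buffers, so thin (quasi-planar) 3D patterns are not
emptied by their z-extent.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from scipy.spatial import Delaunay, QhullError, cKDTree

from .datatypes import (
    AutocorrResult,
    NNResult,
    OrderMetrics,
    RDFResult,
    TerminiPattern,
)
from .exceptions import (
    EmptyResultError,
    InsufficientDataError,
    ParameterError,
    ResolutionError,
    TriangulationError,
)

__all__ = [
    "nearest_neighbor_stats",
    "radial_distribution",
    "autocorrelation_spacing",
    "hexagonal_order",
]


def _interior_mask(points: np.ndarray, extent: np.ndarray, buffer: float) -> np.ndarray:
    """Points at least ``buffer`` from the lateral boundary.  The buffer
    always applies to x and y; the z side of a quasi-planar 3D pattern is
    exempt when thinner than four buffers (it would exclude everything)."""
    mask = np.ones(len(points), dtype=bool)
    if buffer <= 0:
        return mask
    for d in range(points.shape[1]):
        lo, hi = extent[d]
        if d >= 2 and (hi - lo) <= 4 * buffer:
            continue
        mask &= (points[:, d] >= lo + buffer) & (points[:, d] < hi - buffer)
    return mask


def _freedman_diaconis_edges(x: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        width = max(np.ptp(x), 1e-9) / 10 or 1e-9
    else:
        width = 2 * iqr / len(x) ** (1 / 3)
    lo, hi = x.min(), x.max()
    nbins = max(1, int(np.ceil((hi - lo) / width)))
    return np.linspace(lo, hi + 1e-9, nbins + 1)


def _fit_gaussian(edges: np.ndarray, counts: np.ndarray) -> Tuple[float, float]:
    """Least-squares fit of a Gaussian to a histogram (the histogram-overlay
    convention, not sample MLE)."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum() * np.diff(edges).mean()
    density = counts / total if total > 0 else counts

    mu0 = float(np.average(centers, weights=np.maximum(counts, 1e-12)))
    sd0 = float(
        np.sqrt(np.average((centers - mu0) ** 2, weights=np.maximum(counts, 1e-12)))
    )
    if sd0 <= 0 or len(centers) < 3:
        return mu0, max(sd0, 0.0)

    def gauss(x, a, mu, sigma):
        return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    try:
        import warnings as _warnings

        from scipy.optimize import OptimizeWarning

        with _warnings.catch_warnings():
            # a near-point-mass histogram fits perfectly with a singular
            # covariance; the parameters are still the right answer
            _warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                gauss,
                centers,
                density,
                p0=[density.max(), mu0, sd0],
                maxfev=5000,
            )
        return float(popt[1]), float(abs(popt[2]))
    except RuntimeError:
        return mu0, sd0


def nearest_neighbor_stats(
    pattern: TerminiPattern, edge_buffer: float = 0.0
) -> NNResult:
    """Per-point nearest-neighbor distances with mean, sd, histogram and
    Gaussian fit.

    Reference points within ``edge_buffer`` of the boundary are excluded;
    all points (including buffered ones) remain available as neighbors.
    """
    pts = pattern.points
    if len(pts) < 2:
        raise InsufficientDataError("need at least 2 points for NN statistics")
    mask = _interior_mask(pts, pattern.extent, edge_buffer)
    if not mask.any():
        raise EmptyResultError("edge buffer excluded every point")
    tree = cKDTree(pts)
    d, _ = tree.query(pts[mask], k=2)
    nn = d[:, 1]
    if np.any(nn == 0):
        nn = nn[nn > 0]
        if len(nn) == 0:
            raise EmptyResultError("all nearest-neighbor distances are zero")
    edges = _freedman_diaconis_edges(nn)
    counts, edges = np.histogram(nn, bins=edges)
    mu, sigma = _fit_gaussian(edges, counts)
    return NNResult(
        nn_distances=nn,
        mean=float(nn.mean()),
        sd=float(nn.std(ddof=1)) if len(nn) > 1 else 0.0,
        n=int(len(nn)),
        hist_edges=edges,
        hist_counts=counts,
        gaussian_mu=mu,
        gaussian_sigma=sigma,
        edge_buffer=float(edge_buffer),
    )


def _quadratic_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through (x[i-1..i+1], y[i-1..i+1]); falls back
    to x[i] at array edges or degenerate curvature.  Ties break to smaller r
    because the *first* qualifying maximum index is used upstream."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:
        return float(x[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(x[i] + delta * (x[1] - x[0]))


def radial_distribution(
    pattern: TerminiPattern, bin_width: float, r_max: float
) -> RDFResult:
    """Radial distribution function with border edge-correction.

    Reference points lie at least ``r_max`` from every (wide) boundary; all
    points serve as neighbors.  g(r) is normalized by the global density so
    a CSR pattern gives g ~ 1.  ``first_peak_r`` is the first local maximum
    of g above 1, refined by 3-point quadratic interpolation.
    """
    pts = pattern.points
    ext = pattern.extent
    dim = pattern.dimensionality
    # lateral (x, y) sides bound r_max; a thin z side of a quasi-planar 3D
    # pattern does not take part in the border correction
    if r_max > min(ext[d, 1] - ext[d, 0] for d in range(2)) / 2:
        raise ParameterError("r_max must be at most half the shortest lateral side")
    if bin_width > r_max / 20:
        raise ParameterError("bin_width must be <= r_max / 20")
    refs = pts[_interior_mask(pts, ext, r_max)]
    if len(refs) < 30:
        raise InsufficientDataError(
            f"only {len(refs)} interior reference points (need >= 30)"
        )
    volume = np.prod(ext[:, 1] - ext[:, 0])
    density = len(pts) / volume
    tree = cKDTree(pts)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-9]
    pairs = tree.query_ball_point(refs, r_max)
    dists = []
    for i, neigh in enumerate(pairs):
        p = refs[i]
        q = pts[neigh]
        d = np.linalg.norm(q - p, axis=1)
        dists.append(d[d > 0])
    dists = np.concatenate(dists) if dists else np.array([])
    counts, edges = np.histogram(dists, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if dim == 2:
        shell = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    else:
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = len(refs) * density * shell
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(expected > 0, counts / expected, 0.0)

    first_peak = np.nan
    warnings = []
    # peak detection on a lightly smoothed profile with a prominence floor
    # (halfway between 1 and the maximum) and a minimum pair support, so
    # neither noise hovering above 1 nor single close pairs at small r
    # (whose tiny shell areas blow g up) are mistaken for the peak
    gs = np.convolve(g, np.ones(3) / 3.0, mode="same")
    cs = np.convolve(counts.astype(float), np.ones(3), mode="same")
    supported = cs >= 5
    gmax = gs[supported].max() if supported.any() else gs.max()
    floor = 1.0 + 0.5 * max(gmax - 1.0, 0.0)
    for i in range(1, len(gs) - 1):
        if (
            supported[i]
            and gs[i] > floor
            and gs[i] >= gs[i - 1]
            and gs[i] >= gs[i + 1]
        ):
            first_peak = _quadratic_peak(centers, gs, i)
            break
    if np.isnan(first_peak):
        warnings.append("no g(r) peak above 1 found within r_max")
    return RDFResult(
        r=centers,
        g=g,
        first_peak_r=float(first_peak),
        bin_width=float(bin_width),
        edge_correction="border",
        n_reference=int(len(refs)),
        warnings=warnings,
    )


def _render(points: np.ndarray, extent: np.ndarray, px: float, sigma_px: float = 1.2):
    shape = np.ceil((extent[:, 1] - extent[:, 0]) / px).astype(int)
    img = np.zeros(shape[::-1], dtype=float)  # (ny, nx)
    ij = np.floor((points - extent[:, 0]) / px).astype(int)
    ij = np.clip(ij, 0, shape - 1)
    np.add.at(img, (ij[:, 1], ij[:, 0]), 1.0)
    if sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma_px)
    return img


def autocorrelation_spacing(
    pattern: TerminiPattern, render_px: float = 1.0
) -> AutocorrResult:
    """Characteristic spacing from the radially averaged autocorrelation of
    a rendered point image.

    The pattern (projected to 2D if 3D) is rendered as a slightly smoothed
    binary dot image at ``render_px`` nm/pixel; its autocorrelation is
    computed by FFT, radially averaged about zero lag, and the first local
    maximum beyond the central peak is reported.  A degenerate pattern
    (fewer than 2 points) yields ``first_offpeak_r = nan`` with a warning
    flag rather than an exception.
    """
    p2 = pattern.project()
    pts = p2.points
    warnings = []
    if len(pts) >= 2:
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        mean_nn = float(d[:, 1][d[:, 1] > 0].mean())
        if render_px > mean_nn / 4:
            raise ResolutionError(
                f"render_px {render_px} nm exceeds mean spacing/4 ({mean_nn / 4:.2f} nm)"
            )
    img = _render(pts, p2.extent, render_px)
    ny, nx = img.shape
    pad_y, pad_x = 2 * ny, 2 * nx
    F = np.fft.rfft2(img - img.mean(), s=(pad_y, pad_x))
    acf = np.fft.irfft2(np.abs(F) ** 2, s=(pad_y, pad_x))
    acf = np.fft.fftshift(acf)
    cy, cx = pad_y // 2, pad_x // 2
    # radial average in whole-pixel annuli
    yy, xx = np.ogrid[:pad_y, :pad_x]
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    rbin = rr.astype(int)
    r_lim = min(cy, cx)
    flat_r = rbin.ravel()
    sel = flat_r < r_lim
    sums = np.bincount(flat_r[sel], weights=acf.ravel()[sel], minlength=r_lim)
    cnts = np.bincount(flat_r[sel], minlength=r_lim)
    profile = sums / np.maximum(cnts, 1)
    r_nm = np.arange(r_lim) * render_px

    first = np.nan
    if len(pts) < 2:
        warnings.append("degenerate pattern: no off-origin autocorrelation peak")
    else:
        smooth = np.convolve(profile, np.ones(3) / 3.0, mode="same")
        # step past the central peak to its first minimum
        i = 1
        while i < r_lim - 1 and smooth[i + 1] <= smooth[i]:
            i += 1
        if i + 1 < r_lim:
            tail = smooth[i:]
            baseline = float(np.median(tail))
            prominence = float(tail.max() - baseline)
            thresh = baseline + 0.25 * prominence
            # first local maximum with meaningful prominence
            for j in range(i + 1, r_lim - 1):
                if (
                    smooth[j] >= thresh
                    and smooth[j] >= smooth[j - 1]
                    and smooth[j] >= smooth[j + 1]
                ):
                    first = _quadratic_peak(r_nm, smooth, j)
                    break
        if np.isnan(first):
            warnings.append("no off-origin autocorrelation peak found")
    if np.argmax(profile) != 0:
        warnings.append("autocorrelation maximum not at zero lag")
    return AutocorrResult(
        r=r_nm,
        profile=profile,
        first_offpeak_r=float(first),
        render_px=float(render_px),
        warnings=warnings,
    )


def _fft_sixfold_ratio(points: np.ndarray, extent: np.ndarray, px: float) -> float:
    """Power in the six first-order Bragg spots over the azimuthal-mean power
    at the same ring radius."""
    img = _render(points, extent, px, sigma_px=1.0)
    n = 1 << int(np.ceil(np.log2(max(img.shape))))
    F = np.fft.fftshift(np.abs(np.fft.fft2(img - img.mean(), s=(n, n))) ** 2)
    c = n // 2
    yy, xx = np.ogrid[:n, :n]
    rr = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    rbin = rr.astype(int)
    r_lim = c
    sums = np.bincount(rbin.ravel()[rbin.ravel() < r_lim], weights=F.ravel()[rbin.ravel() < r_lim], minlength=r_lim)
    cnts = np.bincount(rbin.ravel()[rbin.ravel() < r_lim], minlength=r_lim)
    radial = sums / np.maximum(cnts, 1)
    if r_lim < 8:
        return 0.0
    ring = 3 + int(np.argmax(radial[3:]))
    band = (rr >= ring - 1.5) & (rr <= ring + 1.5)
    theta = np.arctan2(yy - c, xx - c)[band] % (2 * np.pi)
    power = F[band]
    nbins = 72
    tb = np.minimum((theta / (2 * np.pi) * nbins).astype(int), nbins - 1)
    prof = np.bincount(tb, weights=power, minlength=nbins) / np.maximum(
        np.bincount(tb, minlength=nbins), 1
    )
    mean_p = prof.mean()
    if mean_p <= 0:
        return 0.0
    # best sixfold comb of sectors
    best = 0.0
    for off in range(nbins // 6):
        comb = prof[off :: nbins // 6].mean()
        best = max(best, comb)
    return float(best / mean_p)


def hexagonal_order(
    pattern: TerminiPattern,
    thresholds: Tuple[float, float] = (0.35, 0.7),
    render_px: float = 2.0,
) -> OrderMetrics:
    """Sixfold bond-orientational order and packing-regime classification.

    psi6 = |mean over interior points of (mean over Delaunay neighbors of
    exp(6 i theta))|: 1 for a perfect triangular lattice, ~0 for a liquid.
    Convex-hull vertices are excluded as reference points (their Delaunay
    neighborhoods are boundary artifacts).  The regime call uses
    ``thresholds`` (liquid < lo <= liquid_crystal < hi <= hexagonal), which
    are conventions calibrated on the generator and overridable.
    """
    p2 = pattern.project()
    pts = p2.points
    if len(pts) < 30:
        raise InsufficientDataError("need >= 30 points for hexagonal order")
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise TriangulationError(f"Delaunay triangulation failed: {e}") from e
    indptr, indices = tri.vertex_neighbor_vertices
    hull = set(tri.convex_hull.ravel().tolist())
    psi = []
    for i in range(len(pts)):
        if i in hull:
            continue
        neigh = indices[indptr[i] : indptr[i + 1]]
        if len(neigh) == 0:
            continue
        vec = pts[neigh] - pts[i]
        theta = np.arctan2(vec[:, 1], vec[:, 0])
        psi.append(np.exp(6j * theta).mean())
    if not psi:
        raise InsufficientDataError("no interior points for psi6")
    psi6 = float(abs(np.mean(psi)))
    ratio = _fft_sixfold_ratio(pts, p2.extent, render_px)
    lo, hi = thresholds
    if psi6 >= hi:
        call = "hexagonal"
    elif psi6 >= lo:
        call = "liquid_crystal"
    else:
        call = "liquid"
    return OrderMetrics(
        psi6=psi6,
        fft_sixfold_ratio=ratio,
        regime_call=call,
        thresholds=thresholds,
        n_interior=len(psi),
    )
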