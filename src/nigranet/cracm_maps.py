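"""Circuit-mapping (CRACM) geometry and statistics.

Photostimulation grids recorded in slice coordinates are rotated, flipped
and aspect-normalized into a common anatomical reference frame for the
substantia nigra: 1670 um wide x 1000 um tall, origin at the dorso-medial
corner, +x medial->lateral (coronal) or rostral->caudal (sagittal), +y
dorsal->ventral. All spatial statistics — smoothed input maps, isocontours,
centers of mass, map-vs-map correlation as a function of inter-soma
distance, overlap with afferent axon density, cumulative spatial falloff —
operate in that frame.

Also here: the convergence worked examples (unitary-count estimate from
maximal evoked conductance, convergence radius from neuron density and
connection probability) and the conduction-velocity regression of IPSC
latency on stimulation distance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from skimage import measure

from .errors import (
    AnnotationError,
    InvalidSpecError,
    InsufficientDataError,
    ResampleRequiredError,
)

SN_WIDTH = 1670.0   # um
SN_HEIGHT = 1000.0  # um
SN_ASPECT = SN_WIDTH / SN_HEIGHT
RASTER = 10.0       # um per raster pixel for smoothed images


@dataclass
class StimGrid:
    """Rectangular lattice of stimulation sites.

    sites : (n, 2) um coordinates, row-major order with respect to ``shape``.
    dorsal_edge / medial_edge : site-index lists annotating two
        perpendicular edges of the lattice (used to orient the grid).
    """

    sites: np.ndarray
    shape: tuple
    dorsal_edge: list
    medial_edge: list
    plane: str = "coronal"

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=float)
        if self.sites.shape != (self.shape[0] * self.shape[1], 2):
            raise InvalidSpecError("site count does not match grid shape")


@dataclass
class ResponseMap:
    """Per-site evoked response amplitudes (pA, rectified >= 0) + latencies."""

    amplitudes: np.ndarray
    latencies: np.ndarray
    soma: np.ndarray
    v_hold: float = 20.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.latencies = np.asarray(self.latencies, dtype=float)
        self.soma = np.asarray(self.soma, dtype=float)


@dataclass
class DendriteSkeleton:
    """Dendritic arbor as nodes + segments with per-segment width (um)."""

    nodes: np.ndarray          # (n, 2) um
    edges: np.ndarray          # (m, 2) int node indices
    widths: np.ndarray         # (m,) um

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        self.widths = np.asarray(self.widths, dtype=float)
        if np.any(self.widths <= 0):
            raise InvalidSpecError("segment widths must be positive")


@dataclass(frozen=True)
class AffineTransform:
    """p -> A p + b, the grid-alignment map (also applied to somata etc.)."""

    matrix: np.ndarray
    offset: np.ndarray

    def apply(self, points) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ np.asarray(self.matrix).T + np.asarray(self.offset)
        return out[0] if np.asarray(points).ndim == 1 else out


IDENTITY = AffineTransform(np.eye(2), np.zeros(2))


def _edge_index_sets(shape):
    rows, cols = shape
    idx = np.arange(rows * cols).reshape(rows, cols)
    return {
        "row0": idx[0, :], "rowN": idx[-1, :],
        "col0": idx[:, 0], "colN": idx[:, -1],
    }


def align_grid(grid: StimGrid) -> tuple[StimGrid, AffineTransform]:
    """Rotate/flip/stretch a grid into the SN reference frame.

    The annotated dorsal edge ends up along the top (+x direction at y = 0)
    and the medial edge along the left (+y at x = 0); the lattice is then
    anisotropically scaled about its centroid to the reference aspect ratio
    (width/height = 1.67) and translated so the dorso-medial corner sits at
    the origin. Returns the aligned grid (site order unchanged) and the
    affine transform, which must also be applied to soma positions and
    dendrite skeletons recorded with that grid.
    """
    edges = _edge_index_sets(grid.shape)
    dorsal = _match_edge(grid.dorsal_edge, edges, "dorsal")
    medial = _match_edge(grid.medial_edge, edges, "medial")
    if dorsal[0][:3] == medial[0][:3]:
        raise AnnotationError(
            "dorsal and medial annotations lie on parallel edges")
    d_idx, m_idx = dorsal[1], medial[1]
    corner = np.intersect1d(d_idx, m_idx)
    if corner.size != 1:
        raise AnnotationError("annotated edges do not share a corner site")
    c = grid.sites[corner[0]]
    # unit vectors along the annotated edges, away from the shared corner
    u = _edge_direction(grid.sites, d_idx, corner[0])
    v = _edge_direction(grid.sites, m_idx, corner[0])
    if abs(np.dot(u, v)) > 1e-6:
        raise AnnotationError("annotated edges are not perpendicular")
    rot = np.vstack([u, v])          # orthogonal; det -1 encodes a flip
    p = (grid.sites - c) @ rot.T
    # aspect normalization about the centroid, x only
    width = p[:, 0].max() - p[:, 0].min()
    height = p[:, 1].max() - p[:, 1].min()
    if width <= 0 or height <= 0:
        raise AnnotationError("degenerate grid extent")
    sx = SN_ASPECT / (width / height)
    cen = p.mean(axis=0)
    p[:, 0] = (p[:, 0] - cen[0]) * sx + cen[0]
    shift = p.min(axis=0)
    p -= shift
    scale = np.diag([sx, 1.0])
    a_mat = scale @ rot
    b = scale @ (-rot @ c - cen * [1.0, 0.0]) + cen * [1.0, 0.0] - shift
    new_shape = grid.shape
    if dorsal[0].startswith("col"):
        new_shape = (grid.shape[1], grid.shape[0])
    aligned = StimGrid(sites=p, shape=new_shape,
                       dorsal_edge=list(grid.dorsal_edge),
                       medial_edge=list(grid.medial_edge), plane=grid.plane)
    return aligned, AffineTransform(a_mat, b)


def _match_edge(annot, edges, name):
    s = set(int(i) for i in annot)
    for key, idx in edges.items():
        if s == set(idx.tolist()):
            return key, idx
    raise AnnotationError(f"{name} annotation does not match any lattice edge")


def _edge_direction(sites, edge_idx, corner):
    ends = [i for i in (edge_idx[0], edge_idx[-1]) if i != corner]
    far = ends[-1]
    d = sites[far] - sites[corner]
    return d / np.linalg.norm(d)


# ---------------------------------------------------------------------------
# maps and images
# ---------------------------------------------------------------------------

def response_map(traces_per_site: dict, stim_time: float, soma,
                 window: float = 15.0, baseline: float = 5.0,
                 detection_nsd: float = 3.0, v_hold: float = 20.0,
                 n_sites: int | None = None) -> ResponseMap:
    """Build a ResponseMap from per-site voltage-clamp traces.

    traces_per_site maps site index -> list of Trace (repetitions). The
    per-site amplitude is the baseline-subtracted peak of the trial-averaged
    trace within ``window`` ms after ``stim_time``; sites whose peak stays
    below ``detection_nsd`` baseline SDs are flagged (amplitude 0, latency
    NaN); missing sites are NaN (absent, not zero).
    """
    from .ephys_analysis import ipsc_kinetics  # local import, cycle-free
    n = (max(traces_per_site) + 1) if n_sites is None else n_sites
    amps = np.full(n, np.nan)
    lats = np.full(n, np.nan)
    for site, reps in traces_per_site.items():
        avg = np.mean([tr.data for tr in reps], axis=0)
        tr0 = reps[0]
        i_stim = int(round(stim_time / tr0.dt))
        i_b0 = max(0, i_stim - int(round(baseline / tr0.dt)))
        base = avg[i_b0:i_stim]
        seg = avg[i_stim:i_stim + int(round(window / tr0.dt))]
        peak = seg.max() - base.mean()
        if peak < detection_nsd * max(base.std(), 1e-12):
            amps[site] = 0.0
            continue
        amps[site] = peak
        kin = ipsc_kinetics(
            type(tr0)(avg, tr0.dt, units=tr0.units, v_hold=v_hold,
                      stim_times=[stim_time]), search_window=window)[0]
        lats[site] = kin.latency if kin is not None else np.nan
    return ResponseMap(amplitudes=amps, latencies=lats,
                       soma=np.asarray(soma, dtype=float), v_hold=v_hold)


def frame_raster(raster: float = RASTER):
    """(x, y) coordinate vectors of the SN-frame image raster."""
    x = np.arange(0.0, SN_WIDTH + raster / 2, raster)
    y = np.arange(0.0, SN_HEIGHT + raster / 2, raster)
    return x, y


def smooth_map(grid: StimGrid, rmap: ResponseMap, sigma: float = 75.0,
               raster: float = RASTER) -> np.ndarray:
    """Sum of unit-peak Gaussians at the stimulation sites, scaled by the
    site amplitudes, sampled on the SN-frame raster. NaN (absent) sites are
    skipped. Returns an image of shape (ny, nx)."""
    if sigma <= 0:
        raise InvalidSpecError("sigma must be positive")
    x, y = frame_raster(raster)
    img = np.zeros((y.size, x.size))
    ok = np.isfinite(rmap.amplitudes)
    for (sx, sy), a in zip(grid.sites[ok], rmap.amplitudes[ok]):
        if a == 0:
            continue
        img += a * np.outer(np.exp(-(y - sy) ** 2 / (2 * sigma ** 2)),
                            np.exp(-(x - sx) ** 2 / (2 * sigma ** 2)))
    return img


def isocontour(image: np.ndarray, fraction: float = 0.5,
               raster: float = RASTER) -> list:
    """Marching-squares contours at ``fraction`` of the image maximum.

    Returns a list of (n, 2) polygons in frame um coordinates (x, y).
    Presets used in practice: 0.5 (half maximum), 0.25 and 0.2.
    """
    if not (0 < fraction < 1):
        raise InvalidSpecError("fraction must be in (0, 1)")
    mx = image.max() if image.size else 0.0
    if mx <= 0:
        raise InvalidSpecError("image has no positive values")
    contours = measure.find_contours(image, fraction * mx)
    return [np.column_stack([c[:, 1] * raster, c[:, 0] * raster])
            for c in contours]


def com_points(positions, weights) -> np.ndarray:
    """Weighted centroid of points (the response-magnitude-weighted vector
    average of site positions)."""
    w = np.asarray(weights, dtype=float)
    p = np.asarray(positions, dtype=float)
    ok = np.isfinite(w)
    w, p = w[ok], p[ok]
    tot = w.sum()
    if tot <= 0:
        raise InvalidSpecError("total weight must be positive")
    return (w[:, None] * p).sum(axis=0) / tot


def com_map(grid_or_image, rmap: ResponseMap | None = None,
            raster: float = RASTER) -> np.ndarray:
    """Center of mass of a response map (site-based) or image (pixel-based)."""
    if isinstance(grid_or_image, StimGrid):
        return com_points(grid_or_image.sites, rmap.amplitudes)
    img = np.asarray(grid_or_image, dtype=float)
    x, y = frame_raster(raster)
    xx, yy = np.meshgrid(x[: img.shape[1]], y[: img.shape[0]])
    return com_points(np.column_stack([xx.ravel(), yy.ravel()]), img.ravel())


def com_dendrite(skel: DendriteSkeleton) -> np.ndarray:
    """Width-weighted center of mass of a dendritic arbor.

    Each segment contributes its midpoint weighted by width x length."""
    a = skel.nodes[skel.edges[:, 0]]
    b = skel.nodes[skel.edges[:, 1]]
    mid = 0.5 * (a + b)
    length = np.linalg.norm(b - a, axis=1)
    return com_points(mid, skel.widths * length)


# ---------------------------------------------------------------------------
# correlations and falloff
# ---------------------------------------------------------------------------

def map_correlation_vs_distance(maps: list, bin_width: float = 100.0,
                                fit: bool = True):
    """Pairwise map correlation as a function of inter-soma distance.

    For every pair of maps on the same aligned grid, Pearson r over sites
    present (finite) in both, plus the Euclidean soma distance. Binned means
    are fit with r(d) = a exp(-d / lam) + c. Returns a dict with keys
    ``distance``, ``r``, and (when >= 4 pairs and fitting succeeds)
    ``fit`` = (a, lam, c).
    """
    if len(maps) < 2:
        raise InsufficientDataError("need at least two maps")
    dists, rs = [], []
    for i in range(len(maps)):
        for j in range(i + 1, len(maps)):
            a, b = maps[i], maps[j]
            ok = np.isfinite(a.amplitudes) & np.isfinite(b.amplitudes)
            if ok.sum() < 3:
                continue
            x, yv = a.amplitudes[ok], b.amplitudes[ok]
            if x.std() == 0 or yv.std() == 0:
                continue
            rs.append(stats.pearsonr(x, yv)[0])
            dists.append(float(np.linalg.norm(a.soma - b.soma)))
    dists = np.asarray(dists)
    rs = np.asarray(rs)
    out = {"distance": dists, "r": rs, "fit": None}
    if fit and dists.size >= 4:
        bins = np.arange(0, dists.max() + bin_width, bin_width)
        which = np.digitize(dists, bins)
        bd, br = [], []
        for k in np.unique(which):
            sel = which == k
            bd.append(dists[sel].mean())
            br.append(rs[sel].mean())
        try:
            popt, _ = optimize.curve_fit(
                lambda d, a, lam, c: a * np.exp(-d / lam) + c,
                np.asarray(bd), np.asarray(br),
                p0=[max(br) - min(br), max(200.0, np.ptp(dists) / 3),
                    min(br)],
                maxfev=10000)
            out["fit"] = tuple(popt)
        except RuntimeError:
            pass
    return out


def axon_overlay_correlation(map_image: np.ndarray, axon_image: np.ndarray,
                             soma, axon_com, mask: np.ndarray | None = None):
    """Pixelwise Pearson correlation between an input map image and an axon
    density image, plus the soma -> axon-COM distance (um)."""
    if map_image.shape != axon_image.shape:
        raise ResampleRequiredError(
            f"images on different rasters: {map_image.shape} vs "
            f"{axon_image.shape}")
    m = np.ones(map_image.shape, bool) if mask is None else mask.astype(bool)
    a = map_image[m].ravel()
    b = axon_image[m].ravel()
    r = float(stats.pearsonr(a, b)[0])
    d = float(np.linalg.norm(np.asarray(soma, float) - np.asarray(axon_com,
                                                                  float)))
    return d, r


def spatial_falloff(amplitudes, positions, focus):
    """Cumulative response fraction vs distance from a focus.

    Returns (sorted distances, cumulative normalized magnitude,
    half-response distance) — the distance within which half the total
    response magnitude is contained.
    """
    amp = np.asarray(amplitudes, dtype=float)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    ok = np.isfinite(amp)
    amp, pos = amp[ok], pos[ok]
    if amp.size < 3:
        raise InsufficientDataError("need at least 3 responses")
    tot = amp.sum()
    if tot <= 0:
        raise InvalidSpecError("all response magnitudes are zero")
    d = np.linalg.norm(pos - np.asarray(focus, dtype=float), axis=1)
    order = np.argsort(d)
    d = d[order]
    cum = np.cumsum(amp[order]) / tot
    half = float(d[np.searchsorted(cum, 0.5)])
    return d, cum, half


# ---------------------------------------------------------------------------
# worked examples: convergence and conduction velocity
# ---------------------------------------------------------------------------

def estimate_n_inputs(g_max: float, g_unit: float):
    """Number of convergent unitary inputs implied by the maximal evoked
    conductance: g_max / g_unit (both pS). Returns (exact, nearest int)."""
    if g_max < 0 or g_unit <= 0:
        raise InvalidSpecError("need g_max >= 0 and g_unit > 0")
    x = g_max / g_unit
    return x, int(round(x))


def convergence_radius(density: float, p_connect: float,
                       n_inputs: float) -> float:
    """Radius (um) of the sphere containing ``n_inputs`` presynaptic
    partners at ``density`` neurons/mm^3 and connection probability
    ``p_connect``: r = (3 n / (4 pi rho p))^(1/3)."""
    if density <= 0 or n_inputs <= 0 or not (0 < p_connect <= 1):
        raise InvalidSpecError("all inputs must be positive, p <= 1")
    r_mm = (3.0 * n_inputs / (4.0 * np.pi * density * p_connect)) ** (1 / 3)
    return r_mm * 1e3


def conduction_velocity(latencies, distances):
    """Least-squares latency-vs-distance slope and implied velocity.

    latencies in ms, distances in um. Returns (slope ms/mm, velocity m/s);
    velocity is NaN when the slope is non-positive (ms/mm and m/s are
    reciprocal: v [m/s] = 1 / slope [ms/mm]).
    """
    lat = np.asarray(latencies, dtype=float)
    d = np.asarray(distances, dtype=float)
    if lat.size < 3 or np.ptp(d) < 300.0:
        raise InsufficientDataError(
            "need >= 3 points spanning >= 300 um of distance")
    slope = stats.linregress(d / 1e3, lat).slope  # ms per mm
    velocity = 1.0 / slope if slope > 0 else np.nan
    return float(slope), float(velocity)
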