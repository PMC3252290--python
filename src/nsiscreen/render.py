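"""Synthetic two-timepoint field rendering with pixel-level ground truth.

A *field* is one microscope field of view in one well: a nuclear-stain
channel (655 nm) plus two compound-emission channels (475 and 549 nm),
imaged at T0 (right after compound incubation and wash) and T1 (after a
~60 min clearance window).  The renderer draws anisotropic
Gaussian-profile elliptical nuclei, builds each cell's territory as the
nearest-nucleus tessellation of the union of cell-body ellipses, deposits
compound signal according to the compound's behavior class and
subcellular localization, advances the kinetics to T1, and applies a
rigid/affine stage drift between the two acquisitions.

Everything the downstream pipeline estimates is recorded exactly in
:class:`FieldGroundTruth` before noise and quantization: centroids, label
images at both timepoints, per-cell integrated fluorescence per channel,
and the inter-timepoint affine transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .kinetics import CLEARANCE_MINUTES, CompoundKinetics

__all__ = [
    "CHANNELS",
    "FieldGeometry",
    "NoiseParams",
    "CellTruth",
    "FieldGroundTruth",
    "render_field",
    "identity_drift",
    "translation_drift",
]

CHANNELS = ("655", "475", "549")  # nuclear stain, then the two compound channels
COMPOUND_CHANNELS = ("475", "549")

NUCLEAR_PEAK = 9000.0  # a.u., nuclear stain peak intensity
BLEED_FRACTION = 0.1   # fraction of compound signal emitted in the off channel
RIM_WIDTH_PX = 2       # membrane rim band width in the render


@dataclass
class FieldGeometry:
    shape: tuple[int, int] = (256, 256)
    n_cells: int = 25
    nucleus_radius: tuple[float, float] = (5.0, 9.0)  # px, min/max semi-axis scale
    cell_scale: float = 2.2        # cell-body radius = nucleus radius * cell_scale
    touching_fraction: float = 0.1  # fraction of nuclei placed as tight pairs
    separation: float = 1.0        # required center distance, in summed radii;
                                   # cell_scale gives fully disjoint cell bodies
    margin: float = 18.0           # keep-out border, px
    max_retries: int = 2000


@dataclass
class NoiseParams:
    background: float = 200.0  # a.u. camera offset + autofluorescence
    read_sd: float = 8.0       # additive Gaussian read noise, a.u.
    photon_noise: bool = False  # Poisson resampling of the expected signal
    quantize: bool = True      # round to 16-bit counts; False = float render
                               # (digitization is itself a noise source: on
                               # flat profiles the rounding error is shared by
                               # every pixel and does not average out)


@dataclass
class CellTruth:
    cell_id: int
    centroid_t0: tuple[float, float]  # (row, col) px
    centroid_t1: tuple[float, float]
    nucleus_radius: float
    true_f: dict  # {(channel, timepoint): integrated a.u.}, pre-noise


@dataclass
class FieldGroundTruth:
    cells: list[CellTruth]
    nuclei_t0: np.ndarray   # label images, 0 = background
    regions_t0: np.ndarray
    nuclei_t1: np.ndarray
    regions_t1: np.ndarray
    drift: np.ndarray       # 2x3 affine, maps T0 (row, col) -> T1 (row, col)
    background: float
    noise: NoiseParams = dc_field(default_factory=NoiseParams)


def identity_drift() -> np.ndarray:
    return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def translation_drift(dr: float, dc: float) -> np.ndarray:
    return np.array([[1.0, 0.0, dr], [0.0, 1.0, dc]])


def _apply_affine(points: np.ndarray, m: np.ndarray) -> np.ndarray:
    return points @ m[:, :2].T + m[:, 2]


def _place_nuclei(geom: FieldGeometry, rng: np.random.Generator):
    """Rejection-sample non-overlapping nucleus centers and radii.

    A ``touching_fraction`` of the nuclei are placed as tight pairs whose
    centers sit ~1.2 summed-radii apart, emulating touching cells that the
    segmenter must split.
    """
    h, w = geom.shape
    lo, hi = geom.nucleus_radius
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    n_pairs = int(round(geom.n_cells * geom.touching_fraction / 2.0))
    n_single = geom.n_cells - 2 * n_pairs

    def ok(r, c, rad, gap=3.0):
        if not (geom.margin <= r <= h - geom.margin):
            return False
        if not (geom.margin <= c <= w - geom.margin):
            return False
        for (r0, c0), rad0 in zip(centers, radii):
            if np.hypot(r - r0, c - c0) < geom.separation * (rad + rad0) + gap:
                return False
        return True

    tries = 0
    placed_pairs = 0
    while placed_pairs < n_pairs:
        if tries > geom.max_retries:
            raise RuntimeError(
                f"field too crowded: could not place {geom.n_cells} cells of "
                f"radius {geom.nucleus_radius} in {geom.shape} after "
                f"{geom.max_retries} retries"
            )
        tries += 1
        rad_a = rng.uniform(lo, hi)
        rad_b = rng.uniform(lo, hi)
        r, c = rng.uniform(geom.margin, h - geom.margin), rng.uniform(
            geom.margin, w - geom.margin
        )
        theta = rng.uniform(0, 2 * np.pi)
        # nucleus boundaries in contact: the Gaussian glows merge into one
        # above-threshold component while the cores stay resolvable
        d = 1.05 * (rad_a + rad_b)
        r2, c2 = r + d * np.sin(theta), c + d * np.cos(theta)
        # the partner is not in `centers` yet, so both checks exclude it
        if ok(r, c, rad_a) and ok(r2, c2, rad_b):
            centers.extend([(r, c), (r2, c2)])
            radii.extend([rad_a, rad_b])
            placed_pairs += 1
    placed = 0
    while placed < n_single:
        if tries > geom.max_retries:
            raise RuntimeError(
                f"field too crowded: could not place {geom.n_cells} cells of "
                f"radius {geom.nucleus_radius} in {geom.shape} after "
                f"{geom.max_retries} retries"
            )
        tries += 1
        rad = rng.uniform(lo, hi)
        r, c = rng.uniform(geom.margin, h - geom.margin), rng.uniform(
            geom.margin, w - geom.margin
        )
        if ok(r, c, rad):
            centers.append((r, c))
            radii.append(rad)
            placed += 1
    return np.array(centers).reshape(-1, 2), np.array(radii)


def _q_window(shape, center, radius, ratio, theta, extent):
    """Squared Mahalanobis distance of an ellipse on a cropped window.

    Evaluating per-cell fields on ~(2*extent*radius)^2 windows instead of
    the full frame keeps rendering linear in cell count.
    """
    half = int(np.ceil(extent * radius)) + 2
    r0 = max(int(round(center[0])) - half, 0)
    r1 = min(int(round(center[0])) + half + 1, shape[0])
    c0 = max(int(round(center[1])) - half, 0)
    c1 = min(int(round(center[1])) + half + 1, shape[1])
    win = (slice(r0, r1), slice(c0, c1))
    rr = np.arange(r0, r1, dtype=float)[:, None] - center[0]
    cc = np.arange(c0, c1, dtype=float)[None, :] - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * rr + st * cc
    v = -st * rr + ct * cc
    a, b = radius, radius * ratio
    return win, (u / a) ** 2 + (v / b) ** 2


def _build_scene(shape, centers, radii, ratios, thetas, cell_scale):
    """Label images plus per-cell (window, q) fields for one timepoint.

    Nucleus mask is the unit ellipse (overlap resolved by smallest q);
    foreground is the union of cell bodies (nucleus scaled by
    ``cell_scale``); territories are the nearest-centroid tessellation of
    the foreground, with each nucleus forced into its own territory.
    """
    n = len(centers)
    extent = max(3.2, cell_scale + 0.3)  # covers nuclear glow and cell body
    qmin = np.full(shape, np.inf)
    owner = np.zeros(shape, dtype=np.int32)
    fg = np.zeros(shape, dtype=bool)
    wins, qwins = [], []
    for i in range(n):
        win, q = _q_window(shape, centers[i], radii[i], ratios[i], thetas[i],
                           extent)
        wins.append(win)
        qwins.append(q)
        sub = qmin[win]
        upd = q < sub
        sub[upd] = q[upd]
        qmin[win] = sub
        osub = owner[win]
        osub[upd] = i + 1
        owner[win] = osub
        fg[win] |= q <= cell_scale**2
    nuclei = np.where(qmin <= 1.0, owner, 0).astype(np.int32)

    regions = np.zeros(shape, dtype=np.int32)
    rs, cs = np.nonzero(fg)
    if len(rs):
        d2 = (rs[None, :] - centers[:, 0, None]) ** 2 + (
            cs[None, :] - centers[:, 1, None]
        ) ** 2
        regions[rs, cs] = d2.argmin(axis=0) + 1
    regions[nuclei > 0] = nuclei[nuclei > 0]
    return nuclei, regions, wins, qwins


def _profile(kind, i, win, q, nuclei, regions, radius, cell_scale):
    """Normalized spatial deposition profile of cell i's compound signal."""
    own_region = regions[win] == i + 1
    own_nucleus = nuclei[win] == i + 1
    if kind == "nuclear":
        p = np.exp(-q * 2.0) * own_nucleus
    elif kind == "perinuclear":
        # band just outside the nucleus boundary (1 < sqrt(q) < ~1.6)
        s = np.sqrt(q)
        p = np.exp(-0.5 * ((s - 1.3) / 0.25) ** 2) * own_region * ~own_nucleus
    elif kind == "diffuse":
        # near-uniform plateau across the whole cell body with a soft
        # logistic roll-off at the edge ("diffused across the entire cell")
        s = np.sqrt(q)
        p = own_region / (1.0 + np.exp((s - (cell_scale - 0.6)) / 0.25))
    elif kind == "membrane":
        # rim band of the cell body: sqrt(q) near cell_scale
        s = np.sqrt(q)
        halfw = RIM_WIDTH_PX / (2.0 * radius)
        p = np.exp(-0.5 * ((s - (cell_scale - halfw)) / halfw) ** 2) * own_region
    else:
        raise ValueError(kind)
    tot = p.sum()
    return p / tot if tot > 0 else p


def render_field(
    kin: CompoundKinetics | None,
    geometry: FieldGeometry | None = None,
    noise: NoiseParams | None = None,
    drift: np.ndarray | None = None,
    seed: int = 0,
):
    """Render one field at both timepoints.

    Parameters
    ----------
    kin
        Kinetic truth of the well's compound, or None for a control well
        (compound channels stay at background).
    drift
        2x3 affine (row, col convention) mapping T0 coordinates to T1;
        identity if None.

    Returns
    -------
    (images_t0, images_t1, truth)
        Each image dict maps channel name ('655', '475', '549') to a
        uint16 array; ``truth`` is the :class:`FieldGroundTruth`.
    """
    geometry = geometry or FieldGeometry()
    noise = noise or NoiseParams()
    drift = identity_drift() if drift is None else np.asarray(drift, dtype=float)
    rng = np.random.default_rng(seed)
    shape = geometry.shape

    if geometry.n_cells == 0:
        blank = _quantize(
            {ch: np.zeros(shape) for ch in CHANNELS}, noise, rng
        )
        blank2 = _quantize(
            {ch: np.zeros(shape) for ch in CHANNELS}, noise, rng
        )
        z = np.zeros(shape, dtype=np.int32)
        truth = FieldGroundTruth([], z, z.copy(), z.copy(), z.copy(), drift,
                                 noise.background, noise)
        return blank, blank2, truth

    centers0, radii = _place_nuclei(geometry, rng)
    n = len(centers0)
    ratios = rng.uniform(0.7, 1.0, size=n)
    thetas = rng.uniform(0, np.pi, size=n)
    centers1 = _apply_affine(centers0, drift)

    nuc_amp = NUCLEAR_PEAK * rng.uniform(0.7, 1.3, size=n)

    # Per-cell compound amplitudes and T1/T0 ratios.
    if kin is not None:
        cv = kin.cell_cv
        sigma = np.sqrt(np.log(1.0 + cv**2))
        mult = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))
        f_t0 = kin.amplitude * mult
        ratio_jitter = np.exp(rng.normal(0.0, 0.05, size=n))
        pop_ratio = np.exp((kin.growth - kin.k_out) * CLEARANCE_MINUTES)
        f_t1 = f_t0 * pop_ratio * ratio_jitter
        profile_kind = (
            "membrane" if kin.behavior_class == "membrane_bound"
            else kin.localization
        )
        if kin.behavior_class == "no_entry":
            # residual non-specific surface signal only
            profile_kind = "membrane"
    else:
        f_t0 = f_t1 = np.zeros(n)
        profile_kind = "diffuse"

    def render_scene(centers):
        nuclei, regions, wins, qwins = _build_scene(
            shape, centers, radii, ratios, thetas, geometry.cell_scale
        )
        nuc_img = np.zeros(shape)
        for i in range(n):
            nuc_img[wins[i]] += nuc_amp[i] * np.exp(-qwins[i] * 1.5)
        profiles = [
            _profile(profile_kind, i, wins[i], qwins[i], nuclei, regions,
                     radii[i], geometry.cell_scale)
            for i in range(n)
        ]
        return nuclei, regions, nuc_img, wins, profiles, qwins

    nuclei0, regions0, nuc_img0, wins0, prof0, qwins0 = render_scene(centers0)
    nuclei1, regions1, nuc_img1, wins1, prof1, _ = render_scene(centers1)

    main_ch = str(kin.emission) if kin is not None else "475"
    other_ch = "549" if main_ch == "475" else "475"

    cells: list[CellTruth] = []
    comp0 = {ch: np.zeros(shape) for ch in COMPOUND_CHANNELS}
    comp1 = {ch: np.zeros(shape) for ch in COMPOUND_CHANNELS}
    for i in range(n):
        split0 = {main_ch: (1 - BLEED_FRACTION) * f_t0[i],
                  other_ch: BLEED_FRACTION * f_t0[i]}
        split1 = {main_ch: (1 - BLEED_FRACTION) * f_t1[i],
                  other_ch: BLEED_FRACTION * f_t1[i]}
        true_f = {}
        for ch in COMPOUND_CHANNELS:
            comp0[ch][wins0[i]] += split0[ch] * prof0[i]
            comp1[ch][wins1[i]] += split1[ch] * prof1[i]
            true_f[(ch, "T0")] = float(split0[ch])
            true_f[(ch, "T1")] = float(split1[ch])
        true_f[("655", "T0")] = true_f[("655", "T1")] = float(
            (nuc_amp[i] * np.exp(-qwins0[i] * 1.5)).sum()
        )
        cells.append(CellTruth(
            cell_id=i + 1,
            centroid_t0=tuple(centers0[i]),
            centroid_t1=tuple(centers1[i]),
            nucleus_radius=float(radii[i]),
            true_f=true_f,
        ))

    imgs0 = {"655": nuc_img0, **comp0}
    imgs1 = {"655": nuc_img1, **comp1}
    out0 = _quantize(imgs0, noise, rng)
    out1 = _quantize(imgs1, noise, rng)
    truth = FieldGroundTruth(cells, nuclei0, regions0, nuclei1, regions1,
                             drift, noise.background, noise)
    return out0, out1, truth


def _quantize(images: dict, noise: NoiseParams, rng: np.random.Generator):
    out = {}
    for ch, img in images.items():
        sig = img
        if noise.photon_noise:
            sig = rng.poisson(np.maximum(sig, 0.0)).astype(float)
        sig = sig + noise.background
        if noise.read_sd > 0:
            sig = sig + rng.normal(0.0, noise.read_sd, size=sig.shape)
        if noise.quantize:
            out[ch] = np.clip(np.round(sig), 0, 65535).astype(np.uint16)
        else:
            out[ch] = np.asarray(sig, dtype=np.float64)
    return out
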