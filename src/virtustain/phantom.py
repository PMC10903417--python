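"""Synthetic adipocyte phantom: paired bright-field stacks and fluorescence targets.

The phantom emulates the statistical structure that label-free staining of
fat cells exploits.  A :class:`Scene` holds the geometry of one field of
view — cells with an elliptical nucleus, a smooth cytoplasm blob containing
it, and lipid droplets drawn from two log-normal size populations (small and
large, mirroring the two-pass droplet segmentation downstream).  Two
renderers share each scene:

* :func:`render_fluorescence` produces the 3-channel, 16-bit target
  (droplets / cytoplasm / nuclei) plus exact ground-truth label maps.  The
  cytoplasm carries a multiplicative low-pass texture (the uneven,
  irreproducible dye reaction), droplets a radial intensity fall-off with an
  off-centre interior dip (the darker areas seen inside real droplets).
* :func:`render_brightfield` produces the 7-slice defocus stack.  The
  contrast hierarchy is the essential feature: droplets show strong,
  defocus-dependent rings whose central polarity flips across the focal
  plane; the cytoplasm is faint; nuclei have zero intrinsic contrast by
  default, so any downstream nucleus prediction must be inferred from
  context.

All randomness flows from ``PhantomParams.seed``; outputs are
bit-reproducible given identical parameters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter


class PlacementError(RuntimeError):
    """Nucleus placement failed within the attempt budget."""


@dataclass
class Droplet:
    center: tuple[float, float]  # (row, col)
    radius: float
    population: str  # "small" | "large"
    dip_offset: tuple[float, float] = (0.0, 0.0)  # relative to center, px


@dataclass
class Cell:
    nucleus_center: tuple[float, float]
    nucleus_axes: tuple[float, float]  # semi-axes, px
    nucleus_theta: float
    boundary_base: float  # mean cytoplasm radius, px
    boundary_amp: tuple[float, ...]  # harmonic amplitudes, k = 2..
    boundary_phase: tuple[float, ...]
    droplets: list[Droplet] = field(default_factory=list)

    def boundary_radius(self, phi: np.ndarray) -> np.ndarray:
        r = np.ones_like(phi)
        for k, (a, p) in enumerate(zip(self.boundary_amp, self.boundary_phase),
                                   start=2):
            r = r + a * np.cos(k * phi + p)
        return self.boundary_base * np.clip(r, 0.3, None)


@dataclass
class Scene:
    field_size: tuple[int, int]
    cells: list[Cell]
    texture_seed: int

    @property
    def droplets(self) -> list[Droplet]:
        return [d for c in self.cells for d in c.droplets]


@dataclass
class PhantomParams:
    """Generation parameters for one phantom field.

    Intensities follow the 16-bit convention: rendered images are stored as
    uint16 in [0, 65535].  Contrast weights encode the bright-field
    hierarchy droplet >> cytoplasm > nucleus (nucleus 0 by default:
    refractive-index-matched to the cytoplasm, hence invisible).
    """

    field_size: tuple[int, int] = (256, 256)
    n_cells: int = 6
    droplets_per_cell: int = 25
    large_fraction: float = 0.2
    small_radius_median: float = 4.0
    small_radius_sigma: float = 0.25
    large_radius_median: float = 15.0
    large_radius_sigma: float = 0.2
    nucleus_radius: float = 12.0
    nucleus_aspect_jitter: float = 0.25
    cell_radius: float = 48.0
    cell_irregularity: float = 0.08
    # fluorescence rendering (16-bit counts)
    droplet_level: float = 22000.0
    cytoplasm_level: float = 9000.0
    nucleus_level: float = 15000.0
    fluor_background: float = 800.0
    fluor_noise_sigma: float | tuple[float, float, float] = 300.0
    poisson_gain: float = 0.05
    droplet_falloff: float = 0.3
    droplet_dip_strength: float = 0.2
    cytoplasm_roughness: float = 0.4
    cytoplasm_texture_scale: float = 8.0
    # bright-field rendering
    n_slices: int = 7
    defocus_step: float = 1.0
    bf_background: float = 30000.0
    droplet_contrast: float = 6000.0
    cytoplasm_contrast: float = 1500.0
    nucleus_contrast: float = 0.0
    defocus_blur: float = 1.5
    bf_noise_sigma: float = 300.0
    non_overlapping_droplets: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.n_cells < 0 or self.droplets_per_cell < 0:
            raise ValueError("counts must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if np.min(self.fluor_noise_sigma) < 0 or self.bf_noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if min(self.droplet_contrast, self.cytoplasm_contrast,
               self.nucleus_contrast) < 0:
            raise ValueError("contrast weights must be >= 0")


@dataclass
class GroundTruth:
    """Label maps (0 = background) and per-object records for one field."""

    droplet_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    nucleus_labels: np.ndarray
    objects: dict[str, "object"]  # class -> DataFrame-like dict of records


def _rng(seed, *salt: int) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + salt))


def sample_scene(params: PhantomParams) -> Scene:
    """Draw a random field-of-view geometry.

    Nucleus centres are rejection-sampled so each pair is separated by at
    least one mean nucleus diameter; droplet centres never fall inside a
    previously placed droplet (keeping every label visible in the map).
    """
    rng = _rng(params.seed, 1)
    h, w = params.field_size
    min_sep = 2.0 * params.nucleus_radius
    margin = min(0.45 * params.cell_radius, (h - 1) / 2.2, (w - 1) / 2.2)
    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = 2000 * max(1, params.n_cells)
    while len(centers) < params.n_cells:
        if attempts > budget:
            raise PlacementError(
                f"could not place {params.n_cells} nuclei with separation "
                f"{min_sep:.1f}px in a {h}x{w} field after {budget} attempts")
        attempts += 1
        c = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all(np.hypot(c[0] - o[0], c[1] - o[1]) >= min_sep for o in centers):
            centers.append(c)

    cells = []
    for c in centers:
        amp = tuple(rng.normal(0.0, params.cell_irregularity / k)
                    for k in range(2, 6))
        phase = tuple(rng.uniform(0, 2 * np.pi, size=4))
        base = params.cell_radius * rng.uniform(0.85, 1.15)
        aspect = 1.0 + rng.uniform(-params.nucleus_aspect_jitter,
                                   params.nucleus_aspect_jitter)
        ax = params.nucleus_radius * aspect
        bx = params.nucleus_radius / aspect
        # keep the nucleus strictly inside the cytoplasm support
        min_boundary = base * max(0.3, 1.0 - sum(abs(a) for a in amp))
        scale = min(1.0, 0.8 * min_boundary / max(ax, bx))
        cell = Cell(nucleus_center=c, nucleus_axes=(ax * scale, bx * scale),
                    nucleus_theta=rng.uniform(0, np.pi),
                    boundary_base=base, boundary_amp=amp, boundary_phase=phase)
        _place_droplets(cell, params, rng, existing=[
            d for cc in cells for d in cc.droplets])
        cells.append(cell)
    return Scene(field_size=params.field_size, cells=cells,
                 texture_seed=int(rng.integers(0, 2 ** 31)))


def _place_droplets(cell: Cell, params: PhantomParams,
                    rng: np.random.Generator,
                    existing: list[Droplet]) -> None:
    h, w = params.field_size
    placed = list(existing)
    for _ in range(params.droplets_per_cell):
        for _attempt in range(200):
            if rng.uniform() < params.large_fraction:
                pop, med, sig = ("large", params.large_radius_median,
                                 params.large_radius_sigma)
            else:
                pop, med, sig = ("small", params.small_radius_median,
                                 params.small_radius_sigma)
            r = float(np.exp(np.log(med) + sig * rng.normal()))
            r = max(r, 1.5)
            phi = rng.uniform(0, 2 * np.pi)
            rmax = float(cell.boundary_radius(np.array([phi]))[0]) - 0.6 * r
            if rmax <= 0:
                continue
            rad = rmax * np.sqrt(rng.uniform())
            cy = cell.nucleus_center[0] + rad * np.sin(phi)
            cx = cell.nucleus_center[1] + rad * np.cos(phi)
            if not (0 <= cy < h and 0 <= cx < w):
                continue
            if any(np.hypot(cy - d.center[0], cx - d.center[1]) < d.radius
                   for d in placed):
                continue  # centre inside an existing droplet: label would hide
            if params.non_overlapping_droplets and any(
                    np.hypot(cy - d.center[0], cx - d.center[1])
                    < r + d.radius + 2.0 for d in placed):
                continue
            dip_r = 0.35 * r
            dip_phi = rng.uniform(0, 2 * np.pi)
            d = Droplet(center=(cy, cx), radius=r, population=pop,
                        dip_offset=(dip_r * np.sin(dip_phi),
                                    dip_r * np.cos(dip_phi)))
            placed.append(d)
            cell.droplets.append(d)
            break
        # droplet dropped silently if it cannot be placed (crowded field)


def _cell_mask(cell: Cell, shape: tuple[int, int]) -> tuple[np.ndarray, tuple]:
    """Boolean mask of the cytoplasm blob, restricted to its bounding box."""
    h, w = shape
    cy, cx = cell.nucleus_center
    rmax = cell.boundary_base * (1.0 + sum(abs(a) for a in cell.boundary_amp))
    y0, y1 = max(0, int(cy - rmax) - 1), min(h, int(cy + rmax) + 2)
    x0, x1 = max(0, int(cx - rmax) - 1), min(w, int(cx + rmax) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    mask = rr <= cell.boundary_radius(phi)
    return mask, (y0, y1, x0, x1)


def _nucleus_mask(cell: Cell, shape: tuple[int, int]) -> tuple[np.ndarray, tuple]:
    h, w = shape
    cy, cx = cell.nucleus_center
    a, b = cell.nucleus_axes
    rmax = max(a, b)
    y0, y1 = max(0, int(cy - rmax) - 1), min(h, int(cy + rmax) + 2)
    x0, x1 = max(0, int(cx - rmax) - 1), min(w, int(cx + rmax) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(cell.nucleus_theta), np.sin(cell.nucleus_theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return (u ** 2 + v ** 2) <= 1.0, (y0, y1, x0, x1)


def _droplet_patch(d: Droplet, shape: tuple[int, int], pad: float = 0.0):
    h, w = shape
    cy, cx = d.center
    rmax = d.radius + pad
    y0, y1 = max(0, int(cy - rmax) - 2), min(h, int(cy + rmax) + 3)
    x0, x1 = max(0, int(cx - rmax) - 2), min(w, int(cx + rmax) + 3)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr = np.hypot(yy - cy, xx - cx)
    return rr, (y0, y1, x0, x1)


def _check_scene(scene: Scene, params: PhantomParams) -> None:
    if tuple(scene.field_size) != tuple(params.field_size):
        raise ValueError(
            f"scene field size {scene.field_size} does not match params "
            f"field size {params.field_size}")


def render_fluorescence(scene: Scene,
                        params: PhantomParams) -> tuple[np.ndarray, GroundTruth]:
    """Render the 3-channel fluorescence target and its ground truth.

    Returns ``(image, gt)`` where ``image`` is uint16 of shape (3, H, W)
    with channels ordered droplets, cytoplasm, nuclei.
    """
    _check_scene(scene, params)
    h, w = scene.field_size
    clean = np.full((3, h, w), params.fluor_background, dtype=np.float64)
    drop_lab = np.zeros((h, w), dtype=np.uint16)
    cyto_lab = np.zeros((h, w), dtype=np.uint16)
    nuc_lab = np.zeros((h, w), dtype=np.uint16)

    tex_rng = np.random.default_rng(scene.texture_seed)
    texture = gaussian_filter(tex_rng.normal(size=(h, w)),
                              params.cytoplasm_texture_scale)
    if texture.std() > 0:
        texture = texture / texture.std()
    texture = 1.0 + params.cytoplasm_roughness * texture

    for ci, cell in enumerate(scene.cells, start=1):
        mask, (y0, y1, x0, x1) = _cell_mask(cell, (h, w))
        cyto_lab[y0:y1, x0:x1][mask] = ci
        clean[1, y0:y1, x0:x1][mask] = (
            params.fluor_background
            + params.cytoplasm_level * texture[y0:y1, x0:x1][mask])
        nmask, (ny0, ny1, nx0, nx1) = _nucleus_mask(cell, (h, w))
        nuc_lab[ny0:ny1, nx0:nx1][nmask] = ci
        clean[2, ny0:ny1, nx0:nx1][nmask] = (
            params.fluor_background + params.nucleus_level)

    # large droplets first so small ones stay visible where they overlap
    droplets = sorted(scene.droplets, key=lambda d: -d.radius)
    order = {id(d): k for k, d in enumerate(scene.droplets, start=1)}
    for d in droplets:
        rr, (y0, y1, x0, x1) = _droplet_patch(d, (h, w))
        mask = rr <= d.radius
        prof = 1.0 - params.droplet_falloff * (rr / d.radius) ** 2
        dipy = d.center[0] + d.dip_offset[0]
        dipx = d.center[1] + d.dip_offset[1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dip = np.exp(-((yy - dipy) ** 2 + (xx - dipx) ** 2)
                     / (2 * (0.35 * d.radius) ** 2))
        prof = prof * (1.0 - params.droplet_dip_strength * dip)
        patch = clean[0, y0:y1, x0:x1]
        patch[mask] = params.fluor_background + params.droplet_level * prof[mask]
        drop_lab[y0:y1, x0:x1][mask] = order[id(d)]

    rng = _rng(params.seed, 2)
    sigma = np.reshape(np.broadcast_to(params.fluor_noise_sigma, 3), (3, 1, 1))
    noisy = clean + rng.normal(size=clean.shape) * np.sqrt(
        sigma ** 2 + params.poisson_gain * clean)
    image = np.clip(noisy, 0, 65535).astype(np.uint16)

    objects = {}
    for name, lab, ch in (("droplets", drop_lab, 0),
                          ("cytoplasm", cyto_lab, 1),
                          ("nuclei", nuc_lab, 2)):
        labels = np.unique(lab)
        labels = labels[labels > 0]
        recs = {"label": [], "area": [],
                "mean_droplets": [], "mean_cytoplasm": [], "mean_nuclei": []}
        for lb in labels:
            m = lab == lb
            recs["label"].append(int(lb))
            recs["area"].append(int(m.sum()))
            for k, cname in enumerate(("droplets", "cytoplasm", "nuclei")):
                recs[f"mean_{cname}"].append(float(clean[k][m].mean()))
        objects[name] = recs
    gt = GroundTruth(droplet_labels=drop_lab, cytoplasm_labels=cyto_lab,
                     nucleus_labels=nuc_lab, objects=objects)
    return image, gt


def render_brightfield(scene: Scene, params: PhantomParams) -> np.ndarray:
    """Render the defocus stack, shape (n_slices, H, W), uint16.

    Slice ``j`` sits at defocus ``(j - (n-1)/2) * defocus_step``.  Droplets
    carry a strong signed central contrast that flips polarity across the
    focal plane plus an in-focus dark rim; the cytoplasm is a faint uniform
    darkening; nuclei use their own (default zero) contrast weight, so
    nucleus interiors are statistically indistinguishable from the
    surrounding cytoplasm in the stack.
    """
    _check_scene(scene, params)
    h, w = scene.field_size
    n = params.n_slices
    mid = (n - 1) / 2.0
    rng = _rng(params.seed, 3)
    stack = np.empty((n, h, w), dtype=np.uint16)

    base = np.full((h, w), params.bf_background, dtype=np.float64)
    for cell in scene.cells:
        mask, (y0, y1, x0, x1) = _cell_mask(cell, (h, w))
        base[y0:y1, x0:x1][mask] -= params.cytoplasm_contrast
        if params.nucleus_contrast != 0.0:
            nmask, (ny0, ny1, nx0, nx1) = _nucleus_mask(cell, (h, w))
            base[ny0:ny1, nx0:nx1][nmask] -= params.nucleus_contrast

    for j in range(n):
        delta = 0.0 if mid == 0 else (j - mid) / mid  # signed, in [-1, 1]
        img = base.copy()
        for d in scene.droplets:
            rr, (y0, y1, x0, x1) = _droplet_patch(d, (h, w), pad=3 + 2 * abs(delta))
            center = np.exp(-(rr / (0.55 * d.radius)) ** 2)
            rim_w = 1.0 + 1.5 * abs(delta)
            rim = np.exp(-((rr - d.radius) / rim_w) ** 2)
            prof = (delta * center - 0.5 * delta * rim - 0.35 * rim)
            img[y0:y1, x0:x1] += params.droplet_contrast * prof
        img = gaussian_filter(img, 0.5 + params.defocus_blur * abs(delta))
        img = img + rng.normal(0.0, params.bf_noise_sigma, size=(h, w))
        stack[j] = np.clip(img, 0, 65535).astype(np.uint16)
    return stack


def make_dataset(n_fields: int, params: PhantomParams,
                 out_dir: str | Path, val_fraction: float = 0.0) -> dict:
    """Write ``n_fields`` paired samples as multi-page TIFFs plus a JSON index.

    Per sample: ``*_bf.tif`` (n_slices pages), ``*_fl.tif`` (3 pages),
    ``*_gt.tif`` (3 label-map pages), all 16-bit.  Reproducible given
    ``params.seed``.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_val = int(round(val_fraction * n_fields))
    entries = []
    for i in range(n_fields):
        p = PhantomParams(**{**asdict(params),
                             "seed": None if params.seed is None
                             else (int(params.seed) * 100003 + i) % (2 ** 31)})
        scene = sample_scene(p)
        fl, gt = render_fluorescence(scene, p)
        bf = render_brightfield(scene, p)
        sid = f"sample_{i:04d}"
        bf_path, fl_path, gt_path = (out_dir / f"{sid}_{t}.tif"
                                     for t in ("bf", "fl", "gt"))
        tifffile.imwrite(bf_path, bf, photometric="minisblack")
        tifffile.imwrite(fl_path, fl, photometric="minisblack")
        tifffile.imwrite(gt_path, np.stack([gt.droplet_labels,
                                            gt.cytoplasm_labels,
                                            gt.nucleus_labels]),
                         photometric="minisblack")
        entries.append({
            "id": sid,
            "brightfield": bf_path.name,
            "fluorescence": fl_path.name,
            "ground_truth": gt_path.name,
            "n_slices": p.n_slices,
            "split": "val" if i >= n_fields - n_val else "train",
        })
    index = {"n_fields": n_fields, "field_size": list(params.field_size),
             "seed": params.seed, "entries": entries}
    (out_dir / "index.json").write_text(json.dumps(index, indent=2))
    return index


__all__ = ["PhantomParams", "Scene", "Cell", "Droplet", "GroundTruth",
           "PlacementError", "sample_scene", "render_fluorescence",
           "render_brightfield", "make_dataset"]
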