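"""Phantom generator: geometry invariants, rendering contracts, determinism."""

import json

import numpy as np
import pytest
import tifffile

from virtustain.phantom import (PhantomParams, PlacementError,
                                make_dataset, render_brightfield,
                                render_fluorescence, sample_scene)


def test_zero_cells_gives_empty_scene():
    scene = sample_scene(PhantomParams(n_cells=0, seed=1))
    assert scene.cells == []


def test_scene_is_deterministic_given_seed():
    p = PhantomParams(n_cells=1, droplets_per_cell=10, seed=7)
    a, b = sample_scene(p), sample_scene(p)
    assert a.cells[0].nucleus_center == b.cells[0].nucleus_center
    assert [d.center for d in a.droplets] == [d.center for d in b.droplets]
    assert a.texture_seed == b.texture_seed


def test_nucleus_centres_pairwise_separated():
    p = PhantomParams(n_cells=5, seed=3)
    scene = sample_scene(p)
    centres = [c.nucleus_center for c in scene.cells]
    min_sep = 2 * p.nucleus_radius
    for i in range(len(centres)):
        for j in range(i + 1, len(centres)):
            d = np.hypot(centres[i][0] - centres[j][0],
                         centres[i][1] - centres[j][1])
            assert d >= min_sep


def test_nucleus_inside_cytoplasm_support():
    scene = sample_scene(PhantomParams(n_cells=4, seed=5))
    for cell in scene.cells:
        phi = np.linspace(0, 2 * np.pi, 64)
        boundary = cell.boundary_radius(phi)
        assert boundary.min() >= max(cell.nucleus_axes)


def test_impossible_placement_raises():
    with pytest.raises(PlacementError):
        sample_scene(PhantomParams(field_size=(40, 40), n_cells=30, seed=0))


def test_droplet_radii_positive_and_two_populations():
    scene = sample_scene(PhantomParams(n_cells=3, droplets_per_cell=30,
                                       seed=9))
    pops = {d.population for d in scene.droplets}
    assert all(d.radius > 0 for d in scene.droplets)
    assert pops <= {"small", "large"} and "small" in pops


def test_single_droplet_area_matches_disk():
    p = PhantomParams(field_size=(64, 64), n_cells=1, droplets_per_cell=0,
                      fluor_noise_sigma=0.0, poisson_gain=0.0, seed=2,
                      cell_radius=28.0, nucleus_radius=6.0)
    scene = sample_scene(p)
    from virtustain.phantom import Droplet
    scene.cells[0].droplets.append(Droplet(center=(32.0, 32.0), radius=10.0,
                                           population="large"))
    _, gt = render_fluorescence(scene, p)
    area = (gt.droplet_labels > 0).sum()
    assert area == pytest.approx(np.pi * 100, rel=0.02)


def test_empty_scene_renders_pure_background():
    p = PhantomParams(n_cells=0, fluor_noise_sigma=0.0, poisson_gain=0.0,
                      seed=1, field_size=(32, 32))
    scene = sample_scene(p)
    img, gt = render_fluorescence(scene, p)
    assert np.all(img == int(p.fluor_background))
    assert gt.droplet_labels.max() == 0


def test_ground_truth_label_count_matches_droplets(default_field):
    gt, scene = default_field["gt"], default_field["scene"]
    labels = np.unique(gt.droplet_labels)
    assert len(labels) - 1 == len(scene.droplets)


def test_ground_truth_areas_equal_label_pixel_counts(default_field):
    gt = default_field["gt"]
    for cls, lab in (("droplets", gt.droplet_labels),
                     ("nuclei", gt.nucleus_labels)):
        recs = gt.objects[cls]
        for lb, area in zip(recs["label"], recs["area"]):
            assert (lab == lb).sum() == area


def test_nuclei_invisible_in_brightfield():
    """With zero nucleus contrast, nucleus interiors match the surrounding
    droplet-free cytoplasm to within the read-noise level."""
    from scipy.ndimage import binary_dilation
    params = PhantomParams(n_cells=4, droplets_per_cell=4, seed=21)
    scene = sample_scene(params)
    _, gt = render_fluorescence(scene, params)
    stack = render_brightfield(scene, params)
    droplet_halo = binary_dilation(gt.droplet_labels > 0, iterations=8)
    nuc = (gt.nucleus_labels > 0) & ~droplet_halo
    cyto = (gt.cytoplasm_labels > 0) & (gt.nucleus_labels == 0) & ~droplet_halo
    assert nuc.sum() > 200 and cyto.sum() > 200
    mid = stack[stack.shape[0] // 2].astype(float)
    assert abs(mid[nuc].mean() - mid[cyto].mean()) < params.bf_noise_sigma


def test_brightfield_pure_noise_without_contrast():
    p = PhantomParams(n_cells=2, droplet_contrast=0.0, cytoplasm_contrast=0.0,
                      nucleus_contrast=0.0, seed=4, field_size=(64, 64),
                      cell_radius=20.0, nucleus_radius=6.0)
    scene = sample_scene(p)
    stack = render_brightfield(scene, p)
    flat = stack[0].astype(float)
    assert abs(flat.mean() - p.bf_background) < 5 * p.bf_noise_sigma
    assert flat.std() < 3 * p.bf_noise_sigma


def test_droplet_ring_polarity_flips_across_stack():
    p = PhantomParams(field_size=(64, 64), n_cells=1, droplets_per_cell=0,
                      bf_noise_sigma=0.0, seed=2, cell_radius=28.0,
                      nucleus_radius=6.0)
    scene = sample_scene(p)
    from virtustain.phantom import Droplet
    scene.cells[0].droplets.append(Droplet(center=(32.0, 32.0), radius=8.0,
                                           population="large"))
    stack = render_brightfield(scene, p).astype(float)
    local_bg = stack[:, 5, 5]  # corner, outside the cell
    centre = stack[:, 31:34, 31:34].mean(axis=(1, 2))
    signed = centre - local_bg
    assert np.sign(signed[0]) != np.sign(signed[-1])
    assert abs(signed[0]) > p.droplet_contrast * 0.05


def test_brightfield_regression_favours_droplets_over_nuclei(default_field):
    """The stack linearly explains the droplet channel far better than the
    nucleus channel — the information asymmetry virtual staining must face."""
    stack = default_field["stack"].astype(np.float64) / 65535.0
    fluor = default_field["fluor"].astype(np.float64) / 65535.0
    n = stack.shape[0]
    X = np.c_[stack.reshape(n, -1).T, np.ones(stack[0].size)]

    def r2(y):
        y = y.ravel()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return 1 - resid.var() / y.var()

    assert r2(fluor[0]) > r2(fluor[2]) + 0.2


def test_dataset_roundtrip_and_determinism(tmp_path):
    p = PhantomParams(field_size=(48, 48), n_cells=1, droplets_per_cell=5,
                      cell_radius=20.0, nucleus_radius=6.0, seed=3)
    idx = make_dataset(3, p, tmp_path / "a", val_fraction=0.34)
    assert len(idx["entries"]) == 3
    assert {e["split"] for e in idx["entries"]} == {"train", "val"}
    for e in idx["entries"]:
        for key in ("brightfield", "fluorescence", "ground_truth"):
            assert (tmp_path / "a" / e[key]).exists()
    make_dataset(3, p, tmp_path / "b", val_fraction=0.34)
    for e in idx["entries"]:
        a = tifffile.imread(tmp_path / "a" / e["brightfield"])
        b = tifffile.imread(tmp_path / "b" / e["brightfield"])
        assert np.array_equal(a, b)
    with pytest.raises(ValueError):
        make_dataset(0, p, tmp_path / "c")
    index = json.loads((tmp_path / "a" / "index.json").read_text())
    assert index["n_fields"] == 3


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        PhantomParams(n_slices=0)
    with pytest.raises(ValueError):
        PhantomParams(fluor_noise_sigma=-1.0)
    with pytest.raises(ValueError):
        PhantomParams(droplet_contrast=-5.0)
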