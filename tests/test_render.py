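"""Camera, render loop, image output and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from voxpt import (Camera, Light, Scene, generate_ray, read_pfm, render,
                   tone_map, write_pfm)
from voxpt.cli import main as cli_main
from voxpt.tf import CoefficientVector, TFBinding, TFManager, TransferFunction
from voxpt.volume import ProxyVolumeSet

from conftest import constant_volume


def _empty_scene(E=(2.0, 1.0, 0.5), w=6, h=4):
    vol = constant_volume(8, value=0.0)
    pvs = ProxyVolumeSet({"primary": vol})
    tf = TransferFunction("CCTF", points=[
        (0.0, CoefficientVector(opacity=0.0)),
        (1.0, CoefficientVector(opacity=0.0))])
    mgr = TFManager(pvs, [TFBinding("primary", tf)])
    cam = Camera(position=[0, 0, -2], look_at=[0, 0, 0], width=w, height=h)
    return Scene(pvs, mgr, cam, [Light("uniform_environment", radiance=E)],
                 leaf_level=2)


# -- camera -----------------------------------------------------------------

def test_center_ray_points_at_look_at():
    cam = Camera(position=[1.0, 2.0, -3.0], look_at=[0.0, 0.0, 1.0],
                 fov=50.0, width=9, height=9)
    o, d = generate_ray(cam, 4, 4, 0.5, 0.5)
    expect = np.array([0, 0, 1.0]) - np.array([1.0, 2.0, -3.0])
    assert np.allclose(d, expect / np.linalg.norm(expect), atol=1e-12)
    assert np.allclose(o, cam.position)


def test_vertical_ray_spread_matches_fov():
    cam = Camera(position=[0, 0, -2], look_at=[0, 0, 0], fov=40.0,
                 width=8, height=8)
    _, top = generate_ray(cam, 4, 0, 0.0, 0.0)       # upper image edge
    _, bot = generate_ray(cam, 4, cam.height - 1, 0.0, 1.0)
    ang = np.degrees(np.arccos(np.clip(np.dot(top, bot), -1, 1)))
    assert ang == pytest.approx(40.0, abs=1e-6)


def test_jitter_brackets_pixel_footprint():
    cam = Camera(position=[0, 0, -2], look_at=[0, 0, 0], width=4, height=4)
    _, d00 = generate_ray(cam, 1, 1, 0.0, 0.0)
    _, d11 = generate_ray(cam, 1, 1, 1.0, 1.0)
    _, d_next = generate_ray(cam, 2, 2, 0.0, 0.0)
    assert np.allclose(d11, d_next, atol=1e-12)
    assert not np.allclose(d00, d11)


def test_camera_validation():
    with pytest.raises(ValueError):
        Camera(position=[0, 0, 0], look_at=[0, 0, 1], up=[0, 0, 1])
    with pytest.raises(ValueError):
        Camera(position=[0, 0, 0], look_at=[0, 0, 1], fov=0.0)


# -- render loop ------------------------------------------------------------

def test_empty_scene_returns_environment_exactly():
    E = (2.0, 1.0, 0.5)
    img = render(_empty_scene(E), spp=4, seed=0)
    assert np.all(img == np.asarray(E))


def test_render_is_deterministic(blob_scene):
    a = render(blob_scene, spp=8, seed=5)
    b = render(blob_scene, spp=8, seed=5)
    assert np.array_equal(a, b)
    c = render(blob_scene, spp=8, seed=6)
    assert not np.array_equal(a, c)


def test_accumulation_splits_reproduce_single_run(blob_scene):
    """Counter-based per-sample RNG: averaging the sample ranges [0, 6) and
    [6, 12) equals one 12-sample render bit for bit."""
    a = render(blob_scene, spp=6, seed=4, base_sample=0)
    b = render(blob_scene, spp=6, seed=4, base_sample=6)
    whole = render(blob_scene, spp=12, seed=4)
    assert np.allclose((a + b) / 2, whole, rtol=0, atol=1e-12)


def test_energy_conservation_under_unit_environment(blob_scene):
    """Le = 0, A,S <= 1: the mean radiance cannot exceed the environment."""
    stats = render(blob_scene, spp=32, seed=7, return_stats=True)
    mean, se = stats.mean_se()
    assert np.all(np.isfinite(stats.image))
    assert np.all(stats.image >= 0)
    assert np.all(mean <= 1.0 + 3 * se)


def test_majorant_violation_tripwire(blob_scene):
    blob_scene.prepare()
    saved = blob_scene.octree.max_ext.copy()
    blob_scene.octree.max_ext *= 0.2  # corrupt the stored bounds
    try:
        with pytest.raises(ValueError, match="majorant"):
            render(blob_scene, spp=4, seed=0)
    finally:
        blob_scene.octree.max_ext[:] = saved


def test_tf_edit_then_update_keeps_majorants_sound(blobs32):
    """The interactive loop: change the TF, re-update, render — the
    soundness tripwire must never fire."""
    tf = TransferFunction("CCTF", points=[
        (0.1, CoefficientVector(opacity=0.0)),
        (0.8, CoefficientVector(opacity=0.4))])
    mgr = TFManager(blobs32, [TFBinding("primary", tf)], density_scale=6.0)
    cam = Camera(position=[0, 0, -1.6], look_at=[0, 0, 0], width=8, height=8)
    scene = Scene(blobs32, mgr, cam,
                  [Light("uniform_environment", radiance=[1, 1, 1])],
                  leaf_level=3)
    render(scene, spp=4, seed=1)
    mgr.bindings[0] = TFBinding("primary", TransferFunction("CCTF", points=[
        (0.05, CoefficientVector(opacity=0.0)),
        (0.5, CoefficientVector(opacity=1.0))]))
    scene.invalidate()
    render(scene, spp=4, seed=1)  # must not raise the majorant tripwire


def test_trace_path_single_ray_api(blob_scene):
    """The single-ray entry point: exact env for a miss, finite and
    non-negative radiance through the medium."""
    from voxpt import trace_path
    E = np.array([2.0, 1.0, 0.5])
    scene = _empty_scene(tuple(E))
    out = trace_path([0, 0, -2], [0, 0, 1], scene, rng=3)
    assert np.array_equal(out, E)
    rng = np.random.default_rng(0)
    for seed in range(20):
        o = np.array([rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), -1.5])
        out = trace_path(o, [0, 0.05, 1], blob_scene, rng=seed)
        assert np.all(np.isfinite(out)) and np.all(out >= 0)


# -- images -----------------------------------------------------------------

def test_tone_map_properties():
    assert np.all(tone_map(np.zeros((2, 2, 3))) == 0)
    big = tone_map(np.full((1, 1, 3), 1e9))
    assert np.all(big >= 254)
    rng = np.random.default_rng(0)
    a = rng.random((8, 8, 3)) * 5
    b = a + rng.random((8, 8, 3))
    assert np.all(tone_map(b) >= tone_map(a))
    with pytest.raises(ValueError):
        tone_map(a, exposure=0.0)


def test_pfm_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    img = rng.random((5, 7, 3)).astype(np.float32) * 10
    p = tmp_path / "img.pfm"
    write_pfm(p, img)
    assert np.array_equal(read_pfm(p), img)


# -- CLI --------------------------------------------------------------------

def _write_scene_json(tmp_path, spp=4):
    doc = {
        "volumes": {"phantom": {"family": "gaussian_blobs",
                                "resolution": 24, "seed": 2}},
        "tf": {"proxies": ["primary"], "mode": "multiply",
               "density_scale": 6.0,
               "bindings": [{"proxy": "primary", "form": "CCTF",
                             "points": [{"value": 0.1, "opacity": 0.0},
                                        {"value": 0.8, "opacity": 0.9}]}],
               "materials": []},
        "accelerator": {"leaf_level": 3, "hd": 0.2, "hu": 0.6},
        "integrator": {"spp": spp, "seed": 1, "max_bounces": 16,
                       "shadow_factor_a": 0.8, "channels": "single"},
        "camera": {"position": [0, 0.2, -1.6], "look_at": [0, 0, 0],
                   "fov": 35, "width": 8, "height": 8},
        "lights": [{"kind": "uniform_environment",
                    "radiance": [1.0, 1.0, 1.0]}]}
    path = tmp_path / "scene.json"
    path.write_text(json.dumps(doc))
    return path


def test_cli_render_writes_pfm_and_png(tmp_path):
    scene_path = _write_scene_json(tmp_path)
    runner = CliRunner()
    res = runner.invoke(cli_main, ["render", "--scene", str(scene_path),
                                   "--spp", "2", "--seed", "7",
                                   "--out", str(tmp_path / "img")])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "img.pfm").exists()
    assert (tmp_path / "img.png").exists()
    # end-to-end determinism: a second run is byte-identical
    first = (tmp_path / "img.pfm").read_bytes()
    res = runner.invoke(cli_main, ["render", "--scene", str(scene_path),
                                   "--spp", "2", "--seed", "7",
                                   "--out", str(tmp_path / "img2")])
    assert res.exit_code == 0
    assert (tmp_path / "img2.pfm").read_bytes() == first


def test_cli_phantom_writes_proxy_triplet(tmp_path):
    runner = CliRunner()
    res = runner.invoke(cli_main, ["phantom", "--family", "nested_shells",
                                   "--res", "16", "--seed", "1",
                                   "--out", str(tmp_path / "ph")])
    assert res.exit_code == 0, res.output
    for role in ("primary", "gradient_magnitude", "mask"):
        assert (tmp_path / "ph" / f"{role}.raw").exists()
        assert (tmp_path / "ph" / f"{role}.json").exists()


def test_cli_validate_tf_rejects_bad_binding(tmp_path):
    doc = {"mode": "multiply",
           "bindings": [{"proxy": "mask", "form": "CCTF",
                         "points": [{"value": 0, "opacity": 0},
                                    {"value": 1, "opacity": 1}]}]}
    path = tmp_path / "tf.json"
    path.write_text(json.dumps(doc))
    runner = CliRunner()
    res = runner.invoke(cli_main, ["validate-tf", "--tf", str(path)])
    assert res.exit_code != 0
    assert "binding 0" in res.output


def test_cli_update_octree_reports_levels(tmp_path):
    scene_path = _write_scene_json(tmp_path)
    runner = CliRunner()
    res = runner.invoke(cli_main, ["update-octree", "--scene",
                                   str(scene_path)])
    assert res.exit_code == 0, res.output
    assert "level 0" in res.output and "level 3" in res.output
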