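"""Frame composition, animation semantics, and the dwell-time skip rule."""

import xml.etree.ElementTree as ET

import pytest

from cofoldviz import (
    ParameterError,
    RenderConfig,
    filter_by_occupancy,
    frame_duration_ms,
    generate_fixture,
    min_dwell_time,
    render_animation,
    render_frame,
    write_animation,
)
from cofoldviz.renderer import CURSOR_ID, END_MARKER_ID
from cofoldviz.scene import SVG_NS

CFG = RenderConfig(layout_iterations=60)  # lighter relaxation for test speed


def svg_root(svg: str) -> ET.Element:
    return ET.fromstring(svg)


def find_by_id(root, elem_id):
    return root.find(f".//*[@id='{elem_id}']")


def structure_tiles(root):
    # one id label per treemap tile
    return [
        el
        for el in root.iter(f"{{{SVG_NS}}}text")
        if (el.text or "").startswith("id ")
    ]


def test_single_structure_frame_geometry():
    traj = generate_fixture("single-hairpin", seed=1, n_timepoints=8, final_length=20)
    svg = render_frame(traj, traj.times[0], CFG)
    root = svg_root(svg)  # well-formed XML by construction of the parse
    assert len(structure_tiles(root)) == 1
    marker = find_by_id(root, END_MARKER_ID)
    assert marker is not None
    # marker sits at 75% of the axis width
    m, w = CFG.margin, CFG.width
    expected_x = m + 0.75 * (w - 2 * m)
    assert float(marker.get("x1")) == pytest.approx(expected_x, abs=0.01)
    assert marker.get("x1") == marker.get("x2")
    assert find_by_id(root, CURSOR_ID) is not None


def test_svg_is_self_contained():
    traj = generate_fixture("helix-competition", seed=3, n_timepoints=6, final_length=16)
    svg = render_frame(traj, traj.times[-1], CFG)
    assert "http://www.w3.org/2000/svg" in svg
    for external in ("href", "url(", "<image", "<script"):
        assert external not in svg


def test_sum_of_occupancies_annotation_has_four_decimals(competition_traj):
    svg = render_frame(competition_traj, 2.0, RenderConfig(min_occupancy=0.0, layout_iterations=60))
    root = svg_root(svg)
    label = find_by_id(root, "sum-occupancy")
    assert label.text == "sum of occupancies: 1.0000"
    # filtering drops the 0.05 record: sum becomes 0.95, printed with 4 decimals
    svg2 = render_frame(competition_traj, 2.0, RenderConfig(min_occupancy=0.1, layout_iterations=60))
    label2 = find_by_id(svg_root(svg2), "sum-occupancy")
    assert label2.text == "sum of occupancies: 0.9500"


def test_frame_determinism():
    traj = generate_fixture("helix-competition", seed=5, n_timepoints=6, final_length=16)
    a = render_frame(traj, 1.0, CFG)
    b = render_frame(traj, 1.0, CFG)
    assert a == b  # byte-identical


def test_out_of_range_time_clamped_with_warning():
    traj = generate_fixture("single-hairpin", seed=1, n_timepoints=6, final_length=12)
    with pytest.warns(UserWarning, match="clamp"):
        svg = render_frame(traj, 1e9, CFG)
    assert svg == render_frame(traj, traj.times[-1], CFG)


def test_animation_one_frame_per_time_point():
    traj = generate_fixture("helix-competition", seed=2, n_timepoints=12, final_length=20)
    frames = render_animation(traj, CFG)
    assert len(frames) == 12
    assert [t for t, _ in frames] == list(traj.times)


def test_animation_filtering_drops_frames():
    traj = generate_fixture("helix-competition", seed=2, n_timepoints=8, final_length=16)
    cfg = RenderConfig(min_occupancy=0.2, layout_iterations=60)
    frames = render_animation(traj, cfg)
    assert len(frames) == len(filter_by_occupancy(traj, 0.2).times)


def test_filter_then_render_commutes():
    traj = generate_fixture("helix-competition", seed=4, n_timepoints=6, final_length=16)
    cfg = RenderConfig(min_occupancy=0.1, layout_iterations=60)
    pre = filter_by_occupancy(traj, 0.1)
    t = pre.times[-1]
    assert render_frame(pre, t, cfg) == render_frame(traj, t, cfg)


def test_frame_duration_is_reciprocal_of_speed():
    assert frame_duration_ms(RenderConfig(speed=4.0)) == 250.0


@pytest.mark.parametrize("m,expected", [(1, 5.0), (7, 35.0), (20, 100.0), (0, 0.0)])
def test_min_dwell_time_rule(m, expected):
    assert min_dwell_time(m) == expected


def test_min_dwell_time_rejects_negative():
    with pytest.raises(ParameterError):
        min_dwell_time(-1)


def test_write_animation_svg_series_and_gif(tmp_path):
    traj = generate_fixture("single-hairpin", seed=1, n_timepoints=5, final_length=12)
    cfg = RenderConfig(speed=4.0, layout_iterations=40)
    gif = tmp_path / "anim.gif"
    paths = write_animation(traj, cfg, outdir=tmp_path / "frames", gif_path=gif)
    assert len(paths) == 5
    for p in paths:
        ET.fromstring(p.read_text())  # every frame is well-formed XML
    from PIL import Image

    with Image.open(gif) as img:
        assert img.n_frames == 5
        assert img.info["duration"] == 250


def test_invalid_config_rejected():
    with pytest.raises(ParameterError):
        RenderConfig(min_occupancy=2.0)
    with pytest.raises(ParameterError):
        RenderConfig(speed=0.0)
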