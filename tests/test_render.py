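import xml.etree.ElementTree as ET

import numpy as np
import pytest

from seqbundles import (
    Alignment,
    RenderSpec,
    assign_groups,
    auto_opacity,
    builtin_scale,
    effective_darkness,
    export,
    render_bundle,
    render_streamgraph,
    select_by_residue,
    single_group,
)

SVG_NS = "{http://www.w3.org/2000/svg}"


@pytest.fixture(scope="module")
def scale():
    return builtin_scale("hydrophobicity_wampler")


@pytest.fixture
def small_ga():
    aln = Alignment(
        ("p1", "p2", "p3", "n1", "n2"),
        ("ACDKA", "ACDKA", "AC-KV", "GCDKA", "GCDFA"),
    )
    return assign_groups(
        aln, [("pos", "#000000", [0, 1, 2]), ("neg", "#33A6E6", [3, 4])]
    )


# ------------------------------------------------------ darkness model --

@pytest.mark.parametrize(
    "n,opacity,expected",
    [(1, 0.02, 0.02), (0, 0.5, 0.0), (2, 0.02, 0.0396)],
)
def test_effective_darkness_values(n, opacity, expected):
    assert effective_darkness(n, opacity) == pytest.approx(expected)


def test_effective_darkness_monotone():
    ds = [effective_darkness(n, 0.02) for n in range(0, 200, 5)]
    assert all(b > a for a, b in zip(ds, ds[1:]))
    os_ = [effective_darkness(10, o) for o in np.linspace(0.01, 1.0, 20)]
    assert all(b > a for a, b in zip(os_, os_[1:]))


def test_effective_darkness_domain():
    with pytest.raises(ValueError):
        effective_darkness(-1, 0.5)
    with pytest.raises(ValueError):
        effective_darkness(2, 0.0)


def test_auto_opacity_inverts_darkness():
    for n in (1, 10, 88, 500):
        o = auto_opacity(n, 0.95)
        assert effective_darkness(n, o) == pytest.approx(0.95)


# ------------------------------------------------------- bundle render --

def test_one_path_per_sequence(small_ga, scale):
    doc = render_bundle(small_ga, scale)
    assert len(doc.paths()) == small_ga.alignment.n_rows


def test_identical_sequences_coincide_up_to_stack_offset(scale):
    aln = Alignment(("a", "b"), ("ACDK", "ACDK"))
    doc = render_bundle(single_group(aln), scale)
    p1, p2 = doc.paths()
    segs1, segs2 = p1.meta["segments"], p2.meta["segments"]
    t = RenderSpec().line_thickness
    for s1, s2 in zip(segs1, segs2):
        for (x1, y1), (x2, y2) in zip(s1, s2):
            assert x1 == x2
            assert y2 - y1 == pytest.approx(t)


def test_path_opacity_attribute_matches_spec(small_ga, scale):
    doc = render_bundle(small_ga, scale, RenderSpec(opacity=0.02))
    for p in doc.paths():
        assert p.attrs["opacity"] == "0.02"


def test_group_colors_and_draw_order(small_ga, scale):
    doc = render_bundle(small_ga, scale)
    strokes = [p.attrs["stroke"] for p in doc.paths()]
    assert strokes == ["#000000"] * 3 + ["#33A6E6"] * 2


def test_highlight_adds_copies_on_top(small_ga, scale):
    sel = select_by_residue(small_ga, "pos", 1, "A")
    doc = render_bundle(small_ga, scale, highlight=sel)
    paths = doc.paths()
    assert len(paths) == small_ga.alignment.n_rows + sel.size
    spec = RenderSpec()
    for p in paths[-sel.size:]:
        assert p.attrs["class"] == "highlight"
        assert p.attrs["stroke"] == spec.highlight_color


def test_empty_highlight_identical_to_plain_render(small_ga, scale):
    sel = select_by_residue(small_ga, "pos", 1, "W")
    assert sel.size == 0
    plain = render_bundle(small_ga, scale)
    with_empty = render_bundle(small_ga, scale, highlight=sel)
    assert plain.to_svg() == with_empty.to_svg()


def test_legend_carries_sizes_total_and_ratio(scale):
    n_pos, n_neg = 886, 923
    rows = tuple("A" for _ in range(n_pos + n_neg))
    ids = tuple(f"s{i}" for i in range(n_pos + n_neg))
    ga = assign_groups(
        Alignment(ids, rows),
        [("pos", "#000000", range(n_pos)),
         ("neg", "#33A6E6", range(n_pos, n_pos + n_neg))],
    )
    svg = render_bundle(ga, scale).to_svg()
    assert "1809" in svg
    assert "100:96" in svg


def test_consensus_rows_rendered_per_group(small_ga, scale):
    svg = render_bundle(small_ga, scale).to_svg()
    # group labels of the consensus annotation rows
    assert ">pos</text>" in svg
    assert ">neg</text>" in svg


def test_auto_opacity_used_when_unset(scale):
    n = 40
    aln = Alignment(tuple(f"s{i}" for i in range(n)), ("A",) * n)
    ga = single_group(aln)
    doc = render_bundle(ga, scale, RenderSpec(opacity=None))
    expected = auto_opacity(4)  # floor(40/10) overlay layers
    assert float(doc.paths()[0].attrs["opacity"]) == pytest.approx(expected)


def test_byte_identical_svg_on_repeat(small_ga, scale):
    a = render_bundle(small_ga, scale).to_svg()
    b = render_bundle(small_ga, scale).to_svg()
    assert a == b


# ---------------------------------------------------------- streamgraph --

def test_streamgraph_conserved_full_thickness_ribbons(scale):
    n = 6
    aln = Alignment(tuple(f"s{i}" for i in range(n)), ("ACDK",) * n)
    ga = single_group(aln)
    doc = render_streamgraph(ga, None, scale, k=2, min_support=0.1)
    ribbons = [e for e in doc.elements if e.meta.get("role") == "ribbon"]
    assert len(ribbons) == 3  # one per adjacent column pair
    for r in ribbons:
        assert r.meta["count"] == n


def test_streamgraph_ribbon_thickness_orders_by_count(scale):
    from seqbundles import Bifurcation, FixtureSpec, GroupFixture, generate

    spec = FixtureSpec(
        groups=(
            GroupFixture("g", "#000000", 50,
                         (Bifurcation((1, 5), "KVEGI", "AKADV", 0.4, 0.4),)),
        ),
        n_cols=5, seed=9,
    )
    ga, manifest = generate(spec)
    doc = render_streamgraph(ga, "g", scale, k=3, min_support=0.05)
    ribbons = [e for e in doc.elements if e.meta.get("role") == "ribbon"]
    assert ribbons, "planted bifurcation must produce ribbons"
    for r in ribbons:
        width = float(r.attrs["stroke-width"])
        assert width == pytest.approx(
            RenderSpec().effective_slot_height * r.meta["count"] / 50
        )
    # motif-pair ribbons dominate consensus-chimera ribbons
    feat = manifest["groups"]["g"]["features"][0]
    counts = sorted({r.meta["count"] for r in ribbons}, reverse=True)
    assert counts[0] == max(feat["n_a"], feat["n_b"])


def test_streamgraph_k1_traces_argmax(scale):
    aln = Alignment(tuple("abcd"), ("AAK", "AAK", "AAC", "GAK"))
    ga = single_group(aln)
    doc = render_streamgraph(ga, None, scale, k=1, min_support=0.01)
    bands = [e for e in doc.elements if e.meta.get("role") == "band"]
    assert [b.meta["symbol"] for b in bands] == ["A", "A", "K"]


def test_streamgraph_omits_ribbons_below_min_support(scale):
    aln = Alignment(tuple("abcde"), ("AK", "AK", "AK", "AC", "GC"))
    ga = single_group(aln)
    doc = render_streamgraph(ga, None, scale, k=3, min_support=0.5)
    ribbons = [e for e in doc.elements if e.meta.get("role") == "ribbon"]
    assert [r.meta["pair"] for r in ribbons] == [("A", "K")]


# --------------------------------------------------------------- export --

def test_svg_export_parses_with_correct_path_count(small_ga, scale, tmp_path):
    doc = render_bundle(small_ga, scale)
    out = tmp_path / "b.svg"
    export(doc, out, "svg")
    tree = ET.parse(out)
    paths = tree.getroot().iter(f"{SVG_NS}path")
    assert len(list(paths)) == small_ga.alignment.n_rows


def test_svg_export_byte_identical(small_ga, scale, tmp_path):
    doc = render_bundle(small_ga, scale)
    export(doc, tmp_path / "a.svg", "svg")
    export(doc, tmp_path / "b.svg", "svg")
    assert (tmp_path / "a.svg").read_bytes() == (tmp_path / "b.svg").read_bytes()


def test_pdf_export_written(small_ga, scale, tmp_path):
    doc = render_bundle(small_ga, scale)
    out = tmp_path / "b.pdf"
    export(doc, out, "pdf")
    assert out.read_bytes().startswith(b"%PDF")


def test_png_double_scale_doubles_pixels(small_ga, scale, tmp_path):
    from PIL import Image

    doc = render_bundle(small_ga, scale)
    export(doc, tmp_path / "x1.png", "png", png_scale=1.0)
    export(doc, tmp_path / "x2.png", "png", png_scale=2.0)
    w1, h1 = Image.open(tmp_path / "x1.png").size
    w2, h2 = Image.open(tmp_path / "x2.png").size
    assert (w2, h2) == (2 * w1, 2 * h1)


def test_unknown_format_rejected(small_ga, scale, tmp_path):
    doc = render_bundle(small_ga, scale)
    with pytest.raises(ValueError, match="unknown export format"):
        export(doc, tmp_path / "b.gif", "gif")
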