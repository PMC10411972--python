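"""Morphology module: SWC round trips, Sholl/branch morphometry vs brute
force, and the synthetic generator's genotype presets."""

import warnings

import numpy as np
import pytest

from msnsim import morphology as mm
from msnsim.morphology import (
    MorphNode,
    MorphogenParams,
    Morphology,
    NodeKind,
    ShollProfile,
    StructureError,
    SWCParseError,
)

from conftest import random_tree


# -- SWC I/O ------------------------------------------------------------------


def test_swc_round_trip_random_trees(tmp_path):
    for seed in range(10):
        tree = random_tree(seed)
        path = tmp_path / f"t{seed}.swc"
        mm.write_swc(tree, path)
        back = mm.read_swc(path)
        assert len(back.nodes) == len(tree.nodes)
        for a, b in zip(tree.nodes, back.nodes):
            assert (a.id, a.parent_id, a.kind) == (b.id, b.parent_id, b.kind)
            assert np.allclose(
                [a.x, a.y, a.z, a.radius], [b.x, b.y, b.z, b.radius], atol=1e-6
            )
        # a second write is byte-identical: the format is self-reproducing
        path2 = tmp_path / f"t{seed}b.swc"
        mm.write_swc(back, path2)
        assert path.read_text() == path2.read_text()


def test_read_swc_three_node_stick(tmp_path):
    path = tmp_path / "stick.swc"
    path.write_text(
        "# comment\n1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n3 3 30 0 0 1 2\n"
    )
    morph = mm.read_swc(path)
    assert len(morph.nodes) == 3
    assert mm.total_dendritic_length(morph) == pytest.approx(30.0)


@pytest.mark.parametrize(
    "body,error,match",
    [
        ("1 1 0 0 0 5 -1\n2 3 1 0 0 1 9\n", StructureError, "undefined parent"),
        ("1 1 0 0 0 5 -1\n2 3 1 0 0 1 -1\n", StructureError, "one root"),
        ("1 1 0 0 0 5\n", SWCParseError, "line 1"),
        ("1 1 0 0 zz 5 -1\n", SWCParseError, "line 1"),
    ],
)
def test_read_swc_errors(tmp_path, body, error, match):
    path = tmp_path / "bad.swc"
    path.write_text(body)
    with pytest.raises(error, match=match):
        mm.read_swc(path)


def test_single_soma_writes_one_data_line(tmp_path, fixtures):
    path = tmp_path / "soma.swc"
    mm.write_swc(fixtures["sphere"], path)
    data_lines = [
        l for l in path.read_text().splitlines() if l and not l.startswith("#")
    ]
    assert len(data_lines) == 1


# -- Sholl analysis -----------------------------------------------------------


def brute_force_crossings(morph, r, n_samples=4096):
    """Independent Sholl oracle: dense sampling of the distance profile
    along each dendritic segment, counting sign changes of d(t) - r."""
    center = morph.soma_center()
    total = 0
    ts = np.linspace(0.0, 1.0, n_samples)
    for parent, child in morph.segments(dendrite_only=True):
        pts = parent.xyz[None, :] + ts[:, None] * (child.xyz - parent.xyz)[None, :]
        d = np.linalg.norm(pts - center, axis=1) - r
        signs = np.sign(d)
        # treat exact zeros by nudging towards the previous sign
        for i in range(1, len(signs)):
            if signs[i] == 0:
                signs[i] = -signs[i - 1] if signs[i - 1] != 0 else 1
        total += int(np.sum(signs[1:] * signs[:-1] < 0))
    return total


def test_sholl_star_counts(fixtures):
    profile = mm.sholl(fixtures["star4"], 10.0)
    for r, c in zip(profile.radii, profile.counts):
        assert c == (4 if r <= 80.0 else 0), r


def test_sholl_single_dendrite_counts_at_exact_tip(fixtures):
    profile = mm.sholl(fixtures["stick100"], 10.0)
    assert list(profile.radii) == pytest.approx(list(np.arange(10.0, 101.0, 10.0)))
    assert all(c == 1 for c in profile.counts)


@pytest.mark.parametrize("step", [5.0, 10.0])
def test_sholl_matches_brute_force(step):
    for seed in range(12):
        tree = random_tree(seed)
        profile = mm.sholl(tree, step)
        for r, c in zip(profile.radii, profile.counts):
            assert c == brute_force_crossings(tree, r), (seed, r)


def test_sholl_requires_valid_step(fixtures):
    with pytest.raises(mm.MorphologyError):
        mm.sholl(fixtures["star4"], 0.0)


def test_centroid_and_max_radius():
    profile = ShollProfile(
        radii=np.array([10.0, 20.0]), counts=np.array([1, 3]), step=10.0
    )
    assert mm.centroid(profile) == pytest.approx(17.5)
    assert mm.max_radius(profile) == pytest.approx(20.0)

    sym = ShollProfile(
        radii=np.array([40.0, 50.0, 60.0]), counts=np.array([2, 5, 2]), step=10.0
    )
    assert mm.centroid(sym) == pytest.approx(50.0)

    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = rng.integers(0, 8, size=12)
        if counts.sum() == 0:
            counts[3] = 1
        radii = 5.0 * np.arange(1, 13, dtype=float)
        p = ShollProfile(radii=radii, counts=counts, step=5.0)
        assert mm.centroid(p) == pytest.approx(np.average(radii, weights=counts))
        assert mm.max_radius(p) == pytest.approx(radii[np.nonzero(counts)[0][-1]])

    empty = ShollProfile(
        radii=np.array([10.0, 20.0]), counts=np.array([0, 0]), step=10.0
    )
    with pytest.raises(mm.MorphologyError):
        mm.centroid(empty)
    with pytest.raises(mm.MorphologyError):
        mm.max_radius(empty)


# -- coverage area ------------------------------------------------------------


def gift_wrap_area(points):
    """O(n h) convex hull + shoelace, independent of scipy."""
    pts = [tuple(p) for p in points]
    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for p in pts:
            if p == current:
                continue
            cross = (candidate[0] - current[0]) * (p[1] - current[1]) - (
                candidate[1] - current[1]
            ) * (p[0] - current[0])
            if cross < 0 or (
                cross == 0
                and (p[0] - current[0]) ** 2 + (p[1] - current[1]) ** 2
                > (candidate[0] - current[0]) ** 2
                + (candidate[1] - current[1]) ** 2
            ):
                candidate = p
        if candidate == start:
            break
        hull.append(candidate)
        current = candidate
    area = 0.0
    for i in range(len(hull)):
        x0, y0 = hull[i]
        x1, y1 = hull[(i + 1) % len(hull)]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


def _cloud_morphology(points):
    nodes = [MorphNode(1, -1, NodeKind.soma, 0.0, 0.0, 0.0, 5.0)]
    for x, y in points:
        nodes.append(
            MorphNode(len(nodes) + 1, 1, NodeKind.dendrite, float(x), float(y), 0.0, 0.5)
        )
    return Morphology(nodes)


def test_coverage_square():
    morph = _cloud_morphology([(-50, -50), (-50, 50), (50, 50), (50, -50)])
    assert mm.coverage_area(morph) == pytest.approx(10000.0)


def test_coverage_collinear_is_zero_with_warning():
    morph = _cloud_morphology([(0, 0), (10, 0), (20, 0), (35, 0)])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        assert mm.coverage_area(morph) == 0.0
    assert any("degenerate" in str(w.message) for w in caught)


def test_coverage_matches_gift_wrapping_oracle():
    rng = np.random.default_rng(1)
    for _ in range(30):
        pts = rng.normal(0, 60, size=(rng.integers(4, 40), 2))
        morph = _cloud_morphology(pts)
        assert mm.coverage_area(morph) == pytest.approx(
            gift_wrap_area(pts), rel=1e-9
        )


# -- branch metrics -----------------------------------------------------------


def test_branch_metrics_stick_and_y(fixtures):
    stick = mm.branch_metrics(fixtures["stick100"])
    assert stick.n_branches == 1
    assert stick.n_branching_points == 0
    assert stick.total_dendritic_length == pytest.approx(100.0)

    y = mm.branch_metrics(fixtures["Y_tree"])
    assert y.n_branches == 3
    assert y.n_branching_points == 1
    assert y.total_dendritic_length == pytest.approx(50.0 + 80.0)
    assert y.mean_branch_length == pytest.approx(y.total_dendritic_length / 3)


def test_branch_metrics_conserve_length_on_random_trees():
    for seed in range(15):
        tree = random_tree(seed)
        summary = mm.branch_metrics(tree)
        assert summary.total_dendritic_length == pytest.approx(
            mm.total_dendritic_length(tree), rel=1e-9
        )
        assert summary.n_branches * summary.mean_branch_length == pytest.approx(
            summary.total_dendritic_length, rel=1e-9
        )
        # independent branch count: starts = soma stems + branching fan-outs
        children = {}
        index = {n.id: n for n in tree.nodes}
        for n in tree.nodes:
            if n.kind is NodeKind.dendrite and n.parent_id != -1:
                children.setdefault(n.parent_id, []).append(n)
        n_starts = 0
        for n in tree.nodes:
            kids = len(children.get(n.id, []))
            if n.kind is NodeKind.soma and kids:
                n_starts += kids
            elif n.kind is NodeKind.dendrite and kids >= 2:
                n_starts += kids
        assert summary.n_branches == n_starts


def test_spine_number():
    assert mm.estimate_spine_number(0.0, 1234.0) == 0.0
    assert mm.estimate_spine_number(1.2, 1000.0) == pytest.approx(1200.0)
    assert mm.estimate_spine_number(2.4, 500.0) == pytest.approx(
        mm.estimate_spine_number(1.2, 1000.0)
    )
    with pytest.raises(mm.MorphologyError):
        mm.estimate_spine_number(-1.0, 10.0)


# -- synthetic generator ------------------------------------------------------


def test_synthesize_deterministic():
    params = mm.morphogen_preset("wt")
    a = mm.synthesize_morphology(params, 1)
    b = mm.synthesize_morphology(params, 1)
    assert a.nodes == b.nodes


def test_synthesize_respects_length_target():
    params = MorphogenParams(target_total_length_um=2000.0, target_tolerance=0.10)
    for seed in range(5):
        morph = mm.synthesize_morphology(params, seed)
        assert 1800.0 <= mm.total_dendritic_length(morph) <= 2200.0


def test_synthesize_unreachable_target_raises():
    params = MorphogenParams(
        target_total_length_um=1e6, target_tolerance=0.01, max_attempts=5
    )
    with pytest.raises(mm.GenerationError):
        mm.synthesize_morphology(params, 0)


def test_knockout_preset_exceeds_wild_type():
    """The knockout preset must encode the genotype effect direction:
    larger total dendritic length, more branches, larger maximal radius."""
    wt_p, ko_p = mm.morphogen_preset("wt"), mm.morphogen_preset("ko")
    wt_len, ko_len, wt_br, ko_br, wt_r, ko_r = [], [], [], [], [], []
    for seed in range(25):
        wt = mm.synthesize_morphology(wt_p, seed)
        ko = mm.synthesize_morphology(ko_p, seed)
        wt_len.append(mm.total_dendritic_length(wt))
        ko_len.append(mm.total_dendritic_length(ko))
        ws, ks = mm.branch_metrics(wt), mm.branch_metrics(ko)
        wt_br.append(ws.n_branches)
        ko_br.append(ks.n_branches)
        wt_r.append(ws.max_radius)
        ko_r.append(ks.max_radius)
    assert np.mean(ko_len) > np.mean(wt_len)
    assert np.mean(ko_br) > np.mean(wt_br)
    assert np.mean(ko_r) > np.mean(wt_r)


def test_branching_probability_is_monotone():
    lo = MorphogenParams(branching_prob=0.4, target_tolerance=1e9)
    hi = MorphogenParams(branching_prob=0.85, target_tolerance=1e9)
    lo_bp = [
        mm.branch_metrics(mm.synthesize_morphology(lo, s)).n_branching_points
        for s in range(25)
    ]
    hi_bp = [
        mm.branch_metrics(mm.synthesize_morphology(hi, s)).n_branching_points
        for s in range(25)
    ]
    assert np.mean(hi_bp) > np.mean(lo_bp)
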