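import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hmconf import (
    TorsionRecord,
    build_conformer,
    dihedral,
    hbond_geometry,
    torsions_of,
)
from hmconf.geometry import (
    DegenerateGeometryError,
    MissingAtomError,
    MissingTorsionError,
    place_atom,
    rebuild_amide_hydrogens,
    wrap_angle,
)

from conftest import make_torsions, random_torsions


def dihedral_oracle(p1, p2, p3, p4):
    """Independent formulation: project the outer bonds onto the plane
    normal to the central bond and take the signed angle between them."""
    b = p3 - p2
    b = b / np.linalg.norm(b)
    u = (p1 - p2) - np.dot(p1 - p2, b) * b
    w = (p4 - p3) - np.dot(p4 - p3, b) * b
    return math.degrees(math.atan2(np.dot(np.cross(b, u), w), np.dot(u, w)))


def test_planar_anti_is_180_and_syn_is_0():
    p1 = np.array([1.0, 1.0, 0.0])
    p2 = np.array([1.0, 0.0, 0.0])
    p3 = np.array([0.0, 0.0, 0.0])
    anti = np.array([0.0, -1.0, 0.0])
    syn = np.array([0.0, 1.0, 0.0])
    assert dihedral(p1, p2, p3, anti) == pytest.approx(180.0)
    assert dihedral(p1, p2, p3, syn) == pytest.approx(0.0)


def test_dihedral_matches_independent_formulation_on_random_quadruples():
    rng = np.random.default_rng(42)
    for _ in range(100):
        pts = rng.normal(size=(4, 3)) * 3.0
        a, b = dihedral(*pts), dihedral_oracle(*pts)
        assert abs(wrap_angle(a - b)) < 1e-9


def test_collinear_points_raise():
    line = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
    with pytest.raises(DegenerateGeometryError):
        dihedral(*line)


@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.floats(min_value=-180.0, max_value=180.0),
)
def test_dihedral_invariant_under_rigid_motion(seed, angle):
    """Rotating and translating all four points leaves the dihedral fixed."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4, 3)) * 2.0
    try:
        before = dihedral(*pts)
    except DegenerateGeometryError:
        return
    rot = Rotation.from_rotvec(np.radians(angle) * _unit(rng.normal(size=3)))
    moved = rot.apply(pts) + rng.normal(size=3) * 10.0
    assert abs(wrap_angle(dihedral(*moved) - before)) < 1e-9


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


def test_place_atom_realises_requested_internal_coordinates():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a, b, c = rng.normal(size=(3, 3)) * 2.0
        chi = float(rng.uniform(-179.9, 179.9))
        theta = float(rng.uniform(60.0, 150.0))
        d = place_atom(a, b, c, 1.5, theta, chi)
        assert np.linalg.norm(d - c) == pytest.approx(1.5, abs=1e-9)
        assert dihedral(a, b, c, d) == pytest.approx(chi, abs=1e-9)


def test_build_measure_round_trip_ideal_helix(hm_a1):
    conf = build_conformer(hm_a1, make_torsions(hm_a1, -60.0, -30.0))
    for rec in torsions_of(conf, hm_a1):
        assert rec.phi == pytest.approx(-60.0, abs=1e-6)
        if rec.residue_index < 11:
            assert rec.psi == pytest.approx(-30.0, abs=1e-6)
        else:
            assert rec.psi is None and rec.omega is None


def test_build_measure_round_trip_random(hm_a2):
    rng = np.random.default_rng(11)
    for _ in range(25):
        recs = random_torsions(hm_a2, rng)
        meas = torsions_of(build_conformer(hm_a2, recs), hm_a2)
        for r, m in zip(recs, meas):
            for attr in ("phi", "psi", "omega", "chi1"):
                x, y = getattr(r, attr), getattr(m, attr)
                if x is None:
                    assert y is None or attr == "chi1"
                else:
                    assert abs(wrap_angle(x - y)) < 1e-6


def test_terminal_leucinol_psi_undefined_and_phi1_defined(ideal_310_conformer, hm_a1):
    recs = torsions_of(ideal_310_conformer, hm_a1)
    assert recs[-1].psi is None
    assert recs[0].phi is not None  # defined through the acetyl cap carbonyl


def test_mirror_torsions_give_mirror_conformer(hm_a2):
    """Negating every input torsion flips the sign of every re-measured
    torsion (the backbone becomes its mirror image; the Cα impropers are
    construction constants fixed by each residue's chirality flag)."""
    rng = np.random.default_rng(5)
    recs = random_torsions(hm_a2, rng)
    mirrored = [
        TorsionRecord(
            r.residue_index,
            phi=-r.phi,
            psi=None if r.psi is None else -r.psi,
            omega=None if r.omega is None else -r.omega,
            chi1=None if r.chi1 is None else -r.chi1,
        )
        for r in recs
    ]
    conf = build_conformer(hm_a2, recs)
    conf_m = build_conformer(hm_a2, mirrored)
    for a, b in zip(torsions_of(conf, hm_a2), torsions_of(conf_m, hm_a2)):
        for attr in ("phi", "psi", "omega", "chi1"):
            x, y = getattr(a, attr), getattr(b, attr)
            if x is not None:
                assert abs(wrap_angle(x + y)) < 1e-6


def test_d_isovaline_has_mirrored_cbeta_branch(hm_a1, hm_a2):
    recs1 = make_torsions(hm_a2, -60.0, -30.0)
    conf = build_conformer(hm_a2, recs1)
    d_improper = dihedral(*(conf.atom(1, n) for n in ("N", "C", "CA", "CB")))
    l_improper = dihedral(*(conf.atom(2, n) for n in ("N", "C", "CA", "CB")))
    assert d_improper == pytest.approx(-l_improper, abs=1e-6)
    assert l_improper > 0  # L residues carry the positive improper


def test_bonded_distances_sane(ideal_310_conformer, hm_a1):
    conf = ideal_310_conformer
    for i in range(1, 12):
        for a, b in (((i, "N"), (i, "CA")), ((i, "CA"), (i, "C"))):
            d = np.linalg.norm(conf.atom(*a) - conf.atom(*b))
            assert 0.8 < d < 2.0


def test_build_requires_torsions(hm_a1):
    with pytest.raises(MissingTorsionError):
        build_conformer(hm_a1, [])
    recs = make_torsions(hm_a1, -60.0, -30.0)
    recs[4].phi = None
    with pytest.raises(MissingTorsionError, match="residue 5"):
        build_conformer(hm_a1, recs)


def test_missing_atom_error_names_residue_and_atom(ideal_310_conformer, hm_a1):
    import copy

    conf = copy.deepcopy(ideal_310_conformer)
    del conf.coords[(7, "CA")]
    with pytest.raises(MissingAtomError, match="residue 7.*'CA'"):
        torsions_of(conf, hm_a1)


def test_hbond_geometry_examples():
    n = np.zeros(3)
    h = np.array([1.0, 0.0, 0.0])
    dist, ang = hbond_geometry(n, h, np.array([2.9, 0.0, 0.0]))
    assert (dist, ang) == (pytest.approx(2.9), pytest.approx(180.0))
    dist, ang = hbond_geometry(n, h, np.array([1.0, 1.8, 0.0]))
    assert dist == pytest.approx(math.sqrt(1 + 1.8**2), abs=1e-9)
    assert ang == pytest.approx(90.0, abs=1e-9)
    with pytest.raises(DegenerateGeometryError):
        hbond_geometry(n, h, n)


def test_amide_hydrogen_rebuild_matches_builder(hm_a1):
    rng = np.random.default_rng(8)
    conf = build_conformer(hm_a1, random_torsions(hm_a1, rng))
    originals = {k: v.copy() for k, v in conf.coords.items() if k[1] == "H"}
    for key in originals:
        del conf.coords[key]
    rebuild_amide_hydrogens(conf, hm_a1)
    for key, pos in originals.items():
        assert np.linalg.norm(conf.coords[key] - pos) < 1e-9
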