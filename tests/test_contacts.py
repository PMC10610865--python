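"""Contact detector geometry, invariances, and oracle agreement."""

import math

import numpy as np
import pytest

from asictox.contacts import (
    ContactParams,
    annotate,
    classify_frame,
    detect_hbonds,
    detect_hydrophobic,
    detect_ionic,
    detect_pication,
    detect_stacking,
)
from asictox.structures import Trajectory
from asictox.synthetic import make_salt_bridge_frame, random_frame

from _oracle import implementation_events_as_tuples, oracle_events

PARAMS = ContactParams()


def _traj(atoms):
    """Build a one-frame trajectory from (chain, res, resname, atom, elem, xyz)."""
    cols = list(zip(*atoms))
    coords = np.asarray(cols[5], dtype=float)[None]
    return Trajectory(cols[0], cols[1], cols[2], cols[3], cols[4], coords)


def _aframe(atoms, ann):
    return annotate(_traj(atoms), ann).frame(0)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _hbond_atoms(distance, h_angle_deg=None):
    """Ser OG donor vs Asn OD1 acceptor at a given distance; optionally an
    explicit hydroxyl H placed to give the requested D-H...A angle."""
    atoms = [
        ("A", 1, "SER", "CB", "C", (-1.43, 0.0, 0.0)),
        ("A", 1, "SER", "OG", "O", (0.0, 0.0, 0.0)),
        ("B", 1, "ASN", "OD1", "O", (distance, 0.0, 0.0)),
        ("B", 1, "ASN", "CG", "C", (distance + 1.1, 0.6, 0.0)),
    ]
    if h_angle_deg is not None:
        # H at 1.0 A from OG; acceptor seen from H under the given angle
        theta = math.radians(180.0 - h_angle_deg)
        atoms.append(("A", 1, "SER", "HG", "H",
                      (math.cos(theta), math.sin(theta), 0.0)))
    return atoms


def test_hbond_far_apart_gives_no_event(ann):
    assert detect_hbonds(_aframe(_hbond_atoms(10.0), ann), PARAMS) == []


def test_hbond_with_explicit_hydrogen_angle_criterion(ann):
    good = detect_hbonds(_aframe(_hbond_atoms(2.9, h_angle_deg=170.0), ann),
                         PARAMS)
    assert [e.type for e in good] == ["H"]
    assert good[0].distance == pytest.approx(2.9)
    assert good[0].angle == pytest.approx(170.0, abs=6.0)  # near-linear D-H...A
    bad = detect_hbonds(_aframe(_hbond_atoms(2.9, h_angle_deg=90.0), ann),
                        PARAMS)
    assert bad == []


def test_hbond_heavy_atom_mode_uses_antecedent_angle(ann):
    # antecedent CB behind the donor: angle 180, accepted
    assert len(detect_hbonds(_aframe(_hbond_atoms(2.9), ann), PARAMS)) == 1
    # antecedent between donor and acceptor: angle ~0, rejected
    atoms = _hbond_atoms(2.9)
    atoms[0] = ("A", 1, "SER", "CB", "C", (1.43, 0.0, 0.0))
    assert detect_hbonds(_aframe(atoms, ann), PARAMS) == []


# ---------------------------------------------------------------------------
# ionic / ion-dipole
# ---------------------------------------------------------------------------


def _ionic_atoms(distance, partner=("ASP", "OD1", "O")):
    resname, aname, elem = partner
    return [
        ("A", 1, "LYS", "CE", "C", (1.04, 1.04, 0.0)),
        ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
        ("B", 1, resname, aname, elem, (distance, 0.0, 0.0)),
    ]


def test_opposite_charges_within_cutoff_give_ionic_event(ann):
    events = detect_ionic(_aframe(_ionic_atoms(3.5), ann), PARAMS)
    assert [e.type for e in events] == ["I"]


def test_like_charges_give_no_event(ann):
    atoms = [
        ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
        ("B", 1, "LYS", "NZ", "N", (3.5, 0.0, 0.0)),
    ]
    assert detect_ionic(_aframe(atoms, ann), PARAMS) == []


def test_ionic_boundary_behaviour_at_cutoff(ann):
    assert len(detect_ionic(_aframe(_ionic_atoms(3.9), ann), PARAMS)) == 1
    assert detect_ionic(_aframe(_ionic_atoms(4.1), ann), PARAMS) == []


def test_charged_to_polar_uncharged_is_ion_dipole(ann):
    events = detect_ionic(_aframe(_ionic_atoms(3.7, ("ASN", "OD1", "O")), ann),
                          PARAMS)
    assert [e.type for e in events] == ["D"]


# ---------------------------------------------------------------------------
# pi-cation / stacking
# ---------------------------------------------------------------------------


def _ring_atoms(chain, res, center, normal_axis="z", rotate_deg=0.0):
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    ang = np.arange(6) * math.pi / 3.0 + math.radians(rotate_deg)
    ring = np.stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)], 1)
    if normal_axis == "x":
        ring = ring[:, [2, 0, 1]]
    return [(chain, res, "PHE", n, "C", tuple(p + np.asarray(center)))
            for n, p in zip(names, ring)]


def test_pication_cation_on_ring_axis(ann):
    atoms = _ring_atoms("A", 1, (0, 0, 0)) + [
        ("B", 1, "LYS", "NZ", "N", (0.0, 0.0, 4.0)),
    ]
    events = detect_pication(_aframe(atoms, ann), PARAMS)
    assert [e.type for e in events] == ["P"]
    assert events[0].distance == pytest.approx(4.0)


def test_pication_rejected_in_ring_plane_and_far_away(ann):
    in_plane = _ring_atoms("A", 1, (0, 0, 0)) + [
        ("B", 1, "LYS", "NZ", "N", (4.0, 0.0, 0.0)),
    ]
    assert detect_pication(_aframe(in_plane, ann), PARAMS) == []
    far = _ring_atoms("A", 1, (0, 0, 0)) + [
        ("B", 1, "LYS", "NZ", "N", (0.0, 0.0, 10.0)),
    ]
    assert detect_pication(_aframe(far, ann), PARAMS) == []


def test_stacking_parallel_and_band_rejection(ann):
    parallel = (_ring_atoms("A", 1, (0, 0, 0))
                + _ring_atoms("B", 1, (0, 0, 3.8), rotate_deg=30))
    events = detect_stacking(_aframe(parallel, ann), PARAMS)
    assert [e.type for e in events] == ["S"]
    assert events[0].distance == pytest.approx(3.8)
    far = (_ring_atoms("A", 1, (0, 0, 0))
           + _ring_atoms("B", 1, (0, 0, 9.0)))
    assert detect_stacking(_aframe(far, ann), PARAMS) == []
    # 45 degree tilt falls between the parallel and T bands
    tilted = _ring_atoms("A", 1, (0, 0, 0))
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    ang = np.arange(6) * math.pi / 3.0
    ring = np.stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)], 1)
    c, s = math.cos(math.radians(45)), math.sin(math.radians(45))
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    tilted += [("B", 1, "PHE", n, "C", tuple(p @ rot.T + np.array([0, 0, 4.5])))
               for n, p in zip(names, ring)]
    assert detect_stacking(_aframe(tilted, ann), PARAMS) == []
    # T-shaped orientation is accepted
    t_shape = (_ring_atoms("A", 1, (0, 0, 0))
               + _ring_atoms("B", 1, (0, 0, 5.0), normal_axis="x"))
    assert [e.type for e in detect_stacking(_aframe(t_shape, ann), PARAMS)] \
        == ["S"]


# ---------------------------------------------------------------------------
# hydrophobic
# ---------------------------------------------------------------------------


def test_hydrophobic_boundary_and_polar_exclusion(ann):
    def leu_pair(d):
        return [
            ("A", 1, "LEU", "CD1", "C", (0.0, 0.0, 0.0)),
            ("B", 1, "LEU", "CD1", "C", (d, 0.0, 0.0)),
        ]
    inside = detect_hydrophobic(_aframe(leu_pair(4.4), ann), PARAMS)
    assert [e.type for e in inside] == ["M"]
    assert detect_hydrophobic(_aframe(leu_pair(4.6), ann), PARAMS) == []
    # backbone O/N are polar (f <= 0): no M even in range
    polar = [
        ("A", 1, "GLY", "O", "O", (0.0, 0.0, 0.0)),
        ("B", 1, "GLY", "N", "N", (3.0, 0.0, 0.0)),
    ]
    assert detect_hydrophobic(_aframe(polar, ann), PARAMS) == []


def test_charged_residues_still_contact_through_apolar_stems(ann):
    # Arg aliphatic CB/CG/CD near His ring carbons: an M contact between
    # formally polar/charged residues
    atoms = [
        ("A", 1, "ARG", "CB", "C", (0.0, 0.0, 0.0)),
        ("A", 1, "ARG", "CG", "C", (1.5, 0.0, 0.0)),
        ("B", 1, "HIS", "CD2", "C", (0.0, 3.9, 0.0)),
    ]
    events = detect_hydrophobic(_aframe(atoms, ann), PARAMS)
    assert {e.type for e in events} == {"M"}


def test_weighted_mhp_mode_scores_residue_pairs(ann):
    atoms = [
        ("A", 1, "LEU", "CD1", "C", (0.0, 0.0, 0.0)),
        ("A", 1, "LEU", "CG", "C", (-1.5, 0.0, 0.0)),
        ("B", 1, "LEU", "CD1", "C", (4.0, 0.0, 0.0)),
    ]
    weighted = ContactParams(mhp_weighted=True, mhp_score_min=0.03)
    events = detect_hydrophobic(_aframe(atoms, ann), weighted)
    assert len(events) == 1
    expected = (0.53 * 0.53 * math.exp(-0.5 * 4.0))
    assert events[0].score == pytest.approx(expected, rel=1e-6)
    strict = ContactParams(mhp_weighted=True, mhp_score_min=expected * 1.1)
    assert detect_hydrophobic(_aframe(atoms, ann), strict) == []


# ---------------------------------------------------------------------------
# frame-level behaviour and invariances
# ---------------------------------------------------------------------------


def test_salt_bridge_pair_carries_ionic_hbond_and_hydrophobic_types(ann):
    traj = make_salt_bridge_frame()
    events = classify_frame(annotate(traj, ann).frame(0), PARAMS)
    by_pair = {(e.chain_a, e.res_a, e.chain_b, e.res_b) for e in events}
    assert by_pair == {("A", 15, "B", 91)}
    assert {e.type for e in events} == {"I", "H", "M"}


def test_empty_frame_yields_no_events(ann):
    traj = Trajectory(["A", "B"], [1, 1], ["GLY", "GLY"], ["CA", "CA"],
                      ["C", "C"],
                      np.array([[[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]]))
    assert classify_frame(annotate(traj, ann).frame(0), PARAMS) == []


def test_events_invariant_under_rigid_motion_and_chain_relabeling(ann):
    rng = np.random.default_rng(5)
    traj = random_frame(seed=42)
    base = implementation_events_as_tuples(
        classify_frame(annotate(traj, ann).frame(0), PARAMS))
    # random rotation + translation of the whole frame
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = Trajectory(traj.chain_ids, traj.res_ids, traj.res_names,
                       traj.atom_names, traj.elements,
                       traj.coords @ q.T + rng.uniform(-30, 30, 3))
    rotated = implementation_events_as_tuples(
        classify_frame(annotate(moved, ann).frame(0), PARAMS))
    assert {e[:7] for e in rotated} == {e[:7] for e in base}
    # chain relabeling A<->B permutes labels only
    swap = {"A": "B", "B": "A"}
    relabeled = Trajectory([swap[c] for c in traj.chain_ids], traj.res_ids,
                           traj.res_names, traj.atom_names, traj.elements,
                           traj.coords)
    swapped = implementation_events_as_tuples(
        classify_frame(annotate(relabeled, ann).frame(0), PARAMS))

    def canon(evts, mapping):
        out = set()
        for (t, c1, r1, c2, r2, *_rest) in evts:
            s1, s2 = sorted([(mapping.get(c1, c1), r1),
                             (mapping.get(c2, c2), r2)])
            out.add((t, *s1, *s2))
        return out

    assert canon(swapped, swap) == canon(base, {})


def test_tightening_cutoffs_never_adds_events(ann):
    loose = ContactParams()
    tight = ContactParams(d_hbond=3.0, d_ionic=3.4, d_pication=5.0,
                          pication_cone_deg=30.0, d_stack=4.6,
                          stack_parallel_max_deg=20.0, d_hydrophobic=4.0,
                          hbond_heavy_angle_deg=120.0)
    for seed in range(25):
        traj = random_frame(seed=seed)
        aframe = annotate(traj, ann).frame(0)
        ev_loose = implementation_events_as_tuples(classify_frame(aframe, loose))
        ev_tight = implementation_events_as_tuples(classify_frame(aframe, tight))
        assert ev_tight <= ev_loose


def test_intrachain_pairs_excluded_by_default(ann):
    atoms = [
        ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
        ("A", 2, "ASP", "OD1", "O", (3.0, 0.0, 0.0)),
    ]
    assert detect_ionic(_aframe(atoms, ann), PARAMS) == []
    allow = ContactParams(include_intrachain=True)
    assert len(detect_ionic(_aframe(atoms, ann), allow)) == 1


def test_detectors_agree_with_bruteforce_oracle_on_random_frames(ann):
    for seed in range(100):
        traj = random_frame(seed=seed)
        got = implementation_events_as_tuples(
            classify_frame(annotate(traj, ann).frame(0), PARAMS))
        want = oracle_events(traj, ann, PARAMS)
        assert got == want, f"seed {seed}"
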