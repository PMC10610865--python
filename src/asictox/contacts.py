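"""Geometric typing of inter-chain residue-residue contacts.

Six contact types are detected per frame:

====  =========================================================
H     hydrogen bond (donor-acceptor distance + donor angle)
I     ionic bridge (oppositely charged group heavy atoms)
D     ion-dipole (charged group atom near a polar uncharged O/N)
P     pi-cation (cation near an aromatic ring centroid, axial cone)
S     aromatic stacking (ring-ring, parallel or T-shaped band)
M     hydrophobic contact (apolar atoms by hydrophobicity constant,
      following the molecular-hydrophobic-potential idea; a weighted
      MHP scoring mode is available besides the binary default)
====  =========================================================

Only inter-chain pairs are evaluated by default (the use case is a
ligand/receptor interface); intra-chain analysis sits behind a flag.
All numeric criteria are configurable through :class:`ContactParams`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .chemistry import AnnotationSet, UnknownResidueError
from .structures import Frame, Trajectory

logger = logging.getLogger(__name__)

_H_BOND_MAX = 1.25  # Angstrom; X-H covalent bond upper bound for H attachment


@dataclass(frozen=True)
class ContactParams:
    """Numeric criteria for contact typing (distances in Angstrom).

    Defaults are community-standard interface criteria: 3.5 A donor-acceptor
    with a 120 deg D-H...A angle (or a 90 deg antecedent-D...A angle when
    hydrogens are absent from the coordinates), 4.0 A salt-bridge/ion-dipole
    distance, 6.0 A / 45 deg pi-cation cone, 5.5 A stacking with parallel
    (<=30 deg) and T-shaped (60-90 deg) bands, and 4.5 A between apolar
    (f > 0) heavy atoms for hydrophobic contacts.
    """

    d_hbond: float = 3.5
    hbond_angle_deg: float = 120.0
    hbond_heavy_angle_deg: float = 90.0
    d_ionic: float = 4.0
    d_pication: float = 6.0
    pication_cone_deg: float = 45.0
    d_stack: float = 5.5
    stack_parallel_max_deg: float = 30.0
    stack_t_min_deg: float = 60.0
    stack_t_max_deg: float = 90.0
    d_hydrophobic: float = 4.5
    mhp_weighted: bool = False
    mhp_alpha: float = 0.5  # 1/Angstrom decay of the weighted MHP score
    mhp_score_min: float = 0.05
    include_intrachain: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "ContactParams":
        """Load ``key = value`` overrides from a small config file."""
        known = {f.name: f.type for f in fields(cls)}
        overrides: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in known:
                raise KeyError(f"unknown contact parameter {key!r}")
            if key in ("mhp_weighted", "include_intrachain"):
                overrides[key] = value.lower() in ("1", "true", "yes", "on")
            else:
                overrides[key] = float(value)
        return replace(cls(), **overrides)


@dataclass(frozen=True)
class ContactEvent:
    """One typed inter-chain residue contact observed in one frame.

    Sides are stored in canonical order (sorted by chain id, then residue
    id) so that detection is symmetric in chain order.
    """

    frame_index: int
    chain_a: str
    res_a: int
    resname_a: str
    chain_b: str
    res_b: int
    resname_b: str
    type: str
    atom_a: str
    atom_b: str
    distance: float
    angle: float | None = None
    score: float | None = None

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.chain_a, self.res_a), (self.chain_b, self.res_b)

    def key(self) -> tuple:
        """Frame/pair/type identity (atom-level realization ignored)."""
        return (self.frame_index, self.chain_a, self.res_a, self.chain_b,
                self.res_b, self.type)


def _make_event(frame_index, side1, side2, ctype, dist, angle=None, score=None):
    # side = (chain, res_id, res_name, atom_name)
    if (side2[0], side2[1]) < (side1[0], side1[1]):
        side1, side2 = side2, side1
    return ContactEvent(
        frame_index=frame_index,
        chain_a=side1[0], res_a=side1[1], resname_a=side1[2],
        chain_b=side2[0], res_b=side2[1], resname_b=side2[2],
        type=ctype, atom_a=side1[3], atom_b=side2[3],
        distance=float(dist),
        angle=None if angle is None else float(angle),
        score=None if score is None else float(score),
    )


@dataclass
class _Ring:
    chain_id: str
    res_id: int
    res_name: str
    atom_idx: np.ndarray


@dataclass
class TopologyAnnotation:
    """Per-atom chemistry flags resolved against a trajectory topology."""

    donor_idx: np.ndarray        # heavy-atom donor indices
    donor_antecedent: np.ndarray  # antecedent atom index per donor, -1 if absent
    donor_hydrogens: list[np.ndarray]  # attached H indices per donor
    acceptor_idx: np.ndarray
    positive_idx: np.ndarray
    negative_idx: np.ndarray
    polar_idx: np.ndarray        # polar uncharged O/N
    f: np.ndarray                # hydrophobicity constant per atom (0 for H etc.)
    rings: list[_Ring]
    unknown_residues: list[str]


@dataclass
class AnnotatedFrame:
    frame: Frame
    topology: TopologyAnnotation

    @property
    def coords(self) -> np.ndarray:
        return self.frame.coords


class AnnotatedTrajectory:
    """A trajectory plus the chemistry annotation of its (fixed) topology."""

    def __init__(self, trajectory: Trajectory, topology: TopologyAnnotation):
        self.trajectory = trajectory
        self.topology = topology

    @property
    def n_frames(self) -> int:
        return self.trajectory.n_frames

    def frame(self, index: int) -> AnnotatedFrame:
        return AnnotatedFrame(self.trajectory.frame(index), self.topology)

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def annotate(
    trajectory: Trajectory,
    annotation_set: AnnotationSet | None = None,
    skip_unknown: bool = False,
) -> AnnotatedTrajectory:
    """Tag every atom with donor/acceptor/charge/ring/f attributes.

    Hydrogens attached to donors are identified by element and a covalent
    distance (<= 1.25 A) in the first frame; the topology is constant, so
    the assignment holds for all frames.  Unknown residue names raise
    :class:`~asictox.chemistry.UnknownResidueError` listing them, unless
    ``skip_unknown`` is set, in which case their atoms stay untagged.
    """
    ann = annotation_set or AnnotationSet.default()
    n = trajectory.n_atoms
    f = np.zeros(n)
    donor_idx: list[int] = []
    donor_ante: list[int] = []
    donor_h: list[np.ndarray] = []
    acceptor_idx: list[int] = []
    positive_idx: list[int] = []
    negative_idx: list[int] = []
    polar_idx: list[int] = []
    rings: list[_Ring] = []

    coords0 = trajectory.coords[0]
    is_h = trajectory.elements == "H"

    # group atom indices by residue
    residue_atoms: dict[tuple[str, int, str], dict[str, int]] = {}
    order: list[tuple[str, int, str]] = []
    for i in range(n):
        key = (str(trajectory.chain_ids[i]), int(trajectory.res_ids[i]),
               str(trajectory.res_names[i]))
        if key not in residue_atoms:
            residue_atoms[key] = {}
            order.append(key)
        residue_atoms[key][str(trajectory.atom_names[i])] = i

    unknown = sorted({key[2] for key in order if key[2] not in ann})
    if unknown and not skip_unknown:
        raise UnknownResidueError(
            f"residues without chemistry templates: {', '.join(unknown)} "
            "(pass skip_unknown=True to leave them untagged)"
        )

    for (chain, res_id, res_name) in order:
        if res_name not in ann:
            continue
        tpl = ann.template(res_name)
        atoms = residue_atoms[(chain, res_id, res_name)]
        heavy = {a: i for a, i in atoms.items() if not is_h[i]}
        for a, i in heavy.items():
            chem = tpl.atoms.get(a)
            if chem is not None:
                f[i] = chem.f
        for d, antecedent in tpl.donors.items():
            if d not in heavy:
                continue
            di = heavy[d]
            donor_idx.append(di)
            donor_ante.append(heavy.get(antecedent, -1) if antecedent else -1)
            h_local = [atoms[a] for a in atoms if is_h[atoms[a]]]
            if h_local:
                d_h = np.linalg.norm(coords0[h_local] - coords0[di], axis=1)
                attached = np.asarray(h_local)[d_h <= _H_BOND_MAX]
            else:
                attached = np.empty(0, dtype=int)
            donor_h.append(attached.astype(int))
        acceptor_idx += [heavy[a] for a in tpl.acceptors if a in heavy]
        positive_idx += [heavy[a] for a in tpl.positive if a in heavy]
        negative_idx += [heavy[a] for a in tpl.negative if a in heavy]
        polar_idx += [heavy[a] for a in tpl.polar_uncharged if a in heavy]
        for ring in tpl.rings:
            if all(a in heavy for a in ring):
                rings.append(_Ring(chain, res_id, res_name,
                                   np.array([heavy[a] for a in ring])))

    topo = TopologyAnnotation(
        donor_idx=np.asarray(donor_idx, dtype=int),
        donor_antecedent=np.asarray(donor_ante, dtype=int),
        donor_hydrogens=donor_h,
        acceptor_idx=np.asarray(sorted(set(acceptor_idx)), dtype=int),
        positive_idx=np.asarray(sorted(set(positive_idx)), dtype=int),
        negative_idx=np.asarray(sorted(set(negative_idx)), dtype=int),
        polar_idx=np.asarray(sorted(set(polar_idx)), dtype=int),
        f=f,
        rings=rings,
        unknown_residues=unknown,
    )
    return AnnotatedTrajectory(trajectory, topo)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))


def ring_centroid_normal(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal (best-fit plane, SVD) of a ring atom set."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _acute_deg(angle: float) -> float:
    """Fold an angle between undirected axes into [0, 90] degrees."""
    return min(angle, 180.0 - angle)


def _side(frame: Frame, i: int) -> tuple[str, int, str, str]:
    return (str(frame.chain_ids[i]), int(frame.res_ids[i]),
            str(frame.res_names[i]), str(frame.atom_names[i]))


def _cross_chain_pairs(frame, idx1, idx2, cutoff, include_intrachain):
    """Index pairs (i from idx1, j from idx2) within cutoff on distinct chains."""
    if len(idx1) == 0 or len(idx2) == 0:
        return []
    d = cdist(frame.coords[idx1], frame.coords[idx2])
    out = []
    for a, b in zip(*np.nonzero(d <= cutoff)):
        i, j = int(idx1[a]), int(idx2[b])
        if i == j:
            continue
        if not include_intrachain and frame.chain_ids[i] == frame.chain_ids[j]:
            continue
        out.append((i, j, float(d[a, b])))
    return out


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


def detect_hbonds(aframe: AnnotatedFrame,
                  params: ContactParams = ContactParams()) -> list[ContactEvent]:
    """Hydrogen bonds (type H).

    With explicit hydrogens the D-H...A angle must exceed
    ``hbond_angle_deg``; without them a heavy-atom-only mode requires the
    antecedent-D...A angle to exceed ``hbond_heavy_angle_deg``.  A donor
    without a resolvable antecedent passes on distance alone.
    """
    topo, frame = aframe.topology, aframe.frame
    events = []
    for (di_pos, j, dist) in _cross_chain_pairs(
        frame, topo.donor_idx, topo.acceptor_idx, params.d_hbond,
        params.include_intrachain,
    ):
        k = int(np.nonzero(topo.donor_idx == di_pos)[0][0])
        hydrogens = topo.donor_hydrogens[k]
        if len(hydrogens):
            angles = [
                _angle_deg(frame.coords[di_pos], frame.coords[h], frame.coords[j])
                for h in hydrogens
            ]
            best = max(angles)
            if best < params.hbond_angle_deg:
                continue
        else:
            ante = topo.donor_antecedent[k]
            if ante >= 0:
                best = _angle_deg(frame.coords[ante], frame.coords[di_pos],
                                  frame.coords[j])
                if best < params.hbond_heavy_angle_deg:
                    continue
            else:
                best = None
        events.append(_make_event(frame.index, _side(frame, di_pos),
                                  _side(frame, j), "H", dist, angle=best))
    return events


def detect_ionic(aframe: AnnotatedFrame,
                 params: ContactParams = ContactParams()) -> list[ContactEvent]:
    """Ionic bridges (type I) and ion-dipole contacts (type D).

    I: oppositely charged group heavy atoms within ``d_ionic``.
    D: a charged atom within ``d_ionic`` of a polar uncharged O/N.
    Like-charge proximity emits no event but is logged at DEBUG level
    (charged side chains can still interact through their apolar stems,
    which the hydrophobic detector picks up).
    """
    topo, frame = aframe.topology, aframe.frame
    events = []
    for i, j, dist in _cross_chain_pairs(frame, topo.positive_idx,
                                         topo.negative_idx, params.d_ionic,
                                         params.include_intrachain):
        events.append(_make_event(frame.index, _side(frame, i),
                                  _side(frame, j), "I", dist))
    charged = np.concatenate([topo.positive_idx, topo.negative_idx])
    for i, j, dist in _cross_chain_pairs(frame, charged, topo.polar_idx,
                                         params.d_ionic,
                                         params.include_intrachain):
        events.append(_make_event(frame.index, _side(frame, i),
                                  _side(frame, j), "D", dist))
    for same in (topo.positive_idx, topo.negative_idx):
        for i, j, dist in _cross_chain_pairs(frame, same, same, params.d_ionic,
                                             params.include_intrachain):
            if i < j:
                logger.debug(
                    "like-charge proximity (no event): %s-%s at %.2f A in frame %d",
                    _side(frame, i), _side(frame, j), dist, frame.index,
                )
    return events


def detect_pication(aframe: AnnotatedFrame,
                    params: ContactParams = ContactParams()) -> list[ContactEvent]:
    """Pi-cation contacts (type P): cation within ``d_pication`` of a ring
    centroid and inside the axial cone (``pication_cone_deg``)."""
    topo, frame = aframe.topology, aframe.frame
    events = []
    for ring in topo.rings:
        centroid, normal = ring_centroid_normal(frame.coords[ring.atom_idx])
        for ci in topo.positive_idx:
            ci = int(ci)
            if (not params.include_intrachain
                    and frame.chain_ids[ci] == ring.chain_id):
                continue
            v = frame.coords[ci] - centroid
            dist = float(np.linalg.norm(v))
            if dist == 0.0 or dist > params.d_pication:
                continue
            cosang = np.clip(np.dot(v / dist, normal), -1.0, 1.0)
            axial = _acute_deg(math.degrees(math.acos(float(cosang))))
            if axial > params.pication_cone_deg:
                continue
            ring_side = (ring.chain_id, ring.res_id, ring.res_name, "ring")
            events.append(_make_event(frame.index, _side(frame, ci),
                                      ring_side, "P", dist, angle=axial))
    return events


def detect_stacking(aframe: AnnotatedFrame,
                    params: ContactParams = ContactParams()) -> list[ContactEvent]:
    """Aromatic stacking (type S): centroid distance within ``d_stack`` and
    inter-normal angle in the parallel band (<= ``stack_parallel_max_deg``)
    or the T band (``stack_t_min_deg`` .. ``stack_t_max_deg``)."""
    topo, frame = aframe.topology, aframe.frame
    events = []
    geom = [ring_centroid_normal(frame.coords[r.atom_idx]) for r in topo.rings]
    for a in range(len(topo.rings)):
        for b in range(a + 1, len(topo.rings)):
            r1, r2 = topo.rings[a], topo.rings[b]
            if not params.include_intrachain and r1.chain_id == r2.chain_id:
                continue
            (c1, n1), (c2, n2) = geom[a], geom[b]
            dist = float(np.linalg.norm(c2 - c1))
            if dist > params.d_stack:
                continue
            cosang = np.clip(np.dot(n1, n2), -1.0, 1.0)
            phi = _acute_deg(math.degrees(math.acos(float(cosang))))
            if not (phi <= params.stack_parallel_max_deg
                    or params.stack_t_min_deg <= phi <= params.stack_t_max_deg):
                continue
            side1 = (r1.chain_id, r1.res_id, r1.res_name, "ring")
            side2 = (r2.chain_id, r2.res_id, r2.res_name, "ring")
            events.append(_make_event(frame.index, side1, side2, "S",
                                      dist, angle=phi))
    return events


def detect_hydrophobic(aframe: AnnotatedFrame,
                       params: ContactParams = ContactParams()) -> list[ContactEvent]:
    """Hydrophobic contacts (type M).

    Binary mode (default): any apolar-apolar heavy-atom pair (f > 0 on both
    sides) within ``d_hydrophobic``.  Weighted MHP mode: per residue pair,
    score = sum of f_a * f_b * exp(-alpha * d) over qualifying pairs, event
    iff the score reaches ``mhp_score_min``.
    """
    topo, frame = aframe.topology, aframe.frame
    apolar = np.nonzero(topo.f > 0)[0]
    pairs = _cross_chain_pairs(frame, apolar, apolar, params.d_hydrophobic,
                               params.include_intrachain)
    if not params.mhp_weighted:
        events = []
        for i, j, dist in pairs:
            if (_side(frame, i)[:2]) < (_side(frame, j)[:2]):
                events.append(_make_event(frame.index, _side(frame, i),
                                          _side(frame, j), "M", dist))
            elif (_side(frame, j)[:2]) < (_side(frame, i)[:2]):
                # emitted once from the other orientation of the same pair
                continue
        # each unordered atom pair appears twice in `pairs`; the ordering
        # filter above keeps exactly one orientation
        return events
    scores: dict[tuple, dict] = {}
    for i, j, dist in pairs:
        s_i, s_j = _side(frame, i), _side(frame, j)
        if s_i[:2] >= s_j[:2]:
            continue
        key = (s_i[:3], s_j[:3])
        entry = scores.setdefault(key, {"score": 0.0, "min_d": np.inf,
                                        "atoms": (s_i[3], s_j[3])})
        entry["score"] += (topo.f[i] * topo.f[j]
                           * math.exp(-params.mhp_alpha * dist))
        if dist < entry["min_d"]:
            entry["min_d"] = dist
            entry["atoms"] = (s_i[3], s_j[3])
    events = []
    for (ra, rb), entry in scores.items():
        if entry["score"] >= params.mhp_score_min:
            events.append(_make_event(
                aframe.frame.index,
                (*ra, entry["atoms"][0]), (*rb, entry["atoms"][1]),
                "M", entry["min_d"], score=entry["score"],
            ))
    return events


_DETECTORS = (detect_hbonds, detect_ionic, detect_pication,
              detect_stacking, detect_hydrophobic)


def classify_frame(aframe: AnnotatedFrame,
                   params: ContactParams = ContactParams()) -> list[ContactEvent]:
    """All contact events of a frame (union of the five detectors).

    A residue pair may carry several types simultaneously (e.g. a salt
    bridge whose partners also hydrogen-bond and touch hydrophobically).
    """
    events: list[ContactEvent] = []
    for det in _DETECTORS:
        events.extend(det(aframe, params))
    return events


def classify_trajectory(atraj: AnnotatedTrajectory,
                        params: ContactParams = ContactParams()) -> list[ContactEvent]:
    """Contact events over all frames of an annotated trajectory."""
    events: list[ContactEvent] = []
    for aframe in atraj.frames():
        events.extend(classify_frame(aframe, params))
    return events


EVENT_COLUMNS = ["frame", "chain_a", "res_a", "resname_a", "chain_b", "res_b",
                 "resname_b", "type", "atom_a", "atom_b", "distance", "angle"]


def events_to_frame(events: list[ContactEvent]) -> pd.DataFrame:
    """Tabulate contact events (one row per atom-level event)."""
    return pd.DataFrame(
        [
            {
                "frame": e.frame_index,
                "chain_a": e.chain_a, "res_a": e.res_a, "resname_a": e.resname_a,
                "chain_b": e.chain_b, "res_b": e.res_b, "resname_b": e.resname_b,
                "type": e.type, "atom_a": e.atom_a, "atom_b": e.atom_b,
                "distance": e.distance, "angle": e.angle,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
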