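"""Synthetic data with planted ground truth.

Two generators make every downstream stage testable without cluster-scale
simulations or oocyte recordings:

* :func:`generate_planted_trajectory` builds multi-frame structures in
  which chosen inter-chain residue pairs satisfy a chosen contact
  criterion in a planted per-frame schedule.  Planted geometries use
  minimal side-chain fragments (e.g. a lysine amine opposite an aspartate
  carboxylate) so the ground truth is unambiguous: in "present" frames the
  key geometry sits ``geometry_margin`` Angstrom inside the criterion, in
  "absent" frames the partner fragment is displaced far outside every
  criterion.  The default presence schedule is deterministic (contact
  present in the first k frames) so lifetime recovery is exact; a
  Bernoulli schedule is available for stochastic tests.

* :func:`generate_dose_response` draws per-oocyte inhibition curves from
  the Hill model with additive Gaussian noise on the normalized fraction.

:func:`random_frame` additionally builds random two-chain frames from the
chemistry templates (planar rings, bonded antecedents) for oracle
cross-checks of the detectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import AnnotationSet
from .contacts import ContactParams
from .doseresponse import HillParams, hill_predict
from .structures import CONTACT_TYPES, Trajectory

#: Default concentration grid in nM: spans 0-10 uM and includes the
#: single-dose test concentrations used in oocyte experiments (370 nM at
#: the heterotrimeric channel, 1.1 uM at the homotrimer).
DEFAULT_CONCENTRATIONS_NM = (0.0, 10.0, 30.0, 100.0, 370.0, 1100.0,
                             3000.0, 10000.0)

_MAX_MARGIN = 0.8  # keeps every planted site free of cross-type events
_ABSENT_SHIFT = 25.0  # Angstrom displacement of the partner fragment
_SITE_SPACING = 60.0  # Angstrom between planted sites


@dataclass(frozen=True)
class PlantedContactSpec:
    """One planted inter-chain contact with a target relative lifetime."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    contact_type: str
    target_lifetime: float
    geometry_margin: float = 0.3

    def __post_init__(self):
        if self.contact_type not in CONTACT_TYPES:
            raise ValueError(f"unknown contact type {self.contact_type!r}")
        if not 0.0 <= self.target_lifetime <= 1.0:
            raise ValueError("target_lifetime must lie in [0, 1]")
        if not 0.0 < self.geometry_margin <= _MAX_MARGIN:
            raise ValueError(
                f"geometry_margin must lie in (0, {_MAX_MARGIN}] Angstrom"
            )
        if self.chain_a == self.chain_b:
            raise ValueError("planted pairs must be on distinct chains")


def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(6)], axis=1)


def _fragments(ctype: str, margin: float, params: ContactParams):
    """Fragment atom layouts (resname, {atom: xyz}) for one contact type.

    The key criterion distance is placed ``margin`` inside its cutoff; all
    other criteria are violated by construction (checked in tests against
    the detectors themselves).
    """
    s45 = 1.47 / math.sqrt(2.0)
    if ctype == "H":
        d = params.d_hbond - margin
        return (("SER", {"CB": (-1.43, 0.0, 0.0), "OG": (0.0, 0.0, 0.0)}),
                ("ASN", {"OD1": (d, 0.0, 0.0), "CG": (d + 1.10, 0.60, 0.0)}))
    if ctype == "I":
        d = params.d_ionic - margin
        return (("LYS", {"CE": (s45, s45, 0.0), "NZ": (0.0, 0.0, 0.0)}),
                ("ASP", {"OD1": (d, 0.0, 0.0), "CG": (d + 1.00, 0.75, 0.0),
                         "OD2": (d + 1.60, 1.75, 0.0)}))
    if ctype == "D":
        d = params.d_ionic - margin
        return (("LYS", {"CE": (s45, s45, 0.0), "NZ": (0.0, 0.0, 0.0)}),
                ("ASN", {"OD1": (d, 0.0, 0.0), "CG": (d + 1.10, 0.60, 0.0)}))
    if ctype == "P":
        dz = params.d_pication - margin
        ring = _hexagon()
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        return (("LYS", {"NZ": (0.0, 0.0, dz), "CE": (0.0, 0.0, dz + 1.47)}),
                ("PHE", {n: tuple(p) for n, p in zip(names, ring)}))
    if ctype == "S":
        dz = params.d_stack - margin
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        ring_a = _hexagon()
        rot = math.pi / 6.0
        cz, sz = math.cos(rot), math.sin(rot)
        ring_b = ring_a @ np.array([[cz, -sz, 0.0], [sz, cz, 0.0],
                                    [0.0, 0.0, 1.0]]).T
        ring_b = ring_b + np.array([0.0, 0.0, dz])
        return (("PHE", {n: tuple(p) for n, p in zip(names, ring_a)}),
                ("PHE", {n: tuple(p) for n, p in zip(names, ring_b)}))
    if ctype == "M":
        d = params.d_hydrophobic - margin
        return (("LEU", {"CG": (-1.53, 0.0, 0.0), "CD1": (0.0, 0.0, 0.0)}),
                ("LEU", {"CD1": (d, 0.0, 0.0), "CG": (d + 1.53, 0.0, 0.0)}))
    raise ValueError(ctype)


@dataclass
class GroundTruth:
    """Planted per-frame presence schedule for each spec."""

    specs: list[PlantedContactSpec]
    presence: np.ndarray  # (n_frames, n_specs) bool

    def lifetimes(self) -> np.ndarray:
        """Realized presence fraction per planted contact."""
        return self.presence.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fi in range(self.presence.shape[0]):
            for si, spec in enumerate(self.specs):
                rows.append({
                    "frame": fi, "chain_a": spec.chain_a, "res_a": spec.res_a,
                    "chain_b": spec.chain_b, "res_b": spec.res_b,
                    "type": spec.contact_type,
                    "present": bool(self.presence[fi, si]),
                })
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_planted_trajectory(
    specs: list[PlantedContactSpec],
    n_frames: int,
    seed: int = 0,
    schedule: str = "first_k",
    params: ContactParams | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Build a trajectory realizing the planted contact schedule.

    Each spec occupies its own well-separated site; within a site the two
    fragments satisfy exactly the planted criterion when present and sit
    ~25 A apart when absent.  ``schedule='first_k'`` (default) makes the
    contact present in the first ``round(target_lifetime * n_frames)``
    frames, so the realized lifetime is exact; ``schedule='bernoulli'``
    draws presence per frame at the target rate with the given seed.
    Reusing a residue across specs would demand conflicting geometry and
    is rejected.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if schedule not in ("first_k", "bernoulli"):
        raise ValueError("schedule must be 'first_k' or 'bernoulli'")
    params = params or ContactParams()
    seen: set[tuple[str, int]] = set()
    for spec in specs:
        for key in ((spec.chain_a, spec.res_a), (spec.chain_b, spec.res_b)):
            if key in seen:
                raise ValueError(
                    f"residue {key} reused across planted specs: "
                    "conflicting geometry on the same atoms"
                )
            seen.add(key)

    ann = AnnotationSet.default()
    chain_ids, res_ids, res_names, atom_names, elements = [], [], [], [], []
    base = []          # present-frame coordinates
    shifted_mask = []  # atoms displaced in absent frames (partner fragment)
    spec_atoms: list[np.ndarray] = []
    for si, spec in enumerate(specs):
        offset = np.array([_SITE_SPACING * si, 0.0, 0.0])
        frag_a, frag_b = _fragments(spec.contact_type, spec.geometry_margin,
                                    params)
        idx = []
        for part, (resname, atoms), (chain, res) in zip(
            ("a", "b"), (frag_a, frag_b),
            ((spec.chain_a, spec.res_a), (spec.chain_b, spec.res_b)),
        ):
            tpl = ann.template(resname)
            for aname, xyz in atoms.items():
                idx.append(len(base))
                chain_ids.append(chain)
                res_ids.append(res)
                res_names.append(resname)
                atom_names.append(aname)
                elements.append(tpl.atoms[aname].element)
                base.append(np.asarray(xyz) + offset)
                shifted_mask.append(part == "b")
        spec_atoms.append(np.asarray(idx))

    rng = np.random.default_rng(seed)
    presence = np.zeros((n_frames, len(specs)), dtype=bool)
    for si, spec in enumerate(specs):
        if schedule == "first_k":
            k = int(round(spec.target_lifetime * n_frames))
            presence[:k, si] = True
        else:
            presence[:, si] = rng.random(n_frames) < spec.target_lifetime

    base = np.asarray(base, dtype=float)
    shifted_mask = np.asarray(shifted_mask)
    coords = np.repeat(base[None, :, :], n_frames, axis=0)
    for si in range(len(specs)):
        move = spec_atoms[si][shifted_mask[spec_atoms[si]]]
        absent = ~presence[:, si]
        coords[np.ix_(absent, move)] += np.array([0.0, 0.0, _ABSENT_SHIFT])

    traj = Trajectory(chain_ids, res_ids, res_names, atom_names, elements,
                      coords)
    return traj, GroundTruth(specs=list(specs), presence=presence)


def make_salt_bridge_frame() -> Trajectory:
    """A one-frame structure with a full Lys/Asp salt bridge.

    The pair realizes three contact types at once -- ionic (I), hydrogen
    bond (H) and a hydrophobic contact (M) between the aliphatic stems --
    the classic multi-type anchor residue pattern of interface tables.
    """
    # NZ...OD1 2.8 A with the CE antecedent behind the donor (angle ~170),
    # and the aspartate CB bent to within 4.5 A of the lysine CE stem.
    lys = {"CB": (-5.60, 0.2, 0.0), "CG": (-4.20, -0.4, 0.0),
           "CD": (-2.80, 0.2, 0.0), "CE": (-1.40, -0.4, 0.0),
           "NZ": (0.0, 0.0, 0.0)}
    asp = {"OD1": (2.80, 0.0, 0.0), "CG": (3.50, 1.05, 0.0),
           "OD2": (3.00, 2.20, 0.0), "CB": (1.60, 2.40, 0.0)}
    ann = AnnotationSet.default()
    chain_ids, res_ids, res_names, atom_names, elements, xyz = [], [], [], [], [], []
    for chain, res, resname, atoms in (("A", 15, "ASP", asp),
                                       ("B", 91, "LYS", lys)):
        tpl = ann.template(resname)
        for aname, p in atoms.items():
            chain_ids.append(chain)
            res_ids.append(res)
            res_names.append(resname)
            atom_names.append(aname)
            elements.append(tpl.atoms[aname].element)
            xyz.append(p)
    coords = np.asarray(xyz, dtype=float)[None, :, :]
    return Trajectory(chain_ids, res_ids, res_names, atom_names, elements,
                      coords)


# ---------------------------------------------------------------------------
# random frames for oracle cross-checks
# ---------------------------------------------------------------------------


# approximate planar indole layout (Angstrom) for the tryptophan ring system
_INDOLE_2D = {
    "CG": (0.00, 0.00), "CD1": (1.09, 0.85), "NE1": (0.64, 2.14),
    "CE2": (-0.73, 2.18), "CD2": (-1.15, 0.87), "CE3": (-2.50, 0.48),
    "CZ3": (-3.45, 1.45), "CH2": (-3.06, 2.79), "CZ2": (-1.71, 3.18),
}


def _place_residue(tpl, rng: np.random.Generator, center: np.ndarray
                   ) -> dict[str, np.ndarray]:
    """Place a residue's atoms from the template bond graph.

    Atoms follow their bonded parent at ~1.45 A in random directions;
    aromatic rings are then replaced by randomly oriented regular polygons
    (planarity matters for centroid/normal geometry), and ring
    substituents re-attach to the moved ring atoms.
    """
    def unit():
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)

    pos: dict[str, np.ndarray] = {}
    remaining = dict(tpl.atoms)
    pos["CA"] = center.copy()
    remaining.pop("CA", None)
    while remaining:
        placed_any = False
        for name, chem in list(remaining.items()):
            if chem.parent is None:
                pos[name] = center + 1.45 * unit()
            elif chem.parent in pos:
                pos[name] = pos[chem.parent] + 1.45 * unit()
            else:
                continue
            remaining.pop(name)
            placed_any = True
        if not placed_any:  # orphaned parents; drop the rest near the center
            for name in list(remaining):
                pos[name] = center + 1.45 * unit()
                remaining.pop(name)
    ring_atoms = set()
    # fused ring systems (the indole) must stay coplanar as a whole, so
    # rings sharing atoms are laid out from one rigid planar template
    clusters: list[list[tuple[str, ...]]] = []
    for ring in tpl.rings:
        for cluster in clusters:
            if any(set(ring) & set(r) for r in cluster):
                cluster.append(ring)
                break
        else:
            clusters.append([ring])
    for cluster in clusters:
        atoms_2d: dict[str, np.ndarray] = {}
        if len(cluster) == 1:
            ring = cluster[0]
            n = len(ring)
            radius = 1.39 if n == 6 else 1.32
            ang = np.arange(n) * 2.0 * math.pi / n
            for a, t in zip(ring, ang):
                atoms_2d[a] = np.array([radius * math.cos(t),
                                        radius * math.sin(t), 0.0])
        else:
            union = set().union(*map(set, cluster))
            if union != set(_INDOLE_2D):
                raise NotImplementedError(
                    f"no planar layout for fused ring system {sorted(union)}"
                )
            for a, xy in _INDOLE_2D.items():
                atoms_2d[a] = np.array([xy[0], xy[1], 0.0])
        # random orientation via QR of a random matrix
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        names = list(atoms_2d)
        local = np.stack([atoms_2d[a] for a in names])
        local -= local.mean(axis=0)
        centroid = np.mean([pos[a] for a in names], axis=0)
        for a, p in zip(names, local @ q.T):
            pos[a] = centroid + p
            ring_atoms.add(a)
    for name, chem in tpl.atoms.items():
        if name not in ring_atoms and chem.parent in ring_atoms:
            pos[name] = pos[chem.parent] + 1.45 * unit()
    return pos


def random_frame(seed: int, n_residues: int = 10, box: float = 16.0,
                 max_atoms: int = 60,
                 annotation_set: AnnotationSet | None = None) -> Trajectory:
    """A random one-frame, two-chain structure for detector cross-checks.

    Residue types are drawn from the full template set, placed at random
    centers inside a cube of ``box`` Angstrom so that inter-chain contacts
    of every type occur at realistic rates.
    """
    ann = annotation_set or AnnotationSet.default()
    rng = np.random.default_rng(seed)
    names = sorted(ann.residues)
    chain_ids, res_ids, res_names, atom_names, elements, xyz = [], [], [], [], [], []
    counters = {"A": 0, "B": 0}
    n_atoms = 0
    for _ in range(n_residues):
        resname = names[rng.integers(len(names))]
        tpl = ann.template(resname)
        if n_atoms + len(tpl.atoms) > max_atoms:
            break
        chain = "A" if rng.random() < 0.5 else "B"
        counters[chain] += 1
        center = rng.uniform(0.0, box, size=3)
        pos = _place_residue(tpl, rng, center)
        for aname, p in pos.items():
            chain_ids.append(chain)
            res_ids.append(counters[chain])
            res_names.append(resname)
            atom_names.append(aname)
            elements.append(tpl.atoms[aname].element)
            xyz.append(p)
        n_atoms += len(pos)
    if not xyz:  # degenerate draw; retry deterministically
        return random_frame(seed + 10_000_019, n_residues, box, max_atoms,
                            annotation_set)
    coords = np.asarray(xyz, dtype=float)[None, :, :]
    return Trajectory(chain_ids, res_ids, res_names, atom_names, elements,
                      coords)


# ---------------------------------------------------------------------------
# synthetic dose-response datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseSpec:
    """Generative settings for synthetic per-oocyte inhibition curves."""

    params: HillParams
    concentrations_nm: tuple[float, ...] = DEFAULT_CONCENTRATIONS_NM
    n_replicates: int = 5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.concentrations_nm) == 0:
            raise ValueError("concentration grid must not be empty")
        if any(c < 0 for c in self.concentrations_nm):
            raise ValueError("concentrations must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_dose_response(spec: DoseResponseSpec) -> pd.DataFrame:
    """Draw a tidy dose-response dataset (replicate_id, concentration_nM,
    fraction).

    Every replicate is measured at every grid concentration (each oocyte
    sees the full series).  Fractions are the Hill prediction plus
    additive Gaussian noise, clipped to [0, 1.2]: normalized currents may
    exceed the control slightly through noise, but not without bound.
    """
    rng = np.random.default_rng(spec.seed)
    conc = np.asarray(spec.concentrations_nm, dtype=float)
    clean = hill_predict(spec.params, conc)
    rows = []
    for rep in range(spec.n_replicates):
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(conc)) \
            if spec.noise_sd > 0 else clean.copy()
        noisy = np.clip(noisy, 0.0, 1.2)
        for c, y in zip(conc, noisy):
            rows.append({"replicate_id": rep, "concentration_nM": c,
                         "fraction": float(y)})
    return pd.DataFrame(rows)
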