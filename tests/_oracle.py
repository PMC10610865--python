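"""Independent brute-force contact oracle for cross-checking the detectors.

Deliberately naive: pure-Python all-pairs loops, no neighbor lists, no
shared code with the package detectors.  Ring normals use Newell's polygon
method (the package uses an SVD plane fit); for planar rings the two agree
exactly, so event sets must match bit-for-bit after rounding distances.
"""

from __future__ import annotations

import math


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _angle(a, vertex, b):
    v1 = [x - y for x, y in zip(a, vertex)]
    v2 = [x - y for x, y in zip(b, vertex)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    cosang = sum(x * y for x, y in zip(v1, v2)) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _newell_normal(points):
    nx = ny = nz = 0.0
    n = len(points)
    for i in range(n):
        x1, y1, z1 = points[i]
        x2, y2, z2 = points[(i + 1) % n]
        nx += (y1 - y2) * (z1 + z2)
        ny += (z1 - z2) * (x1 + x2)
        nz += (x1 - x2) * (y1 + y2)
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return (nx / norm, ny / norm, nz / norm)


def _centroid(points):
    n = len(points)
    return tuple(sum(p[i] for p in points) / n for i in range(3))


def _axis_angle_deg(v, normal):
    nv = math.sqrt(sum(x * x for x in v))
    cosang = sum(a * b for a, b in zip(v, normal)) / nv
    ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return min(ang, 180.0 - ang)


class OracleAtoms:
    """Flat chemistry-tagged atom list rebuilt from the templates."""

    def __init__(self, trajectory, annotation_set, frame_index=0):
        self.atoms = []  # dicts
        coords = trajectory.coords[frame_index]
        for i in range(trajectory.n_atoms):
            self.atoms.append({
                "chain": str(trajectory.chain_ids[i]),
                "res": int(trajectory.res_ids[i]),
                "resname": str(trajectory.res_names[i]),
                "name": str(trajectory.atom_names[i]),
                "element": str(trajectory.elements[i]),
                "xyz": tuple(float(x) for x in coords[i]),
            })
        by_res = {}
        for a in self.atoms:
            by_res.setdefault((a["chain"], a["res"], a["resname"]), []).append(a)
        self.donors = []     # (atom, antecedent_or_None, [H atoms])
        self.acceptors = []
        self.positive = []
        self.negative = []
        self.polar = []
        self.apolar = []     # atoms with f > 0
        self.rings = []      # (chain, res, resname, [atoms])
        for (chain, res, resname), atoms in by_res.items():
            if resname not in annotation_set:
                continue
            tpl = annotation_set.template(resname)
            named = {}
            hydrogens = []
            for a in atoms:
                if a["element"] == "H":
                    hydrogens.append(a)
                else:
                    named[a["name"]] = a
            for a in named.values():
                chem = tpl.atoms.get(a["name"])
                if chem is not None and chem.f > 0:
                    self.apolar.append(a)
            for d, antecedent in tpl.donors.items():
                if d not in named:
                    continue
                attached = [h for h in hydrogens
                            if _dist(h["xyz"], named[d]["xyz"]) <= 1.25]
                self.donors.append((named[d],
                                    named.get(antecedent) if antecedent else None,
                                    attached))
            self.acceptors += [named[a] for a in tpl.acceptors if a in named]
            self.positive += [named[a] for a in tpl.positive if a in named]
            self.negative += [named[a] for a in tpl.negative if a in named]
            self.polar += [named[a] for a in tpl.polar_uncharged if a in named]
            for ring in tpl.rings:
                if all(a in named for a in ring):
                    self.rings.append((chain, res, resname,
                                       [named[a] for a in ring]))


def _event(a_side, b_side, ctype, dist):
    # a_side/b_side: (chain, res, atom_name)
    if (b_side[0], b_side[1]) < (a_side[0], a_side[1]):
        a_side, b_side = b_side, a_side
    return (ctype, a_side[0], a_side[1], b_side[0], b_side[1],
            a_side[2], b_side[2], round(dist, 6))


def oracle_events(trajectory, annotation_set, params, frame_index=0):
    """Set of contact-event tuples from an exhaustive all-pairs evaluation."""
    oa = OracleAtoms(trajectory, annotation_set, frame_index)
    events = set()

    for donor, antecedent, hydrogens in oa.donors:
        for acc in oa.acceptors:
            if acc is donor or acc["chain"] == donor["chain"]:
                continue
            d = _dist(donor["xyz"], acc["xyz"])
            if d > params.d_hbond:
                continue
            if hydrogens:
                ok = any(_angle(donor["xyz"], h["xyz"], acc["xyz"])
                         >= params.hbond_angle_deg for h in hydrogens)
            elif antecedent is not None:
                ok = (_angle(antecedent["xyz"], donor["xyz"], acc["xyz"])
                      >= params.hbond_heavy_angle_deg)
            else:
                ok = True
            if ok:
                events.add(_event((donor["chain"], donor["res"], donor["name"]),
                                  (acc["chain"], acc["res"], acc["name"]),
                                  "H", d))

    for pos in oa.positive:
        for neg in oa.negative:
            if pos["chain"] == neg["chain"]:
                continue
            d = _dist(pos["xyz"], neg["xyz"])
            if d <= params.d_ionic:
                events.add(_event((pos["chain"], pos["res"], pos["name"]),
                                  (neg["chain"], neg["res"], neg["name"]),
                                  "I", d))
    for chg in oa.positive + oa.negative:
        for pol in oa.polar:
            if chg is pol or chg["chain"] == pol["chain"]:
                continue
            d = _dist(chg["xyz"], pol["xyz"])
            if d <= params.d_ionic:
                events.add(_event((chg["chain"], chg["res"], chg["name"]),
                                  (pol["chain"], pol["res"], pol["name"]),
                                  "D", d))

    ring_geom = [( # (chain, res, resname, centroid, normal)
        chain, res, resname,
        _centroid([a["xyz"] for a in atoms]),
        _newell_normal([a["xyz"] for a in atoms]),
    ) for chain, res, resname, atoms in oa.rings]

    for chain, res, _resname, centroid, normal in ring_geom:
        for cat in oa.positive:
            if cat["chain"] == chain:
                continue
            d = _dist(cat["xyz"], centroid)
            if d == 0.0 or d > params.d_pication:
                continue
            v = [a - b for a, b in zip(cat["xyz"], centroid)]
            if _axis_angle_deg(v, normal) <= params.pication_cone_deg:
                events.add(_event((cat["chain"], cat["res"], cat["name"]),
                                  (chain, res, "ring"), "P", d))

    for i in range(len(ring_geom)):
        for j in range(i + 1, len(ring_geom)):
            c1, r1, _, cen1, n1 = ring_geom[i]
            c2, r2, _, cen2, n2 = ring_geom[j]
            if c1 == c2:
                continue
            d = _dist(cen1, cen2)
            if d > params.d_stack:
                continue
            cosang = sum(a * b for a, b in zip(n1, n2))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            phi = min(ang, 180.0 - ang)
            if (phi <= params.stack_parallel_max_deg
                    or params.stack_t_min_deg <= phi <= params.stack_t_max_deg):
                events.add(_event((c1, r1, "ring"), (c2, r2, "ring"), "S", d))

    for i in range(len(oa.apolar)):
        for j in range(i + 1, len(oa.apolar)):
            a, b = oa.apolar[i], oa.apolar[j]
            if a["chain"] == b["chain"]:
                continue
            d = _dist(a["xyz"], b["xyz"])
            if d <= params.d_hydrophobic:
                events.add(_event((a["chain"], a["res"], a["name"]),
                                  (b["chain"], b["res"], b["name"]), "M", d))
    return events


def implementation_events_as_tuples(events):
    """Convert package ContactEvents into the oracle tuple form."""
    return {
        (e.type, e.chain_a, e.res_a, e.chain_b, e.res_b,
         e.atom_a, e.atom_b, round(e.distance, 6))
        for e in events
    }
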