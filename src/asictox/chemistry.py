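"""Per-residue chemistry templates used for contact typing.

The annotation tables ship with the package as a versioned JSON file
(``data/residue_chemistry.json``).  For every standard amino acid they list

* hydrogen-bond donor heavy atoms together with their bonded antecedent
  (used for heavy-atom-only angle checks when hydrogens are absent),
* acceptor atoms,
* positively / negatively charged group atoms at physiological protonation
  (Arg/Lys +, Asp/Glu -, His neutral by default),
* planar aromatic ring atom sets (5- or 6-membered),
* a Ghose-Crippen-style atomic hydrophobicity constant ``f`` per atom
  (``f > 0`` marks an apolar atom; used for hydrophobic-contact typing and
  for molecular-hydrophobic-potential weighted scoring).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources


class UnknownResidueError(KeyError):
    """Raised when a residue name has no chemistry template."""


@dataclass(frozen=True)
class AtomChemistry:
    """Chemistry attributes of one template atom."""

    name: str
    element: str
    f: float
    parent: str | None  # bonded heavy-atom antecedent (None for the root)


@dataclass(frozen=True)
class ResidueTemplate:
    """Full chemistry template of one residue type (backbone included)."""

    name: str
    atoms: dict[str, AtomChemistry]
    donors: dict[str, str | None] = field(default_factory=dict)  # donor -> antecedent
    acceptors: frozenset[str] = frozenset()
    positive: frozenset[str] = frozenset()
    negative: frozenset[str] = frozenset()
    rings: tuple[tuple[str, ...], ...] = ()

    @property
    def polar_uncharged(self) -> frozenset[str]:
        """O/N atoms participating in H-bonding that carry no formal charge.

        These are the dipole partners of the ion-dipole (D) contact type.
        """
        polar = {
            a
            for a in set(self.donors) | set(self.acceptors)
            if self.atoms[a].element in ("N", "O")
        }
        return frozenset(polar - set(self.positive) - set(self.negative))


class AnnotationSet:
    """A collection of residue chemistry templates keyed by 3-letter name."""

    def __init__(self, residues: dict[str, ResidueTemplate], version: str = "custom"):
        self.residues = dict(residues)
        self.version = version

    def __contains__(self, res_name: str) -> bool:
        return res_name in self.residues

    def template(self, res_name: str) -> ResidueTemplate:
        try:
            return self.residues[res_name]
        except KeyError:
            raise UnknownResidueError(
                f"no chemistry template for residue {res_name!r}"
            ) from None

    @classmethod
    def from_json(cls, payload: dict) -> "AnnotationSet":
        bb = payload["backbone"]
        residues: dict[str, ResidueTemplate] = {}
        for name, spec in payload["residues"].items():
            atoms = {}
            for aname, a in {**bb["atoms"], **spec["atoms"]}.items():
                atoms[aname] = AtomChemistry(
                    name=aname, element=a["element"], f=float(a["f"]), parent=a["parent"]
                )
            donors = {d: atoms[d].parent for d in spec["donors"]}
            if spec.get("backbone_n_donor", True):
                for d in bb["donors"]:
                    donors[d] = atoms[d].parent
            acceptors = frozenset(spec["acceptors"]) | frozenset(bb["acceptors"])
            residues[name] = ResidueTemplate(
                name=name,
                atoms=atoms,
                donors=donors,
                acceptors=acceptors,
                positive=frozenset(spec["positive"]),
                negative=frozenset(spec["negative"]),
                rings=tuple(tuple(r) for r in spec["rings"]),
            )
        return cls(residues, version=payload.get("version", "unknown"))

    @classmethod
    def default(cls) -> "AnnotationSet":
        return _load_default()


@lru_cache(maxsize=1)
def _load_default() -> AnnotationSet:
    text = (
        resources.files("asictox").joinpath("data/residue_chemistry.json").read_text()
    )
    return AnnotationSet.from_json(json.loads(text))


def element_from_name(atom_name: str) -> str:
    """Best-effort element guess from a PDB atom name (protein atoms)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()
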