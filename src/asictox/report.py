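"""Interface reports: grouped contact listings and region attribution.

The contact listing reproduces the conventional presentation of interface
tables for toxin/channel complexes: one block per ligand residue (ascending
author number), each partner residue annotated with its contact-type
letters in the canonical order I, H, M, P, S.  Ion-dipole (D) contacts are
pooled with ionic (I) in reports, because interface tables conventionally
denote "ionic bridge or ion-dipole" with a single letter; the detectors and
lifetime tables keep them distinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lifetimes import LifetimeTable

TYPE_ORDER = ("I", "H", "M", "P", "S")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def residue_label(res_name: str, res_id: int) -> str:
    """Compact residue label, e.g. ('ASP', 15) -> 'D15'."""
    one = _THREE_TO_ONE.get(res_name.upper(), res_name)
    return f"{one}{res_id}"


@dataclass(frozen=True)
class RegionMap:
    """Named residue intervals on one chain (1-based, inclusive)."""

    chain_id: str
    intervals: tuple[tuple[str, int, int], ...]  # (name, start, stop)

    def __post_init__(self):
        spans = sorted((lo, hi, name) for name, lo, hi in self.intervals)
        for (lo, hi, name) in spans:
            if lo > hi:
                raise ValueError(f"region {name!r} has start > stop")
        for (_, hi1, n1), (lo2, _, n2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"regions {n1!r} and {n2!r} overlap")

    def region_of(self, res_id: int) -> str:
        for name, lo, hi in self.intervals:
            if lo <= res_id <= hi:
                return name
        return "other"

    @classmethod
    def default_toxin_regions(cls, chain_id: str) -> "RegionMap":
        """Default three-finger-toxin region map: only the 'head' (13-16).

        Loop boundaries vary between toxins and are left to configuration.
        """
        return cls(chain_id=chain_id, intervals=(("head", 13, 16),))


@dataclass
class ContactReport:
    """Grouped contact listing (one row per ligand/partner residue pair)."""

    rows: pd.DataFrame  # ligand_res, ligand_label, partner_res, partner_label, types

    def __len__(self) -> int:
        return len(self.rows)

    def to_markdown(self) -> str:
        lines = ["| Ligand | Partner |", "| --- | --- |"]
        last = None
        for _, r in self.rows.iterrows():
            lig = r["ligand_label"] if r["ligand_label"] != last else ""
            last = r["ligand_label"]
            lines.append(f"| {lig} | {r['partner_label']} ({r['types']}) |")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def make_contact_table(filtered: LifetimeTable, ligand_chain: str) -> ContactReport:
    """Build a grouped interface listing from a (filtered) lifetime table.

    Rows are grouped by ligand residue in ascending author numbering; each
    partner residue carries its sorted type letters, with D pooled under I.
    """
    df = filtered.data
    sel_a = df["chain_a"] == ligand_chain
    sel_b = df["chain_b"] == ligand_chain
    rows = pd.concat(
        [
            df.loc[sel_a].rename(columns={
                "res_a": "ligand_res", "resname_a": "ligand_name",
                "res_b": "partner_res", "resname_b": "partner_name",
                "chain_b": "partner_chain"}),
            df.loc[sel_b & ~sel_a].rename(columns={
                "res_b": "ligand_res", "resname_b": "ligand_name",
                "res_a": "partner_res", "resname_a": "partner_name",
                "chain_a": "partner_chain"}),
        ],
        ignore_index=True,
    )
    if len(rows) == 0:
        empty = pd.DataFrame(columns=["ligand_res", "ligand_label",
                                      "partner_chain", "partner_res",
                                      "partner_label", "types"])
        return ContactReport(empty)
    rows["type"] = rows["type"].replace({"D": "I"})
    grouped = (
        rows.groupby(["ligand_res", "ligand_name", "partner_chain",
                      "partner_res", "partner_name"])["type"]
        .agg(lambda ts: ", ".join(
            t for t in TYPE_ORDER if t in set(ts)))
        .reset_index()
        .rename(columns={"type": "types"})
        .sort_values(["ligand_res", "partner_chain", "partner_res"])
        .reset_index(drop=True)
    )
    grouped["ligand_label"] = [
        residue_label(n, r) for n, r in zip(grouped["ligand_name"],
                                            grouped["ligand_res"])
    ]
    grouped["partner_label"] = [
        residue_label(n, r) for n, r in zip(grouped["partner_name"],
                                            grouped["partner_res"])
    ]
    return ContactReport(grouped[["ligand_res", "ligand_label", "partner_chain",
                                  "partner_res", "partner_label", "types"]])


def map_regions(table: LifetimeTable, regions: RegionMap) -> pd.DataFrame:
    """Total contact intensity per named ligand region.

    Returns one row per region (plus "other" for uncovered residues) with
    the summed lifetime and the contributing ligand residues.  Region
    totals conserve the table total: every row of the table lands in
    exactly one region.
    """
    df = table.data
    lig = regions.chain_id
    records = []
    for _, r in df.iterrows():
        if r["chain_a"] == lig:
            res = int(r["res_a"])
        elif r["chain_b"] == lig:
            res = int(r["res_b"])
        else:
            continue
        records.append({"region": regions.region_of(res), "res": res,
                        "lifetime": r["lifetime"]})
    if not records:
        return pd.DataFrame(columns=["region", "total_lifetime", "residues"])
    rec = pd.DataFrame(records)
    out = (
        rec.groupby("region")
        .agg(total_lifetime=("lifetime", "sum"),
             residues=("res", lambda s: sorted(set(s))))
        .reset_index()
    )
    order = [name for name, *_ in regions.intervals] + ["other"]
    out["__o"] = out["region"].map({n: i for i, n in enumerate(order)})
    return (out.sort_values("__o").drop(columns="__o")
            .reset_index(drop=True))
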