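"""Relative contact lifetimes, symmetric-copy averaging, threshold
filtering and summed-intensity interface maps.

The relative lifetime of a (residue pair, contact type) is the fraction of
trajectory frames in which at least one atom-level contact of that type is
present for that pair -- 0 means never observed, 1 means present throughout.
Duplicate atom-level events within one frame count once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import CONTACT_TYPES, LIFETIME_COLUMNS

DEFAULT_THRESHOLDS = {"H": 0.10, "I": 0.10, "D": 0.10,
                      "M": 0.30, "P": 0.10, "S": 0.10}


@dataclass
class LifetimeTable:
    """Relative lifetime per (inter-chain residue pair, contact type).

    ``data`` has one row per (pair, type) with columns ``chain_a, res_a,
    resname_a, chain_b, res_b, resname_b, type, lifetime``; ``n_frames``
    records the denominator used (None for tables read from CSV without
    that context).
    """

    data: pd.DataFrame
    n_frames: int | None = None

    def __post_init__(self):
        df = self.data.reset_index(drop=True)
        missing = [c for c in LIFETIME_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"lifetime table lacks columns {missing}")
        df = df[LIFETIME_COLUMNS].copy()
        df["res_a"] = df["res_a"].astype(int)
        df["res_b"] = df["res_b"].astype(int)
        df["lifetime"] = df["lifetime"].astype(float)
        if len(df):
            bad = df[(df["lifetime"] < 0) | (df["lifetime"] > 1)]
            if len(bad):
                raise ValueError(
                    f"lifetimes outside [0, 1]: {bad['lifetime'].tolist()}"
                )
            unknown = set(df["type"]) - set(CONTACT_TYPES)
            if unknown:
                raise ValueError(f"unknown contact types {sorted(unknown)}")
            keys = df[["chain_a", "res_a", "chain_b", "res_b", "type"]]
            if keys.duplicated().any():
                raise ValueError("duplicate (pair, type) rows in lifetime table")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def total(self) -> float:
        return float(self.data["lifetime"].sum())

    def sort(self) -> "LifetimeTable":
        df = self.data.sort_values(
            ["chain_a", "res_a", "chain_b", "res_b", "type"]
        ).reset_index(drop=True)
        return LifetimeTable(df, n_frames=self.n_frames)


def compute_lifetimes(events, n_frames: int,
                      equilibration_offset: int = 0) -> LifetimeTable:
    """Relative lifetimes from per-frame contact events.

    Parameters
    ----------
    events
        List of :class:`~asictox.contacts.ContactEvent` or a DataFrame in
        the layout of :func:`~asictox.contacts.events_to_frame`.
    n_frames
        Total number of frames analyzed (the lifetime denominator).
    equilibration_offset
        Drop events from the first ``k`` frames and shrink the denominator
        accordingly (default 0: the whole trajectory counts).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if equilibration_offset < 0 or equilibration_offset >= n_frames:
        raise ValueError("equilibration_offset must be in [0, n_frames)")
    from .contacts import events_to_frame

    if isinstance(events, pd.DataFrame):
        df = events
    else:
        df = events_to_frame(list(events))
    denom = n_frames - equilibration_offset
    if len(df) == 0:
        return LifetimeTable(pd.DataFrame(columns=LIFETIME_COLUMNS),
                             n_frames=denom)
    if df["frame"].max() >= n_frames:
        raise ValueError(
            f"event frame index {int(df['frame'].max())} >= n_frames {n_frames}"
        )
    df = df[df["frame"] >= equilibration_offset]
    key_cols = ["chain_a", "res_a", "resname_a", "chain_b", "res_b",
                "resname_b", "type"]
    counts = (
        df.drop_duplicates(subset=key_cols + ["frame"])
        .groupby(key_cols, as_index=False)
        .size()
    )
    counts["lifetime"] = counts.pop("size") / denom
    return LifetimeTable(counts[LIFETIME_COLUMNS], n_frames=denom).sort()


def average_symmetric_copies(
    tables: list[LifetimeTable],
    chain_map: dict[str, str] | None = None,
) -> LifetimeTable:
    """Average lifetimes over symmetry-equivalent molecule copies.

    In a symmetric multimer the same ligand binds several equivalent sites;
    ``chain_map`` renames each copy's chains onto canonical labels (e.g.
    the three toxin chains onto one "toxin" label).  A contact absent from
    a copy counts as lifetime 0 there, not as missing data: all copies
    share the trajectory length, hence a common denominator.
    """
    if len(tables) < 2:
        raise ValueError("need at least two copies to average")
    chain_map = chain_map or {}
    frames = []
    for k, t in enumerate(tables):
        df = t.data.copy()
        df["chain_a"] = df["chain_a"].map(lambda c: chain_map.get(c, c))
        df["chain_b"] = df["chain_b"].map(lambda c: chain_map.get(c, c))
        # re-canonicalize side order after renaming
        flip = pd.Series(
            [
                (cb, rb) < (ca, ra)
                for ca, ra, cb, rb in zip(df["chain_a"], df["res_a"],
                                          df["chain_b"], df["res_b"])
            ],
            index=df.index,
        )
        for a, b in (("chain_a", "chain_b"), ("res_a", "res_b"),
                     ("resname_a", "resname_b")):
            df.loc[flip, [a, b]] = df.loc[flip, [b, a]].values
        df["copy"] = k
        frames.append(df)
    allrows = pd.concat(frames, ignore_index=True)
    key_cols = ["chain_a", "res_a", "resname_a", "chain_b", "res_b",
                "resname_b", "type"]
    agg = allrows.groupby(key_cols, as_index=False)["lifetime"].sum()
    agg["lifetime"] /= len(tables)  # missing copies contribute 0
    n_frames = tables[0].n_frames
    return LifetimeTable(agg[LIFETIME_COLUMNS], n_frames=n_frames).sort()


def filter_contacts(table: LifetimeTable,
                    thresholds: dict[str, float] | None = None) -> LifetimeTable:
    """Keep rows whose lifetime strictly exceeds the per-type threshold.

    Defaults follow the reporting convention for interface tables: H and I
    (and D, P, S) above 10% of the trajectory, hydrophobic M above 30%.
    The inequality is strict, so a lifetime exactly at the threshold drops.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    df = table.data
    keep = df.apply(lambda r: r["lifetime"] > thr.get(r["type"], 0.0), axis=1)
    out = df[keep] if len(df) else df
    return LifetimeTable(out.reset_index(drop=True), n_frames=table.n_frames)


@dataclass
class InterfaceMap:
    """Summed contact intensity per (ligand residue, receptor residue).

    ``matrix`` is indexed by ligand residue id (rows) and receptor residue
    id (columns); each entry sums the lifetimes of all contact types for
    that pair, so it ranges from 0 to the number of types.
    """

    matrix: pd.DataFrame
    ligand_chain: str
    receptor_chain: str
    ligand_resnames: dict[int, str] = field(default_factory=dict)
    receptor_resnames: dict[int, str] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(self.matrix.values.sum())


def sum_intensity_map(
    table: LifetimeTable,
    ligand_chain: str,
    receptor_chain: str,
    receptor_range: tuple[int, int] | None = None,
) -> InterfaceMap:
    """Build the summed-lifetime interface map between two chains.

    All contact types are summed per residue pair.  ``receptor_range``
    (inclusive) restricts the receptor axis, mirroring the practice of
    windowing the map to the interacting stretch of the receptor and
    leaving out residues that contribute nothing.
    """
    df = table.data
    sel_ab = (df["chain_a"] == ligand_chain) & (df["chain_b"] == receptor_chain)
    sel_ba = (df["chain_a"] == receptor_chain) & (df["chain_b"] == ligand_chain)
    lig = pd.concat([df.loc[sel_ab, "res_a"], df.loc[sel_ba, "res_b"]])
    rec = pd.concat([df.loc[sel_ab, "res_b"], df.loc[sel_ba, "res_a"]])
    lignm = pd.concat([df.loc[sel_ab, "resname_a"], df.loc[sel_ba, "resname_b"]])
    recnm = pd.concat([df.loc[sel_ab, "resname_b"], df.loc[sel_ba, "resname_a"]])
    life = pd.concat([df.loc[sel_ab, "lifetime"], df.loc[sel_ba, "lifetime"]])
    pairs = pd.DataFrame({"ligand": lig.values, "receptor": rec.values,
                          "lig_name": lignm.values, "rec_name": recnm.values,
                          "lifetime": life.values})
    if receptor_range is not None:
        lo, hi = receptor_range
        pairs = pairs[(pairs["receptor"] >= lo) & (pairs["receptor"] <= hi)]
    if len(pairs):
        matrix = (
            pairs.pivot_table(index="ligand", columns="receptor",
                              values="lifetime", aggfunc="sum", fill_value=0.0)
            .sort_index(axis=0)
            .sort_index(axis=1)
        )
    else:
        matrix = pd.DataFrame(dtype=float)
    return InterfaceMap(
        matrix=matrix,
        ligand_chain=ligand_chain,
        receptor_chain=receptor_chain,
        ligand_resnames=dict(zip(pairs["ligand"], pairs["lig_name"])),
        receptor_resnames=dict(zip(pairs["receptor"], pairs["rec_name"])),
    )


def plot_interface_map(imap: InterfaceMap, ax=None, cmap: str = "viridis"):
    """Render an interface map as a heatmap (seaborn)."""
    import seaborn as sns

    ax = sns.heatmap(imap.matrix, ax=ax, cmap=cmap,
                     cbar_kws={"label": "summed lifetime"})
    ax.set_xlabel(f"{imap.receptor_chain} residue")
    ax.set_ylabel(f"{imap.ligand_chain} residue")
    return ax
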