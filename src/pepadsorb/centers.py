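"""Step 1 of the screening workflow: locate local adsorption centers.

A center is a confined group of one to three host atoms carrying excess
negative charge.  Atoms whose partial charge falls inside a configurable
window are grouped by single-linkage clustering at covalent-neighbour
distance, ranked by summed (most negative first) excess charge, and labelled
``a, b, c, …`` in rank order.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .structures import InputError, Structure

__all__ = [
    "ChargeWindow",
    "AdsorptionCenter",
    "CenterScanConfig",
    "find_local_centers",
    "rank_centers_by_charge",
    "load_center_fixture",
    "write_center_report",
    "read_center_report",
]


@dataclass(frozen=True)
class ChargeWindow:
    """Charge screening window [lower, upper] in e, both typically negative.

    The default window is deliberately wider than the canonical −0.5…−1.0e
    screening band: published center sets include members near −0.1e and the
    band is explicitly structure-dependent, so the default must cover them.
    """

    lower: float = -1.0
    upper: float = -0.1

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise InputError("charge window lower bound must not exceed upper")

    def contains(self, q: float | np.ndarray):
        return (q >= self.lower) & (q <= self.upper)


@dataclass(frozen=True)
class AdsorptionCenter:
    """A labelled group of 1–3 atoms with centroid and summed excess charge.

    Fixture-derived centers carry only a label and charge (``member_atoms``
    and ``centroid`` are None).
    """

    label: str
    excess_charge: float
    member_atoms: Optional[tuple[int, ...]] = None
    centroid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.member_atoms is not None:
            if not 1 <= len(self.member_atoms) <= 3:
                raise InputError("a center groups one to three atoms")
            object.__setattr__(self, "member_atoms", tuple(int(i) for i in self.member_atoms))
        if self.centroid is not None:
            object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))


@dataclass(frozen=True)
class CenterScanConfig:
    window: ChargeWindow = ChargeWindow()
    k: int = 8  # requested number of centers
    grouping_radius: float = 1.8  # Å, single-linkage threshold

    def __post_init__(self) -> None:
        if self.k < 1:
            raise InputError("k must be at least 1")
        if self.grouping_radius <= 0:
            raise InputError("grouping radius must be positive")


def _labels(n: int) -> list[str]:
    letters = string.ascii_lowercase
    out = []
    for i in range(n):
        lab = ""
        j = i
        while True:
            lab = letters[j % 26] + lab
            j = j // 26 - 1
            if j < 0:
                break
        out.append(lab)
    return out


def _single_linkage_groups(
    indices: np.ndarray, positions: np.ndarray, radius: float
) -> list[list[int]]:
    """Partition candidate atoms into single-linkage clusters at ``radius``."""
    if len(indices) == 1:
        return [[int(indices[0])]]
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    z = linkage(pdist(positions[indices]), method="single")
    assign = fcluster(z, t=radius, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, c in zip(indices, assign):
        groups.setdefault(int(c), []).append(int(idx))
    return list(groups.values())


def find_local_centers(
    s: Structure, cfg: CenterScanConfig = CenterScanConfig()
) -> list[AdsorptionCenter]:
    """Identify up to ``cfg.k`` local adsorption centers on a charged host.

    Candidate atoms (charge inside the window) are grouped by single linkage
    within ``grouping_radius``; groups larger than three are split by keeping
    the three most negative members and returning the remainder to the
    candidate pool.  Groups are ranked by summed charge, most negative first
    (ties by centroid lexicographic order, which is independent of the input
    atom order), and the top k are labelled ``a, b, c, …``.
    """
    if not s.has_charges:
        raise InputError("center search requires per-atom charges")
    q = s.charges
    pos = s.positions
    pool = np.where(cfg.window.contains(q))[0]
    if len(pool) == 0:
        warnings.warn("no atom charge falls inside the screening window")
        return []

    final_groups: list[list[int]] = []
    while len(pool):
        remainder: list[int] = []
        for grp in _single_linkage_groups(pool, pos, cfg.grouping_radius):
            if len(grp) <= 3:
                final_groups.append(grp)
            else:
                ranked = sorted(grp, key=lambda i: (q[i], i))
                final_groups.append(ranked[:3])
                remainder.extend(ranked[3:])
        pool = np.array(remainder, dtype=int)

    def sort_key(grp: list[int]):
        c = pos[grp].mean(axis=0)
        return (float(q[grp].sum()), c[0], c[1], c[2])

    final_groups.sort(key=sort_key)
    if len(final_groups) < cfg.k:
        warnings.warn(
            f"only {len(final_groups)} center(s) found, {cfg.k} requested"
        )
    top = final_groups[: cfg.k]
    return [
        AdsorptionCenter(
            label=lab,
            excess_charge=float(q[grp].sum()),
            member_atoms=tuple(sorted(grp)),
            centroid=pos[grp].mean(axis=0),
        )
        for lab, grp in zip(_labels(len(top)), top)
    ]


def rank_centers_by_charge(
    centers: Sequence[AdsorptionCenter],
) -> list[AdsorptionCenter]:
    """Sort centers by excess charge ascending (most negative first);
    ties are broken alphabetically by label."""
    if len(centers) == 0:
        raise InputError("cannot rank an empty center list")
    return sorted(centers, key=lambda c: (c.excess_charge, c.label))


# ---------------------------------------------------------------------------
# Fixtures and reports
# ---------------------------------------------------------------------------

def _fixture_path(fname: str):
    return resources.files("pepadsorb.data").joinpath(fname)


def load_center_fixture(name: str) -> list[AdsorptionCenter]:
    """Reference per-center excess charges for one of the five pentapeptides
    (CIHNP, CRQVF, DNPIQAVP, DSWAADIP, WHVSC); charges only, original
    lettering preserved."""
    import pandas as pd

    with resources.as_file(_fixture_path("center_charges.tsv")) as p:
        table = pd.read_csv(p, sep="\t", comment="#")
    sub = table[table["peptide"] == name]
    if sub.empty:
        known = sorted(table["peptide"].unique())
        raise KeyError(f"unknown peptide {name!r}; known: {known}")
    return [
        AdsorptionCenter(label=row.label, excess_charge=float(row.charge_e))
        for row in sub.itertuples()
    ]


REPORT_COLUMNS = ["label", "members", "centroid_x", "centroid_y", "centroid_z", "excess_charge_e"]


def write_center_report(centers: Sequence[AdsorptionCenter], path: str | Path) -> None:
    """TSV report: label, 0-based member indices (comma-joined), centroid, charge."""
    lines = ["\t".join(REPORT_COLUMNS)]
    for c in centers:
        members = ",".join(str(i) for i in c.member_atoms) if c.member_atoms else ""
        cx, cy, cz = (c.centroid if c.centroid is not None else (float("nan"),) * 3)
        lines.append(
            f"{c.label}\t{members}\t{cx:.6f}\t{cy:.6f}\t{cz:.6f}\t{c.excess_charge:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_center_report(path: str | Path) -> list[AdsorptionCenter]:
    out = []
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != REPORT_COLUMNS:
        raise InputError(f"{path}: not a center report")
    for line in lines[1:]:
        lab, members, cx, cy, cz, qe = line.split("\t")
        out.append(
            AdsorptionCenter(
                label=lab,
                excess_charge=float(qe),
                member_atoms=tuple(int(i) for i in members.split(",")) if members else None,
                centroid=np.array([float(cx), float(cy), float(cz)]),
            )
        )
    return out
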