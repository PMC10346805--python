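"""Interaction metric panel: volume adaptability, contacts, charge transfer.

Volume adaptability is the change of the host's axis-aligned bounding-box
volume upon binding (negative = contraction, the host wrapping the analyte).
Hydrogen-bond-like contacts are classified purely by distance, using the
observed N–H and O–H contact ranges as default windows.  Charge transfer is
the net change of total charge on the analyte between its isolated and
adsorbed states — zero under the built-in classical model (no polarization),
meaningful with an external engine or fixture charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .energy import EnergyModel
from .structures import InputError, Structure, bounding_box_volume, min_intermolecular_distance

__all__ = [
    "EV_TO_KCAL_PER_MOL",
    "HBondRule",
    "HBondContact",
    "MetricPanel",
    "volume_change",
    "ev_to_kcal",
    "kcal_to_ev",
    "classify_hbonds",
    "charge_transfer",
    "build_metric_panel",
]

#: CODATA-derived conversion, kcal/mol per eV.
EV_TO_KCAL_PER_MOL = 23.060548


def ev_to_kcal(e: float) -> float:
    """eV → kcal/mol (exact linear conversion; round only at presentation)."""
    return e * EV_TO_KCAL_PER_MOL


def kcal_to_ev(e: float) -> float:
    return e / EV_TO_KCAL_PER_MOL


def volume_change(before: Structure, after: Structure) -> tuple[float, float]:
    """Bounding-box volume change (ΔV Å³, ΔV% of the before-volume).

    Both volumes are taken in the shared input coordinate frame; a negative
    value means contraction.
    """
    if len(before) != len(after):
        raise InputError("volume change compares the same molecule before/after")
    v0 = bounding_box_volume(before)
    v1 = bounding_box_volume(after)
    dv = v1 - v0
    return dv, 100.0 * dv / v0 if v0 > 0 else float("nan")


@dataclass(frozen=True)
class HBondRule:
    """Distance windows (Å) for H···acceptor contacts, keyed by acceptor
    element.  Defaults are the observed physisorption contact ranges for
    N and O acceptors."""

    ranges: dict = field(
        default_factory=lambda: {"N": (1.942, 2.108), "O": (1.998, 2.690)}
    )

    def __post_init__(self) -> None:
        for el, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise InputError(f"empty H-bond window for acceptor {el}")


@dataclass(frozen=True)
class HBondContact:
    h_molecule: str  # name of the molecule donating the H
    h_index: int
    acceptor_element: str
    acceptor_index: int
    length: float  # Å
    klass: str  # e.g. "N-H", "O-H"


def classify_hbonds(
    host: Structure, analyte: Structure, rule: HBondRule = HBondRule()
) -> list[HBondContact]:
    """Distance-only hydrogen-bond classification.

    Every hydrogen of either molecule is paired with the N/O acceptors of the
    other molecule; a contact is listed iff its distance lies inside the
    acceptor class window.  No angular criterion is applied.  The contact set
    is symmetric under swapping the two arguments.
    """
    contacts: list[HBondContact] = []
    for donor_mol, acceptor_mol in ((host, analyte), (analyte, host)):
        d_pos = donor_mol.positions
        a_pos = acceptor_mol.positions
        h_idx = [i for i, e in enumerate(donor_mol.elements) if e == "H"]
        for el, (lo, hi) in sorted(rule.ranges.items()):
            acc_idx = [j for j, e in enumerate(acceptor_mol.elements) if e == el]
            for i in h_idx:
                for j in acc_idx:
                    r = float(np.linalg.norm(d_pos[i] - a_pos[j]))
                    if lo <= r <= hi:
                        contacts.append(
                            HBondContact(
                                h_molecule=donor_mol.name,
                                h_index=i,
                                acceptor_element=el,
                                acceptor_index=j,
                                length=r,
                                klass=f"{el}-H",
                            )
                        )
    contacts.sort(key=lambda c: (c.length, c.h_molecule, c.h_index, c.acceptor_index))
    return contacts


def charge_transfer(
    analyte_before: Sequence[float], analyte_after: Sequence[float]
) -> float:
    """Net redistributed charge on the analyte (e): Σq_after − Σq_before."""
    before = np.asarray(analyte_before, dtype=float)
    after = np.asarray(analyte_after, dtype=float)
    if before.shape != after.shape:
        raise InputError("charge lists must have equal length")
    return float(after.sum() - before.sum())


@dataclass
class MetricPanel:
    """Per-complex interaction metrics: host volumes before/after binding,
    minimum intermolecular distance, H-bond contacts, net charge transfer."""

    vp0: float  # Å³, host volume before binding
    vp: float  # Å³, host volume in the optimized complex
    delta_v: float  # Å³
    delta_v_percent: float
    min_distance: float  # Å
    min_distance_pair: tuple[int, int]
    hbonds: list[HBondContact]
    charge_transfer_e: float

    def as_dict(self) -> dict:
        return {
            "vp0_A3": self.vp0,
            "vp_A3": self.vp,
            "delta_v_A3": self.delta_v,
            "delta_v_percent": self.delta_v_percent,
            "min_distance_A": self.min_distance,
            "min_distance_pair": list(self.min_distance_pair),
            "n_hbonds": len(self.hbonds),
            "hbonds": [
                [c.klass, c.h_molecule, c.h_index, c.acceptor_index, round(c.length, 6)]
                for c in self.hbonds
            ],
            "charge_transfer_e": self.charge_transfer_e,
        }


def build_metric_panel(
    host_before: Structure,
    host_after: Structure,
    analyte_before: Structure,
    analyte_after: Structure,
    model: Optional[EnergyModel] = None,
    rule: HBondRule = HBondRule(),
) -> MetricPanel:
    """Assemble the full metric panel for one optimized complex.

    If the model provides post-binding charges they feed the charge-transfer
    metric; the classical model echoes input charges, giving zero transfer.
    """
    dv, dvp = volume_change(host_before, host_after)
    dmin, pair = min_intermolecular_distance(host_after, analyte_after)
    q_before = analyte_before.charges if analyte_before.has_charges else None
    transfer = 0.0
    if q_before is not None:
        if model is not None:
            _, q_after = model.charges([host_after, analyte_after])
        else:
            q_after = analyte_after.charges
        transfer = charge_transfer(q_before, q_after)
    return MetricPanel(
        vp0=bounding_box_volume(host_before),
        vp=bounding_box_volume(host_after),
        delta_v=dv,
        delta_v_percent=dvp,
        min_distance=dmin,
        min_distance_pair=pair,
        hbonds=classify_hbonds(host_after, analyte_after, rule),
        charge_transfer_e=transfer,
    )
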