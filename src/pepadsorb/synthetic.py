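"""Synthetic hosts, the analyte library, and reference fixture tables.

The host generator emulates the structural premise of the screening
workflow: a peptide-scale molecule (tens of atoms) carrying a small number of
localized negative "charge wells" — groups of one to three atoms holding a
summed excess charge in the −0.1…−1.0 e band — on an otherwise near-neutral
background.  Background charges are drawn from a truncated normal so that by
construction only well atoms fall inside the default screening window; the
whole molecule is neutralized exactly.

The analyte library ships idealized rigid geometries (standard bond lengths
and angles) with simple zero-sum dipolar reference charges for the eight
panel molecules: ammonia, methanol, ethanol, acetone, benzene, hexane,
toluene and trinitrotoluene.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from .structures import Atom, InputError, Structure

__all__ = [
    "SyntheticHostSpec",
    "GenerationError",
    "ANALYTE_NAMES",
    "ANALYTE_MASSES",
    "make_host",
    "make_analyte",
    "reference_table",
    "FIXTURE_TABLES",
]


class GenerationError(RuntimeError):
    """The generator could not satisfy the placement constraints."""


#: Reference molar masses, g/mol.  The value stored for the lightest analyte
#: is the published 18.039 g/mol (the NH4 mass); the shipped geometry is NH3.
ANALYTE_MASSES = {
    "ammonia": 18.039,
    "methanol": 32.042,
    "ethanol": 46.069,
    "acetone": 58.079,
    "benzene": 78.114,
    "hexane": 86.178,
    "toluene": 92.141,
    "trinitrotoluene": 227.13,
}
ANALYTE_NAMES = tuple(ANALYTE_MASSES)

_HOST_ELEMENTS = np.array(["C", "N", "O", "H", "S"])
_HOST_ELEMENT_P = np.array([0.35, 0.12, 0.15, 0.36, 0.02])


@dataclass(frozen=True)
class SyntheticHostSpec:
    """Parameters of a synthetic peptide-like host.

    ``well_charge`` is the summed excess charge per well (e), split evenly
    over the well's 1–3 member atoms.  ``background_charge_sd`` is the spread
    of the non-well charges, truncated at ±1.9 SD so the background stays
    outside the default screening window; the residual is neutralized by a
    uniform shift of the background.
    """

    n_atoms: int = 80
    n_wells: int = 3
    well_charge: float | tuple[float, ...] = -0.7
    well_sizes: Optional[tuple[int, ...]] = None  # atoms per well; None = random 1–3
    background_charge_sd: float = 0.05
    min_well_separation: float = 8.0  # Å
    extent: float = 20.0  # Å, cubic placement region
    seed: int = 0

    @property
    def well_charges(self) -> tuple[float, ...]:
        if isinstance(self.well_charge, (int, float)):
            return (float(self.well_charge),) * self.n_wells
        return tuple(float(q) for q in self.well_charge)

    def __post_init__(self) -> None:
        if not 1 <= self.n_wells <= 8:
            raise InputError("n_wells must be between 1 and 8")
        if len(self.well_charges) != self.n_wells:
            raise InputError("one well_charge per well required")
        if self.well_sizes is not None:
            if len(self.well_sizes) != self.n_wells:
                raise InputError("one well size per well required")
            if any(not 1 <= s <= 3 for s in self.well_sizes):
                raise InputError("well sizes must be 1–3 atoms")
        if self.n_atoms < 4 * self.n_wells:
            raise InputError("host too small for the requested number of wells")
        if self.extent <= 0 or self.min_well_separation <= 0:
            raise InputError("extent and well separation must be positive")


def _place_points(
    rng: np.random.Generator,
    n: int,
    extent: float,
    existing: list[np.ndarray],
    min_spacing: float = 1.0,
    max_tries: int = 20000,
) -> list[np.ndarray]:
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise GenerationError(
                f"could not place {n} atoms at {min_spacing} Å spacing in a "
                f"{extent} Å box"
            )
        cand = rng.uniform(0.0, extent, 3)
        others = existing + placed
        if not others or min(np.linalg.norm(cand - p) for p in others) >= min_spacing:
            placed.append(cand)
    return placed


def make_host(spec: SyntheticHostSpec) -> tuple[Structure, list[tuple[int, ...]]]:
    """Generate a charged synthetic host and its ground-truth well memberships.

    Deterministic per seed.  Returns ``(structure, wells)`` where ``wells``
    lists the 1–3 member-atom index tuples of each charge well, in generation
    order (aligned with ``spec.well_charges``).
    """
    rng = np.random.default_rng(spec.seed)

    # well seed sites, mutually separated
    tries = 0
    while True:
        tries += 1
        if tries > 200:
            raise GenerationError(
                f"cannot place {spec.n_wells} wells {spec.min_well_separation} Å "
                f"apart within a {spec.extent} Å box"
            )
        sites = [rng.uniform(0.15 * spec.extent, 0.85 * spec.extent, 3) for _ in range(spec.n_wells)]
        ok = all(
            np.linalg.norm(sites[i] - sites[j]) >= spec.min_well_separation
            for i in range(len(sites))
            for j in range(i + 1, len(sites))
        )
        if ok:
            break

    positions: list[np.ndarray] = []
    wells: list[tuple[int, ...]] = []
    for w, site in enumerate(sites):
        size = int(rng.integers(1, 4)) if spec.well_sizes is None else spec.well_sizes[w]
        members = [len(positions)]
        positions.append(site)
        for _ in range(size - 1):
            for _ in range(1000):
                offset = rng.normal(0, 1, 3)
                offset *= rng.uniform(1.1, 1.6) / np.linalg.norm(offset)
                cand = site + offset
                if min(np.linalg.norm(cand - p) for p in positions) >= 1.0:
                    members.append(len(positions))
                    positions.append(cand)
                    break
            else:
                raise GenerationError("could not grow a well cluster")
        wells.append(tuple(members))

    n_background = spec.n_atoms - len(positions)
    positions.extend(_place_points(rng, n_background, spec.extent, positions))
    pos = np.array(positions)

    charges = np.zeros(spec.n_atoms)
    for members, wq in zip(wells, spec.well_charges):
        charges[list(members)] = wq / len(members)
    well_members = {i for w in wells for i in w}
    bg_idx = np.array([i for i in range(spec.n_atoms) if i not in well_members])
    # truncated normal keeps the background outside the screening window
    raw = rng.normal(0.0, spec.background_charge_sd, size=bg_idx.size)
    lim = 1.9 * spec.background_charge_sd
    raw = np.clip(raw, -lim, lim)
    raw -= (charges.sum() + raw.sum()) / bg_idx.size  # exact neutralization
    charges[bg_idx] = raw

    elements = rng.choice(_HOST_ELEMENTS, size=spec.n_atoms, p=_HOST_ELEMENT_P)
    for members in wells:  # well atoms are the electronegative ones
        for i in members:
            elements[i] = "O" if rng.random() < 0.7 else "N"

    atoms = [Atom(e, p, q) for e, p, q in zip(elements, pos, charges)]
    host = Structure(atoms=atoms, role="host", name=f"synthetic-host-{spec.seed}")
    return host, wells


def make_analyte(name: str) -> Structure:
    """Load one of the eight panel analytes (idealized geometry + reference
    charges); the molar mass is available via :data:`ANALYTE_MASSES`."""
    if name not in ANALYTE_MASSES:
        raise KeyError(f"unknown analyte {name!r}; known: {sorted(ANALYTE_MASSES)}")
    from .structures import read_structure

    with resources.as_file(
        resources.files("pepadsorb.data").joinpath(f"analyte_{name}.xyz")
    ) as p:
        s = read_structure(p, format="xyz", role="analyte", name=name)
    return s


FIXTURE_TABLES = {
    "center_charges": "center_charges.tsv",
    "acetone_best_centers": "acetone_best_centers.tsv",
    "peptide_mean_ebind": "peptide_mean_ebind.tsv",
    "analyte_mean_ebind": "analyte_mean_ebind.tsv",
    "min_distances": "min_distances.tsv",
    "charge_transfer_range": "charge_transfer_range.tsv",
    "synthetic_engine_charges": "synthetic_engine_charges.tsv",
    "synthetic_cihnp_acetone_e_energies": "synthetic_cihnp_acetone_e_energies.tsv",
}


def reference_table(table: str):
    """Load a packaged reference table as a pandas DataFrame.

    Tables hold exact published numbers (no interpolation); the two
    ``synthetic_*`` tables are constructed stand-ins consistent with
    published values, as their names and comments state.
    """
    import pandas as pd

    if table not in FIXTURE_TABLES:
        raise KeyError(f"unknown fixture {table!r}; known: {sorted(FIXTURE_TABLES)}")
    with resources.as_file(
        resources.files("pepadsorb.data").joinpath(FIXTURE_TABLES[table])
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#")
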