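"""Energy backends: a pluggable contract plus a built-in classical model.

The pipeline only ever talks to an :class:`EnergyModel`, which maps one or
more structures to a scalar energy in eV (and optionally per-atom charges and
gradients).  The built-in :class:`ClassicalModel` combines intermolecular
Lennard-Jones + Coulomb terms with an intramolecular elastic network, which is
enough to exercise the adsorption-center search, the pose optimization, and
the binding-energy bookkeeping at desk scale.  Reproducing published
tight-binding energetics requires an external quantum engine plugged in
through :func:`external_engine_adapter`.

Units: energies eV, distances Å, charges e.  The Coulomb prefactor
1/(4πε₀) = 14.3996 eV·Å·e⁻².
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .structures import InputError, Structure, write_xyz

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyModel",
    "ClassicalParams",
    "ClassicalModel",
    "EngineSpec",
    "ConfigurationError",
    "external_engine_adapter",
    "lj_pair",
    "coulomb_pair",
    "classical_energy",
]

COULOMB_CONSTANT = 14.3996  # eV·Å·e⁻²

# UFF-derived 12-6 parameters: sigma (Å) = x_vdW / 2^(1/6); epsilon in eV.
DEFAULT_SIGMA = {
    "H": 2.5711,
    "C": 3.4309,
    "N": 3.2607,
    "O": 3.1181,
    "S": 3.5948,
}
DEFAULT_EPSILON = {
    "H": 0.0019080,
    "C": 0.0045532,
    "N": 0.0029921,
    "O": 0.0026018,
    "S": 0.0118818,
}


class ConfigurationError(RuntimeError):
    """An energy backend could not be constructed (missing engine, params)."""


def lj_pair(r: float, sigma: float, epsilon: float) -> float:
    """12-6 Lennard-Jones pair energy: 4ε[(σ/r)¹² − (σ/r)⁶], eV."""
    if r <= 0:
        raise InputError("pair distance must be positive")
    x = (sigma / r) ** 6
    return 4.0 * epsilon * (x * x - x)


def coulomb_pair(r: float, q1: float, q2: float) -> float:
    """Point-charge Coulomb pair energy k·q₁q₂/r, eV."""
    if r <= 0:
        raise InputError("pair distance must be positive")
    return COULOMB_CONSTANT * q1 * q2 / r


@dataclass
class ClassicalParams:
    """Parameters of the classical surrogate energy model.

    ``sigma``/``epsilon`` are per-element 12-6 parameters combined with the
    Lorentz–Berthelot rules (σ arithmetic mean, ε geometric mean).  The
    elastic network puts a harmonic spring of stiffness ``spring_constant``
    on every intramolecular pair closer than ``network_cutoff`` in the
    reference geometry, which lets a host deform ("adapt") on binding without
    a bonded force field.
    """

    sigma: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    epsilon: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EPSILON))
    coulomb_constant: float = COULOMB_CONSTANT
    spring_constant: float = 2.0  # eV/Å²
    network_cutoff: float = 3.0  # Å

    def __post_init__(self) -> None:
        for table, label in ((self.sigma, "sigma"), (self.epsilon, "epsilon")):
            if any(v <= 0 for v in table.values()):
                raise InputError(f"{label} values must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassicalParams":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def atom_tables(self, elements: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        try:
            sig = np.array([self.sigma[e] for e in elements])
            eps = np.array([self.epsilon[e] for e in elements])
        except KeyError as exc:
            raise InputError(f"no LJ parameters for element {exc.args[0]!r}") from None
        return sig, eps


class EnergyModel(ABC):
    """Backend contract: structures in, scalar energy (eV) out.

    ``evaluate`` must be usable on a single isolated structure as well as a
    complex, so binding energies can reference isolated-molecule energies.
    ``gradient`` returns dE/dx (eV/Å) per atom, concatenated in input order;
    backends without analytic gradients may fall back to finite differences.
    """

    @abstractmethod
    def evaluate(self, structures: Sequence[Structure]) -> float: ...

    def gradient(self, structures: Sequence[Structure]) -> np.ndarray:
        return self._fd_gradient(structures)

    def charges(self, structures: Sequence[Structure]) -> list[np.ndarray]:
        """Per-atom charges after evaluation; default echoes input charges."""
        return [s.charges for s in structures]

    def _fd_gradient(self, structures: Sequence[Structure], h: float = 1e-5) -> np.ndarray:
        grads = []
        for si, s in enumerate(structures):
            pos = s.positions
            g = np.zeros_like(pos)
            for i in range(pos.shape[0]):
                for k in range(3):
                    for sign in (1, -1):
                        p = pos.copy()
                        p[i, k] += sign * h
                        seq = list(structures)
                        seq[si] = s.with_positions(p)
                        g[i, k] += sign * self.evaluate(seq)
            grads.append(g / (2 * h))
        return np.concatenate(grads, axis=0)


class ClassicalModel(EnergyModel):
    """Intermolecular LJ + Coulomb, intramolecular elastic network.

    Reference geometries (one per distinct structure name) are captured at
    construction: they define the elastic-network pair list and equilibrium
    distances d₀, so each molecule at its reference geometry contributes zero
    intramolecular energy.  Charges are fixed inputs — this model has no
    polarization, so ``charges()`` echoes them unchanged.
    """

    def __init__(self, references: Sequence[Structure], params: Optional[ClassicalParams] = None):
        self.params = params or ClassicalParams()
        self._networks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._tables: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        names = [s.name for s in references]
        if len(set(names)) != len(names):
            raise InputError("reference structures must have distinct names")
        for s in references:
            if not s.has_charges:
                raise InputError(f"reference {s.name!r} carries no charges")
            pos = s.positions
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            ii, jj = np.where(np.triu(d <= self.params.network_cutoff, k=1))
            self._networks[s.name] = (ii, jj, d[ii, jj])
            sig, eps = self.params.atom_tables(s.elements)
            self._tables[s.name] = (sig, eps, s.charges)

    def _lookup(self, s: Structure):
        if s.name not in self._networks:
            raise InputError(
                f"structure {s.name!r} was not registered at model construction"
            )
        return self._networks[s.name], self._tables[s.name]

    def evaluate(self, structures: Sequence[Structure]) -> float:
        e = 0.0
        k = self.params.spring_constant
        for s in structures:
            (ii, jj, d0), _ = self._lookup(s)
            if len(ii):
                pos = s.positions
                d = np.linalg.norm(pos[ii] - pos[jj], axis=1)
                e += 0.5 * k * float(np.sum((d - d0) ** 2))
        for a_idx in range(len(structures)):
            for b_idx in range(a_idx + 1, len(structures)):
                e += self._cross_energy(structures[a_idx], structures[b_idx])
        return e

    def _cross_terms(self, a: Structure, b: Structure):
        _, (sig_a, eps_a, q_a) = self._lookup(a)
        _, (sig_b, eps_b, q_b) = self._lookup(b)
        rvec = a.positions[:, None, :] - b.positions[None, :, :]
        r = np.linalg.norm(rvec, axis=-1)
        sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
        eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
        qq = q_a[:, None] * q_b[None, :]
        return rvec, r, sig, eps, qq

    def _cross_energy(self, a: Structure, b: Structure) -> float:
        _, r, sig, eps, qq = self._cross_terms(a, b)
        x = (sig / r) ** 6
        return float(np.sum(4.0 * eps * (x * x - x))
                     + self.params.coulomb_constant * np.sum(qq / r))

    def gradient(self, structures: Sequence[Structure]) -> np.ndarray:
        k = self.params.spring_constant
        kc = self.params.coulomb_constant
        grads = [np.zeros((len(s), 3)) for s in structures]
        for s, g in zip(structures, grads):
            (ii, jj, d0), _ = self._lookup(s)
            if len(ii):
                pos = s.positions
                dvec = pos[ii] - pos[jj]
                d = np.linalg.norm(dvec, axis=1)
                f = (k * (d - d0) / d)[:, None] * dvec  # dE/dx_i per spring
                np.add.at(g, ii, f)
                np.add.at(g, jj, -f)
        for a_idx in range(len(structures)):
            for b_idx in range(a_idx + 1, len(structures)):
                a, b = structures[a_idx], structures[b_idx]
                rvec, r, sig, eps, qq = self._cross_terms(a, b)
                x = (sig / r) ** 6
                # dV/dr for LJ + Coulomb, then chain rule through r
                dvdr = 4.0 * eps * (-12.0 * x * x + 6.0 * x) / r - kc * qq / r**2
                w = (dvdr / r)[:, :, None] * rvec
                grads[a_idx] += w.sum(axis=1)
                grads[b_idx] -= w.sum(axis=0)
        return np.concatenate(grads, axis=0)


def classical_energy(
    host: Structure, analyte: Structure, params: Optional[ClassicalParams] = None
) -> float:
    """Total classical energy of a host/analyte pair (eV).

    Convenience wrapper: the current geometries double as the elastic-network
    reference, so the returned value is the pure intermolecular interaction.
    """
    return ClassicalModel([host, analyte], params).evaluate([host, analyte])


@dataclass
class EngineSpec:
    """How to invoke an external quantum engine.

    The command is run with the path of a combined XYZ file appended; it must
    print the total energy (eV) as the last whitespace-separated token on
    stdout.  With ``charges_flag`` set, a second invocation with that flag is
    expected to print one charge per atom, in file order.
    """

    command: list[str]
    workdir: Optional[str] = None
    charges_flag: Optional[str] = None


class ExternalEngineModel(EnergyModel):
    """Adapter delegating energy (and optionally charge) evaluation to an
    external engine process — the route to published tight-binding energetics,
    never required by the built-in tests."""

    def __init__(self, spec: EngineSpec):
        if not spec.command:
            raise ConfigurationError("engine spec has an empty command")
        exe = spec.command[0]
        if shutil.which(exe) is None and not Path(exe).exists():
            raise ConfigurationError(f"engine executable {exe!r} not found")
        self.spec = spec

    def _run(self, structures: Sequence[Structure], extra: list[str]) -> str:
        merged = Structure(
            atoms=[a for s in structures for a in s.atoms], name="system"
        )
        with tempfile.TemporaryDirectory() as tmp:
            xyz = Path(tmp) / "system.xyz"
            write_xyz(merged, xyz)
            proc = subprocess.run(
                [*self.spec.command, *extra, str(xyz)],
                capture_output=True,
                text=True,
                cwd=self.spec.workdir,
            )
        if proc.returncode != 0:
            raise RuntimeError(f"engine failed ({proc.returncode}): {proc.stderr.strip()}")
        return proc.stdout

    def evaluate(self, structures: Sequence[Structure]) -> float:
        out = self._run(structures, []).split()
        if not out:
            raise RuntimeError("engine produced no output")
        return float(out[-1])

    def charges(self, structures: Sequence[Structure]) -> list[np.ndarray]:
        if self.spec.charges_flag is None:
            return super().charges(structures)
        values = [float(v) for v in self._run(structures, [self.spec.charges_flag]).split()]
        n_total = sum(len(s) for s in structures)
        if len(values) != n_total:
            raise RuntimeError(f"engine returned {len(values)} charges for {n_total} atoms")
        out, k = [], 0
        for s in structures:
            out.append(np.array(values[k : k + len(s)]))
            k += len(s)
        return out


def external_engine_adapter(spec: EngineSpec) -> EnergyModel:
    """Construct an :class:`ExternalEngineModel`; fails fast if the engine
    executable is missing (at construction, not at evaluate time)."""
    return ExternalEngineModel(spec)
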