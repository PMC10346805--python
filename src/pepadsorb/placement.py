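"""Step 2 of the screening workflow: dock analytes at candidate centers.

For each adsorption center a probe analyte is placed just outside the host at
seeded random orientations; every pose is relaxed by a limited-memory
quasi-Newton (L-BFGS) descent in which all atomic coordinates of both
molecules vary.  The binding energy

    E_bind = E_complex − (E_host + E_analyte)

uses isolated-molecule reference energies obtained by minimizing host and
analyte alone under the same energy model.  The center with the lowest
(most negative) binding energy for the probe is the most active one; the full
analyte panel is then docked there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .centers import AdsorptionCenter
from .energy import EnergyModel
from .structures import InputError, Structure, transform

__all__ = [
    "Pose",
    "OptimizationSettings",
    "BindingResult",
    "CenterScanReport",
    "PlacementError",
    "OptimizationError",
    "generate_poses",
    "apply_pose",
    "minimize_structures",
    "minimize_complex",
    "binding_energy",
    "scan_centers",
    "dock_panel",
]

MIN_CONTACT = 0.8  # Å; poses with any closer host–analyte pair are rejected


class PlacementError(RuntimeError):
    """No acceptable pose could be generated at a center."""


class OptimizationError(RuntimeError):
    """Energy went non-finite during descent; carries the last valid state."""

    def __init__(self, message: str, last_valid=None):
        super().__init__(message)
        self.last_valid = last_valid


@dataclass(frozen=True)
class Pose:
    """A rigid placement: rotation about the analyte centroid, then the
    centroid moved to ``center + offset_direction · offset_distance``."""

    rotation: np.ndarray
    offset_direction: np.ndarray
    offset_distance: float

    def __post_init__(self) -> None:
        d = np.asarray(self.offset_direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-8):
            raise InputError("offset_direction must be a unit vector")
        if self.offset_distance <= 0:
            raise InputError("offset_distance must be positive")
        object.__setattr__(self, "offset_direction", d)
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))


@dataclass(frozen=True)
class OptimizationSettings:
    """L-BFGS settings.  Convergence: the energy change per accepted step,
    normalized per atom, drops below ``tolerance`` (default 1e-4 eV/atom)."""

    tolerance: float = 1e-4  # eV/atom
    max_iterations: int = 2000
    history: int = 10  # L-BFGS memory
    armijo_c1: float = 1e-4
    backtrack: float = 0.5
    min_step: float = 1e-12

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise InputError("tolerance must be positive")


@dataclass
class BindingResult:
    """One host/analyte/center docking outcome with its energy bookkeeping."""

    center_label: str
    analyte_name: str
    e_complex: float
    e_host: float
    e_analyte: float
    optimized_host: Optional[Structure] = None
    optimized_analyte: Optional[Structure] = None
    converged: bool = True
    failed: bool = False
    metrics: Optional[dict] = None

    @property
    def e_bind(self) -> float:
        return binding_energy(self.e_complex, self.e_host, self.e_analyte)


@dataclass
class CenterScanReport:
    """Per-center probe results; ``most_active`` minimizes E_bind (ties by
    label order)."""

    results: list[BindingResult]
    most_active: str


def generate_poses(
    center: AdsorptionCenter,
    analyte: Structure,
    host: Structure,
    n_orientations: int = 24,
    approach_distance: float = 3.0,
    seed: int = 0,
) -> list[Pose]:
    """Seeded uniform random orientations at a center, approaching from
    outside (offset points away from the host centroid).  Poses bringing any
    analyte atom within 0.8 Å of a host atom are discarded; if none survive a
    :class:`PlacementError` is raised."""
    if n_orientations < 1:
        raise InputError("need at least one orientation")
    if center.centroid is None:
        raise InputError(f"center {center.label!r} has no centroid")
    away = center.centroid - host.centroid()
    nrm = np.linalg.norm(away)
    direction = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])

    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_orientations, rng=rng)
    poses = []
    for i in range(n_orientations):
        pose = Pose(
            rotation=rots[i].as_matrix(),
            offset_direction=direction,
            offset_distance=approach_distance,
        )
        placed = apply_pose(pose, center, analyte)
        from .structures import min_intermolecular_distance

        d, _ = min_intermolecular_distance(host, placed)
        if d >= MIN_CONTACT:
            poses.append(pose)
    if not poses:
        raise PlacementError(
            f"all {n_orientations} poses at center {center.label!r} clash with the host"
        )
    return poses


def apply_pose(pose: Pose, center: AdsorptionCenter, analyte: Structure) -> Structure:
    """Realize a pose as a rigid transform of the analyte."""
    target = center.centroid + pose.offset_direction * pose.offset_distance
    c0 = analyte.centroid()
    return transform(analyte, pose.rotation, target - pose.rotation @ c0)


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def _split(x: np.ndarray, structures: Sequence[Structure]) -> list[Structure]:
    out, k = [], 0
    for s in structures:
        n = len(s)
        out.append(s.with_positions(x[k : k + n * 3].reshape(n, 3)))
        k += n * 3
    return out


def minimize_structures(
    structures: Sequence[Structure],
    model: EnergyModel,
    settings: OptimizationSettings = OptimizationSettings(),
) -> tuple[list[Structure], float, bool]:
    """Relax all atomic coordinates of all given structures by L-BFGS with
    Armijo backtracking.  Accepted steps never increase the energy; descent
    stops when the per-atom energy change of an accepted step falls below
    ``settings.tolerance`` (converged) or at ``max_iterations``.

    Returns (optimized structures, final energy eV, converged flag).
    """
    n_atoms = sum(len(s) for s in structures)
    x = np.concatenate([s.positions.ravel() for s in structures])

    def f_g(xv):
        ss = _split(xv, structures)
        return model.evaluate(ss), model.gradient(ss).ravel()

    e, g = f_g(x)
    if not np.isfinite(e):
        raise OptimizationError("non-finite energy at the starting geometry")
    if np.linalg.norm(g, ord=np.inf) < 1e-12:
        return _split(x, structures), e, True

    m = settings.history
    s_hist: list[np.ndarray] = []
    y_hist: list[np.ndarray] = []
    converged = False
    for _ in range(settings.max_iterations):
        # two-loop recursion for the quasi-Newton direction
        q = g.copy()
        alphas = []
        for si, yi in zip(reversed(s_hist), reversed(y_hist)):
            rho = 1.0 / (yi @ si)
            a = rho * (si @ q)
            alphas.append((a, rho, si, yi))
            q -= a * yi
        if y_hist:
            ylast, slast = y_hist[-1], s_hist[-1]
            q *= (slast @ ylast) / (ylast @ ylast)
        for a, rho, si, yi in reversed(alphas):
            b = rho * (yi @ q)
            q += si * (a - b)
        d = -q
        if d @ g >= 0:  # not a descent direction; fall back to steepest descent
            d = -g
            s_hist.clear()
            y_hist.clear()

        step = 1.0 if s_hist else min(1.0, 1.0 / max(np.linalg.norm(g), 1e-8))
        gd = g @ d
        accepted = False
        while step >= settings.min_step:
            x_new = x + step * d
            e_new, g_new = f_g(x_new)
            if not np.isfinite(e_new):
                step *= settings.backtrack
                continue
            if e_new <= e + settings.armijo_c1 * step * gd:
                accepted = True
                break
            step *= settings.backtrack
        if not accepted:
            # line search exhausted: we are at (numerical) stationarity
            converged = True
            break

        s_vec = x_new - x
        y_vec = g_new - g
        if (s_vec @ y_vec) > 1e-12:
            s_hist.append(s_vec)
            y_hist.append(y_vec)
            if len(s_hist) > m:
                s_hist.pop(0)
                y_hist.pop(0)
        de = e - e_new
        x, e, g = x_new, e_new, g_new
        if not np.isfinite(e):
            raise OptimizationError("energy became non-finite", last_valid=_split(x, structures))
        if de / n_atoms < settings.tolerance:
            converged = True
            break
        if np.linalg.norm(g, ord=np.inf) < 1e-10:
            converged = True
            break

    return _split(x, structures), float(e), converged


def minimize_complex(
    host: Structure,
    analyte: Structure,
    model: EnergyModel,
    settings: OptimizationSettings = OptimizationSettings(),
) -> tuple[Structure, Structure, float, bool]:
    """Relax a host + analyte complex; all coordinates of both molecules vary."""
    (h, a), e, conv = minimize_structures([host, analyte], model, settings)
    return h, a, e, conv


def binding_energy(e_complex: float, e_host: float, e_analyte: float) -> float:
    """E_bind = E_complex − (E_host + E_analyte); more negative = stronger."""
    return e_complex - (e_host + e_analyte)


# ---------------------------------------------------------------------------
# Center scan and panel docking
# ---------------------------------------------------------------------------

def _reference_energies(
    host: Structure, analyte: Structure, model: EnergyModel, settings: OptimizationSettings
) -> tuple[float, float]:
    (_,), e_host, _ = minimize_structures([host], model, settings)
    (_,), e_analyte, _ = minimize_structures([analyte], model, settings)
    return e_host, e_analyte


def _center_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(index,)).generate_state(1)[0] % (2**31))


def _dock_one(
    host: Structure,
    analyte: Structure,
    center: AdsorptionCenter,
    model: EnergyModel,
    settings: OptimizationSettings,
    seed: int,
    n_orientations: int,
    approach_distance: float,
    e_host: float,
    e_analyte: float,
) -> BindingResult:
    poses = generate_poses(
        center, analyte, host, n_orientations=n_orientations,
        approach_distance=approach_distance, seed=seed,
    )
    best: Optional[BindingResult] = None
    for pose in poses:
        placed = apply_pose(pose, center, analyte)
        h_opt, a_opt, e_cplx, conv = minimize_complex(host, placed, model, settings)
        res = BindingResult(
            center_label=center.label,
            analyte_name=analyte.name,
            e_complex=e_cplx,
            e_host=e_host,
            e_analyte=e_analyte,
            optimized_host=h_opt,
            optimized_analyte=a_opt,
            converged=conv,
        )
        if best is None or res.e_bind < best.e_bind:
            best = res
    assert best is not None
    return best


def scan_centers(
    host: Structure,
    probe: Structure,
    centers: Sequence[AdsorptionCenter],
    model: EnergyModel,
    settings: OptimizationSettings = OptimizationSettings(),
    seed: int = 0,
    n_orientations: int = 24,
    approach_distance: float = 3.0,
) -> CenterScanReport:
    """Dock the probe at every center; flag the most active one.

    Deterministic for a fixed seed: each center gets an independent
    sub-stream derived from the master seed.  Centers where every pose fails
    are marked failed and excluded from the argmin; if all centers fail the
    scan raises."""
    if len(centers) == 0:
        raise InputError("need at least one center to scan")
    e_host, e_analyte = _reference_energies(host, probe, model, settings)
    results: list[BindingResult] = []
    for i, center in enumerate(centers):
        try:
            results.append(
                _dock_one(
                    host, probe, center, model, settings,
                    _center_seed(seed, i), n_orientations, approach_distance,
                    e_host, e_analyte,
                )
            )
        except PlacementError as exc:
            warnings.warn(str(exc))
            results.append(
                BindingResult(
                    center_label=center.label,
                    analyte_name=probe.name,
                    e_complex=float("nan"),
                    e_host=e_host,
                    e_analyte=e_analyte,
                    converged=False,
                    failed=True,
                )
            )
    ok = [r for r in results if not r.failed]
    if not ok:
        raise PlacementError("probe placement failed at every center")
    most_active = min(ok, key=lambda r: (r.e_bind, r.center_label)).center_label
    return CenterScanReport(results=results, most_active=most_active)


def dock_panel(
    host: Structure,
    analytes: Sequence[Structure],
    active_center: AdsorptionCenter,
    model: EnergyModel,
    settings: OptimizationSettings = OptimizationSettings(),
    seed: int = 0,
    n_orientations: int = 24,
    approach_distance: float = 3.0,
    attach_metrics: bool = True,
) -> list[BindingResult]:
    """Dock a panel of analytes at the chosen center, one best-of-poses
    result per analyte, each with its interaction metric panel attached.
    Per-analyte failures are recorded (``failed=True``) and the run continues.
    """
    if len(analytes) == 0:
        raise InputError("analyte panel is empty")
    results = []
    for i, analyte in enumerate(analytes):
        e_host, e_analyte = _reference_energies(host, analyte, model, settings)
        try:
            res = _dock_one(
                host, analyte, active_center, model, settings,
                _center_seed(seed, i), n_orientations, approach_distance,
                e_host, e_analyte,
            )
        except PlacementError as exc:
            warnings.warn(str(exc))
            results.append(
                BindingResult(
                    center_label=active_center.label,
                    analyte_name=analyte.name,
                    e_complex=float("nan"),
                    e_host=e_host,
                    e_analyte=e_analyte,
                    converged=False,
                    failed=True,
                )
            )
            continue
        if attach_metrics:
            from .metrics import build_metric_panel

            res.metrics = build_metric_panel(
                host_before=host,
                host_after=res.optimized_host,
                analyte_before=analyte,
                analyte_after=res.optimized_analyte,
                model=model,
            ).as_dict()
        results.append(res)
    return results
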