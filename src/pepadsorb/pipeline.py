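"""End-to-end orchestration: centers → probe scan → panel docking → report.

A single seed governs every stochastic stage (synthetic host generation and
pose orientations); stage-local seeds are derived deterministically from it,
so identical config + seed produces byte-identical report files.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .centers import CenterScanConfig, ChargeWindow, find_local_centers, write_center_report
from .energy import ClassicalModel, ClassicalParams, EnergyModel
from .metrics import EV_TO_KCAL_PER_MOL, ev_to_kcal
from .placement import (
    BindingResult,
    CenterScanReport,
    OptimizationSettings,
    dock_panel,
    scan_centers,
)
from .structures import InputError, Structure, read_structure, write_xyz
from .synthetic import ANALYTE_NAMES, SyntheticHostSpec, make_analyte, make_host

__all__ = ["PipelineConfig", "run_pipeline", "summarize", "rank_hosts_by_mean"]

_SCAN_COLUMNS = ["center", "analyte", "e_complex_ev", "e_host_ev", "e_analyte_ev",
                 "e_bind_ev", "e_bind_kcal_mol", "converged", "failed"]


def _derive_seed(seed: int, stage: str) -> int:
    import zlib

    # crc32 of the stage tag is stable across processes (unlike str hash)
    return int((seed * 1009 + zlib.crc32(stage.encode()) % 1000) % (2**31))


@dataclass
class PipelineConfig:
    """Validated configuration of a full screening run.

    Either ``host_path`` (+ optional ``charges_path``) or ``synthetic`` must
    be given.  ``backend`` is ``classical`` (built-in) or ``external`` (needs
    ``engine_command``).
    """

    host_path: Optional[str] = None
    charges_path: Optional[str] = None
    synthetic: Optional[SyntheticHostSpec] = None
    probe: str = "acetone"
    panel: tuple[str, ...] = ANALYTE_NAMES
    centers: CenterScanConfig = field(default_factory=CenterScanConfig)
    optimization: OptimizationSettings = field(default_factory=OptimizationSettings)
    backend: str = "classical"
    engine_command: Optional[list[str]] = None
    n_orientations: int = 24
    approach_distance: float = 3.0
    seed: int = 0
    outdir: str = "pepadsorb_run"

    def __post_init__(self) -> None:
        if (self.host_path is None) == (self.synthetic is None):
            raise InputError("give exactly one of host_path or synthetic")
        if self.host_path is not None and not Path(self.host_path).exists():
            raise InputError(f"host file {self.host_path!r} does not exist")
        if self.charges_path is not None and not Path(self.charges_path).exists():
            raise InputError(f"charges file {self.charges_path!r} does not exist")
        if self.probe not in self.panel:
            self.panel = (self.probe, *self.panel)
        unknown = [a for a in self.panel if a not in ANALYTE_NAMES]
        if unknown:
            raise InputError(f"unknown analytes {unknown}")
        if self.backend not in ("classical", "external"):
            raise InputError(f"unknown backend {self.backend!r}")
        if self.backend == "external" and not self.engine_command:
            raise InputError("external backend needs engine_command")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise InputError(f"unknown config keys: {sorted(extra)}")
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticHostSpec(**raw["synthetic"])
        if "centers" in raw and raw["centers"] is not None:
            c = dict(raw["centers"])
            if "window" in c:
                c["window"] = ChargeWindow(**c["window"])
            raw["centers"] = CenterScanConfig(**c)
        if "optimization" in raw and raw["optimization"] is not None:
            raw["optimization"] = OptimizationSettings(**raw["optimization"])
        if "panel" in raw and raw["panel"] is not None:
            raw["panel"] = tuple(raw["panel"])
        return cls(**raw)


def _load_host(cfg: PipelineConfig) -> Structure:
    if cfg.synthetic is not None:
        spec = cfg.synthetic
        if spec.seed != cfg.seed:
            spec = SyntheticHostSpec(**{**asdict(spec), "seed": _derive_seed(cfg.seed, "host")})
        host, _ = make_host(spec)
        return host
    return read_structure(cfg.host_path, charges=cfg.charges_path, role="host")


def _build_model(cfg: PipelineConfig, references: Sequence[Structure]) -> EnergyModel:
    if cfg.backend == "classical":
        return ClassicalModel(references, ClassicalParams())
    from .energy import EngineSpec, external_engine_adapter

    return external_engine_adapter(EngineSpec(command=list(cfg.engine_command)))


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _write_scan_tsv(path: Path, results: Sequence[BindingResult]) -> None:
    lines = ["\t".join(_SCAN_COLUMNS)]
    for r in results:
        lines.append("\t".join([
            r.center_label, r.analyte_name,
            _fmt(r.e_complex), _fmt(r.e_host), _fmt(r.e_analyte),
            _fmt(r.e_bind), _fmt(ev_to_kcal(r.e_bind)),
            str(int(r.converged)), str(int(r.failed)),
        ]))
    path.write_text("\n".join(lines) + "\n")


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and write a report bundle to ``cfg.outdir``.

    Bundle contents: ``host.xyz``, ``centers.tsv``, ``scan.tsv`` (probe at
    every center), ``panel.tsv`` (full panel at the most active center),
    ``metrics.jsonl`` (one metric panel per analyte) and ``manifest.json``.
    Returns a dict with the in-memory results.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    _log("host", "loading host structure")
    host = _load_host(cfg)
    write_xyz(host, out / "host.xyz", comment=f"host {host.name}")

    _log("centers", f"screening window [{cfg.centers.window.lower}, {cfg.centers.window.upper}] e")
    centers = find_local_centers(host, cfg.centers)
    write_center_report(centers, out / "centers.tsv")
    if not centers:
        raise InputError("no adsorption centers found; widen the charge window")
    _log("centers", f"{len(centers)} center(s): " + ", ".join(c.label for c in centers))

    analytes = [make_analyte(n) for n in cfg.panel]
    probe = analytes[cfg.panel.index(cfg.probe)]
    model = _build_model(cfg, [host, *analytes])

    _log("scan", f"probing {len(centers)} center(s) with {cfg.probe}")
    scan = scan_centers(
        host, probe, centers, model, cfg.optimization,
        seed=_derive_seed(cfg.seed, "scan"),
        n_orientations=cfg.n_orientations,
        approach_distance=cfg.approach_distance,
    )
    _write_scan_tsv(out / "scan.tsv", scan.results)
    _log("scan", f"most active center: {scan.most_active}")

    active = next(c for c in centers if c.label == scan.most_active)
    _log("dock", f"docking {len(analytes)} analyte(s) at center {active.label}")
    panel = dock_panel(
        host, analytes, active, model, cfg.optimization,
        seed=_derive_seed(cfg.seed, "panel"),
        n_orientations=cfg.n_orientations,
        approach_distance=cfg.approach_distance,
    )
    _write_scan_tsv(out / "panel.tsv", panel)
    with (out / "metrics.jsonl").open("w") as fh:
        for r in panel:
            rec = {"host": host.name, "center": r.center_label, "analyte": r.analyte_name,
                   "e_bind_ev": round(r.e_bind, 6) if np.isfinite(r.e_bind) else None}
            rec.update(r.metrics or {})
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    manifest = {
        "package": "pepadsorb",
        "version": __version__,
        "seed": cfg.seed,
        "backend": cfg.backend,
        "probe": cfg.probe,
        "panel": list(cfg.panel),
        "host": host.name,
        "n_centers": len(centers),
        "most_active": scan.most_active,
        "ev_to_kcal_per_mol": EV_TO_KCAL_PER_MOL,
        "config": {
            "window": [cfg.centers.window.lower, cfg.centers.window.upper],
            "k": cfg.centers.k,
            "grouping_radius": cfg.centers.grouping_radius,
            "tolerance_ev_per_atom": cfg.optimization.tolerance,
            "max_iterations": cfg.optimization.max_iterations,
            "n_orientations": cfg.n_orientations,
            "approach_distance_A": cfg.approach_distance,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    _log("done", f"bundle written to {out}")
    return {"host": host, "centers": centers, "scan": scan, "panel": panel, "outdir": out}


def rank_hosts_by_mean(table, host_col: str = "host", value_col: str = "mean_ebind_ev") -> list[str]:
    """Order hosts by mean binding energy, most negative (strongest) first."""
    return list(table.sort_values(value_col)[host_col])


def summarize(bundle_paths: Sequence[str | Path]):
    """Cross-host comparison table from one or more report bundles.

    One row per host: mean E_bind (eV and kcal/mol), mean volume change,
    smallest minimum distance, mean charge transfer; hosts ranked by mean
    E_bind ascending, with the best/worst mean ratio in ``ratio_best_worst``.
    """
    import pandas as pd

    if not bundle_paths:
        raise InputError("need at least one bundle")
    rows = []
    for bp in bundle_paths:
        bp = Path(bp)
        mf = json.loads((bp / "manifest.json").read_text())
        if mf.get("package") != "pepadsorb":
            raise InputError(f"{bp}: not a pepadsorb bundle")
        recs = [json.loads(l) for l in (bp / "metrics.jsonl").read_text().splitlines()]
        df = pd.DataFrame(recs)
        ok = df[df["e_bind_ev"].notna()]
        rows.append({
            "host": mf["host"],
            "most_active_center": mf["most_active"],
            "mean_ebind_ev": ok["e_bind_ev"].mean(),
            "mean_ebind_kcal_mol": ev_to_kcal(ok["e_bind_ev"].mean()),
            "mean_delta_v_A3": ok["delta_v_A3"].mean() if "delta_v_A3" in ok else float("nan"),
            "min_distance_A": ok["min_distance_A"].min() if "min_distance_A" in ok else float("nan"),
            "mean_charge_transfer_e": ok["charge_transfer_e"].mean() if "charge_transfer_e" in ok else float("nan"),
        })
    table = pd.DataFrame(rows).sort_values("mean_ebind_ev").reset_index(drop=True)
    table["ratio_best_worst"] = table["mean_ebind_ev"].iloc[0] / table["mean_ebind_ev"].iloc[-1]
    return table
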