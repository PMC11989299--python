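"""Parametric safety study: implant-to-nerve distance x bone stiffness.

Reruns the FE pipeline over every combination of apex-to-canal distance
(default 1.5 / 0.5 / 0.1 mm) and trabecular Young's modulus (default:
the fourteen HU-derived grades), extracts the maximum nerve-surface
pressure, and classifies each case against the conduction-block
threshold (safe iff p < threshold, strict).  Only the trabecular region
is swept; cortical bone and all other materials stay at their reference
values (a config switch can sweep cortical too).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibration
from .fem import LoadCase, Material, adaptive_converge, default_materials
from .geometry import ModelParams, Region

__all__ = ["SweepConfig", "SweepResult", "run_case", "run_sweep",
           "monotonicity_report", "make_curves", "results_frame"]


def _default_grades() -> tuple[tuple[float, float], ...]:
    pts = calibration.build_calibration_table(calibration.DEFAULT_HU_GRADES)
    return tuple((p.hu, p.e_modulus) for p in pts)


@dataclass(frozen=True)
class SweepConfig:
    """Grid, threshold and solver settings for the parametric study.

    ``grades`` are (HU, E_MPa) pairs for the trabecular bone; HU may be
    NaN for grades specified directly by modulus.  ``threshold_mpa``
    defaults to the printed clinical value 0.026 MPa (200 mmHg,
    truncated display).
    """

    distances_mm: tuple[float, ...] = (1.5, 0.5, 0.1)
    grades: tuple[tuple[float, float], ...] = field(default_factory=_default_grades)
    threshold_mpa: float = 0.026
    load_n: float = 200.0
    model: ModelParams = field(default_factory=ModelParams)
    sweep_cortical: bool = False
    rel_tol: float = 0.10
    max_meshes: int = 4
    refine_factor: float = 0.7
    refine_floor: float | None = None
    axial_window: float | None = None

    def __post_init__(self) -> None:
        if not self.grades:
            raise ValueError("stiffness grid must be non-empty")
        if any(d <= 0 for d in self.distances_mm):
            raise ValueError("distances must be > 0")
        if self.threshold_mpa <= 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class SweepResult:
    """One (distance, stiffness) case of the study."""

    distance_mm: float
    hu: float
    e_trab_mpa: float
    p_max_mpa: float
    safe: bool
    converged: bool
    n_tets: int = 0
    error: str | None = None

    @property
    def p_max_mmhg(self) -> float:
        return calibration.mpa_to_mmhg(self.p_max_mpa)


def classify(p_max_mpa: float, threshold_mpa: float) -> bool:
    """Safe iff pressure strictly below the threshold."""
    return p_max_mpa < threshold_mpa


def run_case(d: float, e_trab: float, config: SweepConfig,
             hu: float = float("nan")) -> SweepResult:
    """Solve one distance/stiffness combination to adaptive convergence."""
    params = config.model.with_(apex_to_canal_distance=d)
    materials = default_materials()
    materials[Region.TRABECULAR] = Material(
        float(e_trab), materials[Region.TRABECULAR].nu)
    if config.sweep_cortical:
        materials[Region.CORTICAL] = Material(
            float(e_trab), materials[Region.CORTICAL].nu)
    load = LoadCase(total_load=config.load_n)
    result = adaptive_converge(params, materials, load,
                               rel_tol=config.rel_tol,
                               max_meshes=config.max_meshes,
                               factor=config.refine_factor,
                               floor=config.refine_floor,
                               axial_window=config.axial_window)
    p_max = result.trace[-1]["max_nerve_pressure_MPa"]
    return SweepResult(distance_mm=float(d), hu=float(hu),
                       e_trab_mpa=float(e_trab), p_max_mpa=float(p_max),
                       safe=classify(p_max, config.threshold_mpa),
                       converged=result.converged,
                       n_tets=result.mesh.n_tets)


def run_sweep(config: SweepConfig,
              runner: Callable[..., SweepResult] | None = None
              ) -> list[SweepResult]:
    """All distance x grade combinations, sorted by (-distance, E).

    Per-case failures are recorded in the result row (``error`` field),
    never silently dropped.
    """
    runner = runner or run_case
    results: list[SweepResult] = []
    distances = sorted(config.distances_mm, reverse=True)
    grades = sorted(config.grades, key=lambda g: g[1])
    for d in distances:
        for hu, e in grades:
            try:
                results.append(runner(d, e, config, hu=hu))
            except Exception as exc:  # noqa: BLE001 - per-case bookkeeping
                results.append(SweepResult(
                    distance_mm=float(d), hu=float(hu), e_trab_mpa=float(e),
                    p_max_mpa=float("nan"), safe=False, converged=False,
                    error=f"{type(exc).__name__}: {exc}"))
    return results


def results_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    """Tabular view: one row per case, full precision."""
    return pd.DataFrame([{
        "distance_mm": r.distance_mm,
        "hu": r.hu,
        "e_trab_MPa": r.e_trab_mpa,
        "p_max_MPa": r.p_max_mpa,
        "p_max_mmHg": r.p_max_mmhg,
        "safe": r.safe,
        "converged": r.converged,
        "n_tets": r.n_tets,
        "error": r.error or "",
    } for r in results])


def monotonicity_report(results: Sequence[SweepResult],
                        distance_tol: float = 0.10,
                        overlap_tol: float = 0.25) -> dict:
    """Trend checks mirroring the study's qualitative findings.

    (i)  at each distance, pressure is non-increasing in trabecular E;
    (ii) at each stiffness, pressure does not decrease as the implant
         approaches the nerve, within ``distance_tol`` relative;
    (iii) the two closest distances follow near-overlapping curves,
         quantified by the max relative gap (pass if <= ``overlap_tol``).
    All comparisons are non-strict, so a constant grid passes.
    """
    df = results_frame(results)
    report: dict = {"pressure_monotone_in_E": True,
                    "pressure_ordering_in_distance": True,
                    "close_distance_overlap": True,
                    "violations": [], "max_overlap_gap": 0.0}

    for d, grp in df.groupby("distance_mm"):
        g = grp.sort_values("e_trab_MPa")
        p = g["p_max_MPa"].to_numpy()
        e = g["e_trab_MPa"].to_numpy()
        bad = np.nonzero(np.diff(p) > 1e-12)[0]
        for i in bad:
            report["pressure_monotone_in_E"] = False
            report["violations"].append(
                f"d={d}: p rises {p[i]:.4g}->{p[i + 1]:.4g} MPa "
                f"between E={e[i]:.4g} and E={e[i + 1]:.4g} MPa")

    for e, grp in df.groupby("e_trab_MPa"):
        g = grp.sort_values("distance_mm", ascending=False)
        p = g["p_max_MPa"].to_numpy()
        dd = g["distance_mm"].to_numpy()
        for i in range(len(p) - 1):
            if p[i] > p[i + 1] * (1 + distance_tol) + 1e-15:
                report["pressure_ordering_in_distance"] = False
                report["violations"].append(
                    f"E={e:.4g} MPa: p(d={dd[i]})={p[i]:.4g} exceeds "
                    f"p(d={dd[i + 1]})={p[i + 1]:.4g} by more than "
                    f"{100 * distance_tol:.0f}%")

    dists = sorted(df["distance_mm"].unique())
    if len(dists) >= 2:
        d_lo, d_hi = dists[0], dists[1]
        a = df[df["distance_mm"] == d_lo].sort_values("e_trab_MPa")["p_max_MPa"].to_numpy()
        b = df[df["distance_mm"] == d_hi].sort_values("e_trab_MPa")["p_max_MPa"].to_numpy()
        if len(a) == len(b) and len(a):
            denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-30)
            gap = float(np.max(np.abs(a - b) / denom))
            report["max_overlap_gap"] = gap
            report["close_distance_overlap"] = gap <= overlap_tol

    report["passed"] = (report["pressure_monotone_in_E"]
                        and report["pressure_ordering_in_distance"]
                        and report["close_distance_overlap"])
    return report


def make_curves(results: Sequence[SweepResult],
                threshold_mmhg: float = 200.0) -> dict:
    """Per-distance pressure curves vs HU and vs E, in mmHg.

    Returns plotting-ready series plus the threshold line level; use
    :func:`ianload.fileio.export_curves` to write CSV/PNG.
    """
    df = results_frame(results)
    series = {}
    for d, grp in df.groupby("distance_mm"):
        g = grp.sort_values("e_trab_MPa")
        series[float(d)] = {
            "hu": g["hu"].to_numpy(),
            "e_trab_MPa": g["e_trab_MPa"].to_numpy(),
            "p_mmHg": g["p_max_mmHg"].to_numpy(),
            "p_MPa": g["p_max_MPa"].to_numpy(),
        }
    return {"series": series,
            "threshold_mmHg": threshold_mmhg,
            "threshold_MPa": calibration.mmhg_to_mpa(threshold_mmhg)}
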