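"""End-to-end orchestration: generate/ingest -> order parameters -> landscape
-> states -> kinetics -> structural characterization -> report.

Every stage writes plain-file artifacts (CSV/JSON) when an output directory
is given, so each module's result can be inspected and re-used
independently.  The whole run is reproducible from the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import trajectory_io
from .contact_structure import (
    STANDARD_OBSERVABLES,
    histogram_values,
    prior_to_ts_ensemble,
    ts_frames_by_class,
)
from .errors import ConfigurationError
from .landscape import build_landscape, subset_errors, write_grid
from .model import TURN_PAIR, OrderParamSeries, Trajectory
from .order_parameters import compute_distance_series, compute_series
from .path_kinetics import fit_lifetime, scenario_census, segment_paths, write_segments
from .state_assignment import (
    StateLabelSeries,
    assign_states,
    find_basins,
    refine_tse,
    tse_frames,
    tse_overlap,
)
from .synthetic import GeneratorConfig, emit_coordinates, emit_series_only, simulate_states


@dataclass
class PipelineConfig:
    """Analysis parameters (defaults follow the study conditions) and I/O."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    mode: str = "coordinates"  # "coordinates" (toy geometry) or "series" (fast path)
    n_bins: int = 40
    temperature: float = 300.0  # K
    contact_cutoff: float = 0.55  # nm
    basin_cut: float = 12.0  # kJ/mol
    m_subsets: int = 3
    prior_window_ps: float = 1000.0
    bin_width_nm: float = 0.02
    turn_native_max: float = 0.8  # nm; false-fold turn threshold
    middle_formed_max: float = 0.6  # nm; formed middle-contact threshold
    with_rmsd: bool = False
    out_dir: str | Path | None = None

    def __post_init__(self):
        if self.mode not in ("coordinates", "series"):
            raise ConfigurationError(f"unknown pipeline mode {self.mode!r}")
        if self.with_rmsd and self.mode != "coordinates":
            raise ConfigurationError("the RMSD cross-check needs coordinate trajectories")


def _groups(traj_ids: list[str], m: int) -> list[list[str]]:
    if m < 2 or m > len(traj_ids):
        raise ConfigurationError(f"need 2 <= M <= n_traj subsets, got M={m}")
    groups: list[list[str]] = [[] for _ in range(m)]
    for k, tid in enumerate(traj_ids):
        groups[k % m].append(tid)
    return groups


def _pooled_class_values(
    trajs: list[Trajectory],
    segments_by_traj: dict[str, list],
    observable: tuple[tuple[int, int], str],
) -> dict[str, np.ndarray]:
    """Observable values of TS frames pooled per path class across trajectories."""
    pair, mode = observable
    pooled: dict[str, list] = {}
    for traj in trajs:
        segs = segments_by_traj.get(traj.traj_id, [])
        if not segs:
            continue
        values = compute_distance_series(traj, pair, mode).values
        for cls, idx in ts_frames_by_class(segs).items():
            if idx:
                pooled.setdefault(cls, []).append(values[np.asarray(idx)])
    return {cls: np.concatenate(chunks) for cls, chunks in pooled.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    out = Path(config.out_dir) if config.out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    gen = config.generator
    truth = simulate_states(gen)
    trajs: list[Trajectory] | None = None
    if config.mode == "coordinates":
        trajs, ref = emit_coordinates(truth, gen)
        series = [
            compute_series(t, ref, contact_cutoff=config.contact_cutoff,
                           with_rmsd=config.with_rmsd)
            for t in trajs
        ]
    else:
        series = emit_series_only(truth, gen)

    if out is not None:
        for s in series:
            trajectory_io.write_series(s, out / f"series_{s.traj_id}.csv")

    # free-energy landscape over (Q, R) with subset errors
    grid = build_landscape(
        series, x="Q", y="R", n_bins=config.n_bins, temperature=config.temperature
    )
    groups = _groups([s.traj_id for s in series], config.m_subsets)
    subset_errors(series, groups, grid)
    if out is not None:
        write_grid(grid, out / "landscape.csv", out / "landscape_meta.json")

    # state decomposition and (coordinate mode) TSE refinement
    defn = find_basins(grid, basin_cut=config.basin_cut)
    labels: dict[str, StateLabelSeries] = {}
    refinements = {}
    turn_series = {}
    for k, s in enumerate(series):
        lab = assign_states(grid, defn, s)
        if config.mode == "coordinates":
            turn = compute_distance_series(trajs[k], TURN_PAIR, "calpha")
            turn_series[s.traj_id] = turn
            lab, rep = refine_tse(lab, turn, turn_native_max=config.turn_native_max)
            refinements[s.traj_id] = rep
        labels[s.traj_id] = lab
        if out is not None:
            trajectory_io.write_labels(lab.times, lab.labels, out / f"labels_{s.traj_id}.csv")

    # TS excursions and lifetime kinetics
    segments_by_traj = {
        tid: segment_paths(lab, gen.frame_interval) for tid, lab in labels.items()
    }
    segments = [seg for segs in segments_by_traj.values() for seg in segs]
    fit = fit_lifetime(segments, gen.frame_interval, grouping=groups)
    census = scenario_census(segments)
    if out is not None:
        write_segments(segments, out / "segments.csv")
        fit.to_json(out / "lifetime_fit.json")

    report = {
        "seed": gen.seed,
        "mode": config.mode,
        "n_traj": gen.n_traj,
        "n_frames_total": int(sum(len(s) for s in series)),
        "landscape": {
            "ref_cell": list(grid.ref_cell),
            "f_minimum": list(np.round(grid.cell_center(grid.ref_cell), 4)),
            "u_minimum": list(np.round(grid.cell_center(defn.u_seed), 4)),
            "u_minimum_deltaA_kJmol": float(grid.delta_a[defn.u_seed]),
            "occupied_cells": int(grid.occupied().sum()),
            "median_sigma_kJmol": float(np.nanmedian(grid.sigma)),
        },
        "tse_size_frames": int(
            sum(len(tse_frames(lab, refinements.get(tid))) for tid, lab in labels.items())
        ),
        "kinetics": {
            "tau_ps": fit.tau,
            "tau_error_ps": fit.tau_error,
            "fit_correlation": fit.correlation,
            "n_excursions": fit.n_events,
            "p_fold": fit.p_fold,
            "p_unfold": fit.p_unfold,
        },
        "scenario_census": census,
    }
    if refinements:
        report["tse_refinement"] = {
            "false_folds": sum(len(r.false_folds) for r in refinements.values()),
            "excluded_ts_frames": sum(
                len(r.excluded_ts_indices) for r in refinements.values()
            ),
        }

    # structural characterization needs real geometry
    if config.mode == "coordinates":
        report["structure"] = _structure_report(config, trajs, labels, refinements,
                                                segments_by_traj, out)
        if config.with_rmsd:
            report["rmsd_crosscheck"] = _rmsd_crosscheck(config, series, labels)

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
        (out / "report.md").write_text(_markdown_report(report))
    return report


def _ensemble_peaks(
    trajs: list[Trajectory],
    selector_by_traj: dict[str, list[int]],
    bin_width: float,
    label: str,
) -> dict:
    peaks = {}
    for name, (pair, mode) in STANDARD_OBSERVABLES.items():
        values = []
        for traj in trajs:
            idx = selector_by_traj.get(traj.traj_id, [])
            if idx:
                v = compute_distance_series(traj, pair, mode).values
                values.append(v[np.asarray(idx)])
        if values:
            hist = histogram_values(np.concatenate(values), bin_width, label, name)
            peaks[name] = round(hist.peak, 4)
    return peaks


def _structure_report(config, trajs, labels, refinements, segments_by_traj, out):
    bw = config.bin_width_nm
    tse_sel = {tid: tse_frames(lab, refinements.get(tid)) for tid, lab in labels.items()}
    f_sel = {
        tid: [k for k, l in enumerate(lab.labels) if l == "F"] for tid, lab in labels.items()
    }
    prior_sel = {}
    for tid, lab in labels.items():
        segs = [s for s in segments_by_traj[tid] if s.path_class == "UTSF"]
        if segs:
            prior_sel[tid] = prior_to_ts_ensemble(lab, segs, window=config.prior_window_ps)
    structure = {
        "tse_peaks_nm": _ensemble_peaks(trajs, tse_sel, bw, "TSE"),
        "f_peaks_nm": _ensemble_peaks(trajs, f_sel, bw, "F"),
        "prior_to_ts_peaks_nm": _ensemble_peaks(trajs, prior_sel, bw, "prior-to-TS"),
    }
    # F-TS-F nucleus subpopulation: fraction of TS frames with the middle
    # backbone contact already formed
    middle_by_class = _pooled_class_values(
        trajs, segments_by_traj, STANDARD_OBSERVABLES["middle"]
    )
    if "FTSF" in middle_by_class:
        middle = middle_by_class["FTSF"]
        structure["ftsf_nucleus_fraction"] = float(
            np.mean(middle <= config.middle_formed_max)
        )
        structure["n_ftsf_ts_frames"] = int(len(middle))
    per_class_peaks = {}
    for name, obs in STANDARD_OBSERVABLES.items():
        for cls, values in _pooled_class_values(trajs, segments_by_traj, obs).items():
            hist = histogram_values(values, bw, cls, name)
            per_class_peaks.setdefault(cls, {})[name] = round(hist.peak, 4)
            if out is not None:
                hist.to_frame().to_csv(out / f"hist_{cls}_{name}.csv", index=False)
    structure["per_class_peaks_nm"] = per_class_peaks
    return structure


def _rmsd_crosscheck(config, series, labels_qr):
    """TSE agreement between the R-Q landscape and an RMSD-Q landscape."""
    grid2 = build_landscape(
        series, x="Q", y="RMSD", n_bins=config.n_bins, temperature=config.temperature
    )
    defn2 = find_basins(grid2, basin_cut=config.basin_cut)
    labels2 = [assign_states(grid2, defn2, s) for s in series]
    ref_labels = list(labels_qr.values())
    return {
        "overlap_vs_reference": tse_overlap(ref_labels, labels2, method="reference"),
        "overlap_jaccard": tse_overlap(ref_labels, labels2, method="jaccard"),
    }


def _markdown_report(report: dict) -> str:
    k = report["kinetics"]
    lines = [
        "# Hairpin TSE analysis report",
        "",
        f"Seed {report['seed']}, mode `{report['mode']}`, "
        f"{report['n_traj']} trajectories, {report['n_frames_total']} frames.",
        "",
        "## Free-energy landscape (Q, R)",
        f"- folded minimum at (Q, R) = {tuple(report['landscape']['f_minimum'])}",
        f"- unfolded minimum at (Q, R) = {tuple(report['landscape']['u_minimum'])}, "
        f"dA = {report['landscape']['u_minimum_deltaA_kJmol']:.2f} kJ/mol",
        f"- median subset error {report['landscape']['median_sigma_kJmol']:.2f} kJ/mol "
        f"over {report['landscape']['occupied_cells']} occupied cells",
        "",
        "## TS kinetics",
        f"- lifetime tau = {k['tau_ps']:.2f} +/- {k['tau_error_ps']:.2f} ps "
        f"(fit correlation {k['fit_correlation']:.4f}, {k['n_excursions']} excursions)",
        f"- commitment: {100 * k['p_fold']:.1f}% fold / {100 * k['p_unfold']:.1f}% unfold",
        "",
        "## Path scenarios",
    ]
    for cls in ("UTSF", "FTSU", "UTSU", "FTSF"):
        c = report["scenario_census"][cls]
        lines.append(
            f"- {cls}: {c['count']} excursions, mean residence "
            f"{c['mean_residence_ps']:.1f} ps"
        )
    if "structure" in report:
        s = report["structure"]
        lines += ["", "## TSE structure (modal distances, nm)"]
        lines.append(f"- TSE: {s['tse_peaks_nm']}")
        lines.append(f"- F:   {s['f_peaks_nm']}")
        if "prior_to_ts_peaks_nm" in s and s["prior_to_ts_peaks_nm"]:
            lines.append(f"- prior-to-TS: {s['prior_to_ts_peaks_nm']}")
        if "ftsf_nucleus_fraction" in s:
            lines.append(
                f"- F-TS-F frames with middle contacts formed: "
                f"{100 * s['ftsf_nucleus_fraction']:.1f}%"
            )
    if "rmsd_crosscheck" in report:
        r = report["rmsd_crosscheck"]
        lines += [
            "",
            "## RMSD-Q cross-check",
            f"- TSE overlap vs reference: {100 * r['overlap_vs_reference']:.1f}% "
            f"(Jaccard {100 * r['overlap_jaccard']:.1f}%)",
        ]
    return "\n".join(lines) + "\n"
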