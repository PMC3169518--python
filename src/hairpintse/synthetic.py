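"""Synthetic three-state (U/TS/F) hairpin trajectories with known ground truth.

The generator emulates the statistical and geometric structure the analysis
pipeline assumes, so that every downstream estimator can be validated
against a known answer:

* **Kinetics** - a discrete-time Markov chain at the frame resolution.
  Residence in each state is geometric with per-frame survival probability
  exp(-dt/tau_state), the exact discretization of an exponential residence
  with time constant tau: the residence-time histogram of the emitted chain
  decays exactly as exp(-t/tau), which is what the monoexponential lifetime
  fit estimates.  A TS exit commits to F with probability p_fold, else U;
  basin exits always enter the TS.

* **Geometry** - a 15-residue toy chain (one C-alpha per residue plus one
  pseudo-sidechain atom per non-glycine residue) built from solved template
  conformations: native hairpin, transition-state loop (ends and turn in
  contact, middle strands apart, W11 key-locked between P7 and G9), an
  unfolded coil band, a pre-TS approach conformation (turn formed and
  W11 locked while the ends are still apart), and a folding-nucleus variant
  (middle contacts formed, W11 shifted onto P7) used by a configured
  fraction of F-TS-F excursions.  Along each forward committed crossing the
  last TS frames morph toward a middle-closed/W11-released geometry, so the
  mechanism - turn first, ends at the TS, middle closure plus key-lock
  release on descent - is encoded in the coordinates.

* **Fast path** - ``emit_series_only`` skips geometry and samples (Q, R)
  from state-conditional Gaussians centred on the basin and barrier
  coordinates, for landscape/kinetics validation at large frame counts.

All random draws are clipped at three standard deviations: conformational
jitter within a state is compact, so single-frame order-parameter outliers
do not masquerade as barrier visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm

from .errors import ConstructionError, ResolutionError
from .model import (
    ONE_TO_THREE,
    PEPTIDE1_SEQUENCE,
    AtomRecord,
    Frame,
    OrderParamSeries,
    ReferenceStructure,
    Trajectory,
)
from .trajectory_io import build_reference

STATE_U, STATE_TS, STATE_F = 0, 1, 2
CODE_TO_LABEL = {STATE_U: "U", STATE_TS: "TS", STATE_F: "F"}

N_RES = 15
_BOND = 0.38  # consecutive C-alpha separation, nm


@dataclass
class KineticsConfig:
    """Mean residence times (ps) and TS branching."""

    tau_u: float = 2000.0
    tau_ts: float = 10.2
    tau_f: float = 2000.0
    p_fold: float = 0.527

    def __post_init__(self):
        if min(self.tau_u, self.tau_ts, self.tau_f) <= 0:
            raise ValueError("residence times must be positive")
        if not 0.0 <= self.p_fold <= 1.0:
            raise ValueError("p_fold must be in [0, 1]")


@dataclass
class GeometryConfig:
    """Target distances (nm) of the template conformations and the noise model."""

    # folded-state characteristic distances
    f_end: float = 0.42
    f_turn: float = 0.55
    f_middle: float = 0.54
    # transition-state characteristic distances
    ts_end: float = 0.42
    ts_turn: float = 0.60
    ts_middle: float = 0.72
    # W11 key-lock targets (minimum sidechain distances)
    w11_p7_ts: float = 0.55
    w11_g9_ts: float = 0.55
    w11_p7_nucleus: float = 0.30
    w11_g9_nucleus: float = 0.65
    sidechain_offset: float = 0.25
    #: pseudo-sidechains lean toward the cross-strand partner residue, so a
    #: formed backbone pair packs its sidechains inside the contact cutoff
    sidechain_inward: float = 0.045
    # per-state coordinate noise (nm): the folded hairpin is rigid, the coil
    # mobile; amplitudes keep within-conformation order-parameter jitter
    # inside one landscape grid cell (coil heterogeneity comes from the
    # unfolded band instead)
    noise_sigma: dict = field(
        default_factory=lambda: {STATE_U: 0.015, STATE_TS: 0.015, STATE_F: 0.005}
    )
    ramp_frames: int = 5
    approach_frames: int = 100  # 1 ns at the default 10 ps interval
    #: fraction of unfolded frames drawn from the coil -> turn-formed (pre-TS)
    #: segment instead of the open-coil band: the coil transiently samples
    #: turn-formed conformations, making the unfolded basin contiguous from
    #: the extended band to the committed approach geometry
    u_turn_mix: float = 0.25


@dataclass
class SeriesConfig:
    """State-conditional (Q, R) Gaussians for the geometry-free fast path.

    Each state's cloud is a truncated Gaussian with hard support
    ``center +- max_z * sigma`` per axis (deviations beyond the bound are
    reflected back): conformational basins have bounded extent, so a basin
    frame can never masquerade as a barrier-top outlier.

    The default widths are grid-aligned: on the 40x40 landscape the Q axis
    is fixed to [0, 1] and the R axis spans the pooled data, whose extremes
    are the U support floor and the F support ceiling.  Choosing the basin
    half-widths as whole/half multiples of the implied bin width makes each
    basin tile an integer block of grid cells, with no partially covered
    boundary cell, which keeps the flood-filled basins exactly congruent
    with the emitted clouds.  U spans 4x4 cells, F 3x2 (the folded hairpin
    is the narrower, deeper minimum); the TS cloud needs no alignment.
    """

    centers: dict = field(
        default_factory=lambda: {
            STATE_U: (0.10, 2.10),
            STATE_TS: (0.45, 3.50),
            STATE_F: (0.85, 4.95),
        }
    )
    #: hard truncation bound of the standardized deviation, in sigma units
    max_z: float = 2.2
    n_bins: int = 40
    sigma_q: dict | None = None
    sigma_r: dict | None = None

    def __post_init__(self):
        q_bin = 1.0 / self.n_bins
        r_u, r_f = self.centers[STATE_U][1], self.centers[STATE_F][1]
        # R-axis bin width implied by the supports: U holds 2 bins per side,
        # F 1.5, the distance between the centres fills the remaining bins
        r_bin = (r_f - r_u) / (self.n_bins - 2 - 1.5)
        if self.sigma_q is None:
            self.sigma_q = {
                STATE_U: 2.0 * q_bin / self.max_z,
                STATE_TS: 0.06,
                STATE_F: 1.0 * q_bin / self.max_z,
            }
        if self.sigma_r is None:
            self.sigma_r = {
                STATE_U: 2.0 * r_bin / self.max_z,
                STATE_TS: 0.15,
                STATE_F: 1.5 * r_bin / self.max_z,
            }


@dataclass
class GeneratorConfig:
    n_traj: int = 6
    duration_us: float = 1.0
    frame_interval: float = 10.0
    seed: int = 0
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    series: SeriesConfig = field(default_factory=SeriesConfig)
    nucleus_fraction: float = 0.65

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_us * 1e6 / self.frame_interval))


@dataclass
class Excursion:
    """One TS visit with known flanking states (frame indices inclusive)."""

    origin: str
    destination: str
    start: int
    end: int
    nucleus: bool = False

    @property
    def path_class(self) -> str:
        return f"{self.origin}TS{self.destination}"


@dataclass
class TrajectoryTruth:
    traj_id: str
    states: np.ndarray  # int8 codes per frame
    excursions: list[Excursion]

    def labels(self) -> list[str]:
        return [CODE_TO_LABEL[int(s)] for s in self.states]


@dataclass
class GroundTruth:
    trajectories: list[TrajectoryTruth]
    stationary: dict  # analytic per-state time fractions of the chain

    def state_counts(self) -> dict:
        counts = {"U": 0, "TS": 0, "F": 0}
        for t in self.trajectories:
            for code, label in CODE_TO_LABEL.items():
                counts[label] += int(np.sum(t.states == code))
        return counts


def escape_probabilities(kin: KineticsConfig, frame_interval: float) -> dict:
    """Per-frame escape probability 1 - exp(-dt/tau) for each state."""
    return {
        STATE_U: 1.0 - np.exp(-frame_interval / kin.tau_u),
        STATE_TS: 1.0 - np.exp(-frame_interval / kin.tau_ts),
        STATE_F: 1.0 - np.exp(-frame_interval / kin.tau_f),
    }


def stationary_fractions(kin: KineticsConfig, frame_interval: float) -> dict:
    """Analytic time fraction per state of the embedded renewal cycle."""
    esc = escape_probabilities(kin, frame_interval)
    mean_frames = {s: 1.0 / p for s, p in esc.items()}
    visit_rate = {STATE_TS: 1.0, STATE_U: 1.0 - kin.p_fold, STATE_F: kin.p_fold}
    weight = {s: visit_rate[s] * mean_frames[s] for s in esc}
    total = sum(weight.values())
    return {CODE_TO_LABEL[s]: w / total for s, w in weight.items()}


def simulate_states(config: GeneratorConfig) -> GroundTruth:
    """Run the hidden three-state chain for every trajectory.

    Each trajectory starts unfolded (the simulations the pipeline targets
    begin from unfolded structures).  F-TS-F excursions are flagged as
    folding-nucleus geometry with probability ``nucleus_fraction``.
    """
    kin = config.kinetics
    dt = config.frame_interval
    if dt / kin.tau_u > 1.0 or dt / kin.tau_f > 1.0:
        raise ResolutionError(
            "frame interval exceeds a basin residence time; basins unresolvable"
        )
    esc = escape_probabilities(kin, dt)
    n = config.n_frames
    trajectories = []
    for t in range(config.n_traj):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0, t)))
        states = np.empty(n, dtype=np.int8)
        runs: list[tuple[int, int, int]] = []  # (state, start, end)
        pos = 0
        state = STATE_U
        while pos < n:
            k = int(rng.geometric(esc[state]))
            end = min(pos + k, n) - 1
            states[pos : end + 1] = state
            runs.append((state, pos, end))
            pos = end + 1
            if state == STATE_TS:
                state = STATE_F if rng.random() < kin.p_fold else STATE_U
            else:
                state = STATE_TS
        excursions = []
        for r, (s, start, end) in enumerate(runs):
            if s != STATE_TS or r == 0 or r == len(runs) - 1:
                continue
            excursions.append(
                Excursion(
                    origin=CODE_TO_LABEL[runs[r - 1][0]],
                    destination=CODE_TO_LABEL[runs[r + 1][0]],
                    start=start,
                    end=end,
                )
            )
        for exc in excursions:
            if exc.path_class == "FTSF":
                exc.nucleus = bool(rng.random() < config.nucleus_fraction)
        trajectories.append(TrajectoryTruth(f"traj{t + 1}", states, excursions))
    return GroundTruth(trajectories, stationary_fractions(kin, dt))


def _clipped_normal(rng: np.random.Generator, shape, clip: float = 3.0) -> np.ndarray:
    return np.clip(rng.standard_normal(shape), -clip, clip)


def emit_series_only(truth: GroundTruth, config: GeneratorConfig) -> list[OrderParamSeries]:
    """Sample (Q, R) directly from the state-conditional Gaussians.

    Per-axis deviations beyond ``max_z`` sigma are reflected back into the
    support, so each cloud has hard bounds with the configured Gaussian
    shape in its interior.
    """
    sc = config.series
    mu_q = np.array([sc.centers[s][0] for s in (STATE_U, STATE_TS, STATE_F)])
    mu_r = np.array([sc.centers[s][1] for s in (STATE_U, STATE_TS, STATE_F)])
    sd_q = np.array([sc.sigma_q[s] for s in (STATE_U, STATE_TS, STATE_F)])
    sd_r = np.array([sc.sigma_r[s] for s in (STATE_U, STATE_TS, STATE_F)])
    bound = sc.max_z
    out = []
    for t, tt in enumerate(truth.trajectories):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1, t)))
        s = tt.states.astype(int)
        z = rng.standard_normal((len(s), 2))
        z = np.where(np.abs(z) > bound, np.sign(z) * (2.0 * bound - np.abs(z)), z)
        z = np.clip(z, -bound, bound)
        q = np.clip(mu_q[s] + sd_q[s] * z[:, 0], 0.0, 1.0)
        r = np.maximum(mu_r[s] + sd_r[s] * z[:, 1], 0.05)
        data = pd.DataFrame(
            {"time_ps": np.arange(len(s)) * config.frame_interval, "R": r, "Q": q}
        )
        out.append(OrderParamSeries(tt.traj_id, data))
    return out


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------

# fixed cross-strand scaffold distances (nm) for pairs not exposed in config;
# keys are 1-based residue pairs
_NATIVE_SCAFFOLD = {(6, 10): 0.50, (5, 11): 0.52, (3, 13): 0.50, (2, 14): 0.46, (7, 10): 0.50}
_TS_SCAFFOLD = {(6, 10): 0.70, (5, 11): 0.80, (3, 13): 0.75, (2, 14): 0.60}
_U_SCAFFOLD = {
    (1, 15): 1.50, (6, 9): 1.00, (4, 12): 1.29,
    (6, 10): 1.19, (5, 11): 1.24, (3, 13): 1.19, (2, 14): 1.10,
}
_U2_SCALE = 1.15  # second coil endpoint: the unfolded band spans U..U2
_PRETS_SCAFFOLD = {
    (1, 15): 1.40, (6, 9): 0.65, (4, 12): 1.20, (7, 10): 0.80,
    (6, 10): 0.95, (5, 11): 1.15, (3, 13): 1.15, (2, 14): 1.08,
}
_NUCLEUS_SCAFFOLD = {
    (1, 15): 0.50, (6, 9): 0.60, (4, 12): 0.54,
    (6, 10): 0.62, (5, 11): 0.68, (3, 13): 0.66, (2, 14): 0.60,
}


def _hairpin_guess(gap: float) -> np.ndarray:
    pts = np.zeros((N_RES, 3))
    for i in range(7):  # residues 1-7, first strand
        pts[i] = ((6 - i) * 0.36, 0.0, 0.03 * np.sin(2.1 * i))
    pts[7] = (-0.25, gap / 2.0, 0.05)  # turn apex D8
    for i in range(8, 15):  # residues 9-15, second strand
        pts[i] = ((i - 8) * 0.36, gap, 0.03 * np.sin(2.1 * i + 1.0))
    return pts


def _coil_guess(span_angle: float = 1.5 * np.pi) -> np.ndarray:
    radius = (N_RES - 1) * _BOND / span_angle
    theta = span_angle * np.arange(N_RES) / (N_RES - 1)
    return np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), 0.03 * np.sin(3.0 * np.arange(N_RES))],
        axis=1,
    )


def _solve_chain(pair_targets: dict, guess: np.ndarray) -> np.ndarray:
    """C-alpha positions satisfying bond lengths and the target distances.

    Solved by least squares with a weak pull toward the starting guess to
    fix the rigid-body gauge; raises ConstructionError (naming the worst
    constraint) if the targets are mutually infeasible in 3D.
    """
    constraints = [((i, i + 1), _BOND) for i in range(1, N_RES)]
    constraints += list(pair_targets.items())

    def residuals(x: np.ndarray) -> np.ndarray:
        pts = x.reshape(N_RES, 3)
        res = [np.linalg.norm(pts[i - 1] - pts[j - 1]) - d for (i, j), d in constraints]
        return np.concatenate([np.array(res), 1e-3 * (x - guess.ravel())])

    sol = least_squares(residuals, guess.ravel(), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    pts = sol.x.reshape(N_RES, 3)
    worst_pair, worst_err = None, 0.0
    for (i, j), d in constraints:
        err = abs(np.linalg.norm(pts[i - 1] - pts[j - 1]) - d)
        if err > worst_err:
            worst_pair, worst_err = (i, j), err
    if worst_err > 2e-3:
        raise ConstructionError(
            f"template targets infeasible: pair {worst_pair} misses its "
            f"distance by {worst_err:.4f} nm"
        )
    return pts


def _place_w11(ca: np.ndarray, sc7: np.ndarray, d_p7: float, d_g9: float) -> np.ndarray:
    """Position the W11 pseudo-sidechain at given distances from the P7
    sidechain and the G9 C-alpha (its sidechain proxy), tethered near CA11."""
    ca9, ca11 = ca[8], ca[10]

    def residuals(x):
        return np.array(
            [
                np.linalg.norm(x - sc7) - d_p7,
                np.linalg.norm(x - ca9) - d_g9,
                # weak tether: picks the solution near CA11 on the constraint circle
                0.005 * (np.linalg.norm(x - ca11) - 0.35),
            ]
        )

    start = 0.5 * (sc7 + ca9) + np.array([0.02, 0.03, 0.15])
    sol = least_squares(residuals, start, xtol=1e-14, ftol=1e-14)
    x = sol.x
    errs = {
        "W11-P7": abs(np.linalg.norm(x - sc7) - d_p7),
        "W11-G9": abs(np.linalg.norm(x - ca9) - d_g9),
    }
    worst = max(errs, key=errs.get)
    if errs[worst] > 2e-3:
        raise ConstructionError(f"W11 placement infeasible: {worst} off by {errs[worst]:.4f} nm")
    return x


#: atom layout: (residue_index, residue_name, atom_name), glycine has no CB
ATOM_LAYOUT: list[tuple[int, str, str]] = []
for _i, _aa in enumerate(PEPTIDE1_SEQUENCE, start=1):
    _res = ONE_TO_THREE[_aa]
    ATOM_LAYOUT.append((_i, _res, "CA"))
    if _res != "GLY":
        ATOM_LAYOUT.append((_i, _res, "CB"))

_W11_SC_ROW = ATOM_LAYOUT.index((11, "TRP", "CB"))


def _assemble(ca: np.ndarray, geom: GeometryConfig, w11: np.ndarray | None = None) -> np.ndarray:
    """Stack the atom coordinate matrix: CA plus pseudo-sidechain per residue.

    The pseudo-sidechain sits at a fixed offset normal to the mean hairpin
    plane, so cross-strand sidechain separations track the C-alpha
    separations; W11 may be overridden (key-lock placements).
    """
    rows = []
    for (res_idx, res_name, atom_name) in ATOM_LAYOUT:
        if atom_name == "CA":
            rows.append(ca[res_idx - 1])
            continue
        # beta-strand-like alternation: sidechains point to alternating faces,
        # so in-register cross-strand partners (same parity) can pack while
        # diagonal pairs sit a full offset-gap apart
        side = 1.0 if res_idx % 2 == 0 else -1.0
        pos = ca[res_idx - 1] + np.array([0.0, 0.0, side * geom.sidechain_offset])
        partner = N_RES + 1 - res_idx  # cross-strand in-register partner
        if partner != res_idx:
            direction = ca[partner - 1] - ca[res_idx - 1]
            pos = pos + geom.sidechain_inward * direction / np.linalg.norm(direction)
        rows.append(pos)
    atoms = np.array(rows)
    if w11 is not None:
        atoms[_W11_SC_ROW] = w11
    return atoms


_TEMPLATE_CACHE: dict = {}


def build_templates(geom: GeometryConfig) -> dict:
    """Solve all template conformations; returns name -> (n_atoms, 3) array."""
    key = (
        geom.f_end, geom.f_turn, geom.f_middle, geom.ts_end, geom.ts_turn,
        geom.ts_middle, geom.w11_p7_ts, geom.w11_g9_ts, geom.w11_p7_nucleus,
        geom.w11_g9_nucleus, geom.sidechain_offset,
    )
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    native_targets = dict(_NATIVE_SCAFFOLD)
    native_targets.update({(1, 15): geom.f_end, (6, 9): geom.f_turn, (4, 12): geom.f_middle})
    ts_targets = dict(_TS_SCAFFOLD)
    ts_targets.update({(1, 15): geom.ts_end, (6, 9): geom.ts_turn, (4, 12): geom.ts_middle})
    tsx_targets = dict(ts_targets)
    tsx_targets[(4, 12)] = geom.f_middle  # exit geometry: middle closed

    ca = {
        "native": _solve_chain(native_targets, _hairpin_guess(0.50)),
        "ts": _solve_chain(ts_targets, _hairpin_guess(0.72)),
        "tsx": _solve_chain(tsx_targets, _hairpin_guess(0.62)),
        "nucleus": _solve_chain(_NUCLEUS_SCAFFOLD, _hairpin_guess(0.55)),
        "u": _solve_chain(_U_SCAFFOLD, _coil_guess()),
        "u2": _solve_chain(
            {
                # scaled-out coil endpoint, capped below the chain contour length
                (i, j): min(d * _U2_SCALE, 0.95 * _BOND * abs(j - i))
                for (i, j), d in _U_SCAFFOLD.items()
            },
            _coil_guess(1.3 * np.pi),
        ),
    }
    # the pre-TS conformation is the coil with a formed, W11-locked turn:
    # solving from the coil keeps every coordinate the constraints do not
    # touch coil-like, so the approach stays inside the unfolded basin under
    # any reasonable progress variable (R, RMSD, ...)
    ca["prets"] = _solve_chain(_PRETS_SCAFFOLD, ca["u"])
    templates = {name: _assemble(c, geom) for name, c in ca.items()}
    # key-lock W11 placements for the barrier-region conformations
    for name, (p7, g9) in {
        "ts": (geom.w11_p7_ts, geom.w11_g9_ts),
        "prets": (geom.w11_p7_ts, geom.w11_g9_ts),
        "nucleus": (geom.w11_p7_nucleus, geom.w11_g9_nucleus),
    }.items():
        sc7 = templates[name][ATOM_LAYOUT.index((7, "PRO", "CB"))]
        w11 = _place_w11(ca[name], sc7, p7, g9)
        templates[name] = _assemble(ca[name], geom, w11=w11)
    _TEMPLATE_CACHE[key] = templates
    return templates


def template_frame(name: str, config: GeneratorConfig, time: float = 0.0) -> Frame:
    """A noiseless Frame of one template conformation."""
    atoms_xyz = build_templates(config.geometry)[name]
    atoms = [
        AtomRecord(res_idx, res_name, atom_name, atoms_xyz[k].copy())
        for k, (res_idx, res_name, atom_name) in enumerate(ATOM_LAYOUT)
    ]
    return Frame(time=time, atoms=atoms)


def native_reference(config: GeneratorConfig, contact_cutoff: float = 0.55) -> ReferenceStructure:
    """ReferenceStructure derived from the noiseless native template."""
    return build_reference(template_frame("native", config), contact_cutoff=contact_cutoff)


def emit_coordinates(
    truth: GroundTruth, config: GeneratorConfig
) -> tuple[list[Trajectory], ReferenceStructure]:
    """Emit full toy-hairpin coordinate trajectories for the hidden chain.

    Encoding of the mechanism, per trajectory:

    * U residences sample the unfolded band (interpolation between the two
      coil templates, per-frame);
    * the last ``approach_frames`` U frames before every TS entry adopt the
      pre-TS conformation (turn formed, W11 locked, ends apart), entered
      through a short interpolation ramp;
    * TS residences use the transition-state template (or the nucleus
      template for flagged F-TS-F excursions); forward reactive crossings
      (U-TS-F) morph their last ``ramp_frames`` TS frames toward the
      middle-closed / W11-released exit geometry;
    * F residences use the native template.

    Per-state isotropic coordinate noise (clipped at 3 sigma) is added on top.
    """
    geom = config.geometry
    templates = build_templates(geom)
    n_atoms = len(ATOM_LAYOUT)
    sigma = geom.noise_sigma
    trajs = []
    for t, tt in enumerate(truth.trajectories):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2, t)))
        n = len(tt.states)
        coords = np.empty((n, n_atoms, 3))
        # base assignment by hidden state
        runs = _state_runs(tt.states)
        exc_by_start = {e.start: e for e in tt.excursions}
        for r, (s, start, end) in enumerate(runs):
            length = end - start + 1
            if s == STATE_U:
                svals = rng.uniform(0.0, 1.0, size=length)[:, None, None]
                toward_turn = (rng.random(length) < geom.u_turn_mix)[:, None, None]
                endpoint = np.where(
                    toward_turn, templates["prets"][None], templates["u2"][None]
                )
                coords[start : end + 1] = (
                    templates["u"][None] + svals * (endpoint - templates["u"][None])
                )
                followed_by_ts = r + 1 < len(runs) and runs[r + 1][0] == STATE_TS
                if followed_by_ts:
                    block = min(geom.approach_frames, length)
                    b0 = end - block + 1
                    coords[b0 : end + 1] = templates["prets"][None]
                    ramp = min(geom.ramp_frames, block)
                    for j in range(ramp):
                        frac = (j + 1) / (ramp + 1)
                        coords[b0 + j] = templates["u"] + frac * (
                            templates["prets"] - templates["u"]
                        )
            elif s == STATE_F:
                coords[start : end + 1] = templates["native"][None]
            else:  # TS
                exc = exc_by_start.get(start)
                base = templates["nucleus"] if (exc and exc.nucleus) else templates["ts"]
                coords[start : end + 1] = base[None]
                # committed forward crossings morph toward the exit geometry
                # (middle closure + W11 release) over their last TS frames
                if exc and exc.path_class == "UTSF":
                    morph = min(geom.ramp_frames, length - 1)
                    for j in range(morph):
                        frac = (j + 1) / (morph + 1)
                        coords[end - morph + 1 + j] = templates["ts"] + frac * (
                            templates["tsx"] - templates["ts"]
                        )
        # per-state clipped Gaussian jitter
        noise = _clipped_normal(rng, (n, n_atoms, 3))
        scale = np.array([sigma[int(s)] for s in tt.states])[:, None, None]
        coords += noise * scale

        frames = [
            Frame(
                time=k * config.frame_interval,
                atoms=[
                    AtomRecord(res_idx, res_name, atom_name, coords[k, a])
                    for a, (res_idx, res_name, atom_name) in enumerate(ATOM_LAYOUT)
                ],
            )
            for k in range(n)
        ]
        trajs.append(Trajectory(tt.traj_id, frames, config.frame_interval))
    return trajs, native_reference(config)


def _state_runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    runs = []
    start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            runs.append((int(states[start]), start, k - 1))
            start = k
    return runs


# ---------------------------------------------------------------------------
# analytic predictions used by consistency checks
# ---------------------------------------------------------------------------


def _reflected_axis_mass(lo: float, hi: float, mu: float, sigma: float, max_z: float) -> float:
    """Mass of the reflected-truncated normal on [lo, hi].

    The emission reflects deviations beyond ``max_z`` sigma back into the
    support, so an interval near a support edge also collects the mirrored
    tail mass.
    """
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    a_cl, b_cl = max(a, -max_z), min(b, max_z)
    if b_cl <= a_cl:
        return 0.0
    mass = norm.cdf(b_cl) - norm.cdf(a_cl)
    # right tail z > max_z folds to 2*max_z - z
    mass += norm.cdf(2 * max_z - a_cl) - norm.cdf(2 * max_z - b_cl)
    # left tail z < -max_z folds to -2*max_z - z
    mass += norm.cdf(-2 * max_z - a_cl) - norm.cdf(-2 * max_z - b_cl)
    return mass


def analytic_cell_probability(
    truth: GroundTruth,
    config: GeneratorConfig,
    x_edges: tuple[float, float],
    y_edges: tuple[float, float],
) -> float:
    """Expected probability of one (Q, R) grid cell under the fast path.

    Uses the *realized* per-state frame counts of the chain and the analytic
    masses of each state's (reflected-truncated Gaussian) emission inside
    the cell rectangle.
    """
    counts = truth.state_counts()
    total = sum(counts.values())
    sc = config.series
    prob = 0.0
    for code, label in CODE_TO_LABEL.items():
        mu_q, mu_r = sc.centers[code]
        mass_q = _reflected_axis_mass(x_edges[0], x_edges[1], mu_q, sc.sigma_q[code], sc.max_z)
        mass_r = _reflected_axis_mass(y_edges[0], y_edges[1], mu_r, sc.sigma_r[code], sc.max_z)
        prob += (counts[label] / total) * mass_q * mass_r
    return prob
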