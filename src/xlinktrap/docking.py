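"""Rigid-body search over LBD-dimer arrangements minimising SG accessibility.

Two ligand-binding-domain dimers are treated as rigid bodies.  One dimer is
held fixed; the other is rotated about the two in-plane axes (parallel and
perpendicular to the dimer interface) through its centroid and translated in
the membrane plane.  The objective is the Shrake-Rupley accessible area of
the engineered cysteine's SG atom in the proximal subunit of the fixed
dimer, computed over the posed assembly; trial arrangements with more than
``max_clashes`` inter-dimer atom pairs closer than ``clash_cutoff`` or with
a dimer separation exceeding the seed separation by more than
``proximity_max`` are rejected.  The search is an iterative seeded local
search with a shrinking step size, and retained arrangements are classified
loose (SG-SG < 10 A) or tight (SG-SG > 20 A with the SG packed against the
partner helix) by the distance rules used for known structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import structgeo
from .structgeo import ResidueSelector, Structure


@dataclass(frozen=True)
class Pose:
    """Relative rigid-body pose of the mobile dimer.

    ``dx, dy`` translate in the membrane plane (along the interface axis and
    the in-plane axis orthogonal to it); ``theta_parallel`` rotates about the
    in-plane axis parallel to the dimer interface, ``theta_perp`` about the
    in-plane axis perpendicular to it (the centroid-joining axis).  Rotations
    are degrees in (-180, 180], applied about the mobile dimer's centroid,
    parallel rotation first, then perpendicular, then translation.
    """

    dx: float = 0.0
    dy: float = 0.0
    theta_parallel: float = 0.0
    theta_perp: float = 0.0

    def __post_init__(self) -> None:
        for ang in (self.theta_parallel, self.theta_perp):
            if not -180.0 < ang <= 180.0:
                raise ValueError("rotations must lie in (-180, 180]")

    def inverse_sequence(self) -> "Pose":
        return Pose(-self.dx, -self.dy, -self.theta_parallel, -self.theta_perp)


@dataclass(frozen=True)
class Frame:
    """Search frame: membrane normal and in-plane interface axes."""

    normal: np.ndarray          # unit, membrane normal
    interface_axis: np.ndarray  # unit, in-plane, joins dimer centroids
    in_plane: np.ndarray        # unit, in-plane, parallel to the interface
    mobile_centroid: np.ndarray


@dataclass(frozen=True)
class DockConfig:
    initial_step_translation: float = 4.0   # A
    initial_step_rotation: float = 20.0     # deg
    trials_per_round: int = 24
    step_decay: float = 0.5
    max_clashes: int = 10
    clash_cutoff: float = 2.2               # A
    proximity_max: float = 10.0             # A over the seed COM separation
    rng_seed: int = 0
    min_step_translation: float = 0.1       # A, termination threshold
    min_step_rotation: float = 0.5          # deg
    max_rounds: int = 60
    seeds_per_round: int = 4
    sasa_points: int = 512
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        if not 0 < self.step_decay < 1:
            raise ValueError("step_decay must be in (0, 1)")
        for f in ("initial_step_translation", "initial_step_rotation",
                  "clash_cutoff", "proximity_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.trials_per_round < 0 or self.max_clashes < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class DockResult:
    pose: Pose
    objective: float   # SG accessible area, A^2
    clashes: int
    sg_sg: float       # A
    com_sep: float     # A
    label: str = "other"
    retained: bool = True

    def __post_init__(self) -> None:
        if self.objective < -1e-9:
            raise ValueError("objective must be non-negative")


class DockingError(RuntimeError):
    pass


# -- frame construction ----------------------------------------------------


def split_dimers(tetramer: Structure, dimer1: Sequence[str],
                 dimer2: Sequence[str]) -> tuple[Structure, Structure, Frame]:
    """Partition the LBD chains into a fixed and a mobile dimer and build
    the search frame.

    The interface axis is the in-plane unit vector joining the dimer
    centroids; the membrane normal is the principal axis of the full
    tetramer most orthogonal to that vector (the thin direction of the LBD
    slab, i.e. the pseudo-symmetry axis direction).
    """
    m1 = tetramer.mask(chain=list(dimer1))
    m2 = tetramer.mask(chain=list(dimer2))
    if not m1.any() or not m2.any():
        raise ValueError("dimer chain set selects no atoms")
    fixed = tetramer.subset(m1)
    mobile = tetramer.subset(m2)
    c1 = fixed.centroid()
    c2 = mobile.centroid()
    u = c2 - c1
    norm_u = np.linalg.norm(u)
    if norm_u < 1e-6:
        raise DockingError("degenerate geometry: coincident dimer centroids")
    u = u / norm_u

    xyz = tetramer.coords - tetramer.coords.mean(0)
    cov = xyz.T @ xyz / len(xyz)
    evals, evecs = np.linalg.eigh(cov)
    # candidate axes sorted by orthogonality to u, tie-broken by smallest
    # spatial extent (the slab-normal direction)
    order = np.lexsort((evals, np.abs(evecs.T @ u)))
    normal = evecs[:, order[0]]
    normal = normal - (normal @ u) * u
    normal /= np.linalg.norm(normal)
    if normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    v = np.cross(normal, u)
    return fixed, mobile, Frame(normal, u, v, mobile.centroid())


def _rotation_about(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def apply_pose(mobile: Structure, frame: Frame, pose: Pose) -> Structure:
    """Rigidly transform the mobile dimer by ``pose`` in the search frame."""
    R = (_rotation_about(frame.interface_axis, pose.theta_perp)
         @ _rotation_about(frame.in_plane, pose.theta_parallel))
    t = pose.dx * frame.interface_axis + pose.dy * frame.in_plane
    return mobile.transformed(rotation=R, translation=t,
                              center=frame.mobile_centroid)


# -- evaluation ------------------------------------------------------------


def _proximal_chain(dimer: Structure) -> str:
    roles = dimer.subunit_roles
    prox = [c for c, r in roles.items() if r == "proximal_AC"]
    if len(prox) == 1:
        return prox[0]
    raise DockingError("dimer must label exactly one proximal_AC chain")


def _assemble(fixed: Structure, mobile: Structure) -> Structure:
    def cat(a, b):
        return np.concatenate([a, b])
    roles = dict(fixed.subunit_roles)
    roles.update(mobile.subunit_roles)
    return Structure(cat(fixed.element, mobile.element),
                     cat(fixed.name, mobile.name),
                     cat(fixed.residue_number, mobile.residue_number),
                     cat(fixed.residue_name, mobile.residue_name),
                     cat(fixed.chain, mobile.chain),
                     np.vstack([fixed.coords, mobile.coords]),
                     cat(fixed.vdw_radius, mobile.vdw_radius),
                     roles, fixed.title)


def evaluate(fixed: Structure, mobile: Structure, frame: Frame, pose: Pose,
             config: DockConfig, site: int = 666,
             seed_com_sep: float | None = None,
             both_subunits: bool = False) -> DockResult:
    """Score one arrangement.

    Objective: accessible area of the proximal-subunit Cys-``site`` SG in
    the fixed dimer (optionally summed over both proximal subunits), probe
    1.4 A, over the full posed assembly.  Retention requires at most
    ``max_clashes`` inter-dimer clashes and a dimer separation within
    ``proximity_max`` of the seed separation.
    """
    posed = apply_pose(mobile, frame, pose)
    assembly = _assemble(fixed, posed)
    chain_f = _proximal_chain(fixed)
    chain_m = _proximal_chain(mobile)
    sel_f = ResidueSelector(chain_f, site)
    sel_m = ResidueSelector(chain_m, site)
    try:
        i_f = assembly.atom_index(sel_f, "SG")
        i_m = assembly.atom_index(sel_m, "SG")
    except structgeo.SiteError as err:
        raise DockingError(f"missing Cys{site} SG: {err}") from err

    targets = [i_f, i_m] if both_subunits else [i_f]
    areas = structgeo.sasa(assembly, np.array(targets),
                           probe_radius=config.probe_radius,
                           n_points=config.sasa_points)
    objective = float(areas.sum())
    clashes = structgeo.count_clashes(assembly, fixed.chains(),
                                      posed.chains(), config.clash_cutoff)
    sg_sg = float(np.linalg.norm(assembly.coords[i_f] - assembly.coords[i_m]))
    com_sep = structgeo.com_separation(assembly, fixed.chains(), posed.chains())
    retained = clashes <= config.max_clashes
    if seed_com_sep is not None:
        retained = retained and com_sep <= seed_com_sep + config.proximity_max
    return DockResult(pose, objective, clashes, sg_sg, com_sep,
                      retained=retained)


# -- search ----------------------------------------------------------------


def _perturb(pose: Pose, step_t: float, step_r: float, rng) -> Pose:
    def wrap(angle):
        a = (angle + 180.0) % 360.0 - 180.0
        return 180.0 if a == -180.0 else a
    return Pose(pose.dx + rng.uniform(-step_t, step_t),
                pose.dy + rng.uniform(-step_t, step_t),
                wrap(pose.theta_parallel + rng.uniform(-step_r, step_r)),
                wrap(pose.theta_perp + rng.uniform(-step_r, step_r)))


def search(fixed: Structure, mobile: Structure, frame: Frame,
           config: DockConfig, site: int = 666,
           both_subunits: bool = False) -> list[DockResult]:
    """Iterative seeded local search minimising SG accessibility.

    Each round perturbs every current seed ``trials_per_round`` times at the
    current step sizes; trials that lower the best seed objective and pass
    the clash/proximity constraints are retained and become seeds for the
    next round.  When a round brings no improvement the step sizes shrink by
    ``step_decay``; the search terminates once they fall below the minimum
    resolution (0.1 A / 0.5 deg) with no improvement.  Results are returned
    best (lowest accessibility) first; the run is reproducible under a fixed
    ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    seed_eval = evaluate(fixed, mobile, frame, Pose(), config, site,
                         seed_com_sep=None, both_subunits=both_subunits)
    seed_com = seed_eval.com_sep
    if seed_eval.clashes > config.max_clashes:
        raise DockingError(
            f"seed arrangement violates the clash constraint "
            f"({seed_eval.clashes} > {config.max_clashes})")
    retained: list[DockResult] = [seed_eval]
    seeds = [seed_eval]
    best = seed_eval.objective
    step_t = config.initial_step_translation
    step_r = config.initial_step_rotation

    for _ in range(config.max_rounds):
        improved = False
        new_hits: list[DockResult] = []
        for seed in seeds:
            for _ in range(config.trials_per_round):
                trial_pose = _perturb(seed.pose, step_t, step_r, rng)
                res = evaluate(fixed, mobile, frame, trial_pose, config,
                               site, seed_com_sep=seed_com,
                               both_subunits=both_subunits)
                if res.retained and res.objective < best - 1e-12:
                    new_hits.append(res)
        if new_hits:
            improved = True
            new_hits.sort(key=lambda r: r.objective)
            best = new_hits[0].objective
            retained.extend(new_hits)
            seeds = new_hits[: config.seeds_per_round]
        if not improved:
            at_floor = (step_t <= config.min_step_translation
                        and step_r <= config.min_step_rotation)
            if at_floor:
                break
            step_t = max(step_t * config.step_decay,
                         config.min_step_translation)
            step_r = max(step_r * config.step_decay, config.min_step_rotation)
    retained.sort(key=lambda r: r.objective)
    return retained


# -- classification --------------------------------------------------------


def classify(result: DockResult, assembly: Structure,
             sg_index: int, helix_k_mask: np.ndarray,
             loose_max: float = 10.0, tight_min: float = 20.0,
             tight_contact_max: float = 8.0) -> str:
    """Label an arrangement loose / tight / other.

    Loose: the two proximal SG atoms approach within ``loose_max``.
    Tight: SG-SG beyond ``tight_min`` with the subunit-A SG buried against
    the partner helix K (minimum distance below ``tight_contact_max``).
    """
    if not helix_k_mask.any():
        raise ValueError("helix K selection resolves to no atoms")
    if result.sg_sg < loose_max:
        return "loose"
    if result.sg_sg > tight_min:
        d = np.linalg.norm(assembly.coords[helix_k_mask]
                           - assembly.coords[sg_index], axis=1)
        if d.min() < tight_contact_max:
            return "tight"
    return "other"


def results_frame(results: Sequence[DockResult]):
    import pandas as pd
    return pd.DataFrame([{
        "dx": r.pose.dx, "dy": r.pose.dy,
        "theta_parallel": r.pose.theta_parallel,
        "theta_perp": r.pose.theta_perp,
        "objective_A2": r.objective, "clashes": r.clashes,
        "sg_sg_A": r.sg_sg, "com_sep_A": r.com_sep, "label": r.label,
    } for r in results])
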