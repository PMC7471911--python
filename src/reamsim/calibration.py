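"""Particle-swarm calibration of the sphere density field.

The packing starts from a uniform density distribution; calibration reshapes
it so that the simulated force along a reaming trajectory matches the target
force given by the spline material model.  Because material removal is purely
geometric (densities modulate force, not cutting), the contact geometry along
a fixed trajectory can be replayed once and cached: the simulated force at
step t is then

    F_sim(t) = s(d_t / depth_scale) * (sum_k A_tk * rho_k) / (sum_k A_tk * rho_ref)

i.e. linear in the densities, which makes each swarm evaluation a handful of
matrix products.  Densities are parameterized per radial shell beneath the
cup surface (default 16 shells) to keep the search space desk-scale; a
per-sphere mode is available for small packings.

The optimizer is a standard global-best particle swarm: inertial velocity
update with cognitive and social pulls, positions clamped to the density
bounds, best-so-far objective recorded per iteration (hence non-increasing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .haptics import ReamerTool, query_contacts, remove_material
from .packing import SpherePacking
from .records import PSOConfig
from .spline import SplineMaterialModel, evaluate


@dataclass
class ConvergenceReport:
    """Best-so-far objective per PSO iteration plus the final solution."""

    best_objective: float  # mean absolute force error [N]
    best_objective_history: np.ndarray  # (iterations,), non-increasing
    best_parameters: np.ndarray  # shell (or per-sphere) densities
    mean_target_force: float

    @property
    def relative_error(self) -> float:
        """Final objective as a fraction of the mean target force."""
        return self.best_objective / self.mean_target_force


@dataclass
class TrajectoryContacts:
    """Cached contact geometry of one reaming trajectory.

    ``shell_areas[t, s]`` is the summed contact cap area of shell ``s`` at
    trajectory step ``t``; ``depths`` are the advance depths [mm].
    """

    depths: np.ndarray
    shell_areas: np.ndarray
    total_areas: np.ndarray
    shell_of_sphere: np.ndarray
    shell_edges: np.ndarray


def assign_shells(packing: SpherePacking, n_shells: int,
                  origin: Optional[np.ndarray] = None) -> tuple:
    """Group spheres into radial shells around ``origin`` (default: centroid).

    For the acetabular cup the centroid sits near the center of curvature, so
    shells stack beneath the articular surface — the direction in which tissue
    properties vary as the reamer digs from cartilage into subchondral bone.
    Returns ``(shell_index_per_sphere, shell_edges)``.
    """
    if len(packing) == 0:
        raise ValidationError("cannot shell an empty packing")
    if origin is None:
        origin = packing.centers.mean(axis=0)
    radial = np.linalg.norm(packing.centers - np.asarray(origin, float), axis=1)
    edges = np.linspace(radial.min(), radial.max() + 1e-9, n_shells + 1)
    shell = np.clip(np.searchsorted(edges, radial, side="right") - 1, 0, n_shells - 1)
    return shell, edges


def replay_trajectory(packing: SpherePacking, tool: ReamerTool,
                      depths: Sequence[float], n_shells: int,
                      with_removal: bool = True,
                      origin: Optional[np.ndarray] = None,
                      min_keep_radius: float = 0.05) -> TrajectoryContacts:
    """Replay the (density-independent) contact geometry of a trajectory.

    At each advance depth the tool's contact set is queried and its cap areas
    accumulated per radial shell; with ``with_removal`` the cut material is
    then removed before the next step, as in the virtual experiment.  Works on
    a copy — the input packing is untouched.
    """
    depths = np.asarray(depths, dtype=float)
    shell, edges = assign_shells(packing, n_shells, origin=origin)

    work = packing.copy()
    work_shell = shell.copy()
    shell_areas = np.zeros((len(depths), n_shells))
    total_areas = np.zeros(len(depths))
    for t, depth in enumerate(depths):
        pose = ReamerTool(tool.radius, tool.position + depth * tool.axis,
                          tool.axis, advance=depth)
        contact = query_contacts(work, pose)
        if not contact.is_empty:
            np.add.at(shell_areas[t], work_shell[contact.indices], contact.areas)
            total_areas[t] = contact.areas.sum()
        if with_removal:
            before = work.centers
            work = remove_material(work, pose, min_keep_radius=min_keep_radius)
            # re-derive shell membership: children inherit by position
            radial = np.linalg.norm(work.centers
                                    - (origin if origin is not None
                                       else packing.centers.mean(axis=0)), axis=1)
            work_shell = np.clip(np.searchsorted(edges, radial, side="right") - 1,
                                 0, n_shells - 1)
    return TrajectoryContacts(depths=depths, shell_areas=shell_areas,
                              total_areas=total_areas, shell_of_sphere=shell,
                              shell_edges=edges)


#: velocity clamp, as a fraction of the (log-space) search range
VELOCITY_CLAMP = 0.2


def particle_swarm(objective: Callable[[np.ndarray], float], bounds: tuple,
                   dimension: int, config: PSOConfig,
                   rng: np.random.Generator,
                   start: Optional[np.ndarray] = None) -> ConvergenceReport:
    """Global-best PSO over a box-bounded, multiplicative parameter vector.

    Densities are multiplicative quantities with bounds spanning orders of
    magnitude, so the swarm flies in log-space (which also evens out the
    wildly different sensitivities of deep and shallow shells).  One particle
    starts at ``start`` (the uniform reference density) — the optimization
    begins from the uniform distribution and can only improve on it.
    Velocities are clamped to a fraction of the search range.
    """
    lo, hi = bounds
    llo, lhi = np.log10(lo), np.log10(hi)
    x = rng.uniform(llo, lhi, (config.particles, dimension))
    if start is not None:
        x[0] = np.clip(np.log10(np.asarray(start, float)), llo, lhi)
    v = np.zeros_like(x)
    vmax = VELOCITY_CLAMP * (lhi - llo)
    pbest = x.copy()
    pbest_val = np.array([objective(10.0 ** p) for p in x])
    g = int(np.argmin(pbest_val))
    gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
    history = np.empty(config.iterations)
    for it in range(config.iterations):
        r1 = rng.random(x.shape)
        r2 = rng.random(x.shape)
        v = (config.inertia * v
             + config.cognitive * r1 * (pbest - x)
             + config.social * r2 * (gbest - x))
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, llo, lhi)
        vals = np.array([objective(10.0 ** p) for p in x])
        improved = vals < pbest_val
        pbest[improved] = x[improved]
        pbest_val[improved] = vals[improved]
        g = int(np.argmin(pbest_val))
        if pbest_val[g] < gbest_val:
            gbest, gbest_val = pbest[g].copy(), float(pbest_val[g])
        history[it] = gbest_val
    if not np.isfinite(gbest_val):
        raise ValidationError("PSO objective became non-finite")
    return ConvergenceReport(best_objective=gbest_val, best_objective_history=history,
                             best_parameters=10.0 ** gbest, mean_target_force=np.nan)


def simulated_forces(contacts: TrajectoryContacts, model: SplineMaterialModel,
                     shell_densities: np.ndarray, depth_scale: float = 20.0,
                     reference_density: float = 1.0) -> np.ndarray:
    """Force magnitudes along a cached trajectory for given shell densities."""
    spline_vals = evaluate(model, contacts.depths / depth_scale)
    weighted = contacts.shell_areas @ np.asarray(shell_densities, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(contacts.total_areas > 0,
                         weighted / (contacts.total_areas * reference_density), 0.0)
    return spline_vals * ratio


def calibrate_densities_pso(packing: SpherePacking, target: SplineMaterialModel,
                            tool: ReamerTool, depths: Sequence[float],
                            config: Optional[PSOConfig] = None,
                            depth_scale: float = 20.0,
                            target_forces: Optional[np.ndarray] = None,
                            with_removal: bool = True,
                            seed: Optional[int] = None) -> tuple:
    """Fit the density field so simulated forces match the target model.

    ``depths`` is the reamer advance schedule; it must cover the displacement
    domain over which the target model is meant to be reproduced.  The
    objective is the mean absolute error [N] between simulated force
    magnitudes along the trajectory and the target forces (the target model
    evaluated at the same normalized depths, unless explicit ``target_forces``
    are given, e.g. in a parameter-recovery experiment).

    Returns ``(calibrated_packing, ConvergenceReport)``.
    """
    cfg = config if config is not None else PSOConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    depths = np.asarray(depths, dtype=float)
    if target_forces is None:
        target_forces = evaluate(target, depths / depth_scale)
    else:
        target_forces = np.asarray(target_forces, dtype=float)
        if target_forces.shape != depths.shape:
            raise ParameterError("target_forces must align with depths")

    contacts = replay_trajectory(packing, tool, depths, cfg.n_shells,
                                 with_removal=with_removal)
    active = contacts.total_areas > 0
    if not np.any(active):
        raise ValidationError("trajectory never touches the packing")
    ref = packing.reference_density

    def objective(shell_densities: np.ndarray) -> float:
        sim = simulated_forces(contacts, target, shell_densities,
                               depth_scale=depth_scale, reference_density=ref)
        return float(np.mean(np.abs(sim[active] - target_forces[active])))

    lo, hi = cfg.density_bounds
    report = particle_swarm(objective, (lo * ref, hi * ref), cfg.n_shells, cfg, rng,
                            start=np.full(cfg.n_shells, ref))
    report.mean_target_force = float(np.mean(np.abs(target_forces[active])))

    calibrated = packing.copy()
    calibrated.densities = report.best_parameters[contacts.shell_of_sphere]
    return calibrated, report
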