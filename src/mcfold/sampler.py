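"""Canonical and multicanonical Langevin dynamics on toy potentials.

A single integrator (BAOAB-splitting Langevin with unit masses) drives
both the plain canonical runs and the multicanonical runs; the latter
replace the potential energy E by the multicanonical energy

    E_mc(E) = E + R * T_sim * ln P_c(E, T_sim)

inside the weight function's validity range, with smooth harmonic walls
in energy space beyond the range bounds so trajectories cannot escape the
region where the weight polynomial is trusted.  Forces follow by the
chain rule, ``F = -(dE_mc/dE) * grad E``.

Multi-trajectory execution merges independent single runs (distinct seeds,
dispersed initial configurations) into one sample set; the trajectories
never communicate, so the merge is a plain concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .constants import R_GAS
from .errors import (
    IntegrationFailureError,
    InvalidParameterError,
    WeightDerivativeError,
)
from .toy_systems import PotentialModel

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .weights import WeightFunction

logger = logging.getLogger(__name__)

#: Default stiffness (per (kcal/mol)) of the artificial energy walls.
WALL_STIFFNESS_DEFAULT = 0.25

#: Maximum |dE_mc/dE| contributed by a wall.  Beyond the energy where the
#: harmonic wall reaches this slope the wall continues linearly, keeping
#: restoring forces bounded (a quadratic force feedback in energy space
#: can otherwise run away numerically on steep potentials).
WALL_SLOPE_MAX = 4.0


@dataclass
class SamplerParams:
    """Integrator and thermostat settings for one run.

    ``dt`` is the time step in reduced units (unit masses), ``friction``
    the Langevin coupling in inverse time, ``wall_stiffness`` the harmonic
    constant of the energy-space walls.  A ``burn_in`` fraction of steps is
    discarded before sampling begins.
    """

    dt: float = 0.05
    T_sim: float = 700.0
    friction: float = 1.0
    n_steps: int = 10_000
    sample_every: int = 10
    seed: int = 0
    wall_stiffness: float = WALL_STIFFNESS_DEFAULT
    burn_in: float = 0.1

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if not (self.n_steps >= self.sample_every >= 1):
            raise InvalidParameterError(
                f"need n_steps >= sample_every >= 1, got {self.n_steps}, {self.sample_every}"
            )
        if self.wall_stiffness < 0:
            raise InvalidParameterError("wall_stiffness must be >= 0")
        if not (0.0 <= self.burn_in < 1.0):
            raise InvalidParameterError("burn_in fraction must lie in [0, 1)")
        if self.T_sim <= 0:
            raise InvalidParameterError("T_sim must be > 0")


@dataclass
class SampleSet:
    """Tagged samples from one or more trajectories.

    ``configs`` has shape ``(n, dim)``; ``E`` stores the potential energy
    of each configuration at write time; ``traj_id`` values are contiguous
    ``0..M-1``.  ``histogram`` (counts, edges) is attached by
    multicanonical runs over the weight's validity range.
    """

    configs: np.ndarray
    E: np.ndarray
    traj_id: np.ndarray
    step: np.ndarray
    T_sim: float
    weight_ref: str | None = None
    histogram: tuple[np.ndarray, np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.configs = np.atleast_2d(np.asarray(self.configs, dtype=float))
        self.E = np.asarray(self.E, dtype=float)
        self.traj_id = np.asarray(self.traj_id, dtype=int)
        self.step = np.asarray(self.step, dtype=int)

    def __len__(self) -> int:
        return self.E.shape[0]

    @property
    def n_traj(self) -> int:
        return int(self.traj_id.max()) + 1 if len(self) else 0

    def spot_check_energies(self, model: PotentialModel, frac: float = 0.01, seed: int = 0):
        """Re-evaluate the stored energy on a random subset; max |error|."""
        rng = np.random.default_rng(seed)
        n = max(1, int(frac * len(self)))
        idx = rng.choice(len(self), size=n, replace=False)
        fresh = model.energies(self.configs[idx])
        return float(np.max(np.abs(fresh - self.E[idx])))

    @classmethod
    def concatenate(cls, parts: Sequence["SampleSet"]) -> "SampleSet":
        """Merge independent runs, renumbering trajectory ids contiguously."""
        configs, E, tid, step = [], [], [], []
        offset = 0
        for p in parts:
            configs.append(p.configs)
            E.append(p.E)
            tid.append(p.traj_id + offset)
            step.append(p.step)
            offset += p.n_traj
        return cls(
            configs=np.concatenate(configs, axis=0),
            E=np.concatenate(E),
            traj_id=np.concatenate(tid),
            step=np.concatenate(step),
            T_sim=parts[0].T_sim,
            weight_ref=parts[0].weight_ref,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.configs, columns=[f"x{i}" for i in range(self.configs.shape[1])]
        )
        df["E"] = self.E
        df["trajectory_id"] = self.traj_id
        df["step"] = self.step
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, T_sim: float, weight_ref: str | None = None) -> "SampleSet":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        return cls(
            configs=df[xcols].to_numpy(float),
            E=df["E"].to_numpy(float),
            traj_id=df["trajectory_id"].to_numpy(int),
            step=df["step"].to_numpy(int),
            T_sim=T_sim,
            weight_ref=weight_ref,
        )


def mc_energy(
    weight: "WeightFunction",
    E: np.ndarray | float,
    wall_stiffness: float = WALL_STIFFNESS_DEFAULT,
) -> np.ndarray | float:
    """Multicanonical energy E_mc(E), with harmonic walls outside the range.

    Inside ``[E_lo, E_hi]``: ``E + R T_sim ln P_c(E)``.  Outside, the value
    at the nearest bound plus a harmonic wall ``wall_stiffness *
    (E - bound)^2`` (continuous at the bounds) that turns linear once its
    slope reaches :data:`WALL_SLOPE_MAX`, so restoring forces stay
    bounded.
    """
    E_arr = np.asarray(E, dtype=float)
    scalar = E_arr.ndim == 0
    E_arr = np.atleast_1d(E_arr)
    rt = R_GAS * weight.T_sim
    out = E_arr + rt * weight.ln_pc(E_arr)
    lo_val = weight.E_lo + rt * weight.ln_pc(weight.E_lo)
    hi_val = weight.E_hi + rt * weight.ln_pc(weight.E_hi)
    below = E_arr < weight.E_lo
    above = E_arr > weight.E_hi
    out[below] = lo_val + _wall(weight.E_lo - E_arr[below], wall_stiffness)
    out[above] = hi_val + _wall(E_arr[above] - weight.E_hi, wall_stiffness)
    return float(out[0]) if scalar else out


def _wall(delta, k):
    """Wall energy at penetration depth ``delta`` >= 0."""
    if k == 0:
        return np.zeros_like(delta)
    d_star = WALL_SLOPE_MAX / (2.0 * k)
    quad = k * np.minimum(delta, d_star) ** 2
    lin = WALL_SLOPE_MAX * np.maximum(delta - d_star, 0.0)
    return quad + lin


def _wall_slope(delta, k):
    return min(2.0 * k * delta, WALL_SLOPE_MAX)


def _dmc_dE(weight, E, wall_stiffness):
    """Derivative of E_mc with respect to E (scalar)."""
    if E < weight.E_lo:
        return -_wall_slope(weight.E_lo - E, wall_stiffness)
    if E > weight.E_hi:
        return _wall_slope(E - weight.E_hi, wall_stiffness)
    return 1.0 + R_GAS * weight.T_sim * weight.d_ln_pc(E)


def _dmc_dE_vec(weight, E: np.ndarray, wall_stiffness: float) -> np.ndarray:
    """Vectorised dE_mc/dE over an energy array."""
    out = 1.0 + R_GAS * weight.T_sim * weight.d_ln_pc(E)
    below = E < weight.E_lo
    above = E > weight.E_hi
    if np.any(below):
        out[below] = -np.minimum(
            2.0 * wall_stiffness * (weight.E_lo - E[below]), WALL_SLOPE_MAX
        )
    if np.any(above):
        out[above] = np.minimum(
            2.0 * wall_stiffness * (E[above] - weight.E_hi), WALL_SLOPE_MAX
        )
    return out


def _langevin(
    model: PotentialModel,
    params: SamplerParams,
    rngs: Sequence[np.random.Generator],
    x0s: np.ndarray,
    weight: "WeightFunction | None" = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """BAOAB Langevin core shared by canonical and multicanonical runs.

    Integrates ``m = len(rngs)`` independent walkers simultaneously; each
    walker consumes noise only from its own generator, so a walker's
    trajectory is identical whether it runs alone or inside a batch.
    Returns (configs ``(n_keep, m, dim)``, energies ``(n_keep, m)``, steps,
    diagnostics) with burn-in removed.  A run aborts with
    :class:`IntegrationFailureError` if any walker's energy is non-finite
    or exceeds the overflow guard (``E_hi + 50 R T_sim`` beyond the wall
    for weighted runs, a fixed large bound otherwise).
    """
    dt, gamma = params.dt, params.friction
    rt = R_GAS * params.T_sim
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(rt * (1.0 - c1 * c1))
    m = len(rngs)
    x = np.atleast_2d(np.array(x0s, dtype=float)).copy()  # (m, dim)
    v = np.stack([rng.normal(0.0, np.sqrt(rt), size=model.dim) for rng in rngs])
    guard = weight.E_hi + 50.0 * rt if weight is not None else 1e10

    def force_energy(xc):
        g = model.gradients(xc)
        e = model.energies(xc)
        if weight is None:
            return -g, e
        s = _dmc_dE_vec(weight, e, params.wall_stiffness)
        if not np.all(np.isfinite(s)):
            bad = e[~np.isfinite(s)][0]
            raise WeightDerivativeError(
                f"dE_mc/dE is non-finite at E={bad:.6g} (weight range "
                f"[{weight.E_lo:.6g}, {weight.E_hi:.6g}])"
            )
        return -s[:, None] * g, e

    f, _ = force_energy(x)
    n_burn = int(params.burn_in * params.n_steps)
    n_keep = (params.n_steps - n_burn) // params.sample_every
    configs = np.empty((n_keep, m, model.dim))
    energies = np.empty((n_keep, m))
    steps = np.empty(n_keep, dtype=int)
    kin_acc = np.zeros(m)
    kin_n = 0
    k = 0
    # noise drawn in per-walker blocks; consumption order is deterministic
    block = 2048
    noise = np.empty((block, m, model.dim))
    bi = block
    for istep in range(1, params.n_steps + 1):
        if bi == block:
            for j, rng in enumerate(rngs):
                noise[:, j, :] = rng.normal(size=(block, model.dim))
            bi = 0
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * noise[bi]
        bi += 1
        if istep > n_burn:
            # velocities straight after the O step carry the smallest
            # discretisation bias in the kinetic temperature
            kin_acc += np.sum(v * v, axis=1)
            kin_n += 1
        x += 0.5 * dt * v
        f, e = force_energy(x)
        if not np.all(np.isfinite(e)) or np.any(e > guard):
            j = int(np.flatnonzero(~np.isfinite(e) | (e > guard))[0])
            raise IntegrationFailureError(
                f"trajectory {j} diverged at step {istep} (E={e[j]:.6g}); "
                f"reduce dt={dt} or check the weight function"
            )
        v += 0.5 * dt * f
        if istep > n_burn:
            if (istep - n_burn) % params.sample_every == 0 and k < n_keep:
                configs[k] = x
                energies[k] = e
                steps[k] = istep
                k += 1
    kin_T = kin_acc / (kin_n * model.dim) / R_GAS if kin_n else np.full(m, np.nan)
    diag = {
        "kinetic_temperature": float(kin_T.mean()),
        "kinetic_temperature_per_traj": kin_T.tolist(),
        "n_burn": n_burn,
    }
    return configs[:k], energies[:k], steps[:k], diag


def _default_x0(model: PotentialModel) -> np.ndarray:
    return np.zeros(model.dim)


def _flatten(configs, energies, steps, m):
    """(n_keep, m, dim) walker-major arrays -> trajectory-major flat arrays."""
    n_keep = configs.shape[0]
    flat_c = np.concatenate([configs[:, j, :] for j in range(m)], axis=0)
    flat_e = np.concatenate([energies[:, j] for j in range(m)])
    flat_t = np.repeat(np.arange(m), n_keep)
    flat_s = np.tile(steps, m)
    return flat_c, flat_e, flat_t, flat_s


def run_canonical(
    model: PotentialModel, params: SamplerParams, x0: np.ndarray | None = None
) -> SampleSet:
    """Canonical Langevin run at ``params.T_sim``; deterministic given seed."""
    rng = np.random.default_rng(params.seed)
    x0 = _default_x0(model) if x0 is None else np.asarray(x0, dtype=float)
    configs, E, steps, diag = _langevin(model, params, [rng], x0[None, :], weight=None)
    return SampleSet(
        configs=configs[:, 0, :],
        E=E[:, 0],
        traj_id=np.zeros(E.shape[0], dtype=int),
        step=steps,
        T_sim=params.T_sim,
        diagnostics=diag,
    )


def run_mcmd(
    model: PotentialModel,
    weight: "WeightFunction",
    params: SamplerParams,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    n_hist_bins: int = 100,
) -> SampleSet:
    """Single multicanonical run under a weight function.

    The sampler temperature is taken from the weight (``weight.T_sim``),
    overriding ``params.T_sim``, since a weight defines E_mc only at the
    temperature it was built for.  The returned set carries an energy
    histogram over the weight's validity range.
    """
    params = replace(params, T_sim=weight.T_sim)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x0 = _default_x0(model) if x0 is None else np.asarray(x0, dtype=float)
    configs, E, steps, diag = _langevin(model, params, [rng], x0[None, :], weight=weight)
    E = E[:, 0]
    counts, edges = np.histogram(E, bins=n_hist_bins, range=(weight.E_lo, weight.E_hi))
    return SampleSet(
        configs=configs[:, 0, :],
        E=E,
        traj_id=np.zeros(E.shape[0], dtype=int),
        step=steps,
        T_sim=params.T_sim,
        weight_ref=weight.label,
        histogram=(counts, edges),
        diagnostics=diag,
    )


def run_ttp(
    model: PotentialModel,
    weight: "WeightFunction",
    params: SamplerParams,
    n_traj: int,
    seeds: Sequence[int],
    x0s: Sequence[np.ndarray] | None = None,
    dispersal_T: float | None = None,
    dispersal_steps: int = 2000,
    n_hist_bins: int = 100,
) -> SampleSet:
    """Merged independent multicanonical trajectories (one weight, many seeds).

    Each trajectory starts from its own initial configuration -- supplied
    via ``x0s`` or generated by the dispersal rule: an independent short
    canonical run at ``dispersal_T`` (default: the weight's temperature)
    whose final configuration seeds the multicanonical run.  Trajectories
    never communicate (each consumes only its own random stream, so the
    batched integration is equivalent to independent runs); their samples
    are concatenated with ``trajectory_id`` recording provenance.
    """
    if len(seeds) != n_traj:
        raise InvalidParameterError(
            f"need one seed per trajectory: {len(seeds)} seeds for n_traj={n_traj}"
        )
    if len(set(seeds)) != len(seeds):
        logger.warning("duplicate seeds in TTP run: %s", sorted(seeds))
    if dispersal_T is None:
        dispersal_T = weight.T_sim
    rngs = [np.random.default_rng(s) for s in seeds]
    if x0s is not None:
        x0_arr = np.asarray(x0s, dtype=float)
    else:
        disp = replace(
            params,
            T_sim=dispersal_T,
            n_steps=dispersal_steps,
            sample_every=dispersal_steps,
            burn_in=0.0,
        )
        starts = np.tile(_default_x0(model), (n_traj, 1))
        c, _, _, _ = _langevin(model, disp, rngs, starts, weight=None)
        x0_arr = c[-1]
    mc_params = replace(params, T_sim=weight.T_sim)
    configs, E, steps, diag = _langevin(model, mc_params, rngs, x0_arr, weight=weight)
    flat_c, flat_e, flat_t, flat_s = _flatten(configs, E, steps, n_traj)
    counts, edges = np.histogram(
        flat_e, bins=n_hist_bins, range=(weight.E_lo, weight.E_hi)
    )
    return SampleSet(
        configs=flat_c,
        E=flat_e,
        traj_id=flat_t,
        step=flat_s,
        T_sim=mc_params.T_sim,
        weight_ref=weight.label,
        histogram=(counts, edges),
        diagnostics=diag,
    )
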