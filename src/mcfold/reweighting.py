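"""Canonical-ensemble reconstruction from multicanonical samples.

A multicanonical run performed at T_sim under a weight function visits
energies nearly uniformly; the canonical ensemble at any target
temperature T_tag is recovered as pure post-processing by assigning each
sampled configuration the log-weight

    ln w_i = E_mc(E_i) / (R T_sim) - E_i / (R T_tag)

and normalising.  Log-sum-exp stabilisation is mandatory because E spans
hundreds of RT across the covered range.  Standard errors of ensemble
expectations come from a block bootstrap whose blocks are whole
trajectories, respecting the merged multi-trajectory structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_GAS
from .errors import InvalidParameterError
from .sampler import WALL_STIFFNESS_DEFAULT, SampleSet, mc_energy
from .weights import WeightFunction

logger = logging.getLogger(__name__)


@dataclass
class CanonicalEnsemble:
    """A reweighted view of a :class:`SampleSet` at temperature ``T_tag``.

    ``weights`` are non-negative and sum to one; ``ess`` is the effective
    sample size ``1 / sum(w^2)``.
    """

    samples: SampleSet
    weights: np.ndarray
    T_tag: float
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        s = self.weights.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise InvalidParameterError(f"ensemble weights sum to {s}, expected 1")
        if np.any(self.weights < 0):
            raise InvalidParameterError("ensemble weights must be non-negative")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def weights_to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "weight": self.weights,
                "E": self.samples.E,
                "trajectory_id": self.samples.traj_id,
            }
        ).to_csv(path, index=False)


def reweight(
    samples: SampleSet,
    weight: WeightFunction,
    T_tag: float,
    wall_stiffness: float = WALL_STIFFNESS_DEFAULT,
) -> CanonicalEnsemble:
    """Reconstruct the canonical ensemble at ``T_tag``.

    ``samples`` must have been generated under ``weight`` at the weight's
    own temperature.  The multicanonical ensemble is the flat range
    [E_lo, E_hi]; samples recorded in the wall spill-over region outside
    it are artifacts of the confinement (their de-biasing weights grow as
    exp(wall/RT) and amplify integrator error), so they receive zero
    weight.  An effective sample size below 10 attaches a low-ESS warning
    (not an error).
    """
    if T_tag <= 0:
        raise InvalidParameterError(f"T_tag must be > 0, got {T_tag}")
    E = samples.E
    log_w = np.asarray(mc_energy(weight, E, wall_stiffness)) / (R_GAS * weight.T_sim)
    log_w = log_w - E / (R_GAS * T_tag)
    in_range = (E >= weight.E_lo) & (E <= weight.E_hi)
    log_w[~in_range] = -np.inf
    log_w -= log_w[in_range].max()
    w = np.exp(log_w)
    w /= w.sum()
    ens = CanonicalEnsemble(samples=samples, weights=w, T_tag=float(T_tag))
    if ens.ess < 10:
        msg = f"low effective sample size: {ens.ess:.2f}"
        ens.warnings.append(msg)
        logger.warning(msg)
    return ens


def expectation(
    ensemble: CanonicalEnsemble,
    observable,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Weighted ensemble mean with a trajectory-block bootstrap SE.

    ``observable`` is either a callable mapping a configuration row to a
    scalar or a precomputed array of per-record values.  Bootstrap blocks
    are whole trajectories (within-trajectory samples are correlated, and
    trajectories are the independent unit of a merged multi-run ensemble).
    """
    if callable(observable):
        values = np.array([observable(c) for c in ensemble.samples.configs], dtype=float)
    else:
        values = np.asarray(observable, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("observable produced non-finite values")
    w = ensemble.weights
    mean = float(np.sum(w * values))
    tids = ensemble.samples.traj_id
    unique = np.unique(tids)
    if len(unique) < 2:
        # single trajectory: weighted i.i.d. approximation
        var = np.sum(w * (values - mean) ** 2)
        se = float(np.sqrt(var / max(ensemble.ess, 1.0)))
        return mean, se
    rng = np.random.default_rng(seed)
    groups = {t: np.flatnonzero(tids == t) for t in unique}
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.choice(unique, size=len(unique), replace=True)
        idx = np.concatenate([groups[t] for t in pick])
        wb = w[idx]
        tot = wb.sum()
        boots[b] = np.sum(wb * values[idx]) / tot if tot > 0 else mean
    return mean, float(np.std(boots, ddof=1))


def resample_at(
    ensemble: CanonicalEnsemble, n: int, seed: int
) -> np.ndarray:
    """Importance resampling: ``n`` record indices drawn by the weights.

    Returns indices into the underlying sample set (with replacement), so
    structure-level analyses can operate on an unweighted conformational
    ensemble of the requested size.  Deterministic given ``seed``.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.choice(len(ensemble), size=n, replace=True, p=ensemble.weights)


def weighted_ks_distance(values: np.ndarray, weights: np.ndarray, cdf) -> float:
    """Kolmogorov-Smirnov distance between a weighted sample and a CDF.

    ``cdf`` is a callable evaluating the reference distribution function;
    the weighted empirical CDF is compared at the sample points.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    ref = np.asarray(cdf(v), dtype=float)
    lower = np.concatenate([[0.0], cw[:-1]])
    return float(np.max(np.maximum(np.abs(cw - ref), np.abs(lower - ref))))
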