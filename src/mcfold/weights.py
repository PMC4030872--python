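"""Iterative construction of the multicanonical weight function.

The weight is a polynomial approximation of ln P_c(E, T_sim), the log of
the canonical energy distribution at the simulation temperature, valid on
an energy interval [E_lo, E_hi].  It is estimated by the staged protocol:

1. a high-temperature canonical seed run yields a histogram of E, accurate
   only near its peak; the peak defines E_hi and the lowest trustworthy
   bin defines the initial E_lo;
2. multicanonical runs under the current weight, confined by soft energy
   walls, spill slightly below E_lo; the density of states is re-estimated
   from the biased histogram, the weight is refit, and E_lo is extended
   down to the lowest bin with enough counts;
3. after the first multicanonical iteration the weight is re-expressed at
   a low reset temperature (ln P_c at low T is smoother, so the polynomial
   represents it better), and iterations continue until the energy range
   covers the target temperature and the energy histogram is flat.

All fits are least squares of ln(count density) on occupied bins; empty
bins are excluded, not zero-filled.  Weights are defined up to an additive
constant throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .constants import R_GAS, T_RESET_DEFAULT, T_SEED_DEFAULT, T_TARGET_DEFAULT
from .errors import (
    ConvergenceFailureError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedFlatnessError,
)
from .sampler import SamplerParams, SampleSet, mc_energy, run_canonical, run_ttp
from .toy_systems import PotentialModel

logger = logging.getLogger(__name__)

DEGREE_DEFAULT = 8
N_BINS_DEFAULT = 100
MIN_BIN_COUNT_DEFAULT = 20


@dataclass
class WeightFunction:
    """Polynomial representation of ln P_c(E, T_sim) on [E_lo, E_hi].

    ``poly`` is a :class:`numpy.polynomial.Polynomial` with its own scaled
    domain for conditioning.  ``provenance`` records the iteration index
    and fit diagnostics.  The polynomial extrapolates smoothly outside the
    bounds; the sampler adds energy walls there.
    """

    poly: Polynomial
    T_sim: float
    E_lo: float
    E_hi: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.E_lo < self.E_hi:
            raise InvalidParameterError(
                f"need E_lo < E_hi, got [{self.E_lo}, {self.E_hi}]"
            )
        probe = np.linspace(self.E_lo, self.E_hi, 64)
        if not np.all(np.isfinite(self.poly(probe))):
            raise InvalidParameterError("weight polynomial is non-finite on its range")

    @property
    def degree(self) -> int:
        return len(self.poly.coef) - 1

    @property
    def label(self) -> str:
        it = self.provenance.get("iteration", "?")
        return f"weight(T={self.T_sim:g}K,iter={it})"

    def ln_pc(self, E):
        return self.poly(np.asarray(E, dtype=float))

    def d_ln_pc(self, E):
        d = self.__dict__.get("_deriv")
        if d is None:
            d = self.__dict__["_deriv"] = self.poly.deriv()
        return d(np.asarray(E, dtype=float))

    def to_json(self, path) -> None:
        payload = {
            "coef": list(self.poly.coef),
            "domain": list(self.poly.domain),
            "T_sim": self.T_sim,
            "E_lo": self.E_lo,
            "E_hi": self.E_hi,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "WeightFunction":
        with open(path) as fh:
            d = json.load(fh)
        poly = Polynomial(np.asarray(d["coef"]), domain=d["domain"])
        return cls(
            poly=poly,
            T_sim=d["T_sim"],
            E_lo=d["E_lo"],
            E_hi=d["E_hi"],
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def identity(cls, T_sim: float, E_lo: float, E_hi: float) -> "WeightFunction":
        """ln P_c = 0 everywhere: E_mc reduces to E (canonical dynamics)."""
        return cls(
            poly=Polynomial([0.0], domain=[E_lo, E_hi]),
            T_sim=T_sim,
            E_lo=E_lo,
            E_hi=E_hi,
            provenance={"iteration": 0, "kind": "identity"},
        )


@dataclass
class ProtocolSchedule:
    """Temperatures and stopping rules of the iterative weight protocol.

    ``extension_rule`` is the minimum occupied-bin count for an energy to
    be considered trustworthy when extending E_lo downward; the stop rule
    requires the reweighted mean energy at ``T_target`` to lie safely
    inside the covered range and the energy histogram to be flat within
    ``flatness_threshold`` over the central 90% of the range.
    """

    T_seed: float = T_SEED_DEFAULT
    T_reset: float = T_RESET_DEFAULT
    T_target: float = T_TARGET_DEFAULT
    extension_rule: int = MIN_BIN_COUNT_DEFAULT
    max_iterations: int = 20
    flatness_threshold: float = 2.0
    degree: int = DEGREE_DEFAULT
    n_bins: int = N_BINS_DEFAULT
    n_traj: int = 4
    margin_frac: float = 0.05
    #: Relative flatness improvement below which the iteration is deemed
    #: at its fixed point.  A polynomial weight cannot flatten features of
    #: the density of states it cannot represent (notably the
    #: discontinuity of a one-dimensional density of states at a barrier
    #: energy), so on such landscapes the achievable flatness saturates
    #: above ``flatness_threshold`` and the stall rule ends the iteration.
    stall_tol: float = 0.15

    def __post_init__(self):
        if not self.T_reset < self.T_seed:
            raise InvalidParameterError("need T_reset < T_seed")
        if self.max_iterations < 1:
            raise InvalidParameterError("max_iterations must be >= 1")


def _fit_poly(E_centers, ln_density, degree, E_range):
    if len(E_centers) < degree + 2:
        raise InsufficientDataError(
            f"only {len(E_centers)} occupied bins in [{E_range[0]:.6g}, "
            f"{E_range[1]:.6g}]; need >= degree + 2 = {degree + 2}"
        )
    poly = Polynomial.fit(E_centers, ln_density, deg=degree, domain=list(E_range))
    resid = float(np.sqrt(np.mean((poly(E_centers) - ln_density) ** 2)))
    return poly, resid


def fit_log_pc(
    samples: SampleSet | np.ndarray,
    T: float,
    degree: int = DEGREE_DEFAULT,
    E_range: tuple[float, float] | None = None,
    n_bins: int = N_BINS_DEFAULT,
) -> WeightFunction:
    """Fit ln P_c(E, T) to the energy histogram of a canonical run.

    Bins span ``E_range`` (default: the sampled range) with width
    range/n_bins; the log of the count density on occupied bins is fit by
    least squares with a polynomial of the given degree.  The
    normalisation constant is absorbed: weights are defined up to an
    additive constant.
    """
    E = samples.E if isinstance(samples, SampleSet) else np.asarray(samples, float)
    if E_range is None:
        E_range = (float(E.min()), float(E.max()))
    counts, edges = np.histogram(E, bins=n_bins, range=E_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = counts > 0
    ln_density = np.log(counts[occ] / (len(E) * np.diff(edges)[occ]))
    poly, resid = _fit_poly(centers[occ], ln_density, degree, E_range)
    return WeightFunction(
        poly=poly,
        T_sim=T,
        E_lo=E_range[0],
        E_hi=E_range[1],
        provenance={
            "iteration": 0,
            "fit_rms_residual": resid,
            "n_occupied_bins": int(occ.sum()),
            "n_samples": int(len(E)),
        },
    )


def seed_energy_range(
    samples: SampleSet | np.ndarray,
    n_bins: int = N_BINS_DEFAULT,
    min_count: int = MIN_BIN_COUNT_DEFAULT,
) -> tuple[float, float]:
    """[E_0, E_high] from a canonical seed run.

    The accurately sampled region is the span of bins holding at least
    ``min_count`` samples; E_0 and E_high are its lowest and highest bin
    centres.  (On many-body systems this brackets the peak of the energy
    histogram; on low-dimensional toys, whose energy distribution can peak
    at the lowest bin, the same count rule still applies.)
    """
    E = samples.E if isinstance(samples, SampleSet) else np.asarray(samples, float)
    counts, edges = np.histogram(E, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    trusted = centers[counts >= min_count]
    if trusted.size < 2:
        raise InsufficientDataError(
            f"fewer than 2 bins hold >= {min_count} samples; run a longer seed"
        )
    return float(trusted.min()), float(trusted.max())


def update_weight(
    old: WeightFunction,
    mcmd_samples: SampleSet,
    T_new: float | None = None,
    n_bins: int = N_BINS_DEFAULT,
    min_count: int = MIN_BIN_COUNT_DEFAULT,
    wall_stiffness: float | None = None,
) -> WeightFunction:
    """Re-estimate the weight from a multicanonical run performed under it.

    On occupied bins, ``ln n(E) = ln P_mc(E) + E_mc(E) / (R T_sim)`` where
    E_mc includes the wall term (the walls are part of the bias actually
    applied, so bins in the spill-over region below E_lo are unbiased
    correctly and can extend the range).  The new weight is
    ``ln P_c(E, T') = ln n(E) - E / (R T')`` refit at the same degree;
    E_lo extends down to the lowest bin with >= ``min_count`` counts and
    never moves upward.
    """
    from .sampler import WALL_STIFFNESS_DEFAULT

    if wall_stiffness is None:
        wall_stiffness = WALL_STIFFNESS_DEFAULT
    T_prime = old.T_sim if T_new is None else float(T_new)
    E = mcmd_samples.E
    bin_width = (old.E_hi - old.E_lo) / n_bins
    lo_edge = min(float(E.min()), old.E_lo)
    n_total = int(np.ceil((old.E_hi - lo_edge) / bin_width))
    edges = old.E_hi - bin_width * np.arange(n_total, -1, -1)
    counts, edges = np.histogram(E, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = counts >= 1  # empty bins are excluded from the fit, not zero-filled
    if not np.any(occ):
        raise InsufficientDataError("no occupied bins")
    c = centers[occ]
    ln_pmc = np.log(counts[occ] / (len(E) * bin_width))
    ln_n = ln_pmc + np.asarray(mc_energy(old, c, wall_stiffness)) / (R_GAS * old.T_sim)
    ln_pc = ln_n - c / (R_GAS * T_prime)
    # only bins holding >= min_count samples are trustworthy for extension
    trusted = centers[(counts >= min_count)]
    if trusted.size == 0:
        raise InsufficientDataError(
            f"no bins hold >= {min_count} samples; run longer trajectories"
        )
    new_lo = min(old.E_lo, float(trusted.min()))
    if float(E.min()) >= old.E_lo:
        logger.warning("no samples below E_lo=%.6g; range not extended", old.E_lo)
    sel = (c <= old.E_hi) & (c >= new_lo)
    poly, resid = _fit_poly(c[sel], ln_pc[sel], old.degree, (new_lo, old.E_hi))
    return WeightFunction(
        poly=poly,
        T_sim=T_prime,
        E_lo=new_lo,
        E_hi=old.E_hi,
        provenance={
            "iteration": old.provenance.get("iteration", 0) + 1,
            "fit_rms_residual": resid,
            "previous_E_lo": old.E_lo,
            "n_occupied_bins": int(sel.sum()),
        },
    )


def reset_temperature(weight: WeightFunction, T_new: float) -> WeightFunction:
    """Re-express the weight at a new simulation temperature.

    The density-of-states estimate implied by the weight,
    ``ln n(E) = ln P_c(E, T_sim) + E / (R T_sim)``, is temperature-free;
    the weight at ``T_new`` is ``ln n(E) - E / (R T_new)`` refit at the
    same degree (exact up to conditioning, since only a linear term in E
    changes).  The validity range is unchanged.
    """
    if T_new <= 0:
        raise InvalidParameterError(f"T_new must be > 0, got {T_new}")
    grid = np.linspace(weight.E_lo, weight.E_hi, 512)
    ln_n = weight.ln_pc(grid) + grid / (R_GAS * weight.T_sim)
    ln_pc_new = ln_n - grid / (R_GAS * T_new)
    deg = max(weight.degree, 1)
    poly, resid = _fit_poly(grid, ln_pc_new, deg, (weight.E_lo, weight.E_hi))
    prov = dict(weight.provenance)
    prov.update({"reset_from_T": weight.T_sim, "fit_rms_residual": resid})
    return WeightFunction(
        poly=poly, T_sim=float(T_new), E_lo=weight.E_lo, E_hi=weight.E_hi, provenance=prov
    )


def flatness(
    counts: np.ndarray,
    edges: np.ndarray,
    E_lo: float | None = None,
    E_hi: float | None = None,
    central: float = 0.9,
) -> float:
    """Max/min occupied-bin count over the central fraction of the range.

    The outer ``(1 - central)/2`` of the energy range on each side is
    excluded to avoid wall artifacts.  Requires at least 10 occupied bins.
    """
    counts = np.asarray(counts, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if E_lo is None:
        E_lo = edges[0]
    if E_hi is None:
        E_hi = edges[-1]
    pad = 0.5 * (1.0 - central) * (E_hi - E_lo)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sel = (centers >= E_lo + pad) & (centers <= E_hi - pad) & (counts > 0)
    if sel.sum() < 10:
        raise UndefinedFlatnessError(
            f"only {int(sel.sum())} occupied bins in the central {central:.0%} of the range"
        )
    c = counts[sel]
    return float(c.max() / c.min())


def iterate_weights(
    model: PotentialModel,
    schedule: ProtocolSchedule,
    params: SamplerParams,
) -> tuple[WeightFunction, pd.DataFrame, SampleSet]:
    """Full staged weight-estimation pipeline.

    Canonical seed at T_seed -> initial polynomial fit on [E_0, E_high] ->
    iterated multicanonical runs with walls, range extension, and a single
    temperature reset to T_reset after the first multicanonical iteration
    -> stop when the reweighted mean energy at T_target lies inside
    [E_lo + delta, E_hi - delta] and either the flatness ratio is within
    threshold or it has stopped improving (the polynomial fixed point;
    see :class:`ProtocolSchedule.stall_tol`).  Returns the final weight, a
    per-iteration report, and the last multicanonical sample set.
    """
    from dataclasses import replace

    from .reweighting import reweight

    seed_params = replace(params, T_sim=schedule.T_seed)
    seed_run = run_canonical(model, seed_params)
    e0, e_high = seed_energy_range(seed_run, schedule.n_bins, schedule.extension_rule)
    weight = fit_log_pc(
        seed_run, schedule.T_seed, schedule.degree, (e0, e_high), schedule.n_bins
    )
    rows = []
    last_run = None
    for it in range(1, schedule.max_iterations + 1):
        seeds = [params.seed + 7919 * it + k for k in range(schedule.n_traj)]
        run = run_ttp(
            model,
            weight,
            params,
            n_traj=schedule.n_traj,
            seeds=seeds,
            dispersal_T=schedule.T_seed,
            n_hist_bins=schedule.n_bins,
        )
        last_run = run
        counts, edges = run.histogram
        try:
            flat = flatness(counts, edges, weight.E_lo, weight.E_hi)
        except UndefinedFlatnessError:
            flat = np.inf
        ens = reweight(run, weight, schedule.T_target)
        mean_e = float(np.sum(ens.weights * run.E))
        delta = schedule.margin_frac * (weight.E_hi - weight.E_lo)
        rows.append(
            {
                "iteration": it,
                "T_sim": weight.T_sim,
                "E_lo": weight.E_lo,
                "E_hi": weight.E_hi,
                "flatness": flat,
                "mean_E_at_target": mean_e,
                "ess": ens.ess,
            }
        )
        covered = weight.E_lo + delta <= mean_e <= weight.E_hi - delta
        stalled = (
            len(rows) >= 2
            and np.isfinite(flat)
            and rows[-2]["flatness"] > 0
            and (rows[-2]["flatness"] - flat) / rows[-2]["flatness"] < schedule.stall_tol
            and rows[-2]["E_lo"] == weight.E_lo
        )
        converged = covered and (flat <= schedule.flatness_threshold or stalled)
        if converged:
            report = pd.DataFrame(rows)
            weight.provenance["converged_at_iteration"] = it
            return weight, report, run
        T_new = schedule.T_reset if it == 1 and schedule.T_reset != weight.T_sim else None
        weight = update_weight(
            weight,
            run,
            T_new=T_new,
            n_bins=schedule.n_bins,
            min_count=schedule.extension_rule,
            wall_stiffness=params.wall_stiffness,
        )
    raise ConvergenceFailureError(
        f"weight iteration did not converge in {schedule.max_iterations} iterations",
        report=pd.DataFrame(rows),
    )
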