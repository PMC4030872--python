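"""Toy energy landscapes with exact canonical oracles.

The multicanonical machinery in :mod:`mcfold.sampler` and
:mod:`mcfold.weights` is verified against low-dimensional potentials whose
canonical statistics can be computed independently of any sampler: a
harmonic well (closed form), a one-dimensional double well (quadrature),
and a helix-coil torsion chain (transfer-matrix quadrature).  Each
potential carries an energy, an analytic gradient, and -- where available
-- a :class:`CanonicalOracle` that plays the role of the exact density of
states for ground-truth checks.

Energies are in kcal/mol-equivalent units, temperatures in kelvin, with
the gas constant ``R = 1.987e-3 kcal/(mol K)``, so the protocol's
temperature schedule (700 K seed, 200 K reset, 315 K target) is meaningful
on the toys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .constants import R_GAS
from .errors import IncompatibleModelsError, InvalidParameterError, OracleRangeError

__all__ = [
    "PotentialModel",
    "CanonicalOracle",
    "HarmonicOracle",
    "QuadratureOracle1D",
    "ChainTransferOracle",
    "make_harmonic",
    "make_double_well",
    "make_chain_model",
    "mix_energies",
    "canonical_oracle_eval",
]


@dataclass
class PotentialModel:
    """An energy landscape over ``dim`` degrees of freedom.

    ``energy`` maps a configuration of shape ``(dim,)`` to a scalar;
    ``gradient`` returns its derivative, shape ``(dim,)``.  ``domain`` is a
    per-coordinate ``(lo, hi)`` list or ``None`` for unbounded/periodic
    coordinates.  ``energy_batch`` is an optional vectorised evaluator over
    an ``(n, dim)`` array, used by quadrature oracles for speed.
    """

    name: str
    dim: int
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain: list[tuple[float, float]] | None = None
    oracle: "CanonicalOracle | None" = None
    energy_batch: Callable[[np.ndarray], np.ndarray] | None = None
    gradient_batch: Callable[[np.ndarray], np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def energies(self, configs: np.ndarray) -> np.ndarray:
        """Energy of each row of an ``(n, dim)`` configuration array."""
        configs = np.atleast_2d(np.asarray(configs, dtype=float))
        if self.energy_batch is not None:
            return np.asarray(self.energy_batch(configs), dtype=float)
        return np.array([self.energy(c) for c in configs], dtype=float)

    def gradients(self, configs: np.ndarray) -> np.ndarray:
        """Gradient of each row of an ``(n, dim)`` configuration array."""
        configs = np.atleast_2d(np.asarray(configs, dtype=float))
        if self.gradient_batch is not None:
            return np.asarray(self.gradient_batch(configs), dtype=float)
        return np.array([self.gradient(c) for c in configs], dtype=float)


class CanonicalOracle:
    """Exact canonical statistics of a :class:`PotentialModel`.

    Subclasses implement ``mean_E``, ``var_E``, ``pdf_E``, ``cdf_E`` and
    (when configuration-space integrals are tractable) ``expect``.
    ``T_range`` bounds the temperatures at which the oracle is trusted.
    """

    method = "abstract"

    def __init__(self, model: PotentialModel, T_range: tuple[float, float] = (50.0, 2000.0)):
        self.model = model
        self.T_range = T_range

    def _check_T(self, T: float) -> None:
        lo, hi = self.T_range
        if not (lo <= T <= hi):
            raise OracleRangeError(
                f"T={T} K outside oracle validity range [{lo}, {hi}] K"
            )

    def mean_E(self, T: float) -> float:
        raise NotImplementedError

    def var_E(self, T: float) -> float:
        raise NotImplementedError

    def pdf_E(self, T: float, E: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cdf_E(self, T: float, E: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def expect(self, T: float, observable: Callable[[np.ndarray], float]) -> float:
        raise NotImplementedError

    def energy_histogram(self, T: float, edges: np.ndarray) -> np.ndarray:
        """Probability mass of E falling in each bin of ``edges``."""
        cdf = self.cdf_E(T, np.asarray(edges, dtype=float))
        return np.diff(cdf)


class HarmonicOracle(CanonicalOracle):
    """Closed-form oracle for the isotropic harmonic well.

    For ``E = (k/2) sum x_i^2`` the potential energy at temperature T is
    Gamma-distributed with shape ``dim/2`` and scale ``RT`` (equipartition),
    independent of the stiffness k.
    """

    method = "closed_form"

    def _dist(self, T: float):
        self._check_T(T)
        return stats.gamma(a=self.model.dim / 2.0, scale=R_GAS * T)

    def mean_E(self, T: float) -> float:
        return float(self._dist(T).mean())

    def var_E(self, T: float) -> float:
        return float(self._dist(T).var())

    def pdf_E(self, T: float, E: np.ndarray) -> np.ndarray:
        return self._dist(T).pdf(np.asarray(E, dtype=float))

    def cdf_E(self, T: float, E: np.ndarray) -> np.ndarray:
        return self._dist(T).cdf(np.asarray(E, dtype=float))


class QuadratureOracle1D(CanonicalOracle):
    """Composite-trapezoid Boltzmann quadrature for one-dimensional models.

    The integration bracket is grown symmetrically until the Boltzmann
    factor at the edges is below ``exp(-46)`` of the minimum at the highest
    trusted temperature, keeping the neglected tail mass < 1e-10.  The grid
    is refined by doubling until the partition function changes by less
    than ``rtol`` (default 1e-6) relative.
    """

    method = "quadrature"

    def __init__(self, model, T_range=(50.0, 2000.0), rtol=1e-6, n_start=2049):
        super().__init__(model, T_range)
        self.rtol = rtol
        self.n_start = n_start
        self._bracket = self._find_bracket()
        self._cache: dict[float, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _find_bracket(self) -> tuple[float, float]:
        e = lambda x: float(self.model.energy(np.array([x])))
        probe = np.linspace(-4.0, 4.0, 401)
        e_min = min(e(x) for x in probe)
        cutoff = e_min + 46.0 * R_GAS * self.T_range[1]
        half = 2.0
        while e(half) < cutoff or e(-half) < cutoff:
            half *= 2.0
            if half > 1e6:  # pragma: no cover - pathological potential
                raise InvalidParameterError("could not bracket the Boltzmann integrand")
        return (-half, half)

    def _grid(self, T: float):
        """Converged (x, E(x), normalized Boltzmann weight) triple at T."""
        self._check_T(T)
        if T in self._cache:
            return self._cache[T]
        lo, hi = self._bracket
        n = self.n_start
        z_prev = None
        while True:
            x = np.linspace(lo, hi, n)
            E = self.model.energies(x[:, None])
            w = np.exp(-(E - E.min()) / (R_GAS * T))
            # trapezoid weights
            tw = np.full(n, (hi - lo) / (n - 1))
            tw[0] *= 0.5
            tw[-1] *= 0.5
            z = float(np.sum(w * tw))
            if z_prev is not None and abs(z - z_prev) <= self.rtol * abs(z_prev):
                p = w * tw / z
                self._cache[T] = (x, E, p)
                return self._cache[T]
            z_prev = z
            n = 2 * n - 1
            if n > 2**22:  # pragma: no cover
                raise RuntimeError("quadrature failed to converge")

    def _masked(self, T: float, window: tuple[float, float] | None):
        """(x, E, p) with p renormalised to an energy window, if given.

        A flat-histogram range [E_lo, E_hi] can only represent the
        canonical ensemble restricted to that window; windowed oracle
        values are the exact estimands for reweighting checks.
        """
        x, E, p = self._grid(T)
        if window is None:
            return x, E, p
        lo, hi = window
        sel = (E >= lo) & (E <= hi)
        return x[sel], E[sel], p[sel] / p[sel].sum()

    def mean_E(self, T: float, window: tuple[float, float] | None = None) -> float:
        _, E, p = self._masked(T, window)
        return float(np.sum(p * E))

    def var_E(self, T: float, window: tuple[float, float] | None = None) -> float:
        _, E, p = self._masked(T, window)
        m = np.sum(p * E)
        return float(np.sum(p * (E - m) ** 2))

    def expect(self, T: float, observable, window=None) -> float:
        x, _, p = self._masked(T, window)
        vals = np.array([observable(np.array([xi])) for xi in x], dtype=float)
        return float(np.sum(p * vals))

    def prob(self, T: float, predicate, window=None) -> float:
        """Probability of a configuration-space event, e.g. P(x < 0)."""
        return self.expect(T, lambda c: float(bool(predicate(c))), window=window)

    def _energy_cdf_grid(self, T: float, window=None):
        _, E, p = self._masked(T, window)
        order = np.argsort(E)
        e_sorted = E[order]
        c_sorted = np.cumsum(p[order])
        return e_sorted, c_sorted

    def cdf_E(self, T: float, E: np.ndarray, window=None) -> np.ndarray:
        es, cs = self._energy_cdf_grid(T, window)
        return np.interp(np.asarray(E, dtype=float), es, cs, left=0.0, right=1.0)

    def pdf_E(self, T: float, E: np.ndarray) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        h = max(1e-4, 1e-3 * R_GAS * T)
        return (self.cdf_E(T, E + h) - self.cdf_E(T, E - h)) / (2 * h)


class ChainTransferOracle(CanonicalOracle):
    """Transfer-matrix oracle for the torsion-chain model.

    The chain energy is a sum of per-dihedral double wells plus a
    nearest-neighbour coupling, so its Boltzmann integral factorises into a
    product of transfer matrices over a periodic angle grid.  The grid is
    doubled until the mean energy is stable to ``rtol`` relative.
    """

    method = "quadrature"

    def __init__(self, model, T_range=(50.0, 2000.0), rtol=1e-6, m_start=256):
        super().__init__(model, T_range)
        self.rtol = rtol
        self.m_start = m_start

    def _stats(self, T: float, m: int):
        site = self.model.meta["site_energy"]     # (theta, i) -> per-site term
        bond = self.model.meta["bond_energy"]     # (theta, theta') -> coupling
        helical = self.model.meta["is_helical_angle"]
        n = self.model.dim
        beta = 1.0 / (R_GAS * T)
        theta = np.linspace(-np.pi, np.pi, m, endpoint=False)
        w = 2 * np.pi / m
        V = np.stack([site(theta, i) for i in range(n)])          # (n, m)
        f = np.exp(-beta * (V - V.min()))
        Bmat = bond(theta[:, None], theta[None, :])               # (m, m)
        K = np.exp(-beta * Bmat)
        # forward/backward messages with per-step normalisation
        A = np.empty((n, m))
        A[0] = f[0]
        for i in range(1, n):
            msg = (K.T @ (A[i - 1] * w))
            A[i] = f[i] * msg / msg.max()
        Bw = np.empty((n, m))
        Bw[-1] = 1.0
        for i in range(n - 2, -1, -1):
            msg = K @ (f[i + 1] * Bw[i + 1] * w)
            Bw[i] = msg / msg.max()
        marg = A * Bw
        marg /= marg.sum(axis=1, keepdims=True)  # per-cell probability mass
        mean_site = float(sum(np.sum(marg[i] * V[i]) for i in range(n)))
        # pairwise marginals for bond terms
        mean_bond = 0.0
        for i in range(n - 1):
            P2 = (A[i] * w)[:, None] * K * (f[i + 1] * Bw[i + 1] * w)[None, :]
            P2 /= P2.sum()
            mean_bond += float(np.sum(P2 * Bmat))
        hel = float(np.mean([np.sum(marg[i] * helical(theta)) for i in range(n)]))
        return mean_site + mean_bond, hel

    def _converged(self, T: float):
        self._check_T(T)
        m = self.m_start
        prev = None
        while True:
            cur = self._stats(T, m)
            if prev is not None and abs(cur[0] - prev[0]) <= self.rtol * max(1.0, abs(prev[0])):
                return cur
            prev = cur
            m *= 2
            if m > 2**14:  # pragma: no cover
                raise RuntimeError("transfer-matrix grid failed to converge")

    def mean_E(self, T: float) -> float:
        return self._converged(T)[0]

    def mean_helical_fraction(self, T: float) -> float:
        return self._converged(T)[1]


def make_harmonic(dim: int, k: float) -> PotentialModel:
    """Isotropic harmonic well ``E = (k/2) sum x_i^2`` with closed-form oracle."""
    if not (isinstance(dim, (int, np.integer)) and dim >= 1):
        raise InvalidParameterError(f"dim must be a positive integer, got {dim!r}")
    if not k > 0:
        raise InvalidParameterError(f"stiffness k must be > 0, got {k!r}")

    def energy(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(0.5 * k * np.dot(x, x))

    def gradient(x: np.ndarray) -> np.ndarray:
        return k * np.asarray(x, dtype=float)

    def energy_batch(xs: np.ndarray) -> np.ndarray:
        return 0.5 * k * np.sum(np.asarray(xs, dtype=float) ** 2, axis=1)

    model = PotentialModel(
        name=f"harmonic(dim={dim},k={k})",
        dim=int(dim),
        energy=energy,
        gradient=gradient,
        domain=None,
        energy_batch=energy_batch,
        gradient_batch=lambda xs: k * np.asarray(xs, dtype=float),
        meta={"k": float(k)},
    )
    model.oracle = HarmonicOracle(model)
    return model


def make_double_well(a: float, b: float = 0.0) -> PotentialModel:
    """One-dimensional double well ``E = a (x^2 - 1)^2 + b x``.

    ``a`` sets the barrier height between the wells near x = ±1 and ``b``
    tilts them; a quadrature oracle supplies exact canonical statistics.
    """
    if not a > 0:
        raise InvalidParameterError(f"barrier scale a must be > 0, got {a!r}")
    b = float(b)

    def energy(x: np.ndarray) -> float:
        x0 = float(np.asarray(x, dtype=float)[0])
        return a * (x0 * x0 - 1.0) ** 2 + b * x0

    def gradient(x: np.ndarray) -> np.ndarray:
        x0 = float(np.asarray(x, dtype=float)[0])
        return np.array([4.0 * a * x0 * (x0 * x0 - 1.0) + b])

    def energy_batch(xs: np.ndarray) -> np.ndarray:
        x0 = np.asarray(xs, dtype=float)[:, 0]
        return a * (x0 * x0 - 1.0) ** 2 + b * x0

    def gradient_batch(xs: np.ndarray) -> np.ndarray:
        x0 = np.asarray(xs, dtype=float)[:, 0]
        return (4.0 * a * x0 * (x0 * x0 - 1.0) + b)[:, None]

    model = PotentialModel(
        name=f"double_well(a={a},b={b})",
        dim=1,
        energy=energy,
        gradient=gradient,
        domain=None,
        energy_batch=energy_batch,
        gradient_batch=gradient_batch,
        meta={"a": float(a), "b": b},
    )
    model.oracle = QuadratureOracle1D(model)
    return model


# Torsion-chain geometry: the helical dihedral value and the half-width of
# the angular window counted as "helical" by the geometric predicate.
THETA_HELIX = np.deg2rad(50.0)
HELIX_WINDOW = np.deg2rad(40.0)


def make_chain_model(
    n_beads: int,
    helix_bias: float | Sequence[float] = 1.0,
    barrier: float = 2.0,
    coupling: float = 0.5,
) -> PotentialModel:
    """Helix-coil chain of beads described by its backbone dihedrals.

    A chain of ``n_beads`` beads with rigid bonds has ``n_beads - 3``
    dihedral angles; each dihedral sees a periodic double well with minima
    at the helical angle (+50 deg) and the extended angle (+50+180 deg),
    separated by ``barrier``.  ``helix_bias`` (scalar or per-dihedral)
    deepens the helical minimum, emulating a nascent per-residue helix
    propensity; ``coupling`` is a short-range attraction between adjacent
    dihedrals that rewards locally uniform (cooperative) conformations.
    With zero bias the helical and extended minima are exactly degenerate.

    The model exposes ``meta['is_helical']``, a per-dihedral geometric
    predicate used for planted-truth tests, and a transfer-matrix oracle.
    """
    if not (isinstance(n_beads, (int, np.integer)) and n_beads >= 4):
        raise InvalidParameterError(f"n_beads must be an integer >= 4, got {n_beads!r}")
    n_dih = int(n_beads) - 3
    bias = np.broadcast_to(np.asarray(helix_bias, dtype=float), (n_dih,)).copy()
    B, J = float(barrier), float(coupling)

    def site_energy(theta, i):
        d = theta - THETA_HELIX
        return 0.5 * B * (1.0 - np.cos(2.0 * d)) - 0.5 * bias[i] * (1.0 + np.cos(d))

    def bond_energy(t1, t2):
        return 0.5 * J * (1.0 - np.cos(t1 - t2))

    def energy(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        e = sum(float(site_energy(x[i], i)) for i in range(n_dih))
        e += float(np.sum(bond_energy(x[:-1], x[1:])))
        return e

    def gradient(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = x - THETA_HELIX
        g = B * np.sin(2.0 * d) + 0.5 * bias * np.sin(d)
        diff = x[:-1] - x[1:]
        g[:-1] += 0.5 * J * np.sin(diff)
        g[1:] -= 0.5 * J * np.sin(diff)
        return g

    def energy_batch(xs: np.ndarray) -> np.ndarray:
        xs = np.asarray(xs, dtype=float)
        d = xs - THETA_HELIX
        e = np.sum(0.5 * B * (1.0 - np.cos(2.0 * d)) - 0.5 * bias * (1.0 + np.cos(d)), axis=1)
        e += np.sum(0.5 * J * (1.0 - np.cos(xs[:, :-1] - xs[:, 1:])), axis=1)
        return e

    def gradient_batch(xs: np.ndarray) -> np.ndarray:
        xs = np.asarray(xs, dtype=float)
        d = xs - THETA_HELIX
        g = B * np.sin(2.0 * d) + 0.5 * bias * np.sin(d)
        diff = xs[:, :-1] - xs[:, 1:]
        g[:, :-1] += 0.5 * J * np.sin(diff)
        g[:, 1:] -= 0.5 * J * np.sin(diff)
        return g

    def is_helical(x: np.ndarray) -> np.ndarray:
        d = np.mod(np.asarray(x, dtype=float) - THETA_HELIX + np.pi, 2 * np.pi) - np.pi
        return np.abs(d) < HELIX_WINDOW

    def is_helical_angle(theta: np.ndarray) -> np.ndarray:
        d = np.mod(theta - THETA_HELIX + np.pi, 2 * np.pi) - np.pi
        return (np.abs(d) < HELIX_WINDOW).astype(float)

    model = PotentialModel(
        name=f"chain(n_beads={n_beads})",
        dim=n_dih,
        energy=energy,
        gradient=gradient,
        domain=None,  # periodic in each dihedral
        energy_batch=energy_batch,
        gradient_batch=gradient_batch,
        meta={
            "n_beads": int(n_beads),
            "helix_bias": bias,
            "barrier": B,
            "coupling": J,
            "is_helical": is_helical,
            "is_helical_angle": is_helical_angle,
            "site_energy": lambda theta, i: site_energy(theta, i),
            "bond_energy": bond_energy,
        },
    )
    model.oracle = ChainTransferOracle(model)
    return model


def mix_energies(model_a: PotentialModel, model_b: PotentialModel, omega: float) -> PotentialModel:
    """Linear mixture ``E = (1 - omega) E_a + omega E_b`` of two potentials.

    Mirrors hybrid force-field construction where two parameterisations of
    the same system are blended by a mixing rate; the gradients mix with
    the same coefficients.
    """
    if not (0.0 <= omega <= 1.0):
        raise InvalidParameterError(f"omega must lie in [0, 1], got {omega!r}")
    if model_a.dim != model_b.dim:
        raise IncompatibleModelsError(
            f"cannot mix models of dim {model_a.dim} and {model_b.dim}"
        )
    if model_a.domain != model_b.domain:
        raise IncompatibleModelsError("cannot mix models with different domains")
    w_a, w_b = 1.0 - omega, omega

    def energy(x):
        return w_a * model_a.energy(x) + w_b * model_b.energy(x)

    def gradient(x):
        return w_a * model_a.gradient(x) + w_b * model_b.gradient(x)

    energy_batch = None
    if model_a.energy_batch is not None and model_b.energy_batch is not None:
        def energy_batch(xs):
            return w_a * model_a.energy_batch(xs) + w_b * model_b.energy_batch(xs)

    gradient_batch = None
    if model_a.gradient_batch is not None and model_b.gradient_batch is not None:
        def gradient_batch(xs):
            return w_a * model_a.gradient_batch(xs) + w_b * model_b.gradient_batch(xs)

    return PotentialModel(
        name=f"mix({model_a.name},{model_b.name},omega={omega})",
        dim=model_a.dim,
        energy=energy,
        gradient=gradient,
        domain=model_a.domain,
        energy_batch=energy_batch,
        gradient_batch=gradient_batch,
        meta={"omega": float(omega)},
    )


def canonical_oracle_eval(
    oracle: CanonicalOracle,
    T: float,
    quantity: str,
    observable: Callable | None = None,
    E: np.ndarray | None = None,
):
    """Evaluate an exact canonical quantity at temperature T.

    ``quantity`` is one of ``mean_E``, ``var_E``, ``pdf_E`` (requires
    ``E``), or ``expectation`` (requires a configuration-space
    ``observable``; quadrature oracles only).
    """
    if quantity == "mean_E":
        return oracle.mean_E(T)
    if quantity == "var_E":
        return oracle.var_E(T)
    if quantity == "pdf_E":
        if E is None:
            raise InvalidParameterError("pdf_E requires the E grid argument")
        return oracle.pdf_E(T, E)
    if quantity == "expectation":
        if observable is None:
            raise InvalidParameterError("expectation requires an observable")
        return oracle.expect(T, observable)
    raise InvalidParameterError(f"unknown oracle quantity {quantity!r}")
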