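"""Target densities and observables.

All targets are Gibbs distributions π(x) ∝ exp(−β V(x)) for a smooth
confining potential V and inverse temperature β, on either Euclidean
space or a flat torus.  Built-in targets carry analytic gradients; a
central-finite-difference checker is provided to validate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "TargetDensity",
    "Observable",
    "DimerParams",
    "make_gaussian",
    "make_warped_gaussian",
    "make_periodic",
    "make_dimer",
    "reaction_coordinate",
    "make_observable",
    "make_observable_quadratic",
    "check_gradient",
    "write_xyz",
    "read_xyz",
]


@dataclass
class TargetDensity:
    """Unnormalised Gibbs target π ∝ exp(−β V).

    ``potential`` and ``grad_potential`` operate on arrays whose last axis
    has length ``dim``; built-in targets are fully vectorised over leading
    axes (the dimer target accepts single configurations only).

    Parameters
    ----------
    dim : int
        Dimension of the state space.
    potential : callable
        V(x), defined up to an additive constant.
    grad_potential : callable
        ∇V(x).
    beta : float
        Inverse temperature; folded into the reversible drift as
        ∇log π = −β ∇V.
    domain : {"euclidean", "torus"}
    period : float or None
        Side length L of the torus per coordinate (torus domains only).
    """

    dim: int
    potential: Callable[[np.ndarray], np.ndarray]
    grad_potential: Callable[[np.ndarray], np.ndarray]
    beta: float = 1.0
    domain: str = "euclidean"
    period: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.domain not in ("euclidean", "torus"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.domain == "torus" and (self.period is None or self.period <= 0):
            raise ValueError("torus domain requires a positive period")

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """log π(x) up to an additive constant (= −β V(x))."""
        return -self.beta * self.potential(np.asarray(x, dtype=float))

    def grad_log_density(self, x: np.ndarray) -> np.ndarray:
        """∇log π(x) = −β ∇V(x)."""
        return -self.beta * self.grad_potential(np.asarray(x, dtype=float))

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Map coordinates into the fundamental cell [0, L)^dim."""
        if self.domain == "torus":
            return np.mod(x, self.period)
        return x


@dataclass
class Observable:
    """Scalar observable f whose expectation π(f) is estimated."""

    name: str
    eval: Callable[[np.ndarray], np.ndarray]
    known_mean: Optional[float] = None

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.eval(np.asarray(x, dtype=float))


@dataclass
class DimerParams:
    """Parameters of the dimer-in-WCA-solvent model.

    N particles in a periodic 2-D box of side L: particles 1 and 2 form a
    dimer bonded by a double-well potential with barrier height h and well
    half-separation w; all other pairs (excluding the dimer pair itself)
    interact through the purely repulsive WCA potential with parameters
    (epsilon, sigma).  The WCA cutoff r0 = 2^{1/6} σ is derived, never
    stored.
    """

    n_particles: int = 16
    box_length: float = 5.0
    epsilon: float = 1.0
    sigma: float = 1.0
    h: float = 1.0
    w: float = 0.5
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("dimer model needs at least 2 particles")
        if min(self.box_length, self.epsilon, self.sigma, self.h) <= 0:
            raise ValueError("box_length, epsilon, sigma, h must be positive")
        if self.w <= 0:
            # w = 0 makes the double well and the reaction coordinate singular
            raise ValueError("w must be strictly positive")

    @property
    def r0(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma


# ---------------------------------------------------------------------------
# Built-in targets
# ---------------------------------------------------------------------------


def make_gaussian(dim: int) -> TargetDensity:
    """Standard Gaussian target π(x) ∝ exp(−|x|²/2)."""
    if dim < 1:
        raise ValueError(f"dim must be >= 1, got {dim}")

    def potential(x: np.ndarray) -> np.ndarray:
        return 0.5 * np.sum(x * x, axis=-1)

    def grad(x: np.ndarray) -> np.ndarray:
        return np.array(x, dtype=float, copy=True)

    return TargetDensity(dim=dim, potential=potential, grad_potential=grad,
                         beta=1.0, name=f"gaussian{dim}d")


def make_warped_gaussian(b: float = 0.05) -> TargetDensity:
    """2-D warped ("banana") Gaussian, V(x) = x₁²/100 + (x₂ + b x₁² − 100 b)².

    The mass concentrates along the parabola x₂ = 100 b − b x₁²; the
    warping strength b > 0 controls the curvature.
    """
    if b <= 0:
        raise ValueError(f"b must be positive, got {b}")

    def potential(x: np.ndarray) -> np.ndarray:
        x1, x2 = x[..., 0], x[..., 1]
        u = x2 + b * x1 * x1 - 100.0 * b
        return x1 * x1 / 100.0 + u * u

    def grad(x: np.ndarray) -> np.ndarray:
        x1, x2 = x[..., 0], x[..., 1]
        u = x2 + b * x1 * x1 - 100.0 * b
        g = np.empty_like(np.asarray(x, dtype=float))
        g[..., 0] = 2.0 * x1 / 100.0 + 4.0 * b * x1 * u
        g[..., 1] = 2.0 * u
        return g

    return TargetDensity(dim=2, potential=potential, grad_potential=grad,
                         beta=1.0, name="warped_gaussian")


def make_periodic(beta: float = 10.0) -> TargetDensity:
    """2-D periodic target on the unit torus, V(x) = sin(2πx₁) cos(2πx₂)."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    tau = 2.0 * np.pi

    def potential(x: np.ndarray) -> np.ndarray:
        return np.sin(tau * x[..., 0]) * np.cos(tau * x[..., 1])

    def grad(x: np.ndarray) -> np.ndarray:
        x1, x2 = x[..., 0], x[..., 1]
        g = np.empty_like(np.asarray(x, dtype=float))
        g[..., 0] = tau * np.cos(tau * x1) * np.cos(tau * x2)
        g[..., 1] = -tau * np.sin(tau * x1) * np.sin(tau * x2)
        return g

    return TargetDensity(dim=2, potential=potential, grad_potential=grad,
                         beta=beta, domain="torus", period=1.0,
                         name="periodic2d")


# ---------------------------------------------------------------------------
# Dimer in WCA solvent
# ---------------------------------------------------------------------------


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def _wca(r: np.ndarray, eps: float, sig: float, r0: float):
    """WCA potential and dV/dr, truncated (and shifted by ε) at r0."""
    inside = r <= r0
    sr6 = (sig / r) ** 6
    v = np.where(inside, 4.0 * eps * (sr6 * sr6 - sr6) + eps, 0.0)
    dv = np.where(inside, 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r, 0.0)
    return v, dv


def _double_well(r: float, h: float, w: float, r0: float):
    u = 1.0 - (r - r0 - w) ** 2 / w**2
    v = h * u * u
    dv = -4.0 * h * u * (r - r0 - w) / w**2
    return v, dv


def make_dimer(params: DimerParams) -> TargetDensity:
    """Dimer pair in a WCA solvent inside a periodic 2-D box.

    The state is the flattened configuration q ∈ R^{2N} (particle i at
    q[2i:2i+2]); all distances use the minimum-image convention.  Total
    energy: double well between particles 1–2 plus WCA over solvent–solvent
    and dimer–solvent pairs.  Exactly overlapping particles (r = 0) raise
    ValueError so samplers can flag divergence deterministically instead of
    propagating infinities.
    """
    N, L, r0 = params.n_particles, params.box_length, params.r0
    eps, sig, h, w = params.epsilon, params.sigma, params.h, params.w
    iu, ju = np.triu_indices(N, k=1)
    # drop the dimer pair (0,1) from the WCA pair list
    keep = ~((iu == 0) & (ju == 1))
    iu, ju = iu[keep], ju[keep]

    def _pair_distances(q: np.ndarray):
        pos = q.reshape(N, 2)
        d = _min_image(pos[iu] - pos[ju], L)
        r = np.hypot(d[:, 0], d[:, 1])
        db = _min_image(pos[0] - pos[1], L)
        rb = np.hypot(db[0], db[1])
        if rb == 0.0 or np.any(r == 0.0):
            raise ValueError("overlapping particles (zero separation)")
        return pos, d, r, db, rb

    def potential(q: np.ndarray) -> float:
        _, _, r, _, rb = _pair_distances(q)
        vs, _ = _double_well(rb, h, w, r0)
        vw, _ = _wca(r, eps, sig, r0)
        return float(vs + vw.sum())

    def grad(q: np.ndarray) -> np.ndarray:
        pos, d, r, db, rb = _pair_distances(q)
        g = np.zeros_like(pos)
        _, dvw = _wca(r, eps, sig, r0)
        f = (dvw / r)[:, None] * d          # ∂V/∂q_i for pair (i, j)
        np.add.at(g, iu, f)
        np.add.at(g, ju, -f)
        _, dvs = _double_well(rb, h, w, r0)
        fb = dvs / rb * db
        g[0] += fb
        g[1] -= fb
        return g.ravel()

    return TargetDensity(dim=2 * N, potential=potential, grad_potential=grad,
                         beta=params.beta, domain="torus", period=L,
                         name=f"dimer{N}")


def reaction_coordinate(q: np.ndarray, params: DimerParams) -> float:
    """Dimer reaction coordinate ξ(q) = (|q₁−q₂| − r0) / (2w).

    ξ = 0 in the compact state, ξ = 1 in the stretched state.
    """
    q = np.asarray(q, dtype=float)
    d = _min_image(q[0:2] - q[2:4], params.box_length)
    return float((np.hypot(d[0], d[1]) - params.r0) / (2.0 * params.w))


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------


def make_observable(name: str, fn: Callable[[np.ndarray], np.ndarray],
                    known_mean: Optional[float] = None) -> Observable:
    return Observable(name=name, eval=fn, known_mean=known_mean)


def make_observable_quadratic(M: np.ndarray,
                              l: Optional[np.ndarray] = None,
                              k: Optional[float] = None) -> Observable:
    """Quadratic observable f(x) = x·Mx + l·x + k (M symmetric).

    With ``k=None`` the constant is set to −Tr M, which centres f under a
    standard Gaussian target (E[x·Mx] = Tr M).  ``known_mean`` is filled
    with the standard-Gaussian moment Tr M + k; ignore it for other
    targets.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("M must be a square matrix")
    if not np.allclose(M, M.T, atol=1e-12):
        raise ValueError("M must be symmetric")
    d = M.shape[0]
    lv = np.zeros(d) if l is None else np.asarray(l, dtype=float)
    if lv.shape != (d,):
        raise ValueError("l has incompatible shape")
    kc = float(-np.trace(M)) if k is None else float(k)

    def fn(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.einsum("...i,ij,...j->...", x, M, x) + x @ lv + kc

    return Observable(name="quadratic", eval=fn,
                      known_mean=float(np.trace(M)) + kc)


# ---------------------------------------------------------------------------
# Validation and IO helpers
# ---------------------------------------------------------------------------


def check_gradient(target: TargetDensity, x: np.ndarray,
                   h: float = 1e-5) -> float:
    """Max abs error between analytic ∇V and central finite differences."""
    x = np.asarray(x, dtype=float)
    g = target.grad_potential(x)
    num = np.empty_like(x)
    for i in range(target.dim):
        e = np.zeros_like(x)
        e[i] = h
        num[i] = (target.potential(x + e) - target.potential(x - e)) / (2 * h)
    return float(np.max(np.abs(g - num)))


def write_xyz(path, q: np.ndarray, params: DimerParams,
              comment: str = "") -> None:
    """Write a dimer configuration in XYZ format (tags D = dimer, S = solvent)."""
    pos = np.asarray(q, dtype=float).reshape(params.n_particles, 2)
    with open(path, "w") as fh:
        fh.write(f"{params.n_particles}\n{comment}\n")
        for i, (x, y) in enumerate(pos):
            tag = "D" if i < 2 else "S"
            fh.write(f"{tag} {x:.12g} {y:.12g} 0.0\n")


def read_xyz(path) -> np.ndarray:
    """Read a configuration written by :func:`write_xyz` (flattened 2-D)."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        rows = [fh.readline().split() for _ in range(n)]
    return np.array([[float(r[1]), float(r[2])] for r in rows]).ravel()
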