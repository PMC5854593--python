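"""Finite-horizon minimum-energy control and input-matrix optimization.

For the linear dynamics ``x'(t) = A x(t) + B u(t)`` on the horizon
``[0, t_f]`` the controllability Gramian

    W_B = int_0^{t_f} e^{At} B B^T e^{A^T t} dt

governs how much input energy is needed: the control

    u(t) = -B^T e^{A^T (t_f - t)} W_B^{-1} e^{A t_f} x_0

drives the state to the origin with the minimal cost
``x_0^T e^{A^T t_f} W_B^{-1} e^{A t_f} x_0``.  Averaging over random
initial states with second moment ``Sigma_0`` gives the expected cost

    E(B) = tr( W_B^{-1} e^{A t_f} Sigma_0 e^{A^T t_f} ).

Treating the input matrix B as the decision variable (columns constrained
to be orthonormal, ``B^T B = I_M``) turns minimum-energy control into a
non-convex matrix optimization.  :func:`opgm` solves it with a projected
gradient iteration on the Stiefel manifold:

    B_hat = B - eta (I - B B^T) dE/dB,
    B    <- sqrt( tr(B_hat^T B_hat) / tr((B_hat^T B_hat)^2) ) * B_hat,

where the rescaling step enforces ``tr((B^T B)^2) = tr(B^T B)`` exactly
(for orthonormal columns both traces equal M).  Direct matrix calculus of
E(B) gives

    dE/dB = -2 [ int_0^{t_f} e^{A^T t} W_B^{-1} e^{A t_f} Sigma_0
                 e^{A^T t_f} W_B^{-1} e^{A t} dt ] B,

a negative-semidefinite multiple of B: enlarging B in the integral's
leading directions always lowers the cost, which is exactly why the
orthonormality constraint (and its rescaling projection) is needed.  The
iteration steps along ``-dE/dB`` so the cost decreases for small eta; the
analytic gradient is validated against finite differences in the tests.

All matrix integrals use the Van Loan block-exponential construction.  For
severely ill-conditioned Gramians (long unbroken control paths push
``cond(W_B)`` beyond double precision — the numerical controllability
transition) an arbitrary-precision backend evaluates the cost with mpmath.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np
import pandas as pd
from scipy.integrate import quad, solve_ivp
from scipy.linalg import cho_factor, cho_solve, expm, qr

from .graph_core import DirectedNetwork

__all__ = [
    "LTISystem",
    "OPGMConfig",
    "OPGMResult",
    "MinimumEnergyControl",
    "ControllabilityError",
    "ControllabilityWarning",
    "gramian",
    "min_energy_control",
    "expected_cost",
    "grad_cost",
    "opgm",
    "cost_vs_longest_path",
]

#: condition number of W_B beyond which double-precision costs are not trusted
COND_LIMIT = 1e12


class ControllabilityError(RuntimeError):
    """The Gramian is singular to working precision: (A, B) cannot be
    steered numerically with the given inputs."""


class ControllabilityWarning(UserWarning):
    """The Gramian is severely ill-conditioned (numerical controllability
    transition); results may lose most significant digits."""


@dataclass
class LTISystem:
    """Linear time-invariant system ``x' = A x + B u`` on ``[0, t_f]``.

    ``A`` follows the package adjacency convention (edge i -> j stored at
    row j, column i).  ``sigma0`` is the second moment of the random
    initial state; the default None means the identity, i.e. i.i.d. zero
    mean, unit variance initial components.
    """

    A: np.ndarray
    t_f: float = 1.0
    sigma0: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if not (np.isfinite(self.t_f) and self.t_f > 0):
            raise ValueError("t_f must be finite and positive")
        if self.sigma0 is not None:
            self.sigma0 = np.asarray(self.sigma0, dtype=float)
            if self.sigma0.shape != self.A.shape:
                raise ValueError("sigma0 must be N x N")
            if not np.allclose(self.sigma0, self.sigma0.T):
                raise ValueError("sigma0 must be symmetric")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @classmethod
    def from_network(cls, net: DirectedNetwork, t_f: float = 1.0) -> "LTISystem":
        return cls(net.adjacency_matrix(), t_f=t_f)

    def _sigma0(self) -> np.ndarray:
        return np.eye(self.n) if self.sigma0 is None else self.sigma0


# -- matrix integrals ----------------------------------------------------


def _psd_integral(a: np.ndarray, q: np.ndarray, t_f: float) -> np.ndarray:
    """Van Loan construction of ``int_0^{t_f} e^{at} q e^{a^T t} dt``.

    expm of the block matrix [[-a, q], [0, a^T]] carries e^{-a t} H(t) in
    its upper-right block and e^{a^T t} in the lower-right, from which the
    integral H(t_f) is recovered.
    """
    n = a.shape[0]
    blk = np.zeros((2 * n, 2 * n))
    blk[:n, :n] = -a
    blk[:n, n:] = q
    blk[n:, n:] = a.T
    f = expm(blk * t_f)
    w = f[n:, n:].T @ f[:n, n:]
    return (w + w.T) / 2.0


def gramian(sys: LTISystem, b: np.ndarray) -> np.ndarray:
    """Controllability Gramian ``W_B`` over ``[0, t_f]`` (symmetric PSD)."""
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if b.shape[0] != sys.n:
        raise ValueError("B must have N rows")
    w = _psd_integral(sys.A, b @ b.T, sys.t_f)
    if not np.all(np.isfinite(w)):
        raise FloatingPointError("non-finite entries in the Gramian")
    _check_conditioning(w)
    return w


def _check_conditioning(w: np.ndarray) -> None:
    ev = np.linalg.eigvalsh(w)
    if ev[-1] <= 0:
        return
    if ev[0] <= 0 or ev[-1] / ev[0] > COND_LIMIT:
        warnings.warn(
            "Gramian condition number exceeds the double-precision trust "
            "limit; consider more control inputs or extended precision",
            ControllabilityWarning,
            stacklevel=3,
        )


def _solve_spd(w: np.ndarray, rhs: np.ndarray, clip: bool) -> np.ndarray:
    """W^{-1} rhs for symmetric PSD W; optionally regularize a numerically
    singular W by flooring its spectrum at eps * max eigenvalue."""
    try:
        return cho_solve(cho_factor(w), rhs)
    except np.linalg.LinAlgError:
        pass
    except ValueError:
        pass
    ev, vec = np.linalg.eigh(w)
    floor = ev[-1] * np.finfo(float).eps
    if ev[0] <= 0 and not clip:
        raise ControllabilityError(
            f"Gramian numerically singular (min eigenvalue {ev[0]:.3e}, "
            f"max {ev[-1]:.3e}): the system is not steerable with these inputs"
        )
    ev = np.maximum(ev, floor)
    return vec @ ((vec.T @ rhs) / ev[:, None])


# -- minimum-energy control ---------------------------------------------


@dataclass
class MinimumEnergyControl:
    """Closed-form minimum-energy control for one initial state."""

    sys: LTISystem
    B: np.ndarray
    x0: np.ndarray
    cost: float
    _y: np.ndarray = field(repr=False)  # W^{-1} e^{A t_f} x0

    def u(self, t: float) -> np.ndarray:
        """Input vector at time t."""
        return -self.B.T @ expm(self.sys.A.T * (self.sys.t_f - t)) @ self._y

    def simulate(self, rtol: float = 1e-10, atol: float = 1e-12):
        """Integrate the controlled dynamics; returns (times, states)."""
        a, b = self.sys.A, self.B
        sol = solve_ivp(
            lambda t, x: a @ x + b @ self.u(t),
            (0.0, self.sys.t_f),
            self.x0,
            rtol=rtol,
            atol=atol,
            dense_output=False,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return sol.t, sol.y.T

    def terminal_state(self, **kw) -> np.ndarray:
        _, xs = self.simulate(**kw)
        return xs[-1]

    def realized_cost(self) -> float:
        """Numerically integrate ||u(t)||^2 over the horizon."""
        val, _ = quad(
            lambda t: float(self.u(t) @ self.u(t)), 0.0, self.sys.t_f, limit=200
        )
        return val


def min_energy_control(sys: LTISystem, b: np.ndarray, x0) -> MinimumEnergyControl:
    """Closed-form input driving ``x0`` to the origin at minimal energy."""
    b = np.atleast_2d(np.asarray(b, dtype=float))
    x0 = np.asarray(x0, dtype=float).reshape(-1)
    if x0.size != sys.n:
        raise ValueError("x0 must have N components")
    w = gramian(sys, b)
    z = expm(sys.A * sys.t_f) @ x0
    y = _solve_spd(w, z[:, None], clip=False)[:, 0]
    cost = float(z @ y)
    return MinimumEnergyControl(sys=sys, B=b, x0=x0, cost=cost, _y=y)


def expected_cost(
    sys: LTISystem,
    b: np.ndarray,
    precision: int | None = None,
    clip_singular: bool = False,
) -> float:
    """Expected control cost ``E(B) = tr(W_B^{-1} e^{A t_f} Sigma_0 e^{A^T t_f})``.

    ``precision`` switches to an arbitrary-precision evaluation with that
    many significant digits (needed once the Gramian condition number
    exceeds ~1e12).  ``clip_singular`` floors a numerically singular
    spectrum instead of raising, which biases the cost but keeps method
    comparisons on an equal footing.
    """
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if precision is not None:
        return _expected_cost_mp(sys, b, precision)
    w = gramian(sys, b)
    e_tf = expm(sys.A * sys.t_f)
    c = e_tf @ sys._sigma0() @ e_tf.T
    return float(np.trace(_solve_spd(w, c, clip=clip_singular)))


def grad_cost(sys: LTISystem, b: np.ndarray) -> np.ndarray:
    """Analytic derivative dE/dB of the expected cost (N x M)."""
    b = np.atleast_2d(np.asarray(b, dtype=float))
    w = gramian(sys, b)
    e_tf = expm(sys.A * sys.t_f)
    c = e_tf @ sys._sigma0() @ e_tf.T
    k = _solve_spd(w, _solve_spd(w, c, clip=False).T, clip=False)
    k = (k + k.T) / 2.0
    s = _psd_integral(sys.A.T, k, sys.t_f)
    return -2.0 * s @ b


# -- OPGM ----------------------------------------------------------------


@dataclass
class OPGMConfig:
    """Settings for the projected gradient iteration.

    eta:        learning step (must be small enough for monotone descent).
    max_iters:  iteration cap.
    tol:        relative cost-change stopping threshold.
    init:       initial B (defaults to a random matrix with orthonormalized
                columns drawn from the seeded RNG).
    seed:       RNG seed for the default initialization.
    patience:   consecutive cost increases tolerated before declaring
                divergence.
    """

    eta: float = 1e-3
    max_iters: int = 500
    tol: float = 1e-10
    init: np.ndarray | None = None
    seed: int = 0
    patience: int = 25

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class OPGMResult:
    B: np.ndarray
    costs: np.ndarray  # cost trajectory E(B_k), k = 0 .. iterations
    iterations: int
    orthonormality_residual: float  # ||B^T B - I_M||_F


class OPGMDivergenceError(RuntimeError):
    pass


def opgm(sys: LTISystem, m: int, cfg: OPGMConfig | None = None) -> OPGMResult:
    """Minimize E(B) over N x M input matrices with orthonormal columns."""
    cfg = cfg or OPGMConfig()
    if not 1 <= m <= sys.n:
        raise ValueError("need 1 <= M <= N")
    if cfg.init is not None:
        b = np.asarray(cfg.init, dtype=float)
        if b.shape != (sys.n, m):
            raise ValueError(f"init must be {sys.n} x {m}")
        b = b.copy()
    else:
        rng = np.random.default_rng(cfg.seed)
        b, _ = qr(rng.standard_normal((sys.n, m)), mode="economic")

    e_tf = expm(sys.A * sys.t_f)
    c = e_tf @ sys._sigma0() @ e_tf.T
    eye = np.eye(sys.n)

    def cost_and_grad(bk):
        w = gramian(sys, bk)
        winv_c = _solve_spd(w, c, clip=False)
        cost = float(np.trace(winv_c))
        k = _solve_spd(w, winv_c.T, clip=False)
        s = _psd_integral(sys.A.T, (k + k.T) / 2.0, sys.t_f)
        return cost, -2.0 * s @ bk

    costs = []
    bad = 0
    it = 0
    for it in range(1, cfg.max_iters + 1):
        cost, grad = cost_and_grad(b)
        if not costs:
            costs.append(cost)
        b_hat = b - cfg.eta * (eye - b @ b.T) @ grad
        t = b_hat.T @ b_hat
        tr1 = np.trace(t)
        tr2 = np.trace(t @ t)
        if not (np.isfinite(tr1) and np.isfinite(tr2)) or tr1 <= 0 or tr2 <= 0:
            raise OPGMDivergenceError("iterate overflowed; retry with a smaller eta")
        scale = math.sqrt(tr1 / tr2)
        b = scale * b_hat
        new_cost = expected_cost(sys, b)
        costs.append(new_cost)
        if new_cost > cost * (1 + 1e-12):
            bad += 1
            if bad > cfg.patience:
                raise OPGMDivergenceError(
                    "cost increased repeatedly; retry with a smaller eta"
                )
        else:
            bad = 0
        if abs(new_cost - cost) <= cfg.tol * max(abs(cost), 1.0):
            break
    resid = float(np.linalg.norm(b.T @ b - np.eye(m)))
    return OPGMResult(
        B=b, costs=np.asarray(costs), iterations=it, orthonormality_residual=resid
    )


# -- extended-precision backend ------------------------------------------


def _mp_gl_nodes(q: int):
    """Gauss-Legendre nodes/weights on [0, 1] at the current mp precision.

    Newton iteration on the Legendre polynomial P_q, seeded with the
    Chebyshev approximation of its roots; standard and self-contained.
    """
    nodes, weights = [], []
    for i in range(1, q + 1):
        x = mp.cos(mp.pi * (i - mp.mpf(1) / 4) / (q + mp.mpf(1) / 2))
        for _ in range(60):
            p0, p1 = mp.mpf(1), x
            for k in range(2, q + 1):
                p0, p1 = p1, ((2 * k - 1) * x * p1 - (k - 1) * p0) / k
            dp = q * (x * p1 - p0) / (x * x - 1)
            dx = p1 / dp
            x -= dx
            if abs(dx) < mp.eps * 10:
                break
        p0, p1 = mp.mpf(1), x
        for k in range(2, q + 1):
            p0, p1 = p1, ((2 * k - 1) * x * p1 - (k - 1) * p0) / k
        dp = q * (x * p1 - p0) / (x * x - 1)
        w = 2 / ((1 - x * x) * dp * dp)
        nodes.append((x + 1) / 2)  # map [-1, 1] -> [0, 1]
        weights.append(w / 2)
    return nodes, weights


def _mp_sparse(a: np.ndarray):
    """Nonzero entries of A as (row, col, mpf) triples."""
    rows, cols = np.nonzero(a)
    return [(int(i), int(j), mp.mpf(float(a[i, j]))) for i, j in zip(rows, cols)]


def _mp_apply(entries, x, n, m):
    """y = A x for the sparse triple list, x an n x m list-of-rows."""
    y = [[mp.mpf(0)] * m for _ in range(n)]
    for i, j, w in entries:
        xj = x[j]
        yi = y[i]
        for c in range(m):
            yi[c] += w * xj[c]
    return y


def _mp_expm_times(entries, x, n, m, t, terms: int):
    """e^{A t} x via the truncated Taylor series (t scalar mpf)."""
    acc = [row[:] for row in x]
    term = [row[:] for row in x]
    for k in range(1, terms + 1):
        term = _mp_apply(entries, term, n, m)
        f = t / k
        for i in range(n):
            ti = term[i]
            ai = acc[i]
            for c in range(m):
                ti[c] *= f
                ai[c] += ti[c]
    return acc


def _expected_cost_mp(sys: LTISystem, b: np.ndarray, digits: int) -> float:
    """E(B) evaluated with ``digits`` significant digits.

    The Gramian integral is computed by Gauss-Legendre quadrature of
    (e^{At}B)(e^{At}B)^T with the exponential expanded as a truncated
    Taylor series; the node count matches the truncation order so the
    quadrature is exact for the truncated integrand.
    """
    n, m_cols = b.shape
    a = sys.A
    t_f = sys.t_f
    norm_a = float(np.linalg.norm(a, 1)) or 1.0
    # truncation: ||A t||^k / k! below the target absolute precision
    terms, bound = 1, norm_a * t_f
    log_target = -(digits + 25) * math.log(10.0)
    log_term = math.log(max(bound, 1e-30))
    while log_term > log_target and terms < 500:
        terms += 1
        log_term += math.log(max(bound, 1e-30)) - math.log(terms)
    with mp.workdps(digits + 15):
        entries = _mp_sparse(a)
        b_mp = [[mp.mpf(float(b[i, c])) for c in range(m_cols)] for i in range(n)]
        nodes, weights = _mp_gl_nodes(terms + 1)
        w_mat = mp.zeros(n, n)
        for x, wq in zip(nodes, weights):
            e_b = _mp_expm_times(entries, b_mp, n, m_cols, x * t_f, terms)
            for i in range(n):
                for j in range(i + 1):
                    s = mp.mpf(0)
                    for c in range(m_cols):
                        s += e_b[i][c] * e_b[j][c]
                    w_mat[i, j] += wq * t_f * s
        for i in range(n):
            for j in range(i):
                w_mat[j, i] = w_mat[i, j]
        ident = [[mp.mpf(1) if i == j else mp.mpf(0) for j in range(n)] for i in range(n)]
        e_tf = _mp_expm_times(entries, ident, n, n, mp.mpf(float(t_f)), terms)
        e_tf_mat = mp.matrix(e_tf)
        sig = sys._sigma0()
        if sys.sigma0 is None:
            c_mat = e_tf_mat * e_tf_mat.T
        else:
            c_mat = e_tf_mat * mp.matrix(sig.tolist()) * e_tf_mat.T
        w_inv = w_mat**-1
        prod = w_inv * c_mat
        cost = mp.mpf(0)
        for i in range(n):
            cost += prod[i, i]
        return float(cost)


# -- circle layout study -------------------------------------------------


def _longest_gap(positions, n: int) -> int:
    """Longest run of edges between cyclically consecutive control nodes."""
    pos = sorted(positions)
    if len(pos) == 1:
        return n
    gaps = [b - a for a, b in zip(pos, pos[1:])]
    gaps.append(pos[0] + n - pos[-1])
    return max(gaps)


def cost_vs_longest_path(
    circle_n: int,
    m: int,
    layouts=None,
    n_layouts: int = 20,
    t_f: float = 1.0,
    precision: str | int | None = "auto",
    seed: int = 0,
) -> pd.DataFrame:
    """Expected cost versus longest inter-input segment on a circle.

    Places ``m`` inputs on an ``circle_n``-node elementary circle in each
    layout (random distinct positions unless given), and records the
    expected control cost together with the longest number of edges
    between cyclically adjacent control nodes.  With ``precision="auto"``
    layouts whose Gramian is too ill-conditioned for double precision are
    transparently re-evaluated with enough extra digits; an int forces
    that digit count everywhere; None forces plain double precision.
    """
    from .mlcp import build_B
    from .netgen import make_circle

    net = make_circle(circle_n)
    sys = LTISystem(net.adjacency_matrix(), t_f=t_f)
    if layouts is None:
        rng = np.random.default_rng(seed)
        layouts = [
            sorted(rng.choice(circle_n, size=m, replace=False) + 1)
            for _ in range(n_layouts)
        ]
    rows = []
    for layout in layouts:
        layout = [int(p) for p in layout]
        b = build_B(net, [str(p) for p in layout])
        gap = _longest_gap(layout, circle_n)
        digits = None
        if isinstance(precision, int) and not isinstance(precision, bool):
            digits = precision
        elif precision == "auto" and _needs_extended(sys, b):
            digits = max(30, int(2 * math.lgamma(gap + 1) / math.log(10)) + 25)
        if digits is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ControllabilityWarning)
                cost = expected_cost(sys, b, clip_singular=True)
        else:
            cost = expected_cost(sys, b, precision=digits)
        rows.append(
            {
                "layout": tuple(layout),
                "longest_segment": gap,
                "cost": cost,
                "digits": digits if digits is not None else 0,
            }
        )
    return pd.DataFrame(rows)


def _needs_extended(sys: LTISystem, b: np.ndarray) -> bool:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ControllabilityWarning)
        w = _psd_integral(sys.A, b @ b.T, sys.t_f)
    ev = np.linalg.eigvalsh(w)
    return bool(ev[0] <= 0 or ev[-1] / ev[0] > COND_LIMIT)
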