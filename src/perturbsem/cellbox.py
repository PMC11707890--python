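"""Linear Cellbox: an ODE model of perturbation response and its exact
correspondence with causal structure regression.

The dynamics for condition ``i`` are

    dx_j/dt = tau_j * phi( sum_{k != j} w_jk x_k + u_j ) + w_jj x_j

with interaction matrix ``W`` (off-diagonal entries are interactions,
the diagonal is decay back to the unperturbed level), envelope ``phi``
and saturation ``tau``.  This module implements the linear variant —
``phi`` the identity and ``tau = 1`` — for which the right-hand side
collapses to ``W x + u`` and, whenever all eigenvalues of ``W`` have
negative real part, the steady state from ``x(0) = 0`` has the closed
form ``x* = -W^{-1} u``.

Identifying ``u = g(D) = B D`` makes the steady state equal to the SEM
mean response with ``A = W + I``: fitting linear Cellbox by penalized
least squares on steady states is a reparameterization of CSR, so the
fit here is performed through :class:`~perturbsem.estimators.
CausalStructureRegression` and mapped back via ``W = A_hat - I``.
No ODE solver is needed for fitting or prediction; the numerical
integrator is provided to witness the steady state and for
cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator, RegressorMixin

from .estimators import CausalStructureRegression, _check_matrix
from .sem import PerturbationDataset

__all__ = [
    "CellboxLinearModel",
    "SteadyStateReport",
    "ode_rhs",
    "steady_state_ode",
    "steady_state_closed",
    "CellboxLinear",
    "fit_cellbox_linear",
    "csr_to_cellbox",
    "cellbox_to_csr",
    "random_stable_w",
]

#: state-norm guard above which integration is declared divergent
DIVERGENCE_GUARD = 1e8


@dataclass
class CellboxLinearModel:
    """Interaction matrix ``W`` with identity envelope and ``tau = 1``.

    The constructor rejects any other envelope or saturation: the linear
    reduction (and its closed-form steady state) holds only for this
    configuration.
    """

    W: np.ndarray
    tau: np.ndarray | None = None
    envelope: str = "identity"
    stable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError(f"W must be square, got shape {self.W.shape}")
        p = self.W.shape[0]
        if self.tau is None:
            self.tau = np.ones(p)
        else:
            self.tau = np.asarray(self.tau, dtype=float)
            if self.tau.shape != (p,) or not np.allclose(self.tau, 1.0):
                raise ValueError("linear Cellbox requires tau = 1 for every response")
        if self.envelope != "identity":
            raise ValueError(
                f"linear Cellbox requires the identity envelope, got {self.envelope!r}"
            )
        self.stable = bool(np.all(np.linalg.eigvals(self.W).real < 0))

    @property
    def p(self) -> int:
        return self.W.shape[0]


@dataclass
class SteadyStateReport:
    converged: bool
    t_end: float
    residual: float  # ||dx/dt||_inf at the final state


def _check_u(model: CellboxLinearModel, u) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.shape != (model.p,):
        raise ValueError(f"u has shape {u.shape}, expected ({model.p},)")
    return u


def ode_rhs(model: CellboxLinearModel, x, u) -> np.ndarray:
    """Right-hand side ``W x + u`` of the linear Cellbox dynamics."""
    x = np.asarray(x, dtype=float)
    u = _check_u(model, u)
    if x.shape != (model.p,):
        raise ValueError(f"x has shape {x.shape}, expected ({model.p},)")
    return model.W @ x + u


def steady_state_ode(
    model: CellboxLinearModel,
    u,
    t_max: float = 200.0,
    tol: float = 1e-9,
    rtol: float | None = None,
    atol: float | None = None,
) -> tuple[np.ndarray, SteadyStateReport]:
    """Steady state by numerical integration from ``x(0) = 0``.

    Integrates with adaptive Runge-Kutta 4(5) until ``||dx/dt||_inf``
    drops below ``tol`` (reported as converged) or ``t_max`` is reached
    (reported as not converged).  The integrator's own error tolerances
    default to two decades below ``tol`` — the residual cannot settle
    below the integration error, so the settling test needs headroom.
    Raises on divergence (state norm exceeding the overflow guard),
    which occurs when ``W`` has an eigenvalue with nonnegative real
    part.
    """
    if rtol is None:
        rtol = max(tol * 1e-2, 1e-13)
    if atol is None:
        atol = max(tol * 1e-2, 1e-14)
    u = _check_u(model, u)
    if not model.stable:
        import warnings

        warnings.warn(
            "W has an eigenvalue with nonnegative real part; the ODE may "
            "not converge to a steady state",
            stacklevel=2,
        )

    W = model.W

    def rhs(t, x):
        return W @ x + u

    def settled(t, x):
        return float(np.max(np.abs(W @ x + u))) - tol

    settled.terminal = True
    settled.direction = -1

    def diverged(t, x):
        return float(np.max(np.abs(x))) - DIVERGENCE_GUARD

    diverged.terminal = True
    diverged.direction = 1

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        np.zeros(model.p),
        method="RK45",
        rtol=rtol,
        atol=atol,
        events=(settled, diverged),
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    if sol.t_events[1].size > 0:
        raise FloatingPointError(
            f"ODE state diverged past {DIVERGENCE_GUARD:.0e} at "
            f"t={sol.t_events[1][0]:.3g}; W is not a stable interaction matrix"
        )
    x_end = sol.y[:, -1]
    residual = float(np.max(np.abs(W @ x_end + u)))
    converged = sol.t_events[0].size > 0 or residual < tol
    return x_end, SteadyStateReport(
        converged=converged, t_end=float(sol.t[-1]), residual=residual
    )


def steady_state_closed(model: CellboxLinearModel, u) -> np.ndarray:
    """Closed-form steady state ``x* = -W^{-1} u``."""
    u = _check_u(model, u)
    s = np.linalg.svd(model.W, compute_uv=False)
    if s[-1] <= 1e-12 * s[0]:
        raise np.linalg.LinAlgError("W is singular; no unique steady state")
    return -np.linalg.solve(model.W, u)


class CellboxLinear(RegressorMixin, BaseEstimator):
    """Linear Cellbox fitted by its exact CSR reparameterization.

    Minimizes ``sum_i ||X_i - (-W^{-1}) B D_i||^2 +
    alpha ||W - diag(W)||_1`` over ``W`` by fitting CSR on the same data
    (closed form for ``alpha=0``, proximal otherwise) and setting
    ``W = A_hat - I``; the closed-form predictions are identical to the
    CSR predictions.  Parameters mirror
    :class:`~perturbsem.estimators.CausalStructureRegression`.

    Attributes
    ----------
    W_ : (p, p) ndarray — fitted interaction matrix.
    model_ : CellboxLinearModel — ``W_`` wrapped with the stability flag.
    csr_ : the underlying fitted CSR estimator.
    """

    def __init__(
        self,
        B=None,
        alpha: float = 0.0,
        mask=None,
        pd_mode: str = "real-eigenvalue",
        max_iter: int = 100_000,
        tol: float = 1e-8,
        seed: int = 0,
        drug_names=None,
        response_names=None,
    ):
        self.B = B
        self.alpha = alpha
        self.mask = mask
        self.pd_mode = pd_mode
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed
        self.drug_names = drug_names
        self.response_names = response_names

    def fit(self, D, X):
        csr = CausalStructureRegression(
            B=self.B,
            alpha=self.alpha,
            mask=self.mask,
            pd_mode=self.pd_mode,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
            drug_names=self.drug_names,
            response_names=self.response_names,
        ).fit(D, X)
        if csr.A_hat_ is None:
            raise np.linalg.LinAlgError(
                "fitted total-effect matrix is singular; no interaction "
                "matrix W corresponds to it"
            )
        self.csr_ = csr
        self.W_ = csr.A_hat_ - np.eye(csr.A_hat_.shape[0])
        self.model_ = CellboxLinearModel(W=self.W_)
        self.stable_ = self.model_.stable
        self.n_features_in_ = csr.n_features_in_
        self.n_outputs_ = csr.n_outputs_
        return self

    def predict(self, D, B=None) -> np.ndarray:
        """Steady-state predictions ``-W^{-1} B D_i`` (closed form)."""
        D = _check_matrix(D, "D")
        B_use = self.B if B is None else B
        B_use = _check_matrix(B_use, "B")
        if D.shape[1] != B_use.shape[1]:
            raise ValueError(
                f"D has {D.shape[1]} drug columns but B covers {B_use.shape[1]}"
            )
        U = D @ B_use.T
        return -np.linalg.solve(self.W_, U.T).T


def fit_cellbox_linear(
    data: PerturbationDataset, B, lam: float = 0.0, mask=None, seed: int = 0
) -> CellboxLinear:
    """Fit linear Cellbox on a dataset via the CSR reparameterization."""
    est = CellboxLinear(
        B=B,
        alpha=lam,
        mask=mask,
        seed=seed,
        drug_names=list(data.drug_names),
        response_names=list(data.response_names),
    )
    return est.fit(data.D, data.X)


def csr_to_cellbox(csr: CausalStructureRegression) -> CellboxLinearModel:
    """Map a fitted CSR model to the equivalent interaction matrix
    ``W = A_hat - I``."""
    if getattr(csr, "A_hat_", None) is None:
        raise np.linalg.LinAlgError(
            "CSR model has no invertible total-effect matrix; cannot map to W"
        )
    return CellboxLinearModel(W=csr.A_hat_ - np.eye(csr.A_hat_.shape[0]))


def cellbox_to_csr(cb: CellboxLinearModel) -> CausalStructureRegression:
    """Map an interaction matrix back to a CSR model with
    ``T = -W^{-1}`` and ``A_hat = W + I``."""
    p = cb.p
    s = np.linalg.svd(cb.W, compute_uv=False)
    if s[-1] <= 1e-12 * s[0]:
        raise np.linalg.LinAlgError("W is singular; T = -W^{-1} does not exist")
    csr = CausalStructureRegression()
    csr.T_ = -np.linalg.solve(cb.W, np.eye(p))
    csr.A_hat_ = cb.W + np.eye(p)
    csr.pd_report_ = {"mode": csr.pd_mode, "pd_ok": cb.stable}
    csr.n_features_in_ = None
    csr.n_outputs_ = p
    return csr


def random_stable_w(p: int, seed: int, margin: float = 0.5) -> np.ndarray:
    """A random interaction matrix whose eigenvalues all have real part
    below ``-margin``: a Gaussian matrix with its diagonal shifted left
    past its rightmost eigenvalue."""
    rng = np.random.default_rng(seed)
    M = rng.normal(0, 1.0 / np.sqrt(p), (p, p))
    shift = float(np.max(np.linalg.eigvals(M).real)) + margin
    return M - shift * np.eye(p)
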