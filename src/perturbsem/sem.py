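"""Linear structural equation model (SEM) for drug-perturbation experiments.

The model is

    X = A X + g(D) + eps,        g(D) = B D,

where ``X`` is a length-``p`` vector of responses (proteins, phenotypes),
``D`` a length-``q`` vector of drug concentrations, ``A`` the matrix of
direct causal effects among the responses (``A[j, k]`` is the effect of a
one-unit change of response ``k`` on response ``j``), ``B`` the matrix of
direct drug-on-response effects, and ``eps`` exogenous noise independent
of ``D``.  When ``I - A`` is invertible the mean response under an
intervention ``do(D)`` is ``(I - A)^{-1} B D``; the matrix
``T = (I - A)^{-1}`` collects the total (direct plus mediated) effects of
each response on each other response.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "CausalSEM",
    "PerturbationDataset",
    "SemValidityReport",
    "mean_response",
    "total_effect_matrix",
    "validate_sem",
    "positive_definite_verdict",
    "edge_list",
    "sem_to_yaml",
    "sem_from_yaml",
]

#: default lower bound on the reciprocal condition number of I - A
RCOND_MIN = 1e-12


def _as_matrix(M, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} must be a 2-d matrix, got ndim={M.ndim}")
    return M


@dataclass
class CausalSEM:
    """A linear causal SEM with known drug-target map ``g(D) = B D``.

    Parameters
    ----------
    A : (p, p) array
        Direct causal effects among responses; ``A[j, k]`` is the effect
        of response ``k`` on response ``j``.
    B : (p, q) array
        Direct effects of the ``q`` drugs on the ``p`` responses.
    noise_sd : float
        Standard deviation of each element of the exogenous error.
    response_names, drug_names : list of str, optional
        Default to ``X1..Xp`` / ``D1..Dq``.
    noise_cov : (p, p) array, optional
        Full noise covariance modelling hidden confounding among the
        responses; when given it overrides ``noise_sd`` in simulation.
    rcond_min : float
        Invertibility threshold on the reciprocal condition number of
        ``I - A``.
    """

    A: np.ndarray
    B: np.ndarray
    noise_sd: float = 0.0
    response_names: list[str] | None = None
    drug_names: list[str] | None = None
    noise_cov: np.ndarray | None = None
    rcond_min: float = RCOND_MIN

    def __post_init__(self) -> None:
        self.A = _as_matrix(self.A, "A")
        self.B = _as_matrix(self.B, "B")
        p, q = self.B.shape
        if self.A.shape != (p, p):
            raise ValueError(
                f"A must be square with side matching B's rows: "
                f"A is {self.A.shape}, B is {self.B.shape}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.response_names is None:
            self.response_names = [f"X{j + 1}" for j in range(p)]
        if self.drug_names is None:
            self.drug_names = [f"D{k + 1}" for k in range(q)]
        if len(self.response_names) != p:
            raise ValueError(
                f"expected {p} response names, got {len(self.response_names)}"
            )
        if len(self.drug_names) != q:
            raise ValueError(f"expected {q} drug names, got {len(self.drug_names)}")
        if self.noise_cov is not None:
            self.noise_cov = _as_matrix(self.noise_cov, "noise_cov")
            if self.noise_cov.shape != (p, p):
                raise ValueError(
                    f"noise_cov must be {p}x{p}, got {self.noise_cov.shape}"
                )
        rc = _rcond(np.eye(p) - self.A)
        if not rc > self.rcond_min:
            raise ValueError(
                f"I - A is numerically singular "
                f"(reciprocal condition number {rc:.2e} <= {self.rcond_min:.0e})"
            )

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def q(self) -> int:
        return self.B.shape[1]


@dataclass
class PerturbationDataset:
    """Paired drug-concentration matrix ``D`` (n x q) and response matrix
    ``X`` (n x p), one row per experimental condition."""

    D: np.ndarray
    X: np.ndarray
    drug_names: list[str]
    response_names: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.D = _as_matrix(self.D, "D")
        self.X = _as_matrix(self.X, "X")
        if self.D.shape[0] != self.X.shape[0]:
            raise ValueError(
                f"D and X must have the same number of rows: "
                f"{self.D.shape[0]} vs {self.X.shape[0]}"
            )
        if not (np.isfinite(self.D).all() and np.isfinite(self.X).all()):
            raise ValueError("dataset contains missing or non-finite values")
        if len(self.drug_names) != self.D.shape[1]:
            raise ValueError("drug_names length does not match D columns")
        if len(self.response_names) != self.X.shape[1]:
            raise ValueError("response_names length does not match X columns")
        if len(self.condition_ids) != self.D.shape[0]:
            raise ValueError("condition_ids length does not match row count")

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.D.shape[1]

    def subset(self, ids) -> "PerturbationDataset":
        """Return the sub-dataset for the given condition ids (order kept)."""
        index = {c: i for i, c in enumerate(self.condition_ids)}
        rows = [index[c] for c in ids]
        return PerturbationDataset(
            D=self.D[rows],
            X=self.X[rows],
            drug_names=list(self.drug_names),
            response_names=list(self.response_names),
            condition_ids=[self.condition_ids[i] for i in rows],
        )


def _rcond(M: np.ndarray) -> float:
    """Reciprocal condition number in the 2-norm (0 for exactly singular)."""
    s = np.linalg.svd(M, compute_uv=False)
    if s[0] == 0:
        return 0.0
    return float(s[-1] / s[0])


def mean_response(sem: CausalSEM, D) -> np.ndarray:
    """Mean response ``E[X | do(D)] = (I - A)^{-1} B D`` for one condition."""
    D = np.asarray(D, dtype=float)
    if D.shape != (sem.q,):
        raise ValueError(
            f"drug vector has length {D.shape[0] if D.ndim == 1 else D.shape}, "
            f"expected {sem.q}"
        )
    return np.linalg.solve(np.eye(sem.p) - sem.A, sem.B @ D)


def total_effect_matrix(sem: CausalSEM) -> np.ndarray:
    """Total-effect matrix ``T = (I - A)^{-1}``."""
    M = np.eye(sem.p) - sem.A
    rc = _rcond(M)
    if not rc > sem.rcond_min:
        raise np.linalg.LinAlgError(
            f"I - A is singular (reciprocal condition number {rc:.2e})"
        )
    return np.linalg.solve(M, np.eye(sem.p))


def positive_definite_verdict(M: np.ndarray, mode: str = "real-eigenvalue") -> bool:
    """Positive-definiteness verdict for a possibly non-symmetric matrix.

    ``"real-eigenvalue"``: all eigenvalues of ``M`` have positive real part
    (the stability condition for the ODE steady state).
    ``"symmetric-part"``: all eigenvalues of ``(M + M.T)/2`` are positive.
    """
    if mode == "real-eigenvalue":
        return bool(np.all(np.linalg.eigvals(M).real > 0))
    if mode == "symmetric-part":
        return bool(np.all(np.linalg.eigvalsh((M + M.T) / 2) > 0))
    raise ValueError(f"unknown pd mode {mode!r}")


@dataclass
class SemValidityReport:
    invertible: bool
    rcond: float
    pd_mode: str
    pd_ok: bool
    acyclic: bool


def _is_acyclic(A: np.ndarray) -> bool:
    """Whether the directed graph of nonzero entries of A (edge k -> j for
    A[j, k] != 0, self-loops included) is a DAG, i.e. A is permutable to a
    strictly triangular matrix."""
    g = nx.DiGraph()
    p = A.shape[0]
    g.add_nodes_from(range(p))
    rows, cols = np.nonzero(A)
    g.add_edges_from(zip(cols.tolist(), rows.tolist()))
    return nx.is_directed_acyclic_graph(g)


def validate_sem(sem: CausalSEM, pd_mode: str = "real-eigenvalue") -> SemValidityReport:
    """Structural validity report for a SEM: invertibility of ``I - A``,
    a positive-definiteness verdict under the chosen convention, and
    acyclicity of ``A``.  Reports, never raises."""
    M = np.eye(sem.p) - sem.A
    rc = _rcond(M)
    invertible = rc > sem.rcond_min
    pd_ok = invertible and positive_definite_verdict(M, pd_mode)
    return SemValidityReport(
        invertible=bool(invertible),
        rcond=rc,
        pd_mode=pd_mode,
        pd_ok=pd_ok,
        acyclic=_is_acyclic(sem.A),
    )


def edge_list(
    A: np.ndarray,
    names: list[str] | None = None,
    threshold: float = 0.2,
):
    """Off-diagonal entries of a structure matrix as (source, target, weight)
    rows, keeping entries with ``|weight| >= threshold``.

    Edge direction follows the causal reading: entry ``A[j, k]`` is the
    effect of ``k`` (source) on ``j`` (target).
    """
    import pandas as pd

    p = A.shape[0]
    if names is None:
        names = [f"X{j + 1}" for j in range(p)]
    rows = []
    for j in range(p):
        for k in range(p):
            if j != k and abs(A[j, k]) >= threshold:
                rows.append({"source": names[k], "target": names[j], "weight": A[j, k]})
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


# ---------------------------------------------------------------------------
# serialization

def sem_to_dict(sem: CausalSEM) -> dict:
    d = {
        "A": sem.A.tolist(),
        "B": sem.B.tolist(),
        "noise_sd": float(sem.noise_sd),
        "response_names": list(sem.response_names),
        "drug_names": list(sem.drug_names),
    }
    if sem.noise_cov is not None:
        d["noise_cov"] = sem.noise_cov.tolist()
    return d


def sem_from_dict(d: dict) -> CausalSEM:
    return CausalSEM(
        A=np.array(d["A"], dtype=float),
        B=np.array(d["B"], dtype=float),
        noise_sd=float(d["noise_sd"]),
        response_names=list(d["response_names"]),
        drug_names=list(d["drug_names"]),
        noise_cov=(np.array(d["noise_cov"], dtype=float) if "noise_cov" in d else None),
    )


def sem_to_yaml(sem: CausalSEM, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sem_to_dict(sem), fh, sort_keys=False)


def sem_from_yaml(path) -> CausalSEM:
    with open(path) as fh:
        return sem_from_dict(yaml.safe_load(fh))
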