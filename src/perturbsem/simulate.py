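"""Synthetic perturbation data generated from a causal SEM.

The built-in benchmark SEM has p = 5 responses and q = 15 drugs: drugs
1-5 each target a single response with strength 1 (B's first five columns
are the identity) and drugs 6-15 each target two responses with strength
0.5, the ten columns enumerating all C(5, 2) response pairs in
lexicographic order (1,2), (1,3), ..., (4,5).  Response 1 causally
affects response 2 with strength 1.6 and response 3 with strength 1.2;
response 3 affects response 4 with strength 2; all other direct effects
among responses are zero.  The exogenous error is N(0, 0.1^2) per
element.  The matching design applies every two-drug combination once,
so q = 15 gives n = C(15, 2) = 105 conditions.

Note: the lexicographic completion of the two-target columns is an
assumption of this module; recovery of A does not depend on which
pairing order is used as long as the design has full rank.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .sem import CausalSEM, PerturbationDataset

__all__ = [
    "DesignMatrix",
    "benchmark_sem",
    "all_pairs_design",
    "simulate",
    "misspecify_b",
    "random_dag_sem",
    "random_mixed_design",
]


@dataclass
class DesignMatrix:
    """Drug-concentration design: one row per planned condition."""

    D: np.ndarray
    drug_names: list[str]
    condition_ids: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("design D must be 2-d")
        if len(self.drug_names) != self.D.shape[1]:
            raise ValueError("drug_names length does not match D columns")
        if len(self.condition_ids) != self.D.shape[0]:
            raise ValueError("condition_ids length does not match D rows")

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def q(self) -> int:
        return self.D.shape[1]


def benchmark_sem() -> CausalSEM:
    """The 5-response / 15-drug benchmark SEM (see module docstring)."""
    p, q = 5, 15
    B = np.zeros((p, q))
    B[:, :p] = np.eye(p)
    for col, (j, k) in enumerate(itertools.combinations(range(p), 2), start=p):
        B[j, col] = 0.5
        B[k, col] = 0.5
    A = np.zeros((p, p))
    A[1, 0] = 1.6
    A[2, 0] = 1.2
    A[3, 2] = 2.0
    return CausalSEM(A=A, B=B, noise_sd=0.1)


def all_pairs_design(q: int, drug_names: list[str] | None = None) -> DesignMatrix:
    """Design applying every unordered pair of drugs once at unit
    concentration, pairs in lexicographic order (1,2), (1,3), ..., (q-1,q)."""
    if q < 2:
        raise ValueError(f"need at least 2 drugs for a pairs design, got q={q}")
    if drug_names is None:
        drug_names = [f"D{k + 1}" for k in range(q)]
    pairs = list(itertools.combinations(range(q), 2))
    D = np.zeros((len(pairs), q))
    ids = []
    for i, (a, b) in enumerate(pairs):
        D[i, a] = 1.0
        D[i, b] = 1.0
        ids.append(f"{drug_names[a]}+{drug_names[b]}")
    return DesignMatrix(D=D, drug_names=drug_names, condition_ids=ids)


def simulate(sem: CausalSEM, design: DesignMatrix, seed: int) -> PerturbationDataset:
    """Draw one dataset from the SEM under the given design.

    Noise is drawn at the structural level and propagated through the
    network: each row solves ``(I - A) X_i = B D_i + eps_i``, so the
    residual covariance is ``(I-A)^{-1} Sigma_eps (I-A)^{-T}``, not
    ``Sigma_eps``.
    """
    if design.q != sem.q:
        raise ValueError(
            f"design has {design.q} drug columns but the SEM expects {sem.q}"
        )
    rng = np.random.default_rng(seed)
    n, p = design.n, sem.p
    if sem.noise_cov is not None:
        eps = rng.multivariate_normal(np.zeros(p), sem.noise_cov, size=n)
    else:
        eps = rng.normal(0.0, sem.noise_sd, size=(n, p))
    rhs = design.D @ sem.B.T + eps            # rows: B D_i + eps_i
    X = np.linalg.solve(np.eye(p) - sem.A, rhs.T).T
    return PerturbationDataset(
        D=design.D.copy(),
        X=X,
        drug_names=list(design.drug_names),
        response_names=list(sem.response_names),
        condition_ids=list(design.condition_ids),
    )


def misspecify_b(B: np.ndarray) -> np.ndarray:
    """Corrupt a drug-target matrix by inflating every 0.5 entry to 1.

    This models the analyst over-stating the strength of two-target
    drugs while keeping the targets themselves correct.  The input is
    not mutated.
    """
    B = np.asarray(B, dtype=float)
    if not np.isin(B, (0.0, 0.5, 1.0)).all():
        warnings.warn(
            "misspecify_b expects entries in {0, 0.5, 1}; other values are "
            "passed through unchanged",
            stacklevel=2,
        )
    out = B.copy()
    out[out == 0.5] = 1.0
    return out


# ---------------------------------------------------------------------------
# generic random instances (for property tests and shape dry-runs)

def random_dag_sem(
    p: int,
    q: int,
    seed: int,
    edge_prob: float = 0.15,
    effect_scale: float = 0.5,
    targets_per_drug: int = 2,
    noise_sd: float = 0.1,
) -> CausalSEM:
    """A random acyclic SEM: A strictly lower-triangular with Bernoulli
    edges and N(0, effect_scale^2) weights; each drug directly targets
    ``targets_per_drug`` random responses with strength 1/targets."""
    rng = np.random.default_rng(seed)
    A = np.tril(rng.normal(0, effect_scale, (p, p)), k=-1)
    A *= rng.random((p, p)) < edge_prob
    B = np.zeros((p, q))
    for k in range(q):
        targets = rng.choice(p, size=min(targets_per_drug, p), replace=False)
        B[targets, k] = 1.0 / len(targets)
    return CausalSEM(A=A, B=B, noise_sd=noise_sd)


def random_mixed_design(
    n: int, q: int, seed: int, drug_names: list[str] | None = None
) -> DesignMatrix:
    """A design of ``n`` conditions each using one or two drugs at unit
    concentration, mimicking single-agent plus combination screens.

    The first drug of each condition cycles through the panel so every
    drug appears in at least ``floor(n / q)`` conditions, as a screen
    design would ensure; the optional second drug is uniform random.
    """
    rng = np.random.default_rng(seed)
    if drug_names is None:
        drug_names = [f"D{k + 1}" for k in range(q)]
    D = np.zeros((n, q))
    ids = []
    for i in range(n):
        drugs = [i % q]
        if rng.random() < 0.5:
            other = int(rng.integers(q - 1))
            drugs.append(other if other < drugs[0] else other + 1)
        D[i, drugs] = 1.0
        ids.append("+".join(drug_names[d] for d in sorted(drugs)) + f"#{i}")
    return DesignMatrix(D=D, drug_names=drug_names, condition_ids=ids)
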