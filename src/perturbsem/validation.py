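"""Train/test splitting, metrics, and the benchmark experiment drivers.

Two validation regimes for perturbation-response models:

* **Random-fold (RF)**: test conditions are a simple random sample of
  all conditions, so every drug appears in training.  Favors plain
  regression.
* **Leave-one-drug-out (LODO)**: all test conditions use a drug whose
  training concentration is identically zero — an extrapolation test
  that only causal models with known drug targets can pass.

Metrics follow the pooled-scatter convention: truth and prediction are
flattened over all (condition, response) cells before computing
Pearson's r and the mean absolute error; per-response correlations are
additionally reported where relevant.

All experiment drivers take a single master seed; per-repetition seeds
are spawned deterministically from it with ``numpy.random.SeedSequence``
so any single repetition is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import fit_csr, fit_lr, predict_csr, predict_lr
from .sem import PerturbationDataset, edge_list
from .simulate import all_pairs_design, benchmark_sem, misspecify_b, simulate

__all__ = [
    "SplitSpec",
    "EvalResult",
    "random_fold_split",
    "lodo_split_by_drug",
    "lodo_per_condition",
    "evaluate",
    "run_benchmark_experiment",
    "repeated_random_fold",
    "spawn_seeds",
]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class SplitSpec:
    """A train/test partition of condition identifiers."""

    train_ids: list
    test_ids: list
    kind: str = "random_fold"  # random_fold | lodo_by_drug | lodo_per_condition
    held_out_drug: str | None = None

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train and test sets overlap: {sorted(overlap)[:5]}")


@dataclass
class EvalResult:
    """Per-split metric records plus the long-format prediction table."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["estimator", "split", "pearson_r", "mae", "n_test"]
        )
    )
    predictions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["condition_id", "response", "truth", "prediction", "split", "estimator"]
        )
    )
    networks: dict = field(default_factory=dict)

    def add_record(self, estimator: str, split: str, r: float, mae: float, n_test: int):
        row = pd.DataFrame(
            [
                {
                    "estimator": estimator,
                    "split": split,
                    "pearson_r": r,
                    "mae": mae,
                    "n_test": n_test,
                }
            ]
        )
        self.records = (
            row if self.records.empty else pd.concat([self.records, row], ignore_index=True)
        )

    def add_predictions(
        self, estimator: str, split: str, condition_ids, response_names, truth, pred
    ):
        truth = np.asarray(truth)
        pred = np.asarray(pred)
        m, p = truth.shape
        tab = pd.DataFrame(
            {
                "condition_id": np.repeat(list(condition_ids), p),
                "response": np.tile(list(response_names), m),
                "truth": truth.ravel(),
                "prediction": pred.ravel(),
                "split": split,
                "estimator": estimator,
            }
        )
        self.predictions = (
            tab
            if self.predictions.empty
            else pd.concat([self.predictions, tab], ignore_index=True)
        )

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(outdir / "metrics.csv", index=False)
        self.predictions.to_csv(outdir / "predictions.csv", index=False)
        for name, edges in self.networks.items():
            edges.to_csv(outdir / f"network_{name}.csv", index=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def random_fold_split(ids, train_frac: float, seed: int) -> SplitSpec:
    """Uniform random partition with train size
    ``round(train_frac * n)`` (half rounds away from zero).

    ``ids`` may be a list of condition identifiers or an integer ``n``
    (identifiers then being ``0..n-1``).
    """
    if isinstance(ids, (int, np.integer)):
        ids = list(range(int(ids)))
    else:
        ids = list(ids)
    n = len(ids)
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    n_train = _round_half_away(train_frac * n)
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"degenerate split: n={n}, train_frac={train_frac} gives "
            f"train size {n_train}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return SplitSpec(train_ids=train, test_ids=test, kind="random_fold")


def lodo_split_by_drug(data: PerturbationDataset, drug: str) -> SplitSpec:
    """Leave-one-drug-out split: training conditions have zero
    concentration of ``drug``; test conditions use it."""
    if drug not in data.drug_names:
        raise ValueError(f"unknown drug {drug!r}")
    col = data.D[:, data.drug_names.index(drug)]
    used = col != 0
    if used.all():
        raise ValueError(f"drug {drug!r} is used in every condition; no training set")
    if not used.any():
        raise ValueError(f"drug {drug!r} is never used; no test set")
    train = [c for c, u in zip(data.condition_ids, used) if not u]
    test = [c for c, u in zip(data.condition_ids, used) if u]
    return SplitSpec(
        train_ids=train, test_ids=test, kind="lodo_by_drug", held_out_drug=drug
    )


def lodo_per_condition(
    data: PerturbationDataset, base_split: SplitSpec, seed: int
) -> list[dict]:
    """Per-condition LODO refit plan for a two-drugs-per-condition design.

    For each test condition of ``base_split``, one of its two active
    drugs is chosen uniformly at random (seeded); the returned training
    subset is the base training conditions in which that drug is unused.
    Each test condition therefore gets its own refit training set.
    """
    rng = np.random.default_rng(seed)
    index = {c: i for i, c in enumerate(data.condition_ids)}
    plans = []
    for cid in base_split.test_ids:
        row = data.D[index[cid]]
        active = np.nonzero(row)[0]
        if len(active) != 2:
            raise ValueError(
                f"condition {cid!r} has {len(active)} active drugs; "
                "per-condition LODO requires exactly two"
            )
        held = int(rng.choice(active))
        held_name = data.drug_names[held]
        train_ids = [
            t for t in base_split.train_ids if data.D[index[t], held] == 0
        ]
        plans.append(
            {
                "test_id": cid,
                "held_out_drug": held_name,
                "train_ids": train_ids,
            }
        )
    return plans


def evaluate(truth, pred) -> tuple[float, float]:
    """Pooled Pearson correlation and mean absolute error over all
    flattened (condition, response) cells."""
    truth = np.asarray(truth, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    if truth.size < 2:
        raise ValueError("need at least 2 entries to evaluate")
    if np.ptp(truth) == 0:
        raise ValueError("truth is constant; correlation undefined")
    mae = float(np.mean(np.abs(truth - pred)))
    if np.ptp(pred) == 0:
        # correlation with a constant prediction is undefined; report 0
        return 0.0, mae
    r = float(stats.pearsonr(truth, pred).statistic)
    return r, mae


def per_response_correlations(truth, pred, response_names) -> pd.Series:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    out = {}
    for j, name in enumerate(response_names):
        t, pr = truth[:, j], pred[:, j]
        if np.ptp(t) == 0 or np.ptp(pr) == 0:
            out[name] = np.nan
        else:
            out[name] = float(stats.pearsonr(t, pr).statistic)
    return pd.Series(out, name="pearson_r")


# ---------------------------------------------------------------------------
# the three-setting benchmark experiment

def run_benchmark_experiment(
    seed: int,
    noise_sd: float | None = None,
    train_frac: float = 2.0 / 3.0,
    lam: float = 0.0,
    edge_threshold: float = 0.2,
) -> EvalResult:
    """Run the full simulation comparison of LR and CSR.

    Generates one dataset from the built-in benchmark SEM and evaluates
    both estimators under three settings:

    * ``rf`` — random 2/3 train / 1/3 test split;
    * ``rf_misspecified_b`` — same split, but CSR is fitted and
      predicts with the corrupted drug-target matrix (two-target
      strengths inflated from 0.5 to 1).  LR ignores B, so its
      predictions are re-emitted unchanged;
    * ``lodo`` — per test condition, one of its two drugs is held out:
      both estimators are refitted on the training conditions not using
      that drug, LR with the held-out drug's coefficient forced to zero.

    Returns an :class:`EvalResult` with pooled metrics, the long-format
    prediction table, and estimated-network edge lists for the RF,
    misspecified-B and (one) LODO CSR fits.
    """
    sem = benchmark_sem()
    if noise_sd is not None:
        sem.noise_sd = noise_sd
    seeds = spawn_seeds(seed, 3)
    design = all_pairs_design(sem.q, drug_names=sem.drug_names)
    data = simulate(sem, design, seed=seeds[0])

    split = random_fold_split(data.condition_ids, train_frac, seed=seeds[1])
    train = data.subset(split.train_ids)
    test = data.subset(split.test_ids)
    result = EvalResult()
    result.networks["true"] = edge_list(
        sem.A, sem.response_names, threshold=edge_threshold
    )

    # --- RF
    lr = fit_lr(train, lam=lam)
    lr_pred = predict_lr(lr, test.D)
    r, mae = evaluate(test.X, lr_pred)
    result.add_record("lr", "rf", r, mae, test.n)
    result.add_predictions("lr", "rf", test.condition_ids, test.response_names, test.X, lr_pred)

    csr = fit_csr(train, sem.B, lam=lam)
    csr_pred = predict_csr(csr, sem.B, test.D)
    r, mae = evaluate(test.X, csr_pred)
    result.add_record("csr", "rf", r, mae, test.n)
    result.add_predictions("csr", "rf", test.condition_ids, test.response_names, test.X, csr_pred)
    result.networks["rf"] = edge_list(
        csr.A_hat_, sem.response_names, threshold=edge_threshold
    )

    # --- RF with misspecified B (LR is B-free: identical predictions)
    B_bad = misspecify_b(sem.B)
    result.add_record("lr", "rf_misspecified_b", *evaluate(test.X, lr_pred), test.n)
    result.add_predictions(
        "lr", "rf_misspecified_b", test.condition_ids, test.response_names, test.X, lr_pred
    )
    csr_bad = fit_csr(train, B_bad, lam=lam)
    csr_bad_pred = predict_csr(csr_bad, B_bad, test.D)
    r, mae = evaluate(test.X, csr_bad_pred)
    result.add_record("csr", "rf_misspecified_b", r, mae, test.n)
    result.add_predictions(
        "csr", "rf_misspecified_b", test.condition_ids, test.response_names, test.X, csr_bad_pred
    )
    result.networks["rf_misspecified_b"] = edge_list(
        csr_bad.A_hat_, sem.response_names, threshold=edge_threshold
    )

    # --- LODO: per-condition refits
    plans = lodo_per_condition(data, split, seed=seeds[2])
    truth_rows, lr_rows, csr_rows, cids = [], [], [], []
    lodo_net_recorded = False
    for plan in plans:
        sub = data.subset(plan["train_ids"])
        test_row = data.subset([plan["test_id"]])
        lr_l = fit_lr(sub, lam=lam, zeroed_drugs=[plan["held_out_drug"]])
        csr_l = fit_csr(sub, sem.B, lam=lam)
        lr_rows.append(predict_lr(lr_l, test_row.D)[0])
        csr_rows.append(predict_csr(csr_l, sem.B, test_row.D)[0])
        truth_rows.append(test_row.X[0])
        cids.append(plan["test_id"])
        if not lodo_net_recorded:
            result.networks["lodo"] = edge_list(
                csr_l.A_hat_, sem.response_names, threshold=edge_threshold
            )
            lodo_net_recorded = True
    truth = np.array(truth_rows)
    for tag, rows in (("lr", lr_rows), ("csr", csr_rows)):
        pred = np.array(rows)
        r, mae = evaluate(truth, pred)
        result.add_record(tag, "lodo", r, mae, len(cids))
        result.add_predictions(tag, "lodo", cids, data.response_names, truth, pred)

    return result


# ---------------------------------------------------------------------------
# repeated random-fold protocol with across-run averaging

def repeated_random_fold(
    data: PerturbationDataset,
    fit_predict,
    n_repeats: int,
    train_frac: float,
    seed: int,
) -> tuple[float, float, pd.DataFrame]:
    """Repeated random-fold validation with prediction averaging.

    Repeats the random split ``n_repeats`` times; for each repetition
    ``fit_predict(train_dataset, test_dataset) -> (m, p) array`` supplies
    test-set predictions.  For every (condition, response) cell the
    predictions are averaged across the runs in which the condition fell
    in the test set, and the pooled Pearson r and MAE of these averaged
    predictions against the truth are returned together with the
    averaged prediction table.
    """
    n, p = data.n, data.p
    sums = np.zeros((n, p))
    counts = np.zeros(n)
    seeds = spawn_seeds(seed, n_repeats)
    index = {c: i for i, c in enumerate(data.condition_ids)}
    for s in seeds:
        split = random_fold_split(data.condition_ids, train_frac, seed=s)
        train = data.subset(split.train_ids)
        test = data.subset(split.test_ids)
        pred = np.asarray(fit_predict(train, test))
        rows = [index[c] for c in split.test_ids]
        sums[rows] += pred
        counts[rows] += 1
    seen = counts > 0
    avg = sums[seen] / counts[seen, None]
    truth = data.X[seen]
    r, mae = evaluate(truth, avg)
    table = pd.DataFrame(
        {
            "condition_id": np.repeat(
                [c for c, ok in zip(data.condition_ids, seen) if ok], p
            ),
            "response": np.tile(list(data.response_names), int(seen.sum())),
            "truth": truth.ravel(),
            "prediction": avg.ravel(),
        }
    )
    return r, mae, table
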