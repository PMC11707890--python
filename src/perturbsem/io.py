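"""CSV and YAML input/output.

Conventions: comma-separated UTF-8 with a "." decimal point; the first
column holds condition/row identifiers and the first row holds names.
Datasets are stored as two CSVs, ``drugs.csv`` (condition_id + one
column per drug) and ``responses.csv`` (condition_id + one column per
response), with identical condition-id order.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .sem import PerturbationDataset

__all__ = [
    "read_matrix_csv",
    "write_matrix_csv",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
]


def read_matrix_csv(path) -> pd.DataFrame:
    """Read a named numeric matrix: header row, first column = row ids.

    Raises ``ValueError`` naming the offending cell (row label, column,
    1-based file line) for missing or non-numeric cells, and for
    duplicate row or column names; ragged rows surface the parser error
    with the path prepended.
    """
    path = pathlib.Path(path)
    # pandas silently renames duplicate header fields; check them raw
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    dups = [n for i, n in enumerate(header[1:]) if n in header[1 : 1 + i]]
    if dups:
        raise ValueError(f"{path}: duplicate column names {sorted(set(dups))}")
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row names {dups}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            line = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise ValueError(
                f"{path}: non-numeric value {df.loc[row, col]!r} in cell "
                f"(row {row!r}, column {col!r}, line {line})"
            )
        df[col] = converted
    if df.isna().any().any():
        mask = df.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"{path}: missing value in cell (row {df.index[i]!r}, "
            f"column {df.columns[j]!r}, line {int(i) + 2})"
        )
    return df


def write_matrix_csv(path, values, row_names, col_names, index_label: str = "id") -> None:
    df = pd.DataFrame(np.asarray(values), index=list(row_names), columns=list(col_names))
    df.to_csv(path, index_label=index_label)


def save_dataset(data: PerturbationDataset, outdir) -> None:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(
        outdir / "drugs.csv", data.D, data.condition_ids, data.drug_names,
        index_label="condition_id",
    )
    write_matrix_csv(
        outdir / "responses.csv", data.X, data.condition_ids, data.response_names,
        index_label="condition_id",
    )


def load_dataset(drugs_path, responses_path) -> PerturbationDataset:
    """Load the two-CSV dataset; condition-id order must match exactly."""
    drugs = read_matrix_csv(drugs_path)
    responses = read_matrix_csv(responses_path)
    if list(drugs.index) != list(responses.index):
        raise ValueError(
            f"condition ids of {drugs_path} and {responses_path} do not match "
            "(same ids in the same order are required)"
        )
    return PerturbationDataset(
        D=drugs.to_numpy(dtype=float),
        X=responses.to_numpy(dtype=float),
        drug_names=[str(c) for c in drugs.columns],
        response_names=[str(c) for c in responses.columns],
        condition_ids=[str(i) for i in drugs.index],
    )


# ---------------------------------------------------------------------------
# fitted-model serialization

def save_model(model, path) -> None:
    """Serialize a fitted LR / CSR / Cellbox estimator to YAML."""
    from .cellbox import CellboxLinear
    from .estimators import CausalStructureRegression, LinearResponseRegression

    if isinstance(model, LinearResponseRegression):
        doc = {
            "kind": "lr",
            "R": model.coef_.tolist(),
            "lambda": float(model.alpha),
            "zeroed_drugs": (
                [model.drug_names[i] for i in model.zeroed_idx_]
                if model.drug_names is not None
                else list(model.zeroed_idx_)
            ),
            "drug_names": model.drug_names,
            "response_names": model.response_names,
        }
    elif isinstance(model, CausalStructureRegression):
        doc = {
            "kind": "csr",
            "T": model.T_.tolist(),
            "A_hat": None if model.A_hat_ is None else model.A_hat_.tolist(),
            "B": np.asarray(model.B).tolist(),
            "lambda": float(model.alpha),
            "pd_report": model.pd_report_,
            "objective": float(model.objective_),
            "drug_names": model.drug_names,
            "response_names": model.response_names,
        }
    elif isinstance(model, CellboxLinear):
        doc = {
            "kind": "cellbox",
            "W": model.W_.tolist(),
            "B": np.asarray(model.B).tolist(),
            "lambda": float(model.alpha),
            "stable": bool(model.stable_),
            "pd_report": model.csr_.pd_report_,
            "objective": float(model.csr_.objective_),
            "drug_names": model.drug_names,
            "response_names": model.response_names,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path):
    """Reconstruct a fitted estimator from :func:`save_model` output."""
    from .cellbox import CellboxLinear, CellboxLinearModel
    from .estimators import CausalStructureRegression, LinearResponseRegression

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kind = doc.get("kind")
    if kind == "lr":
        est = LinearResponseRegression(
            alpha=doc["lambda"],
            zeroed=doc["zeroed_drugs"],
            drug_names=doc["drug_names"],
            response_names=doc["response_names"],
        )
        est.coef_ = np.array(doc["R"], dtype=float)
        est.n_features_in_ = est.coef_.shape[1]
        est.n_outputs_ = est.coef_.shape[0]
        est.zeroed_idx_ = tuple(est._resolve_zeroed(est.n_features_in_))
        est.D_mean_ = None
        est.X_mean_ = None
        return est
    if kind == "csr":
        est = CausalStructureRegression(
            B=np.array(doc["B"], dtype=float),
            alpha=doc["lambda"],
            drug_names=doc["drug_names"],
            response_names=doc["response_names"],
        )
        est.T_ = np.array(doc["T"], dtype=float)
        est.A_hat_ = None if doc["A_hat"] is None else np.array(doc["A_hat"], dtype=float)
        est.pd_report_ = doc["pd_report"]
        est.objective_ = doc["objective"]
        est.n_features_in_ = np.asarray(est.B).shape[1]
        est.n_outputs_ = est.T_.shape[0]
        return est
    if kind == "cellbox":
        est = CellboxLinear(
            B=np.array(doc["B"], dtype=float),
            alpha=doc["lambda"],
            drug_names=doc["drug_names"],
            response_names=doc["response_names"],
        )
        est.W_ = np.array(doc["W"], dtype=float)
        est.model_ = CellboxLinearModel(W=est.W_)
        est.stable_ = est.model_.stable
        est.n_features_in_ = np.asarray(est.B).shape[1]
        est.n_outputs_ = est.W_.shape[0]
        return est
    raise ValueError(f"{path}: unknown model kind {kind!r}")
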