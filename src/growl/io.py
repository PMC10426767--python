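"""Dataset and model I/O, propensity estimation, and run manifests.

Dataset schema (delimited text, header required): covariate columns
``x1..xd``, a treatment column ``a`` (integers 1..M or arbitrary string
labels, which are mapped to 1..M and the map persisted), an outcome column
``r``, and either a single column ``p`` (propensity of the received arm —
accepted on read but insufficient for group propensities, so the full
matrix is estimated) or the full vector ``p1..pM``.  Models are serialised
as JSON so they are inspectable and diffable.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from . import __version__
from .ramsvm import (
    KernelDecisionModel,
    KernelSpec,
    LinearDecisionModel,
    Partition,
    TrialDataset,
)

__all__ = ["read_dataset", "write_dataset", "estimate_propensities",
           "save_model", "load_model", "RunManifest"]

_PROP_FLOOR = 1e-6  # guards IPW blow-up with estimated propensities


def read_dataset(path, estimate_missing_propensities: bool = False
                 ) -> tuple[TrialDataset, dict]:
    """Read a CSV dataset; returns (dataset, label_map).

    ``label_map`` maps original treatment labels to 1..M (identity for
    integer labels).  Rows with missing values and invalid propensity rows
    are rejected with their line numbers.
    """
    df = pd.read_csv(path)
    xcols = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    if not xcols:
        raise ValueError("no covariate columns x1..xd found")
    for need in ("a", "r"):
        if need not in df.columns:
            raise ValueError(f"missing required column {need!r}")
    bad = df[xcols + ["a", "r"]].isna().any(axis=1)
    if bad.any():
        lines = (np.nonzero(bad.to_numpy())[0] + 2).tolist()  # header = line 1
        raise ValueError(f"rows with missing values at lines {lines}")

    raw_labels = df["a"].tolist()
    uniq = sorted(set(raw_labels), key=lambda v: (str(type(v)), v))
    if all(isinstance(v, (int, np.integer)) for v in uniq) and min(uniq) == 1:
        label_map = {int(v): int(v) for v in uniq}
        M = int(max(uniq))
    else:
        label_map = {v: i + 1 for i, v in enumerate(uniq)}
        M = len(uniq)
    A = np.array([label_map[v] for v in raw_labels], dtype=int)

    pcols = [c for c in df.columns
             if c.startswith("p") and c[1:].isdigit()]
    if pcols:
        pcols = sorted(pcols, key=lambda c: int(c[1:]))
        if len(pcols) != M:
            raise ValueError(f"found {len(pcols)} propensity columns, need {M}")
        prop = df[pcols].to_numpy(dtype=float)
        if np.any(prop <= 0):
            lines = (np.nonzero((prop <= 0).any(axis=1))[0] + 2).tolist()
            raise ValueError(f"non-positive propensities at lines {lines}")
        sums = prop.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            lines = (np.nonzero(off)[0] + 2).tolist()
            raise ValueError(f"propensity rows not summing to 1 at lines {lines}")
        prop = prop / sums[:, None]
    elif estimate_missing_propensities or "p" in df.columns:
        X = df[xcols].to_numpy(dtype=float)
        prop = estimate_propensities(X, A, M)
    else:
        raise ValueError("no propensity columns (p or p1..pM); "
                         "pass estimate_missing_propensities=True to fit them")
    X = df[xcols].to_numpy(dtype=float)
    return TrialDataset(X=X, A=A, R=df["r"].to_numpy(dtype=float), prop=prop), label_map


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write a dataset in the schema that :func:`read_dataset` accepts."""
    cols = {f"x{j+1}": dataset.X[:, j] for j in range(dataset.d)}
    cols["a"] = dataset.A
    cols["r"] = dataset.R
    for a in range(dataset.M):
        cols[f"p{a+1}"] = dataset.prop[:, a]
    pd.DataFrame(cols).to_csv(path, index=False)


def estimate_propensities(X: np.ndarray, A: np.ndarray, M: int | None = None
                          ) -> np.ndarray:
    """Multinomial logistic propensity model p(a | x).

    Near-unregularised maximum likelihood first; on non-convergence or
    separation, a ridge-regularised refit with a warning.  Fitted rows are
    floored at 1e-6 and renormalised.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.asarray(A, dtype=int)
    M = M or int(A.max())
    counts = np.bincount(A, minlength=M + 1)[1:]
    if np.any(counts < 2):
        raise ValueError("every arm must be observed at least twice")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf = LogisticRegression(C=1e6, max_iter=1000)
        clf.fit(X, A)
        trouble = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    # fitted probabilities collapsing to 0/1 indicate (quasi-)separation even
    # when the optimiser reports convergence
    trouble = trouble or bool(np.any(clf.predict_proba(X) > 1 - 1e-3))
    if trouble:
        warnings.warn("propensity MLE did not converge (separation?); "
                      "refitting with ridge regularisation", RuntimeWarning)
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X, A)
    probs = np.zeros((X.shape[0], M))
    probs[:, clf.classes_ - 1] = clf.predict_proba(X)
    probs = np.maximum(probs, _PROP_FLOOR)
    return probs / probs.sum(axis=1, keepdims=True)


# --------------------------------------------------------------------------
# model serialisation
# --------------------------------------------------------------------------


def save_model(path, model, partition: Partition, label_map: dict | None = None
               ) -> None:
    """Serialise a fitted decision model + partition to JSON."""
    doc: dict = {
        "format": "growl-model",
        "version": 1,
        "K": partition.K,
        "partition": list(partition.labels),
        "label_map": {str(k): v for k, v in (label_map or {}).items()},
    }
    if isinstance(model, LinearDecisionModel):
        doc["kind"] = "linear"
        doc["B"] = model.B.tolist()
    elif isinstance(model, KernelDecisionModel):
        doc["kind"] = "kernel"
        doc["kernel"] = model.spec.kernel
        doc["sigma2"] = model.spec.sigma2
        doc["train_X"] = model.train_X.tolist()
        doc["Theta"] = model.Theta.tolist()
        doc["intercepts"] = model.intercepts.tolist()
    else:
        raise TypeError(f"cannot serialise model of type {type(model).__name__}")
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path):
    """Inverse of :func:`save_model`; returns (model, partition, label_map)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "growl-model":
        raise ValueError(f"{path} is not a growl model file")
    partition = Partition(doc["partition"], doc["K"])
    label_map = doc.get("label_map", {})
    if doc["kind"] == "linear":
        model = LinearDecisionModel(B=np.asarray(doc["B"], dtype=float))
    else:
        model = KernelDecisionModel(
            spec=KernelSpec(doc["kernel"], sigma2=doc["sigma2"]),
            train_X=np.asarray(doc["train_X"], dtype=float),
            Theta=np.asarray(doc["Theta"], dtype=float),
            intercepts=np.asarray(doc["intercepts"], dtype=float),
        )
    return model, partition, label_map


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to reproduce a stochastic run bit-for-bit."""

    command: str
    master_seed: int | None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)     # path -> sha256
    outputs: list = field(default_factory=list)
    started: str = ""
    finished: str = ""

    @staticmethod
    def digest(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now(datetime.UTC).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.UTC).isoformat()
        return self

    def write(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["environment"] = {
            "growl": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str))
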