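"""Central-fixation criteria: threshold sweep, linear discriminants, decisions.

Method 1 sweeps a scalar threshold theta over a fixed grid and scores each
level by the pooled L1 distance of the normalized central-fixation power
(P2.5 + P6.5)/P4.5 of both calibration sets to theta; the minimizer of that
objective is the grid point nearest the pooled median. Method 2 fits a
pooled-covariance linear discriminant K + P L^T = 0 on 2-4 normalized
powers and classifies by which side of the hyperplane a measurement falls,
conventionally written as "P6.5/P4.5 > z" with z a linear function of the
remaining features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectral import NormalizedFeatures

__all__ = [
    "ThresholdModel",
    "LDAModel",
    "sweep_threshold",
    "fit_lda",
    "lda_features",
    "classify_record",
    "session_decision",
    "evaluate",
    "save_model",
    "load_model",
]

GRID_MIN, GRID_MAX, GRID_STEP = 0.3, 8.0, 0.001


@dataclass
class ThresholdModel:
    """Method 1: scalar threshold on r_cf = (P2.5 + P6.5)/P4.5."""

    theta: float = 0.8750
    grid_min: float = GRID_MIN
    grid_max: float = GRID_MAX
    grid_step: float = GRID_STEP
    trace: np.ndarray | None = None  # (levels, 3): E_cf, E_para, total
    provenance: dict = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


#: Feature maps of the 2-, 3- and 4-way discriminants. The last entry is the
#: threshold-side variable (the paper's "z" in the 3D case); the 4D map
#: splits the para-central sum into its two components.
LDA_FEATURE_MAPS = {
    2: ("r_para", "r_cf"),
    3: ("r_para", "r25", "r65"),
    4: ("r35", "r55", "r25", "r65"),
}


@dataclass
class LDAModel:
    """Method 2: pooled-covariance linear discriminant on normalized powers.

    ``K + P @ L = 0`` is the boundary; g = K + P @ L is positive on the
    central-fixation side. The ``a`` coefficients rewrite the boundary as
    z = a0 + a1 x1 + ... over the leading features, with the last feature
    compared against z.
    """

    dims: int
    K: float
    L: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.dims not in LDA_FEATURE_MAPS:
            raise ValueError("dims must be 2, 3 or 4")
        if self.L.shape != (self.dims,):
            raise ValueError("L must have one coefficient per feature")
        if self.L[-1] == 0:
            raise ValueError("L(last) must be nonzero")

    @property
    def a(self) -> np.ndarray:
        """Derived coefficients: a0 = -K/L[-1], a_i = -L[i-1]/L[-1]."""
        return np.concatenate(([-self.K], -self.L[:-1])) / self.L[-1]

    @classmethod
    def from_a(cls, a, dims: int | None = None, provenance: dict | None = None) -> "LDAModel":
        """Build from published a-coefficients, taking L(last) = 1."""
        a = np.asarray(a, dtype=float)
        dims = dims or len(a)
        if len(a) != dims:
            raise ValueError("need dims coefficients a0..a_{dims-1}")
        return cls(dims=dims, K=-a[0], L=np.concatenate((-a[1:], [1.0])),
                   provenance=provenance or {})


def sweep_threshold(cf_features, para_features, grid: np.ndarray | None = None,
                    objective: str = "l1") -> ThresholdModel:
    """Calibrate the Method-1 threshold on labeled r_cf values.

    ``objective='l1'`` (the instrument's rule) minimizes the summed absolute
    deviations of both sets from theta, E^CF + E^paraCF, ties broken to the
    smallest theta; ``'errors'`` is a non-standard alternative minimizing the
    misclassification count on the same grid.
    """
    cf = np.asarray(cf_features, dtype=float)
    para = np.asarray(para_features, dtype=float)
    if cf.size == 0 or para.size == 0:
        raise ValueError("both calibration sets must be non-empty")
    model = ThresholdModel()
    g = grid if grid is not None else model.grid
    e_cf = np.abs(cf[:, None] - g[None, :]).sum(axis=0)
    e_para = np.abs(para[:, None] - g[None, :]).sum(axis=0)
    if objective == "l1":
        total = e_cf + e_para
    elif objective == "errors":
        # CF misclassified when r_cf <= theta; para when r_cf > theta.
        total = (cf[:, None] <= g[None, :]).sum(axis=0) + (para[:, None] > g[None, :]).sum(axis=0)
    else:
        raise ValueError(f"unknown objective {objective!r}")
    # ties break to the smallest theta; the tolerance absorbs float rounding
    # on exactly flat stretches of the piecewise-linear L1 objective
    tmin = total.min()
    i = int(np.argmax(total <= tmin * (1 + 1e-12) + 1e-12))
    model.theta = float(g[i])
    model.trace = np.column_stack([e_cf, e_para, e_cf + e_para])
    model.provenance = {"objective": objective, "n_cf": int(cf.size), "n_para": int(para.size)}
    return model


def lda_features(nf: NormalizedFeatures, dims: int) -> np.ndarray:
    """Map normalized powers to the feature vector of the ``dims``-way LDA."""
    names = LDA_FEATURE_MAPS[dims]
    return np.array([getattr(nf, name) for name in names], dtype=float)


def fit_lda(features, labels, dims: int | None = None,
            priors: str = "equal", ridge: float = 0.0) -> LDAModel:
    """Fit a two-class pooled-covariance linear discriminant.

    ``features`` is (n, dims); ``labels`` is boolean/0-1 with True for the
    central-fixation class. Equal priors by default despite any class
    imbalance (proportional priors via ``priors='proportional'``). A singular
    pooled covariance raises, advising the ``ridge`` regularizer.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    dims = dims or X.shape[1]
    if X.shape[1] != dims:
        raise ValueError("feature/dims mismatch")
    X1, X0 = X[y], X[~y]
    if len(X1) < 2 or len(X0) < 2:
        raise ValueError("need at least 2 samples per class")
    mu1, mu0 = X1.mean(axis=0), X0.mean(axis=0)
    S = ((X1 - mu1).T @ (X1 - mu1) + (X0 - mu0).T @ (X0 - mu0)) / (len(X) - 2)
    if ridge > 0:
        S = S + ridge * np.eye(dims)
    try:
        L = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; re-fit with ridge=1e-8"
        ) from exc
    K = -0.5 * (mu1 + mu0) @ L
    if priors == "proportional":
        K += np.log(len(X1) / len(X0))
    elif priors != "equal":
        raise ValueError("priors must be 'equal' or 'proportional'")
    return LDAModel(dims=dims, K=float(K), L=L,
                    provenance={"priors": priors, "ridge": ridge,
                                "n_cf": int(len(X1)), "n_para": int(len(X0))})


def classify_record(nf: NormalizedFeatures, model) -> bool:
    """Per-record central-fixation decision (strict inequality at the boundary).

    Method 1 passes iff r_cf > theta. Method 2 passes iff the measurement
    lies strictly on the central-fixation side of the discriminant, i.e.
    r_last > z = a0 + a1 x1 + ... when L(last) > 0.
    """
    if isinstance(model, ThresholdModel):
        return nf.r_cf > model.theta
    if isinstance(model, LDAModel):
        P = lda_features(nf, model.dims)
        return float(model.K + P @ model.L) > 0.0
    raise TypeError(f"unknown model type {type(model).__name__}")


def session_decision(per_record_flags, k: int = 2, n: int = 12) -> bool:
    """k-of-n session rule: pass iff at least ``k`` of ``n`` records pass."""
    flags = list(per_record_flags)
    if len(flags) != n:
        raise ValueError(f"expected {n} record flags, got {len(flags)}")
    return sum(bool(f) for f in flags) >= k


def evaluate(predictions, gold):
    """Confusion counts and rates, screening convention: positive = abnormal.

    ``predictions`` and ``gold`` are boolean vectors with True = fails the
    criterion (abnormal). Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP);
    a rate with zero denominator is reported as None.
    """
    p = np.asarray(predictions).astype(bool)
    g = np.asarray(gold).astype(bool)
    if p.shape != g.shape:
        raise ValueError("length mismatch between predictions and gold")
    tp = int(np.sum(p & g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    fp = int(np.sum(p & ~g))
    sens = 100.0 * tp / (tp + fn) if tp + fn else None
    spec = 100.0 * tn / (tn + fp) if tn + fp else None
    return {"TN": tn, "FP": fp, "TP": tp, "FN": fn,
            "sensitivity_pct": sens, "specificity_pct": spec}


def save_model(model, path: str | Path) -> Path:
    """Serialize a fitted model (either method) to JSON."""
    path = Path(path)
    if isinstance(model, ThresholdModel):
        d = {"method": "threshold", "theta": model.theta,
             "grid": [model.grid_min, model.grid_max, model.grid_step],
             "provenance": model.provenance}
    elif isinstance(model, LDAModel):
        d = {"method": "lda", "dims": model.dims, "K": model.K,
             "L": model.L.tolist(), "a": model.a.tolist(),
             "provenance": model.provenance}
    else:
        raise TypeError(f"unknown model type {type(model).__name__}")
    path.write_text(json.dumps(d, indent=1))
    return path


def load_model(path: str | Path):
    d = json.loads(Path(path).read_text())
    if d["method"] == "threshold":
        gmin, gmax, gstep = d.get("grid", [GRID_MIN, GRID_MAX, GRID_STEP])
        return ThresholdModel(theta=d["theta"], grid_min=gmin, grid_max=gmax,
                              grid_step=gstep, provenance=d.get("provenance", {}))
    if d["method"] == "lda":
        return LDAModel(dims=d["dims"], K=d["K"], L=np.asarray(d["L"]),
                        provenance=d.get("provenance", {}))
    raise ValueError(f"unknown model method {d['method']!r}")
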