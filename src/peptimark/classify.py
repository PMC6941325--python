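"""Fluid-level marker classifier and the fixed-coefficient combined test.

Each body fluid (bile, urine) gets a support-vector machine trained on the
log-transformed ion-signal matrix of its peptide markers. A sample's
"membership probability" is the signed Euclidean distance of its
log-intensity vector to the maximal-margin separating hyperplane, saturated
into a fluid-specific range (bile: [-2.5, 2.5]; urine: [-3.5, 3.5]);
positive values lie on the case side. A fluid calls the sample positive when
its score strictly exceeds the fluid threshold (bile 0.08, urine -0.89).

The two fluid scores are combined by a logistic-regression equation with
published coefficients:

    BPA/UPA match = 1.6128 + 1.8325 * BPA + 2.6363 * UPA

and the combined test is positive when this value strictly exceeds -0.52.
``fit_combination`` re-estimates such coefficients on new cohorts by
maximum-likelihood logistic regression.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ValidationError
from .profiles import ProfileMatrix

__all__ = [
    "MarkerModel",
    "CombinedModel",
    "DEFAULT_COMBINED_MODEL",
    "FLUID_SCALES",
    "FLUID_THRESHOLDS",
    "train_marker_model",
    "membership_probability",
    "classify_fluid",
    "combine_scores",
    "classify_combined",
    "fit_combination",
    "cross_val_accuracy",
]

FLUID_SCALES = {"bile": 2.5, "urine": 3.5}
FLUID_THRESHOLDS = {"bile": 0.08, "urine": -0.89}


@dataclass
class MarkerModel:
    """Linear max-margin fluid classifier on log-transformed intensities."""

    fluid: str
    marker_ids: list[str]
    weights: np.ndarray
    bias: float
    scale: float
    threshold: float
    training_accuracy: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        if self.scale <= 0:
            raise ValidationError("scale must be positive (range is [-scale, scale])")
        if not -self.scale <= self.threshold <= self.scale:
            raise ValidationError("threshold must lie within the score range")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "fluid": self.fluid, "marker_ids": self.marker_ids,
            "weights": self.weights.tolist(), "bias": self.bias,
            "scale": self.scale, "threshold": self.threshold,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerModel":
        d = json.loads(Path(path).read_text())
        return cls(d["fluid"], d["marker_ids"], np.array(d["weights"]),
                   d["bias"], d["scale"], d["threshold"])


@dataclass(frozen=True)
class CombinedModel:
    """Fixed-coefficient logistic combiner of bile (BPA) and urine (UPA) scores."""

    intercept: float = 1.6128
    coef_bile: float = 1.8325
    coef_urine: float = 2.6363
    threshold: float = -0.52

    def __post_init__(self) -> None:
        vals = (self.intercept, self.coef_bile, self.coef_urine, self.threshold)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError("all combined-model coefficients must be finite")


DEFAULT_COMBINED_MODEL = CombinedModel()


def log_transform(intensities: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Natural-log transform with pseudo-count 1 (keeps absent peptides at 0)."""
    return np.log1p(np.asarray(intensities, float))


def train_marker_model(
    matrix: ProfileMatrix,
    labels: Mapping[str, str] | pd.Series,
    case: str = "case",
    C: float = 1.0,
    seed: int = 0,
) -> MarkerModel:
    """Train the soft-margin linear separator for one fluid.

    Intensities are natural-log transformed with pseudo-count 1; samples with
    label ``case`` form the positive class. Requires >= 5 samples per class.
    Deterministic given the seed.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = (labels.reindex(matrix.sample_ids) == case).to_numpy().astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training requires both classes")
    if counts.min() < 5:
        raise ValidationError("training requires >= 5 samples per class")
    X = log_transform(matrix.intensities.T.to_numpy())
    svc = SVC(kernel="linear", C=C, random_state=seed)
    svc.fit(X, y)
    w = svc.coef_.ravel()
    model = MarkerModel(
        fluid=matrix.fluid, marker_ids=matrix.marker_ids,
        weights=w, bias=float(svc.intercept_[0]),
        scale=FLUID_SCALES.get(matrix.fluid, 2.5),
        threshold=FLUID_THRESHOLDS.get(matrix.fluid, 0.0),
        training_accuracy=float((svc.predict(X) == y).mean()),
    )
    return model


def membership_probability(model: MarkerModel, log_intensities: np.ndarray) -> float:
    """Signed Euclidean distance to the hyperplane, clipped into the scale range.

    Accepts a single sample's log-intensity vector over the model's markers.
    Positive scores lie on the case side.
    """
    x = np.asarray(log_intensities, float).ravel()
    if x.size != len(model.marker_ids):
        raise ValidationError(
            f"expected {len(model.marker_ids)} marker intensities, got {x.size}"
        )
    norm = np.linalg.norm(model.weights)
    if norm == 0:
        raise ValidationError("degenerate model (zero weight vector)")
    dist = (float(model.weights @ x) + model.bias) / norm
    return float(np.clip(dist, -model.scale, model.scale))


def score_matrix(model: MarkerModel, matrix: ProfileMatrix) -> pd.Series:
    """Membership probabilities for every sample of a profile matrix."""
    sub = matrix.intensities.reindex(model.marker_ids).fillna(0.0)
    X = log_transform(sub.T.to_numpy())
    return pd.Series(
        [membership_probability(model, row) for row in X],
        index=matrix.sample_ids, name=f"{model.fluid}_score",
    )


def classify_fluid(score: float, model: MarkerModel) -> str:
    """'positive' iff the membership probability strictly exceeds the threshold."""
    return "positive" if score > model.threshold else "negative"


def combine_scores(bpa: float, upa: float,
                   model: CombinedModel = DEFAULT_COMBINED_MODEL) -> float:
    """Evaluate the combined regression score (exact affine arithmetic)."""
    if not (np.isfinite(bpa) and np.isfinite(upa)):
        raise ValidationError("scores must be finite")
    return model.intercept + model.coef_bile * bpa + model.coef_urine * upa


def classify_combined(bpa: float, upa: float,
                      model: CombinedModel = DEFAULT_COMBINED_MODEL) -> str:
    """'positive' iff the combined score strictly exceeds the combined threshold."""
    return "positive" if combine_scores(bpa, upa, model) > model.threshold else "negative"


@dataclass
class CombinedFit:
    """Result of re-estimating the combined logistic model on a cohort."""

    model: CombinedModel
    params: pd.Series
    bse: pd.Series
    converged: bool
    separation: bool = False
    _sm_result: object = field(default=None, repr=False)

    def summary(self):
        if self._sm_result is not None:
            return self._sm_result.summary()
        return pd.DataFrame({"coef": self.params, "se": self.bse})


def fit_combination(
    bpa_scores: Sequence[float],
    upa_scores: Sequence[float],
    labels: Sequence[int],
    coef_cap: float = 25.0,
) -> CombinedFit:
    """Maximum-likelihood logistic fit of case status on the two fluid scores.

    Newton/IRLS iterations, convergence when the coefficient change drops
    below 1e-8 (at most 100 iterations). Perfectly separable cohorts are
    flagged and their coefficients capped at ``coef_cap`` in absolute value
    with a warning rather than diverging.
    """
    bpa = np.asarray(bpa_scores, float)
    upa = np.asarray(upa_scores, float)
    y = np.asarray(labels, int)
    if not (len(bpa) == len(upa) == len(y)):
        raise ValidationError("inputs must have equal length")
    if len(y) < 10:
        raise ValidationError("need >= 10 samples to refit the combination")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    X = sm.add_constant(np.column_stack([bpa, upa]), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(method="newton", tol=1e-8, maxiter=100, disp=0)
        except Exception:
            separation = True
            res = None
        if res is not None and any("separat" in str(w.message).lower() for w in caught):
            separation = True
    if res is not None:
        params = np.asarray(res.params, float)
        bse = np.asarray(res.bse, float)
        converged = bool(res.mle_retvals.get("converged", True))
    else:  # refit with a ridge penalty to obtain finite coefficients
        ridge = sm.Logit(y, X).fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0)
        params = np.asarray(ridge.params, float)
        bse = np.full(3, np.nan)
        converged = False
    if separation or np.abs(params).max() > coef_cap:
        separation = True
        warnings.warn(
            "perfect separation detected; coefficients capped", stacklevel=2
        )
        params = np.clip(params, -coef_cap, coef_cap)
    names = ["intercept", "bpa", "upa"]
    model = CombinedModel(intercept=float(params[0]), coef_bile=float(params[1]),
                          coef_urine=float(params[2]))
    return CombinedFit(
        model=model,
        params=pd.Series(params, index=names),
        bse=pd.Series(bse, index=names),
        converged=converged, separation=separation, _sm_result=res,
    )


def cross_val_accuracy(
    matrix: ProfileMatrix,
    labels: Mapping[str, str] | pd.Series,
    case: str = "case",
    n_splits: int = 5,
    C: float = 1.0,
    seed: int = 0,
) -> float:
    """Stratified k-fold cross-validated accuracy of the fluid classifier."""
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    y = (labels.reindex(matrix.sample_ids) == case).to_numpy().astype(int)
    X = log_transform(matrix.intensities.T.to_numpy())
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, y):
        svc = SVC(kernel="linear", C=C, random_state=seed)
        svc.fit(X[train], y[train])
        correct += int((svc.predict(X[test]) == y[test]).sum())
    return correct / len(y)
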