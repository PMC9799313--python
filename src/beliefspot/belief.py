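"""Belief-theoretic object labelling.

A reference model is the sample mean and covariance of the feature
vectors of objects detected in images carrying one image-level label.
A target object's Mahalanobis distance to that population, z-normalised
within its image, is converted to a plausibility through the one-sided
Chebyshev (Cantelli) tail bound

    Pr[Z >= z] <= 1 / (1 + z^2),

the theoretical upper limit on the probability that the object belongs
to the labelled population.  Plausibility from model J and the swapped
model I combine into a Dempster-style triplet (p, q, r): belief for the
label, belief against it, and residual uncertainty, summing to one.

Nested label hierarchies (a specific label inside a broader one) are
handled with a small algebra: plausibility for the specific stratum is
the clipped difference of plausibilities, and the belief that an object
belongs to none of a set of excluded labels is the product of their
complements.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .exceptions import DegenerateModelError
from .features import FEATURE_COLUMNS

__all__ = [
    "PlausibilityModel",
    "BeliefTriplet",
    "LabelFrame",
    "fit_reference_model",
    "mahalanobis_distance",
    "z_normalize",
    "cantelli_plausibility",
    "assign_plausibility",
    "bidirectional_triplet",
    "subtract_plausibility",
    "unique_label_belief",
    "save_model",
    "load_model",
]

# condition number above which a small ridge keeps the covariance invertible
_COND_LIMIT = 1e12
_RIDGE_SCALE = 1e-9


@dataclass(frozen=True)
class BeliefTriplet:
    """Belief for, belief against, and uncertainty; sums to one."""

    p: float
    q: float
    r: float
    clamped: bool = False


@dataclass
class LabelFrame:
    """The set of labels under discussion and their declared nestings."""

    labels: set[str]
    subset_relations: set[tuple[str, str]]  # (sub, super) pairs

    def __post_init__(self) -> None:
        for sub, sup in self.subset_relations:
            if sub not in self.labels or sup not in self.labels:
                raise ValueError(f"relation ({sub}, {sup}) uses undeclared labels")
        # reject cycles: repeated relaxation over the subset relation
        order: dict[str, int] = {}
        pending = set(self.labels)
        while pending:
            progressed = False
            for lab in list(pending):
                if all(sub in order for sub, sup in self.subset_relations if sup == lab):
                    order[lab] = len(order)
                    pending.discard(lab)
                    progressed = True
            if not progressed:
                raise ValueError(f"subset relation contains a cycle among {pending}")


class PlausibilityModel(BaseEstimator):
    """Reference population model for one image-level label.

    Fit on the feature matrix of objects drawn from images carrying the
    label; scoring a new object measures its Mahalanobis distance to
    this population.

    Parameters
    ----------
    label : str
        The image-level label this model provides evidence for.

    Attributes
    ----------
    mean_ : ndarray of shape (d,)
        Sample mean of the fitting features.
    covariance_ : ndarray of shape (d, d)
        Sample covariance (1/(n-1)).
    ridge_ : float
        Regularisation actually added to the diagonal (0 when the
        covariance was well conditioned).
    n_objects_ : int
        Number of objects used in the fit.
    """

    def __init__(self, label: str = "reference") -> None:
        self.label = label

    def fit(self, X: np.ndarray, y=None) -> "PlausibilityModel":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        n, d = X.shape
        if n < d + 1:
            raise DegenerateModelError(
                f"need at least {d + 1} objects to fit a {d}-feature model, got {n}"
            )
        if not np.all(np.isfinite(X)):
            raise DegenerateModelError("feature matrix contains non-finite values")
        variances = X.var(axis=0)
        if np.any(variances == 0):
            names = (
                [FEATURE_COLUMNS[i] for i in np.where(variances == 0)[0]]
                if d == len(FEATURE_COLUMNS)
                else list(np.where(variances == 0)[0])
            )
            raise DegenerateModelError(f"zero-variance feature(s): {names}")
        self.mean_ = X.mean(axis=0)
        self.covariance_ = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
        self.ridge_ = 0.0
        if np.linalg.cond(self.covariance_) > _COND_LIMIT:
            self.ridge_ = _RIDGE_SCALE * np.trace(self.covariance_) / d
        self.n_objects_ = n
        self.n_features_ = d
        self._factor_ = linalg.cho_factor(
            self.covariance_ + self.ridge_ * np.eye(d), lower=True
        )
        return self

    def mahalanobis(self, X: np.ndarray) -> np.ndarray:
        """Mahalanobis distances of rows of ``X`` to the fitted population."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1]}"
            )
        delta = X - self.mean_
        solved = linalg.cho_solve(self._factor_, delta.T)
        return np.sqrt(np.einsum("ij,ji->i", delta, solved))

    def predict_plausibility(
        self,
        X: np.ndarray,
        image_ids: Sequence | None = None,
        z_scope: str = "image",
        cantelli: str = "literal",
    ) -> pd.DataFrame:
        """Distance -> per-image z -> Cantelli plausibility for each row."""
        return assign_plausibility(X, self, image_ids, z_scope=z_scope, cantelli=cantelli)


def fit_reference_model(features: np.ndarray | pd.DataFrame, label: str) -> PlausibilityModel:
    """Fit a :class:`PlausibilityModel` on a feature matrix or table."""
    if isinstance(features, pd.DataFrame):
        features = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    return PlausibilityModel(label=label).fit(features)


def mahalanobis_distance(x: np.ndarray, model: PlausibilityModel) -> float:
    """Distance of a single feature vector to the model population."""
    return float(model.mahalanobis(np.asarray(x, dtype=float)[None, :])[0])


def z_normalize(distances: Sequence[float] | np.ndarray) -> np.ndarray:
    """Standardise distances with population (1/n) std.

    A single distance or a zero-spread set is mapped to z = 0 (no
    relative information within the image).
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("need at least one distance")
    std = d.std()
    if d.size == 1 or std == 0:
        warnings.warn("degenerate distance spread; all z set to 0", stacklevel=2)
        return np.zeros_like(d)
    return (d - d.mean()) / std


def cantelli_plausibility(z: float | np.ndarray, convention: str = "literal") -> float | np.ndarray:
    """Cantelli tail bound 1/(1+z^2) as a plausibility.

    ``literal`` squares z as given; ``one-sided`` clamps negative z at 0
    first (the bound only constrains the upper tail), so below-mean
    distances receive plausibility 1.
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("z must be finite")
    if convention == "one-sided":
        z_arr = np.maximum(z_arr, 0.0)
    elif convention != "literal":
        raise ValueError("convention must be 'literal' or 'one-sided'")
    out = 1.0 / (1.0 + z_arr ** 2)
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def assign_plausibility(
    features: np.ndarray | pd.DataFrame,
    model: PlausibilityModel,
    image_ids: Sequence | None = None,
    z_scope: str = "image",
    cantelli: str = "literal",
) -> pd.DataFrame:
    """Score target objects against a reference model.

    Distances are z-normalised per image by default (``z_scope=
    "image"``); ``"dataset"`` pools all objects into one normalisation
    group.  Returns a table with columns image_id, object_id, label,
    mahalanobis, z, pl.
    """
    if z_scope not in ("image", "dataset"):
        raise ValueError("z_scope must be 'image' or 'dataset'")
    if isinstance(features, pd.DataFrame):
        if image_ids is None and "image_id" in features.columns:
            image_ids = features["image_id"].to_numpy()
        object_ids = (
            features["object_id"].to_numpy()
            if "object_id" in features.columns
            else np.arange(1, len(features) + 1)
        )
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        object_ids = np.arange(1, X.shape[0] + 1)
    if image_ids is None:
        image_ids = np.repeat("image_0", X.shape[0])
    image_ids = np.asarray(image_ids)
    distances = model.mahalanobis(X)
    z = np.empty_like(distances)
    if z_scope == "dataset":
        z[:] = z_normalize(distances)
    else:
        for img in pd.unique(image_ids):
            sel = image_ids == img
            z[sel] = z_normalize(distances[sel])
    pl = cantelli_plausibility(z, convention=cantelli)
    return pd.DataFrame(
        {
            "image_id": image_ids,
            "object_id": object_ids,
            "label": model.label,
            "mahalanobis": distances,
            "z": z,
            "pl": pl,
        }
    )


def bidirectional_triplet(q_J: float, q_I: float) -> BeliefTriplet:
    """Belief triplet for label L_J from the two directional scores.

    ``q_J`` is the plausibility of the object under the model of the
    target label; ``q_I`` under the swapped model.  Belief for L_J is
    the complement of the swapped plausibility (Bel(A) = 1 - Pl(not A)),
    and the uncertainty is the belief–plausibility gap.  When the two
    plausibilities sum below one the raw gap is negative; it is clamped
    to zero with the ``clamped`` flag raised.
    """
    for name, v in (("q_J", q_J), ("q_I", q_I)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    pl = q_J
    p = 1.0 - q_I
    r = pl - p
    clamped = False
    if r < 0:
        clamped = True
        r = 0.0
        p = pl
    return BeliefTriplet(p=p, q=1.0 - pl, r=r, clamped=clamped)


def subtract_plausibility(q_super: float, q_sub: float) -> float:
    """Plausibility unique to the enclosing label: max(q_super - q_sub, 0).

    The floor at zero guarantees outlier objects that score higher under
    the nested (more specific) model than under the enclosing one are
    assigned zero plausibility for the enclosing stratum.
    """
    for name, v in (("q_super", q_super), ("q_sub", q_sub)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return max(q_super - q_sub, 0.0)


def unique_label_belief(qs: Sequence[float]) -> float:
    """Belief the object belongs to none of the excluded labels:
    the product of the plausibility complements."""
    qs = list(qs)
    if not qs:
        warnings.warn("empty exclusion list; belief defaults to 1", stacklevel=2)
        return 1.0
    out = 1.0
    for q in qs:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"plausibility must be in [0, 1], got {q}")
        out *= 1.0 - q
    return out


def save_model(model: PlausibilityModel, path) -> None:
    """Serialise a fitted model to JSON (reproducible labelling without
    the reference images)."""
    from . import __version__

    payload = {
        "label": model.label,
        "mean": model.mean_.tolist(),
        "covariance": model.covariance_.tolist(),
        "ridge": model.ridge_,
        "n_objects": model.n_objects_,
        "version": __version__,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> PlausibilityModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    model = PlausibilityModel(label=payload["label"])
    model.mean_ = np.asarray(payload["mean"], dtype=float)
    model.covariance_ = np.asarray(payload["covariance"], dtype=float)
    model.ridge_ = float(payload["ridge"])
    model.n_objects_ = int(payload["n_objects"])
    model.n_features_ = model.mean_.shape[0]
    model._factor_ = linalg.cho_factor(
        model.covariance_ + model.ridge_ * np.eye(model.n_features_), lower=True
    )
    return model
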