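"""Canopy cover to tiller-number regression.

Tiller number per square metre is estimated from the canopy cover ratio
``C`` (in percent, 0-100) by a quadratic model

    T(C) = a * C**2 + b * C + c

The built-in coefficients, derived from field calibration data for the
cultivar 'Koshihikari' at planting densities of 11.0-18.3 hills per m2,
are ``a = -0.0548``, ``b = 9.13``, ``c = 77.7``.  Because ``a < 0`` the
parabola peaks at ``C = -b / 2a`` (about 83.3 % cover for the default
model); estimates beyond the vertex decrease with cover and are flagged
as extrapolated rather than clamped, so downstream diagnosis can see
that the model has left its monotone region.

Refitting from calibration pairs is ordinary least squares.  The
:class:`TillerRegressor` estimator exposes the same model in
scikit-learn form (``fit``/``predict``); :func:`fit_model`,
:func:`estimate_tillers` and :func:`default_model` are the functional
surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateModelError, InputDomainError, UnderdeterminedFitError

__all__ = [
    "DEFAULT_COEFFICIENTS",
    "QuadraticModel",
    "TillerEstimate",
    "TillerRegressor",
    "default_model",
    "estimate_tillers",
    "vertex_cover",
    "fit_model",
    "read_calibration_csv",
]

#: (a, b, c) of the built-in cover->tiller quadratic.
DEFAULT_COEFFICIENTS: Tuple[float, float, float] = (-0.0548, 9.13, 77.7)

#: Planting-density range (hills per m2) under which the built-in model
#: was calibrated.  Recorded as documentation, never enforced: density
#: is not observable from a single image.
DEFAULT_MODEL_DENSITY_RANGE = (11.0, 18.3)


@dataclass(frozen=True)
class QuadraticModel:
    """Quadratic cover->tiller model ``T = a*C**2 + b*C + c``.

    ``calibration_domain``, when set, is the closed cover interval (in
    percent) spanned by the data the model was fitted to; predictions
    outside it are flagged as extrapolated.
    """

    a: float
    b: float
    c: float
    calibration_domain: Optional[Tuple[float, float]] = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if not np.isfinite(getattr(self, name)):
                raise InputDomainError(f"coefficient {name} must be finite")
        if self.calibration_domain is not None:
            lo, hi = self.calibration_domain
            if not (0 <= lo <= hi <= 100):
                raise InputDomainError(
                    "calibration_domain must be an ordered interval in [0, 100]"
                )

    def predict(self, cover_percent):
        """Evaluate the quadratic (vectorised, no range checks)."""
        c = np.asarray(cover_percent, dtype=np.float64)
        out = self.a * c**2 + self.b * c + self.c
        return float(out) if out.ndim == 0 else out

    @property
    def vertex(self) -> float:
        if self.a == 0:
            raise DegenerateModelError("a = 0: the model has no vertex")
        return -self.b / (2.0 * self.a)

    def to_json(self) -> str:
        payload = {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "calibration_domain": (
                list(self.calibration_domain) if self.calibration_domain else None
            ),
        }
        if self.metadata:
            payload["metadata"] = self.metadata
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QuadraticModel":
        payload = json.loads(text)
        domain = payload.get("calibration_domain")
        return cls(
            a=float(payload["a"]),
            b=float(payload["b"]),
            c=float(payload["c"]),
            calibration_domain=tuple(domain) if domain else None,
            metadata=payload.get("metadata", {}),
        )


@dataclass(frozen=True)
class TillerEstimate:
    """A model evaluation: cover in, tillers per m2 out.

    ``extrapolated`` is true when the cover lies beyond the model's
    vertex (the quadratic is no longer increasing there) or outside its
    calibration domain when one is recorded.
    """

    cover_percent: float
    tillers_per_m2: float
    extrapolated: bool

    def to_dict(self) -> dict:
        return {
            "cover_percent": self.cover_percent,
            "tillers_per_m2": self.tillers_per_m2,
            "extrapolated": self.extrapolated,
        }


def default_model() -> QuadraticModel:
    """The built-in 'Koshihikari'-derived cover->tiller quadratic."""
    return QuadraticModel(
        *DEFAULT_COEFFICIENTS,
        calibration_domain=None,
        metadata={
            "source": "built-in",
            "cultivar": "Koshihikari",
            "planting_density_hills_per_m2": list(DEFAULT_MODEL_DENSITY_RANGE),
        },
    )


def vertex_cover(model: QuadraticModel) -> float:
    """Cover percent at the parabola's vertex, ``-b / (2a)``."""
    return model.vertex


def estimate_tillers(model: QuadraticModel, cover_percent: float) -> TillerEstimate:
    """Evaluate the quadratic at a cover percentage in ``[0, 100]``."""
    if not np.isfinite(cover_percent) or not 0 <= cover_percent <= 100:
        raise InputDomainError("cover_percent must lie in [0, 100]")
    value = model.predict(cover_percent)
    extrapolated = False
    if model.a < 0 and cover_percent > model.vertex:
        extrapolated = True
    if model.calibration_domain is not None:
        lo, hi = model.calibration_domain
        if not lo <= cover_percent <= hi:
            extrapolated = True
    return TillerEstimate(
        cover_percent=float(cover_percent),
        tillers_per_m2=float(value),
        extrapolated=extrapolated,
    )


def fit_model(pairs: Sequence[Tuple[float, float]]) -> QuadraticModel:
    """Ordinary least-squares quadratic fit of (cover %, tillers/m2) pairs.

    Requires at least three pairs with three distinct cover values; the
    fitted model records ``[min cover, max cover]`` as its calibration
    domain.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputDomainError("pairs must be a sequence of (cover, tillers)")
    cover, tillers = arr[:, 0], arr[:, 1]
    reg = TillerRegressor().fit(cover.reshape(-1, 1), tillers)
    return reg.model_


def read_calibration_csv(path: str | PathLike) -> list:
    """Read calibration pairs from a CSV with header
    ``cover_percent,tillers_per_m2``."""
    df = pd.read_csv(path)
    missing = {"cover_percent", "tillers_per_m2"} - set(df.columns)
    if missing:
        raise InputDomainError(f"calibration CSV missing columns: {sorted(missing)}")
    return list(zip(df["cover_percent"].astype(float), df["tillers_per_m2"].astype(float)))


class TillerRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn estimator for the cover->tiller quadratic.

    ``fit(X, y)`` takes cover percentages (``(n, 1)`` array or 1-D) and
    tiller counts and solves the ordinary least-squares quadratic.
    Fitted attributes: ``a_``, ``b_``, ``c_``, ``calibration_domain_``
    and ``model_`` (the equivalent :class:`QuadraticModel`).

    ``TillerRegressor.pretrained()`` returns an instance carrying the
    built-in field-calibrated coefficients without fitting.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise InputDomainError("X must be a single cover-percent column")
            X = X[:, 0]
        if X.ndim != 1 or X.shape != y.shape:
            raise InputDomainError("X and y must be matching 1-D sequences")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise InputDomainError("calibration data must be finite")
        if np.unique(X).size < 3:
            raise UnderdeterminedFitError(
                "need at least 3 distinct cover values to fit a quadratic"
            )
        # Vandermonde least squares; rescaling is unnecessary at these sizes.
        design = np.vander(X, 3)
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.a_, self.b_, self.c_ = (float(v) for v in coef)
        self.calibration_domain_ = (float(X.min()), float(X.max()))
        self.model_ = QuadraticModel(
            self.a_, self.b_, self.c_, calibration_domain=self.calibration_domain_
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[:, 0]
        return self.model_.predict(X)

    def estimate(self, cover_percent: float) -> TillerEstimate:
        """Domain-checked single-cover evaluation with extrapolation flag."""
        check_is_fitted(self, "model_")
        return estimate_tillers(self.model_, cover_percent)

    @classmethod
    def pretrained(cls) -> "TillerRegressor":
        reg = cls()
        model = default_model()
        reg.a_, reg.b_, reg.c_ = model.a, model.b, model.c
        reg.calibration_domain_ = model.calibration_domain
        reg.model_ = model
        reg.n_features_in_ = 1
        return reg
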