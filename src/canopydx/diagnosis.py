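"""Cultivar-threshold diagnosis of mid-season drainage timing.

Mid-season drainage of a flooded paddy is timed to the stand reaching a
cultivar-specific target tiller number.  The built-in registry carries
the Chiba-prefecture targets: 400 tillers/m2 for 'Fusaotome', 360 for
'Fusakogane', 320 for 'Koshihikari'.  The decision rule is inclusive:
an estimated tiller number at or above the target diagnoses the field
as at the optimal drainage timing; below target, tillering is not yet
sufficient.  The real-valued estimate is compared unrounded — rounding
first would introduce an undocumented second threshold.

:func:`diagnose_image` chains the full pipeline (segment -> cover ->
estimate -> diagnose) with no hidden state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from os import PathLike
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import estimation, imaging
from .errors import InputDomainError, UnknownCultivarError

__all__ = [
    "DiagnosisStatus",
    "CultivarProfile",
    "DiagnosisResult",
    "DiagnosisRecord",
    "DrainageDiagnoser",
    "builtin_registry",
    "load_registry",
    "resolve_cultivar",
    "diagnose",
    "diagnose_image",
]


class DiagnosisStatus(str, Enum):
    OPTIMAL_DRAINAGE_TIMING = "OPTIMAL_DRAINAGE_TIMING"
    INSUFFICIENT_TILLER_NUMBER = "INSUFFICIENT_TILLER_NUMBER"


@dataclass(frozen=True)
class CultivarProfile:
    """A cultivar and its target tiller number (tillers per m2)."""

    name: str
    target_tillers_per_m2: float

    def __post_init__(self):
        if not self.name:
            raise InputDomainError("cultivar name must be non-empty")
        if not self.target_tillers_per_m2 > 0:
            raise InputDomainError("target tiller number must be positive")


_BUILTIN = (
    CultivarProfile("Fusaotome", 400.0),
    CultivarProfile("Fusakogane", 360.0),
    CultivarProfile("Koshihikari", 320.0),
)


def builtin_registry() -> list[CultivarProfile]:
    """The three built-in cultivar profiles."""
    return list(_BUILTIN)


def load_registry(path: Optional[str | PathLike] = None) -> list[CultivarProfile]:
    """Built-in profiles, optionally extended/overridden by a JSON file.

    The file is a JSON array of ``{"name": ..., "target_tillers_per_m2": ...}``
    objects; an entry whose name matches a built-in cultivar replaces it.
    """
    profiles = {p.name: p for p in _BUILTIN}
    if path is not None:
        with open(path) as fh:
            entries = json.load(fh)
        if not isinstance(entries, list):
            raise InputDomainError("registry JSON must be an array of profiles")
        for entry in entries:
            profile = CultivarProfile(
                str(entry["name"]), float(entry["target_tillers_per_m2"])
            )
            profiles[profile.name] = profile
    return list(profiles.values())


def resolve_cultivar(
    name: str, registry: Optional[Sequence[CultivarProfile]] = None
) -> CultivarProfile:
    """Exact, case-sensitive lookup of a cultivar profile."""
    for profile in registry if registry is not None else _BUILTIN:
        if profile.name == name:
            return profile
    raise UnknownCultivarError(f"unknown cultivar {name!r}")


@dataclass(frozen=True)
class DiagnosisResult:
    """Outcome of comparing an estimate against a cultivar target."""

    status: DiagnosisStatus
    estimated_tillers: float
    target_tillers: float
    margin: float  # estimated - target; >= 0 iff optimal timing
    cultivar: str

    def to_dict(self) -> dict:
        return {
            "status": self.status.value,
            "estimated_tillers": self.estimated_tillers,
            "target_tillers": self.target_tillers,
            "margin": self.margin,
            "cultivar": self.cultivar,
        }


def diagnose(estimated_tillers: float, profile: CultivarProfile) -> DiagnosisResult:
    """Apply the inclusive threshold rule: optimal iff estimate >= target."""
    if not np.isfinite(estimated_tillers) or estimated_tillers < 0:
        raise InputDomainError("estimated tiller number must be finite and >= 0")
    margin = float(estimated_tillers) - profile.target_tillers_per_m2
    status = (
        DiagnosisStatus.OPTIMAL_DRAINAGE_TIMING
        if margin >= 0
        else DiagnosisStatus.INSUFFICIENT_TILLER_NUMBER
    )
    return DiagnosisResult(
        status=status,
        estimated_tillers=float(estimated_tillers),
        target_tillers=profile.target_tillers_per_m2,
        margin=margin,
        cultivar=profile.name,
    )


@dataclass(frozen=True)
class DiagnosisRecord:
    """Full pipeline record: cover, estimate, and diagnosis."""

    cover: imaging.CoverResult
    estimate: estimation.TillerEstimate
    diagnosis: DiagnosisResult

    def to_dict(self) -> dict:
        return {
            "cover": self.cover.to_dict(),
            "estimate": self.estimate.to_dict(),
            "diagnosis": self.diagnosis.to_dict(),
        }


def diagnose_image(
    image,
    cultivar: str,
    model: Optional[estimation.QuadraticModel] = None,
    threshold: float = imaging.VEGETATION_THRESHOLD,
    registry: Optional[Sequence[CultivarProfile]] = None,
) -> DiagnosisRecord:
    """Run the whole pipeline on one image.

    Composition of ``segment -> cover_ratio -> estimate_tillers ->
    diagnose``; equivalent, value for value, to calling the four stages
    by hand.
    """
    profile = resolve_cultivar(cultivar, registry)
    if model is None:
        model = estimation.default_model()
    mask = imaging.segment(image, threshold=threshold)
    cover = imaging.cover_ratio(mask)
    estimate = estimation.estimate_tillers(model, cover.cover_percent)
    result = diagnose(estimate.tillers_per_m2, profile)
    return DiagnosisRecord(cover=cover, estimate=estimate, diagnosis=result)


class DrainageDiagnoser(BaseEstimator):
    """Threshold classifier over tiller estimates, scikit-learn style.

    ``predict`` maps an array of estimated tiller numbers to status
    strings for the configured cultivar.  ``fit`` only resolves the
    cultivar (there is nothing to learn: the target is an agronomic
    constant).

    Parameters
    ----------
    cultivar : str, default "Koshihikari"
        Name resolved against the registry.
    registry : sequence of CultivarProfile, optional
        Defaults to the built-in registry.
    """

    def __init__(self, cultivar: str = "Koshihikari", registry=None):
        self.cultivar = cultivar
        self.registry = registry

    def fit(self, X=None, y=None):
        self.profile_ = resolve_cultivar(self.cultivar, self.registry)
        self.classes_ = np.array([s.value for s in DiagnosisStatus])
        return self

    def predict(self, X):
        if not hasattr(self, "profile_"):
            self.fit()
        X = np.asarray(X, dtype=np.float64).ravel()
        return np.array([diagnose(v, self.profile_).status.value for v in X])
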