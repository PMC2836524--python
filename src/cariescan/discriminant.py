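"""Two-class linear discriminant for treatment planning.

Maps per-tooth features — fractal dimension (FD) of the pit-and-fissure
discoloration, area proportion (PA), and the laser-fluorescence reading
(DD) — to a preventive vs operative treatment decision via a linear score

    Y = sum_j c_j * x_j + intercept,      Y > 0  =>  operative.

Fitting uses the classic pooled-within-class-covariance discriminant with
class-frequency priors; the cut point is placed where Y = 0 at the
prior-weighted mean of the two class score means (i.e. the grand mean
score).  Four built-in reference models, derived from a 100-tooth clinical
sample of occlusal lesions, ship under the names ``reference-fd``,
``reference-pa``, ``reference-dd`` and ``reference-fd-pa``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PREVENTIVE",
    "OPERATIVE",
    "FeatureRecord",
    "DiscriminantModel",
    "REFERENCE_MODELS",
    "fit_discriminant",
    "predict",
    "decision_threshold",
]

PREVENTIVE = "preventive"
OPERATIVE = "operative"

#: diagnosis -> treatment mapping: C0 needs preventive care only; C1 (enamel
#: cavity) and C2 (dentin cavity, pulp intact) need operative treatment.
TREATMENT_BY_DIAGNOSIS = {"C0": PREVENTIVE, "C1": OPERATIVE, "C2": OPERATIVE}

SCORE_CONVENTION = "Y = coefficients . features + intercept; Y > 0 => operative"


@dataclass
class FeatureRecord:
    """Per-tooth feature vector with optional clinical labels.

    ``dd`` may be given as a sequence of replicate device readings, in
    which case their mean is stored.  A missing treatment label is derived
    from the diagnosis (C0 -> preventive, C1/C2 -> operative).
    """

    tooth_id: str
    fd: float | None = None
    pa: float | None = None
    dd: float | Sequence[float] | None = None
    diagnosis: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.dd is not None and not np.isscalar(self.dd):
            self.dd = float(np.mean(np.asarray(self.dd, dtype=float)))
        if self.fd is not None and not 0.0 <= self.fd <= 2.5:
            raise ValueError(f"fd out of range [0, 2.5]: {self.fd}")
        if self.pa is not None and not 0.0 <= self.pa <= 1.0:
            raise ValueError(f"pa out of range [0, 1]: {self.pa}")
        if self.dd is not None and not 0.0 <= self.dd <= 99.0:
            raise ValueError(f"dd out of range [0, 99]: {self.dd}")
        if self.diagnosis is not None:
            if self.diagnosis not in TREATMENT_BY_DIAGNOSIS:
                raise ValueError(f"unknown diagnosis: {self.diagnosis!r}")
            implied = TREATMENT_BY_DIAGNOSIS[self.diagnosis]
            if self.treatment is None:
                self.treatment = implied
            elif self.treatment != implied:
                raise ValueError(
                    f"treatment {self.treatment!r} inconsistent with diagnosis {self.diagnosis!r}"
                )
        if self.treatment is not None and self.treatment not in (PREVENTIVE, OPERATIVE):
            raise ValueError(f"unknown treatment label: {self.treatment!r}")

    def features(self) -> dict[str, float]:
        out = {}
        for name in ("fd", "pa", "dd"):
            v = getattr(self, name)
            if v is not None:
                out[name] = float(v)
        return out


@dataclass(frozen=True)
class DiscriminantModel:
    variables: tuple[str, ...]
    coefficients: tuple[float, ...]
    intercept: float
    convention: str = SCORE_CONVENTION

    def __post_init__(self) -> None:
        if len(self.variables) != len(self.coefficients):
            raise ValueError("one coefficient per variable required")

    def score(self, features: Mapping[str, float]) -> float:
        y = self.intercept
        for name, c in zip(self.variables, self.coefficients):
            if name not in features or features[name] is None:
                raise ValueError(f"missing feature: {name}")
            y += c * float(features[name])
        return y

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "variables": list(self.variables),
                "coefficients": [c.hex() for c in map(float, self.coefficients)],
                "intercept": float(self.intercept).hex(),
                "convention": self.convention,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "DiscriminantModel":
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = json.loads(text)
        return cls(
            variables=tuple(data["variables"]),
            coefficients=tuple(float.fromhex(c) if isinstance(c, str) else float(c) for c in data["coefficients"]),
            intercept=float.fromhex(data["intercept"]) if isinstance(data["intercept"], str) else float(data["intercept"]),
            convention=data.get("convention", SCORE_CONVENTION),
        )


#: Built-in reference discriminant formulas (clinical 100-tooth sample).
REFERENCE_MODELS: dict[str, DiscriminantModel] = {
    "reference-fd": DiscriminantModel(("fd",), (6.74,), -8.12),
    "reference-pa": DiscriminantModel(("pa",), (63.3,), -0.77),
    "reference-dd": DiscriminantModel(("dd",), (0.05,), -1.44),
    "reference-fd-pa": DiscriminantModel(("fd", "pa"), (5.68, 17.8), -7.29),
}


def _as_table(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for r in records:
        if isinstance(r, FeatureRecord):
            row = {"tooth_id": r.tooth_id, **r.features()}
            row["treatment"] = r.treatment
            rows.append(row)
        else:
            rows.append(dict(r))
    return pd.DataFrame(rows)


def fit_discriminant(records, variables: Sequence[str]) -> DiscriminantModel:
    """Fit the pooled-covariance linear discriminant on labeled records.

    ``records`` is a DataFrame (or iterable of :class:`FeatureRecord`)
    with a ``treatment`` column; ``variables`` selects the feature subset.
    The score is oriented so the operative class mean score is positive,
    and the intercept places Y = 0 at the frequency-weighted mean of the
    two class score means.
    """
    table = _as_table(records)
    variables = tuple(variables)
    if "treatment" not in table:
        raise ValueError("records must carry a treatment label")
    for v in variables:
        if v not in table or table[v].isna().any():
            raise ValueError(f"missing values in selected variable: {v}")
    y = table["treatment"].to_numpy()
    classes = set(y)
    if classes != {PREVENTIVE, OPERATIVE}:
        raise ValueError("both treatment classes must be present")
    X = table.loc[:, variables].to_numpy(dtype=float)
    X0 = X[y == PREVENTIVE]
    X1 = X[y == OPERATIVE]
    n0, n1 = len(X0), len(X1)
    if n0 < 2 or n1 < 2:
        raise ValueError("need >= 2 records per class")
    mu0 = X0.mean(axis=0)
    mu1 = X1.mean(axis=0)
    s0 = np.cov(X0, rowvar=False).reshape(len(variables), len(variables))
    s1 = np.cov(X1, rowvar=False).reshape(len(variables), len(variables))
    pooled = ((n0 - 1) * s0 + (n1 - 1) * s1) / (n0 + n1 - 2)
    try:
        w = np.linalg.solve(pooled, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate features: singular pooled covariance") from exc
    if not np.all(np.isfinite(w)):
        raise ValueError("degenerate features: singular pooled covariance")
    pi0 = n0 / (n0 + n1)
    pi1 = n1 / (n0 + n1)
    grand = pi0 * (w @ mu0) + pi1 * (w @ mu1)
    return DiscriminantModel(variables=variables, coefficients=tuple(map(float, w)), intercept=float(-grand))


def predict(model: DiscriminantModel, record) -> tuple[str, float]:
    """Score one record and return (treatment label, Y).

    Y > 0 maps to operative; the tie Y = 0 maps to preventive (the
    conservative choice for a screening tool).
    """
    features = record.features() if isinstance(record, FeatureRecord) else record
    y = model.score(features)
    return (OPERATIVE if y > 0 else PREVENTIVE), y


def decision_threshold(model: DiscriminantModel) -> float:
    """Feature-axis cut point -intercept/coefficient of a 1-variable model."""
    nonzero = [(v, c) for v, c in zip(model.variables, model.coefficients) if c != 0.0]
    if len(model.variables) != 1 or len(nonzero) != 1:
        raise ValueError("decision threshold is defined for single-variable models only")
    _, c = nonzero[0]
    return -model.intercept / c
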