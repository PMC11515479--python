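"""Candidate regressor catalogue over the 17 base variables.

Every base variable (the 15 recorded channels plus the derived oxygen
indices O2diff and O2quot) contributes its identity, square and cube as
candidate regressors; the natural logarithm is added only for bases that
are strictly positive in every kept sample, so no log cell can be
undefined.  The untransformed etCO2 term is not a candidate: it is forced
into the model from the start.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .channels import BASE_VARIABLES
from .errors import DesignMatrixError, DomainError
from .preprocess import AveragedSample

TRANSFORMS = ("identity", "square", "cube", "log")


@dataclass(frozen=True, order=True)
class CandidateDescriptor:
    """One candidate regressor: a base variable and a transform."""

    base: str
    transform: str

    @property
    def label(self) -> str:
        if self.transform == "identity":
            return self.base
        if self.transform == "square":
            return f"{self.base}^2"
        if self.transform == "cube":
            return f"{self.base}^3"
        return f"log({self.base})"

    def apply(self, x: float) -> float:
        if self.transform == "identity":
            return float(x)
        if self.transform == "square":
            return float(x) ** 2
        if self.transform == "cube":
            return float(x) ** 3
        if x <= 0:
            raise DomainError(f"log transform of non-positive value {x} "
                              f"for base {self.base!r}")
        return float(np.log(x))


#: The term always present in the model besides the intercept.
FORCED_TERM = CandidateDescriptor("etCO2", "identity")


def derive_oxygen_indices(sample: AveragedSample) -> tuple[float, float]:
    """Oxygenation indices from averaged FiO2 and SpO2.

    O2diff = FiO2 - SpO2 (%, typically negative) and O2quot = SpO2 / FiO2
    (unitless); both are simple markers of how much inspired oxygen is
    needed to reach the observed saturation.
    """
    fio2 = sample.values.get("FiO2")
    spo2 = sample.values.get("SpO2")
    if fio2 is None or spo2 is None:
        raise DomainError("FiO2 and SpO2 required to derive oxygen indices")
    if fio2 <= 0:
        raise DomainError("FiO2 must be positive")
    if not 0 <= spo2 <= 100:
        raise DomainError("SpO2 must lie in [0, 100]")
    return fio2 - spo2, spo2 / fio2


def base_variable_values(sample: AveragedSample) -> dict[str, float]:
    """The 17 base-variable values of a sample (channels + derived indices)."""
    out = dict(sample.values)
    o2diff, o2quot = derive_oxygen_indices(sample)
    out["O2diff"] = o2diff
    out["O2quot"] = o2quot
    return out


def enumerate_candidates(samples: Sequence[AveragedSample],
                         forced: CandidateDescriptor = FORCED_TERM
                         ) -> list[CandidateDescriptor]:
    """Enumerate the candidate catalogue for a set of complete samples.

    Order is canonical and stable: bases in catalogue order, transforms in
    the order identity < square < cube < log.  The log transform is
    emitted only for bases strictly positive in every sample; the forced
    term is excluded from the pool.
    """
    if not samples:
        raise DomainError("enumerate_candidates requires at least one sample")
    table = {name: np.array([base_variable_values(s)[name] for s in samples])
             for name in BASE_VARIABLES}
    catalogue: list[CandidateDescriptor] = []
    for name in BASE_VARIABLES:
        eligible = bool(np.all(table[name] > 0))
        for transform in TRANSFORMS:
            if transform == "log" and not eligible:
                continue
            desc = CandidateDescriptor(name, transform)
            if desc == forced:
                continue
            catalogue.append(desc)
    return catalogue


@dataclass
class DesignMatrix:
    """Regression inputs: transformed candidate columns and the response."""

    X: np.ndarray                      # (n_samples, n_candidates)
    y: np.ndarray                      # PaCO2 (mmHg)
    descriptors: list[CandidateDescriptor]
    sample_ids: list[str]

    def column(self, desc: CandidateDescriptor) -> np.ndarray:
        return self.X[:, self.descriptors.index(desc)]


def build_design_matrix(samples: Sequence[AveragedSample],
                        catalogue: Iterable[CandidateDescriptor]
                        ) -> DesignMatrix:
    """Evaluate every catalogue transform on every sample.

    Raises :class:`DesignMatrixError` naming the offending row and column
    if any transformed value is non-finite.
    """
    descriptors = list(catalogue)
    n, p = len(samples), len(descriptors)
    X = np.empty((n, p))
    y = np.empty(n)
    ids: list[str] = []
    for i, s in enumerate(samples):
        base = base_variable_values(s)
        for j, d in enumerate(descriptors):
            try:
                X[i, j] = d.apply(base[d.base])
            except (DomainError, KeyError) as exc:
                raise DesignMatrixError(
                    f"row {i} (animal {s.animal_id!r}, t={s.reference_time}), "
                    f"column {d.label!r}: {exc}") from exc
        if not np.isfinite(X[i]).all():
            j = int(np.flatnonzero(~np.isfinite(X[i]))[0])
            raise DesignMatrixError(
                f"non-finite value in row {i}, column {descriptors[j].label!r}")
        if s.paco2 is None:
            raise DesignMatrixError(f"row {i} has no PaCO2 response")
        y[i] = s.paco2
        ids.append(s.animal_id)
    return DesignMatrix(X=X, y=y, descriptors=descriptors, sample_ids=ids)
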