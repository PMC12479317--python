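"""Estimand definitions: counterfactual means, ATEs, and k-point
average interaction effects (AIEs).

An AIE of order ``k`` is an alternating signed sum of covariate-adjusted
counterfactual outcome means over the ``2**k`` vertices of the hypercube
spanned by per-treatment (baseline, target) level pairs.  The ATE is the
``k = 1`` special case; a counterfactual mean is a single vertex with
positive sign.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TreatmentLevels",
    "Contrast",
    "EstimandSpec",
    "VertexWeight",
    "vertex_weights",
    "estimand_vertices",
    "plugin_estimate",
    "InvalidEstimandError",
    "IncompleteNuisanceError",
]


class InvalidEstimandError(ValueError):
    """Raised when an estimand specification is internally inconsistent."""


class IncompleteNuisanceError(ValueError):
    """Raised when nuisance predictions are missing for a required vertex."""


@dataclass(frozen=True)
class TreatmentLevels:
    """Declared, ordered category labels of one treatment variable.

    The ordering is meaningful: it defines what "one additional copy"
    contrasts (e.g. ``0 -> 1`` and ``1 -> 2`` for genotype dosages, or
    ``"TT" -> "TC"`` for allele strings) refer to.
    """

    name: str
    levels: tuple

    def __post_init__(self):
        if len(self.levels) < 2:
            raise InvalidEstimandError(
                f"treatment {self.name!r} needs at least 2 levels"
            )
        if len(set(self.levels)) != len(self.levels):
            raise InvalidEstimandError(
                f"treatment {self.name!r} has duplicate levels"
            )

    def index_of(self, level) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise InvalidEstimandError(
                f"level {level!r} not among levels of treatment {self.name!r}"
            ) from None

    def adjacent_contrasts(self) -> list[tuple]:
        """All (level, next level) pairs in declared order."""
        return list(zip(self.levels[:-1], self.levels[1:]))


@dataclass(frozen=True)
class Contrast:
    """Per-treatment (baseline, target) level pairs for a k-dim estimand."""

    pairs: tuple  # tuple of (baseline, target) tuples, one per treatment

    def __post_init__(self):
        for base, target in self.pairs:
            if base == target:
                raise InvalidEstimandError(
                    f"baseline and target coincide ({base!r}) in contrast"
                )

    @property
    def k(self) -> int:
        return len(self.pairs)

    @property
    def baseline(self) -> tuple:
        return tuple(p[0] for p in self.pairs)

    @property
    def target(self) -> tuple:
        return tuple(p[1] for p in self.pairs)

    def label(self) -> str:
        return "&".join(f"{b}->{t}" for b, t in self.pairs)


@dataclass(frozen=True)
class EstimandSpec:
    """A single estimand: what to estimate, on which columns.

    kind:
        ``"counterfactual_mean"`` — adjusted mean at the contrast target;
        ``"ate"`` — order-1 difference; ``"aie"`` — order-k (k >= 2)
        interaction.
    """

    kind: str
    outcome: str
    treatments: tuple
    contrast: Contrast
    confounders: tuple = ()
    covariates: tuple = ()
    outcome_family: str = "gaussian"  # or "binomial"
    treatment_levels: Mapping[str, TreatmentLevels] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("counterfactual_mean", "ate", "aie"):
            raise InvalidEstimandError(f"unknown estimand kind {self.kind!r}")
        if len(self.treatments) != len(set(self.treatments)):
            raise InvalidEstimandError("treatment names must be distinct")
        if self.contrast.k != len(self.treatments):
            raise InvalidEstimandError(
                "number of contrast pairs must equal number of treatments"
            )
        if self.kind == "ate" and self.k != 1:
            raise InvalidEstimandError("ATE requires exactly one treatment")
        if self.kind == "aie" and self.k < 2:
            raise InvalidEstimandError("AIE requires order k >= 2")
        # validate levels against declared orderings when available
        for name, (base, target) in zip(self.treatments, self.contrast.pairs):
            tl = self.treatment_levels.get(name)
            if tl is not None:
                tl.index_of(base)
                tl.index_of(target)

    @property
    def k(self) -> int:
        return self.contrast.k

    def columns(self) -> list[str]:
        return (
            [self.outcome]
            + list(self.treatments)
            + list(self.confounders)
            + list(self.covariates)
        )

    def label(self) -> str:
        return f"{self.kind}:{self.outcome}~{'*'.join(self.treatments)}[{self.contrast.label()}]"


@dataclass(frozen=True)
class VertexWeight:
    """One vertex of the contrast hypercube with its alternating sign."""

    s: tuple  # binary selector, length k
    assignment: tuple  # treatment levels chosen by s
    sign: int  # (-1) ** (k - sum(s))


def vertex_weights(contrast: Contrast, k: int) -> list[VertexWeight]:
    """Enumerate the ``2**k`` signed vertices of a k-point interaction.

    Vertex ``s`` picks the baseline level where ``s_i = 0`` and the target
    level where ``s_i = 1``; its sign is ``(-1) ** (k - sum(s))``.  Vertices
    are returned in lexicographic order of ``s`` for reproducible reporting.
    """
    if k <= 0:
        raise InvalidEstimandError(f"interaction order must be >= 1, got {k}")
    if contrast.k != k:
        raise InvalidEstimandError(
            f"contrast has {contrast.k} pairs but k={k} was requested"
        )
    out = []
    for s in itertools.product((0, 1), repeat=k):
        assignment = tuple(
            pair[si] for pair, si in zip(contrast.pairs, s)
        )
        sign = (-1) ** (k - sum(s))
        out.append(VertexWeight(s=s, assignment=assignment, sign=sign))
    return out


def estimand_vertices(spec: EstimandSpec) -> list[VertexWeight]:
    """Signed vertices of an estimand.

    A counterfactual mean is a single positively-signed vertex at the
    contrast target; ATE/AIE expand the full signed hypercube.
    """
    if spec.kind == "counterfactual_mean":
        return [
            VertexWeight(s=(1,) * spec.k, assignment=spec.contrast.target, sign=1)
        ]
    return vertex_weights(spec.contrast, spec.k)


def plugin_estimate(
    vertices: Sequence[VertexWeight],
    qbar_at_vertices: Mapping[tuple, np.ndarray],
) -> float:
    """Substitution estimator over the empirical covariate distribution.

    Returns ``sum_s sign_s * mean_i Qbar(a(s), W_i)``.
    """
    total = 0.0
    for v in vertices:
        preds = qbar_at_vertices.get(v.assignment)
        if preds is None:
            raise IncompleteNuisanceError(
                f"missing outcome predictions at vertex {v.assignment!r}"
            )
        total += v.sign * float(np.mean(preds))
    return total
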