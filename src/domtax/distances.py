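"""Step 2 — pairwise species distances from profile overlap.

Every distance is a function of the overlap triple (a, b, c): the profile
sizes of species A and B and the size of their shared part. For the set
models (content, organization) these are plain set cardinalities; for the
frequency models they are multiset totals with elementwise-minimum sharing.

Three distance models are provided, all ranging over [0, 1]:

Jaccard
    ``(a + b − 2c) / (a + b − c)`` — one minus the fraction of the union
    that is shared; assumes domain changes are random and independent.
Poisson
    ``sqrt(−ln(c/a) · −ln(c/b))`` — the geometric mean of each species'
    Poisson-process distance to the common ancestor, clamped at 1 (the raw
    expression is unbounded as c → 0; c = 0 maps to 1).
loss-corrected
    ``1 − c / min(a, b)`` — measures against the smaller profile so that
    massive loss in one lineage does not inflate the distance.

Empty profiles (no surviving domain hits) get distance 1 to any non-empty
profile and 0 to another empty profile, with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from domtax.profiles import SpeciesProfile

logger = logging.getLogger(__name__)

#: The three distance models, in canonical order, with their short names.
DISTANCE_MODELS = ("jaccard", "poisson", "loss_corrected")

#: Abbreviations used in combination names (e.g. "org_ja").
DISTANCE_ABBREV = {"jaccard": "ja", "poisson": "po", "loss_corrected": "lo"}
MODEL_ABBREV = {
    "content": "con",
    "organization": "org",
    "f_content": "f_con",
    "f_organization": "f_org",
}


@dataclass(frozen=True)
class ProfileOverlap:
    """The (a, b, c) triple: sizes of two profiles and of their overlap."""

    a: int
    b: int
    c: int
    model: str = "content"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("overlap counts must be non-negative")
        if self.c > min(self.a, self.b):
            raise ValueError(f"c ({self.c}) exceeds min(a, b) = {min(self.a, self.b)}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise species distances for one model combination."""

    species_ids: list[str]
    values: np.ndarray
    statistical_model: str
    distance_model: str

    def __post_init__(self) -> None:
        n = len(self.species_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} species"
            )

    def validate(self) -> None:
        """Check symmetry, zero diagonal and the [0, 1] range."""
        v = self.values
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("distances must lie in [0, 1]")


def profile_overlap(p: SpeciesProfile, q: SpeciesProfile) -> ProfileOverlap:
    """Compute (a, b, c) for two profiles built under the same model.

    Set models: a = |p|, b = |q|, c = |p ∩ q|. Frequency models use
    multiset semantics: a and b are total counts and c sums the
    elementwise minimum count over shared keys.
    """
    if p.model != q.model:
        raise ValueError(f"profile models differ: {p.model!r} vs {q.model!r}")
    if isinstance(p.items, Mapping):
        a = sum(p.items.values())
        b = sum(q.items.values())
        c = sum(min(n, q.items[k]) for k, n in p.items.items() if k in q.items)
    else:
        a, b = len(p.items), len(q.items)
        c = len(p.items & q.items)
    return ProfileOverlap(a=a, b=b, c=c, model=p.model)


def jaccard_distance(o: ProfileOverlap) -> float:
    """Jaccard distance (a + b − 2c) / (a + b − c), in [0, 1]."""
    union = o.a + o.b - o.c
    if union == 0:
        logger.warning("Jaccard distance of two empty profiles defined as 0")
        return 0.0
    return (o.a + o.b - 2 * o.c) / union


def poisson_distance(o: ProfileOverlap) -> float:
    """Poisson-process distance sqrt(−ln(c/a) · −ln(c/b)), clamped to 1."""
    if o.a == 0 or o.b == 0:
        return _empty_profile_distance(o)
    if o.c == 0:
        return 1.0
    raw = math.sqrt(math.log(o.a / o.c) * math.log(o.b / o.c))
    return min(raw, 1.0)


def loss_corrected_distance(o: ProfileOverlap) -> float:
    """Loss-corrected distance 1 − c / min(a, b), in [0, 1]."""
    if min(o.a, o.b) == 0:
        return _empty_profile_distance(o)
    if o.a <= o.b:
        return (o.a - o.c) / o.a
    return (o.b - o.c) / o.b


def _empty_profile_distance(o: ProfileOverlap) -> float:
    """Distance involving at least one empty profile: 1 against a
    non-empty profile, 0 against another empty one."""
    logger.warning("distance involving an empty profile (a=%d, b=%d)", o.a, o.b)
    return 0.0 if o.a == o.b == 0 else 1.0


_DISTANCE_FUNCS: dict[str, Callable[[ProfileOverlap], float]] = {
    "jaccard": jaccard_distance,
    "poisson": poisson_distance,
    "loss_corrected": loss_corrected_distance,
}


def distance_function(distance_model: str) -> Callable[[ProfileOverlap], float]:
    try:
        return _DISTANCE_FUNCS[distance_model]
    except KeyError:
        raise ValueError(
            f"unknown distance model {distance_model!r}; expected one of {DISTANCE_MODELS}"
        ) from None


def distance_matrix(
    profiles: Sequence[SpeciesProfile], distance_model: str
) -> DistanceMatrix:
    """Assemble the full symmetric distance matrix over a profile list.

    All profiles must share one statistical model and carry distinct
    species IDs; the diagonal is exactly zero.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 species to build a distance matrix")
    models = {p.model for p in profiles}
    if len(models) > 1:
        raise ValueError(f"profiles mix statistical models: {sorted(models)}")
    ids = [p.species_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species_id in profile list")
    func = distance_function(distance_model)
    n = len(profiles)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = func(profile_overlap(profiles[i], profiles[j]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(
        species_ids=ids,
        values=values,
        statistical_model=models.pop(),
        distance_model=distance_model,
    )
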