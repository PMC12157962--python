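"""Attribute spaces, dummy coding, sample-size rules and blocked choice designs.

The canonical attribute space describes seven nonpharmaceutical interventions
(NPIs) offered in a stated-preference survey: mask mandates, dining-in group
limits, vocalization activities, large-scale events, post-travel quarantine,
vaccine-booster mandates, and a one-time fee (SGD) that identifies willingness
to pay.  Every categorical attribute is dummy coded against its least stringent
level ("no restriction"); alternatives additionally carry an alternative-
specific constant for the first-listed (left) position so a left-right reading
bias is estimable.

Designs are unlabeled, one-stage, and blocked: ``B`` blocks of ``a`` binary
choice tasks, each task showing ``t`` full-profile alternatives.  The
generator is a seeded swap-based optimizer of a composite criterion combining
level balance, D-efficiency of the dummy-coded design at zero coefficients,
and a moderate-overlap penalty (the "balanced overlap" idea: some attribute
repetition within a task eases the respondent's comparison without destroying
statistical efficiency).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import DesignError, EncodingError

__all__ = [
    "Attribute",
    "AttributeSpace",
    "DesignDims",
    "DesignWeights",
    "ChoiceDesign",
    "SampleSize",
    "sample_size_requirements",
    "generate_design",
    "design_score",
    "encode_alternative",
    "decode_alternative",
]


@dataclass(frozen=True)
class Attribute:
    """One survey attribute: an ordered tuple of levels, reference first.

    ``kind`` is ``"categorical"`` (dummy coded) or ``"cost"`` (entered
    linearly); a cost attribute carries the money value of each level in
    ``values`` (SGD).
    """

    name: str
    levels: tuple[str, ...]
    kind: str = "categorical"
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise DesignError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise DesignError(f"attribute {self.name!r} has duplicate levels")
        if self.kind not in ("categorical", "cost"):
            raise DesignError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "cost":
            if self.values is None or len(self.values) != len(self.levels):
                raise DesignError(
                    f"cost attribute {self.name!r} needs one money value per level"
                )


@dataclass(frozen=True)
class AttributeSpace:
    """An ordered collection of attributes defining the full profile space.

    At most one attribute may be a cost attribute; willingness-to-pay
    reporting requires one.  Level index 0 of every categorical attribute is
    its reference (least stringent) level.
    """

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        if not self.attributes:
            raise DesignError("attribute space is empty")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise DesignError("attribute names must be unique")
        if sum(a.kind == "cost" for a in self.attributes) > 1:
            raise DesignError("at most one cost attribute is allowed")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_attributes(self) -> int:
        return len(self.attributes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(a.levels) for a in self.attributes)

    @property
    def n_profiles(self) -> int:
        return int(np.prod(self.shape))

    @property
    def max_levels(self) -> int:
        return max(self.shape)

    @property
    def cost_attribute(self) -> Attribute | None:
        for a in self.attributes:
            if a.kind == "cost":
                return a
        return None

    # -- encoding layout ---------------------------------------------------

    @property
    def predictor_names(self) -> list[str]:
        """Column names of the encoded matrix: left ASC, dummies, cost."""
        names = ["asc_left"]
        for a in self.attributes:
            if a.kind == "cost":
                names.append(a.name)
            else:
                names.extend(f"{a.name}:{lvl}" for lvl in a.levels[1:])
        return names

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    def attribute_index(self, name: str) -> int:
        for i, a in enumerate(self.attributes):
            if a.name == name:
                return i
        raise KeyError(name)

    # -- profile arithmetic (mixed radix over level indices) ----------------

    def profile_levels(self, profile_idx: np.ndarray | int) -> np.ndarray:
        """Map flat profile indices to per-attribute level indices."""
        arr = np.unravel_index(np.asarray(profile_idx), self.shape)
        return np.stack(arr, axis=-1)

    def profile_index(self, levels: Sequence[int] | np.ndarray) -> np.ndarray | int:
        levels = np.asarray(levels)
        return np.ravel_multi_index(tuple(np.moveaxis(levels, -1, 0)), self.shape)

    def profile_matrix(self) -> np.ndarray:
        """Encoded rows (without ASC) for the full factorial, profile-major."""
        out = np.zeros((self.n_profiles, self.n_predictors - 1))
        lv = self.profile_levels(np.arange(self.n_profiles))
        col = 0
        for j, a in enumerate(self.attributes):
            if a.kind == "cost":
                out[:, col] = np.asarray(a.values)[lv[:, j]]
                col += 1
            else:
                for k in range(1, len(a.levels)):
                    out[:, col] = lv[:, j] == k
                    col += 1
        return out

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "attributes": [
                {
                    "name": a.name,
                    "levels": list(a.levels),
                    "kind": a.kind,
                    **({"values": list(a.values)} if a.values is not None else {}),
                }
                for a in self.attributes
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AttributeSpace":
        return cls(
            tuple(
                Attribute(
                    name=a["name"],
                    levels=tuple(a["levels"]),
                    kind=a.get("kind", "categorical"),
                    values=tuple(a["values"]) if "values" in a else None,
                )
                for a in d["attributes"]
            )
        )

    @classmethod
    def canonical(cls) -> "AttributeSpace":
        """The seven-attribute NPI space used throughout: masks (3 levels),
        dining-in (4), vocalization (2), large events (2), quarantine (3),
        booster (2), and a one-time fee of 0/10/30/50 SGD."""
        return cls(
            (
                Attribute("masks", ("none", "mandatory_public", "mandatory_indoors")),
                Attribute("dining", ("any_group", "not_allowed", "two_people", "five_people")),
                Attribute("vocalization", ("allowed", "not_allowed")),
                Attribute("large_events", ("allowed", "not_allowed")),
                Attribute("quarantine", ("none", "government_facility", "home")),
                Attribute("booster", ("not_compulsory", "compulsory")),
                Attribute("fee", ("0", "10", "30", "50"), kind="cost", values=(0.0, 10.0, 30.0, 50.0)),
            )
        )


class DesignDims(NamedTuple):
    """Blocked design dimensions: B blocks × a tasks × t alternatives; ``c``
    is the largest level count over attributes (the Orme formula's symbol)."""

    n_blocks: int
    tasks_per_block: int
    alts_per_task: int
    max_levels: int

    @classmethod
    def for_space(
        cls, space: AttributeSpace, n_blocks: int = 20, tasks_per_block: int = 7, alts_per_task: int = 2
    ) -> "DesignDims":
        return cls(n_blocks, tasks_per_block, alts_per_task, space.max_levels)


class SampleSize(NamedTuple):
    orme_n: int
    block_rule_n: int
    recommended_n: int


def sample_size_requirements(dims: DesignDims, per_block_rule: int = 20) -> SampleSize:
    """Minimum respondent counts under two stated-preference rules of thumb.

    The Johnson–Orme rule requires ``n > 500 c / (t a)`` respondents, where
    ``c`` is the largest number of levels of any attribute, ``t`` the number
    of alternatives per task and ``a`` the number of tasks per block
    (ceiling-rounded).  The per-block rule requires ``per_block_rule``
    respondents for each of the ``B`` blocks.  The recommendation is the
    larger of the two.
    """
    B, a, t, c = dims.n_blocks, dims.tasks_per_block, dims.alts_per_task, dims.max_levels
    if min(B, a, t, c) <= 0 or per_block_rule <= 0:
        raise DesignError("all design dimensions must be positive")
    if t < 2:
        raise DesignError("need at least 2 alternatives per task")
    orme = math.ceil(500 * c / (t * a))
    block = per_block_rule * B
    return SampleSize(orme, block, max(orme, block))


# ---------------------------------------------------------------------------
# alternative encoding


def _resolve_levels(space: AttributeSpace, levels) -> np.ndarray:
    """Accept level indices, level labels, or a name→label mapping."""
    if isinstance(levels, Mapping):
        out = []
        for a in space.attributes:
            if a.name not in levels:
                raise EncodingError(f"missing attribute {a.name!r}")
            out.append(levels[a.name])
        levels = out
    if len(levels) != space.n_attributes:
        raise EncodingError(
            f"expected {space.n_attributes} levels, got {len(levels)}"
        )
    idx = np.empty(space.n_attributes, dtype=np.int64)
    for j, (a, lv) in enumerate(zip(space.attributes, levels)):
        if isinstance(lv, str):
            try:
                idx[j] = a.levels.index(lv)
            except ValueError:
                raise EncodingError(f"unknown level {lv!r} for attribute {a.name!r}") from None
        else:
            lv = int(lv)
            if not 0 <= lv < len(a.levels):
                raise EncodingError(f"level index {lv} out of range for {a.name!r}")
            idx[j] = lv
    return idx


def encode_alternative(space: AttributeSpace, levels, left: bool = False) -> np.ndarray:
    """Dummy-code one alternative; money enters linearly; index 0 is the ASC.

    An all-reference alternative with zero fee encodes to the zero vector
    (ASC aside)."""
    idx = _resolve_levels(space, levels)
    vec = np.zeros(space.n_predictors)
    vec[0] = 1.0 if left else 0.0
    col = 1
    for j, a in enumerate(space.attributes):
        if a.kind == "cost":
            vec[col] = a.values[idx[j]]
            col += 1
        else:
            k = idx[j]
            if k > 0:
                vec[col + k - 1] = 1.0
            col += len(a.levels) - 1
    return vec


def decode_alternative(space: AttributeSpace, vector: np.ndarray) -> tuple[dict, bool]:
    """Invert :func:`encode_alternative`; raises if the vector is malformed."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (space.n_predictors,):
        raise EncodingError("encoded vector has the wrong width")
    left = bool(round(vector[0]))
    out: dict[str, str] = {}
    col = 1
    for a in space.attributes:
        if a.kind == "cost":
            vals = np.asarray(a.values)
            hit = np.flatnonzero(np.isclose(vals, vector[col]))
            if hit.size == 0:
                raise EncodingError(f"{a.name!r}: {vector[col]} is not a design level")
            out[a.name] = a.levels[hit[0]]
            col += 1
        else:
            L = len(a.levels)
            block = vector[col : col + L - 1]
            on = np.flatnonzero(np.isclose(block, 1.0))
            if np.any(~(np.isclose(block, 0.0) | np.isclose(block, 1.0))) or on.size > 1:
                raise EncodingError(f"{a.name!r}: invalid dummy block {block}")
            out[a.name] = a.levels[on[0] + 1] if on.size else a.levels[0]
            col += L - 1
    return out, left


# ---------------------------------------------------------------------------
# design generation


@dataclass(frozen=True)
class DesignWeights:
    """Non-negative weights of the composite design criterion.

    ``overlap_target`` is the per-task fraction of attributes that may share
    one level across alternatives; pushing toward a moderate value rather
    than zero is what distinguishes a balanced-overlap design from a purely
    D-efficient one."""

    balance: float = 2.0
    d_efficiency: float = 1.0
    overlap: float = 1.0
    overlap_target: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.balance, self.d_efficiency, self.overlap) < 0:
            raise DesignError("weights must be non-negative")


@dataclass(frozen=True)
class ChoiceDesign:
    """A blocked design stored as flat profile indices, shape (B, a, t)."""

    space: AttributeSpace
    profiles: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles)
        if p.ndim != 3:
            raise DesignError("profiles must have shape (blocks, tasks, alternatives)")
        if p.shape[2] < 2:
            raise DesignError("each task needs at least 2 alternatives")
        if np.any(p < 0) or np.any(p >= self.space.n_profiles):
            raise DesignError("profile index out of range")
        # no exact-duplicate alternatives within a task
        for b, s in itertools.product(range(p.shape[0]), range(p.shape[1])):
            if len(set(p[b, s].tolist())) != p.shape[2]:
                raise DesignError(f"duplicate alternatives in block {b}, task {s}")
        object.__setattr__(self, "profiles", p)

    @property
    def dims(self) -> DesignDims:
        B, a, t = self.profiles.shape
        return DesignDims(B, a, t, self.space.max_levels)

    def levels_array(self) -> np.ndarray:
        """Per-attribute level indices, shape (B, a, t, n_attributes)."""
        return self.space.profile_levels(self.profiles)

    def encoded(self) -> np.ndarray:
        """Encoded design, shape (B, a, t, P); alternative 0 carries the ASC."""
        Xp = self.space.profile_matrix()[self.profiles]  # (B,a,t,P-1)
        B, a, t, _ = Xp.shape
        X = np.zeros((B, a, t, self.space.n_predictors))
        X[..., 1:] = Xp
        X[..., 0, 0] = 1.0  # left-listed alternative
        return X

    def to_frame(self):
        import pandas as pd

        lv = self.levels_array()
        B, a, t, _ = lv.shape
        rows = []
        for b, s, j in itertools.product(range(B), range(a), range(t)):
            row = {"block": b, "task": s, "alternative": j, "left_asc": int(j == 0)}
            for k, attr in enumerate(self.space.attributes):
                row[attr.name] = attr.levels[lv[b, s, j, k]]
                if attr.kind == "cost":
                    row[f"{attr.name}_value"] = attr.values[lv[b, s, j, k]]
            rows.append(row)
        return pd.DataFrame(rows)


def _balance_deviation(space: AttributeSpace, levels_flat: np.ndarray) -> float:
    # mean absolute deviation of level counts from perfect balance, per slot
    n = levels_flat.shape[0]
    dev = 0.0
    for j, L in enumerate(space.shape):
        counts = np.bincount(levels_flat[:, j], minlength=L)
        dev += np.abs(counts - n / L).sum()
    return dev / (n * space.n_attributes)


def _overlap_fractions(levels: np.ndarray) -> np.ndarray:
    # fraction of attributes fully overlapped (same level for all alts) per task
    same = (levels == levels[..., :1, :]).all(axis=-2)  # (B,a,n_attr)
    return same.mean(axis=-1)


def design_score(
    space: AttributeSpace,
    profiles: np.ndarray,
    weights: DesignWeights = DesignWeights(),
    _Xall: np.ndarray | None = None,
) -> tuple[float, dict]:
    """Composite score (lower is better) and its components.

    Components: ``balance`` — mean absolute level-count deviation;
    ``d_error`` — det(information)^(−1/P) of the encoded design under zero
    coefficients (ASC included); ``overlap`` — mean squared distance of the
    per-task full-overlap fraction from the target.
    """
    profiles = np.asarray(profiles)
    B, a, t = profiles.shape
    levels = space.profile_levels(profiles)
    balance = _balance_deviation(space, levels.reshape(-1, space.n_attributes))
    overlap = float(np.mean((_overlap_fractions(levels) - weights.overlap_target) ** 2))

    if _Xall is None:
        _Xall = space.profile_matrix()
    X = np.zeros((B * a, t, space.n_predictors))
    X[..., 1:] = _Xall[profiles.reshape(B * a, t)]
    X[:, 0, 0] = 1.0
    Z = X - X.mean(axis=1, keepdims=True)
    info = np.einsum("stp,stq->pq", Z, Z) / (t * B * a)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        d_error = 1e6
    else:
        d_error = float(np.exp(-logdet / space.n_predictors))

    total = (
        weights.balance * balance
        + weights.d_efficiency * d_error
        + weights.overlap * overlap
    )
    return total, {"balance": balance, "d_error": d_error, "overlap": overlap}


def _random_design(space: AttributeSpace, dims: DesignDims, rng: np.random.Generator) -> np.ndarray:
    B, a, t = dims.n_blocks, dims.tasks_per_block, dims.alts_per_task
    out = np.empty((B, a, t), dtype=np.int64)
    for b, s in itertools.product(range(B), range(a)):
        out[b, s] = rng.choice(space.n_profiles, size=t, replace=False)
    return out


def generate_design(
    space: AttributeSpace,
    dims: DesignDims | None = None,
    seed: int = 0,
    weights: DesignWeights = DesignWeights(),
    n_iter: int = 6000,
) -> ChoiceDesign:
    """Seeded swap-based optimization of the composite design criterion.

    Starts from a uniformly random design (no duplicate alternatives within a
    task) and proposes single-attribute level changes, accepting strict
    improvements.  Deterministic given ``seed``.
    """
    if dims is None:
        dims = DesignDims.for_space(space)
    B, a, t = dims.n_blocks, dims.tasks_per_block, dims.alts_per_task
    if min(B, a) < 1 or t < 2:
        raise DesignError("need B>=1, a>=1, t>=2")
    if t > space.n_profiles:
        raise DesignError(
            f"infeasible: {t} alternatives requested but only "
            f"{space.n_profiles} distinct profiles exist"
        )

    rng = np.random.default_rng(seed)
    prof = _random_design(space, dims, rng)
    Xall = space.profile_matrix()
    strides = np.array(
        [int(np.prod(space.shape[j + 1 :])) for j in range(space.n_attributes)],
        dtype=np.int64,
    )
    score, _ = design_score(space, prof, weights, _Xall=Xall)

    n_attr = space.n_attributes
    bs = rng.integers(0, B, size=n_iter)
    ss = rng.integers(0, a, size=n_iter)
    js = rng.integers(0, t, size=n_iter)
    ks = rng.integers(0, n_attr, size=n_iter)
    us = rng.random(n_iter)
    for it in range(n_iter):
        b, s, j, k = bs[it], ss[it], js[it], ks[it]
        L = space.shape[k]
        cur = prof[b, s, j]
        cur_level = (cur // strides[k]) % L
        new_level = int(us[it] * (L - 1))
        if new_level >= cur_level:
            new_level += 1
        cand = cur + (new_level - cur_level) * strides[k]
        if cand in prof[b, s]:
            continue
        old = prof[b, s, j]
        prof[b, s, j] = cand
        new_score, _ = design_score(space, prof, weights, _Xall=Xall)
        if new_score < score - 1e-12:
            score = new_score
        else:
            prof[b, s, j] = old
    return ChoiceDesign(space=space, profiles=prof, seed=seed)
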