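"""Data model for two-stage SMART trajectories.

A SMART (sequential multiple assignment randomized trial) randomizes
subjects at up to two decision points.  A trajectory records baseline
covariates ``Z1``, the stage-1 treatment ``A1``, intermediate covariates
and tailoring variables ``Z2``, whether the subject entered the stage-2
randomization, the stage-2 treatment ``A2`` (only when re-randomized),
and a final outcome ``Y`` with smaller values preferred.

Treatments are coded as centered reals so that ``E(A_k) = 0`` under the
design's allocation ratio (e.g. a 2:1 allocation is coded +1 / -2).  This
centering is a modelling requirement, not a convenience: the stage-2
omitted-variable bias analysis relies on it, so codings whose expectation
under the declared allocation is nonzero are rejected outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreatmentCoding",
    "ModelSpec",
    "DesignMatrices",
    "TrialData",
    "load_trial",
    "build_design",
    "design_blocks",
]


@dataclass(frozen=True)
class TreatmentCoding:
    """Arm labels, centered numeric codes, and allocation probabilities.

    The codes must satisfy ``sum(codes * allocation) == 0`` so that the
    coded treatment variable has expectation zero under the randomization
    scheme.  Only binary (two-arm) codings are supported.
    """

    labels: tuple[str, ...]
    codes: tuple[float, ...]
    allocation: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != 2 or len(self.codes) != 2 or len(self.allocation) != 2:
            raise ValueError("TreatmentCoding supports exactly two arms")
        if any(p <= 0 for p in self.allocation):
            raise ValueError("allocation probabilities must be positive")
        if abs(sum(self.allocation) - 1.0) > 1e-9:
            raise ValueError(f"allocation must sum to 1, got {sum(self.allocation)}")
        expectation = sum(c * p for c, p in zip(self.codes, self.allocation))
        if abs(expectation) > 1e-9:
            raise ValueError(
                f"treatment codes {self.codes} have expectation "
                f"{expectation:.6g} != 0 under allocation {self.allocation}"
            )
        if self.codes[0] == self.codes[1]:
            raise ValueError("arm codes must be distinct")

    def code_of(self, label: str) -> float:
        try:
            return self.codes[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown arm label {label!r}; known: {self.labels}") from None

    @property
    def sorted_codes(self) -> tuple[float, float]:
        """Codes in ascending order; ties in rules break to the smaller code."""
        return tuple(sorted(self.codes))


#: balanced two-arm design coded -1/+1
BALANCED = TreatmentCoding(labels=("neg", "pos"), codes=(-1.0, 1.0), allocation=(0.5, 0.5))


@dataclass(frozen=True)
class ModelSpec:
    """Which history columns enter a stage's main- and treatment-effect blocks.

    Each term is a column name or a ``*``-separated product of column
    names (e.g. ``"Z1*A1"``).  An intercept implicitly heads both blocks,
    so the realized design vectors are (1, main terms) and (1, effect
    terms).  Stage-1 terms may reference only baseline columns; stage-2
    terms may additionally reference ``A1`` and post-stage-1 columns.
    """

    stage: int
    main_terms: tuple[str, ...] = ()
    effect_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        object.__setattr__(self, "main_terms", tuple(self.main_terms))
        object.__setattr__(self, "effect_terms", tuple(self.effect_terms))

    @property
    def p0(self) -> int:
        return 1 + len(self.main_terms)

    @property
    def p1(self) -> int:
        return 1 + len(self.effect_terms)

    @property
    def main_names(self) -> tuple[str, ...]:
        return ("const",) + self.main_terms

    @property
    def effect_names(self) -> tuple[str, ...]:
        return ("const",) + self.effect_terms


@dataclass(frozen=True)
class DesignMatrices:
    """Realized design blocks for one stage.

    ``M0`` realizes the main-effect vector (intercept first), ``M1`` the
    treatment-effect vector, ``a`` the treatment codes, and ``full`` the
    stacked fitting matrix ``[M0 | a * M1]`` (each column of M1 scaled
    elementwise by a).
    """

    M0: np.ndarray
    M1: np.ndarray
    a: np.ndarray
    column_names: tuple[str, ...]

    @property
    def full(self) -> np.ndarray:
        return np.hstack([self.M0, self.a[:, None] * self.M1])


def _term_values(frame: pd.DataFrame, term: str) -> np.ndarray:
    """Evaluate a term (column name or product of column names) on a frame."""
    out = np.ones(len(frame), dtype=float)
    for name in term.split("*"):
        name = name.strip()
        if name not in frame.columns:
            raise KeyError(
                f"term {term!r}: column {name!r} not found among {list(frame.columns)}"
            )
        out = out * frame[name].to_numpy(dtype=float)
    return out


def design_blocks(frame: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build (M0, M1) for a spec on an arbitrary history frame.

    Used both for fitting and for evaluating fitted Q-functions at new
    histories (e.g. every subject of an evaluation population).
    """
    n = len(frame)
    M0 = np.column_stack([np.ones(n)] + [_term_values(frame, t) for t in spec.main_terms])
    M1 = np.column_stack([np.ones(n)] + [_term_values(frame, t) for t in spec.effect_terms])
    return M0, M1


class TrialData:
    """Validated container for SMART trajectories.

    Wraps a DataFrame whose columns are mapped to roles by ``schema``:
    ``z1`` (list of baseline columns), ``a1``, ``z2`` (list of post-stage-1
    columns), ``rerandomized``, ``a2``, ``y``.  Treatment columns hold the
    centered numeric codes.  ``a2`` is NaN for subjects who were not
    re-randomized (embedded tailoring) and is never used for them.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        schema: Mapping[str, object],
        codings: Mapping[str, TreatmentCoding],
    ) -> None:
        self.frame = frame.reset_index(drop=True)
        self.schema = dict(schema)
        self.codings = dict(codings)
        self._validate()

    # -- role accessors -------------------------------------------------
    @property
    def a1(self) -> np.ndarray:
        return self.frame[self.schema["a1"]].to_numpy(dtype=float)

    @property
    def a2(self) -> np.ndarray:
        return self.frame[self.schema["a2"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.schema["y"]].to_numpy(dtype=float)

    @property
    def rerandomized(self) -> np.ndarray:
        return self.frame[self.schema["rerandomized"]].to_numpy(dtype=bool)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def subject_id(self) -> pd.Series:
        col = self.schema.get("subject_id")
        if col is not None and col in self.frame.columns:
            return self.frame[col]
        return pd.Series(np.arange(self.n), name="subject_id")

    def _validate(self) -> None:
        for role in ("a1", "rerandomized", "a2", "y"):
            if role not in self.schema:
                raise ValueError(f"schema is missing required role {role!r}")
        rr = self.rerandomized
        for stage, role in ((1, "a1"), (2, "a2")):
            coding = self.codings.get(f"a{stage}")
            if coding is None:
                raise ValueError(f"no TreatmentCoding declared for a{stage}")
            vals = self.frame[self.schema[role]].to_numpy(dtype=float)
            mask = np.ones(len(vals), bool) if stage == 1 else rr
            bad = mask & ~np.isin(vals, coding.codes)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"row {i}: a{stage} value {vals[i]!r} is not one of the "
                    f"declared codes {coding.codes}"
                )
        used = [self.schema["a1"], self.schema["rerandomized"], self.schema["y"]]
        used += list(self.schema.get("z1", [])) + list(self.schema.get("z2", []))
        if self.frame[used].isna().any().any():
            raise ValueError("missing values in schema-used columns (complete-case contract)")
        if rr.any() and self.frame.loc[rr, self.schema["a2"]].isna().any():
            raise ValueError("missing a2 among re-randomized subjects")

    def subset(self, mask: np.ndarray) -> "TrialData":
        return TrialData(self.frame.loc[np.asarray(mask, bool)], self.schema, self.codings)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_trial(
    path,
    schema: Mapping[str, object],
    codings: Mapping[str, TreatmentCoding],
) -> TrialData:
    """Read a delimited trajectory table, map arm labels to codes, drop incomplete rows.

    ``schema`` assigns roles to columns (see :class:`TrialData`).  Arm
    columns may contain either labels declared in the coding or the
    numeric codes themselves.  Rows with missing values in any used
    column are dropped (complete-case) with the count logged.
    """
    frame = pd.read_csv(path)
    frame = frame.copy()

    for stage in (1, 2):
        role = f"a{stage}"
        col = schema[role]
        coding = codings[role]
        mapped = []
        for i, v in enumerate(frame[col]):
            if pd.isna(v):
                mapped.append(np.nan)
                continue
            try:
                fv = float(v)
            except (TypeError, ValueError):
                fv = None
            if fv is not None and fv in coding.codes:
                mapped.append(fv)
            elif isinstance(v, str) and v in coding.labels:
                mapped.append(coding.code_of(v))
            else:
                raise ValueError(
                    f"row {i}, column {col!r}: unknown arm label/code {v!r} "
                    f"(labels {coding.labels}, codes {coding.codes})"
                )
        frame[col] = mapped

    rr_col = schema["rerandomized"]
    frame[rr_col] = frame[rr_col].astype(bool)

    used = [schema["a1"], rr_col, schema["y"]]
    used += list(schema.get("z1", [])) + list(schema.get("z2", []))
    complete = ~frame[used].isna().any(axis=1)
    # a2 is required only for re-randomized subjects
    complete &= ~(frame[rr_col] & frame[schema["a2"]].isna())
    dropped = int((~complete).sum())
    if dropped:
        logger.info("load_trial: dropped %d incomplete row(s) of %d", dropped, len(frame))
    return TrialData(frame.loc[complete], schema, codings)


def build_design(data: TrialData, spec: ModelSpec) -> DesignMatrices:
    """Realize a ModelSpec against trial data.

    For a stage-2 spec the caller is responsible for restricting ``data``
    to re-randomized subjects before fitting; the blocks themselves are
    well defined for every subject.
    """
    M0, M1 = design_blocks(data.frame, spec)
    a = data.a1 if spec.stage == 1 else data.a2
    names = tuple(f"main:{t}" for t in spec.main_names) + tuple(
        f"A{spec.stage}x{t}" for t in spec.effect_names
    )
    return DesignMatrices(M0=M0, M1=M1, a=a, column_names=names)
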