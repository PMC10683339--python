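"""OLS machinery and the two non-interactive backward-induction learners.

Both stages of a two-stage dynamic treatment regime are modelled with
linear Q-functions

    Q_j(H_j, A_j) = X̃_j0' beta_j0 + A_j X̃_j1' beta_j1,

fit by ordinary least squares, stage 2 first.  The stage-2 treatment
contrast t = X̃_21' beta_21 determines the optimal stage-2 arm
(d2 = -sgn t, with sgn 0 = 1 so ties break to arm -1) and the benefit
|t| of taking it.  The two learners here differ only in the stage-1
pseudo-outcome:

* standard Q-learning plugs in the fitted optimum
  X̃_20' beta_20 - |t|, discarding the stage-2 residual;
* modified Q-learning applies a regret adjustment to the observed
  outcome, Y + (min_a2 a2 t - A2 t) = Y - A2 t - |t|, which keeps the
  stage-2 residual and with it any signal the stage-2 main-effect model
  failed to capture.

Subjects not re-randomized at stage 2 (embedded tailoring) had no
stage-2 choice: their continuation is by design their optimal one, so
their pseudo-outcome is the observed Y under both learners.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .trial_data import DesignMatrices, ModelSpec, TrialData, build_design, design_blocks

__all__ = [
    "StageFit",
    "FittedDTR",
    "ols_fit",
    "fit_stage2",
    "contrast",
    "rule_stage2",
    "pseudo_outcome",
    "fit_stage1",
    "rule_stage1_linear",
    "fit_dtr",
]

METHODS = ("Q", "mQ", "IQ", "mIQ")


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is collinear; no silent pseudo-inverse is taken."""


@dataclass
class StageFit:
    """OLS fit of one stage's Q-function.

    ``beta0``/``beta1`` are the main- and treatment-block coefficient
    vectors, intercept first.  ``resid_sd`` uses denominator n - p
    (p = total number of columns), defined as 0 when n == p.
    """

    beta0: np.ndarray
    beta1: np.ndarray
    n_fit: int
    resid_sd: float
    spec: ModelSpec

    def main_value(self, frame: pd.DataFrame) -> np.ndarray:
        """X̃_j0' beta_j0 evaluated on an arbitrary history frame."""
        M0, _ = design_blocks(frame, self.spec)
        return M0 @ self.beta0

    def effect_value(self, frame: pd.DataFrame) -> np.ndarray:
        """X̃_j1' beta_j1 (the treatment contrast) on an arbitrary frame."""
        _, M1 = design_blocks(frame, self.spec)
        return M1 @ self.beta1

    def q_value(self, frame: pd.DataFrame, a: np.ndarray | float) -> np.ndarray:
        return self.main_value(frame) + np.asarray(a, dtype=float) * self.effect_value(frame)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0.tolist(),
            "beta1": self.beta1.tolist(),
            "n_fit": self.n_fit,
            "resid_sd": self.resid_sd,
            "spec": {
                "stage": self.spec.stage,
                "main_terms": list(self.spec.main_terms),
                "effect_terms": list(self.spec.effect_terms),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageFit":
        return cls(
            beta0=np.asarray(d["beta0"], float),
            beta1=np.asarray(d["beta1"], float),
            n_fit=int(d["n_fit"]),
            resid_sd=float(d["resid_sd"]),
            spec=ModelSpec(**d["spec"]),
        )


def _check_rank(X: np.ndarray, names: tuple[str, ...] | None = None) -> None:
    n, p = X.shape
    if n < p:
        raise RankDeficientError(f"fewer rows ({n}) than columns ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # QR with column pivoting localizes the collinear columns
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[rank:])
        labels = [names[i] if names else f"col{i}" for i in bad]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear column(s): {labels}"
        )


def ols_fit(
    X: np.ndarray, y: np.ndarray, names: tuple[str, ...] | None = None
) -> tuple[np.ndarray, float]:
    """Least squares with a hard collinearity check.

    Returns the coefficient vector and the residual standard deviation
    with denominator n - p (0 when n == p).  A rank-deficient design
    raises :class:`RankDeficientError` naming the offending columns
    rather than falling back to a pseudo-inverse, since collinearity in
    this setting usually signals a mis-declared model.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    _check_rank(X, names)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    n, p = X.shape
    if n == p:
        return coef, 0.0
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, float(np.sqrt(rss / (n - p)))


def _split(coef: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
    return coef[: spec.p0], coef[spec.p0 :]


def fit_stage2(data: TrialData, spec2: ModelSpec) -> StageFit:
    """Regress Y on (H2, A2) among re-randomized subjects only."""
    rr = data.rerandomized
    if not rr.any():
        raise ValueError("no re-randomized subjects; cannot fit stage 2")
    sub = data.subset(rr)
    dm = build_design(sub, spec2)
    X = dm.full
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"stage-2 fit needs n > p; got n={X.shape[0]}, p={X.shape[1]}"
        )
    coef, resid_sd = ols_fit(X, sub.y, dm.column_names)
    beta0, beta1 = _split(coef, spec2)
    return StageFit(beta0=beta0, beta1=beta1, n_fit=int(rr.sum()), resid_sd=resid_sd, spec=spec2)


def contrast(fit: StageFit, data: TrialData) -> np.ndarray:
    """Estimated stage-2 treatment contrast t̂_i = X̃_21,i' beta_21.

    Defined for every subject — the contrast is a function of H2, which
    exists whether or not the subject was re-randomized.
    """
    return fit.effect_value(data.frame)


def _rule_from_contrast(t: np.ndarray, codes: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Arm minimizing a * t over the two codes; ties break to the smaller code."""
    lo, hi = sorted(codes)
    t = np.asarray(t, float)
    # lo*t <= hi*t  <=>  t*(lo-hi) <= 0  <=>  t >= 0 (lo < hi)
    return np.where(t >= 0, lo, hi)


def rule_stage2(t_hat: np.ndarray, codes: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
    """Estimated optimal stage-2 arm, d̂2 = -sgn(t̂) for the ±1 coding.

    The sgn convention takes sgn(0) = 1, so a zero contrast maps to arm
    -1.  This is a probability-zero event under the usual regularity
    condition but must still be deterministic.
    """
    return _rule_from_contrast(t_hat, codes)


def pseudo_outcome(
    fit: StageFit, data: TrialData, method: Literal["Q", "mQ"]
) -> np.ndarray:
    """Stage-1 response Ŷopt under standard (Q) or modified (mQ) Q-learning.

    Re-randomized subjects:
      Q  : X̃_20' beta_20 - |t̂|         (fitted value at the optimal arm)
      mQ : Y - A2 t̂ - |t̂|              (observed Y plus estimated regret)
    Non-re-randomized subjects: Ŷopt = Y under both methods.
    """
    rr = data.rerandomized
    t = contrast(fit, data)
    out = data.y.astype(float).copy()
    if method == "Q":
        m = fit.main_value(data.frame)
        out[rr] = m[rr] - np.abs(t[rr])
    elif method == "mQ":
        out[rr] = data.y[rr] - data.a2[rr] * t[rr] - np.abs(t[rr])
    else:
        raise ValueError(f"unknown method {method!r}; expected 'Q' or 'mQ'")
    return out


def fit_stage1(pseudo: np.ndarray, data: TrialData, spec1: ModelSpec) -> StageFit:
    """OLS of the pseudo-outcome on [X̃_10 | A1 X̃_11] over all subjects."""
    pseudo = np.asarray(pseudo, float)
    if len(pseudo) != data.n:
        raise ValueError("pseudo-outcome must have one value per subject")
    dm = build_design(data, spec1)
    coef, resid_sd = ols_fit(dm.full, pseudo, dm.column_names)
    beta0, beta1 = _split(coef, spec1)
    return StageFit(beta0=beta0, beta1=beta1, n_fit=data.n, resid_sd=resid_sd, spec=spec1)


def rule_stage1_linear(
    fit: StageFit, frame: pd.DataFrame, codes: tuple[float, float] = (-1.0, 1.0)
) -> np.ndarray:
    """Stage-1 rule from a linear stage-1 fit: d̂1 = -sgn(X̃_11' beta_11).

    ``frame`` may be the trial frame or any history frame (e.g. an
    evaluation population) carrying the spec's stage-1 columns.
    """
    return _rule_from_contrast(fit.effect_value(frame), codes)


@dataclass
class FittedDTR:
    """A fitted two-stage regime under one of the four learners.

    For Q/mQ the stage-1 model is a linear :class:`StageFit`; for the
    interactive learners it is the (main-effect fit, g-model) pair.
    Exactly one representation is populated.
    """

    method: str
    stage2: StageFit
    stage1: StageFit | None = None
    main_effect: "object | None" = None  # interactive_core.MainEffectFit
    g: "object | None" = None  # interactive_core.GModel
    g_variant: Literal["normal", "empirical", "none"] = "none"

    def __post_init__(self) -> None:
        if self.method in ("Q", "mQ"):
            if self.stage1 is None or self.main_effect is not None:
                raise ValueError(f"method {self.method} requires a linear stage-1 fit")
        elif self.method in ("IQ", "mIQ"):
            if self.main_effect is None or self.g is None or self.stage1 is not None:
                raise ValueError(f"method {self.method} requires (main effect, g) pair")
        else:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")

    @property
    def interactive(self) -> bool:
        return self.method in ("IQ", "mIQ")

    def q1(self, frame: pd.DataFrame, a1: np.ndarray | float) -> np.ndarray:
        """Q̂1(h1, a1) evaluated on an arbitrary stage-1 history frame."""
        if self.interactive:
            from .interactive_core import q1_interactive

            return q1_interactive(self.main_effect, self.g, frame, a1)
        return self.stage1.q_value(frame, a1)

    def rule1(self, frame: pd.DataFrame, codes: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
        """Estimated optimal stage-1 arm for each row of the frame."""
        if self.interactive:
            from .interactive_core import rule_stage1_interactive

            return rule_stage1_interactive(self.main_effect, self.g, frame, codes)
        return rule_stage1_linear(self.stage1, frame, codes)

    def rule2(self, frame: pd.DataFrame, codes: tuple[float, float] = (-1.0, 1.0)) -> np.ndarray:
        """Estimated optimal stage-2 arm: -sgn of the fitted contrast."""
        return _rule_from_contrast(self.stage2.effect_value(frame), codes)

    def to_dict(self) -> dict:
        d = {"method": self.method, "g_variant": self.g_variant, "stage2": self.stage2.to_dict()}
        if self.interactive:
            d["main_effect"] = self.main_effect.to_dict()
            d["g"] = self.g.to_dict()
        else:
            d["stage1"] = self.stage1.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDTR":
        from .interactive_core import GModel, MainEffectFit

        kwargs = dict(
            method=d["method"],
            g_variant=d.get("g_variant", "none"),
            stage2=StageFit.from_dict(d["stage2"]),
        )
        if "stage1" in d:
            kwargs["stage1"] = StageFit.from_dict(d["stage1"])
        else:
            kwargs["main_effect"] = MainEffectFit.from_dict(d["main_effect"])
            kwargs["g"] = GModel.from_dict(d["g"])
        return cls(**kwargs)


def fit_dtr(
    data: TrialData,
    spec1: ModelSpec,
    spec2: ModelSpec,
    method: str,
    g_kind: Literal["normal", "empirical"] = "normal",
    g_rows: Literal["rerandomized", "all"] = "rerandomized",
    stage2_fit: StageFit | None = None,
) -> FittedDTR:
    """Fit one of the four learners end to end (stage 2, then stage 1).

    ``stage2_fit`` lets callers reuse a stage-2 fit shared across
    methods on the same data (all four learners use the identical
    stage-2 OLS).
    """
    s2 = stage2_fit if stage2_fit is not None else fit_stage2(data, spec2)
    if method in ("Q", "mQ"):
        po = pseudo_outcome(s2, data, method)
        s1 = fit_stage1(po, data, spec1)
        return FittedDTR(method=method, stage2=s2, stage1=s1)
    if method in ("IQ", "mIQ"):
        from .interactive_core import fit_g, fit_main_effect

        variant = "iq" if method == "IQ" else "miq"
        m = fit_main_effect(data, s2, spec1, variant)
        g = fit_g(data, s2, spec1, kind=g_kind, g_rows=g_rows)
        return FittedDTR(method=method, stage2=s2, main_effect=m, g=g, g_variant=g_kind)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
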