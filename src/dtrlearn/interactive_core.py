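"""Interactive learners: IQ and the modified interactive variant (mIQ).

Instead of regressing a single stage-1 pseudo-outcome, the interactive
approach models the two ingredients of the optimal stage-1 Q-function
separately and recombines them:

    Q1(h1, a1) = m(h1, a1) - E[ |T| | h1, a1 ],

where T = X̃_21' psi_21 is the stage-2 treatment contrast and m is the
conditional mean of the outcome net of the realized stage-2 treatment
effect.  Modelling the conditional law g of T given (H1, A1) and taking
the expected absolute value sidesteps the nonlinearity that |T| induces
in a plain linear stage-1 regression.

The two variants differ in the response of the m-regression:

* IQ regresses the fitted stage-2 main effect X̃_20' beta_20 — correct
  when the stage-2 main-effect model is correct;
* mIQ regresses Y - A2 X̃_21' beta_21, the observed outcome net of the
  estimated stage-2 treatment effect, which retains the stage-2
  residual and is therefore robust to omitted terms (e.g. a stage-1
  treatment-by-covariate interaction) in the stage-2 main-effect model.

Under the g-model, T | H1, A1 is location-scale: either normal with
constant variance (closed-form folded-normal expectation) or a
location shift of the empirical residual pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .qlearn_core import StageFit, contrast, ols_fit
from .trial_data import ModelSpec, TrialData, build_design, design_blocks

__all__ = [
    "MainEffectFit",
    "GModel",
    "fit_main_effect",
    "fit_g",
    "expected_abs",
    "q1_interactive",
    "rule_stage1_interactive",
]

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


@dataclass
class MainEffectFit:
    """OLS fit of m(H1, A1) on the stage-1 design [X̃_10 | A1 X̃_11]."""

    coef: np.ndarray
    variant: Literal["iq", "miq"]
    n_fit: int
    spec: ModelSpec

    def predict(self, frame: pd.DataFrame, a1: np.ndarray | float) -> np.ndarray:
        M0, M1 = design_blocks(frame, self.spec)
        p0 = self.spec.p0
        return M0 @ self.coef[:p0] + np.asarray(a1, float) * (M1 @ self.coef[p0:])

    def to_dict(self) -> dict:
        return {
            "coef": self.coef.tolist(),
            "variant": self.variant,
            "n_fit": self.n_fit,
            "spec": {
                "stage": self.spec.stage,
                "main_terms": list(self.spec.main_terms),
                "effect_terms": list(self.spec.effect_terms),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MainEffectFit":
        return cls(
            coef=np.asarray(d["coef"], float),
            variant=d["variant"],
            n_fit=int(d["n_fit"]),
            spec=ModelSpec(**d["spec"]),
        )


@dataclass
class GModel:
    """Fitted conditional law of the stage-2 contrast given (H1, A1).

    The location mu(h1, a1) is linear in the same stage-1 design used
    for the m-regression.  The scale is either a constant sigma (normal
    kind, residual-SD with denominator n - p) or an empirical pool of
    OLS residuals (location-shift model).
    """

    kind: Literal["normal", "empirical"]
    mu_coef: np.ndarray
    spec: ModelSpec
    sigma: float = 0.0
    residual_pool: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def mu(self, frame: pd.DataFrame, a1: np.ndarray | float) -> np.ndarray:
        M0, M1 = design_blocks(frame, self.spec)
        p0 = self.spec.p0
        return M0 @ self.mu_coef[:p0] + np.asarray(a1, float) * (M1 @ self.mu_coef[p0:])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "mu_coef": self.mu_coef.tolist(),
            "sigma": self.sigma,
            "residual_pool": self.residual_pool.tolist(),
            "spec": {
                "stage": self.spec.stage,
                "main_terms": list(self.spec.main_terms),
                "effect_terms": list(self.spec.effect_terms),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GModel":
        return cls(
            kind=d["kind"],
            mu_coef=np.asarray(d["mu_coef"], float),
            sigma=float(d["sigma"]),
            residual_pool=np.asarray(d["residual_pool"], float),
            spec=ModelSpec(**d["spec"]),
        )


def fit_main_effect(
    data: TrialData,
    stage2: StageFit,
    spec1: ModelSpec,
    variant: Literal["iq", "miq"],
) -> MainEffectFit:
    """Regress the stage-2-net response on [X̃_10 | A1 X̃_11] over all subjects.

    Response for re-randomized subject i: IQ uses the fitted stage-2
    main effect X̃_20,i' beta_20; mIQ uses Y_i - A2,i t̂_i.  Subjects not
    re-randomized contribute their observed Y under both variants (their
    fixed continuation carries no stage-2 treatment effect to net out).
    """
    if variant not in ("iq", "miq"):
        raise ValueError(f"unknown variant {variant!r}")
    rr = data.rerandomized
    resp = data.y.astype(float).copy()
    if variant == "iq":
        m2 = stage2.main_value(data.frame)
        resp[rr] = m2[rr]
    else:
        t = contrast(stage2, data)
        resp[rr] = data.y[rr] - data.a2[rr] * t[rr]
    dm = build_design(data, spec1)
    coef, _ = ols_fit(dm.full, resp, dm.column_names)
    return MainEffectFit(coef=coef, variant=variant, n_fit=data.n, spec=spec1)


def fit_g(
    data: TrialData,
    stage2: StageFit,
    spec1: ModelSpec,
    kind: Literal["normal", "empirical"] = "normal",
    g_rows: Literal["rerandomized", "all"] = "rerandomized",
) -> GModel:
    """Fit the conditional distribution of the contrast given (H1, A1).

    Regresses t̂ = X̃_21' beta_21 on the stage-1 design.  ``g_rows``
    selects which subjects' rows enter this regression: by default only
    re-randomized ones, since |t̂| corrects a stage-2 choice that
    non-re-randomized subjects never faced; ``"all"`` uses every subject
    (t̂ is a function of H2 and exists for all).
    """
    if kind not in ("normal", "empirical"):
        raise ValueError(f"unknown g kind {kind!r}")
    if g_rows == "rerandomized":
        sub = data.subset(data.rerandomized)
    elif g_rows == "all":
        sub = data
    else:
        raise ValueError(f"g_rows must be 'rerandomized' or 'all', got {g_rows!r}")
    t = contrast(stage2, sub)
    dm = build_design(sub, spec1)
    coef, resid_sd = ols_fit(dm.full, t, dm.column_names)
    if kind == "normal":
        return GModel(kind="normal", mu_coef=coef, sigma=resid_sd, spec=spec1)
    resid = t - dm.full @ coef
    return GModel(kind="empirical", mu_coef=coef, spec=spec1, residual_pool=resid - resid.mean())


def folded_normal_mean(mu: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """E|Z| for Z ~ N(mu, sigma^2).

    Closed form: sigma * sqrt(2/pi) * exp(-mu^2 / (2 sigma^2))
                 + mu * (1 - 2 Phi(-mu/sigma)),
    degenerating to |mu| as sigma -> 0.
    """
    mu = np.asarray(mu, float)
    if sigma == 0.0:
        out = np.abs(mu)
        return float(out) if out.ndim == 0 else out
    z = mu / sigma
    out = sigma * _SQRT_2_OVER_PI * np.exp(-0.5 * z * z) + mu * (1.0 - 2.0 * ndtr(-z))
    return float(out) if out.ndim == 0 else out


def expected_abs(
    g: GModel, frame: pd.DataFrame, a1: np.ndarray | float
) -> np.ndarray:
    """E[ |T| | h1, a1 ] under the fitted g, vectorized over the frame's rows.

    Normal kind: folded-normal mean at (mu(h1, a1), sigma).  Empirical
    kind: average of |mu(h1, a1) + e_j| over the residual pool.
    """
    mu = np.atleast_1d(g.mu(frame, a1))
    if g.kind == "normal":
        return np.asarray(folded_normal_mean(mu, g.sigma))
    pool = g.residual_pool
    if pool.size == 0:
        return np.abs(mu)
    return np.abs(mu[:, None] + pool[None, :]).mean(axis=1)


def q1_interactive(
    m: MainEffectFit, g: GModel, frame: pd.DataFrame, a1: np.ndarray | float
) -> np.ndarray:
    """Q̂1(h1, a1) = m̂(h1, a1) - E_ĝ[ |T| | h1, a1 ]."""
    return m.predict(frame, a1) - expected_abs(g, frame, a1)


def rule_stage1_interactive(
    m: MainEffectFit,
    g: GModel,
    frame: pd.DataFrame,
    codes: tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """Arm minimizing Q̂1(h1, a1) over the two codes; ties break to the smaller."""
    lo, hi = sorted(codes)
    q_lo = q1_interactive(m, g, frame, lo)
    q_hi = q1_interactive(m, g, frame, hi)
    return np.where(q_lo <= q_hi, lo, hi)
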