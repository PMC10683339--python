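"""Simulation study for the four backward-induction learners.

The generative model is a two-stage SMART with balanced +/-1 treatments
at both stages and no embedded tailoring:

    Z1 ~ N(-2, 1),   Z2 = Z1 + N(0, 4),   A1, A2 ~ 2 Bernoulli(0.5) - 1,
    Y  = 3 - Z1 + 0.1 A1 - 0.1 Z2 + c1 Z1 A1
         + c2 A2 (-6 - 4 Z1 + 5 A1 - 0.2 Z2) + N(0, 1),

with smaller Y preferred.  c1 scales the stage-1 heterogeneous
treatment effect (the Z1*A1 interaction, deliberately omitted from the
analysts' stage-2 main-effect model) and c2 scales the stage-2
heterogeneous treatment effect.  The analysis models used throughout
are the deliberately plain ones: stage-2 main and effect blocks both
(1, Z1, A1, Z2); stage-1 blocks both (1, Z1).

Performance is measured against a fixed evaluation population of N
subjects whose expected potential outcomes under all four (a1, a2)
regimes — and hence true optimal rules and true optimal values — are
known exactly.  Two metrics:

* PCI — probability of correctly identified stage-1 optimal rules: the
  population fraction where the estimated stage-1 rule matches the
  truth;
* value bias — population average of Q̂1(z1, d̂1) minus the true optimal
  value (positive = overestimating how good the best regime is, on the
  minimized-outcome scale... sign is estimated minus true).

A moment-based omitted-variable-bias oracle predicts the asymptotic
bias of the stage-2 coefficients when the Z1*A1 term is left out, via
bias = E[X'X]^{-1} E[X'V] gamma with the moments computed by Monte
Carlo under the generative law.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .qlearn_core import FittedDTR, fit_dtr, fit_stage2, METHODS
from .trial_data import ModelSpec, TreatmentCoding, TrialData, build_design

__all__ = [
    "SimConfig",
    "Population",
    "ScenarioResult",
    "SIM_SCHEMA",
    "SIM_CODINGS",
    "sim_spec1",
    "sim_spec2",
    "generate_trial",
    "build_population",
    "evaluate_pci",
    "evaluate_value_bias",
    "run_scenario",
    "run_grid",
    "ovb_oracle",
]

#: true stage-2 contrast weights (1, Z1, A1, Z2), scaled by c2 in the outcome
PSI21 = np.array([-6.0, -4.0, 5.0, -0.2])
#: true stage-2 main-effect weights (1, Z1, A1, Z2); the Z1*A1 term has weight c1
PSI20 = np.array([3.0, -1.0, 0.1, -0.1])

SIM_SCHEMA = {
    "subject_id": "subject_id",
    "z1": ["Z1"],
    "a1": "A1",
    "z2": ["Z2"],
    "rerandomized": "R",
    "a2": "A2",
    "y": "Y",
}

_BAL = TreatmentCoding(labels=("neg", "pos"), codes=(-1.0, 1.0), allocation=(0.5, 0.5))
SIM_CODINGS = {"a1": _BAL, "a2": _BAL}


def sim_spec1() -> ModelSpec:
    """Analysts' stage-1 model: main and effect blocks both (1, Z1)."""
    return ModelSpec(stage=1, main_terms=("Z1",), effect_terms=("Z1",))


def sim_spec2() -> ModelSpec:
    """Analysts' stage-2 model: main and effect blocks both (1, Z1, A1, Z2).

    Note the main block deliberately omits the Z1*A1 interaction that is
    part of the generative truth whenever c1 != 0.
    """
    return ModelSpec(stage=2, main_terms=("Z1", "A1", "Z2"), effect_terms=("Z1", "A1", "Z2"))


@dataclass(frozen=True)
class SimConfig:
    """One scenario of the simulation study.

    Defaults are the study conditions: samples of n = 250, an
    evaluation population of N = 10,000, and 1000 replicates.
    """

    c1: float = 0.0
    c2: float = 1.0
    n: int = 250
    N: int = 10_000
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 8:
            raise ValueError("n must exceed the widest design (8 columns)")
        if self.reps < 1 or self.N < 1:
            raise ValueError("reps and N must be >= 1")

    # -- named RNG substreams ------------------------------------------
    # A single master seed spawns independent, order-insensitive streams
    # so replicates can run in any order (or in parallel) without
    # changing any result.  Scenario coordinates are folded in so each
    # (c1, c2) gets its own population.
    def _key(self) -> tuple[int, int]:
        return (int(round(self.c1 * 1000)) % 2**31, int(round(self.c2 * 1000)) % 2**31)

    def population_rng(self) -> np.random.Generator:
        k1, k2 = self._key()
        return np.random.default_rng(np.random.SeedSequence([self.seed % 2**31, k1, k2, 0]))

    def replicate_rng(self, r: int) -> np.random.Generator:
        k1, k2 = self._key()
        return np.random.default_rng(np.random.SeedSequence([self.seed % 2**31, k1, k2, 1, r]))


def _main_part(z1: np.ndarray, a1: np.ndarray, z2: np.ndarray, c1: float) -> np.ndarray:
    return 3.0 - z1 + 0.1 * a1 - 0.1 * z2 + c1 * z1 * a1


def _contrast_part(z1: np.ndarray, a1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    return -6.0 - 4.0 * z1 + 5.0 * a1 - 0.2 * z2


def generate_trial(cfg: SimConfig, rng: np.random.Generator | None = None) -> TrialData:
    """Draw one SMART sample of size cfg.n from the generative law.

    Every subject is re-randomized (no embedded tailoring in this
    design).  Deterministic given (cfg, stream): the same config and
    replicate index always produce the identical sample.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed % 2**31))
    n = cfg.n
    z1 = rng.normal(-2.0, 1.0, n)
    z2 = z1 + rng.normal(0.0, 2.0, n)
    a1 = 2.0 * rng.integers(0, 2, n) - 1.0
    a2 = 2.0 * rng.integers(0, 2, n) - 1.0
    eps = rng.normal(0.0, 1.0, n)
    y = _main_part(z1, a1, z2, cfg.c1) + cfg.c2 * a2 * _contrast_part(z1, a1, z2) + eps
    frame = pd.DataFrame(
        {
            "subject_id": np.arange(n),
            "Z1": z1,
            "A1": a1,
            "Z2": z2,
            "R": np.ones(n, bool),
            "A2": a2,
            "Y": y,
        }
    )
    return TrialData(frame, SIM_SCHEMA, SIM_CODINGS)


@dataclass
class Population:
    """N pseudo-subjects with known expected potential outcomes.

    ``mu`` has one column per regime in the order
    (a1, a2) = (-1,-1), (-1,+1), (+1,-1), (+1,+1); noise is excluded.
    True rules minimize the expected potential outcome, with ties
    breaking to arm -1 at both stages.  The truth is conditional on the
    realized (z1, z2) pair, which caps attainable stage-1 PCI below 1:
    a stage-1 decision cannot observe z2.
    """

    z1: np.ndarray
    z2: np.ndarray
    mu: np.ndarray
    d1_true: np.ndarray
    d2_true: np.ndarray
    v_opt: np.ndarray

    REGIMES = ((-1.0, -1.0), (-1.0, 1.0), (1.0, -1.0), (1.0, 1.0))

    @property
    def frame(self) -> pd.DataFrame:
        """Stage-1 history frame (baseline covariates only)."""
        return pd.DataFrame({"Z1": self.z1})

    @property
    def n(self) -> int:
        return len(self.z1)


def build_population(cfg: SimConfig, rng: np.random.Generator | None = None) -> Population:
    """Draw the evaluation population and tabulate the four-regime truth."""
    if rng is None:
        rng = cfg.population_rng()
    N = cfg.N
    z1 = rng.normal(-2.0, 1.0, N)
    z2 = z1 + rng.normal(0.0, 2.0, N)
    mu = np.empty((N, 4))
    for j, (a1, a2) in enumerate(Population.REGIMES):
        a1v = np.full(N, a1)
        mu[:, j] = _main_part(z1, a1v, z2, cfg.c1) + cfg.c2 * a2 * _contrast_part(z1, a1v, z2)
    # per-row minimum within each a1; ties favor a2 = -1 (listed first)
    row_neg = mu[:, :2]
    row_pos = mu[:, 2:]
    best_neg = row_neg.min(axis=1)
    best_pos = row_pos.min(axis=1)
    d1 = np.where(best_neg <= best_pos, -1.0, 1.0)
    d2 = np.where(
        d1 == -1.0,
        np.where(row_neg[:, 0] <= row_neg[:, 1], -1.0, 1.0),
        np.where(row_pos[:, 0] <= row_pos[:, 1], -1.0, 1.0),
    )
    v_opt = np.minimum(best_neg, best_pos)
    return Population(z1=z1, z2=z2, mu=mu, d1_true=d1, d2_true=d2, v_opt=v_opt)


def evaluate_pci(d1_hat: np.ndarray, pop: Population) -> float:
    """Fraction of the population whose estimated stage-1 rule is correct."""
    return float(np.mean(np.asarray(d1_hat) == pop.d1_true))


def evaluate_value_bias(fitted: FittedDTR, pop: Population) -> float:
    """Population-average of Q̂1(z1, d̂1) minus the true optimal value."""
    frame = pop.frame
    d1_hat = fitted.rule1(frame)
    q1 = fitted.q1(frame, d1_hat)
    return float(np.mean(q1 - pop.v_opt))


@dataclass
class ScenarioResult:
    method: str
    c1: float
    c2: float
    pci_mean: float
    pci_sd: float
    bias_mean: float
    bias_sd: float
    reps: int

    def as_row(self) -> dict:
        return {
            "c1": self.c1,
            "c2": self.c2,
            "method": self.method,
            "bias_mean": self.bias_mean,
            "bias_sd": self.bias_sd,
            "pci_mean": self.pci_mean,
            "pci_sd": self.pci_sd,
            "reps": self.reps,
        }


def run_scenario(
    cfg: SimConfig,
    methods: Sequence[str] = METHODS,
    g_kind: str = "normal",
    pop: Population | None = None,
) -> list[ScenarioResult]:
    """Run one (c1, c2) scenario: one shared population, cfg.reps fresh trials.

    All methods are fit on the identical replicate data (sharing the
    stage-2 OLS they have in common), so comparisons between methods
    are paired.  Results are independent of the order methods are
    listed in.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    if pop is None:
        pop = build_population(cfg)
    spec1, spec2 = sim_spec1(), sim_spec2()
    pci = {m: np.empty(cfg.reps) for m in methods}
    bias = {m: np.empty(cfg.reps) for m in methods}
    for r in range(cfg.reps):
        data = generate_trial(cfg, cfg.replicate_rng(r))
        try:
            s2 = fit_stage2(data, spec2)
            for m in methods:
                fitted = fit_dtr(data, spec1, spec2, m, g_kind=g_kind, stage2_fit=s2)
                pci[m][r] = evaluate_pci(fitted.rule1(pop.frame), pop)
                bias[m][r] = evaluate_value_bias(fitted, pop)
        except Exception as exc:
            raise RuntimeError(
                f"replicate {r} of scenario (c1={cfg.c1}, c2={cfg.c2}) failed"
            ) from exc
    out = []
    for m in methods:
        out.append(
            ScenarioResult(
                method=m,
                c1=cfg.c1,
                c2=cfg.c2,
                pci_mean=float(pci[m].mean()),
                pci_sd=float(pci[m].std(ddof=1)) if cfg.reps > 1 else 0.0,
                bias_mean=float(bias[m].mean()),
                bias_sd=float(bias[m].std(ddof=1)) if cfg.reps > 1 else 0.0,
                reps=cfg.reps,
            )
        )
    return out


def run_grid(
    methods: Sequence[str],
    c1_list: Iterable[float],
    c2_list: Iterable[float],
    cfg: SimConfig,
    g_kind: str = "normal",
) -> list[ScenarioResult]:
    """Full experiment grid: every (c1, c2) pair, one population each."""
    results: list[ScenarioResult] = []
    for c1 in c1_list:
        for c2 in c2_list:
            scen = replace(cfg, c1=float(c1), c2=float(c2))
            results.extend(run_scenario(scen, methods, g_kind=g_kind))
    return results


def results_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def format_bias_table(results: Sequence[ScenarioResult]) -> str:
    """Text table of value bias, mean (SD), scenarios x methods."""
    df = results_frame(results)
    methods = list(dict.fromkeys(df["method"]))
    lines = ["c1    c2    " + "".join(f"{m:>14s}" for m in methods)]
    for (c1, c2), grp in df.groupby(["c1", "c2"], sort=True):
        cells = []
        for m in methods:
            row = grp[grp["method"] == m]
            if len(row):
                cells.append(f"{row.bias_mean.iloc[0]:.2f} ({row.bias_sd.iloc[0]:.2f})")
            else:
                cells.append("-")
        lines.append(f"{c1:<6.1f}{c2:<6.1f}" + "".join(f"{c:>14s}" for c in cells))
    return "\n".join(lines)


def ovb_oracle(
    cfg: SimConfig,
    spec2: ModelSpec | None = None,
    omitted_terms: Sequence[tuple[str, float]] | None = None,
    mc_n: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Asymptotic OLS bias of the stage-2 coefficients from omitted terms.

    Computes bias = E[X'X]^{-1} E[X'V] gamma, where X is the full
    included stage-2 design [X̃_20 | A2 X̃_21], V holds the omitted
    generative columns and gamma their true weights.  Moments are Monte
    Carlo averages over ``mc_n`` draws of (Z1, A1, Z2, A2) from the
    generative law.  Defaults to the omitted Z1*A1 main-effect term
    with weight c1; a zero gamma yields an exactly zero bias vector.
    Returns one bias entry per included coefficient, labelled.
    """
    if spec2 is None:
        spec2 = sim_spec2()
    if omitted_terms is None:
        omitted_terms = [("Z1*A1", cfg.c1)]
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed % 2**31, *cfg._key(), 2])
        )
    z1 = rng.normal(-2.0, 1.0, mc_n)
    z2 = z1 + rng.normal(0.0, 2.0, mc_n)
    a1 = 2.0 * rng.integers(0, 2, mc_n) - 1.0
    a2 = 2.0 * rng.integers(0, 2, mc_n) - 1.0
    frame = pd.DataFrame(
        {
            "subject_id": np.arange(mc_n),
            "Z1": z1,
            "A1": a1,
            "Z2": z2,
            "R": np.ones(mc_n, bool),
            "A2": a2,
            "Y": np.zeros(mc_n),
        }
    )
    data = TrialData(frame, SIM_SCHEMA, SIM_CODINGS)
    dm = build_design(data, spec2)
    X = dm.full
    from .trial_data import _term_values

    V = np.column_stack([_term_values(frame, t) for t, _ in omitted_terms])
    gamma = np.array([g for _, g in omitted_terms], float)
    M = X.T @ X / mc_n
    C = X.T @ V / mc_n
    if np.linalg.matrix_rank(M) < M.shape[0]:
        raise np.linalg.LinAlgError("singular moment matrix E[X'X]")
    bias = np.linalg.solve(M, C @ gamma)
    return pd.Series(bias, index=list(dm.column_names))
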