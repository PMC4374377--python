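"""Synthetic case-control cohorts for pediatric head-injury risk modelling.

Real patient-level data from the source registry are not public, so every
downstream stage (univariable statistics, logistic modelling, the ELM
ensemble, ROC evaluation) is exercised on cohorts drawn from a generative
model calibrated to the published marginal summaries: a 1:4 case:control
design age-matched year for year, ages approximately Normal(8.1, 4.2)
truncated to [0, 16), and class-conditional Bernoulli predictors whose
prevalences default to the printed case/control counts (e.g. loss of
consciousness in 25/39 cases vs 8/156 controls).

Only the marginals are published; the joint predictor distribution is not.
The default is class-conditional independence, with an optional shared
latent Gaussian severity factor (loading ``rho``) to induce positive
within-class dependence via a Gaussian copula.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CASE",
    "CONTROL",
    "MODEL_PREDICTORS",
    "LOGISTIC_PREDICTORS",
    "CohortSpec",
    "Cohort",
    "MatchingError",
    "generate_cohort",
    "age_match",
    "fixture_tables",
    "fixture_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]

CASE = 1  # C1: moderate-to-severe TBI (CT-confirmed bleed/fracture)
CONTROL = 0  # C0: head-injured child who remained well

#: The seven binary predictors available to the machine-learning model.
MODEL_PREDICTORS = (
    "rta",
    "loc",
    "vomiting",
    "seizure",
    "confusion",
    "skull_fracture_signs",
    "bos_fracture_signs",
)

#: The four predictors retained by the multivariable logistic regression.
LOGISTIC_PREDICTORS = ("rta", "loc", "vomiting", "bos_fracture_signs")

#: Auxiliary univariable items; subgroup items apply only to one age band.
AUXILIARY_PREDICTORS = (
    "difficult_arousal",
    "altered_mental_status",
    "scalp_hematoma",
    "scalp_laceration",
)
VERBAL_PREDICTORS = ("headache", "amnesia")  # asked of children aged >= 2
PREVERBAL_PREDICTORS = ("irritability",)  # asked of children aged < 2

#: Age (years) below which a child is treated as preverbal.
VERBAL_AGE_THRESHOLD = 2.0

# Class-conditional prevalences (case, control) taken from the published
# case-control counts; subgroup items are conditional on applicability.
DEFAULT_PREVALENCES: dict[str, tuple[float, float]] = {
    "rta": (17 / 39, 3 / 156),
    "loc": (25 / 39, 8 / 156),
    "vomiting": (11 / 39, 26 / 156),
    "seizure": (6 / 39, 0 / 156),
    "confusion": (33 / 39, 3 / 156),
    "skull_fracture_signs": (2 / 39, 1 / 156),
    "bos_fracture_signs": (13 / 39, 4 / 156),
    "difficult_arousal": (27 / 39, 3 / 156),
    "altered_mental_status": (36 / 39, 1 / 156),
    "scalp_hematoma": (20 / 39, 36 / 156),
    "scalp_laceration": (7 / 39, 32 / 156),
    "headache": (8 / 32, 45 / 130),
    "amnesia": (1 / 32, 6 / 131),
    "irritability": (0 / 7, 1 / 22),
}


class MatchingError(ValueError):
    """Raised when the control pool cannot satisfy the matching ratio."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic case-control generator.

    Parameters
    ----------
    n_cases
        Number of cases (positive class).
    control_ratio
        Age-matched controls per case; the study design used 4.
    age_mean, age_sd
        Mean and SD of the (truncated) Normal age model in years.
    age_range
        Truncation bounds, half-open; the study enrolled children < 16 y.
    prevalences
        ``{predictor: (p_case, p_control)}``; defaults to the published
        marginal counts.
    rho
        Loading of a shared latent severity factor in [0, 1); 0 gives
        class-conditional independence between predictors.
    seed
        RNG seed; identical spec + seed reproduces the cohort exactly.
    """

    n_cases: int = 39
    control_ratio: int = 4
    age_mean: float = 8.1
    age_sd: float = 4.2
    age_range: tuple[float, float] = (0.0, 16.0)
    prevalences: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.control_ratio < 1:
            raise ValueError("control_ratio must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        for name, (pc, pn) in self.prevalences.items():
            if not (0.0 <= pc <= 1.0 and 0.0 <= pn <= 1.0):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")


@dataclass
class Cohort:
    """An ordered collection of patient records.

    ``data`` has one row per patient with columns ``age`` (float years),
    ``group`` (1 = case, 0 = control) and one 0/1 column per predictor;
    NaN marks a subgroup item that does not apply to the child.
    """

    data: pd.DataFrame
    provenance: CohortSpec | str = "fixture"

    @property
    def cases(self) -> pd.DataFrame:
        return self.data[self.data["group"] == CASE]

    @property
    def controls(self) -> pd.DataFrame:
        return self.data[self.data["group"] == CONTROL]

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("age", "group")]

    def __len__(self) -> int:
        return len(self.data)


def _truncnorm_ages(n: int, mean: float, sd: float,
                    lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_predictors(ages: np.ndarray, prevalences: Mapping[str, tuple[float, float]],
                     which: int, rho: float, rng: np.random.Generator) -> pd.DataFrame:
    """Gaussian-copula Bernoulli draws for one class.

    Each subject carries a latent severity u ~ N(0,1); predictor j fires
    when rho*u + sqrt(1-rho^2)*e_j falls below the normal quantile of its
    class prevalence, so marginals are exact and rho=0 decouples items.
    """
    n = len(ages)
    u = rng.standard_normal(n)
    out: dict[str, np.ndarray] = {}
    for name, probs in prevalences.items():
        p = probs[0] if which == CASE else probs[1]
        z = rho * u + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        vals = (z < stats.norm.ppf(p)).astype(float) if 0.0 < p < 1.0 else np.full(n, p)
        if name in VERBAL_PREDICTORS:
            vals = np.where(ages >= VERBAL_AGE_THRESHOLD, vals, np.nan)
        elif name in PREVERBAL_PREDICTORS:
            vals = np.where(ages < VERBAL_AGE_THRESHOLD, vals, np.nan)
        out[name] = vals
    return pd.DataFrame(out)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a matched case-control cohort from the generative model.

    Cases receive truncated-Normal ages; each case is matched by exactly
    ``control_ratio`` controls sharing its integer age year (control age =
    matched year + U[0,1)), so the floor(age) distributions of the two
    groups are identical by construction.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    case_ages = _truncnorm_ages(spec.n_cases, spec.age_mean, spec.age_sd, lo, hi, rng)
    ctrl_years = np.repeat(np.floor(case_ages), spec.control_ratio)
    ctrl_ages = ctrl_years + rng.uniform(0.0, 1.0, size=ctrl_years.size)

    cases = _draw_predictors(case_ages, spec.prevalences, CASE, spec.rho, rng)
    cases.insert(0, "group", CASE)
    cases.insert(0, "age", case_ages)
    ctrls = _draw_predictors(ctrl_ages, spec.prevalences, CONTROL, spec.rho, rng)
    ctrls.insert(0, "group", CONTROL)
    ctrls.insert(0, "age", ctrl_ages)

    data = pd.concat([cases, ctrls], ignore_index=True)
    return Cohort(data=data, provenance=spec)


def age_match(cases: Cohort, pool: Cohort, ratio: int = 4,
              seed: int | np.random.Generator = 0) -> Cohort:
    """Select ``ratio`` controls per case from ``pool``, year for year.

    Controls are sampled without replacement within integer age strata
    (floor of age). Raises :class:`MatchingError` naming every deficient
    stratum if the pool cannot meet the demand.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_years = np.floor(cases.cases["age"]).astype(int)
    pool_df = pool.data[pool.data["group"] == CONTROL]
    pool_years = np.floor(pool_df["age"]).astype(int)

    demand = case_years.value_counts() * ratio
    supply = pool_years.value_counts()
    deficient = {int(y): (int(demand[y]), int(supply.get(y, 0)))
                 for y in demand.index if supply.get(y, 0) < demand[y]}
    if deficient:
        detail = "; ".join(f"age {y}: need {d}, have {s}"
                           for y, (d, s) in sorted(deficient.items()))
        raise MatchingError(f"insufficient controls in strata: {detail}")

    chosen: list[np.ndarray] = []
    for year in sorted(demand.index):
        idx = pool_df.index[pool_years == year].to_numpy()
        chosen.append(rng.choice(idx, size=int(demand[year]), replace=False))
    matched = pool_df.loc[np.concatenate(chosen)]
    data = pd.concat([cases.cases, matched], ignore_index=True)
    return Cohort(data=data, provenance="age_match")


# ---------------------------------------------------------------------------
# Published contingency tables, embedded as fixtures
# ---------------------------------------------------------------------------

def fixture_tables():
    """The published univariable cross-tabulations, keyed by variable.

    2x2 tables are oriented rows = (cases, controls), columns =
    (present, absent); the mechanism-of-injury tables are r x 2 with
    rows = mechanism and columns = (cases, controls). The unequal-pupils
    row was printed as percentages only; its counts are back-computed and
    the table is flagged uncertain.
    """
    from .cohort_stats import ContingencyTable  # local import avoids a cycle

    def t22(a, b, c, d, rows=("case", "control"), cols=("yes", "no")):
        return ContingencyTable(np.array([[a, b], [c, d]]), list(rows), list(cols))

    mech_rows = ["fall", "rta", "projectile", "non_accidental", "other"]
    tables = {
        "female": t22(14, 25, 44, 112),
        "mechanism": ContingencyTable(
            np.array([[19, 110], [17, 3], [0, 3], [2, 9], [1, 31]]),
            mech_rows, ["case", "control"]),
        "mechanism_le2y": ContingencyTable(
            np.array([[3, 18], [2, 0], [0, 0], [0, 0], [0, 2]]),
            mech_rows, ["case", "control"]),
        "loc": t22(25, 14, 8, 148),
        "loc_gt_1min": t22(24, 1, 4, 4),
        "difficult_arousal": t22(27, 12, 3, 153),
        "vomiting": t22(11, 28, 26, 130),
        "seizure": t22(6, 33, 0, 156),
        "confusion": t22(33, 6, 3, 153),
        "irritability": t22(0, 7, 1, 21),
        "headache": t22(8, 24, 45, 85),
        "amnesia": t22(1, 31, 6, 125),
        "altered_mental_status": t22(36, 3, 1, 155),
        "unequal_pupils": t22(10, 29, 2, 154),  # back-computed from 26%/1%; uncertain
        "skull_fracture_signs": t22(2, 37, 1, 155),
        "bos_fracture_signs": t22(13, 26, 4, 152),
        "scalp_hematoma": t22(20, 19, 36, 120),
        "frontal_hematoma": t22(1, 19, 13, 23),
        "scalp_laceration": t22(7, 32, 32, 124),
        "open_fontanelle": t22(4, 3, 17, 5),
        "tense_fontanelle": t22(3, 1, 0, 17),
    }
    return tables


def fixture_cohort(seed: int = 0) -> Cohort:
    """A 39-case / 156-control cohort whose 2x2 margins equal the
    published counts exactly (predictors assigned, not sampled).

    Each predictor column contains exactly the printed number of positives
    per class, independently shuffled, so every univariable 2x2 rebuilt
    from the cohort reproduces the printed table. Joint structure is
    arbitrary; use :func:`generate_cohort` when the joint matters.
    """
    rng = np.random.default_rng(seed)
    n_case, n_ctrl = 39, 156
    ages_case = _truncnorm_ages(n_case, 8.1, 4.2, 0.0, 16.0, rng)
    ages_ctrl = np.repeat(np.floor(ages_case), 4) + rng.uniform(0, 1, 4 * n_case)

    counts = {  # positives among (cases, controls), full-cohort items only
        "rta": (17, 3), "loc": (25, 8), "vomiting": (11, 26), "seizure": (6, 0),
        "confusion": (33, 3), "skull_fracture_signs": (2, 1),
        "bos_fracture_signs": (13, 4), "difficult_arousal": (27, 3),
        "altered_mental_status": (36, 1), "scalp_hematoma": (20, 36),
        "scalp_laceration": (7, 32),
    }

    def fill(n: int, k: int) -> np.ndarray:
        v = np.zeros(n)
        v[:k] = 1.0
        rng.shuffle(v)
        return v

    frames = []
    for group, ages, n, which in ((CASE, ages_case, n_case, 0),
                                  (CONTROL, ages_ctrl, n_ctrl, 1)):
        cols = {"age": ages, "group": group}
        for name, ks in counts.items():
            cols[name] = fill(n, ks[which])
        frames.append(pd.DataFrame(cols))
    data = pd.concat(frames, ignore_index=True)
    return Cohort(data=data, provenance="fixture")


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: Cohort, path) -> None:
    """One row per patient; binary fields as 0/1, not-applicable empty."""
    df = cohort.data.copy()
    for c in cohort.predictors:
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    df = pd.read_csv(path)
    if "age" not in df.columns or "group" not in df.columns:
        raise ValueError("cohort CSV must contain 'age' and 'group' columns")
    for c in df.columns:
        if c not in ("age", "group"):
            df[c] = df[c].astype(float)
    return Cohort(data=df, provenance=str(path))
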