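"""Synthetic cohorts with the statistical structure of a community screening study.

Emulates a cohort of community-dwelling older adults measured for sarcopenia
screening: per-sex marginal distributions for age, anthropometry, vertical
power, grip strength, five-times sit-to-stand time and body composition,
coupled through a Gaussian copula so that rank correlations are honored while
each marginal keeps its published shape (normal for mean/SD variables,
log-normal matched to median/IQR for right-skewed ones).

From the drawn variables the generator back-solves a plausible chair-rise
recording (frame pair at 240 fps) from the inverted power regression, derives
SMI and BMI, induces reference-standard labels via the EWGSOP2 rules, and
optionally draws index-style labels from a known logistic truth — the basis
of parameter-recovery experiments.

Default marginals encode a screening cohort of 686 Spanish community-dwelling
older adults (406 women, 280 men); default rank correlations are plausible
placeholders, NOT estimated from any published cohort, and are overridable.
"""

from __future__ import annotations

import copy
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import kinematics
from .ewgsop2 import (
    SarcopeniaCriterion,
    RISK_FACTORS,
    FRAILTY_CRITERIA,
    GRIP_CUTOFF_KG,
    reference_labels,
)

__all__ = [
    "Marginal",
    "CohortSpec",
    "default_spec",
    "generate",
    "calibrate_prevalence",
    "PrevalenceCalibrationError",
]

logger = logging.getLogger(__name__)

_Z75 = stats.norm.ppf(0.75)  # 0.6744897...

#: Copula variable order (SMI and BMI are derived, not drawn).
VARIABLES = (
    "power", "fivests", "grip", "asm", "calf", "femur", "age", "height", "weight",
)


@dataclass(frozen=True)
class Marginal:
    """One marginal distribution.

    ``kind="normal"`` uses (loc=mean, scale=SD).  ``kind="lognormal"`` is
    parameterized by the printed median and quartiles: the log-scale location
    is ln(median) and the log-scale SD is ln(q75/q25) / (2 * z_0.75).
    """

    kind: str
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lognormal"):
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @classmethod
    def normal(cls, mean: float, sd: float) -> "Marginal":
        return cls("normal", mean, sd)

    @classmethod
    def lognormal_from_quartiles(cls, median: float, q25: float, q75: float) -> "Marginal":
        if not 0 < q25 < median < q75:
            raise ValueError(f"need 0 < q25 < median < q75, got {(q25, median, q75)}")
        sigma = math.log(q75 / q25) / (2 * _Z75)
        return cls("lognormal", math.log(median), sigma)

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        """Transform standard-normal latents to this marginal (copula step)."""
        if self.kind == "normal":
            return self.loc + self.scale * z
        return np.exp(self.loc + self.scale * z)

    def shifted(self, delta: float) -> "Marginal":
        """Location lowered by *delta* units of scale (log-scale for lognormal)."""
        return replace(self, loc=self.loc - delta * self.scale)


@dataclass
class CohortSpec:
    """Everything needed to draw a cohort: sizes, marginals, correlations.

    ``rank_corr`` maps unordered variable pairs to Spearman rank
    correlations; unlisted pairs are independent.  ``classifier_truth``
    optionally supplies (b0, b_power, b_calf) to draw logistic labels
    (column ``sarc_model``) for recovery experiments.
    ``target_prevalence`` maps criterion labels to desired per-sex
    prevalences for :func:`calibrate_prevalence`.
    """

    n_female: int = 406
    n_male: int = 280
    marginals: dict[str, dict[str, Marginal]] = field(default_factory=dict)
    rank_corr: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("power", "fivests"): -0.6,
            ("calf", "asm"): 0.6,
            ("grip", "power"): 0.4,
            ("height", "femur"): 0.5,
            ("height", "weight"): 0.4,
            ("weight", "asm"): 0.5,
        }
    )
    classifier_truth: tuple[float, float, float] | None = None
    target_prevalence: dict[str, float] = field(default_factory=dict)
    fps: float = 240.0

    def correlation_matrix(self) -> np.ndarray:
        """Latent (Pearson) correlation implied by the Spearman entries.

        Uses the Gaussian-copula identity r = 2 sin(pi * rho_s / 6); repaired
        to the nearest positive semi-definite matrix if needed (warning).
        """
        k = len(VARIABLES)
        R = np.eye(k)
        idx = {v: i for i, v in enumerate(VARIABLES)}
        for (a, b), rs in self.rank_corr.items():
            if a not in idx or b not in idx:
                raise ValueError(f"unknown variable pair {(a, b)}")
            if not -1 < rs < 1:
                raise ValueError(f"rank correlation for {(a, b)} must be in (-1, 1)")
            r = 2 * math.sin(math.pi * rs / 6)
            R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        eigvals = np.linalg.eigvalsh(R)
        if eigvals.min() < 1e-10:
            warnings.warn(
                "correlation matrix not positive definite; repaired by "
                "eigenvalue clipping",
                UserWarning,
                stacklevel=2,
            )
            w, V = np.linalg.eigh(R)
            R = V @ np.diag(np.clip(w, 1e-8, None)) @ V.T
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
        return R


def default_spec() -> CohortSpec:
    """Study-conditions cohort: 406 women / 280 men with published marginals.

    Mean/SD variables are normal; median/IQR variables are log-normal matched
    to their printed quartiles.  Lengths in meters, masses in kg, times in s.
    """
    female = {
        "power": Marginal.normal(5.0, 1.1),
        "fivests": Marginal.lognormal_from_quartiles(12.1, 10.6, 14.1),
        "grip": Marginal.normal(22.6, 4.3),
        "asm": Marginal.lognormal_from_quartiles(14.4, 13.1, 15.7),
        "calf": Marginal.lognormal_from_quartiles(0.36, 0.34, 0.38),
        "femur": Marginal.lognormal_from_quartiles(0.36, 0.34, 0.38),
        "age": Marginal.lognormal_from_quartiles(71, 68, 75),
        "height": Marginal.normal(1.55, 0.06),
        "weight": Marginal.lognormal_from_quartiles(66.0, 59.6, 73.2),
    }
    male = {
        "power": Marginal.normal(5.89, 1.0),
        "fivests": Marginal.lognormal_from_quartiles(12.2, 10.7, 14.2),
        "grip": Marginal.normal(37.5, 6.8),
        "asm": Marginal.lognormal_from_quartiles(20.2, 18.7, 22.3),
        "calf": Marginal.lognormal_from_quartiles(0.37, 0.35, 0.39),
        "femur": Marginal.lognormal_from_quartiles(0.39, 0.36, 0.40),
        "age": Marginal.lognormal_from_quartiles(72, 68, 76),
        "height": Marginal.normal(1.68, 0.06),
        "weight": Marginal.lognormal_from_quartiles(79.3, 71.6, 88.5),
    }
    return CohortSpec(marginals={"female": female, "male": male})


# base rates of the health-related booleans (whole-cohort frequencies) and
# the latent "poor health" odds multiplier tying them to low power/calf —
# plausible placeholders for construct-validity machinery tests
_RISK_BASE_RATES = {
    "education_low": 0.47,
    "socioeconomic_low": 0.15,
    "comorbidity_2plus": 0.77,
    "smoking": 0.11,
    "polypharmacy_5plus": 0.21,
    "self_perceived_health_low": 0.19,
    "depression": 0.19,
    "falls_2plus": 0.12,
    "hospitalized": 0.13,
}
_POOR_HEALTH_OR = 2.5
_FRAILTY_BASE_RATE = 0.05


def _draw_sex(
    spec: CohortSpec, sex: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    marg = spec.marginals[sex]
    missing = [v for v in VARIABLES if v not in marg]
    if missing:
        raise ValueError(f"spec lacks marginals for {missing} ({sex})")
    R = spec.correlation_matrix()
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(VARIABLES)))
    z = rng.standard_normal((n, len(VARIABLES))) @ L.T
    draws = {v: marg[v].from_latent(z[:, i]) for i, v in enumerate(VARIABLES)}

    df = pd.DataFrame({
        "sex": sex,
        "age_years": draws["age"],
        "height_m": draws["height"],
        "weight_kg": draws["weight"],
        "handgrip_kg": np.maximum(draws["grip"], 1.0),
        "fivests_s": draws["fivests"],
        "asm_kg": draws["asm"],
        "calf_circumference_m": draws["calf"],
        "femur_length_m": draws["femur"],
        "power_wkg": draws["power"],
    })
    df["bmi"] = df["weight_kg"] / df["height_m"] ** 2
    df["smi_kg_m2"] = df["asm_kg"] / df["height_m"] ** 2

    # chair-rise recording implied by power and femur length: invert the
    # power regression for rising time, then quantize to the frame grid
    t = (
        kinematics.POWER_INTERCEPT
        + kinematics.POWER_COEF_FEMUR * df["femur_length_m"]
        - df["power_wkg"]
    ) / -kinematics.POWER_COEF_TIME
    t = np.maximum(t, 2.0 / spec.fps)
    df["fps"] = spec.fps
    df["start_frame"] = 0
    df["end_frame"] = np.maximum(np.rint(t * spec.fps).astype(int), 1)

    # health-related booleans, tied to a latent poor-health indicator
    poor = (df["power_wkg"] < np.quantile(df["power_wkg"], 0.2)) | (
        df["calf_circumference_m"] < np.quantile(df["calf_circumference_m"], 0.2)
    )
    shift = math.log(_POOR_HEALTH_OR)
    for factor, base in _RISK_BASE_RATES.items():
        logit = math.log(base / (1 - base)) + shift * poor.to_numpy()
        df[factor] = rng.random(n) < expit(logit)
    df["weakness"] = df["handgrip_kg"] < df["sex"].map(GRIP_CUTOFF_KG).astype(float)
    for crit in ("slowness", "exhaustion", "weight_loss", "low_activity"):
        logit = math.log(_FRAILTY_BASE_RATE / (1 - _FRAILTY_BASE_RATE)) + shift * poor.to_numpy()
        df[crit] = rng.random(n) < expit(logit)
    df["frailty_count"] = df[list(FRAILTY_CRITERIA)].sum(axis=1)
    df["frail"] = df["frailty_count"] >= 3
    return df


def generate(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw a cohort table; deterministic given *seed*.

    Columns: demographics and measurements (meters/kg/seconds), the chair-rise
    frame pair (``start_frame``/``end_frame``/``fps``), risk-factor and
    frailty booleans, reference labels ``sarc_hg_asm`` ... ``sarc_5sts_smi``,
    and ``sarc_model`` when ``spec.classifier_truth`` is set.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for sex, n in (("female", spec.n_female), ("male", spec.n_male)):
        if n > 0:
            parts.append(_draw_sex(spec, sex, n, rng))
    df = pd.concat(parts, ignore_index=True)
    df.insert(0, "participant_id", [f"P{i:05d}" for i in range(len(df))])
    for criterion in SarcopeniaCriterion:
        df[f"sarc_{criterion.label}"] = (
            reference_labels(df, criterion).astype(bool).astype(int)
        )
    if spec.classifier_truth is not None:
        b0, bp, bc = spec.classifier_truth
        p = expit(b0 + bp * df["power_wkg"] + bc * df["calf_circumference_m"])
        df["sarc_model"] = (rng.random(len(df)) < p).astype(int)
    return df


class PrevalenceCalibrationError(RuntimeError):
    """Bisection failed to reach the target prevalence."""


def _criterion_vars(criterion: SarcopeniaCriterion) -> tuple[str, str]:
    strength = "grip" if criterion.strength_test == "HG" else "fivests"
    # SMI is ASM / height^2, so SMI-based criteria are calibrated through ASM
    return strength, "asm"


def calibrate_prevalence(
    spec: CohortSpec,
    criterion: SarcopeniaCriterion | str,
    sex: str,
    target: float | None = None,
    seed: int = 0,
    n: int = 100_000,
    tol: float = 0.005,
    max_iter: int = 60,
) -> CohortSpec:
    """Shift strength/quantity marginals until the criterion hits *target*.

    A common location shift delta (in units of each marginal's scale) is
    applied to the criterion's strength variable (toward weakness) and to
    ASM (toward low mass) and found by bisection on a Monte-Carlo cohort of
    *n* draws with common random numbers — induced prevalence is monotone in
    delta.  Returns a new spec; raises after *max_iter* without convergence.
    """
    criterion = (
        SarcopeniaCriterion.parse(criterion) if isinstance(criterion, str) else criterion
    )
    if target is None:
        target = spec.target_prevalence.get(criterion.label)
    if target is None or not 0 < target < 1:
        raise ValueError(f"target prevalence must be in (0, 1), got {target}")

    strength_var, quantity_var = _criterion_vars(criterion)
    marg = spec.marginals[sex]
    R = spec.correlation_matrix()
    idx = {v: i for i, v in enumerate(VARIABLES)}
    keep = [idx[v] for v in (strength_var, quantity_var, "height")]
    Rsub = R[np.ix_(keep, keep)]
    L = np.linalg.cholesky(Rsub + 1e-12 * np.eye(3))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 3)) @ L.T  # common random numbers

    from .ewgsop2 import ASM_CUTOFF_KG, SMI_CUTOFF_KG_M2, FIVESTS_CUTOFF_S

    height = marg["height"].from_latent(z[:, 2])

    def prevalence(delta: float) -> float:
        # delta > 0 pushes strength toward weakness and mass toward low
        if strength_var == "grip":
            s = marg["grip"].shifted(delta).from_latent(z[:, 0])
            low_strength = s < GRIP_CUTOFF_KG[sex]
        else:
            s = marg["fivests"].shifted(-delta).from_latent(z[:, 0])
            low_strength = s > FIVESTS_CUTOFF_S
        asm = marg["asm"].shifted(delta).from_latent(z[:, 1])
        if criterion.quantity_measure == "ASM":
            low_quantity = asm < ASM_CUTOFF_KG[sex]
        else:
            low_quantity = asm / height**2 < SMI_CUTOFF_KG_M2[sex]
        return float((low_strength & low_quantity).mean())

    lo, hi = -6.0, 6.0
    p_lo, p_hi = prevalence(lo), prevalence(hi)
    trace = [(lo, p_lo), (hi, p_hi)]
    if not p_lo <= target <= p_hi:
        raise PrevalenceCalibrationError(
            f"target {target:.3f} outside achievable range [{p_lo:.4f}, {p_hi:.4f}]"
        )
    delta = 0.0
    for _ in range(max_iter):
        delta = (lo + hi) / 2
        p = prevalence(delta)
        trace.append((delta, p))
        if abs(p - target) <= tol:
            break
        if p < target:
            lo = delta
        else:
            hi = delta
    else:
        raise PrevalenceCalibrationError(
            f"no convergence after {max_iter} iterations; trace tail: {trace[-5:]}"
        )
    logger.info(
        "calibrated %s/%s to prevalence %.4f (target %.4f) with delta=%.4f",
        sex, criterion.label, p, target, delta,
    )
    new_marg = copy.deepcopy(spec.marginals)
    if strength_var == "grip":
        new_marg[sex]["grip"] = marg["grip"].shifted(delta)
    else:
        new_marg[sex]["fivests"] = marg["fivests"].shifted(-delta)
    new_marg[sex]["asm"] = marg["asm"].shifted(delta)
    return replace(spec, marginals=new_marg)
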