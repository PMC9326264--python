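"""Synthetic binary foraging datasets with the study's design structure.

The generator mirrors the experiment: 7 ALAN treatments x 3 tanks x 4 snails
x 13 observation nights x 2 time-of-day strata = 2184 Bernoulli records.
Foraging probability follows a logistic model with treatment-specific
intercept offsets and moonlight slopes, a linear night-of-observation trend,
and Gaussian random intercepts for tank and for snail nested in tank:

    logit p = b0 + b_alan[t] + b_moon[t] * moonlux + g_night * night
              + u_tank + u_snail

The nightly maximum moonlight covariate defaults to the package's own
modeled values for the 13 observation nights of 2 Feb - 2 Mar 2020 at Menai
Bridge (normalized so the calendar-2020 peak is 0.5 lx); both strata of a
night share the night's value.  The default "reversal" scenario seeds the
effect the study reports: foraging decreases with moonlight in the control
and increases under 10 lx, 10 lx-mitigation and 50 lx ALAN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from moonsim.scheduler import STUDY_TREATMENTS, Treatment

__all__ = [
    "OBSERVATION_NIGHTS",
    "NIGHTLY_MAX_LUX",
    "ForagingDesign",
    "ForagingParams",
    "study_design",
    "reversal_params",
    "null_params",
    "generate_dataset",
]

#: Observation-night indices within the 28-day period (every second night,
#: night 21 lost to a charging error).
OBSERVATION_NIGHTS: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 23, 25, 27)

#: Modeled nightly maximum moonlight (lx) for those nights, as produced by
#: skybright with default parameters for Menai Bridge (night n starts on
#: civil date 1 Feb 2020 + n days); regenerate with
#: ``scripts/acceptance.py`` or the skybright API.
NIGHTLY_MAX_LUX: tuple[float, ...] = (
    0.039110, 0.100908, 0.221652, 0.393588, 0.188887, 0.064504, 0.019735,
    0.005359, 0.001072, 0.000000, 0.000057, 0.000693, 0.004564,
)

TIME_OF_DAY = ("night", "day")


@dataclass(frozen=True)
class ForagingDesign:
    treatments: tuple[Treatment, ...] = STUDY_TREATMENTS
    tanks_per_treatment: int = 3
    snails_per_tank: int = 4
    nights: tuple[int, ...] = OBSERVATION_NIGHTS
    nightly_max_lux: tuple[float, ...] = NIGHTLY_MAX_LUX
    strata: tuple[str, ...] = TIME_OF_DAY

    def __post_init__(self) -> None:
        if len(self.nights) != len(self.nightly_max_lux):
            raise ValueError("one lux value per observation night is required")

    @property
    def n_records(self) -> int:
        return (
            len(self.treatments)
            * self.tanks_per_treatment
            * self.snails_per_tank
            * len(self.nights)
            * len(self.strata)
        )


@dataclass(frozen=True)
class ForagingParams:
    """Generative coefficients, all on the logit scale.

    ``beta_alan`` and ``beta_moon`` hold one value per treatment, in design
    order (control first); ``beta_moon`` is the slope per lux of nightly
    maximum moonlight.
    """

    beta0: float = 0.0
    beta_alan: tuple[float, ...] = (0.0,) * 7
    beta_moon: tuple[float, ...] = (0.0,) * 7
    gamma_night: float = 0.0
    sigma_tank: float = 0.0
    sigma_snail: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_tank < 0 or self.sigma_snail < 0:
            raise ValueError("random-intercept standard deviations must be >= 0")


def study_design() -> ForagingDesign:
    """The experiment's layout with the package-modeled moonlight covariate."""
    return ForagingDesign()


def reversal_params(seed: int = 0) -> ForagingParams:
    """Default effect scenario: the moonlight slope reverses under bright ALAN.

    Slopes (logit per lux): -3 for the control, 0 for 0.1/0.5/1 lx, +3 for
    10 lx, 10 lx-mitigation and 50 lx.  Magnitudes were calibrated by
    simulation at the study's sample size: the smallest round value at which
    the ALAN x Moonlight interaction test clearly exceeds 80% power while
    the control/50 lx slope signs are recovered in at least 95% of runs.
    Random-intercept spreads are moderate (0.25 between tanks, 0.5 between
    snails).
    """
    return ForagingParams(
        beta0=-0.3,
        beta_alan=(0.0,) * 7,
        beta_moon=(-3.0, 0.0, 0.0, 0.0, 3.0, 3.0, 3.0),
        gamma_night=0.01,
        sigma_tank=0.25,
        sigma_snail=0.5,
        seed=seed,
    )


def null_params(seed: int = 0, beta0: float = -0.3) -> ForagingParams:
    """No effects at all: every record is Bernoulli(expit(beta0))."""
    return ForagingParams(beta0=beta0, seed=seed)


def generate_dataset(
    design: ForagingDesign = ForagingDesign(),
    params: ForagingParams = ForagingParams(),
) -> pd.DataFrame:
    """Simulate one long-format foraging dataset.

    Returns a DataFrame with columns snail_id, tank_id, treatment,
    night_index, nightly_max_moon_lux, time_of_day, foraging, plus the
    generating probability in ``p_true``.  Identical (design, params) give
    byte-identical output.
    """
    n_t = len(design.treatments)
    if not (len(params.beta_alan) == len(params.beta_moon) == n_t):
        raise ValueError("beta_alan / beta_moon must have one entry per treatment")
    rng = np.random.default_rng(params.seed)

    rows = []
    for ti, treat in enumerate(design.treatments):
        for k in range(design.tanks_per_treatment):
            tank_id = f"{treat.label}:tank{k + 1}"
            for s in range(design.snails_per_tank):
                snail_id = f"{tank_id}:snail{s + 1}"
                for night, lux in zip(design.nights, design.nightly_max_lux):
                    for tod in design.strata:
                        rows.append(
                            (snail_id, tank_id, treat.label, ti, night, lux, tod)
                        )
    df = pd.DataFrame(
        rows,
        columns=[
            "snail_id", "tank_id", "treatment", "_ti",
            "night_index", "nightly_max_moon_lux", "time_of_day",
        ],
    )

    tanks = df["tank_id"].unique()
    snails = df["snail_id"].unique()
    u_tank = dict(zip(tanks, params.sigma_tank * rng.standard_normal(len(tanks))))
    u_snail = dict(zip(snails, params.sigma_snail * rng.standard_normal(len(snails))))

    ti = df["_ti"].to_numpy()
    logit = (
        params.beta0
        + np.asarray(params.beta_alan)[ti]
        + np.asarray(params.beta_moon)[ti] * df["nightly_max_moon_lux"].to_numpy()
        + params.gamma_night * df["night_index"].to_numpy()
        + df["tank_id"].map(u_tank).to_numpy()
        + df["snail_id"].map(u_snail).to_numpy()
    )
    if not np.all(np.isfinite(logit)):
        raise ValueError("non-finite linear predictor; check coefficients")
    p = 1.0 / (1.0 + np.exp(-logit))
    df["p_true"] = p
    df["foraging"] = rng.binomial(1, p)
    return df.drop(columns="_ti")
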