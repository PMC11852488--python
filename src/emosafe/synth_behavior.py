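"""Seeded synthetic behavioral trial tables.

Raw behavioral data for the hazard-identification / risk-assessment study
design (22 participants, each measured under neutral, fear and anger) are
unavailable, so this module generates trial tables with a controllable
population structure: per-emotion mean shifts on the four dependent
variables, a psychological-capital moderation (opposite half-deltas applied
to the low and high PsyCap groups so marginal emotion means are
unaffected), linear covariate effects for five personal factors, and
residual noise — Gaussian for the bounded DVs (RA, RS), lognormal for the
response times (strictly positive, right-skewed, as reaction times are).

``preset_reported_means`` ships a specification whose population means follow
the reported ordinal pattern (RA: fear > anger > neutral; RT1 and RT2
shortest under fear; RS highest under fear and lowest under anger).  It is
an ordinal-pattern emulation, not a fit to the study's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DVS = ("RA", "RT1", "RS", "RT2")
EMOTIONS = ("neutral", "fear", "anger")
COVARIATES = ("sleep", "smoke", "alcohol", "trainings", "lectures")

#: PsyCap observed range and dichotomization threshold.
PSYCAP_RANGE = (3.29, 4.75)
PSYCAP_THRESHOLD = 4.0

#: Population means of the personal factors (used to center covariate terms).
COVARIATE_MEANS = {
    "sleep": 7.77,
    "smoke": 1.18,
    "alcohol": 1.68,
    "trainings": 1.68,
    "lectures": 1.64,
}


def _zero_shifts() -> dict:
    return {dv: {e: 0.0 for e in EMOTIONS} for dv in DVS}


def _zero_slopes() -> dict:
    return {dv: {c: 0.0 for c in COVARIATES} for dv in DVS}


@dataclass(frozen=True)
class BehaviorEffectSpec:
    """Population parameters of the synthetic behavioral model.

    ``baseline[dv]`` is the neutral-condition population mean;
    ``emotion_shift[dv][emotion]`` an additive mean shift;
    ``moderation[dv][emotion]`` the high-minus-low PsyCap difference
    (applied as +/- half to each group); ``covariate_slopes[dv][cov]``
    linear effects of mean-centered personal factors.  ``residual_sd``
    holds Gaussian SDs for RA and RS and lognormal sigma (log-scale SD)
    for RT1 and RT2.
    """

    n_participants: int = 22
    baseline: dict = field(
        default_factory=lambda: {"RA": 0.55, "RT1": 3800.0, "RS": 3.3, "RT2": 3300.0}
    )
    emotion_shift: dict = field(default_factory=_zero_shifts)
    moderation: dict = field(default_factory=_zero_shifts)
    covariate_slopes: dict = field(default_factory=_zero_slopes)
    residual_sd: dict = field(
        default_factory=lambda: {"RA": 0.07, "RT1": 0.40, "RS": 0.40, "RT2": 0.40}
    )

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError(
                f"need at least 4 participants, got {self.n_participants}"
            )
        for dv in DVS:
            if self.residual_sd[dv] <= 0:
                raise ValueError(f"residual SD for {dv} must be positive")

    @staticmethod
    def null(n_participants: int = 22) -> "BehaviorEffectSpec":
        """All effects zero: the type-I-error calibration population."""
        return BehaviorEffectSpec(n_participants=n_participants)


def preset_reported_means(n_participants: int = 22) -> BehaviorEffectSpec:
    """Shipped spec reproducing the reported ordinal pattern of means.

    Neutral-condition baselines and emotion shifts place the population
    means at RA (54.86, 65.22, 59.55)%, RT1 (3996.9, 3456.1, 3772.5) ms,
    RS (3.30, 3.35, 3.26) and RT2 (3339.5, 3056.5, 3392.1) ms for
    (neutral, fear, anger).  Moderation deltas follow the direction of the
    reported low/high PsyCap cell means; covariate slopes keep the
    reported signs at modest magnitudes.
    """
    return BehaviorEffectSpec(
        n_participants=n_participants,
        baseline={"RA": 0.5486, "RT1": 3996.92, "RS": 3.30, "RT2": 3339.5},
        emotion_shift={
            "RA": {"neutral": 0.0, "fear": 0.1036, "anger": 0.0469},
            "RT1": {"neutral": 0.0, "fear": -540.81, "anger": -224.42},
            "RS": {"neutral": 0.0, "fear": 0.05, "anger": -0.04},
            "RT2": {"neutral": 0.0, "fear": -282.99, "anger": 52.63},
        },
        moderation={
            "RA": {"neutral": 0.02, "fear": 0.02, "anger": 0.03},
            "RT1": {"neutral": 351.0, "fear": 239.0, "anger": -917.0},
            "RS": {"neutral": -0.24, "fear": -0.35, "anger": -0.14},
            "RT2": {"neutral": 243.0, "fear": 518.0, "anger": -298.0},
        },
        covariate_slopes={
            "RA": {
                "sleep": 0.01, "smoke": 0.002, "alcohol": -0.01,
                "trainings": 0.03, "lectures": 0.01,
            },
            "RT1": {
                "sleep": -300.0, "smoke": -100.0, "alcohol": 150.0,
                "trainings": -400.0, "lectures": 200.0,
            },
            "RS": {
                "sleep": -0.05, "smoke": 0.03, "alcohol": 0.05,
                "trainings": -0.05, "lectures": 0.1,
            },
            "RT2": {
                "sleep": -265.0, "smoke": -500.0, "alcohol": 440.0,
                "trainings": -500.0, "lectures": 350.0,
            },
        },
        residual_sd={"RA": 0.07, "RT1": 0.40, "RS": 0.40, "RT2": 0.40},
    )


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Personal factors matching the reported ranges and approximate means."""
    sleep = np.clip(rng.normal(7.77, 0.42, size=n), 6.0, 8.0).round(1)
    smoke = rng.choice([1, 2, 3, 4], size=n, p=[0.88, 0.08, 0.02, 0.02])
    alcohol = rng.choice([1, 2, 3], size=n, p=[0.37, 0.58, 0.05])
    trainings = rng.choice([1, 2, 3], size=n, p=[0.37, 0.58, 0.05])
    lectures = rng.choice([1, 2, 3], size=n, p=[0.46, 0.44, 0.10])
    return pd.DataFrame(
        {
            "sleep": sleep,
            "smoke": smoke,
            "alcohol": alcohol,
            "trainings": trainings,
            "lectures": lectures,
        }
    )


def generate_trials(spec: BehaviorEffectSpec, seed: int = 0) -> pd.DataFrame:
    """One row per participant x emotion, fully reproducible per seed.

    PsyCap scores are drawn uniformly on [3.29, 4.0) for the first half of
    participants and [4.0, 4.75] for the second, so the low/high split at
    4.0 is balanced by construction (the odd participant, if any, goes to
    the low group).  RA is clipped to [0, 1] and RS to [1, 5] as a safety
    net; at the shipped parameter scales clipping does not activate.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_participants
    n_low = (n + 1) // 2

    psycap = np.empty(n)
    psycap[:n_low] = rng.uniform(PSYCAP_RANGE[0], PSYCAP_THRESHOLD, size=n_low)
    psycap[n_low:] = rng.uniform(PSYCAP_THRESHOLD, PSYCAP_RANGE[1], size=n - n_low)
    group = np.where(psycap < PSYCAP_THRESHOLD, "low", "high")
    cov = _draw_covariates(rng, n)

    rows = []
    for pid in range(n):
        cov_term = {
            dv: sum(
                spec.covariate_slopes[dv][c]
                * (cov.loc[pid, c] - COVARIATE_MEANS[c])
                for c in COVARIATES
            )
            for dv in DVS
        }
        sign = 0.5 if group[pid] == "high" else -0.5
        for emotion in EMOTIONS:
            row = {
                "participant": f"P{pid + 1:02d}",
                "emotion": emotion,
                "psycap_score": round(float(psycap[pid]), 3),
                "psycap_group": group[pid],
            }
            for dv in DVS:
                mean = (
                    spec.baseline[dv]
                    + spec.emotion_shift[dv][emotion]
                    + sign * spec.moderation[dv][emotion]
                    + cov_term[dv]
                )
                sd = spec.residual_sd[dv]
                if dv in ("RT1", "RT2"):
                    # lognormal with expectation equal to the model mean
                    value = mean * np.exp(
                        sd * rng.standard_normal() - sd**2 / 2.0
                    )
                else:
                    value = mean + sd * rng.standard_normal()
                row[dv] = float(value)
            rows.append({**row, **{c: cov.loc[pid, c] for c in COVARIATES}})

    table = pd.DataFrame(rows)
    table["RA"] = table["RA"].clip(0.0, 1.0)
    table["RS"] = table["RS"].clip(1.0, 5.0)
    return table


def with_n(spec: BehaviorEffectSpec, n_participants: int) -> BehaviorEffectSpec:
    """Copy of ``spec`` with a different participant count."""
    return replace(spec, n_participants=n_participants)
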