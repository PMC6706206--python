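"""Generators for every input the analysis pipeline consumes.

Nothing in the package requires external data: the mortality estimator runs
on a deterministic dummy survivorship series, the allometry and staging
utilities can be exercised on synthetic field-style samples of pereon
lengths and podomere counts, and the named feeding regimes reproduce the
study conditions for both species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .environment import FeedingRegime
from .life_history import (
    PODOMERE_MATURE,
    PODOMERE_MAX,
    PODOMERE_MIN,
    DEBParams,
    StageLabel,
    body_length_to_pereon,
    pereon_to_body_length,
)

__all__ = [
    "survival_series",
    "synthetic_sample",
    "paper_regimes",
    "FIELD_NEWBORN_MEAN_MM",
    "FIELD_NEWBORN_SD_MM",
    "FIELD_MATURITY_MEAN_MM",
    "FIELD_MATURITY_SD_MM",
]

# Field-observed body-length summaries for the amphipod (mm): newborns
# 3.80 +/- 0.37 SD, females at maturity 7.28 +/- 0.50 SD.
FIELD_NEWBORN_MEAN_MM = 3.80
FIELD_NEWBORN_SD_MM = 0.37
FIELD_MATURITY_MEAN_MM = 7.28
FIELD_MATURITY_SD_MM = 0.50


def survival_series(daily_mortality: float, n_days: int = 365) -> pd.DataFrame:
    """Deterministic dummy survivorship series s_{t+1} = s_t - m * s_t.

    Returns a DataFrame with columns ``day`` (0..n_days) and ``survivors``
    (proportion, starting at 1).  The recursion is exactly geometric:
    survivors[t] = (1 - m)**t.
    """
    m = float(daily_mortality)
    if not (0.0 < m < 1.0):
        raise ValueError(f"daily mortality must lie strictly in (0, 1), got {m}")
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    survivors = np.empty(n_days + 1)
    survivors[0] = 1.0
    for t in range(n_days):
        survivors[t + 1] = survivors[t] - m * survivors[t]
    return pd.DataFrame({"day": np.arange(n_days + 1), "survivors": survivors})


def synthetic_sample(
    params: DEBParams,
    n: int,
    seed,
    juvenile_fraction: float = 0.5,
    newborn_mean: float = FIELD_NEWBORN_MEAN_MM,
    newborn_sd: float = FIELD_NEWBORN_SD_MM,
    mature_mean: float = FIELD_MATURITY_MEAN_MM,
    mature_sd: float = FIELD_MATURITY_SD_MM,
) -> pd.DataFrame:
    """Synthetic field-style sample of pereon lengths and podomere counts.

    Body lengths are drawn from a two-class (juvenile/mature) Gaussian
    mixture using the field-observed class means and SDs, then inverted
    through the allometry to pereon lengths.  Podomere counts are drawn
    uniformly on the stage-consistent ranges ([4, 11] for juveniles,
    [12, 21] for matures) — placeholder distributions for exercising the
    staging utilities, not a biological model of moult schedules.

    Returns a DataFrame with columns ``pereon_length``, ``podomere_count``,
    ``body_length`` and ``stage``; reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not (0.0 <= juvenile_fraction <= 1.0):
        raise ValueError("juvenile_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_juvenile = rng.random(n) < juvenile_fraction
    means = np.where(is_juvenile, newborn_mean, mature_mean)
    sds = np.where(is_juvenile, newborn_sd, mature_sd)
    body = rng.normal(means, sds)
    # keep lengths physically meaningful (above the allometry intercept)
    floor = 0.5
    body = np.clip(body, floor, None)
    podomeres = np.where(
        is_juvenile,
        rng.integers(PODOMERE_MIN, PODOMERE_MATURE, size=n),
        rng.integers(PODOMERE_MATURE, PODOMERE_MAX + 1, size=n),
    )
    stage = np.where(
        is_juvenile, StageLabel.JUVENILE.value, StageLabel.SUBADULT_OR_ADULT.value
    )
    return pd.DataFrame(
        {
            "pereon_length": body_length_to_pereon(body),
            "podomere_count": podomeres,
            "body_length": body,
            "stage": stage,
        }
    )


def paper_regimes(p: float = 0.5, q: float = 0.5) -> dict[str, FeedingRegime]:
    """The study's named feeding regimes for both species and noise levels.

    Good/bad feeding levels are (1.0, 0.4) for the amphipod and (0.9, 0.5)
    for the manta ray — bracketing each species' equilibrium feeding level —
    each with low (sigma(Y) = 0.1) and high (sigma(Y) = 0.5) feeding-level
    variability.  Switch probabilities default to white noise (p = q = 0.5)
    and are meant to be overridden per grid cell.
    """
    out = {}
    for species, (low, high) in {
        "orchestia": (0.4, 1.0),
        "manta": (0.5, 0.9),
    }.items():
        for sigma in (0.1, 0.5):
            key = f"{species}_sigma{str(sigma).replace('.', '')}"
            out[key] = FeedingRegime(p=p, q=q, EY_low=low, EY_high=high, sigma_Y=sigma)
    return out
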