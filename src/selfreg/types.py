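"""Core domain types shared across the package.

Conventions used throughout:

* Food ratings live on a continuous -5..+5 scale for taste (``tr``) and
  health (``hr``); the band within ±5% of the total scale length around
  zero (|r| <= 0.5) is the "neutral zone".
* Trial types: ``HTLH`` (high-taste/low-health) and ``LTHH``
  (low-taste/high-health) are self-control challenges; ``HTHH`` and
  ``LTLH`` are aligned, non-challenge trials.
* Affect ratings use the 9-point SAM valence scale, 1 = most negative,
  9 = most positive.
* Drift-diffusion boundary convention: upper boundary = "yes/eat",
  lower boundary = "no/refuse"; the relative starting point ``z_rel``
  is measured from the lower (refuse) boundary, so ``z_rel < 0.5`` is a
  bias toward refusing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CHALLENGE_TYPES = ("HTLH", "LTHH")
NONCHALLENGE_TYPES = ("HTHH", "LTLH")
TRIAL_TYPES = CHALLENGE_TYPES + NONCHALLENGE_TYPES

#: Block types of the emotion session: (valence, condition) pairs.
BLOCK_TYPES = (
    "negative_view",
    "negative_reappraise",
    "neutral_view",
    "positive_reappraise",
    "positive_view",
)

RATING_MIN, RATING_MAX = -5.0, 5.0
#: Half-width of the neutral zone: 5% of the 10-unit scale on each side of zero.
NEUTRAL_HALFWIDTH = 0.5
#: Response window of the food-choice task, seconds.
RESPONSE_WINDOW_S = 3.0


class ConfigurationError(ValueError):
    """Raised when a configuration violates its domain constraints."""


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters for the food-choice model.

    Parameters
    ----------
    a : boundary separation, evidence units (> 0).
    z_rel : relative starting point in (0, 1), fraction of ``a`` measured
        from the lower (refuse) boundary.  Default 1/3: a bias toward
        refusing the foods.
    t0 : non-decision time, seconds (>= 0).
    drift_scale : drift per unit subjective value.
    sigma : diffusion coefficient; fixed at 1 for identifiability.
    """

    a: float = 1.5
    z_rel: float = 1.0 / 3.0
    t0: float = 0.3
    drift_scale: float = 1.0
    sigma: float = 1.0

    def __post_init__(self):
        if not (self.a > 0):
            raise ConfigurationError(f"boundary separation must be > 0, got {self.a}")
        if not (0 < self.z_rel < 1):
            raise ConfigurationError(f"z_rel must lie in (0, 1), got {self.z_rel}")
        if self.t0 < 0:
            raise ConfigurationError(f"non-decision time must be >= 0, got {self.t0}")
        if self.sigma != 1.0:
            raise ConfigurationError("sigma is fixed at 1 (scaling convention)")


@dataclass(frozen=True)
class DDMFit:
    """Result of a maximum-likelihood drift-diffusion fit."""

    params: DDMParams
    neg_loglik: float
    converged: bool
    n_used: int
    boundary_warning: bool = False


@dataclass(frozen=True)
class ParticipantProfile:
    """Ground-truth generative parameters for one synthetic participant."""

    participant_id: str
    beta0: float
    w_taste: float
    w_health: float
    ddm: DDMParams
    delta_neg: float
    delta_pos: float
    hunger_pct: float
    bmi: float
    restraint: float
    gender: str

    def __post_init__(self):
        if self.delta_neg < 0 or self.delta_pos < 0:
            raise ConfigurationError("regulation efficacies must be >= 0")
        if not (0 <= self.hunger_pct <= 100):
            raise ConfigurationError("hunger_pct must lie in [0, 100]")
        for name in ("beta0", "w_taste", "w_health"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


@dataclass(frozen=True)
class RatingModel:
    """Mixture sampler for (taste, health) rating pairs.

    Items fall into one of the four quadrants or the neutral band, with
    configurable masses; within a quadrant each attribute's magnitude is
    uniform over its configured range, then sign-flipped per quadrant.
    The defaults encode a snack-pool structure: a skew toward
    tasty-unhealthy items; tempting items that are strongly unhealthy;
    healthy-but-unpalatable items that are strongly unpalatable; and
    aligned palatable-healthy items (fresh fruit and the like) rated
    high on both attributes.
    """

    p_htlh: float = 0.42
    p_lthh: float = 0.12
    p_hthh: float = 0.22
    p_ltlh: float = 0.14
    p_neutral: float = 0.10
    # (low, high) magnitude ranges per quadrant, in rating units above
    # the neutral boundary
    htlh_taste: tuple = (0.5, 5.0)
    htlh_health: tuple = (3.0, 5.0)
    lthh_taste: tuple = (3.0, 5.0)
    lthh_health: tuple = (0.5, 5.0)
    hthh_both: tuple = (3.5, 5.0)
    ltlh_both: tuple = (0.5, 2.5)

    def masses(self) -> np.ndarray:
        m = np.array([self.p_htlh, self.p_lthh, self.p_hthh, self.p_ltlh, self.p_neutral])
        if np.any(m < 0) or not np.isclose(m.sum(), 1.0):
            raise ConfigurationError("rating-model masses must be nonnegative and sum to 1")
        return m


#: In-scan SAM condition means under passive viewing (the unregulated
#: baseline); reappraise-condition means are derived from these by each
#: participant's regulation efficacy.
DEFAULT_CONDITION_MEANS = {
    "negative_view": 2.69,
    "neutral_view": 5.26,
    "positive_view": 7.09,
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``coupling_rho`` is the latent correlation between a participant's
    emotion-regulation efficacy (mean of the negative and positive
    deltas) and their health weight in food choice; it is the knob that
    induces (or, at 0, removes) a cross-task association.
    """

    n_participants: int = 38
    n_items: int = 180
    n_trials: int = 100
    n_challenge_target: int = 75
    min_challenge: int = 50
    rating_model: RatingModel = field(default_factory=RatingModel)
    coupling_rho: float = 0.0
    seed: int = 0
    condition_means: dict = field(default_factory=lambda: dict(DEFAULT_CONDITION_MEANS))
    ddm_defaults: DDMParams = field(default_factory=DDMParams)
    # population distributions of the generative weights (log-odds per rating unit)
    w_taste_mean: float = 0.55
    w_taste_sd: float = 0.12
    w_health_mean: float = 0.50
    w_health_sd: float = 0.12
    beta0_mean: float = 0.0
    beta0_sd: float = 0.2
    # regulation efficacy (SAM units shifted toward neutral)
    delta_neg_mean: float = 1.56
    delta_neg_sd: float = 0.5
    delta_pos_mean: float = 1.88
    delta_pos_sd: float = 0.5
    # SAM rating noise: trial-level SD and participant-level baseline shift SD
    sam_trial_sd: float = 1.0
    sam_participant_sd: float = 0.4

    def __post_init__(self):
        if not (-1.0 <= self.coupling_rho <= 1.0):
            raise ConfigurationError(
                f"coupling_rho must lie in [-1, 1], got {self.coupling_rho}"
            )
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.n_items < self.n_trials:
            raise ConfigurationError("n_items must cover at least n_trials foods")
        self.rating_model.masses()  # validate


@dataclass(frozen=True)
class WeightFit:
    """Per-participant logistic taste/health weight fit (log-odds units)."""

    beta0: float
    w_taste: float
    w_health: float
    converged: bool
    separation_flag: bool
    se_taste: float = float("nan")
    se_health: float = float("nan")
    n_used: int = 0


@dataclass(frozen=True)
class SelfControlSummary:
    """Self-control success levels over responded challenge trials."""

    level: Optional[float]
    level_htlh: Optional[float]
    level_lthh: Optional[float]
    n_challenge_responded: int
    n_htlh_responded: int
    n_lthh_responded: int
    n_missed_challenge: int
    defined: bool


@dataclass(frozen=True)
class ReappraisalScores:
    """Valence-wise and overall reappraisal success scores (SAM units)."""

    success_neg: Optional[float]
    success_pos: Optional[float]
    success_overall: Optional[float]
    n_neg: int
    n_pos: int


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation point estimate with a bootstrap 95% interval."""

    rho: float
    interval_low: float
    interval_high: float
    pp_positive: float
    method: str
    n: int
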