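"""Synthetic cohort generation with known ground truth.

Every downstream stage (choice-set design, scoring, drift-diffusion
fitting, association inference) is testable against cohorts generated
here, with all generative parameters recorded.

Generative model
----------------
* Each participant carries logistic-scale taste/health weights, a
  drift-diffusion parameterization with a refusal-biased starting
  point, and regulation efficacies ``delta_neg``/``delta_pos`` (how far,
  in SAM units, reappraisal shifts their ratings toward neutral).
* A single latent regulation-capacity factor drives both efficacies;
  its correlation with the health weight is ``coupling_rho``, the knob
  for a cross-task association (default 0: no true coupling).
* Ratings come from a quadrant mixture skewed toward tasty-unhealthy
  items; choices and RTs from the diffusion simulator within a 3-s
  window; SAM ratings from a discretized truncated Gaussian around the
  condition means.
* Hunger, BMI, restraint and gender are generated but inert (their
  generative coefficients are zero), so covariate regressions can be
  exercised against a known null.

Reproducibility: one RNG stream per participant, derived from the
cohort seed and the participant index, so any participant can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ddm
from .design import ChoiceSet, InsufficientChallengeError, build_choice_set
from .types import (
    BLOCK_TYPES,
    CohortConfig,
    ConfigurationError,
    DDMParams,
    ParticipantProfile,
    RESPONSE_WINDOW_S,
)

__all__ = [
    "generate_participant_profiles",
    "generate_food_ratings",
    "simulate_food_choices",
    "simulate_emotion_session",
    "generate_cohort",
    "CohortDataset",
]

_QUADRANTS = ("HTLH", "LTHH", "HTHH", "LTLH", "neutral")
# (taste sign, health sign); +1 above the neutral zone, -1 below
_QUADRANT_SIGNS = {"HTLH": (1, -1), "LTHH": (-1, 1), "HTHH": (1, 1), "LTLH": (-1, -1)}


def _participant_rng(config: CohortConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, index]))


def generate_participant_profiles(config: CohortConfig) -> list[ParticipantProfile]:
    """Draw ground-truth participant parameters.

    The latent regulation-capacity factor ``e`` and the health-weight
    disturbance are bivariate standard normal with correlation
    ``coupling_rho``; both regulation deltas load on the same ``e``
    (a single-trait model), so corr(mean efficacy, w_health) equals
    ``coupling_rho`` up to the rare truncation of deltas at zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    rho = config.coupling_rho
    n = config.n_participants
    e = rng.standard_normal(n)
    u = rng.standard_normal(n)
    h_latent = rho * e + np.sqrt(1.0 - rho**2) * u
    w_health = config.w_health_mean + config.w_health_sd * h_latent
    w_taste = config.w_taste_mean + config.w_taste_sd * rng.standard_normal(n)
    beta0 = config.beta0_mean + config.beta0_sd * rng.standard_normal(n)
    delta_neg = np.clip(config.delta_neg_mean + config.delta_neg_sd * e, 0.0, None)
    delta_pos = np.clip(config.delta_pos_mean + config.delta_pos_sd * e, 0.0, None)
    hunger = rng.uniform(0.0, 100.0, n)
    bmi = rng.normal(23.0, 3.0, n)
    restraint = rng.standard_normal(n)
    gender = rng.choice(["f", "m"], size=n, p=[21 / 38, 17 / 38])

    width = max(3, len(str(n)))
    return [
        ParticipantProfile(
            participant_id=f"sub-{i:0{width}d}",
            beta0=float(beta0[i]),
            w_taste=float(w_taste[i]),
            w_health=float(w_health[i]),
            ddm=config.ddm_defaults,
            delta_neg=float(delta_neg[i]),
            delta_pos=float(delta_pos[i]),
            hunger_pct=float(hunger[i]),
            bmi=float(bmi[i]),
            restraint=float(restraint[i]),
            gender=str(gender[i]),
        )
        for i in range(n)
    ]


def generate_food_ratings(
    profile: ParticipantProfile,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    seed=None,
) -> pd.DataFrame:
    """Draw a rating profile of ``config.n_items`` (taste, health) pairs.

    Items are assigned to one of the four quadrants or the neutral band
    with the configured masses; within a quadrant, each attribute is
    uniform between the neutral boundary (0.5) and the scale end (5).
    Neutral items have one attribute inside the band (they exercise the
    exclusion rule downstream).
    """
    if config.n_items < 1:
        raise ConfigurationError("n_items must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rm = config.rating_model
    masses = rm.masses()
    ranges = {
        "HTLH": (rm.htlh_taste, rm.htlh_health),
        "LTHH": (rm.lthh_taste, rm.lthh_health),
        "HTHH": (rm.hthh_both, rm.hthh_both),
        "LTLH": (rm.ltlh_both, rm.ltlh_both),
    }
    cats = rng.choice(len(_QUADRANTS), size=config.n_items, p=masses)
    tr = np.empty(config.n_items)
    hr = np.empty(config.n_items)
    for i, c in enumerate(cats):
        name = _QUADRANTS[c]
        if name == "neutral":
            # one attribute in the band, the other anywhere on the scale
            neutral_attr = rng.random() < 0.5
            band = rng.uniform(-0.5, 0.5)
            other = rng.uniform(-5.0, 5.0)
            tr[i], hr[i] = (band, other) if neutral_attr else (other, band)
        else:
            st, sh = _QUADRANT_SIGNS[name]
            (t_lo, t_hi), (h_lo, h_hi) = ranges[name]
            tr[i] = st * rng.uniform(t_lo, t_hi)
            hr[i] = sh * rng.uniform(h_lo, h_hi)
    tr = np.clip(tr, -5.0, 5.0)
    hr = np.clip(hr, -5.0, 5.0)
    return pd.DataFrame(
        {
            "participant_id": profile.participant_id,
            "food_id": [f"food-{i:03d}" for i in range(config.n_items)],
            "tr": np.round(tr, 4),
            "hr": np.round(hr, 4),
        }
    )


def simulate_food_choices(
    profile: ParticipantProfile,
    choice_set: ChoiceSet,
    rng: np.random.Generator | None = None,
    seed=None,
    max_rt: float = RESPONSE_WINDOW_S,
) -> pd.DataFrame:
    """Simulate one participant's choices over their tailored set.

    The trial drift is ``drift_scale * (w_taste*tr_c + w_health*hr_c)``
    with ratings mean-centered over the presented foods, fed through the
    diffusion simulator; first passages beyond the response window are
    recorded as missed with no choice.
    """
    if len(choice_set) == 0:
        raise ValueError("empty choice set")
    if rng is None:
        rng = np.random.default_rng(seed)
    trials = choice_set.trials
    tr_c = trials["tr"].to_numpy() - trials["tr"].mean()
    hr_c = trials["hr"].to_numpy() - trials["hr"].mean()
    sv = profile.w_taste * tr_c + profile.w_health * hr_c
    drifts = profile.ddm.drift_scale * sv
    choices, rts = ddm.simulate_trials(profile.ddm, drifts, max_rt=max_rt, rng=rng)
    out = trials.copy()
    out["participant_id"] = profile.participant_id
    out["choice"] = choices
    out["rt_s"] = np.round(rts, 4)
    out["missed"] = out["choice"] == "missed"
    cols = ["participant_id", "trial_idx", "food_id", "trial_type", "tr", "hr",
            "choice", "rt_s", "missed"]
    return out[cols]


def _sam_draw(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Discretized truncated Gaussian on the 1-9 SAM scale."""
    return np.clip(np.rint(rng.normal(mean, sd, size)), 1, 9).astype(int)


def simulate_emotion_session(
    profile: ParticipantProfile,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    seed=None,
    n_per_block: int = 20,
) -> pd.DataFrame:
    """Simulate the 100-trial emotion session (5 block types x 20 trials).

    View-condition ratings are drawn around the configured condition
    means (plus a participant-level baseline shift); reappraise-condition
    ratings are shifted toward the neutral midpoint by ``delta_neg``
    (negative stimuli) or ``delta_pos`` (positive stimuli).  Every
    reappraised stimulus also receives a post-scan rating drawn from the
    unregulated view distribution.  Neutral stimuli appear only in the
    view condition.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    shift = rng.normal(0.0, config.sam_participant_sd)
    means = config.condition_means
    block_mean = {
        "negative_view": means["negative_view"] + shift,
        "neutral_view": means["neutral_view"] + shift,
        "positive_view": means["positive_view"] + shift,
        "negative_reappraise": means["negative_view"] + shift + profile.delta_neg,
        "positive_reappraise": means["positive_view"] + shift - profile.delta_pos,
    }
    rows = []
    for bt in BLOCK_TYPES:
        valence, condition = bt.rsplit("_", 1)
        inscan = _sam_draw(rng, block_mean[bt], config.sam_trial_sd, n_per_block)
        if condition == "reappraise":
            base = means[f"{valence}_view"] + shift
            postscan = _sam_draw(rng, base, config.sam_trial_sd, n_per_block).astype(float)
        else:
            postscan = np.full(n_per_block, np.nan)
        for j in range(n_per_block):
            rows.append(
                {
                    "participant_id": profile.participant_id,
                    "block_type": bt,
                    "stim_id": f"{bt}-{j:02d}",
                    "condition": condition,
                    "valence": valence,
                    "rating_inscan": int(inscan[j]),
                    "rating_postscan": postscan[j],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CohortDataset:
    """All tables of one synthetic cohort, plus the ground truth."""

    config: CohortConfig
    profiles: list[ParticipantProfile]
    ratings: pd.DataFrame
    choicesets: pd.DataFrame
    choices: pd.DataFrame
    emotion: pd.DataFrame
    ground_truth: pd.DataFrame
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "ratings": self.ratings,
            "choiceset": self.choicesets,
            "choices": self.choices,
            "emotion": self.emotion,
            "ground_truth": self.ground_truth,
            "exclusions": self.exclusions,
        }


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Generate a full cohort: profiles, ratings, tailored choice sets,
    simulated choices, and emotion sessions.

    Participants whose rating profile yields too few challenge items are
    retained in the dataset with an exclusion record (mirroring an
    insufficient-challenge exclusion), not silently dropped; they
    receive no choice set or choices.
    """
    profiles = generate_participant_profiles(config)
    ratings_l, sets_l, choices_l, emotion_l, gt_l, excl_l = [], [], [], [], [], []
    for i, prof in enumerate(profiles):
        rng = _participant_rng(config, i)
        ratings = generate_food_ratings(prof, config, rng=rng)
        ratings_l.append(ratings)
        excluded, reason = False, ""
        try:
            cs = build_choice_set(
                ratings,
                n_trials=config.n_trials,
                n_challenge_target=config.n_challenge_target,
                min_challenge=config.min_challenge,
                rng=rng,
            )
        except (InsufficientChallengeError, ValueError) as err:
            excluded, reason = True, str(err)
            cs = None
        if cs is not None:
            cst = cs.trials.copy()
            cst.insert(0, "participant_id", prof.participant_id)
            sets_l.append(cst)
            choices_l.append(simulate_food_choices(prof, cs, rng=rng))
        emotion_l.append(simulate_emotion_session(prof, config, rng=rng))
        gt_l.append(
            {
                "participant_id": prof.participant_id,
                "beta0": prof.beta0,
                "w_taste": prof.w_taste,
                "w_health": prof.w_health,
                "ddm_a": prof.ddm.a,
                "ddm_z_rel": prof.ddm.z_rel,
                "ddm_t0": prof.ddm.t0,
                "ddm_drift_scale": prof.ddm.drift_scale,
                "delta_neg": prof.delta_neg,
                "delta_pos": prof.delta_pos,
                "hunger_pct": prof.hunger_pct,
                "bmi": prof.bmi,
                "restraint": prof.restraint,
                "gender": prof.gender,
                "excluded": excluded,
                "exclusion_reason": reason,
            }
        )
        excl_l.append(
            {"participant_id": prof.participant_id, "excluded": excluded, "reason": reason}
        )
    return CohortDataset(
        config=config,
        profiles=profiles,
        ratings=pd.concat(ratings_l, ignore_index=True),
        choicesets=(
            pd.concat(sets_l, ignore_index=True) if sets_l else pd.DataFrame()
        ),
        choices=(
            pd.concat(choices_l, ignore_index=True) if choices_l else pd.DataFrame()
        ),
        emotion=pd.concat(emotion_l, ignore_index=True),
        ground_truth=pd.DataFrame(gt_l),
        exclusions=pd.DataFrame(excl_l),
    )
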