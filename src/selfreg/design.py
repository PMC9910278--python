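"""Rating classification and tailored choice-set construction.

Foods rated within the neutral zone (±5% of the 10-unit scale around
zero, i.e. |r| <= 0.5) on either attribute never enter a choice set.
The remaining items partition into four types by the signs of the taste
and health ratings; the two sign-discordant types (HTLH, LTHH) are
self-control challenges.  Each participant's 100-trial set is built to
contain ~75 challenges when their rating profile allows it; a profile
with too few challenge items cannot support the paradigm and raises
``InsufficientChallengeError`` (such participants are excluded, not
silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    CHALLENGE_TYPES,
    NEUTRAL_HALFWIDTH,
    NONCHALLENGE_TYPES,
    RATING_MAX,
    RATING_MIN,
)

__all__ = [
    "classify_rating",
    "classify_trial_type",
    "build_choice_set",
    "ChoiceSet",
    "InsufficientChallengeError",
]


class InsufficientChallengeError(ValueError):
    """Raised when a rating profile yields too few challenge items."""


@dataclass(frozen=True)
class ChoiceSet:
    """An ordered, tailored choice set for one participant."""

    trials: pd.DataFrame  # columns: food_id, trial_type, tr, hr
    n_challenge: int
    n_nonchallenge: int

    def __len__(self) -> int:
        return len(self.trials)


def classify_rating(r: float) -> str:
    """Classify a -5..+5 rating as negative / neutral / positive.

    The neutral zone is closed: |r| <= 0.5 (5% of the total 10-unit
    scale length on each side of zero).
    """
    if not (RATING_MIN <= r <= RATING_MAX):
        raise ValueError(f"rating {r} outside [{RATING_MIN}, {RATING_MAX}]")
    if abs(r) <= NEUTRAL_HALFWIDTH:
        return "neutral"
    return "positive" if r > 0 else "negative"


def classify_trial_type(tr: float, hr: float) -> str | None:
    """Map a (taste, health) rating pair to its trial type.

    Returns ``"HTLH"``, ``"LTHH"``, ``"HTHH"`` or ``"LTLH"``, or ``None``
    if either attribute falls in the neutral zone (the item is excluded
    from choice sets).
    """
    t_cls = classify_rating(tr)
    h_cls = classify_rating(hr)
    if t_cls == "neutral" or h_cls == "neutral":
        return None
    key = (t_cls == "positive", h_cls == "positive")
    return {
        (True, False): "HTLH",
        (False, True): "LTHH",
        (True, True): "HTHH",
        (False, False): "LTLH",
    }[key]


def _proportional_counts(n_total: int, available: dict[str, int]) -> dict[str, int]:
    """Split n_total across categories proportionally to availability,
    never exceeding it (largest-remainder rounding)."""
    types = [t for t, n in available.items() if n > 0]
    avail = np.array([available[t] for t in types], dtype=float)
    n_total = min(n_total, int(avail.sum()))
    quota = n_total * avail / avail.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n_total - counts.sum()
    for i in np.argsort(-remainder):
        if short == 0:
            break
        if counts[i] < available[types[i]]:
            counts[i] += 1
            short -= 1
    # availability caps may still leave a shortfall; distribute greedily
    while short > 0:
        room = [i for i in range(len(types)) if counts[i] < available[types[i]]]
        if not room:
            break
        counts[room[0]] += 1
        short -= 1
    return dict(zip(types, counts.tolist()))


def build_choice_set(
    ratings: pd.DataFrame,
    n_trials: int = 100,
    n_challenge_target: int = 75,
    min_challenge: int = 50,
    seed=None,
    rng: np.random.Generator | None = None,
) -> ChoiceSet:
    """Construct a tailored choice set from one participant's ratings.

    Parameters
    ----------
    ratings : DataFrame with columns ``food_id``, ``tr``, ``hr``.
    n_trials : set size (default 100).
    n_challenge_target : challenge trials aimed for (default 75); the
        achieved count is ``min(target, available challenge items)``.
    min_challenge : below this many available challenge items the
        participant's profile cannot support the paradigm and
        ``InsufficientChallengeError`` is raised.

    Sampling is without replacement; the challenge-type mix (HTLH vs
    LTHH) and the filler mix are proportional to availability.  Trial
    order is randomized; deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    df = ratings.copy()
    df["trial_type"] = [classify_trial_type(t, h) for t, h in zip(df["tr"], df["hr"])]
    df = df[df["trial_type"].notna()]
    if len(df) < n_trials:
        raise ValueError(
            f"only {len(df)} non-neutral items available; need {n_trials}"
        )

    by_type = {t: df[df["trial_type"] == t] for t in df["trial_type"].unique()}
    avail_ch = {t: len(by_type.get(t, ())) for t in CHALLENGE_TYPES}
    avail_nc = {t: len(by_type.get(t, ())) for t in NONCHALLENGE_TYPES}
    n_ch_avail = sum(avail_ch.values())
    if n_ch_avail < min_challenge:
        raise InsufficientChallengeError(
            f"only {n_ch_avail} challenge items available (< {min_challenge})"
        )

    n_challenge = min(n_challenge_target, n_ch_avail, n_trials)
    n_fill = n_trials - n_challenge
    if n_fill > sum(avail_nc.values()):
        # too few aligned items: top the set up with extra challenges
        extra = n_fill - sum(avail_nc.values())
        n_fill = sum(avail_nc.values())
        n_challenge = min(n_challenge + extra, n_ch_avail)
    if n_challenge + n_fill < n_trials:
        raise ValueError("non-neutral items cannot fill the requested set size")

    counts = _proportional_counts(n_challenge, avail_ch)
    counts.update(_proportional_counts(n_fill, avail_nc))

    parts = []
    for t, n in counts.items():
        if n > 0:
            pick = rng.choice(len(by_type[t]), size=n, replace=False)
            parts.append(by_type[t].iloc[np.sort(pick)])
    sel = pd.concat(parts, ignore_index=True)
    order = rng.permutation(len(sel))
    sel = sel.iloc[order].reset_index(drop=True)
    sel.index.name = "trial_idx"
    n_ch = int(sel["trial_type"].isin(CHALLENGE_TYPES).sum())
    return ChoiceSet(
        trials=sel[["food_id", "trial_type", "tr", "hr"]].reset_index(),
        n_challenge=n_ch,
        n_nonchallenge=len(sel) - n_ch,
    )
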