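"""Reappraisal-task scoring on the 9-point SAM valence scale.

The session has five block types: view and reappraise for negative and
positive pictures, plus neutral view.  Reappraisal success for one
stimulus is the difference between the in-scan rating given while
reappraising it and the post-scan rating given while viewing the same
picture unregulated, signed so that larger = more successful:
``reappraise - view`` for negative stimuli (successful reappraisal
pushes the rating up toward neutral), ``view - reappraise`` for
positive stimuli.  The overall score is the mean of the two valence
scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import BLOCK_TYPES, ReappraisalScores

__all__ = [
    "condition_means",
    "classify_reappraisal_trial",
    "reappraisal_success_scores",
]


def condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the in-scan rating per block type.

    Returns one row per block type; block types absent from the data are
    flagged with ``present=False`` and NaN statistics.
    """
    rows = []
    for bt in BLOCK_TYPES:
        sub = trials[trials["block_type"] == bt]["rating_inscan"]
        rows.append(
            {
                "block_type": bt,
                "mean": float(sub.mean()) if len(sub) else np.nan,
                "sd": float(sub.std(ddof=1)) if len(sub) > 1 else (0.0 if len(sub) == 1 else np.nan),
                "n": int(len(sub)),
                "present": bool(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def classify_reappraisal_trial(valence: str, rating_inscan: float,
                               rating_postscan: float) -> str:
    """Label one reappraised stimulus as success or failure.

    A negative stimulus counts as a success iff the regulated in-scan
    rating is strictly above the unregulated post-scan rating; a
    positive stimulus iff strictly below.  Ties are failures (success
    requires an actual rating change).
    """
    if valence == "neutral":
        raise ValueError("neutral stimuli are never reappraised")
    if rating_postscan is None or (isinstance(rating_postscan, float) and np.isnan(rating_postscan)):
        raise ValueError("post-scan rating required to classify a reappraisal trial")
    if valence == "negative":
        return "success" if rating_inscan > rating_postscan else "failure"
    if valence == "positive":
        return "success" if rating_inscan < rating_postscan else "failure"
    raise ValueError(f"unknown valence {valence!r}")


def reappraisal_success_scores(trials: pd.DataFrame) -> ReappraisalScores:
    """Valence-wise and overall reappraisal success scores.

    Differences are taken per stimulus (regulated in-scan rating vs the
    post-scan unregulated view rating of the same picture), averaged
    within valence, then averaged across the two valences.  Stimuli
    missing a post-scan rating are skipped with a warning; a valence
    with no usable stimuli leaves that score (and the overall score)
    undefined.
    """
    reapp = trials[trials["condition"] == "reappraise"].copy()
    missing = reapp["rating_postscan"].isna()
    if missing.any():
        warnings.warn(
            f"skipping {int(missing.sum())} reappraised stimuli without post-scan ratings",
            RuntimeWarning,
            stacklevel=2,
        )
        reapp = reapp[~missing]

    def _valence_score(valence: str, sign: float):
        sub = reapp[reapp["valence"] == valence]
        if len(sub) == 0:
            return None, 0
        diffs = sign * (sub["rating_inscan"] - sub["rating_postscan"])
        return float(diffs.mean()), int(len(sub))

    success_neg, n_neg = _valence_score("negative", +1.0)
    success_pos, n_pos = _valence_score("positive", -1.0)
    overall = (
        (success_neg + success_pos) / 2.0
        if success_neg is not None and success_pos is not None
        else None
    )
    return ReappraisalScores(success_neg, success_pos, overall, n_neg, n_pos)
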