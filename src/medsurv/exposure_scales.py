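"""Questionnaire scoring and exposure construction.

Implements the demand-control (job strain) and effort-reward imbalance
scales and the principal-component combination of the three socioeconomic
indicators (education, income, occupation) into tertiles.

Scale conventions
-----------------
* Psychological demands: 9 four-point Likert items, summed (range 9-36).
* Job control (decision latitude): 9 items split into 6 skill-discretion
  and 3 decision-authority items, weighted 2 and 4 respectively so the
  score spans 24-96 (the standard Job Content Questionnaire arrangement).
* Job strain: demands >= 24 (population-median cut) AND control <= 72.
* Reward: 9 items, summed (range 9-36), with an orientation map for
  reverse-coded items; effort is proxied by the demands score, and
  imbalance is effort/reward strictly greater than 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

JOBSTRAIN_DEMANDS_THRESHOLD = 24
JOBSTRAIN_CONTROL_THRESHOLD = 72
CONTROL_WEIGHTS = (2, 4)  # (skill discretion, decision authority)

SES_TERTILE_LABELS = ("low", "medium", "high")


def _check_items(items, n_items=9):
    arr = np.asarray(items)
    if arr.ndim != 1 or arr.shape[0] != n_items:
        raise ValueError(f"expected {n_items} items, got shape {arr.shape}")
    if not np.all(np.isin(arr, [1, 2, 3, 4])):
        raise ValueError("Likert items must take values in {1, 2, 3, 4}")
    return arr.astype(int)


def score_demands(items) -> int:
    """Sum of the 9 psychological-demands items (range 9-36)."""
    return int(_check_items(items).sum())


def score_control(items, n_skill=6, weights=CONTROL_WEIGHTS) -> int:
    """Decision-latitude score mapping 9 items onto the 24-96 range.

    The first ``n_skill`` items are skill discretion (weight 2) and the
    remainder decision authority (weight 4); the weight vector is
    configurable for alternative scorings.
    """
    arr = _check_items(items)
    ws, wa = weights
    return int(ws * arr[:n_skill].sum() + wa * arr[n_skill:].sum())


def score_reward(items, reverse_items=()) -> int:
    """Sum of the 9 reward items; ``reverse_items`` are indices coded 5 - x."""
    arr = _check_items(items)
    arr = arr.copy()
    for i in reverse_items:
        arr[i] = 5 - arr[i]
    return int(arr.sum())


def classify_job_strain(demands: int, control: int) -> bool:
    """Job strain: demands >= 24 and control <= 72 (both inclusive)."""
    if not (9 <= demands <= 36):
        raise ValueError(f"demands score {demands} outside [9, 36]")
    if not (24 <= control <= 96):
        raise ValueError(f"control score {control} outside [24, 96]")
    return demands >= JOBSTRAIN_DEMANDS_THRESHOLD and control <= JOBSTRAIN_CONTROL_THRESHOLD


def classify_eri(demands_sum: int, reward_sum: int):
    """Effort-reward imbalance: ratio of demands (effort proxy) to reward > 1.

    Returns ``(ratio, imbalance)`` with a strict comparison at 1.0.
    """
    if not (9 <= demands_sum <= 36):
        raise ValueError(f"demands score {demands_sum} outside [9, 36]")
    if not (9 <= reward_sum <= 36):
        raise ValueError(f"reward score {reward_sum} outside [9, 36]")
    ratio = demands_sum / reward_sum
    return ratio, ratio > 1.0


@dataclass
class CombinedSES:
    component_loadings: np.ndarray  # education, income, occupation
    scores: np.ndarray
    tertile: np.ndarray  # "low" / "medium" / "high"
    variance_explained: float


def combined_ses(education, income, occupation) -> CombinedSES:
    """First principal component of the three standardized SES indicators.

    PCA is taken on the Pearson correlation matrix of the ordinal codes
    treated as numeric; the component is sign-normalized so that a higher
    score means higher SES (positive correlation with education).  Scores
    are split into tertiles by rank, ties broken by stable subject order.
    """
    cols = {"education": education, "income": income, "occupation": occupation}
    mats = []
    for name, col in cols.items():
        x = np.asarray(col, dtype=float)
        if x.ndim != 1:
            raise ValueError(f"{name} must be one-dimensional")
        if np.unique(x).size < 2:
            raise ValueError(f"indicator {name!r} is constant; PCA is degenerate")
        mats.append(x)
    X = np.column_stack(mats)
    n = X.shape[0]
    if n < 3:
        raise ValueError("combined SES needs at least 3 subjects")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(n_components=3)
    pca.fit(Z)
    loadings = pca.components_[0]
    # sign convention: higher score = higher SES
    sign = np.sign(loadings[0]) or np.sign(loadings.sum()) or 1.0
    loadings = loadings * sign
    scores = Z @ loadings
    order = np.argsort(scores, kind="stable")
    tertile = np.empty(n, dtype=object)
    for label, part in zip(SES_TERTILE_LABELS, np.array_split(order, 3)):
        tertile[part] = label
    return CombinedSES(loadings, scores, tertile, float(pca.explained_variance_ratio_[0]))


def score_cohort(df: pd.DataFrame, items_config: dict) -> pd.DataFrame:
    """Append scored exposure columns to a table of raw questionnaire items.

    ``items_config`` lists the item columns per scale::

        demands_items: [...9 columns...]
        control_skill_items: [...6 columns...]
        control_authority_items: [...3 columns...]
        reward_items: [...9 columns...]
        reward_reverse_items: [optional subset of reward_items]

    Adds ``demands``, ``control``, ``reward``, ``jobstrain`` (0/1),
    ``eri_ratio`` and ``eri`` (0/1).
    """
    out = df.copy()
    dem = df[list(items_config["demands_items"])].to_numpy()
    skill = df[list(items_config["control_skill_items"])].to_numpy()
    auth = df[list(items_config["control_authority_items"])].to_numpy()
    rew = df[list(items_config["reward_items"])].to_numpy(dtype=float)
    for name, arr, k in (
        ("demands", dem, 9), ("control skill", skill, 6),
        ("control authority", auth, 3), ("reward", rew, 9),
    ):
        if arr.shape[1] != k:
            raise ValueError(f"{name} items: expected {k} columns, got {arr.shape[1]}")
        if not np.all(np.isin(arr, [1, 2, 3, 4])):
            raise ValueError(f"{name} items must take values in {{1, 2, 3, 4}}")
    for col in items_config.get("reward_reverse_items", []):
        j = list(items_config["reward_items"]).index(col)
        rew[:, j] = 5 - rew[:, j]
    ws, wa = CONTROL_WEIGHTS
    out["demands"] = dem.sum(axis=1).astype(int)
    out["control"] = (ws * skill.sum(axis=1) + wa * auth.sum(axis=1)).astype(int)
    out["reward"] = rew.sum(axis=1).astype(int)
    out["jobstrain"] = (
        (out["demands"] >= JOBSTRAIN_DEMANDS_THRESHOLD)
        & (out["control"] <= JOBSTRAIN_CONTROL_THRESHOLD)
    ).astype(int)
    out["eri_ratio"] = out["demands"] / out["reward"]
    out["eri"] = (out["eri_ratio"] > 1.0).astype(int)
    return out
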