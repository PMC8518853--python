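"""Diet composition, richness and trophic niche breadth.

The central diet descriptor is the weighted percent of occurrence (wPOO):
each faecal sample contributes equally, its unit weight split evenly across
the prey detected in it, so

    p_i = (1/S) * sum_k  I_ik / n_k

over the S samples of a group with at least one detection, where n_k is the
number of prey detected in sample k.  The resulting utilization distribution
p feeds Levins' niche breadth B = 1 / sum(p_i^2) and the overlap and
ordination stages.

Richness of a group's prey spectrum is summarized by incidence counts
(uniques Q1, duplicates Q2 across samples) and extrapolated with the Chao2
minimum estimator of asymptotic richness; ``samples_needed`` inverts the
sample-based extrapolation curve to the number of samples required to reach
a target fraction of that asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import DetectionTable, MotuAssignment

__all__ = [
    "IncidenceSummary",
    "wpoo",
    "incidence_summary",
    "chao2",
    "samples_needed",
    "levins",
    "family_rollup",
    "sharing_summary",
]


@dataclass(frozen=True)
class IncidenceSummary:
    """Incidence frequency counts for a set of samples.

    m: number of samples; S_obs: observed prey richness; Q1: prey seen in
    exactly one sample (uniques); Q2: prey seen in exactly two (duplicates).
    """

    m: int
    S_obs: int
    Q1: int
    Q2: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("need at least one sample")
        if self.Q1 + self.Q2 > self.S_obs:
            raise ValueError("Q1 + Q2 exceeds observed richness")
        if min(self.S_obs, self.Q1, self.Q2) < 0:
            raise ValueError("negative incidence counts")


def wpoo(
    occ: DetectionTable | pd.DataFrame,
    group: Sequence[str] | None = None,
) -> pd.Series:
    """Weighted percent-of-occurrence utilization distribution.

    Each sample with at least one detection carries weight 1/S, split evenly
    over the prey it contains; samples without detections are excluded from
    S.  Returns a prey-indexed Series summing to 1, restricted to prey with
    positive weight.
    """
    frame = occ.counts if isinstance(occ, DetectionTable) else occ
    if group is not None:
        missing = pd.Index(group).difference(frame.index)
        if len(missing):
            raise KeyError(f"unknown sample(s): {sorted(missing)}")
        frame = frame.loc[list(group)]
    if frame.shape[0] == 0:
        raise ValueError("empty sample group")
    binary = (frame > 0).astype(float)
    n_k = binary.sum(axis=1)
    binary = binary.loc[n_k > 0]
    if binary.shape[0] == 0:
        raise ValueError("group contains no detections")
    weights = binary.div(binary.sum(axis=1), axis=0)
    p = weights.sum(axis=0) / binary.shape[0]
    p = p[p > 0]
    return p


def incidence_summary(
    occ: DetectionTable | pd.DataFrame,
    group: Sequence[str] | None = None,
) -> IncidenceSummary:
    """Tally m, S_obs, Q1 and Q2 from a binary detection table."""
    frame = occ.counts if isinstance(occ, DetectionTable) else occ
    if group is not None:
        frame = frame.loc[list(group)]
    binary = (frame > 0).astype(int)
    freq = binary.sum(axis=0)
    freq = freq[freq > 0]
    return IncidenceSummary(
        m=int(binary.shape[0]),
        S_obs=int((freq > 0).sum()),
        Q1=int((freq == 1).sum()),
        Q2=int((freq == 2).sum()),
    )


def chao2(inc: IncidenceSummary, bias_corrected: bool = False) -> float:
    """Chao2 minimum estimator of asymptotic species richness.

    Classic form S_obs + ((m-1)/m) * Q1^2 / (2 Q2) when Q2 > 0; the
    bias-corrected form S_obs + ((m-1)/m) * Q1 (Q1-1) / (2 (Q2+1)) is used
    when Q2 = 0, or always when ``bias_corrected`` is set.  Never below
    S_obs.
    """
    if inc.m < 2:
        raise ValueError("Chao2 needs at least two samples")
    k = (inc.m - 1) / inc.m
    if bias_corrected or inc.Q2 == 0:
        extra = k * inc.Q1 * (inc.Q1 - 1) / (2.0 * (inc.Q2 + 1))
    else:
        extra = k * inc.Q1**2 / (2.0 * inc.Q2)
    return float(inc.S_obs + extra)


def expected_richness(inc: IncidenceSummary, m_star: int,
                      bias_corrected: bool = False) -> float:
    """Expected richness after ``m_star`` additional samples.

    Sample-based extrapolation: S_obs + Q0_hat * [1 - (1 - Q1/(m*Q0_hat +
    Q1))^m*] with Q0_hat = S_est - S_obs the estimated number of undetected
    species.
    """
    if m_star < 0:
        raise ValueError("m_star must be non-negative")
    s_est = chao2(inc, bias_corrected=bias_corrected)
    q0 = s_est - inc.S_obs
    if m_star == 0 or q0 == 0 or inc.Q1 == 0:
        return float(inc.S_obs)
    rate = inc.Q1 / (inc.m * q0 + inc.Q1)
    return float(inc.S_obs + q0 * (1.0 - (1.0 - rate) ** m_star))


def samples_needed(
    inc: IncidenceSummary,
    g: float,
    bias_corrected: bool = False,
    max_samples: int = 10**6,
) -> int:
    """Smallest total number of samples reaching a fraction g of Chao2.

    Returns ``inc.m`` when the target g * S_est is already observed;
    otherwise iterates the extrapolation curve over additional samples m*
    and returns m + m*.  Raises if the target exceeds the estimated
    asymptote (unreachable).
    """
    if not 0.0 < g < 1.0:
        raise ValueError("g must lie in (0, 1)")
    s_est = chao2(inc, bias_corrected=bias_corrected)
    target = g * s_est
    if target <= inc.S_obs:
        return inc.m
    if inc.Q1 == 0:
        raise ValueError("no uniques: extrapolation curve is flat")
    q0 = s_est - inc.S_obs
    if target > inc.S_obs + q0:
        raise ValueError("target exceeds the estimated asymptote")
    # closed-form solve of the extrapolation, then integer rounding up
    rate = inc.Q1 / (inc.m * q0 + inc.Q1)
    need = (target - inc.S_obs) / q0
    if need >= 1.0:
        raise ValueError("target exceeds the estimated asymptote")
    m_star = int(np.ceil(np.log(1.0 - need) / np.log(1.0 - rate)))
    m_star = max(m_star, 1)
    # guard against floating-point edge: verify, stepping at most a few
    while (
        expected_richness(inc, m_star, bias_corrected) < target
        and m_star < max_samples
    ):
        m_star += 1
    return inc.m + m_star


def levins(profile: pd.Series | Mapping[str, float] | np.ndarray) -> float:
    """Levins' niche breadth B = 1 / sum(p_i^2).

    Accepts unnormalized weights (renormalized internally), so the measure
    is scale-free.  B ranges from 1 (single resource) to the number of
    resources used (uniform profile).
    """
    p = np.asarray(pd.Series(profile), dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("empty niche profile")
    p = p / p.sum()
    return float(1.0 / np.sum(p**2))


def family_rollup(
    profile: pd.Series,
    assignments: Mapping[str, MotuAssignment],
) -> pd.Series:
    """Aggregate a prey-level utilization profile to family level.

    Prey lacking a family are bucketed under their order (prefixed
    ``order:``), or ``unplaced`` when neither is known.  Weights are summed,
    so the rollup preserves the total of 1.
    """
    buckets: dict[str, float] = {}
    for prey, weight in profile.items():
        rec = assignments.get(prey)
        if rec is not None and rec.family:
            key = rec.family
        elif rec is not None and rec.order:
            key = f"order:{rec.order}"
        else:
            key = "unplaced"
        buckets[key] = buckets.get(key, 0.0) + float(weight)
    return pd.Series(buckets).sort_values(ascending=False)


def order_rollup(
    profile: pd.Series,
    assignments: Mapping[str, MotuAssignment],
) -> pd.Series:
    """Aggregate a prey-level utilization profile to order level."""
    buckets: dict[str, float] = {}
    for prey, weight in profile.items():
        rec = assignments.get(prey)
        key = rec.order if rec is not None and rec.order else "unplaced"
        buckets[key] = buckets.get(key, 0.0) + float(weight)
    return pd.Series(buckets).sort_values(ascending=False)


def sharing_summary(prey_sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Counts of every intersection region among predator prey sets.

    Returns a mapping from a region label (``+``-joined sorted member
    names) to the number of prey exclusive to exactly that combination of
    predators; region counts partition the union.
    """
    sets = {k: set(v) for k, v in prey_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two prey sets")
    names = sorted(sets)
    union = set().union(*sets.values())
    regions: dict[str, int] = {}
    for prey in union:
        members = tuple(n for n in names if prey in sets[n])
        label = "+".join(members)
        regions[label] = regions.get(label, 0) + 1
    return regions
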