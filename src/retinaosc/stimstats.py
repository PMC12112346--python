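"""Stimulation efficiency and its condition comparisons.

Stimulation efficiency is the spike-rate ratio: the post-stimulus action
potential rate (0.4 s after the pulse) divided by the pre-stimulus rate
(8 s before the pulse).  Efficiency distributions across the pharmacology
phases (control / GABA / washout) are compared with the two-sided
Mann–Whitney rank test; significance is flagged with the asterisk ladder
**** (p <= 1e-4), *** (p <= 1e-3), * (p <= 0.05), else ns — the ladder has
no ** rung.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import Condition
from .spikes import RateEstimate, SpikeTrain, spike_rate

__all__ = [
    "MWUMode",
    "EfficiencyResult",
    "ComparisonResult",
    "stimulation_efficiency",
    "mann_whitney_u",
    "stars",
    "compare_phases",
]

logger = logging.getLogger(__name__)

DEFAULT_POST_S = 0.4
DEFAULT_PRE_S = 8.0

#: significance ladder; deliberately has no ** rung
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (0.05, "*"))


class MWUMode(enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "asymptotic"


@dataclass
class EfficiencyResult:
    """Per-stimulus spike-rate ratios pooled into mean ± SEM."""

    per_stimulus_ratio: List[float]
    mean: float
    sem: float
    n: int
    condition: Condition = Condition.NONE
    group_label: str = ""
    n_excluded: int = 0

    @classmethod
    def from_ratios(
        cls,
        ratios: Sequence[float],
        condition: Condition = Condition.NONE,
        group_label: str = "",
        n_excluded: int = 0,
    ) -> "EfficiencyResult":
        r = np.asarray(ratios, dtype=float)
        n = int(r.size)
        mean = float(r.mean()) if n else float("nan")
        sem = float(r.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return cls(list(map(float, r)), mean, sem, n, condition, group_label, n_excluded)


@dataclass(frozen=True)
class ComparisonResult:
    u_statistic: float
    p_value: float
    stars: str
    groups: Tuple[str, str]


def stimulation_efficiency(
    train: SpikeTrain,
    stim_times: Sequence[float],
    post_s: float = DEFAULT_POST_S,
    pre_s: float = DEFAULT_PRE_S,
    condition: Condition = Condition.NONE,
    group_label: str = "",
) -> EfficiencyResult:
    """Spike-rate ratio per stimulus, pooled as mean ± SEM.

    For stimulus at ``t``: ``ratio = rate([t, t+post_s)) / rate([t-pre_s, t))``.
    Stimuli with a zero pre-window rate are excluded (logged count).
    """
    if post_s <= 0 or pre_s <= 0:
        raise ValueError("window lengths must be positive")
    ratios: List[float] = []
    excluded = 0
    for t in stim_times:
        pre = spike_rate(train, (t - pre_s, t))
        post = spike_rate(train, (t, t + post_s))
        if pre.rate_hz == 0.0:
            excluded += 1
            continue
        ratios.append(post.rate_hz / pre.rate_hz)
    if excluded:
        logger.info(
            "stimulation_efficiency: excluded %d/%d stimuli with zero pre-window rate",
            excluded,
            len(stim_times),
        )
    return EfficiencyResult.from_ratios(
        ratios, condition=condition, group_label=group_label, n_excluded=excluded
    )


def stars(p: float) -> str:
    """Map a p-value to the asterisk ladder (no ** rung)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for thr, label in STAR_THRESHOLDS:
        if p <= thr:
            return label
    return "ns"


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    mode: Optional[MWUMode] = None,
    groups: Tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Mann–Whitney U test.

    ``EXACT`` enumerates the null distribution (required when both groups
    have at most 8 observations and there are no ties); ``NORMAL_APPROX``
    uses the tie-corrected normal approximation with continuity correction.
    When ``mode`` is omitted, EXACT is chosen for small tie-free samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if mode is None:
        mode = (
            MWUMode.EXACT
            if (a.size <= 8 and b.size <= 8 and not has_ties)
            else MWUMode.NORMAL_APPROX
        )
    if mode is MWUMode.EXACT and has_ties:
        mode = MWUMode.NORMAL_APPROX  # exact null invalid under ties; midranks used
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mode.value)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        u_statistic=float(res.statistic), p_value=p, stars=stars(p), groups=groups
    )


#: phase pairs compared, in reporting order
PHASE_PAIRS = (
    (Condition.PRE_GABA, Condition.GABA),
    (Condition.GABA, Condition.WASHOUT),
    (Condition.PRE_GABA, Condition.WASHOUT),
)


def compare_phases(
    results: Dict[Condition, EfficiencyResult]
) -> List[ComparisonResult]:
    """Pairwise efficiency comparisons across pharmacology phases.

    Compares PRE vs GABA, GABA vs WASHOUT and PRE vs WASHOUT where both
    phases are present; no multiple-comparison correction is applied.
    """
    if len(results) < 2:
        logger.info("compare_phases: fewer than two conditions, nothing to compare")
        return []
    out: List[ComparisonResult] = []
    for c1, c2 in PHASE_PAIRS:
        if c1 not in results or c2 not in results:
            logger.info("compare_phases: skipping %s vs %s (missing phase)", c1, c2)
            continue
        r1, r2 = results[c1], results[c2]
        if r1.n == 0 or r2.n == 0:
            logger.info("compare_phases: skipping %s vs %s (empty group)", c1, c2)
            continue
        out.append(
            mann_whitney_u(
                r1.per_stimulus_ratio,
                r2.per_stimulus_ratio,
                groups=(c1.value, c2.value),
            )
        )
    return out
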