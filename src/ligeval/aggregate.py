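"""Group-level aggregation: skip-penalized means, success rates, rankings,
target difficulty, and reliability-score (LScore) evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UndefinedScoreError
from .pose import PoseScore

RANKING_KEYS = (
    "skip_penalized_mean_lddt_pli",
    "skip_penalized_success_rate",
    "best_model_mean_lddt_pli",
)

DEFAULT_SUCCESS_CUTOFF = 2.5


@dataclass
class GroupSummary:
    group_id: int
    n_submitted: int
    skip_penalized_mean_lddt_pli: float
    skip_penalized_success_rate: float
    best_model_mean_lddt_pli: float
    per_supertarget_means: dict[str, float] = field(default_factory=dict)
    lscore_tau: float | None = None


@dataclass
class TargetDifficulty:
    target_id: str
    mean_best_lddt_pli: float
    max_model1_lddt_pli: float
    max_any_model_lddt_pli: float


def skip_penalized_mean(
    scores: dict[str, float | None], targets: list[str]
) -> float:
    """Mean over *all* targets, with missing/skipped entries counted as zero."""
    if not targets:
        raise ValueError("empty target list")
    unknown = set(scores) - set(targets)
    if unknown:
        raise ValueError(f"scores for targets not in list: {sorted(unknown)}")
    total = sum(scores.get(t) or 0.0 for t in targets)
    return total / len(targets)


def success_rate(
    rmsds: dict[str, float | None],
    targets: list[str],
    cutoff: float = DEFAULT_SUCCESS_CUTOFF,
) -> float:
    """Fraction of targets with RMSD <= cutoff; skips count as failures."""
    if not targets:
        raise ValueError("empty target list")
    unknown = set(rmsds) - set(targets)
    if unknown:
        raise ValueError(f"RMSDs for targets not in list: {sorted(unknown)}")
    hits = sum(
        1 for t in targets if rmsds.get(t) is not None and rmsds[t] <= cutoff
    )
    return hits / len(targets)


def best_of_models(scores: list[PoseScore]) -> PoseScore | None:
    """The model with the highest LDDT-PLI; ties go to the lowest model number.

    A group's sole Model 1 is trivially its own best. Returns None when the
    list is empty (all models skipped)."""
    if not scores:
        return None
    return max(scores, key=lambda s: (s.lddt_pli, -(s.model_num or 0)))


def rank_groups(summaries: list[GroupSummary], key: str) -> list[GroupSummary]:
    """Descending by the chosen statistic; ties broken by ascending group id."""
    if key not in RANKING_KEYS:
        raise KeyError(f"unknown ranking key {key!r}; choose from {RANKING_KEYS}")
    return sorted(summaries, key=lambda s: (-getattr(s, key), s.group_id))


def target_difficulty(
    best_scores: dict[tuple[int, str], PoseScore],
    model1_scores: dict[tuple[int, str], PoseScore] | None = None,
    all_scores: list[PoseScore] | None = None,
) -> list[TargetDifficulty]:
    """Per-target difficulty from each group's best-of-models LDDT-PLI.

    The mean is over groups that scored the target (no skip penalty); skipped
    groups are simply absent from *best_scores*.
    """
    targets: dict[str, list[float]] = {}
    for (_group, target), score in best_scores.items():
        targets.setdefault(target, []).append(score.lddt_pli)
    model1_max: dict[str, float] = {}
    if model1_scores:
        for (_group, target), score in model1_scores.items():
            model1_max[target] = max(model1_max.get(target, 0.0), score.lddt_pli)
    any_max: dict[str, float] = {}
    for score in all_scores or []:
        if score.target_id is not None:
            any_max[score.target_id] = max(any_max.get(score.target_id, 0.0), score.lddt_pli)
    out = []
    for target, vals in sorted(targets.items()):
        max_any = any_max.get(target, max(vals))
        out.append(
            TargetDifficulty(
                target_id=target,
                mean_best_lddt_pli=float(np.mean(vals)),
                max_model1_lddt_pli=model1_max.get(target, 0.0),
                max_any_model_lddt_pli=max_any,
            )
        )
    return out


def lscore_reliability(
    lscores: list[float], lddt_plis: list[float]
) -> float:
    """Tie-corrected Kendall tau between self-reported reliability and accuracy.

    Computed over all scored models of one group, with no penalty for skips.
    Constant reliability vectors (e.g. all 1.0) leave tau undefined.
    """
    if len(lscores) != len(lddt_plis):
        raise ValueError("lscores and accuracies must be paired")
    if len(lscores) < 2:
        raise UndefinedScoreError("need >=2 scored entries with reliability values")
    if len(set(lscores)) == 1:
        raise UndefinedScoreError("constant reliability vector: tau undefined")
    tau = stats.kendalltau(lscores, lddt_plis).statistic
    if np.isnan(tau):
        raise UndefinedScoreError("tau undefined (constant accuracy vector)")
    return float(tau)


def cross_supertarget_consistency(
    per_group_means_a: dict[int, float], per_group_means_b: dict[int, float]
) -> float:
    """Squared Pearson correlation of per-group (non-penalized) means between
    two supertargets, over groups present in both."""
    common = sorted(set(per_group_means_a) & set(per_group_means_b))
    if len(common) < 3:
        raise UndefinedScoreError("need >=3 groups present in both supertargets")
    a = [per_group_means_a[g] for g in common]
    b = [per_group_means_b[g] for g in common]
    r = stats.pearsonr(a, b).statistic
    return float(r**2)


def summarize_group(
    group_id: int,
    model1_scores: dict[str, PoseScore],
    best_scores: dict[str, PoseScore],
    targets: list[str],
    supertarget_of: dict[str, str] | None = None,
    success_cutoff: float = DEFAULT_SUCCESS_CUTOFF,
    lscore_tau: float | None = None,
) -> GroupSummary:
    """Assemble a GroupSummary from per-target Model-1 and best-of-models scores."""
    pli = {t: s.lddt_pli for t, s in model1_scores.items()}
    rmsd = {t: s.rmsd for t, s in model1_scores.items()}
    best_pli = {t: s.lddt_pli for t, s in best_scores.items()}
    per_super: dict[str, float] = {}
    if supertarget_of:
        groups: dict[str, list[float]] = {}
        for t in targets:
            st = supertarget_of.get(t)
            if st is not None and t in pli:
                groups.setdefault(st, []).append(pli[t])
        per_super = {st: float(np.mean(v)) for st, v in groups.items()}
    return GroupSummary(
        group_id=group_id,
        n_submitted=len(model1_scores),
        skip_penalized_mean_lddt_pli=skip_penalized_mean(pli, targets),
        skip_penalized_success_rate=success_rate(rmsd, targets, success_cutoff),
        best_model_mean_lddt_pli=skip_penalized_mean(best_pli, targets),
        per_supertarget_means=per_super,
        lscore_tau=lscore_tau,
    )
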