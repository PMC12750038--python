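"""Affinity-ranking assessment.

Predictions arrive as absolute dissociation constants, relative affinities or
plain rankings; everything is reduced to a ranking and compared against the
experimental IC50-derived ranking by tie-corrected Kendall tau. A
resampling-based "ceiling" estimates the best tau a perfect predictor could
achieve given Gaussian experimental noise on the free-energy scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UndefinedScoreError

#: RT in kcal/mol chosen so that RT * ln(3) = 0.66 kcal/mol at room temperature.
DEFAULT_RT = 0.6

#: Resampling noise levels (kcal/mol): ~3x and ~30x uncertainty in IC50.
DEFAULT_SIGMAS = (0.66, 2.0)


@dataclass
class AffinityDataset:
    supertarget: str
    measurements: dict[str, float]  # target_id -> IC50 (nM)
    stage: int = 1

    def __post_init__(self) -> None:
        if len(self.measurements) < 2:
            raise ValueError("affinity dataset needs >=2 measurements")
        if any(v <= 0 for v in self.measurements.values()):
            raise ValueError("IC50 values must be positive")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")

    def dg(self, rt: float = DEFAULT_RT) -> dict[str, float]:
        return {t: ic50_to_dg(v, rt) for t, v in self.measurements.items()}

    def without(self, blacklist: set[str] | list[str]) -> "AffinityDataset":
        keep = {t: v for t, v in self.measurements.items() if t not in set(blacklist)}
        return AffinityDataset(self.supertarget, keep, self.stage)


@dataclass
class AffinityPrediction:
    group_id: int
    supertarget: str
    kind: str  # absolute_kd | relative | rank
    values: dict[str, float]
    reference_target: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("absolute_kd", "relative", "rank"):
            raise ValueError(f"unknown prediction kind {self.kind!r}")
        if self.kind == "rank" and any(v <= 0 for v in self.values.values()):
            raise ValueError("ranks must be positive")
        if self.kind == "relative":
            if self.reference_target is None or self.reference_target not in self.values:
                raise ValueError("relative predictions need an in-set reference target")
            if any(v <= 0 for v in self.values.values()):
                raise ValueError("relative affinity ratios must be positive")


@dataclass
class CeilingEstimate:
    mean_tau: float
    sd_tau: float
    sigma: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_resamples < 1 or self.sigma < 0 or self.sd_tau < 0:
            raise ValueError("invalid ceiling estimate fields")


def ic50_to_dg(ic50: float, rt: float = DEFAULT_RT) -> float:
    """Binding free energy estimate RT * ln(IC50), IC50 in its native unit."""
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return rt * math.log(ic50)


def normalize_to_ranking(pred: AffinityPrediction) -> dict[str, float]:
    """Reduce any prediction kind to ranks with 1 = strongest binder.

    Absolute/relative dissociation constants rank ascending (small Kd binds
    tightest); rank submissions pass through. Ties receive average ranks.
    """
    targets = sorted(pred.values)
    if pred.kind == "rank":
        raw = np.array([pred.values[t] for t in targets], dtype=float)
    elif pred.kind == "absolute_kd":
        raw = np.array([pred.values[t] for t in targets], dtype=float)
    else:  # relative: ratio to reference has the same ordering as absolute Kd
        ref = pred.values[pred.reference_target]
        raw = np.array([pred.values[t] / ref for t in targets], dtype=float)
    ranks = stats.rankdata(raw)  # average ranks for ties
    return dict(zip(targets, ranks))


def kendall_tau(x: list[float] | np.ndarray, y: list[float] | np.ndarray) -> float:
    """Tie-corrected Kendall tau-b. Raises when either vector is all-tied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of >=2 values")
    tau = stats.kendalltau(x, y).statistic
    if np.isnan(tau):
        raise UndefinedScoreError("tau undefined: a vector is constant")
    return float(tau)


def tau_vs_experiment(
    pred: AffinityPrediction, dataset: AffinityDataset, rt: float = DEFAULT_RT
) -> tuple[float, int]:
    """(tau, n) for one group's prediction against the experimental ranking.

    Computed over the intersection of targets present in both; a perfect
    prediction yields tau = +1.
    """
    ranks = normalize_to_ranking(pred)
    common = sorted(set(ranks) & set(dataset.measurements))
    if len(common) < 2:
        raise UndefinedScoreError("fewer than 2 targets shared with experiment")
    # experimental: tightest binder (lowest IC50) gets rank 1, so tau with
    # predicted ranks is +1 for a perfect prediction
    exp = [dataset.measurements[t] for t in common]
    prd = [ranks[t] for t in common]
    return kendall_tau(prd, exp), len(common)


def n_weighted_tau(components: list[tuple[float, int]]) -> float:
    """Submission-count-weighted combination: sum(n_i tau_i) / sum(n_i)."""
    if not components:
        raise ValueError("no components to combine")
    if any(n < 1 for _tau, n in components):
        raise ValueError("component sizes must be >= 1")
    num = sum(tau * n for tau, n in components)
    den = sum(n for _tau, n in components)
    return num / den


def ceiling_tau(
    dg: list[float] | np.ndarray,
    sigma: float,
    n_resamples: int = 1000,
    seed: int = 0,
) -> CeilingEstimate:
    """Expected best achievable tau given Gaussian experimental noise.

    Each replicate adds i.i.d. N(0, sigma^2) to the free energies and is
    ranked against the unperturbed values; mean/SD of tau over replicates are
    returned. Deterministic given *seed* (replicate i uses substream i).
    """
    dg = np.asarray(dg, dtype=float)
    if dg.size < 3:
        raise ValueError("need >=3 free-energy values")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    taus = np.empty(n_resamples)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(n_resamples)
    for i in range(n_resamples):
        rng = np.random.default_rng(streams[i])
        noisy = dg + rng.normal(0.0, sigma, size=dg.size)
        taus[i] = stats.kendalltau(noisy, dg).statistic
    return CeilingEstimate(
        mean_tau=float(np.mean(taus)),
        sd_tau=float(np.std(taus)),
        sigma=sigma,
        n_resamples=n_resamples,
        seed=seed,
    )


def expected_tau_under_noise(dg: np.ndarray, sigma: float) -> float:
    """Closed-form E[tau] for distinct values under Gaussian noise on one copy.

    Pair (i, j) stays concordant with probability 1 - Phi(-|dG_i - dG_j| /
    (sigma * sqrt(2))); E[tau] averages (2p - 1) over pairs.
    """
    dg = np.asarray(dg, dtype=float)
    n = dg.size
    iu = np.triu_indices(n, k=1)
    gaps = np.abs(dg[iu[0]] - dg[iu[1]])
    if sigma == 0:
        return 1.0
    p_flip = stats.norm.cdf(-gaps / (sigma * math.sqrt(2.0)))
    return float(np.mean(1.0 - 2.0 * p_flip))


_MASS_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molecular_weight(formula_or_ligand) -> float:
    """Molecular weight from a Hill formula string (e.g. 'C6H6') or a Ligand."""
    from rdkit.Chem import GetPeriodicTable

    pt = GetPeriodicTable()
    if hasattr(formula_or_ligand, "atoms"):
        return float(sum(pt.GetAtomicWeight(a.element.capitalize())
                         for a in formula_or_ligand.atoms))
    formula = formula_or_ligand.strip()
    if not formula or not re.fullmatch(f"(?:{_MASS_TOKEN.pattern})+", formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    total = 0.0
    for symbol, count in _MASS_TOKEN.findall(formula):
        if not symbol:
            continue
        total += pt.GetAtomicWeight(symbol) * (int(count) if count else 1)
    return total


def descriptor_baseline(
    descriptors: dict[str, float],
    direction: str,
    group_id: int = -1,
    supertarget: str = "baseline",
) -> AffinityPrediction:
    """Rank targets by a scalar descriptor (e.g. molecular weight, cLogP).

    direction='higher_binds_tighter' assigns rank 1 to the largest descriptor.
    """
    if direction not in ("higher_binds_tighter", "lower_binds_tighter"):
        raise ValueError(f"unknown direction {direction!r}")
    if not descriptors:
        raise ValueError("no descriptors given")
    vals = np.array([descriptors[t] for t in sorted(descriptors)], dtype=float)
    if direction == "higher_binds_tighter":
        vals = -vals
    ranks = stats.rankdata(vals)
    return AffinityPrediction(
        group_id=group_id,
        supertarget=supertarget,
        kind="rank",
        values=dict(zip(sorted(descriptors), ranks)),
    )


@dataclass
class StageComparison:
    stage1_taus: dict[int, float]
    stage2_taus: dict[int, float]
    mean_shift: float
    median_shift: float

    def summary(self) -> dict:
        return {
            "n_stage1": len(self.stage1_taus),
            "n_stage2": len(self.stage2_taus),
            "stage1_mean": float(np.mean(list(self.stage1_taus.values()))),
            "stage2_mean": float(np.mean(list(self.stage2_taus.values()))),
            "mean_shift": self.mean_shift,
            "median_shift": self.median_shift,
        }


def stage_comparison(
    stage1: dict[int, float], stage2: dict[int, float]
) -> StageComparison:
    """Compare tau distributions before vs after structure release.

    Group sets may differ; no pairing is assumed — the shift is the difference
    of per-stage distribution means (and medians).
    """
    if not stage1 or not stage2:
        raise ValueError("both stages need at least one group")
    m1, m2 = np.mean(list(stage1.values())), np.mean(list(stage2.values()))
    md1, md2 = np.median(list(stage1.values())), np.median(list(stage2.values()))
    return StageComparison(
        stage1_taus=dict(stage1),
        stage2_taus=dict(stage2),
        mean_shift=float(m2 - m1),
        median_shift=float(md2 - md1),
    )
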