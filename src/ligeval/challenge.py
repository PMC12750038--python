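"""Published composition of the CASP16 protein-ligand challenge datasets.

These counts and ID lists are bookkeeping inputs (target manifests), not
computed results: per-system pose and affinity target counts, and the IDs of
affinity targets excluded from assessment because their experimental data had
been disclosed (in patents or publications) before the challenge closed.
"""

from __future__ import annotations

#: Pose-prediction targets per protein system (Mpro reduced from 25 to 20
#: after five structures were found to have been publicly available).
POSE_TARGET_COUNTS = {
    "chymase": 17,
    "cathepsin_g": 2,
    "autotaxin": 189,
    "mpro": 20,
    "wdr55": 1,
}

#: Affinity-prediction targets per system and stage (Stage 1: before
#: experimental structures were released; Stage 2: after).
AFFINITY_TARGET_COUNTS = {
    1: {"chymase": 17, "autotaxin": 123},
    2: {"chymase": 17, "autotaxin": 93},
}

#: Autotaxin dataset composition: pairs with structures and affinities,
#: structures only, affinities only.
AUTOTAXIN_SUBSET_COUNTS = {
    "structures_and_affinities": 93,
    "structures_only": 96,
    "affinities_only": 30,
}

#: Affinity targets whose experimental data had been previously disclosed.
DISCLOSED_CHYMASE_AFFINITY = frozenset({"L1003", "L1010", "L1013"})
DISCLOSED_AUTOTAXIN_AFFINITY = frozenset(
    {
        "L3009", "L3047", "L3196", "L3197", "L3211", "L3213", "L3214", "L3216",
        "L3217", "L3219", "L3222", "L3224", "L3225", "L3226", "L3229",
    }
)
DISCLOSED_AFFINITY_TARGETS = DISCLOSED_CHYMASE_AFFINITY | DISCLOSED_AUTOTAXIN_AFFINITY


def total_pose_targets() -> int:
    return sum(POSE_TARGET_COUNTS.values())


def total_affinity_targets(stage: int = 1) -> int:
    return sum(AFFINITY_TARGET_COUNTS[stage].values())


def autotaxin_pose_targets_from_subsets() -> int:
    """Pose-target count reconstructed from the structure-bearing subsets."""
    return (
        AUTOTAXIN_SUBSET_COUNTS["structures_and_affinities"]
        + AUTOTAXIN_SUBSET_COUNTS["structures_only"]
    )


def chymase_affinity_target_ids() -> list[str]:
    """The 17 chymase affinity target IDs (L1001..L1017)."""
    return [f"L1{i:03d}" for i in range(1, AFFINITY_TARGET_COUNTS[1]["chymase"] + 1)]


def autotaxin_affinity_target_ids(stage: int = 1) -> list[str]:
    """A Stage-1/2 autotaxin affinity target ID list of the published size.

    The full published membership is not reproduced here; the list contains
    every disclosed (blacklisted) ID plus enough of the remaining L3xxx range
    to reach the published count, which is sufficient for all counting and
    blacklist arithmetic.
    """
    want = AFFINITY_TARGET_COUNTS[stage]["autotaxin"]
    ids = sorted(DISCLOSED_AUTOTAXIN_AFFINITY) if stage == 1 else []
    i = 1
    while len(ids) < want:
        cand = f"L3{i:03d}"
        if cand not in ids:
            ids.append(cand)
        i += 1
    return sorted(ids[:want])


def apply_blacklist(target_ids: list[str], blacklist=DISCLOSED_AFFINITY_TARGETS) -> list[str]:
    """Drop blacklisted targets (the disclosed-data exclusion mechanism)."""
    bl = set(blacklist)
    return [t for t in target_ids if t not in bl]
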