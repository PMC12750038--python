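"""Structural pose-accuracy metrics.

Four metrics per (prediction, reference) pairing:

* ``rmsd`` — binding-site superposed, symmetry-corrected ligand RMSD: binding
  site residues (heavy atoms within 4 A of the ligand) define a Kabsch
  superposition of predicted onto reference C-alpha atoms, and the reported
  value is the minimum heavy-atom RMSD over all element- and
  adjacency-preserving atom mappings of the ligand.
* ``lddt_pli`` — local distance difference test over ligand-protein contacts,
  with a penalty for predicted contacts absent in the reference; the score is
  maximised over ligand automorphisms. Superposition-free.
* ``bb_rmsd`` — C-alpha RMSD of binding-site residues under the site
  superposition of the best-RMSD pairing.
* ``lddt_lp`` — LDDT over all inter-residue heavy-atom pairs within the
  binding site (pocket structure accuracy), superposition-free.

When the reference holds multiple ligand copies or alternate conformations,
all (reference instance x predicted pose) pairings are scored; LDDT-PLI is
reported from the best-LDDT-PLI pairing and the RMSD trio from the
best-RMSD pairing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .errors import SuperpositionError, UndefinedScoreError
from .structures import (
    Ligand,
    PredictedEntry,
    ProteinStructure,
    ReferenceComplex,
    Residue,
    element_node_match,
)

DEFAULT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
DEFAULT_SITE_CUTOFF = 4.0
DEFAULT_INCLUSION_RADIUS = 4.0
AUTOMORPHISM_CAP = 10_000


@dataclass
class BindingSite:
    """Reference binding site: residues with heavy atoms near the ligand."""

    residues: list[Residue]
    ca_keys: list[tuple[str, int]]
    ca_coords_ref: np.ndarray
    atom_records: list[tuple[tuple[str, int], str, np.ndarray]]

    @property
    def residue_keys(self) -> set[tuple[str, int]]:
        return {r.match_key for r in self.residues}


@dataclass
class PoseScore:
    rmsd: float
    lddt_pli: float
    bb_rmsd: float
    lddt_lp: float
    matched_reference: str = ""
    matched_pose: str = ""
    matched_reference_rmsd: str = ""
    matched_pose_rmsd: str = ""
    automorphism_used: int = 0
    group_id: int | None = None
    target_id: str | None = None
    model_num: int | None = None
    lscore: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.lddt_pli <= 1.0 and 0.0 <= self.lddt_lp <= 1.0):
            raise ValueError("LDDT scores must lie in [0, 1]")
        if self.rmsd < 0 or self.bb_rmsd < 0:
            raise ValueError("RMSD values must be >= 0")


# ---------------------------------------------------------------------------
# Binding site and superposition
# ---------------------------------------------------------------------------

def find_binding_site(
    ref: ReferenceComplex,
    instance: Ligand,
    cutoff: float = DEFAULT_SITE_CUTOFF,
    include_nonpolymer: bool = True,
) -> BindingSite:
    """Residues of the reference protein with heavy atoms within *cutoff* of the ligand.

    C-alpha coordinates are drawn from polymer residues only. Raises
    SuperpositionError when fewer than 3 site residues provide a C-alpha.
    """
    lig_xyz = instance.heavy_coords()
    residues: list[Residue] = []
    for res in ref.protein.residues:
        if not res.is_polymer and not include_nonpolymer:
            continue
        xyz = res.heavy_coords()
        if xyz.size and cdist(xyz, lig_xyz).min() <= cutoff:
            residues.append(res)
    ca_keys, ca_coords = [], []
    atom_records: list[tuple[tuple[str, int], str, np.ndarray]] = []
    for res in residues:
        if res.is_polymer:
            ca = res.ca()
            if ca is not None:
                ca_keys.append(res.match_key)
                ca_coords.append(ca.pos)
        for atom in res.atoms:
            if atom.is_heavy:
                atom_records.append((res.match_key, atom.name, atom.pos))
    if len(ca_keys) < 3:
        raise SuperpositionError(
            f"binding site of {ref.target_id}/{instance.instance_id} has "
            f"{len(ca_keys)} C-alpha atoms; >=3 required for superposition"
        )
    return BindingSite(residues, ca_keys, np.array(ca_coords), atom_records)


def kabsch_superpose(
    ref_pts: np.ndarray, mov_pts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Least-squares rigid superposition of mov_pts onto ref_pts (Kabsch/SVD).

    Returns (rotation, translation, fit_rmsd, degenerate) with the proper
    rotation (det +1) applied as ``x' = R @ x + t``. Degenerate (rank-deficient,
    e.g. collinear) point sets are flagged but still solved.
    """
    ref = np.asarray(ref_pts, dtype=float)
    mov = np.asarray(mov_pts, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[0] < 3:
        raise ValueError("need two equal-length point lists of >=3 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    h = (mov - mov_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    degenerate = bool(np.sum(s > 1e-8 * max(s.max(), 1.0)) < 3)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = ref_c - rot @ mov_c
    moved = mov @ rot.T + trans
    fit_rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, fit_rmsd, degenerate


# ---------------------------------------------------------------------------
# Ligand symmetry
# ---------------------------------------------------------------------------

def ligand_automorphisms(lig: Ligand, cap: int = AUTOMORPHISM_CAP) -> list[tuple[int, ...]]:
    """Element- and adjacency-preserving permutations of the heavy-atom graph.

    Permutations are positional over the ligand's heavy atoms in file order,
    sorted lexicographically so the identity comes first; the list is
    truncated at *cap* with a warning.
    """
    heavy = lig.heavy_indices()
    index_of = {atom_idx: pos for pos, atom_idx in enumerate(heavy)}
    g = lig.graph()
    matcher = nx.isomorphism.GraphMatcher(g, g, node_match=element_node_match)
    perms = []
    for mapping in matcher.isomorphisms_iter():
        perms.append(tuple(index_of[mapping[a]] for a in heavy))
        if len(perms) > cap:
            break
    perms.sort()
    if len(perms) > cap:
        warnings.warn(
            f"ligand has more than {cap} automorphisms; list truncated", stacklevel=2
        )
        identity = tuple(range(len(heavy)))
        perms = [identity] + [p for p in perms[:cap] if p != identity][: cap - 1]
    return perms


def ligand_isomorphisms(pose: Ligand, instance: Ligand) -> list[tuple[int, ...]]:
    """All mappings M with pose heavy atom p corresponding to instance heavy atom M[p]."""
    g_pose = pose.graph()
    g_inst = instance.graph()
    heavy_pose = pose.heavy_indices()
    index_of_inst = {atom_idx: pos for pos, atom_idx in enumerate(instance.heavy_indices())}
    matcher = nx.isomorphism.GraphMatcher(g_pose, g_inst, node_match=element_node_match)
    maps = sorted(
        tuple(index_of_inst[mapping[a]] for a in heavy_pose)
        for mapping in matcher.isomorphisms_iter()
    )
    return maps


# ---------------------------------------------------------------------------
# Chain correspondence
# ---------------------------------------------------------------------------

def candidate_chain_maps(
    ref_protein: ProteinStructure, pred_protein: ProteinStructure, cap: int = 24
) -> list[dict[str, str]]:
    """Bijections ref chain -> pred chain between chains of equal residue-name sequence.

    The identity-like map (matching chain ids) is always tried first when
    available; covers e.g. homodimer symmetry where a predictor swaps chains.
    """
    ref_seqs = {
        cid: tuple(r.name for r in residues if r.is_polymer)
        for cid, residues in ref_protein.chains().items()
    }
    pred_seqs = {
        cid: tuple(r.name for r in residues if r.is_polymer)
        for cid, residues in pred_protein.chains().items()
    }
    ref_ids = sorted(ref_seqs)
    maps: list[dict[str, str]] = []
    for perm in itertools.permutations(sorted(pred_seqs), len(ref_ids)):
        if all(ref_seqs[r] == pred_seqs[p] for r, p in zip(ref_ids, perm)):
            maps.append(dict(zip(ref_ids, perm)))
        if len(maps) >= cap:
            break
    identity = {c: c for c in ref_ids}
    if identity in maps:
        maps.remove(identity)
        maps.insert(0, identity)
    return maps or [identity]


def _pred_atom_lookup(pred_protein: ProteinStructure) -> dict:
    table: dict[tuple[str, int, str], np.ndarray] = {}
    for (chain, seq), name, pos in pred_protein.heavy_atom_records():
        table[(chain, seq, name)] = pos
    return table


def _mapped_coords(
    records: list[tuple[tuple[str, int], str, np.ndarray]],
    lookup: dict,
    chain_map: dict[str, str],
) -> np.ndarray:
    """Predicted counterparts of reference atom records; NaN where missing."""
    out = np.full((len(records), 3), np.nan)
    for i, ((chain, seq), name, _pos) in enumerate(records):
        pos = lookup.get((chain_map.get(chain, chain), seq, name))
        if pos is not None:
            out[i] = pos
    return out


# ---------------------------------------------------------------------------
# LDDT machinery
# ---------------------------------------------------------------------------

def lddt_core(
    ref_dists: np.ndarray,
    model_dists: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    penalty_pairs: int = 0,
) -> float:
    """Fraction of reference distances preserved within each threshold.

    ``score = sum_pairs sum_t [|d_model - d_ref| <= t] /
    (n_thresholds * (n_ref_pairs + penalty_pairs))``. Model distances of NaN
    (no counterpart in the model) fail every threshold.
    """
    ref_dists = np.asarray(ref_dists, dtype=float)
    model_dists = np.asarray(model_dists, dtype=float)
    if ref_dists.size == 0:
        raise UndefinedScoreError("LDDT undefined: zero reference pairs")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    delta = np.abs(model_dists - ref_dists)
    with np.errstate(invalid="ignore"):
        hits = sum(int(np.sum(delta <= t)) for t in thresholds)
    denom = len(thresholds) * (ref_dists.size + penalty_pairs)
    return hits / denom


def _contact_tables(
    ref: ReferenceComplex,
    instance: Ligand,
    inclusion_radius: float,
    include_nonpolymer: bool,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Reference ligand-protein distance matrix and the env atom records."""
    records = []
    for res in ref.protein.residues:
        if not res.is_polymer and not include_nonpolymer:
            continue
        for atom in res.atoms:
            if atom.is_heavy:
                records.append((res.match_key, atom.name, atom.pos))
    env_xyz = np.array([r[2] for r in records]).reshape(-1, 3)
    d_ref = cdist(instance.heavy_coords(), env_xyz)
    mask = d_ref <= inclusion_radius
    return d_ref, records, mask


def lddt_pli(
    ref: ReferenceComplex,
    instance: Ligand,
    pred: PredictedEntry,
    pose: Ligand,
    inclusion_radius: float = DEFAULT_INCLUSION_RADIUS,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    include_nonpolymer: bool = True,
    chain_map: dict[str, str] | None = None,
    mappings: list[tuple[int, ...]] | None = None,
) -> float:
    """Contact-preservation score in [0, 1], maximised over ligand automorphisms.

    Reference contacts are (ligand heavy atom, protein heavy atom) pairs within
    the inclusion radius; predicted-only contacts incur a denominator penalty.
    """
    if pred.protein is None:
        raise UndefinedScoreError("predicted protein absent; LDDT-PLI undefined")
    chain_map = chain_map or {}
    d_ref, records, ref_mask = _contact_tables(ref, instance, inclusion_radius, include_nonpolymer)
    if not ref_mask.any():
        raise UndefinedScoreError(
            f"ligand {instance.instance_id} has no reference contacts within "
            f"{inclusion_radius} A"
        )
    env_mod = _mapped_coords(records, _pred_atom_lookup(pred.protein), chain_map)
    pose_xyz = pose.heavy_coords()
    if mappings is None:
        mappings = ligand_isomorphisms(pose, instance)
    if not mappings:
        raise UndefinedScoreError("pose not graph-isomorphic to reference ligand")
    best = 0.0
    for mapping in mappings:
        inv = np.empty(len(mapping), dtype=int)
        inv[np.array(mapping)] = np.arange(len(mapping))
        d_mod = cdist(pose_xyz[inv], env_mod)  # rows follow instance atom order
        with np.errstate(invalid="ignore"):
            penalty = int(np.sum((d_mod <= inclusion_radius) & ~ref_mask))
        score = lddt_core(d_ref[ref_mask], d_mod[ref_mask], thresholds, penalty)
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# RMSD metrics
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    fit_rmsd: float
    n_matched: int
    n_site: int
    flags: list[str]


def site_superposition(
    site: BindingSite,
    pred_protein: ProteinStructure,
    chain_map: dict[str, str] | None = None,
) -> SuperpositionResult:
    """Kabsch superposition of predicted site C-alphas onto the reference site."""
    chain_map = chain_map or {}
    lookup = {}
    for res in pred_protein.polymer_residues():
        ca = res.ca()
        if ca is not None:
            lookup[res.match_key] = ca.pos
    ref_pts, mov_pts = [], []
    for key, ref_pos in zip(site.ca_keys, site.ca_coords_ref):
        mapped = (chain_map.get(key[0], key[0]), key[1])
        if mapped in lookup:
            ref_pts.append(ref_pos)
            mov_pts.append(lookup[mapped])
    flags = []
    if len(mov_pts) < 3:
        raise SuperpositionError(
            f"only {len(mov_pts)} matching site C-alphas; >=3 required"
        )
    if len(mov_pts) < 0.5 * len(site.ca_keys):
        flags.append("sparse_site_match")
    rot, trans, fit_rmsd, degenerate = kabsch_superpose(np.array(ref_pts), np.array(mov_pts))
    if degenerate:
        flags.append("degenerate_superposition")
    return SuperpositionResult(rot, trans, fit_rmsd, len(mov_pts), len(site.ca_keys), flags)


@dataclass
class BisyResult:
    rmsd: float
    mapping_index: int
    superposition: SuperpositionResult
    site: BindingSite


def bisy_rmsd(
    ref: ReferenceComplex,
    instance: Ligand,
    pred: PredictedEntry,
    pose: Ligand,
    site_cutoff: float = DEFAULT_SITE_CUTOFF,
    include_nonpolymer: bool = True,
    chain_map: dict[str, str] | None = None,
    mappings: list[tuple[int, ...]] | None = None,
    site: BindingSite | None = None,
) -> BisyResult:
    """Binding-site superposed, symmetry-corrected ligand RMSD."""
    if pred.protein is None:
        raise SuperpositionError("predicted protein absent; superposition undefined")
    if site is None:
        site = find_binding_site(ref, instance, site_cutoff, include_nonpolymer)
    sup = site_superposition(site, pred.protein, chain_map)
    pose_xyz = pose.heavy_coords() @ sup.rotation.T + sup.translation
    inst_xyz = instance.heavy_coords()
    if mappings is None:
        mappings = ligand_isomorphisms(pose, instance)
    if not mappings:
        raise UndefinedScoreError("pose not graph-isomorphic to reference ligand")
    best, best_idx = np.inf, 0
    for idx, mapping in enumerate(mappings):
        rmsd = float(
            np.sqrt(np.mean(np.sum((pose_xyz - inst_xyz[np.array(mapping)]) ** 2, axis=1)))
        )
        if rmsd < best:
            best, best_idx = rmsd, idx
    return BisyResult(best, best_idx, sup, site)


def lddt_lp(
    site: BindingSite,
    pred_protein: ProteinStructure,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    chain_map: dict[str, str] | None = None,
) -> float:
    """LDDT over all inter-residue heavy-atom pairs within the binding site."""
    chain_map = chain_map or {}
    records = site.atom_records
    ref_xyz = np.array([r[2] for r in records]).reshape(-1, 3)
    res_ids = np.array(
        [hash((r[0][0], r[0][1])) for r in records]
    )  # same-residue pairs excluded below
    mod_xyz = _mapped_coords(records, _pred_atom_lookup(pred_protein), chain_map)
    n = len(records)
    iu = np.triu_indices(n, k=1)
    inter = res_ids[iu[0]] != res_ids[iu[1]]
    d_ref = np.sqrt(np.sum((ref_xyz[iu[0]] - ref_xyz[iu[1]]) ** 2, axis=1))[inter]
    d_mod = np.sqrt(np.sum((mod_xyz[iu[0]] - mod_xyz[iu[1]]) ** 2, axis=1))[inter]
    return lddt_core(d_ref, d_mod, thresholds, penalty_pairs=0)


def site_metrics(
    ref: ReferenceComplex,
    instance: Ligand,
    pred: PredictedEntry,
    pose: Ligand | None = None,
    site_cutoff: float = DEFAULT_SITE_CUTOFF,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    include_nonpolymer: bool = True,
    chain_map: dict[str, str] | None = None,
) -> tuple[float, float]:
    """(BB-RMSD, LDDT-LP) of the predicted binding-site structure."""
    if pred.protein is None:
        raise SuperpositionError("predicted protein absent")
    site = find_binding_site(ref, instance, site_cutoff, include_nonpolymer)
    sup = site_superposition(site, pred.protein, chain_map)
    lp = lddt_lp(site, pred.protein, thresholds, chain_map)
    return sup.fit_rmsd, lp


# ---------------------------------------------------------------------------
# Best-score selection over copies, conformations and permutations
# ---------------------------------------------------------------------------

def score_target(
    ref: ReferenceComplex,
    pred: PredictedEntry,
    site_cutoff: float = DEFAULT_SITE_CUTOFF,
    inclusion_radius: float = DEFAULT_INCLUSION_RADIUS,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    include_nonpolymer: bool = True,
    try_chain_maps: bool = True,
) -> PoseScore:
    """Score one predicted entry against a reference complex.

    All (reference instance x predicted pose x chain map) pairings are
    evaluated. LDDT-PLI comes from its best pairing; RMSD, BB-RMSD and
    LDDT-LP come from the best-RMSD pairing's superposition. Raises
    UndefinedScoreError / SuperpositionError when nothing is scorable.
    """
    if not pred.scorable:
        raise UndefinedScoreError("entry is skipped or invalid; no pose score")
    if pred.protein is None or not pred.ligand_poses:
        raise UndefinedScoreError("entry lacks predicted protein or ligand poses")

    chain_maps = (
        candidate_chain_maps(ref.protein, pred.protein) if try_chain_maps else [{}]
    )
    sites = {
        lig.instance_id: find_binding_site(ref, lig, site_cutoff, include_nonpolymer)
        for lig in ref.ligand_instances
    }
    best_pli: tuple[float, str, str, int] | None = None
    best_rmsd: tuple[float, BisyResult, dict] | None = None
    errors: list[str] = []
    for instance in ref.ligand_instances:
        for pose in pred.ligand_poses:
            mappings = ligand_isomorphisms(pose, instance)
            if not mappings:
                errors.append(
                    f"pose {pose.instance_id} not isomorphic to instance {instance.instance_id}"
                )
                continue
            for cmap in chain_maps:
                try:
                    pli = lddt_pli(
                        ref, instance, pred, pose,
                        inclusion_radius, thresholds, include_nonpolymer,
                        cmap, mappings,
                    )
                    if best_pli is None or pli > best_pli[0]:
                        best_pli = (pli, instance.instance_id, pose.instance_id, 0)
                except UndefinedScoreError as exc:
                    errors.append(str(exc))
                try:
                    bisy = bisy_rmsd(
                        ref, instance, pred, pose, site_cutoff,
                        include_nonpolymer, cmap, mappings,
                        site=sites[instance.instance_id],
                    )
                    if best_rmsd is None or bisy.rmsd < best_rmsd[0]:
                        best_rmsd = (bisy.rmsd, bisy, cmap, instance.instance_id, pose.instance_id)
                except (SuperpositionError, UndefinedScoreError) as exc:
                    errors.append(str(exc))
    if best_pli is None and best_rmsd is None:
        raise UndefinedScoreError("; ".join(errors) or "no scorable pairing")
    if best_pli is None or best_rmsd is None:
        raise UndefinedScoreError(
            "inconsistent pairing outcomes: " + ("; ".join(errors) or "unknown")
        )

    _, bisy, cmap, rmsd_inst, rmsd_pose = best_rmsd
    lp = lddt_lp(bisy.site, pred.protein, thresholds, cmap)
    return PoseScore(
        rmsd=best_rmsd[0],
        lddt_pli=best_pli[0],
        bb_rmsd=bisy.superposition.fit_rmsd,
        lddt_lp=lp,
        matched_reference=best_pli[1],
        matched_pose=best_pli[2],
        matched_reference_rmsd=rmsd_inst,
        matched_pose_rmsd=rmsd_pose,
        automorphism_used=bisy.mapping_index,
        group_id=pred.group_id,
        target_id=pred.target_id,
        model_num=pred.model_num,
        lscore=pred.lscore,
        flags=bisy.superposition.flags + errors,
    )
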