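"""Template-similarity scoring: ligand overlap (SuCOS-style) times
binding-pocket sequence coverage.

The residue alignment between target and template (and any rigid transform
placing the template into the target frame) is an input; this module only
consumes it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import UndefinedScoreError
from .pose import kabsch_superpose
from .structures import Ligand, ReferenceComplex, ligand_to_rdkit

DEFAULT_POCKET_CUTOFF = 6.0

#: Fixed Gaussian radius (A) for volume overlap; per-element radii deliberately
#: not used — a single carbon-like radius keeps the score simple and symmetric.
DEFAULT_ATOM_RADIUS = 1.7

#: Pharmacophore families considered for the chemical-feature overlap term.
DEFAULT_FEATURE_FAMILIES = ("Donor", "Acceptor", "Aromatic", "Hydrophobe", "LumpedHydrophobe")

#: Gaussian exponent such that each atom Gaussian has ~the hard-sphere volume.
_KAPPA = 2.41798793102


@dataclass
class SimilarityRecord:
    sucos: float
    pocket_coverage: float
    combined: float
    template_id: str

    def __post_init__(self) -> None:
        for v in (self.sucos, self.pocket_coverage, self.combined):
            if not 0.0 <= v <= 1.0 + 1e-9:
                raise ValueError("similarity components must lie in [0, 1]")
        if abs(self.combined - self.sucos * self.pocket_coverage) > 1e-9:
            raise ValueError("combined must equal sucos * pocket_coverage")


@dataclass
class PocketAlignment:
    """Injective residue mapping target -> template (e.g. from a fold search)."""

    residue_pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    source: str = ""

    def __post_init__(self) -> None:
        lhs = [a for a, _ in self.residue_pairs]
        rhs = [b for _, b in self.residue_pairs]
        if len(set(lhs)) != len(lhs) or len(set(rhs)) != len(rhs):
            raise ValueError("residue alignment must be injective both ways")

    def mapping(self) -> dict[tuple[str, int], tuple[str, int]]:
        return dict(self.residue_pairs)


def pocket_residues(
    complex_: ReferenceComplex, cutoff: float = DEFAULT_POCKET_CUTOFF
) -> set[tuple[str, int]]:
    """Residues with any heavy atom within *cutoff* of any ligand heavy atom."""
    lig_xyz = np.concatenate([lig.heavy_coords() for lig in complex_.ligand_instances])
    pocket = set()
    for res in complex_.protein.residues:
        xyz = res.heavy_coords()
        if xyz.size and cdist(xyz, lig_xyz).min() <= cutoff:
            pocket.add(res.match_key)
    if not pocket:
        raise UndefinedScoreError(
            f"empty pocket for {complex_.target_id} at cutoff {cutoff} A"
        )
    return pocket


def pocket_coverage(
    target_pocket: set[tuple[str, int]],
    template_pocket: set[tuple[str, int]],
    aln: PocketAlignment,
) -> float:
    """Fraction of target-pocket residues mapped onto template-pocket residues."""
    if not target_pocket:
        raise UndefinedScoreError("empty target pocket")
    mapping = aln.mapping()
    hit = sum(
        1 for res in target_pocket if mapping.get(res) in template_pocket
    )
    return hit / len(target_pocket)


def _gaussian_overlap(a: np.ndarray, b: np.ndarray, radius: float) -> float:
    """Total pairwise Gaussian-product volume between two point sets."""
    if a.size == 0 or b.size == 0:
        return 0.0
    alpha = _KAPPA / radius**2
    d2 = cdist(a, b) ** 2
    prefac = (np.pi / (2.0 * alpha)) ** 1.5
    return float(np.sum(prefac * np.exp(-0.5 * alpha * d2)))


def _feature_points(lig: Ligand, families: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Pharmacophore feature centroids per family via the RDKit feature factory."""
    from rdkit import RDConfig
    from rdkit.Chem import ChemicalFeatures

    mol = ligand_to_rdkit(lig)
    fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    factory = ChemicalFeatures.BuildFeatureFactory(fdef)
    out: dict[str, list[np.ndarray]] = {}
    try:
        feats = factory.GetFeaturesForMol(mol)
    except Exception:  # unsanitizable molecule: no feature term
        return {}
    coords = lig.coords()
    for feat in feats:
        if feat.GetFamily() not in families:
            continue
        pts = coords[list(feat.GetAtomIds())]
        out.setdefault(feat.GetFamily(), []).append(pts.mean(axis=0))
    return {fam: np.array(v) for fam, v in out.items()}


def shape_overlap_score(query: Ligand, ref: Ligand, radius: float = DEFAULT_ATOM_RADIUS) -> float:
    """Normalized Gaussian volume overlap V_qr / sqrt(V_qq * V_rr) in [0, 1]."""
    q = query.heavy_coords()
    r = ref.heavy_coords()
    v_qr = _gaussian_overlap(q, r, radius)
    v_qq = _gaussian_overlap(q, q, radius)
    v_rr = _gaussian_overlap(r, r, radius)
    return float(np.clip(v_qr / np.sqrt(v_qq * v_rr), 0.0, 1.0))


def feature_overlap_score(
    query: Ligand,
    ref: Ligand,
    radius: float = DEFAULT_ATOM_RADIUS,
    families: tuple[str, ...] = DEFAULT_FEATURE_FAMILIES,
) -> float | None:
    """Chemical-feature overlap normalized by the reference self-overlap.

    Returns None when the reference carries no features (the term is then
    dropped and the score falls back to shape only). Asymmetric by design:
    normalization is by the reference molecule, mirroring how a query is
    scored against a known template.
    """
    ref_feats = _feature_points(ref, families)
    if not ref_feats:
        return None
    query_feats = _feature_points(query, families)
    num = 0.0
    den = 0.0
    for fam, ref_pts in ref_feats.items():
        den += _gaussian_overlap(ref_pts, ref_pts, radius)
        q_pts = query_feats.get(fam)
        if q_pts is not None:
            num += _gaussian_overlap(q_pts, ref_pts, radius)
    return float(np.clip(num / den, 0.0, 1.0))


def sucos(
    query: Ligand,
    ref: Ligand,
    radius: float = DEFAULT_ATOM_RADIUS,
    families: tuple[str, ...] = DEFAULT_FEATURE_FAMILIES,
    shape_weight: float = 0.5,
) -> float:
    """Combined overlap score: shape and chemical-feature terms, each in [0, 1].

    Both molecules must already sit in a common frame. An exact in-place copy
    scores 1; molecules far apart score 0.
    """
    if not query.atoms or not ref.atoms:
        raise UndefinedScoreError("empty molecule")
    shape = shape_overlap_score(query, ref, radius)
    feats = feature_overlap_score(query, ref, radius, families)
    if feats is None:
        return shape
    return shape_weight * shape + (1.0 - shape_weight) * feats


def alignment_transform(
    target: ReferenceComplex, template: ReferenceComplex, aln: PocketAlignment
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform placing the template into the target frame, derived by
    Kabsch superposition over the aligned residues' C-alpha atoms."""
    target_ca = {
        r.match_key: r.ca().pos
        for r in target.protein.polymer_residues()
        if r.ca() is not None
    }
    template_ca = {
        r.match_key: r.ca().pos
        for r in template.protein.polymer_residues()
        if r.ca() is not None
    }
    ref_pts, mov_pts = [], []
    for t_key, tpl_key in aln.residue_pairs:
        if t_key in target_ca and tpl_key in template_ca:
            ref_pts.append(target_ca[t_key])
            mov_pts.append(template_ca[tpl_key])
    if len(ref_pts) < 3:
        raise UndefinedScoreError("fewer than 3 aligned C-alpha pairs for superposition")
    rot, trans, _rmsd, _deg = kabsch_superpose(np.array(ref_pts), np.array(mov_pts))
    return rot, trans


def combined_similarity(
    target: ReferenceComplex,
    template: ReferenceComplex | None,
    aln: PocketAlignment | None,
    transform: tuple[np.ndarray, np.ndarray] | None = None,
    pocket_cutoff: float = DEFAULT_POCKET_CUTOFF,
    radius: float = DEFAULT_ATOM_RADIUS,
) -> SimilarityRecord:
    """SuCOS x pocket coverage for one template; absent template scores 0."""
    if template is None or aln is None:
        return SimilarityRecord(0.0, 0.0, 0.0, template_id="none")
    if transform is None:
        transform = alignment_transform(target, template, aln)
    rot, trans = transform
    template_lig = template.ligand_instances[0].transformed(rot, trans)
    score = sucos(target.ligand_instances[0], template_lig, radius)
    coverage = pocket_coverage(
        pocket_residues(target, pocket_cutoff),
        pocket_residues(template, pocket_cutoff),
        aln,
    )
    return SimilarityRecord(
        sucos=score,
        pocket_coverage=coverage,
        combined=score * coverage,
        template_id=template.target_id,
    )


def best_template_similarity(
    target: ReferenceComplex,
    templates: list[tuple[ReferenceComplex, PocketAlignment]],
    pocket_cutoff: float = DEFAULT_POCKET_CUTOFF,
    radius: float = DEFAULT_ATOM_RADIUS,
) -> SimilarityRecord:
    """Highest combined score across a template list; empty list scores 0."""
    if not templates:
        return SimilarityRecord(0.0, 0.0, 0.0, template_id="none")
    records = [
        combined_similarity(target, tpl, aln, None, pocket_cutoff, radius)
        for tpl, aln in templates
    ]
    return max(records, key=lambda r: r.combined)
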