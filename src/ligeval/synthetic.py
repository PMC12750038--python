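"""Synthetic reference complexes, prediction cohorts and affinity datasets.

Every generator is a pure function of (spec, seed): miniature proteins are
procedural (an idealized backbone of N, CA, C, O plus a pseudo side-chain
atom per residue, arranged around the ligand), ligands come from hard-coded
connectivity templates, and noise models are Gaussian. The emitted file
layout is exactly what ``read_submission_dir`` consumes, so the fixtures
double as format-contract tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .affinity import DEFAULT_RT, AffinityDataset, AffinityPrediction
from .pose import ligand_automorphisms, lddt_pli
from .structures import (
    Atom,
    Ligand,
    PredictedEntry,
    ProteinStructure,
    ReferenceComplex,
    Residue,
)

_AA_CYCLE = ("ALA", "VAL", "LEU", "SER", "THR", "PHE", "ASP", "LYS", "GLY", "ILE")


# ---------------------------------------------------------------------------
# Ligand templates
# ---------------------------------------------------------------------------

def _hexagon(radius: float = 1.4) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _template_ring6() -> Ligand:
    """Benzene-like symmetric six-ring (12 graph automorphisms)."""
    atoms = [Atom("C", f"C{i+1}", p) for i, p in enumerate(_hexagon())]
    bonds = [(i, (i + 1) % 6, 1) for i in range(6)]
    return Ligand(atoms, bonds, "ring6")


def _template_branched() -> Ligand:
    """Asymmetric branched chain; identity is its only automorphism."""
    coords = np.array(
        [
            [0.0, 0.0, 0.0],   # C
            [1.5, 0.0, 0.0],   # C
            [2.0, 1.3, 0.0],   # O
            [2.3, -1.2, 0.5],  # C
            [3.7, -1.4, 0.3],  # N
        ]
    )
    elements = ["C", "C", "O", "C", "N"]
    atoms = [Atom(e, f"{e}{i+1}", p) for i, (e, p) in enumerate(zip(elements, coords))]
    bonds = [(0, 1, 1), (1, 2, 1), (1, 3, 1), (3, 4, 1)]
    return Ligand(atoms, bonds, "branched")


def _template_hybrid() -> Ligand:
    """Six-ring plus a three-atom tail: one mirror symmetry, one rotatable bond."""
    ring = _hexagon()
    tail = np.array([[2.9, 0.0, 0.0], [3.6, 1.2, 0.4], [5.0, 1.2, 0.5]])
    coords = np.vstack([ring, tail])
    elements = ["C"] * 7 + ["C", "O"]
    atoms = [Atom(e, f"{e}{i+1}", p) for i, (e, p) in enumerate(zip(elements, coords))]
    bonds = [(i, (i + 1) % 6, 1) for i in range(6)] + [(0, 6, 1), (6, 7, 1), (7, 8, 1)]
    return Ligand(atoms, bonds, "hybrid")


LIGAND_TEMPLATES = {
    "ring6": _template_ring6,
    "branched": _template_branched,
    "hybrid": _template_hybrid,
}


def get_template(name: str) -> Ligand:
    try:
        return LIGAND_TEMPLATES[name]()
    except KeyError:
        raise ValueError(f"unknown ligand template {name!r}") from None


# ---------------------------------------------------------------------------
# Complex generation
# ---------------------------------------------------------------------------

def _centered(lig: Ligand) -> Ligand:
    xyz = lig.heavy_coords()
    return lig.with_coords(lig.coords() - xyz.mean(axis=0))


def _min_dist_to(points: np.ndarray, target: np.ndarray) -> float:
    return float(np.sqrt(np.min(np.sum((points - target) ** 2, axis=1))))


def _place_at_distance(
    lig_xyz: np.ndarray, direction: np.ndarray, z: float, want: float
) -> np.ndarray:
    """Point c * direction + z*e_z whose min distance to lig_xyz equals *want*."""
    lo, hi = 0.5, 40.0
    point = lambda c: np.array([c * direction[0], c * direction[1], z])
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _min_dist_to(lig_xyz, point(mid)) < want:
            lo = mid
        else:
            hi = mid
    return point(0.5 * (lo + hi))


def _pocket_residues_around(
    lig: Ligand,
    n_res: int,
    n_close: int,
    chain_id: str,
    first_seq: int,
    rng: np.random.Generator,
    close_dist: float = 3.2,
    far_dist: float = 6.5,
) -> list[Residue]:
    """Residues on a ring around the ligand; the first n_close sit inside 4 A."""
    lig_xyz = lig.heavy_coords()
    center = lig_xyz.mean(axis=0)
    rel_xyz = lig_xyz - center
    residues = []
    for i in range(n_res):
        theta = 2.0 * math.pi * i / n_res + rng.uniform(-0.08, 0.08)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])
        z = (1.2 if i % 2 else -1.2) + rng.uniform(-0.2, 0.2)
        want = close_dist + rng.uniform(-0.15, 0.15) if i < n_close else far_dist + rng.uniform(0.0, 0.6)
        cb = _place_at_distance(rel_xyz, u, z, want) + center
        outward = np.array([u[0], u[1], 0.0])
        ca = cb + 2.0 * outward + np.array([0.0, 0.0, 0.3 * (1 if i % 2 else -1)])
        n = ca + np.array([-0.9, 1.0, 0.2])
        c = ca + np.array([1.0, 0.9, -0.2])
        o = c + np.array([0.4, 1.1, 0.3])
        name = _AA_CYCLE[i % len(_AA_CYCLE)]
        atoms = [
            Atom("N", "N", n),
            Atom("C", "CA", ca),
            Atom("C", "C", c),
            Atom("O", "O", o),
            Atom("C", "CB", cb),
        ]
        residues.append(Residue(chain_id, first_seq + i, name, atoms))
    return residues


def _rotation_about_z(angle_rad: float) -> np.ndarray:
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def make_complex(
    seed: int,
    ligand_template: str | Ligand = "hybrid",
    pocket_size: int = 8,
    target_id: str = "T0001",
    multi_copy: bool = False,
    alt_conf: bool = False,
    incidental: bool = False,
) -> ReferenceComplex:
    """Procedural miniature reference complex, deterministic per seed.

    The ligand sits in a pocket of *pocket_size* residues of which at least
    four fall inside the 4 A binding-site cutoff. Options add a second ligand
    copy in its own pocket, an alternate in-place conformation, or an
    incidental chloride ion 4 A from the ligand.
    """
    if pocket_size < 4:
        raise ValueError("pocket_size must be >= 4")
    rng = np.random.default_rng(seed)
    base = (
        get_template(ligand_template)
        if isinstance(ligand_template, str)
        else ligand_template
    )
    centered = _centered(base)
    lig0 = centered.with_coords(centered.coords(), instance_id="0")
    instances = [lig0]
    n_close = max(4, pocket_size // 2)
    residues = _pocket_residues_around(lig0, pocket_size, n_close, "A", 1, rng)
    if alt_conf:
        rot = _rotation_about_z(math.radians(20.0))
        alt = lig0.with_coords(lig0.coords() @ rot.T, instance_id="1")
        instances.append(alt)
    if multi_copy:
        offset = np.array([16.0, 0.0, 0.0])
        copy = lig0.with_coords(lig0.coords() + offset, instance_id=str(len(instances)))
        instances.append(copy)
        residues += _pocket_residues_around(
            copy, pocket_size, n_close, "A", 1 + pocket_size, rng
        )
    incidentals: list[Ligand] = []
    if incidental:
        lig_xyz = lig0.heavy_coords()
        anchor = lig_xyz[int(rng.integers(len(lig_xyz)))]
        ion_pos = anchor + np.array([0.0, 0.0, 4.0])
        incidentals.append(Ligand([Atom("Cl", "CL", ion_pos)], [], "ion0"))
    protein = ProteinStructure(residues)
    return ReferenceComplex(target_id, protein, instances, incidentals)


# ---------------------------------------------------------------------------
# Pose perturbation
# ---------------------------------------------------------------------------

PERTURB_MODES = ("translate", "rotate", "torsion", "symmetry_flip", "rebind_site")


def _bridge_rotation(lig: Ligand, angle_rad: float) -> np.ndarray | None:
    """Coordinates after rotating the smaller side of a bridge bond, if any."""
    g = lig.graph()
    coords = lig.coords().copy()
    for i, j in nx.bridges(g):
        h = g.copy()
        h.remove_edge(i, j)
        side = nx.node_connected_component(h, j)
        if len(side) < 2 or len(g) - len(side) < 2:
            continue
        axis = coords[j] - coords[i]
        if np.linalg.norm(axis) < 1e-9:
            continue
        rot = _rotation_about_axis(axis, angle_rad)
        moving = sorted(side - {j})
        coords[moving] = (coords[moving] - coords[j]) @ rot.T + coords[j]
        return coords
    return None


def perturb_pose(
    ref: ReferenceComplex,
    mode: str,
    magnitude: float,
    seed: int,
    group_id: int = 1,
    model_num: int = 1,
    protein_sigma: float = 0.0,
) -> PredictedEntry:
    """Controlled perturbation of the first reference ligand instance.

    translate: rigid shift by exactly *magnitude* Angstrom (random direction);
    rotate: rigid rotation about the centroid by *magnitude* degrees;
    torsion: rotation about a bridge bond by *magnitude* degrees;
    symmetry_flip: a non-identity automorphism applied to the coordinates;
    rebind_site: ligand moved 30 A out of the pocket.
    The predicted protein is a copy of the reference, optionally jittered.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if mode not in PERTURB_MODES:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    rng = np.random.default_rng(seed)
    lig = ref.ligand_instances[0]
    coords = lig.coords()
    if mode == "translate":
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        new = coords + magnitude * direction
    elif mode == "rotate":
        axis = rng.normal(size=3)
        rot = _rotation_about_axis(axis, math.radians(magnitude))
        centroid = coords.mean(axis=0)
        new = (coords - centroid) @ rot.T + centroid
    elif mode == "torsion":
        new = _bridge_rotation(lig, math.radians(magnitude))
        if new is None:  # no rotatable bond: fall back to a rigid rotation
            axis = rng.normal(size=3)
            rot = _rotation_about_axis(axis, math.radians(magnitude))
            centroid = coords.mean(axis=0)
            new = (coords - centroid) @ rot.T + centroid
    elif mode == "symmetry_flip":
        autos = ligand_automorphisms(lig)
        perm = autos[1] if len(autos) > 1 else autos[0]
        new = coords[np.array(perm)]
    else:  # rebind_site
        new = coords + np.array([30.0, 0.0, 0.0])
    protein = ref.protein
    if protein_sigma > 0:
        jittered = []
        for res in protein.residues:
            atoms = [
                Atom(a.element, a.name, a.pos + rng.normal(0, protein_sigma, 3))
                for a in res.atoms
            ]
            jittered.append(Residue(res.chain_id, res.seq_num, res.name, atoms, res.is_polymer))
        protein = ProteinStructure(jittered)
    pose = lig.with_coords(new, instance_id=f"m{model_num}")
    return PredictedEntry(
        group_id=group_id,
        target_id=ref.target_id,
        model_num=model_num,
        protein=protein,
        ligand_poses=[pose],
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    group_id: int
    sigma_pose: float
    skip_prob: float = 0.0
    lscore_rho: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_pose < 0 or not 0.0 <= self.skip_prob <= 1.0:
            raise ValueError("invalid group profile")
        if self.lscore_rho is not None and not 0.0 <= self.lscore_rho <= 1.0:
            raise ValueError("lscore_rho must be in [0, 1]")


@dataclass
class CohortSpec:
    n_targets: int
    group_profiles: list[GroupProfile]
    ligand_templates: list[str] = field(default_factory=lambda: ["ring6", "branched", "hybrid"])
    multi_copy_fraction: float = 0.15
    alt_conf_fraction: float = 0.15
    incidental_fraction: float = 0.2
    n_models: int = 5
    pocket_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or not self.group_profiles:
            raise ValueError("need >=1 target and >=1 group")
        for frac in (self.multi_copy_fraction, self.alt_conf_fraction, self.incidental_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if not 1 <= self.n_models <= 5:
            raise ValueError("n_models must be in 1..5")
        names = set(self.ligand_templates)
        if not names <= set(LIGAND_TEMPLATES):
            raise ValueError(f"unknown ligand templates: {names - set(LIGAND_TEMPLATES)}")

    @property
    def n_groups(self) -> int:
        return len(self.group_profiles)


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, ReferenceComplex], list[PredictedEntry]]:
    """References plus multi-group, multi-model submissions with known ground truth.

    Per group and target, Models 1..n are drawn with translational noise that
    grows with the model number (Model 1 lowest on average); skips are i.i.d.
    per the group's skip probability; when a group has an lscore_rho, each
    model's LScore is its true LDDT-PLI plus N(0, (1 - rho) * 0.3), clamped
    to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    references: dict[str, ReferenceComplex] = {}
    template_cycle = itertools.cycle(spec.ligand_templates)
    for i in range(spec.n_targets):
        tid = f"T{i+1:04d}"
        references[tid] = make_complex(
            seed=int(rng.integers(2**31)),
            ligand_template=next(template_cycle),
            pocket_size=spec.pocket_size,
            target_id=tid,
            multi_copy=bool(rng.random() < spec.multi_copy_fraction),
            alt_conf=bool(rng.random() < spec.alt_conf_fraction),
            incidental=bool(rng.random() < spec.incidental_fraction),
        )
    entries: list[PredictedEntry] = []
    for profile in spec.group_profiles:
        for tid, ref in references.items():
            if rng.random() < profile.skip_prob:
                entries.append(
                    PredictedEntry(profile.group_id, tid, 1, skipped=True)
                )
                continue
            for m in range(1, spec.n_models + 1):
                sigma_m = profile.sigma_pose * (1.0 + 0.3 * (m - 1))
                shift = rng.normal(0.0, sigma_m / math.sqrt(3.0), size=3)
                lig = ref.ligand_instances[0]
                pose = lig.with_coords(lig.coords() + shift, instance_id=f"m{m}")
                entry = PredictedEntry(
                    group_id=profile.group_id,
                    target_id=tid,
                    model_num=m,
                    protein=ref.protein,
                    ligand_poses=[pose],
                )
                if profile.lscore_rho is not None:
                    true_pli = max(
                        lddt_pli(ref, inst, entry, pose)
                        for inst in ref.ligand_instances
                    )
                    noise = rng.normal(0.0, (1.0 - profile.lscore_rho) * 0.3)
                    entry.lscore = float(np.clip(true_pli + noise, 0.0, 1.0))
                entries.append(entry)
    return references, entries


# ---------------------------------------------------------------------------
# Affinity simulation
# ---------------------------------------------------------------------------

@dataclass
class AffinitySimSpec:
    n: int
    dg_span: float
    sigma_exp: float
    group_sigmas: list[float]
    seed: int = 0
    supertarget: str = "SIM"
    rt: float = DEFAULT_RT

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 affinity targets")
        if self.dg_span < 0 or self.sigma_exp < 0 or any(s < 0 for s in self.group_sigmas):
            raise ValueError("spans and sigmas must be >= 0")


def simulate_affinity(
    spec: AffinitySimSpec,
) -> tuple[AffinityDataset, dict[int, AffinityPrediction], np.ndarray]:
    """Experimental dataset + per-group predictions with known true free energies.

    True dG ~ Uniform(0, dg_span); the experimental values add N(0, sigma_exp^2)
    and are emitted as IC50 = exp(dG / RT); group g predicts dG_true +
    N(0, sigma_g^2) as absolute dissociation constants.
    """
    rng = np.random.default_rng(spec.seed)
    dg_true = rng.uniform(0.0, spec.dg_span, size=spec.n)
    dg_exp = dg_true + rng.normal(0.0, spec.sigma_exp, size=spec.n)
    targets = [f"A{i+1:04d}" for i in range(spec.n)]
    def _ic50(dg: float) -> float:
        # clamp the exponent so extreme noise cannot overflow; ranking-based
        # assessment only cares about the ordering
        return float(math.exp(min(max(dg / spec.rt, -500.0), 500.0)))

    dataset = AffinityDataset(
        spec.supertarget,
        {t: _ic50(dg) for t, dg in zip(targets, dg_exp)},
    )
    predictions: dict[int, AffinityPrediction] = {}
    for gid, sigma_g in enumerate(spec.group_sigmas, start=1):
        dg_pred = dg_true + rng.normal(0.0, sigma_g, size=spec.n)
        predictions[gid] = AffinityPrediction(
            group_id=gid,
            supertarget=spec.supertarget,
            kind="absolute_kd",
            values={t: _ic50(dg) for t, dg in zip(targets, dg_pred)},
        )
    return dataset, predictions, dg_true


# ---------------------------------------------------------------------------
# Writing fixture trees (the format contract with read_submission_dir)
# ---------------------------------------------------------------------------

def ligand_smiles(lig: Ligand) -> str:
    from rdkit import Chem

    from .structures import ligand_to_rdkit

    return Chem.MolToSmiles(ligand_to_rdkit(lig))


def write_cohort(
    references: dict[str, ReferenceComplex],
    entries: list[PredictedEntry],
    root: str | Path,
) -> Path:
    """Emit references + submissions in the on-disk layout the readers consume."""
    import csv

    import yaml

    from .structures import write_ligand, write_protein

    root = Path(root)
    refs_dir = root / "references"
    subs_dir = root / "submissions"
    groups = sorted({e.group_id for e in entries})
    targets = sorted(references)
    for tid, ref in references.items():
        tdir = refs_dir / tid
        tdir.mkdir(parents=True, exist_ok=True)
        write_protein(ref.protein, tdir / "protein.pdb")
        for i, lig in enumerate(ref.ligand_instances):
            write_ligand(lig, tdir / f"ligand_{i}.sdf")
        for i, lig in enumerate(ref.incidental_ligands):
            write_ligand(lig, tdir / f"incidental_{i}.sdf")
        (tdir / "smiles.txt").write_text(ligand_smiles(ref.ligand_instances[0]) + "\n")
    lscore_rows: dict[int, list[tuple[str, int, float]]] = {}
    for entry in entries:
        if entry.skipped:
            continue
        edir = subs_dir / str(entry.group_id) / entry.target_id
        edir.mkdir(parents=True, exist_ok=True)
        if entry.protein is not None:
            write_protein(entry.protein, edir / f"model_{entry.model_num}.pdb")
        for i, pose in enumerate(entry.ligand_poses):
            name = (
                f"model_{entry.model_num}.sdf"
                if i == 0
                else f"model_{entry.model_num}_pose{i}.sdf"
            )
            write_ligand(pose, edir / name)
        if entry.lscore is not None:
            lscore_rows.setdefault(entry.group_id, []).append(
                (entry.target_id, entry.model_num, entry.lscore)
            )
    for gid, rows in lscore_rows.items():
        gdir = subs_dir / str(gid)
        gdir.mkdir(parents=True, exist_ok=True)
        with open(gdir / "lscores.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["target", "model", "lscore"])
            writer.writerows(sorted(rows))
    manifest = {"groups": groups, "targets": targets, "n_models": 5}
    root.mkdir(parents=True, exist_ok=True)
    (root / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return root
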