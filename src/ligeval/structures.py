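"""Domain types and file I/O for proteins, ligands and challenge submissions.

Proteins are read from PDB files (highest-occupancy altloc kept, hydrogens
and waters dropped), ligands from MDL molfiles / SDF. Ligand identity is
validated against a SMILES string by element-labelled graph isomorphism,
ignoring bond orders so that kekulization differences between files do not
cause spurious rejections.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml
from Bio.PDB import PDBParser

from .errors import LigandMismatchError, ParseError

logger = logging.getLogger(__name__)

#: Standard amino acid 3-letter codes (polymer residues in written PDB files).
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    """A single atom with element, label and Cartesian position in Angstrom."""

    element: str
    name: str
    pos: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.pos, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "pos", pos)
        if not self.element or not self.element[0].isalpha():
            raise ValueError(f"invalid element symbol {self.element!r}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    """One residue (or non-polymer hetero group) of a protein structure."""

    chain_id: str
    seq_num: int
    name: str
    atoms: list[Atom]
    is_polymer: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.name)

    @property
    def match_key(self) -> tuple[str, int]:
        """Key used to pair residues between predicted and reference proteins."""
        return (self.chain_id, self.seq_num)

    def ca(self) -> Atom | None:
        for atom in self.atoms:
            if atom.name == "CA" and atom.element.upper() == "C":
                return atom
        return None

    def heavy_coords(self) -> np.ndarray:
        pts = [a.pos for a in self.atoms if a.is_heavy]
        return np.array(pts).reshape(-1, 3)


@dataclass
class ProteinStructure:
    """An ordered collection of residues, polymer and non-polymer alike."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_num, name) residue keys")

    def __len__(self) -> int:
        return len(self.residues)

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def by_match_key(self) -> dict[tuple[str, int], Residue]:
        return {r.match_key: r for r in self.residues}

    def heavy_atom_records(self) -> list[tuple[tuple[str, int], str, np.ndarray]]:
        """(residue match key, atom name, position) for every heavy atom."""
        out = []
        for res in self.residues:
            for atom in res.atoms:
                if atom.is_heavy:
                    out.append((res.match_key, atom.name, atom.pos))
        return out

    def chains(self) -> dict[str, list[Residue]]:
        chains: dict[str, list[Residue]] = {}
        for res in self.residues:
            chains.setdefault(res.chain_id, []).append(res)
        return chains

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        new = []
        for res in self.residues:
            atoms = [Atom(a.element, a.name, rotation @ a.pos + translation) for a in res.atoms]
            new.append(Residue(res.chain_id, res.seq_num, res.name, atoms, res.is_polymer))
        return ProteinStructure(new)


@dataclass
class Ligand:
    """A small molecule: atoms plus an explicit bond list (orders kept as metadata)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]]
    instance_id: str = "0"

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not any(a.is_heavy for a in self.atoms):
            raise ValueError("ligand must have at least one heavy atom")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError("bond indices out of range")
        if not nx.is_connected(self.graph(include_h=True)):
            raise ValueError("ligand connectivity graph is not connected")

    def graph(self, include_h: bool = False) -> nx.Graph:
        """Element-labelled connectivity graph (heavy atoms only by default)."""
        g = nx.Graph()
        for idx, atom in enumerate(self.atoms):
            if include_h or atom.is_heavy:
                g.add_node(idx, element=atom.element.upper())
        for i, j, order in self.bonds:
            if g.has_node(i) and g.has_node(j):
                g.add_edge(i, j, order=order)
        return g

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([self.atoms[i].pos for i in self.heavy_indices()]).reshape(-1, 3)

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms]).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Ligand":
        atoms = [Atom(a.element, a.name, rotation @ a.pos + translation) for a in self.atoms]
        return Ligand(atoms, list(self.bonds), self.instance_id)

    def with_coords(self, coords: np.ndarray, instance_id: str | None = None) -> "Ligand":
        atoms = [
            Atom(a.element, a.name, c) for a, c in zip(self.atoms, coords, strict=True)
        ]
        return Ligand(atoms, list(self.bonds), instance_id or self.instance_id)


def element_node_match(a: Mapping, b: Mapping) -> bool:
    return a["element"] == b["element"]


def graphs_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    return nx.is_isomorphic(g1, g2, node_match=element_node_match)


@dataclass
class ReferenceComplex:
    """Crystal structure ground truth: protein plus >=1 drug-like ligand instance."""

    target_id: str
    protein: ProteinStructure
    ligand_instances: list[Ligand]
    incidental_ligands: list[Ligand] = field(default_factory=list)
    covalent_note: str | None = None

    def __post_init__(self) -> None:
        if not self.ligand_instances:
            raise ValueError("reference complex needs at least one ligand instance")
        g0 = self.ligand_instances[0].graph()
        for lig in self.ligand_instances[1:]:
            if not graphs_isomorphic(g0, lig.graph()):
                raise ValueError("ligand instances are not mutually graph-isomorphic")


@dataclass
class PredictedEntry:
    """One group's model for one target, or an explicit skip."""

    group_id: int
    target_id: str
    model_num: int
    protein: ProteinStructure | None = None
    ligand_poses: list[Ligand] = field(default_factory=list)
    lscore: float | None = None
    skipped: bool = False
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.model_num <= 5:
            raise ValueError("model_num must be in 1..5")
        if self.skipped and (self.protein is not None or self.ligand_poses):
            raise ValueError("skipped entries carry no coordinates")
        if self.lscore is not None and not 0.0 <= self.lscore <= 1.0:
            raise ValueError("lscore must be in [0, 1]")

    @property
    def scorable(self) -> bool:
        return not self.skipped and self.invalid_reason is None


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_protein(path: str | Path) -> ProteinStructure | None:
    """Read a PDB file into a ProteinStructure.

    Hydrogens and waters are dropped; for altloc'd atoms the highest-occupancy
    location is kept (ties broken by altloc letter). A template file whose
    coordinates are all zero is treated as an absent protein (returns None).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc

    residues: list[Residue] = []
    model = next(structure.get_models(), None)
    if model is None:
        raise ParseError(f"no model in PDB file {path}")
    for chain in model:
        for res in chain:
            hetflag, seq_num, _icode = res.id
            name = res.get_resname().strip()
            if name in _WATER_NAMES or hetflag == "W":
                continue
            atoms: list[Atom] = []
            for atom in res:
                if atom.is_disordered():
                    # highest occupancy wins; ties broken by altloc letter
                    alts = sorted(
                        atom.child_dict.items(),
                        key=lambda kv: (-(kv[1].get_occupancy() or 0.0), kv[0]),
                    )
                    atom = alts[0][1]
                element = (atom.element or atom.get_name()[0]).strip().capitalize()
                if element.upper() == "H" or element.upper() == "D":
                    continue
                atoms.append(Atom(element, atom.get_name().strip(), np.array(atom.get_coord(), dtype=float)))
            if not atoms:
                continue
            is_polymer = hetflag == " "
            residues.append(Residue(chain.id, seq_num, name, atoms, is_polymer))
    if not residues:
        raise ParseError(f"no residues in PDB file {path}")
    coords = np.concatenate([[a.pos for a in r.atoms] for r in residues])
    if np.allclose(coords, 0.0):
        return None  # zero-filled template => protein absent
    return ProteinStructure(residues)


def write_protein(protein: ProteinStructure, path: str | Path) -> None:
    """Write a ProteinStructure as fixed-width PDB ATOM/HETATM records."""
    lines = []
    serial = 1
    for res in protein.residues:
        record = "ATOM  " if res.is_polymer else "HETATM"
        for atom in res.atoms:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.pos
            lines.append(
                f"{record}{serial:5d} {name:<4s} {res.name:<3s} {res.chain_id:1s}"
                f"{res.seq_num:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element.upper():>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Ligand I/O (RDKit-backed)
# ---------------------------------------------------------------------------

def _rdkit():
    from rdkit import Chem  # deferred: import cost

    return Chem


def read_ligand(path: str | Path, instance_id: str | None = None) -> Ligand:
    """Read a ligand from an MDL molfile / single-record SDF, dropping hydrogens."""
    Chem = _rdkit()
    path = Path(path)
    mol = Chem.MolFromMolFile(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise ParseError(f"cannot parse molfile {path}")
    if mol.GetNumConformers() == 0:
        raise ParseError(f"molfile {path} has no coordinates")
    return ligand_from_rdkit(mol, instance_id or path.stem)


def ligand_from_rdkit(mol, instance_id: str = "0") -> Ligand:
    """Convert an RDKit Mol (with a conformer) to a heavy-atom Ligand."""
    conf = mol.GetConformer()
    keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol().upper() != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    atoms = []
    for old in keep:
        a = mol.GetAtomWithIdx(old)
        p = conf.GetAtomPosition(old)
        atoms.append(Atom(a.GetSymbol(), f"{a.GetSymbol()}{old + 1}", np.array([p.x, p.y, p.z])))
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            order = int(b.GetBondTypeAsDouble()) or 1
            bonds.append((remap[i], remap[j], order))
    return Ligand(atoms, bonds, instance_id)


def ligand_to_rdkit(lig: Ligand):
    """Build an RDKit RWMol (with conformer) from a Ligand; sanitization is attempted."""
    Chem = _rdkit()
    from rdkit.Chem import rdchem
    from rdkit.Geometry import Point3D

    order_map = {1: rdchem.BondType.SINGLE, 2: rdchem.BondType.DOUBLE,
                 3: rdchem.BondType.TRIPLE}
    rw = Chem.RWMol()
    for atom in lig.atoms:
        # implicit hydrogens are left to RDKit so valences (and pharmacophore
        # typing) come out standard; all ligeval metrics ignore hydrogens
        rw.AddAtom(Chem.Atom(atom.element.capitalize()))
    for i, j, order in lig.bonds:
        rw.AddBond(i, j, order_map.get(order, rdchem.BondType.SINGLE))
    conf = rdchem.Conformer(len(lig.atoms))
    for idx, atom in enumerate(lig.atoms):
        conf.SetAtomPosition(idx, Point3D(*map(float, atom.pos)))
    rw.AddConformer(conf)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # pragma: no cover - tolerated for odd valences
        pass
    return mol


def write_ligand(lig: Ligand, path: str | Path) -> None:
    Chem = _rdkit()
    mol = ligand_to_rdkit(lig)
    Path(path).write_text(Chem.MolToMolBlock(mol, kekulize=False) + "$$$$\n")


def smiles_graph(smiles: str) -> nx.Graph:
    """Heavy-atom element-labelled connectivity graph of a SMILES string."""
    Chem = _rdkit()
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise ParseError(f"cannot parse SMILES {smiles!r}")
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetSymbol().upper() != "H":
            g.add_node(atom.GetIdx(), element=atom.GetSymbol().upper())
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if g.has_node(i) and g.has_node(j):
            g.add_edge(i, j)
    return g


def matches_smiles(lig: Ligand, smiles: str) -> bool:
    """Element+connectivity graph isomorphism check (bond orders ignored)."""
    return graphs_isomorphic(lig.graph(), smiles_graph(smiles))


# ---------------------------------------------------------------------------
# Reference complexes and incidental-ligand detection
# ---------------------------------------------------------------------------

def read_reference(
    protein_path: str | Path,
    ligand_paths: Sequence[str | Path],
    smiles: str,
    target_id: str | None = None,
    incidental_paths: Sequence[str | Path] = (),
    covalent_note: str | None = None,
) -> ReferenceComplex:
    """Assemble a reference complex from a PDB file plus ligand molfiles.

    Every drug-like ligand instance must be graph-isomorphic to the heavy-atom
    graph of *smiles* or a LigandMismatchError is raised (the challenge's
    technical-validity check).
    """
    protein = read_protein(protein_path)
    if protein is None:
        raise ParseError(f"reference protein {protein_path} has all-zero coordinates")
    instances = [read_ligand(p, instance_id=str(i)) for i, p in enumerate(ligand_paths)]
    for lig, p in zip(instances, ligand_paths):
        if not matches_smiles(lig, smiles):
            raise LigandMismatchError(
                f"ligand {p} does not match SMILES {smiles!r} (element/connectivity)"
            )
    incidentals = [read_ligand(p, instance_id=f"inc{i}") for i, p in enumerate(incidental_paths)]
    tid = target_id or Path(protein_path).stem
    return ReferenceComplex(tid, protein, instances, incidentals, covalent_note)


def detect_incidental(
    ref: ReferenceComplex, candidates: Iterable[Ligand], cutoff: float = 4.5
) -> tuple[list[Ligand], list[Ligand]]:
    """Partition candidate hetero molecules into (incidental, non-incidental).

    A candidate is incidental iff any of its heavy atoms lies within *cutoff*
    Angstrom of any heavy atom of any drug-like ligand instance.
    """
    from scipy.spatial.distance import cdist

    drug_coords = np.concatenate([lig.heavy_coords() for lig in ref.ligand_instances])
    incidental, other = [], []
    for cand in candidates:
        d = cdist(cand.heavy_coords(), drug_coords)
        (incidental if d.min() <= cutoff else other).append(cand)
    return incidental, other


def read_reference_dir(refs_dir: str | Path) -> dict[str, ReferenceComplex]:
    """Read every ``<refs_dir>/<target>/`` reference complex.

    Each target directory holds ``protein.pdb``, ``ligand_<i>.sdf`` instance
    files, a ``smiles.txt`` identity record and optional ``incidental_<i>.sdf``.
    """
    refs_dir = Path(refs_dir)
    out: dict[str, ReferenceComplex] = {}
    for tdir in sorted(p for p in refs_dir.iterdir() if p.is_dir()):
        ligands = sorted(tdir.glob("ligand_*.sdf"))
        if not ligands:
            continue
        smiles = (tdir / "smiles.txt").read_text().strip()
        out[tdir.name] = read_reference(
            tdir / "protein.pdb",
            ligands,
            smiles,
            target_id=tdir.name,
            incidental_paths=sorted(tdir.glob("incidental_*.sdf")),
        )
    return out


# ---------------------------------------------------------------------------
# Submission trees
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    for key in ("groups", "targets"):
        if key not in manifest:
            raise ParseError(f"manifest missing key {key!r}")
    manifest.setdefault("n_models", 5)
    return manifest


def _read_lscores(group_dir: Path) -> dict[tuple[str, int], float | str]:
    """target,model,lscore CSV -> map; out-of-range values map to an error tag."""
    out: dict[tuple[str, int], float | str] = {}
    f = group_dir / "lscores.csv"
    if not f.exists():
        return out
    with open(f) as fh:
        for row in csv.DictReader(fh):
            try:
                val = float(row["lscore"])
            except (KeyError, ValueError):
                out[(row.get("target", "?"), int(row.get("model", 0) or 0))] = "unparsable"
                continue
            key = (row["target"], int(row["model"]))
            out[key] = val if 0.0 <= val <= 1.0 else "out_of_range"
    return out


def read_submission_dir(root: str | Path, manifest: dict | str | Path) -> list[PredictedEntry]:
    """Read a submission tree into PredictedEntry records.

    Layout: ``<root>/<group>/<target>/model_<m>.pdb`` + ``model_<m>.sdf`` with an
    optional per-group ``lscores.csv``. Every (group, target) in the manifest
    yields at least one entry; targets with no files become skipped entries.
    Malformed files yield entries flagged invalid (treated as skips downstream).
    """
    root = Path(root)
    if not isinstance(manifest, dict):
        manifest = load_manifest(manifest)
    entries: list[PredictedEntry] = []
    for group_id in manifest["groups"]:
        group_dir = root / str(group_id)
        lscores = _read_lscores(group_dir) if group_dir.exists() else {}
        for target_id in manifest["targets"]:
            tdir = group_dir / str(target_id)
            found_any = False
            for m in range(1, manifest.get("n_models", 5) + 1):
                sdf = tdir / f"model_{m}.sdf"
                pdb = tdir / f"model_{m}.pdb"
                if not sdf.exists():
                    continue
                found_any = True
                lscore = lscores.get((str(target_id), m))
                invalid = None
                protein = None
                poses: list[Ligand] = []
                try:
                    poses = [read_ligand(sdf, instance_id=f"m{m}")]
                    extra = sorted(tdir.glob(f"model_{m}_pose*.sdf"))
                    poses += [read_ligand(p) for p in extra]
                    if pdb.exists():
                        protein = read_protein(pdb)
                    if protein is None:
                        invalid = "missing or all-zero predicted protein"
                except ParseError as exc:
                    invalid = str(exc)
                    protein, poses = None, []
                if isinstance(lscore, str):
                    invalid = invalid or f"lscore {lscore}"
                    lscore = None
                entries.append(
                    PredictedEntry(
                        group_id=int(group_id),
                        target_id=str(target_id),
                        model_num=m,
                        protein=protein,
                        ligand_poses=poses,
                        lscore=lscore,
                        skipped=False,
                        invalid_reason=invalid,
                    )
                )
                if invalid:
                    logger.warning(
                        "group %s target %s model %d flagged invalid: %s",
                        group_id, target_id, m, invalid,
                    )
            if not found_any:
                entries.append(
                    PredictedEntry(
                        group_id=int(group_id),
                        target_id=str(target_id),
                        model_num=1,
                        skipped=True,
                    )
                )
    return entries
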