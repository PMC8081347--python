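"""Post-docking structural analytics.

Consumes receptor and docked-pose coordinates in PDB format (poses are
inputs; no docking is performed here) and produces two summaries used to
compare analog poses against nicotine:

* a per-residue interaction fingerprint flagging hydrogen-bond capable
  contacts (ligand N/O/F within 3.5 A of a residue N/O) and hydrophobic
  contacts (ligand carbon within 4.0 A of a residue carbon);
* a trimmed superposition RMSD: optimal least-squares rigid fit (SVD),
  followed by up to three outlier-rejection cycles that discard atoms
  deviating more than 2x the current RMSD, with a floor on the retained
  atom fraction so the statistic always reports how much of the structure
  it describes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ContactTable",
    "RMSDResult",
    "read_structure",
    "detect_contacts",
    "contact_matrix",
    "trimmed_rmsd",
]

HBOND_LIGAND_ELEMENTS = {"N", "O", "F"}
HBOND_RESIDUE_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    resname: str
    resnum: int
    chain: str
    xyz: tuple[float, float, float]
    het: bool = False


@dataclass
class StructureModel:
    atoms: list[AtomRecord]
    source: str = ""

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serial numbers")
        for a in self.atoms:
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates for atom serial {a.serial}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def subset(self, mask) -> "StructureModel":
        return StructureModel([a for a, m in zip(self.atoms, mask) if m], self.source)


def _element_of(atom) -> str:
    el = (atom.element or "").strip()
    if not el:
        el = atom.get_name().strip().lstrip("0123456789")[:1]
    return el.upper()


def read_structure(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records into a flat atom list (HETATM tagged)."""
    path = Path(path)
    # cheap pre-scan for coordinate fields so errors carry a line number
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed coordinate record") from None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        struct = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    atoms = []
    for model in struct:
        for chain in model:
            for residue in chain:
                het = residue.id[0].strip() != ""
                for atom in residue:
                    x, y, z = atom.coord
                    atoms.append(AtomRecord(
                        serial=int(atom.serial_number),
                        name=atom.get_name(),
                        element=_element_of(atom),
                        resname=residue.get_resname(),
                        resnum=int(residue.id[1]),
                        chain=chain.id,
                        xyz=(float(x), float(y), float(z)),
                        het=het,
                    ))
        break  # first model only
    if not atoms:
        raise ValueError(f"{path.name}: no ATOM/HETATM records found")
    return StructureModel(atoms, source=path.name)


@dataclass
class ContactTable:
    """Residue-keyed interaction flags for one ligand pose.

    Keys are ``(resname, resnum, chain)``; a residue may carry both flags.
    """

    contacts: dict[tuple[str, int, str], dict[str, bool]] = field(default_factory=dict)
    parameters: dict[str, float] = field(default_factory=dict)

    def residues(self) -> list[tuple[str, int, str]]:
        return sorted(self.contacts, key=lambda k: (k[2], k[1], k[0]))

    def __eq__(self, other):
        return isinstance(other, ContactTable) and self.contacts == other.contacts


def detect_contacts(receptor: StructureModel, ligand: StructureModel,
                    hbond_max: float = 3.5, hydrophobic_max: float = 4.0) -> ContactTable:
    """Distance-based interaction fingerprint of a docked pose.

    Criteria are element+distance only (no angular term): donor/acceptor
    heavy atoms within ``hbond_max``, carbon-carbon pairs within
    ``hydrophobic_max``.
    """
    if not receptor.atoms or not ligand.atoms:
        raise ValueError("receptor and ligand must both contain atoms")
    table: dict[tuple[str, int, str], dict[str, bool]] = {}

    def scan(lig_elems, rec_elems, cutoff, flag):
        lig = [a for a in ligand.atoms if a.element in lig_elems]
        rec = [a for a in receptor.atoms if a.element in rec_elems]
        if not lig or not rec:
            return
        d = cdist([a.xyz for a in lig], [a.xyz for a in rec])
        for j in np.flatnonzero((d <= cutoff).any(axis=0)):
            key = (rec[j].resname, rec[j].resnum, rec[j].chain)
            entry = table.setdefault(key, {"hbond": False, "hydrophobic": False})
            entry[flag] = True

    scan(HBOND_LIGAND_ELEMENTS, HBOND_RESIDUE_ELEMENTS, hbond_max, "hbond")
    scan({"C"}, {"C"}, hydrophobic_max, "hydrophobic")
    return ContactTable(table, {"hbond_max": hbond_max, "hydrophobic_max": hydrophobic_max})


def _residue_token(key: tuple[str, int, str]) -> str:
    resname, resnum, chain = key
    return f"{resname}{resnum}:{chain}"


def contact_matrix(tables: dict[str, ContactTable],
                   residue_order: list[tuple[str, int, str]] | None = None) -> pd.DataFrame:
    """Binary ligand x (residue, interaction-type) matrix.

    Rows are ligands, columns are ``RESNUM:CHAIN|type`` tokens; 1 marks the
    presence of the interaction.
    """
    if not tables:
        raise ValueError("no contact tables given")
    if residue_order is None:
        residues = sorted({k for t in tables.values() for k in t.contacts},
                          key=lambda k: (k[2], k[1], k[0]))
    else:
        residues = list(residue_order)
    cols = [f"{_residue_token(r)}|{typ}" for r in residues
            for typ in ("hbond", "hydrophobic")]
    data = np.zeros((len(tables), len(cols)), dtype=int)
    for i, (_, table) in enumerate(sorted(tables.items())):
        for j, r in enumerate(residues):
            flags = table.contacts.get(r, {})
            data[i, 2 * j] = int(flags.get("hbond", False))
            data[i, 2 * j + 1] = int(flags.get("hydrophobic", False))
    return pd.DataFrame(data, index=sorted(tables), columns=cols)


@dataclass
class RMSDResult:
    rmsd: float
    retained_fraction: float
    cycles_run: int
    rejected_atoms: list[int]  # serial numbers

    def __post_init__(self):
        if self.rmsd < 0 or not 0 < self.retained_fraction <= 1:
            raise ValueError("invalid RMSD result")


def _superpose(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-atom deviations after optimal rigid superposition of B onto A."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    rot, _ = Rotation.align_vectors(A - ca, B - cb)
    Bf = rot.apply(B - cb) + ca
    return np.linalg.norm(A - Bf, axis=1)


def trimmed_rmsd(A: StructureModel, B: StructureModel, max_cycles: int = 3,
                 sigma_factor: float = 2.0, min_retained: float = 0.75) -> RMSDResult:
    """Superposition RMSD with iterative outlier rejection.

    Atoms are matched by serial number (names must agree).  Each cycle
    superposes the retained set, then discards atoms whose deviation
    exceeds ``sigma_factor`` times the current RMSD; iteration stops after
    ``max_cycles``, when no atom is rejected, or when a further rejection
    would drop the retained fraction below ``min_retained``.
    """
    a_by_serial = {a.serial: a for a in A.atoms}
    b_by_serial = {a.serial: a for a in B.atoms}
    if set(a_by_serial) != set(b_by_serial):
        raise ValueError("atom serial sets differ; no correspondence")
    serials = sorted(a_by_serial)
    for s in serials:
        if a_by_serial[s].name != b_by_serial[s].name:
            raise ValueError(f"atom name mismatch at serial {s}")
    if len(serials) < 3:
        raise ValueError("need at least 3 matched atoms")

    XA = np.array([a_by_serial[s].xyz for s in serials])
    XB = np.array([b_by_serial[s].xyz for s in serials])
    n_total = len(serials)
    keep = np.ones(n_total, dtype=bool)
    rejected: list[int] = []
    cycles = 0
    rmsd = 0.0
    for _ in range(max_cycles):
        cycles += 1
        dev = _superpose(XA[keep], XB[keep])
        rmsd = float(np.sqrt((dev ** 2).mean()))
        if rmsd < 1e-9:  # numerically exact fit: nothing left to reject
            break
        out = dev > sigma_factor * rmsd
        if not out.any():
            break
        n_keep_after = keep.sum() - out.sum()
        if n_keep_after < max(3, np.ceil(min_retained * n_total)):
            break
        keep_idx = np.flatnonzero(keep)
        rejected.extend(serials[i] for i in keep_idx[out])
        keep[keep_idx[out]] = False
    else:
        # cycles exhausted: report RMSD of the final retained set
        dev = _superpose(XA[keep], XB[keep])
        rmsd = float(np.sqrt((dev ** 2).mean()))
    return RMSDResult(rmsd=rmsd, retained_fraction=float(keep.sum() / n_total),
                      cycles_run=cycles, rejected_atoms=rejected)
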