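"""Reading PDB/mmCIF files into a uniform in-memory structure model.

Parsing is delegated to gemmi, which handles both formats natively; the
model kept here is deliberately small: one coordinate model, waters
stripped, alternate locations resolved to the highest-occupancy conformer.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(Exception):
    """Base class for structure I/O failures."""


class StructureParseError(StructureError):
    pass


class EmptyStructureError(StructureError):
    pass


@dataclasses.dataclass
class Atom:
    """A single atom with resolved alternate location."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seq_id: int
    icode: str
    res_name: str
    atoms: dict[str, Atom]
    is_standard: bool = True

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the residue inside its structure."""
        return (self.chain_id, self.seq_id, self.icode)

    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X") if self.is_standard else "X"

    def coord(self, atom_name: str) -> np.ndarray | None:
        atom = self.atoms.get(atom_name)
        return None if atom is None else atom.coord


@dataclasses.dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    source_format: str = "PDB"
    model_index: int = 1

    def iter_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def get_residue(self, key: tuple[str, int, str]) -> Residue:
        chain_id, seq_id, icode = key
        for res in self.chains.get(chain_id, []):
            if res.seq_id == seq_id and res.icode == icode:
                return res
        raise KeyError(f"residue {key} not found")


def _resolve_altlocs(gemmi_res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: the highest-occupancy altloc, first-in-file on ties."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in gemmi_res:
        name = atom.name
        if name not in best:
            best[name] = atom
            order.append(name)
        elif atom.occ > best[name].occ:  # strict: ties keep the earlier atom
            best[name] = atom
    return [best[name] for name in order]


def read_structure(path: str | Path, format_hint: str | None = None) -> Structure:
    """Parse a PDB or mmCIF file into a :class:`Structure`.

    Only the first coordinate model is kept.  Waters are dropped; HETATM
    residues are retained but flagged nonstandard.  ``format_hint`` may be
    ``"pdb"`` or ``"mmcif"`` to bypass extension-based detection.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = gemmi.CoorFormat.Unknown
    if format_hint is not None:
        fmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[
            format_hint.lower()
        ]
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate model")
    source = "mmCIF" if st.input_format == gemmi.CoorFormat.Mmcif else "PDB"
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    n_protein = 0
    for chain in model:
        residues: list[Residue] = []
        for gres in chain:
            if gres.is_water() or gres.name in _WATER_NAMES:
                continue
            is_standard = gres.name in THREE_TO_ONE and gres.het_flag != "H"
            atoms: dict[str, Atom] = {}
            for atom in _resolve_altlocs(gres):
                altloc = atom.altloc if atom.altloc not in ("\x00",) else ""
                atoms[atom.name] = Atom(
                    name=atom.name,
                    element=atom.element.name.upper(),
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    altloc=altloc,
                    bfactor=atom.b_iso,
                )
            if not atoms:
                continue
            icode = gres.seqid.icode.strip()
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_id=gres.seqid.num,
                    icode=icode,
                    res_name=gres.name,
                    atoms=atoms,
                    is_standard=is_standard,
                )
            )
            if is_standard:
                n_protein += 1
        if residues:
            chains.setdefault(chain.name, []).extend(residues)
    if n_protein == 0:
        raise EmptyStructureError(f"{path}: no protein residues")
    return Structure(id=path.stem, chains=chains, source_format=source, model_index=1)


def extract_sequence(
    structure: Structure, chain_id: str
) -> tuple[str, list[tuple[int, str]]]:
    """One-letter sequence of a chain plus the (seq_id, icode) of each position.

    Nonstandard residues appear as ``X``.  The index map is parallel to the
    string, so ``map[i]`` is the residue emitting ``seq[i]``.
    """
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure {structure.id}")
    seq = []
    index_map: list[tuple[int, str]] = []
    for res in structure.chains[chain_id]:
        seq.append(res.one_letter())
        index_map.append((res.seq_id, res.icode))
    return "".join(seq), index_map


# --- output table -----------------------------------------------------------

TSV_COLUMNS = [
    "structure_id", "chain", "r1_bond", "r_cat", "r2_bond",
    "r1_bond_name", "r_cat_name", "r2_bond_name",
    "probability", "rmsd", "r_asa", "template", "type",
    "bond_length", "zscore", "zscore_flag",
    "phi_psi_likelihood", "omega_psi_likelihood", "omega_phi_likelihood",
    "geometry_flag",
]


def _fmt(value, digits: int) -> str:
    if value is None:
        return "NA"
    return f"{value:.{digits}f}"


def write_tsv(rows: list[dict], path: str | Path) -> None:
    """Write prediction rows (dicts keyed by :data:`TSV_COLUMNS`) as TSV.

    Rows are sorted by (structure_id, chain, lysine residue number) so reruns
    are byte-identical.
    """
    ordered = sorted(rows, key=lambda r: (r["structure_id"], r["chain"], r["r1_bond"]))
    lines = ["\t".join(TSV_COLUMNS)]
    for row in ordered:
        fields = []
        for col in TSV_COLUMNS:
            value = row.get(col)
            if col in ("probability", "r_asa"):
                fields.append(_fmt(value, 4))
            elif col in ("rmsd", "bond_length"):
                fields.append(_fmt(value, 3))
            elif col in ("zscore", "phi_psi_likelihood", "omega_psi_likelihood",
                         "omega_phi_likelihood"):
                fields.append(_fmt(value, 3))
            else:
                fields.append("NA" if value is None else str(value))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# --- writers for generated fixtures ----------------------------------------

def write_pdb(structure: Structure, path: str | Path) -> None:
    """Serialize a structure as minimal PDB (used for generated fixtures)."""
    lines = []
    serial = 1
    for chain_id in structure.chains:
        for res in structure.chains[chain_id]:
            record = "ATOM  " if res.is_standard else "HETATM"
            for atom in res.atoms.values():
                name = atom.name
                # PDB atom-name column convention: pad 1/2-letter elements
                field = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.coord
                lines.append(
                    f"{record}{serial:>5d} {field:<4s}{'':1s}{res.res_name:>3s} "
                    f"{chain_id:1s}{res.seq_id:>4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_mmcif(structure: Structure, path: str | Path) -> None:
    """Serialize a structure as a minimal mmCIF atom_site loop.

    Coordinates are written at PDB precision (3 decimals) so that a model
    serialized in both formats parses back to bitwise-identical coordinates.
    """
    lines = [
        f"data_{structure.id}",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_comp_id",
        "_atom_site.auth_asym_id",
        "_atom_site.auth_atom_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 1
    for chain_id in structure.chains:
        for i, res in enumerate(structure.chains[chain_id], start=1):
            record = "ATOM" if res.is_standard else "HETATM"
            for atom in res.atoms.values():
                x, y, z = atom.coord
                lines.append(
                    f"{record} {serial} {atom.element} {atom.name} . {res.res_name} "
                    f"{chain_id} {i} {res.icode or '?'} "
                    f"{x:.3f} {y:.3f} {z:.3f} {atom.occupancy:.2f} {atom.bfactor:.2f} "
                    f"{res.seq_id} {res.res_name} {chain_id} {atom.name} 1"
                )
                serial += 1
    lines.append("#")
    Path(path).write_text("\n".join(lines) + "\n")
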