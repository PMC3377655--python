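"""Read/write PDB-format structures and identify bound metal ions.

The in-memory model is deliberately light: plain dataclasses holding the
atoms, residues and chains the alignment engine needs, plus the metal ions
found among the HETATM records.  Parsing and serialization are delegated to
gemmi; this module fixes the policies (altloc selection, hydrogen removal,
element-based metal detection) on top of it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

#: Metals the predictor knows about (element symbols, upper case).
SUPPORTED_METALS = frozenset({"CA", "CU", "FE", "MG", "MN", "ZN"})

#: Chains shorter than this many amino acids are discarded during curation
#: ("more than 50 residues" read strictly).
MIN_CHAIN_LENGTH = 51

#: A residue binds a metal when any of its non-hydrogen atoms lies within
#: this distance (Å) of the ion center.
BINDING_CUTOFF = 3.5


class EmptyStructureError(ValueError):
    """Raised when a source contains no parsable ATOM/HETATM records."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element is empty")


@dataclass
class Residue:
    res_name: str
    seq_num: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_standard_aa: bool = False

    @property
    def one_letter(self) -> str:
        """One-letter code; any non-standard residue maps to 'X'."""
        if not self.is_standard_aa:
            return "X"
        info = gemmi.find_tabulated_residue(self.res_name)
        code = info.one_letter_code.upper() if info else "X"
        return code if code.isalpha() else "X"

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def has_backbone(self) -> bool:
        return all(self.get_atom(n) is not None for n in ("N", "CA", "C"))

    def min_distance(self, point: np.ndarray) -> float:
        """Smallest distance (Å) from any atom to ``point``."""
        xyz = np.array([a.coords for a in self.atoms])
        return float(np.min(np.linalg.norm(xyz - point, axis=1)))


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_ref(self, residue: Residue) -> str:
        return f"{self.chain_id}:{residue.seq_num}:{residue.insertion_code}"


@dataclass
class MetalIon:
    metal_type: str
    coords: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.metal_type = self.metal_type.upper()
        if self.metal_type not in SUPPORTED_METALS:
            raise ValueError(f"unsupported metal type {self.metal_type!r}")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("metal coords must be a finite 3-vector")


@dataclass
class ProteinStructure:
    structure_id: str
    chains: list[Chain] = field(default_factory=list)
    metal_ions: list[MetalIon] = field(default_factory=list)
    hetero_residues: list[tuple[str, Residue]] = field(default_factory=list)


def _is_metal_residue(residue: Residue) -> bool:
    """Single non-H hetero atom whose element is a supported metal.

    Identification is by element, never by residue or atom name: the Cα
    carbon is named "CA" but its element is C, so it can never be mistaken
    for a calcium ion here.
    """
    if len(residue.atoms) != 1:
        return False
    return residue.atoms[0].element.upper() in SUPPORTED_METALS


def _select_altloc(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: blank or 'A' altlocs only, the
    higher-occupancy of the two, preferring 'A' on a tie."""
    chosen: dict[str, Atom] = {}
    for atom in atoms:
        if atom.altloc not in ("", "A"):
            continue
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
        elif atom.occupancy > prev.occupancy or (
            atom.occupancy == prev.occupancy and atom.altloc == "A"
        ):
            chosen[atom.name] = atom
    return list(chosen.values())


def _looks_like_pdb_text(source: str) -> bool:
    return "\n" in source or source.lstrip()[:6].upper() in (
        "ATOM  ", "HETATM", "MODEL ", "HEADER", "REMARK",
    )


def read_pdb(source: str | os.PathLike) -> ProteinStructure:
    """Parse PDB-format text (or a path to it) into a ProteinStructure.

    Only the first MODEL is used.  Hydrogens are dropped.  HETATM records
    holding a lone supported-metal atom become MetalIon entries; waters and
    other hetero groups are kept aside in ``hetero_residues``; everything
    tabulated as an amino acid (standard or not) joins its chain.
    """
    if isinstance(source, str) and _looks_like_pdb_text(source):
        text = source
        structure_id = "UNKN"
    else:
        path = os.fspath(source)
        with open(path) as fh:
            text = fh.read()
        structure_id = os.path.splitext(os.path.basename(path))[0][:8].upper()

    # explicit id carriers beat the filename: our own REMARK 99 line,
    # then the HEADER idCode field
    for line in text.splitlines():
        if line.startswith("REMARK  99 STRUCTURE_ID "):
            structure_id = line[24:].strip()[:8].upper()
            break
        if line.startswith("HEADER") and len(line) >= 66 and line[62:66].strip():
            structure_id = line[62:66].strip().upper()
            break

    gst = gemmi.read_pdb_string(text)
    if len(gst) == 0:
        raise EmptyStructureError("no parsable records in source")
    model = gst[0]

    out = ProteinStructure(structure_id=structure_id)
    for gchain in model:
        chain = Chain(chain_id=gchain.name or "A")
        for gres in gchain:
            atoms = []
            for gat in gres:
                if gat.element.name.upper() in ("H", "D"):
                    continue
                altloc = "" if gat.altloc in ("\x00", " ", "") else gat.altloc
                atoms.append(
                    Atom(
                        name=gat.name,
                        element=gat.element.name.upper() or gat.name.strip()[:2].upper(),
                        coords=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                        altloc=altloc,
                        occupancy=gat.occ,
                        is_hetero=gres.het_flag == "H",
                    )
                )
            atoms = _select_altloc(atoms)
            if not atoms:
                continue
            info = gemmi.find_tabulated_residue(gres.name)
            is_aa = bool(info and info.is_amino_acid())
            residue = Residue(
                res_name=gres.name,
                seq_num=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                atoms=atoms,
                is_standard_aa=bool(info and info.is_standard() and is_aa),
            )
            if gres.het_flag == "H" and _is_metal_residue(residue):
                out.metal_ions.append(
                    MetalIon(
                        metal_type=residue.atoms[0].element,
                        coords=residue.atoms[0].coords,
                        source_id=f"{structure_id}:{gres.name}:{gres.seqid.num}",
                    )
                )
            elif is_aa or gres.het_flag != "H":
                chain.residues.append(residue)
            else:
                out.hetero_residues.append((chain.chain_id, residue))
        if chain.residues:
            chain.residues.sort(key=lambda r: (r.seq_num, r.insertion_code))
            out.chains.append(chain)

    if not out.chains and not out.metal_ions and not out.hetero_residues:
        raise EmptyStructureError("no parsable records in source")
    return out


def write_pdb(structure: ProteinStructure, path: str | os.PathLike | None = None) -> str:
    """Serialize to fixed-column PDB text (gemmi backend); returns the text.

    Metal ions are written as single-atom HETATM residues named after the
    element, appended after the polymer chains.
    """
    gst = gemmi.Structure()
    gst.name = structure.structure_id
    model = gemmi.Model("1")

    max_seq = 0
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_num, res.insertion_code or " ")
            gres.het_flag = "A" if res.is_standard_aa else "H"
            for atom in res.atoms:
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(*atom.coords)
                gat.occ = atom.occupancy
                gat.altloc = atom.altloc or "\x00"
                gres.add_atom(gat)
            gchain.add_residue(gres)
            max_seq = max(max_seq, res.seq_num)
        model.add_chain(gchain)

    extra: dict[str, gemmi.Chain] = {}

    def _extra_chain(cid: str) -> gemmi.Chain:
        if cid not in extra:
            extra[cid] = gemmi.Chain(cid)
        return extra[cid]

    for i, ion in enumerate(structure.metal_ions):
        gres = gemmi.Residue()
        gres.name = ion.metal_type
        gres.seqid = gemmi.SeqId(max_seq + 1 + i, " ")
        gres.het_flag = "H"
        gat = gemmi.Atom()
        gat.name = ion.metal_type
        gat.element = gemmi.Element(ion.metal_type)
        gat.pos = gemmi.Position(*ion.coords)
        gat.occ = 1.0
        gres.add_atom(gat)
        cid = structure.chains[0].chain_id if structure.chains else "A"
        _extra_chain(cid).add_residue(gres)

    for cid, res in structure.hetero_residues:
        gres = gemmi.Residue()
        gres.name = res.res_name
        gres.seqid = gemmi.SeqId(res.seq_num, res.insertion_code or " ")
        gres.het_flag = "H"
        for atom in res.atoms:
            gat = gemmi.Atom()
            gat.name = atom.name
            gat.element = gemmi.Element(atom.element)
            gat.pos = gemmi.Position(*atom.coords)
            gat.occ = atom.occupancy
            gres.add_atom(gat)
        _extra_chain(cid).add_residue(gres)

    for gchain in extra.values():
        model.add_chain(gchain)

    gst.add_model(model)
    gst.setup_entities()
    text = f"REMARK  99 STRUCTURE_ID {structure.structure_id}\n" + gst.make_pdb_string()
    if path is not None:
        with open(os.fspath(path), "w") as fh:
            fh.write(text)
    return text


def identify_metal_ions(
    structure: ProteinStructure, metal_types: set[str] | frozenset[str] = SUPPORTED_METALS
) -> list[MetalIon]:
    """Metal ions of the requested types found among the HETATM records."""
    wanted = {m.upper() for m in metal_types}
    return [ion for ion in structure.metal_ions if ion.metal_type in wanted]


def _is_nucleic(res: Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.res_name)
    return bool(info and info.is_nucleic_acid())


def extract_polypeptide_chains(
    structure: ProteinStructure,
    min_length: int = MIN_CHAIN_LENGTH,
    require_binding: bool = False,
    metal_types: set[str] | frozenset[str] = SUPPORTED_METALS,
    cutoff: float = BINDING_CUTOFF,
) -> list[Chain]:
    """Curate chains: drop nucleic acids, short chains, and (optionally)
    chains with no residue within ``cutoff`` of any metal ion."""
    ions = identify_metal_ions(structure, metal_types)
    kept: list[Chain] = []
    for chain in structure.chains:
        residues = [
            r for r in chain.residues
            if not _is_nucleic(r)
            and bool(
                (info := gemmi.find_tabulated_residue(r.res_name)) and info.is_amino_acid()
            )
        ]
        if len(residues) < min_length:
            continue
        if require_binding:
            if not any(
                res.min_distance(ion.coords) <= cutoff
                for ion in ions
                for res in residues
            ):
                continue
        kept.append(Chain(chain_id=chain.chain_id, residues=residues))
    return kept


def get_sequence(chain: Chain) -> str:
    """One-letter sequence of a chain; non-standard residues become 'X'."""
    if not chain.residues:
        raise ValueError(f"chain {chain.chain_id!r} is empty")
    return "".join(res.one_letter for res in chain.residues)
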