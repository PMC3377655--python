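"""Metal-site templates: binding-residue definition, template construction,
library curation and composition profiling.

A binding residue has at least one non-hydrogen atom within 3.5 Å of a
metal ion's center; a site qualifies as a template only when it has more
than two such residues, each with a complete N/Cα/C backbone.  The library
groups templates per metal type and serializes to JSON.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .fragment_transform import Triplet
from .structure_io import (
    BINDING_CUTOFF,
    Atom,
    Chain,
    MetalIon,
    ProteinStructure,
    Residue,
)

MIN_SITE_RESIDUES = 3  # "more than two" binding residues


@dataclass
class BindingResidue:
    residue_ref: str  # chain:seq_num:icode
    res_name: str
    min_metal_distance: float
    residue: Residue

    @property
    def one_letter(self) -> str:
        return self.residue.one_letter


@dataclass
class MetalSiteTemplate:
    template_id: str
    metal_type: str
    source_structure_id: str
    chain_ids: list[str]
    metal_coords: np.ndarray
    binding_residues: list[BindingResidue]

    @property
    def triplets(self) -> list[Triplet]:
        """Backbone triplets of the binding residues, site order."""
        out = []
        for idx, br in enumerate(self.binding_residues):
            res = br.residue
            coords = np.array([res.get_atom(n).coords for n in ("N", "CA", "C")])
            out.append(
                Triplet(
                    residue_index=idx,
                    res_name=br.res_name,
                    one_letter=br.one_letter,
                    ref=br.residue_ref,
                    coords=coords,
                )
            )
        return out


@dataclass
class TemplateLibrary:
    templates: dict[str, list[MetalSiteTemplate]] = field(default_factory=dict)
    cutoff: float = BINDING_CUTOFF
    min_residues: int = MIN_SITE_RESIDUES
    build_date: str = ""

    def counts(self) -> dict[str, int]:
        return {metal: len(ts) for metal, ts in sorted(self.templates.items())}

    def all_templates(self) -> list[MetalSiteTemplate]:
        return [t for ts in self.templates.values() for t in ts]

    def get(self, metal: str) -> list[MetalSiteTemplate]:
        return self.templates.get(metal.upper(), [])


def find_binding_residues(
    chains: list[Chain], metal: MetalIon, cutoff: float = BINDING_CUTOFF
) -> list[BindingResidue]:
    """Residues with any non-H atom within ``cutoff`` Å of the metal center,
    across all supplied chains, each with its minimum distance."""
    found = []
    for chain in chains:
        for res in chain.residues:
            if not res.atoms:
                continue
            d = res.min_distance(metal.coords)
            if d <= cutoff:
                found.append(
                    BindingResidue(
                        residue_ref=chain.residue_ref(res),
                        res_name=res.res_name,
                        min_metal_distance=d,
                        residue=res,
                    )
                )
    return found


def build_template(
    metal: MetalIon,
    binding: list[BindingResidue],
    min_residues: int = MIN_SITE_RESIDUES,
    template_id: str = "",
    source_structure_id: str = "",
) -> MetalSiteTemplate | None:
    """A template from a metal and its binding shell, or None (rejection)
    when the site has fewer than ``min_residues`` residues or any residue
    lacks a complete backbone."""
    if len(binding) < min_residues:
        return None
    if any(not br.residue.has_backbone() for br in binding):
        return None
    chain_ids = sorted({br.residue_ref.split(":")[0] for br in binding})
    return MetalSiteTemplate(
        template_id=template_id or f"{source_structure_id}:{metal.metal_type}",
        metal_type=metal.metal_type,
        source_structure_id=source_structure_id,
        chain_ids=chain_ids,
        metal_coords=np.asarray(metal.coords, dtype=float),
        binding_residues=binding,
    )


def build_library(
    structures: list[ProteinStructure],
    metal_types: set[str] | None = None,
    cutoff: float = BINDING_CUTOFF,
    min_residues: int = MIN_SITE_RESIDUES,
) -> TemplateLibrary:
    """All qualifying metal-site templates from a curated structure set."""
    import warnings

    lib = TemplateLibrary(cutoff=cutoff, min_residues=min_residues,
                          build_date=date.today().isoformat())
    if not structures:
        warnings.warn("no input structures; library is empty")
        return lib
    for structure in structures:
        ions = structure.metal_ions
        if metal_types is not None:
            wanted = {m.upper() for m in metal_types}
            ions = [i for i in ions if i.metal_type in wanted]
        for k, ion in enumerate(ions):
            binding = find_binding_residues(structure.chains, ion, cutoff)
            template = build_template(
                ion,
                binding,
                min_residues,
                template_id=f"{structure.structure_id}:{ion.metal_type}:{k}",
                source_structure_id=structure.structure_id,
            )
            if template is None:
                continue
            lib.templates.setdefault(ion.metal_type, []).append(template)
    return lib


def _pairwise_identity(a: str, b: str, aligner: PairwiseAligner) -> float:
    """Global-alignment identity: identical positions / alignment length."""
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length if aln.length else 0.0


def cluster_by_identity(
    sequences: list[tuple[str, str]], threshold: float = 0.25
) -> list[str]:
    """Non-redundancy curation: single-linkage clusters under pairwise
    global-alignment identity >= ``threshold``; the first entry (input
    order) of each cluster is its representative."""
    if not sequences:
        raise ValueError("at least one sequence required")
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-11,
        extend_gap_score=-1,
    )
    n = len(sequences)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if _pairwise_identity(sequences[i][1], sequences[j][1], aligner) >= threshold:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    reps = {}
    for idx, lab in enumerate(labels):
        reps.setdefault(lab, sequences[idx][0])  # first in input order
    return [reps[lab] for lab in sorted(reps, key=lambda l: list(labels).index(l))]


_STANDARD_AA = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def composition_profile(
    library: TemplateLibrary,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-metal composition of binding sites.

    Returns (residue_freq, atom_freq): residue_freq rows are metals and
    columns the 20 standard residue types (frequency among binding
    residues); atom_freq columns are backbone/side-chain x element of the
    contact atom (the residue atom nearest the metal).  Rows sum to 1.
    """
    if not library.all_templates():
        raise ValueError("empty template library")
    res_counts: dict[str, dict[str, int]] = {}
    atom_counts: dict[str, dict[str, int]] = {}
    for metal, templates in library.templates.items():
        rc = res_counts.setdefault(metal, {})
        ac = atom_counts.setdefault(metal, {})
        for tmpl in templates:
            for br in tmpl.binding_residues:
                if br.res_name in _STANDARD_AA:
                    rc[br.res_name] = rc.get(br.res_name, 0) + 1
                contact = min(
                    br.residue.atoms,
                    key=lambda a: float(np.linalg.norm(a.coords - tmpl.metal_coords)),
                )
                part = "backbone" if contact.name in _BACKBONE_ATOMS else "sidechain"
                key = f"{part}_{contact.element}"
                ac[key] = ac.get(key, 0) + 1

    res_df = pd.DataFrame(
        [
            {aa: res_counts[m].get(aa, 0) for aa in _STANDARD_AA} | {"metal": m}
            for m in sorted(res_counts)
        ]
    ).set_index("metal")
    res_df = res_df.div(res_df.sum(axis=1), axis=0)

    atom_keys = sorted({k for ac in atom_counts.values() for k in ac})
    atom_df = pd.DataFrame(
        [
            {k: atom_counts[m].get(k, 0) for k in atom_keys} | {"metal": m}
            for m in sorted(atom_counts)
        ]
    ).set_index("metal")
    atom_df = atom_df.div(atom_df.sum(axis=1), axis=0)
    return res_df, atom_df


# ---------------------------------------------------------------------------
# JSON serialization (coordinates at 3 decimals, PDB precision)

def _round3(arr: np.ndarray) -> list:
    return [round(float(v), 3) for v in np.asarray(arr).ravel()]


def save_library(library: TemplateLibrary, path: str | os.PathLike) -> None:
    payload = {
        "format": "metalsite-template-library",
        "version": 1,
        "cutoff": library.cutoff,
        "min_residues": library.min_residues,
        "build_date": library.build_date,
        "counts": library.counts(),
        "templates": [
            {
                "template_id": t.template_id,
                "metal_type": t.metal_type,
                "source_structure_id": t.source_structure_id,
                "chain_ids": t.chain_ids,
                "metal_coords": _round3(t.metal_coords),
                "binding_residues": [
                    {
                        "residue_ref": br.residue_ref,
                        "res_name": br.res_name,
                        "min_metal_distance": round(br.min_metal_distance, 3),
                        "is_standard_aa": br.residue.is_standard_aa,
                        "atoms": [
                            {
                                "name": a.name,
                                "element": a.element,
                                "coords": _round3(a.coords),
                            }
                            for a in br.residue.atoms
                        ],
                    }
                    for br in t.binding_residues
                ],
            }
            for t in library.all_templates()
        ],
    }
    with open(os.fspath(path), "w") as fh:
        json.dump(payload, fh, indent=1)


def load_library(path: str | os.PathLike) -> TemplateLibrary:
    with open(os.fspath(path)) as fh:
        payload = json.load(fh)
    if payload.get("format") != "metalsite-template-library":
        raise ValueError("not a template library file")
    lib = TemplateLibrary(
        cutoff=payload["cutoff"],
        min_residues=payload["min_residues"],
        build_date=payload.get("build_date", ""),
    )
    for td in payload["templates"]:
        binding = []
        for brd in td["binding_residues"]:
            chain_id, seq_num, icode = brd["residue_ref"].split(":")
            res = Residue(
                res_name=brd["res_name"],
                seq_num=int(seq_num),
                insertion_code=icode,
                atoms=[
                    Atom(name=a["name"], element=a["element"], coords=np.array(a["coords"]))
                    for a in brd["atoms"]
                ],
                is_standard_aa=brd["is_standard_aa"],
            )
            binding.append(
                BindingResidue(
                    residue_ref=brd["residue_ref"],
                    res_name=brd["res_name"],
                    min_metal_distance=brd["min_metal_distance"],
                    residue=res,
                )
            )
        tmpl = MetalSiteTemplate(
            template_id=td["template_id"],
            metal_type=td["metal_type"],
            source_structure_id=td["source_structure_id"],
            chain_ids=td["chain_ids"],
            metal_coords=np.array(td["metal_coords"]),
            binding_residues=binding,
        )
        lib.templates.setdefault(tmpl.metal_type, []).append(tmpl)
    return lib
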