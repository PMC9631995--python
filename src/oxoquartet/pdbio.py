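"""PDB reading and writing for quartet/core models (gemmi-backed).

Residue naming follows wwPDB chemical-component codes: ``DG`` for
2'-deoxyguanosine, ``8OG`` for 8-oxo-2'-deoxyguanosine, ``DT`` for
thymidine stubs.  Cations are written as HETATM records (NA/K/CS).
Coordinates round-trip at PDB precision (0.001 A).
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

from .core import CoreModel, Residue, StructureModel

__all__ = ["write_pdb", "read_pdb", "write_ensemble", "PDBParseError"]

_QUARTET_RESNAMES = {"DG", "8OG", "G", "GUA", "OXG"}
_CATION_RESNAMES = {"NA": "Na", "K": "K", "CS": "Cs"}
_ELEMENT_FIX = {"NA": "Na", "CS": "Cs"}


class PDBParseError(ValueError):
    """Malformed PDB content; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


def _to_gemmi_model(struct: StructureModel, name: str) -> gemmi.Model:
    model = gemmi.Model(name)
    for chain_id in struct.chains:
        chain = gemmi.Chain(chain_id)
        for res in struct.strand(chain_id):
            residue = gemmi.Residue()
            residue.name = res.resname
            residue.seqid = gemmi.SeqId(res.number, " ")
            for atom_name, pos in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(res.elements[atom_name])
                atom.pos = gemmi.Position(*map(float, pos))
                atom.occ = 1.0
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    if struct.cations:
        chain = gemmi.Chain("E")
        for i, (element, pos) in enumerate(struct.cations, start=1):
            residue = gemmi.Residue()
            residue.name = element.upper()
            residue.seqid = gemmi.SeqId(i, " ")
            residue.het_flag = "H"
            atom = gemmi.Atom()
            atom.name = element.upper()
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*map(float, pos))
            atom.occ = 1.0
            residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    return model


def _as_structure(obj) -> StructureModel:
    if isinstance(obj, StructureModel):
        return obj
    if isinstance(obj, CoreModel):
        return obj.to_structure()
    raise TypeError(f"cannot write {type(obj).__name__} as PDB")


def write_pdb(model, path: str | os.PathLike) -> None:
    """Write a CoreModel or StructureModel to *path* as PDB."""
    st = gemmi.Structure()
    st.name = "oxoquartet"
    st.add_model(_to_gemmi_model(_as_structure(model), "1"))
    st.setup_entities()
    doc = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=False))
    with open(path, "w") as fh:
        fh.write(doc)


def write_ensemble(models, path: str | os.PathLike) -> None:
    """Write an iterable of models to *path* as a multi-MODEL PDB."""
    st = gemmi.Structure()
    st.name = "oxoquartet-ensemble"
    for i, model in enumerate(models, start=1):
        st.add_model(_to_gemmi_model(_as_structure(model), str(i)))
    st.setup_entities()
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)))


def _validate_pdb_text(path) -> None:
    n_atoms = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError("truncated coordinate record", lineno)
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise PDBParseError("unparsable coordinates", lineno) from None
                n_atoms += 1
    if n_atoms == 0:
        raise PDBParseError("no ATOM/HETATM records found")


def read_pdb(path: str | os.PathLike, model_index: int = 0) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Quartet planes are inferred by grouping guanine/oxoG residues that
    share a residue number across exactly four chains (the layout this
    package writes and the standard layout of tetramolecular parallel
    quadruplexes); anything else is kept as an unassigned residue.
    """
    _validate_pdb_text(path)
    try:
        st = gemmi.read_structure(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"gemmi failed to parse: {exc}") from None
    if len(st) == 0:
        raise PDBParseError("no models in file")
    model = st[model_index]

    residues: list[Residue] = []
    cations: list[tuple[str, np.ndarray]] = []
    for chain in model:
        for res in chain:
            if res.name.upper() in _CATION_RESNAMES and len(res) == 1:
                atom = res[0]
                cations.append(
                    (
                        _CATION_RESNAMES[res.name.upper()],
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                )
                continue
            atoms = {}
            elements = {}
            for atom in res:
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                el = atom.element.name
                elements[atom.name] = _ELEMENT_FIX.get(el.upper(), el)
            residues.append(
                Residue(
                    chain=chain.name,
                    number=res.seqid.num,
                    resname=res.name,
                    atoms=atoms,
                    elements=elements,
                )
            )

    # infer quartet planes: quartet-forming residues grouped by residue number
    by_number: dict[int, list[Residue]] = {}
    for r in residues:
        if r.resname.upper() in _QUARTET_RESNAMES:
            by_number.setdefault(r.number, []).append(r)
    plane_numbers = sorted(n for n, group in by_number.items() if len(group) == 4)
    for k, n in enumerate(plane_numbers):
        for r in by_number[n]:
            r.plane = k
            r.flag = "syn" if r.resname.upper() in ("8OG", "OXG") else "anti"
    return StructureModel(residues=residues, cations=cations)
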