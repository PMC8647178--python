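"""Structure completeness: Cα matching of a built model against a deposited one.

Completeness is the fraction of residues in the deposited (reference) model
that are reproduced in the built model — a deposited residue counts as
reproduced when some built residue has the same three-letter residue type
and its Cα atom lies strictly within a distance cutoff (default 1.0 Å) of
the deposited Cα.  Matching is one-to-one in both directions, assigned
greedily by ascending Cα-Cα distance.  Both models are assumed to sit in
the same crystal frame; no superposition is performed first.

R_free and R_work are NOT computed here: they come from refinement and are
ingested as plain numbers wherever the predictive layer needs them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

__all__ = [
    "Residue",
    "StructureModel",
    "CompletenessResult",
    "ModelError",
    "ModelReadError",
    "EmptyModelError",
    "read_model",
    "write_model",
    "structure_completeness",
]


class ModelError(Exception):
    """Base class for coordinate-model failures."""


class ModelReadError(ModelError):
    """File is unreadable or not a PDB/mmCIF coordinate file."""


class EmptyModelError(ModelError):
    """Model contains no polymer residues (or no Cα where one is required)."""


@dataclass(frozen=True)
class Residue:
    chain_id: str
    seq_num: int
    insertion_code: str
    residue_type: str
    ca_position: Optional[tuple[float, float, float]] = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.insertion_code)


@dataclass
class StructureModel:
    """An ordered list of polymer residues with optional Cα coordinates."""

    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_num, insertion_code) in model")
        for r in self.residues:
            if not r.residue_type:
                raise ValueError("residue_type must be a non-empty code")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_array(self) -> tuple[np.ndarray, np.ndarray]:
        """Indices (into ``residues``) and coordinates of Cα-bearing residues."""
        idx = [i for i, r in enumerate(self.residues) if r.ca_position is not None]
        coords = np.array([self.residues[i].ca_position for i in idx], dtype=float)
        return np.asarray(idx, dtype=int), coords.reshape(len(idx), 3)


@dataclass
class CompletenessResult:
    completeness: float
    n_deposited: int
    n_matched: int
    matched_pairs: list[tuple[int, int, float]]  # (built idx, deposited idx, distance Å)

    def to_json(self) -> str:
        return json.dumps(
            {
                "completeness": self.completeness,
                "n_deposited": self.n_deposited,
                "n_matched": self.n_matched,
                "matched_pairs": [
                    {"built": b, "deposited": d, "distance": dist}
                    for b, d, dist in self.matched_pairs
                ],
            }
        )


def _best_ca(residue: gemmi.Residue) -> Optional[tuple[float, float, float]]:
    # altloc resolution: highest occupancy wins, ties go to file order
    best = None
    best_occ = -1.0
    for atom in residue:
        if atom.name == "CA" and atom.element == gemmi.Element("C"):
            if atom.occ > best_occ:
                best = atom.pos
                best_occ = atom.occ
    if best is None:
        return None
    return (best.x, best.y, best.z)


def read_model(path: str | Path) -> StructureModel:
    """Read polymer residues (with Cα positions) from a PDB or mmCIF file.

    A residue is treated as polymer when its name is a tabulated amino acid;
    unknown residue names carrying a Cα atom are kept as well, so sparse
    synthetic models survive the round trip.
    """
    path = Path(path)
    if not path.is_file():
        raise ModelReadError(f"{path}: no such file")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ModelReadError(f"{path}: unparseable coordinate file ({exc})") from exc
    residues: list[Residue] = []
    if len(st) > 0:
        for chain in st[0]:
            for res in chain:
                info = gemmi.find_tabulated_residue(res.name)
                is_aa = info is not None and info.is_amino_acid()
                ca = _best_ca(res)
                if not is_aa and ca is None:
                    continue  # waters, ligands, ions
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_num=res.seqid.num,
                        insertion_code=(res.seqid.icode or " ").strip(),
                        residue_type=res.name,
                        ca_position=ca,
                    )
                )
    if not residues:
        raise EmptyModelError(f"{path}: no polymer residues found")
    return StructureModel(residues=residues)


def write_model(model: StructureModel, path: str | Path) -> None:
    """Write a Cα-only coordinate file; format chosen by extension (.pdb/.cif).

    Residues without a Cα are written with a single backbone N placeholder
    atom (a residue only exists in these formats through its atoms), so they
    survive a round trip as Cα-less residues.
    """
    st = gemmi.Structure()
    st.name = "model"
    st.cell = gemmi.UnitCell(500, 500, 500, 90, 90, 90)
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in model.residues:
        chain = chains.get(r.chain_id)
        if chain is None:
            chain = gemmi.Chain(r.chain_id)
            chains[r.chain_id] = chain
        gres = gemmi.Residue()
        gres.name = r.residue_type
        gres.seqid = gemmi.SeqId(r.seq_num, r.insertion_code or " ")
        atom = gemmi.Atom()
        atom.occ = 1.0
        atom.b_iso = 20.0
        if r.ca_position is not None:
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*r.ca_position)
        else:
            atom.name = "N"
            atom.element = gemmi.Element("N")
            atom.pos = gemmi.Position(0.0, 0.0, 0.0)
        gres.add_atom(atom)
        chain.add_residue(gres)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def structure_completeness(
    built: StructureModel, deposited: StructureModel, cutoff: float = 1.0
) -> CompletenessResult:
    """Fraction of deposited Cα-bearing residues reproduced in the built model.

    A deposited residue is matched when a built residue shares its residue
    type and the Cα-Cα distance is strictly below ``cutoff``.  Eligible
    pairs are assigned greedily by ascending distance, each residue used at
    most once on either side.  Deposited residues without a Cα atom are
    excluded from the denominator (the criterion is undefined for them).

    An empty built model is valid and yields completeness 0; a deposited
    model with no Cα atoms raises :class:`EmptyModelError`.
    """
    dep_idx, dep_xyz = deposited.ca_array()
    if len(dep_idx) == 0:
        raise EmptyModelError("deposited model has no Cα atoms")
    n_deposited = len(dep_idx)
    blt_idx, blt_xyz = built.ca_array()
    matched_pairs: list[tuple[int, int, float]] = []
    if len(blt_idx) > 0:
        dists = np.linalg.norm(blt_xyz[:, None, :] - dep_xyz[None, :, :], axis=2)
        dep_types = np.array([deposited.residues[i].residue_type for i in dep_idx])
        blt_types = np.array([built.residues[i].residue_type for i in blt_idx])
        eligible = (dists < cutoff) & (blt_types[:, None] == dep_types[None, :])
        bi, di = np.nonzero(eligible)
        order = np.lexsort((di, bi, dists[bi, di]))  # distance first, then stable ids
        used_built: set[int] = set()
        used_dep: set[int] = set()
        for k in order:
            b, d = int(bi[k]), int(di[k])
            if b in used_built or d in used_dep:
                continue
            used_built.add(b)
            used_dep.add(d)
            matched_pairs.append((int(blt_idx[b]), int(dep_idx[d]), float(dists[b, d])))
    n_matched = len(matched_pairs)
    return CompletenessResult(
        completeness=n_matched / n_deposited,
        n_deposited=n_deposited,
        n_matched=n_matched,
        matched_pairs=matched_pairs,
    )
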