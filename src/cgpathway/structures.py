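"""Coarse-grained structure model and PDB/mmCIF I/O.

A protein is reduced to two beads per residue: the Cα position and the
unweighted centroid of the resolved side-chain heavy atoms (everything
past Cα, excluding the backbone N/C/O).  Glycine, and residues whose
side chain is entirely unresolved, carry no centroid bead.  Hetero
groups (ligands, sterols) are opt-in by residue name and become one
rigid bead per heavy atom.

Structures are assumed pre-oriented with the membrane normal along +z
(OPM-style); nothing in this module re-orients them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    EmptyStructureError,
    GeometryError,
    PairingError,
    StructureFormatError,
)

logger = logging.getLogger("cgpathway")

#: Backbone heavy atoms excluded from the side-chain centroid.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: (chain_id, author residue number, insertion code)
ResidueKey = tuple[str, int, str]


@dataclass(eq=False)
class Residue:
    """One coarse-grained residue: Cα bead plus optional side-chain centroid."""

    chain_id: str
    res_number: int
    insertion_code: str
    res_name: str
    ca: np.ndarray
    centroid: np.ndarray | None
    n_sidechain_atoms: int
    bw_label: str | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        if self.centroid is not None:
            self.centroid = np.asarray(self.centroid, dtype=float)
        if not np.all(np.isfinite(self.ca)):
            raise ValueError(f"non-finite CA coordinate in {self.key}")
        if self.centroid is not None and not np.all(np.isfinite(self.centroid)):
            raise ValueError(f"non-finite centroid coordinate in {self.key}")
        if (self.centroid is None) != (self.n_sidechain_atoms == 0):
            raise ValueError(
                f"{self.key}: centroid must be absent exactly when "
                f"n_sidechain_atoms == 0"
            )

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_number, self.insertion_code)

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id,
            self.res_number,
            self.insertion_code,
            self.res_name,
            self.ca.copy(),
            None if self.centroid is None else self.centroid.copy(),
            self.n_sidechain_atoms,
            self.bw_label,
        )


@dataclass(eq=False)
class HeteroBead:
    """A rigid non-protein bead (one per heavy atom of a selected hetero group)."""

    name: str
    coord: np.ndarray
    charge: float = 0.0
    radius: float = 2.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for hetero bead {self.name}")
        if self.radius <= 0:
            raise ValueError(f"hetero bead {self.name}: radius must be > 0")

    def copy(self) -> "HeteroBead":
        return HeteroBead(self.name, self.coord.copy(), self.charge, self.radius)


@dataclass(eq=False)
class CGStructure:
    """An ordered list of coarse-grained residues plus optional hetero beads."""

    residues: list[Residue]
    hetero: list[HeteroBead] = field(default_factory=list)
    label: str = ""
    membrane_normal_axis: str = "z"

    def __post_init__(self) -> None:
        if len(self.residues) == 0:
            raise EmptyStructureError(f"structure {self.label!r} has no residues")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            seen: set[ResidueKey] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate residue identifier {dup}")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) array of Cα positions."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def interaction_coords(self) -> np.ndarray:
        """(n, 3) array of interaction beads: the centroid, or Cα when absent."""
        return np.array(
            [r.ca if r.centroid is None else r.centroid for r in self.residues],
            dtype=float,
        )

    def index_of(self, key: ResidueKey) -> int:
        for i, r in enumerate(self.residues):
            if r.key == key:
                return i
        raise KeyError(f"residue {key} not found in {self.label!r}")

    def copy(self) -> "CGStructure":
        return CGStructure(
            [r.copy() for r in self.residues],
            [h.copy() for h in self.hetero],
            self.label,
            self.membrane_normal_axis,
        )

    def transformed(
        self, rotation: np.ndarray, translation: np.ndarray
    ) -> "CGStructure":
        """Return a rigidly transformed copy (x -> R x + t), hetero included."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        out = self.copy()
        for r in out.residues:
            r.ca = rotation @ r.ca + translation
            if r.centroid is not None:
                r.centroid = rotation @ r.centroid + translation
        for h in out.hetero:
            h.coord = rotation @ h.coord + translation
        return out


@dataclass(eq=False)
class Superposition:
    """Optimal rigid transform (x -> R x + t) of a mobile set onto a reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass(eq=False)
class ResiduePairing:
    """Residue correspondence between two structures, ordered like the first."""

    pairs: list[tuple[int, int]]
    unmatched_a: list[ResidueKey]
    unmatched_b: list[ResidueKey]


def _is_amino_acid(res: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None:
        return bool(info.is_amino_acid())
    # Unknown residue names: accept if they look peptidic (have a CA).
    return any(a.name == "CA" for a in res)


def read_structure(
    path: str | Path,
    model_index: int = 0,
    chains: Sequence[str] | None = None,
    hetero_names: Sequence[str] = (),
    hetero_charges: Mapping[str, float] | None = None,
    hetero_radius: float = 2.0,
    label: str | None = None,
) -> CGStructure:
    """Read a PDB or mmCIF file and coarse-grain it.

    Parameters
    ----------
    path:
        Input file; format is auto-detected by gemmi.
    model_index:
        0-based model to use (NMR/multi-model files).
    chains:
        Optional chain whitelist (author chain ids).
    hetero_names:
        Residue names (e.g. ligand codes) to carry as rigid hetero beads,
        one bead per heavy atom.  Hetero groups not listed are dropped.
    hetero_charges:
        Optional per-atom partial charges keyed by "RESNAME:ATOMNAME".
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if model_index >= len(st):
        raise StructureFormatError(
            f"{path}: model {model_index} not present ({len(st)} model(s))"
        )
    model = st[model_index]
    hetero_names = set(hetero_names)
    hetero_charges = dict(hetero_charges or {})

    residues: list[Residue] = []
    hetero: list[HeteroBead] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            icode = res.seqid.icode.strip()
            if res.name in hetero_names:
                for atom in res:
                    if atom.element.is_hydrogen:
                        continue
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    aname = f"{res.name}:{atom.name}"
                    hetero.append(
                        HeteroBead(
                            name=aname,
                            coord=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            charge=hetero_charges.get(aname, 0.0),
                            radius=hetero_radius,
                        )
                    )
                continue
            if not _is_amino_acid(res):
                continue
            ca = None
            side: list[np.ndarray] = []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                if atom.altloc not in ("", "\x00", "A"):
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if atom.name == "CA":
                    ca = pos
                elif atom.name not in BACKBONE_ATOMS:
                    side.append(pos)
            if ca is None:
                logger.warning(
                    "%s: residue %s %s%d%s lacks a CA atom; skipped",
                    path.name, res.name, chain.name, res.seqid.num, icode,
                )
                continue
            if not side and res.name not in ("GLY",):
                logger.warning(
                    "%s: %s %s%d%s has no resolved side-chain atoms; "
                    "treated as glycine-like",
                    path.name, res.name, chain.name, res.seqid.num, icode,
                )
            centroid = np.mean(side, axis=0) if side else None
            residues.append(
                Residue(
                    chain_id=chain.name,
                    res_number=res.seqid.num,
                    insertion_code=icode,
                    res_name=res.name,
                    ca=ca,
                    centroid=centroid,
                    n_sidechain_atoms=len(side),
                )
            )
    if not residues:
        raise EmptyStructureError(
            f"{path}: selection (model {model_index}, chains={chains}) "
            f"contains no amino-acid residues"
        )
    return CGStructure(
        residues=residues,
        hetero=hetero,
        label=label if label is not None else path.stem,
    )


def write_cg_pdb(
    structures: CGStructure | Sequence[CGStructure], path: str | Path
) -> None:
    """Write one or more coarse-grained frames as a multi-model PDB.

    Each residue contributes a CA record and, when a side-chain centroid
    exists, a pseudo-atom named "CEN".  Hetero beads become HETATM
    records in a residue named "HTB".
    """
    if isinstance(structures, CGStructure):
        structures = [structures]
    st = gemmi.Structure()
    st.name = structures[0].label or "cgpathway"
    for mi, s in enumerate(structures, start=1):
        model = gemmi.Model(mi)
        by_chain: dict[str, gemmi.Chain] = {}
        for r in s.residues:
            chain = by_chain.get(r.chain_id)
            if chain is None:
                chain = gemmi.Chain(r.chain_id)
                by_chain[r.chain_id] = chain
            res = gemmi.Residue()
            res.name = r.res_name
            res.seqid = gemmi.SeqId(r.res_number, r.insertion_code or " ")
            a = gemmi.Atom()
            a.name = "CA"
            a.element = gemmi.Element("C")
            a.pos = gemmi.Position(*r.ca)
            res.add_atom(a)
            if r.centroid is not None:
                c = gemmi.Atom()
                c.name = "CEN"
                c.element = gemmi.Element("C")
                c.pos = gemmi.Position(*r.centroid)
                res.add_atom(c)
            chain.add_residue(res)
        if s.hetero:
            hchain = by_chain.setdefault("X", gemmi.Chain("X"))
            hres = gemmi.Residue()
            hres.name = "HTB"
            hres.seqid = gemmi.SeqId(9000, " ")
            hres.het_flag = "H"
            for bi, b in enumerate(s.hetero, start=1):
                a = gemmi.Atom()
                a.name = f"B{bi}"
                a.element = gemmi.Element("C")
                a.pos = gemmi.Position(*b.coord)
                hres.add_atom(a)
            hchain.add_residue(hres)
        for chain in by_chain.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def pair_residues(a: CGStructure, b: CGStructure) -> ResiduePairing:
    """Match residues between two structures on (chain, number, icode).

    The pair order follows structure ``a``.  Unmatched residues on either
    side are reported (and logged) rather than raising, unless nothing at
    all matches.
    """
    index_b = {r.key: j for j, r in enumerate(b.residues)}
    pairs: list[tuple[int, int]] = []
    unmatched_a: list[ResidueKey] = []
    matched_b: set[int] = set()
    for i, r in enumerate(a.residues):
        j = index_b.get(r.key)
        if j is None:
            unmatched_a.append(r.key)
        else:
            pairs.append((i, j))
            matched_b.add(j)
    unmatched_b = [r.key for j, r in enumerate(b.residues) if j not in matched_b]
    if not pairs:
        raise PairingError(
            f"no residues in common between {a.label!r} and {b.label!r}"
        )
    if unmatched_a or unmatched_b:
        logger.warning(
            "pairing %r/%r: %d unmatched in first, %d in second",
            a.label, b.label, len(unmatched_a), len(unmatched_b),
        )
    return ResiduePairing(pairs, unmatched_a, unmatched_b)


def _paired_ca(
    mobile: CGStructure, reference: CGStructure, pairing: ResiduePairing
) -> tuple[np.ndarray, np.ndarray]:
    mob = np.array([mobile.residues[i].ca for i, _ in pairing.pairs])
    ref = np.array([reference.residues[j].ca for _, j in pairing.pairs])
    return mob, ref


def superpose(
    mobile: CGStructure,
    reference: CGStructure,
    pairing: ResiduePairing | None = None,
) -> Superposition:
    """Least-squares (Kabsch) rigid superposition on paired Cα positions.

    Returns the proper rotation (det = +1) and translation minimising the
    Cα RMSD of ``mobile`` against ``reference``.
    """
    if pairing is None:
        pairing = pair_residues(mobile, reference)
    mob, ref = _paired_ca(mobile, reference, pairing)
    if len(mob) < 3:
        raise GeometryError(f"superposition needs >= 3 pairs, got {len(mob)}")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    sv = np.linalg.svd(ref_c, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1.0):
        raise GeometryError("paired CA positions are collinear")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd = float(rssd) / np.sqrt(len(mob))
    rotation = rot.as_matrix()
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_after_superposition(
    a: CGStructure,
    b: CGStructure,
    pairing: ResiduePairing | None = None,
    include_sidechains: bool = False,
) -> float:
    """Optimal Cα RMSD between two structures (Å); symmetric in its arguments.

    With ``include_sidechains`` the superposition is still fitted on the
    Cα pairs, but the reported RMSD additionally covers the side-chain
    centroid beads present on both sides — the metric the pathway
    progress coordinate uses, so that side-chain rearrangements count
    as conformational change.
    """
    if pairing is None:
        pairing = pair_residues(a, b)
    sup = superpose(a, b, pairing)
    if not include_sidechains:
        return sup.rmsd
    mob_pts: list[np.ndarray] = []
    ref_pts: list[np.ndarray] = []
    for i, j in pairing.pairs:
        ra, rb = a.residues[i], b.residues[j]
        mob_pts.append(ra.ca)
        ref_pts.append(rb.ca)
        if ra.centroid is not None and rb.centroid is not None:
            mob_pts.append(ra.centroid)
            ref_pts.append(rb.centroid)
    mob = sup.apply(np.array(mob_pts))
    ref = np.array(ref_pts)
    return float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
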