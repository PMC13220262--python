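"""Surrogate coarse-grained membrane free-energy function.

The conformational energy of a two-bead-per-residue structure is a sum
of five transparent terms, every constant of which lives in
:class:`EnergyParams`:

* ``membrane_burial`` — per-residue transfer free energy h(res) scaled by
  a smooth slab occupancy f(z) of the side-chain bead (f = 1 inside the
  slab, falling to 0 over a 6 Å taper outside it);
* ``electrostatic`` — screened Coulomb 332.0637 q_i q_j / (ε(r) r) between
  formally charged side-chain beads, with a distance-dependent
  dielectric ε(r) = ε₀ + m·r; below ``elec_r_min`` the interaction is
  capped at its value there (zero force), so the potential is bounded;
* ``contact`` — an attractive 8-6 well between side-chain beads,
  ε_c[(σ/r)⁸ − 2(σ/r)⁶], clamped to ≤ 0 so the excluded-volume term is
  the only short-range repulsion;
* ``excluded_volume`` — harmonic overlap penalty k(r₀ − r)² between Cα
  beads closer than r₀, and likewise between side-chain beads (the
  attractive terms would otherwise let oppositely charged side chains
  collapse onto each other);
* ``ligand_interaction`` — the electrostatic and contact terms between
  rigid hetero beads and residue beads.

Pair terms act between side-chain interaction beads (the centroid, or
the Cα for residues without one), are restricted to sequence
separations ≥ ``min_seq_separation`` within a chain (inter-chain pairs
always qualify), and are tapered to zero with a cos² switching function
over the last ``switch_width`` Å before ``pair_cutoff`` so the energy is
continuous in the coordinates.

This is a potential energy of a single frame; no entropic contribution
is estimated.  Profiles built from it are conformational energy
profiles of relaxed frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from types import SimpleNamespace
from typing import Mapping

import numpy as np

from .errors import EnergyEvaluationError, ParameterError
from .hydrophobicity import FORMAL_CHARGES, WIMLEY_WHITE_OCTANOL
from .structures import CGStructure

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB = 332.0637

#: Width (Å) of the burial taper outside the membrane slab.
MEMBRANE_TAPER = 6.0


@dataclass
class EnergyParams:
    """All constants of the surrogate CG energy function."""

    membrane_z_min: float = -15.0
    membrane_z_max: float = 15.0
    hydrophobicity_scale: dict[str, float] = field(
        default_factory=lambda: dict(WIMLEY_WHITE_OCTANOL)
    )
    residue_charges: dict[str, float] = field(
        default_factory=lambda: dict(FORMAL_CHARGES)
    )
    dielectric_eps0: float = 1.0
    dielectric_slope: float = 3.9
    contact_epsilon: float = 0.3
    contact_radius: float = 6.0
    repulsion_radius: float = 4.0
    repulsion_k: float = 10.0
    min_seq_separation: int = 3
    pair_cutoff: float = 12.0
    switch_width: float = 2.0
    elec_r_min: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.membrane_z_min < self.membrane_z_max:
            raise ParameterError("membrane_z_min must be < membrane_z_max")
        if not (self.contact_radius > self.repulsion_radius > 0):
            raise ParameterError(
                "need contact_radius > repulsion_radius > 0"
            )
        if self.dielectric_eps0 < 1.0:
            raise ParameterError("dielectric_eps0 must be >= 1")
        if self.pair_cutoff <= self.contact_radius:
            raise ParameterError("pair_cutoff must exceed contact_radius")
        if not (0 < self.switch_width < self.pair_cutoff):
            raise ParameterError("switch_width must lie in (0, pair_cutoff)")
        if self.elec_r_min <= 0:
            raise ParameterError("elec_r_min must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "EnergyParams":
        return cls(**dict(d))


@dataclass
class EnergyBreakdown:
    """Per-term decomposition of the CG energy (kcal/mol)."""

    membrane_burial: float
    electrostatic: float
    contact: float
    excluded_volume: float
    ligand_interaction: float
    total: float

    @classmethod
    def from_terms(
        cls,
        membrane_burial: float,
        electrostatic: float,
        contact: float,
        excluded_volume: float,
        ligand_interaction: float,
    ) -> "EnergyBreakdown":
        return cls(
            membrane_burial,
            electrostatic,
            contact,
            excluded_volume,
            ligand_interaction,
            membrane_burial
            + electrostatic
            + contact
            + excluded_volume
            + ligand_interaction,
        )

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def slab_occupancy(z: np.ndarray | float, p: EnergyParams) -> np.ndarray | float:
    """Smooth membrane occupancy f(z): 1 inside the slab, 0 beyond the taper."""
    z = np.asarray(z, dtype=float)
    d = np.maximum(np.maximum(p.membrane_z_min - z, z - p.membrane_z_max), 0.0)
    f = np.where(
        d >= MEMBRANE_TAPER,
        0.0,
        np.cos(np.pi * d / (2.0 * MEMBRANE_TAPER)) ** 2,
    )
    return f if f.shape else float(f)


def _slab_occupancy_grad(z: np.ndarray, p: EnergyParams) -> np.ndarray:
    """df/dz."""
    below = z < p.membrane_z_min
    above = z > p.membrane_z_max
    d = np.where(below, p.membrane_z_min - z, np.where(above, z - p.membrane_z_max, 0.0))
    dfdd = np.where(
        d >= MEMBRANE_TAPER,
        0.0,
        -(np.pi / (2.0 * MEMBRANE_TAPER)) * np.sin(np.pi * d / MEMBRANE_TAPER),
    )
    dddz = np.where(below, -1.0, np.where(above, 1.0, 0.0))
    return dfdd * dddz


def _switch(r: np.ndarray, p: EnergyParams) -> tuple[np.ndarray, np.ndarray]:
    """cos² taper S(r) over [cutoff - width, cutoff], with dS/dr."""
    r_on = p.pair_cutoff - p.switch_width
    w = p.switch_width
    t = np.clip((r - r_on) / w, 0.0, 1.0)
    s = np.where(r <= r_on, 1.0, np.where(r >= p.pair_cutoff, 0.0,
                 np.cos(0.5 * np.pi * t) ** 2))
    ds = np.where(
        (r > r_on) & (r < p.pair_cutoff),
        -(np.pi / (2.0 * w)) * np.sin(np.pi * t),
        0.0,
    )
    return s, ds


def build_arrays(s: CGStructure, p: EnergyParams) -> SimpleNamespace:
    """Flatten a structure into the arrays the evaluator works on."""
    n = len(s.residues)
    ca = s.ca_coords()
    cent = np.zeros((n, 3))
    has_cent = np.zeros(n, dtype=bool)
    for i, r in enumerate(s.residues):
        if r.centroid is not None:
            cent[i] = r.centroid
            has_cent[i] = True
        else:
            cent[i] = r.ca
    h = np.array(
        [p.hydrophobicity_scale.get(r.res_name, 0.0) for r in s.residues]
    )
    q = np.array([p.residue_charges.get(r.res_name, 0.0) for r in s.residues])
    chain_ids = {c: i for i, c in enumerate(dict.fromkeys(r.chain_id for r in s.residues))}
    chain_idx = np.array([chain_ids[r.chain_id] for r in s.residues])
    res_num = np.array([r.res_number for r in s.residues])
    het_xyz = (
        np.array([b.coord for b in s.hetero]).reshape(-1, 3)
        if s.hetero
        else np.zeros((0, 3))
    )
    het_q = np.array([b.charge for b in s.hetero], dtype=float)
    het_sigma = np.array(
        [b.radius + 0.5 * p.contact_radius for b in s.hetero], dtype=float
    )
    names = [f"{r.chain_id}:{r.res_number}{r.insertion_code}" for r in s.residues]
    return SimpleNamespace(
        ca=ca, cent=cent, has_cent=has_cent, h=h, q=q,
        chain_idx=chain_idx, res_num=res_num,
        het_xyz=het_xyz, het_q=het_q, het_sigma=het_sigma,
        names=names,
    )


def _sep_mask(chain_idx: np.ndarray, res_num: np.ndarray, min_sep: int) -> np.ndarray:
    """Upper-triangular mask of pairs satisfying the sequence-separation rule."""
    same_chain = chain_idx[:, None] == chain_idx[None, :]
    sep = np.abs(res_num[:, None] - res_num[None, :])
    ok = ~same_chain | (sep >= min_sep)
    n = len(chain_idx)
    return ok & np.triu(np.ones((n, n), dtype=bool), k=1)


def _contact_raw(r: np.ndarray, sigma, eps: float, grad: bool):
    """Clamped attractive 8-6 well and (optionally) its radial derivative."""
    x6 = (sigma / r) ** 6
    x8 = (sigma / r) ** 8
    raw = eps * (x8 - 2.0 * x6)
    neg = raw < 0.0
    e = np.where(neg, raw, 0.0)
    if not grad:
        return e, None
    draw = eps * (-8.0 * x8 + 12.0 * x6) / r
    return e, np.where(neg, draw, 0.0)


def _energy_arrays(
    A: SimpleNamespace, p: EnergyParams, grad: bool = False
):
    """Evaluate all terms on flattened arrays; optionally return gradients.

    Returns ``(breakdown, g_ca, g_ib)`` where the gradient arrays are
    ``None`` unless ``grad`` is true.  ``g_ib`` is the gradient with
    respect to the interaction bead (centroid, or Cα fallback).
    """
    ca, cent = A.ca, A.cent
    for arr, which in ((ca, "CA"), (cent, "centroid"), (A.het_xyz, "hetero")):
        if arr.size and not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0][0]
            name = A.names[bad] if which != "hetero" else f"hetero[{bad}]"
            raise EnergyEvaluationError(
                f"non-finite {which} coordinate at bead {name}"
            )
    ib = cent  # build_arrays already substitutes CA where no centroid exists
    n = len(ca)
    g_ca = np.zeros_like(ca) if grad else None
    g_ib = np.zeros_like(ib) if grad else None

    # --- membrane burial -------------------------------------------------
    f = slab_occupancy(ib[:, 2], p)
    e_burial = float(np.sum(A.h * f))
    if grad:
        g_ib[:, 2] += A.h * _slab_occupancy_grad(ib[:, 2], p)

    tiny = 1e-8

    def accumulate(g, coords, dEdr, iu, ju, rv, dv):
        # force along the pair axis; dv = coords[i]-coords[j], rv = |dv|
        fvec = (dEdr / rv)[:, None] * dv
        np.add.at(g, iu, fvec)
        np.add.at(g, ju, -fvec)

    # --- protein pair terms over interaction beads -----------------------
    e_elec = 0.0
    e_contact = 0.0
    if n > 1:
        mask = _sep_mask(A.chain_idx, A.res_num, p.min_seq_separation)
        iu, ju = np.nonzero(mask)
        dv = ib[iu] - ib[ju]
        rv = np.maximum(np.linalg.norm(dv, axis=1), tiny)
        within = rv <= p.pair_cutoff
        iu, ju, dv, rv = iu[within], ju[within], dv[within], rv[within]
        if len(rv):
            S, dS = _switch(rv, p)
            qq = A.q[iu] * A.q[ju]
            rc = np.maximum(rv, p.elec_r_min)
            eps_r = p.dielectric_eps0 + p.dielectric_slope * rc
            u = 1.0 / (rc * eps_r)
            e_pair = COULOMB * qq * u
            e_elec = float(np.sum(e_pair * S))
            craw, dcraw = _contact_raw(rv, p.contact_radius, p.contact_epsilon, grad)
            e_contact = float(np.sum(craw * S))
            if grad:
                du = np.where(
                    rv > p.elec_r_min,
                    -(p.dielectric_eps0 + 2.0 * p.dielectric_slope * rc) * u**2,
                    0.0,
                )
                dEdr = COULOMB * qq * (du * S + u * dS) + dcraw * S + craw * dS
                accumulate(g_ib, ib, dEdr, iu, ju, rv, dv)

    # --- excluded volume over CA beads and side-chain beads ---------------
    e_excl = 0.0
    if n > 1:
        mask = _sep_mask(A.chain_idx, A.res_num, p.min_seq_separation)
        for coords, g_arr in ((ca, g_ca), (ib, g_ib)):
            iu, ju = np.nonzero(mask)
            dv = coords[iu] - coords[ju]
            rv = np.maximum(np.linalg.norm(dv, axis=1), tiny)
            close = rv < p.repulsion_radius
            iu, ju, dv, rv = iu[close], ju[close], dv[close], rv[close]
            if len(rv):
                e_excl += float(
                    np.sum(p.repulsion_k * (p.repulsion_radius - rv) ** 2)
                )
                if grad:
                    dEdr = -2.0 * p.repulsion_k * (p.repulsion_radius - rv)
                    accumulate(g_arr, coords, dEdr, iu, ju, rv, dv)

    # --- ligand interaction: hetero beads vs residue beads ----------------
    e_lig = 0.0
    if len(A.het_xyz):
        dv = A.het_xyz[:, None, :] - ib[None, :, :]  # (m, n, 3)
        rv = np.maximum(np.linalg.norm(dv, axis=2), tiny)
        within = rv <= p.pair_cutoff
        bi, ri = np.nonzero(within)
        d = dv[bi, ri]
        r = rv[bi, ri]
        if len(r):
            S, dS = _switch(r, p)
            qq = A.het_q[bi] * A.q[ri]
            rc = np.maximum(r, p.elec_r_min)
            eps_r = p.dielectric_eps0 + p.dielectric_slope * rc
            u = 1.0 / (rc * eps_r)
            e_pair = COULOMB * qq * u
            craw, dcraw = _contact_raw(r, A.het_sigma[bi], p.contact_epsilon, grad)
            e_lig = float(np.sum((e_pair + craw) * S))
            if grad:
                du = np.where(
                    r > p.elec_r_min,
                    -(p.dielectric_eps0 + 2.0 * p.dielectric_slope * rc) * u**2,
                    0.0,
                )
                dEdr = COULOMB * qq * (du * S + u * dS) + dcraw * S + craw * dS
                # hetero beads are rigid; only the residue bead feels the force
                fvec = (dEdr / r)[:, None] * d
                np.add.at(g_ib, ri, -fvec)

    breakdown = EnergyBreakdown.from_terms(
        e_burial, e_elec, e_contact, e_excl, e_lig
    )
    return breakdown, g_ca, g_ib


def evaluate_energy(s: CGStructure, p: EnergyParams) -> EnergyBreakdown:
    """Evaluate the CG energy of a structure, term by term (kcal/mol)."""
    A = build_arrays(s, p)
    breakdown, _, _ = _energy_arrays(A, p, grad=False)
    return breakdown


def relative_energy(
    frame: CGStructure, reference: CGStructure, p: EnergyParams
) -> float:
    """Total energy of ``frame`` minus that of ``reference`` (kcal/mol)."""
    return evaluate_energy(frame, p).total - evaluate_energy(reference, p).total
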