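"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops over bead pairs,
deliberately sharing no code with the package's vectorised evaluator.
"""

from __future__ import annotations

import math


def _f_slab(z, zmin, zmax, taper=6.0):
    if z < zmin:
        d = zmin - z
    elif z > zmax:
        d = z - zmax
    else:
        d = 0.0
    if d >= taper:
        return 0.0
    return math.cos(math.pi * d / (2 * taper)) ** 2


def _switch(r, cutoff, width):
    r_on = cutoff - width
    if r <= r_on:
        return 1.0
    if r >= cutoff:
        return 0.0
    t = (r - r_on) / width
    return math.cos(0.5 * math.pi * t) ** 2


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_energy(structure, p) -> dict:
    """O(n²) reference evaluation of every energy component."""
    res = structure.residues
    n = len(res)
    ib = [
        (r.centroid if r.centroid is not None else r.ca).tolist() for r in res
    ]
    ca = [r.ca.tolist() for r in res]
    h = [p.hydrophobicity_scale.get(r.res_name, 0.0) for r in res]
    q = [p.residue_charges.get(r.res_name, 0.0) for r in res]

    burial = sum(
        h[i] * _f_slab(ib[i][2], p.membrane_z_min, p.membrane_z_max)
        for i in range(n)
    )

    def sep_ok(i, j):
        if res[i].chain_id != res[j].chain_id:
            return True
        return abs(res[i].res_number - res[j].res_number) >= p.min_seq_separation

    elec = 0.0
    contact = 0.0
    excl = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if not sep_ok(i, j):
                continue
            r = _dist(ib[i], ib[j])
            if r <= p.pair_cutoff and r > 0:
                s = _switch(r, p.pair_cutoff, p.switch_width)
                rc = max(r, p.elec_r_min)
                elec += (
                    332.0637 * q[i] * q[j]
                    / (rc * (p.dielectric_eps0 + p.dielectric_slope * rc))
                    * s
                )
                x6 = (p.contact_radius / r) ** 6
                x8 = (p.contact_radius / r) ** 8
                raw = p.contact_epsilon * (x8 - 2 * x6)
                if raw < 0:
                    contact += raw * s
            for coords in (ca, ib):
                rr = _dist(coords[i], coords[j])
                if rr < p.repulsion_radius:
                    excl += p.repulsion_k * (p.repulsion_radius - rr) ** 2

    lig = 0.0
    for b in structure.hetero:
        bc = b.coord.tolist()
        sigma = b.radius + 0.5 * p.contact_radius
        for i in range(n):
            r = _dist(bc, ib[i])
            if r <= p.pair_cutoff and r > 0:
                s = _switch(r, p.pair_cutoff, p.switch_width)
                rc = max(r, p.elec_r_min)
                lig += (
                    332.0637 * b.charge * q[i]
                    / (rc * (p.dielectric_eps0 + p.dielectric_slope * rc))
                    * s
                )
                x6 = (sigma / r) ** 6
                x8 = (sigma / r) ** 8
                raw = p.contact_epsilon * (x8 - 2 * x6)
                if raw < 0:
                    lig += raw * s

    return {
        "membrane_burial": burial,
        "electrostatic": elec,
        "contact": contact,
        "excluded_volume": excl,
        "ligand_interaction": lig,
        "total": burial + elec + contact + excl + lig,
    }


def brute_rmsd(a_coords, b_coords) -> float:
    """Plain RMSD of two coordinate lists (no superposition)."""
    assert len(a_coords) == len(b_coords)
    return math.sqrt(
        sum(_dist(x, y) ** 2 for x, y in zip(a_coords, b_coords)) / len(a_coords)
    )


def reverse_barriers(s, G) -> list[float]:
    """Barriers of the reversed profile, located by exhaustive search.

    For each interior maximum of the reversed series, the barrier is the
    value minus the lowest preceding minimum-candidate — evaluated on
    the raw reversed arrays with simple scans.
    """
    Gr = list(reversed(G))
    out = []
    for k in range(1, len(Gr) - 1):
        if Gr[k] > Gr[k - 1] and Gr[k] > Gr[k + 1]:
            # preceding local minimum in the reversed series
            j = k - 1
            while j > 0 and not (Gr[j] < Gr[j - 1] and Gr[j] < Gr[j + 1]):
                j -= 1
            out.append(Gr[k] - Gr[j])
    return out
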