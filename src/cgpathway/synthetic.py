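"""Synthetic two-state membrane proteins and analytic free-energy
landscapes with known ground truth.

The toy protein is an ideal antiparallel two-helix hairpin (helical
rise 1.5 Å, 100° twist per residue, Cβ-like side-chain beads 1.53 Å
from the Cα).  Its "activation" consists of the two motion classes the
pipeline analyses: a collective hinge rotation of the second helix
about the loop, and a discrete rotamer switch of one designated
residue whose side-chain bead points radially outward ("flattened") in
the inactive state and along the membrane normal ("vertical") in the
active state.  Every residue that differs between the two states is
book-kept, so tests can assert exactly which coordinates moved.

Analytic landscapes are sums of Gaussian wells and bumps on s ∈ [0, 1];
their stationary points are located at construction by a dense-grid
search refined to ~1e-10, giving closed-form-grade ground truth for
barrier-detection tests.  The default triple-well mimics the
three-transition-state shape of a GPCR activation profile, with
barriers on the scale seen for chemokine-receptor activation
(roughly 12, 4 and 7 kcal/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .energy import EnergyParams
from .errors import ParameterError
from .morph import MorphConfig, PathwayEnsemble
from .profiles import FreeEnergyProfile
from .structures import (
    CGStructure,
    Residue,
    ResidueKey,
    pair_residues,
    rmsd_after_superposition,
    superpose,
)

_PALETTE = [
    "LEU", "ILE", "VAL", "PHE", "MET", "SER", "THR", "TYR",
    "LYS", "ASP", "GLU", "ARG", "ASN", "GLN", "ALA",
]

_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_CB_DIST = 1.53


@dataclass(eq=False)
class ToyTwoState:
    """A synthetic inactive/active endpoint pair with known ground truth."""

    inactive: CGStructure
    active: CGStructure
    moving_residues: list[ResidueKey]
    switch_residue: ResidueKey
    hinge_angle: float
    seed: int


def _rot_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def make_toy_two_state(
    n_res: int,
    hinge_angle: float,
    seed: int = 0,
    switch_flip: bool = True,
) -> ToyTwoState:
    """Build a two-helix hairpin and its hinge-rotated active state.

    ``hinge_angle`` (degrees) rotates the second helix about an in-plane
    axis through the loop midpoint; ``switch_flip`` controls whether the
    designated switch residue's side-chain bead is re-oriented in the
    active state.  The residue sequence is drawn deterministically from
    the seed; the switch residue is always a tryptophan.
    """
    if n_res < 12:
        raise ParameterError("toy two-state needs n_res >= 12")
    rng = np.random.default_rng(seed)
    names = [str(rng.choice(_PALETTE)) for _ in range(n_res)]
    n1 = n_res // 2
    switch_idx = n1 // 2
    names[switch_idx] = "TRP"

    z0 = _HELIX_RISE * (n1 - 1) / 2.0  # centre the hairpin on the slab mid-plane
    residues: list[Residue] = []
    for i in range(n_res):
        theta = _HELIX_TWIST * i
        if i < n1:
            axis_xy = np.array([0.0, 0.0])
            z = _HELIX_RISE * i - z0
        else:
            axis_xy = np.array([10.0, 0.0])
            z = _HELIX_RISE * (n_res - 1 - i) - z0
        xy = axis_xy + _HELIX_RADIUS * np.array([np.cos(theta), np.sin(theta)])
        ca = np.array([xy[0], xy[1], z])
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        centroid = ca + _CB_DIST * radial
        residues.append(
            Residue(
                chain_id="A",
                res_number=i + 1,
                insertion_code="",
                res_name=names[i],
                ca=ca,
                centroid=centroid,
                n_sidechain_atoms=1,
            )
        )
    inactive = CGStructure(residues=residues, label="toy-inactive")

    active = inactive.copy()
    active.label = "toy-active"
    pivot = 0.5 * (inactive.residues[n1 - 1].ca + inactive.residues[n1].ca)
    R = _rot_x(hinge_angle)
    for r in active.residues[n1:]:
        r.ca = R @ (r.ca - pivot) + pivot
        r.centroid = R @ (r.centroid - pivot) + pivot
    if switch_flip:
        sw = active.residues[switch_idx]
        sw.centroid = sw.ca + _CB_DIST * np.array([0.0, 0.0, 1.0])

    return ToyTwoState(
        inactive=inactive,
        active=active,
        moving_residues=[r.key for r in inactive.residues[n1:]],
        switch_residue=inactive.residues[switch_idx].key,
        hinge_angle=hinge_angle,
        seed=seed,
    )


@dataclass(eq=False)
class AnalyticLandscape:
    """Closed-form landscape G(s) = Σ bumps − Σ wells (Gaussians), G(0) = 0."""

    kind: str
    wells: list[tuple[float, float]]  # (centre, depth)
    bumps: list[tuple[float, float]]  # (centre, height)
    width: float
    stationary_s: np.ndarray = field(init=False)
    stationary_G: np.ndarray = field(init=False)
    stationary_kind: list[str] = field(init=False)

    def _raw(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        g = np.zeros_like(s)
        for c, d in self.wells:
            g = g - d * np.exp(-((s - c) ** 2) / (2 * self.width**2))
        for c, h in self.bumps:
            g = g + h * np.exp(-((s - c) ** 2) / (2 * self.width**2))
        return g

    def __call__(self, s) -> np.ndarray | float:
        out = self._raw(np.asarray(s, dtype=float)) - self._raw(np.array(0.0))
        return float(out) if np.ndim(s) == 0 else out

    def __post_init__(self) -> None:
        expected_maxima = {"double_well": 1, "triple_well": 3}.get(self.kind)
        if expected_maxima is None:
            raise ParameterError(f"unknown landscape kind {self.kind!r}")
        grid = np.linspace(0.0, 1.0, 100001)
        g = self._raw(grid)
        d = np.diff(g)
        sign = np.sign(d)
        s_pts: list[float] = []
        g_pts: list[float] = []
        kinds: list[str] = []
        for i in range(1, len(sign)):
            if sign[i] == sign[i - 1] or sign[i] == 0:
                continue
            kind = "max" if sign[i - 1] > 0 else "min"
            lo, hi = grid[max(i - 2, 0)], grid[min(i + 1, len(grid) - 1)]
            obj = (lambda x: -self._raw(np.array(x))) if kind == "max" else (
                lambda x: self._raw(np.array(x))
            )
            res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-12})
            s_pts.append(float(res.x))
            g_pts.append(float(self(res.x)))
            kinds.append(kind)
        n_max = sum(1 for k in kinds if k == "max")
        if n_max != expected_maxima:
            raise ParameterError(
                f"{self.kind} parameters produce {n_max} interior maxima "
                f"(expected {expected_maxima}); wells have merged"
            )
        # boundary wells: endpoints count as minima when the landscape
        # rises away from them (profiles treat endpoints the same way)
        if g[1] > g[0]:
            s_pts.insert(0, 0.0)
            g_pts.insert(0, 0.0)
            kinds.insert(0, "min")
        if g[-2] > g[-1]:
            s_pts.append(1.0)
            g_pts.append(float(self(1.0)))
            kinds.append("min")
        self.stationary_s = np.array(s_pts)
        self.stationary_G = np.array(g_pts)
        self.stationary_kind = kinds

    def true_barriers(self) -> list[float]:
        """ΔG‡ of each interior maximum over the preceding minimum.

        The s=0 endpoint acts as the first minimum (the landscape is
        anchored there), matching how profiles are analysed.
        """
        barriers = []
        last_min_G = 0.0
        for sp, gp, kind in zip(
            self.stationary_s, self.stationary_G, self.stationary_kind
        ):
            if kind == "min":
                last_min_G = gp
            else:
                barriers.append(gp - last_min_G)
        return barriers


_DEFAULTS = {
    "double_well": dict(
        wells=[(0.2, 3.0), (0.8, 3.0)],
        bumps=[(0.5, 3.0)],
        width=0.09,
    ),
    "triple_well": dict(
        wells=[(0.0, 2.0), (0.36, 4.0), (0.62, 3.0), (1.0, 5.0)],
        bumps=[(0.17, 11.0), (0.48, 1.5), (0.82, 4.5)],
        width=0.055,
    ),
}


def analytic_landscape(kind: str, params: Mapping | None = None) -> AnalyticLandscape:
    """Construct a double- or triple-well landscape (defaults provided)."""
    if kind not in _DEFAULTS:
        raise ParameterError(f"unknown landscape kind {kind!r}")
    cfg = dict(_DEFAULTS[kind])
    if params:
        cfg.update(params)
    return AnalyticLandscape(kind=kind, **cfg)


def sample_profile(
    L: AnalyticLandscape, n: int, noise_sd: float = 0.0, seed: int = 0
) -> FreeEnergyProfile:
    """Evaluate a landscape on a uniform grid with optional Gaussian noise."""
    if n < 3:
        raise ParameterError("sample_profile needs n >= 3")
    s = np.linspace(0.0, 1.0, n)
    G = L(s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        G = G + rng.normal(0.0, noise_sd, n)
    G = G - G[0]
    G[0] = 0.0
    return FreeEnergyProfile(s=s, G=G, system_label=f"analytic-{L.kind}")


def make_interpolating_morph_fn(
    lifts: Mapping[ResidueKey, float] | None = None,
) -> Callable[[CGStructure, CGStructure, EnergyParams, MorphConfig], PathwayEnsemble]:
    """Deterministic straight-line pathway generator with optional planted
    side-chain excursions.

    Returns a drop-in replacement for ``targeted_morph`` that linearly
    interpolates the superposed endpoints over ``cfg.n_steps`` frames.
    For each residue key in ``lifts``, the side-chain bead is displaced
    along +z by ``height·sin²(πt)`` — a transition-region excursion that
    peaks at mid-path and vanishes at both endpoints.  This plants a
    known per-residue membrane-burial contribution into the
    transition-state region, giving alanine-scanning tests an exact
    expected ΔΔG‡.
    """
    lifts = dict(lifts or {})

    def morph_fn(
        start: CGStructure,
        target: CGStructure,
        p: EnergyParams,
        cfg: MorphConfig,
    ) -> PathwayEnsemble:
        pairing = pair_residues(start, target)
        sup = superpose(target, start, pair_residues(target, start))
        target_al = target.transformed(sup.rotation, sup.translation)
        jmap = dict(pairing.pairs)
        frames: list[CGStructure] = []
        ts = np.linspace(0.0, 1.0, cfg.n_steps)
        for t in ts:
            f = start.copy()
            for i, r in enumerate(f.residues):
                j = jmap.get(i)
                if j is None:
                    continue
                rt = target_al.residues[j]
                r.ca = (1 - t) * start.residues[i].ca + t * rt.ca
                if r.centroid is not None and rt.centroid is not None:
                    r.centroid = (
                        (1 - t) * start.residues[i].centroid + t * rt.centroid
                    )
            for key, height in lifts.items():
                idx = f.index_of(key)
                c = f.residues[idx].centroid
                if c is None:
                    raise ParameterError(f"lift site {key} has no side-chain bead")
                c[2] += height * np.sin(np.pi * t) ** 2
            frames.append(f)
        d0 = [rmsd_after_superposition(fr, start, include_sidechains=True) for fr in frames]
        d1 = [rmsd_after_superposition(fr, target, include_sidechains=True) for fr in frames]
        # the interpolation parameter IS the ground-truth progress here:
        # a large planted excursion would otherwise dominate the RMSD
        # ratio and pin it near 1/2 through the transition region
        return PathwayEnsemble(
            frames=frames,
            s=[float(t) for t in ts],
            rmsd_to_start=d0,
            rmsd_to_target=d1,
            endpoints=(start.label, target.label),
        )

    return morph_fn
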