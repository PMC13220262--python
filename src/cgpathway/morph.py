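"""Activation-pathway generation by steered relaxation.

A desk-scale surrogate for targeted molecular dynamics: the mobile
beads descend the CG energy under a harmonic RMSD-to-target restraint
½·k_steer·(R − ρ)² whose centre ρ is scheduled linearly from the
start-target RMSD down to 0, exactly the restraint protocol that
defines targeted MD.  There is no thermostat and no explicit membrane;
relaxation is plain gradient descent with a bounded per-move
displacement and optional seeded Gaussian coordinate noise.

The progress coordinate along the resulting path is
``s = d0 / (d0 + d1)`` with d0/d1 the RMSD of a frame to the
start/target endpoint over all beads (Cα plus side-chain centroids,
after a Cα fit): dimensionless, symmetric, 0 at the start and 1 at
the target.  Side-chain beads are included so that rotamer
rearrangements register as progress; a Cα-only metric saturates once
the backbone has converged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np

from .energy import EnergyParams, build_arrays, _energy_arrays
from .errors import (
    DegenerateEndpointsError,
    MorphConvergenceError,
    PairingError,
    ParameterError,
)
from .structures import (
    CGStructure,
    ResidueKey,
    pair_residues,
    rmsd_after_superposition,
    superpose,
)

logger = logging.getLogger("cgpathway")


@dataclass
class MorphConfig:
    """Knobs of the steered relaxation.

    ``restrained_selection`` is a small selection language: ``"hetero"``
    (default — ligand/sterol beads held rigid), ``"none"``, or
    ``"hetero+A:35,A:36"`` to additionally freeze residues by
    chain:number.
    """

    n_steps: int = 120
    k_steer: float = 1000.0
    relax_iters: int = 40
    step_size: float = 0.02
    noise_sd: float = 0.0
    seed: int = 0
    restrained_selection: str = "hetero"
    convergence_tol: float = 0.15
    k_tether: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_steps < 2:
            raise ParameterError("n_steps must be >= 2")
        if self.k_steer <= 0:
            raise ParameterError("k_steer must be > 0")
        if self.convergence_tol <= 0:
            raise ParameterError("convergence_tol must be > 0")
        if self.relax_iters < 1:
            raise ParameterError("relax_iters must be >= 1")
        if self.step_size <= 0:
            raise ParameterError("step_size must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.k_tether < 0:
            raise ParameterError("k_tether must be >= 0")

    def restrained_residue_keys(self) -> set[tuple[str, int]]:
        """Residues (chain, number) frozen in place by the selection string."""
        keys: set[tuple[str, int]] = set()
        for token in self.restrained_selection.replace("+", ",").split(","):
            token = token.strip()
            if token in ("", "hetero", "none"):
                continue
            try:
                chain, num = token.split(":")
                keys.add((chain, int(num)))
            except ValueError as exc:
                raise ParameterError(
                    f"bad restrained_selection token {token!r}; "
                    f"expected chain:resnum"
                ) from exc
        return keys

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MorphConfig":
        return cls(**dict(d))


@dataclass(eq=False)
class PathwayEnsemble:
    """Ordered conformational frames with progress values s ∈ [0, 1]."""

    frames: list[CGStructure]
    s: list[float]
    rmsd_to_start: list[float]
    rmsd_to_target: list[float]
    endpoints: tuple[str, str]

    def __post_init__(self) -> None:
        n = len(self.frames)
        if not (len(self.s) == len(self.rmsd_to_start) == len(self.rmsd_to_target) == n):
            raise ValueError("pathway field lengths disagree")
        if n == 0:
            raise ValueError("empty pathway")
        if self.s[0] != 0.0:
            raise ValueError("s[0] must be 0")
        if n > 1 and self.s[-1] != 1.0:
            raise ValueError("s[-1] must be 1")
        diffs = np.diff(self.s)
        if len(diffs) and diffs.min() < -1e-6:
            raise ValueError("progress coordinate decreases beyond tolerance")

    def __len__(self) -> int:
        return len(self.frames)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("frame\ts\trmsd_to_start\trmsd_to_target\n")
            for i in range(len(self.frames)):
                fh.write(
                    f"{i}\t{self.s[i]:.10g}\t{self.rmsd_to_start[i]:.10g}"
                    f"\t{self.rmsd_to_target[i]:.10g}\n"
                )


def progress_coordinate(
    frame: CGStructure, start: CGStructure, target: CGStructure
) -> float:
    """s = d0/(d0+d1), the RMSD-ratio progress of a frame between endpoints."""
    if rmsd_after_superposition(start, target) < 1e-9:
        raise DegenerateEndpointsError(
            "progress coordinate undefined: start and target coincide"
        )
    d0 = rmsd_after_superposition(frame, start, include_sidechains=True)
    d1 = rmsd_after_superposition(frame, target, include_sidechains=True)
    if d0 < 1e-12:
        return 0.0
    if d1 < 1e-12:
        return 1.0
    return d0 / (d0 + d1)


def _direct_rmsd(x: np.ndarray, t: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((x - t) ** 2, axis=1))))


def relax_structure(
    s: CGStructure,
    p: EnergyParams,
    iters: int = 200,
    step_size: float = 0.02,
    k_tether: float = 100.0,
) -> CGStructure:
    """Unrestrained energy descent of a structure (hetero beads fixed).

    Used to settle endpoints onto the CG energy surface before morphing,
    so profiles score relaxed frames and the first morph step does not
    mix steering with a large relaxation jump.  Deterministic.
    """
    A = build_arrays(s, p)
    ca = A.ca.copy()
    cent = A.cent.copy()
    has_cent = A.has_cent
    tether_len = np.where(has_cent, np.linalg.norm(cent - ca, axis=1), 0.0)
    for _ in range(iters):
        A.ca, A.cent = ca, cent
        _, g_ca, g_ib = _energy_arrays(A, p, grad=True)
        g_tot_ca = g_ca + np.where(has_cent[:, None], 0.0, g_ib)
        g_tot_cent = np.where(has_cent[:, None], g_ib, 0.0)
        if k_tether > 0:
            dvec = cent - ca
            L = np.maximum(np.linalg.norm(dvec, axis=1), 1e-9)
            coef = np.where(has_cent, k_tether * (L - tether_len) / L, 0.0)
            g_tot_cent += coef[:, None] * dvec
            g_tot_ca -= coef[:, None] * dvec
        gmax = max(
            float(np.max(np.linalg.norm(g_tot_ca, axis=1), initial=0.0)),
            float(np.max(np.linalg.norm(g_tot_cent, axis=1), initial=0.0)),
        )
        if gmax < 1e-10:
            break
        eta = step_size / max(1.0, gmax)
        ca = ca - eta * g_tot_ca
        cent = cent - eta * g_tot_cent
        cent[~has_cent] = ca[~has_cent]
    return _rebuild(s, ca, cent)


def targeted_morph(
    start: CGStructure,
    target: CGStructure,
    p: EnergyParams,
    cfg: MorphConfig,
) -> PathwayEnsemble:
    """Morph ``start`` into ``target`` under a scheduled RMSD restraint.

    The target is first superposed onto the start so steering acts in a
    common frame.  Frame 0 is the start itself; the last frame, once the
    restraint has converged to within ``cfg.convergence_tol``, is set to
    the target conformation exactly (restrained beads keep their start
    coordinates throughout).
    """
    pairing = pair_residues(start, target)
    coverage = len(pairing.pairs) / max(len(start), len(target))
    if coverage < 0.9:
        raise PairingError(
            f"residue pairing covers only {coverage:.0%} of residues (need 90%)"
        )
    sup = superpose(target, start, pair_residues(target, start))
    target_al = target.transformed(sup.rotation, sup.translation)

    A = build_arrays(start, p)
    n = len(start)
    ca = A.ca.copy()
    cent = A.cent.copy()
    has_cent = A.has_cent
    tether_len = np.where(
        has_cent, np.linalg.norm(cent - ca, axis=1), 0.0
    )

    # steering targets (indices into start) --------------------------------
    t_ca = np.zeros_like(ca)
    t_cent = np.zeros_like(cent)
    m_ca = np.zeros(n, dtype=bool)
    m_cent = np.zeros(n, dtype=bool)
    for i, j in pairing.pairs:
        rj = target_al.residues[j]
        t_ca[i] = rj.ca
        m_ca[i] = True
        if has_cent[i] and rj.centroid is not None:
            t_cent[i] = rj.centroid
            m_cent[i] = True

    # frozen beads ---------------------------------------------------------
    frozen_keys = cfg.restrained_residue_keys()
    frozen = np.array(
        [(r.chain_id, r.res_number) in frozen_keys for r in start.residues]
    )
    m_ca &= ~frozen
    m_cent &= ~frozen
    mobile_ca = ~frozen
    mobile_cent = has_cent & ~frozen

    n_steer = int(m_ca.sum() + m_cent.sum())
    if n_steer == 0:
        raise PairingError("no steerable beads after applying restraints")

    def steer_rmsd(ca_, cent_) -> float:
        sq = np.sum((ca_[m_ca] - t_ca[m_ca]) ** 2) + np.sum(
            (cent_[m_cent] - t_cent[m_cent]) ** 2
        )
        return float(np.sqrt(sq / n_steer))

    r0 = steer_rmsd(ca, cent)
    if r0 < 1e-9:
        logger.info("start and target coincide; returning a single-frame path")
        return PathwayEnsemble(
            frames=[start.copy()],
            s=[0.0],
            rmsd_to_start=[0.0],
            rmsd_to_target=[0.0],
            endpoints=(start.label, target.label),
        )

    rng = np.random.default_rng(cfg.seed)
    frames_xyz: list[tuple[np.ndarray, np.ndarray]] = [(ca.copy(), cent.copy())]

    for step in range(1, cfg.n_steps):
        rho = r0 * (1.0 - step / (cfg.n_steps - 1))
        for _ in range(cfg.relax_iters):
            A.ca, A.cent = ca, cent
            _, g_ca, g_ib = _energy_arrays(A, p, grad=True)
            g_tot_ca = g_ca + np.where(has_cent[:, None], 0.0, g_ib)
            g_tot_cent = np.where(has_cent[:, None], g_ib, 0.0)
            if cfg.k_tether > 0:
                dvec = cent - ca
                L = np.maximum(np.linalg.norm(dvec, axis=1), 1e-9)
                coef = np.where(
                    has_cent, cfg.k_tether * (L - tether_len) / L, 0.0
                )
                g_tot_cent += coef[:, None] * dvec
                g_tot_ca -= coef[:, None] * dvec
            R = steer_rmsd(ca, cent)
            if R > 1e-12:
                coeff = cfg.k_steer * (R - rho) / (n_steer * R)
                g_tot_ca[m_ca] += coeff * (ca[m_ca] - t_ca[m_ca])
                g_tot_cent[m_cent] += coeff * (cent[m_cent] - t_cent[m_cent])
            g_tot_ca[~mobile_ca] = 0.0
            g_tot_cent[~mobile_cent] = 0.0
            gmax = max(
                float(np.max(np.linalg.norm(g_tot_ca, axis=1), initial=0.0)),
                float(np.max(np.linalg.norm(g_tot_cent, axis=1), initial=0.0)),
            )
            eta = cfg.step_size / max(1.0, gmax)
            ca = ca - eta * g_tot_ca
            cent = cent - eta * g_tot_cent
            if cfg.noise_sd > 0:
                noise_ca = rng.normal(0.0, cfg.noise_sd, ca.shape)
                noise_cent = rng.normal(0.0, cfg.noise_sd, cent.shape)
                noise_ca[~mobile_ca] = 0.0
                noise_cent[~mobile_cent] = 0.0
                ca = ca + noise_ca
                cent = cent + noise_cent
            cent[~has_cent] = ca[~has_cent]
        frames_xyz.append((ca.copy(), cent.copy()))

    achieved = steer_rmsd(ca, cent)
    if achieved > cfg.convergence_tol:
        raise MorphConvergenceError(
            f"morph did not converge: final steered RMSD {achieved:.3f} Å "
            f"> tolerance {cfg.convergence_tol} Å",
            achieved_rmsd=achieved,
        )
    # snap the terminal frame onto the target so the path ends exactly there
    ca, cent = frames_xyz[-1]
    ca[m_ca] = t_ca[m_ca]
    cent[m_cent] = t_cent[m_cent]
    cent[~has_cent] = ca[~has_cent]
    frames_xyz[-1] = (ca, cent)

    frames = [_rebuild(start, xc, cc) for xc, cc in frames_xyz]
    d0 = [rmsd_after_superposition(f, start, include_sidechains=True) for f in frames]
    d1 = [rmsd_after_superposition(f, target, include_sidechains=True) for f in frames]
    s = [a / (a + b) if (a + b) > 0 else 0.0 for a, b in zip(d0, d1)]
    s[0], s[-1] = 0.0, 1.0
    return PathwayEnsemble(
        frames=frames,
        s=s,
        rmsd_to_start=d0,
        rmsd_to_target=d1,
        endpoints=(start.label, target.label),
    )


def _rebuild(template: CGStructure, ca: np.ndarray, cent: np.ndarray) -> CGStructure:
    out = template.copy()
    for i, r in enumerate(out.residues):
        r.ca = ca[i].copy()
        if r.centroid is not None:
            r.centroid = cent[i].copy()
    return out


def extract_intermediates(path: PathwayEnsemble, n: int = 30) -> PathwayEnsemble:
    """Pick the frames nearest to a uniform grid of n progress values.

    Endpoints are always included; grid points mapping to the same frame
    are collapsed (with a warning), so the result can hold fewer than n
    frames on strongly non-uniform paths.
    """
    if n < 2:
        raise ParameterError("extract_intermediates needs n >= 2")
    s = np.asarray(path.s)
    grid = np.linspace(0.0, 1.0, n)
    idx = [int(np.argmin(np.abs(s - g))) for g in grid]
    idx[0], idx[-1] = 0, len(s) - 1
    unique: list[int] = []
    for i in sorted(set(idx)):
        if unique and s[i] <= s[unique[-1]]:
            continue
        unique.append(i)
    if len(unique) < n:
        logger.warning(
            "uniform extraction collapsed %d duplicate frame(s); "
            "returning %d of %d requested",
            n - len(unique), len(unique), n,
        )
    return PathwayEnsemble(
        frames=[path.frames[i] for i in unique],
        s=[path.s[i] for i in unique],
        rmsd_to_start=[path.rmsd_to_start[i] for i in unique],
        rmsd_to_target=[path.rmsd_to_target[i] for i in unique],
        endpoints=path.endpoints,
    )
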