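"""In-silico mutagenesis: alanine scanning and side-chain rotamer
transfer, with per-transition-state ΔΔG‡ reporting.

ΔΔG‡ = ΔG‡_mutant − ΔG‡_WT per transition state, the convention being
that a positive value means the mutation raises the activation barrier
(inhibits activation) and a negative value lowers it (facilitates).
Mutations are applied to BOTH endpoints and the full pathway pipeline
is re-run with the same seed, so each mutant has its own morph;
transition states are matched to the wild-type ones by rank order
along the progress coordinate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .energy import EnergyParams
from .errors import CGPathwayError, MutationError
from .morph import (
    MorphConfig,
    PathwayEnsemble,
    extract_intermediates,
    relax_structure,
    targeted_morph,
)
from .profiles import (
    FreeEnergyProfile,
    StationaryReport,
    build_profile,
    find_stationary_points,
    smooth_profile,
)
from .structures import CGStructure, ResidueKey, superpose, pair_residues

logger = logging.getLogger("cgpathway")

#: Cβ distance used when truncating a side chain to alanine (Å).
ALA_CB_DISTANCE = 1.52


@dataclass(frozen=True)
class MutationSpec:
    """A mutation site: alanine truncation or rotamer transfer."""

    chain_id: str
    res_number: int
    insertion_code: str = ""
    mode: str = "ALA"  # "ALA" | "ROTAMER_FROM_REFERENCE"
    reference_label: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("ALA", "ROTAMER_FROM_REFERENCE"):
            raise MutationError(f"unknown mutation mode {self.mode!r}")
        if self.mode == "ROTAMER_FROM_REFERENCE" and not self.reference_label:
            raise MutationError("rotamer transfer requires a reference_label")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_number, self.insertion_code)


def mutate_to_ala(s: CGStructure, site: MutationSpec) -> CGStructure:
    """Truncate one residue's side chain to an alanine Cβ bead.

    The side-chain bead is moved to 1.52 Å from the Cα along the
    original Cα→centroid direction and the residue renamed ALA, so the
    site picks up alanine's energy parameters.  Mutating an alanine is
    a warned no-op; glycine (no side-chain direction) is an error.
    """
    idx = s.index_of(site.key)  # KeyError if absent
    out = s.copy()
    r = out.residues[idx]
    if r.res_name == "GLY" or r.centroid is None:
        raise MutationError(
            f"cannot truncate {r.res_name} at {site.key}: no side-chain direction"
        )
    if r.res_name == "ALA":
        logger.warning("site %s is already alanine; mutation is a no-op", site.key)
        return out
    direction = r.centroid - r.ca
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise MutationError(f"degenerate side-chain direction at {site.key}")
    r.centroid = r.ca + ALA_CB_DISTANCE * direction / norm
    r.res_name = "ALA"
    r.n_sidechain_atoms = 1
    return out


def set_sidechain_from_reference(
    s: CGStructure, site: MutationSpec, ref: CGStructure
) -> CGStructure:
    """Transfer a side-chain rotamer from a reference conformation.

    The reference's local backbone window (site ± 2 residues, Cα only)
    is superposed onto the corresponding window of ``s``; the site's
    side-chain bead is then replaced by the transformed reference bead.
    Residue types must match; glycine is rejected.
    """
    idx = s.index_of(site.key)
    ridx = ref.index_of(site.key)
    r = s.residues[idx]
    rr = ref.residues[ridx]
    if r.res_name != rr.res_name:
        raise MutationError(
            f"residue type mismatch at {site.key}: "
            f"{r.res_name} vs {rr.res_name} in reference"
        )
    if r.res_name == "GLY" or r.centroid is None or rr.centroid is None:
        raise MutationError(f"no side-chain bead to transfer at {site.key}")

    window_keys = [
        s.residues[i].key
        for i in range(max(0, idx - 2), min(len(s), idx + 3))
    ]
    sub_s = CGStructure(
        [s.residues[s.index_of(k)].copy() for k in window_keys], label="win-s"
    )
    ref_keys = [k for k in window_keys if _has_key(ref, k)]
    sub_r = CGStructure(
        [ref.residues[ref.index_of(k)].copy() for k in ref_keys], label="win-r"
    )
    sup = superpose(sub_r, sub_s, pair_residues(sub_r, sub_s))
    out = s.copy()
    out.residues[idx].centroid = sup.rotation @ rr.centroid + sup.translation
    return out


def _has_key(s: CGStructure, key: ResidueKey) -> bool:
    try:
        s.index_of(key)
        return True
    except KeyError:
        return False


def classify(ddg: float, tau: float) -> str:
    if ddg > tau:
        return "inhibits"
    if ddg < -tau:
        return "facilitates"
    return "neutral"


@dataclass
class TSRecord:
    ts_label: str
    dg_wt: float | None
    dg_mut: float | None
    ddg: float | None
    classification: str | None


@dataclass
class MutationResult:
    site: MutationSpec
    ts_records: list[TSRecord]
    ts_count_mismatch: bool = False
    error: str | None = None


@dataclass(eq=False)
class DDGReport:
    """Per-mutation, per-TS activation-barrier changes."""

    results: list[MutationResult]
    tau: float
    wt_barriers: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            base = {
                "chain": res.site.chain_id,
                "res_number": res.site.res_number,
                "mode": res.site.mode,
                "error": res.error or "",
                "ts_count_mismatch": res.ts_count_mismatch,
            }
            if not res.ts_records:
                rows.append(base)
            for rec in res.ts_records:
                rows.append(
                    base
                    | {
                        "ts_label": rec.ts_label,
                        "dG_wt": rec.dg_wt,
                        "dG_mut": rec.dg_mut,
                        "ddG": rec.ddg,
                        "classification": rec.classification,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        counts: dict[str, dict[str, int]] = {}
        for res in self.results:
            for rec in res.ts_records:
                if rec.classification is None:
                    continue
                c = counts.setdefault(rec.ts_label, {})
                c[rec.classification] = c.get(rec.classification, 0) + 1
        return {
            "tau": self.tau,
            "wt_barriers": self.wt_barriers,
            "n_sites": len(self.results),
            "n_failed": sum(1 for r in self.results if r.error),
            "classification_counts": counts,
        }

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(
    start: CGStructure,
    target: CGStructure,
    p: EnergyParams,
    cfg: MorphConfig,
    n_intermediates: int = 30,
    smooth_window: int = 1,
    prominence_threshold: float = 0.5,
    morph_fn: Callable = targeted_morph,
    endpoint_relax_iters: int = 200,
) -> tuple[PathwayEnsemble, FreeEnergyProfile, StationaryReport]:
    """(relax endpoints) → morph → uniform extraction → profile →
    smoothing → stationary points."""
    if endpoint_relax_iters > 0:
        start = relax_structure(
            start, p, endpoint_relax_iters, cfg.step_size, cfg.k_tether
        )
        target = relax_structure(
            target, p, endpoint_relax_iters, cfg.step_size, cfg.k_tether
        )
    path = morph_fn(start, target, p, cfg)
    if len(path) > 1:
        path = extract_intermediates(path, n_intermediates)
    prof = build_profile(path, p)
    if smooth_window > 1 and smooth_window <= len(prof):
        prof = smooth_profile(prof, smooth_window)
    if len(prof) >= 3:
        report = find_stationary_points(prof, prominence_threshold)
    else:
        report = StationaryReport([], [], {}, None, prominence_threshold)
    return path, prof, report


def _apply_mutation(
    structure: CGStructure,
    site: MutationSpec,
    references: dict[str, CGStructure] | None,
) -> CGStructure:
    if site.mode == "ALA":
        return mutate_to_ala(structure, site)
    refs = references or {}
    if site.reference_label not in refs:
        raise MutationError(
            f"reference structure {site.reference_label!r} not supplied"
        )
    return set_sidechain_from_reference(structure, site, refs[site.reference_label])


def ddg_scan(
    start: CGStructure,
    target: CGStructure,
    sites: Sequence[MutationSpec],
    p: EnergyParams,
    cfg: MorphConfig,
    tau: float = 0.25,
    n_intermediates: int = 30,
    smooth_window: int = 1,
    prominence_threshold: float = 0.5,
    morph_fn: Callable = targeted_morph,
    references: dict[str, CGStructure] | None = None,
    endpoint_relax_iters: int = 200,
) -> DDGReport:
    """Alanine-scan (or rotamer-switch) ΔΔG‡ over a list of sites.

    The wild-type pipeline runs once; each mutant re-runs the identical
    pipeline (same seed and config) on mutated endpoints.  Transition
    states are matched by rank order along s; count mismatches are
    flagged and unmatched TS reported with missing values rather than
    imputed.  Pipeline failures for individual mutants are recorded and
    the scan continues.
    """
    _, _, wt_report = run_pipeline(
        start, target, p, cfg, n_intermediates, smooth_window,
        prominence_threshold, morph_fn, endpoint_relax_iters,
    )
    wt_barriers = wt_report.barriers
    wt_labels = [ts.label for ts in wt_report.maxima]

    results: list[MutationResult] = []
    for site in sites:
        try:
            mut_start = _apply_mutation(start, site, references)
            mut_target = _apply_mutation(target, site, references)
            _, _, mut_report = run_pipeline(
                mut_start, mut_target, p, cfg, n_intermediates,
                smooth_window, prominence_threshold, morph_fn,
                endpoint_relax_iters,
            )
        except (CGPathwayError, KeyError) as exc:
            logger.warning("site %s failed: %s", site.key, exc)
            results.append(
                MutationResult(site=site, ts_records=[], error=str(exc))
            )
            continue
        mut_labels = [ts.label for ts in mut_report.maxima]
        mismatch = len(mut_labels) != len(wt_labels)
        records: list[TSRecord] = []
        for k, wt_label in enumerate(wt_labels):
            dg_wt = wt_barriers[wt_label]
            if k < len(mut_labels):
                dg_mut = mut_report.barriers[mut_labels[k]]
                ddg = dg_mut - dg_wt
                records.append(
                    TSRecord(wt_label, dg_wt, dg_mut, ddg, classify(ddg, tau))
                )
            else:
                records.append(TSRecord(wt_label, dg_wt, None, None, None))
        results.append(
            MutationResult(site=site, ts_records=records, ts_count_mismatch=mismatch)
        )
    return DDGReport(results=results, tau=tau, wt_barriers=wt_barriers)
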