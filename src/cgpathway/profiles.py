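"""Free-energy profiles along the activation coordinate and their
stationary-point structure.

A profile is a (s, G) series in kcal/mol, zeroed at the first (inactive)
frame.  Stationary-point analysis labels alternating local minima
("Int1", "Int2", ...) and maxima ("TS1", "TS2", ...), computes the
activation barrier of each transition state relative to the preceding
minimum, and names the rate-limiting step — the TS with the largest
barrier (ties resolved toward the lower index).  Maxima whose barrier is
below a prominence threshold are treated as sampling jitter and merged
away.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .energy import EnergyParams, evaluate_energy
from .errors import ParameterError
from .morph import PathwayEnsemble

logger = logging.getLogger("cgpathway")


@dataclass(eq=False)
class FreeEnergyProfile:
    s: np.ndarray
    G: np.ndarray
    G_smoothed: np.ndarray | None = None
    system_label: str = ""
    endpoint_ids: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.G_smoothed is not None:
            self.G_smoothed = np.asarray(self.G_smoothed, dtype=float)
        if len(self.s) != len(self.G):
            raise ValueError("s and G lengths disagree")
        if len(self.s) == 0:
            raise ValueError("empty profile")
        if self.G[0] != 0.0:
            raise ValueError("G[0] must be exactly 0 (profile is anchored)")
        if len(self.s) > 1 and np.diff(self.s).min() <= 0:
            raise ValueError("s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.s)

    @property
    def values(self) -> np.ndarray:
        """The series stationary-point analysis should use."""
        return self.G if self.G_smoothed is None else self.G_smoothed

    def write_tsv(self, path) -> None:
        gs = self.G if self.G_smoothed is None else self.G_smoothed
        with open(path, "w") as fh:
            fh.write("s\tG_kcal_mol\tG_smoothed\n")
            for i in range(len(self.s)):
                fh.write(f"{self.s[i]:.10g}\t{self.G[i]:.10g}\t{gs[i]:.10g}\n")


@dataclass
class StationaryPoint:
    index: int
    s: float
    G: float
    label: str


@dataclass(eq=False)
class StationaryReport:
    """Alternating minima/maxima of a profile with per-TS barriers."""

    minima: list[StationaryPoint]
    maxima: list[StationaryPoint]
    barriers: dict[str, float]
    rate_limiting: str | None
    prominence_threshold: float

    def to_dict(self) -> dict:
        return {
            "minima": [vars(m) for m in self.minima],
            "maxima": [vars(m) for m in self.maxima],
            "barriers": self.barriers,
            "rate_limiting": self.rate_limiting,
            "prominence_threshold": self.prominence_threshold,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_profile(path: PathwayEnsemble, p: EnergyParams) -> FreeEnergyProfile:
    """Score every pathway frame relative to the first one."""
    totals = [evaluate_energy(f, p).total for f in path.frames]
    G = np.array(totals) - totals[0]
    G[0] = 0.0
    return FreeEnergyProfile(
        s=np.asarray(path.s, dtype=float),
        G=G,
        system_label=path.endpoints[0],
        endpoint_ids=path.endpoints,
    )


def smooth_profile(prof: FreeEnergyProfile, window: int) -> FreeEnergyProfile:
    """Centred moving average with symmetrically shrinking edge windows.

    The smoothed series is re-anchored so its first value is 0.
    """
    if window % 2 == 0 or window < 1:
        raise ParameterError("smoothing window must be odd and >= 1")
    n = len(prof)
    if window > n:
        raise ParameterError(f"window {window} exceeds profile length {n}")
    half = window // 2
    g = prof.G
    sm = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        sm[i] = g[i - k : i + k + 1].mean()
    sm = sm - sm[0]
    return FreeEnergyProfile(
        s=prof.s.copy(),
        G=prof.G.copy(),
        G_smoothed=sm,
        system_label=prof.system_label,
        endpoint_ids=prof.endpoint_ids,
    )


def _raw_extrema(y: np.ndarray) -> list[tuple[int, str]]:
    """Alternating (index, 'min'|'max') including endpoint candidates.

    Plateaus collapse to their midpoint index.  Endpoints enter as
    candidate minima only; an endpoint that would be a maximum is
    dropped.
    """
    n = len(y)
    # collapse exact plateaus to their midpoint index
    groups: list[list[int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        groups.append([i, j])
        i = j + 1
    mids = [(lo + hi) // 2 for lo, hi in groups]
    vals = np.array([y[m] for m in mids])
    m = len(mids)
    out: list[tuple[int, str]] = []
    if m == 1:
        return [(mids[0], "min")]
    for k in range(m):
        if k == 0:
            kind = "min" if vals[1] > vals[0] else "max"
        elif k == m - 1:
            kind = "min" if vals[m - 2] > vals[m - 1] else "max"
        else:
            if vals[k] < vals[k - 1] and vals[k] < vals[k + 1]:
                kind = "min"
            elif vals[k] > vals[k - 1] and vals[k] > vals[k + 1]:
                kind = "max"
            else:
                continue
        if kind == "max" and k in (0, m - 1):
            continue  # endpoints are candidate minima only
        out.append((mids[k], kind))
    return out


def find_stationary_points(
    prof: FreeEnergyProfile, prominence_threshold: float = 0.5
) -> StationaryReport:
    """Locate alternating Int/TS points and their barriers.

    Works on ``G_smoothed`` when present, otherwise on ``G``.  A maximum
    whose barrier over the preceding minimum falls below the prominence
    threshold is merged away together with the shallower neighbouring
    minimum, so reported minima and maxima strictly alternate and every
    barrier is at least the threshold.
    """
    if len(prof) < 3:
        raise ParameterError("stationary-point analysis needs >= 3 samples")
    y = prof.values
    ext = _raw_extrema(y)

    # enforce alternation (possible after endpoint-max dropping)
    cleaned: list[tuple[int, str]] = []
    for idx, kind in ext:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx, _ = cleaned[-1]
            if kind == "min":
                if y[idx] < y[prev_idx]:
                    cleaned[-1] = (idx, kind)
            else:
                if y[idx] > y[prev_idx]:
                    cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))
    ext = cleaned

    # prominence merging: repeatedly remove the weakest sub-threshold TS
    def barrier_list(e: list[tuple[int, str]]) -> list[tuple[int, float]]:
        out = []
        for pos, (idx, kind) in enumerate(e):
            if kind != "max":
                continue
            prev_min = next(
                (e[q][0] for q in range(pos - 1, -1, -1) if e[q][1] == "min"),
                None,
            )
            if prev_min is None:
                out.append((pos, np.inf))
            else:
                out.append((pos, y[idx] - y[prev_min]))
        return out

    while True:
        blist = barrier_list(ext)
        weak = [(b, pos) for pos, b in blist if b < prominence_threshold]
        if not weak:
            break
        _, pos = min(weak)
        # drop the max and the shallower adjacent minimum to keep alternation
        left = pos - 1 if pos - 1 >= 0 and ext[pos - 1][1] == "min" else None
        right = pos + 1 if pos + 1 < len(ext) and ext[pos + 1][1] == "min" else None
        drop = {pos}
        if left is not None and right is not None:
            drop.add(left if y[ext[left][0]] >= y[ext[right][0]] else right)
        elif left is not None and pos == len(ext) - 1:
            pass  # trailing max with no following min: just drop the max
        elif right is not None and pos == 0:
            pass
        ext = [e for q, e in enumerate(ext) if q not in drop]
        # re-merge equal-kind neighbours created by the removal
        merged: list[tuple[int, str]] = []
        for idx, kind in ext:
            if merged and merged[-1][1] == kind:
                pidx, _ = merged[-1]
                keep = (
                    idx
                    if (kind == "min") == (y[idx] < y[pidx])
                    else pidx
                )
                merged[-1] = (keep, kind)
            else:
                merged.append((idx, kind))
        ext = merged

    minima = [
        StationaryPoint(idx, float(prof.s[idx]), float(y[idx]), "")
        for idx, kind in ext
        if kind == "min"
    ]
    maxima = [
        StationaryPoint(idx, float(prof.s[idx]), float(y[idx]), "")
        for idx, kind in ext
        if kind == "max"
    ]
    for i, mpt in enumerate(minima, 1):
        mpt.label = f"Int{i}"
    for i, mpt in enumerate(maxima, 1):
        mpt.label = f"TS{i}"
    report = StationaryReport(
        minima=minima,
        maxima=maxima,
        barriers={},
        rate_limiting=None,
        prominence_threshold=prominence_threshold,
    )
    barriers, rate_limiting = barriers_and_rate_limiting(report)
    report.barriers = barriers
    report.rate_limiting = rate_limiting
    return report


def barriers_and_rate_limiting(
    rep: StationaryReport,
) -> tuple[dict[str, float], str | None]:
    """Per-TS barriers ΔG‡ = G(TS) − G(preceding Int) and the largest one."""
    barriers: dict[str, float] = {}
    for ts in rep.maxima:
        preceding = [m for m in rep.minima if m.index < ts.index]
        if not preceding:
            logger.warning("%s has no preceding minimum; skipped", ts.label)
            continue
        barriers[ts.label] = ts.G - preceding[-1].G
    if not barriers:
        return {}, None
    best = max(barriers.values())
    rate_limiting = next(k for k, v in barriers.items() if v == best)
    return barriers, rate_limiting
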