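"""Methyl HMQC peak-list analytics: assignment transfer, chemical-shift
perturbation, split-peak detection and bound-state conformer classification.

In slow-exchange protein-DNA titrations the bound-state cross peaks cannot
be followed from the free positions; their identity is inferred from
proximity to the free-protein peak. A free-state assignment that acquires
two (or more) nearby bound peaks is "split" — the signature of multiple
bound conformations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .exchange import InvalidInputError

__all__ = [
    "Peak",
    "PeakList",
    "MatchReport",
    "transfer_assignments",
    "combined_csp",
    "conformer_populations",
    "classify_complex",
    "read_peaklist",
    "write_peaklist",
    "DEFAULT_TOL_H",
    "DEFAULT_TOL_C",
]

#: assignment-transfer tolerances, ppm (typical methyl linewidths)
DEFAULT_TOL_H = 0.05
DEFAULT_TOL_C = 0.3

#: conventional 13C down-weighting in the combined CSP metric
DEFAULT_W_C = 0.25

_METHYL_H_RANGE = (-2.0, 3.0)
_METHYL_C_RANGE = (5.0, 30.0)


@dataclass(frozen=True)
class Peak:
    """One 2D methyl cross peak. ``assignment`` is empty if unassigned."""

    assignment: str
    aa: str
    methyl_id: str
    dH: float
    dC: float
    intensity: float

    def __post_init__(self) -> None:
        if not (self.intensity > 0):
            raise InvalidInputError(f"peak intensity must be > 0, got {self.intensity}")


@dataclass
class PeakList:
    """Peak list of one sample state (free protein or a DNA complex)."""

    state_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        outside = [
            p for p in self.peaks
            if not (_METHYL_H_RANGE[0] <= p.dH <= _METHYL_H_RANGE[1]
                    and _METHYL_C_RANGE[0] <= p.dC <= _METHYL_C_RANGE[1])
        ]
        if outside:
            warnings.warn(
                f"{len(outside)} peak(s) in {self.state_label!r} fall outside the "
                f"methyl region ({_METHYL_H_RANGE} ppm 1H, {_METHYL_C_RANGE} ppm 13C)",
                stacklevel=2,
            )

    @property
    def assigned(self) -> list[Peak]:
        return [p for p in self.peaks if p.assignment]

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class AssignmentMatch:
    """Bound peaks matched to one free-state assignment."""

    assignment: str
    components: list[Peak]            # matched bound peaks, closest first
    deltas: list[tuple[float, float]]  # (dH, dC) per component
    csp: float                         # combined CSP of the closest component
    split: bool
    intensity_ratio: Optional[float]   # minor/major, in (0, 1]; None if unsplit


@dataclass
class MatchReport:
    """Per-assignment match table plus unmatched bound peaks."""

    reference_label: str
    target_label: str
    matches: dict[str, AssignmentMatch]
    unmatched_reference: list[str]
    unmatched_target: list[Peak]
    tol_h: float
    tol_c: float

    @property
    def split_assignments(self) -> list[str]:
        return [a for a, m in self.matches.items() if m.split]

    @property
    def split_residues(self) -> set[int]:
        return {_residue_of(a) for a in self.split_assignments}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, m in sorted(self.matches.items()):
            for i, (pk, (dh, dc)) in enumerate(zip(m.components, m.deltas)):
                rows.append(
                    (a, i, pk.dH, pk.dC, pk.intensity, dh, dc,
                     combined_csp(dh, dc), m.split,
                     m.intensity_ratio if m.split else "")
                )
        return pd.DataFrame(
            rows,
            columns=["assignment", "component", "dH_ppm", "dC_ppm", "intensity",
                     "delta_h_ppm", "delta_c_ppm", "csp_ppm", "split",
                     "intensity_ratio"],
        )


def _residue_of(assignment: str) -> int:
    return int(assignment[1:].split("-")[0])


def combined_csp(dH: float, dC: float, w_c: float = DEFAULT_W_C) -> float:
    """Combined 1H/13C chemical-shift perturbation: sqrt(dH^2 + (w_c dC)^2)."""
    if not (math.isfinite(dH) and math.isfinite(dC)):
        raise InvalidInputError("shift differences must be finite")
    return math.hypot(dH, w_c * dC)


def transfer_assignments(
    reference: PeakList,
    target: PeakList,
    tol_h: float = DEFAULT_TOL_H,
    tol_c: float = DEFAULT_TOL_C,
) -> MatchReport:
    """Transfer assignments from a fully assigned reference list to a target.

    Each target peak is matched to the reference assignment minimising the
    scaled elliptical distance d = sqrt((dH/tol_h)^2 + (dC/tol_c)^2), with
    matches accepted only for d <= 1. Matching is greedy in order of
    increasing d: target peaks are consumed once, but a reference
    assignment may acquire several target peaks — a split, indicating
    multiple bound conformations.
    """
    if not reference.peaks or not target.peaks:
        raise InvalidInputError("reference and target peak lists must be non-empty")
    ref = reference.assigned
    if len(ref) != len(reference.peaks):
        raise InvalidInputError("reference list must be fully assigned")
    if tol_h <= 0 or tol_c <= 0:
        raise InvalidInputError("tolerances must be > 0")

    candidates = []
    for ti, tp in enumerate(target.peaks):
        for rp in ref:
            d = math.hypot((tp.dH - rp.dH) / tol_h, (tp.dC - rp.dC) / tol_c)
            if d <= 1.0:
                candidates.append((d, rp.assignment, ti))
    candidates.sort(key=lambda c: c[0])

    matched: dict[str, list[int]] = {}
    taken: set[int] = set()
    for d, assignment, ti in candidates:
        if ti in taken:
            continue
        taken.add(ti)
        matched.setdefault(assignment, []).append(ti)

    matches: dict[str, AssignmentMatch] = {}
    ref_by_assignment = {p.assignment: p for p in ref}
    for assignment, idxs in matched.items():
        rp = ref_by_assignment[assignment]
        comps = [target.peaks[i] for i in idxs]
        # order components by distance to the reference position
        comps.sort(key=lambda p: math.hypot((p.dH - rp.dH) / tol_h, (p.dC - rp.dC) / tol_c))
        deltas = [(p.dH - rp.dH, p.dC - rp.dC) for p in comps]
        split = len(comps) >= 2
        ratio = None
        if split:
            inten = sorted((p.intensity for p in comps), reverse=True)
            ratio = inten[1] / inten[0]
        matches[assignment] = AssignmentMatch(
            assignment=assignment, components=comps, deltas=deltas,
            csp=combined_csp(*deltas[0]), split=split, intensity_ratio=ratio,
        )
    unmatched_ref = sorted(set(ref_by_assignment) - set(matches))
    unmatched_tgt = [p for i, p in enumerate(target.peaks) if i not in taken]
    return MatchReport(
        reference_label=reference.state_label, target_label=target.state_label,
        matches=matches, unmatched_reference=unmatched_ref,
        unmatched_target=unmatched_tgt, tol_h=tol_h, tol_c=tol_c,
    )


def conformer_populations(intensities: Sequence[float]) -> list[float]:
    """Fractional conformer populations from split-component intensities.

    Intensities are normalised to sum to one. Intensity is proportional to
    population only if the components relax identically; treat the result
    as an estimate under that assumption.
    """
    if len(intensities) < 2:
        raise InvalidInputError("need >= 2 split components")
    if any(i <= 0 for i in intensities):
        raise InvalidInputError("intensities must be > 0")
    total = float(sum(intensities))
    return [float(i) / total for i in intensities]


def classify_complex(report: MatchReport, min_split: int = 2) -> str:
    """"multiple_conformations" iff >= ``min_split`` assignments are split.

    With no matched assignments at all the verdict defaults to
    "single_conformation" with a low-confidence warning.
    """
    if not report.matches:
        warnings.warn(
            "no assignments matched between the peak lists; "
            "'single_conformation' verdict has low confidence",
            stacklevel=2,
        )
        return "single_conformation"
    n_split = len(report.split_assignments)
    return "multiple_conformations" if n_split >= min_split else "single_conformation"


# ---------------------------------------------------------------------------
# peak-list table format
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = ["assignment", "aa", "methyl_id", "dH_ppm", "dC_ppm", "intensity"]


def write_peaklist(pl: PeakList, path) -> None:
    rows = [
        (p.assignment, p.aa, p.methyl_id, p.dH, p.dC, p.intensity) for p in pl.peaks
    ]
    with open(path, "w") as fh:
        fh.write(f"# state: {pl.state_label}\n")
        pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(
            fh, sep="\t", index=False, float_format="%.10g"
        )


def read_peaklist(path, state_label: Optional[str] = None) -> PeakList:
    label = state_label
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# state:") and label is None:
            label = first.split(":", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"peak list {path} missing columns {missing}")
    peaks = []
    for i, row in df.iterrows():
        try:
            peaks.append(
                Peak(
                    assignment="" if pd.isna(row["assignment"]) else str(row["assignment"]),
                    aa=str(row["aa"]), methyl_id=str(row["methyl_id"]),
                    dH=float(row["dH_ppm"]), dC=float(row["dC_ppm"]),
                    intensity=float(row["intensity"]),
                )
            )
        except (ValueError, InvalidInputError) as exc:
            raise InvalidInputError(f"{path} line {i + 3}: {exc}") from exc
    return PeakList(state_label=label or str(path), peaks=peaks)
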