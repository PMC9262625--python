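"""Synthetic dispersion datasets and HMQC peak lists with known ground truth.

The generator emulates the acquisition design of a two-field methyl
single-quantum CPMG study of the NF-kB p50 Rel-homology-region (RHR)
homodimer and its isolated DNA-binding domain (DBD): 11.7 T and 18.8 T
(1H 500/800 MHz), a 20 ms constant relaxation period, 18 refocusing
frequencies with duplicate measurements at the reference and at
nu = 200 and 6000 s^-1, and ILV methyl probes. Residue clusters carry the
published shared exchange parameters, so every downstream stage (screening,
individual fits, clustering, global fits, Monte Carlo) can be scored
against exact ground truth.

Presets
-------
dbd_300K
    Isolated DBD at 300 K: 18 dispersing residues; cluster 1 (14 residues)
    with k_ex = 1640 s^-1, p_B = 0.042; cluster 2 (I139, V210, L212) with
    k_ex = 420 s^-1, p_B = 0.146; L106 carries an off-cluster process.
rhr_300K
    Full-length RHR homodimer at 300 K: 19 dispersing residues; main
    cluster (16 residues) with k_ex = 1600 s^-1, p_B = 0.051; second
    cluster (V210, L212) with k_ex = 660 s^-1, p_B = 0.14; L106 off-cluster.
dbd_290K
    DBD at 290 K: one global process, k_ex = 480 s^-1, p_B = 0.029.
rhr_mhc_h2_bound
    RHR bound to the 11-bp MHC H2 kB duplex, single field (18.8 T):
    loop-proximal dispersion quenched (flat, p_B = 0); the surface residues
    I104 and V233 keep their free-state dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .exchange import CpmgSchedule, ExchangeParams, FieldContext, InvalidInputError
from .profiles import SIGMA_FLOOR, DispersionProfile
from .peaks import Peak, PeakList

__all__ = [
    "DEFAULT_FIELDS",
    "DEFAULT_SCHEDULE",
    "DatasetSpec",
    "GroundTruth",
    "ResidueSpec",
    "ClusterSpec",
    "preset",
    "PRESET_NAMES",
    "make_dispersion_dataset",
    "make_peaklists",
    "PEAK_SCENARIOS",
]

#: 13C Larmor frequencies follow from the 1H fields via gamma_C/gamma_H ~ 0.2515
DEFAULT_FIELDS = {
    "11.7T": FieldContext("11.7T", 11.7, 125.7),
    "18.8T": FieldContext("18.8T", 18.8, 201.2),
}

#: 18 refocusing frequencies, ~log-spaced; all are multiples of 50 s^-1 so the
#: 20 ms constant-time block holds an even pulse count at every nu
DEFAULT_SCHEDULE = CpmgSchedule(
    t_relax=0.020,
    nu_cpmg=(100, 150, 200, 250, 300, 400, 500, 650, 800, 1000,
             1200, 1500, 1800, 2100, 2500, 3000, 4000, 6000),
)

#: schedule positions measured twice (plus the reference experiment)
DEFAULT_DUPLICATE_NUS = (200.0, 6000.0)


@dataclass(frozen=True)
class ResidueSpec:
    residue_id: int
    aa: str  # I, L or V

    @property
    def methyl_ids(self) -> tuple[str, ...]:
        return ("d1",) if self.aa == "I" else ("a", "b")


@dataclass(frozen=True)
class ClusterSpec:
    members: frozenset[int]  # residue ids
    k_ex: float
    p_B: float


@dataclass
class DatasetSpec:
    """Full description of one synthetic dispersion dataset.

    ``rex_min`` is the guaranteed noiseless dispersion amplitude (at the
    highest field) of every planted dispersing methyl: dw_ppm draws that
    fall below it are redrawn, so ground-truth dispersing residues sit
    safely above the R_ex > 5 s^-1 screen.
    """

    name: str
    fields: dict[str, FieldContext] = field(
        default_factory=lambda: dict(DEFAULT_FIELDS)
    )
    schedule: CpmgSchedule = DEFAULT_SCHEDULE
    residues: tuple[ResidueSpec, ...] = ()
    clusters: tuple[ClusterSpec, ...] = ()
    off_cluster: dict[int, tuple[float, float]] = field(default_factory=dict)
    dw_range: tuple[float, float] = (0.4, 1.6)
    r20_range: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"11.7T": (10.0, 18.0), "18.8T": (14.0, 24.0)}
    )
    noise_sigma: float = 0.3
    duplicate_nus: tuple[float, ...] = DEFAULT_DUPLICATE_NUS
    rex_min: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")
        ids = [r.residue_id for r in self.residues]
        if len(ids) != len(set(ids)):
            raise InvalidInputError("residue ids must be unique")
        seen: set[int] = set()
        for c in self.clusters:
            if c.members & seen:
                raise InvalidInputError("cluster members must be disjoint")
            seen |= c.members
        known = set(ids)
        for c in self.clusters:
            if not c.members <= known:
                raise InvalidInputError("cluster members must appear in residues")
        if not set(self.off_cluster) <= known:
            raise InvalidInputError("off-cluster residues must appear in residues")

    @property
    def dispersing_residues(self) -> set[int]:
        out = set(self.off_cluster)
        for c in self.clusters:
            out |= set(c.members)
        return out


@dataclass
class GroundTruth:
    """Generating parameters for every methyl, plus cluster memberships."""

    params_by_methyl: dict[tuple[int, str], ExchangeParams]
    cluster_members: list[set[tuple[int, str]]]
    dispersing_residues: set[int]
    cluster_params: list[tuple[float, float]]  # (k_ex, p_B) per cluster


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_DBD_CLUSTER1 = {
    44: "I", 67: "L", 91: "V", 97: "L", 118: "I", 124: "V", 134: "L",
    147: "V", 156: "I", 170: "L", 181: "V", 196: "L", 224: "I", 237: "I",
}
_DBD_CLUSTER2 = {139: "I", 210: "V", 212: "L"}
_DBD_FLAT = {
    58: "V", 73: "L", 85: "I", 102: "V", 128: "L", 151: "I",
    163: "V", 178: "L", 190: "I", 203: "V", 218: "L", 230: "I",
}
_L106 = {106: "L"}
_L106_PARAMS = (5000.0, 0.08)  # a third process, off both printed clusters

# full-length homodimer: DBD spine (with I139 joining the main cluster; only
# V210/L212 keep a separate slower process) plus the surface residues I104
# and V233; the dimerization domain (260-350) is rigid -> flat profiles
_RHR_CLUSTER1 = {
    **{rid: aa for rid, aa in _DBD_CLUSTER1.items() if rid != 44},
    139: "I", 104: "I", 233: "V",
}
_RHR_CLUSTER2 = {210: "V", 212: "L"}
_RHR_FLAT = {
    58: "V", 73: "L", 85: "I", 265: "I", 278: "V", 290: "L",
    301: "I", 315: "V", 322: "L", 334: "I", 340: "V", 348: "L",
}

PRESET_NAMES = ("dbd_300K", "rhr_300K", "dbd_290K", "rhr_mhc_h2_bound")


def _residues(*tables: Mapping[int, str]) -> tuple[ResidueSpec, ...]:
    merged: dict[int, str] = {}
    for t in tables:
        merged.update(t)
    return tuple(ResidueSpec(rid, aa) for rid, aa in sorted(merged.items()))


def preset(name: str) -> DatasetSpec:
    """Dataset spec whose cluster parameters equal the published values."""
    if name == "dbd_300K":
        return DatasetSpec(
            name=name,
            residues=_residues(_DBD_CLUSTER1, _DBD_CLUSTER2, _L106, _DBD_FLAT),
            clusters=(
                ClusterSpec(frozenset(_DBD_CLUSTER1), k_ex=1640.0, p_B=0.042),
                ClusterSpec(frozenset(_DBD_CLUSTER2), k_ex=420.0, p_B=0.146),
            ),
            off_cluster={106: _L106_PARAMS},
            seed=100,
        )
    if name == "rhr_300K":
        return DatasetSpec(
            name=name,
            residues=_residues(_RHR_CLUSTER1, _RHR_CLUSTER2, _L106, _RHR_FLAT),
            clusters=(
                ClusterSpec(frozenset(_RHR_CLUSTER1), k_ex=1600.0, p_B=0.051),
                ClusterSpec(frozenset(_RHR_CLUSTER2), k_ex=660.0, p_B=0.14),
            ),
            off_cluster={106: _L106_PARAMS},
            seed=200,
        )
    if name == "dbd_290K":
        return DatasetSpec(
            name=name,
            residues=_residues(_DBD_CLUSTER1, _DBD_CLUSTER2, _DBD_FLAT),
            clusters=(
                ClusterSpec(
                    frozenset({**_DBD_CLUSTER1, **_DBD_CLUSTER2}), k_ex=480.0, p_B=0.029
                ),
            ),
            seed=300,
        )
    if name == "rhr_mhc_h2_bound":
        return DatasetSpec(
            name=name,
            fields={"18.8T": DEFAULT_FIELDS["18.8T"]},
            r20_range={"18.8T": (16.0, 28.0)},  # slower tumbling in the complex
            residues=_residues(_RHR_CLUSTER1, _RHR_CLUSTER2, _L106, _RHR_FLAT),
            clusters=(
                ClusterSpec(frozenset({104: "I", 233: "V"}), k_ex=1600.0, p_B=0.051),
            ),
            seed=400,
        )
    raise InvalidInputError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


# ---------------------------------------------------------------------------
# dispersion dataset generation
# ---------------------------------------------------------------------------

def _truth_for_methyl(
    spec: DatasetSpec,
    rid: int,
    rng: np.random.Generator,
    highest_field: FieldContext,
) -> ExchangeParams:
    from .exchange import dispersion_curve  # local import avoids cycle at import time

    kex_pb: Optional[tuple[float, float]] = None
    for c in spec.clusters:
        if rid in c.members:
            kex_pb = (c.k_ex, c.p_B)
    if rid in spec.off_cluster:
        kex_pb = spec.off_cluster[rid]

    r20 = {
        label: float(rng.uniform(*spec.r20_range[label])) for label in spec.fields
    }
    if kex_pb is None:
        # non-dispersing methyls carry p_B = 0: the flat/exchange distinction
        # is unambiguous in ground truth
        return ExchangeParams(k_ex=1000.0, p_B=0.0, dw_ppm=0.0, r20_by_field=r20)

    k_ex, p_B = kex_pb
    for _ in range(200):
        dw = float(rng.uniform(*spec.dw_range))
        p = ExchangeParams(k_ex=k_ex, p_B=p_B, dw_ppm=dw, r20_by_field=r20)
        curve = dispersion_curve(p, highest_field, spec.schedule)
        order = np.argsort(spec.schedule.nu_cpmg)
        rex = float(np.mean(curve[order][:2]) - np.mean(curve[order][-2:]))
        if rex > spec.rex_min:
            return p
    raise InvalidInputError(
        f"could not draw dw_ppm giving R_ex > {spec.rex_min} s^-1 for residue {rid} "
        f"(k_ex={k_ex}, p_B={p_B}); widen dw_range"
    )


def make_dispersion_dataset(
    spec: DatasetSpec, seed: Optional[int] = None
) -> tuple[list[DispersionProfile], GroundTruth]:
    """Generate noisy two-field profiles plus exact ground truth.

    Noiseless curves come from the Bloch-McConnell forward model; Gaussian
    noise at ``spec.noise_sigma`` is added per point. Duplicate measurements
    are emitted at the reference and at ``spec.duplicate_nus``; duplicated
    points enter the profile as the average of their pair, with the pair
    retained for pooled error estimation. Per-point sigma is set to
    ``noise_sigma`` (floored), the value the duplicate-based estimate
    targets. Deterministic under the seed (``spec.seed`` unless overridden).
    """
    from .exchange import dispersion_curve

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    highest = spec.fields[max(spec.fields)]
    sigma_point = max(spec.noise_sigma, SIGMA_FLOOR)

    profiles: list[DispersionProfile] = []
    truth_params: dict[tuple[int, str], ExchangeParams] = {}
    for res in spec.residues:
        for mid in res.methyl_ids:
            p = _truth_for_methyl(spec, res.residue_id, rng, highest)
            truth_params[(res.residue_id, mid)] = p
            for label, fctx in spec.fields.items():
                curve = dispersion_curve(p, fctx, spec.schedule)
                noisy = curve + rng.normal(0.0, spec.noise_sigma, size=len(curve))
                duplicates: list[tuple[Optional[float], tuple[float, float]]] = []
                # second measurement of the reference experiment: its scatter
                # around the (zero-decay) reference is what the pair records
                ref_pair = rng.normal(0.0, spec.noise_sigma, size=2)
                duplicates.append((None, (float(ref_pair[0]), float(ref_pair[1]))))
                nus = np.asarray(spec.schedule.nu_cpmg, float)
                for dup_nu in spec.duplicate_nus:
                    idx = np.nonzero(nus == dup_nu)[0]
                    if len(idx) == 0:
                        continue
                    i = int(idx[0])
                    second = curve[i] + rng.normal(0.0, spec.noise_sigma)
                    duplicates.append((float(dup_nu), (float(noisy[i]), float(second))))
                    noisy[i] = 0.5 * (noisy[i] + second)
                profiles.append(
                    DispersionProfile(
                        residue_id=res.residue_id, aa=res.aa, methyl_id=mid,
                        field_label=label, nu=nus.copy(), r2eff=noisy,
                        sigma=np.full(len(nus), sigma_point),
                        duplicates=duplicates,
                    )
                )

    members_by_cluster = [
        {
            (rid, mid)
            for rid in c.members
            for mid in next(r for r in spec.residues if r.residue_id == rid).methyl_ids
        }
        for c in spec.clusters
    ]
    truth = GroundTruth(
        params_by_methyl=truth_params,
        cluster_members=members_by_cluster,
        dispersing_residues=spec.dispersing_residues,
        cluster_params=[(c.k_ex, c.p_B) for c in spec.clusters],
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# peak-list scenarios
# ---------------------------------------------------------------------------

PEAK_SCENARIOS = ("free", "kB_proto", "H2_kB", "MHC_H2", "MHC_H2_M1", "MHC_H2_M2")

# residues perturbed by DNA binding (DNA-binding loops + hydrophobic spine)
_SHIFTED_RESIDUES = (42, 58, 67, 97, 112, 139, 147, 209, 210, 212, 237)
# residues whose bound cross peaks split in the 10-bp complexes
_SPLIT_SETS = {
    "kB_proto": (42, 58, 112, 147, 209),
    "H2_kB": (42, 67, 112, 147),
    "MHC_H2_M2": (42, 58, 112, 147, 209),
}
# planted split intensity fractions (major conformer); V209 comparable,
# V112 clearly unequal
_SPLIT_MAJOR = {209: 0.5, 112: 0.7}

# bound-state offsets (dH ppm, dC ppm) of the two single-conformer complexes;
# chosen well inside the assignment-transfer tolerance so both split
# components of M2 still map to the free-state assignment
_OFFSET_MHC = (0.022, 0.14)
_OFFSET_M1 = (-0.018, -0.11)
_OFFSET_PROTO = (0.015, 0.17)
_OFFSET_PROTO_B = (-0.020, -0.15)
_OFFSET_H2KB = (0.025, -0.12)
_OFFSET_H2KB_B = (-0.012, 0.16)

_AA_CARBON_BASE = {"I": 10.0, "L": 23.0, "V": 20.0}


def _free_peaklist(rng: np.random.Generator) -> PeakList:
    """Assigned methyl HMQC peak list of the free protein.

    Peaks are laid on a jittered lattice with spacing (0.13 ppm 1H, 0.9 ppm
    13C) so that nearest neighbours sit outside the assignment-transfer
    tolerance ellipse even after bound-state offsets.
    """
    residues = {**_RHR_CLUSTER1, **_RHR_CLUSTER2, **_L106, **_RHR_FLAT,
                42: "L", 58: "V", 112: "V", 209: "V"}
    peaks = []
    count_by_aa = {"I": 0, "L": 0, "V": 0}
    for rid in sorted(residues):
        aa = residues[rid]
        for mid in (("d1",) if aa == "I" else ("a", "b")):
            i = count_by_aa[aa]
            count_by_aa[aa] += 1
            col, row = i % 7, i // 7
            dh = 0.30 + 0.13 * col + float(rng.uniform(-0.01, 0.01))
            dc = _AA_CARBON_BASE[aa] + 0.75 * row + float(rng.uniform(-0.06, 0.06))
            peaks.append(
                Peak(
                    assignment=f"{aa}{rid}-{mid}", aa=aa, methyl_id=mid,
                    dH=round(dh, 4), dC=round(dc, 4),
                    intensity=round(float(rng.uniform(0.6, 1.4)), 4),
                )
            )
            i += 1
    return PeakList(state_label="free", peaks=peaks)


def _offset_for(scenario: str, rid: int, component: int) -> tuple[float, float]:
    if scenario == "MHC_H2":
        return _OFFSET_MHC
    if scenario == "MHC_H2_M1":
        return _OFFSET_M1
    if scenario == "MHC_H2_M2":
        # the two bound orientations recapitulate the MHC H2 and M1 positions
        return _OFFSET_MHC if component == 0 else _OFFSET_M1
    if scenario == "kB_proto":
        return _OFFSET_PROTO if component == 0 else _OFFSET_PROTO_B
    if scenario == "H2_kB":
        return _OFFSET_H2KB if component == 0 else _OFFSET_H2KB_B
    raise InvalidInputError(f"unknown scenario {scenario!r}")


def make_peaklists(
    scenario: str, seed: int = 0
) -> tuple[PeakList, PeakList, dict]:
    """Free and bound methyl peak lists for one DNA-complex scenario.

    Returns (free, bound, ground_truth) where ground_truth records the
    planted split residues, per-residue offsets and split populations.
    Deterministic under seed. Scenario "free" returns the free list twice.
    """
    if scenario not in PEAK_SCENARIOS:
        raise InvalidInputError(
            f"unknown scenario {scenario!r}; available: {PEAK_SCENARIOS}"
        )
    rng = np.random.default_rng(seed)
    free = _free_peaklist(rng)
    if scenario == "free":
        bound = PeakList(state_label="free-rerun", peaks=list(free.peaks))
        return free, bound, {"split_residues": set(), "populations": {}}

    split_set = set(_SPLIT_SETS.get(scenario, ()))
    shifted = set(_SHIFTED_RESIDUES)
    noise = 0.02  # fractional intensity noise on bound peaks
    bound_peaks = []
    populations: dict[int, tuple[float, float]] = {}
    for pk in free.peaks:
        rid = int(pk.assignment[1:].split("-")[0])
        if rid in split_set:
            major = _SPLIT_MAJOR.get(rid, float(rng.uniform(0.55, 0.75)))
            populations[rid] = (major, 1.0 - major)
            for comp, frac in enumerate((major, 1.0 - major)):
                dh_off, dc_off = _offset_for(scenario, rid, comp)
                inten = pk.intensity * frac * float(1.0 + rng.normal(0.0, noise))
                bound_peaks.append(
                    Peak(
                        assignment="", aa=pk.aa, methyl_id=pk.methyl_id,
                        dH=round(pk.dH + dh_off, 4), dC=round(pk.dC + dc_off, 4),
                        intensity=round(max(inten, 1e-3), 4),
                    )
                )
        else:
            if rid in shifted:
                dh_off, dc_off = _offset_for(scenario, rid, 0)
            else:
                dh_off, dc_off = (
                    float(rng.uniform(-0.003, 0.003)),
                    float(rng.uniform(-0.02, 0.02)),
                )
            inten = pk.intensity * float(1.0 + rng.normal(0.0, noise))
            bound_peaks.append(
                Peak(
                    assignment="", aa=pk.aa, methyl_id=pk.methyl_id,
                    dH=round(pk.dH + dh_off, 4), dC=round(pk.dC + dc_off, 4),
                    intensity=round(max(inten, 1e-3), 4),
                )
            )
    bound = PeakList(state_label=scenario, peaks=bound_peaks)
    truth = {
        "split_residues": split_set,
        "populations": populations,
        "shifted_residues": shifted,
    }
    return free, bound, truth
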