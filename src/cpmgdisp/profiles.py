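"""Dispersion profiles: R2,eff construction from intensities, duplicate-based
error estimation, R_ex screening, and the tab-separated table formats."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exchange import InvalidInputError

__all__ = [
    "DispersionProfile",
    "IntensityRecord",
    "SIGMA_FLOOR",
    "r2eff_from_intensities",
    "estimate_sigma_from_duplicates",
    "rex_observed",
    "screen_dispersing",
    "read_dispersion_table",
    "write_dispersion_table",
    "read_intensity_table",
    "write_intensity_table",
    "profiles_from_intensity_records",
]

#: lower bound applied to pooled duplicate-based sigma estimates, s^-1
SIGMA_FLOOR = 0.1

VALID_METHYL_IDS = ("a", "b", "d1")


@dataclass
class DispersionProfile:
    """One methyl group's R2,eff(nu_CPMG) curve at one static field.

    ``points`` rows are (nu s^-1, R2,eff s^-1, sigma s^-1) with unique,
    strictly positive nu. ``duplicates`` holds repeat-measurement pairs in
    R2,eff units, keyed by nu (or None for the reference experiment), kept
    for pooled error estimation. Prochiral Leu/Val methyls carry
    ``methyl_id`` "a"/"b" (not stereospecifically assigned); Ile delta-1 is
    "d1".
    """

    residue_id: int
    aa: str
    methyl_id: str
    field_label: str
    nu: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray
    duplicates: list[tuple[Optional[float], tuple[float, float]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        self.nu = np.asarray(self.nu, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.nu) == len(self.r2eff) == len(self.sigma)):
            raise InvalidInputError("nu, r2eff and sigma must have equal length")
        if np.any(self.nu <= 0):
            raise InvalidInputError("nu values must be strictly positive")
        if len(np.unique(self.nu)) != len(self.nu):
            raise InvalidInputError("nu values must be unique within a profile")
        if np.any(self.sigma <= 0):
            raise InvalidInputError("per-point sigma must be > 0")
        if self.methyl_id not in VALID_METHYL_IDS:
            raise InvalidInputError(
                f"methyl_id must be one of {VALID_METHYL_IDS}, got {self.methyl_id!r}"
            )
        if self.aa == "I" and self.methyl_id != "d1":
            raise InvalidInputError("Ile methyls must use methyl_id 'd1'")

    @property
    def key(self) -> tuple[int, str]:
        """(residue_id, methyl_id) — the unit of fitting and clustering."""
        return (self.residue_id, self.methyl_id)

    def with_sigma(self, sigma: float) -> "DispersionProfile":
        return replace(self, sigma=np.full(len(self.nu), float(sigma)))


@dataclass(frozen=True)
class IntensityRecord:
    """One measured peak intensity: a (nu, replicate) cell of the pseudo-3D.

    ``nu`` is None for the reference experiment (no CPMG relaxation block).
    """

    residue_id: int
    aa: str
    methyl_id: str
    field_label: str
    nu: Optional[float]
    intensity: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not (self.intensity > 0):
            raise InvalidInputError(
                f"intensity must be > 0, got {self.intensity} "
                f"(residue {self.residue_id}{self.methyl_id})"
            )


def r2eff_from_intensities(
    records: Sequence[IntensityRecord], t_relax: float
) -> DispersionProfile:
    """Build a profile from constant-time peak intensities for one methyl+field.

    R2,eff(nu) = -(1/t_relax) ln(I(nu)/I_ref), with the reference intensity
    averaged over its replicates. Duplicated nu values are averaged, and each
    replicate pair is retained (in R2,eff units) for pooled error
    estimation; the reference replicate pair is stored as the deviations of
    the individual reference R2,eff values from their mean (nu key None).
    Negative R2,eff (I > I_ref) is permitted but triggers a warning.

    Sigma is initialised at the floor value; callers should overwrite it via
    :func:`estimate_sigma_from_duplicates` or explicit assignment.
    """
    if not (t_relax > 0):
        raise InvalidInputError("t_relax must be > 0")
    if not records:
        raise InvalidInputError("no intensity records supplied")
    keys = {(r.residue_id, r.aa, r.methyl_id, r.field_label) for r in records}
    if len(keys) != 1:
        raise InvalidInputError(f"records span several methyl/field keys: {sorted(keys)}")
    residue_id, aa, methyl_id, field_label = keys.pop()

    refs = [r.intensity for r in records if r.nu is None]
    if len(refs) < 1:
        raise InvalidInputError("at least one reference record is required")
    i_ref = float(np.mean(refs))

    by_nu: dict[float, list[float]] = {}
    for r in records:
        if r.nu is not None:
            by_nu.setdefault(float(r.nu), []).append(r.intensity)

    duplicates: list[tuple[Optional[float], tuple[float, float]]] = []
    if len(refs) >= 2:
        ref_r2 = [-np.log(i / i_ref) / t_relax for i in refs[:2]]
        duplicates.append((None, (float(ref_r2[0]), float(ref_r2[1]))))

    nus, r2s = [], []
    for nu in sorted(by_nu):
        vals = [-np.log(i / i_ref) / t_relax for i in by_nu[nu]]
        if len(vals) >= 2:
            duplicates.append((nu, (float(vals[0]), float(vals[1]))))
        r2 = float(np.mean(vals))
        if r2 < 0:
            warnings.warn(
                f"negative R2,eff = {r2:.3f} s^-1 at nu = {nu} s^-1 for residue "
                f"{aa}{residue_id}({methyl_id}): I(nu) exceeds the reference",
                stacklevel=2,
            )
        nus.append(nu)
        r2s.append(r2)

    if not nus:
        raise InvalidInputError("no CPMG (non-reference) records supplied")
    return DispersionProfile(
        residue_id=residue_id,
        aa=aa,
        methyl_id=methyl_id,
        field_label=field_label,
        nu=np.array(nus),
        r2eff=np.array(r2s),
        sigma=np.full(len(nus), SIGMA_FLOOR),
        duplicates=duplicates,
    )


def estimate_sigma_from_duplicates(
    profiles: Iterable[DispersionProfile],
) -> dict[str, float]:
    """Pooled per-field sigma from duplicate-pair half-differences, s^-1.

    For a pair (x1, x2) of repeat measurements with common true value,
    x1 - x2 ~ N(0, 2 sigma^2), so sigma^2 is estimated as the mean of
    d^2 / 2 pooled over all pairs of a field. The estimate is floored at
    ``SIGMA_FLOOR``. Raises if no field has any duplicate pair.
    """
    sq: dict[str, list[float]] = {}
    for p in profiles:
        for _nu, (x1, x2) in p.duplicates:
            sq.setdefault(p.field_label, []).append((x1 - x2) ** 2 / 2.0)
    if not sq:
        raise InvalidInputError(
            "no duplicate pairs found in any profile; supply per-point sigma explicitly"
        )
    return {
        label: max(float(np.sqrt(np.mean(v))), SIGMA_FLOOR) for label, v in sq.items()
    }


def apply_pooled_sigma(
    profiles: Sequence[DispersionProfile], sigma_by_field: Mapping[str, float]
) -> list[DispersionProfile]:
    """Return profiles with the per-field pooled sigma applied uniformly."""
    out = []
    for p in profiles:
        out.append(p.with_sigma(sigma_by_field.get(p.field_label, SIGMA_FLOOR)))
    return out


def rex_observed(profile: DispersionProfile) -> float:
    """Observed exchange contribution: displacement of the dispersion curve.

    Mean R2,eff of the two lowest-nu points minus the mean of the two
    highest-nu points (two-point means damp single-point noise). With only
    two points this reduces to their difference.
    """
    if len(profile.nu) < 2:
        raise InvalidInputError("rex_observed needs at least 2 points")
    order = np.argsort(profile.nu)
    r = profile.r2eff[order]
    k = min(2, len(r) - 1)  # a 2-point profile reduces to a plain difference
    return float(np.mean(r[:k]) - np.mean(r[-k:]))


def screen_dispersing(
    profiles: Iterable[DispersionProfile],
    threshold: float = 5.0,
    field_label: Optional[str] = None,
) -> set[int]:
    """Residues whose observed R_ex exceeds ``threshold`` (s^-1).

    A residue passes if any of its methyls passes. The screen runs on the
    profiles of ``field_label`` (default: the lexically largest label, which
    for the standard "11.7T"/"18.8T" pair is the higher field); dispersion
    amplitudes grow with the static field since Delta-omega in rad/s scales
    with B0, so the highest field is the natural screening field.
    """
    profiles = list(profiles)
    if not profiles:
        raise InvalidInputError("no profiles to screen")
    if field_label is None:
        # pick the field whose profiles have the largest mean R_ex range:
        # callers with standard two-field data should pass the 18.8 T label
        field_label = max({p.field_label for p in profiles})
    passing: set[int] = set()
    for p in profiles:
        if p.field_label != field_label:
            continue
        if len(p.nu) >= 2 and rex_observed(p) > threshold:
            passing.add(p.residue_id)
    return passing


# ---------------------------------------------------------------------------
# table formats
# ---------------------------------------------------------------------------

_DISP_COLUMNS = [
    "residue_id", "aa", "methyl_id", "field_label", "nu_cpmg_hz", "r2eff_s", "sigma_s",
]
_INT_COLUMNS = [
    "residue_id", "aa", "methyl_id", "field_label", "nu_cpmg_hz", "intensity",
    "replicate_index",
]


def write_dispersion_table(profiles: Sequence[DispersionProfile], path) -> None:
    """Write profiles as a tab-separated dispersion table.

    Duplicate pairs are emitted as extra rows sharing the same nu (the
    reference pair uses an empty nu field), so the table round-trips the
    error-estimation information.
    """
    rows = []
    for p in profiles:
        dup_by_nu = {nu: pair for nu, pair in p.duplicates if nu is not None}
        ref_pairs = [pair for nu, pair in p.duplicates if nu is None]
        meta = (p.residue_id, p.aa, p.methyl_id, p.field_label)
        for pair in ref_pairs:
            for v in pair:
                rows.append((*meta, "", v, np.nan))
        for nu, r2, sg in zip(p.nu, p.r2eff, p.sigma):
            if nu in dup_by_nu:
                for v in dup_by_nu[nu]:
                    rows.append((*meta, nu, v, sg))
            else:
                rows.append((*meta, nu, r2, sg))
    df = pd.DataFrame(rows, columns=_DISP_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dispersion_table(path) -> list[DispersionProfile]:
    """Read a tab-separated dispersion table back into profiles.

    Repeated nu rows are averaged into one point and retained as duplicate
    pairs; rows with an empty nu field are reference duplicate pairs.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InvalidInputError(f"cannot parse dispersion table {path}: {exc}") from exc
    missing = [c for c in _DISP_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"dispersion table {path} missing columns {missing}")
    profiles = []
    for (rid, aa, mid, fl), grp in df.groupby(
        ["residue_id", "aa", "methyl_id", "field_label"], sort=True
    ):
        duplicates: list[tuple[Optional[float], tuple[float, float]]] = []
        ref_rows = grp[grp["nu_cpmg_hz"].isna()]
        if len(ref_rows) >= 2:
            v = ref_rows["r2eff_s"].to_numpy()
            duplicates.append((None, (float(v[0]), float(v[1]))))
        data = grp[~grp["nu_cpmg_hz"].isna()]
        nus, r2s, sgs = [], [], []
        for nu, sub in data.groupby("nu_cpmg_hz", sort=True):
            vals = sub["r2eff_s"].to_numpy()
            if len(vals) >= 2:
                duplicates.append((float(nu), (float(vals[0]), float(vals[1]))))
            nus.append(float(nu))
            r2s.append(float(np.mean(vals)))
            sgs.append(float(sub["sigma_s"].iloc[0]))
        profiles.append(
            DispersionProfile(
                residue_id=int(rid), aa=str(aa), methyl_id=str(mid),
                field_label=str(fl), nu=np.array(nus), r2eff=np.array(r2s),
                sigma=np.array(sgs), duplicates=duplicates,
            )
        )
    return profiles


def write_intensity_table(records: Sequence[IntensityRecord], path) -> None:
    rows = [
        (r.residue_id, r.aa, r.methyl_id, r.field_label,
         "REF" if r.nu is None else r.nu, r.intensity, r.replicate)
        for r in records
    ]
    pd.DataFrame(rows, columns=_INT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_intensity_table(path) -> list[IntensityRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _INT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"intensity table {path} missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        raw = row["nu_cpmg_hz"]
        nu = None if (pd.isna(raw) or str(raw).upper() == "REF") else float(raw)
        try:
            records.append(
                IntensityRecord(
                    residue_id=int(row["residue_id"]), aa=str(row["aa"]),
                    methyl_id=str(row["methyl_id"]),
                    field_label=str(row["field_label"]), nu=nu,
                    intensity=float(row["intensity"]),
                    replicate=int(row["replicate_index"]),
                )
            )
        except (ValueError, InvalidInputError) as exc:
            raise InvalidInputError(f"{path} line {i + 2}: {exc}") from exc
    return records


def profiles_from_intensity_records(
    records: Sequence[IntensityRecord], t_relax: float
) -> list[DispersionProfile]:
    """Group records by methyl+field and convert each group to a profile,
    then apply the pooled duplicate-based sigma per field."""
    groups: dict[tuple, list[IntensityRecord]] = {}
    for r in records:
        groups.setdefault((r.residue_id, r.aa, r.methyl_id, r.field_label), []).append(r)
    profiles = [r2eff_from_intensities(g, t_relax) for g in groups.values()]
    sigma = estimate_sigma_from_duplicates(profiles)
    return apply_pooled_sigma(profiles, sigma)
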