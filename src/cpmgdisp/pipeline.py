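"""End-to-end dispersion and peak-list pipelines with reproducible runs.

The dispersion pipeline follows the analysis sequence of the study design:

1. pooled duplicate-based error estimation;
2. R_ex screen (threshold 5 s^-1 at the highest field);
3. independent two-site fits of every screened methyl, with F-test model
   selection against a flat model;
4. clustering of exchange-model fits on log10(k_ex), cluster-global fits of
   shared (k_ex, p_B) with chi2-ratio ejection, and a rescue pass that
   offers unclustered methyls to fitted clusters (tie-break: lowest
   member chi2 under the cluster parameters);
5. Monte Carlo uncertainties of the shared parameters.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exchange import CpmgSchedule, FieldContext, InvalidInputError
from .fitting import (
    ClusterExchangeModel,
    ClusterExchangeResults,
    MethylExchangeModel,
    MethylExchangeResults,
    accept_member,
    chi2_under_shared,
    cluster_by_kex,
    model_select,
)
from .profiles import (
    DispersionProfile,
    apply_pooled_sigma,
    estimate_sigma_from_duplicates,
    read_dispersion_table,
    rex_observed,
    screen_dispersing,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_dispersion_pipeline",
    "run_peaks_pipeline",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML."""

    preset: Optional[str] = None
    input_table: Optional[str] = None
    output_dir: Optional[str] = None
    seed: int = 0
    n_reps: int = 100
    threshold_rex: float = 5.0
    alpha: float = 0.01
    cluster_gap: float = 0.25
    screen_field: Optional[str] = None
    sigma_override: Optional[float] = None
    monte_carlo: bool = True

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything one dispersion run produced."""

    config: RunConfig
    sigma_by_field: dict[str, float]
    screened_residues: set[int]
    individual: dict[tuple[int, str], MethylExchangeResults]
    flat: dict[tuple[int, str], MethylExchangeResults]
    model_choice: dict[tuple[int, str], str]
    clusters: list[ClusterExchangeResults]
    unclustered: list[tuple[int, str]]
    warnings_log: list[str] = field(default_factory=list)

    def report_frame(self) -> pd.DataFrame:
        """One row per fitted methyl: model, parameters, sigmas, cluster id."""
        cluster_of: dict[tuple[int, str], int] = {}
        for ci, cl in enumerate(self.clusters):
            for key in cl.member_ids:
                cluster_of[key] = ci
        rows = []
        for key in sorted(set(self.individual) | set(self.flat)):
            choice = self.model_choice.get(key, "flat")
            res = self.individual.get(key) if choice == "exchange" else self.flat.get(key)
            if res is None:
                res = self.flat.get(key) or self.individual.get(key)
            ci = cluster_of.get(key)
            cl = self.clusters[ci] if ci is not None else None
            s = (res.param_sigmas or {}) if res else {}
            row = {
                "residue_id": key[0],
                "aa": res.aa,
                "methyl_id": key[1],
                "model": choice,
                "k_ex_s": res.params.k_ex if choice == "exchange" else "",
                "p_B": res.params.p_B if choice == "exchange" else "",
                "dw_ppm": res.params.dw_ppm if choice == "exchange" else "",
                "k_ex_sigma": s.get("k_ex", ""),
                "p_B_sigma": s.get("p_B", ""),
                "chi2_reduced_individual": res.chi2_reduced,
                "cluster_id": ci if ci is not None else "",
                "cluster_k_ex_s": cl.k_ex if cl else "",
                "cluster_p_B": cl.p_B if cl else "",
                "cluster_dw_ppm": cl.dw_by_member.get(key, "") if cl else "",
                "chi2_reduced_cluster": cl.chi2_by_member.get(key, "") if cl else "",
            }
            for lbl, r20 in sorted(res.params.r20_by_field.items()):
                row[f"r20_{lbl}_s"] = r20
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        buf = io.StringIO()
        cfg = self.config
        print("# cpmgdisp dispersion pipeline summary", file=buf)
        print(f"preset = {cfg.preset or ''}", file=buf)
        print(f"input_table = {cfg.input_table or ''}", file=buf)
        print(f"seed = {cfg.seed}", file=buf)
        print(f"n_reps = {cfg.n_reps}", file=buf)
        print(f"threshold_rex_s = {cfg.threshold_rex}", file=buf)
        print(f"alpha = {cfg.alpha}", file=buf)
        print(f"cluster_gap_log10 = {cfg.cluster_gap}", file=buf)
        for lbl, sg in sorted(self.sigma_by_field.items()):
            print(f"sigma_{lbl}_s = {sg:.6g}", file=buf)
        print(
            f"screened_residues ({len(self.screened_residues)}) = "
            + ",".join(str(r) for r in sorted(self.screened_residues)),
            file=buf,
        )
        n_ex = sum(1 for v in self.model_choice.values() if v == "exchange")
        print(f"exchange_methyls = {n_ex}", file=buf)
        for ci, cl in enumerate(self.clusters):
            s = cl.param_sigmas or {}
            kex_s = s.get("k_ex")
            pb_s = s.get("p_B")
            print(
                f"cluster_{ci}: n_methyls = {len(cl.member_ids)}, "
                f"n_residues = {len({r for r, _ in cl.member_ids})}, "
                f"k_ex = {cl.k_ex:.1f}"
                + (f" +/- {kex_s:.1f}" if kex_s is not None else "")
                + f" s^-1, p_B = {cl.p_B:.4f}"
                + (f" +/- {pb_s:.4f}" if pb_s is not None else ""),
                file=buf,
            )
            print(
                f"cluster_{ci}_members = "
                + ",".join(f"{r}{m}" for r, m in cl.member_ids),
                file=buf,
            )
        print(
            "unclustered_methyls = " + ",".join(f"{r}{m}" for r, m in self.unclustered),
            file=buf,
        )
        for w in self.warnings_log:
            print(f"warning = {w}", file=buf)
        return buf.getvalue()

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.report_frame().to_csv(out / "fit_report.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        (out / "run_summary.txt").write_text(self.summary())
        self.config.to_yaml(out / "config.yaml")


def _group_profiles(
    profiles: Sequence[DispersionProfile],
) -> dict[tuple[int, str], list[DispersionProfile]]:
    groups: dict[tuple[int, str], list[DispersionProfile]] = {}
    for p in profiles:
        groups.setdefault(p.key, []).append(p)
    return groups


def run_dispersion_pipeline(
    config: RunConfig,
    profiles: Optional[Sequence[DispersionProfile]] = None,
    fields: Optional[Mapping[str, FieldContext]] = None,
    schedule: Optional[CpmgSchedule] = None,
) -> PipelineResult:
    """Run screen -> individual fits -> clustering -> global fits -> Monte Carlo.

    Inputs come from (in order of precedence) the ``profiles`` argument, the
    config's ``input_table``, or the config's ``preset`` (simulated with the
    config seed). Deterministic given the seed.
    """
    from . import simulate  # deferred: simulate imports peaks

    log: list[str] = []
    if profiles is None:
        if config.input_table:
            profiles = read_dispersion_table(config.input_table)
        elif config.preset:
            spec = simulate.preset(config.preset)
            profiles, _ = simulate.make_dispersion_dataset(spec, seed=config.seed)
            fields = fields or spec.fields
            schedule = schedule or spec.schedule
        else:
            raise InvalidInputError("config needs a preset, an input table, or profiles")
    profiles = list(profiles)
    if fields is None:
        fields = {lbl: DEFAULT_FIELD_FALLBACK[lbl]
                  for lbl in {p.field_label for p in profiles}}
    if schedule is None:
        schedule = simulate.DEFAULT_SCHEDULE

    labels = {p.field_label for p in profiles}
    if not labels <= set(fields):
        raise InvalidInputError(
            f"profiles reference unknown field labels {sorted(labels - set(fields))}"
        )

    # 1. per-field uncertainties
    if config.sigma_override is not None:
        sigma_by_field = {lbl: float(config.sigma_override) for lbl in labels}
    else:
        sigma_by_field = estimate_sigma_from_duplicates(profiles)
    profiles = apply_pooled_sigma(profiles, sigma_by_field)

    # 2. R_ex screen at the highest field
    screen_field = config.screen_field or max(labels)
    screened = screen_dispersing(profiles, config.threshold_rex, screen_field)

    groups = _group_profiles(profiles)
    individual: dict[tuple[int, str], MethylExchangeResults] = {}
    flat: dict[tuple[int, str], MethylExchangeResults] = {}
    choice: dict[tuple[int, str], str] = {}

    # 3. per-methyl fits + model selection
    for key in sorted(groups):
        group = groups[key]
        model = MethylExchangeModel(group, fields, schedule)
        flat[key] = model.fit_flat()
        if key[0] not in screened:
            # below the dispersion screen: flat by construction of the screen
            choice[key] = "flat"
            continue
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            ex = model.fit()
        for w in caught:
            log.append(f"{key}: {w.message}")
        individual[key] = ex
        screen_profiles = [p for p in group if p.field_label == screen_field]
        rex = rex_observed(screen_profiles[0]) if screen_profiles else None
        choice[key] = model_select(
            ex, flat[key], alpha=config.alpha, rex=rex,
            rex_threshold=config.threshold_rex,
        )
        if not ex.converged:
            log.append(f"{key}: exchange fit did not converge")

    exchange_fits = {k: v for k, v in individual.items() if choice.get(k) == "exchange"}

    # 4. clustering + global fits with ejection
    candidates = [g for g in cluster_by_kex(exchange_fits, config.cluster_gap)
                  if len(g) >= 2]
    clusters: list[ClusterExchangeResults] = []
    cluster_models: list[ClusterExchangeModel] = []
    clustered: set[tuple[int, str]] = set()
    for cand in candidates:
        cmodel = ClusterExchangeModel(
            {k: groups[k] for k in cand}, fields, schedule, exchange_fits
        )
        cres = cmodel.fit()
        if cres.is_empty:
            log.append(f"candidate {cand}: {cres.diagnostic}")
            continue
        clusters.append(cres)
        cluster_models.append(cmodel)
        clustered |= set(cres.member_ids)

    # rescue pass: offer unclustered exchange methyls to every fitted cluster;
    # on multiple acceptances take the lowest chi2 under the cluster params
    leftovers = [k for k in exchange_fits if k not in clustered]
    adopted: dict[int, list[tuple[int, str]]] = {}
    for key in leftovers:
        offers = []
        for ci, cres in enumerate(clusters):
            chi2_c, _dw = chi2_under_shared(
                groups[key], fields, schedule, cres.k_ex, cres.p_B
            )
            if accept_member(chi2_c, exchange_fits[key].chi2_reduced):
                offers.append((chi2_c, ci))
        if offers:
            offers.sort()
            adopted.setdefault(offers[0][1], []).append(key)
    for ci, new_keys in adopted.items():
        members = set(clusters[ci].member_ids) | set(new_keys)
        cmodel = ClusterExchangeModel(
            {k: groups[k] for k in members}, fields, schedule, exchange_fits
        )
        cres = cmodel.fit()
        if not cres.is_empty:
            clusters[ci] = cres
            cluster_models[ci] = cmodel
            clustered |= set(cres.member_ids)

    clusters.sort(key=lambda c: len(c.member_ids), reverse=True)
    unclustered = sorted(k for k in exchange_fits if not any(
        k in c.member_ids for c in clusters
    ))

    # 5. Monte Carlo uncertainties of shared parameters
    if config.monte_carlo:
        rng = np.random.default_rng(config.seed)
        for cres in clusters:
            mc_seed = int(rng.integers(0, 2**31 - 1))
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cres.monte_carlo(n_reps=config.n_reps, seed=mc_seed)
            for w in caught:
                log.append(f"cluster MC: {w.message}")

    return PipelineResult(
        config=config,
        sigma_by_field=sigma_by_field,
        screened_residues=screened,
        individual=individual,
        flat=flat,
        model_choice=choice,
        clusters=clusters,
        unclustered=unclustered,
        warnings_log=log,
    )


# fallback field contexts for tables that use the standard labels
DEFAULT_FIELD_FALLBACK = {
    "11.7T": FieldContext("11.7T", 11.7, 125.7),
    "18.8T": FieldContext("18.8T", 18.8, 201.2),
}


def run_peaks_pipeline(
    free,
    bound,
    tol_h: float = None,
    tol_c: float = None,
    min_split: int = 2,
):
    """Assignment transfer + classification for one free/bound list pair.

    Returns (MatchReport, verdict string).
    """
    from .peaks import (
        DEFAULT_TOL_C,
        DEFAULT_TOL_H,
        classify_complex,
        transfer_assignments,
    )

    report = transfer_assignments(
        free, bound,
        tol_h=DEFAULT_TOL_H if tol_h is None else tol_h,
        tol_c=DEFAULT_TOL_C if tol_c is None else tol_c,
    )
    return report, classify_complex(report, min_split=min_split)
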