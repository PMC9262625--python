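"""Per-methyl and cluster-global fitting of the two-site exchange model.

Model/Results pairs in the statsmodels style:

* :class:`MethylExchangeModel` — one methyl group, all fields jointly; free
  parameters {k_ex, p_B, dw_ppm, R2,0 per field}. ``fit()`` returns a
  :class:`MethylExchangeResults`.
* :class:`ClusterExchangeModel` — a candidate cluster of methyls sharing
  (k_ex, p_B) with per-member dw and per-field R2,0; members violating the
  chi2_cluster/chi2_individual < 2 acceptance rule are ejected and the fit
  repeated until stable. ``fit()`` returns a :class:`ClusterExchangeResults`.

Both Results objects estimate parameter uncertainties by Monte Carlo:
synthetic datasets are drawn as best-fit curve + Gaussian noise at the
per-point sigma, refitted, and the parameter spread over replicates
reported.

Numerical strategy: the per-field baselines R2,0 enter the model linearly
(the exchange contribution is independent of R2,0), so they are profiled
out analytically (variable projection); the nonlinear search runs over
(log10 k_ex, p_B, dw_ppm) only, within physical bounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .exchange import (
    CpmgSchedule,
    ExchangeParams,
    FieldContext,
    InvalidInputError,
    _r2eff_exchange_only,
)
from .profiles import DispersionProfile

__all__ = [
    "FIT_BOUNDS",
    "DEFAULT_START_GRID",
    "MethylExchangeModel",
    "MethylExchangeResults",
    "ClusterExchangeModel",
    "ClusterExchangeResults",
    "fit_individual",
    "fit_flat",
    "model_select",
    "cluster_by_kex",
    "fit_cluster_global",
    "accept_member",
    "monte_carlo_sigmas",
]

#: physical bounds for methyl 13C two-site exchange fits
FIT_BOUNDS = {
    "k_ex": (10.0, 2.0e4),
    "p_B": (1.0e-4, 0.4999),
    "dw_ppm": (1.0e-6, 6.0),
    "r20": (1.0e-6, 200.0),
}

#: multi-start grid covering slow-to-fast exchange regimes
DEFAULT_START_GRID = {
    "k_ex": (200.0, 600.0, 1600.0, 4000.0),
    "p_B": (0.01, 0.05, 0.15),
    "dw_ppm": (0.3, 1.0, 2.0),
}

_LKEX_LO, _LKEX_HI = math.log10(FIT_BOUNDS["k_ex"][0]), math.log10(FIT_BOUNDS["k_ex"][1])


def _projected_r20(y: np.ndarray, g: np.ndarray) -> float:
    """Optimal baseline for uniform weights, clipped to physical bounds."""
    lo, hi = FIT_BOUNDS["r20"]
    return float(np.clip(np.mean(y - g), lo, hi))


def accept_member(chi2_cluster: float, chi2_individual: float) -> bool:
    """Cluster acceptance rule: chi2_cluster / chi2_individual < 2 (strict).

    A member whose individually fitted reduced chi2 is (numerically) zero is
    accepted only if its cluster chi2 is also ~zero.
    """
    if chi2_individual < 0 or chi2_cluster < 0:
        raise InvalidInputError("reduced chi2 values must be non-negative")
    if chi2_individual <= 1e-12:
        return chi2_cluster <= 1e-12
    return chi2_cluster / chi2_individual < 2.0


@dataclass
class _FieldData:
    """Per-field observation block for one methyl."""

    context: FieldContext
    nu: np.ndarray
    y: np.ndarray
    sigma: np.ndarray


def _collect_field_data(
    profiles: Sequence[DispersionProfile], fields: Mapping[str, FieldContext]
) -> dict[str, _FieldData]:
    out: dict[str, _FieldData] = {}
    for p in profiles:
        if p.field_label not in fields:
            raise InvalidInputError(
                f"profile field {p.field_label!r} has no FieldContext "
                f"(known: {sorted(fields)})"
            )
        if p.field_label in out:
            raise InvalidInputError(f"duplicate profile for field {p.field_label!r}")
        out[p.field_label] = _FieldData(
            context=fields[p.field_label],
            nu=np.asarray(p.nu, float),
            y=np.asarray(p.r2eff, float),
            sigma=np.asarray(p.sigma, float),
        )
    return out


class MethylExchangeModel:
    """Two-site exchange model for one methyl group, all fields jointly.

    Parameters
    ----------
    profiles : sequence of DispersionProfile
        One profile per static field for a single (residue, methyl).
    fields : mapping of field label -> FieldContext
    schedule : CpmgSchedule
        Supplies t_relax (and validates the nu grid convention).
    """

    def __init__(
        self,
        profiles: Sequence[DispersionProfile],
        fields: Mapping[str, FieldContext],
        schedule: CpmgSchedule,
    ):
        profiles = list(profiles)
        if not profiles:
            raise InvalidInputError("no profiles supplied")
        keys = {p.key for p in profiles}
        if len(keys) != 1:
            raise InvalidInputError(f"profiles span several methyls: {sorted(keys)}")
        self.key = keys.pop()
        self.aa = profiles[0].aa
        self.profiles = profiles
        self.schedule = schedule
        self.data = _collect_field_data(profiles, fields)
        self.field_labels = sorted(self.data)
        self.n_points = int(sum(len(d.y) for d in self.data.values()))
        n_free = 3 + len(self.data)
        if self.n_points < 8:
            raise InvalidInputError(
                f"need >= 8 points across fields, got {self.n_points}"
            )
        if self.n_points <= n_free:
            raise InvalidInputError(
                f"{self.n_points} points cannot constrain {n_free} free parameters"
            )

    # -- residuals ---------------------------------------------------------

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        lkex, p_B, dw_ppm = x
        k_ex = 10.0**lkex
        res = []
        for label in self.field_labels:
            d = self.data[label]
            g = _r2eff_exchange_only(
                k_ex, p_B, d.context.dw_rad_s(dw_ppm), self.schedule.t_relax, d.nu
            )
            r20 = _projected_r20(d.y, g)
            res.append((d.y - g - r20) / d.sigma)
        return np.concatenate(res)

    def _chi2(self, x: np.ndarray) -> float:
        r = self._residuals(x)
        return float(r @ r)

    def _r20_for(self, x: np.ndarray) -> dict[str, float]:
        lkex, p_B, dw_ppm = x
        k_ex = 10.0**lkex
        out = {}
        for label in self.field_labels:
            d = self.data[label]
            g = _r2eff_exchange_only(
                k_ex, p_B, d.context.dw_rad_s(dw_ppm), self.schedule.t_relax, d.nu
            )
            out[label] = _projected_r20(d.y, g)
        return out

    # -- fitting -----------------------------------------------------------

    def _default_starts(self) -> list[np.ndarray]:
        grid = DEFAULT_START_GRID
        starts = [
            np.array([math.log10(k), p, w])
            for k in grid["k_ex"] for p in grid["p_B"] for w in grid["dw_ppm"]
        ]
        return starts

    def _refine(self, x0: np.ndarray) -> optimize.OptimizeResult:
        lo = [_LKEX_LO, FIT_BOUNDS["p_B"][0], FIT_BOUNDS["dw_ppm"][0]]
        hi = [_LKEX_HI, FIT_BOUNDS["p_B"][1], FIT_BOUNDS["dw_ppm"][1]]
        x0 = np.clip(x0, lo, hi)
        return optimize.least_squares(
            self._residuals, x0, bounds=(lo, hi), method="trf",
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )

    def fit(
        self,
        starts: Optional[Sequence[np.ndarray]] = None,
        n_refine: int = 4,
    ) -> "MethylExchangeResults":
        """Multi-start weighted least squares for the exchange model.

        All starts are scored by their initial chi2; the ``n_refine`` best
        are refined with bounded trust-region least squares and the best
        converged refinement is returned.
        """
        if starts is None:
            starts = self._default_starts()
        scored = sorted(starts, key=self._chi2)
        best: Optional[optimize.OptimizeResult] = None
        for x0 in scored[:n_refine]:
            sol = self._refine(np.asarray(x0, float))
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            return self._make_results(
                np.asarray(scored[0], float), model="exchange", converged=False
            )
        return self._make_results(best.x, model="exchange", converged=True)

    def fit_flat(self) -> "MethylExchangeResults":
        """No-exchange model: a per-field constant R2,0 (p_B = 0)."""
        chi2 = 0.0
        r20 = {}
        for label in self.field_labels:
            d = self.data[label]
            r20[label] = float(np.clip(np.mean(d.y), *FIT_BOUNDS["r20"]))
            chi2 += float(np.sum(((d.y - r20[label]) / d.sigma) ** 2))
        n_free = len(self.field_labels)
        params = ExchangeParams(
            k_ex=FIT_BOUNDS["k_ex"][0], p_B=0.0, dw_ppm=0.0, r20_by_field=r20
        )
        return MethylExchangeResults(
            model="flat", key=self.key, aa=self.aa, params=params, chi2=chi2,
            n_points=self.n_points, n_free=n_free, converged=True, _model=self,
        )

    def _make_results(
        self, x: np.ndarray, model: str, converged: bool
    ) -> "MethylExchangeResults":
        chi2 = self._chi2(x)
        params = ExchangeParams(
            k_ex=10.0 ** x[0], p_B=float(x[1]), dw_ppm=float(x[2]),
            r20_by_field=self._r20_for(x),
        )
        return MethylExchangeResults(
            model=model, key=self.key, aa=self.aa, params=params, chi2=chi2,
            n_points=self.n_points, n_free=3 + len(self.field_labels),
            converged=converged, _model=self, _x=np.array(x),
        )

    # -- simulation --------------------------------------------------------

    def simulate_from(
        self, params: ExchangeParams, rng: np.random.Generator
    ) -> "MethylExchangeModel":
        """Clone of this model with data replaced by params' curve + noise."""
        import copy

        clone = copy.copy(self)
        clone.data = {}
        for label in self.field_labels:
            d = self.data[label]
            g = _r2eff_exchange_only(
                params.k_ex, params.p_B, d.context.dw_rad_s(params.dw_ppm),
                self.schedule.t_relax, d.nu,
            )
            y = params.r20(label) + g + rng.normal(0.0, d.sigma)
            clone.data[label] = _FieldData(d.context, d.nu, y, d.sigma)
        return clone


@dataclass
class MethylExchangeResults:
    """Fit results for one methyl group.

    ``chi2`` is the weighted sum of squared residuals; ``chi2_reduced``
    divides by (n_points - n_free). ``param_sigmas`` is populated by
    :meth:`monte_carlo`.
    """

    model: str  # "exchange" | "flat"
    key: tuple[int, str]
    aa: str
    params: ExchangeParams
    chi2: float
    n_points: int
    n_free: int
    converged: bool
    param_sigmas: Optional[dict[str, float]] = None
    mc_warning: Optional[str] = None
    _model: Optional[MethylExchangeModel] = dc_field(default=None, repr=False)
    _x: Optional[np.ndarray] = dc_field(default=None, repr=False)

    @property
    def chi2_reduced(self) -> float:
        return self.chi2 / max(self.n_points - self.n_free, 1)

    def predict(self, field_label: str, nu: Optional[np.ndarray] = None) -> np.ndarray:
        """Best-fit R2,eff curve at one field (defaults to the fitted nu grid)."""
        d = self._model.data[field_label]
        nus = d.nu if nu is None else np.asarray(nu, float)
        g = _r2eff_exchange_only(
            self.params.k_ex, self.params.p_B,
            d.context.dw_rad_s(self.params.dw_ppm),
            self._model.schedule.t_relax, nus,
        )
        return self.params.r20(field_label) + g

    def monte_carlo(
        self, n_reps: int = 100, seed: int = 0
    ) -> dict[str, float]:
        """Monte Carlo parameter uncertainties (deterministic under seed).

        Draws ``n_reps`` synthetic datasets (best-fit curve + Gaussian noise
        at the per-point sigma), refits each starting from the converged
        solution, and reports the standard deviation of each parameter over
        the converged replicates. A warning is attached if more than 20% of
        replicates fail to converge.
        """
        if not self.converged:
            raise InvalidInputError("Monte Carlo requires a converged fit")
        if self.model != "exchange":
            raise InvalidInputError("Monte Carlo applies to the exchange model")
        rng = np.random.default_rng(seed)
        draws: dict[str, list[float]] = {
            "k_ex": [], "p_B": [], "dw_ppm": [],
            **{f"r20_{lbl}": [] for lbl in self._model.field_labels},
        }
        failures = 0
        for _ in range(n_reps):
            sim = self._model.simulate_from(self.params, rng)
            sol = sim._refine(self._x.copy())
            if not sol.success:
                failures += 1
                continue
            draws["k_ex"].append(10.0 ** sol.x[0])
            draws["p_B"].append(float(sol.x[1]))
            draws["dw_ppm"].append(float(sol.x[2]))
            for lbl, r in sim._r20_for(sol.x).items():
                draws[f"r20_{lbl}"].append(r)
        if failures > 0.2 * n_reps:
            self.mc_warning = (
                f"{failures}/{n_reps} Monte Carlo replicates failed to converge"
            )
            warnings.warn(self.mc_warning, stacklevel=2)
        self.param_sigmas = {
            k: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            for k, v in draws.items()
        }
        return self.param_sigmas

    def summary(self) -> str:
        rid, mid = self.key
        lines = [
            f"Methyl {self.aa}{rid}({mid})  model={self.model}  "
            f"converged={self.converged}",
            f"  chi2 = {self.chi2:.4g}  chi2_reduced = {self.chi2_reduced:.4g}  "
            f"(n = {self.n_points}, free = {self.n_free})",
        ]
        if self.model == "exchange":
            s = self.param_sigmas or {}
            def fmt(name, val):
                sig = s.get(name)
                return f"{val:.4g}" + (f" +/- {sig:.2g}" if sig is not None else "")
            lines.append(
                f"  k_ex = {fmt('k_ex', self.params.k_ex)} s^-1   "
                f"p_B = {fmt('p_B', self.params.p_B)}   "
                f"|dw| = {fmt('dw_ppm', self.params.dw_ppm)} ppm"
            )
        for lbl in sorted(self.params.r20_by_field):
            lines.append(f"  R2,0({lbl}) = {self.params.r20(lbl):.4g} s^-1")
        if self.mc_warning:
            lines.append(f"  WARNING: {self.mc_warning}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Dispersion data and best-fit curves, one axes for all fields."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for lbl in self._model.field_labels:
            d = self._model.data[lbl]
            ax.errorbar(d.nu, d.y, yerr=d.sigma, fmt="o", label=f"{lbl} data")
            grid = np.geomspace(d.nu.min(), d.nu.max(), 100)
            ax.plot(grid, self.predict(lbl, grid), "-", label=f"{lbl} fit")
        rid, mid = self.key
        ax.set_xlabel(r"$\nu_\mathrm{CPMG}$ (s$^{-1}$)")
        ax.set_ylabel(r"$R_{2,\mathrm{eff}}$ (s$^{-1}$)")
        ax.set_title(f"{self.aa}{rid}({mid}) [{self.model}]")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# model selection and clustering
# ---------------------------------------------------------------------------

def model_select(
    exchange_fit: MethylExchangeResults,
    flat_fit: MethylExchangeResults,
    alpha: float = 0.01,
    rex: Optional[float] = None,
    rex_threshold: float = 5.0,
) -> str:
    """Choose "exchange" or "flat" by F-test plus the R_ex screen.

    The exchange model is selected only if the chi2 reduction over the flat
    model is significant at ``alpha`` (F-test on the added parameters) AND
    the observed dispersion amplitude exceeds ``rex_threshold`` (if ``rex``
    is provided). This guards against overfitting flat profiles, which the
    exchange model can always shadow at a parameter bound.
    """
    if exchange_fit.n_points != flat_fit.n_points:
        raise InvalidInputError("fits must be on identical data")
    d1 = exchange_fit.n_free - flat_fit.n_free
    d2 = exchange_fit.n_points - exchange_fit.n_free
    if d1 <= 0 or d2 <= 0:
        return "flat"
    if not exchange_fit.converged:
        return "flat"
    if exchange_fit.chi2 <= 1e-12:
        p = 0.0 if flat_fit.chi2 > 1e-9 else 1.0
    else:
        F = ((flat_fit.chi2 - exchange_fit.chi2) / d1) / (exchange_fit.chi2 / d2)
        p = float(stats.f.sf(max(F, 0.0), d1, d2))
    if p < alpha and (rex is None or rex > rex_threshold):
        return "exchange"
    return "flat"


def cluster_by_kex(
    fits: Mapping[tuple[int, str], MethylExchangeResults],
    gap: float = 0.25,
) -> list[list[tuple[int, str]]]:
    """Candidate clusters by 1-D single-linkage grouping of log10(k_ex).

    Only converged exchange-model fits participate. Consecutive sorted
    log10(k_ex) values further apart than ``gap`` start a new group.
    Candidates are returned largest first (singletons included; the caller
    decides what to do with them).
    """
    items = [
        (math.log10(r.params.k_ex), key)
        for key, r in fits.items()
        if r.model == "exchange" and r.converged
    ]
    if not items:
        return []
    items.sort()
    groups: list[list[tuple[int, str]]] = [[items[0][1]]]
    for (prev, _), (cur, key) in zip(items, items[1:]):
        if cur - prev > gap:
            groups.append([key])
        else:
            groups[-1].append(key)
    groups.sort(key=len, reverse=True)
    return groups


class ClusterExchangeModel:
    """Joint model: shared (k_ex, p_B), per-member dw_ppm and per-field R2,0."""

    def __init__(
        self,
        profiles_by_member: Mapping[tuple[int, str], Sequence[DispersionProfile]],
        fields: Mapping[str, FieldContext],
        schedule: CpmgSchedule,
        individual: Optional[Mapping[tuple[int, str], MethylExchangeResults]] = None,
    ):
        if len(profiles_by_member) < 2:
            raise InvalidInputError("a cluster candidate needs >= 2 members")
        if individual is None:
            individual = {}  # fixed-membership fits only; fit() needs individual
        missing = set(profiles_by_member) - set(individual)
        if missing and individual:
            raise InvalidInputError(f"no individual fits for members {sorted(missing)}")
        self.schedule = schedule
        self.fields = dict(fields)
        self.members = sorted(profiles_by_member)
        self.data = {
            key: _collect_field_data(profiles_by_member[key], fields)
            for key in self.members
        }
        self.aa_by_member = {
            key: list(profiles_by_member[key])[0].aa for key in self.members
        }
        self.individual = dict(individual)

    def _member_residuals(
        self, key: tuple[int, str], k_ex: float, p_B: float, dw_ppm: float
    ) -> np.ndarray:
        res = []
        for label in sorted(self.data[key]):
            d = self.data[key][label]
            g = _r2eff_exchange_only(
                k_ex, p_B, d.context.dw_rad_s(dw_ppm), self.schedule.t_relax, d.nu
            )
            r20 = _projected_r20(d.y, g)
            res.append((d.y - g - r20) / d.sigma)
        return np.concatenate(res)

    def _residuals(self, x: np.ndarray, members: Sequence[tuple[int, str]]) -> np.ndarray:
        k_ex, p_B = 10.0 ** x[0], x[1]
        return np.concatenate(
            [
                self._member_residuals(key, k_ex, p_B, x[2 + i])
                for i, key in enumerate(members)
            ]
        )

    def _start(self, members: Sequence[tuple[int, str]]) -> np.ndarray:
        lkex = float(np.median([math.log10(self.individual[m].params.k_ex) for m in members]))
        p_B = float(np.median([self.individual[m].params.p_B for m in members]))
        dws = [self.individual[m].params.dw_ppm for m in members]
        lo = [_LKEX_LO, FIT_BOUNDS["p_B"][0]] + [FIT_BOUNDS["dw_ppm"][0]] * len(members)
        hi = [_LKEX_HI, FIT_BOUNDS["p_B"][1]] + [FIT_BOUNDS["dw_ppm"][1]] * len(members)
        return np.clip(np.array([lkex, p_B, *dws]), lo, hi)

    def _solve(
        self, members: Sequence[tuple[int, str]], x0: Optional[np.ndarray] = None
    ) -> optimize.OptimizeResult:
        lo = [_LKEX_LO, FIT_BOUNDS["p_B"][0]] + [FIT_BOUNDS["dw_ppm"][0]] * len(members)
        hi = [_LKEX_HI, FIT_BOUNDS["p_B"][1]] + [FIT_BOUNDS["dw_ppm"][1]] * len(members)
        if x0 is None:
            x0 = self._start(members)
        return optimize.least_squares(
            lambda x: self._residuals(x, members), np.clip(x0, lo, hi),
            bounds=(lo, hi), method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )

    def fit_fixed_membership(
        self, x0: Optional[np.ndarray] = None
    ) -> "ClusterExchangeResults":
        """One joint solve with membership held fixed (no ejection).

        ``x0`` is (log10 k_ex, p_B, dw_1..dw_M) in member order; defaults to
        the individual-fit medians (which requires individual results).
        Useful for scoring recovery against known ground-truth memberships
        and for replicate refits.
        """
        members = list(self.members)
        sol = self._solve(members, x0)
        k_ex, p_B = 10.0 ** sol.x[0], float(sol.x[1])
        chi2_map = {}
        for i, key in enumerate(members):
            r = self._member_residuals(key, k_ex, p_B, sol.x[2 + i])
            chi2_map[key] = float(r @ r) / max(len(r) - 3, 1)
        return self._make_results(sol, members, chi2_map, [], [float(2 * sol.cost)])

    def fit(self, max_rounds: int = 20) -> "ClusterExchangeResults":
        """Global fit with iterative ejection of chi2-ratio violators.

        Each round fits all current members jointly, evaluates every
        member's reduced chi2 under the shared parameters (dof = per-member
        points minus the 3 member-specific parameters), and ejects the
        *worst* violator of the < 2 acceptance ratio against its individual
        reduced chi2 (one per round: a single discordant member can drag
        the shared parameters enough to make well-behaved members look like
        violators too). Stops when membership is stable; an empty cluster
        is returned (with the ejection history) if fewer than 2 members
        remain.
        """
        if not self.individual:
            raise InvalidInputError(
                "fit() needs individual fit results for the chi2-ratio rule; "
                "use fit_fixed_membership() when membership is known"
            )
        members = list(self.members)
        ejected: list[tuple[int, str]] = []
        objective_history: list[float] = []
        sol = None
        for _ in range(max_rounds):
            if len(members) < 2:
                return ClusterExchangeResults(
                    member_ids=[], k_ex=float("nan"), p_B=float("nan"),
                    dw_by_member={}, r20_by_member={}, chi2_by_member={},
                    chi2_total=float("nan"), converged=False, ejected=ejected,
                    objective_history=objective_history,
                    diagnostic="all members ejected by the chi2-ratio rule",
                    _model=self,
                )
            sol = self._solve(members)
            objective_history.append(float(2 * sol.cost))
            k_ex, p_B = 10.0 ** sol.x[0], float(sol.x[1])
            violators = []
            chi2_map = {}
            for i, key in enumerate(members):
                r = self._member_residuals(key, k_ex, p_B, sol.x[2 + i])
                dof = max(len(r) - 3, 1)
                chi2_map[key] = float(r @ r) / dof
                indiv = max(self.individual[key].chi2_reduced, 1e-12)
                if not accept_member(chi2_map[key], self.individual[key].chi2_reduced):
                    violators.append((chi2_map[key] / indiv, key))
            if not violators:
                return self._make_results(sol, members, chi2_map, ejected,
                                          objective_history)
            worst = max(violators)[1]
            ejected.append(worst)
            members = [m for m in members if m != worst]
        raise NumericalFailureErrorFromFit(
            "cluster ejection did not stabilise within max_rounds"
        )

    def _make_results(self, sol, members, chi2_map, ejected, history):
        k_ex, p_B = 10.0 ** sol.x[0], float(sol.x[1])
        dw = {key: float(sol.x[2 + i]) for i, key in enumerate(members)}
        r20 = {}
        for key in members:
            r20[key] = {}
            for label in sorted(self.data[key]):
                d = self.data[key][label]
                g = _r2eff_exchange_only(
                    k_ex, p_B, d.context.dw_rad_s(dw[key]), self.schedule.t_relax, d.nu
                )
                r20[key][label] = _projected_r20(d.y, g)
        return ClusterExchangeResults(
            member_ids=list(members), k_ex=k_ex, p_B=p_B, dw_by_member=dw,
            r20_by_member=r20, chi2_by_member=chi2_map,
            chi2_total=float(2 * sol.cost), converged=bool(sol.success),
            ejected=ejected, objective_history=history, _model=self,
            _x=np.array(sol.x),
        )

    def member_chi2_under(
        self, key: tuple[int, str], k_ex: float, p_B: float
    ) -> tuple[float, float]:
        """Reduced chi2 (and best dw) of one methyl under given shared params,
        optimising only its dw and baselines. Used for the cross-cluster
        tie-break and rescue pass."""
        lo, hi = FIT_BOUNDS["dw_ppm"]
        def obj(w):
            r = self._member_residuals(key, k_ex, p_B, w)
            return float(r @ r)
        sol = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded")
        n = sum(len(d.y) for d in self.data[key].values())
        return float(sol.fun) / max(n - 3, 1), float(sol.x)


class NumericalFailureErrorFromFit(ArithmeticError):
    pass


def chi2_under_shared(
    profiles: Sequence[DispersionProfile],
    fields: Mapping[str, FieldContext],
    schedule: CpmgSchedule,
    k_ex: float,
    p_B: float,
) -> tuple[float, float]:
    """Reduced chi2 of one methyl under imposed shared (k_ex, p_B).

    Only the methyl's own dw_ppm (1-D bounded search) and per-field
    baselines are optimised. Returns (reduced chi2, best dw_ppm); dof is
    points minus the 3 member-specific parameters, as in the cluster fit.
    """
    data = _collect_field_data(profiles, fields)

    def residuals(w: float) -> np.ndarray:
        res = []
        for label in sorted(data):
            d = data[label]
            g = _r2eff_exchange_only(
                k_ex, p_B, d.context.dw_rad_s(w), schedule.t_relax, d.nu
            )
            r20 = _projected_r20(d.y, g)
            res.append((d.y - g - r20) / d.sigma)
        return np.concatenate(res)

    lo, hi = FIT_BOUNDS["dw_ppm"]
    sol = optimize.minimize_scalar(
        lambda w: float(residuals(w) @ residuals(w)), bounds=(lo, hi), method="bounded"
    )
    n = sum(len(d.y) for d in data.values())
    return float(sol.fun) / max(n - 3, 1), float(sol.x)


@dataclass
class ClusterExchangeResults:
    """Results of a cluster-global fit.

    ``chi2_by_member`` holds each retained member's reduced chi2 under the
    shared (k_ex, p_B); ``ejected`` lists members removed by the acceptance
    rule, in ejection order. ``param_sigmas`` (shared parameters) is filled
    by :meth:`monte_carlo`.
    """

    member_ids: list[tuple[int, str]]
    k_ex: float
    p_B: float
    dw_by_member: dict[tuple[int, str], float]
    r20_by_member: dict[tuple[int, str], dict[str, float]]
    chi2_by_member: dict[tuple[int, str], float]
    chi2_total: float
    converged: bool
    ejected: list[tuple[int, str]] = dc_field(default_factory=list)
    objective_history: list[float] = dc_field(default_factory=list)
    diagnostic: Optional[str] = None
    param_sigmas: Optional[dict[str, float]] = None
    mc_warning: Optional[str] = None
    _model: Optional[ClusterExchangeModel] = dc_field(default=None, repr=False)
    _x: Optional[np.ndarray] = dc_field(default=None, repr=False)

    @property
    def is_empty(self) -> bool:
        return not self.member_ids

    def member_params(self, key: tuple[int, str]) -> ExchangeParams:
        return ExchangeParams(
            k_ex=self.k_ex, p_B=self.p_B, dw_ppm=self.dw_by_member[key],
            r20_by_field=self.r20_by_member[key],
        )

    def monte_carlo(self, n_reps: int = 100, seed: int = 0) -> dict[str, float]:
        """Monte Carlo uncertainties of the shared (k_ex, p_B).

        Synthetic datasets are drawn around the cluster best-fit curves of
        every retained member and the joint fit repeated with membership
        fixed, starting from the converged solution.
        """
        if self.is_empty or not self.converged:
            raise InvalidInputError("Monte Carlo requires a converged, non-empty cluster")
        model = self._model
        rng = np.random.default_rng(seed)
        kex_draws, pb_draws = [], []
        failures = 0
        # cache noiseless member curves
        curves: dict[tuple, dict[str, np.ndarray]] = {}
        for key in self.member_ids:
            curves[key] = {}
            for label, d in model.data[key].items():
                g = _r2eff_exchange_only(
                    self.k_ex, self.p_B, d.context.dw_rad_s(self.dw_by_member[key]),
                    model.schedule.t_relax, d.nu,
                )
                curves[key][label] = self.r20_by_member[key][label] + g
        true_y = {k: {l: d.y for l, d in model.data[k].items()} for k in model.data}
        try:
            for _ in range(n_reps):
                for key in self.member_ids:
                    for label, d in model.data[key].items():
                        d.y = curves[key][label] + rng.normal(0.0, d.sigma)
                sol = model._solve(self.member_ids, self._x.copy())
                if not sol.success:
                    failures += 1
                    continue
                kex_draws.append(10.0 ** sol.x[0])
                pb_draws.append(float(sol.x[1]))
        finally:
            for key in model.data:
                for label, d in model.data[key].items():
                    d.y = true_y[key][label]
        if failures > 0.2 * n_reps:
            self.mc_warning = (
                f"{failures}/{n_reps} Monte Carlo replicates failed to converge"
            )
            warnings.warn(self.mc_warning, stacklevel=2)
        self.param_sigmas = {
            "k_ex": float(np.std(kex_draws, ddof=1)) if len(kex_draws) > 1 else float("nan"),
            "p_B": float(np.std(pb_draws, ddof=1)) if len(pb_draws) > 1 else float("nan"),
        }
        return self.param_sigmas

    def summary(self) -> str:
        if self.is_empty:
            return f"Empty cluster: {self.diagnostic}"
        s = self.param_sigmas or {}
        def fmt(name, val):
            sig = s.get(name)
            return f"{val:.4g}" + (f" +/- {sig:.2g}" if sig is not None else "")
        lines = [
            f"Cluster of {len(self.member_ids)} methyls "
            f"({len(set(r for r, _ in self.member_ids))} residues)",
            f"  shared k_ex = {fmt('k_ex', self.k_ex)} s^-1   "
            f"p_B = {fmt('p_B', self.p_B)}",
        ]
        for key in self.member_ids:
            rid, mid = key
            aa = self._model.aa_by_member[key]
            lines.append(
                f"  {aa}{rid}({mid}): |dw| = {self.dw_by_member[key]:.3f} ppm  "
                f"chi2_cluster = {self.chi2_by_member[key]:.3g}"
            )
        if self.ejected:
            lines.append(f"  ejected: {self.ejected}")
        if self.mc_warning:
            lines.append(f"  WARNING: {self.mc_warning}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers (operation-level surface)
# ---------------------------------------------------------------------------

def fit_individual(
    profiles: Sequence[DispersionProfile],
    fields: Mapping[str, FieldContext],
    schedule: CpmgSchedule,
) -> MethylExchangeResults:
    """Independent two-site fit of one methyl's profiles (all fields jointly)."""
    return MethylExchangeModel(profiles, fields, schedule).fit()


def fit_flat(
    profiles: Sequence[DispersionProfile],
    fields: Mapping[str, FieldContext],
    schedule: CpmgSchedule,
) -> MethylExchangeResults:
    return MethylExchangeModel(profiles, fields, schedule).fit_flat()


def fit_cluster_global(
    profiles_by_member: Mapping[tuple[int, str], Sequence[DispersionProfile]],
    fields: Mapping[str, FieldContext],
    schedule: CpmgSchedule,
    individual: Mapping[tuple[int, str], MethylExchangeResults],
) -> ClusterExchangeResults:
    """Joint fit of a candidate cluster with chi2-ratio ejection."""
    return ClusterExchangeModel(profiles_by_member, fields, schedule, individual).fit()


def monte_carlo_sigmas(
    fit, n_reps: int = 100, seed: int = 0
) -> dict[str, float]:
    """Monte Carlo parameter uncertainties for a methyl or cluster results object."""
    return fit.monte_carlo(n_reps=n_reps, seed=seed)
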