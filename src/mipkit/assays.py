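"""Quantification of oocyte functional assays.

Osmotic water permeability (Pf, cm/s) is estimated from the initial linear
phase of an oocyte swelling time-course recorded after transfer into
hypo-osmotic medium:

    Pf = V0 * d(V/V0)/dt / (S * Vw * (Osm_in - Osm_out))

with V0 the initial oocyte volume (cm^3), S its surface area (cm^2),
Vw = 18 cm^3/mol the molar volume of water, and osmolarities converted
from mOsm to mol/cm^3 (factor 1e-6).  The slope d(V/V0)/dt comes from an
ordinary least-squares fit over the configured initial window (default the
first 20 s, sampled every 2 s).  When only the oocyte diameter is given,
spherical geometry supplies V0 = pi d^3 / 6 and S = pi d^2.

Radiolabeled solute uptake (glycerol, urea) is corrected per oocyte by
subtracting the zero-time baseline (signal from externally bound solute),
floored at zero with a flag.  Group comparisons use the classical pooled
two-sided Student's t test with significance at p < 0.01 (Welch available
via ``welch=True``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Molar volume of water, cm^3/mol.
VW_WATER = 18.0
#: mOsm -> osmol/cm^3.
MOSM_TO_MOL_PER_CM3 = 1e-6


@dataclass(frozen=True)
class SwellingTimecourse:
    """One oocyte's relative-volume series under an osmotic gradient."""

    oocyte_id: str
    group: str
    times: tuple[float, ...]  # seconds from transfer
    relative_volume: tuple[float, ...]  # V/V0
    osm_in: float  # mOsm
    osm_out: float  # mOsm
    diameter_cm: float | None = None
    v0_cm3: float | None = None
    s_cm2: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if len(t) != len(self.relative_volume):
            raise ValueError(f"{self.oocyte_id}: times/volumes length mismatch")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError(f"{self.oocyte_id}: times must be strictly increasing")
        if self.diameter_cm is None and (self.v0_cm3 is None or self.s_cm2 is None):
            raise ValueError(
                f"{self.oocyte_id}: need diameter_cm or explicit v0_cm3 + s_cm2"
            )

    @property
    def v0(self) -> float:
        if self.v0_cm3 is not None:
            return self.v0_cm3
        return math.pi * self.diameter_cm ** 3 / 6.0

    @property
    def surface(self) -> float:
        if self.s_cm2 is not None:
            return self.s_cm2
        return math.pi * self.diameter_cm ** 2


@dataclass(frozen=True)
class PfEstimate:
    pf: float  # cm/s
    slope: float  # d(V/V0)/dt, 1/s
    fit_window: tuple[float, float]
    fit_quality: float  # R^2 of the linear fit
    n_points: int
    vw_used: float = VW_WATER


@dataclass(frozen=True)
class UptakeMeasurement:
    oocyte_id: str
    group: str
    solute: str  # "glycerol" or "urea"
    counts: float  # counts at the uptake endpoint
    baseline_counts: float  # zero-time signal from externally bound solute

    def __post_init__(self) -> None:
        if self.counts < 0 or self.baseline_counts < 0:
            raise ValueError(f"{self.oocyte_id}: counts must be >= 0")

    @property
    def corrected(self) -> float:
        return max(0.0, self.counts - self.baseline_counts)

    @property
    def floored(self) -> bool:
        return self.counts - self.baseline_counts < 0


@dataclass(frozen=True)
class AssayComparison:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_statistic: float
    p_value: float
    alpha: float
    fold_change: float  # mean_a / mean_b (b = control)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compute_pf(
    tc: SwellingTimecourse,
    vw: float = VW_WATER,
    fit_window: tuple[float, float] = (0.0, 20.0),
) -> PfEstimate:
    """Estimate Pf from the initial slope of a swelling time-course.

    Requires at least three points in the fit window and a non-zero osmotic
    gradient.  The sign convention makes hypo-osmotic swelling
    (Osm_in > Osm_out, positive slope) yield a positive Pf.
    """
    lo, hi = fit_window
    if hi <= lo:
        raise ValueError("fit window must have positive length")
    if tc.osm_in == tc.osm_out:
        raise ValueError(
            f"{tc.oocyte_id}: osmotic gradient is zero (osm_in == osm_out)"
        )
    t = np.asarray(tc.times, dtype=float)
    v = np.asarray(tc.relative_volume, dtype=float)
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"{tc.oocyte_id}: need >=3 points in fit window, got {int(mask.sum())}"
        )
    fit = stats.linregress(t[mask], v[mask])
    gradient = (tc.osm_in - tc.osm_out) * MOSM_TO_MOL_PER_CM3
    pf = tc.v0 * fit.slope / (tc.surface * vw * gradient)
    return PfEstimate(
        pf=float(pf),
        slope=float(fit.slope),
        fit_window=(lo, hi),
        fit_quality=float(fit.rvalue ** 2) if not math.isnan(fit.rvalue) else 1.0,
        n_points=int(mask.sum()),
        vw_used=vw,
    )


def group_compare(
    values_a, values_b, alpha: float = 0.01, welch: bool = False
) -> AssayComparison:
    """Unpaired two-sided Student's t test between two groups.

    The classical pooled-variance form is the default; ``welch=True``
    switches to the unequal-variance form.  Two groups with zero variance
    and equal means take the convention t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
    mean_b = b.mean()
    return AssayComparison(
        mean_a=float(a.mean()),
        sem_a=float(a.std(ddof=1) / math.sqrt(len(a))),
        n_a=len(a),
        mean_b=float(mean_b),
        sem_b=float(b.std(ddof=1) / math.sqrt(len(b))),
        n_b=len(b),
        t_statistic=float(t_stat),
        p_value=float(p),
        alpha=alpha,
        fold_change=float(a.mean() / mean_b) if mean_b != 0 else math.inf,
    )


@dataclass(frozen=True)
class InhibitionReport:
    percent_inhibition: float
    blocked: bool  # treated vs baseline significant
    reversible: bool | None  # None when no recovered group supplied
    treated_vs_baseline: AssayComparison
    recovered_vs_baseline: AssayComparison | None


def inhibition_analysis(
    baseline, treated, recovered=None, alpha: float = 0.01
) -> InhibitionReport:
    """Quantify mercurial block of permeability and its reversibility.

    Percent inhibition is ``(1 - mean_treated / mean_baseline) * 100``.
    The block is ``reversible`` iff the recovered group is not
    significantly different from baseline while the treated group is.
    """
    baseline = np.asarray(baseline, dtype=float)
    if len(baseline) == 0 or len(np.asarray(treated)) == 0:
        raise ValueError("baseline and treated groups must be non-empty")
    if baseline.mean() <= 0:
        raise ValueError("mean baseline permeability must be positive")
    cmp_treated = group_compare(treated, baseline, alpha=alpha)
    inhibition = (1.0 - cmp_treated.mean_a / baseline.mean()) * 100.0
    cmp_recovered = None
    reversible: bool | None = None
    if recovered is not None:
        cmp_recovered = group_compare(recovered, baseline, alpha=alpha)
        reversible = (not cmp_recovered.significant) and cmp_treated.significant
    return InhibitionReport(
        percent_inhibition=float(inhibition),
        blocked=cmp_treated.significant,
        reversible=reversible,
        treated_vs_baseline=cmp_treated,
        recovered_vs_baseline=cmp_recovered,
    )


@dataclass(frozen=True)
class UptakeSummary:
    table: pd.DataFrame  # per (group, solute): corrected mean, SEM, n, flags
    comparisons: dict  # (group, solute) -> AssayComparison vs control


def uptake_summary(
    measurements: list[UptakeMeasurement],
    control_group: str,
    alpha: float = 0.01,
) -> UptakeSummary:
    """Baseline-corrected uptake means +/- SEM and significance vs control."""
    groups = {m.group for m in measurements}
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent from data")
    rows = []
    corrected: dict[tuple[str, str], list[float]] = {}
    for m in measurements:
        corrected.setdefault((m.group, m.solute), []).append(m.corrected)
    for (group, solute), vals in sorted(corrected.items()):
        vals_arr = np.asarray(vals)
        rows.append({
            "group": group,
            "solute": solute,
            "n": len(vals),
            "corrected_mean": float(vals_arr.mean()),
            "sem": float(vals_arr.std(ddof=1) / math.sqrt(len(vals)))
                   if len(vals) > 1 else float("nan"),
            "n_floored": sum(
                m.floored for m in measurements
                if (m.group, m.solute) == (group, solute)
            ),
        })
    comparisons = {}
    for (group, solute), vals in sorted(corrected.items()):
        if group == control_group:
            continue
        key = (control_group, solute)
        if key not in corrected:
            raise ValueError(
                f"no control-group ({control_group!r}) measurements for {solute}"
            )
        comparisons[(group, solute)] = group_compare(
            vals, corrected[key], alpha=alpha
        )
    return UptakeSummary(pd.DataFrame(rows), comparisons)


# ---------------------------------------------------------------------------
# CSV ingest
# ---------------------------------------------------------------------------

def read_swelling_csv(path) -> list[SwellingTimecourse]:
    """Read swelling time-courses from a long-format CSV.

    Columns: oocyte_id, group, time_s, rel_volume, osm_in, osm_out and
    either diameter_cm or v0_cm3 + s_cm2.
    """
    table = pd.read_csv(path)
    out = []
    for oid, sub in table.groupby("oocyte_id", sort=False):
        sub = sub.sort_values("time_s")
        first = sub.iloc[0]
        out.append(SwellingTimecourse(
            oocyte_id=str(oid),
            group=str(first["group"]),
            times=tuple(sub["time_s"].astype(float)),
            relative_volume=tuple(sub["rel_volume"].astype(float)),
            osm_in=float(first["osm_in"]),
            osm_out=float(first["osm_out"]),
            diameter_cm=float(first["diameter_cm"])
                if "diameter_cm" in sub.columns else None,
            v0_cm3=float(first["v0_cm3"]) if "v0_cm3" in sub.columns else None,
            s_cm2=float(first["s_cm2"]) if "s_cm2" in sub.columns else None,
        ))
    return out


def read_uptake_csv(path) -> list[UptakeMeasurement]:
    """Read uptake counts (CSV: oocyte_id, group, solute, counts, baseline_counts)."""
    table = pd.read_csv(path)
    return [
        UptakeMeasurement(
            oocyte_id=str(r.oocyte_id), group=str(r.group), solute=str(r.solute),
            counts=float(r.counts), baseline_counts=float(r.baseline_counts),
        )
        for r in table.itertuples(index=False)
    ]
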