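"""Target identification from replicate melting-point shifts.

Two vehicle (DMSO) and two drug-treated TPP runs give four melting curves
per protein.  A protein is screened as a potential target when

1. both drug-vs-vehicle melting-point shifts have the same sign
   (replicate sign concordance),
2. both shifts exceed, in magnitude, the shift between the two vehicle
   runs (the technical noise floor), and
3. all of its curves pass the flat-slope quality filter
   (|inflection slope| >= 0.06 by default).

Surviving proteins are then ranked by the maximum-magnitude
per-temperature -log2 fold change of drug vs vehicle relative abundance,
with a symmetric cutoff of +-1 (a two-fold soluble-fraction change at some
temperature).  Negative ΔTm with positive fold-change score indicates
drug-induced thermal destabilization; the reverse indicates stabilization.

The module also carries the single-protein CETSA validation stage: a
balanced two-way ANOVA (temperature x treatment) on western-blot band
intensities with Bonferroni-adjusted per-temperature comparisons, plus
condition-wise melting fits for a ΔTm estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, ValidationError
from .melt_fit import (
    MeltingCurveFit,
    SLOPE_THRESHOLD,
    fit_melting_curve,
    passes_slope_filter,
)
from .quant_io import MeltProfile, TemperatureGradient, normalize_condition

__all__ = [
    "ShiftRecord",
    "TargetCall",
    "TargetCallResult",
    "CetsaResult",
    "FC_CUTOFF",
    "ABUNDANCE_FLOOR",
    "compute_shift_record",
    "apply_shift_criteria",
    "apply_fc_cutoff",
    "call_targets",
    "analyze_cetsa",
]

#: Symmetric cutoff on the maximum -log2 fold-change score.
FC_CUTOFF = 1.0
#: Floor applied to relative abundances before taking log ratios.
ABUNDANCE_FLOOR = 1e-6

EXCLUSION_REASONS = (
    "none", "unfittable", "flat_slope", "sign_discordant",
    "below_control", "below_fc_cutoff",
)

CurveKey = Tuple[str, int]  # (condition, replicate)


@dataclass(frozen=True)
class ShiftRecord:
    """Per-protein ΔTm triplet, criteria flags and fold-change score.

    ``dtm_1``/``dtm_2`` are drug-vs-vehicle melting-point shifts for the
    paired replicates; ``dtm_ctrl`` is the vehicle rep1 - rep2 shift used
    as the noise floor.  ``fc_profile`` holds per-temperature
    ``-log2(drug/vehicle)`` mean relative-abundance ratios and
    ``max_fc_score`` its largest-magnitude entry (sign preserved).
    Unfittable records (any undefined Tm) carry no criteria flags.
    """

    protein_id: str
    dtm_1: Optional[float]
    dtm_2: Optional[float]
    dtm_ctrl: Optional[float]
    sign_concordant: Optional[bool]
    exceeds_control: Optional[bool]
    slope_pass: Optional[bool]
    fc_profile: Optional[Tuple[float, ...]]
    max_fc_score: Optional[float]
    tm_vehicle: Tuple[Optional[float], Optional[float]] = (None, None)
    tm_drug: Tuple[Optional[float], Optional[float]] = (None, None)
    min_abs_slope: Optional[float] = None
    unfittable: bool = False
    n_floored: int = 0

    def __post_init__(self) -> None:
        # canonicalize so file round-trips compare equal
        for name in ("tm_vehicle", "tm_drug"):
            v = getattr(self, name)
            object.__setattr__(self, name, (None, None) if v is None else tuple(v))
        if self.fc_profile is not None:
            object.__setattr__(self, "fc_profile", tuple(self.fc_profile))


@dataclass(frozen=True)
class TargetCall:
    """Final classification of one protein."""

    protein_id: str
    classification: str  # candidate_destabilized | candidate_stabilized | excluded
    exclusion_reason: str
    shift: ShiftRecord


@dataclass
class TargetCallResult:
    """Ordered calls plus run-summary counts at each filter stage."""

    calls: list
    summary: Dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self):
        return len(self.calls)


def _fc_profile(
    profiles: Mapping[CurveKey, MeltProfile],
    n_temps: int,
    floor: float = ABUNDANCE_FLOOR,
) -> Tuple[Tuple[float, ...], float, int]:
    """Per-temperature -log2(mean drug / mean vehicle) with a floor guard."""
    veh = [np.asarray(profiles[k].rel_abundance) for k in profiles if k[0] == "vehicle"]
    drg = [np.asarray(profiles[k].rel_abundance) for k in profiles if k[0] == "drug"]
    if not veh or not drg:
        raise ValidationError("fold-change profile needs both conditions")
    with np.errstate(invalid="ignore"):
        mv = np.nanmean(np.vstack(veh), axis=0)
        md = np.nanmean(np.vstack(drg), axis=0)
    n_floored = int(np.sum((mv < floor) | (md < floor) | ~np.isfinite(mv) | ~np.isfinite(md)))
    mv = np.where(np.isfinite(mv), np.maximum(mv, floor), floor)
    md = np.where(np.isfinite(md), np.maximum(md, floor), floor)
    fc = -np.log2(md / mv)
    peak = int(np.argmax(np.abs(fc)))
    return tuple(float(v) for v in fc), float(fc[peak]), n_floored


def compute_shift_record(
    fits: Mapping[CurveKey, MeltingCurveFit],
    profiles: Mapping[CurveKey, MeltProfile],
    gradient: TemperatureGradient,
    *,
    slope_threshold: float = SLOPE_THRESHOLD,
    slope_scope: str = "all",
    pairing: str = "index",
) -> ShiftRecord:
    """Assemble the ΔTm triplet and criteria flags for one protein.

    ``fits``/``profiles`` are keyed by ``(condition, replicate)`` with
    conditions ``vehicle``/``drug`` and replicates 1 and 2.  With
    ``pairing='index'`` drug replicate i is compared against vehicle
    replicate i; ``pairing='min'`` pairs each drug replicate with the
    vehicle replicate minimizing |ΔTm| (conservative).  ``slope_scope``
    is ``'all'`` (all four curves must pass the slope filter) or
    ``'vehicle'`` (vehicle curves only).

    If any of the four curves is missing, non-converged, or has an
    undefined Tm, the record is flagged unfittable and no criteria are
    evaluated.
    """
    pid = next(iter(profiles.values())).protein_id if profiles else "?"
    keys = [("vehicle", 1), ("vehicle", 2), ("drug", 1), ("drug", 2)]
    fits = {(normalize_condition(c), r): f for (c, r), f in fits.items()}
    if any(k not in fits for k in keys) or any(
        not fits[k].converged or fits[k].tm is None for k in keys
    ):
        tm_of = lambda k: fits[k].tm if k in fits and fits[k].converged else None
        return ShiftRecord(
            protein_id=pid,
            dtm_1=None, dtm_2=None, dtm_ctrl=None,
            sign_concordant=None, exceeds_control=None, slope_pass=None,
            fc_profile=None, max_fc_score=None,
            tm_vehicle=(tm_of(("vehicle", 1)), tm_of(("vehicle", 2))),
            tm_drug=(tm_of(("drug", 1)), tm_of(("drug", 2))),
            unfittable=True,
        )

    tm = {k: float(fits[k].tm) for k in keys}
    if pairing == "index":
        dtm_1 = tm[("drug", 1)] - tm[("vehicle", 1)]
        dtm_2 = tm[("drug", 2)] - tm[("vehicle", 2)]
    elif pairing == "min":
        dtm_1 = min(
            (tm[("drug", 1)] - tm[("vehicle", j)] for j in (1, 2)), key=abs
        )
        dtm_2 = min(
            (tm[("drug", 2)] - tm[("vehicle", j)] for j in (1, 2)), key=abs
        )
    else:
        raise ValidationError(f"unknown replicate pairing mode {pairing!r}")
    dtm_ctrl = tm[("vehicle", 1)] - tm[("vehicle", 2)]

    if slope_scope == "all":
        slope_keys = keys
    elif slope_scope == "vehicle":
        slope_keys = [("vehicle", 1), ("vehicle", 2)]
    else:
        raise ValidationError(f"unknown slope_scope {slope_scope!r}")
    slope_pass = all(passes_slope_filter(fits[k], slope_threshold) for k in slope_keys)
    slopes = [abs(fits[k].slope) for k in keys if fits[k].slope is not None]

    profiles = {(normalize_condition(c), r): p for (c, r), p in profiles.items()}
    fc_profile, max_fc, n_floored = _fc_profile(profiles, len(gradient))

    return ShiftRecord(
        protein_id=pid,
        dtm_1=dtm_1,
        dtm_2=dtm_2,
        dtm_ctrl=dtm_ctrl,
        sign_concordant=dtm_1 * dtm_2 > 0,
        exceeds_control=min(abs(dtm_1), abs(dtm_2)) > abs(dtm_ctrl),
        slope_pass=slope_pass,
        fc_profile=fc_profile,
        max_fc_score=max_fc,
        tm_vehicle=(tm[("vehicle", 1)], tm[("vehicle", 2)]),
        tm_drug=(tm[("drug", 1)], tm[("drug", 2)]),
        min_abs_slope=min(slopes) if slopes else None,
        n_floored=n_floored,
    )


def apply_shift_criteria(record: ShiftRecord) -> Tuple[bool, str]:
    """Evaluate the screening criteria in order: slope, sign, control.

    Returns ``(passes, reason)`` where ``reason`` names the first failing
    criterion (``flat_slope``, ``sign_discordant``, ``below_control``) or
    ``none`` on a pass.  Unfittable records fail with ``unfittable``.
    """
    if record.unfittable:
        return False, "unfittable"
    if not record.slope_pass:
        return False, "flat_slope"
    if not record.sign_concordant:
        return False, "sign_discordant"
    if not record.exceeds_control:
        return False, "below_control"
    return True, "none"


def apply_fc_cutoff(record: ShiftRecord, cutoff: float = FC_CUTOFF) -> bool:
    """Symmetric fold-change cutoff: |max_fc_score| >= cutoff (inclusive)."""
    if cutoff <= 0:
        return True
    if record.max_fc_score is None or not math.isfinite(record.max_fc_score):
        return False
    return abs(record.max_fc_score) >= cutoff


def _classify(record: ShiftRecord) -> str:
    return "candidate_destabilized" if record.dtm_1 < 0 else "candidate_stabilized"


def call_targets(
    profiles: Iterable[MeltProfile],
    gradient: TemperatureGradient,
    *,
    slope_threshold: float = SLOPE_THRESHOLD,
    fc_cutoff: float = FC_CUTOFF,
    min_points: int = 8,
    pairing: str = "index",
    slope_scope: str = "all",
    r_squared_min: Optional[float] = None,
    fits: Optional[Mapping[Tuple[str, str, int], MeltingCurveFit]] = None,
) -> TargetCallResult:
    """Run the full screen over a proteome of normalized profiles.

    Every input protein yields exactly one :class:`TargetCall`.  Candidates
    come first, ordered by |max_fc_score| descending, ties by
    |dtm_1 + dtm_2| descending, then protein id; excluded proteins follow
    in protein-id order.  ``fits`` may supply precomputed curves keyed by
    ``(protein_id, condition, replicate)`` (the staged CLI path); missing
    curves are fitted here.

    The optional ``r_squared_min`` gate (off by default) treats fits below
    the threshold as unusable, excluding the protein as unfittable.
    """
    by_protein: Dict[str, Dict[CurveKey, MeltProfile]] = {}
    for prof in profiles:
        by_protein.setdefault(prof.protein_id, {})[(prof.condition, prof.replicate)] = prof

    fits = dict(fits) if fits else {}
    calls = []
    for pid in sorted(by_protein):
        curves = by_protein[pid]
        prot_fits: Dict[CurveKey, MeltingCurveFit] = {}
        for key, prof in curves.items():
            fit = fits.get((pid,) + key)
            if fit is None:
                fit = fit_melting_curve(prof, gradient, min_points=min_points)
            if (
                r_squared_min is not None
                and fit.converged
                and (fit.r_squared is None or fit.r_squared < r_squared_min)
            ):
                fit = MeltingCurveFit(
                    fit.params, None, None, fit.r_squared, fit.n_points,
                    False, "below r_squared gate",
                )
            prot_fits[key] = fit
        record = compute_shift_record(
            prot_fits, curves, gradient,
            slope_threshold=slope_threshold,
            slope_scope=slope_scope, pairing=pairing,
        )
        passed, reason = apply_shift_criteria(record)
        if passed and not apply_fc_cutoff(record, fc_cutoff):
            passed, reason = False, "below_fc_cutoff"
        classification = _classify(record) if passed else "excluded"
        calls.append(TargetCall(pid, classification, reason, record))

    candidates = [c for c in calls if c.classification != "excluded"]
    excluded = [c for c in calls if c.classification == "excluded"]
    candidates.sort(
        key=lambda c: (
            -abs(c.shift.max_fc_score),
            -abs(c.shift.dtm_1 + c.shift.dtm_2),
            c.protein_id,
        )
    )
    excluded.sort(key=lambda c: c.protein_id)
    ordered = candidates + excluded

    reasons = {r: 0 for r in EXCLUSION_REASONS}
    for c in ordered:
        reasons[c.exclusion_reason] += 1
    n = len(ordered)
    n_fittable = n - reasons["unfittable"]
    n_slope = n_fittable - reasons["flat_slope"]
    n_criteria = n_slope - reasons["sign_discordant"] - reasons["below_control"]
    n_final = n_criteria - reasons["below_fc_cutoff"]
    summary = {
        "n_proteins": n,
        "n_fittable": n_fittable,
        "n_slope_pass": n_slope,
        "n_criteria_pass": n_criteria,
        "n_candidates": n_final,
        "n_candidate_destabilized": sum(
            1 for c in ordered if c.classification == "candidate_destabilized"
        ),
        "n_candidate_stabilized": sum(
            1 for c in ordered if c.classification == "candidate_stabilized"
        ),
    }
    summary.update({f"n_excluded_{r}": reasons[r] for r in EXCLUSION_REASONS if r != "none"})
    return TargetCallResult(ordered, summary)


# ---------------------------------------------------------------------------
# CETSA-WB validation

@dataclass
class CetsaResult:
    """Two-way ANOVA summary of a CETSA melt with per-temperature posttests.

    ``anova`` has rows treatment/temperature/interaction/residual with
    df, sum_sq, mean_sq, F and p.  ``contrasts`` has one row per
    temperature with the condition means, the Welch t statistic and
    raw/Bonferroni-adjusted p-values.  ``tm_vehicle``/``tm_drug`` come
    from condition-wise sigmoid fits of the mean normalized series.
    """

    anova: pd.DataFrame
    contrasts: pd.DataFrame
    means: pd.DataFrame
    n_replicates: int
    tm_vehicle: Optional[float]
    tm_drug: Optional[float]
    dtm: Optional[float]

    @property
    def treatment_f(self) -> float:
        return float(self.anova.loc["treatment", "F"])

    @property
    def interaction_f(self) -> float:
        return float(self.anova.loc["interaction", "F"])

    @property
    def temperature_f(self) -> float:
        return float(self.anova.loc["temperature", "F"])


def analyze_cetsa(
    table: pd.DataFrame,
    temperatures: Sequence[float],
    *,
    min_points: int = 8,
) -> CetsaResult:
    """Analyze a CETSA band-intensity table (2 conditions x k temperatures).

    Each replicate series is first normalized to its value at the lowest
    temperature.  A balanced two-way ANOVA (treatment x temperature, with
    interaction) is fitted on the normalized values; unbalanced tables are
    rejected, and designs with a single replicate per cell or zero
    within-cell variance everywhere raise
    :class:`~meltshift.errors.DegenerateDesignError`.  Per-temperature
    vehicle-vs-drug comparisons are Welch t-tests (per-cell variances, which respect
    the heteroscedasticity of ratio-normalized band intensities) with
    Bonferroni adjustment by the number of temperatures.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    temps = [float(t) for t in temperatures]
    k = len(temps)
    for col in ("replicate", "condition"):
        if col not in table.columns:
            raise ValidationError(f"CETSA table lacks column '{col}'")

    # per-series normalization to the lowest temperature
    rows = []
    for _, row in table.iterrows():
        cond = normalize_condition(row["condition"])
        ref = float(row[temps[0]])
        if not math.isfinite(ref) or ref <= 0:
            raise ValidationError(
                f"CETSA series (rep {row['replicate']}, {cond}): zero or missing "
                "reference-temperature intensity"
            )
        for t in temps:
            rows.append(
                {
                    "replicate": int(row["replicate"]),
                    "condition": cond,
                    "temperature": t,
                    "value": float(row[t]) / ref,
                }
            )
    long = pd.DataFrame(rows)

    counts = long.groupby(["condition", "temperature"])["value"].count()
    if counts.nunique() != 1:
        raise ValidationError("unbalanced CETSA design: unequal cell counts")
    r = int(counts.iloc[0])
    if r < 2:
        raise DegenerateDesignError(
            "CETSA analysis needs >= 2 replicates per condition x temperature cell"
        )
    if set(long["condition"]) != {"vehicle", "drug"}:
        raise ValidationError("CETSA table must contain both vehicle and drug series")

    model = smf.ols("value ~ C(condition) * C(temperature)", data=long).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    anova = pd.DataFrame(
        {
            "df": [
                aov.loc["C(condition)", "df"],
                aov.loc["C(temperature)", "df"],
                aov.loc["C(condition):C(temperature)", "df"],
                aov.loc["Residual", "df"],
            ],
            "sum_sq": [
                aov.loc["C(condition)", "sum_sq"],
                aov.loc["C(temperature)", "sum_sq"],
                aov.loc["C(condition):C(temperature)", "sum_sq"],
                aov.loc["Residual", "sum_sq"],
            ],
            "F": [
                aov.loc["C(condition)", "F"],
                aov.loc["C(temperature)", "F"],
                aov.loc["C(condition):C(temperature)", "F"],
                np.nan,
            ],
            "p": [
                aov.loc["C(condition)", "PR(>F)"],
                aov.loc["C(temperature)", "PR(>F)"],
                aov.loc["C(condition):C(temperature)", "PR(>F)"],
                np.nan,
            ],
        },
        index=["treatment", "temperature", "interaction", "residual"],
    )
    anova["mean_sq"] = anova["sum_sq"] / anova["df"]
    ms_resid = float(anova.loc["residual", "mean_sq"])
    df_resid = float(anova.loc["residual", "df"])
    ss_total = float(np.sum((long["value"] - long["value"].mean()) ** 2))
    if ms_resid <= 0 or float(anova.loc["residual", "sum_sq"]) <= 1e-12 * max(ss_total, 1e-300):
        raise DegenerateDesignError(
            "zero within-cell variance across all cells; ANOVA is degenerate"
        )

    means = long.groupby(["condition", "temperature"])["value"].mean().unstack()
    sems = long.groupby(["condition", "temperature"])["value"].sem().unstack()

    # Bonferroni posttests: Welch t-test of drug vs vehicle per temperature.
    # Per-cell variances (not the pooled residual MS) because multiplicative
    # band-intensity noise makes the normalized values strongly
    # heteroscedastic across temperatures; pooling would understate the
    # variance of the cold cells and inflate the family-wise error.
    contrast_rows = []
    for t in temps:
        veh_vals = long.query("condition == 'vehicle' and temperature == @t")["value"].to_numpy()
        drg_vals = long.query("condition == 'drug' and temperature == @t")["value"].to_numpy()
        diff = float(means.loc["drug", t] - means.loc["vehicle", t])
        v1, v2 = drg_vals.var(ddof=1), veh_vals.var(ddof=1)
        if v1 + v2 > 0:
            se_t = math.sqrt(v1 / r + v2 / r)
            tstat = diff / se_t
            df_w = (v1 / r + v2 / r) ** 2 / (
                (v1 / r) ** 2 / (r - 1) + (v2 / r) ** 2 / (r - 1)
            )
            p_raw = 2.0 * sps.t.sf(abs(tstat), df_w)
        else:
            tstat = 0.0 if diff == 0 else math.copysign(math.inf, diff)
            p_raw = 1.0 if diff == 0 else 0.0
        contrast_rows.append(
            {
                "temperature": t,
                "mean_vehicle": float(means.loc["vehicle", t]),
                "mean_drug": float(means.loc["drug", t]),
                "sem_vehicle": float(sems.loc["vehicle", t]),
                "sem_drug": float(sems.loc["drug", t]),
                "diff": diff,
                "t": tstat,
                "p_raw": p_raw,
                "p_adj": min(1.0, k * p_raw),
            }
        )
    contrasts = pd.DataFrame(contrast_rows)

    gradient = TemperatureGradient.from_temperatures(temps)
    tms = {}
    for cond in ("vehicle", "drug"):
        mean_series = [float(means.loc[cond, t]) for t in temps]
        prof = MeltProfile(f"cetsa_{cond}", cond, 1, tuple(mean_series))
        fit = fit_melting_curve(prof, gradient, min_points=min(min_points, k))
        tms[cond] = fit.tm if fit.converged else None
    dtm = (
        tms["drug"] - tms["vehicle"]
        if tms["drug"] is not None and tms["vehicle"] is not None
        else None
    )

    return CetsaResult(
        anova=anova,
        contrasts=contrasts,
        means=means,
        n_replicates=r,
        tm_vehicle=tms["vehicle"],
        tm_drug=tms["drug"],
        dtm=dtm,
    )
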