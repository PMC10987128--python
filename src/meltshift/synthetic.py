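"""Synthetic TPP-TR experiments and CETSA tables with known ground truth.

The generator emulates the standard TPP-TR design this package analyzes:
10 heat-treatment temperatures encoded in one TMT 10-plex run per
condition x replicate, 2 conditions (vehicle/drug) x 2 replicates, and a
proteome of a few hundred to a few thousand proteins, a configurable
fraction of which are spiked drug targets with stabilized (positive ΔTm)
or destabilized (negative ΔTm) drug-condition curves.

Per protein, a true melting curve is drawn by sampling a melting point,
an inflection-slope magnitude and a plateau, then solving for the sigmoid
parameters (a, b): with c = ln(1 - 2p),

    Tm = a / (b + c)            and |slope| = (1 - p) b^2 / (4 a)

give a quadratic in b with the positive root

    b = (2 Tm s + 2 sqrt(Tm^2 s^2 + (1 - p) Tm s c)) / (1 - p),   a = Tm (b + c).

Drug-induced shifts are injected by re-solving b at fixed a and p for the
shifted Tm, which preserves curve steepness (the destabilization
phenotype: the curve moves left, its shape does not change).
Per-replicate biological variability enters as a small Tm jitter so the
vehicle-vs-vehicle control shift has realistic nonzero spread.
Measured abundances are base_intensity x f(T) x exp(eps) with
eps ~ Normal(0, noise_sd^2) i.i.d. per point, base intensities
log-uniform over [1e5, 1e8].  All randomness flows from one seeded
generator; identical configs and seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .melt_fit import SigmoidParams, compute_tm, sigmoid
from .quant_io import (
    CETSA_TEMPERATURES,
    DEFAULT_GRADIENT,
    RawProfile,
    TemperatureGradient,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "simulate_experiment",
    "simulate_cetsa",
    "write_ground_truth",
]

_TM_FEASIBLE = (30.0, 75.0)
_MAX_REDRAWS = 100
_BASE_INTENSITY_RANGE = (1e5, 1e8)


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for one simulated TPP-TR experiment.

    Defaults describe a realistic mammalian-lysate screen: vehicle melting
    points centered at 52 +- 4 degC, inflection-slope magnitudes spanning
    shallow-to-steep curves (0.03-0.4 per degC, so a tail of curves fails
    the 0.06 flat-slope filter, as in real data), plateaus up to 0.3,
    target |ΔTm| of 4 +- 1 degC, 3% multiplicative noise and 0.3 degC
    replicate Tm jitter.
    """

    n_proteins: int = 100
    n_targets_destab: int = 0
    n_targets_stab: int = 0
    tm_mean: float = 52.0
    tm_sd: float = 4.0
    slope_range: Tuple[float, float] = (0.03, 0.4)
    plateau_range: Tuple[float, float] = (0.0, 0.3)
    shift_mean: float = 4.0
    shift_sd: float = 1.0
    noise_sd: float = 0.03
    replicate_tm_jitter: float = 0.3
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.n_targets_destab < 0 or self.n_targets_stab < 0:
            raise ConfigError("target counts must be non-negative")
        if self.n_targets_destab + self.n_targets_stab > self.n_proteins:
            raise ConfigError("more spiked targets than proteins")
        for name in ("tm_sd", "shift_sd", "noise_sd", "replicate_tm_jitter"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 < self.slope_range[0] <= self.slope_range[1]):
            raise ConfigError("slope_range must be positive and ordered")
        if not (0 <= self.plateau_range[0] <= self.plateau_range[1] < 0.5):
            raise ConfigError("plateau_range must lie in [0, 0.5) and be ordered")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")


@dataclass
class GroundTruth:
    """True parameters behind a simulated experiment.

    ``table`` has one row per protein: ``protein_id``, ``true_dtm``,
    ``label`` (none/destabilized/stabilized), ``tm_vehicle``, ``slope``,
    ``plateau``.  ``params`` maps ``(protein_id, condition, replicate)``
    to the exact :class:`SigmoidParams` each curve was generated from.
    """

    table: pd.DataFrame
    params: Dict[Tuple[str, str, int], SigmoidParams] = field(default_factory=dict)

    @property
    def target_ids(self) -> Tuple[str, ...]:
        mask = self.table["label"] != "none"
        return tuple(self.table.loc[mask, "protein_id"])


def _solve_curve(tm: float, slope_mag: float, p: float) -> SigmoidParams:
    """Invert (Tm, |slope|, p) to sigmoid parameters (a, b)."""
    c = math.log1p(-2.0 * p)
    disc = tm * tm * slope_mag * slope_mag + (1.0 - p) * tm * slope_mag * c
    if disc <= 0:
        raise ConfigError(f"infeasible curve: Tm={tm}, slope={slope_mag}, p={p}")
    b = (2.0 * tm * slope_mag + 2.0 * math.sqrt(disc)) / (1.0 - p)
    a = tm * (b + c)
    return SigmoidParams(a, b, p)


def _shift_tm(params: SigmoidParams, new_tm: float) -> SigmoidParams:
    """Move the melting point at fixed a and p by re-solving b."""
    c = math.log1p(-2.0 * params.p)
    b = params.a / new_tm - c
    if b <= 0:
        raise ConfigError(f"shifted Tm {new_tm:.1f} degC is infeasible for this curve")
    return SigmoidParams(params.a, b, params.p)


def _draw_protein(rng: np.random.Generator, cfg: SyntheticConfig, shift: float):
    """Draw one protein's true curve family; redraw infeasible combinations."""
    for _ in range(_MAX_REDRAWS):
        tm_v = rng.normal(cfg.tm_mean, cfg.tm_sd)
        slope = rng.uniform(*cfg.slope_range)
        p = rng.uniform(*cfg.plateau_range)
        tm_d = tm_v + shift
        jit = rng.normal(0.0, cfg.replicate_tm_jitter, size=2 * cfg.n_replicates)
        tms = [tm_v + jit[i] for i in range(cfg.n_replicates)] + [
            tm_d + jit[cfg.n_replicates + i] for i in range(cfg.n_replicates)
        ]
        if all(_TM_FEASIBLE[0] <= t <= _TM_FEASIBLE[1] for t in tms + [tm_v, tm_d]):
            base = _solve_curve(tm_v, slope, p)
            try:
                curves = {
                    ("vehicle", i + 1): _shift_tm(base, tms[i])
                    for i in range(cfg.n_replicates)
                }
                curves.update(
                    {
                        ("drug", i + 1): _shift_tm(base, tms[cfg.n_replicates + i])
                        for i in range(cfg.n_replicates)
                    }
                )
            except ConfigError:
                continue
            return tm_v, slope, p, curves
    raise ConfigError(
        "could not draw a feasible melting curve in "
        f"{_MAX_REDRAWS} attempts; check tm/shift settings"
    )


def simulate_experiment(
    config: SyntheticConfig,
    gradient: TemperatureGradient = DEFAULT_GRADIENT,
) -> Tuple[list, GroundTruth]:
    """Simulate a full TPP-TR experiment.

    Returns raw (un-normalized) profiles for every protein x condition x
    replicate, plus the :class:`GroundTruth`.  Spiked targets are assigned
    to randomly chosen proteins; destabilized targets draw a negative ΔTm
    and stabilized targets a positive one, |ΔTm| ~ Normal(shift_mean,
    shift_sd) truncated to be positive.
    """
    rng = np.random.default_rng(config.seed)
    temps = np.asarray(gradient.temperatures)
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(1, n + 1)]

    labels = np.array(["none"] * n, dtype=object)
    target_idx = rng.choice(n, size=config.n_targets_destab + config.n_targets_stab,
                            replace=False)
    labels[target_idx[: config.n_targets_destab]] = "destabilized"
    labels[target_idx[config.n_targets_destab:]] = "stabilized"

    profiles = []
    truth_rows = []
    params: Dict[Tuple[str, str, int], SigmoidParams] = {}
    lo, hi = np.log(_BASE_INTENSITY_RANGE[0]), np.log(_BASE_INTENSITY_RANGE[1])
    for pid, label in zip(ids, labels):
        if label == "none":
            shift = 0.0
        else:
            mag = abs(rng.normal(config.shift_mean, config.shift_sd))
            for _ in range(_MAX_REDRAWS):
                if mag > 0:
                    break
                mag = abs(rng.normal(config.shift_mean, config.shift_sd))
            shift = -mag if label == "destabilized" else mag
        tm_v, slope, p, curves = _draw_protein(rng, config, shift)
        truth_rows.append(
            {
                "protein_id": pid,
                "true_dtm": shift,
                "label": label,
                "tm_vehicle": tm_v,
                "slope": -slope,
                "plateau": p,
            }
        )
        for (cond, rep), cp in sorted(curves.items()):
            params[(pid, cond, rep)] = cp
            base = math.exp(rng.uniform(lo, hi))
            eps = rng.normal(0.0, config.noise_sd, size=len(temps))
            y = base * sigmoid(temps, cp.a, cp.b, cp.p) * np.exp(eps)
            profiles.append(RawProfile(pid, cond, rep, tuple(float(v) for v in y)))

    truth = GroundTruth(table=pd.DataFrame(truth_rows), params=params)
    return profiles, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the ground-truth table (`protein_id  true_dtm  label` + extras)."""
    truth.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def simulate_cetsa(
    config: SyntheticConfig,
    temperatures: Sequence[float] = CETSA_TEMPERATURES,
    *,
    n_replicates: int = 3,
    drug_shift: float = 0.0,
) -> pd.DataFrame:
    """Simulate a single-protein CETSA-WB band-intensity table.

    One protein's curve is drawn from ``config``'s distributions; the drug
    condition's melting point is moved by ``drug_shift`` degC (0 = null).
    Each replicate series gets independent multiplicative noise.  Returns
    a DataFrame in the CETSA dialect: ``replicate``, ``condition``, one
    column per temperature.
    """
    if n_replicates < 2:
        raise ConfigError("CETSA simulation needs >= 2 replicates per condition")
    rng = np.random.default_rng(config.seed)
    temps = np.asarray([float(t) for t in temperatures])

    for _ in range(_MAX_REDRAWS):
        tm_v = rng.normal(config.tm_mean, config.tm_sd)
        slope = rng.uniform(*config.slope_range)
        p = rng.uniform(*config.plateau_range)
        tm_d = tm_v + drug_shift
        if (
            _TM_FEASIBLE[0] <= tm_v <= _TM_FEASIBLE[1]
            and _TM_FEASIBLE[0] <= tm_d <= _TM_FEASIBLE[1]
        ):
            break
    else:
        raise ConfigError("could not draw a feasible CETSA curve")
    veh = _solve_curve(tm_v, slope, p)
    drg = _shift_tm(veh, tm_d)

    lo, hi = np.log(_BASE_INTENSITY_RANGE[0]), np.log(_BASE_INTENSITY_RANGE[1])
    rows = []
    for cond, cp in (("vehicle", veh), ("drug", drg)):
        for rep in range(1, n_replicates + 1):
            base = math.exp(rng.uniform(lo, hi))
            eps = rng.normal(0.0, config.noise_sd, size=len(temps))
            y = base * sigmoid(temps, cp.a, cp.b, cp.p) * np.exp(eps)
            row = {"replicate": rep, "condition": cond}
            row.update({float(t): float(v) for t, v in zip(temps, y)})
            rows.append(row)
    return pd.DataFrame(rows)
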