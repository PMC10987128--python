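"""Data model and tabular I/O for temperature-gradient protein quantification.

A TPP-TR experiment quantifies each protein's soluble fraction at a ladder
of temperatures encoded by TMT reporter channels.  This module holds the
gradient definition, the per-curve containers (:class:`RawProfile`,
:class:`MeltProfile`), and the readers/writers for the package's
tab-separated dialects:

* quant tables  — ``protein_id  condition  replicate  <channel_1> ... <channel_k>``
* results tables — one row per protein with Tm, ΔTm, criteria flags and
  classification (see :func:`write_results`)
* CETSA band-intensity tables — ``replicate  condition  <T_1> ... <T_k>``

All files are UTF-8, ``#`` starts a comment line, and the missing-value
token is ``NA``.  Relative abundances are normalized per protein to the
lowest gradient temperature, whose value is fixed at 1.0.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, NormalizationError, ValidationError

__all__ = [
    "TemperatureGradient",
    "RawProfile",
    "MeltProfile",
    "DEFAULT_GRADIENT",
    "CETSA_TEMPERATURES",
    "MISSING_TOKEN",
    "normalize_condition",
    "read_quant_table",
    "write_quant_table",
    "normalize_profile",
    "write_results",
    "read_results",
    "write_fit_table",
    "read_fit_table",
    "read_cetsa_table",
]

MISSING_TOKEN = "NA"

#: Case-insensitive aliases for the two experimental arms.
CONDITION_ALIASES = {
    "vehicle": "vehicle",
    "veh": "vehicle",
    "dmso": "vehicle",
    "drug": "drug",
    "treated": "drug",
    "da": "drug",
}


def normalize_condition(label: str) -> str:
    """Map a condition label to the canonical ``vehicle``/``drug`` pair."""
    key = str(label).strip().lower()
    if key not in CONDITION_ALIASES:
        raise ValidationError(
            f"unknown condition label {label!r}; expected one of "
            f"{sorted(CONDITION_ALIASES)}"
        )
    return CONDITION_ALIASES[key]


@dataclass(frozen=True)
class TemperatureGradient:
    """Ordered temperature ladder with its aligned reporter-channel names."""

    temperatures: tuple[float, ...]
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temperatures)
        labels = tuple(str(c) for c in self.channel_labels)
        object.__setattr__(self, "temperatures", temps)
        object.__setattr__(self, "channel_labels", labels)
        if len(temps) < 4:
            raise ValidationError("gradient needs at least 4 temperatures")
        if len(temps) != len(labels):
            raise ValidationError(
                f"{len(temps)} temperatures but {len(labels)} channel labels"
            )
        if any(t2 <= t1 for t1, t2 in zip(temps, temps[1:])):
            raise ValidationError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temperatures)

    @classmethod
    def from_temperatures(cls, temperatures: Sequence[float]) -> "TemperatureGradient":
        """Build a gradient with generic ``T<temp>`` channel labels."""
        labels = tuple(f"T{float(t):g}" for t in temperatures)
        return cls(tuple(temperatures), labels)


#: The 10-point TMT-10plex TPP-TR gradient used throughout as the default:
#: channels TMT126..TMT131 encode 37.0-66.8 degC heat treatments.
DEFAULT_GRADIENT = TemperatureGradient(
    temperatures=(37.0, 40.0, 43.2, 46.9, 49.6, 53.0, 56.0, 59.5, 62.8, 66.8),
    channel_labels=(
        "TMT126", "TMT127N", "TMT127C", "TMT128N", "TMT128C",
        "TMT129N", "TMT129C", "TMT130N", "TMT130C", "TMT131",
    ),
)

#: The 10 temperatures of the western-blot CETSA ladder.
CETSA_TEMPERATURES = (37.0, 41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 63.0, 67.0)


@dataclass(frozen=True)
class RawProfile:
    """Raw reporter abundances for one protein x condition x replicate."""

    protein_id: str
    condition: str
    replicate: int
    intensities: tuple[float, ...]  # NaN marks a missing channel

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", normalize_condition(self.condition))
        vals = tuple(float(v) for v in self.intensities)
        object.__setattr__(self, "intensities", vals)
        if self.replicate < 1:
            raise ValidationError(
                f"{self.protein_id}: replicate must be a positive integer"
            )
        finite = [v for v in vals if math.isfinite(v)]
        if any(v < 0 for v in finite):
            raise ValidationError(f"{self.protein_id}: negative intensity")
        if not any(v > 0 for v in finite):
            raise ValidationError(
                f"{self.protein_id}: needs at least one positive intensity"
            )


@dataclass(frozen=True)
class MeltProfile:
    """Relative soluble fraction f(T) for one curve, anchored at 1.0.

    ``rel_abundance[0]`` (the lowest gradient temperature) is exactly 1.0;
    missing points are NaN and ``n_present`` counts the finite entries.
    """

    protein_id: str
    condition: str
    replicate: int
    rel_abundance: tuple[float, ...]
    n_present: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", normalize_condition(self.condition))
        vals = tuple(float(v) for v in self.rel_abundance)
        object.__setattr__(self, "rel_abundance", vals)
        if any(math.isinf(v) for v in vals):
            raise ValidationError(f"{self.protein_id}: non-finite relative abundance")
        n = sum(1 for v in vals if math.isfinite(v))
        object.__setattr__(self, "n_present", n)

    @property
    def missing_mask(self) -> tuple[bool, ...]:
        return tuple(not math.isfinite(v) for v in self.rel_abundance)


def normalize_profile(raw: RawProfile | MeltProfile) -> MeltProfile:
    """Scale a raw curve to its lowest-temperature intensity.

    The reference point is the first (lowest) gradient temperature; its
    relative abundance is set to exactly 1.0.  Applying this to an
    already-normalized :class:`MeltProfile` is the identity.
    """
    if isinstance(raw, MeltProfile):
        values = raw.rel_abundance
    else:
        values = raw.intensities
    ref = values[0]
    if not math.isfinite(ref) or ref <= 0:
        raise NormalizationError(
            f"{raw.protein_id} ({raw.condition} rep {raw.replicate}): "
            "reference-temperature intensity is zero or missing"
        )
    rel = tuple(v / ref for v in values)
    rel = (1.0,) + rel[1:]  # anchor exactly
    return MeltProfile(raw.protein_id, raw.condition, raw.replicate, rel)


# ---------------------------------------------------------------------------
# quant tables

_META_COLUMNS = ("protein_id", "condition", "replicate")


def _parse_float(token: str) -> float:
    token = token.strip()
    if token == MISSING_TOKEN or token == "":
        return math.nan
    return float(token)


def read_quant_table(path, gradient: TemperatureGradient) -> list[RawProfile]:
    """Read a quant table, re-aligning channel columns to gradient order.

    Channel columns may appear in any order in the file header; they are
    matched to ``gradient.channel_labels`` by name.  Malformed rows are
    collected and reported together with their 1-based line numbers.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _read_quant_stream(fh, gradient, str(path))


def _read_quant_stream(fh, gradient, name):
    reader = csv.reader(fh, delimiter="\t")
    header = None
    line_no = 0
    for row in reader:
        line_no += 1
        if row and row[0].startswith("#"):
            continue
        header = [c.strip() for c in row]
        break
    if header is None:
        raise FormatError(f"{name}: empty file")
    for col in _META_COLUMNS:
        if col not in header:
            raise FormatError(f"{name}: missing required column '{col}'")
    for label in gradient.channel_labels:
        if label not in header:
            raise FormatError(f"{name}: missing channel column '{label}'")
    idx = {c: i for i, c in enumerate(header)}
    chan_idx = [idx[label] for label in gradient.channel_labels]
    pid_i, cond_i, rep_i = (idx[c] for c in _META_COLUMNS)

    profiles: list[RawProfile] = []
    bad: list[str] = []
    for row in reader:
        line_no += 1
        if not row or row[0].startswith("#"):
            continue
        if len(row) != len(header):
            bad.append(f"line {line_no}: expected {len(header)} fields, got {len(row)}")
            continue
        try:
            rep = int(row[rep_i])
            intensities = tuple(_parse_float(row[i]) for i in chan_idx)
            profiles.append(
                RawProfile(row[pid_i].strip(), row[cond_i], rep, intensities)
            )
        except ValidationError:
            raise
        except ValueError as exc:
            bad.append(f"line {line_no}: {exc}")
    if bad:
        raise FormatError(f"{name}: {len(bad)} malformed row(s): " + "; ".join(bad))
    return profiles


def _fmt(value) -> str:
    """Serialize one value; floats use shortest round-trip repr."""
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "true" if value else "false"
    if isinstance(value, float) or isinstance(value, np.floating):
        if math.isnan(value):
            return MISSING_TOKEN
        return repr(float(value))
    return str(value)


def write_quant_table(profiles: Iterable[RawProfile], gradient: TemperatureGradient,
                      path) -> None:
    """Write raw profiles in the quant-table dialect (gradient column order)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_META_COLUMNS + gradient.channel_labels) + "\n")
        for p in profiles:
            fields = [p.protein_id, p.condition, str(p.replicate)]
            fields += [_fmt(v) for v in p.intensities]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# results tables

RESULTS_COLUMNS = (
    "protein_id", "classification", "exclusion_reason",
    "tm_vehicle_1", "tm_vehicle_2", "tm_drug_1", "tm_drug_2",
    "dtm_1", "dtm_2", "dtm_ctrl",
    "min_abs_slope", "sign_concordant", "exceeds_control", "slope_pass",
    "max_fc_score", "n_floored", "fc_profile",
)


def write_results(records, path) -> None:
    """Write per-protein target calls as a tab-separated results table.

    Column order is :data:`RESULTS_COLUMNS`; undefined fields are ``NA``;
    the per-temperature fold-change profile is ``;``-joined in one column.
    Floats are written with shortest round-trip precision so that
    :func:`read_results` reproduces them bit-identically.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for rec in records:
            s = rec.shift
            tm_v = s.tm_vehicle or (None, None)
            tm_d = s.tm_drug or (None, None)
            fc = (
                ";".join(_fmt(v) for v in s.fc_profile)
                if s.fc_profile is not None
                else MISSING_TOKEN
            )
            fields = [
                rec.protein_id, rec.classification, rec.exclusion_reason,
                _fmt(tm_v[0]), _fmt(tm_v[1]), _fmt(tm_d[0]), _fmt(tm_d[1]),
                _fmt(s.dtm_1), _fmt(s.dtm_2), _fmt(s.dtm_ctrl),
                _fmt(s.min_abs_slope), _fmt(s.sign_concordant),
                _fmt(s.exceeds_control), _fmt(s.slope_pass),
                _fmt(s.max_fc_score), str(s.n_floored), fc,
            ]
            fh.write("\t".join(fields) + "\n")


def _parse_opt_float(token: str):
    return None if token == MISSING_TOKEN else float(token)


def _parse_opt_bool(token: str):
    if token == MISSING_TOKEN:
        return None
    return token == "true"


def read_results(path):
    """Read a results table back into :class:`~meltshift.target_call.TargetCall`s."""
    from .target_call import ShiftRecord, TargetCall  # avoid import cycle

    calls = []
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and not r[0].startswith("#")]
    if not rows:
        raise FormatError(f"{path}: empty results file")
    header = tuple(rows[0])
    if header != RESULTS_COLUMNS:
        raise FormatError(f"{path}: unexpected results header {header}")
    for row in rows[1:]:
        d = dict(zip(RESULTS_COLUMNS, row))
        tm_v1, tm_v2 = _parse_opt_float(d["tm_vehicle_1"]), _parse_opt_float(d["tm_vehicle_2"])
        tm_d1, tm_d2 = _parse_opt_float(d["tm_drug_1"]), _parse_opt_float(d["tm_drug_2"])
        fc = d["fc_profile"]
        fc_profile = (
            None if fc == MISSING_TOKEN
            else tuple(_parse_float(v) for v in fc.split(";"))
        )
        shift = ShiftRecord(
            protein_id=d["protein_id"],
            dtm_1=_parse_opt_float(d["dtm_1"]),
            dtm_2=_parse_opt_float(d["dtm_2"]),
            dtm_ctrl=_parse_opt_float(d["dtm_ctrl"]),
            sign_concordant=_parse_opt_bool(d["sign_concordant"]),
            exceeds_control=_parse_opt_bool(d["exceeds_control"]),
            slope_pass=_parse_opt_bool(d["slope_pass"]),
            fc_profile=fc_profile,
            max_fc_score=_parse_opt_float(d["max_fc_score"]),
            tm_vehicle=(tm_v1, tm_v2),
            tm_drug=(tm_d1, tm_d2),
            min_abs_slope=_parse_opt_float(d["min_abs_slope"]),
            unfittable=d["exclusion_reason"] == "unfittable",
            n_floored=int(d["n_floored"]),
        )
        calls.append(
            TargetCall(d["protein_id"], d["classification"], d["exclusion_reason"], shift)
        )
    return calls


# ---------------------------------------------------------------------------
# fit tables (per-curve diagnostics, used by the staged CLI)

FIT_COLUMNS = (
    "protein_id", "condition", "replicate",
    "a", "b", "p", "tm", "slope", "r_squared", "n_points", "converged",
)


def write_fit_table(fits, path) -> None:
    """Write per-curve fit diagnostics keyed by protein/condition/replicate.

    ``fits`` maps ``(protein_id, condition, replicate)`` to a
    :class:`~meltshift.melt_fit.MeltingCurveFit`.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(FIT_COLUMNS) + "\n")
        for (pid, cond, rep), fit in fits.items():
            if fit.params is not None:
                a, b, p = fit.params.a, fit.params.b, fit.params.p
            else:
                a = b = p = None
            fields = [
                pid, cond, str(rep),
                _fmt(a), _fmt(b), _fmt(p),
                _fmt(fit.tm), _fmt(fit.slope), _fmt(fit.r_squared),
                str(fit.n_points), _fmt(fit.converged),
            ]
            fh.write("\t".join(fields) + "\n")


def read_fit_table(path):
    """Read a fit table back into a ``{(pid, cond, rep): MeltingCurveFit}`` map."""
    from .melt_fit import MeltingCurveFit, SigmoidParams

    fits = {}
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and not r[0].startswith("#")]
    if not rows or tuple(rows[0]) != FIT_COLUMNS:
        raise FormatError(f"{path}: unexpected fit-table header")
    for row in rows[1:]:
        d = dict(zip(FIT_COLUMNS, row))
        a = _parse_opt_float(d["a"])
        params = (
            SigmoidParams(a, float(d["b"]), float(d["p"])) if a is not None else None
        )
        fit = MeltingCurveFit(
            params=params,
            tm=_parse_opt_float(d["tm"]),
            slope=_parse_opt_float(d["slope"]),
            r_squared=_parse_opt_float(d["r_squared"]),
            n_points=int(d["n_points"]),
            converged=d["converged"] == "true",
        )
        fits[(d["protein_id"], normalize_condition(d["condition"]), int(d["replicate"]))] = fit
    return fits


# ---------------------------------------------------------------------------
# CETSA band-intensity tables

def read_cetsa_table(path, temperatures: Sequence[float] = CETSA_TEMPERATURES) -> pd.DataFrame:
    """Read a CETSA band-intensity table.

    Expected dialect: ``replicate  condition  <T_1> ... <T_k>`` with one row
    per replicate series.  Temperature columns are matched numerically to
    ``temperatures`` (header tokens like ``37`` or ``37.0`` both work).
    Returns a DataFrame with columns ``replicate``, ``condition`` and one
    float column per temperature (named by ``float`` value).
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING_TOKEN])
    for col in ("replicate", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    temp_cols = {}
    for col in df.columns:
        if col in ("replicate", "condition"):
            continue
        try:
            temp_cols[float(col)] = col
        except ValueError:
            raise FormatError(f"{path}: unexpected non-numeric column '{col}'")
    missing = [t for t in temperatures if float(t) not in temp_cols]
    if missing:
        raise FormatError(f"{path}: missing temperature column(s) {missing}")
    out = pd.DataFrame({
        "replicate": df["replicate"].astype(int),
        "condition": df["condition"].map(normalize_condition),
    })
    for t in temperatures:
        out[float(t)] = df[temp_cols[float(t)]].astype(float)
    return out


def cetsa_table_to_string(df: pd.DataFrame) -> str:
    """Serialize a CETSA table produced by the simulator or reader."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, na_rep=MISSING_TOKEN)
    return buf.getvalue()
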