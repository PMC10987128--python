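"""End-to-end pipeline runner: normalize -> fit -> filter -> criteria -> report.

`run_pipeline` is the single-shot path used by ``meltshift run``; the
staged CLI subcommands (``fit`` then ``call``) go through the same
functions, so staged and single-shot execution produce identical results
tables.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .errors import NormalizationError
from .melt_fit import MIN_POINTS, SLOPE_THRESHOLD, fit_melting_curve
from .quant_io import (
    DEFAULT_GRADIENT,
    TemperatureGradient,
    normalize_profile,
    read_quant_table,
    write_fit_table,
    write_results,
)
from .target_call import FC_CUTOFF, TargetCallResult, call_targets

__all__ = ["RunConfig", "run_pipeline", "fit_all", "write_summary"]

log = logging.getLogger("meltshift")


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and options for one pipeline run (defaults as documented)."""

    gradient: TemperatureGradient = DEFAULT_GRADIENT
    slope_threshold: float = SLOPE_THRESHOLD
    fc_cutoff: float = FC_CUTOFF
    min_points: int = MIN_POINTS
    pairing: str = "index"
    slope_scope: str = "all"
    r_squared_min: Optional[float] = None

    def echo(self) -> str:
        """One machine-readable key=value line for provenance logging."""
        parts = [f"version={__version__}"]
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, TemperatureGradient):
                v = ",".join(f"{t:g}" for t in v.temperatures)
            parts.append(f"{f.name}={v}")
        return " ".join(parts)


def fit_all(profiles, gradient, min_points: int = MIN_POINTS):
    """Fit every profile; returns ``{(pid, cond, rep): MeltingCurveFit}``."""
    return {
        (p.protein_id, p.condition, p.replicate): fit_melting_curve(
            p, gradient, min_points=min_points
        )
        for p in profiles
    }


def normalize_all(raw_profiles):
    """Normalize profiles, dropping (and reporting) unnormalizable ones.

    A curve whose reference-temperature intensity is zero or missing
    cannot be scaled; it is dropped here, which downstream marks its
    protein unfittable.  Returns ``(profiles, dropped)``.
    """
    out, dropped = [], []
    for raw in raw_profiles:
        try:
            out.append(normalize_profile(raw))
        except NormalizationError as exc:
            dropped.append(str(exc))
    return out, dropped


def write_summary(result: TargetCallResult, config: RunConfig, path) -> None:
    """Write the run summary as key<TAB>value lines (stage counts first)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# meltshift run summary\n")
        fh.write(f"# config: {config.echo()}\n")
        for key, value in result.summary.items():
            fh.write(f"{key}\t{value}\n")


def run_pipeline(
    quant_path,
    config: RunConfig = RunConfig(),
    out_dir=".",
    *,
    write_fits: bool = False,
) -> TargetCallResult:
    """Run the full screen on a quant table and write results + summary.

    Outputs in ``out_dir``: ``results.tsv`` (per-protein calls, candidate
    ordering), ``summary.tsv`` (stage counts: input -> fittable -> slope
    pass -> criteria pass -> candidates), ``run.log`` (timestamped, with
    the effective config echoed), and optionally ``fits.tsv``.
    Deterministic: the same input and config give byte-identical results
    and summary files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def _log(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")
        log.info(msg)

    _log(f"config: {config.echo()}")
    raw = read_quant_table(quant_path, config.gradient)
    _log(f"read {len(raw)} profiles from {quant_path}")
    profiles, dropped = normalize_all(raw)
    for msg in dropped:
        _log(f"dropped unnormalizable profile: {msg}")

    fits = fit_all(profiles, config.gradient, config.min_points)
    _log(f"fitted {len(fits)} melting curves")
    result = call_targets(
        profiles,
        config.gradient,
        slope_threshold=config.slope_threshold,
        fc_cutoff=config.fc_cutoff,
        min_points=config.min_points,
        pairing=config.pairing,
        slope_scope=config.slope_scope,
        r_squared_min=config.r_squared_min,
        fits=fits,
    )
    _log(
        "called targets: "
        + " ".join(f"{k}={v}" for k, v in result.summary.items())
    )

    write_results(result.calls, out / "results.tsv")
    write_summary(result, config, out / "summary.tsv")
    if write_fits:
        write_fit_table(fits, out / "fits.tsv")
    with open(out / "run.log", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return result
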