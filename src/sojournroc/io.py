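"""CSV/JSON/YAML input and output for screening tables and results."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import yaml

from ._rounding import round_half_up
from .correction import OperatingPoint, PCDPEstimate, PSAStratum, ScreeningTable
from .roc import AUCEstimate, ROCCurve

__all__ = [
    "RunConfig",
    "load_screening_table",
    "write_metrics_csv",
    "write_pcdp_csv",
    "roc_summary",
    "write_roc_json",
    "load_run_config",
]

STRATA_COLUMNS = [
    "psa_low",
    "psa_high",
    "n_participants",
    "screen_detected",
    "interval_cancers",
]


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one correction run."""

    mst_years: float = 6.75
    interval_years: float = 4.0
    cutoffs: tuple[float, ...] = (1.0, 2.0, 2.5, 3.0, 3.5, 4.0)
    lambda1_source: Union[str, tuple[float, ...]] = "invert-exact"
    referral_threshold: float = 4.0
    rounding_digits: int = 1
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.mst_years <= 0 or self.interval_years <= 0:
            raise ValueError("mst_years and interval_years must be > 0")
        if list(self.cutoffs) != sorted(self.cutoffs):
            raise ValueError("cutoffs must be sorted ascending")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Read a RunConfig from a YAML mapping (keys = field names)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("cutoffs", "lambda1_source"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def load_screening_table(
    path: Union[str, Path], interval_years: float = 4.0
) -> ScreeningTable:
    """Read a stratified screening table from CSV.

    Expects the header ``psa_low,psa_high,n_participants,screen_detected,
    interval_cancers``; ``inf`` is accepted as the terminal upper bound and
    ``#`` lines are comments.  Malformed rows are reported with their line
    position; overlap/contiguity violations surface from the table's own
    validation.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file, expected columns {STRATA_COLUMNS}")
    missing = [c for c in STRATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    strata = []
    for idx, row in df.iterrows():
        try:
            strata.append(
                PSAStratum(
                    psa_low=float(row["psa_low"]),
                    psa_high=float(row["psa_high"]),
                    n_participants=_as_count(row["n_participants"]),
                    screen_detected=_as_count(row["screen_detected"]),
                    interval_cancers=_as_count(row["interval_cancers"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, data row {idx + 1}: {exc}") from exc
    return ScreeningTable(tuple(strata), interval_years=interval_years)


def _as_count(value) -> int:
    f = float(value)
    if not f.is_integer():
        raise ValueError(f"expected an integer count, got {value!r}")
    return int(f)


def write_strata_csv(table: ScreeningTable, path: Union[str, Path]) -> None:
    rows = [
        {
            "psa_low": s.psa_low,
            "psa_high": s.psa_high,
            "n_participants": s.n_participants,
            "screen_detected": s.screen_detected,
            "interval_cancers": s.interval_cancers,
        }
        for s in table.strata
    ]
    pd.DataFrame(rows, columns=STRATA_COLUMNS).to_csv(path, index=False)


def write_metrics_csv(points: Iterable[OperatingPoint], path: Union[str, Path]) -> None:
    rows = [
        {
            "cutoff": p.cutoff,
            "variant": p.variant,
            "tp": p.tp,
            "fn": p.fn,
            "fp": p.fp,
            "tn": p.tn,
            "sensitivity": p.sensitivity,
            "specificity": p.specificity,
            "ppv": p.ppv,
            "npv": p.npv,
            "youden": p.youden,
        }
        for p in points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_pcdp_csv(estimates: Iterable[PCDPEstimate], path: Union[str, Path]) -> None:
    rows = [
        {
            "psa_low": e.stratum.psa_low,
            "psa_high": e.stratum.psa_high,
            "n": e.stratum.n_participants,
            "interval_cancers": e.stratum.interval_cancers,
            "p_ic": e.p_ic,
            "lambda1": e.lambda1,
            "p_pcdp": e.p_pcdp,
            "expected_cases": e.expected_cases,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def roc_summary(curve: ROCCurve, estimate: AUCEstimate) -> dict:
    return {
        "variant": curve.variant,
        "auc": estimate.auc,
        "se": estimate.se,
        "ci": [estimate.ci_low, estimate.ci_high],
        "level": estimate.level,
        "n_cases": curve.n_cases,
        "n_noncases": curve.n_noncases,
    }


def write_roc_json(summaries: Sequence[dict], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(summaries, fh, indent=2)
        fh.write("\n")


def format_metrics(points: Iterable[OperatingPoint], digits: int = 1) -> pd.DataFrame:
    """Presentation table: metrics rounded half-up to ``digits`` decimals."""
    rows = [
        {
            "cutoff": p.cutoff,
            "variant": p.variant,
            "sensitivity": round_half_up(p.sensitivity, digits),
            "specificity": round_half_up(p.specificity, digits),
            "ppv": round_half_up(p.ppv, digits),
            "npv": round_half_up(p.npv, digits),
            "youden": round_half_up(p.youden, digits),
        }
        for p in points
    ]
    return pd.DataFrame(rows)
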