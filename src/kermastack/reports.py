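"""Report writers: CSV tables plus a JSON run manifest.

Fractions are written to 6 decimals with '.' as the decimal separator; a
3-decimal rounded view (matching the precision of published correction
tables) can be produced with ``rounded_view``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd

from .mc import ComparisonReport, TallyResult
from .physics import CorrectionTable
from .scheduling import ScheduleReport


def _pkg_version() -> str:
    try:
        return version("kermastack")
    except PackageNotFoundError:
        return "unknown"


def corrections_frame(rows: list[CorrectionTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"n_front": r.n_front, "attenuation": r.attenuation,
          "distance": r.distance, "total": r.total} for r in rows])


def schedule_frame(report: ScheduleReport) -> pd.DataFrame:
    return pd.DataFrame(
        [{"epoch": r.epoch, "residual": r.residual_output,
          "new_activity": r.new_activity_total,
          "activity_saving": r.activity_saving,
          "encapsulation_saving": r.encapsulation_saving}
         for r in report.records])


def comparison_frame(report: ComparisonReport) -> pd.DataFrame:
    return pd.DataFrame(
        [{"n_front": r.n_front, "analytic": r.analytic, "mc_mean": r.mc_mean,
          "mc_standard_error": r.mc_standard_error,
          "difference_pp": r.difference_pp} for r in report.rows])


def rounded_view(frame: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Rounded comparison view; numpy rounds half to even, as the published
    tables' precision convention assumes."""
    return frame.round(decimals)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def write_reports(results: dict, out_dir: str | Path,
                  seed: int | None = None,
                  config_text: str | None = None) -> list[Path]:
    """Write every recognized result object and a JSON run manifest.

    ``results`` maps a basename to a result object: a list of
    CorrectionTable rows, a ScheduleReport, a ComparisonReport or a
    TallyResult.  Returns the paths written.  The manifest records the
    package version, the seed and a hash of the configuration used, so a
    run can be replayed bit-for-bit; the timestamp lives only here.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in results.items():
        if isinstance(obj, ScheduleReport):
            path = out / f"{name}.csv"
            _write_csv(schedule_frame(obj), path)
            written.append(path)
            actions = out / f"{name}_actions.json"
            actions.write_text(json.dumps(
                [dataclasses.asdict(a) for a in obj.actions], indent=2))
            written.append(actions)
        elif isinstance(obj, ComparisonReport):
            path = out / f"{name}.csv"
            _write_csv(comparison_frame(obj), path)
            written.append(path)
        elif isinstance(obj, TallyResult):
            path = out / f"{name}.json"
            path.write_text(json.dumps(dataclasses.asdict(obj), indent=2))
            written.append(path)
        elif isinstance(obj, list) and all(
                isinstance(r, CorrectionTable) for r in obj):
            path = out / f"{name}.csv"
            _write_csv(corrections_frame(obj), path)
            written.append(path)
        else:
            raise TypeError(f"don't know how to report {name!r}: {type(obj)}")

    manifest = {
        "package": "kermastack",
        "version": _pkg_version(),
        "seed": seed,
        "config_sha256": (hashlib.sha256(config_text.encode()).hexdigest()
                          if config_text else None),
        "written": [p.name for p in written],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written.append(manifest_path)
    return written
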