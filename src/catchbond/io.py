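"""File formats, run configuration and reproducibility plumbing.

Curves and clamp traces travel as TSV files with a JSON metadata sidecar;
rupture and lifetime tables as CSV with unit-suffixed column names; model
and run configurations as JSON.  Formats are plain text on purpose: the
data volumes are desk-scale and diff-ability aids testing.

Every stochastic output can embed a provenance block (package version,
master seed, configuration hash) so re-running with the same pair
reproduces it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import ClampTrace, ForceCurve

__all__ = [
    "RunConfig",
    "write_curves",
    "read_curves",
    "write_clamp_traces",
    "read_clamp_traces",
    "config_hash",
]

_CURVE_COLUMNS = ("extension_nm", "force_pN")
_TRACE_COLUMNS = ("time_s", "force_pN", "head_height_nm")


def config_hash(payload: dict) -> str:
    """Stable hash of a configuration: changes iff any parameter changes."""
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunConfig:
    """Master seed + free-form parameter block with a stable hash."""

    master_seed: int = 0
    output_dir: str = "."
    parameters: dict = dataclasses.field(default_factory=dict)

    KNOWN_KEYS = frozenset({"master_seed", "output_dir", "parameters"})

    @property
    def hash(self) -> str:
        return config_hash(
            {"master_seed": self.master_seed, "parameters": self.parameters}
        )

    def provenance(self) -> dict:
        from . import __version__

        return {
            "package": "catchbond",
            "version": __version__,
            "master_seed": self.master_seed,
            "config_hash": self.hash,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "master_seed": self.master_seed,
                    "output_dir": self.output_dir,
                    "parameters": self.parameters,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - cls.KNOWN_KEYS
        if unknown:
            raise ValueError(
                f"unknown configuration keys {sorted(unknown)}; "
                "refusing to silently ignore them"
            )
        return cls(
            master_seed=raw.get("master_seed", 0),
            output_dir=raw.get("output_dir", "."),
            parameters=raw.get("parameters", {}),
        )


def _read_tsv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(numeric.isna() & df[col].notna())
        if bad.size:
            # +2: one for the header row, one for 1-based line numbers
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = numeric
    return df


def write_curves(curves: list[ForceCurve], directory) -> list[Path]:
    """Write each curve as <curve_id>.tsv plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for curve in curves:
        tsv = directory / f"{curve.curve_id}.tsv"
        pd.DataFrame(
            {"extension_nm": curve.extension, "force_pN": curve.force}
        ).to_csv(tsv, sep="\t", index=False, float_format="%.9g")
        sidecar = {
            "curve_id": curve.curve_id,
            "experiment_id": curve.experiment_id,
            "pulling_speed_nm_s": curve.pulling_speed,
            "spring_constant_N_m": curve.spring_constant,
        }
        tsv.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        written.append(tsv)
    return written


def read_curves(directory) -> list[ForceCurve]:
    """Read every curve TSV (+ required sidecar) in a directory.

    A TSV without its JSON sidecar is refused; an empty directory returns
    an empty collection with a warning.
    """
    directory = Path(directory)
    curves = []
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        warnings.warn(f"no curve files found in {directory}", stacklevel=2)
    for tsv in paths:
        sidecar_path = tsv.with_suffix(".json")
        if not sidecar_path.exists():
            raise ValueError(
                f"{tsv}: missing metadata sidecar {sidecar_path.name}; refusing to read"
            )
        meta = json.loads(sidecar_path.read_text())
        df = _read_tsv(tsv, _CURVE_COLUMNS)
        curves.append(
            ForceCurve(
                extension=df["extension_nm"].to_numpy(),
                force=df["force_pN"].to_numpy(),
                pulling_speed=float(meta["pulling_speed_nm_s"]),
                spring_constant=float(meta["spring_constant_N_m"]),
                curve_id=str(meta.get("curve_id", tsv.stem)),
                experiment_id=str(meta.get("experiment_id", "exp")),
            )
        )
    return curves


def write_clamp_traces(traces: list[ClampTrace], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for trace in traces:
        tsv = directory / f"{trace.trace_id}.tsv"
        pd.DataFrame(
            {
                "time_s": trace.time,
                "force_pN": trace.force,
                "head_height_nm": trace.head_height,
            }
        ).to_csv(tsv, sep="\t", index=False, float_format="%.9g")
        sidecar = {
            "trace_id": trace.trace_id,
            "experiment_id": trace.experiment_id,
            "target_setpoint_pN": trace.target_setpoint,
        }
        tsv.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        written.append(tsv)
    return written


def read_clamp_traces(directory) -> list[ClampTrace]:
    directory = Path(directory)
    traces = []
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        warnings.warn(f"no clamp traces found in {directory}", stacklevel=2)
    for tsv in paths:
        sidecar_path = tsv.with_suffix(".json")
        if not sidecar_path.exists():
            raise ValueError(f"{tsv}: missing metadata sidecar; refusing to read")
        meta = json.loads(sidecar_path.read_text())
        df = _read_tsv(tsv, _TRACE_COLUMNS)
        traces.append(
            ClampTrace(
                time=df["time_s"].to_numpy(),
                force=df["force_pN"].to_numpy(),
                head_height=df["head_height_nm"].to_numpy(),
                target_setpoint=float(meta["target_setpoint_pN"]),
                trace_id=str(meta.get("trace_id", tsv.stem)),
                experiment_id=str(meta.get("experiment_id", "exp")),
            )
        )
    return traces
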