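"""Recording/manifest CSV formats, run configuration, and the pipeline
driver binding simulate -> analyze -> screen into one reproducible run.

A "run" is a directory of per-sample recording CSVs plus ``manifest.csv``
and the resolved ``config.json`` that produced them.  Every numeric
column name carries its unit (``time_s``, ``Lm_um``, ``x_px``, ``x_um``,
``Fs_uN``), and the same config and seed always reproduce the same files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .bench import Recording, generate_population
from .dma import summarize_run
from .probe import PROBE_PRESETS, probe_preset
from .samples import CONDITION_GRIDS, condition_grid

__all__ = [
    "RecordingFormatError",
    "read_recording",
    "write_recording",
    "RunConfig",
    "run_pipeline",
    "load_run",
]

log = logging.getLogger("fibermech")

RECORDING_COLUMNS = ["time_s", "Lm_um", "x_px", "x_um", "Fs_uN", "stim", "medium"]


class RecordingFormatError(ValueError):
    """Malformed recording file (missing columns, non-uniform time...)."""


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write one recording as a unit-annotated CSV.

    A ``# key=value`` header line carries the metadata needed to rebuild
    SI values losslessly (stiffness, pixel size, geometry).
    """
    path = Path(path)
    px = float(recording.metadata["pixel_size"])
    df = pd.DataFrame(
        {
            "time_s": recording.time,
            "Lm_um": recording.probe_displacement * 1e6,
            "x_px": np.round(recording.tip_deflection / px).astype(int)
            if np.allclose(recording.tip_deflection / px,
                           np.round(recording.tip_deflection / px), atol=1e-6)
            else recording.tip_deflection / px,
            "x_um": recording.tip_deflection * 1e6,
            "Fs_uN": recording.force * 1e6,
            "stim": recording.stimulus.astype(int),
            "medium": recording.medium,
        }
    )
    if recording.command_force is not None:
        df["Fcmd_uN"] = recording.command_force * 1e6
    def _jsonable(v):
        if isinstance(v, (int, float, str, bool)) or v is None:
            return True
        return isinstance(v, dict) and all(_jsonable(x) for x in v.values())

    meta = {
        "sample_id": recording.sample_id,
        "protocol": recording.protocol,
        **{k: v for k, v in recording.metadata.items() if _jsonable(v)},
    }
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a recording CSV back into SI values.

    Validates the column set and the time grid; rows with NaN force are
    flagged in ``metadata['nan_rows']`` (analysis excludes them).  A
    legacy file lacking ``x_um`` has it reconstructed from
    ``x_px * pixel_size``.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise RecordingFormatError(f"{path}:1: missing metadata header line")
        try:
            meta = json.loads(first[2:])
        except json.JSONDecodeError as exc:
            raise RecordingFormatError(f"{path}:1: bad metadata: {exc}") from exc
        df = pd.read_csv(fh)

    required = set(RECORDING_COLUMNS) - {"x_um"}
    missing = required - set(df.columns)
    if missing:
        raise RecordingFormatError(
            f"{path}: missing columns {sorted(missing)}"
        )
    extra = set(df.columns) - set(RECORDING_COLUMNS) - {"Fcmd_uN"}
    if extra:
        raise RecordingFormatError(f"{path}: unexpected columns {sorted(extra)}")

    t = df["time_s"].to_numpy(float)
    if len(t) > 2:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            bad = int(np.argmax(~np.isclose(dt, dt[0], rtol=1e-6))) + 3
            raise RecordingFormatError(f"{path}:{bad}: non-uniform time grid")

    px = float(meta.get("pixel_size", np.nan))
    if "x_um" in df.columns:
        x = df["x_um"].to_numpy(float) * 1e-6
    else:
        if not np.isfinite(px):
            raise RecordingFormatError(
                f"{path}: no x_um column and no pixel_size metadata"
            )
        x = df["x_px"].to_numpy(float) * px

    force = df["Fs_uN"].to_numpy(float) * 1e-6
    nan_rows = np.flatnonzero(~np.isfinite(force))
    meta.setdefault("nan_rows", nan_rows.tolist())
    rec = Recording(
        sample_id=str(meta.get("sample_id", path.stem)),
        time=t,
        probe_displacement=df["Lm_um"].to_numpy(float) * 1e-6,
        tip_deflection=x,
        force=force,
        stimulus=df["stim"].to_numpy(bool),
        medium=str(df["medium"].iloc[0]),
        protocol=str(meta.get("protocol", "oscillation")),
        metadata=meta,
        command_force=(df["Fcmd_uN"].to_numpy(float) * 1e-6
                       if "Fcmd_uN" in df.columns else None),
    )
    # unit consistency: Fs must equal k * x within rounding
    k = meta.get("stiffness")
    if k is not None:
        good = np.isfinite(force)
        if not np.allclose(force[good], float(k) * x[good], rtol=1e-6,
                           atol=1e-12):
            raise RecordingFormatError(
                f"{path}: Fs_uN inconsistent with stiffness * x_um"
            )
    return rec


# -- run configuration -------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable description of one simulated screening run."""

    probe: str = "short"
    grid: str = "gelma12"
    n_replicates: int = 8
    frequency: float = 0.1
    amplitude_strain: float = 0.10
    medium: str = "solution"
    seed: int = 0
    noise_px: float = 0.3
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.probe not in PROBE_PRESETS:
            raise ValueError(
                f"unknown probe preset {self.probe!r}; valid: "
                f"{sorted(PROBE_PRESETS)}"
            )
        if self.grid not in CONDITION_GRIDS:
            raise ValueError(
                f"unknown grid {self.grid!r}; valid: {sorted(CONDITION_GRIDS)}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a condition grid, analyze it, and write the run directory.

    Produces ``config.json``, per-sample recording CSVs, ``manifest.csv``
    and ``summary.csv`` (per-sample viscoelasticity).  Idempotent for a
    fixed config: rerunning yields byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run start: grid=%s seed=%d", config.grid, config.seed)
    config.to_json(out / "config.json")

    probe = probe_preset(config.probe)
    grid = condition_grid(config.grid)
    recordings, manifest = generate_population(
        grid,
        config.n_replicates,
        probe,
        seed=config.seed,
        medium=config.medium,
        amplitude_strain=config.amplitude_strain,
        frequency=config.frequency,
        noise_px=config.noise_px,
        quantize=config.quantize,
    )
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for rec in recordings:
        write_recording(rec, rec_dir / f"{rec.sample_id}.csv")
    manifest.to_csv(out / "manifest.csv", index=False)
    log.info("simulated %d recordings (%d grid conditions, seed=%d)",
             len(recordings), len(grid), config.seed)

    summary = summarize_run(recordings)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.8g")
    log.info("analysis summary: %d samples", len(summary))
    return out


def load_run(run_dir: str | Path) -> tuple[list[Recording], pd.DataFrame]:
    """Load all recordings and the manifest of a run directory."""
    run_dir = Path(run_dir)
    rec_dir = run_dir / "recordings"
    files = sorted(rec_dir.glob("*.csv")) if rec_dir.is_dir() else []
    if not files:
        raise FileNotFoundError(f"no recordings found under {run_dir}")
    manifest = pd.read_csv(run_dir / "manifest.csv")
    return [read_recording(f) for f in files], manifest
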