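"""Navigator-series file formats and pipeline configuration.

The interchange format for one scan is a pair of files:

* ``<name>.csv`` — one row per TR, columns ``tr_index`` then
  ``ch{j}_re, ch{j}_im`` per channel, full float precision;
* ``<name>.json`` — sidecar with ``tr_seconds``, ``n_steps`` and
  ``subject_id``.

Output files embed the SHA-256 hash of the active configuration in a
``# config=`` comment line for provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fidnav.detection import DICHOTOMIZATIONS
from fidnav.preprocess import FidnavSeries


class NavigatorFormatError(ValueError):
    """Malformed navigator series file."""


def write_navigator_csv(
    series: FidnavSeries, path: str | Path, subject_id: str = ""
) -> None:
    """Write a navigator series and its JSON sidecar (lossless round trip)."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"tr_index": np.arange(1, series.n_tr + 1)}
    for j in range(series.n_channels):
        cols[f"ch{j + 1}_re"] = series.signal[j].real
        cols[f"ch{j + 1}_im"] = series.signal[j].imag
    pd.DataFrame(cols).to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    sidecar = {
        "tr_seconds": series.tr_seconds,
        "n_steps": series.n_steps,
        "subject_id": subject_id,
        "n_channels": series.n_channels,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_navigator_csv(path: str | Path) -> FidnavSeries:
    """Read a navigator series written by :func:`write_navigator_csv`.

    Raises :class:`NavigatorFormatError` on a missing/invalid header,
    ragged rows, missing channel columns, or non-finite values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise NavigatorFormatError(f"{path}: empty navigator file") from exc
    except pd.errors.ParserError as exc:
        raise NavigatorFormatError(f"{path}: {exc}") from exc
    if df.empty:
        raise NavigatorFormatError(f"{path}: no TR rows")
    if "tr_index" not in df.columns:
        raise NavigatorFormatError(f"{path}: missing 'tr_index' column")
    chan_ids = sorted(
        int(c[2:].split("_")[0])
        for c in df.columns
        if c.startswith("ch") and c[2:].split("_")[0].isdigit()
    )
    n_c = max(chan_ids, default=0)
    if n_c == 0:
        raise NavigatorFormatError(f"{path}: no channel columns (ch{{j}}_re/ch{{j}}_im)")
    for j in range(1, n_c + 1):
        for suffix in ("re", "im"):
            col = f"ch{j}_{suffix}"
            if col not in df.columns:
                raise NavigatorFormatError(f"{path}: missing column {col}")
    data = np.empty((n_c, len(df)), dtype=complex)
    for j in range(n_c):
        re = df[f"ch{j + 1}_re"].to_numpy(dtype=float)
        im = df[f"ch{j + 1}_im"].to_numpy(dtype=float)
        bad = ~(np.isfinite(re) & np.isfinite(im))
        if bad.any():
            line = int(np.nonzero(bad)[0][0]) + 2  # 1-based + header line
            raise NavigatorFormatError(f"{path}: non-finite value at line {line}")
        data[j] = re + 1j * im

    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise NavigatorFormatError(f"{path}: missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    tr_seconds = float(meta["tr_seconds"])
    if not math.isfinite(tr_seconds) or tr_seconds <= 0:
        raise NavigatorFormatError(f"{path}: invalid tr_seconds in sidecar")
    return FidnavSeries(
        signal=data, tr_seconds=tr_seconds, n_steps=meta.get("n_steps")
    )


@dataclass
class PipelineConfig:
    """Validated configuration for the end-to-end pipeline."""

    tr_seconds: float = 1.54
    n_channels: int = 32
    n_tr: int = 163
    ta_minutes: float = 4.2
    n_discard: int = 3
    n_ref: int = 3
    window: tuple[int, int] | None = None
    dichotomization: str = "12v345"
    bootstrap_b: int = 1000
    seed: int = 0
    weights_source: str = "default"
    slot_cost: float = 2828.0
    slot_minutes: float = 45.0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("tr_seconds", "n_channels", "n_tr", "ta_minutes", "n_ref",
                     "bootstrap_b", "slot_cost", "slot_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.dichotomization not in DICHOTOMIZATIONS:
            raise ValueError(
                f"dichotomization must be one of {DICHOTOMIZATIONS}"
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "window" in raw and raw["window"] is not None:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @property
    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON form, for output provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_csv_with_provenance(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """Write a report CSV with a leading ``# config=<hash>`` comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config={config.config_hash}\n")
        df.to_csv(fh, index=False)
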