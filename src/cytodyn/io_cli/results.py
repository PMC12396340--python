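"""Result tables with provenance sidecars."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import pandas as pd

__all__ = ["RunConfig", "write_results"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a CLI run."""

    subcommand: str
    inputs: Dict[str, str] = field(default_factory=dict)
    calibration: Dict[str, float] = field(default_factory=dict)
    parameters: Dict[str, Any] = field(default_factory=dict)
    seed: Optional[int] = None
    outdir: str = "."

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def write_results(
    tables: Dict[str, pd.DataFrame],
    outdir: str | Path,
    config: Optional[RunConfig] = None,
    units: Optional[Dict[str, Dict[str, str]]] = None,
) -> Dict[str, Path]:
    """Write CSV tables (header + optional units row) plus a JSON sidecar.

    Column order is taken from each DataFrame, so reruns with the same
    config and seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, Path] = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        unit_row = None
        if units and name in units:
            unit_row = pd.DataFrame(
                [{c: units[name].get(c, "") for c in df.columns}])
        with open(path, "w") as fh:
            fh.write(",".join(map(str, df.columns)) + "\n")
            if unit_row is not None:
                fh.write(",".join(map(str, unit_row.iloc[0])) + "\n")
            df.to_csv(fh, header=False, index=False)
        written[name] = path
    if config is not None:
        sidecar = outdir / "run_config.json"
        sidecar.write_text(config.to_json())
        written["run_config"] = sidecar
    return written
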