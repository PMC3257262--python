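"""Run configuration: every stage parameter with its documented default."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .jcoupling import DEFAULT_AROMATIC_CORRECTION_HZ
from .proline import DEFAULT_BOUNDARY_PPM, DEFAULT_MARGIN_PPM
from .relaxation import DEFAULT_K_SIGMA
from .secondary_shifts import DEFAULT_MIN_LEN, DEFAULT_THRESHOLD_PPM
from .hierarchy import DEFAULT_FLANK_WINDOW
from .synthetic import DEFAULT_DMSO_LADDER


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters in one declarative object.

    Loadable from a JSON file; unknown keys are rejected so that a typo in a
    parameter name fails loudly instead of silently using a default.
    """

    dmso_ladder: tuple[float, ...] = DEFAULT_DMSO_LADDER
    threshold_ppm: float = DEFAULT_THRESHOLD_PPM
    min_len: int = DEFAULT_MIN_LEN
    k_sigma: float = DEFAULT_K_SIGMA
    exchange_min_len: int = 3
    flank_window: int = DEFAULT_FLANK_WINDOW
    boundary_ppm: float = DEFAULT_BOUNDARY_PPM
    margin_ppm: float = DEFAULT_MARGIN_PPM
    aromatic_correction_hz: float = DEFAULT_AROMATIC_CORRECTION_HZ
    field_mhz: float = 800.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "dmso_ladder" in data:
            data["dmso_ladder"] = tuple(data["dmso_ladder"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dmso_ladder"] = list(d["dmso_ladder"])
        return d
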