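"""Core scan-record container shared by the simulator, calibration and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: mandatory columns of a scan record, in file order
SCAN_COLUMNS = [
    "x_robot",
    "y_robot",
    "z_robot",
    "x_meas",
    "y_meas",
    "z_meas",
    "u",
    "v",
    "depth",
    "v1",
    "v2",
    "v3",
    "v_mean",
]


@dataclass
class ScanRecord:
    """Measured voltages at robot/measurement coordinates with session metadata.

    ``data`` has one row per measured point, in scan order, with the columns
    of :data:`SCAN_COLUMNS` (lengths cm, voltages V).  ``metadata`` carries
    the session context (generator power, phantom properties, applicator,
    seed, session id, plane kind, spacing).
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SCAN_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"scan record missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def session_id(self) -> str | None:
        return self.metadata.get("session_id")

    @property
    def spacing(self) -> float | None:
        return self.metadata.get("spacing_cm")

    @property
    def plane_kind(self) -> str | None:
        return self.metadata.get("plane_kind")
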