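"""Run configuration shared by the command-line subcommands."""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field


@dataclass
class RunConfig:
    """Resolved configuration of a CLI run (TOML file values overridden by flags)."""

    t_max: int = 1000
    bin_width: int = 10
    p_mode: str = "mml"
    symmetrize_match: bool = False
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.p_mode not in {"mml", "stationary", "file"}:
            raise ValueError(f"unknown p_mode {self.p_mode!r}")

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        values: dict = {}
        if path is not None:
            with open(path, "rb") as fh:
                data = tomllib.load(fh)
            known = {f for f in cls.__dataclass_fields__ if f != "extra"}
            values = {k: v for k, v in data.items() if k in known}
            values["extra"] = {k: v for k, v in data.items() if k not in known}
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def digest(self) -> str:
        """Short hash of the resolved configuration, for report headers."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
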