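"""Run configuration: flat key-value YAML in degrees and Angstrom.

A run's configuration is echoed into its output directory so every result
can be regenerated from the files it sits next to.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Serializable settings for grid sampling and network search runs."""

    # coiled-coil grid (degrees / Angstrom)
    dphi1_min: float = -100.0
    dphi1_max: float = 100.0
    dphi1_step: float = 20.0
    radius_min: float = 6.5
    radius_max: float = 7.5
    radius_step: float = 0.25
    z_offsets: list = field(default_factory=lambda: [-1.5, 0.0, 1.5])
    helix_length: int = 77
    antiparallel: bool = False
    # register / mask
    pattern: str = "NPNPNPNPN"
    # hbnet
    trials: int = 100_000
    seed: int = 0
    min_network_residues: int = 3
    networks_required: int = 3
    min_aromatics_total: int = 2
    extra_rotamers: bool = True
    hb_min_distance: float = 2.6
    hb_max_distance: float = 3.3
    hb_min_donor_angle: float = 120.0
    hb_min_acceptor_angle: float = 90.0
    # ring filters
    max_close_err: float = 1.0
    max_clashes: int = 0
    output_dir: str = "bundleforge-out"

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def echo_to(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / "run-config.yaml"
        self.save(path)
        return path
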