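"""Flat key = value run configuration with lossless text round-trip.

A run configuration bundles the landscape, the pulling protocol, the
restraint, the scenario table (label -> shielding) and the analysis options.
Nested parameters use dotted keys (``landscape.well_depth = 10.0``,
``scenario.shielded = 1.0``); every stochastic stage derives its seed from the
single top-level seed, and the SHA-256 hash of the canonical text form is the
provenance tag stamped on every output file.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace

from .landscape import LandscapeModel
from .simulate import PullingProtocol, RestraintSpec

__all__ = ["RunConfig", "config_hash"]

_SECTIONS = {
    "landscape": LandscapeModel,
    "protocol": PullingProtocol,
    "restraint": RestraintSpec,
}


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to rerun the simulate -> PMF -> energetics pipeline."""

    seed: int = 1
    outdir: str = "results/pipeline"
    n_boot: int = 10
    stage1_ns: float = 2.0
    rdf_frames: int = 200
    rdf_exclusion_radius: float = 5.0
    reference: str = "wt_LEN"
    endpoints_tsv: str = ""  # published/endpoint table mode (skips simulation)
    affinity_tsv: str = ""  # per-complex ΔG_bin for the correlation stage
    quiet: bool = False
    landscape: LandscapeModel = field(default_factory=LandscapeModel)
    protocol: PullingProtocol = field(default_factory=PullingProtocol)
    restraint: RestraintSpec = field(default_factory=RestraintSpec)
    scenarios: dict = field(
        default_factory=lambda: {"shielded": 1.0, "unshielded": 0.0}
    )

    def to_text(self) -> str:
        """Canonical flat text form (sorted keys; round-trips losslessly)."""
        lines = []
        for f in fields(self):
            if f.name in _SECTIONS or f.name == "scenarios":
                continue
            lines.append(f"{f.name} = {getattr(self, f.name)!r}")
        for section, cls in _SECTIONS.items():
            obj = getattr(self, section)
            for f in fields(cls):
                lines.append(f"{section}.{f.name} = {getattr(obj, f.name)!r}")
        for label in sorted(self.scenarios):
            lines.append(f"scenario.{label} = {self.scenarios[label]!r}")
        return "\n".join(sorted(lines)) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        import ast

        top: dict = {}
        sections: dict = {name: {} for name in _SECTIONS}
        scenarios: dict = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, _, value = line.partition("=")
            key = key.strip()
            value = ast.literal_eval(value.strip())
            if "." in key:
                section, _, name = key.partition(".")
                if section == "scenario":
                    scenarios[name] = float(value)
                elif section in sections:
                    sections[section][name] = value
                else:
                    raise ValueError(f"unknown config section: {section!r}")
            else:
                top[key] = value
        kwargs = dict(top)
        for section, cls_ in _SECTIONS.items():
            kwargs[section] = cls_(**sections[section])
        if scenarios:
            kwargs["scenarios"] = scenarios
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))


def config_hash(cfg: RunConfig) -> str:
    """Short SHA-256 tag of the canonical config text."""
    return hashlib.sha256(cfg.to_text().encode()).hexdigest()[:12]
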