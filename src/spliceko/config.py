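"""Run configuration: every tunable of the pipeline in one serializable record."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .guide_design import BaseEditorProfile

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters with their documented defaults.

    editor_name/pam/window: the base-editor profile (SpCas9-BE4: NGG PAM,
    editing window protospacer positions 4-8).
    flank: nt extracted on each side of a splice junction (>= 20 so a
    protospacer+PAM covering the critical C always fits).
    weight_window / weight_transcript: combined-score weights.
    ddpcr_variant: 'per_diploid' (junctions per diploid genome) or
    'quantasoft' (doubled fractional abundance).
    detection_limit_percent: ddPCR reporting threshold.
    include_noncanonical: also design against non-GT/AG junctions.
    """

    editor_name: str = "BE4"
    pam: str = "NGG"
    window_start: int = 4
    window_end: int = 8
    flank: int = 30
    weight_window: float = 0.7
    weight_transcript: float = 0.3
    ddpcr_variant: str = "per_diploid"
    detection_limit_percent: float = 0.01
    include_noncanonical: bool = False
    seed: int = 0
    outdir: str = "spliceko_out"

    def profile(self) -> BaseEditorProfile:
        return BaseEditorProfile(
            name=self.editor_name,
            pam=self.pam,
            window_start=self.window_start,
            window_end=self.window_end,
        )

    @property
    def weights(self) -> tuple[float, float]:
        return (self.weight_window, self.weight_transcript)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        """Load from a YAML string or path; unknown keys are rejected."""
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
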