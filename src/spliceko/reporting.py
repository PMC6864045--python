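"""Tabular and BED output of designs, outcomes and summaries.

All writers are deterministic: fixed column order, fixed float formatting,
no timestamps in table bodies — identical inputs give byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .guide_design import GuideCandidate
from .outcomes import CandidateSummary, EditOutcome

__all__ = [
    "guides_to_frame",
    "guides_to_bed",
    "outcomes_to_frame",
    "summaries_to_frame",
    "write_tsv",
]

FLOAT_FORMAT = "%.6g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def guides_to_frame(guides: Iterable[GuideCandidate]) -> pd.DataFrame:
    """One row per candidate: location, sequences, critical positions, scores."""
    rows = [
        {
            "transcript_id": g.transcript_id,
            "design_class": g.design_class,
            "target_id": g.target_id,
            "protospacer": g.protospacer,
            "pam": g.pam_observed,
            "strand": g.strand,
            "contig": g.contig,
            "start": g.start,
            "end": g.end,
            "genome_strand": g.genome_strand,
            "critical_positions": ";".join(map(str, g.critical_positions)),
            "window_cs": ";".join(map(str, g.window_cs)),
            "window_score": g.window_score,
            "transcript_score": g.transcript_score,
            "combined_score": g.combined_score,
            "flags": ";".join(sorted(g.flags)),
        }
        for g in guides
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "design_class",
            "target_id",
            "protospacer",
            "pam",
            "strand",
            "contig",
            "start",
            "end",
            "genome_strand",
            "critical_positions",
            "window_cs",
            "window_score",
            "transcript_score",
            "combined_score",
            "flags",
        ],
    )


def guides_to_bed(guides: Iterable[GuideCandidate]) -> str:
    """BED6 of protospacer footprints; score = round(1000 * combined)."""
    lines = []
    for g in guides:
        score = 0 if g.combined_score is None else round(1000 * g.combined_score)
        lines.append(
            "\t".join(
                [
                    g.contig,
                    str(g.start),
                    str(g.end),
                    f"{g.design_class}:{g.transcript_id}",
                    str(score),
                    g.genome_strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def outcomes_to_frame(outcomes: Iterable[EditOutcome]) -> pd.DataFrame:
    rows = [
        {
            "candidate_id": o.candidate_id,
            "assignment": o.assignment_string,
            "edited_protospacer": o.edited_protospacer,
            "consequence": o.consequence,
            "transcript_effect": o.transcript_effect,
            "flags": ";".join(sorted(o.flags)),
        }
        for o in outcomes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_id",
            "assignment",
            "edited_protospacer",
            "consequence",
            "transcript_effect",
            "flags",
        ],
    )


def summaries_to_frame(summaries: Iterable[CandidateSummary]) -> pd.DataFrame:
    rows = [
        {
            "candidate_id": s.candidate_id,
            "design_class": s.design_class,
            "n_outcomes": s.n_outcomes,
            "n_critical_edited": s.n_critical_edited,
            "knockout_fraction": s.knockout_fraction,
            "missense_fraction": s.missense_fraction,
            "silent_fraction": s.silent_fraction,
            "flags": ";".join(sorted(s.flags)),
            "warning": s.warning,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "candidate_id",
            "design_class",
            "n_outcomes",
            "n_critical_edited",
            "knockout_fraction",
            "missense_fraction",
            "silent_fraction",
            "flags",
            "warning",
        ],
    )
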