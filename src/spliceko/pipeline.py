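"""End-to-end design runs tying the modules together."""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .gene_model import load_genome, load_transcripts
from .guide_design import find_pmstop_guides, find_splice_guides, rank_guides, score_guide
from .outcomes import classify_outcome, enumerate_outcomes, summarize_candidate
from .reporting import (
    guides_to_bed,
    guides_to_frame,
    outcomes_to_frame,
    summaries_to_frame,
    write_tsv,
)

__all__ = ["run_design"]

log = logging.getLogger("spliceko")


def run_design(
    config: RunConfig,
    genome_path,
    annotation_path,
    transcript_ids: list[str],
    *,
    classes: tuple[str, ...] = ("splice", "pmstop"),
    with_outcomes: bool = True,
    outdir=None,
) -> dict[str, pd.DataFrame]:
    """Design guides (and optionally outcome/summary tables) for transcripts.

    Outputs are deterministic for fixed inputs and config.  When ``outdir``
    (default ``config.outdir``) is set, writes guides.tsv, guides.bed and,
    with ``with_outcomes``, outcomes.tsv and summary.tsv.
    """
    if not transcript_ids:
        raise ValueError("no transcript ids given")
    profile = config.profile()
    genome = load_genome(genome_path)
    models = {t.transcript_id: t for t in load_transcripts(annotation_path, genome)}
    log.info(
        "spliceko %s | config %s | %d transcript(s) in annotation",
        __version__,
        hashlib.sha256(config.to_yaml().encode()).hexdigest()[:12],
        len(models),
    )
    missing = [tid for tid in transcript_ids if tid not in models]
    if missing:
        raise KeyError(
            f"unknown transcript id(s) {missing}; available: {sorted(models)}"
        )

    guides = []
    for tid in transcript_ids:
        t = models[tid]
        found = []
        if "splice" in classes and t.n_exons >= 2:
            found.extend(
                find_splice_guides(
                    t,
                    genome,
                    profile,
                    flank=config.flank,
                    include_noncanonical=config.include_noncanonical,
                )
            )
        if "pmstop" in classes and t.cds_intervals:
            found.extend(find_pmstop_guides(t, genome, profile))
        for c in found:
            score_guide(c, t, profile, weights=config.weights)
        log.info("transcript %s: %d candidate(s)", tid, len(found))
        guides.extend(rank_guides(found))

    tables: dict[str, pd.DataFrame] = {"guides": guides_to_frame(guides)}
    if with_outcomes:
        all_outcomes, all_summaries = [], []
        for g in guides:
            outs = enumerate_outcomes(g, profile)
            t = models[g.transcript_id]
            for o in outs:
                classify_outcome(o, t)
            all_outcomes.extend(outs)
            all_summaries.append(summarize_candidate(g, outs))
        tables["outcomes"] = outcomes_to_frame(all_outcomes)
        tables["summary"] = summaries_to_frame(all_summaries)

    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(tables["guides"], outdir / "guides.tsv")
    (outdir / "guides.bed").write_text(guides_to_bed(guides))
    if with_outcomes:
        write_tsv(tables["outcomes"], outdir / "outcomes.tsv")
        write_tsv(tables["summary"], outdir / "summary.tsv")
    return tables
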