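"""Quantification math for the multiplex-editing readout assays.

* droplet-digital PCR (ddPCR) translocation frequency: Poisson-corrected
  fractional abundance of an experimental junction probe (FAM) against an
  internal reference probe (HEX), adjusted for the two reference copies
  per diploid genome;
* PD-1 flow-cytometry normalization: stimulation does not upregulate PD-1
  uniformly across control cells, so positive/negative fractions are
  rescaled by the control-sample ratio r_PD1 while conserving their sum;
* RNA off-target candidate ranking: percent-maximal-expression score over
  CD4+/CD8+ read counts, filtered to genes with previously observed
  editing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DdpcrAssayCounts",
    "ddpcr_translocation_frequency",
    "ddpcr_frequency_ci",
    "FlowFractions",
    "NormalizedFractions",
    "normalize_pd1",
    "ExpressionRecord",
    "rank_rna_ot_candidates",
    "DETECTION_LIMIT_PERCENT",
]

#: reporting threshold quoted for the ddPCR assay (percent); a parameter,
#: not a hard-coded truth
DETECTION_LIMIT_PERCENT = 0.01


@dataclass(frozen=True)
class DdpcrAssayCounts:
    """Droplet counts of one duplexed ddPCR assay."""

    n: int  # total droplets
    k_fam: int  # experimental junction-probe positives
    k_hex: int  # internal reference-probe positives

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("total droplet count must be positive")
        if not (0 <= self.k_fam <= self.n and 0 <= self.k_hex <= self.n):
            raise ValueError("positive-droplet counts must lie in [0, n]")


def _lam(k: int, n: int) -> float:
    """Poisson mean copies/droplet from the positive-droplet fraction."""
    return -math.log(1.0 - k / n)


def ddpcr_translocation_frequency(
    c: DdpcrAssayCounts,
    *,
    variant: str = "per_diploid",
    reference_copies: int = 2,
) -> float:
    """Translocation frequency (percent) from duplexed droplet counts.

    Default ``per_diploid``: frequency = 100 * reference_copies *
    lambda_fam / lambda_hex, i.e. junctions per diploid genome given
    ``reference_copies`` reference sequences per genome.  Variant
    ``quantasoft`` doubles the fractional abundance
    lambda_fam / (lambda_fam + lambda_hex) instead.
    """
    if c.k_hex == 0:
        raise ValueError("no reference (HEX) signal: cannot normalize")
    if c.k_hex == c.n:
        raise ValueError("reference channel saturated (k_hex = n)")
    if c.k_fam == c.n:
        raise ValueError("target channel saturated (k_fam = n)")
    if c.k_fam == 0:
        return 0.0
    lam_fam = _lam(c.k_fam, c.n)
    lam_hex = _lam(c.k_hex, c.n)
    if variant == "per_diploid":
        return 100.0 * reference_copies * lam_fam / lam_hex
    if variant == "quantasoft":
        return 100.0 * reference_copies * lam_fam / (lam_fam + lam_hex)
    raise ValueError(f"unknown ddPCR variant {variant!r}")


def ddpcr_frequency_ci(
    c: DdpcrAssayCounts,
    *,
    z: float = 1.96,
    reference_copies: int = 2,
) -> tuple[float, float]:
    """Delta-method confidence interval (percent) for the per-diploid frequency.

    Var(lambda) ~= p / ((1-p) n) for p = k/n; the two channels are treated
    as independent binomials.
    """
    freq = ddpcr_translocation_frequency(c, reference_copies=reference_copies)
    if c.k_fam == 0:
        return (0.0, 0.0)
    p_f, p_h = c.k_fam / c.n, c.k_hex / c.n
    lam_f, lam_h = _lam(c.k_fam, c.n), _lam(c.k_hex, c.n)
    var_lf = p_f / ((1 - p_f) * c.n)
    var_lh = p_h / ((1 - p_h) * c.n)
    rel_var = var_lf / lam_f**2 + var_lh / lam_h**2
    half = z * freq * math.sqrt(rel_var)
    return (max(0.0, freq - half), freq + half)


@dataclass(frozen=True)
class FlowFractions:
    """Non-normalized PD-1 positive/negative percentages and control ratio."""

    f_pos: float  # percent PD-1 positive (non-normalized)
    f_neg: float  # percent PD-1 negative (non-normalized)
    r_pd1: float  # PD-1+/PD-1- ratio in control samples

    def __post_init__(self) -> None:
        if self.r_pd1 <= 0:
            raise ValueError("r_PD1 must be positive")
        if self.f_pos < 0 or self.f_neg < 0:
            raise ValueError("fractions must be non-negative")
        if self.f_pos + self.f_neg > 100.0 + 1e-6:
            raise ValueError("PD-1 fractions exceed 100%")


@dataclass(frozen=True)
class NormalizedFractions:
    f_pos: float
    f_neg: float
    out_of_range: bool  # normalization pushed a value outside [0, 100]


def normalize_pd1(f: FlowFractions, *, clamp: bool = False) -> NormalizedFractions:
    """Rescale PD-1 fractions by the control ratio, conserving their sum.

    F'_pos = F_pos + F_pos * (1 - r_PD1);
    F'_neg = F_neg - F_pos * (1 - r_PD1).
    The identity F'_pos + F'_neg = F_pos + F_neg holds exactly.  Values
    outside [0, 100] are flagged and clamped only on request.
    """
    shift = f.f_pos * (1.0 - f.r_pd1)
    pos = f.f_pos + shift
    neg = f.f_neg - shift
    out = not (0.0 <= pos <= 100.0 and 0.0 <= neg <= 100.0)
    if clamp and out:
        pos = min(100.0, max(0.0, pos))
        neg = min(100.0, max(0.0, neg))
    return NormalizedFractions(f_pos=pos, f_neg=neg, out_of_range=out)


@dataclass(frozen=True)
class ExpressionRecord:
    """Read counts of one gene in CD4+ and CD8+ T cells, with editing history."""

    gene_id: str
    reads_cd4: float
    reads_cd8: float
    previously_edited: bool

    def __post_init__(self) -> None:
        if self.reads_cd4 < 0 or self.reads_cd8 < 0:
            raise ValueError("read counts must be non-negative")


def rank_rna_ot_candidates(
    records: Sequence[ExpressionRecord],
    top_n: int = 5,
    *,
    denominator: str = "per_gene_product",
) -> pd.DataFrame:
    """Rank RNA off-target candidate genes by percent-maximal expression.

    score_i = (Reads_CD4,i * Reads_CD8,i) / max_j(Reads_CD4,j * Reads_CD8,j);
    genes without previously observed editing are filtered out and the top
    ``top_n`` returned, ties broken by gene id.  ``denominator`` selects
    the default per-gene-product maximum or the product of per-compartment
    maxima (``per_compartment``).
    """
    if not records:
        raise ValueError("no expression records supplied")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    products = [r.reads_cd4 * r.reads_cd8 for r in records]
    if denominator == "per_gene_product":
        denom = max(products)
    elif denominator == "per_compartment":
        denom = max(r.reads_cd4 for r in records) * max(r.reads_cd8 for r in records)
    else:
        raise ValueError(f"unknown denominator variant {denominator!r}")
    if denom == 0:
        raise ValueError("all expression products are zero; scores undefined")
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "reads_cd4": [r.reads_cd4 for r in records],
            "reads_cd8": [r.reads_cd8 for r in records],
            "previously_edited": [r.previously_edited for r in records],
            "percent_maximal_expression": [p / denom for p in products],
        }
    )
    out = (
        df[df["previously_edited"]]
        .sort_values(
            ["percent_maximal_expression", "gene_id"], ascending=[False, True]
        )
        .head(top_n)
        .reset_index(drop=True)
    )
    return out


def ddpcr_table(df: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Append a ``frequency_percent`` column to a droplet-count table.

    Expects columns ``n``, ``k_fam``, ``k_hex`` (an ``assay`` label column
    is carried through).
    """
    freqs = [
        ddpcr_translocation_frequency(
            DdpcrAssayCounts(int(r["n"]), int(r["k_fam"]), int(r["k_hex"])), **kwargs
        )
        for _, r in df.iterrows()
    ]
    out = df.copy()
    out["frequency_percent"] = freqs
    out["above_detection_limit"] = np.array(freqs) >= DETECTION_LIMIT_PERCENT
    return out


def flow_table(df: pd.DataFrame, *, clamp: bool = False) -> pd.DataFrame:
    """Append normalized PD-1 columns to a flow-fraction table.

    Expects columns ``f_pos``, ``f_neg``, ``r_pd1``.
    """
    rows = [
        normalize_pd1(
            FlowFractions(float(r["f_pos"]), float(r["f_neg"]), float(r["r_pd1"])),
            clamp=clamp,
        )
        for _, r in df.iterrows()
    ]
    out = df.copy()
    out["f_pos_normalized"] = [r.f_pos for r in rows]
    out["f_neg_normalized"] = [r.f_neg for r in rows]
    out["out_of_range"] = [r.out_of_range for r in rows]
    return out
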