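"""Candidate-window definition and partner-SNP choice.

The partner for each anchor SNP is the candidate in a local window with the
highest metric score; ties go to the candidate appearing first in the window.
Correlation is computed on all individuals regardless of phenotype, which
keeps the choice statistically independent of the subsequent association
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import SnpRecord
from .metric import UNDEFINED, MetricCurve, genotype_r2, score

__all__ = ["WindowSpec", "PartnerChoice", "candidate_window", "select_partner"]


@dataclass(frozen=True)
class WindowSpec:
    """Candidate window: ``snp_count`` mode takes the *size* nearest SNPs
    (half per side, extended at chromosome ends); ``bp_distance`` mode takes
    every same-chromosome SNP within *size* base pairs (inclusive)."""

    mode: str = "snp_count"
    size: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("snp_count", "bp_distance"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.size < 1:
            raise ValueError("window size must be >= 1")


@dataclass(frozen=True)
class PartnerChoice:
    """Outcome of partner selection for one anchor SNP."""

    anchor_index: int
    partner_index: int | None
    r2: float | None
    score: float
    n_candidates: int


def candidate_window(
    anchor_index: int, snps: Sequence[SnpRecord], spec: WindowSpec
) -> list[int]:
    """Indices of candidate partner SNPs for ``anchor_index``, in map order.

    Candidates never cross chromosome boundaries and exclude the anchor.  In
    ``snp_count`` mode, floor(w/2) SNPs left and ceil(w/2) right of an
    interior anchor; near a chromosome end the deficit is taken from the
    other side so the total is min(w, available).
    """
    chrom = snps[anchor_index].chromosome
    lo = anchor_index
    while lo > 0 and snps[lo - 1].chromosome == chrom:
        lo -= 1
    hi = anchor_index
    while hi + 1 < len(snps) and snps[hi + 1].chromosome == chrom:
        hi += 1

    if spec.mode == "snp_count":
        w = spec.size
        n_left_avail = anchor_index - lo
        n_right_avail = hi - anchor_index
        n_left = w // 2
        n_right = w - n_left  # ceil(w/2)
        if n_left > n_left_avail:
            n_right += n_left - n_left_avail
            n_left = n_left_avail
        if n_right > n_right_avail:
            n_left = min(n_left + n_right - n_right_avail, n_left_avail)
            n_right = n_right_avail
        left = list(range(anchor_index - n_left, anchor_index))
        right = list(range(anchor_index + 1, anchor_index + 1 + n_right))
        return left + right

    pos = snps[anchor_index].bp_position
    return [
        j
        for j in range(lo, hi + 1)
        if j != anchor_index and abs(snps[j].bp_position - pos) <= spec.size
    ]


def select_partner(
    anchor_index: int,
    candidates: Sequence[int],
    genotypes: np.ndarray,
    curve: MetricCurve,
) -> PartnerChoice:
    """Choose the highest-scoring candidate partner for one anchor.

    r² against each candidate uses every individual (phenotype is never
    consulted).  Monomorphic candidates (UNDEFINED r²) score 0.  If there are
    no candidates, or every candidate has UNDEFINED r², no partner is chosen.
    """
    anchor = genotypes[:, anchor_index]
    best: tuple[float, int, int, float | None] | None = None
    any_defined = False
    for pos, j in enumerate(candidates):
        r2 = genotype_r2(anchor, genotypes[:, j])
        defined = r2 is not UNDEFINED
        any_defined |= defined
        s = score(curve, r2)
        # a defined r2 beats UNDEFINED at equal score; otherwise earliest wins
        key = (s, int(defined))
        if best is None or key > (best[0], best[1]):
            best = (s, int(defined), pos, r2)
    if best is None or not any_defined:
        return PartnerChoice(anchor_index, None, None, 0.0, len(candidates))
    s, _, pos, r2 = best
    return PartnerChoice(anchor_index, int(candidates[pos]), r2, s, len(candidates))
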