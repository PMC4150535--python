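"""Synthetic multi-SNP case/control panels and in-package fixtures.

These generators stand in for reference-panel-derived data: haplotype pools
are small explicit lists of m-SNP haplotypes with frequencies, individuals
are two independent haplotype draws (random mating, no recombination within
the pool region), and disease follows a genotype-relative-risk penetrance at
a designated causal SNP whose column can be withheld from the emitted panel
to emulate an untyped causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import GenotypeDataset, SnpRecord, write_plink_binary

__all__ = [
    "MultiSnpScenario",
    "generate_panel",
    "table1_fixture",
    "write_plink_fixture",
    "weak_tagging_scenario",
    "strong_tagging_scenario",
    "null_ld_scenario",
]


@dataclass(frozen=True)
class MultiSnpScenario:
    """An m-SNP haplotype pool with a designated causal SNP.

    ``relative_risks`` are genotype relative risks (g1, g2) for one/two
    copies of the risk allele; the baseline penetrance is solved so the
    population prevalence matches ``prevalence``.  With ``causal_typed``
    False the causal column is dropped from emitted panels.
    """

    haplotypes: np.ndarray            # (H, m) 0/1 allele matrix
    frequencies: np.ndarray           # (H,)
    positions: tuple[int, ...]        # bp, one per SNP
    causal_index: int
    relative_risks: tuple[float, float] = (1.5, 2.25)
    causal_typed: bool = False
    n_cases: int = 1_000
    n_controls: int = 1_000
    prevalence: float = 0.01
    chromosome: str = "1"
    snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        H = np.asarray(self.haplotypes, dtype=np.int8)
        f = np.asarray(self.frequencies, dtype=float)
        if H.ndim != 2 or H.shape[0] != f.size:
            raise ValueError("haplotypes and frequencies are inconsistent")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-4:
            raise ValueError("haplotype frequencies must sum to 1")
        if not 0 <= self.causal_index < H.shape[1]:
            raise ValueError("causal_index out of range")
        if len(self.positions) != H.shape[1]:
            raise ValueError("positions length must equal SNP count")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        object.__setattr__(self, "haplotypes", H)
        object.__setattr__(self, "frequencies", f / f.sum())
        if not self.snp_ids:
            object.__setattr__(
                self, "snp_ids",
                tuple(f"snp{j + 1}" for j in range(H.shape[1])),
            )

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def risk_multipliers(self) -> np.ndarray:
        g1, g2 = self.relative_risks
        return np.array([1.0, g1, g2])

    def analytic_r2(self, i: int, j: int) -> float | None:
        """Population r² between the allele indicators of SNPs i and j."""
        from .metric import haplotype_r2_from_counts

        return haplotype_r2_from_counts(
            self.frequencies, self.haplotypes[:, i], self.haplotypes[:, j]
        )


def _pair_distributions(
    scenario: MultiSnpScenario,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Case/control distributions over ordered haplotype pairs + baseline."""
    f = scenario.frequencies
    pair_p = np.outer(f, f).ravel()
    causal = scenario.haplotypes[:, scenario.causal_index].astype(int)
    count = (causal[:, None] + causal[None, :]).ravel()
    rr = scenario.risk_multipliers()[count]
    mean_rr = pair_p @ rr
    baseline = scenario.prevalence / mean_rr
    pen = baseline * rr
    if np.any(pen > 1.0):
        raise ValueError(
            "unattainable prevalence: implied penetrance exceeds 1"
        )
    case_p = pair_p * pen
    ctrl_p = pair_p * (1.0 - pen)
    return case_p / case_p.sum(), ctrl_p / ctrl_p.sum(), baseline


def generate_panel(
    scenario: MultiSnpScenario, rng: np.random.Generator
) -> tuple[GenotypeDataset, int]:
    """Simulate one case/control panel from a scenario.

    Haplotype pairs are drawn from the exact conditional pair distributions
    given status, so exactly ``n_cases``/``n_controls`` are produced.
    Returns ``(dataset, causal_bp_position)``; when the causal SNP is
    untyped its column is absent from the dataset but its position is still
    returned for detection-window bookkeeping.
    """
    case_p, ctrl_p, _ = _pair_distributions(scenario)
    H = len(scenario.frequencies)
    idx_case = rng.choice(H * H, size=scenario.n_cases, p=case_p)
    idx_ctrl = rng.choice(H * H, size=scenario.n_controls, p=ctrl_p)
    idx = np.concatenate([idx_case, idx_ctrl])
    h1, h2 = idx // H, idx % H
    geno = (scenario.haplotypes[h1] + scenario.haplotypes[h2]).astype(np.int8)
    pheno = np.concatenate(
        [np.ones(scenario.n_cases), np.zeros(scenario.n_controls)]
    )
    cols = list(range(scenario.n_snps))
    if not scenario.causal_typed:
        cols.remove(scenario.causal_index)
    snps = [
        SnpRecord(scenario.chromosome, scenario.snp_ids[j], 0.0,
                  scenario.positions[j], "A", "B")
        for j in cols
    ]
    n = scenario.n_cases + scenario.n_controls
    dataset = GenotypeDataset(
        genotypes=geno[:, cols],
        snps=snps,
        phenotype=pheno,
        phenotype_type="binary",
        individual_ids=[f"ind{i + 1}" for i in range(n)],
    )
    return dataset, scenario.positions[scenario.causal_index]


# ---------------------------------------------------------------------------
# in-package fixtures
# ---------------------------------------------------------------------------

#: Expected haplotype counts for (causal rs334, partner rs2340349, anchor
#: rs16931041) estimated separately in cases and controls of the Gambian
#: severe-malaria study; the protective rs334 A allele rides exclusively on
#: partner/anchor backgrounds C-C and C-T.
_TABLE1_HAPLOTYPES = (
    "A-C-C", "A-C-T", "A-T-C", "A-T-T", "T-C-C", "T-C-T", "T-T-C", "T-T-T",
)
_TABLE1_CASE_COUNTS = (8.978, 3.022, 0.0, 0.0, 42.100, 1476.000, 68.930, 1.074)
_TABLE1_CONTROL_COUNTS = (131.700, 53.330, 0.0, 0.0, 66.330, 2099.000, 110.000, 0.0)


def table1_fixture() -> dict:
    """The published three-SNP haplotype expected counts (malaria study).

    Returns haplotype labels (causal-partner-anchor allele order), per-column
    expected counts, and 0/1 indicator arrays for the causal A, partner C and
    anchor C alleles.
    """
    labels = _TABLE1_HAPLOTYPES
    split = [lab.split("-") for lab in labels]
    return {
        "haplotypes": labels,
        "case_counts": np.array(_TABLE1_CASE_COUNTS),
        "control_counts": np.array(_TABLE1_CONTROL_COUNTS),
        "causal_is_A": np.array([s[0] == "A" for s in split], dtype=float),
        "partner_is_C": np.array([s[1] == "C" for s in split], dtype=float),
        "anchor_is_C": np.array([s[2] == "C" for s in split], dtype=float),
    }


def write_plink_fixture(dataset: GenotypeDataset, prefix) -> None:
    """Write a dataset as a PLINK 1 binary fileset (round-trippable)."""
    write_plink_binary(dataset, prefix)


# ---------------------------------------------------------------------------
# bundled demo scenarios
# ---------------------------------------------------------------------------
# Three-SNP pools over (causal, anchor, partner); frequencies were chosen by
# numerical search on the haplotype simplex to realize the stated LD targets
# and are fixed.  Haplotype column order below: (causal, anchor, partner).

# anchor-partner r2 = 0.297; causal-anchor 0.145; causal-partner 0.062;
# causal vs anchor+partner combination 0.439 -> the AI test's home turf.
_WEAK_FREQS = (0.0192, 0.2727, 0.4778, 0.0800, 0.1199, 0.0109, 0.0186, 0.0009)

# causal-anchor r2 = 0.890 (anchor tags the causal SNP well), anchor-partner
# 0.207, causal-partner only 0.080 -> single-SNP testing already works and
# conditioning on the partner costs almost nothing.
_STRONG_FREQS = (0.0184, 0.0007, 0.0006, 0.7810, 0.0372, 0.1620, 0.0001, 0.0)

_THREE_SNP_HAPS = np.array(
    [[1, 1, 1], [1, 1, 0], [1, 0, 1], [1, 0, 0],
     [0, 1, 1], [0, 1, 0], [0, 0, 1], [0, 0, 0]], dtype=np.int8
)


def _three_snp_scenario(freqs, **kw) -> MultiSnpScenario:
    base = dict(
        haplotypes=_THREE_SNP_HAPS,
        frequencies=np.asarray(freqs, dtype=float),
        positions=(50_000, 100_000, 150_000),  # causal between... anchor mid
        causal_index=0,
        relative_risks=(1.5, 2.25),
        causal_typed=False,
        n_cases=1_000,
        n_controls=1_000,
        prevalence=0.01,
        snp_ids=("causal", "anchor", "partner"),
    )
    base.update(kw)
    return MultiSnpScenario(**base)


def weak_tagging_scenario(**kw) -> MultiSnpScenario:
    """Untyped causal SNP tagged only by the anchor+partner combination."""
    return _three_snp_scenario(_WEAK_FREQS, **kw)


def strong_tagging_scenario(**kw) -> MultiSnpScenario:
    """Untyped causal SNP tagged well (r² ≈ 0.9) by the anchor alone."""
    return _three_snp_scenario(_STRONG_FREQS, **kw)


def null_ld_scenario(**kw) -> MultiSnpScenario:
    """Null model (relative risks 1): LD structure, no phenotype effect."""
    return _three_snp_scenario(_WEAK_FREQS, relative_risks=(1.0, 1.0), **kw)


# A wider null panel for the type-I detection bound: five typed SNPs in
# moderate mutual LD (pairwise r2 0.24-0.84, MAF 0.15-0.40) around an
# untyped, effect-free "causal" position.  The 12-haplotype support and
# frequencies were drawn once under those constraints and frozen.
_NULL6_HAPS = np.array(
    [[0, 0, 0, 0, 1, 1], [0, 1, 1, 1, 1, 0], [0, 0, 0, 0, 1, 1],
     [0, 0, 1, 0, 0, 0], [1, 1, 0, 0, 0, 0], [1, 1, 0, 0, 1, 0],
     [1, 1, 1, 0, 0, 0], [0, 1, 1, 1, 0, 0], [1, 1, 1, 0, 1, 0],
     [0, 1, 0, 1, 0, 1], [1, 1, 1, 1, 0, 0], [1, 0, 0, 0, 0, 0]],
    dtype=np.int8,
)
_NULL6_FREQS = (0.0423, 0.0071, 0.1046, 0.0075, 0.0467, 0.0521,
                0.0697, 0.0359, 0.0681, 0.0047, 0.5503, 0.0111)


def null_window_scenario(**kw) -> MultiSnpScenario:
    """Five correlated typed SNPs, null phenotype: type-I harness input."""
    base = dict(
        haplotypes=_NULL6_HAPS,
        frequencies=np.asarray(_NULL6_FREQS, dtype=float),
        positions=(95_000, 20_000, 60_000, 100_000, 140_000, 180_000),
        causal_index=0,
        relative_risks=(1.0, 1.0),
        causal_typed=False,
        n_cases=1_000,
        n_controls=1_000,
        prevalence=0.01,
        snp_ids=("null_causal", "t1", "t2", "t3", "t4", "t5"),
    )
    base.update(kw)
    return MultiSnpScenario(**base)
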