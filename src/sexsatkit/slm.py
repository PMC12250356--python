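"""Sex-linked SNP marker screening on collapsed genotype matrices.

A DArT-style genotype matrix codes each locus x individual call as
0 (homozygous reference), 1 (homozygous alternate), 2 (heterozygous) or
missing. Under male heterogamety (XY) a perfectly sex-linked SNP is
heterozygous in every male and homozygous in every female; under female
heterogamety (ZW) the pattern is mirrored. Because perfect association can
arise by chance in small samples, the screen is paired with the binomial
null expectation

    E = L * h**n_het_sex * (1 - h)**n_hom_sex

where L is the number of scanned loci, h the per-individual heterozygosity
probability and the exponents the numbers of individuals that must be
heterozygous resp. homozygous for the pattern. A verdict is only
"suggestive" of a sex-determination system when the observed count exceeds
this expectation with a small one-sided Poisson tail probability —
otherwise the markers are indistinguishable from chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING

HET = 2
HOM_CODES = (0, 1)


@dataclass
class SLMResult:
    xy_loci: list[str] = field(default_factory=list)
    zw_loci: list[str] = field(default_factory=list)
    expected_by_chance_xy: float = 0.0
    expected_by_chance_zw: float = 0.0
    n_loci_scanned: int = 0
    het_prob: float = 0.5
    verdict: str = "inconclusive"
    p_xy: float = 1.0
    p_zw: float = 1.0


def _split_sexes(matrix: pd.DataFrame, sexes: dict[str, str]) -> tuple[list[str], list[str]]:
    males = [ind for ind in matrix.columns if sexes.get(str(ind)) == "M"]
    females = [ind for ind in matrix.columns if sexes.get(str(ind)) == "F"]
    unassigned = [ind for ind in matrix.columns if str(ind) not in sexes]
    if unassigned:
        raise ValueError(f"individuals without sex assignment: {unassigned}")
    if not males or not females:
        raise ValueError("need at least one male and one female")
    return males, females


def _scan(matrix: pd.DataFrame, het_cols: list[str], hom_cols: list[str],
          max_missing: int) -> list[str]:
    het = matrix[het_cols].to_numpy()
    hom = matrix[hom_cols].to_numpy()
    missing = (het == MISSING).sum(axis=1) + (hom == MISSING).sum(axis=1)
    het_ok = ((het == HET) | (het == MISSING)).all(axis=1)
    hom_ok = (np.isin(hom, HOM_CODES) | (hom == MISSING)).all(axis=1)
    keep = (missing <= max_missing) & het_ok & hom_ok
    return [str(locus) for locus in matrix.index[keep]]


def scan_xy(matrix: pd.DataFrame, sexes: dict[str, str], max_missing: int = 0) -> list[str]:
    """Loci heterozygous in all (non-missing) males, homozygous in all females.

    ``max_missing`` bounds the missing calls tolerated per locus; the
    default 0 demands complete loci, since "all males" is otherwise
    undefined.
    """
    males, females = _split_sexes(matrix, sexes)
    return _scan(matrix, males, females, max_missing)


def scan_zw(matrix: pd.DataFrame, sexes: dict[str, str], max_missing: int = 0) -> list[str]:
    """Mirror scan: heterozygous in all females, homozygous in all males."""
    males, females = _split_sexes(matrix, sexes)
    return _scan(matrix, females, males, max_missing)


def expected_by_chance(L: int, n_m: int, n_f: int, h: float, pattern: str = "xy") -> float:
    """Expected count of perfectly sex-linked patterns arising by chance.

    Each of ``L`` independent null loci shows the XY pattern with
    probability ``h**n_m * (1-h)**n_f`` (all males heterozygous, all
    females homozygous); ZW swaps the exponents. At h = 1/2 both reduce to
    ``L * 2**-(n_m + n_f)``.
    """
    if L < 0 or n_m < 0 or n_f < 0:
        raise ValueError("L, n_m and n_f must be non-negative")
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"heterozygosity probability {h} outside [0, 1]")
    if pattern == "xy":
        return L * h**n_m * (1.0 - h) ** n_f
    if pattern == "zw":
        return L * h**n_f * (1.0 - h) ** n_m
    raise ValueError(f"unknown pattern {pattern!r}")


def _poisson_tail(observed: int, expected: float) -> float:
    """One-sided P(X >= observed) for X ~ Poisson(expected)."""
    if observed <= 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def classify_system(result: SLMResult, alpha_margin: float = 0.05) -> str:
    """Verdict on the sex-determination system given scans and expectations.

    XY-suggestive only when the observed XY count exceeds its chance
    expectation and the one-sided Poisson tail is below ``alpha_margin``;
    mirrored for ZW; if both qualify the smaller tail wins; otherwise
    inconclusive.
    """
    n_xy, n_zw = len(result.xy_loci), len(result.zw_loci)
    p_xy = _poisson_tail(n_xy, result.expected_by_chance_xy)
    p_zw = _poisson_tail(n_zw, result.expected_by_chance_zw)
    result.p_xy, result.p_zw = p_xy, p_zw
    xy_ok = n_xy > result.expected_by_chance_xy and p_xy < alpha_margin
    zw_ok = n_zw > result.expected_by_chance_zw and p_zw < alpha_margin
    if xy_ok and zw_ok:
        return "XY-suggestive" if p_xy <= p_zw else "ZW-suggestive"
    if xy_ok:
        return "XY-suggestive"
    if zw_ok:
        return "ZW-suggestive"
    return "inconclusive"


def observed_het_rate(matrix: pd.DataFrame) -> float:
    """Fraction of heterozygous calls among all non-missing calls."""
    arr = matrix.to_numpy()
    called = arr != MISSING
    n_called = called.sum()
    if n_called == 0:
        return 0.0
    return float((arr[called] == HET).mean())


def analyze(
    matrix: pd.DataFrame,
    sexes: dict[str, str],
    max_missing: int = 0,
    het_prob: float | str = "auto",
    alpha_margin: float = 0.05,
) -> SLMResult:
    """Full screen: XY and ZW scans, chance expectations, verdict.

    ``het_prob='auto'`` uses the dataset's observed heterozygosity rate;
    pass a number (e.g. 0.5) to override. L for the expectation is the
    number of loci satisfying the missingness filter.
    """
    males, females = _split_sexes(matrix, sexes)
    xy = scan_xy(matrix, sexes, max_missing)
    zw = scan_zw(matrix, sexes, max_missing)
    n_missing = (matrix.to_numpy() == MISSING).sum(axis=1)
    L = int((n_missing <= max_missing).sum())
    h = observed_het_rate(matrix) if het_prob == "auto" else float(het_prob)
    result = SLMResult(
        xy_loci=xy,
        zw_loci=zw,
        expected_by_chance_xy=expected_by_chance(L, len(males), len(females), h, "xy"),
        expected_by_chance_zw=expected_by_chance(L, len(males), len(females), h, "zw"),
        n_loci_scanned=L,
        het_prob=h,
    )
    result.verdict = classify_system(result, alpha_margin)
    return result
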