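"""Read-based satDNA quantification: abundance, male:female ratio, divergence.

Each read of a low-coverage WGS library is aligned on both strands against a
head-to-tail concatemer of every catalog consensus (so monomer phase never
matters) and assigned to the satDNA giving its best alignment, provided the
alignment reaches the identity floor and minimum aligned length. Genomic
abundance is reported as the fraction of analyzed nucleotides aligned to the
satDNA (a RepeatMasker-style masked fraction); the literal reads-per-
nucleotide variant is available via ``abundance_mode``.

Divergence between a library and a consensus uses the Kimura 2-parameter
model, which corrects observed transition (P) and transversion (Q)
proportions for multiple hits:

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Per-satDNA mean divergence is the aligned-bp-weighted mean of per-read K.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_PURINES = frozenset("AG")
_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

#: defaults mirroring conventional satellitome practice: 80% identity floor,
#: one monomer length (28 bp here is the shortest unit handled) and a
#: 2 x 5,000,000-read subsample per library, scaled down in tests via config.
DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_ALIGNED = 28
DEFAULT_SUBSAMPLE = 10_000_000


class SaturationError(ValueError):
    """Kimura 2-parameter divergence is undefined (substitution saturation)."""


@dataclass
class AlignmentSummary:
    """Transition/transversion proportions over aligned, ungapped columns."""

    p: float
    q: float
    columns: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1 and 0 <= self.q <= 1 and self.p + self.q <= 1):
            raise ValueError(f"invalid proportions p={self.p}, q={self.q}")


@dataclass
class MappingResult:
    sat_name: str
    library: str
    mapped_reads: int
    aligned_bp: int
    analyzed_bp: int
    abundance: float
    mean_divergence: float


@dataclass
class ReadHit:
    """Best placement of one read on one consensus concatemer."""

    matches: int
    mismatches: int
    aligned_bp: int  # read bases aligned
    columns: int  # alignment columns incl. internal gaps
    transitions: int
    transversions: int
    strand: str
    target_start: int  # start on the forward concatemer

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def dimerize(consensus: str, min_length: int) -> str:
    """Concatemerize a consensus until it exceeds ``min_length`` (>= 2 copies)."""
    copies = max(2, math.ceil(min_length / len(consensus)) + 1)
    return consensus * copies


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


def _align_one_strand(read: str, concatemer: str, strand: str) -> ReadHit | None:
    import edlib

    res = edlib.align(read, concatemer, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start = res["locations"][0][0]
    qpos, tpos = 0, t_start
    matches = mismatches = aligned = columns = ts = tv = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
            aligned += n
            qpos += n
            tpos += n
        elif op in "XM":
            for _ in range(n):
                rb, tb = read[qpos], concatemer[tpos]
                if rb == tb and rb != "N":
                    matches += 1
                elif rb != "N" and tb != "N":
                    mismatches += 1
                    if _is_transition(rb, tb):
                        ts += 1
                    else:
                        tv += 1
                qpos += 1
                tpos += 1
            aligned += n
        elif op == "I":  # read base absent from consensus
            qpos += n
            aligned += n
        elif op == "D":  # consensus base absent from read
            tpos += n
    return ReadHit(matches, mismatches, aligned, columns, ts, tv, strand, t_start)


def align_read(read: str, consensus: str) -> ReadHit | None:
    """Best strand-resolved placement of a read inside a consensus concatemer."""
    concatemer = dimerize(consensus, len(read) + 2 * len(consensus))
    fwd = _align_one_strand(read, concatemer, "+")
    rev = _align_one_strand(reverse_complement(read), concatemer, "-")
    hits = [h for h in (fwd, rev) if h is not None]
    if not hits:
        return None
    return max(hits, key=lambda h: (h.matches, h.strand == "+"))


# ---------------------------------------------------------------------------
# Kimura 2-parameter divergence


def kimura2p(p: float | AlignmentSummary, q: float | None = None) -> float:
    """Kimura 2-parameter distance from transition/transversion proportions.

    Accepts either an :class:`AlignmentSummary` or the proportions
    ``(p, q)`` directly. Raises :class:`SaturationError` when the
    logarithm's argument is non-positive (1 - 2p - q <= 0 or 1 - 2q <= 0).
    """
    if isinstance(p, AlignmentSummary):
        p, q = p.p, p.q
    if q is None:
        raise TypeError("kimura2p needs both p and q")
    if not (0 <= p <= 1 and 0 <= q <= 1 and p + q <= 1):
        raise ValueError(f"invalid proportions p={p}, q={q}")
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"divergence undefined for p={p}, q={q}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


# ---------------------------------------------------------------------------
# Library mapping


def map_reads(
    reads: list[str],
    catalog: list,
    library: str = "library",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aligned: int = DEFAULT_MIN_ALIGNED,
    subsample: int | None = None,
    seed: int = 0,
    abundance_mode: str = "aligned_bp",
) -> list[MappingResult]:
    """Assign each read to its best-matching satDNA and summarize per family.

    ``catalog`` is a list of records with ``name`` and ``consensus``
    attributes (:class:`sexsatkit.catalog.SatRecord`). A read counts for at
    most one satDNA: the one with the most matching bases, subject to
    ``identity >= min_identity`` and ``aligned_bp >= min_aligned``.
    ``abundance_mode`` selects ``aligned_bp`` (aligned bases over analyzed
    bases, default) or ``mapped_reads`` (reads over analyzed bases).
    """
    if not reads:
        raise ValueError("empty read set")
    if not catalog:
        raise ValueError("empty catalog")
    if abundance_mode not in {"aligned_bp", "mapped_reads"}:
        raise ValueError(f"unknown abundance_mode {abundance_mode!r}")

    if subsample is not None and subsample < len(reads):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(reads), size=subsample, replace=False)
        reads = [reads[i] for i in sorted(idx)]
    elif subsample is not None and subsample > len(reads):
        warnings.warn(
            f"subsample {subsample} exceeds library size {len(reads)}; using all reads"
        )

    analyzed_bp = sum(len(r) for r in reads)
    per_sat: dict[str, dict] = {
        rec.name: {"reads": 0, "aligned": 0, "kw": 0.0, "w": 0}
        for rec in catalog
    }
    for read in reads:
        best_name, best_hit = None, None
        for rec in catalog:
            hit = align_read(read, rec.consensus)
            if hit is None or hit.identity < min_identity or hit.aligned_bp < min_aligned:
                continue
            if best_hit is None or hit.matches > best_hit.matches:
                best_name, best_hit = rec.name, hit
        if best_hit is None:
            continue
        acc = per_sat[best_name]
        acc["reads"] += 1
        acc["aligned"] += best_hit.aligned_bp
        ungapped = best_hit.matches + best_hit.mismatches
        if ungapped > 0:
            try:
                k = kimura2p(best_hit.transitions / ungapped, best_hit.transversions / ungapped)
            except SaturationError:
                k = None
            if k is not None:
                acc["kw"] += k * best_hit.aligned_bp
                acc["w"] += best_hit.aligned_bp

    out = []
    for rec in catalog:
        acc = per_sat[rec.name]
        if abundance_mode == "aligned_bp":
            abundance = acc["aligned"] / analyzed_bp
        else:
            abundance = acc["reads"] / analyzed_bp
        out.append(
            MappingResult(
                sat_name=rec.name,
                library=library,
                mapped_reads=acc["reads"],
                aligned_bp=acc["aligned"],
                analyzed_bp=analyzed_bp,
                abundance=abundance,
                mean_divergence=acc["kw"] / acc["w"] if acc["w"] else 0.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sex-ratio table and paired catalog comparison


@dataclass
class SexRatioTable:
    rows: list[dict] = field(default_factory=list)

    def candidates(self) -> list[dict]:
        return [r for r in self.rows if r["candidate"]]

    def top_candidate(self) -> dict | None:
        """Candidate with the most extreme fold change (max of ratio, 1/ratio)."""
        cands = self.candidates()
        if not cands:
            return None

        def fold(row: dict) -> float:
            r = row["ratio"]
            if r == math.inf:
                return math.inf
            if r == 0:
                return math.inf
            return max(r, 1.0 / r)

        return max(cands, key=fold)


def sex_ratio(
    results_male: list[MappingResult],
    results_female: list[MappingResult],
    candidate_threshold: float = 1.5,
) -> SexRatioTable:
    """Male:female abundance ratio per satDNA, flagging sex-biased candidates.

    A satDNA missing from one side is treated as abundance 0 (with a
    warning). A ratio of ``inf`` marks male-specific families (female
    abundance 0); candidates are families at least ``candidate_threshold``-
    fold biased in either direction.
    """
    if candidate_threshold < 1.0:
        raise ValueError("candidate_threshold must be >= 1")
    male = {r.sat_name: r.abundance for r in results_male}
    female = {r.sat_name: r.abundance for r in results_female}
    names = list(dict.fromkeys(list(male) + list(female)))
    missing = (set(male) ^ set(female)) & set(names)
    if missing:
        warnings.warn(f"satDNAs missing from one library treated as 0: {sorted(missing)}")
    rows = []
    for name in names:
        m = male.get(name, 0.0)
        f = female.get(name, 0.0)
        if f == 0.0:
            ratio = math.inf if m > 0 else 0.0
        else:
            ratio = m / f
        if ratio == math.inf:
            candidate = True
        elif ratio == 0.0:
            candidate = f > 0  # female-specific
        else:
            candidate = ratio >= candidate_threshold or ratio <= 1.0 / candidate_threshold
        rows.append(
            {
                "sat_name": name,
                "abundance_male": m,
                "abundance_female": f,
                "ratio": ratio,
                "candidate": candidate,
            }
        )
    return SexRatioTable(rows=rows)


def paired_catalog_test(
    proportions_a: list[float] | np.ndarray,
    proportions_b: list[float] | np.ndarray,
) -> tuple[float, float, bool]:
    """Classical paired t-test between matched repeat-class proportions.

    Returns ``(t, p, significant)`` with significance at 95% confidence.
    Degenerate cases: all-zero differences give (0, 1, False); zero-variance
    differences with nonzero mean give (+/-inf, 0, True).
    """
    a = np.asarray(proportions_a, dtype=float)
    b = np.asarray(proportions_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, False
        return math.copysign(math.inf, mean), 0.0, True
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), bool(p < 0.05)
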