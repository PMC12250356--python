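"""Satellite-DNA catalog curation and cross-catalog comparison.

A satellitome catalog is a set of consensus monomers, one per satDNA
family, named ``<prefix>Sat<rank>-<rul>`` where rank follows decreasing
genomic abundance and rul is the repeat-unit length in bp. Because a
tandem-repeat consensus has no natural phase and no natural strand, two
deposited consensuses of the same family may be arbitrary rotations and/or
reverse complements of each other; identity here is therefore computed by
aligning one monomer against the *dimer* (head-to-tail doubling) of the
other, on both strands, which makes the measure rotation- and
strand-invariant.

Relationship classes follow the conventional similarity thresholds for
satDNA curation: >95% identity means the same variant, >80% different
variants of the same family, >50% members of a superfamily, and anything
at or below 50% is treated as unrelated (boundary values fall to the
lower class).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Seq import Seq

VALID_BASES = set("ACGTN")

RELATION_ORDER = ["unrelated", "superfamily", "same_family", "same_variant"]

#: classification thresholds (strict: identity must exceed the bound)
VARIANT_THRESHOLD = 95.0
FAMILY_THRESHOLD = 80.0
SUPERFAMILY_THRESHOLD = 50.0

_NAME_RE = re.compile(r"^(?P<prefix>.+?)Sat(?P<rank>\d+)-(?P<rul>\d+)$")


@dataclass
class SatRecord:
    """One satDNA consensus with its catalog metadata."""

    name: str
    prefix: str
    rank: int
    rul: int
    consensus: str
    abundance: float | None = None
    abundance_male: float | None = None
    abundance_female: float | None = None

    def __post_init__(self) -> None:
        if self.rul != len(self.consensus):
            raise ValueError(
                f"{self.name}: declared repeat-unit length {self.rul} != "
                f"consensus length {len(self.consensus)}"
            )


@dataclass
class PairwiseRelation:
    id_a: str
    id_b: str
    identity: float
    relation: str


@dataclass
class CatalogOverlap:
    relations: list[PairwiseRelation] = field(default_factory=list)
    shared_family_count: int = 0
    identical_pair_count: int = 0


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence for {label}")
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in {label}")
    return seq


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    """Glocal aligner: the query must align end-to-end, the target may overhang.

    Free end gaps on the target let the query land anywhere inside the
    dimerized partner, which is what makes monomer phase irrelevant.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on the target (the dimer) only
    if hasattr(aligner, "open_end_deletion_score"):
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:  # Biopython < 1.86 attribute names
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
    return aligner


def _identity_one_way(query: str, target: str, aligner: Align.PairwiseAligner) -> float:
    """Percent identity of the best glocal placement of query inside target."""
    alignment = aligner.align(target, query)[0]
    tgt_row, qry_row = str(alignment[0]), str(alignment[1])
    # strip target overhang columns (query-side end gaps)
    start = len(qry_row) - len(qry_row.lstrip("-"))
    end = len(qry_row.rstrip("-"))
    matches = columns = 0
    for t, q in zip(tgt_row[start:end], qry_row[start:end]):
        columns += 1
        if t == q and t != "-" and t != "N":
            matches += 1
    return 100.0 * matches / columns if columns else 0.0


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Rotation- and strand-invariant percent identity between two monomers.

    The shorter sequence is aligned end-to-end against the dimer of the
    longer one and against its reverse complement (best over both strands
    and all phases); identity is matches over aligned columns. ``N`` bases
    never count as matches.
    """
    a = _check_sequence(a, "sequence a")
    b = _check_sequence(b, "sequence b")
    if aligner is None:
        aligner = _make_aligner()
    query, longer = (a, b) if len(a) <= len(b) else (b, a)
    dimer = longer + longer
    fwd = _identity_one_way(query, dimer, aligner)
    rev = _identity_one_way(query, str(Seq(dimer).reverse_complement()), aligner)
    return max(fwd, rev)


def classify_relationship(identity: float) -> str:
    """Map a percent identity onto a relationship class (strict thresholds)."""
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity {identity} outside [0, 100]")
    if identity > VARIANT_THRESHOLD:
        return "same_variant"
    if identity > FAMILY_THRESHOLD:
        return "same_family"
    if identity > SUPERFAMILY_THRESHOLD:
        return "superfamily"
    return "unrelated"


def parse_sat_name(name: str) -> tuple[str, int, int]:
    """Parse ``<prefix>Sat<rank>-<rul>`` back into (prefix, rank, rul)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"cannot parse satDNA name {name!r}")
    return m.group("prefix"), int(m.group("rank")), int(m.group("rul"))


def name_catalog(records: list[tuple[str, float]], prefix: str) -> list[SatRecord]:
    """Rank consensuses by decreasing abundance and assign catalog names.

    Ties are broken by longer repeat unit first, then lexicographic
    consensus, so the ordering is total and stable. Duplicate consensus
    strings are kept but flagged with a warning.
    """
    cleaned = []
    for consensus, abundance in records:
        consensus = _check_sequence(consensus, "catalog record")
        if abundance is None or abundance < 0:
            raise ValueError("every record needs a non-negative abundance")
        cleaned.append((consensus, float(abundance)))
    seen: dict[str, int] = {}
    for consensus, _ in cleaned:
        seen[consensus] = seen.get(consensus, 0) + 1
    for consensus, count in seen.items():
        if count > 1:
            warnings.warn(
                f"duplicate consensus ({count} copies, length {len(consensus)}) kept in catalog"
            )
    ordered = sorted(cleaned, key=lambda rec: (-rec[1], -len(rec[0]), rec[0]))
    out = []
    for rank, (consensus, abundance) in enumerate(ordered, start=1):
        rul = len(consensus)
        out.append(
            SatRecord(
                name=f"{prefix}Sat{rank:02d}-{rul}",
                prefix=prefix,
                rank=rank,
                rul=rul,
                consensus=consensus,
                abundance=abundance,
            )
        )
    return out


def compare_catalogs(
    cat_a: list[SatRecord],
    cat_b: list[SatRecord],
    family_threshold: float = SUPERFAMILY_THRESHOLD,
) -> CatalogOverlap:
    """All-pairs cross-catalog comparison.

    ``identical_pair_count`` counts cross pairs at exactly 100% identity.
    ``shared_family_count`` counts records of the smaller catalog having at
    least one cross-catalog partner above ``family_threshold`` (default:
    superfamily level, 50%; pass 80 for the stricter family-level reading).
    """
    if not cat_a or not cat_b:
        raise ValueError("both catalogs must be non-empty")
    aligner = _make_aligner()
    relations = []
    partners_a: dict[str, int] = {r.name: 0 for r in cat_a}
    partners_b: dict[str, int] = {r.name: 0 for r in cat_b}
    identical = 0
    for rec_a in cat_a:
        for rec_b in cat_b:
            identity = pairwise_identity(rec_a.consensus, rec_b.consensus, aligner)
            relations.append(
                PairwiseRelation(rec_a.name, rec_b.name, identity, classify_relationship(identity))
            )
            if identity >= 100.0 - 1e-9:
                identical += 1
            if identity > family_threshold:
                partners_a[rec_a.name] += 1
                partners_b[rec_b.name] += 1
    smaller = partners_a if len(cat_a) <= len(cat_b) else partners_b
    shared = sum(1 for n in smaller.values() if n > 0)
    return CatalogOverlap(
        relations=relations,
        shared_family_count=shared,
        identical_pair_count=identical,
    )
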