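"""High-confidence (HC) somatic-mutation filtering for a tumor pair.

A locus survives filtering only when the germline sample supports a
confident homozygous-reference call (enough high-quality reads, at most one
alternate read, alternate fraction under 5%), the locus is not a known
polymorphism (dbSNP), and both tumors have adequate coverage (40x) so that
a private/shared distinction is meaningful.  Surviving loci are partitioned
into shared (called in both tumors) and private (called in exactly one);
``X = |shared|`` and ``n = |shared| + |private|`` feed the CLS test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

from .exceptions import ValidationError
from .variant_io import LocusEvidence, LocusKey

#: Rejection reason codes, in precedence order.
REASONS = (
    "dbsnp",
    "germline_coverage",
    "germline_alt_reads",
    "germline_alt_fraction",
    "tumor_coverage",
    "no_tumor_call",
)


@dataclass(frozen=True)
class HCFilterParams:
    """Thresholds of the HC filtering rules.

    Defaults implement the stringent pipeline: germline homozygous-reference
    requires >= 15 reads of base quality above ``germline_hq_quality_threshold``
    with at most one alternate read and < 5% alternate fraction; both tumors
    need >= 40x coverage; dbSNP members are excluded.
    """

    germline_min_hq_depth: int = 15
    germline_hq_quality_threshold: float = 20.0
    germline_max_alt_reads: int = 1
    germline_max_alt_fraction: float = 0.05
    tumor_min_depth: int = 40
    exclude_dbsnp: bool = True

    def __post_init__(self) -> None:
        if min(self.germline_min_hq_depth, self.germline_max_alt_reads,
               self.tumor_min_depth) < 0:
            raise ValidationError("filter thresholds must be non-negative")
        if not 0.0 <= self.germline_max_alt_fraction <= 1.0:
            raise ValidationError("germline_max_alt_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class HCProfile:
    """Shared/private HC mutation sets of a tumor pair.

    The three sets are pairwise disjoint; ``filter_log`` tallies every
    rejected locus by its (first failing) reason code.
    """

    shared: frozenset[LocusKey]
    private_a: frozenset[LocusKey]
    private_b: frozenset[LocusKey]
    filter_log: dict = field(default_factory=dict)

    @property
    def X(self) -> int:
        """Number of shared HC mutations."""
        return len(self.shared)

    @property
    def n(self) -> int:
        """Total distinct HC mutations called in either tumor."""
        return len(self.shared) + len(self.private_a) + len(self.private_b)

    @classmethod
    def from_counts(cls, X: int, n: int) -> "HCProfile":
        """Synthesize a profile with the requested X and n (anonymous keys).

        Used when only the counts are known (e.g. published tallies); the
        private mutations are arbitrarily assigned to tumor A.
        """
        if not 0 <= X <= n:
            raise ValidationError(f"need 0 <= X <= n, got X={X}, n={n}")
        shared = frozenset(LocusKey("chrS", i + 1, "A", "T") for i in range(X))
        private = frozenset(LocusKey("chrP", i + 1, "A", "T") for i in range(n - X))
        return cls(shared=shared, private_a=private, private_b=frozenset())


def classify_locus(
    evidence: LocusEvidence, params: HCFilterParams = HCFilterParams()
) -> tuple[str, str | None]:
    """Classify one locus as shared / private_a / private_b / rejected.

    Returns ``(outcome, reason)`` where ``outcome`` is one of ``"shared"``,
    ``"private_a"``, ``"private_b"``, ``"rejected"`` and ``reason`` is the
    first failing rule's code (None when assigned).  Rules are checked in a
    fixed precedence (dbSNP, germline, tumor coverage, tumor call) so that
    filter-log tallies are deterministic; precedence never changes X or n.
    """
    g = evidence.germline
    if params.exclude_dbsnp and evidence.in_dbsnp:
        return "rejected", "dbsnp"
    if g.hq_depth < params.germline_min_hq_depth:
        return "rejected", "germline_coverage"
    if g.alt_count > params.germline_max_alt_reads:
        return "rejected", "germline_alt_reads"
    if g.alt_fraction >= params.germline_max_alt_fraction:
        return "rejected", "germline_alt_fraction"
    if (evidence.tumor_a.total_depth < params.tumor_min_depth
            or evidence.tumor_b.total_depth < params.tumor_min_depth):
        return "rejected", "tumor_coverage"
    a, b = evidence.tumor_a.called, evidence.tumor_b.called
    if a and b:
        return "shared", None
    if a:
        return "private_a", None
    if b:
        return "private_b", None
    return "rejected", "no_tumor_call"


def build_profile(
    evidence_collection: Iterable[LocusEvidence],
    params: HCFilterParams = HCFilterParams(),
) -> HCProfile:
    """Apply the HC filter to a locus-deduplicated evidence collection.

    Raises :class:`ValidationError` on duplicate locus keys (the input
    contract is one record per key per trio).
    """
    shared: set[LocusKey] = set()
    private_a: set[LocusKey] = set()
    private_b: set[LocusKey] = set()
    log: Counter = Counter()
    seen: set[LocusKey] = set()
    for ev in evidence_collection:
        if ev.key in seen:
            raise ValidationError(f"duplicate locus key in evidence collection: {ev.key}")
        seen.add(ev.key)
        outcome, reason = classify_locus(ev, params)
        if outcome == "shared":
            shared.add(ev.key)
        elif outcome == "private_a":
            private_a.add(ev.key)
        elif outcome == "private_b":
            private_b.add(ev.key)
        else:
            log[reason] += 1
    return HCProfile(
        shared=frozenset(shared),
        private_a=frozenset(private_a),
        private_b=frozenset(private_b),
        filter_log=dict(log),
    )
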