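"""Cross-species annotation transfer from alignment hit tables.

For a non-model organism with no reference annotation, protein identities are
borrowed from the best alignment hit in a panel of related species.  Per
query, the lowest-E-value hit in each organism is kept; the annotation that
is actually transferred is the subject of the globally best hit, provided it
passes the transfer cutoff (default 1e-20, stringent because the reference
panel is evolutionarily distant).  Every query additionally receives a
homology-confidence class from its best E-value:

* class 1 — E < 1e-20 (high-confidence homolog),
* class 2 — 1e-20 <= E <= 1e-5 (low confidence; both boundaries inclusive),
* class 3 — E > 1e-5 (no credible homolog).

Queries whose only strong hits are against a bacterial contaminant database
are flagged rather than annotated.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

DEFAULT_EVALUE_CUTOFF = 1e-20
DEFAULT_CONFIDENCE_BOUNDS = (1e-20, 1e-5)


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit of a query protein against a subject database entry."""

    query_id: str
    subject_id: str
    organism: str
    evalue: float
    identity: float
    bitscore: float
    align_len: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue} for {self.query_id}")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0, 100]")


@dataclass(frozen=True)
class AnnotationResult:
    """Per-query transfer decision with its confidence class."""

    query_id: str
    per_organism_best: Mapping[str, HitRecord]
    transferred_annotation: str | None
    confidence_class: int | None
    is_contaminant: bool = False

    @property
    def best_hit(self) -> HitRecord | None:
        """Globally best hit across organisms (lowest E-value, deterministic ties)."""
        if not self.per_organism_best:
            return None
        return min(self.per_organism_best.values(), key=_hit_order)

    @property
    def is_orphan(self) -> bool:
        """True when no annotation could be transferred or homology is weak."""
        return self.transferred_annotation is None or self.confidence_class == 3


def _hit_order(h: HitRecord) -> tuple:
    # lowest E-value wins; ties broken by higher bit score, then subject id
    return (h.evalue, -h.bitscore, h.subject_id)


def best_hit_per_organism(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Lowest-E-value hit per organism for one query.

    All hits must share a single query id.  Ties on E-value are broken by
    higher bit score, then lexicographically smaller subject id, so the
    result is deterministic regardless of input order.
    """
    best: dict[str, HitRecord] = {}
    query: str | None = None
    for h in hits:
        if query is None:
            query = h.query_id
        elif h.query_id != query:
            raise ValueError(
                f"mixed query ids: {query!r} and {h.query_id!r} in one collection"
            )
        cur = best.get(h.organism)
        if cur is None or _hit_order(h) < _hit_order(cur):
            best[h.organism] = h
    return best


def assign_confidence_class(
    evalue: float,
    bounds: tuple[float, float] = DEFAULT_CONFIDENCE_BOUNDS,
) -> int:
    """Map an E-value to homology-confidence class 1, 2 or 3.

    The middle class is closed at both ends: an E-value exactly equal to
    either bound lands in class 2, so the three classes partition [0, inf).
    """
    if evalue < 0:
        raise ValueError(f"negative E-value {evalue}")
    lo, hi = bounds
    if evalue < lo:
        return 1
    if evalue <= hi:
        return 2
    return 3


def transfer_annotation(
    best_hits: Mapping[str, HitRecord],
    query_id: str,
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    bounds: tuple[float, float] = DEFAULT_CONFIDENCE_BOUNDS,
) -> AnnotationResult:
    """Decide the transferred annotation for one query.

    The transferred label is the subject of the globally lowest-E-value hit
    among those passing ``evalue < cutoff``; ``None`` when no hit qualifies.
    The confidence class always reflects the best hit overall, including
    queries whose best hit fails the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    candidates = [h for h in best_hits.values() if h.evalue < cutoff]
    best_overall = min(best_hits.values(), key=_hit_order) if best_hits else None
    if candidates:
        winner = min(candidates, key=_hit_order)
        annotation = winner.subject_id
    else:
        annotation = None
    conf = (
        assign_confidence_class(best_overall.evalue, bounds)
        if best_overall is not None
        else None
    )
    return AnnotationResult(
        query_id=query_id,
        per_organism_best=dict(best_hits),
        transferred_annotation=annotation,
        confidence_class=conf,
    )


def annotate_all(
    hits: Iterable[HitRecord],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
    bounds: tuple[float, float] = DEFAULT_CONFIDENCE_BOUNDS,
    query_ids: Sequence[str] | None = None,
) -> list[AnnotationResult]:
    """Annotate every query in a hit table.

    ``query_ids``, when given, fixes the output universe and order; queries
    without any hit become results with no annotation and no class.  Without
    it, queries appear in first-seen order.
    """
    by_query: dict[str, list[HitRecord]] = defaultdict(list)
    order: list[str] = []
    for h in hits:
        if h.query_id not in by_query:
            order.append(h.query_id)
        by_query[h.query_id].append(h)
    universe = list(query_ids) if query_ids is not None else order
    results = []
    for q in universe:
        best = best_hit_per_organism(by_query.get(q, []))
        results.append(transfer_annotation(best, q, cutoff, bounds))
    return results


def flag_contaminants(
    results: Iterable[AnnotationResult],
    contaminant_hits: Iterable[HitRecord],
    cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[AnnotationResult]:
    """Mark queries whose contaminant-database hit beats every species hit.

    A query is flagged iff its best hit against the contaminant database both
    passes the transfer cutoff and has a strictly lower E-value than its best
    cross-species hit (absence of a species hit counts as E-value infinity).
    """
    best_contam: dict[str, HitRecord] = {}
    for h in contaminant_hits:
        cur = best_contam.get(h.query_id)
        if cur is None or _hit_order(h) < _hit_order(cur):
            best_contam[h.query_id] = h
    out = []
    for r in results:
        contam = best_contam.get(r.query_id)
        flagged = False
        if contam is not None and contam.evalue < cutoff:
            best = r.best_hit
            species_e = best.evalue if best is not None else float("inf")
            flagged = contam.evalue < species_e
        out.append(replace(r, is_contaminant=flagged))
    return out


@dataclass(frozen=True)
class AnnotationSummary:
    total: int
    annotated: int
    efficiency_percent: float
    class_counts: Mapping[int, int]
    orphans: tuple[str, ...]
    contaminants: tuple[str, ...]


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{ndigits}"),
                                           rounding=ROUND_HALF_UP))


def annotation_summary(results: Sequence[AnnotationResult]) -> AnnotationSummary:
    """Counts, transfer efficiency, and the orphan list.

    Efficiency is 100 x annotated / total, rounded to one decimal (half away
    from zero).  Orphans are queries with class 3 homology or no hit at all.
    """
    total = len(results)
    annotated = sum(1 for r in results if r.transferred_annotation is not None)
    counts: dict[int, int] = {1: 0, 2: 0, 3: 0}
    orphans = []
    contaminants = []
    for r in results:
        if r.confidence_class is not None:
            counts[r.confidence_class] += 1
        if r.is_orphan:
            orphans.append(r.query_id)
        if r.is_contaminant:
            contaminants.append(r.query_id)
    eff = _round_half_up(100.0 * annotated / total) if total else 0.0
    return AnnotationSummary(
        total=total,
        annotated=annotated,
        efficiency_percent=eff,
        class_counts=counts,
        orphans=tuple(orphans),
        contaminants=tuple(contaminants),
    )


def write_annotation_report(results: Sequence[AnnotationResult], path) -> None:
    """One TSV row per query: annotation, class, per-organism E-values, flag."""
    organisms = sorted({o for r in results for o in r.per_organism_best})
    with open(path, "w") as fh:
        header = ["query_id", "annotation", "confidence_class", "is_contaminant"]
        header += [f"evalue_{o}" for o in organisms]
        fh.write("\t".join(header) + "\n")
        for r in results:
            row = [
                r.query_id,
                r.transferred_annotation or "",
                str(r.confidence_class) if r.confidence_class is not None else "",
                "1" if r.is_contaminant else "0",
            ]
            for o in organisms:
                h = r.per_organism_best.get(o)
                row.append(f"{h.evalue:g}" if h is not None else "")
            fh.write("\t".join(row) + "\n")
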