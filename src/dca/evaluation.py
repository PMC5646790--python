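"""Evaluation of predicted complex sets: OS matching, Sn/Sp/F, enrichment.

The overlap score between a predicted complex pc and a known complex kc,

    OS(pc, kc) = |pc ∩ kc|^2 / (|pc| * |kc|),

lies in [0, 1], is symmetric, and equals 1 exactly when the member sets
are identical.  Two complexes match when OS >= 0.2, the customary
threshold.  Matching is many-to-many: a prediction is a true positive if
it matches any reference, a reference is covered if any prediction
matches it, and no one-to-one assignment is attempted.  Sensitivity
Sn = TP/(TP+FN), specificity Sp = TP/(TP+FP) and their harmonic mean
(the F-measure) summarize a run.

Functional coherence of a complex of C proteins sharing k members with a
term annotated to F of N background proteins is scored by the
hypergeometric upper tail

    p = 1 - sum_{i=0}^{k-1} C(F,i) C(N-F, C-i) / C(N, C),

the probability of observing k or more term members by chance; a complex
is deemed biologically significant when its best term has p <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .io_formats import AnnotationMap, Complex, ComplexSet

#: p-value bins conventionally used to histogram enrichment results.
PVALUE_BINS: tuple[float, ...] = (1e-15, 1e-10, 1e-5, 0.01)


@dataclass
class MatchStats:
    """Outcome of matching a predicted set against a reference set."""

    tp: int
    fp: int
    fn: int
    sn: float
    sp: float
    f_measure: float
    matched_reference_count: int
    best_os: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class EnrichmentResult:
    """Best-term enrichment of one complex."""

    complex_id: str
    term: str | None
    k: int
    complex_size: int
    term_size: int
    background_n: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.term is not None and self.p_value <= 0.01


def overlap_score(pc: Iterable[str], kc: Iterable[str]) -> float:
    """OS(pc, kc) = |pc ∩ kc|^2 / (|pc| |kc|); both sets must be non-empty."""
    pcs, kcs = set(pc), set(kc)
    if not pcs or not kcs:
        raise ValueError("overlap score is undefined for empty sets")
    inter = len(pcs & kcs)
    return (inter * inter) / (len(pcs) * len(kcs))


def match_and_score(
    predicted: ComplexSet,
    reference: ComplexSet,
    *,
    os_threshold: float = 0.2,
) -> MatchStats:
    """Many-to-many OS matching with Sn/Sp/F summary.

    F is defined as 0 when TP = 0 (Sn = Sp = 0) to avoid 0/0.  Also
    reports the number of distinct reference complexes covered (the
    "matched known complexes" count) and each prediction's best OS.
    """
    if len(reference) == 0:
        raise ValueError("reference complex set is empty")
    ref_sets = reference.member_sets()
    best_os: list[float] = []
    matched_refs: set[int] = set()
    tp = 0
    for cx in predicted:
        members = cx.members
        best = 0.0
        for j, ref in enumerate(ref_sets):
            score = overlap_score(members, ref)
            if score > best:
                best = score
            if score >= os_threshold:
                matched_refs.add(j)
        best_os.append(best)
        if best >= os_threshold:
            tp += 1
    fp = len(predicted) - tp
    fn = len(reference) - len(matched_refs)
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * sn * sp / (sn + sp) if sn + sp > 0 else 0.0
    return MatchStats(
        tp=tp, fp=fp, fn=fn, sn=sn, sp=sp, f_measure=f,
        matched_reference_count=len(matched_refs), best_os=best_os,
    )


def enrichment_pvalue(k: int, complex_size: int, term_size: int, background_n: int) -> float:
    """Hypergeometric probability of >= k term members in the complex.

    Computed via the survival function (log-gamma space internally) and
    clamped to [0, 1]; p(k=0) = 1 since observing zero or more is certain.
    """
    if not (0 <= k <= complex_size <= background_n):
        raise ValueError("need 0 <= k <= C <= N")
    if not (0 <= term_size <= background_n):
        raise ValueError("need 0 <= F <= N")
    if k > min(complex_size, term_size):
        raise ValueError("k cannot exceed min(C, F)")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, background_n, term_size, complex_size))
    return min(1.0, max(0.0, p))


def annotate_complexes(
    cset: ComplexSet,
    annot: AnnotationMap,
    *,
    significance: float = 0.01,
) -> list[EnrichmentResult]:
    """Best-term enrichment for every complex.

    For each complex every term with at least one shared member is
    scored and the minimal-p term reported; ties broken by term name for
    determinism.  A complex with no annotated member yields a result
    with ``term=None`` and p = 1 (flagged unannotated).  The
    ``significant`` flag uses the 0.01 cutoff by default.
    """
    if not annot.terms:
        raise ValueError("empty annotation map")
    results: list[EnrichmentResult] = []
    n = annot.background_n
    for cx in cset:
        members = cx.members
        c_size = len(members)
        best: EnrichmentResult | None = None
        for term in sorted(annot.terms):
            genes = annot.terms[term]
            k = len(members & genes)
            if k == 0:
                continue
            p = enrichment_pvalue(k, c_size, len(genes), n)
            if best is None or p < best.p_value:
                best = EnrichmentResult(
                    complex_id=cx.id, term=term, k=k, complex_size=c_size,
                    term_size=len(genes), background_n=n, p_value=p,
                )
        if best is None:
            best = EnrichmentResult(
                complex_id=cx.id, term=None, k=0, complex_size=c_size,
                term_size=0, background_n=n, p_value=1.0,
            )
        results.append(best)
    return results


def pvalue_histogram(results: Sequence[EnrichmentResult]) -> dict[str, int]:
    """Histogram of best p-values over the conventional significance bins."""
    edges = (0.0,) + PVALUE_BINS
    labels = [
        f"({edges[i]:g}, {edges[i+1]:g}]" for i in range(len(edges) - 1)
    ] + [f"> {edges[-1]:g}"]
    counts = dict.fromkeys(labels, 0)
    for r in results:
        placed = False
        for i in range(len(edges) - 1):
            if edges[i] < r.p_value <= edges[i + 1]:
                counts[labels[i]] += 1
                placed = True
                break
        if not placed:
            counts[labels[-1]] += 1
    return counts
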