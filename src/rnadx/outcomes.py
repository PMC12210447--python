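"""Deterministic diagnostic-outcome coding and cohort tallies.

Each proband's RNA-seq result is adjudicated into a handful of booleans
(analysis successful? transcript effect present? judged clinically
significant? protein-level mechanism still possible?) and a rule engine
maps those to one of five outcome categories with the matching ACMG
functional-evidence tags:

* ``Diagnostic`` — a significant deleterious transcript effect (PS3 +/- PM1);
* ``RNA_VUS`` — a transcript effect whose clinical impact stays uncertain;
* ``Diagnosis_Ruled_Out`` — no (or only a minor) effect and no alternative
  protein-level mechanism (BS3);
* ``Transcript_Effect_Ruled_Out`` — no transcript effect, but a protein
  mechanism (e.g. missense) remains possible (BS3 for the transcript only);
* ``Unsuccessful`` — the transcript of interest could not be analyzed.

The expert judgment "is the impact significant?" is an *input*
(``effect_significant``), never inferred here; an advisory helper
(:func:`suggest_effect_significant`) exists but its output is never used
for the packaged fixture.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

GROUPS = (
    "splice_noncanonical",
    "canonical_splice_atypical",
    "intragenic_cnv",
    "regulatory_utr",
    "wgs_negative",
)

CATEGORIES = (
    "Diagnostic",
    "RNA_VUS",
    "Diagnosis_Ruled_Out",
    "Transcript_Effect_Ruled_Out",
    "Unsuccessful",
)


class AdjudicationError(ValueError):
    """A CaseAdjudication violates its invariants."""


@dataclass(frozen=True)
class CaseAdjudication:
    """Adjudicated RNA-seq result for one proband."""

    case_id: str
    group: str
    analysis_successful: bool
    effect_present: bool
    effect_significant: Optional[bool]  # None = uncertain; defined only if effect_present
    protein_mechanism_possible: bool
    gene: str = "NA"
    n_splice_vus: int = 0
    hi_analysis: bool = False  # re-screened hypothesis-independently
    hi_candidate_found: bool = False
    citation: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise AdjudicationError(f"{self.case_id}: unknown group {self.group!r}")
        if not self.effect_present and self.effect_significant is not None:
            raise AdjudicationError(
                f"{self.case_id}: effect_significant defined without effect_present"
            )


@dataclass(frozen=True)
class Outcome:
    case_id: str
    category: str
    acmg_tags: frozenset[str]  # subset of {PS3, PM1, BS3}


def code_outcome(adj: CaseAdjudication) -> Outcome:
    """Map one adjudication to its unique outcome category.

    Rule table:
      * analysis failed -> Unsuccessful
      * effect present and judged significant -> Diagnostic (PS3)
      * effect present, significance uncertain (None) -> RNA_VUS
      * otherwise (no effect, or a present-but-minor effect) -> a Ruled-Out
        category (BS3): Transcript_Effect_Ruled_Out when a protein-level
        mechanism such as missense remains possible, else Diagnosis_Ruled_Out.
    """
    if not adj.analysis_successful:
        return Outcome(adj.case_id, "Unsuccessful", frozenset())
    if adj.effect_present and adj.effect_significant is True:
        return Outcome(adj.case_id, "Diagnostic", frozenset({"PS3"}))
    if adj.effect_present and adj.effect_significant is None:
        return Outcome(adj.case_id, "RNA_VUS", frozenset())
    # no effect, or effect present with significance judged false (minor impact)
    if adj.protein_mechanism_possible:
        return Outcome(adj.case_id, "Transcript_Effect_Ruled_Out", frozenset({"BS3"}))
    return Outcome(adj.case_id, "Diagnosis_Ruled_Out", frozenset({"BS3"}))


def tally(
    outcomes: Iterable[Outcome],
    groups: Optional[dict[str, str]] = None,
    denominator: Optional[int] = None,
) -> dict:
    """Counts and percentages per category (overall and per group).

    Percentages use ``denominator`` when given, otherwise the number of
    outcomes; both the raw and nearest-integer-rounded values are reported.
    """
    outcomes = list(outcomes)
    counts = Counter(o.category for o in outcomes)
    denom = denominator if denominator is not None else len(outcomes)

    def pct_entry(count: int) -> dict:
        raw = 100.0 * count / denom if denom else 0.0
        return {"count": count, "pct_raw": raw, "pct": round(raw)}

    table = {
        "n": len(outcomes),
        "denominator": denom,
        "categories": {cat: pct_entry(counts.get(cat, 0)) for cat in CATEGORIES},
    }
    if groups:
        by_group: dict[str, Counter] = {}
        for o in outcomes:
            by_group.setdefault(groups.get(o.case_id, "unknown"), Counter())[
                o.category
            ] += 1
        table["by_group"] = {
            g: {cat: c.get(cat, 0) for cat in CATEGORIES} for g, c in by_group.items()
        }
    return table


def cohort_summary(cases: Iterable[CaseAdjudication]) -> dict:
    """Headline cohort statistics for a full adjudicated cohort.

    Computes, from scratch, the quantities a study report prints:
    category percentages among candidate-variant probands, the positive
    and diagnostic rates within the non-canonical splice-variant subgroup,
    variant-level analyzability in that subgroup, and the
    hypothesis-independent screen yield.
    """
    cases = list(cases)
    candidates = [c for c in cases if c.group != "wgs_negative"]
    outcomes = {c.case_id: code_outcome(c) for c in candidates}

    n_cand = len(candidates)

    def share(category: str) -> dict:
        count = sum(1 for o in outcomes.values() if o.category == category)
        raw = 100.0 * count / n_cand if n_cand else 0.0
        return {"count": count, "pct_raw": raw, "pct": round(raw)}

    splice = [c for c in candidates if c.group == "splice_noncanonical"]
    n_splice = len(splice)
    splice_positive = sum(1 for c in splice if c.effect_present)
    splice_diagnostic = sum(
        1 for c in splice if outcomes[c.case_id].category == "Diagnostic"
    )
    splice_variants = sum(c.n_splice_vus for c in splice)
    splice_variants_analyzed = sum(
        c.n_splice_vus for c in splice if c.analysis_successful
    )

    hi_cases = [c for c in cases if c.hi_analysis]
    hi_hits = sum(1 for c in hi_cases if c.hi_candidate_found)
    n_hi = len(hi_cases)

    return {
        "n_cases": len(cases),
        "n_candidate": n_cand,
        "n_wgs_negative": len(cases) - n_cand,
        "candidate": {cat: share(cat) for cat in CATEGORIES},
        "splice_subgroup": {
            "n_probands": n_splice,
            "n_variants": splice_variants,
            "positive": {
                "count": splice_positive,
                "pct_raw": 100.0 * splice_positive / n_splice if n_splice else 0.0,
                "pct": round(100.0 * splice_positive / n_splice) if n_splice else 0,
            },
            "diagnostic": {
                "count": splice_diagnostic,
                "pct_raw": 100.0 * splice_diagnostic / n_splice if n_splice else 0.0,
                "pct": round(100.0 * splice_diagnostic / n_splice) if n_splice else 0,
            },
            "variants_analyzed_pct": (
                100.0 * splice_variants_analyzed / splice_variants
                if splice_variants
                else 0.0
            ),
        },
        "hi_screen": {
            "n_screened": n_hi,
            "n_hits": hi_hits,
            "yield_pct_raw": 100.0 * hi_hits / n_hi if n_hi else 0.0,
            "yield_pct": round(100.0 * hi_hits / n_hi) if n_hi else 0,
        },
    }


def suggest_effect_significant(
    aberrant_fraction: float, frame: str, domain_loss: bool = False
) -> bool:
    """Advisory significance suggestion from quantitative evidence only.

    A transcript effect is suggested significant when it affects >= 20% of
    transcripts and either shifts the reading frame or removes a known
    functional domain.  The coder never uses this; expert adjudication does.
    """
    return aberrant_fraction >= 0.2 and (frame == "frameshift" or domain_loss)
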