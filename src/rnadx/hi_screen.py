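"""Hypothesis-independent, phenotype-driven genome-wide screen.

Without a candidate DNA variant, aberrant junctions are filtered down to a
short review list by combining phenotype relevance (genes mapped from the
patient's HPO terms) with usage-score thresholds: a novel junction must be
used appreciably by the patient (score > 0.2) while essentially absent
from controls (cohort mean < 0.2); a missing/outlier junction must be
clearly reduced in the patient (score < 0.75) at a junction controls use
consistently (cohort mean >= 0.6, observed in >= 80% of the cohort).
Genes carrying multiple aberrations rank first, since splice-altering
variants frequently disrupt more than one junction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from rnadx.aberrance import AberrantJunction
from rnadx.expression import ExpressionOutlier

logger = logging.getLogger("rnadx")

NOVEL_PATIENT_MIN = 0.2  # patient usage of a novel junction must exceed this
NOVEL_COHORT_MAX = 0.2  # ... while the cohort mean stays below this
MISSING_PATIENT_MAX = 0.75  # patient usage of a missing/outlier junction below this
MISSING_COHORT_MIN = 0.6  # ... at a junction the cohort uses at least this much
MISSING_DETECTION_MIN = 0.8  # ... observed in at least 80% of cohort samples


@dataclass(frozen=True)
class HiCandidate:
    gene_id: str
    aberrant_junctions: tuple[AberrantJunction, ...]
    n_aberrations: int
    expression_outlier: Optional[ExpressionOutlier] = None
    priority_rank: int = 0

    @property
    def max_abs_z(self) -> float:
        return max((abs(a.z) for a in self.aberrant_junctions), default=0.0)


def hpo_gene_set(
    hpo_terms: Iterable[str], hpo_map: Mapping[str, set[str]]
) -> set[str]:
    """Union of genes mapped by the patient's HPO terms.

    Unknown terms are logged and skipped; an empty union is returned with
    a warning (the screen then proceeds genome-wide).
    """
    genes: set[str] = set()
    for term in hpo_terms:
        mapped = hpo_map.get(term)
        if mapped is None:
            logger.warning("HPO term %s not in map; skipped", term)
            continue
        genes |= mapped
    if not genes:
        logger.warning("HPO terms map to no genes; screen will run genome-wide")
    return genes


def _passes(a: AberrantJunction) -> bool:
    st = a.junction_z.stats
    if a.klass == "novel":
        return a.patient_score > NOVEL_PATIENT_MIN and st.mean_score < NOVEL_COHORT_MAX
    # missing or outlier
    return (
        a.patient_score < MISSING_PATIENT_MAX
        and st.mean_score >= MISSING_COHORT_MIN
        and st.detection_fraction >= MISSING_DETECTION_MIN
    )


def hi_filter(
    aberrant: Sequence[AberrantJunction],
    gene_set: Optional[set[str]] = None,
    expression: Iterable[ExpressionOutlier] = (),
) -> list[HiCandidate]:
    """Apply the junction-score filters and group survivors by gene.

    ``gene_set`` restricts to phenotype-relevant genes when non-empty.
    Expression outliers in surviving genes are attached to the candidate.
    """
    expr_by_gene = {e.gene_id: e for e in expression if e.is_outlier}
    per_gene: dict[str, list[AberrantJunction]] = {}
    for a in aberrant:
        if not _passes(a):
            continue
        for gene_id in a.gene_ids or ("<unassigned>",):
            if gene_set and gene_id not in gene_set:
                continue
            per_gene.setdefault(gene_id, []).append(a)
    return [
        HiCandidate(
            gene_id=g,
            aberrant_junctions=tuple(js),
            n_aberrations=len(js),
            expression_outlier=expr_by_gene.get(g),
        )
        for g, js in per_gene.items()
    ]


def prioritize(candidates: Sequence[HiCandidate]) -> list[HiCandidate]:
    """Rank candidates: aberration count desc, then max |z| desc, then gene id."""
    ranked = sorted(
        candidates, key=lambda c: (-c.n_aberrations, -c.max_abs_z, c.gene_id)
    )
    return [
        HiCandidate(
            gene_id=c.gene_id,
            aberrant_junctions=c.aberrant_junctions,
            n_aberrations=c.n_aberrations,
            expression_outlier=c.expression_outlier,
            priority_rank=i + 1,
        )
        for i, c in enumerate(ranked)
    ]
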