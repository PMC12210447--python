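"""Control-cohort reference statistics and patient junction Z-scores.

A reference cohort (e.g. tissue-matched GTEx samples passing QC) supplies,
for every junction, the mean and standard deviation of its usage score and
the fraction of samples that detect it at all.  A patient junction's
Z-score is then ``(patient_score - mean) / max(sd, sd_floor)``; a small
floor on the standard deviation keeps Z finite for junctions whose usage
is invariant across controls.

A control that does not report a junction still contributes a true zero
when the junction's donor or acceptor site carries enough reads in that
control to have measured it (``min_site_reads``); otherwise the junction
is simply unmeasurable there and the sample is excluded from that
junction's statistics.  This separates "not used" from "not expressed".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from rnadx.formats import SampleQc
from rnadx.junctions import JunctionScore

logger = logging.getLogger("rnadx")

SD_FLOOR = 0.01  # scores live in [0,1]; bounds |z| by ~100*|delta score|
MIN_SITE_READS = 10  # site coverage needed to call an absent junction a true zero

JunctionKey = tuple[str, int, int, str]
Site = tuple[str, int, str]


def key_donor_site(key: JunctionKey) -> Site:
    chrom, start, end, strand = key
    return (chrom, start if strand != "-" else end, strand)


def key_acceptor_site(key: JunctionKey) -> Site:
    chrom, start, end, strand = key
    return (chrom, end if strand != "-" else start, strand)


@dataclass(frozen=True)
class CohortJunctionStats:
    junction_key: JunctionKey
    n_samples: int  # cohort size
    n_contributing: int  # samples contributing a value (detected or true zero)
    n_detected: int  # samples reporting the junction with >= 1 unique read
    mean_score: float
    sd_score: float
    annotated: bool
    mean_donor: float = 0.0
    sd_donor: float = 0.0
    mean_acceptor: float = 0.0
    sd_acceptor: float = 0.0

    @property
    def detection_fraction(self) -> float:
        return self.n_detected / self.n_samples if self.n_samples else 0.0

    @property
    def usable(self) -> bool:
        return self.n_contributing >= 2


@dataclass(frozen=True)
class JunctionZ:
    junction_key: JunctionKey
    patient_score: float
    z: float
    stats: CohortJunctionStats
    donor_z: Optional[float] = None
    acceptor_z: Optional[float] = None

    @property
    def annotated(self) -> bool:
        return self.stats.annotated

    @property
    def direction(self) -> str:
        return "increased" if self.z >= 0 else "decreased"


def qc_filter_controls(samples: Iterable[SampleQc]) -> list[str]:
    """IDs of control samples passing all five QC thresholds.

    RIN strictly > 7; autolysis less than severe; mapping rate strictly
    > 0.80; intergenic rate strictly < 0.15; rRNA strictly < 10%.
    """
    passing = []
    for s in samples:
        checks = {
            "rin": s.rin > 7,
            "autolysis": s.autolysis_grade in ("none", "mild", "moderate"),
            "mapping_rate": s.mapping_rate > 0.80,
            "intergenic_rate": s.intergenic_rate < 0.15,
            "rrna_pct": s.rrna_pct < 10,
        }
        if all(checks.values()):
            passing.append(s.sample_id)
        else:
            failed = [k for k, ok in checks.items() if not ok]
            logger.info("control %s excluded by QC: %s", s.sample_id, ", ".join(failed))
    return passing


def _mean_sd(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def sample_site_totals(scores: Iterable[JunctionScore]) -> tuple[dict[Site, int], dict[Site, int]]:
    """Donor/acceptor site read totals implied by one sample's scores."""
    donor: dict[Site, int] = {}
    acceptor: dict[Site, int] = {}
    for s in scores:
        donor[s.donor_site] = s.donor_total_reads
        acceptor[s.acceptor_site] = s.acceptor_total_reads
    return donor, acceptor


def build_cohort_stats(
    control_scores: Mapping[str, list[JunctionScore]],
    annotation: set[JunctionKey],
    min_site_reads: int = MIN_SITE_READS,
) -> dict[JunctionKey, CohortJunctionStats]:
    """Per-junction reference statistics from control samples.

    ``control_scores`` maps sample id to that sample's junction scores —
    score controls with ``min_unique=1`` so that weakly supported junctions
    still count as detected.  The statistic universe is every junction seen
    in any control plus every annotated junction.
    """
    if len(control_scores) < 2:
        raise ValueError("cohort statistics require >= 2 control samples")

    per_sample: list[tuple[dict[JunctionKey, JunctionScore], dict[Site, int], dict[Site, int]]] = []
    universe: set[JunctionKey] = set(annotation)
    for sid in sorted(control_scores):
        scores = control_scores[sid]
        by_key = {s.junction_key: s for s in scores}
        donor_tot, acc_tot = sample_site_totals(scores)
        per_sample.append((by_key, donor_tot, acc_tot))
        universe.update(by_key)

    n_cohort = len(per_sample)
    stats: dict[JunctionKey, CohortJunctionStats] = {}
    for key in universe:
        dsite, asite = key_donor_site(key), key_acceptor_site(key)
        values: list[float] = []
        dvalues: list[float] = []
        avalues: list[float] = []
        n_detected = 0
        for by_key, donor_tot, acc_tot in per_sample:
            score = by_key.get(key)
            if score is not None and score.unique_reads >= 1:
                n_detected += 1
                values.append(score.score)
                dvalues.append(score.donor_score if score.donor_score is not None else 0.0)
                avalues.append(score.acceptor_score if score.acceptor_score is not None else 0.0)
            elif (
                donor_tot.get(dsite, 0) >= min_site_reads
                or acc_tot.get(asite, 0) >= min_site_reads
            ):
                values.append(0.0)
                dvalues.append(0.0)
                avalues.append(0.0)
            # else: junction unmeasurable in this sample; no contribution
        if not values:
            mean = sd = md = sdd = ma = sda = 0.0
        else:
            mean, sd = _mean_sd(values)
            md, sdd = _mean_sd(dvalues)
            ma, sda = _mean_sd(avalues)
        stats[key] = CohortJunctionStats(
            junction_key=key,
            n_samples=n_cohort,
            n_contributing=len(values),
            n_detected=n_detected,
            mean_score=mean,
            sd_score=sd,
            annotated=key in annotation,
            mean_donor=md,
            sd_donor=sdd,
            mean_acceptor=ma,
            sd_acceptor=sda,
        )
    return stats


def _z(value: float, mean: float, sd: float, sd_floor: float) -> float:
    return (value - mean) / max(sd, sd_floor)


def junction_z(
    patient: list[JunctionScore],
    stats: Mapping[JunctionKey, CohortJunctionStats],
    sd_floor: float = SD_FLOOR,
    min_site_reads: int = MIN_SITE_READS,
) -> list[JunctionZ]:
    """Z-scores of the patient's junction usage against the cohort.

    Patient junctions absent from the reference get zero-mean, zero-sd
    stats (the floor then applies).  Annotated junctions with usable stats
    that the *patient* lacks — while covering the relevant splice sites —
    are emitted with patient_score 0 so that "missing" junctions surface.
    """
    if sd_floor <= 0:
        raise ValueError("sd_floor must be > 0")
    out: list[JunctionZ] = []
    patient_keys = {s.junction_key for s in patient}
    donor_tot, acc_tot = sample_site_totals(patient)

    for s in patient:
        st = stats.get(s.junction_key)
        if st is None:
            st = CohortJunctionStats(
                junction_key=s.junction_key,
                n_samples=0,
                n_contributing=0,
                n_detected=0,
                mean_score=0.0,
                sd_score=0.0,
                annotated=s.annotated,
            )
        elif not st.usable:
            logger.info("junction %s: unusable cohort stats; skipped", s.junction_key)
            continue
        out.append(
            JunctionZ(
                junction_key=s.junction_key,
                patient_score=s.score,
                z=_z(s.score, st.mean_score, st.sd_score, sd_floor),
                stats=st,
                donor_z=(
                    _z(s.donor_score, st.mean_donor, st.sd_donor, sd_floor)
                    if s.donor_score is not None
                    else None
                ),
                acceptor_z=(
                    _z(s.acceptor_score, st.mean_acceptor, st.sd_acceptor, sd_floor)
                    if s.acceptor_score is not None
                    else None
                ),
            )
        )

    for key, st in stats.items():
        if not st.annotated or key in patient_keys or not st.usable:
            continue
        covered = (
            donor_tot.get(key_donor_site(key), 0) >= min_site_reads
            or acc_tot.get(key_acceptor_site(key), 0) >= min_site_reads
        )
        if covered:
            out.append(
                JunctionZ(
                    junction_key=key,
                    patient_score=0.0,
                    z=_z(0.0, st.mean_score, st.sd_score, sd_floor),
                    stats=st,
                )
            )
    return out
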