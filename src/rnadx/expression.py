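"""Expression-outlier detection against a control TPM cohort.

For every gene shared between the patient and the controls, the patient's
TPM is converted to a Z-score against the control mean and standard
deviation; genes with |Z| above the threshold (default 2) are expression
outliers.  Z is computed on the raw TPM scale by default; a
``log2(TPM+1)`` switch exists because raw-scale Z is heavy-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

from rnadx.formats import TpmMatrix

Z_EXPR = 2.0  # |Z| > 2 marks an expression outlier


@dataclass(frozen=True)
class ExpressionOutlier:
    gene_id: str
    patient_tpm: float
    cohort_mean: float
    cohort_sd: float
    z: float
    is_outlier: bool


def _sd_floor_default(mean: np.ndarray) -> np.ndarray:
    # prevents invariant low-expression genes from dominating the ranking
    return np.maximum(0.1, 0.05 * mean)


def expression_z(
    patient_tpm: Mapping[str, float],
    controls: TpmMatrix,
    z_expr: float = Z_EXPR,
    sd_floor_tpm: Optional[float] = None,
    log_scale: bool = False,
) -> list[ExpressionOutlier]:
    """Per-gene expression Z-scores on the patient/control gene intersection.

    ``sd_floor_tpm``: fixed floor for the control SD; defaults to
    ``max(0.1, 5% of the cohort mean)`` per gene.  Genes with zero cohort
    mean and zero patient TPM get z = 0.
    """
    genes = [g for g in controls.gene_ids if g in patient_tpm]
    if not genes:
        raise ValueError("no genes shared between patient and control matrix")
    values = controls.values.loc[genes].to_numpy(dtype=float)
    patient = np.array([patient_tpm[g] for g in genes], dtype=float)
    if log_scale:
        values = np.log2(values + 1.0)
        patient = np.log2(patient + 1.0)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    floor = (
        np.full_like(mean, sd_floor_tpm) if sd_floor_tpm is not None else _sd_floor_default(mean)
    )
    z = (patient - mean) / np.maximum(sd, floor)
    z[(mean == 0) & (patient == 0)] = 0.0
    return [
        ExpressionOutlier(
            gene_id=g,
            patient_tpm=float(patient[i]),
            cohort_mean=float(mean[i]),
            cohort_sd=float(sd[i]),
            z=float(z[i]),
            is_outlier=bool(abs(z[i]) > z_expr),
        )
        for i, g in enumerate(genes)
    ]


def rank_expression_outliers(
    outliers: Iterable[ExpressionOutlier],
    hpo_genes: Optional[set[str]] = None,
) -> list[ExpressionOutlier]:
    """Restrict to phenotype-relevant genes (when given) and sort by |z|.

    Ties break on gene_id lexicographically.
    """
    records = [
        o for o in outliers if not hpo_genes or o.gene_id in hpo_genes
    ]
    return sorted(records, key=lambda o: (-abs(o.z), o.gene_id))
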