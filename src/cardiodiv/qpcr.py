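"""Relative expression by the comparative-Ct (2^-ddCt) method.

Ct is the PCR cycle at which a transcript's amplification signal crosses
threshold; one cycle is one doubling, so relative abundance between
conditions follows from Ct differences.  For each condition the target
gene's mean Ct is normalised against a reference gene (dCt); the treated
condition's dCt minus the control's gives ddCt, and the fold change is
``2**(-ddCt)``.  Replicate scatter propagates by root-sum-square of the
target and reference standard deviations, and is reported as a fold-change
interval ``[2**-(ddCt+sd), 2**-(ddCt-sd)]``.  Amplification efficiency is
fixed at 2 (exact doubling per cycle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate Ct values for one (condition, gene) pair."""

    condition: str
    gene: str
    replicate_cts: tuple[float, ...]

    def __post_init__(self) -> None:
        cts = tuple(float(c) for c in self.replicate_cts)
        if not cts:
            raise ValueError("at least one replicate Ct required")
        if not all(math.isfinite(c) for c in cts):
            raise ValueError("Ct values must be finite")
        object.__setattr__(self, "replicate_cts", cts)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_cts))

    @property
    def sd(self) -> float:
        # single replicate: no scatter estimate, report 0
        if len(self.replicate_cts) < 2:
            return 0.0
        return float(np.std(self.replicate_cts, ddof=1))


@dataclass(frozen=True)
class DeltaCt:
    """Reference-normalised Ct for one condition (cycles)."""

    condition: str
    value: float
    sd: float


@dataclass(frozen=True)
class RelativeExpressionResult:
    """Fold change of the treated condition relative to control."""

    delta_ct_treated: DeltaCt
    delta_ct_control: DeltaCt
    delta_delta_ct: float
    fold_change: float
    fold_range: tuple[float, float]


def delta_ct(target: CtMeasurement, reference: CtMeasurement) -> DeltaCt:
    """dCt = mean(target Ct) - mean(reference Ct), within one condition.

    The standard deviation combines target and reference replicate scatter
    as independent errors: ``sqrt(sd_target**2 + sd_reference**2)``.
    """
    if target.condition != reference.condition:
        raise ValueError(
            f"condition mismatch: target {target.condition!r} vs "
            f"reference {reference.condition!r}"
        )
    return DeltaCt(
        condition=target.condition,
        value=target.mean - reference.mean,
        sd=math.hypot(target.sd, reference.sd),
    )


def relative_expression(treated: DeltaCt, control: DeltaCt) -> RelativeExpressionResult:
    """Fold change ``2**(-ddCt)`` with a replicate-scatter fold interval."""
    ddct = treated.value - control.value
    fold = 2.0 ** (-ddct)
    lo = 2.0 ** (-(ddct + treated.sd))
    hi = 2.0 ** (-(ddct - treated.sd))
    return RelativeExpressionResult(
        delta_ct_treated=treated,
        delta_ct_control=control,
        delta_delta_ct=ddct,
        fold_change=fold,
        fold_range=(lo, hi),
    )


def quantify_table(
    ct_table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    target_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Comparative-Ct quantification of a replicate Ct table.

    Parameters
    ----------
    ct_table
        Long-format table with columns ``condition``, ``gene``,
        ``replicate``, ``ct``.
    reference_gene, control_condition
        The normaliser gene and the baseline condition.
    target_genes
        Genes to quantify; defaults to every non-reference gene.

    Returns
    -------
    One row per (gene, non-control condition) with the treated and control
    dCt, ddCt, fold change and fold range.
    """
    required = {"condition", "gene", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")

    def measurement(condition: str, gene: str) -> CtMeasurement:
        sub = ct_table[(ct_table["condition"] == condition) & (ct_table["gene"] == gene)]
        if sub.empty:
            raise ValueError(f"no Ct rows for condition {condition!r}, gene {gene!r}")
        return CtMeasurement(condition, gene, tuple(sub["ct"].astype(float)))

    conditions = [
        c for c in ct_table["condition"].unique() if c != control_condition
    ]
    if control_condition not in set(ct_table["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in table")
    if target_genes is None:
        target_genes = [g for g in ct_table["gene"].unique() if g != reference_gene]

    rows = []
    for gene in target_genes:
        control = delta_ct(
            measurement(control_condition, gene),
            measurement(control_condition, reference_gene),
        )
        for condition in conditions:
            treated = delta_ct(
                measurement(condition, gene),
                measurement(condition, reference_gene),
            )
            res = relative_expression(treated, control)
            rows.append(
                {
                    "gene": gene,
                    "condition": condition,
                    "control_condition": control_condition,
                    "reference_gene": reference_gene,
                    "delta_ct": treated.value,
                    "delta_ct_sd": treated.sd,
                    "delta_delta_ct": res.delta_delta_ct,
                    "fold_change": res.fold_change,
                    "fold_lo": res.fold_range[0],
                    "fold_hi": res.fold_range[1],
                }
            )
    return pd.DataFrame(rows)
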