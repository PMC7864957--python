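"""Rule-based classification of cardiac progenitor cell-division defects.

A wild-type *Drosophila* cardiac hemisegment contains four Tinman-expressing
cardial cells (Tin-CCs), two Seven up-expressing cardial cells (Svp-CCs) and
two Seven up-expressing pericardial cells (Svp-PCs).  Departures from this
(4, 2, 2) configuration diagnose which progenitor cell division went wrong:

* **specification** — no cardial cells at all (``tin_cc == 0 and svp_cc == 0``):
  the progenitors were never specified, so no division can be scored.
* **symmetric** — any Tin-CC count other than four: the two symmetric
  divisions that produce the Tin-CCs misfired.
* **asymmetric** — an Svp-CC/Svp-PC imbalance, or enlarged Svp-CC nuclei with
  a missing partner PC (a karyokinesis error scored at the microscope and
  passed in as a boolean flag): an asymmetric Svp-precursor division failed.
* **earlier** — one or three complete Svp-CC/Svp-PC pairs instead of two: the
  earlier division that sets the number of Svp precursors misfired.

Specification failure pre-empts the three division categories; the division
categories may co-occur within one hemisegment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from numbers import Integral
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Division-defect categories, in canonical reporting order.
CATEGORIES: tuple[str, ...] = ("asymmetric", "symmetric", "earlier")

#: Wild-type hemisegment configuration (tin_cc, svp_cc, svp_pc).
WILD_TYPE = (4, 2, 2)

_COUNT_FIELDS = ("tin_cc", "svp_cc", "svp_pc")

#: Counts beyond this are accepted but logged as suspicious.
_SUSPICIOUS_MAX = 6


class InvalidObservationError(ValueError):
    """A hemisegment observation violates the count invariants."""


def _check_count(name: str, value) -> int:
    if isinstance(value, bool) or not isinstance(value, (Integral, np.integer)):
        raise InvalidObservationError(
            f"{name} must be a non-negative integer, got {value!r}"
        )
    value = int(value)
    if value < 0:
        raise InvalidObservationError(f"{name} must be >= 0, got {value}")
    if value > _SUSPICIOUS_MAX:
        logger.warning("suspicious %s=%d (wild type is %s)", name, value, WILD_TYPE)
    return value


@dataclass(frozen=True)
class HemisegmentObservation:
    """Cardiac cell counts for one scored hemisegment of one embryo."""

    embryo_id: str
    genotype: str
    hemisegment_index: int
    tin_cc: int
    svp_cc: int
    svp_pc: int
    enlarged_svp_cc: bool = False

    def __post_init__(self) -> None:
        for name in _COUNT_FIELDS:
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.hemisegment_index < 0:
            raise InvalidObservationError(
                f"hemisegment_index must be >= 0, got {self.hemisegment_index}"
            )


@dataclass(frozen=True)
class DefectCall:
    """Boolean defect flags for one hemisegment.

    ``specification`` is exclusive of the three division flags; the division
    flags may co-occur.
    """

    asymmetric: bool
    symmetric: bool
    earlier: bool
    specification: bool

    def any_division_defect(self) -> bool:
        return self.asymmetric or self.symmetric or self.earlier


def classify_counts(
    tin_cc: int, svp_cc: int, svp_pc: int, enlarged_svp_cc: bool = False
) -> DefectCall:
    """Classify a single hemisegment from its raw counts.

    Rules, applied in order:

    1. specification := ``tin_cc == 0 and svp_cc == 0`` (all cardial cells
       absent); if set, the division flags are all False.
    2. symmetric := ``tin_cc != 4``.
    3. asymmetric := ``svp_cc != svp_pc`` or ``enlarged_svp_cc``.
    4. earlier := ``svp_cc == svp_pc != 2`` (one or three complete pairs).
    """
    tin_cc = _check_count("tin_cc", tin_cc)
    svp_cc = _check_count("svp_cc", svp_cc)
    svp_pc = _check_count("svp_pc", svp_pc)
    if tin_cc == 0 and svp_cc == 0:
        return DefectCall(False, False, False, True)
    return DefectCall(
        asymmetric=(svp_cc != svp_pc) or bool(enlarged_svp_cc),
        symmetric=tin_cc != 4,
        earlier=(svp_cc == svp_pc) and (svp_cc != 2),
        specification=False,
    )


def classify_hemisegment(obs: HemisegmentObservation) -> DefectCall:
    """Classify one :class:`HemisegmentObservation`."""
    return classify_counts(obs.tin_cc, obs.svp_cc, obs.svp_pc, obs.enlarged_svp_cc)


def classify_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification of a hemisegment table.

    Parameters
    ----------
    table
        One row per hemisegment with integer columns ``tin_cc``, ``svp_cc``,
        ``svp_pc`` and boolean ``enlarged_svp_cc``.

    Returns
    -------
    A copy of ``table`` with boolean columns ``asymmetric``, ``symmetric``,
    ``earlier`` and ``specification`` appended.
    """
    for name in _COUNT_FIELDS:
        col = table[name]
        if not pd.api.types.is_integer_dtype(col):
            raise InvalidObservationError(f"column {name} must be integer-typed")
        if (col < 0).any():
            row = int(col[col < 0].index[0])
            raise InvalidObservationError(f"negative {name} at row {row}")
        if (col > _SUSPICIOUS_MAX).any():
            logger.warning(
                "column %s has %d values above %d",
                name,
                int((col > _SUSPICIOUS_MAX).sum()),
                _SUSPICIOUS_MAX,
            )
    tin = table["tin_cc"].to_numpy()
    svp_cc = table["svp_cc"].to_numpy()
    svp_pc = table["svp_pc"].to_numpy()
    flag = table["enlarged_svp_cc"].to_numpy().astype(bool)

    spec = (tin == 0) & (svp_cc == 0)
    out = table.copy()
    out["asymmetric"] = ~spec & ((svp_cc != svp_pc) | flag)
    out["symmetric"] = ~spec & (tin != 4)
    out["earlier"] = ~spec & (svp_cc == svp_pc) & (svp_cc != 2)
    out["specification"] = spec
    return out


@dataclass(frozen=True)
class EmbryoSummary:
    """Per-embryo defect tallies; the response unit of the regression models.

    ``scored`` counts the hemisegments that enter the division-defect
    denominators; hemisegments with a specification defect are excluded from
    it and reported separately (``specification`` out of ``total``).
    """

    embryo_id: str
    genotype: str
    total: int
    scored: int
    defect_counts: dict[str, int] = field(default_factory=dict)
    specification: int = 0

    def proportion(self, category: str) -> float:
        return self.defect_counts[category] / self.scored

    @property
    def proportions(self) -> dict[str, float]:
        return {c: self.proportion(c) for c in CATEGORIES}


def summarize_embryo(observations: Iterable[HemisegmentObservation]) -> EmbryoSummary:
    """Tally defect calls for the hemisegments of one embryo."""
    observations = list(observations)
    if not observations:
        raise ValueError("no observations supplied")
    ids = {o.embryo_id for o in observations}
    if len(ids) != 1:
        raise ValueError(f"observations span multiple embryos: {sorted(ids)}")
    calls = [classify_hemisegment(o) for o in observations]
    n_spec = sum(c.specification for c in calls)
    scored = len(calls) - n_spec
    if scored == 0:
        raise ValueError(
            f"embryo {observations[0].embryo_id!r} has no scorable hemisegments "
            "(all specification defects)"
        )
    counts = {c: sum(getattr(call, c) for call in calls) for c in CATEGORIES}
    return EmbryoSummary(
        embryo_id=observations[0].embryo_id,
        genotype=observations[0].genotype,
        total=len(calls),
        scored=scored,
        defect_counts=counts,
        specification=n_spec,
    )


def summarize_embryos(table: pd.DataFrame) -> pd.DataFrame:
    """Per-embryo defect tallies for a whole hemisegment table.

    Returns one row per embryo with columns ``embryo_id``, ``genotype``,
    ``total``, ``scored``, ``specification``, and per-category ``<cat>``
    (count) and ``prop_<cat>`` (proportion of ``scored``).
    """
    if table.empty:
        raise ValueError("empty hemisegment table")
    classified = classify_table(table)
    gb = classified.groupby(["embryo_id", "genotype"], sort=True)
    agg = gb.agg(
        total=("specification", "size"),
        specification=("specification", "sum"),
        **{c: (c, "sum") for c in CATEGORIES},
    ).reset_index()
    agg["scored"] = agg["total"] - agg["specification"]
    if (agg["scored"] == 0).any():
        bad = agg.loc[agg["scored"] == 0, "embryo_id"].tolist()
        raise ValueError(f"embryos with no scorable hemisegments: {bad}")
    for c in CATEGORIES:
        agg[f"prop_{c}"] = agg[c] / agg["scored"]
    cols = (
        ["embryo_id", "genotype", "total", "scored", "specification"]
        + list(CATEGORIES)
        + [f"prop_{c}" for c in CATEGORIES]
    )
    return agg[cols]


@dataclass(frozen=True)
class GenotypeSummary:
    """Pooled per-genotype defect fractions (hemisegment-level)."""

    genotype: str
    n_embryos: int
    total_hemisegments: int
    scored: int
    defect_counts: dict[str, int]
    specification: int

    def fraction(self, category: str) -> float:
        return self.defect_counts[category] / self.scored


def summarize_genotype(summaries: Sequence[EmbryoSummary]) -> GenotypeSummary:
    """Pool embryo summaries of one genotype into hemisegment-level fractions."""
    if not summaries:
        raise ValueError("no embryo summaries supplied")
    genotypes = {s.genotype for s in summaries}
    if len(genotypes) != 1:
        raise ValueError(f"summaries span multiple genotypes: {sorted(genotypes)}")
    return GenotypeSummary(
        genotype=summaries[0].genotype,
        n_embryos=len(summaries),
        total_hemisegments=sum(s.total for s in summaries),
        scored=sum(s.scored for s in summaries),
        defect_counts={
            c: sum(s.defect_counts[c] for s in summaries) for c in CATEGORIES
        },
        specification=sum(s.specification for s in summaries),
    )


def genotype_table(embryo_summaries: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-genotype summary: one row per (genotype, category).

    Columns: genotype, category, defective, scored, fraction — the layout of
    a per-genotype percent-defective bar chart.
    """
    rows = []
    for genotype, sub in embryo_summaries.groupby("genotype", sort=True):
        scored = int(sub["scored"].sum())
        for c in CATEGORIES:
            defective = int(sub[c].sum())
            rows.append(
                {
                    "genotype": genotype,
                    "category": c,
                    "defective": defective,
                    "scored": scored,
                    "fraction": defective / scored,
                }
            )
    return pd.DataFrame(rows)
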