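"""Synthetic embryo/hemisegment generator for the cell-division analysis.

Each simulated embryo contributes a fixed number of scored hemisegments.
Every hemisegment independently draws one outcome from {none, asymmetric,
symmetric, earlier} with per-genotype probabilities, optionally perturbed
per embryo by a mean-preserving Dirichlet draw (between-embryo
overdispersion).  Outcomes are rendered as concrete cardiac cell counts that
the classifier maps back to exactly the generated category:

* none       -> (tin_cc, svp_cc, svp_pc) = (4, 2, 2)
* symmetric  -> tin_cc drawn from {3, 5}, Svp counts (2, 2)
* asymmetric -> (svp_cc, svp_pc) drawn from {(3, 1), (1, 3)}, tin_cc = 4
* earlier    -> (svp_cc, svp_pc) drawn from {(1, 1), (3, 3)}, tin_cc = 4

The four-genotype interaction scenario mirrors a double-heterozygote
synergy assay: the double genotype's per-category probability is
``p_A + p_B - p_0 + delta``, so ``delta = 0`` is exactly additive in
expectation and a positive ``delta`` is a super-additive (synergistic)
effect the interaction test should detect.

Defaults emulate a typical scoring experiment in this system: roughly 190
hemisegments per genotype (16 embryos x 12 hemisegments), near-zero
baseline defect rates and single-heterozygote rates of a few percent.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CATEGORIES

logger = logging.getLogger(__name__)

_OUTCOMES = ("none",) + CATEGORIES

#: Default per-category defect probabilities.
DEFAULT_BASELINE = {"asymmetric": 0.005, "symmetric": 0.005, "earlier": 0.005}
DEFAULT_SINGLE_HET = {"asymmetric": 0.04, "symmetric": 0.04, "earlier": 0.04}


def _validate_probs(label: str, probs: dict[str, float]) -> dict[str, float]:
    unknown = set(probs) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"{label}: unknown categories {sorted(unknown)}")
    full = {c: float(probs.get(c, 0.0)) for c in CATEGORIES}
    for c, p in full.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{label}: probability {c}={p} outside [0, 1]")
    if sum(full.values()) > 1.0 + 1e-12:
        raise ValueError(f"{label}: category probabilities sum above 1")
    return full


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of the synthetic embryo generator.

    Parameters
    ----------
    genotypes
        Mapping of genotype label to its ``(I_n, I_M)`` indicator coding.
    probabilities
        Per-genotype, per-category defect probabilities; omitted categories
        default to 0.
    embryos_per_genotype, hemisegments_per_embryo
        Design size; defaults 16 x 12 give ~190 hemisegments per genotype.
    overdispersion
        Dirichlet concentration for the per-embryo random effect on the
        outcome probabilities; ``None`` (the default) disables it.  Smaller
        values give more between-embryo spread; the mean is preserved.
    seed
        Seed for the generator; identical config + seed reproduce the table.
    """

    genotypes: dict[str, tuple[int, int]]
    probabilities: dict[str, dict[str, float]]
    embryos_per_genotype: int = 16
    hemisegments_per_embryo: int = 12
    overdispersion: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.genotypes:
            raise ValueError("at least one genotype required")
        missing = set(self.genotypes) - set(self.probabilities)
        if missing:
            raise ValueError(f"no probabilities for genotypes {sorted(missing)}")
        object.__setattr__(
            self,
            "probabilities",
            {g: _validate_probs(g, p) for g, p in self.probabilities.items()},
        )
        if self.embryos_per_genotype < 1:
            raise ValueError("embryos_per_genotype must be >= 1")
        if self.hemisegments_per_embryo < 1:
            raise ValueError("hemisegments_per_embryo must be >= 1")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion concentration must be > 0")


def _embryo_outcome_probs(
    mean_probs: np.ndarray, concentration: float | None, rng: np.random.Generator
) -> np.ndarray:
    """Per-embryo outcome probabilities over (none, asymmetric, symmetric, earlier)."""
    if concentration is None:
        return mean_probs
    pos = mean_probs > 0.0
    draw = np.zeros_like(mean_probs)
    draw[pos] = rng.dirichlet(concentration * mean_probs[pos])
    return draw


_RENDER = {
    # outcome -> list of (tin_cc, svp_cc, svp_pc) variants, drawn uniformly
    "none": [(4, 2, 2)],
    "symmetric": [(3, 2, 2), (5, 2, 2)],
    "asymmetric": [(4, 3, 1), (4, 1, 3)],
    "earlier": [(4, 1, 1), (4, 3, 3)],
}


def generate_dataset(config: SynthConfig) -> pd.DataFrame:
    """Generate a hemisegment count table from a :class:`SynthConfig`.

    Returns a table with one row per hemisegment and the columns consumed by
    the classifier: embryo_id, genotype, hemisegment_index, tin_cc, svp_cc,
    svp_pc, enlarged_svp_cc.
    """
    rng = np.random.default_rng(config.seed)
    H = config.hemisegments_per_embryo
    rows_embryo, rows_geno, rows_outcome = [], [], []
    for genotype in config.genotypes:
        probs = config.probabilities[genotype]
        mean = np.array([1.0 - sum(probs.values())] + [probs[c] for c in CATEGORIES])
        for e in range(config.embryos_per_genotype):
            p = _embryo_outcome_probs(mean, config.overdispersion, rng)
            outcomes = rng.choice(len(_OUTCOMES), size=H, p=p)
            rows_embryo.append(np.full(H, f"{genotype}-e{e:03d}"))
            rows_geno.append(np.full(H, genotype))
            rows_outcome.append(outcomes)
    outcome = np.concatenate(rows_outcome)
    n = outcome.size
    variant = rng.integers(0, 2, size=n)  # which rendering of a defect
    counts = np.empty((n, 3), dtype=np.int64)
    for k, name in enumerate(_OUTCOMES):
        opts = np.array(_RENDER[name], dtype=np.int64)
        mask = outcome == k
        counts[mask] = opts[variant[mask] % len(opts)]
    table = pd.DataFrame(
        {
            "embryo_id": np.concatenate(rows_embryo),
            "genotype": np.concatenate(rows_geno),
            "hemisegment_index": np.tile(np.arange(H), n // H),
            "tin_cc": counts[:, 0],
            "svp_cc": counts[:, 1],
            "svp_pc": counts[:, 2],
            "enlarged_svp_cc": np.zeros(n, dtype=bool),
        }
    )
    return table


def interaction_config(
    baseline: dict[str, float] | None = None,
    single_a: dict[str, float] | None = None,
    single_b: dict[str, float] | None = None,
    delta: dict[str, float] | float = 0.0,
    embryos_per_genotype: int = 16,
    hemisegments_per_embryo: int = 12,
    overdispersion: float | None = None,
    seed: int | None = None,
    genotype_labels: tuple[str, str, str, str] = (
        "wild_type",
        "het_a",
        "het_b",
        "double_het",
    ),
) -> SynthConfig:
    """Build the four-genotype double-heterozygote scenario.

    The double heterozygote's per-category probability is
    ``p_A + p_B - p_0 + delta`` (clamped to [0, 1]); clamping that censors
    more than 10% of the requested effect is logged as a warning.
    """
    p0 = _validate_probs("baseline", baseline or DEFAULT_BASELINE)
    pa = _validate_probs("single_a", single_a or DEFAULT_SINGLE_HET)
    pb = _validate_probs("single_b", single_b or DEFAULT_SINGLE_HET)
    if not isinstance(delta, dict):
        delta = {c: float(delta) for c in CATEGORIES}
    delta = {c: float(delta.get(c, 0.0)) for c in CATEGORIES}
    double = {}
    for c in CATEGORIES:
        raw = pa[c] + pb[c] - p0[c] + delta[c]
        clamped = min(1.0, max(0.0, raw))
        if abs(raw - clamped) > 0.1 * max(abs(delta[c]), 1e-12):
            logger.warning(
                "double-het %s probability clamped from %.4f to %.4f; "
                "the configured interaction effect is censored",
                c,
                raw,
                clamped,
            )
        double[c] = clamped
    wt, a, b, d = genotype_labels
    return SynthConfig(
        genotypes={wt: (0, 0), a: (1, 0), b: (0, 1), d: (1, 1)},
        probabilities={wt: p0, a: pa, b: pb, d: double},
        embryos_per_genotype=embryos_per_genotype,
        hemisegments_per_embryo=hemisegments_per_embryo,
        overdispersion=overdispersion,
        seed=seed,
    )


def generate_interaction_scenario(config: SynthConfig) -> pd.DataFrame:
    """Generate a dataset from a four-genotype interaction config.

    Thin alias of :func:`generate_dataset` for configs built with
    :func:`interaction_config`; validates the four-genotype structure.
    """
    codes = set(config.genotypes.values())
    if not {(0, 1), (1, 0), (1, 1)}.issubset(codes):
        raise ValueError(
            "interaction scenario needs genotypes coded (1,0), (0,1) and (1,1)"
        )
    return generate_dataset(config)


def indicator_columns(
    embryo_summaries: pd.DataFrame, config: SynthConfig
) -> pd.DataFrame:
    """Attach ``i_n``/``i_m`` indicator columns from a config's genotype coding."""
    coding = {g: code for g, code in config.genotypes.items()}
    out = embryo_summaries.copy()
    out["i_n"] = out["genotype"].map(lambda g: coding[g][0])
    out["i_m"] = out["genotype"].map(lambda g: coding[g][1])
    return out


def config_to_dict(config: SynthConfig) -> dict:
    """Resolved config as a plain dict (for logging / provenance blocks)."""
    return dataclasses.asdict(config)
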