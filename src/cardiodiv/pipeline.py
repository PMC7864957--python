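"""Reproducible end-to-end runs: classify, test, simulate, quantify.

A :class:`RunConfig` names the analysis mode, the inputs, the genotype
contrast and the randomisation parameters; :func:`run` executes it and
writes delimited result tables plus a human-readable report with a
provenance block (config hash, seed, package version).  Identical config
and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import CATEGORIES, genotype_table, summarize_embryos
from .io import read_ct_table, read_hemisegment_table, write_table
from .permutation import (
    DEFAULT_PERMUTATIONS,
    PermutationResult,
    interaction_test,
    two_group_test,
)
from .qpcr import quantify_table
from .simulate import SynthConfig, generate_dataset, interaction_config

logger = logging.getLogger(__name__)

MODES = ("classify", "two-group", "interaction", "simulate", "qpcr")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``contrast`` maps indicator roles to genotype labels:
    for ``two-group`` mode, ``{"reference": ..., "test": ...}``;
    for ``interaction`` mode, ``{"single_a": ..., "single_b": ...,
    "double": ...}`` (embryos of any other genotype are excluded from the
    fit, matching the three-genotype synergy contrast).
    """

    mode: str
    input_path: str | None = None
    out_dir: str = "results"
    contrast: dict[str, str] = field(default_factory=dict)
    n_permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "input_path": self.input_path,
            "out_dir": self.out_dir,
            "contrast": dict(self.contrast),
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "simulate": dict(self.simulate),
            "qpcr": dict(self.qpcr),
        }


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one run produced, plus provenance."""

    embryo_summary: pd.DataFrame | None
    genotype_summary: pd.DataFrame | None
    results: pd.DataFrame | None
    provenance: dict


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "cardiodiv",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_permutations": config.n_permutations,
    }


def _check_genotypes(required: dict[str, str], present: set[str]) -> None:
    unknown = {role: g for role, g in required.items() if g not in present}
    if unknown:
        raise ValueError(
            "contrast names genotypes absent from the data: "
            + ", ".join(f"{role}={g!r}" for role, g in unknown.items())
        )


def _result_row(
    contrast: str, category: str, res: PermutationResult
) -> dict:
    logger.info(
        "contrast=%s category=%s method=%s N=%d exceed=%d seed=%s",
        contrast,
        category,
        res.method,
        res.n_permutations,
        res.exceed_count,
        res.seed,
    )
    return {
        "contrast": contrast,
        "category": category,
        "observed_coefficient": res.observed_stat,
        "n_permutations": res.n_permutations,
        "exceed_count": res.exceed_count,
        "p_value": res.p_value,
        "seed": res.seed,
        "method": res.method,
    }


def _two_group_results(summaries: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    roles = config.contrast
    for key in ("reference", "test"):
        if key not in roles:
            raise ValueError(f"two-group contrast needs a {key!r} genotype")
    _check_genotypes(roles, set(summaries["genotype"]))
    sub = summaries[summaries["genotype"].isin([roles["reference"], roles["test"]])]
    indicator = (sub["genotype"] == roles["test"]).astype(int).to_numpy()
    name = f"{roles['test']}_vs_{roles['reference']}"
    rows = []
    for i, cat in enumerate(CATEGORIES):
        res = two_group_test(
            sub[f"prop_{cat}"].to_numpy(),
            indicator,
            n_permutations=config.n_permutations,
            seed=config.seed + i,
        )
        rows.append(_result_row(name, cat, res))
    return pd.DataFrame(rows)


def _interaction_results(summaries: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    roles = config.contrast
    for key in ("single_a", "single_b", "double"):
        if key not in roles:
            raise ValueError(f"interaction contrast needs a {key!r} genotype")
    _check_genotypes(roles, set(summaries["genotype"]))
    keep = [roles["single_a"], roles["single_b"], roles["double"]]
    sub = summaries[summaries["genotype"].isin(keep)]
    i_n = sub["genotype"].isin([roles["single_a"], roles["double"]]).astype(int)
    i_m = sub["genotype"].isin([roles["single_b"], roles["double"]]).astype(int)
    name = f"{roles['single_a']}_x_{roles['single_b']}"
    rows = []
    for i, cat in enumerate(CATEGORIES):
        res = interaction_test(
            sub[f"prop_{cat}"].to_numpy(),
            i_n.to_numpy(),
            i_m.to_numpy(),
            n_permutations=config.n_permutations,
            seed=config.seed + i,
        )
        rows.append(_result_row(name, cat, res))
    return pd.DataFrame(rows)


def _simulate_table(config: RunConfig) -> pd.DataFrame:
    params = dict(config.simulate)
    scenario = params.pop("scenario", "interaction")
    params.setdefault("seed", config.seed)
    if scenario == "interaction":
        synth = interaction_config(**params)
    elif scenario == "custom":
        synth = SynthConfig(**params)
    else:
        raise ValueError(f"unknown simulate scenario {scenario!r}")
    logger.info("resolved synthetic config: %s", synth)
    return generate_dataset(synth)


def run(config: RunConfig) -> AnalysisReport:
    """Execute one configured analysis and write its outputs.

    Writes, under ``config.out_dir``: ``embryo_summary.csv`` and
    ``genotype_summary.csv`` (classification modes), ``results.csv`` (test
    modes), ``simulated_hemisegments.csv`` (simulate mode),
    ``qpcr_results.csv`` (qpcr mode), and always ``provenance.json`` and
    ``report.txt``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = _provenance(config)

    embryo_summary = genotype_summary = results = None
    report_lines = [f"cardiodiv {__version__} — mode: {config.mode}"]

    if config.mode == "simulate":
        table = _simulate_table(config)
        write_table(table, out / "simulated_hemisegments.csv")
        report_lines.append(
            f"simulated {len(table)} hemisegments, "
            f"{table['embryo_id'].nunique()} embryos, "
            f"{table['genotype'].nunique()} genotypes"
        )
    elif config.mode == "qpcr":
        if config.input_path is None:
            raise ValueError("qpcr mode requires input_path")
        ct = read_ct_table(config.input_path)
        results = quantify_table(
            ct,
            reference_gene=config.qpcr["reference_gene"],
            control_condition=config.qpcr["control_condition"],
        )
        write_table(results, out / "qpcr_results.csv")
        for _, r in results.iterrows():
            report_lines.append(
                f"{r['gene']} [{r['condition']}]: fold {r['fold_change']:.3f} "
                f"({r['fold_lo']:.3f}–{r['fold_hi']:.3f})"
            )
    else:
        if config.input_path is None:
            raise ValueError(f"{config.mode} mode requires input_path")
        table = read_hemisegment_table(config.input_path)
        embryo_summary = summarize_embryos(table)
        genotype_summary = genotype_table(embryo_summary)
        write_table(embryo_summary, out / "embryo_summary.csv")
        write_table(genotype_summary, out / "genotype_summary.csv")
        report_lines.append(
            f"{len(table)} hemisegments across "
            f"{embryo_summary.shape[0]} embryos"
        )
        if config.mode == "two-group":
            results = _two_group_results(embryo_summary, config)
        elif config.mode == "interaction":
            results = _interaction_results(embryo_summary, config)
        if results is not None:
            write_table(results, out / "results.csv")
            for _, r in results.iterrows():
                report_lines.append(
                    f"{r['contrast']} / {r['category']}: "
                    f"coef={r['observed_coefficient']:.5f} "
                    f"p={r['p_value']:.6g} (N={r['n_permutations']})"
                )

    report_lines.append("")
    report_lines.append("provenance: " + json.dumps(provenance, sort_keys=True))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return AnalysisReport(embryo_summary, genotype_summary, results, provenance)
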