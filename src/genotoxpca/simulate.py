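"""Synthetic expression studies with the structure the pipeline assumes.

The generator emulates the reference study design — concurrent vehicle
controls, three rats per group, three dose levels per chemical — with a
simple additive model on the log2 scale:

    log2 intensity = baseline[gene] + effect(class, dose rank, gene)
                     + Normal(0, noise_sd[gene])

Genotoxic hepatocarcinogens induce every marker gene linearly in ordinal
dose rank (1/2/3 for low/middle/high); non-genotoxic chemicals leave the
markers flat; intermediates respond per ``intermediate_mode``. Additive
Gaussian log-scale noise mirrors the variance-stabilized scale the real
analysis works on. Each chemical draws from its own deterministic
substream, so adding or removing a chemical never perturbs the others.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .preprocess import expression_to_ratios
from .reference import available_doses, builtin_annotations, builtin_panel
from .types import (
    ChemClass,
    DoseLevel,
    ExpressionTable,
    GenePanel,
    Scale,
    TimePoint,
)

_TREATED = (DoseLevel.LOW, DoseLevel.MIDDLE, DoseLevel.HIGH)


def _per_gene(value, genes: Sequence[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {g: float(value.get(g, 0.0)) for g in genes}
    else:
        out = {g: float(value) for g in genes}
    if name == "noise_sd" and any(v < 0 for v in out.values()):
        raise ConfigError("noise_sd must be non-negative")
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    ``chemicals`` is a tuple of ``(abbreviation, ChemClass, doses)``;
    ``effect`` maps a chemical class to a per-gene dose slope in log2
    fold-change per dose rank (scalars broadcast over the panel).
    """

    panel: GenePanel
    chemicals: tuple[tuple[str, ChemClass, tuple[DoseLevel, ...]], ...]
    time_point: TimePoint = TimePoint.SINGLE_24H
    n_replicates: int = 3
    baseline_mu: Mapping[str, float] | float = 10.0
    noise_sd: Mapping[str, float] | float = 0.25
    effect: Mapping[ChemClass, Mapping[str, float] | float] = field(
        default_factory=lambda: {ChemClass.GTHC: 1.0}
    )
    intermediate_mode: str = "high_dose_only"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        sd_values = (
            self.noise_sd.values()
            if isinstance(self.noise_sd, Mapping)
            else (self.noise_sd,)
        )
        if any(v < 0 for v in sd_values):
            raise ConfigError("noise_sd must be non-negative")
        if self.intermediate_mode not in ("high_dose_only", "half_magnitude"):
            raise ConfigError(
                f"unknown intermediate_mode: {self.intermediate_mode!r}"
            )
        for abbr, cls, doses in self.chemicals:
            ChemClass(cls)
            if not doses:
                raise ConfigError(f"chemical {abbr}: empty dose list")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def default_config(
    panel: GenePanel | str = "FOUR",
    time_point: TimePoint = TimePoint.SINGLE_24H,
    include_intermediates: bool = False,
    seed: int = 0,
    **overrides,
) -> SyntheticConfig:
    """Study config mirroring the reference chemical set and dose layout."""
    if isinstance(panel, str):
        panel = builtin_panel(panel)
    time_point = TimePoint(time_point)
    chems = []
    for ann in builtin_annotations():
        if ann.class_label is ChemClass.INTERMEDIATE and not include_intermediates:
            continue
        doses = available_doses(ann.abbreviation, time_point)
        if doses:
            chems.append((ann.abbreviation, ann.class_label, doses))
    return SyntheticConfig(
        panel=panel,
        chemicals=tuple(chems),
        time_point=time_point,
        seed=seed,
        **overrides,
    )


def paper24h_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """23 chemicals x 3 doses at 24 h (69 dose points)."""
    return default_config(
        time_point=TimePoint.SINGLE_24H, include_intermediates=False,
        seed=seed, **overrides,
    )


def paper29d_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The 63-point day-29 layout, intermediates included."""
    return default_config(
        time_point=TimePoint.REPEAT_29D, include_intermediates=True,
        seed=seed, **overrides,
    )


def true_effect(
    config: SyntheticConfig, chem_class: ChemClass, dose: DoseLevel, gene: str
) -> float:
    """Mean log2 ratio implied by the config for one (class, dose, gene)."""
    if dose is DoseLevel.CONTROL:
        return 0.0
    genes = config.panel.genes
    rank = dose.rank
    if chem_class is ChemClass.INTERMEDIATE:
        gthc = _per_gene(config.effect.get(ChemClass.GTHC, 0.0), genes, "effect")
        if config.intermediate_mode == "high_dose_only":
            return gthc[gene] * rank if dose is DoseLevel.HIGH else 0.0
        return 0.5 * gthc[gene] * rank
    slope = _per_gene(config.effect.get(chem_class, 0.0), genes, "effect")
    return slope[gene] * rank


def _chemical_rng(seed: int, abbreviation: str) -> np.random.Generator:
    sub = zlib.crc32(abbreviation.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([seed, sub])


def generate_study(config: SyntheticConfig) -> tuple[ExpressionTable, pd.DataFrame]:
    """Draw one study; returns the expression table and its ground truth.

    Ground truth has one row per (chemical, dose, gene) — controls
    included with true ratio 0 — plus the chemical's class label.
    """
    genes = list(config.panel.genes)
    baseline = _per_gene(config.baseline_mu, genes, "baseline_mu")
    sd = _per_gene(config.noise_sd, genes, "noise_sd")

    records = []
    truth_rows = []
    for abbr, cls, doses in config.chemicals:
        cls = ChemClass(cls)
        rng = _chemical_rng(config.seed, abbr)
        groups = (DoseLevel.CONTROL,) + tuple(doses)
        noise = rng.normal(
            0.0, 1.0, size=(len(groups), config.n_replicates, len(genes))
        )
        for gi, dose in enumerate(groups):
            for g_idx, gene in enumerate(genes):
                mean = baseline[gene] + true_effect(config, cls, dose, gene)
                truth_rows.append(
                    {
                        "chemical": abbr,
                        "class": cls,
                        "dose": dose,
                        "gene": gene,
                        "true_ratio": true_effect(config, cls, dose, gene),
                    }
                )
                for rep in range(config.n_replicates):
                    records.append(
                        {
                            "chemical": abbr,
                            "dose": dose,
                            "time": config.time_point,
                            "replicate": rep + 1,
                            "gene": gene,
                            "value": mean + sd[gene] * noise[gi, rep, g_idx],
                        }
                    )
    table = ExpressionTable(pd.DataFrame(records), scale=Scale.LOG2)
    truth = pd.DataFrame(truth_rows).drop_duplicates(
        subset=["chemical", "dose", "gene"]
    )
    return table, truth.reset_index(drop=True)


@dataclass
class RecoveryReport:
    """Estimation error of dose-group mean ratios against ground truth."""

    cells: pd.DataFrame
    per_class: pd.DataFrame
    slopes: pd.DataFrame

    @property
    def rmse(self) -> float:
        return float(np.sqrt((self.cells["error"] ** 2).mean()))

    @property
    def bias(self) -> float:
        return float(self.cells["error"].mean())


def theoretical_cell_rmse(noise_sd: float, n_treated: int, n_control: int) -> float:
    """Closed-form RMSE of one dose group's mean log2 ratio.

    The estimate is (treated group mean) - (control group mean), so its
    standard error is sd * sqrt(1/n_treated + 1/n_control).
    """
    return float(noise_sd) * np.sqrt(1.0 / n_treated + 1.0 / n_control)


def recover_effects(table: ExpressionTable, truth: pd.DataFrame) -> RecoveryReport:
    """Compare the preprocessing output with the generator's ground truth."""
    matrix = expression_to_ratios(table)
    est = matrix.data.stack().rename("estimate").reset_index()
    est.columns = ["dose_point", "gene", "estimate"]
    from .types import parse_dose_point

    parsed = [parse_dose_point(r) for r in est["dose_point"]]
    est["chemical"] = [p[0] for p in parsed]
    est["dose"] = [p[1] for p in parsed]

    treated_truth = truth[truth["dose"] != DoseLevel.CONTROL]
    cells = est.merge(
        treated_truth, on=["chemical", "dose", "gene"], how="outer", indicator=True
    )
    if (cells["_merge"] != "both").any():
        raise DomainError("table and ground truth cover different designs")
    cells = cells.drop(columns="_merge")
    cells["error"] = cells["estimate"] - cells["true_ratio"]

    per_class = (
        cells.groupby("class", observed=True)["error"]
        .agg(bias="mean", rmse=lambda e: float(np.sqrt((e**2).mean())), n_cells="size")
        .reset_index()
    )

    # per (chemical, gene) dose slope via least squares through the origin
    cells["rank"] = cells["dose"].map(lambda d: d.rank)
    def _slope(sub: pd.DataFrame) -> pd.Series:
        r = sub["rank"].to_numpy(dtype=float)
        return pd.Series(
            {
                "slope_hat": float((r * sub["estimate"]).sum() / (r * r).sum()),
                "slope_true": float((r * sub["true_ratio"]).sum() / (r * r).sum()),
            }
        )

    slopes = (
        cells.groupby(["chemical", "class", "gene"], observed=True)
        .apply(_slope, include_groups=False)
        .reset_index()
    )
    return RecoveryReport(cells=cells, per_class=per_class, slopes=slopes)
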