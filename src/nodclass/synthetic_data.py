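"""Synthetic expression datasets and Ct tables with planted structure.

The generator reproduces the study design downstream stages expect: seven
nodule conditions (plus an implicit common control) with four replicates of
log2(sample/control) ratios, and qRT-PCR panels over eight root conditions
plus control roots with three replicates and a constant reference gene.
Replicate noise is Gaussian on the log2 / Ct scale (log-normal on the linear
scale), the standard two-colour array error model.

Planted nodule probes follow the per-class level templates of
:mod:`nodclass.nodule_class_assignment` (single source of truth), with
"maximal induction" at ``max_log2_effect`` (default 3.0, linear 8-fold) and
"weak induction" at ``weak_log2_effect`` (default 0.8, linear ~1.74 — above
the 1.5 call threshold yet below half the maximal ratio, exercising the
weak/max distinction).  Planted root genes follow concrete fold profiles
that realise each pattern's symbol row under the default calling thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model_io import (
    CONTROL,
    NODULE_CONDITIONS,
    ROOT_CONDITIONS,
    CtTable,
    ExpressionDataset,
)
from .nodule_class_assignment import CLASS_TEMPLATES, DOWN, MAX, NONE, NOT_DE, WEAK
from .root_pattern_analysis import ROOT_PATTERNS


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-condition parameters for the generators.

    ``n_probes_per_class`` maps class labels (or ``not_DE``) to probe
    counts.  ``noise_sd`` is the replicate standard deviation on the log2
    (or Ct) scale; the study design fixes ``n_replicates`` at 4 for arrays
    and the qRT-PCR generator always uses 3 biological repetitions.
    """

    n_probes_per_class: dict[str, int] = field(default_factory=dict)
    noise_sd: float = 0.15
    n_replicates: int = 4
    max_log2_effect: float = 3.0
    weak_log2_effect: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be >= 0")
        if not 0 < self.weak_log2_effect < self.max_log2_effect:
            raise SimConfigError("need 0 < weak_log2_effect < max_log2_effect")
        if self.n_replicates < 2:
            raise SimConfigError("n_replicates must be >= 2")
        bad = {k: v for k, v in self.n_probes_per_class.items() if v < 0}
        if bad:
            raise SimConfigError(f"negative probe counts: {bad}")
        unknown = set(self.n_probes_per_class) - set(CLASS_TEMPLATES) - {NOT_DE}
        if unknown:
            raise SimConfigError(f"unknown class labels: {sorted(unknown)}")


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: per-probe label and true mean profile."""

    labels: pd.Series
    true_means: pd.DataFrame


def _level_effect(level: str, config: SimConfig) -> float:
    return {
        MAX: config.max_log2_effect,
        WEAK: config.weak_log2_effect,
        NONE: 0.0,
        DOWN: -config.max_log2_effect,
    }[level]


def generate_nodule_dataset(config: SimConfig) -> tuple[ExpressionDataset, PlantedTruth]:
    """Simulate a replicated nodule log2-ratio matrix with planted classes.

    Each probe's replicate values are its class template's true means plus
    Gaussian(0, noise_sd) noise; identical seeds give identical output.
    Annotations mark every tenth probe of a class as a regulator and every
    seventh as an NCR gene so census cross-tabs are exercised.
    """
    rng = np.random.default_rng(config.seed)
    probe_ids: list[str] = []
    labels: list[str] = []
    means_rows: list[list[float]] = []
    families: list[str] = []
    regulator: list[bool] = []
    ncr: list[bool] = []

    order = [c for c in list(CLASS_TEMPLATES) + [NOT_DE] if c in config.n_probes_per_class]
    for label in order:
        template = CLASS_TEMPLATES.get(label)
        for j in range(config.n_probes_per_class[label]):
            probe_ids.append(f"MTS{len(probe_ids):05d}")
            labels.append(label)
            if label == NOT_DE:
                means_rows.append([0.0] * len(NODULE_CONDITIONS))
            else:
                means_rows.append([_level_effect(lv, config) for lv in template])
            families.append(f"FAM{j % 5}")
            regulator.append(j % 10 == 0)
            ncr.append(j % 7 == 0)

    index = pd.Index(probe_ids, name="probe")
    true_means = pd.DataFrame(means_rows, index=index, columns=list(NODULE_CONDITIONS))

    cols = pd.MultiIndex.from_tuples(
        [(c, r + 1) for c in NODULE_CONDITIONS for r in range(config.n_replicates)],
        names=["condition", "replicate"],
    )
    base = np.repeat(true_means.to_numpy(), config.n_replicates, axis=1)
    noise = rng.normal(0.0, config.noise_sd, size=(len(index), len(cols)))
    values = pd.DataFrame(base + noise, index=index, columns=cols)

    annotations = pd.DataFrame(
        {"family": families, "is_regulator": regulator, "is_NCR": ncr}, index=index
    )
    dataset = ExpressionDataset(values=values, panel="nodule", annotations=annotations)
    truth = PlantedTruth(labels=pd.Series(labels, index=index), true_means=true_means)
    return dataset, truth


#: Concrete linear fold profiles realising each root pattern's symbol row
#: under the default thresholds (ratio 1.5, high_factor 2.0, weak_vs_wt 0.5).
#: Composite template slots are planted at one representative symbol.
ROOT_FOLD_PROFILES: dict[str, dict[str, float]] = {
    "A1": {"NF": 3, "WT1": 3, "WT3": 3, "nfp": 1, "hcl1": 3, "lin": 3, "exoA": 3, "efd1": 3},
    "A2": {"NF": 3, "WT1": 3, "WT3": 8, "nfp": 1, "hcl1": 1, "lin": 3, "exoA": 1, "efd1": 3},
    "A3": {"NF": 1, "WT1": 4, "WT3": 10, "nfp": 1, "hcl1": 1, "lin": 1.7, "exoA": 1.7, "efd1": 4},
    "A4": {"NF": 1, "WT1": 4, "WT3": 10, "nfp": 1, "hcl1": 1, "lin": 1, "exoA": 1, "efd1": 4},
    "R1": {"NF": 1 / 3, "WT1": 1 / 3, "WT3": 1 / 3, "nfp": 1, "hcl1": 1 / 3,
           "lin": 1 / 3, "exoA": 1 / 3, "efd1": 1 / 3},
    "R2": {"NF": 1, "WT1": 1 / 3, "WT3": 1 / 3, "nfp": 1, "hcl1": 1, "lin": 1,
           "exoA": 1, "efd1": 1 / 3},
    "R3": {"NF": 1 / 3, "WT1": 1 / 3, "WT3": 1 / 3, "nfp": 1 / 3, "hcl1": 1 / 3,
           "lin": 1, "exoA": 1, "efd1": 1 / 3},
    "R4": {c: 1 / 3 for c in ROOT_CONDITIONS},
    "none": {c: 1.0 for c in ROOT_CONDITIONS},
}

_QPCR_REPLICATES = 3  # three biological repetitions per sample
_REF_CT = 20.0        # reference (ubiquitin) gene baseline Ct
_TARGET_CT = 25.0     # target-gene Ct in control roots

REFERENCE_GENE = "MtUBI"


def generate_root_qpcr(
    config: SimConfig, pattern_counts: dict[str, int]
) -> tuple[CtTable, PlantedTruth]:
    """Simulate a qRT-PCR Ct table with planted root patterns.

    Target-gene Ct values are ``control Ct - log2(planted fold)`` plus
    Gaussian(0, noise_sd) noise per replicate; the reference gene is
    constant across conditions up to the same noise.  Three replicates per
    condition, control roots included.
    """
    unknown = set(pattern_counts) - set(ROOT_PATTERNS) - {"none"}
    if unknown:
        raise SimConfigError(f"unknown root patterns: {sorted(unknown)}")
    bad = {k: v for k, v in pattern_counts.items() if v < 0}
    if bad:
        raise SimConfigError(f"negative gene counts: {bad}")

    rng = np.random.default_rng(config.seed)
    conds = list(ROOT_CONDITIONS) + [CONTROL]
    cols = pd.MultiIndex.from_tuples(
        [(c, r + 1) for c in conds for r in range(_QPCR_REPLICATES)],
        names=["condition", "replicate"],
    )

    gene_ids: list[str] = [REFERENCE_GENE]
    labels: list[str] = []
    rows: list[np.ndarray] = [np.full(len(cols), _REF_CT)]
    means_rows: list[list[float]] = []

    order = [p for p in list(ROOT_PATTERNS) + ["none"] if p in pattern_counts]
    for pattern in order:
        profile = ROOT_FOLD_PROFILES[pattern]
        true_ct = np.array(
            [
                _TARGET_CT - (np.log2(profile[c]) if c != CONTROL else 0.0)
                for c, _ in cols
            ]
        )
        for _ in range(pattern_counts[pattern]):
            gene_ids.append(f"MTG{len(gene_ids):04d}")
            labels.append(pattern)
            rows.append(true_ct)
            means_rows.append([np.log2(profile[c]) for c in ROOT_CONDITIONS])

    base = np.vstack(rows)
    noise = rng.normal(0.0, config.noise_sd, size=base.shape)
    values = pd.DataFrame(base + noise, index=pd.Index(gene_ids, name="gene"), columns=cols)
    table = CtTable(values=values, reference=REFERENCE_GENE)

    target_index = pd.Index(gene_ids[1:], name="gene")
    truth = PlantedTruth(
        labels=pd.Series(labels, index=target_index),
        true_means=pd.DataFrame(
            means_rows, index=target_index, columns=list(ROOT_CONDITIONS)
        ),
    )
    return table, truth


def default_nodule_config(
    n_per_class: int = 50, noise_sd: float = 0.15, seed: int = 0
) -> SimConfig:
    """Study-condition simulation: n probes in each of the 16 classes plus
    an equal block of non-differential probes, four replicates."""
    counts = {label: n_per_class for label in CLASS_TEMPLATES}
    counts[NOT_DE] = n_per_class
    return SimConfig(n_probes_per_class=counts, noise_sd=noise_sd, seed=seed)


def default_root_config(
    n_per_pattern: int = 5, noise_sd: float = 0.0, seed: int = 0
) -> tuple[SimConfig, dict[str, int]]:
    """qRT-PCR panel: n genes per pattern plus n unregulated genes."""
    counts = {p: n_per_pattern for p in ROOT_PATTERNS}
    counts["none"] = n_per_pattern
    return SimConfig(n_probes_per_class={}, noise_sd=noise_sd, seed=seed), counts
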