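"""Summary tables: DE counts, unique-up fractions, class census, overlaps.

Percentages are rounded to the nearest integer with halves away from zero,
the only convention consistent with every cell of the published class table
(e.g. 2.60% prints as 3%, 16.29% as 16%).  The up-gene percentage column is
taken over all up-regulated DE probes (every class except the repressed
one); the regulator percentage over all up-regulated regulator probes.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .data_model_io import RegulationCallTable
from .nodule_class_assignment import CLASS_LABELS, NOT_DE

#: Classes of up-regulated genes (all classes except the repressed one).
UP_CLASSES = tuple(c for c in CLASS_LABELS if c != "repressed")


def percent(numerator: float, denominator: float) -> int:
    """100*n/d rounded to the nearest integer, halves away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class CensusReport:
    """All census tables; percentages recompute from the stored counts."""

    class_counts: pd.Series
    regulator_counts: pd.Series
    pct_up_genes: pd.Series
    pct_regulators: pd.Series
    family_table: pd.DataFrame
    ncr_counts: pd.Series
    total_de: int
    total_up: int
    total_up_regulators: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "class_counts": self.class_counts.to_dict(),
            "regulator_counts": self.regulator_counts.to_dict(),
            "pct_up_genes": self.pct_up_genes.to_dict(),
            "pct_regulators": self.pct_regulators.to_dict(),
            "ncr_counts": self.ncr_counts.to_dict(),
            "family_table": self.family_table.to_dict(orient="index"),
            "total_de": self.total_de,
            "total_up": self.total_up,
            "total_up_regulators": self.total_up_regulators,
            "metadata": self.metadata,
        }


def per_condition_counts(calls: RegulationCallTable) -> pd.DataFrame:
    """Number of up and down calls per condition."""
    return pd.DataFrame(
        {
            "n_up": (calls.call == "up").sum(axis=0),
            "n_down": (calls.call == "down").sum(axis=0),
        }
    )


def unique_up_fraction(calls: RegulationCallTable) -> pd.Series:
    """Per condition: fraction of its up genes that are up nowhere else.

    Conditions with zero up genes report NA.
    """
    up = calls.call == "up"
    n_up_total = up.sum(axis=1)
    out = {}
    for cond in calls.conditions:
        denom = int(up[cond].sum())
        if denom == 0:
            out[cond] = float("nan")
        else:
            out[cond] = float((up[cond] & (n_up_total == 1)).sum() / denom)
    return pd.Series(out)


def class_census(
    assignment: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
) -> CensusReport:
    """Build the full class census from an assignment plus annotations.

    ``assignment`` must carry a ``label`` column; ``annotations`` may carry
    ``family``, ``is_regulator`` and ``is_NCR`` columns.  Probes missing
    from the annotation table are excluded from the family and NCR tallies
    only (with a note in the metadata).
    """
    labels = assignment["label"]
    de_labels = labels[labels != NOT_DE]
    class_counts = de_labels.value_counts().reindex(CLASS_LABELS, fill_value=0)
    total_de = int(class_counts.sum())
    total_up = int(class_counts[list(UP_CLASSES)].sum())

    metadata = {
        "pct_up_denominator": "total up-regulated DE probes",
        "pct_regulator_denominator": "total up-regulated regulator probes",
        "rounding": "nearest integer, half away from zero",
    }

    if annotations is not None:
        known = de_labels.index.intersection(annotations.index)
        missing = de_labels.index.difference(annotations.index)
        if len(missing):
            metadata["unannotated_probes"] = sorted(map(str, missing))
        ann = annotations.loc[known]
        lab = de_labels.loc[known]
        is_reg = ann.get("is_regulator", pd.Series(False, index=known)).astype(bool)
        is_ncr = ann.get("is_NCR", pd.Series(False, index=known)).astype(bool)
        regulator_counts = (
            lab[is_reg].value_counts().reindex(CLASS_LABELS, fill_value=0)
        )
        ncr_counts = lab[is_ncr].value_counts().reindex(CLASS_LABELS, fill_value=0)

        up_reg_mask = is_reg & lab.isin(UP_CLASSES)
        total_up_regulators = int(up_reg_mask.sum())
        fam = ann.loc[up_reg_mask, "family"] if "family" in ann else pd.Series(dtype=object)
        fam_lab = lab[up_reg_mask]
        family_table = pd.DataFrame(
            {
                "induced_genes": fam.groupby(fam).size(),
                "regulation_classes": fam_lab.groupby(fam).nunique(),
            }
        ).fillna(0).astype(int)
    else:
        regulator_counts = pd.Series(0, index=list(CLASS_LABELS))
        ncr_counts = pd.Series(0, index=list(CLASS_LABELS))
        total_up_regulators = 0
        family_table = pd.DataFrame(columns=["induced_genes", "regulation_classes"])

    pct_up = pd.Series(
        {
            c: percent(class_counts[c], total_up) if total_up else 0
            for c in UP_CLASSES
        }
    )
    pct_reg = pd.Series(
        {
            c: percent(regulator_counts[c], total_up_regulators)
            if total_up_regulators
            else 0
            for c in UP_CLASSES
        }
    )

    return CensusReport(
        class_counts=class_counts,
        regulator_counts=regulator_counts,
        pct_up_genes=pct_up,
        pct_regulators=pct_reg,
        family_table=family_table,
        ncr_counts=ncr_counts,
        total_de=total_de,
        total_up=total_up,
        total_up_regulators=total_up_regulators,
        metadata=metadata,
    )


def _read_data_tsv(name: str) -> pd.DataFrame:
    text = resources.files("nodclass.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", na_values=["NA"])


def load_published_census() -> pd.DataFrame:
    """Published class-census figures (counts and printed percentage cells)."""
    return _read_data_tsv("published_class_census.tsv").set_index("label")


def load_published_families() -> pd.DataFrame:
    """Published regulator-family table (induced-gene counts per family)."""
    return _read_data_tsv("published_regulator_families.tsv").set_index("family")


def pairwise_overlap(calls: RegulationCallTable) -> dict[str, pd.DataFrame]:
    """Condition x condition counts of shared DE genes, up and down apart.

    Symmetric matrices; each diagonal cell equals that condition's own
    up (resp. down) count.
    """
    out = {}
    for direction in ("up", "down"):
        mask = (calls.call == direction).to_numpy(dtype=int)
        overlap = mask.T @ mask
        out[direction] = pd.DataFrame(
            overlap, index=calls.conditions, columns=calls.conditions
        )
    return out


def opposite_regulation_families(
    calls: RegulationCallTable, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Families containing both up- and down-called members (paralog report)."""
    any_up = (calls.call == "up").any(axis=1)
    any_down = (calls.call == "down").any(axis=1)
    known = calls.call.index.intersection(annotations.index)
    fam = annotations.loc[known, "family"]
    rows = []
    for family, probes in fam.groupby(fam).groups.items():
        up_members = sorted(p for p in probes if any_up.get(p, False))
        down_members = sorted(p for p in probes if any_down.get(p, False))
        if up_members and down_members:
            rows.append(
                {
                    "family": family,
                    "n_up": len(up_members),
                    "n_down": len(down_members),
                }
            )
    return pd.DataFrame(rows, columns=["family", "n_up", "n_down"])
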